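{
 "description": "Recalibrated parameters for the Wang reduction sequence: each reduced model fitted to the noiseless full-model reference trace (default 5000 ms protocol, 1 ms sampling) produced by the packaged default parameter fixture.",
 "seed": 7,
 "restarts": 4,
 "thetas": {
  "wang-r0": {
   "p1": 0.013733,
   "p2": 0.038198,
   "p3": 6.89e-05,
   "p4": 0.04178,
   "p5": 0.023761,
   "p6": 0.036778,
   "p7": 0.090821,
   "p8": 0.023391,
   "p9": 0.006497,
   "p10": 0.03268,
   "p11": 0.022348,
   "p12": 0.01176,
   "p13": 0.047002,
   "p14": 0.0631,
   "g": 0.1524
  },
  "wang-r1": {
   "p1": 0.025267142496711123,
   "p2": 0.02833415929084907,
   "p3": 6.491467100414015e-05,
   "p4": 0.04223681936317931,
   "p7": 0.09045046897239406,
   "p8": 0.02340811935126007,
   "p9": 0.0064767068819481825,
   "p10": 0.032742985022942345,
   "p11": 0.010710447854082497,
   "p12": 0.01969187112123105,
   "p13": 0.017056395278665034,
   "p14": 0.06438582916838038,
   "phi1": 0.22527399463487127,
   "g": 0.15216576758882464
  },
  "wang-r2": {
   "p1": 0.007413744566212288,
   "p2": 0.028332744040619383,
   "p3": 6.501105706732617e-05,
   "p4": 0.04222401377822107,
   "p7": 0.09046821159056302,
   "p8": 0.023403206266952886,
   "p9": 0.0064780273391935,
   "p10": 0.03274072172906063,
   "p11": 0.006713775013051878,
   "p12": 0.019677071364933803,
   "p14": 0.06242640344191001,
   "phi2": 0.015158838186594026,
   "g": 0.1521574736475952
  },
  "wang-r3": {
   "p1": 0.004540457585594692,
   "p2": 0.01638898525297082,
   "p3": 7.742448408542461e-05,
   "p4": 0.04116754082596335,
   "p7": 0.0952987960595376,
   "p8": 0.023602435429102543,
   "p9": 0.0067195793264574625,
   "p10": 0.031877099140072404,
   "p11": 0.013120111234592436,
   "p12": 0.08871030716458181,
   "phi2": 0.018444702968433913,
   "g": 0.15559417807527495
  },
  "wang-r4": {
   "p1": 0.008847926882425423,
   "p3": 8.438720281327051e-05,
   "p4": 0.04179898820121438,
   "p7": 0.09658667822771652,
   "p8": 0.023477065936343813,
   "p9": 0.006721117561995358,
   "p10": 0.031635470976938335,
   "p11": 0.011738377483262894,
   "p12": 0.09910813911147537,
   "phi2": 0.04441855683329747,
   "g": 0.15799610562232794
  },
  "wang-r5": {
   "p4": 0.04247636354829476,
   "p7": 0.10115952836837537,
   "p8": 0.024435228255855666,
   "p9": 0.007231565808729134,
   "p10": 0.030834909170427006,
   "p11": 0.0010824222044158996,
   "p12": 0.058430345686206545,
   "phi2": 650.2280808738664,
   "phi3": 1.0000000516850071e-07,
   "g": 0.15470275340791212
  },
  "wang-r6": {
   "p4": 0.0424764854699919,
   "p7": 0.10115830168232226,
   "p8": 0.02443544272615887,
   "p9": 0.007231563864552832,
   "p10": 0.03083495348433941,
   "p11": 0.0010824255621253297,
   "p12": 0.05843043320076004,
   "phi6": 6.502108456016991e-05,
   "g": 0.15470090487177932
  },
  "wang-r7": {
   "p4": 0.037328323598733594,
   "p7": 1.9189596640331257,
   "p8": 0.03970904190242417,
   "p9": 0.011683005520654863,
   "p11": 0.00238551438290134,
   "p12": 0.11739859521479626,
   "phi6": 0.0014088347439482525,
   "g": 1.8052705047381141
  },
  "wang-r8": {
   "p4": 0.0466595660993108,
   "p8": 0.05236354453635993,
   "p11": 0.0029535880477469675,
   "p12": 0.1847875729194301,
   "phi6": 3.534647049818592e-05,
   "phi7": 12.429883055666338,
   "g": 0.144093290443704
  }
 },
 "ledger": [
  {
   "model": "wang-r1",
   "limit": "r0->r1: p5,p6 -> inf, phi1 = p5/p6 (lump C2,C3)",
   "n_parameters": 14,
   "n_states": 4,
   "emrms": 0.0024832643244130335,
   "cost": 0.059266226225371955
  },
  {
   "model": "wang-r2",
   "limit": "r1->r2: p13,phi1 -> inf, phi2 = p13/phi1",
   "n_parameters": 13,
   "n_states": 4,
   "emrms": 0.0024831132895896287,
   "cost": 0.059229299198392885
  },
  {
   "model": "wang-r3",
   "limit": "r2->r3: p14 -> 0",
   "n_parameters": 12,
   "n_states": 4,
   "emrms": 0.013198958813438905,
   "cost": 1.7313863949866393
  },
  {
   "model": "wang-r4",
   "limit": "r3->r4: p2 -> 0",
   "n_parameters": 11,
   "n_states": 4,
   "emrms": 0.013875980936766617,
   "cost": 1.9068529013247102
  },
  {
   "model": "wang-r5",
   "limit": "r4->r5: p1,p3 -> inf, phi3 = p3/p1 (lump C23,O)",
   "n_parameters": 10,
   "n_states": 3,
   "emrms": 0.030713713176816457,
   "cost": 7.749842263776217
  },
  {
   "model": "wang-r6",
   "limit": "r5->r6: phi2 -> inf, phi3 -> 0, phi6 = phi2*phi3",
   "n_parameters": 9,
   "n_states": 3,
   "emrms": 0.030713629254613063,
   "cost": 7.7498044027039645
  },
  {
   "model": "wang-r7",
   "limit": "r6->r7: p10 -> 0",
   "n_parameters": 8,
   "n_states": 3,
   "emrms": 0.07550637797724513,
   "cost": 106.71986435963333
  },
  {
   "model": "wang-r8",
   "limit": "r7->r8: p7,p9 -> inf, phi7 = p7/p9 (lump O,I)",
   "n_parameters": 7,
   "n_states": 2,
   "emrms": 0.0931883824106125,
   "cost": 235.4514436530077
  }
 ]
}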