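{
 "schema": "mbamkit-model/1",
 "name": "wang-r8",
 "states": [
  "C1",
  "Opp"
 ],
 "open_state": "Opp",
 "observable": "Opp/(phi7*exp(V*p8) + 1)",
 "conductance": "g",
 "reversal_potential_mV": -93.04191715807177,
 "parameters": [
  {
   "name": "p4",
   "kind": "slope"
  },
  {
   "name": "p8",
   "kind": "slope"
  },
  {
   "name": "p11",
   "kind": "prefactor"
  },
  {
   "name": "p12",
   "kind": "slope"
  },
  {
   "name": "phi6",
   "kind": "combined"
  },
  {
   "name": "phi7",
   "kind": "combined"
  },
  {
   "name": "g",
   "kind": "conductance"
  }
 ],
 "transitions": [
  {
   "from": "C1",
   "to": "Opp",
   "rate": "p11*exp(V*p12)"
  },
  {
   "from": "Opp",
   "to": "C1",
   "rate": "phi6*exp(-V*p4)/(phi7*exp(V*p8) + 1)"
  }
 ],
 "units": {
  "time": "ms",
  "voltage": "mV",
  "conductance": "uS",
  "current": "nA"
 },
 "meta": {
  "reduced_from": "wang-r7",
  "limit": "r7->r8: p7,p9 -> inf, phi7 = p7/p9 (lump O,I)"
 }
}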