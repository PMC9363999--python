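{
 "schema": "mbamkit-model/1",
 "name": "wang-r5",
 "states": [
  "C1",
  "Op",
  "I"
 ],
 "open_state": "Op",
 "observable": "Op*exp(V*p4)/(phi3 + exp(V*p4))",
 "conductance": "g",
 "reversal_potential_mV": -93.04191715807177,
 "parameters": [
  {
   "name": "p4",
   "kind": "slope"
  },
  {
   "name": "p7",
   "kind": "prefactor"
  },
  {
   "name": "p8",
   "kind": "slope"
  },
  {
   "name": "p9",
   "kind": "prefactor"
  },
  {
   "name": "p10",
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
   "name": "phi2",
   "kind": "combined"
  },
  {
   "name": "phi3",
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
   "to": "Op",
   "rate": "p11*exp(V*p12)"
  },
  {
   "from": "Op",
   "to": "C1",
   "rate": "phi2*phi3/(phi3 + exp(V*p4))"
  },
  {
   "from": "Op",
   "to": "I",
   "rate": "p7*exp(V*(p4 + p8))/(phi3 + exp(V*p4))"
  },
  {
   "from": "I",
   "to": "Op",
   "rate": "p9*exp(-V*p10)"
  }
 ],
 "units": {
  "time": "ms",
  "voltage": "mV",
  "conductance": "uS",
  "current": "nA"
 },
 "meta": {
  "reduced_from": "wang-r4",
  "limit": "r4->r5: p1,p3 -> inf, phi3 = p3/p1 (lump C23,O)"
 }
}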