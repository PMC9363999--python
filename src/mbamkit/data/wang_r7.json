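{
 "schema": "mbamkit-model/1",
 "name": "wang-r7",
 "states": [
  "C1",
  "Op",
  "I"
 ],
 "open_state": "Op",
 "observable": "Op",
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
   "rate": "phi6*exp(-V*p4)"
  },
  {
   "from": "Op",
   "to": "I",
   "rate": "p7*exp(V*p8)"
  },
  {
   "from": "I",
   "to": "Op",
   "rate": "p9"
  }
 ],
 "units": {
  "time": "ms",
  "voltage": "mV",
  "conductance": "uS",
  "current": "nA"
 },
 "meta": {
  "reduced_from": "wang-r6",
  "limit": "r6->r7: p10 -> 0"
 }
}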