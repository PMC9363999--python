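{
 "schema": "mbamkit-model/1",
 "name": "wang-r4",
 "states": [
  "C1",
  "C23",
  "O",
  "I"
 ],
 "open_state": "O",
 "observable": "O",
 "conductance": "g",
 "reversal_potential_mV": -93.04191715807177,
 "parameters": [
  {
   "name": "p1",
   "kind": "prefactor"
  },
  {
   "name": "p3",
   "kind": "prefactor"
  },
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
   "name": "g",
   "kind": "conductance"
  }
 ],
 "transitions": [
  {
   "from": "C1",
   "to": "C23",
   "rate": "p11*exp(V*p12)"
  },
  {
   "from": "C23",
   "to": "C1",
   "rate": "phi2"
  },
  {
   "from": "C23",
   "to": "O",
   "rate": "p1"
  },
  {
   "from": "O",
   "to": "C23",
   "rate": "p3*exp(-V*p4)"
  },
  {
   "from": "O",
   "to": "I",
   "rate": "p7*exp(V*p8)"
  },
  {
   "from": "I",
   "to": "O",
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
  "reduced_from": "wang-r3",
  "limit": "r3->r4: p2 -> 0"
 }
}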