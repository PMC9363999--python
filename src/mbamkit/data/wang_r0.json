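{
 "schema": "mbamkit-model/1",
 "name": "wang-r0",
 "states": [
  "C1",
  "C2",
  "C3",
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
   "name": "p2",
   "kind": "slope"
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
   "name": "p5",
   "kind": "prefactor"
  },
  {
   "name": "p6",
   "kind": "prefactor"
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
   "name": "p13",
   "kind": "prefactor"
  },
  {
   "name": "p14",
   "kind": "slope"
  },
  {
   "name": "g",
   "kind": "conductance"
  }
 ],
 "transitions": [
  {
   "from": "C1",
   "to": "C2",
   "rate": "p11*exp(p12*V)"
  },
  {
   "from": "C2",
   "to": "C1",
   "rate": "p13*exp(-p14*V)"
  },
  {
   "from": "C2",
   "to": "C3",
   "rate": "p5"
  },
  {
   "from": "C3",
   "to": "C2",
   "rate": "p6"
  },
  {
   "from": "C3",
   "to": "O",
   "rate": "p1*exp(p2*V)"
  },
  {
   "from": "O",
   "to": "C3",
   "rate": "p3*exp(-p4*V)"
  },
  {
   "from": "O",
   "to": "I",
   "rate": "p7*exp(p8*V)"
  },
  {
   "from": "I",
   "to": "O",
   "rate": "p9*exp(-p10*V)"
  }
 ],
 "units": {
  "time": "ms",
  "voltage": "mV",
  "conductance": "uS",
  "current": "nA"
 },
 "meta": {}
}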