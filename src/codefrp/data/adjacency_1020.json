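{
 "nodes": [
  "A2",
  "C3",
  "C4",
  "CP3",
  "CP4",
  "CPz",
  "Cz",
  "F3",
  "F4",
  "F7",
  "F8",
  "FC3",
  "FC4",
  "FC5",
  "FC6",
  "FCz",
  "Fp1",
  "Fp2",
  "Fz",
  "O1",
  "O2",
  "P3",
  "P4",
  "P7",
  "P8",
  "Pz",
  "T7",
  "T8"
 ],
 "edges": [
  [
   "A2",
   "T8"
  ],
  [
   "C3",
   "CP3"
  ],
  [
   "C3",
   "Cz"
  ],
  [
   "C3",
   "FC3"
  ],
  [
   "C3",
   "FC5"
  ],
  [
   "C3",
   "T7"
  ],
  [
   "C4",
   "CP4"
  ],
  [
   "C4",
   "Cz"
  ],
  [
   "C4",
   "FC4"
  ],
  [
   "C4",
   "FC6"
  ],
  [
   "C4",
   "T8"
  ],
  [
   "CP3",
   "CPz"
  ],
  [
   "CP3",
   "Cz"
  ],
  [
   "CP3",
   "P3"
  ],
  [
   "CP3",
   "P7"
  ],
  [
   "CP3",
   "T7"
  ],
  [
   "CP4",
   "CPz"
  ],
  [
   "CP4",
   "Cz"
  ],
  [
   "CP4",
   "P4"
  ],
  [
   "CP4",
   "P8"
  ],
  [
   "CP4",
   "T8"
  ],
  [
   "CPz",
   "Cz"
  ],
  [
   "CPz",
   "P3"
  ],
  [
   "CPz",
   "P4"
  ],
  [
   "CPz",
   "Pz"
  ],
  [
   "Cz",
   "FC3"
  ],
  [
   "Cz",
   "FC4"
  ],
  [
   "Cz",
   "FCz"
  ],
  [
   "F3",
   "F7"
  ],
  [
   "F3",
   "FC3"
  ],
  [
   "F3",
   "FC5"
  ],
  [
   "F3",
   "FCz"
  ],
  [
   "F3",
   "Fp1"
  ],
  [
   "F3",
   "Fz"
  ],
  [
   "F4",
   "F8"
  ],
  [
   "F4",
   "FC4"
  ],
  [
   "F4",
   "FC6"
  ],
  [
   "F4",
   "FCz"
  ],
  [
   "F4",
   "Fp2"
  ],
  [
   "F4",
   "Fz"
  ],
  [
   "F7",
   "FC5"
  ],
  [
   "F8",
   "FC6"
  ],
  [
   "FC3",
   "FC5"
  ],
  [
   "FC3",
   "FCz"
  ],
  [
   "FC4",
   "FC6"
  ],
  [
   "FC4",
   "FCz"
  ],
  [
   "FC5",
   "T7"
  ],
  [
   "FC6",
   "T8"
  ],
  [
   "FCz",
   "Fz"
  ],
  [
   "Fp1",
   "Fp2"
  ],
  [
   "Fp1",
   "Fz"
  ],
  [
   "Fp2",
   "Fz"
  ],
  [
   "O1",
   "O2"
  ],
  [
   "O1",
   "P3"
  ],
  [
   "O1",
   "P7"
  ],
  [
   "O1",
   "Pz"
  ],
  [
   "O2",
   "P4"
  ],
  [
   "O2",
   "P8"
  ],
  [
   "O2",
   "Pz"
  ],
  [
   "P3",
   "P7"
  ],
  [
   "P3",
   "Pz"
  ],
  [
   "P4",
   "P8"
  ],
  [
   "P4",
   "Pz"
  ],
  [
   "P7",
   "T7"
  ],
  [
   "P8",
   "T8"
  ]
 ]
}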