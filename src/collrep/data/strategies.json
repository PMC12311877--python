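{
 "format_version": 1,
 "strategies": [
  {
   "id": "L1",
   "assessment": {
    "raG|rpG|bC": "G",
    "raG|rpG|bD": "B",
    "raG|rpB|bC": "G",
    "raG|rpB|bD": "G",
    "raB|rpG|bC": "G",
    "raB|rpG|bD": "B",
    "raB|rpB|bC": "G",
    "raB|rpB|bD": "B"
   },
   "action": {
    "raG|rpG": "C",
    "raG|rpB": "D",
    "raB|rpG": "C",
    "raB|rpB": "C"
   }
  },
  {
   "id": "L2",
   "assessment": {
    "raG|rpG|bC": "G",
    "raG|rpG|bD": "B",
    "raG|rpB|bC": "B",
    "raG|rpB|bD": "G",
    "raB|rpG|bC": "G",
    "raB|rpG|bD": "B",
    "raB|rpB|bC": "G",
    "raB|rpB|bD": "B"
   },
   "action": {
    "raG|rpG": "C",
    "raG|rpB": "D",
    "raB|rpG": "C",
    "raB|rpB": "C"
   }
  },
  {
   "id": "L3",
   "assessment": {
    "raG|rpG|bC": "G",
    "raG|rpG|bD": "B",
    "raG|rpB|bC": "G",
    "raG|rpB|bD": "G",
    "raB|rpG|bC": "G",
    "raB|rpG|bD": "B",
    "raB|rpB|bC": "G",
    "raB|rpB|bD": "G"
   },
   "action": {
    "raG|rpG": "C",
    "raG|rpB": "D",
    "raB|rpG": "C",
    "raB|rpB": "D"
   }
  },
  {
   "id": "L4",
   "assessment": {
    "raG|rpG|bC": "G",
    "raG|rpG|bD": "B",
    "raG|rpB|bC": "G",
    "raG|rpB|bD": "G",
    "raB|rpG|bC": "G",
    "raB|rpG|bD": "B",
    "raB|rpB|bC": "B",
    "raB|rpB|bD": "G"
   },
   "action": {
    "raG|rpG": "C",
    "raG|rpB": "D",
    "raB|rpG": "C",
    "raB|rpB": "D"
   }
  },
  {
   "id": "L5",
   "assessment": {
    "raG|rpG|bC": "G",
    "raG|rpG|bD": "B",
    "raG|rpB|bC": "B",
    "raG|rpB|bD": "G",
    "raB|rpG|bC": "G",
    "raB|rpG|bD": "B",
    "raB|rpB|bC": "G",
    "raB|rpB|bD": "G"
   },
   "action": {
    "raG|rpG": "C",
    "raG|rpB": "D",
    "raB|rpG": "C",
    "raB|rpB": "D"
   }
  },
  {
   "id": "L6",
   "assessment": {
    "raG|rpG|bC": "G",
    "raG|rpG|bD": "B",
    "raG|rpB|bC": "B",
    "raG|rpB|bD": "G",
    "raB|rpG|bC": "G",
    "raB|rpG|bD": "B",
    "raB|rpB|bC": "B",
    "raB|rpB|bD": "G"
   },
   "action": {
    "raG|rpG": "C",
    "raG|rpB": "D",
    "raB|rpG": "C",
    "raB|rpB": "D"
   }
  },
  {
   "id": "L7",
   "assessment": {
    "raG|rpG|bC": "G",
    "raG|rpG|bD": "B",
    "raG|rpB|bC": "G",
    "raG|rpB|bD": "G",
    "raB|rpG|bC": "G",
    "raB|rpG|bD": "B",
    "raB|rpB|bC": "B",
    "raB|rpB|bD": "B"
   },
   "action": {
    "raG|rpG": "C",
    "raG|rpB": "D",
    "raB|rpG": "C",
    "raB|rpB": "D"
   }
  },
  {
   "id": "L8",
   "assessment": {
    "raG|rpG|bC": "G",
    "raG|rpG|bD": "B",
    "raG|rpB|bC": "B",
    "raG|rpB|bD": "G",
    "raB|rpG|bC": "G",
    "raB|rpG|bD": "B",
    "raB|rpB|bC": "B",
    "raB|rpB|bD": "B"
   },
   "action": {
    "raG|rpG": "C",
    "raG|rpB": "D",
    "raB|rpG": "C",
    "raB|rpB": "D"
   }
  },
  {
   "id": "ALLC",
   "assessment": {
    "raG|rpG|bC": "G",
    "raG|rpG|bD": "G",
    "raG|rpB|bC": "G",
    "raG|rpB|bD": "G",
    "raB|rpG|bC": "G",
    "raB|rpG|bD": "G",
    "raB|rpB|bC": "G",
    "raB|rpB|bD": "G"
   },
   "action": {
    "raG|rpG": "C",
    "raG|rpB": "C",
    "raB|rpG": "C",
    "raB|rpB": "C"
   }
  },
  {
   "id": "ALLD",
   "assessment": {
    "raG|rpG|bC": "B",
    "raG|rpG|bD": "B",
    "raG|rpB|bC": "B",
    "raG|rpB|bD": "B",
    "raB|rpG|bC": "B",
    "raB|rpG|bD": "B",
    "raB|rpB|bC": "B",
    "raB|rpB|bD": "B"
   },
   "action": {
    "raG|rpG": "D",
    "raG|rpB": "D",
    "raB|rpG": "D",
    "raB|rpB": "D"
   }
  }
 ]
}
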