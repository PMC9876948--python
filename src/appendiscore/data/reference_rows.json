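{
  "comment": "Published operating characteristics of the Alvarado, AIR and RIPASA scores in a 132-patient appendectomy cohort (histopathology gold standard: 121 positive, 11 negative appendectomies). Values are kept as printed strings so each cell's display precision is preserved.",
  "n_pos": 121,
  "n_neg": 11,
  "rows": [
    {
      "system": "alvarado",
      "cutoff": ">7",
      "sensitivity": "88.4",
      "specificity": "63.6",
      "ppv": "96.4",
      "npv": "33.3",
      "plr": "2.43",
      "nlr": "0.18",
      "accuracy": "86.3"
    },
    {
      "system": "air",
      "cutoff": ">5",
      "sensitivity": "77.7",
      "specificity": "81.8",
      "ppv": "97.9",
      "npv": "25",
      "plr": "4.27",
      "nlr": "0.27",
      "accuracy": "78.03"
    },
    {
      "system": "ripasa",
      "cutoff": ">=7.5",
      "sensitivity": "96.7",
      "specificity": "72.7",
      "ppv": "97.5",
      "npv": "66.7",
      "plr": "3.54",
      "nlr": "0.05",
      "accuracy": "94.6"
    }
  ]
}
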