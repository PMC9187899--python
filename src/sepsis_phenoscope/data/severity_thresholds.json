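{
  "version": "sofa-1996 / sic-2019",
  "sofa": {
    "respiration": {
      "variable": "pao2_fio2",
      "unit": "mmHg",
      "intervals": [
        [400, null, 0],
        [300, 400, 1],
        [200, 300, 2],
        [100, 200, 3],
        [null, 100, 4]
      ]
    },
    "coagulation": {
      "variable": "platelets",
      "unit": "K/uL",
      "intervals": [
        [150, null, 0],
        [100, 150, 1],
        [50, 100, 2],
        [20, 50, 3],
        [null, 20, 4]
      ]
    },
    "liver": {
      "variable": "bilirubin",
      "unit": "mg/dL",
      "intervals": [
        [null, 1.2, 0],
        [1.2, 2.0, 1],
        [2.0, 6.0, 2],
        [6.0, 12.0, 3],
        [12.0, null, 4]
      ]
    },
    "cardiovascular": {
      "variable": "map_mmHg",
      "unit": "mmHg",
      "intervals": [
        [70, null, 0],
        [null, 70, 1]
      ],
      "vasopressor_tiers": [2, 3, 4]
    },
    "cns": {
      "variable": "gcs",
      "unit": "score",
      "intervals": [
        [15, null, 0],
        [13, 15, 1],
        [10, 13, 2],
        [6, 10, 3],
        [null, 6, 4]
      ]
    },
    "renal": {
      "variable": "creatinine",
      "unit": "mg/dL",
      "intervals": [
        [null, 1.2, 0],
        [1.2, 2.0, 1],
        [2.0, 3.5, 2],
        [3.5, 5.0, 3],
        [5.0, null, 4]
      ]
    }
  },
  "sic": {
    "platelets": {
      "unit": "K/uL",
      "intervals": [
        [150, null, 0],
        [100, 150, 1],
        [null, 100, 2]
      ]
    },
    "inr": {
      "unit": "ratio",
      "intervals": [
        [null, 1.2, 0],
        [1.2, 1.4, 1],
        [1.4, null, 2]
      ]
    },
    "sofa_subtotal": {
      "unit": "points (respiration+cardiovascular+liver+renal)",
      "intervals": [
        [null, 1, 0],
        [1, 2, 1],
        [2, null, 2]
      ]
    }
  }
}
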