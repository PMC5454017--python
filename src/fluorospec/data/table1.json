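{
  "266": {
    "peak_labels": {
      "peak1": {"fluorophore": "tryptophan", "wavelength_nm": 331},
      "peak2": {"fluorophore": "NADH", "wavelength_nm": 435}
    },
    "AD": {
      "replicates": [
        [1.032, 0.266, 3.88],
        [1.016, 0.271, 3.75],
        [1.001, 0.269, 3.73],
        [0.986, 0.268, 3.68],
        [0.965, 0.268, 3.60]
      ],
      "mean": [1.000, 0.268, 3.73]
    },
    "N": {
      "replicates": [
        [0.522, 0.174, 3.01],
        [0.495, 0.170, 2.91],
        [0.495, 0.169, 2.93],
        [0.491, 0.167, 2.93],
        [0.480, 0.167, 2.88]
      ],
      "mean": [0.497, 0.169, 2.93]
    }
  },
  "300": {
    "peak_labels": {
      "peak1": {"fluorophore": "tryptophan", "wavelength_nm": 335},
      "peak2": {"fluorophore": "NADH", "wavelength_nm": 492}
    },
    "AD": {
      "replicates": [
        [1.013, 0.164, 6.19],
        [1.014, 0.161, 6.29],
        [1.005, 0.161, 6.25],
        [0.989, 0.161, 6.15],
        [0.979, 0.158, 6.19]
      ],
      "mean": [1.000, 0.161, 6.21]
    },
    "N": {
      "replicates": [
        [0.536, 0.101, 5.31],
        [0.537, 0.100, 5.36],
        [0.531, 0.099, 5.35],
        [0.530, 0.099, 5.34],
        [0.526, 0.099, 5.31]
      ],
      "mean": [0.532, 0.100, 5.33]
    }
  },
  "340": {
    "peak_labels": {
      "peak1": {"fluorophore": "NADH", "wavelength_nm": 462},
      "peak2": {"fluorophore": "FAD", "wavelength_nm": 557}
    },
    "AD": {
      "replicates": [
        [1.032, 0.358, 2.88],
        [1.010, 0.355, 2.84],
        [0.998, 0.353, 2.83],
        [0.983, 0.348, 2.82],
        [0.978, 0.343, 2.85]
      ],
      "mean": [1.000, 0.352, 2.84]
    },
    "N": {
      "replicates": [
        [0.606, 0.212, 2.86],
        [0.609, 0.206, 2.95],
        [0.609, 0.205, 2.97],
        [0.605, 0.206, 2.93],
        [0.602, 0.207, 2.92]
      ],
      "mean": [0.606, 0.207, 2.928]
    }
  }
}
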