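{
  "comment": "Recurrent-CNV block layouts for the 12 synthetic benchmark cases. Sample and probe ranges are 1-based inclusive; sign +1 = gain (true signal +1), -1 = loss (true signal -1). Cases 7-12 share the layouts of cases 1-6 and differ only in the noise model.",
  "n": 50,
  "p": 300,
  "probe_windows": [[76, 85], [86, 95], [96, 105], [106, 125]],
  "noise": {
    "gaussian": {"kind": "gaussian", "sigma": 0.3},
    "scaled_t": {"kind": "scaled_t", "scale": 0.5, "df": 1}
  },
  "cases": {
    "1": {
      "noise": "gaussian",
      "blocks": [
        {"samples": [1, 50], "probes": [76, 85], "sign": 1},
        {"samples": [1, 50], "probes": [86, 95], "sign": 1}
      ]
    },
    "2": {
      "noise": "gaussian",
      "blocks": [
        {"samples": [1, 20], "probes": [96, 105], "sign": -1},
        {"samples": [1, 20], "probes": [106, 125], "sign": -1},
        {"samples": [21, 50], "probes": [96, 105], "sign": 1},
        {"samples": [21, 50], "probes": [106, 125], "sign": 1}
      ]
    },
    "3": {
      "noise": "gaussian",
      "blocks": [
        {"samples": [1, 20], "probes": [76, 85], "sign": -1},
        {"samples": [1, 20], "probes": [86, 95], "sign": -1},
        {"samples": [21, 50], "probes": [96, 105], "sign": 1},
        {"samples": [21, 50], "probes": [106, 125], "sign": 1}
      ]
    },
    "4": {
      "noise": "gaussian",
      "blocks": [
        {"samples": [1, 20], "probes": [76, 85], "sign": 1},
        {"samples": [1, 20], "probes": [86, 95], "sign": 1},
        {"samples": [1, 20], "probes": [96, 105], "sign": 1},
        {"samples": [21, 30], "probes": [76, 85], "sign": 1},
        {"samples": [21, 30], "probes": [86, 95], "sign": 1},
        {"samples": [31, 50], "probes": [96, 105], "sign": -1},
        {"samples": [31, 50], "probes": [106, 125], "sign": -1}
      ]
    },
    "5": {
      "noise": "gaussian",
      "blocks": [
        {"samples": [1, 10], "probes": [76, 85], "sign": 1},
        {"samples": [1, 10], "probes": [86, 95], "sign": 1},
        {"samples": [1, 10], "probes": [96, 105], "sign": 1},
        {"samples": [11, 30], "probes": [76, 85], "sign": -1},
        {"samples": [11, 30], "probes": [86, 95], "sign": -1},
        {"samples": [11, 30], "probes": [96, 105], "sign": -1},
        {"samples": [31, 50], "probes": [76, 85], "sign": 1},
        {"samples": [31, 50], "probes": [86, 95], "sign": 1},
        {"samples": [31, 50], "probes": [96, 105], "sign": 1}
      ]
    },
    "6": {
      "noise": "gaussian",
      "blocks": [
        {"samples": [1, 10], "probes": [86, 95], "sign": 1},
        {"samples": [1, 10], "probes": [96, 105], "sign": 1},
        {"samples": [1, 10], "probes": [106, 125], "sign": 1},
        {"samples": [31, 40], "probes": [76, 85], "sign": 1},
        {"samples": [31, 40], "probes": [86, 95], "sign": 1},
        {"samples": [41, 50], "probes": [96, 105], "sign": -1},
        {"samples": [41, 50], "probes": [106, 125], "sign": -1}
      ]
    },
    "7": {"noise": "scaled_t", "same_blocks_as": 1},
    "8": {"noise": "scaled_t", "same_blocks_as": 2},
    "9": {"noise": "scaled_t", "same_blocks_as": 3},
    "10": {"noise": "scaled_t", "same_blocks_as": 4},
    "11": {"noise": "scaled_t", "same_blocks_as": 5},
    "12": {"noise": "scaled_t", "same_blocks_as": 6}
  }
}
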