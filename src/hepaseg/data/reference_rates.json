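{
  "HL U-net-1": {
    "rates": {"tp": 9.3, "tn": 83.3, "fp": 3.9, "fn": 3.5},
    "reported_metrics": {"accuracy": 92.6, "specificity": 95.5, "precision": 70.4, "npv": 96.0, "recall": 72.8, "iou": 55.8, "dice": 71.6}
  },
  "HL U-net-2": {
    "rates": {"tp": 11.4, "tn": 77.6, "fp": 9.6, "fn": 1.4},
    "reported_metrics": {"accuracy": 89.0, "specificity": 89.0, "precision": 54.2, "npv": 98.3, "recall": 89.2, "iou": 50.9, "dice": 67.4}
  },
  "HL U-net-3": {
    "rates": {"tp": 11.1, "tn": 79.5, "fp": 7.8, "fn": 1.7},
    "reported_metrics": {"accuracy": 90.5, "specificity": 91.1, "precision": 58.7, "npv": 97.9, "recall": 86.6, "iou": 53.8, "dice": 70.0}
  },
  "MLA U-net-1": {
    "rates": {"tp": 13.5, "tn": 73.1, "fp": 3.6, "fn": 9.8},
    "reported_metrics": {"accuracy": 86.7, "specificity": 95.4, "precision": 79.0, "npv": 88.2, "recall": 58.0, "iou": 50.3, "dice": 66.9}
  },
  "MLA U-net-2": {
    "rates": {"tp": 16.6, "tn": 71.8, "fp": 4.9, "fn": 6.7},
    "reported_metrics": {"accuracy": 88.3, "specificity": 93.6, "precision": 77.2, "npv": 91.4, "recall": 71.1, "iou": 58.8, "dice": 74.0}
  },
  "MLA U-net-3": {
    "rates": {"tp": 16.6, "tn": 71.9, "fp": 4.8, "fn": 6.7},
    "reported_metrics": {"accuracy": 88.6, "specificity": 93.8, "precision": 77.7, "npv": 91.5, "recall": 71.2, "iou": 59.2, "dice": 74.4}
  },
  "LM U-net-1": {
    "rates": {"tp": 2.0, "tn": 79.3, "fp": 10.6, "fn": 8.1},
    "reported_metrics": {"accuracy": 81.3, "specificity": 88.2, "precision": 16.0, "npv": 90.7, "recall": 19.9, "iou": 9.7, "dice": 17.7}
  },
  "LM U-net-2": {
    "rates": {"tp": 3.6, "tn": 79.0, "fp": 10.9, "fn": 6.5},
    "reported_metrics": {"accuracy": 82.6, "specificity": 87.9, "precision": 24.9, "npv": 92.4, "recall": 35.6, "iou": 17.1, "dice": 29.3}
  },
  "LM U-net-3": {
    "rates": {"tp": 2.0, "tn": 88.3, "fp": 1.6, "fn": 8.1},
    "reported_metrics": {"accuracy": 90.3, "specificity": 98.2, "precision": 55.6, "npv": 91.6, "recall": 19.7, "iou": 17.0, "dice": 29.1}
  },
  "Alternative LM U-net-3": {
    "rates": {"tp": 1.8, "tn": 89.8, "fp": 0.1, "fn": 8.3},
    "reported_metrics": {"accuracy": 91.5, "specificity": 99.9, "precision": 94.7, "npv": 91.5, "recall": 17.6, "iou": 17.3, "dice": 29.9}
  }
}
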