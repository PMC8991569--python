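levels: coded
factors:
  - {name: CaCl2, unit: g/L, low: 0.375, high: 1.125, center: 0.75}
  - {name: TraceElement, unit: mL/L, low: 0.25, high: 0.75, center: 0.5}
  - {name: Volume, unit: mL/500mL, low: 75.0, high: 225.0, center: 150.0}
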