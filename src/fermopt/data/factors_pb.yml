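levels: coded
factors:
  - {name: Glucose, unit: g/L, low: 10.0, high: 30.0, center: 20.0}
  - {name: KNO3, unit: g/L, low: 7.5, high: 22.5, center: 15.0}
  - {name: K2HPO4, unit: g/L, low: 1.25, high: 3.75, center: 2.5}
  - {name: CaCl2, unit: g/L, low: 0.25, high: 0.75, center: 0.5}
  - {name: MgSO4, unit: g/L, low: 0.5, high: 1.5, center: 1.0}
  - {name: Tyrosine, unit: g/L, low: 0.5, high: 1.5, center: 1.0}
  - {name: TraceElement, unit: mL/L, low: 0.5, high: 1.5, center: 1.0}
  - {name: pH, unit: pH units, low: 4.5, high: 6.5, center: 5.5}
  - {name: CultureAge, unit: days, low: 4.0, high: 10.0, center: 7.0}
  - {name: InoculumSize, unit: mL/L, low: 0.5, high: 1.5, center: 1.0}
  - {name: Volume, unit: mL/500mL, low: 50.0, high: 150.0, center: 100.0}
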