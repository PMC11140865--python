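# PPLFER system parameters for the nine supported endpoints, at 25 C.
# Partition rows KAW / KOA / KOW_wet and the pure-phase rows VP_liquid /
# SW_liquid were calibrated on experimental data; KOW_dry, KOO,
# SO_dry_liquid and SO_wet_liquid are derived by thermodynamic property
# cycle with standard errors propagated in quadrature, stored here at the
# published 2-decimal precision.
schema_version: 1
endpoints:
  KAW:
    coef: {s: -2.26, a: -3.72, b: -4.78, d: 0.0, v: 2.19, l: -0.38, c: 0.64}
    se: {s: 0.05, a: 0.04, b: 0.04, d: 0.0, v: 0.06, l: 0.02, c: 0.03}
    total_se: 0.17
    units: log10(dimensionless ratio)
  KOA:
    coef: {s: 0.69, a: 3.56, b: 0.73, d: 0.0, v: 0.52, l: 0.79, c: -0.26}
    se: {s: 0.05, a: 0.04, b: 0.04, d: 0.0, v: 0.08, l: 0.02, c: 0.03}
    total_se: 0.16
    units: log10(dimensionless ratio)
  KOW_wet:
    coef: {s: -1.36, a: -0.13, b: -3.49, d: 0.0, v: 2.41, l: 0.41, c: 0.41}
    se: {s: 0.04, a: 0.03, b: 0.03, d: 0.0, v: 0.06, l: 0.01, c: 0.03}
    total_se: 0.15
    units: log10(dimensionless ratio)
  KOW_dry:
    coef: {s: -1.57, a: -0.16, b: -4.05, d: 0.0, v: 2.71, l: 0.41, c: 0.38}
    se: {s: 0.07, a: 0.06, b: 0.06, d: 0.0, v: 0.10, l: 0.02, c: 0.04}
    total_se: 0.23
    units: log10(dimensionless ratio)
  KOO:
    coef: {s: 0.21, a: 0.03, b: 0.56, d: 0.0, v: -0.30, l: 0.00, c: 0.03}
    se: {s: 0.08, a: 0.06, b: 0.06, d: 0.0, v: 0.12, l: 0.03, c: 0.05}
    total_se: 0.28
    units: log10(dimensionless ratio)
  VP_liquid:
    coef: {s: -1.55, a: -0.92, b: -0.63, d: -1.60, v: -1.30, l: -0.51, c: 7.13}
    se: {s: 0.12, a: 0.23, b: 0.13, d: 0.27, v: 0.18, l: 0.05, c: 0.08}
    total_se: 0.59
    units: log10(Pa)
  SW_liquid:
    coef: {s: 0.71, a: 2.80, b: 4.15, d: -1.60, v: -3.49, l: -0.13, c: 0.18}
    se: {s: 0.11, a: 0.23, b: 0.13, d: 0.27, v: 0.17, l: 0.04, c: 0.07}
    total_se: 0.60
    units: log10(mol/L)
  SO_dry_liquid:
    coef: {s: -0.86, a: 2.64, b: 0.10, d: -1.60, v: -0.78, l: 0.28, c: 0.56}
    se: {s: 0.13, a: 0.23, b: 0.14, d: 0.27, v: 0.20, l: 0.05, c: 0.08}
    total_se: 0.64
    units: log10(mol/L)
  SO_wet_liquid:
    coef: {s: -0.65, a: 2.67, b: 0.66, d: -1.60, v: -1.08, l: 0.28, c: 0.59}
    se: {s: 0.12, a: 0.23, b: 0.13, d: 0.27, v: 0.18, l: 0.04, c: 0.08}
    total_se: 0.62
    units: log10(mol/L)
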