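# pplfer

Thermodynamically consistent prediction of physical–chemical properties of
neutral organic chemicals from Abraham solute descriptors, with
applicability-domain uncertainty levels and calibrated 95% prediction
intervals.

Chemical fate, exposure and risk assessment need six interrelated properties
for every chemical: the octanol–water, air–water and octanol–air partition
ratios (log *K*<sub>OW</sub>, log *K*<sub>AW</sub>, log *K*<sub>OA</sub>),
vapor pressure (*VP*, Pa), and solubility in water and octanol
(*S*<sub>W</sub>, *S*<sub>O</sub>, mol/L). This package predicts all of them
from one consistent set of inputs — the Abraham solute descriptors *S*
(dipolarity/polarizability), *A* (H-bond donor), *B* (H-bond acceptor), *V*
(McGowan volume) and *L* (log hexadecane–air partitioning) — and quantifies
how much each prediction should be trusted.

## The model

Partition ratios use a poly-parameter linear free energy relationship
(PPLFER, also known as an Abraham equation):

    log K = s·S + a·A + b·B + v·V + l·L + c

Pure-phase properties (VP and the solubilities) add a term for hydrogen
bonding between molecules of the chemical itself:

    log S = s·S + a·A + b·B + d·(A·B)^0.5 + v·V + l·L + c

The lower-case system parameters are calibrated by multiple linear
regression against experimental data for the directly measurable endpoints
(K<sub>AW</sub>, K<sub>OA</sub>, wet K<sub>OW</sub>, VP, S<sub>W</sub>).
The remaining endpoints are **derived by thermodynamic property cycles**
(the "three-solubility approach": partition ratios are ratios of
solubilities in octanol, water and air), which builds thermodynamic
consistency into every prediction:

    dry log K_OW = log K_OA + log K_AW
    log K_OO     = wet log K_OW − dry log K_OW     (wet/dry octanol ratio)
    log S_O[d]   = log S_W + dry log K_OW
    log S_O[w]   = log S_W + wet log K_OW

Standard errors of derived coefficients propagate in quadrature. On top of
the point predictions the package provides:

* **state classification** (gas / liquid / maybe-solid / solid at system
  temperature) and the **Van't Hoff correction** converting supercooled
  liquid values to solid-phase values using ΔS<sub>M</sub> and T<sub>M</sub>;
* **boundary caps** — solubility at the pure-liquid molarity 1/MV, vapor
  pressure at atmospheric pressure — with capped predictions flagged and
  assigned uncertainty level (UL) 6;
* **applicability-domain diagnostics** (leverage, a nearest-neighbour
  chemical similarity score, and a negative-domain substructure check)
  combined into ULs 0–5;
* **95% prediction intervals** M ± 1.96 × adjusted RMSEP, where the
  adjustment ladder (global ×1.25; ×1.67 for VP of solids; ×1.25 for
  S<sub>W</sub> of solids; a further ×1.25 for VP at UL 2/3/5) was
  calibrated so intervals cover at least 95% of external data.

## Worked example

Predict all nine endpoints for a naphthalene-like aromatic solid
(descriptors S=0.92, A=0, B=0.20, V=1.0854, L=5.16; T<sub>M</sub>=353.4 K,
T<sub>B</sub>=491.1 K, ΔS<sub>M</sub>=53.8 J/(mol·K), MV=0.125 L/mol):

```python
import pandas as pd, pplfer

df = pd.DataFrame([{
    "id": "arene", "S": 0.92, "A": 0.0, "B": 0.20, "V": 1.0854, "L": 5.16,
    "Tm_K": 353.4, "Tb_K": 491.1, "dSm_J_molK": 53.8, "MV_L_mol": 0.125,
}])
print(pplfer.predict_batch(df).round(2).to_string(index=False))
```

```
     endpoint  value  ul  rmsep  pi_low  pi_high state flags
          KAW  -1.98   0   0.21   -2.40    -1.56 solid
          KOA   5.16   0   0.20    4.77     5.55 solid
      KOW_wet   3.19   0   0.19    2.82     3.56 solid
      KOW_dry   3.18   0   0.29    2.62     3.75 solid
          KOO   0.01   0   0.35   -0.68     0.70 solid
    VP_liquid   1.54   0   1.23   -0.88     3.95 solid
    SW_liquid  -2.80   0   0.94   -4.63    -0.96 solid
SO_dry_liquid   0.39   0   0.80   -1.18     1.95 solid
SO_wet_liquid   0.40   0   0.78   -1.12     1.92 solid
```

Each row is one endpoint: the predicted log value, its uncertainty level
(0 = well inside the applicability domain), the adjusted RMSEP and the
symmetric 95% prediction interval, plus the predicted physical state.
Values are supercooled-liquid convention by default (the fate-modelling
standard); passing `PredictionConfig(solid_output="solid")` applies the
Van't Hoff correction to VP and the solubilities of predicted solids. Note
the chemical's hydrophobicity (log K<sub>OW</sub> ≈ 3.2) and low Henry's
law constant (log K<sub>AW</sub> ≈ −2.0) are each within ~0.2 log units of
the well-known experimental values for naphthalene.

The same pipeline is available from the shell:

```sh
pplfer predict solutes.csv predictions.csv
pplfer audit-cycle                 # verify thermodynamic consistency
pplfer calibrate data.csv fit.yaml --form eq1 --endpoint KAW
pplfer evaluate eval.csv stats.csv --group ul
pplfer simulate synth.csv --what dataset --endpoint KAW --n 500 --seed 1
```

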