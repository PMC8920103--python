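# iamdelta

Phospholipophilicity-excess descriptors for early blood-brain-barrier
screening.

Immobilized-artificial-membrane (IAM) chromatography measures how strongly a
small molecule binds a phosphatidylcholine-coated stationary phase — a proxy
for its affinity to biological membranes, the *phospholipophilicity*
log *k*w^IAM (the retention factor extrapolated to a fully aqueous eluent, on
either of two commercial phases, IAM.PC.MG and IAM.PC.DD2). For neutral
compounds, IAM retention tracks plain octanol/water lipophilicity along an
affine law

```
log kw^IAM = a · log P + b            (per phase)
```

The interesting signal is the *excess* over that expectation,

```
Δlog kw^IAM = clog kw^IAM − (a · lip + b)
```

computed here entirely from in-silico retention values (hence the *c*
prefix). `lip` is the experimental log *P*ᴺ of the neutral species where
available, a calculated log *P* otherwise — except for acids, which use the
calculated distribution coefficient log *D*⁷·⁴ and carry the primed name
Δ′log *k*w^IAM. A large positive excess marks polar/electrostatic membrane
interactions beyond what lipophilicity explains, and is inversely related to
log BB = log₁₀(C_brain/C_blood), the steady-state brain/blood distribution.
The package is aimed at discovery-stage profiling: flagging candidates whose
brain penetration is likely to be substandard before any animal work.

It provides, as an importable library:

- a validated compound-table data model with CSV I/O and a packaged
  56-compound reference dataset (ionization class, in-silico retention on
  both phases, experimental/calculated lipophilicity, log BB);
- the delta engine: lipophilicity-selection policy, calibration lines, and
  recovery of the calibration coefficients by least squares from published
  per-compound deltas;
- OLS regression with the QSPR statistics panel (r², leave-one-out q², SE,
  F, p, Amemiya prediction criterion in two variants);
- the automatic model-building pipeline: univariate r² screen, iterative
  variance-inflation-factor (VIF < 5) collinearity filter, exhaustive subset
  search over 1–5 variables ranked by LOO q², optional single-compound
  exclusion search;
- hydrophilic–lipophilic balance calculators (Griffin, Davies, polar-surface
  based, and their mean HLB_M) plus a pluggable linear retention-model
  evaluator;
- seeded synthetic generators for compound tables and descriptor matrices
  with known truths, and a thin `iamdelta` CLI
  (`deltas` / `reproduce` / `stepwise` / `synth`).

## Worked example

```python
from iamdelta import (load_reference_table, load_reference_deltas,
                      recover_both_calibrations, compute_delta)

table = load_reference_table()                       # 56 compounds
cals = recover_both_calibrations(table, load_reference_deltas())
print(cals["DD2"].slope, cals["DD2"].intercept)      # 0.934 -0.883
res = compute_delta(table["valproic acid"], cals["DD2"])
print(f"{res.delta:.3f}", res.is_prime)              # 2.079 True
```

Running `python examples/logbb_regression.py` prints:

```
MG: full set  n=56  r2=0.37  q2(LOO)=0.32  SE=0.414  F=32.34
MG: subset    n=8  r2=0.59  slope=-0.514  excluded=['valproic acid']
DD2: full set  n=56  r2=0.38  q2(LOO)=0.32  SE=0.413  F=32.82
DD2: subset    n=8  r2=0.79  slope=-0.523  excluded=['valproic acid']
DD2 subset, all-calculated lipophilicity: r2=0.68
```

Over all 56 compounds the inverse relation between excess and log BB is real
but weak (r² ≈ 0.38). Restricted to the poorly penetrating range
(log BB < −0.20, the inconsistent acid valproic acid excluded) it tightens to
r² = 0.79 on the DD2 phase with a negative slope: the larger the polar
excess, the less the compound partitions into brain. Replacing experimental
with calculated log P degrades the subset fit to r² = 0.68.

The other scripts in `examples/` walk through delta computation, the
stepwise search on a planted synthetic matrix, HLB profiles, and synthetic
calibration recovery.

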