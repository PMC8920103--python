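"""Generate a synthetic compound table and recover its calibration truth.

The generator draws lipophilicities, builds IAM retention as
calibration(lipophilicity) + class-dependent polar excess + noise, and
returns the generating truths; least-squares recovery from the true
excess values must find the configured line.
"""

from iamdelta import SyntheticConfig, gen_compound_table, recover_calibration

config = SyntheticConfig(seed=42, n_compounds=200, retention_noise_sd=0.05)
table, truths = gen_compound_table(config)

print(f"generated {len(table)} compounds "
      f"({sum(r.ionization_class == 'A' for r in table)} acids)")

for phase, key in [("MG", "true_delta_mg"), ("DD2", "true_delta_dd2")]:
    cal = recover_calibration(table, truths[key], phase, min_r2=0.99)
    true = truths["calibration"][phase]
    print(f"{phase}: recovered slope {cal.slope:.4f} (true {true.slope}), "
          f"intercept {cal.intercept:.4f} (true {true.intercept}), r2={cal.r2:.5f}")

# With retention noise of 0.05 log units over 200 compounds the recovered
# line sits within a few thousandths of the configured truth — the same
# inversion that pins the reference calibrations from the published table.
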