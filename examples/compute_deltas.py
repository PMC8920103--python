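"""Compute phospholipophilicity-excess descriptors for the reference compounds.

Recovers the isolipophilic-neutral calibration lines from the packaged
56-compound table and recomputes the cΔ/Δ'log kw^IAM values on both IAM
phases for a few representative compounds.
"""

from iamdelta import (
    compute_delta,
    load_reference_deltas,
    load_reference_table,
    recover_both_calibrations,
)

table = load_reference_table()
cals = recover_both_calibrations(table, load_reference_deltas())

for phase, cal in cals.items():
    print(f"{phase}: log kw = {cal.slope:.3f} * lip + {cal.intercept:.3f}  (r2={cal.r2:.6f})")

for name in ("cyclohexane", "valproic acid", "trifluoperazine", "didanosine"):
    rec = table[name]
    for phase in ("MG", "DD2"):
        res = compute_delta(rec, cals[phase])
        tag = "Δ'" if res.is_prime else "Δ"
        print(f"{name:18s} {phase:3s} {tag} = {res.delta:+.3f}  "
              f"(lip {res.lipophilicity_used:+.2f} from {res.lipophilicity_source})")

# A positive delta means the compound binds the membrane-mimetic phase more
# strongly than a neutral molecule of equal lipophilicity would — excess
# polar/electrostatic interaction, which is associated with poor brain uptake.
# The primed values (acids) use log D at pH 7.4 instead of neutral log P.
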