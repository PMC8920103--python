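"""Hydrophilic-lipophilic balance variants and a user-supplied retention model.

Computes the three HLB estimates and their consensus for a small
polyethoxylated surfactant-like input, then evaluates a linear
phospholipophilicity model whose coefficients come from a model file.
"""

from iamdelta import LinearQSPR, hlb_davies, hlb_griffin, hlb_mean, hlb_psa, predict_logkw

# hydrophilic head 220 g/mol of a 386 g/mol molecule; four ether oxygens
# and one free hydroxyl against ten CH2/CH3 groups; PSA 47 A^2 of 520 A^2
g = hlb_griffin(hydrophilic_mass=220.0, molar_mass=386.0)
d = hlb_davies([1.3, 1.3, 1.3, 1.3, 1.9], n_lipophilic_groups=10)
p = hlb_psa(psa=47.0, total_surface=520.0)
profile = hlb_mean(g, d, p)

print(f"HLB Griffin: {g:.2f}")
print(f"HLB Davies : {d:.2f}")
print(f"HLB PSA    : {p:.2f}")
print(f"HLB_M mean : {profile.hlb_mean:.2f}")

# Evaluate a toy linear retention model on descriptors including HLB_M.
model = LinearQSPR(
    phase="MG",
    terms=(("miLogP", 0.45), ("HLB_M", -0.06)),
    intercept=-0.30,
)
logkw = predict_logkw({"miLogP": 2.8, "HLB_M": profile.hlb_mean}, model)
print(f"predicted log kw^IAM.MG: {logkw:.3f}")

# The three HLB variants weigh different evidence (mass fraction, group
# contributions, polar surface fraction); their mean HLB_M is the
# balance descriptor fed to retention models. The linear model is fully
# user-supplied: the package evaluates, it does not hard-code coefficients.
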