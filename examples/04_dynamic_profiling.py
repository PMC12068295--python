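"""Dynamic profiling: detect a pre-treatment-induced change in apoptotic dependency.

JEKO1-like cells are pre-treated for 20 h with ironomycin or vehicle (DMSO),
then challenged with the MCL-1 inhibitor at 1 µM. The dynamic shift is the
pre-treated arm's ∆ Annexin V minus the vehicle arm's — positive when the
pre-treatment primes the cells toward that dependency.
"""

from bh3kit.validation import recover_dynamic_shift

out = recover_dynamic_shift(
    sample_id="JEKO1",
    pretreatment_name="ironomycin",
    drug="AZD-5991",
    dose_nM=1000.0,
    vehicle_arm_delta_pp=10.0,
    treated_arm_delta_pp=19.9,
    n_pairs=3,
    seed=0,
)

print(f"vehicle-arm ∆ Annexin V:    {out['vehicle_arm_delta']:5.1f} pp")
print(f"ironomycin-arm ∆ Annexin V: {out['treated_arm_delta']:5.1f} pp")
print(f"dynamic shift:              {out['estimated_shift']:+5.1f} pp "
      f"(injected truth {out['true_shift']:+.1f})")
print("\na positive shift at the MCL-1 axis means ironomycin pre-treatment increased")
print("MCL-1 dependency — the kind of combination signal dynamic profiling screens for.")
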