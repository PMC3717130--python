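"""Generate a synthetic calibration task with a known ground truth.

Builds a 200-VP cohort on 10 mechanistic axes with three simulated therapy
arms, then derives trial targets (binned ACR-N counts plus mean/SD) as the
exact expectations of a known axes-weight solution. The printed target rows
are what a real calibration would take from published trial tables.
"""

from mapel import SyntheticSpec, generate_cohort, targets_from_truth, truth_solution

spec = SyntheticSpec(n_vps=200, n_axes=10, seed=1)
cohort = generate_cohort(spec)
truth = truth_solution(cohort, spec)
targets = targets_from_truth(cohort, truth, n_trial=spec.n_trial, mode="exact")

print(f"cohort: {cohort.n_vps} VPs x {cohort.n_axes} axes; "
      f"therapies: {[t for t, _ in cohort.response_keys]}")
print(f"ground-truth upper-bin probabilities p*: {truth.p.round(3)}")
for t in targets:
    counts = [b.count for b in t.bins]
    print(f"  target {t.therapy}@{t.months:g}m: N_T={t.n_trial}, "
          f"bins {counts}, mean={t.mean:.2f}%, sd={t.sd:.2f}%")
print("Each target row is the response distribution a virtual population "
      "must reproduce; counts sum to N_T by construction.")
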