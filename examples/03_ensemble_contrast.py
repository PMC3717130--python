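"""Build an ensemble of alternate populations and contrast responder groups.

Repeated calibration from randomized starting points yields alternate
prevalence-weight solutions that all match the trial targets for one therapy
(here "anti_tnf"). Because the targets leave the other therapy's response
unconstrained, the valid populations differ widely in their mean rituximab
response. Splitting the ensemble at the median rituximab response and
contrasting the per-axis upper-bin probabilities between strong and weak
responder populations then points to the mechanistic axes that drive the
response difference — in this synthetic task, axes 2 (+) and 3 (-) are the
true rituximab drivers.
"""

import numpy as np

from mapel import (
    CalibrationSettings,
    SyntheticSpec,
    build_ensemble,
    contrast_groups,
    generate_cohort,
    split_ensemble_by_response,
    targets_from_truth,
    truth_solution,
)
from mapel.analysis import member_mean_response

M = 8
loadings = np.zeros((2, M))
loadings[0, 0], loadings[0, 1] = 45.0, -30.0  # anti_tnf driven by axes 0, 1
loadings[1, 2], loadings[1, 3] = 40.0, -35.0  # rituximab driven by axes 2, 3
spec = SyntheticSpec(
    n_vps=150, n_axes=M,
    therapies=[("anti_tnf", 6.0), ("rituximab", 6.0)],
    loadings=loadings, intercepts=np.array([35.0, 40.0]),
    noise_sd=np.array([6.0, 6.0]), n_trial=250, seed=7,
)
cohort = generate_cohort(spec)
targets = [
    t
    for t in targets_from_truth(
        cohort, truth_solution(cohort, spec), n_trial=250, mode="exact"
    )
    if t.therapy == "anti_tnf"
]

settings = CalibrationSettings(seed=11, restarts=1, sigma_seed=1.0, max_iterations=150)
ensemble = build_ensemble(cohort, targets, settings, n_populations=16)

means = np.array(
    [member_mean_response(m, cohort, "rituximab", 6.0) for m in ensemble.members]
)
print(f"{len(ensemble)} valid populations (all match the anti_tnf targets); "
      f"mean rituximab response spans {means.min():.1f}..{means.max():.1f}% ACR-N")

cut = float(np.median(means))
strong, weak = split_ensemble_by_response(
    ensemble, cohort, "rituximab", 6.0, hi_cut=cut, lo_cut=cut
)
contrast = contrast_groups(strong, weak)
print(f"split at the median ({cut:.1f}%): strong {len(strong)}, weak {len(weak)}")
print("axes ordered by separation of the group medians of p_j:")
for _, row in contrast.table.iterrows():
    print(f"  {row['axis']}: median diff {row['median_diff']:+.3f} "
          f"(strong {row['median_strong']:.3f} vs weak {row['median_weak']:.3f})")
print("Axes 2 and 3 carry the true rituximab loadings; their recovered "
      "median differences have the correct signs, while axes with large "
      "spurious differences reflect directions the targets leave free.")
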