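"""Axes-weight optimization and ensemble construction.

A candidate solution (upper-bin probabilities p, optional pair correlations
rho) is scored by converting it to prevalence weights, computing the weighted
population statistics for every therapy/timepoint target, and aggregating
the per-statistic p-values into the Fisher composite. The sum of log
p-values is maximized with Nelder-Mead over the unconstrained hyperspherical
coordinates (theta with p = sin^2 theta, eta with rho = tanh eta), so the
simplex can move freely without box constraints.

Ensembles of alternate virtual populations are built by repeated calibration:
each attempt starts either from a fresh random solution or from a Gaussian
perturbation (in unconstrained space) of a uniformly chosen previously
accepted member, and a population is kept when its composite goodness-of-fit
exceeds the acceptance threshold.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .cohort_io import AxisBinning, Cohort, TrialTarget, compute_axis_binning
from .errors import AllMassLostError, CalibrationFailureError, MapelError
from .gof import GofReport, StatResult, bins_pvalue, composite_gof, mean_pvalue, sd_pvalue
from .popstats import bin_fractions, weighted_mean, weighted_sd
from .prevalence import (
    AxesWeightSolution,
    PrevalenceWeights,
    UnconstrainedVector,
    compute_weights,
    effective_sample_size,
    from_unconstrained,
    read_solution,
    to_unconstrained,
    write_solution,
    write_weights,
)

__all__ = [
    "CalibrationSettings",
    "CalibrationResult",
    "EnsembleMember",
    "VPopEnsemble",
    "evaluate_solution",
    "calibrate_vpop",
    "random_solution",
    "perturb_solution",
    "build_ensemble",
]

logger = logging.getLogger(__name__)

# Kish effective sample sizes below this are point-mass degenerate; the t/F
# tests need n > 1, so the evaluator floors n_eff here.
_N_EFF_FLOOR = 2.0


@dataclass
class CalibrationSettings:
    """Run configuration for calibration and ensemble construction.

    ``threshold`` is the composite-p acceptance cut (a population is valid
    when composite > threshold). ``sigma_seed`` is the SD of the Gaussian
    perturbation, in unconstrained coordinates, applied when re-seeding from
    an accepted member. ``n_eff_mode`` selects how the weighted population is
    sized in the t/F tests: Kish effective sample size (default) or the
    trial's own N on both sides.
    """

    threshold: float = 0.05
    max_iterations: int = 2000
    fatol: float = 1e-6
    xatol: float = 1e-6
    restarts: int = 5
    seed: int = 0
    sigma_seed: float = 0.25
    include_mean: bool = True
    include_sd: bool = True
    include_bins: bool = True
    correlated_pairs: list[tuple[str, str]] = field(default_factory=list)
    attempt_budget_factor: int = 20
    n_eff_mode: str = "kish"  # "kish" | "trial"
    f_test_two_sided: bool = True
    min_distance: float | None = None
    clip_bins: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0) and self.threshold != 1.0:
            # threshold == 1.0 is permitted so an unsatisfiable run fails loudly
            raise MapelError("threshold must lie in (0, 1]")
        if self.sigma_seed < 0:
            raise MapelError("sigma_seed must be >= 0")
        if self.n_eff_mode not in ("kish", "trial"):
            raise MapelError("n_eff_mode must be 'kish' or 'trial'")

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "max_iterations": self.max_iterations,
            "fatol": self.fatol,
            "xatol": self.xatol,
            "restarts": self.restarts,
            "seed": self.seed,
            "sigma_seed": self.sigma_seed,
            "include_mean": self.include_mean,
            "include_sd": self.include_sd,
            "include_bins": self.include_bins,
            "correlated_pairs": [list(p) for p in self.correlated_pairs],
            "attempt_budget_factor": self.attempt_budget_factor,
            "n_eff_mode": self.n_eff_mode,
            "f_test_two_sided": self.f_test_two_sided,
            "min_distance": self.min_distance,
            "clip_bins": self.clip_bins,
        }


class _Evaluator:
    """Precomputed target arrays for fast repeated solution scoring."""

    def __init__(
        self,
        cohort: Cohort,
        binning: AxisBinning,
        targets: Sequence[TrialTarget],
        settings: CalibrationSettings,
    ) -> None:
        self.cohort = cohort
        self.binning = binning
        self.settings = settings
        self.targets = list(targets)
        self.n_vps = cohort.n_vps
        self._x = [cohort.response_vector(t.therapy, t.months) for t in self.targets]
        self.n_stats = sum(
            (settings.include_mean and t.mean is not None)
            + (settings.include_sd and t.sd is not None)
            + (settings.include_bins and len(t.bins) >= 2)
            for t in self.targets
        )
        if self.n_stats == 0:
            raise MapelError("no statistics selected: check targets and include_* flags")
        self.worst_objective = self.n_stats * math.log(1e-300)

    def report(self, sol: AxesWeightSolution) -> GofReport:
        weights = compute_weights(self.cohort, self.binning, sol)
        return self.report_for_weights(weights)

    def report_for_weights(self, weights: PrevalenceWeights) -> GofReport:
        s = self.settings
        n_eff = max(effective_sample_size(weights), _N_EFF_FLOOR)
        results: list[StatResult] = []
        for target, x in zip(self.targets, self._x):
            n_pop = n_eff if s.n_eff_mode == "kish" else float(target.n_trial)
            mean = weighted_mean(x, weights)
            sd = weighted_sd(x, weights, self.n_vps)
            if s.include_mean and target.mean is not None:
                p = mean_pvalue(mean, sd, n_pop, target.mean, target.sd, target.n_trial)
                results.append(StatResult(target.therapy, target.months, "mean", p))
            if s.include_sd and target.sd is not None:
                if sd <= 0.0:
                    p = 0.0  # degenerate population spread: worst score, not an exception
                else:
                    p = sd_pvalue(sd, n_pop, target.sd, target.n_trial, s.f_test_two_sided)
                results.append(StatResult(target.therapy, target.months, "sd", p))
            if s.include_bins and len(target.bins) >= 2:
                frac = bin_fractions(x, weights, target.bins, clip=s.clip_bins)
                p = bins_pvalue(frac, target)
                results.append(StatResult(target.therapy, target.months, "bins", p))
        return GofReport(results=results).finalize()

    def objective_from_vector(self, values: np.ndarray, pairs: list[tuple[str, str]]) -> float:
        sol = from_unconstrained(
            UnconstrainedVector(values, self.binning.axis_names, pairs)
        )
        try:
            return self.report(sol).objective
        except AllMassLostError:
            return self.worst_objective


def evaluate_solution(
    cohort: Cohort,
    binning: AxisBinning,
    targets: Sequence[TrialTarget],
    sol: AxesWeightSolution,
    settings: CalibrationSettings | None = None,
) -> GofReport:
    """Score one axes-weight solution against the targets (pure function)."""
    settings = settings or CalibrationSettings()
    return _Evaluator(cohort, binning, targets, settings).report(sol)


def random_solution(
    cohort: Cohort,
    rng: np.random.Generator,
    correlated_pairs: Sequence[tuple[str, str]] = (),
) -> AxesWeightSolution:
    """Random initialization: p_j ~ Uniform(0,1), rho ~ Uniform(-0.5, 0.5)."""
    p = rng.uniform(0.0, 1.0, cohort.n_axes)
    correlations = [
        (k, l, float(rng.uniform(-0.5, 0.5))) for k, l in correlated_pairs
    ]
    return AxesWeightSolution.from_cohort(cohort, p, correlations)


def perturb_solution(
    sol: AxesWeightSolution,
    sigma_seed: float,
    seed: int | np.random.Generator | None = None,
) -> AxesWeightSolution:
    """Gaussian jitter (SD sigma_seed) in unconstrained space; sigma 0 is identity."""
    if sigma_seed < 0:
        raise MapelError("sigma_seed must be >= 0")
    if sigma_seed == 0.0:
        return AxesWeightSolution(
            p=sol.p.copy(),
            axis_names=list(sol.axis_names),
            correlations=list(sol.correlations),
            mu=sol.mu,
            sigma=sol.sigma,
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    vec = to_unconstrained(sol)
    jittered = vec.values + rng.normal(0.0, sigma_seed, len(vec.values))
    return from_unconstrained(
        UnconstrainedVector(jittered, vec.axis_names, vec.pairs), mu=sol.mu, sigma=sol.sigma
    )


@dataclass
class CalibrationResult:
    solution: AxesWeightSolution
    report: GofReport
    trace: list[float]
    converged: bool
    restarts_used: int
    seed: int


def _run_nelder_mead(
    evaluator: _Evaluator,
    start: AxesWeightSolution,
    settings: CalibrationSettings,
) -> tuple[AxesWeightSolution, float, list[float], bool]:
    vec0 = to_unconstrained(start)
    pairs = vec0.pairs
    trace: list[float] = []
    best = -math.inf

    def neg_objective(v: np.ndarray) -> float:
        nonlocal best
        obj = evaluator.objective_from_vector(v, pairs)
        best = max(best, obj)
        return -obj

    def record(_xk: np.ndarray) -> None:
        trace.append(best)

    res = minimize(
        neg_objective,
        vec0.values,
        method="Nelder-Mead",
        callback=record,
        options={
            "maxiter": settings.max_iterations,
            "fatol": settings.fatol,
            "xatol": settings.xatol,
            "adaptive": False,
        },
    )
    sol = from_unconstrained(
        UnconstrainedVector(res.x, vec0.axis_names, pairs), mu=start.mu, sigma=start.sigma
    )
    return sol, -float(res.fun), trace, bool(res.success)


def calibrate_vpop(
    cohort: Cohort,
    targets: Sequence[TrialTarget],
    settings: CalibrationSettings | None = None,
    init: AxesWeightSolution | None = None,
) -> CalibrationResult:
    """Maximize the log-p objective with Nelder-Mead, with random restarts.

    The first run starts from ``init`` when given, otherwise from a random
    solution; subsequent restarts are random. Restarting stops early once a
    run's composite exceeds the acceptance threshold. A run that hits the
    iteration cap is returned best-so-far with ``converged=False``.
    """
    settings = settings or CalibrationSettings()
    binning = compute_axis_binning(cohort)
    evaluator = _Evaluator(cohort, binning, targets, settings)
    rng = np.random.default_rng(settings.seed)

    best: tuple[AxesWeightSolution, float, list[float], bool] | None = None
    restarts = max(1, settings.restarts)
    used = 0
    for r in range(restarts):
        if r == 0 and init is not None:
            start = init
        else:
            start = random_solution(cohort, rng, settings.correlated_pairs)
        run = _run_nelder_mead(evaluator, start, settings)
        used += 1
        if best is None or run[1] > best[1]:
            best = run
        report = evaluator.report(best[0])
        if report.accepted(settings.threshold):
            break

    assert best is not None
    solution, _, trace, converged = best
    report = evaluator.report(solution)
    return CalibrationResult(
        solution=solution,
        report=report,
        trace=trace,
        converged=converged,
        restarts_used=used,
        seed=settings.seed,
    )


# ---------------------------------------------------------------------------
# Ensembles
# ---------------------------------------------------------------------------

@dataclass
class EnsembleMember:
    member_id: int
    solution: AxesWeightSolution
    weights: PrevalenceWeights
    composite: float
    seed: int
    parent_id: int | None = None
    report: GofReport | None = None


@dataclass
class VPopEnsemble:
    """Accepted alternate virtual populations, each above the composite threshold."""

    members: list[EnsembleMember]
    threshold: float
    settings: CalibrationSettings | None = None

    def __len__(self) -> int:
        return len(self.members)

    def p_matrix(self) -> pd.DataFrame:
        """Member-by-axis table of upper-bin probabilities."""
        if not self.members:
            raise MapelError("empty ensemble")
        names = self.members[0].solution.axis_names
        return pd.DataFrame(
            [m.solution.p for m in self.members],
            columns=names,
            index=[m.member_id for m in self.members],
        )

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest = {
            "threshold": self.threshold,
            "settings": self.settings.to_dict() if self.settings else None,
            "members": [],
        }
        for m in self.members:
            stem = f"member_{m.member_id:04d}"
            write_solution(m.solution, out / f"{stem}_solution.csv")
            write_weights(m.weights, out / f"{stem}_weights.csv")
            manifest["members"].append(
                {
                    "member_id": m.member_id,
                    "composite": m.composite,
                    "seed": m.seed,
                    "parent_id": m.parent_id,
                }
            )
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)

    @classmethod
    def load(cls, out_dir: str | Path) -> "VPopEnsemble":
        out = Path(out_dir)
        with open(out / "manifest.json") as fh:
            manifest = json.load(fh)
        members = []
        for rec in manifest["members"]:
            stem = f"member_{rec['member_id']:04d}"
            sol = read_solution(out / f"{stem}_solution.csv")
            wf = pd.read_csv(out / f"{stem}_weights.csv")
            weights = PrevalenceWeights(
                vp_ids=[str(v) for v in wf["vp_id"]],
                w=wf["weight"].to_numpy(dtype=float),
            )
            members.append(
                EnsembleMember(
                    member_id=int(rec["member_id"]),
                    solution=sol,
                    weights=weights,
                    composite=float(rec["composite"]),
                    seed=int(rec["seed"]),
                    parent_id=rec.get("parent_id"),
                )
            )
        return cls(members=members, threshold=float(manifest["threshold"]))


def build_ensemble(
    cohort: Cohort,
    targets: Sequence[TrialTarget],
    settings: CalibrationSettings | None = None,
    n_populations: int = 10,
) -> VPopEnsemble:
    """Accumulate alternate acceptable populations by randomized re-seeding.

    Each attempt draws its randomness from a seed derived from the master
    seed and the attempt index, so the member set is reproducible. Once at
    least one member exists, new attempts start from a perturbation of a
    uniformly chosen accepted member; before that, from random solutions.
    """
    if n_populations < 1:
        raise MapelError("n_populations must be >= 1")
    settings = settings or CalibrationSettings()
    budget = settings.attempt_budget_factor * n_populations
    binning = compute_axis_binning(cohort)
    evaluator = _Evaluator(cohort, binning, targets, settings)

    members: list[EnsembleMember] = []
    attempts = 0
    for attempt in range(budget):
        if len(members) >= n_populations:
            break
        attempts += 1
        seed_int = int(
            np.random.SeedSequence([settings.seed, attempt]).generate_state(1)[0]
        )
        rng = np.random.default_rng(seed_int)
        parent_id = None
        init = None
        if members:
            parent = members[int(rng.integers(len(members)))]
            parent_id = parent.member_id
            init = perturb_solution(parent.solution, settings.sigma_seed, rng)
        run_settings = replace(settings, seed=seed_int)
        result = calibrate_vpop(cohort, targets, run_settings, init=init)
        accepted = result.report.accepted(settings.threshold)
        if accepted and settings.min_distance is not None:
            for m in members:
                if float(np.max(np.abs(m.solution.p - result.solution.p))) < settings.min_distance:
                    accepted = False
                    break
        logger.info(
            "ensemble attempt %d: composite=%.4g objective=%.4g accepted=%s",
            attempt,
            result.report.composite,
            result.report.objective,
            accepted,
        )
        if accepted:
            weights = compute_weights(cohort, binning, result.solution)
            members.append(
                EnsembleMember(
                    member_id=len(members),
                    solution=result.solution,
                    weights=weights,
                    composite=result.report.composite,
                    seed=seed_int,
                    parent_id=parent_id,
                    report=result.report,
                )
            )

    logger.info(
        "ensemble: %d/%d members accepted in %d attempts (acceptance rate %.2f)",
        len(members),
        n_populations,
        attempts,
        len(members) / max(attempts, 1),
    )
    if not members:
        raise CalibrationFailureError(
            f"no acceptable population found in {attempts} attempts "
            f"(threshold {settings.threshold}); consider more restarts or a "
            f"larger attempt budget"
        )
    if len(members) < n_populations:
        logger.warning(
            "attempt budget exhausted with %d of %d members", len(members), n_populations
        )
    return VPopEnsemble(members=members, threshold=settings.threshold, settings=settings)
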