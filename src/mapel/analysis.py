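"""Post-calibration analyses over an ensemble of virtual populations.

Three workflows:

* **Response contrast** — split ensemble members into strong and weak
  responder populations by their weighted mean response to a therapy, then
  contrast the per-axis upper-bin probabilities between the groups (medians
  and interquartile ranges, axes ordered by the separation of the medians).
* **Scenario re-statting** — apply previously calibrated prevalence weights,
  unchanged, to an alternate set of per-VP responses (e.g. a simulation with
  one pathway effect locked on or off) and recompute the population
  statistics. No re-optimization takes place.
* **Multianalyte biomarkers** — prune highly correlated mediator panels,
  then exhaustively search all size-k weighted linear regressions of
  response on mediator concentrations for each population, and tabulate how
  often each analyte enters the best model across populations.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .calibrate import EnsembleMember, VPopEnsemble
from .cohort_io import Cohort, TrialTarget
from .errors import AlignmentError, MapelError, SubsetBudgetError
from .popstats import PopulationStats, population_stats, weighted_mean
from .prevalence import PrevalenceWeights, effective_sample_size

__all__ = [
    "GroupContrast",
    "BiomarkerModel",
    "split_ensemble_by_response",
    "contrast_groups",
    "restat_scenario",
    "prune_correlated_mediators",
    "best_subset_regression",
    "ensemble_biomarker_models",
    "analyte_selection_frequency",
]

#: Strong-responder cut: populations with weighted mean ACR-N above this are
#: "strong"; the weak cut is the trial's observed mean response.
DEFAULT_HI_CUT = 48.0
DEFAULT_LO_CUT = 44.75


def member_mean_response(
    member: EnsembleMember, cohort: Cohort, therapy: str, months: float
) -> float:
    x = cohort.response_vector(therapy, months)
    return weighted_mean(x, member.weights)


def split_ensemble_by_response(
    ensemble: VPopEnsemble,
    cohort: Cohort,
    therapy: str,
    months: float,
    hi_cut: float = DEFAULT_HI_CUT,
    lo_cut: float = DEFAULT_LO_CUT,
) -> tuple[list[EnsembleMember], list[EnsembleMember]]:
    """Partition members into strong (> hi_cut) and weak (< lo_cut) responders.

    Members with mean response inside [lo_cut, hi_cut] are excluded. An empty
    group raises a warning flag (UserWarning) but the analysis proceeds.
    """
    if hi_cut < lo_cut:
        raise MapelError("hi_cut must be >= lo_cut")
    strong, weak = [], []
    for m in ensemble.members:
        mean = member_mean_response(m, cohort, therapy, months)
        if mean > hi_cut:
            strong.append(m)
        elif mean < lo_cut:
            weak.append(m)
    if not strong:
        warnings.warn("strong responder group is empty", stacklevel=2)
    if not weak:
        warnings.warn("weak responder group is empty", stacklevel=2)
    return strong, weak


@dataclass
class GroupContrast:
    """Per-axis medians/IQRs of upper-bin probabilities in two member groups.

    ``table`` has one row per axis, ordered by decreasing absolute difference
    of the group medians — the leading rows are the mechanistic axes that
    most separate strong from weak responder populations.
    """

    table: pd.DataFrame

    @property
    def ordered_axes(self) -> list[str]:
        return list(self.table["axis"])


def _group_p(members: Sequence[EnsembleMember]) -> np.ndarray:
    return np.array([m.solution.p for m in members], dtype=float)


def contrast_groups(
    strong: Sequence[EnsembleMember], weak: Sequence[EnsembleMember]
) -> GroupContrast:
    """Median/IQR of p_j per axis in each group, ordered by median separation."""
    if not strong or not weak:
        raise MapelError("both groups must be non-empty")
    names = strong[0].solution.axis_names
    ps, pw = _group_p(strong), _group_p(weak)
    med_s = np.median(ps, axis=0)
    med_w = np.median(pw, axis=0)
    q1_s, q3_s = np.percentile(ps, [25, 75], axis=0)
    q1_w, q3_w = np.percentile(pw, [25, 75], axis=0)
    table = pd.DataFrame(
        {
            "axis": names,
            "median_strong": med_s,
            "iqr_lo_strong": q1_s,
            "iqr_hi_strong": q3_s,
            "median_weak": med_w,
            "iqr_lo_weak": q1_w,
            "iqr_hi_weak": q3_w,
            "median_diff": med_s - med_w,
        }
    )
    table["abs_diff"] = table["median_diff"].abs()
    table = table.sort_values("abs_diff", ascending=False, kind="stable").drop(
        columns="abs_diff"
    )
    return GroupContrast(table=table.reset_index(drop=True))


def restat_scenario(
    weights: PrevalenceWeights,
    scenario_responses: pd.Series,
    target: TrialTarget,
    n_vps: int | None = None,
) -> PopulationStats:
    """Population statistics of scenario responses under fixed, precomputed weights.

    ``scenario_responses`` must be indexed by vp_id and cover exactly the
    weighted VPs (order-insensitive); a mismatch raises AlignmentError.
    """
    idx = pd.Index(weights.vp_ids)
    missing = idx.difference(scenario_responses.index)
    extra = scenario_responses.index.difference(idx)
    if len(missing) or len(extra):
        raise AlignmentError(
            f"scenario responses misaligned: missing {list(missing[:5])}, "
            f"unexpected {list(extra[:5])}"
        )
    x = scenario_responses.loc[idx].to_numpy(dtype=float)
    return population_stats(x, weights, target, n_vps=n_vps)


def prune_correlated_mediators(
    mediators: pd.DataFrame, rho_cut: float = 0.8
) -> list[str]:
    """Collapse sets of highly correlated analytes to one representative each.

    Analytes with pairwise Pearson |rho| > rho_cut are joined into a graph;
    within each connected component of size > 1 exactly one analyte is kept:
    the one with the lowest mean absolute correlation against all *other*
    analytes of the panel (ties broken by column order). Singletons are kept.
    Constant columns have no defined correlation; they are treated as
    uncorrelated, retained, and flagged with a warning.
    """
    if mediators.shape[1] < 2:
        raise MapelError("mediator pruning needs at least 2 analytes")
    if not (0.0 < rho_cut < 1.0):
        raise MapelError("rho_cut must lie in (0, 1)")
    corr = mediators.corr().abs()
    constant = [c for c in mediators.columns if mediators[c].nunique() <= 1]
    if constant:
        warnings.warn(
            f"constant mediator column(s) retained as uncorrelated: {constant}",
            stacklevel=2,
        )
    filled = corr.fillna(0.0).to_numpy()
    np.fill_diagonal(filled, 0.0)
    adjacency = csr_matrix(filled > rho_cut)
    n_comp, labels = connected_components(adjacency, directed=False)
    mean_abs = filled.sum(axis=1) / (filled.shape[1] - 1)
    cols = list(mediators.columns)
    retained = []
    for comp in range(n_comp):
        idx = np.nonzero(labels == comp)[0]
        if len(idx) == 1:
            retained.append(cols[idx[0]])
        else:
            best = idx[int(np.argmin(mean_abs[idx]))]  # argmin keeps first on ties
            retained.append(cols[best])
    return [c for c in cols if c in set(retained)]


@dataclass
class BiomarkerModel:
    """Best size-k weighted linear model of response on mediator concentrations."""

    analytes: list[str]
    coefficients: np.ndarray
    intercept: float
    r2: float
    adj_r2: float
    bic: float
    k: int
    vpop_id: int | None = None


def _weighted_fit(
    X: np.ndarray, y: np.ndarray, w: np.ndarray
) -> tuple[np.ndarray, float, float]:
    """Weighted least squares; returns (beta, RSS_w, R2_w) with sum(w)=1."""
    design = np.column_stack([np.ones(len(y)), X])
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(design * sw[:, None], y * sw, rcond=None)
    resid = y - design @ beta
    rss = float(w @ resid**2)
    ybar = float(w @ y)
    tss = float(w @ (y - ybar) ** 2)
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    return beta, rss, r2


def best_subset_regression(
    mediators: pd.DataFrame,
    response: np.ndarray | pd.Series,
    weights: PrevalenceWeights | np.ndarray,
    k: int,
    candidates: Sequence[str] | None = None,
    budget: int = 200_000,
    vpop_id: int | None = None,
) -> BiomarkerModel:
    """Exhaustive best size-k prevalence-weighted regression over analyte subsets.

    Every size-k subset of the candidate analytes is fit by weighted least
    squares; the subset maximizing the weighted R^2 wins. The adjusted R^2
    and BIC are computed with the Kish effective sample size n_eff::

        adj R2 = 1 - (1 - R2) (n_eff - 1) / (n_eff - k - 1)
        BIC    = n_eff ln(sum_i w_i r_i^2) + (k + 1) ln(n_eff)

    Raises SubsetBudgetError when C(#candidates, k) exceeds ``budget``.
    """
    cols = list(candidates) if candidates is not None else list(mediators.columns)
    if k < 1:
        raise MapelError("k must be >= 1")
    if len(cols) < k:
        raise MapelError(f"only {len(cols)} candidate analytes for model size {k}")
    w = weights.w if isinstance(weights, PrevalenceWeights) else np.asarray(weights, float)
    w = w / w.sum()
    y = np.asarray(response, dtype=float)
    if mediators.shape[0] != len(y) or len(w) != len(y):
        raise MapelError("mediators, response, and weights must share length")
    if len(y) < k + 2:
        raise MapelError("need at least k + 2 observations")
    from math import comb

    n_models = comb(len(cols), k)
    if n_models > budget:
        raise SubsetBudgetError(
            f"{n_models} size-{k} subsets exceed the budget of {budget}; "
            f"prune the mediator panel first"
        )

    data = mediators[cols].to_numpy(dtype=float)
    col_index = {c: i for i, c in enumerate(cols)}
    best: tuple[float, tuple[str, ...], np.ndarray, float] | None = None
    for subset in itertools.combinations(cols, k):
        X = data[:, [col_index[c] for c in subset]]
        beta, rss, r2 = _weighted_fit(X, y, w)
        if best is None or r2 > best[0]:
            best = (r2, subset, beta, rss)

    assert best is not None
    r2, subset, beta, rss = best
    n_eff = effective_sample_size(w)
    adj = 1.0 - (1.0 - r2) * (n_eff - 1.0) / (n_eff - k - 1.0) if n_eff > k + 1 else -np.inf
    bic = n_eff * np.log(max(rss, 1e-300)) + (k + 1) * np.log(n_eff)
    return BiomarkerModel(
        analytes=list(subset),
        coefficients=beta[1:],
        intercept=float(beta[0]),
        r2=float(r2),
        adj_r2=float(adj),
        bic=float(bic),
        k=k,
        vpop_id=vpop_id,
    )


def ensemble_biomarker_models(
    ensemble: VPopEnsemble,
    cohort: Cohort,
    therapy: str,
    months: float,
    k: int = 5,
    rho_cut: float = 0.8,
    budget: int = 200_000,
) -> list[BiomarkerModel]:
    """Best size-k biomarker model for every population, after panel pruning."""
    if cohort.mediators is None:
        raise MapelError("cohort has no mediator panel")
    retained = prune_correlated_mediators(cohort.mediators, rho_cut=rho_cut)
    y = cohort.response_vector(therapy, months)
    return [
        best_subset_regression(
            cohort.mediators,
            y,
            m.weights,
            k,
            candidates=retained,
            budget=budget,
            vpop_id=m.member_id,
        )
        for m in ensemble.members
    ]


def analyte_selection_frequency(models: Sequence[BiomarkerModel]) -> pd.DataFrame:
    """Per-analyte count and fraction of populations selecting it.

    Counts sum to k x #models across analytes; fractions are per-model shares.
    """
    if not models:
        raise MapelError("at least one model required")
    counts: dict[str, int] = {}
    for model in models:
        for a in model.analytes:
            counts[a] = counts.get(a, 0) + 1
    frame = pd.DataFrame(
        {
            "analyte": list(counts),
            "count": list(counts.values()),
        }
    )
    frame["fraction"] = frame["count"] / len(models)
    return frame.sort_values(
        ["count", "analyte"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
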