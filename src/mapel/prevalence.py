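"""Prevalence weights from axes weights: independent and Gaussian-copula forms.

Every virtual patient i carries an unnormalized mass

    u_i = prod_j [ (1 - p_j)  if C_ij in LOWER_j  else  p_j ]

where p_j is the probability weight placed on the upper median bin of axis j.
Normalizing u over the cohort gives the prevalence weights w_i: the fraction
of the virtual population each VP statistically represents. A dependence
between one or more disjoint axis pairs (k, l) is introduced through a
Gaussian copula: the pair's product of marginal bin probabilities is replaced
by the probability that a standard bivariate normal with correlation rho
falls in the rectangle whose margins reproduce the bin probabilities. With
the latent cutpoint z_j* = Phi^{-1}(1 - p_j), LOWER maps to (-inf, z_j*] and
UPPER to (z_j*, inf), so at rho = 0 the rectangle probability factorizes into
(1 - p_k or p_k) * (1 - p_l or p_l) and the copula form reduces exactly to
the independent form.

For optimization, solutions are mapped to an unconstrained real vector by the
hyperspherical transform p = sin^2(theta) (2-bin case) and rho = tanh(eta),
which is periodic/unbounded and therefore free of box-edge complications.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.special import ndtr, ndtri

from .cohort_io import AxisBinning, Cohort
from .errors import AllMassLostError, MapelError

__all__ = [
    "AxesWeightSolution",
    "PrevalenceWeights",
    "UnconstrainedVector",
    "to_unconstrained",
    "from_unconstrained",
    "weights_independent",
    "weights_with_copula",
    "compute_weights",
    "bivariate_rectangle_probability",
    "effective_sample_size",
    "write_weights",
    "write_solution",
    "read_solution",
]


@dataclass
class AxesWeightSolution:
    """Upper-bin probabilities per axis plus optional pairwise correlations.

    ``p[j]`` is the probability mass on the upper median bin of axis
    ``axis_names[j]``; ``correlations`` lists ``(axis_k, axis_l, rho)`` with
    every axis appearing in at most one pair. ``mu``/``sigma`` record the
    cohort mean/SD per axis (the z-transform of the copula formulation); they
    are bookkeeping only — the rectangle limits depend solely on p and the
    bin membership.
    """

    p: np.ndarray
    axis_names: list[str]
    correlations: list[tuple[str, str, float]] = field(default_factory=list)
    mu: np.ndarray | None = None
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        self.axis_names = list(self.axis_names)
        self.validate()

    def validate(self) -> None:
        if self.p.ndim != 1 or len(self.p) != len(self.axis_names):
            raise MapelError("p must be a vector aligned with axis_names")
        if np.any((self.p < 0) | (self.p > 1)):
            raise MapelError("all p_j must lie in [0, 1]")
        seen: set[str] = set()
        for k, l, rho in self.correlations:
            for name in (k, l):
                if name not in self.axis_names:
                    raise MapelError(f"correlated axis {name!r} not among axis_names")
                if name in seen:
                    raise MapelError(f"axis {name!r} appears in more than one pair")
                seen.add(name)
            if not abs(rho) < 1:
                raise MapelError(f"|rho| must be < 1, got {rho}")

    @classmethod
    def from_cohort(
        cls,
        cohort: Cohort,
        p: Sequence[float],
        correlations: Sequence[tuple[str, str, float]] = (),
    ) -> "AxesWeightSolution":
        """Attach cohort axis names and standardization parameters to a p-vector."""
        return cls(
            p=np.asarray(p, dtype=float),
            axis_names=cohort.axis_names,
            correlations=list(correlations),
            mu=cohort.axes.mean(axis=0).to_numpy(),
            sigma=cohort.axes.std(axis=0, ddof=1).to_numpy(),
        )

    def p_of(self, axis: str) -> float:
        return float(self.p[self.axis_names.index(axis)])


@dataclass
class PrevalenceWeights:
    """Normalized probability mass per VP (w_i >= 0, sum_i w_i = 1)."""

    vp_ids: list[str]
    w: np.ndarray

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if len(self.w) != len(self.vp_ids):
            raise MapelError("weights and vp_ids differ in length")
        if np.any(self.w < 0):
            raise MapelError("prevalence weights must be non-negative")
        if abs(float(self.w.sum()) - 1.0) > 1e-12:
            raise MapelError(f"weights must sum to 1, got {self.w.sum()!r}")

    def as_series(self) -> pd.Series:
        return pd.Series(self.w, index=pd.Index(self.vp_ids, name="vp_id"), name="weight")


@dataclass
class UnconstrainedVector:
    """Image of a solution under the hyperspherical/arctanh transform.

    The first ``len(axis_names)`` coordinates are theta_j with
    p_j = sin^2(theta_j); the remaining ones are atanh(rho) per correlated
    pair, in ``pairs`` order. Any real vector is a valid point.
    """

    values: np.ndarray
    axis_names: list[str]
    pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.axis_names) + len(self.pairs):
            raise MapelError("unconstrained vector length mismatch")


def to_unconstrained(sol: AxesWeightSolution) -> UnconstrainedVector:
    """Map p -> theta = arcsin(sqrt(p)) and rho -> atanh(rho)."""
    theta = np.arcsin(np.sqrt(sol.p))
    etas = [math.atanh(rho) for _, _, rho in sol.correlations]
    return UnconstrainedVector(
        values=np.concatenate([theta, np.asarray(etas, dtype=float)]),
        axis_names=list(sol.axis_names),
        pairs=[(k, l) for k, l, _ in sol.correlations],
    )


def from_unconstrained(
    vec: UnconstrainedVector,
    mu: np.ndarray | None = None,
    sigma: np.ndarray | None = None,
) -> AxesWeightSolution:
    """Map theta -> p = sin^2(theta) in [0,1] and eta -> rho = tanh(eta) in (-1,1)."""
    m = len(vec.axis_names)
    p = np.sin(vec.values[:m]) ** 2
    rhos = np.tanh(vec.values[m:])
    correlations = [
        (k, l, float(r)) for (k, l), r in zip(vec.pairs, rhos)
    ]
    return AxesWeightSolution(
        p=p, axis_names=list(vec.axis_names), correlations=correlations, mu=mu, sigma=sigma
    )


# ---------------------------------------------------------------------------
# Weight computation
# ---------------------------------------------------------------------------

def _normalize(u: np.ndarray, vp_ids: list[str]) -> PrevalenceWeights:
    total = float(u.sum())
    if total <= 0.0:
        raise AllMassLostError(
            "every VP received zero unnormalized weight (a p_j at 0 or 1 "
            "annihilates all occupied bin patterns)"
        )
    return PrevalenceWeights(vp_ids=vp_ids, w=u / total)


def _independent_factors(binning: AxisBinning, sol: AxesWeightSolution, axes: list[str]) -> np.ndarray:
    """Per-VP product of (1-p_j)/p_j factors over the listed axes."""
    if not axes:
        return np.ones(binning.upper.shape[0])
    upper = binning.upper[axes].to_numpy()
    p = np.array([sol.p_of(a) for a in axes])
    return np.prod(np.where(upper, p, 1.0 - p), axis=1)


def weights_independent(
    cohort: Cohort, binning: AxisBinning, sol: AxesWeightSolution
) -> PrevalenceWeights:
    """Prevalence weights with independent axes (correlation pairs ignored)."""
    u = _independent_factors(binning, sol, list(binning.axis_names))
    return _normalize(u, cohort.vp_ids)


def _bvn_cdf(h: float, k: float, rho: float) -> float:
    """P(Z1 <= h, Z2 <= k) for standard bivariate normal with correlation rho.

    Uses the single-integral identity
    Phi2(h,k;rho) = Phi(h)Phi(k) + (1/2pi) int_0^rho
        exp(-(h^2 - 2 r h k + k^2) / (2(1-r^2))) / sqrt(1-r^2) dr,
    integrated adaptively; absolute error well below 1e-10.
    """
    if math.isinf(h) or math.isinf(k):
        if h == -math.inf or k == -math.inf:
            return 0.0
        if h == math.inf:
            return float(ndtr(k))
        return float(ndtr(h))
    base = float(ndtr(h) * ndtr(k))
    if rho == 0.0:
        return base

    def integrand(r: float) -> float:
        om = 1.0 - r * r
        return math.exp(-(h * h - 2.0 * r * h * k + k * k) / (2.0 * om)) / math.sqrt(om)

    val, _ = quad(integrand, 0.0, rho, epsabs=1e-12, epsrel=1e-12, limit=200)
    return min(1.0, max(0.0, base + val / (2.0 * math.pi)))


def bivariate_rectangle_probability(
    upper_k: bool, upper_l: bool, p_k: float, p_l: float, rho: float
) -> float:
    """Probability that correlated latent normals land in the two axes' bins.

    The latent cutpoint for an axis with upper-bin probability p is
    z* = Phi^{-1}(1 - p): LOWER is (-inf, z*], UPPER is (z*, inf), so the
    marginals are 1-p and p. At rho = 0 the result is the product of the two
    marginal bin probabilities. Absolute accuracy <= 1e-8.
    """
    if not (0.0 <= p_k <= 1.0 and 0.0 <= p_l <= 1.0):
        raise MapelError("bin probabilities must lie in [0, 1]")
    if not abs(rho) < 1:
        raise MapelError(f"|rho| must be < 1, got {rho}")
    zk = float(ndtri(1.0 - p_k)) if 0.0 < p_k < 1.0 else (math.inf if p_k == 0.0 else -math.inf)
    zl = float(ndtri(1.0 - p_l)) if 0.0 < p_l < 1.0 else (math.inf if p_l == 0.0 else -math.inf)
    both_lower = _bvn_cdf(zk, zl, rho)
    if not upper_k and not upper_l:
        prob = both_lower
    elif not upper_k and upper_l:
        prob = float(ndtr(zk)) - both_lower if not math.isinf(zk) else (
            (1.0 if zk > 0 else 0.0) - both_lower
        )
    elif upper_k and not upper_l:
        prob = float(ndtr(zl)) - both_lower if not math.isinf(zl) else (
            (1.0 if zl > 0 else 0.0) - both_lower
        )
    else:
        pk_low = float(ndtr(zk)) if not math.isinf(zk) else (1.0 if zk > 0 else 0.0)
        pl_low = float(ndtr(zl)) if not math.isinf(zl) else (1.0 if zl > 0 else 0.0)
        prob = 1.0 - pk_low - pl_low + both_lower
    return min(1.0, max(0.0, prob))


def weights_with_copula(
    cohort: Cohort, binning: AxisBinning, sol: AxesWeightSolution
) -> PrevalenceWeights:
    """Prevalence weights with Gaussian-copula factors for each correlated pair.

    Axes outside every pair contribute their independent (1-p_j)/p_j factor;
    each pair contributes the bivariate rectangle probability of the VP's bin
    combination. With all rho = 0 this equals :func:`weights_independent`.
    """
    paired = {name for k, l, _ in sol.correlations for name in (k, l)}
    free_axes = [a for a in binning.axis_names if a not in paired]
    u = _independent_factors(binning, sol, free_axes)
    for k, l, rho in sol.correlations:
        rect = {
            (uk, ul): bivariate_rectangle_probability(uk, ul, sol.p_of(k), sol.p_of(l), rho)
            for uk in (False, True)
            for ul in (False, True)
        }
        up_k = binning.upper[k].to_numpy()
        up_l = binning.upper[l].to_numpy()
        factors = np.empty(len(up_k))
        for (uk, ul), val in rect.items():
            factors[(up_k == uk) & (up_l == ul)] = val
        u = u * factors
    return _normalize(u, cohort.vp_ids)


def compute_weights(
    cohort: Cohort, binning: AxisBinning, sol: AxesWeightSolution
) -> PrevalenceWeights:
    """Dispatch to the copula form when the solution has correlated pairs."""
    if sol.correlations:
        return weights_with_copula(cohort, binning, sol)
    return weights_independent(cohort, binning, sol)


def effective_sample_size(weights: PrevalenceWeights | np.ndarray) -> float:
    """Kish effective sample size (sum w)^2 / sum w^2 of a weighted population."""
    w = weights.w if isinstance(weights, PrevalenceWeights) else np.asarray(weights, float)
    return float(w.sum() ** 2 / (w**2).sum())


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_weights(weights: PrevalenceWeights, path: str | Path) -> None:
    weights.as_series().to_csv(path)


def write_solution(sol: AxesWeightSolution, path: str | Path) -> None:
    """CSV with one `axis, p_upper` row per axis plus `pair_k, pair_l, rho` rows."""
    rows = [
        {"record": "axis", "axis": a, "p_upper": p, "pair_k": "", "pair_l": "", "rho": ""}
        for a, p in zip(sol.axis_names, sol.p)
    ]
    rows += [
        {"record": "pair", "axis": "", "p_upper": "", "pair_k": k, "pair_l": l, "rho": rho}
        for k, l, rho in sol.correlations
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_solution(path: str | Path) -> AxesWeightSolution:
    frame = pd.read_csv(path)
    axes = frame[frame["record"] == "axis"]
    pairs = frame[frame["record"] == "pair"]
    return AxesWeightSolution(
        p=axes["p_upper"].to_numpy(dtype=float),
        axis_names=[str(a) for a in axes["axis"]],
        correlations=[
            (str(r["pair_k"]), str(r["pair_l"]), float(r["rho"]))
            for _, r in pairs.iterrows()
        ],
    )
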