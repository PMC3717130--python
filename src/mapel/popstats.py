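"""Weighted virtual-population statistics and trial statistics from binned data.

With normalized prevalence weights w and per-VP responses x (ACR-N percent):

    weighted mean   x_bar = sum_i w_i x_i
    weighted SD     s     = sqrt( N * sum_i w_i (x_i - x_bar)^2 / (N - 1) )

where N is the number of VPs in the calibration (the SD reduces to the
classical sample SD when w is uniform). Binned response fractions sum the
prevalence weight of the VPs falling in each target bin; bins are half-open
[lo, hi), with the extreme bins extended to -inf/+inf by default so that out
of range responses are clipped into the edge bins (strict mode errors
instead).

Trial-side statistics from a reported binned distribution use bin midpoints:

    mean = (1/N_T) sum_b c_b n_b
    sd   = sqrt( sum_b n_b (c_b - mean)^2 / (N_T - 1) )
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort_io import TrialBin, TrialTarget
from .errors import CoverageError, MapelError
from .prevalence import PrevalenceWeights

__all__ = [
    "PopulationStats",
    "weighted_mean",
    "weighted_sd",
    "bin_fractions",
    "trial_stats_from_bins",
    "population_stats",
    "write_population_stats",
]


def _as_weights(w: PrevalenceWeights | np.ndarray) -> np.ndarray:
    return w.w if isinstance(w, PrevalenceWeights) else np.asarray(w, dtype=float)


def weighted_mean(x: np.ndarray, w: PrevalenceWeights | np.ndarray) -> float:
    """Prevalence-weighted mean sum_i w_i x_i (w normalized)."""
    x = np.asarray(x, dtype=float)
    wv = _as_weights(w)
    if len(x) != len(wv):
        raise MapelError(f"length mismatch: {len(x)} responses vs {len(wv)} weights")
    return float(wv @ x)


def weighted_sd(x: np.ndarray, w: PrevalenceWeights | np.ndarray, n_vps: int) -> float:
    """Prevalence-weighted SD sqrt(N * sum_i w_i (x_i - x_bar)^2 / (N - 1))."""
    if n_vps < 2:
        raise MapelError("weighted SD requires at least 2 VPs")
    x = np.asarray(x, dtype=float)
    wv = _as_weights(w)
    if len(x) != len(wv):
        raise MapelError(f"length mismatch: {len(x)} responses vs {len(wv)} weights")
    xbar = float(wv @ x)
    var = n_vps * float(wv @ (x - xbar) ** 2) / (n_vps - 1)
    return float(np.sqrt(max(var, 0.0)))


def bin_fractions(
    x: np.ndarray,
    w: PrevalenceWeights | np.ndarray,
    bins: Sequence[TrialBin],
    clip: bool = True,
) -> np.ndarray:
    """Total prevalence weight falling in each response bin.

    Bins are half-open [lo, hi); the lowest/highest bins are extended to
    -inf/+inf when ``clip`` is true. In strict mode (``clip=False``) a
    response outside every bin raises :class:`CoverageError` naming the VP.
    """
    x = np.asarray(x, dtype=float)
    wv = _as_weights(w)
    if len(bins) < 1:
        raise MapelError("at least one bin required")
    lows = np.array([b.lo for b in bins])
    highs = np.array([b.hi for b in bins])
    if np.any(lows[1:] < highs[:-1]) and np.any(lows[1:] != highs[:-1]):
        raise MapelError("bins must be ordered and non-overlapping")
    # contiguity assumed (target validation enforces ordering); assign by lower edge
    edges = lows[1:]
    idx = np.searchsorted(edges, x, side="right")
    if not clip:
        below = x < lows[0]
        above = x >= highs[-1]
        if below.any() or above.any():
            bad = int(np.nonzero(below | above)[0][0])
            raise CoverageError(f"response {x[bad]} of VP index {bad} outside all bins")
    frac = np.zeros(len(bins))
    np.add.at(frac, idx, wv)
    return frac


def trial_stats_from_bins(target: TrialTarget) -> tuple[float, float]:
    """Mean and SD of a reported binned trial distribution via bin midpoints."""
    return target.stats_from_bins()


@dataclass
class PopulationStats:
    """Weighted mean, SD, and bin fractions for one therapy at one timepoint."""

    therapy: str
    months: float
    mean: float
    sd: float
    fractions: np.ndarray
    bin_labels: list[str]

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if abs(float(self.fractions.sum()) - 1.0) > 1e-12:
            raise MapelError("bin fractions must sum to 1")
        if self.sd < 0:
            raise MapelError("weighted SD must be non-negative")


def population_stats(
    x: np.ndarray,
    w: PrevalenceWeights | np.ndarray,
    target: TrialTarget,
    n_vps: int | None = None,
    clip: bool = True,
) -> PopulationStats:
    """Weighted mean/SD/bin fractions of responses x against a target's bins."""
    wv = _as_weights(w)
    n = len(wv) if n_vps is None else n_vps
    return PopulationStats(
        therapy=target.therapy,
        months=target.months,
        mean=weighted_mean(x, wv),
        sd=weighted_sd(x, wv, n),
        fractions=bin_fractions(x, wv, target.bins, clip=clip) if target.bins else np.ones(1),
        bin_labels=[b.label for b in target.bins] if target.bins else ["all"],
    )


def write_population_stats(stats: Sequence[PopulationStats], path: str | Path) -> None:
    """Long-format CSV: therapy, months, mean, sd, bin_label, fraction."""
    rows = []
    for s in stats:
        for label, frac in zip(s.bin_labels, s.fractions):
            rows.append(
                {
                    "therapy": s.therapy,
                    "months": s.months,
                    "mean": s.mean,
                    "sd": s.sd,
                    "bin_label": label,
                    "fraction": frac,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
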