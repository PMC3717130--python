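"""Cohort and trial-target data model, file dialects, and median axis binning.

A *cohort* is a table of virtual patients (VPs): each row carries the VP's
mechanistic-axis coefficients, its simulated ACR-N responses (percent
improvement) for each therapy and sample time, and optionally a panel of
baseline synovial mediator concentrations. A *trial target* summarizes one
published therapy arm: patient count, binned ACR response counts with bin
midpoints, and (directly reported or derived) mean and standard deviation.

Canonical file dialect is CSV with a header row:

* cohort — ``vp_id``, ``axis:<name>`` per axis, ``resp:<therapy>:<months>``
  per therapy/time, optional ``med:<analyte>`` per mediator;
* targets — long format, one row per bin: ``therapy, months, n_trial,
  bin_label, bin_lo, bin_hi, bin_mid, count`` with optional ``mean, sd``.

Targets may equivalently be given as YAML/JSON records with the same fields.
Column roles are resolved case-insensitively, and a :class:`CohortSchema`
can remap arbitrary column layouts onto the roles.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import (
    CohortParseError,
    CohortValidationError,
    DegenerateAxisError,
    SchemaError,
    TargetConsistencyError,
    TargetValidationError,
)

__all__ = [
    "TrialBin",
    "TrialTarget",
    "Cohort",
    "CohortSchema",
    "AxisBinning",
    "DEFAULT_ACR_BINS",
    "default_acr_bins",
    "compute_axis_binning",
    "read_cohort",
    "write_cohort",
    "read_targets",
    "write_targets",
    "read_config",
]

LOWER = "lower"
UPPER = "upper"


@dataclass(frozen=True)
class TrialBin:
    """One ACR response bin: half-open interval [lo, hi) with a representative midpoint."""

    label: str
    lo: float
    hi: float
    mid: float
    count: int = 0


#: Default ACR-N response bins. The 20-50 midpoint of 35 follows the standard
#: convention for trial calibration; the open edge bins use 10 and 85.
DEFAULT_ACR_BINS: tuple[tuple[str, float, float, float], ...] = (
    ("<20", -math.inf, 20.0, 10.0),
    ("20-50", 20.0, 50.0, 35.0),
    ("50-70", 50.0, 70.0, 60.0),
    (">=70", 70.0, math.inf, 85.0),
)


def default_acr_bins(counts: Sequence[int] | None = None) -> list[TrialBin]:
    """Build the default ACR bin list, optionally attaching per-bin counts."""
    if counts is None:
        counts = [0] * len(DEFAULT_ACR_BINS)
    if len(counts) != len(DEFAULT_ACR_BINS):
        raise TargetValidationError(
            f"expected {len(DEFAULT_ACR_BINS)} counts, got {len(counts)}"
        )
    return [
        TrialBin(label, lo, hi, mid, int(c))
        for (label, lo, hi, mid), c in zip(DEFAULT_ACR_BINS, counts)
    ]


@dataclass
class TrialTarget:
    """Published statistics for one therapy arm at one sample time.

    ``bins`` may be empty when only mean/SD are reported; conversely, when the
    mean/SD are absent but bins are present they are filled from the binned
    distribution (midpoint formulas)::

        mean = (1/N_T) * sum_b c_b * n_b
        sd   = sqrt( sum_b n_b * (c_b - mean)^2 / (N_T - 1) )
    """

    therapy: str
    months: float
    n_trial: int
    bins: list[TrialBin] = field(default_factory=list)
    mean: float | None = None
    sd: float | None = None

    def __post_init__(self) -> None:
        self.validate()
        if (self.mean is None or self.sd is None) and self.bins:
            m, s = self.stats_from_bins()
            if self.mean is None:
                self.mean = m
            if self.sd is None:
                self.sd = s

    def validate(self) -> None:
        if self.n_trial < 2:
            raise TargetValidationError(
                f"target {self.therapy}@{self.months}m: n_trial must be >= 2"
            )
        if not self.bins:
            if self.mean is None or self.sd is None:
                raise TargetValidationError(
                    f"target {self.therapy}@{self.months}m: needs bins and/or mean+sd"
                )
            return
        total = sum(b.count for b in self.bins)
        if total != self.n_trial:
            raise TargetConsistencyError(
                f"target {self.therapy}@{self.months}m: bin counts sum to {total}, "
                f"but n_trial = {self.n_trial}"
            )
        for b in self.bins:
            if b.count < 0:
                raise TargetValidationError(f"bin {b.label}: negative count")
            if not (b.lo <= b.mid <= b.hi):
                raise TargetValidationError(
                    f"bin {b.label}: midpoint {b.mid} outside [{b.lo}, {b.hi}]"
                )
        for prev, nxt in zip(self.bins, self.bins[1:]):
            if nxt.lo < prev.hi:
                raise TargetValidationError(
                    f"bins {prev.label} and {nxt.label} overlap or are out of order"
                )

    def stats_from_bins(self) -> tuple[float, float]:
        """Mean and SD of the binned trial distribution via bin midpoints."""
        if not self.bins:
            raise TargetValidationError("no bins from which to compute statistics")
        counts = np.array([b.count for b in self.bins], dtype=float)
        mids = np.array([b.mid for b in self.bins], dtype=float)
        n = float(self.n_trial)
        mean = float(counts @ mids / n)
        sd = float(math.sqrt(float(counts @ (mids - mean) ** 2) / (n - 1.0)))
        return mean, sd

    @property
    def key(self) -> tuple[str, float]:
        return (self.therapy, self.months)


@dataclass
class Cohort:
    """Virtual-patient cohort: axis coefficients, per-therapy responses, mediators.

    ``axes`` is an (N x M) frame indexed by vp_id; ``responses`` has a
    two-level column index (therapy, months); ``mediators`` is optional,
    one column per analyte (baseline concentrations).
    """

    axes: pd.DataFrame
    responses: pd.DataFrame
    mediators: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- structural invariants -------------------------------------------------
    def validate(self) -> None:
        idx = self.axes.index
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise CohortValidationError(f"duplicate vp_id(s): {dups}")
        if len(idx) < 2:
            raise CohortValidationError("cohort must contain at least 2 VPs")
        if self.axes.shape[1] < 1:
            raise CohortValidationError("cohort must have at least one axis")
        if self.axes.isna().any().any():
            bad = self.axes.columns[self.axes.isna().any()].tolist()
            raise CohortValidationError(f"missing axis values in columns: {bad}")
        if not self.responses.index.equals(idx):
            raise CohortValidationError("responses index does not match axes index")
        if self.responses.isna().any().any():
            bad = [c for c in self.responses.columns if self.responses[c].isna().any()]
            raise CohortValidationError(f"missing response values in columns: {bad}")
        if self.mediators is not None and not self.mediators.index.equals(idx):
            raise CohortValidationError("mediators index does not match axes index")

    @property
    def vp_ids(self) -> list[str]:
        return list(self.axes.index)

    @property
    def n_vps(self) -> int:
        return self.axes.shape[0]

    @property
    def n_axes(self) -> int:
        return self.axes.shape[1]

    @property
    def axis_names(self) -> list[str]:
        return list(self.axes.columns)

    @property
    def response_keys(self) -> list[tuple[str, float]]:
        return list(self.responses.columns)

    def response_vector(self, therapy: str, months: float) -> np.ndarray:
        try:
            return self.responses[(therapy, float(months))].to_numpy(dtype=float)
        except KeyError as exc:
            raise SchemaError(
                f"cohort has no responses for therapy {therapy!r} at {months} months"
            ) from exc


@dataclass
class CohortSchema:
    """Column-role mapping for cohort files that do not follow the prefix dialect.

    Any mapping left ``None`` falls back to the prefix convention
    (``vp_id`` / ``axis:`` / ``resp:<therapy>:<months>`` / ``med:``),
    matched case-insensitively.
    """

    vp_id: str = "vp_id"
    axes: Mapping[str, str] | None = None  # column -> axis name
    responses: Mapping[str, tuple[str, float]] | None = None  # column -> (therapy, months)
    mediators: Mapping[str, str] | None = None  # column -> analyte name


@dataclass
class AxisBinning:
    """Per-axis median split of the cohort.

    ``cutpoints`` holds the empirical median of each axis. A VP belongs to the
    LOWER bin when its coefficient is <= the cutpoint (half-open intervals
    (-inf, med] / (med, inf)); ``upper`` is the boolean (N x M) membership of
    the upper bin. Assignments are reproducible from the cutpoints alone.
    """

    cutpoints: pd.Series
    upper: pd.DataFrame

    @property
    def axis_names(self) -> list[str]:
        return list(self.upper.columns)

    def counts(self) -> pd.DataFrame:
        up = self.upper.sum(axis=0)
        return pd.DataFrame({"upper": up, "lower": self.upper.shape[0] - up})


def compute_axis_binning(cohort: Cohort) -> AxisBinning:
    """Split every axis at its empirical median (values <= median go LOWER).

    Raises :class:`DegenerateAxisError` when an axis is constant (or its
    maximum equals the median), which would leave the upper bin empty.
    """
    med = cohort.axes.median(axis=0)
    upper = cohort.axes.gt(med, axis=1)
    n_up = upper.sum(axis=0)
    empty = n_up[(n_up == 0) | (n_up == cohort.n_vps)].index.tolist()
    if empty:
        raise DegenerateAxisError(
            f"axis/axes {empty} cannot be median-split: one bin would be empty"
        )
    return AxisBinning(cutpoints=med, upper=upper)


# ---------------------------------------------------------------------------
# Cohort file I/O
# ---------------------------------------------------------------------------

def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        return pd.read_excel(path)  # requires openpyxl (the "excel" extra)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep)


def _resolve_roles(
    columns: Sequence[str], schema: CohortSchema
) -> tuple[str, dict[str, str], dict[str, tuple[str, float]], dict[str, str]]:
    lower_map: dict[str, str] = {}
    for c in columns:
        key = str(c).strip().lower()
        if key in lower_map:
            raise SchemaError(f"duplicate column (case-insensitively): {c!r}")
        lower_map[key] = c

    def find(name: str) -> str | None:
        return lower_map.get(name.strip().lower())

    id_col = find(schema.vp_id)
    if id_col is None:
        raise SchemaError(f"missing vp_id column {schema.vp_id!r}")

    axes: dict[str, str] = {}
    resps: dict[str, tuple[str, float]] = {}
    meds: dict[str, str] = {}

    if schema.axes is not None:
        for col, axis in schema.axes.items():
            real = find(col)
            if real is None:
                raise SchemaError(f"missing axis column {col!r}")
            axes[real] = axis
    if schema.responses is not None:
        for col, (therapy, months) in schema.responses.items():
            real = find(col)
            if real is None:
                raise SchemaError(f"missing response column {col!r}")
            resps[real] = (therapy, float(months))
    if schema.mediators is not None:
        for col, analyte in schema.mediators.items():
            real = find(col)
            if real is None:
                raise SchemaError(f"missing mediator column {col!r}")
            meds[real] = analyte

    for c in columns:
        if c == id_col or c in axes or c in resps or c in meds:
            continue
        key = str(c).strip()
        low = key.lower()
        if schema.axes is None and low.startswith("axis:"):
            axes[c] = key.split(":", 1)[1]
        elif schema.responses is None and low.startswith("resp:"):
            parts = key.split(":")
            if len(parts) != 3:
                raise SchemaError(
                    f"response column {c!r} must look like resp:<therapy>:<months>"
                )
            try:
                months = float(parts[2])
            except ValueError as exc:
                raise SchemaError(f"response column {c!r}: bad months {parts[2]!r}") from exc
            resps[c] = (parts[1], months)
        elif schema.mediators is None and low.startswith("med:"):
            meds[c] = key.split(":", 1)[1]

    if not axes:
        raise SchemaError("no axis columns found")
    if not resps:
        raise SchemaError("no response columns found")
    return id_col, axes, resps, meds


def _numeric(frame: pd.DataFrame, kind: str, ids: pd.Index) -> pd.DataFrame:
    out = frame.apply(pd.to_numeric, errors="coerce")
    bad = out.isna() & ~frame.isna()
    if bad.any().any():
        rows, cols = np.nonzero(bad.to_numpy())
        vp = ids[rows[0]]
        col = frame.columns[cols[0]]
        raise CohortParseError(
            f"non-numeric {kind} value at vp_id {vp!r}, column {col!r}: "
            f"{frame.iloc[rows[0], cols[0]]!r}"
        )
    return out


def read_cohort(path: str | Path, schema: CohortSchema | None = None) -> Cohort:
    """Read and validate a VP cohort table (CSV/TSV, or .xlsx with the excel extra)."""
    schema = schema or CohortSchema()
    raw = _read_table(path)
    id_col, axes_map, resp_map, med_map = _resolve_roles(list(raw.columns), schema)

    ids = pd.Index(raw[id_col].astype(str), name="vp_id")
    if ids.has_duplicates:
        dups = ids[ids.duplicated()].unique().tolist()
        raise CohortValidationError(f"duplicate vp_id(s): {dups}")

    axes = _numeric(raw[list(axes_map)], "axis", ids)
    axes.columns = [axes_map[c] for c in axes.columns]
    axes.index = ids

    resp = _numeric(raw[list(resp_map)], "response", ids)
    resp.columns = pd.MultiIndex.from_tuples(
        [resp_map[c] for c in resp.columns], names=["therapy", "months"]
    )
    resp.index = ids
    if resp.isna().any().any():
        bad = [c for c in resp.columns if resp[c].isna().any()]
        raise CohortValidationError(f"missing response values in columns: {bad}")

    mediators = None
    if med_map:
        mediators = _numeric(raw[list(med_map)], "mediator", ids)
        mediators.columns = [med_map[c] for c in mediators.columns]
        mediators.index = ids

    return Cohort(axes=axes, responses=resp, mediators=mediators)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort in the canonical prefix dialect (round-trips read_cohort)."""
    out = pd.DataFrame(index=cohort.axes.index)
    for name in cohort.axis_names:
        out[f"axis:{name}"] = cohort.axes[name]
    for therapy, months in cohort.response_keys:
        months_txt = f"{months:g}"
        out[f"resp:{therapy}:{months_txt}"] = cohort.responses[(therapy, months)]
    if cohort.mediators is not None:
        for name in cohort.mediators.columns:
            out[f"med:{name}"] = cohort.mediators[name]
    out.index.name = "vp_id"
    sep = "\t" if Path(path).suffix.lower() in (".tsv", ".tab") else ","
    out.to_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# Target file I/O
# ---------------------------------------------------------------------------

_TARGET_COLS = ["therapy", "months", "n_trial", "bin_label", "bin_lo", "bin_hi", "bin_mid", "count"]


def _targets_from_records(records: Sequence[Mapping]) -> list[TrialTarget]:
    targets = []
    for rec in records:
        bins = [
            TrialBin(
                label=str(b["label"]),
                lo=float(b.get("lo", -math.inf)),
                hi=float(b.get("hi", math.inf)),
                mid=float(b["mid"]),
                count=int(b["count"]),
            )
            for b in rec.get("bins", [])
        ]
        targets.append(
            TrialTarget(
                therapy=str(rec["therapy"]),
                months=float(rec["months"]),
                n_trial=int(rec["n_trial"]),
                bins=bins,
                mean=None if rec.get("mean") is None else float(rec["mean"]),
                sd=None if rec.get("sd") is None else float(rec["sd"]),
            )
        )
    return targets


def read_targets(path: str | Path) -> list[TrialTarget]:
    """Read trial targets from long-format CSV or from a YAML/JSON record list."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".yaml", ".yml", ".json"):
        with open(path) as fh:
            data = json.load(fh) if suffix == ".json" else yaml.safe_load(fh)
        if isinstance(data, Mapping) and "targets" in data:
            data = data["targets"]
        return _targets_from_records(data)

    frame = pd.read_csv(path)
    cols = {str(c).strip().lower(): c for c in frame.columns}
    missing = [c for c in _TARGET_COLS if c not in cols]
    if missing:
        raise SchemaError(f"target file missing column(s): {missing}")
    targets = []
    for (therapy, months), grp in frame.groupby(
        [cols["therapy"], cols["months"]], sort=False
    ):
        n_trial = grp[cols["n_trial"]].unique()
        if len(n_trial) != 1:
            raise TargetConsistencyError(
                f"target {therapy}@{months}m: inconsistent n_trial values {n_trial}"
            )
        bins = [
            TrialBin(
                label=str(row[cols["bin_label"]]),
                lo=float(row[cols["bin_lo"]]),
                hi=float(row[cols["bin_hi"]]),
                mid=float(row[cols["bin_mid"]]),
                count=int(row[cols["count"]]),
            )
            for _, row in grp.iterrows()
        ]
        mean = sd = None
        if "mean" in cols and grp[cols["mean"]].notna().any():
            mean = float(grp[cols["mean"]].iloc[0])
        if "sd" in cols and grp[cols["sd"]].notna().any():
            sd = float(grp[cols["sd"]].iloc[0])
        targets.append(
            TrialTarget(
                therapy=str(therapy),
                months=float(months),
                n_trial=int(n_trial[0]),
                bins=bins,
                mean=mean,
                sd=sd,
            )
        )
    return targets


def write_targets(targets: Sequence[TrialTarget], path: str | Path) -> None:
    """Write targets in the long CSV dialect (round-trips read_targets)."""
    rows = []
    for t in targets:
        for b in t.bins:
            rows.append(
                {
                    "therapy": t.therapy,
                    "months": t.months,
                    "n_trial": t.n_trial,
                    "bin_label": b.label,
                    "bin_lo": b.lo,
                    "bin_hi": b.hi,
                    "bin_mid": b.mid,
                    "count": b.count,
                    "mean": t.mean,
                    "sd": t.sd,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_config(path: str | Path) -> dict:
    """Read a run-configuration mapping from YAML or JSON."""
    path = Path(path)
    with open(path) as fh:
        if path.suffix.lower() == ".json":
            return json.load(fh)
        return yaml.safe_load(fh)
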