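"""Per-frame production-count traces and population-level summaries.

A :class:`LineageTrace` is one cell lineage followed through divisions:
ordered frames of (time, cro_count, ci_count, cell age, division flag),
optionally with the generator's hidden state as ground truth. Frames carry
a ``segment_id`` so that frame-removal filters (e.g. the young-cell filter)
can mark chain breaks that downstream dwell/HMM analysis must not bridge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TRACE_COLUMNS = [
    "lineage_id",
    "frame",
    "time_min",
    "cell_id",
    "cell_age",
    "division_flag",
    "cro_count",
    "ci_count",
]

CLASS_CI_ONLY = "ci_only"
CLASS_CRO_ONLY = "cro_only"
CLASS_BOTH = "both"
CLASS_LOW_LOW = "low_low"
CLASSES = (CLASS_CI_ONLY, CLASS_CRO_ONLY, CLASS_BOTH, CLASS_LOW_LOW)


@dataclass
class LineageTrace:
    lineage_id: str
    frame_interval: float
    time_min: np.ndarray
    cro: np.ndarray
    ci: np.ndarray
    cell_age: np.ndarray
    division_flag: np.ndarray
    cell_id: np.ndarray | None = None
    segment_id: np.ndarray | None = None
    true_state: np.ndarray | None = None

    def __post_init__(self):
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.cro = np.asarray(self.cro, dtype=np.int64)
        self.ci = np.asarray(self.ci, dtype=np.int64)
        self.cell_age = np.asarray(self.cell_age, dtype=float)
        self.division_flag = np.asarray(self.division_flag, dtype=bool)
        if self.cell_id is None:
            self.cell_id = np.zeros(len(self.time_min), dtype=np.int64)
        else:
            self.cell_id = np.asarray(self.cell_id, dtype=np.int64)
        if self.segment_id is None:
            self.segment_id = np.zeros(len(self.time_min), dtype=np.int64)
        else:
            self.segment_id = np.asarray(self.segment_id, dtype=np.int64)
        if self.true_state is not None:
            self.true_state = np.asarray(self.true_state, dtype=np.int64)
        self.validate()

    def validate(self) -> None:
        n = len(self.time_min)
        if n < 1:
            raise ValueError("trace must contain at least one frame")
        for name in ("cro", "ci", "cell_age", "division_flag", "cell_id", "segment_id"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length mismatch")
        if np.any(self.cro < 0) or np.any(self.ci < 0):
            raise ValueError("counts must be non-negative")
        if np.any(self.cell_age < 0) or np.any(self.cell_age > 1 + 1e-9):
            raise ValueError("cell_age must lie in [0, 1]")
        # times strictly increasing within segments, step = frame_interval
        for seg in np.unique(self.segment_id):
            t = self.time_min[self.segment_id == seg]
            if len(t) > 1 and not np.allclose(
                np.diff(t), self.frame_interval, atol=1e-6
            ):
                raise ValueError(
                    f"times within segment {seg} must advance by frame_interval"
                )

    def __len__(self) -> int:
        return len(self.time_min)

    @property
    def counts(self) -> np.ndarray:
        """(n_frames, 2) integer array of (cro, ci) counts."""
        return np.column_stack([self.cro, self.ci])

    def segments(self) -> list[np.ndarray]:
        """Index arrays of contiguous frame runs (chain-break aware)."""
        out = []
        for seg in np.unique(self.segment_id):
            out.append(np.flatnonzero(self.segment_id == seg))
        return out

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "lineage_id": self.lineage_id,
                "frame": np.round(self.time_min / self.frame_interval).astype(int),
                "time_min": self.time_min,
                "cell_id": self.cell_id,
                "cell_age": self.cell_age,
                "division_flag": self.division_flag.astype(int),
                "cro_count": self.cro,
                "ci_count": self.ci,
                "segment_id": self.segment_id,
            }
        )
        if self.true_state is not None:
            df["true_state"] = self.true_state
        return df


def total_frames(traces: list[LineageTrace]) -> int:
    return int(sum(len(t) for t in traces))


# ---------------------------------------------------------------------------
# TSV I/O (format shared with the generator)
# ---------------------------------------------------------------------------

def write_traces(traces: list[LineageTrace], path) -> None:
    if traces:
        df = pd.concat([t.to_frame() for t in traces], ignore_index=True)
    else:
        df = pd.DataFrame(columns=TRACE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_traces(path, frame_interval: float = 5.0) -> list[LineageTrace]:
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        return []
    return assemble_traces(df, frame_interval=frame_interval, select_per_colony=False)


# ---------------------------------------------------------------------------
# Trace assembly and filters
# ---------------------------------------------------------------------------

def assemble_traces(
    table: pd.DataFrame,
    frame_interval: float = 5.0,
    seed: int = 0,
    colony_col: str = "colony_id",
    select_per_colony: bool = True,
) -> list[LineageTrace]:
    """Build LineageTraces from a per-frame count table.

    When the table carries colony identifiers and ``select_per_colony`` is
    set, exactly one lineage per colony is retained by a seeded uniform
    choice (avoids double-counting sister lineages). Lineages with missing
    frames are dropped with a log entry.
    """
    if table.empty:
        return []
    table = table.copy()
    if colony_col not in table.columns:
        table[colony_col] = table["lineage_id"]
    rng = np.random.default_rng(seed)

    keep_ids = []
    for colony, sub in table.groupby(colony_col, sort=True):
        lineages = sorted(sub["lineage_id"].unique())
        if select_per_colony and len(lineages) > 1:
            keep_ids.append(lineages[rng.integers(len(lineages))])
        else:
            keep_ids.extend(lineages)

    out = []
    for lid in keep_ids:
        sub = table[table["lineage_id"] == lid].sort_values("frame")
        frames = sub["frame"].to_numpy()
        if len(frames) == 0:
            continue
        if np.any(np.diff(frames) != 1):
            logger.warning("lineage %s has missing frames; dropped", lid)
            continue
        seg = (
            sub["segment_id"].to_numpy()
            if "segment_id" in sub.columns
            else np.zeros(len(sub), dtype=int)
        )
        out.append(
            LineageTrace(
                lineage_id=str(lid),
                frame_interval=frame_interval,
                time_min=sub["time_min"].to_numpy(),
                cro=sub["cro_count"].to_numpy(),
                ci=sub["ci_count"].to_numpy(),
                cell_age=sub["cell_age"].to_numpy(),
                division_flag=sub["division_flag"].to_numpy().astype(bool),
                cell_id=sub["cell_id"].to_numpy()
                if "cell_id" in sub.columns
                else None,
                segment_id=seg,
                true_state=sub["true_state"].to_numpy()
                if "true_state" in sub.columns
                else None,
            )
        )
    return out


def filter_young_cells(
    traces: list[LineageTrace], age_cutoff: float = 0.4
) -> list[LineageTrace]:
    """Keep only frames with cell age <= cutoff.

    Removed frames introduce chain breaks: surviving runs are renumbered
    into fresh segment ids so dwell/HMM analysis never bridges a gap.
    """
    out = []
    for tr in traces:
        mask = tr.cell_age <= age_cutoff + 1e-12
        if not mask.any():
            continue
        idx = np.flatnonzero(mask)
        # new segment wherever the previous surviving frame is not adjacent
        # or belonged to a different original segment
        breaks = np.ones(len(idx), dtype=bool)
        breaks[1:] = (np.diff(idx) != 1) | (
            np.diff(tr.segment_id[idx]) != 0
        )
        seg = np.cumsum(breaks) - 1
        out.append(
            LineageTrace(
                lineage_id=tr.lineage_id,
                frame_interval=tr.frame_interval,
                time_min=tr.time_min[idx],
                cro=tr.cro[idx],
                ci=tr.ci[idx],
                cell_age=tr.cell_age[idx],
                division_flag=tr.division_flag[idx],
                cell_id=tr.cell_id[idx],
                segment_id=seg,
                true_state=None if tr.true_state is None else tr.true_state[idx],
            )
        )
    return out


# ---------------------------------------------------------------------------
# Steady-state population classification
# ---------------------------------------------------------------------------

def classify_population(
    ci_total: int,
    cro_total: int,
    r_hi: float = 0.8,
    r_lo: float = 0.2,
    low_total: int = 2,
) -> str:
    """Classify one cell by the copy-number ratio r = CI / (CI + Cro).

    Cells with total copies below ``low_total`` (or exactly zero total) are
    the low-low class; otherwise r >= r_hi is CI-only, r <= r_lo is
    Cro-only, and intermediate ratios are 'both'.
    """
    if ci_total < 0 or cro_total < 0:
        raise ValueError("counts must be non-negative")
    total = ci_total + cro_total
    if total == 0 or total < low_total:
        return CLASS_LOW_LOW
    r = ci_total / total
    if r >= r_hi:
        return CLASS_CI_ONLY
    if r <= r_lo:
        return CLASS_CRO_ONLY
    return CLASS_BOTH


@dataclass
class PopulationSummary:
    percentages: dict
    standard_errors: dict
    n_cells: int
    thresholds: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class": list(self.percentages),
                "percent": [self.percentages[c] for c in self.percentages],
                "se_percent": [self.standard_errors[c] for c in self.percentages],
            }
        )


def population_percentages(
    snapshot: pd.DataFrame,
    r_hi: float = 0.8,
    r_lo: float = 0.2,
    low_total: int = 2,
) -> PopulationSummary:
    """Class percentages (with binomial standard errors) for a snapshot
    table with columns ``ci_total`` and ``cro_total``."""
    if len(snapshot) < 1:
        raise ValueError("snapshot table must contain at least one cell")
    labels = [
        classify_population(ci, cro, r_hi=r_hi, r_lo=r_lo, low_total=low_total)
        for ci, cro in zip(snapshot["ci_total"], snapshot["cro_total"])
    ]
    n = len(labels)
    pct, se = {}, {}
    for c in CLASSES:
        p = sum(1 for x in labels if x == c) / n
        pct[c] = 100.0 * p
        se[c] = 100.0 * float(np.sqrt(p * (1 - p) / n))
    return PopulationSummary(
        percentages=pct,
        standard_errors=se,
        n_cells=n,
        thresholds={"r_hi": r_hi, "r_lo": r_lo, "low_total": low_total},
    )


# ---------------------------------------------------------------------------
# mRNA co-expression summary
# ---------------------------------------------------------------------------

@dataclass
class CoexpressionSummary:
    fraction_both: float
    fraction_both_se: float
    mean_a: float
    mean_a_se: float
    mean_b: float
    mean_b_se: float
    n_cells: int


def coexpression_summary(counts) -> CoexpressionSummary:
    """Fraction of cells with >= 1 molecule of both species, plus per-species
    means, from an (n, 2) integer count table."""
    arr = np.asarray(counts, dtype=float)
    if arr.size == 0:
        raise ValueError("empty input")
    arr = np.atleast_2d(arr)
    if arr.shape[1] != 2:
        raise ValueError("counts must be (n, 2)")
    n = arr.shape[0]
    both = np.mean((arr[:, 0] >= 1) & (arr[:, 1] >= 1))
    return CoexpressionSummary(
        fraction_both=float(both),
        fraction_both_se=float(np.sqrt(both * (1 - both) / n)),
        mean_a=float(arr[:, 0].mean()),
        mean_a_se=float(arr[:, 0].std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        mean_b=float(arr[:, 1].mean()),
        mean_b_se=float(arr[:, 1].std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        n_cells=n,
    )
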