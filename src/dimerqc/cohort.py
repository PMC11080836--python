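"""Cross-sample read-loss analysis.

Samples are ordered by increasing read-loss percentage and the loss-vs-rank
profile is fit by exhaustive piecewise ordinary least squares; BIC picks the
number of segments.  A cohort splitting into a shallow segment and a steep
one is the signature of a contaminated subgroup.  Loss is also decomposed
per sample into its dimer / short-read / low-quality components, and read
loss can be correlated (Spearman) against RNA input amount.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CohortTable",
    "Segmentation",
    "SegmentFit",
    "segment_by_read_loss",
    "decompose_loss",
    "loss_vs_input_correlation",
]

_PCT_COLS = ["pct_read_loss", "pct_dimer", "pct_short", "pct_lowq"]


@dataclass
class CohortTable:
    """Per-sample loss percentages, optionally with RNA input in ng."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"sample_id", *_PCT_COLS} - set(self.frame.columns)
        if missing:
            raise ValueError(f"cohort table missing columns: {sorted(missing)}")
        if self.frame["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids")
        for col in _PCT_COLS:
            vals = self.frame[col]
            if ((vals < 0) | (vals > 100)).any():
                raise ValueError(f"{col} outside [0, 100]")

    @staticmethod
    def from_sample_qcs(qcs: list) -> "CohortTable":
        rows = [
            {
                "sample_id": qc.sample_id,
                "pct_read_loss": qc.pct_read_loss,
                "pct_dimer": qc.pct_dimer,
                "pct_short": qc.pct_short,
                "pct_lowq": qc.pct_lowq,
            }
            for qc in qcs
        ]
        return CohortTable(pd.DataFrame(rows))

    @staticmethod
    def from_tsv(path: str | Path) -> "CohortTable":
        return CohortTable(pd.read_csv(path, sep="\t"))

    def with_rna_input(self, inputs: dict[str, float]) -> "CohortTable":
        frame = self.frame.copy()
        frame["rna_input_ng"] = frame["sample_id"].map(inputs)
        return CohortTable(frame)

    def __len__(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class SegmentFit:
    """OLS fit of loss on rank over one contiguous run of ordered samples."""

    start: int  # 0-based index into the order, inclusive
    stop: int  # exclusive
    slope: float  # % loss per rank
    intercept: float
    r_squared: float


@dataclass
class Segmentation:
    """Piecewise-linear grouping of samples ordered by read loss."""

    order: list[str]
    breakpoints: list[int]  # 0-based start index of each segment after the first
    segments: list[SegmentFit]
    bic: float


def _segment_stats(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """(slope, intercept, rss, r_squared) of OLS y ~ x."""
    n = len(x)
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    sxy = float(((x - xm) * (y - ym)).sum())
    syy = float(((y - ym) ** 2).sum())
    slope = sxy / sxx
    rss = max(syy - sxy**2 / sxx, 0.0)
    r2 = 1.0 if syy < 1e-12 else 1.0 - rss / syy
    return slope, ym - slope * xm, rss, r2


def segment_by_read_loss(
    table: CohortTable, max_segments: int = 3, min_segment_size: int = 3
) -> Segmentation:
    """Exhaustive piecewise-OLS of loss on rank with BIC model selection.

    Samples are sorted by ascending ``pct_read_loss`` (ranks 1..n are the
    regressor).  Every placement of 0..max_segments-1 breakpoints with at
    least ``min_segment_size`` samples per segment is fit; the model
    minimizing ``n*ln(RSS/n) + k*ln(n)`` with ``k = 2*segments +
    (segments-1)`` wins, ties going to fewer segments.  Cohorts smaller
    than 6 samples are returned as a single segment.
    """
    if len(table) < 2:
        raise ValueError("segmentation needs at least 2 samples")
    frame = table.frame.sort_values(
        ["pct_read_loss", "sample_id"], kind="mergesort"
    ).reset_index(drop=True)
    order = list(frame["sample_id"])
    y = frame["pct_read_loss"].to_numpy(dtype=float)
    n = len(y)
    x = np.arange(1, n + 1, dtype=float)

    def fit(breaks: tuple[int, ...]) -> tuple[float, list[SegmentFit]]:
        bounds = [0, *breaks, n]
        segs = []
        rss_total = 0.0
        for a, b in itertools.pairwise(bounds):
            slope, intercept, rss, r2 = _segment_stats(x[a:b], y[a:b])
            segs.append(SegmentFit(a, b, slope, intercept, r2))
            rss_total += rss
        nseg = len(segs)
        k = 2 * nseg + (nseg - 1)
        bic = n * math.log(max(rss_total, n * 1e-12) / n) + k * math.log(n)
        return bic, segs

    best_bic, best_segs = fit(())
    best_breaks: tuple[int, ...] = ()
    if n >= 6:
        for nseg in range(2, max_segments + 1):
            if nseg * min_segment_size > n:
                break
            positions = range(min_segment_size, n - min_segment_size + 1)
            for breaks in itertools.combinations(positions, nseg - 1):
                if any(
                    b2 - b1 < min_segment_size
                    for b1, b2 in itertools.pairwise(breaks)
                ):
                    continue
                bic, segs = fit(breaks)
                if bic < best_bic - 1e-12:
                    best_bic, best_segs, best_breaks = bic, segs, breaks
    return Segmentation(
        order=order,
        breakpoints=list(best_breaks),
        segments=best_segs,
        bic=best_bic,
    )


def decompose_loss(table: CohortTable, tolerance: float = 0.1) -> pd.DataFrame:
    """Per-sample fractions of total loss by cause, plus the dominant cause.

    Fractions of ``pct_read_loss`` attributable to dimers, short reads and
    low quality; the dominant cause is the argmax (NONE for zero-loss
    samples, whose fractions are NaN).  Raises when the three components do
    not sum to the total within ``tolerance`` points, listing offenders.
    """
    frame = table.frame
    resid = (
        frame["pct_dimer"] + frame["pct_short"] + frame["pct_lowq"]
        - frame["pct_read_loss"]
    ).abs()
    bad = frame.loc[resid > tolerance, "sample_id"]
    if len(bad):
        raise ValueError(
            f"loss components do not sum to pct_read_loss for: {list(bad)}"
        )
    rows = []
    for _, r in frame.iterrows():
        loss = r["pct_read_loss"]
        if loss == 0:
            rows.append(
                (r["sample_id"], math.nan, math.nan, math.nan, "NONE")
            )
            continue
        fracs = {
            "DIMER": r["pct_dimer"] / loss,
            "SHORT": r["pct_short"] / loss,
            "LOW_QUALITY": r["pct_lowq"] / loss,
        }
        dominant = max(fracs, key=lambda c: (fracs[c], -list(fracs).index(c)))
        rows.append(
            (
                r["sample_id"],
                fracs["DIMER"],
                fracs["SHORT"],
                fracs["LOW_QUALITY"],
                dominant,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["sample_id", "frac_dimer", "frac_short", "frac_lowq", "dominant"],
    )


def loss_vs_input_correlation(table: CohortTable) -> tuple[float, float]:
    """Spearman correlation of RNA input with read loss.

    Exact permutation p-value for n <= 9 samples (full enumeration of
    rank permutations, two-sided), the large-sample approximation above.
    Constant input makes rho undefined: returns (nan, nan) with a warning.
    """
    frame = table.frame
    if "rna_input_ng" not in frame.columns:
        raise ValueError("cohort table has no rna_input_ng column")
    sub = frame.dropna(subset=["rna_input_ng"])
    if len(sub) < 5:
        raise ValueError("need >= 5 samples with rna_input_ng")
    x = sub["rna_input_ng"].to_numpy(dtype=float)
    y = sub["pct_read_loss"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input or loss; Spearman rho undefined")
        return (math.nan, math.nan)
    n = len(x)
    rho, p_approx = stats.spearmanr(x, y)
    if n > 9:
        return float(rho), float(p_approx)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    perms = np.array(list(itertools.permutations(rx)))
    rc = perms - perms.mean(axis=1, keepdims=True)
    yc = ry - ry.mean()
    rhos = (rc @ yc) / np.sqrt((rc**2).sum(axis=1) * (yc**2).sum())
    p_exact = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    return float(rho), p_exact
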