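"""Cohort-level statistics: paired comparisons, correlations, reliability.

The analysis pattern over a cohort of subjects measured before (T1) and
after (T2) surgery:

* paired t tests between Dev and N-Dev sides at each timepoint, and between
  T1 and T2, for each measurement;
* Pearson correlations between the similarity index and the
  non-overlapping volume (and the bilateral measurement differences);
* intraclass correlation for repeat-measurement reliability.

Because dice = 1 − NOV/(|A|+|B|) per subject, dice and NOV correlate at
exactly −1 over any cohort in which |A|+|B| is constant, and strongly
negatively whenever total volume varies little — the within-cohort analogue
of the strong negative correlations seen clinically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DegenerateVarianceError",
    "SubjectRecord",
    "PairedTResult",
    "paired_t",
    "pearson",
    "icc",
    "records_to_frame",
    "build_table",
    "holm_adjust",
]


class DegenerateVarianceError(ValueError):
    """A statistic is undefined because the relevant variance is zero."""


@dataclass(frozen=True)
class PairedTResult:
    t: float
    df: int
    p: float


def paired_t(x, y) -> PairedTResult:
    """Two-sided paired t test: t = mean(d) / (sd(d)/sqrt(n)), d = x − y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired_t needs two equal-length 1D arrays")
    n = x.size
    if n < 2:
        raise ValueError("paired_t needs at least 2 pairs")
    d = x - y
    if np.std(d, ddof=1) == 0:
        raise DegenerateVarianceError("all paired differences identical; t undefined")
    res = stats.ttest_rel(x, y)
    return PairedTResult(t=float(res.statistic), df=n - 1, p=float(res.pvalue))


def pearson(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with two-sided p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("pearson needs two equal-length 1D arrays, n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateVarianceError("zero variance input; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def icc(session1, session2=None) -> float:
    """Intraclass correlation, two-way random effects, absolute agreement,
    single measures (ICC(2,1)).

    Accepts either two equal-length arrays (one per measurement session) or
    a single (subjects × sessions) matrix.  Computed from the two-way ANOVA
    mean squares:

        ICC = (MSR − MSE) / (MSR + (k−1) MSE + k (MSC − MSE) / n)
    """
    if session2 is not None:
        Y = np.column_stack([np.asarray(session1, float), np.asarray(session2, float)])
    else:
        Y = np.asarray(session1, dtype=float)
    if Y.ndim != 2 or Y.shape[1] < 2:
        raise ValueError("icc needs a (subjects x sessions) matrix with >= 2 sessions")
    n, k = Y.shape
    if n < 5:
        raise ValueError("icc needs at least 5 subjects")
    grand = Y.mean()
    row_means = Y.mean(axis=1)
    col_means = Y.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((Y - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if abs(denom) < 1e-300:
        raise DegenerateVarianceError("no variance in ratings; ICC undefined")
    return float((msr - mse) / denom)


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjusted p values (optional; off by default in tables)."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


# ---------------------------------------------------------------------------
# Cohort records and summary tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubjectRecord:
    """Per-subject, per-timepoint measurement bundle.

    ``dice`` and ``nov_mm3`` are keyed by reference plane ("AMP", "MSP",
    "SOFT" for the soft-tissue MSP analysis); ``measures`` holds per-side
    scalar measurements keyed ``(plane, side, quantity)`` with side in
    {"dev", "ndev"} and quantity names like "hemi_volume_mm3".
    """

    subject_id: str
    timepoint: str  # "T1" | "T2"
    deviation_mm: float
    dev_side: str
    dice: dict[str, float] = field(default_factory=dict)
    nov_mm3: dict[str, float] = field(default_factory=dict)
    total_voxels: dict[str, int] = field(default_factory=dict)
    measures: dict[tuple[str, str, str], float] = field(default_factory=dict)


def records_to_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    """Flatten records into one row per subject × timepoint."""
    rows = []
    for rec in records:
        row: dict = {
            "subject_id": rec.subject_id,
            "timepoint": rec.timepoint,
            "deviation_mm": rec.deviation_mm,
            "dev_side": rec.dev_side,
        }
        for plane, v in rec.dice.items():
            row[f"dice_{plane}"] = v
        for plane, v in rec.nov_mm3.items():
            row[f"nov_mm3_{plane}"] = v
        for plane, v in rec.total_voxels.items():
            row[f"total_voxels_{plane}"] = v
        for (plane, side, qty), v in rec.measures.items():
            row[f"{qty}_{plane}_{side}"] = v
        rows.append(row)
    return pd.DataFrame(rows).sort_values(["subject_id", "timepoint"]).reset_index(drop=True)


def _paired_rows(frame: pd.DataFrame) -> pd.DataFrame:
    """Wide frame with one row per subject and T1/T2 column suffixes;
    subjects missing a timepoint are dropped with a warning."""
    t1 = frame[frame.timepoint == "T1"].set_index("subject_id")
    t2 = frame[frame.timepoint == "T2"].set_index("subject_id")
    common = t1.index.intersection(t2.index)
    dropped = set(t1.index.symmetric_difference(t2.index))
    if dropped:
        warnings.warn(f"dropping unpaired subjects: {sorted(dropped)}", stacklevel=2)
    return t1.loc[common].add_suffix("_T1").join(t2.loc[common].add_suffix("_T2"))


def _safe_paired_t(x, y) -> tuple[float, float]:
    # degenerate or too-small cells appear as NaN rather than aborting tables
    try:
        res = paired_t(x, y)
        return res.t, res.p
    except (DegenerateVarianceError, ValueError):
        return float("nan"), float("nan")


def _safe_pearson(x, y) -> tuple[float, float]:
    try:
        return pearson(x, y)
    except (DegenerateVarianceError, ValueError):
        return float("nan"), float("nan")


def build_table(
    records: list[SubjectRecord],
    holm: bool = False,
) -> dict[str, pd.DataFrame]:
    """Summary tables over a cohort of subject records.

    Returns a dict of DataFrames:

    ``bilateral``
        Dev vs N-Dev paired comparison of every per-side quantity at each
        timepoint (mean ± SD on each side, mean difference Dev − N-Dev, t, p).
    ``longitudinal``
        T1 vs T2 paired comparison of NOV, dice, and bilateral differences.
    ``correlation``
        Pearson r (and p) between each similarity index and each
        non-overlapping volume across timepoints.

    With ``holm=True`` a Holm-adjusted p column is appended to each table.
    """
    frame = records_to_frame(records)
    tables: dict[str, pd.DataFrame] = {}

    # --- Dev vs N-Dev per timepoint ---------------------------------------
    dev_cols = sorted(c[: -len("_dev")] for c in frame.columns if c.endswith("_dev"))
    rows = []
    for timepoint, sub in frame.groupby("timepoint"):
        for base in dev_cols:
            dev = sub[f"{base}_dev"].to_numpy()
            ndev = sub[f"{base}_ndev"].to_numpy()
            t, p = _safe_paired_t(dev, ndev)
            diff = dev - ndev
            rows.append({
                "timepoint": timepoint,
                "quantity": base,
                "dev_mean": dev.mean(), "dev_sd": dev.std(ddof=1),
                "ndev_mean": ndev.mean(), "ndev_sd": ndev.std(ddof=1),
                "difference_mean": diff.mean(), "difference_sd": diff.std(ddof=1),
                "t": t, "p": p,
            })
    tables["bilateral"] = pd.DataFrame(rows)

    # --- T1 vs T2 ----------------------------------------------------------
    paired = _paired_rows(frame)
    rows = []
    numeric = [
        c for c in frame.columns
        if c.startswith(("dice_", "nov_mm3_")) or c.endswith(("_dev", "_ndev"))
    ]
    for col in numeric:
        a = paired[f"{col}_T1"].to_numpy(dtype=float)
        b = paired[f"{col}_T2"].to_numpy(dtype=float)
        t, p = _safe_paired_t(a, b)
        rows.append({
            "quantity": col,
            "t1_mean": a.mean(), "t1_sd": a.std(ddof=1),
            "t2_mean": b.mean(), "t2_sd": b.std(ddof=1),
            "change_mean": (b - a).mean(),
            "t": t, "p": p,
        })
    tables["longitudinal"] = pd.DataFrame(rows)

    # --- dice x NOV correlation matrix -------------------------------------
    dice_cols = [c for c in frame.columns if c.startswith("dice_")]
    nov_cols = [c for c in frame.columns if c.startswith("nov_mm3_")]
    rows = []
    for tp_d in ("T1", "T2"):
        sub_d = frame[frame.timepoint == tp_d].set_index("subject_id")
        for dc in dice_cols:
            row: dict = {"similarity": f"{tp_d} {dc}"}
            for tp_n in ("T1", "T2"):
                sub_n = frame[frame.timepoint == tp_n].set_index("subject_id")
                common = sub_d.index.intersection(sub_n.index)
                for nc in nov_cols:
                    r, p = _safe_pearson(
                        sub_d.loc[common, dc].to_numpy(dtype=float),
                        sub_n.loc[common, nc].to_numpy(dtype=float),
                    )
                    row[f"r {tp_n} {nc}"] = r
                    row[f"p {tp_n} {nc}"] = p
            rows.append(row)
    tables["correlation"] = pd.DataFrame(rows)

    if holm:
        for name in ("bilateral", "longitudinal"):
            tab = tables[name]
            mask = tab["p"].notna()
            adj = np.full(len(tab), np.nan)
            if mask.any():
                adj[mask.to_numpy()] = holm_adjust(tab.loc[mask, "p"].to_numpy())
            tab["p_holm"] = adj
    return tables
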