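"""Pixel-level segmentation scoring: confusion counts, PM and CR.

A system mask (SYS) is compared with an expert ground truth (GT) pixel by
pixel, yielding TP/FP/FN/TN counts and two scores:

    PM (percent match)        = 100 * TP / GT
    CR (correspondence ratio) = (TP - 0.5 * FP) / GT

where GT = TP + FN is the ground-truth tumor area.  PM is the sensitivity
against the expert contour; CR additionally penalises false positives and
goes negative when they dominate (a system with PM near 100 but negative
CR is accurate but error-prone).  Multi-case studies are summarised as
mean ± sample SD, and paired methods compared with a paired t-test.

The packaged reference table (``load_reference_cases``) holds the printed
per-case counts and scores from a 29-case clinical meningioma evaluation of
this pipeline, used to validate the score formulas and summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "SegMetrics",
    "confusion",
    "pm_cr",
    "summarize_cases",
    "paired_ttest",
    "load_reference_cases",
    "cases_report",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def gt(self) -> int:
        """Ground-truth tumor pixel count."""
        return self.tp + self.fn

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class SegMetrics:
    pm: float  # percent, [0, 100]
    cr: float  # <= 1, may be negative


def confusion(sys_mask: np.ndarray, gt_mask: np.ndarray) -> ConfusionCounts:
    """Pixel-level confusion counts between a system mask and a ground truth."""
    sys_mask = np.asarray(sys_mask, dtype=bool)
    gt_mask = np.asarray(gt_mask, dtype=bool)
    if sys_mask.shape != gt_mask.shape:
        raise ValueError(f"shape mismatch: sys {sys_mask.shape} vs gt {gt_mask.shape}")
    tp = int((sys_mask & gt_mask).sum())
    fp = int((sys_mask & ~gt_mask).sum())
    fn = int((~sys_mask & gt_mask).sum())
    tn = int((~sys_mask & ~gt_mask).sum())
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def pm_cr(counts: ConfusionCounts) -> SegMetrics:
    """PM and CR from confusion counts; undefined (raises) when GT is empty."""
    if counts.gt == 0:
        raise ValueError("ground truth is empty: PM and CR are undefined")
    pm = 100.0 * counts.tp / counts.gt
    cr = (counts.tp - 0.5 * counts.fp) / counts.gt
    return SegMetrics(pm=pm, cr=cr)


def summarize_cases(
    metrics: list[SegMetrics],
    exclude_ids: list[int] | None = None,
) -> dict[str, float]:
    """Mean ± sample SD of PM and CR over cases (0-based `exclude_ids` dropped).

    With a single included case the SD is reported as 0.0 and
    ``sd_defined`` is False.
    """
    excluded = set(exclude_ids or [])
    included = [m for i, m in enumerate(metrics) if i not in excluded]
    if not included:
        raise ValueError("no cases left after exclusion")
    pm = np.array([m.pm for m in included])
    cr = np.array([m.cr for m in included])
    single = len(included) == 1
    return {
        "n": len(included),
        "pm_mean": float(pm.mean()),
        "pm_sd": 0.0 if single else float(pm.std(ddof=1)),
        "cr_mean": float(cr.mean()),
        "cr_sd": 0.0 if single else float(cr.std(ddof=1)),
        "sd_defined": not single,
    }


def paired_ttest(values_a: list[float], values_b: list[float]) -> float:
    """Two-sided paired t-test p-value between matched per-case metrics.

    Raises on unequal lengths, fewer than two pairs, or zero-variance
    differences (the statistic is undefined there).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValueError("need at least two pairs")
    if np.var(a - b, ddof=1) == 0:
        raise ValueError("differences have zero variance: t statistic undefined")
    result = stats.ttest_rel(a, b)
    return float(result.pvalue)


def load_reference_cases() -> pd.DataFrame:
    """Packaged 29-case clinical reference: per-case GT/SYS/TP/FP/FN/TN, PM, CR."""
    with resources.files("menseg.data").joinpath("clinical_cases.csv").open() as fh:
        return pd.read_csv(fh)


def cases_report(counts: pd.DataFrame) -> pd.DataFrame:
    """Recompute PM/CR from a per-case counts table (columns gt, tp, fp).

    Returns the table with ``pm`` and ``cr`` columns recomputed at full
    precision (round only for display).
    """
    out = counts.copy()
    out["pm"] = 100.0 * out["tp"] / out["gt"]
    out["cr"] = (out["tp"] - 0.5 * out["fp"]) / out["gt"]
    return out
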