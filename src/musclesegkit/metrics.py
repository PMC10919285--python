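"""3D per-muscle segmentation metrics and paired model comparison.

Metrics (computed per muscle on binary masks):

* DSC  = 2|R∩P| / (|R|+|P|) — overlap in [0, 1];
* RVE  = |V_ref − V_pred| / V_ref — relative volume error (absolute
  value; reported alongside its complement 1−RVE as a volume accuracy);
* HD   = max(max_r d(r, P), max_p d(p, R)) — the full symmetric Hausdorff
  distance between boundary voxels, in mm.

Model comparison follows the paired protocol: per-muscle differences are
checked for normality (Kolmogorov-Smirnov on standardised differences);
when normality is rejected a Wilcoxon signed-rank test is used (exact
sign-flip enumeration for n ≤ 25, normal approximation with tie and zero
handling above), otherwise a paired t-test.  Significance level 0.05, no
multiple-testing correction across muscles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .core import LabelMap

__all__ = [
    "LabelMetrics",
    "PairedComparison",
    "dsc",
    "rve",
    "hausdorff",
    "evaluate_subject",
    "compare_models",
    "wilcoxon_signed_rank",
]


@dataclass
class LabelMetrics:
    """Per-(subject, muscle) metric row; ``hd_mm`` is NaN when undefined
    (prediction missing)."""

    subject_id: str
    label_id: int
    dsc: float
    rve: float
    one_minus_rve: float
    hd_mm: float

    def as_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "label_id": self.label_id,
            "dsc": self.dsc,
            "rve": self.rve,
            "one_minus_rve": self.one_minus_rve,
            "hd_mm": self.hd_mm,
        }


@dataclass
class PairedComparison:
    metric: str
    n: int
    normality_p: float
    test_used: str
    statistic: float
    p_value: float
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return bool(self.p_value < self.alpha)

    def stars(self) -> str:
        if self.p_value < 0.01:
            return "**"
        if self.p_value < 0.05:
            return "*"
        return ""


def _check_grids(a, b):
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")


def dsc(reference: np.ndarray, prediction: np.ndarray) -> float:
    """Dice similarity coefficient; 1.0 when both masks are empty."""
    r = np.asarray(reference, dtype=bool)
    p = np.asarray(prediction, dtype=bool)
    _check_grids(r, p)
    denom = int(r.sum()) + int(p.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.logical_and(r, p).sum()) / denom


def rve(
    reference: np.ndarray,
    prediction: np.ndarray,
    spacing: Sequence[float] = (1.0, 1.0, 1.0),
) -> tuple[float, float]:
    """Relative volume error and its complement, from voxel counts.

    Volumes are |mask| * voxel volume (mm^3); the voxel volume cancels but
    is accepted so callers can reason in physical units.
    """
    r = np.asarray(reference, dtype=bool)
    p = np.asarray(prediction, dtype=bool)
    _check_grids(r, p)
    vv = float(np.prod(spacing))
    v_ref = r.sum() * vv
    if v_ref == 0:
        raise ValueError("empty reference mask: RVE undefined")
    v_pred = p.sum() * vv
    e = abs(v_ref - v_pred) / v_ref
    return float(e), float(1.0 - e)


def _boundary(mask: np.ndarray) -> np.ndarray:
    """Foreground voxels with at least one 6-neighbour background voxel."""
    eroded = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(3, 1), border_value=0
    )
    return mask & ~eroded


def hausdorff(
    reference: np.ndarray,
    prediction: np.ndarray,
    spacing: Sequence[float] = (1.0, 1.0, 1.0),
) -> float:
    """Symmetric Hausdorff distance between boundary voxels, in mm.

    Uses Euclidean distance transforms of each boundary sampled at the
    other boundary's voxels (exact for voxel-centre distances).
    """
    r = np.asarray(reference, dtype=bool)
    p = np.asarray(prediction, dtype=bool)
    _check_grids(r, p)
    if not r.any():
        raise ValueError("empty reference mask: Hausdorff undefined")
    if not p.any():
        raise ValueError("empty prediction mask: Hausdorff undefined")
    br, bp = _boundary(r), _boundary(p)
    dt_r = ndimage.distance_transform_edt(~br, sampling=spacing)
    dt_p = ndimage.distance_transform_edt(~bp, sampling=spacing)
    return float(max(dt_p[br].max(), dt_r[bp].max()))


def evaluate_subject(
    reference: LabelMap,
    prediction: LabelMap,
    label_ids: Sequence[int] | None = None,
    subject_id: str = "",
) -> list[LabelMetrics]:
    """One LabelMetrics row per requested muscle label.

    A label absent from the prediction scores dsc 0, rve 1 and an
    undefined (NaN) Hausdorff distance.
    """
    if reference.shape != prediction.shape:
        raise ValueError("reference and prediction must share the grid")
    if label_ids is None:
        label_ids = [int(v) for v in reference.labels()]
    rows = []
    for lab in label_ids:
        r = reference.mask(lab)
        p = prediction.mask(lab)
        if not p.any():
            rows.append(
                LabelMetrics(subject_id, int(lab), 0.0, 1.0, 0.0, float("nan"))
            )
            continue
        e, acc = rve(r, p, reference.spacing)
        rows.append(
            LabelMetrics(
                subject_id,
                int(lab),
                dsc(r, p),
                e,
                acc,
                hausdorff(r, p, reference.spacing),
            )
        )
    return rows


def metrics_table(rows: Sequence[LabelMetrics]) -> pd.DataFrame:
    return pd.DataFrame([m.as_dict() for m in rows])


# ---------------------------------------------------------------------------
# paired statistics


def _signed_rank_distribution(ranks2: np.ndarray) -> np.ndarray:
    """Null distribution of 2*W+ for given doubled ranks, by convolution."""
    total = int(ranks2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in ranks2:
        r = int(r)
        new = dist.copy()
        new[r:] += dist[: total + 1 - r]
        dist = new
    return dist / dist.sum()


def wilcoxon_signed_rank(diffs: np.ndarray, exact_max_n: int = 25) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are discarded; ties share average ranks.  For
    n ≤ ``exact_max_n`` the p-value comes from exact enumeration of the
    2^n sign assignments (computed by convolution over the rank
    distribution); larger n uses the normal approximation with tie
    correction and continuity correction.

    Returns (W, p) with W = min(W+, W-).
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all differences are zero: test degenerate")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)
    if n <= exact_max_n:
        ranks2 = np.rint(2.0 * ranks).astype(int)  # half-integer ranks doubled
        dist = _signed_rank_distribution(ranks2)
        w2 = int(round(2.0 * w))
        p_low = dist[: w2 + 1].sum()
        p = min(1.0, 2.0 * p_low)
        return w, float(p)
    mean = n * (n + 1) / 4.0
    # variance with tie correction: sum of squared ranks / 4
    var = float((ranks**2).sum()) / 4.0
    z = (w - mean + 0.5) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return w, float(min(1.0, p))


def compare_models(
    values_a: Sequence[float],
    values_b: Sequence[float],
    metric: str = "dsc",
    alpha: float = 0.05,
) -> PairedComparison:
    """Paired comparison of one metric between two models.

    ``values_a``/``values_b`` are matched per-muscle (or per-subject)
    values.  Normality of the differences decides the test; all-zero
    differences yield a degenerate report with p = 1 and no test.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired value vectors must have equal length")
    if len(a) < 5:
        raise ValueError("need at least 5 paired values")
    d = a - b
    if np.all(d == 0):
        return PairedComparison(metric, len(d), 1.0, "degenerate", 0.0, 1.0, alpha)
    sd = d.std(ddof=1)
    standardized = (d - d.mean()) / (sd if sd > 0 else 1.0)
    ks = stats.kstest(standardized, "norm")
    if ks.pvalue < alpha:
        w, p = wilcoxon_signed_rank(d)
        return PairedComparison(
            metric, len(d), float(ks.pvalue), "wilcoxon-signed-rank", w, p, alpha
        )
    t = stats.ttest_rel(a, b)
    return PairedComparison(
        metric, len(d), float(ks.pvalue), "paired-t", float(t.statistic), float(t.pvalue), alpha
    )
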