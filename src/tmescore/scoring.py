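"""Categorical immune scores from densities, G-cross values and CLR counts.

The scores follow the Immunoscore template: raw per-tumor quantities are
converted to cohort percentiles (mid-rank convention, so ties are symmetric)
and categorised by fixed percentile brackets.  The T-cell density score uses
the mean of the four percentiles of CD3/CD8 densities at the tumor center
(CT) and invasive margin (IM), cut at 25 and 70 into low / intermediate /
high; the T-cell proximity score applies the identical machinery to the four
G-cross values at a 20-μm radius.  Crohn's-like reaction (CLR) density —
lymphoid aggregates per mm of invasive margin — is dichotomised at 0.42/mm,
a cut-off derived from an ROC curve against disease-specific survival.

All cohort-level operations accept array-likes / pandas Series and propagate
NaN as "missing": a missing input never produces a default category.
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

DENSITY_BREAKS = (25.0, 70.0)
SCORE_LABELS = ("low", "intermediate", "high")
TERTILE_LABELS = ("low", "moderate", "high")
CLR_CUTOFF_PER_MM = 0.42
PDL1_TUMOR_LABELS = ("negative", "1-<5", ">=5")


def percentile_rank(values) -> np.ndarray:
    """Mid-rank percentile of each value within its cohort.

    percentile(v) = 100 * (#{values < v} + 0.5 * #{values == v}) / n, with n
    the number of non-missing values.  Missing values get NaN percentiles and
    do not count toward n.  Requires at least two non-missing values.
    """
    x = np.asarray(values, dtype=float)
    ok = ~np.isnan(x)
    n = int(ok.sum())
    if n == 0:
        raise ValueError("percentile_rank: all values are missing")
    if n < 2:
        raise ValueError("percentile_rank: need at least 2 non-missing values")
    out = np.full(x.shape, np.nan)
    ranks = rankdata(x[ok], method="average")  # mid-rank for ties
    out[ok] = 100.0 * (ranks - 0.5) / n
    return out


def _bracket(mean_pct: np.ndarray, breaks: tuple[float, float]) -> np.ndarray:
    lo, hi = breaks
    out = np.full(mean_pct.shape, None, dtype=object)
    ok = ~np.isnan(mean_pct)
    out[ok & (mean_pct <= lo)] = "low"
    out[ok & (mean_pct > lo) & (mean_pct <= hi)] = "intermediate"
    out[ok & (mean_pct > hi)] = "high"
    return out


def percentile_score(
    components: pd.DataFrame, breaks: tuple[float, float] = DENSITY_BREAKS
) -> pd.DataFrame:
    """Shared machinery behind the density and proximity scores.

    Each column of ``components`` is converted to cohort percentiles; per row
    the mean of the *available* component percentiles is bracketed at
    ``breaks`` (closed at the lower break: exactly 25 is still "low").  Rows
    with every component missing get a missing score.

    Returns a frame with the per-component percentiles, ``mean_percentile``
    and ``score``.
    """
    if components.shape[1] < 1:
        raise ValueError("need at least one component column")
    pct = pd.DataFrame(index=components.index)
    for col in components.columns:
        pct[f"{col}_pct"] = percentile_rank(components[col].to_numpy(dtype=float))
    mean_pct = pct.mean(axis=1, skipna=True).to_numpy()
    out = pct
    out["mean_percentile"] = mean_pct
    out["score"] = _bracket(mean_pct, breaks)
    return out


def density_score(
    cd3_ct, cd3_im, cd8_ct, cd8_im, breaks: tuple[float, float] = DENSITY_BREAKS
) -> pd.DataFrame:
    """T-cell density score from the four CD3/CD8 × CT/IM density columns."""
    comp = pd.DataFrame(
        {"cd3_ct": np.asarray(cd3_ct, dtype=float),
         "cd3_im": np.asarray(cd3_im, dtype=float),
         "cd8_ct": np.asarray(cd8_ct, dtype=float),
         "cd8_im": np.asarray(cd8_im, dtype=float)}
    )
    return percentile_score(comp, breaks)


def proximity_score(
    gcross_cd3_ct, gcross_cd3_im, gcross_cd8_ct, gcross_cd8_im,
    breaks: tuple[float, float] = DENSITY_BREAKS,
) -> pd.DataFrame:
    """T-cell proximity score: the density-score machinery applied to the four
    G-cross values at 20 μm (CD3/CD8 × CT/IM)."""
    comp = pd.DataFrame(
        {"gcross_cd3_ct": np.asarray(gcross_cd3_ct, dtype=float),
         "gcross_cd3_im": np.asarray(gcross_cd3_im, dtype=float),
         "gcross_cd8_ct": np.asarray(gcross_cd8_ct, dtype=float),
         "gcross_cd8_im": np.asarray(gcross_cd8_im, dtype=float)}
    )
    return percentile_score(comp, breaks)


def clr_density(clr_count, margin_length_mm):
    """CLR density in aggregates per mm: count / margin length."""
    count = np.asarray(clr_count, dtype=float)
    length = np.asarray(margin_length_mm, dtype=float)
    if np.any(length[~np.isnan(length)] <= 0):
        raise ValueError("margin_length_mm must be positive")
    if np.any(count[~np.isnan(count)] < 0):
        raise ValueError("clr_count must be non-negative")
    out = count / length
    return float(out) if out.ndim == 0 else out


def clr_categorize(density, cutoff: float = CLR_CUTOFF_PER_MM) -> np.ndarray:
    """Dichotomise CLR density: 'high' iff density >= cutoff (inclusive)."""
    x = np.atleast_1d(np.asarray(density, dtype=float))
    out = np.full(x.shape, None, dtype=object)
    ok = ~np.isnan(x)
    out[ok] = np.where(x[ok] >= cutoff, "high", "low")
    return out


class RocCutoff(NamedTuple):
    cutoff: float
    youden_j: float
    sensitivity: float
    specificity: float


def roc_optimal_cutoff(values, events) -> RocCutoff:
    """Threshold maximising Youden's J = sensitivity + specificity − 1.

    Candidate thresholds are the midpoints between consecutive sorted unique
    values plus ±infinity; a sample is classified positive when its value is
    at or above the threshold.  Ties in J break toward the smallest
    threshold.  Both outcome classes must be present.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(events, dtype=bool)
    if x.shape != y.shape:
        raise ValueError("values and events must have the same length")
    ok = ~np.isnan(x)
    x, y = x[ok], y[ok]
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_optimal_cutoff: both outcome classes must be present")
    uniq = np.unique(x)
    mids = (uniq[:-1] + uniq[1:]) / 2.0 if uniq.size > 1 else np.empty(0)
    candidates = np.concatenate(([-np.inf], mids, [np.inf]))
    best = None
    for t in candidates:
        pred = x >= t
        sens = float(np.sum(pred & y)) / n_pos
        spec = float(np.sum(~pred & ~y)) / n_neg
        j = sens + spec - 1.0
        if best is None or j > best.youden_j + 1e-12:
            best = RocCutoff(float(t), j, sens, spec)
    return best


def tertile_classify(values) -> np.ndarray:
    """Cohort tertiles: low / moderate / high at the 33.33rd and 66.67th
    mid-rank percentiles; boundary values fall to the lower group; ties share
    one group so group sizes may be unequal.  Missing stays missing."""
    x = np.asarray(values, dtype=float)
    pct = percentile_rank(x)
    out = np.full(x.shape, None, dtype=object)
    ok = ~np.isnan(pct)
    lo, hi = 100.0 / 3.0, 200.0 / 3.0
    out[ok & (pct <= lo)] = "low"
    out[ok & (pct > lo) & (pct <= hi)] = "moderate"
    out[ok & (pct > hi)] = "high"
    return out


def pdl1_tumor_categorize(histoscore) -> np.ndarray:
    """PD-L1 tumor-cell histoscore brackets: negative (<1), 1-<5, >=5."""
    x = np.atleast_1d(np.asarray(histoscore, dtype=float))
    out = np.full(x.shape, None, dtype=object)
    ok = ~np.isnan(x)
    out[ok & (x < 1)] = "negative"
    out[ok & (x >= 1) & (x < 5)] = "1-<5"
    out[ok & (x >= 5)] = ">=5"
    return out
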