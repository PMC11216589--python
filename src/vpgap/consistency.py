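"""Measurement reliability and agreement between encoding models.

*Internal consistency* quantifies how reproducible a site's trial-averaged
response profile is: repetitions are randomly split into two halves, the
half-mean response vectors are correlated, and the Spearman-Brown
correction 2c/(1+c) estimates the reliability of the full-data average.
The median over 100 random splits is the site's internal consistency;
sites at or below 0.7 are conventionally excluded from population analyses.

*Score consistency* correlates the per-site predictivity profiles of two
encoding models; *prediction consistency* correlates their per-stimulus
predictions for a single site, restricted to model pairs whose predictivity
scores are nearly equal (so that any disagreement is about *how* the site
is predicted, not *how well*).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "spearman_brown",
    "InternalConsistencyResult",
    "internal_consistency",
    "filter_sites",
    "score_consistency",
    "prediction_consistency",
]


def spearman_brown(c: float | np.ndarray) -> float | np.ndarray:
    """Reliability of a doubled-length test given split-half correlation c."""
    return 2.0 * np.asarray(c) / (1.0 + np.asarray(c))


@dataclass
class InternalConsistencyResult:
    site_id: str
    c_splits: np.ndarray  # per-split raw half-half correlations (NaN if undefined)
    corrected: float  # median over splits of 2c/(1+c)
    n_splits: int
    unreliable: bool  # > 50% of splits undefined


def internal_consistency(
    trials: np.ndarray,
    n_splits: int = 100,
    seed: int = 0,
    site_id: str = "site",
) -> InternalConsistencyResult:
    """Split-half reliability of one site's repetition x stimulus matrix.

    Odd repetition counts are split floor(n/2) / ceil(n/2) so no trial is
    discarded.  Splits with a constant half-mean vector are undefined and
    excluded from the median; a site with more than half its splits
    undefined is flagged unreliable.
    """
    trials = np.asarray(trials, dtype=float)
    if trials.ndim != 2:
        raise ValueError("trials must be (repetitions, stimuli)")
    n_rep, n_stim = trials.shape
    if n_rep < 4:
        raise ValueError("need at least 4 repetitions")
    if n_stim < 3:
        raise ValueError("need at least 3 stimuli")
    rng = np.random.default_rng(seed)
    half = n_rep // 2
    cs = np.full(n_splits, np.nan)
    for s in range(n_splits):
        perm = rng.permutation(n_rep)
        a = trials[perm[:half]].mean(axis=0)
        b = trials[perm[half:]].mean(axis=0)
        if a.std() < 1e-14 or b.std() < 1e-14:
            continue
        cs[s] = np.corrcoef(a, b)[0, 1]
    defined = ~np.isnan(cs)
    unreliable = defined.mean() <= 0.5
    if unreliable:
        warnings.warn(f"site {site_id}: > 50% of splits undefined", stacklevel=2)
        corrected = float("nan")
    else:
        corrected = float(np.median(spearman_brown(cs[defined])))
    return InternalConsistencyResult(
        site_id=site_id,
        c_splits=cs,
        corrected=corrected,
        n_splits=n_splits,
        unreliable=unreliable,
    )


def filter_sites(
    results: list[InternalConsistencyResult], threshold: float = 0.7
) -> list[str]:
    """Site ids with internal consistency strictly greater than the threshold."""
    return [
        r.site_id
        for r in results
        if not r.unreliable and r.corrected > threshold
    ]


def score_consistency(scores_a: np.ndarray, scores_b: np.ndarray) -> float:
    """Pearson correlation between two models' per-site predictivity profiles."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("score vectors must be 1-D and aligned")
    if len(a) < 3:
        raise ValueError("need at least 3 sites")
    if a.std() < 1e-14 or b.std() < 1e-14:
        return float("nan")
    return float(stats.pearsonr(a, b).statistic)


def prediction_consistency(
    predictions: dict[str, np.ndarray],
    scores: dict[str, float],
    tolerance: float = 0.02,
    relative: bool = False,
) -> pd.DataFrame:
    """Pairwise correlation of per-stimulus predictions for one site.

    Only pairs whose predictivity scores differ by at most ``tolerance``
    (absolute by default; relative to the larger score with
    ``relative=True``) are eligible.  Returns one row per eligible pair.
    """
    keys = list(predictions)
    if set(keys) != set(scores):
        raise ValueError("predictions and scores must cover the same models")
    rows = []
    for a, b in itertools.combinations(keys, 2):
        diff = abs(scores[a] - scores[b])
        if relative:
            denom = max(abs(scores[a]), abs(scores[b]), 1e-14)
            diff = diff / denom
        if diff > tolerance:
            continue
        pa = np.asarray(predictions[a], dtype=float)
        pb = np.asarray(predictions[b], dtype=float)
        if pa.shape != pb.shape:
            raise ValueError(f"prediction vectors for {a!r}/{b!r} are misaligned")
        if pa.std() < 1e-14 or pb.std() < 1e-14:
            r = float("nan")
        else:
            r = float(stats.pearsonr(pa, pb).statistic)
        rows.append((a, b, scores[a], scores[b], r))
    df = pd.DataFrame(
        rows, columns=["model_a", "model_b", "score_a", "score_b", "correlation"]
    )
    if df.empty:
        warnings.warn(
            f"fewer than 2 models within tolerance {tolerance}; empty result",
            stacklevel=2,
        )
    return df
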