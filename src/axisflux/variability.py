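"""Intra-individual variability of S-A loadings and its comparison/decoding.

A subject's intra-individual variability map is the per-parcel standard
deviation of S-A axis loadings across daily sessions.  Two subjects'
variance is compared parcel-wise with Levene's test (BH-FDR across
parcels), with the SD difference carrying the direction of the effect.
Variability maps are decoded against user-supplied parcel-wise feature maps
via Spearman correlation with spin-permutation p-values and BH-FDR across
features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_model import ValidationError
from .gradients import AlignedAxes
from .spatial_null import SpinIndex, spin_pvalue

__all__ = [
    "VariabilityMap",
    "VarianceComparison",
    "parcel_sd",
    "variance_comparison",
    "levene_statistic",
    "decode_map",
]


@dataclass(frozen=True)
class VariabilityMap:
    """Per-parcel SD of S-A loadings across sessions for one subject."""

    values: np.ndarray
    n_sessions: int
    subject_id: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, float)
        if np.any(v < 0):
            raise ValidationError("variability values must be nonnegative")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class VarianceComparison:
    """Parcel-wise variance comparison between two subjects.

    ``diff = SD_A - SD_B`` carries direction (positive = subject A more
    variable); significance comes from Levene's test with BH-FDR across
    parcels.
    """

    diff: np.ndarray
    levene_F: np.ndarray
    p: np.ndarray
    q: np.ndarray
    significant: np.ndarray
    q_threshold: float


def parcel_sd(axes: AlignedAxes) -> VariabilityMap:
    """Sample SD (denominator S-1) of each parcel's loading across sessions."""
    if axes.n_sessions < 2:
        raise ValidationError("need >= 2 sessions for a variability map")
    return VariabilityMap(
        values=axes.loadings.std(axis=1, ddof=1),
        n_sessions=axes.n_sessions,
        subject_id=axes.subject_id,
    )


def levene_statistic(
    a: np.ndarray, b: np.ndarray, center: str = "mean"
) -> tuple[float, float]:
    """Levene's test for equality of variances between two samples.

    Classic Levene uses absolute deviations from the group mean;
    ``center="median"`` gives the Brown-Forsythe variant.  Returns (F, p)
    with df (1, n_a + n_b - 2).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if center not in ("mean", "median"):
        raise ValidationError("center must be 'mean' or 'median'")
    loc = np.mean if center == "mean" else np.median
    za, zb = np.abs(a - loc(a)), np.abs(b - loc(b))
    na, nb = za.size, zb.size
    zbar_a, zbar_b = za.mean(), zb.mean()
    zbar = np.concatenate([za, zb]).mean()
    num = na * (zbar_a - zbar) ** 2 + nb * (zbar_b - zbar) ** 2
    den = (np.sum((za - zbar_a) ** 2) + np.sum((zb - zbar_b) ** 2)) / (
        na + nb - 2
    )
    if den == 0:
        return (0.0, 1.0) if num == 0 else (np.inf, 0.0)
    F = num / den
    p = float(stats.f.sf(F, 1, na + nb - 2))
    return float(F), p


def variance_comparison(
    axesA: AlignedAxes,
    axesB: AlignedAxes,
    q_threshold: float = 0.05,
    center: str = "mean",
) -> VarianceComparison:
    """Parcel-wise Levene comparison of loading variance between subjects.

    diff = SD_A - SD_B per parcel; Levene F and p per parcel; BH-FDR across
    the P parcels at ``q_threshold``.
    """
    if axesA.n_parcels != axesB.n_parcels:
        raise ValidationError(
            f"parcellation mismatch: {axesA.n_parcels} != {axesB.n_parcels}"
        )
    if axesA.n_sessions < 3 or axesB.n_sessions < 3:
        raise ValidationError("need >= 3 sessions per subject")
    P = axesA.n_parcels
    sdA = axesA.loadings.std(axis=1, ddof=1)
    sdB = axesB.loadings.std(axis=1, ddof=1)
    F = np.empty(P)
    p = np.empty(P)
    for i in range(P):
        F[i], p[i] = levene_statistic(
            axesA.loadings[i], axesB.loadings[i], center=center
        )
    _, q, _, _ = multipletests(p, alpha=q_threshold, method="fdr_bh")
    return VarianceComparison(
        diff=sdA - sdB,
        levene_F=F,
        p=p,
        q=q,
        significant=q < q_threshold,
        q_threshold=q_threshold,
    )


def decode_map(
    vmap: VariabilityMap | np.ndarray,
    features: dict[str, np.ndarray] | pd.DataFrame,
    spins: SpinIndex,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Decode a parcel map against named feature maps with spin-corrected p.

    For each feature: Spearman r between the map and the feature; a
    two-sided spin p-value obtained by rotating the *map* (one shared null
    serves all features) and recomputing r per rotation; BH-FDR across
    features.  Parcels where a feature is missing (NaN) are dropped pairwise
    for that feature.
    """
    values = vmap.values if isinstance(vmap, VariabilityMap) else np.asarray(vmap)
    if isinstance(features, pd.DataFrame):
        features = {c: features[c].to_numpy(float) for c in features.columns}
    P = values.size
    if spins.n_parcels != P:
        raise ValidationError("spin index does not match the map's parcellation")
    rows = []
    spun = values[spins.index]  # P × n_perm
    for name, feat in features.items():
        feat = np.asarray(feat, float)
        if feat.size != P:
            raise ValidationError(
                f"feature {name!r} has length {feat.size}, expected {P}"
            )
        ok = np.isfinite(feat)
        r = stats.spearmanr(values[ok], feat[ok]).statistic
        null = np.array(
            [
                stats.spearmanr(spun[ok, j], feat[ok]).statistic
                for j in range(spins.n_perm)
            ]
        )
        rows.append((name, r, spin_pvalue(r, null, two_sided=True)))
    df = pd.DataFrame(rows, columns=["feature", "spearman_r", "p_spin"])
    _, df["q"], _, _ = multipletests(df["p_spin"], method="fdr_bh")
    df["significant"] = df["q"] < q_threshold
    return df
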