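"""Local-level covariate effects on S-A loadings.

Per cortical parcel, session loadings are regressed on z-scored covariates
(hormone concentrations, perceived stress) in a linear model with a random
intercept grouped by experimental session, acknowledging the longitudinal
structure of dense-sampling data.  With one observation per session the
random-intercept variance is only weakly identified, so fitting follows a
deterministic fallback ladder: REML mixed model → boundary flag when the
random-effect variance collapses to ~0 → ordinary least squares when
estimation fails outright.  t-maps are FDR-corrected across parcels per
covariate; cross-subject t-maps are compared by Spearman correlation with a
spin-permutation p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.linear_model import GLSAR, OLS
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .data_model import CovariateTable, ValidationError
from .gradients import AlignedAxes
from .spatial_null import SpinIndex, spin_pvalue

__all__ = [
    "EffectMap",
    "fit_local_effects",
    "fit_session_model",
    "compare_tmaps",
    "compare_covariate_distributions",
]

#: named covariate presets mirroring the dense-sampling model families
MODEL_PRESETS = {
    "female_predominant": ["estradiol", "progesterone"],
    "male_predominant": ["testosterone", "cortisol"],
    "common": ["estradiol", "testosterone"],
    "stress_only": ["pss_score"],
}


@dataclass(frozen=True)
class EffectMap:
    """Per-parcel t/p/q statistics for one covariate in one model."""

    covariate: str
    t: np.ndarray
    p: np.ndarray
    q: np.ndarray
    significant: np.ndarray
    n_sessions: int
    model_flags: np.ndarray  # per-parcel {mixed_ok, boundary_fit, ols_fallback}
    q_threshold: float = 0.05


def _zscore(x: np.ndarray, label: str) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValidationError(f"covariate {label!r} is constant")
    return (x - x.mean()) / sd


def fit_session_model(
    y: np.ndarray,
    Z: np.ndarray,
    session_codes: np.ndarray,
    method: str = "mixed",
) -> tuple[np.ndarray, np.ndarray, str]:
    """Fit one response series on z-scored covariates with session grouping.

    Returns (t, p, flag) for the covariate columns of ``Z`` (intercept
    fitted but not reported).  ``method`` is "mixed" (REML random intercept
    with the fallback ladder), "ols", or "ols_ar1" (AR(1) errors across
    consecutive sessions via iterated feasible GLS).
    """
    n, k = Z.shape
    exog = np.column_stack([np.ones(n), Z])
    if method == "ols":
        return _ols_tp(y, exog) + ("ols_fallback",)
    if method == "ols_ar1":
        res = GLSAR(y, exog, rho=1).iterative_fit(maxiter=5)
        return res.tvalues[1:], res.pvalues[1:], "ols_ar1"
    if method != "mixed":
        raise ValidationError(f"unknown fit method {method!r}")
    # with one observation per group the random-intercept variance is not
    # identifiable (it is confounded with the residual variance); the model
    # collapses to OLS, which we fit directly for deterministic inference
    _, counts = np.unique(session_codes, return_counts=True)
    if counts.max() == 1:
        return _ols_tp(y, exog) + ("ols_fallback",)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", UserWarning)
            model = MixedLM(y, exog, groups=session_codes)
            res = model.fit(reml=True)
        t = np.asarray(res.tvalues[1 : k + 1])
        p = np.asarray(res.pvalues[1 : k + 1])
        if not (np.isfinite(t).all() and np.isfinite(p).all()):
            raise ValueError("non-finite mixed-model statistics")
        scale = max(res.scale, np.finfo(float).tiny)
        boundary = float(np.trace(np.atleast_2d(res.cov_re))) < 1e-6 * scale
        return t, p, ("boundary_fit" if boundary else "mixed_ok")
    except Exception:
        return _ols_tp(y, exog) + ("ols_fallback",)


def _ols_tp(y: np.ndarray, exog: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    res = OLS(y, exog).fit()
    return np.asarray(res.tvalues[1:]), np.asarray(res.pvalues[1:])


def fit_local_effects(
    axes: AlignedAxes,
    cov: CovariateTable,
    covariates: Sequence[str],
    q_threshold: float = 0.05,
    method: str = "mixed",
) -> list[EffectMap]:
    """Per-parcel covariate effects on S-A loadings, FDR across parcels.

    All named covariates enter one joint model (z-scored, intercept
    included); one EffectMap per covariate is returned, with BH-FDR across
    the P parcels applied to each covariate's p-map separately.
    """
    session_ids = list(axes.session_ids)
    Z = np.column_stack(
        [_zscore(cov.column(c, session_ids), c) for c in covariates]
    )
    S = len(session_ids)
    if axes.loadings.shape[1] != S:
        raise ValidationError("axes/covariates session mismatch")
    codes = np.arange(S)  # one experimental session per observation
    P = axes.n_parcels
    k = len(covariates)
    t = np.empty((P, k))
    p = np.empty((P, k))
    flags = np.empty(P, dtype=object)
    for i in range(P):
        t[i], p[i], flags[i] = fit_session_model(
            axes.loadings[i], Z, codes, method=method
        )
    maps = []
    for j, name in enumerate(covariates):
        _, q, _, _ = multipletests(p[:, j], alpha=q_threshold, method="fdr_bh")
        maps.append(
            EffectMap(
                covariate=name,
                t=t[:, j],
                p=p[:, j],
                q=q,
                significant=q < q_threshold,
                n_sessions=S,
                model_flags=flags.copy(),
                q_threshold=q_threshold,
            )
        )
    return maps


def compare_tmaps(
    mapA: EffectMap | np.ndarray,
    mapB: EffectMap | np.ndarray,
    spins: SpinIndex,
) -> tuple[float, float]:
    """Spearman correlation of two unthresholded t-maps with a spin p-value.

    The null spins mapA's t-vector; the p-value is two-sided.
    """
    ta = mapA.t if isinstance(mapA, EffectMap) else np.asarray(mapA, float)
    tb = mapB.t if isinstance(mapB, EffectMap) else np.asarray(mapB, float)
    if ta.size != tb.size:
        raise ValidationError(f"t-map length mismatch {ta.size} != {tb.size}")
    if spins.n_parcels != ta.size:
        raise ValidationError("spin index does not match the t-maps")
    r = stats.spearmanr(ta, tb).statistic
    null = np.array(
        [
            stats.spearmanr(ta[spins.index[:, j]], tb).statistic
            for j in range(spins.n_perm)
        ]
    )
    return float(r), spin_pvalue(r, null, two_sided=True)


def compare_covariate_distributions(
    a: np.ndarray, b: np.ndarray
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U comparison of two covariate samples.

    Exact (full enumeration) inference when the combined sample size is at
    most 20 — via the closed-form exact distribution without ties, or full
    permutation enumeration of U with ties — and the tie-corrected normal
    approximation otherwise.  Returns (U, p) with U counted for the first
    sample.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be nonempty")
    n = a.size + b.size
    combined = np.concatenate([a, b])
    has_ties = np.unique(combined).size < n
    if n <= 20:
        if not has_ties:
            res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            return float(res.statistic), float(res.pvalue)
        U_obs = float(stats.mannwhitneyu(a, b, alternative="two-sided").statistic)

        def centered_u(x, y):
            return (
                stats.mannwhitneyu(x, y, alternative="two-sided").statistic
                - x.size * y.size / 2.0
            )

        perm = stats.permutation_test(
            (a, b),
            centered_u,
            permutation_type="independent",
            alternative="two-sided",
            n_resamples=comb(n, a.size) + 1,
        )
        return U_obs, float(perm.pvalue)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)
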