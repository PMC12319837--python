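"""System-level network topology statistics along the S-A axis.

Within-network dispersion of a session is the sum of squared distances of a
network's parcel loadings from the network centroid (the median loading of
its parcels); larger values mean the network spreads more widely along the
axis (greater segregation).  Between-network dispersion is the distance
between two networks' median loadings.  The axis is one-dimensional, so
Euclidean distance reduces to absolute difference.

Covariate effects on the 7 within- and 21 between-network measures are fit
with the same session-grouped models used for local effects, tested at
Bonferroni family thresholds 0.025/7 and 0.025/21; effects that survive are
localized with a network-label spin test (spinning relabels parcels'
networks while loadings stay fixed, so a spatially global effect survives
relabeling and yields a large p).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import (
    NETWORK_ORDER,
    CovariateTable,
    ParcellationMeta,
    ValidationError,
)
from .effects import _zscore, fit_session_model
from .gradients import AlignedAxes
from .spatial_null import SpinIndex, spin_pvalue

__all__ = [
    "DispersionSeries",
    "within_dispersion",
    "between_dispersion",
    "dispersion_series",
    "fit_dispersion_effects",
    "spin_specificity",
]


def _present_networks(labels: np.ndarray) -> list[str]:
    present = set(labels)
    return [n for n in NETWORK_ORDER if n in present]


def pair_names(networks: Sequence[str]) -> list[str]:
    """Canonical unordered network pairs, lexicographic in canonical order."""
    return [f"{a}–{b}" for a, b in combinations(networks, 2)]


@dataclass(frozen=True)
class DispersionSeries:
    """Session-wise within- (S×7) and between- (S×21) network dispersion."""

    within: np.ndarray
    between: np.ndarray
    network_names: tuple[str, ...]
    pair_names: tuple[str, ...]
    session_ids: tuple[str, ...]

    def __post_init__(self):
        n = len(self.network_names)
        if len(self.pair_names) != n * (n - 1) // 2:
            raise ValidationError("pair count must be n(n-1)/2")
        if np.any(self.within < 0) or np.any(self.between < 0):
            raise ValidationError("dispersion values must be nonnegative")

    def measure(self, name: str) -> np.ndarray:
        """Session series for a named within (network) or between (pair) measure."""
        if name in self.network_names:
            return self.within[:, self.network_names.index(name)]
        if name in self.pair_names:
            return self.between[:, self.pair_names.index(name)]
        raise ValidationError(f"unknown measure {name!r}")


def within_dispersion(loadings: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Sum of squared deviations from the network median, per network."""
    loadings = np.asarray(loadings, float)
    networks = _present_networks(np.asarray(labels))
    out = np.empty(len(networks))
    for i, net in enumerate(networks):
        g = loadings[labels == net]
        if g.size == 0:
            raise ValidationError(f"empty network {net!r}")
        out[i] = np.sum((g - np.median(g)) ** 2)
    return out


def between_dispersion(loadings: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Absolute distance between network median loadings, per pair."""
    loadings = np.asarray(loadings, float)
    networks = _present_networks(np.asarray(labels))
    med = {}
    for net in networks:
        g = loadings[labels == net]
        if g.size == 0:
            raise ValidationError(f"empty network {net!r}")
        med[net] = np.median(g)
    return np.array([abs(med[a] - med[b]) for a, b in combinations(networks, 2)])


def dispersion_series(
    axes: AlignedAxes, meta: ParcellationMeta, labels: np.ndarray | None = None
) -> DispersionSeries:
    """Within/between dispersion of every session's loadings."""
    labels = meta.network if labels is None else np.asarray(labels)
    if labels.size != axes.n_parcels:
        raise ValidationError("labels do not cover all parcels")
    networks = _present_networks(labels)
    S = axes.n_sessions
    within = np.empty((S, len(networks)))
    between = np.empty((S, len(networks) * (len(networks) - 1) // 2))
    for s in range(S):
        within[s] = within_dispersion(axes.loadings[:, s], labels)
        between[s] = between_dispersion(axes.loadings[:, s], labels)
    return DispersionSeries(
        within=within,
        between=between,
        network_names=tuple(networks),
        pair_names=tuple(pair_names(networks)),
        session_ids=axes.session_ids,
    )


def fit_dispersion_effects(
    series: DispersionSeries,
    cov: CovariateTable,
    covariates: Sequence[str],
    alpha_within: float = 0.025 / 7,
    alpha_between: float = 0.025 / 21,
    method: str = "mixed",
) -> pd.DataFrame:
    """Covariate effects on each dispersion measure, Bonferroni families.

    One session-grouped model per measure (same structure and fallback
    ladder as the local-effects models); within measures are tested at
    ``alpha_within`` and between measures at ``alpha_between``.  Positive t
    = segregation increases with the covariate, negative t = integration.
    """
    session_ids = list(series.session_ids)
    Z = np.column_stack(
        [_zscore(cov.column(c, session_ids), c) for c in covariates]
    )
    codes = np.arange(len(session_ids))
    rows = []
    for kind, names, mat, alpha in (
        ("within", series.network_names, series.within, alpha_within),
        ("between", series.pair_names, series.between, alpha_between),
    ):
        for i, name in enumerate(names):
            t, p, flag = fit_session_model(mat[:, i], Z, codes, method=method)
            for j, covname in enumerate(covariates):
                rows.append(
                    {
                        "kind": kind,
                        "measure": name,
                        "covariate": covname,
                        "t": t[j],
                        "p": p[j],
                        "alpha": alpha,
                        "bonferroni_significant": p[j] < alpha,
                        "model_flag": flag,
                    }
                )
    return pd.DataFrame(rows)


def spin_specificity(
    axes: AlignedAxes,
    meta: ParcellationMeta,
    cov: CovariateTable,
    measure: str,
    covariate: str,
    spins: SpinIndex,
    method: str = "mixed",
) -> float:
    """Spatial specificity of a dispersion effect via network-label spins.

    Each permutation relabels parcels' networks through the spin index
    (loadings stay fixed), recomputes the session series of the named
    measure and refits the model, building a null distribution of t-values;
    returns the two-sided permutation p of the empirical t.  A network-
    specific effect yields a small p; a global effect (all networks scaled
    alike) survives relabeling and does not.
    """
    session_ids = list(axes.session_ids)
    Z = np.column_stack(
        [_zscore(cov.column(c, session_ids), c) for c in [covariate]]
    )
    codes = np.arange(len(session_ids))

    def _t_for(labels: np.ndarray) -> float:
        ser = dispersion_series(axes, meta, labels=labels)
        y = ser.measure(measure)
        t, _, _ = fit_session_model(y, Z, codes, method=method)
        return float(t[0])

    t_obs = _t_for(meta.network)
    null = []
    for j in range(spins.n_perm):
        labels = meta.network[spins.index[:, j]]
        try:
            null.append(_t_for(labels))
        except ValidationError:
            # a rotation may drop a small network entirely; that permutation
            # carries no information about the measure and is skipped
            continue
    return spin_pvalue(t_obs, np.asarray(null), two_sided=True)
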