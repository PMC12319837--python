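"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the statistical structure of a dense-sampling study:
a spherical parcellation with contiguous functional networks, ~30 daily
sessions of hormone and perceived-stress covariates (menstrual-cycle-like
estradiol/progesterone, AR(1) testosterone/cortisol), a smooth latent
sensorimotor-association (S-A) axis, and planted covariate effects on parcel
loadings and on network dispersion.  Each generator is deterministic given a
seed; one global seed is split into per-component substreams by stable
hashing of component names, so adding a generator never perturbs others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import (
    NETWORK_ORDER,
    CovariateTable,
    ParcellationMeta,
    SessionRecord,
    ValidationError,
)

__all__ = [
    "GroundTruth",
    "make_parcellation",
    "make_ground_truth",
    "simulate_covariates",
    "simulate_session_loadings",
    "simulate_timeseries",
    "simulate_study",
]


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent RNG substream derived from a global seed and a label."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())])
    )


@dataclass
class GroundTruth:
    """Planted generative parameters for session loadings.

    ``g0`` is the latent S-A axis (centered).  ``beta_local[h]`` gives the
    per-parcel loading change per SD of covariate ``h``; ``gamma_dispersion
    [h][network]`` scales deviations about the network median by
    ``1 + gamma * z(h)``, planting a dispersion effect.
    """

    g0: np.ndarray
    beta_local: dict[str, np.ndarray] = field(default_factory=dict)
    gamma_dispersion: dict[str, dict[str, float]] = field(default_factory=dict)
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self):
        g0 = np.asarray(self.g0, dtype=float)
        if abs(g0.mean()) > 1e-8 * max(1.0, np.abs(g0).max()):
            g0 = g0 - g0.mean()
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        P = g0.size
        for name, beta in self.beta_local.items():
            if np.asarray(beta).shape != (P,):
                raise ValidationError(f"beta_local[{name!r}] must have length {P}")
        self.g0 = g0


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform points on the unit sphere (golden-angle lattice)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    return pts / np.linalg.norm(pts, axis=1, keepdims=True)


def make_parcellation(
    n_parcels: int, n_networks: int = 7, seed: int = 0
) -> ParcellationMeta:
    """Generate a bilaterally symmetric parcellation on the sphere.

    Half the parcels form the left hemisphere on a Fibonacci lattice; the
    right hemisphere mirrors it across the sagittal (x) plane.  Network
    labels are spatially contiguous patches: ``n_networks`` seed parcels are
    drawn at random and every parcel joins its nearest seed (mirrored to the
    right hemisphere, so networks are bilateral).
    """
    if n_parcels % 2:
        raise ValidationError(f"n_parcels must be even, got {n_parcels}")
    half = n_parcels // 2
    if not 1 <= n_networks <= half:
        raise ValidationError("need 1 <= n_networks <= n_parcels/2")
    rng = substream(seed, "parcellation")
    left = _fibonacci_sphere(half)
    # nudge the lattice off its poles so mirrored centroids never coincide
    rot = _random_rotation(rng)
    left = left @ rot.T
    right = left * np.array([-1.0, 1.0, 1.0])

    seeds = rng.choice(half, size=n_networks, replace=False)
    # contiguous patches: nearest seed by geodesic (equivalently max cosine)
    labels_half = np.argmax(left @ left[seeds].T, axis=1)
    names = np.array(NETWORK_ORDER[:n_networks], dtype=object)
    network = np.concatenate([names[labels_half], names[labels_half]])
    return ParcellationMeta(
        parcel_id=np.arange(1, n_parcels + 1),
        hemisphere=np.array(["L"] * half + ["R"] * half, dtype=object),
        network=network,
        centroids=np.vstack([left, right]),
    )


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3-D rotation (QR of a Gaussian, det corrected to +1)."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def simulate_covariates(
    n_sessions: int,
    design: str = "cycle",
    seed: int = 0,
    subject_id: str | None = None,
) -> CovariateTable:
    """Simulate daily covariate trajectories for one subject.

    design="cycle" (female-like): serum estradiol follows a menstrual-cycle
    shape — a dominant ovulatory peak just before mid-series and a smaller
    luteal rise — and progesterone is near zero through the follicular half
    and elevated in the luteal half.  Units: pg/mL and ng/mL, levels matched
    to typical dense-sampling serum panels.  design="diurnal" (male-like):
    morning salivary testosterone (pg/mL) and cortisol (ug/dL) as positive
    AR(1) series.  Both designs add an integer perceived-stress score 0-40.
    The cycle length equals the session count, so one series spans one cycle.
    """
    if n_sessions < 3:
        raise ValidationError("need n_sessions >= 3")
    if design not in ("cycle", "diurnal"):
        raise ValidationError(f"unknown design {design!r}")
    rng = substream(seed, f"covariates:{design}")
    day = np.arange(1, n_sessions + 1, dtype=float)
    t = day / n_sessions  # cycle phase in (0, 1]
    cols: dict[str, np.ndarray] = {}
    if design == "cycle":
        # ovulatory peak centered at phase 13.5/29 (~0.466), luteal shoulder
        ovul = np.exp(-0.5 * ((t - 0.466) / 0.055) ** 2)
        luteal = np.exp(-0.5 * ((t - 0.78) / 0.11) ** 2)
        e2 = 40.0 + 180.0 * ovul + 60.0 * luteal
        e2 *= np.exp(rng.normal(0.0, 0.08, n_sessions))
        p4 = 0.6 + 14.0 / (1.0 + np.exp(-(t - 0.62) / 0.045)) * np.exp(
            -0.5 * ((t - 0.80) / 0.16) ** 2
        )
        p4 *= np.exp(rng.normal(0.0, 0.12, n_sessions))
        cols["estradiol"] = e2
        cols["progesterone"] = p4
        pss_mean, pss_sd = 8.3, 5.0
        subject_id = subject_id or "sub-F"
    else:
        cols["testosterone"] = _positive_ar1(rng, n_sessions, 101.6, 10.0, 0.3)
        cols["cortisol"] = _positive_ar1(rng, n_sessions, 0.50, 0.13, 0.3)
        pss_mean, pss_sd = 10.1, 2.1
        subject_id = subject_id or "sub-M"
    pss = np.clip(np.round(rng.normal(pss_mean, pss_sd, n_sessions)), 0, 40)
    cols["pss_score"] = pss.astype(int)
    df = pd.DataFrame(cols)
    df["subject_id"] = subject_id
    df["session_id"] = [f"day_{d:02d}" for d in range(1, n_sessions + 1)]
    return CovariateTable(df.set_index(["subject_id", "session_id"]))


def _positive_ar1(
    rng: np.random.Generator, n: int, mean: float, sd: float, rho: float
) -> np.ndarray:
    innov = rng.standard_normal(n) * sd * np.sqrt(1 - rho**2)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    for i in range(1, n):
        x[i] = rho * x[i - 1] + innov[i]
    return np.maximum(mean + x, 0.05 * mean)


def smooth_map(
    meta: ParcellationMeta, seed: int = 0, order: int = 4, asymmetry: float = 0.1
) -> np.ndarray:
    """A random smooth, largely bilaterally symmetric field on the sphere.

    Built from random directional harmonics of the centroid coordinates
    with the left-right coordinate folded (made even), so mirrored parcels
    get near-identical values — like real cortical feature maps, which are
    strongly bilaterally symmetric.  ``asymmetry`` adds that fraction of
    hemisphere-specific noise.  Spatially autocorrelated by construction,
    which makes it a suitable null map for calibrating spin tests.
    """
    rng = substream(seed, "smooth_map")
    # each hemisphere is its own sphere; evaluating the field at sagittally
    # mirrored coordinates for the right hemisphere gives mirror-partner
    # parcels near-identical values
    coords = meta.centroids.copy()
    coords[meta.hemisphere == "R"] *= np.array([-1.0, 1.0, 1.0])
    f = np.zeros(meta.n_parcels)
    for _ in range(order):
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        proj = coords @ u
        f = f + rng.standard_normal() * proj + rng.standard_normal() * proj**2
    if asymmetry > 0:
        f = f + asymmetry * f.std() * rng.standard_normal(meta.n_parcels)
    return f - f.mean()


def make_ground_truth(
    meta: ParcellationMeta,
    beta_local: Mapping[str, np.ndarray] | None = None,
    gamma_dispersion: Mapping[str, Mapping[str, float]] | None = None,
    noise_sd: float = 0.01,
    seed: int = 0,
) -> GroundTruth:
    """Build a smooth latent S-A axis on the parcellation.

    The axis is a smooth function of centroid position (a low-order harmonic
    along z plus a small random smooth field), shifted per network so that
    default-mode parcels sit at the association end and somatomotor parcels
    at the sensorimotor end — matching the axis's canonical orientation.
    """
    rng = substream(seed, "ground_truth")
    cen = meta.centroids
    g0 = 0.6 * cen[:, 2] + 0.25 * cen[:, 2] ** 2
    # smooth random field: mix of a few random spherical directions
    for _ in range(3):
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        g0 = g0 + 0.12 * rng.standard_normal() * (cen @ u) ** 2
    offsets = dict.fromkeys(NETWORK_ORDER, 0.0)
    offsets["somatomotor"] = -0.35
    offsets["visual"] = -0.25
    offsets["default_mode"] = 0.35
    offsets["frontoparietal"] = 0.20
    g0 = g0 + np.array([offsets[n] for n in meta.network])
    # rank-uniformize to [-1, 1]: a monotone transform that keeps the field
    # smooth on the sphere and the network ordering intact, while giving the
    # axis an even parcel density so it forms a single dominant gradient
    P = g0.size
    g0 = (stats.rankdata(g0) - (P + 1) / 2) / P * 2.0
    g0 = g0 - g0.mean()
    return GroundTruth(
        g0=g0,
        beta_local={k: np.asarray(v, float) for k, v in (beta_local or {}).items()},
        gamma_dispersion={
            k: dict(v) for k, v in (gamma_dispersion or {}).items()
        },
        noise_sd=noise_sd,
        seed=seed,
    )


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValidationError("cannot z-score a constant covariate")
    return (x - x.mean()) / sd


def simulate_session_loadings(
    meta: ParcellationMeta, truth: GroundTruth, cov: CovariateTable
) -> np.ndarray:
    """Generate a P×S matrix of session loadings with planted effects.

    Per session s: start from ``g0``; add ``beta_local[h] * z(h_s)`` for each
    planted covariate; then for each network with a planted dispersion
    effect, scale deviations about the network median by
    ``1 + gamma * z(h_s)``; finally add isotropic Gaussian noise.  Covariates
    are z-scored across sessions, so betas are loading change per covariate
    SD.  With no planted effects and zero noise every column equals ``g0``.
    """
    P = truth.g0.size
    if meta.n_parcels != P:
        raise ValidationError("ground truth and parcellation disagree on P")
    session_ids = [k[1] for k in cov.data.index]
    S = len(session_ids)
    for name in list(truth.beta_local) + list(truth.gamma_dispersion):
        if name not in cov.data.columns:
            raise ValidationError(f"covariate {name!r} missing from table")
    z = {
        name: _zscore(cov.data[name].to_numpy(float))
        for name in set(truth.beta_local) | set(truth.gamma_dispersion)
    }
    rng = substream(truth.seed, "session_loadings")
    masks = meta.network_masks()
    loadings = np.empty((P, S))
    for s in range(S):
        g = truth.g0.copy()
        for name, beta in truth.beta_local.items():
            g = g + beta * z[name][s]
        for name, per_net in truth.gamma_dispersion.items():
            for net, gamma in per_net.items():
                m = masks[net]
                med = np.median(g[m])
                g[m] = med + (g[m] - med) * (1.0 + gamma * z[name][s])
        if truth.noise_sd > 0:
            g = g + rng.normal(0.0, truth.noise_sd, P)
        loadings[:, s] = g
    return loadings


def simulate_timeseries(
    loadings_col: np.ndarray,
    n_timepoints: int,
    tr: float = 0.72,
    seed: int = 0,
    coupling: float = 1.0,
    noise_sd: float = 0.3,
    n_sources: int = 12,
    kernel_width: float = 0.25,
    band: tuple[float, float] = (0.01, 0.17),
    subject_id: str = "sub-synth",
    session_id: str = "day_01",
) -> SessionRecord:
    """Generate one session of parcel time series from an axis column.

    Factor model: ``n_sources`` band-limited latent signals sit at centers
    spread along the loading axis; parcel p mixes source k with weight
    ``exp(-(g_p - c_k)^2 / 2 l^2)``, so parcels with similar loadings share
    sources and therefore show high pairwise coherence, while distant
    parcels decohere.  The leading coherence-connectome embedding of such a
    session recovers the loading axis.  ``coupling=0`` yields independent
    white noise (a null session).
    """
    if n_timepoints < 128:
        raise ValidationError(f"need >= 128 timepoints, got {n_timepoints}")
    g = np.asarray(loadings_col, float)
    P = g.size
    rng = substream(seed, f"timeseries:{subject_id}:{session_id}")
    sources = _bandlimited_noise(rng, n_sources, n_timepoints, tr, band)
    lo, hi = np.min(g), np.max(g)
    centers = np.linspace(lo, hi, n_sources) if hi > lo else np.zeros(n_sources)
    scale = (hi - lo) * kernel_width if hi > lo else 1.0
    w = np.exp(-0.5 * ((g[:, None] - centers[None, :]) / scale) ** 2)
    w /= np.linalg.norm(w, axis=1, keepdims=True)
    x = coupling * (w @ sources) + noise_sd * rng.standard_normal((P, n_timepoints))
    return SessionRecord(
        subject_id=subject_id,
        session_id=session_id,
        tr=tr,
        series=x,
        time_of_day="morning",
    )


def _bandlimited_noise(
    rng: np.random.Generator,
    n_series: int,
    n: int,
    tr: float,
    band: tuple[float, float],
) -> np.ndarray:
    """White noise FFT-filtered to the passband, unit variance per series."""
    freqs = np.fft.rfftfreq(n, d=tr)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if not mask.any():
        raise ValidationError("passband contains no Fourier frequencies")
    white = rng.standard_normal((n_series, n))
    spec = np.fft.rfft(white, axis=1) * mask[None, :]
    x = np.fft.irfft(spec, n=n, axis=1)
    sd = x.std(axis=1, keepdims=True)
    return x / np.where(sd > 0, sd, 1.0)


def simulate_study(
    n_parcels: int = 100,
    n_sessions: int = 20,
    n_timepoints: int = 512,
    tr: float = 0.72,
    design: str = "cycle",
    seed: int = 0,
    truth: GroundTruth | None = None,
    **ts_kwargs,
) -> tuple[ParcellationMeta, GroundTruth, CovariateTable, list[SessionRecord]]:
    """End-to-end convenience: parcellation, truth, covariates and sessions."""
    meta = make_parcellation(n_parcels, 7, seed=seed)
    cov = simulate_covariates(n_sessions, design=design, seed=seed)
    if truth is None:
        truth = make_ground_truth(meta, seed=seed)
    loadings = simulate_session_loadings(meta, truth, cov)
    session_ids = [k[1] for k in cov.data.index]
    subject = cov.data.index[0][0]
    records = [
        simulate_timeseries(
            loadings[:, s],
            n_timepoints,
            tr=tr,
            seed=seed,
            subject_id=subject,
            session_id=session_ids[s],
            **ts_kwargs,
        )
        for s in range(n_sessions)
    ]
    return meta, truth, cov, records
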