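"""Per-session S-A axis via diffusion map embedding of connectomes.

Each session's coherence connectome is sparsified (top 10% of each row),
converted to a normalized-angle affinity, and embedded with anisotropic
diffusion maps (alpha = 0.5, diffusion time 0, 10 components).  Session
embeddings are Procrustes-aligned to the embedding of the subject's mean
connectome, and the first aligned component — the sensorimotor-association
(S-A) axis — is oriented so that default-mode parcels load higher than
somatomotor parcels (association-positive convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.linalg import orthogonal_procrustes
from scipy.sparse.csgraph import connected_components

from .connectivity import CoherenceMatrix
from .data_model import AnalysisConfig, ParcellationMeta, ValidationError

__all__ = [
    "EmbeddingResult",
    "AlignedAxes",
    "row_threshold",
    "affinity_normalized_angle",
    "diffusion_map",
    "procrustes_align",
    "compute_sa_axes",
    "session_qc",
]


@dataclass(frozen=True)
class EmbeddingResult:
    """Diffusion map embedding: components, eigenvalues, variance explained.

    The trivial constant eigenvector (eigenvalue 1) is excluded; reported
    eigenvalues are non-increasing and strictly below 1.  Variance explained
    is each eigenvalue's share of the sum over retained components — a
    toolbox convention, not an absolute variance decomposition.
    """

    components: np.ndarray
    eigenvalues: np.ndarray
    variance_explained: np.ndarray

    def __post_init__(self):
        lam = np.asarray(self.eigenvalues, float)
        if np.any(np.diff(lam) > 1e-12) or np.any(lam >= 1.0):
            raise ValidationError("eigenvalues must be non-increasing and < 1")
        if self.components.shape[1] != lam.size:
            raise ValidationError("component count must match eigenvalue count")


@dataclass(frozen=True)
class AlignedAxes:
    """Aligned, oriented per-session S-A axes for one subject.

    loadings: P×S matrix of session axes; mean_axis: the subject's reference
    axis; session_corr: Spearman correlation of each session axis with the
    mean axis; variance_explained_pc1: per-session share of the first
    component.
    """

    loadings: np.ndarray
    mean_axis: np.ndarray
    session_ids: tuple[str, ...]
    session_corr: np.ndarray
    variance_explained_pc1: np.ndarray
    subject_id: str = ""

    @property
    def n_sessions(self) -> int:
        return self.loadings.shape[1]

    @property
    def n_parcels(self) -> int:
        return self.loadings.shape[0]


def row_threshold(W: np.ndarray | CoherenceMatrix, density: float) -> np.ndarray:
    """Keep the top ``ceil(density * P)`` entries of each row, zero the rest.

    The result is generally asymmetric (each row keeps its own strongest
    connections).  Ties are broken toward lower column indices.
    """
    if not 0 < density <= 1:
        raise ValidationError(f"density must be in (0, 1], got {density}")
    vals = W.values if isinstance(W, CoherenceMatrix) else np.asarray(W, float)
    P = vals.shape[1]
    k = int(np.ceil(density * P))
    if k >= P:
        return vals.copy()
    # stable argsort of -row → ties resolved by lower column index
    order = np.argsort(-vals, axis=1, kind="stable")
    out = np.zeros_like(vals)
    rows = np.repeat(np.arange(vals.shape[0]), k)
    cols = order[:, :k].ravel()
    out[rows, cols] = vals[rows, cols]
    return out


def affinity_normalized_angle(X: np.ndarray) -> np.ndarray:
    """Normalized-angle affinity between rows: a = 1 - arccos(cos_sim)/pi.

    Maps cosine similarity in [-1, 1] to affinity in [0, 1]; identical rows
    get 1, orthogonal rows 0.5, anti-parallel rows 0.
    """
    X = np.asarray(X, float)
    norms = np.linalg.norm(X, axis=1)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        raise ValidationError(f"all-zero row for parcel index {zero[0]}")
    Xn = X / norms[:, None]
    cos = np.clip(Xn @ Xn.T, -1.0, 1.0)
    a = 1.0 - np.arccos(cos) / np.pi
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 1.0)
    return a


def diffusion_map(
    A: np.ndarray,
    alpha: float = 0.5,
    diffusion_time: int = 0,
    n_components: int = 10,
) -> EmbeddingResult:
    """Anisotropic diffusion map embedding of a symmetric affinity matrix.

    The affinity is density-normalized, ``A_ij / (d_i^alpha d_j^alpha)``,
    then row-normalized into a Markov operator whose eigenvectors (the
    trivial constant one dropped) are scaled by ``lambda / (1 - lambda)``
    at diffusion time 0, or ``lambda^t`` for t > 0.
    """
    A = np.asarray(A, float)
    P = A.shape[0]
    if A.shape != (P, P) or np.abs(A - A.T).max() > 1e-10:
        raise ValidationError("affinity must be square symmetric")
    if A.min() < 0:
        raise ValidationError("affinity must be nonnegative")
    n_comp, _ = connected_components(A > 0, directed=False)
    if n_comp > 1:
        raise ValidationError("affinity graph not connected")
    d = A.sum(axis=1)
    if np.any(d <= 0):
        raise ValidationError("affinity has a zero-degree node")
    with np.errstate(divide="ignore"):
        Da = d**-alpha
    At = A * np.outer(Da, Da)
    dt = At.sum(axis=1)
    # symmetric conjugate of the Markov operator M = D^-1 At
    inv_sqrt = 1.0 / np.sqrt(dt)
    S = At * np.outer(inv_sqrt, inv_sqrt)
    S = (S + S.T) / 2.0
    lam, phi = np.linalg.eigh(S)
    order = np.argsort(lam)[::-1]
    lam, phi = lam[order], phi[:, order]
    psi = phi * inv_sqrt[:, None]
    # normalize against the trivial eigenvector (constant after conversion)
    psi = psi / np.linalg.norm(psi, axis=0, keepdims=True)
    K = min(n_components, P - 1)
    lam_k = np.clip(lam[1 : K + 1], None, 1.0 - 1e-12)
    lam_k = np.maximum.accumulate(lam_k[::-1])[::-1]  # enforce monotone
    psi_k = psi[:, 1 : K + 1]
    if diffusion_time == 0:
        scale = lam_k / (1.0 - lam_k)
    else:
        scale = lam_k**diffusion_time
    components = psi_k * scale[None, :]
    lam_pos = np.maximum(lam_k, 0.0)
    total = lam_pos.sum()
    ve = lam_pos / total if total > 0 else np.zeros(K)
    return EmbeddingResult(
        components=components, eigenvalues=lam_k, variance_explained=ve
    )


def procrustes_align(source: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Orthogonal Procrustes alignment of source onto reference (no scaling).

    Both matrices are column mean-centered; the source is rotated/reflected
    by the orthogonal matrix minimizing the Frobenius distance to the
    centered reference.  No scaling is applied, preserving the dispersion of
    loadings along each axis.
    """
    source = np.asarray(source, float)
    reference = np.asarray(reference, float)
    if source.shape != reference.shape:
        raise ValidationError(
            f"shape mismatch {source.shape} != {reference.shape}"
        )
    src = source - source.mean(axis=0)
    ref = reference - reference.mean(axis=0)
    R, _ = orthogonal_procrustes(src, ref)
    return src @ R


def _embed_fc(
    W: CoherenceMatrix | np.ndarray, cfg: AnalysisConfig
) -> EmbeddingResult:
    thr = row_threshold(W, cfg.density)
    aff = affinity_normalized_angle(thr)
    return diffusion_map(
        aff,
        alpha=cfg.alpha,
        diffusion_time=cfg.diffusion_time,
        n_components=cfg.n_components,
    )


def compute_sa_axes(
    fcs: Sequence[CoherenceMatrix],
    meta: ParcellationMeta,
    cfg: AnalysisConfig | None = None,
    subject_id: str = "",
) -> AlignedAxes:
    """S-A axis per session, aligned to the subject's mean-connectome axis.

    The mean connectome across sessions is embedded to give the reference;
    each session connectome is embedded with the same parameters and
    Procrustes-aligned to the reference; the first aligned component is that
    session's S-A axis.  All axes (reference included) are flipped together
    if needed so default-mode parcels load above somatomotor parcels.
    """
    cfg = cfg or AnalysisConfig()
    if len(fcs) < 2:
        raise ValidationError("need >= 2 sessions")
    P = meta.n_parcels
    for fc in fcs:
        if fc.n_parcels != P:
            raise ValidationError(
                f"session {fc.session_id}: {fc.n_parcels} parcels != {P}"
            )
    mean_fc = np.mean([fc.values for fc in fcs], axis=0)
    ref = _embed_fc(mean_fc, cfg)
    ref_comp = ref.components - ref.components.mean(axis=0)

    S = len(fcs)
    loadings = np.empty((P, S))
    ve1 = np.empty(S)
    for s, fc in enumerate(fcs):
        emb = _embed_fc(fc, cfg)
        aligned = procrustes_align(emb.components, ref_comp)
        loadings[:, s] = aligned[:, 0]
        ve1[s] = emb.variance_explained[0]

    mean_axis = ref_comp[:, 0].copy()
    dmn = meta.network == "default_mode"
    smn = meta.network == "somatomotor"
    if dmn.any() and smn.any():
        if mean_axis[dmn].mean() < mean_axis[smn].mean():
            mean_axis = -mean_axis
            loadings = -loadings
    corr = np.array(
        [stats.spearmanr(loadings[:, s], mean_axis).statistic for s in range(S)]
    )
    return AlignedAxes(
        loadings=loadings,
        mean_axis=mean_axis,
        session_ids=tuple(fc.session_id for fc in fcs),
        session_corr=corr,
        variance_explained_pc1=ve1,
        subject_id=subject_id,
    )


def session_qc(
    axes: AlignedAxes,
    corr_threshold: float = 0.5,
    ve_z_threshold: float = 3.0,
) -> list[str]:
    """Flag sessions whose axis is markedly dissimilar to the subject mean.

    A session is flagged when its Spearman correlation with the mean axis
    falls below ``corr_threshold`` or its first-component variance explained
    lies more than ``ve_z_threshold`` robust SDs below the median (median /
    MAD rule).  This automates the kind of by-inspection exclusion dense-
    sampling studies apply to corrupted sessions.
    """
    if axes.n_sessions < 3:
        raise ValidationError("need >= 3 sessions for QC")
    flagged = set(np.array(axes.session_ids)[axes.session_corr < corr_threshold])
    ve = axes.variance_explained_pc1
    med = np.median(ve)
    mad = np.median(np.abs(ve - med)) * 1.4826
    if mad > 0:
        z = (med - ve) / mad
        flagged |= set(np.array(axes.session_ids)[z > ve_z_threshold])
    return sorted(flagged, key=list(axes.session_ids).index)
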