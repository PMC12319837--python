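"""Session-wise coherence connectomes.

Regional time series are band-limited with a maximal overlap discrete
wavelet transform (MODWT) multiresolution analysis — detail scales 3..6 at a
typical fMRI sampling rate cover ~0.01-0.17 Hz — and pairwise connectivity
is the magnitude-squared coherence |S_xy|^2 / (S_xx S_yy) averaged over the
passband.  Coherence is insensitive to per-region hemodynamic response
shape, which is the reason this workflow prefers it to correlation.

Estimator: Welch cross-spectra (Hann window, 50% overlap).  With d
effectively independent segment averages the null distribution of MSC for
unrelated Gaussian series is P(C > c) = (1-c)^(d-1), which supplies edge
p-values for Benjamini-Hochberg thresholding of the connectome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import signal
from statsmodels.stats.multitest import multipletests

from .data_model import AnalysisConfig, SessionRecord, ValidationError

__all__ = [
    "CoherenceMatrix",
    "first_eigenvariate",
    "passband_edges",
    "modwt_band_series",
    "session_coherence_fc",
]

#: least-asymmetric length-8 wavelet (Daubechies LA(8))
WAVELET = "sym4"


@dataclass(frozen=True)
class CoherenceMatrix:
    """P×P magnitude-squared-coherence connectome for one session."""

    values: np.ndarray
    tr: float
    band: tuple[float, float]
    n_segments: int
    session_id: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError("coherence matrix must be square")
        if np.abs(v - v.T).max() > 1e-10:
            raise ValidationError("coherence matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValidationError("diagonal must be zero")
        if v.min() < 0 or v.max() > 1:
            raise ValidationError("coherence values must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    @property
    def n_parcels(self) -> int:
        return self.values.shape[0]


def first_eigenvariate(block: np.ndarray) -> np.ndarray:
    """Rank-1 temporal summary of a voxels × timepoints block.

    Returns the unit-norm leading right singular vector (the shared temporal
    factor), with its sign fixed so that its mean correlation with the voxel
    rows is positive — i.e. it tracks the majority of voxels.
    """
    block = np.asarray(block, float)
    if block.ndim == 1:
        block = block[None, :]
    if block.shape[0] < 1 or block.shape[1] < 2:
        raise ValidationError("block must have >= 1 voxel and >= 2 timepoints")
    if not np.isfinite(block).all():
        raise ValidationError("block contains non-finite values")
    if not np.any(block):
        raise ValidationError("degenerate block: all zeros")
    _, _, vt = np.linalg.svd(block, full_matrices=False)
    v = vt[0]
    v = v / np.linalg.norm(v)
    rows = block - block.mean(axis=1, keepdims=True)
    vc = v - v.mean()
    denom = np.linalg.norm(rows, axis=1) * np.linalg.norm(vc)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, rows @ vc / denom, 0.0)
    if corr.mean() < 0:
        v = -v
    return v


def passband_edges(tr: float, scales: tuple[int, int]) -> tuple[float, float]:
    """Frequency band covered by the union of dyadic MODWT detail scales.

    Detail scale j spans [fs / 2^(j+1), fs / 2^j] with fs = 1/tr, so scales
    [j_lo, j_hi] jointly cover (fs / 2^(j_hi+1), fs / 2^j_lo).
    """
    j_lo, j_hi = scales
    if j_lo > j_hi or j_lo < 1:
        raise ValidationError(f"bad scale range {scales}")
    if tr <= 0:
        raise ValidationError("tr must be positive")
    fs = 1.0 / tr
    return fs / 2 ** (j_hi + 1), fs / 2**j_lo


def modwt_band_series(
    record: SessionRecord, scales: tuple[int, int] = (3, 6)
) -> SessionRecord:
    """Band-limit each parcel series to a set of MODWT detail scales.

    Each series is replaced by the sum of its MODWT multiresolution detail
    components over the requested scales (reflection boundary, LA(8)
    filter).  Detail components carry no DC, so outputs are near zero-mean.
    """
    j_lo, j_hi = scales
    n = record.n_timepoints
    if n < 2 ** (j_hi + 1):
        raise ValidationError(
            f"series too short for scale {j_hi}: need >= {2 ** (j_hi + 1)} points"
        )
    block = 2**j_hi
    pad = (-n) % block
    x = record.series
    if pad:
        x = np.pad(x, ((0, 0), (0, pad)), mode="reflect")
    out = np.empty_like(x)
    for p in range(x.shape[0]):
        # mra returns [S_jhi, D_jhi, ..., D_1]; pick scales j_lo..j_hi
        comps = pywt.mra(x[p], WAVELET, level=j_hi, transform="swt")
        details = comps[1:]  # D_jhi .. D_1
        keep = [details[j_hi - j] for j in range(j_lo, j_hi + 1)]
        out[p] = np.sum(keep, axis=0)
    return SessionRecord(
        subject_id=record.subject_id,
        session_id=record.session_id,
        tr=record.tr,
        series=out[:, :n],
        time_of_day=record.time_of_day,
    )


def _welch_spectra(
    x: np.ndarray, nperseg: int, noverlap: int
) -> tuple[np.ndarray, np.ndarray, int]:
    """Windowed segment FFTs for all parcels.

    Returns (freqs, Z, n_segments) with Z of shape parcels × segments ×
    rfft bins; cross-spectra follow as averages of Z_i * conj(Z_j).
    """
    P, n = x.shape
    step = nperseg - noverlap
    n_seg = (n - nperseg) // step + 1
    if n_seg < 2:
        raise ValidationError(
            f"insufficient data for coherence df: {n_seg} Welch segment(s)"
        )
    win = signal.get_window("hann", nperseg)
    idx = np.arange(nperseg)[None, :] + step * np.arange(n_seg)[:, None]
    segs = x[:, idx]  # P × n_seg × nperseg
    segs = (segs - segs.mean(axis=2, keepdims=True)) * win[None, None, :]
    Z = np.fft.rfft(segs, axis=2)
    freqs = np.fft.rfftfreq(nperseg, d=1.0)  # in cycles/sample; scaled later
    return freqs, Z, n_seg


def session_coherence_fc(
    record: SessionRecord,
    cfg: AnalysisConfig | None = None,
    band_limit: bool = True,
    fdr: bool = True,
) -> CoherenceMatrix:
    """Magnitude-squared coherence connectome for one session.

    The record is MODWT band-limited per the config (unless ``band_limit``
    is False because it already was), Welch cross-spectra are averaged over
    segments, and coherence is averaged over the frequency bins inside the
    dyadic passband.  Edge p-values p = (1-C)^(d-1), with d the effective
    (overlap-corrected) number of independent segments, are BH-FDR
    thresholded across the P(P-1)/2 edges; non-significant edges are zeroed.
    """
    cfg = cfg or AnalysisConfig()
    band = passband_edges(record.tr, cfg.scales)
    rec = modwt_band_series(record, cfg.scales) if band_limit else record
    nperseg = min(cfg.segment_length, rec.n_timepoints)
    noverlap = int(round(nperseg * cfg.overlap))
    freqs, Z, n_seg = _welch_spectra(rec.series, nperseg, noverlap)
    freqs_hz = freqs / record.tr
    in_band = (freqs_hz >= band[0]) & (freqs_hz <= band[1])
    if not in_band.any():
        in_band = np.zeros_like(freqs_hz, bool)
        in_band[np.argmin(np.abs(freqs_hz - np.mean(band)))] = True

    P = rec.n_parcels
    coh = np.zeros((P, P))
    for f in np.flatnonzero(in_band):
        Zf = Z[:, :, f]  # P × n_seg
        S = Zf @ Zf.conj().T / n_seg
        auto = np.real(np.diag(S))
        denom = np.outer(auto, auto)
        with np.errstate(invalid="ignore", divide="ignore"):
            cf = np.where(denom > 0, np.abs(S) ** 2 / denom, 0.0)
        coh += cf
    coh /= in_band.sum()
    coh = np.clip((coh + coh.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(coh, 0.0)

    # effective independent averages: 50% overlap halves each extra segment
    d_eff = 1.0 + (n_seg - 1) * (1.0 - cfg.overlap) * 2.0 * 0.5
    if fdr:
        iu = np.triu_indices(P, k=1)
        pvals = (1.0 - coh[iu]) ** (d_eff - 1.0)
        reject, _, _, _ = multipletests(pvals, alpha=cfg.fdr_q, method="fdr_bh")
        mask = np.zeros((P, P), bool)
        mask[iu] = reject
        mask |= mask.T
        coh = np.where(mask, coh, 0.0)
    return CoherenceMatrix(
        values=coh,
        tr=record.tr,
        band=band,
        n_segments=n_seg,
        session_id=record.session_id,
    )
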