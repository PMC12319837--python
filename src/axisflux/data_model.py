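"""Core domain types and file I/O.

The pipeline operates on parcellated BOLD time series collected in a
dense-sampling design (one subject scanned on ~30 consecutive days).  All
downstream modules consume the validated containers defined here:

* :class:`ParcellationMeta` — parcel identities, hemispheres, seven-network
  labels and spherical centroids (the substrate for spin permutation tests).
* :class:`SessionRecord` — one session's parcels × timepoints matrix.
* :class:`CovariateTable` — session-keyed hormone and perceived-stress values.
* :class:`AnalysisConfig` — the knobs of the gradient/coherence/statistics
  stages, with defaults matching the canonical dense-sampling workflow.

Parcel ids are 1-based in files and external tables, 0-based internally;
matrices are always indexed in the order of the parcellation metadata file.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("axisflux")

#: canonical seven-network order used for dispersion tables and plots
NETWORK_ORDER = (
    "visual",
    "somatomotor",
    "dorsal_attention",
    "ventral_attention",
    "limbic",
    "frontoparietal",
    "default_mode",
)

HEMISPHERES = ("L", "R")


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


@dataclass(frozen=True)
class ParcellationMeta:
    """Parcellation metadata: ids, hemispheres, network labels, centroids.

    Parameters
    ----------
    parcel_id : (P,) int array, 1..P contiguous and unique.
    hemisphere : (P,) array of "L"/"R".
    network : (P,) array of the seven canonical network names.
    centroids : (P, 3) float array of unit-norm spherical centroids.
    """

    parcel_id: np.ndarray
    hemisphere: np.ndarray
    network: np.ndarray
    centroids: np.ndarray

    def __post_init__(self):
        pid = np.asarray(self.parcel_id, dtype=int)
        hemi = np.asarray(self.hemisphere, dtype=object)
        net = np.asarray(self.network, dtype=object)
        cen = np.asarray(self.centroids, dtype=float)
        P = pid.size
        if not np.array_equal(np.sort(pid), np.arange(1, P + 1)):
            raise ValidationError("parcel_ids must be unique and contiguous 1..P")
        if hemi.shape != (P,) or not set(hemi) <= set(HEMISPHERES):
            raise ValidationError("hemisphere must be 'L' or 'R' for every parcel")
        unknown = set(net) - set(NETWORK_ORDER)
        if net.shape != (P,) or unknown:
            raise ValidationError(f"unknown network labels: {sorted(map(str, unknown))}")
        if cen.shape != (P, 3):
            raise ValidationError(f"centroids must be (P, 3), got {cen.shape}")
        norms = np.linalg.norm(cen, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            bad = int(np.argmax(np.abs(norms - 1.0)))
            raise ValidationError(
                f"centroid of parcel {pid[bad]} has norm {norms[bad]:.6g}, expected 1"
            )
        object.__setattr__(self, "parcel_id", pid)
        object.__setattr__(self, "hemisphere", hemi)
        object.__setattr__(self, "network", net)
        object.__setattr__(self, "centroids", cen)

    @property
    def n_parcels(self) -> int:
        return self.parcel_id.size

    def network_masks(self) -> dict[str, np.ndarray]:
        """Boolean mask per canonical network (only networks present)."""
        return {
            name: self.network == name
            for name in NETWORK_ORDER
            if np.any(self.network == name)
        }

    @classmethod
    def from_csv(cls, path: str | Path) -> "ParcellationMeta":
        df = pd.read_csv(path)
        required = {"parcel_id", "hemisphere", "network", "x", "y", "z"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"parcellation CSV missing columns: {sorted(missing)}")
        return cls(
            parcel_id=df["parcel_id"].to_numpy(),
            hemisphere=df["hemisphere"].to_numpy(),
            network=df["network"].to_numpy(),
            centroids=df[["x", "y", "z"]].to_numpy(float),
        )

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "parcel_id": self.parcel_id,
                "hemisphere": self.hemisphere,
                "network": self.network,
                "x": self.centroids[:, 0],
                "y": self.centroids[:, 1],
                "z": self.centroids[:, 2],
            }
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class SessionRecord:
    """One scanning session: parcels × timepoints regional time series."""

    subject_id: str
    session_id: str
    tr: float
    series: np.ndarray
    time_of_day: str = "unspecified"

    #: minimum timepoints for wavelet scale-6 support
    MIN_TIMEPOINTS = 128

    def __post_init__(self):
        series = np.asarray(self.series, dtype=float)
        if self.tr <= 0:
            raise ValidationError(f"tr must be positive, got {self.tr}")
        if self.time_of_day not in ("morning", "evening", "unspecified"):
            raise ValidationError(f"bad time_of_day: {self.time_of_day}")
        if series.ndim != 2:
            raise ValidationError("series must be a 2-D parcels × timepoints matrix")
        if series.shape[1] < self.MIN_TIMEPOINTS:
            raise ValidationError(
                f"session {self.session_id}: {series.shape[1]} timepoints < "
                f"{self.MIN_TIMEPOINTS} required"
            )
        bad = np.argwhere(~np.isfinite(series))
        if bad.size:
            locs = ", ".join(f"(row {r}, col {c})" for r, c in bad[:5])
            raise ValidationError(
                f"session {self.session_id}: non-finite values at {locs}"
            )
        object.__setattr__(self, "series", series)

    @property
    def n_parcels(self) -> int:
        return self.series.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.series.shape[1]


@dataclass(frozen=True)
class CovariateTable:
    """Session-keyed covariates (hormone concentrations, PSS scores).

    Wraps a DataFrame indexed by (subject_id, session_id) with one row per
    session.  Known columns carry their units: estradiol pg/mL, progesterone
    ng/mL, testosterone ng/dL or pg/mL, cortisol ug/dL, pss_score integer
    0–40.  Unknown columns are preserved as generic covariates.
    """

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data
        if not isinstance(df.index, pd.MultiIndex) or df.index.names != [
            "subject_id",
            "session_id",
        ]:
            raise ValidationError(
                "CovariateTable must be indexed by (subject_id, session_id)"
            )
        dup = df.index[df.index.duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate session keys: {list(dup[:5])}")
        if "pss_score" in df.columns:
            pss = df["pss_score"].to_numpy()
            if np.any((pss < 0) | (pss > 40)):
                raise ValidationError("pss_score outside [0, 40]")
        for col in ("estradiol", "progesterone", "testosterone", "cortisol"):
            if col in df.columns and np.any(df[col].to_numpy(float) < 0):
                raise ValidationError(f"{col} contains negative values")

    @property
    def covariate_names(self) -> list[str]:
        return list(self.data.columns)

    def column(self, name: str, session_ids: Sequence[str] | None = None) -> np.ndarray:
        """Covariate values, optionally reordered to the given session ids."""
        if name not in self.data.columns:
            raise ValidationError(f"unknown covariate: {name!r}")
        if session_ids is None:
            return self.data[name].to_numpy(float)
        df = self.data.reset_index().set_index("session_id")
        missing = [s for s in session_ids if s not in df.index]
        if missing:
            raise ValidationError(f"sessions missing from covariate table: {missing}")
        return df.loc[list(session_ids), name].to_numpy(float)

    def to_csv(self, path: str | Path) -> None:
        self.data.reset_index().to_csv(path, index=False)


@dataclass
class AnalysisConfig:
    """Tunable parameters of the full pipeline, with workflow defaults.

    Gradient stage: keep the top ``density`` fraction of each connectome row,
    embed with diffusion maps at anisotropy ``alpha`` and diffusion time
    ``diffusion_time``, retaining ``n_components`` axes.  Coherence stage:
    MODWT detail scales ``scales`` define the passband; Welch segments of
    ``segment_length`` samples with fractional ``overlap``; edges kept at
    FDR level ``fdr_q``.  Statistics: ``n_perm`` spatial rotations and the
    Bonferroni families for the 7 within- / 21 between-network dispersion
    tests.
    """

    density: float = 0.10
    alpha: float = 0.5
    diffusion_time: int = 0
    n_components: int = 10
    scales: tuple[int, int] = (3, 6)
    segment_length: int = 128
    overlap: float = 0.5
    fdr_q: float = 0.05
    n_perm: int = 1000
    seed: int = 0
    bonferroni_alpha: float = 0.025
    n_within_family: int = 7
    n_between_family: int = 21
    include_sessions: list[str] = field(default_factory=list)
    exclude_sessions: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not 0 < self.density <= 1:
            raise ValidationError(f"density must be in (0, 1], got {self.density}")
        if not 0 <= self.alpha <= 1:
            raise ValidationError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.n_perm < 1:
            raise ValidationError("n_perm must be >= 1")
        if int(self.seed) != self.seed:
            raise ValidationError("seed must be an integer")

    @property
    def alpha_within(self) -> float:
        """Bonferroni threshold for the within-network dispersion family."""
        return self.bonferroni_alpha / self.n_within_family

    @property
    def alpha_between(self) -> float:
        """Bonferroni threshold for the between-network dispersion family."""
        return self.bonferroni_alpha / self.n_between_family

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "scales" in raw:
            raw["scales"] = tuple(raw["scales"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["scales"] = list(d["scales"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# I/O operations


def read_session(
    series_path: str | Path,
    meta: ParcellationMeta,
    tr: float,
    subject_id: str = "sub-01",
    session_id: str | None = None,
    time_of_day: str = "unspecified",
) -> SessionRecord:
    """Read a parcels × timepoints delimited-text file as a SessionRecord.

    Rows are parcels in metadata order; a header row is tolerated.  Raises a
    structured error on parcel-count mismatch or non-numeric/missing cells.
    """
    path = Path(series_path)
    df = pd.read_csv(path, sep=None, engine="python", header=None)
    # drop a header row of non-numeric cells if present
    first = pd.to_numeric(df.iloc[0], errors="coerce")
    if first.isna().all():
        df = df.iloc[1:]
    arr = df.apply(pd.to_numeric, errors="coerce").to_numpy(float)
    if arr.shape[0] != meta.n_parcels:
        raise ValidationError(
            f"parcel count mismatch {arr.shape[0]} != {meta.n_parcels}"
        )
    bad = np.argwhere(~np.isfinite(arr))
    if bad.size:
        locs = ", ".join(f"(row {r}, col {c})" for r, c in bad[:5])
        raise ValidationError(f"{path.name}: missing/non-numeric values at {locs}")
    return SessionRecord(
        subject_id=subject_id,
        session_id=session_id or path.stem,
        tr=tr,
        series=arr,
        time_of_day=time_of_day,
    )


def write_session(record: SessionRecord, path: str | Path) -> None:
    """Write the session series as a TSV (parcels as rows, no header)."""
    np.savetxt(path, record.series, delimiter="\t", fmt="%.17g")


def read_covariates(path: str | Path) -> CovariateTable:
    """Read a session-keyed covariate CSV.

    Requires ``subject_id`` and ``session_id`` columns; all other columns
    become covariates.  Enforces pss range and session-key uniqueness.
    """
    df = pd.read_csv(path)
    for col in ("subject_id", "session_id"):
        if col not in df.columns:
            raise ValidationError(f"covariate CSV missing column {col!r}")
    df["subject_id"] = df["subject_id"].astype(str)
    df["session_id"] = df["session_id"].astype(str)
    return CovariateTable(df.set_index(["subject_id", "session_id"]))


def filter_sessions(
    records: Sequence[SessionRecord], include: Sequence[str]
) -> list[SessionRecord]:
    """Subset sessions to the listed ids, preserving the include-list order.

    Mirrors the dense-sampling designs in which analyses run on an explicit
    list of experimental days (e.g. an evenly spaced 20-day subsample of a
    30-day study, or a morning-session-only subset).
    """
    by_id = {r.session_id: r for r in records}
    unknown = [s for s in include if s not in by_id]
    if unknown:
        raise ValidationError(f"unknown session ids: {unknown}")
    return [by_id[s] for s in include]


# ---------------------------------------------------------------------------
# HDF5 persistence for matrix stacks (connectomes, embeddings, spins)


def save_matrices(
    path: str | Path,
    datasets: dict[str, np.ndarray],
    attrs: dict | None = None,
) -> None:
    """Persist named arrays in an HDF5 container with exact round-trip."""
    with h5py.File(path, "w") as fh:
        for name, arr in datasets.items():
            fh.create_dataset(name, data=np.asarray(arr))
        for key, val in (attrs or {}).items():
            fh.attrs[key] = val


def load_matrices(path: str | Path) -> tuple[dict[str, np.ndarray], dict]:
    with h5py.File(path, "r") as fh:
        data = {name: fh[name][()] for name in fh}
        attrs = dict(fh.attrs)
    return data, attrs
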