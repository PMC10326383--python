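"""Construction of functional and structural brain connectivity matrices.

Functional connectivity is the Pearson correlation between regional
signal time series; structural connectivity is a streamline-count matrix
normalized by total brain volume.  Matrices of the two modalities are
stacked channel-wise into multi-modal samples for classification.

Conventions: a functional matrix has unit diagonal and entries in
[-1, 1]; a structural matrix is non-negative with zero diagonal
(self-connections are undefined for tractography).  Region ordering is
taken from the input and must match across a subject's modalities —
nothing is re-sorted silently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

FUNCTIONAL = "functional"
STRUCTURAL = "structural"

_SYMMETRY_TOL = 1e-8


@dataclass
class TimeSeriesSet:
    """Regional signal table for one subject: R regions × T timepoints."""

    subject_id: str
    regions: list[str]
    series: np.ndarray

    def __post_init__(self):
        self.series = np.asarray(self.series, dtype=float)
        r, t = self.series.shape
        if r != len(self.regions):
            raise ValueError("series row count does not match region labels")
        if r < 2:
            raise ValueError("need at least 2 regions")
        if t < 3:
            raise ValueError("need at least 3 timepoints")
        if len(set(self.regions)) != r:
            raise ValueError("region labels must be unique")
        if not np.isfinite(self.series).all():
            raise ValueError("time series contains missing/non-finite values")

    @property
    def n_regions(self) -> int:
        return self.series.shape[0]


@dataclass
class ConnectivityMatrix:
    """One subject's square symmetric weighted network for one modality."""

    subject_id: str
    modality: str
    matrix: np.ndarray
    regions: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not self.regions:
            self.regions = [f"r{i}" for i in range(m.shape[0])]
        if len(self.regions) != m.shape[0]:
            raise ValueError("region labels do not match matrix size")
        if np.abs(m - m.T).max() > _SYMMETRY_TOL:
            raise ValueError("connectivity matrix is not symmetric")
        if self.modality == FUNCTIONAL:
            if np.abs(np.diag(m) - 1.0).max() > _SYMMETRY_TOL:
                raise ValueError("functional matrix must have unit diagonal")
            if m.min() < -1 - _SYMMETRY_TOL or m.max() > 1 + _SYMMETRY_TOL:
                raise ValueError("functional entries must lie in [-1, 1]")
        elif self.modality == STRUCTURAL:
            if m.min() < 0:
                raise ValueError("structural entries must be non-negative")
        else:
            raise ValueError(f"unknown modality {self.modality!r}")

    @property
    def n_regions(self) -> int:
        return self.matrix.shape[0]


@dataclass
class MultiModalSample:
    """Channel-stacked connectivity matrices with a binary class label.

    ``label`` is 1 for the abnormal (AD) group and 0 for healthy
    controls.  ``tensor`` has shape R × R × n_channels.
    """

    subject_id: str
    channels: list[ConnectivityMatrix]
    label: int
    is_original: bool = True
    shift: int = 0

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError("label must be 0 (HC) or 1 (AB)")
        if not self.channels:
            raise ValueError("need at least one channel")

    @property
    def n_regions(self) -> int:
        return self.channels[0].n_regions

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def tensor(self) -> np.ndarray:
        return np.stack([c.matrix for c in self.channels], axis=-1)

    @property
    def sample_id(self) -> str:
        return f"{self.subject_id}#s{self.shift}"


def pearson_connectivity(ts: TimeSeriesSet) -> ConnectivityMatrix:
    """Pearson-correlation functional network from regional time series.

    Entry (X, Y) is cov(X, Y) / (sigma_X * sigma_Y) over timepoints; the
    normalization constant cancels, so population vs sample variance is
    immaterial.  Results are clamped to [-1, 1] and the diagonal set to
    exactly 1 to absorb floating-point rounding.
    """
    sd = ts.series.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = ", ".join(ts.regions[i] for i in dead)
        raise ValueError(f"zero-variance region(s): {names}")
    r = np.corrcoef(ts.series)
    r = np.clip(r, -1.0, 1.0)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(ts.subject_id, FUNCTIONAL, r, list(ts.regions))


def normalize_structural(streamline_counts: np.ndarray, brain_volume: float,
                         subject_id: str = "", regions: list[str] | None = None
                         ) -> ConnectivityMatrix:
    """Structural network: streamline counts divided by brain volume (mm^3)."""
    counts = np.asarray(streamline_counts, dtype=float)
    if brain_volume <= 0:
        raise ValueError(f"brain volume must be positive, got {brain_volume}")
    if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
        raise ValueError("streamline counts must be a square matrix")
    if np.abs(counts - counts.T).max() > _SYMMETRY_TOL * max(1.0, np.abs(counts).max()):
        raise ValueError("streamline counts are asymmetric beyond tolerance")
    if counts.min() < 0:
        raise ValueError("streamline counts must be non-negative")
    m = counts / float(brain_volume)
    np.fill_diagonal(m, 0.0)
    return ConnectivityMatrix(subject_id, STRUCTURAL, m,
                              list(regions) if regions else [])


def stack_modalities(mats: list[ConnectivityMatrix], label: int,
                     subject_id: str | None = None) -> MultiModalSample:
    """Stack per-modality matrices of one subject into a multi-channel sample."""
    if not mats:
        raise ValueError("need at least one connectivity matrix")
    first = mats[0]
    for m in mats[1:]:
        if m.n_regions != first.n_regions:
            raise ValueError(
                f"channel size mismatch: {m.n_regions} vs {first.n_regions}")
        for i, (a, b) in enumerate(zip(first.regions, m.regions)):
            if a != b:
                raise ValueError(
                    f"region order mismatch at index {i}: {a!r} vs {b!r}")
    sid = subject_id if subject_id is not None else first.subject_id
    logger.debug("stacked %d channels of %d regions for %s",
                 len(mats), first.n_regions, sid)
    return MultiModalSample(sid, list(mats), label)
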