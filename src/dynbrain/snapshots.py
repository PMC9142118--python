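"""Sliding-window segmentation of BOLD series and windowed Pearson connectivity.

A BOLD matrix of T volumes is cut into windows of length ``t`` advanced by a
step ``s``; only fully contained windows count, so the number of windows is
``n = floor((T - t) / s) + 1``.  Within each window the pairwise Pearson
correlation of the regional signals forms one *observed snapshot* of the
dynamic functional network, timestamped at the window centre
``start + (t - 1) / 2`` on the 0-based volume axis.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import RoiTimeSeries

logger = logging.getLogger("dynbrain")

__all__ = [
    "WindowScheme",
    "Snapshot",
    "SnapshotSequence",
    "window_count",
    "slice_windows",
    "pearson_corr",
    "build_observed_snapshots",
    "save_sequence",
    "load_sequence",
]

_PROVENANCES = ("observed", "in", "out")


@dataclass(frozen=True)
class WindowScheme:
    """Sliding-window parameters: window length ``t`` and step ``s`` in volumes."""

    window_length: int = 6
    step: int = 5

    def __post_init__(self) -> None:
        if self.window_length < 1:
            raise ValueError("window_length must be >= 1")
        if self.step < 1:
            raise ValueError("step must be >= 1")


@dataclass
class Snapshot:
    """A square connectivity matrix at a nominal time on the volume axis.

    ``provenance`` tags where the matrix came from: ``observed`` (windowed
    correlation), ``in`` (interpolated inside the acquisition window) or
    ``out`` (extrapolated beyond it).  Observed snapshots are exactly
    symmetric with unit diagonal and entries in [-1, 1].
    """

    time_index: float
    matrix: np.ndarray
    provenance: str = "observed"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        m, n = self.matrix.shape
        if m != n:
            raise ValueError("snapshot matrix must be square")
        if self.provenance not in _PROVENANCES:
            raise ValueError(f"provenance must be one of {_PROVENANCES}")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-8):
            raise ValueError("snapshot matrix must be symmetric")
        if self.provenance == "observed":
            if not np.allclose(np.diag(self.matrix), 1.0):
                raise ValueError("observed snapshot must have unit diagonal")
            if np.any(np.abs(self.matrix) > 1.0 + 1e-9):
                raise ValueError("observed snapshot entries must lie in [-1, 1]")

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]


@dataclass
class SnapshotSequence:
    """Time-ordered snapshots for one subject; time_index strictly increasing."""

    subject_id: str
    snapshots: list[Snapshot] = field(default_factory=list)

    def __post_init__(self) -> None:
        times = self.times
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("snapshot time indices must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.asarray([s.time_index for s in self.snapshots], dtype=float)

    @property
    def matrices(self) -> np.ndarray:
        return np.stack([s.matrix for s in self.snapshots])

    def __len__(self) -> int:
        return len(self.snapshots)

    def __iter__(self):
        return iter(self.snapshots)

    def __getitem__(self, i):
        return self.snapshots[i]


def window_count(T: int, scheme: WindowScheme) -> int:
    """Number of fully contained sliding windows, ``floor((T - t)/s) + 1``."""
    if scheme.window_length > T:
        raise ValueError(
            f"window length {scheme.window_length} exceeds series length {T}"
        )
    return (T - scheme.window_length) // scheme.step + 1


def slice_windows(
    series: RoiTimeSeries, scheme: WindowScheme
) -> list[tuple[int, np.ndarray]]:
    """Half-open windows ``[k*s, k*s + t)`` as (start, m x t sub-matrix) pairs."""
    T = series.n_volumes
    n = window_count(T, scheme)
    t, s = scheme.window_length, scheme.step
    return [(k * s, series.data[:, k * s : k * s + t]) for k in range(n)]


def pearson_corr(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation of two equal-length signals.

    Computed in the classical summation form
    ``r = (N Σxy − Σx Σy) / (sqrt(N Σx² − (Σx)²) sqrt(N Σy² − (Σy)²))``.
    A zero-variance input makes r undefined; callers substitute 0 for such
    pairs (see :func:`build_observed_snapshots`), so here it raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("inputs must be equal-length 1-D vectors of length >= 2")
    n = x.size
    sx, sy = x.sum(), y.sum()
    sxx, syy, sxy = (x * x).sum(), (y * y).sum(), (x * y).sum()
    vx = n * sxx - sx * sx
    vy = n * syy - sy * sy
    if vx <= 0 or vy <= 0:
        raise ZeroDivisionError("zero-variance input: correlation undefined")
    r = (n * sxy - sx * sy) / (np.sqrt(vx) * np.sqrt(vy))
    return float(np.clip(r, -1.0, 1.0))


def _window_corr(seg: np.ndarray) -> np.ndarray:
    """Correlation matrix of an m x t segment; undefined pairs -> 0, diag -> 1."""
    bad = seg.std(axis=1) == 0.0
    if bad.any():
        logger.warning(
            "zero-variance segment for %d region(s); correlations set to 0",
            int(bad.sum()),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(seg)
    c = np.nan_to_num(c, nan=0.0)
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return c


def build_observed_snapshots(
    series: RoiTimeSeries, scheme: WindowScheme
) -> SnapshotSequence:
    """One observed snapshot per sliding window, timestamped at the window centre."""
    half = (scheme.window_length - 1) / 2.0
    snaps = [
        Snapshot(time_index=start + half, matrix=_window_corr(seg), provenance="observed")
        for start, seg in slice_windows(series, scheme)
    ]
    logger.info(
        "%s: %d observed snapshots (t=%d, s=%d)",
        series.subject_id, len(snaps), scheme.window_length, scheme.step,
    )
    return SnapshotSequence(subject_id=series.subject_id, snapshots=snaps)


def save_sequence(seq: SnapshotSequence, directory: str | Path) -> Path:
    """Serialize as per-snapshot TSV matrices plus a JSON index."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    index = {"subject_id": seq.subject_id, "snapshots": []}
    for k, snap in enumerate(seq):
        fname = f"snapshot_{k:04d}.tsv"
        np.savetxt(directory / fname, snap.matrix, delimiter="\t", fmt="%.17g")
        index["snapshots"].append(
            {"file": fname, "time_index": snap.time_index, "provenance": snap.provenance}
        )
    (directory / "index.json").write_text(json.dumps(index, indent=2))
    return directory


def load_sequence(directory: str | Path) -> SnapshotSequence:
    directory = Path(directory)
    index = json.loads((directory / "index.json").read_text())
    snaps = [
        Snapshot(
            time_index=rec["time_index"],
            matrix=np.loadtxt(directory / rec["file"], delimiter="\t"),
            provenance=rec["provenance"],
        )
        for rec in index["snapshots"]
    ]
    return SnapshotSequence(subject_id=index["subject_id"], snapshots=snaps)
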