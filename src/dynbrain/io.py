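"""Reading, validating and writing ROI BOLD time-series matrices and subject manifests.

The exchange format is delimited text (TSV by default, CSV accepted by
delimiter sniffing): one row per brain region, first column the region id,
remaining columns the BOLD value at each acquired volume.  The contract
starts at already-extracted regional time series; raw image preprocessing
(realignment, normalisation, filtering) is out of scope.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger("dynbrain")

__all__ = [
    "RoiTimeSeries",
    "SubjectManifest",
    "ManifestEntry",
    "read_roi_series",
    "write_roi_series",
    "read_manifest",
    "write_manifest",
]


@dataclass
class RoiTimeSeries:
    """One subject's regions x time BOLD matrix.

    Attributes
    ----------
    subject_id : str
        Identifier of the subject the series belongs to.
    region_ids : list of str
        Ordered region identifiers; node index ``i`` in every downstream
        connectivity matrix refers to ``region_ids[i]``.
    data : ndarray of shape (m, T)
        BOLD signal per region (rows) and volume (columns), arbitrary units.
    tr_seconds : float
        Repetition time; metadata only, the time axis used internally is the
        0-based integer volume index.
    """

    subject_id: str
    region_ids: list[str]
    data: np.ndarray
    tr_seconds: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D regions x time matrix")
        m, T = self.data.shape
        if m < 2 or T < 2:
            raise ValueError(f"need at least 2 regions and 2 time points, got {m} x {T}")
        if len(self.region_ids) != m:
            raise ValueError(
                f"{len(self.region_ids)} region ids for {m} data rows"
            )
        if len(set(self.region_ids)) != m:
            raise ValueError("region_ids must be unique")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite values in BOLD matrix")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[1]


@dataclass
class ManifestEntry:
    subject_id: str
    group_label: str
    path: Path


@dataclass
class SubjectManifest:
    """List of (subject_id, group label, series file) records."""

    entries: list[ManifestEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.subject_id for e in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate subject ids in manifest: {dupes}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def groups(self) -> list[str]:
        return sorted({e.group_label for e in self.entries})


def _sniff_delimiter(sample: str) -> str:
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,;").delimiter
    except csv.Error:
        return "\t"


def read_roi_series(path: str | Path, tr_seconds: float = 1.0) -> RoiTimeSeries:
    """Parse a delimited region x volume matrix with region ids in column 0.

    Raises a :class:`ValueError` naming the offending row/column for
    non-numeric cells and for ragged rows.  Constant (zero-variance) regions
    are only warned about; the correlation stage substitutes 0 for undefined
    coefficients.
    """
    path = Path(path)
    text = path.read_text()
    delim = _sniff_delimiter(text[:4096])
    region_ids: list[str] = []
    rows: list[list[float]] = []
    for li, line in enumerate(text.splitlines()):
        if not line.strip():
            continue
        cells = line.split(delim)
        region_ids.append(cells[0].strip())
        vals = []
        for ci, cell in enumerate(cells[1:], start=1):
            try:
                vals.append(float(cell))
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric cell at row {li + 1}, column {ci + 1}: {cell!r}"
                ) from None
        rows.append(vals)
    if not rows:
        raise ValueError(f"{path}: empty file")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ValueError(f"{path}: ragged rows, widths {sorted(widths)}")
    data = np.asarray(rows, dtype=float)
    series = RoiTimeSeries(
        subject_id=path.stem, region_ids=region_ids, data=data, tr_seconds=tr_seconds
    )
    n_const = int(np.sum(np.std(data, axis=1) == 0.0))
    if n_const:
        logger.warning("%s: %d constant (zero-variance) region(s)", path, n_const)
    logger.info("read %s: %d regions x %d volumes", path, *data.shape)
    return series


def write_roi_series(series: RoiTimeSeries, path: str | Path, fmt: str = "%.17g") -> Path:
    """Write a series as TSV; ``read_roi_series`` round-trips it bit-for-bit."""
    path = Path(path)
    with path.open("w") as fh:
        for rid, row in zip(series.region_ids, series.data):
            fh.write(rid + "\t" + "\t".join(fmt % v for v in row) + "\n")
    return path


def read_manifest(path: str | Path) -> SubjectManifest:
    """Read a subject manifest (TSV/CSV with header subject_id, group, path).

    Relative paths are resolved against the manifest's directory; every path
    must resolve to an existing file.
    """
    path = Path(path)
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if len(lines) < 2:
        raise ValueError(f"{path}: no entries")
    delim = _sniff_delimiter(lines[0])
    header = [c.strip().lower() for c in lines[0].split(delim)]
    required = ["subject_id", "group", "path"]
    if header[: len(required)] != required:
        raise ValueError(f"{path}: header must start with {required}, got {header}")
    entries = []
    for ln in lines[1:]:
        cells = [c.strip() for c in ln.split(delim)]
        if len(cells) < 3:
            raise ValueError(f"{path}: short row {ln!r}")
        p = Path(cells[2])
        if not p.is_absolute():
            p = path.parent / p
        if not p.is_file():
            raise FileNotFoundError(f"{path}: series file not found for {cells[0]}: {p}")
        entries.append(ManifestEntry(cells[0], cells[1], p))
    manifest = SubjectManifest(entries)
    logger.info("manifest %s: %d subjects, groups %s", path, len(manifest), manifest.groups)
    return manifest


def write_manifest(manifest: SubjectManifest, path: str | Path) -> Path:
    path = Path(path)
    base = path.resolve().parent
    with path.open("w") as fh:
        fh.write("subject_id\tgroup\tpath\n")
        for e in manifest.entries:
            p = Path(e.path).resolve()
            try:
                p = p.relative_to(base)
            except ValueError:
                pass  # outside the manifest directory: keep absolute
            fh.write(f"{e.subject_id}\t{e.group_label}\t{p}\n")
    return path
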