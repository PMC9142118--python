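"""Scoring predicted snapshots against reference windowed networks.

A predicted snapshot at volume index ``i`` is compared with the Pearson
network of the BOLD segment of the training window length starting at
``i - 3`` (a reference window re-centred near ``i`` for the default length-6
window).  Discrepancies are summed over the upper triangle (diagonal
excluded): l1 is the sum of absolute differences, l2 the Euclidean norm of
the differences.  Reports aggregate mean +/- sd over the feasible snapshot
indices; indices whose reference window would leave the series are skipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import RoiTimeSeries
from .ndcn import NdcnConfig, NdcnModel, build_coupling_graph, fit, \
    predict_in_snapshots, predict_out_snapshots
from .snapshots import Snapshot, WindowScheme, _window_corr, \
    build_observed_snapshots

logger = logging.getLogger("dynbrain")

__all__ = [
    "LossReport",
    "reference_window_network",
    "snapshot_loss",
    "evaluate_sequence",
    "window_size_sweep",
]

_REF_OFFSET = 3  # reference window starts offset volumes before the snapshot index


@dataclass
class LossReport:
    """Per-snapshot (time_index, l1, l2) rows plus mean/sd aggregates."""

    per_snapshot: list[tuple[float, float, float]]
    mean_l1: float
    mean_l2: float
    sd_l1: float
    sd_l2: float
    skipped: list[float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.per_snapshot, columns=["time_index", "l1", "l2"])


def reference_window_network(
    series: RoiTimeSeries, i: int, window_length: int
) -> Snapshot:
    """Pearson network of the segment [i-3, i-3+window_length) of the series."""
    start = i - _REF_OFFSET
    T = series.n_volumes
    if start < 0 or start + window_length > T:
        raise ValueError(
            f"reference window [{start}, {start + window_length}) outside [0, {T})"
        )
    seg = series.data[:, start : start + window_length]
    return Snapshot(time_index=float(i), matrix=_window_corr(seg), provenance="observed")


def snapshot_loss(pred: Snapshot | np.ndarray, ref: Snapshot | np.ndarray) -> tuple[float, float]:
    """Upper-triangle (diagonal excluded) l1 sum and l2 norm of pred - ref."""
    P = pred.matrix if isinstance(pred, Snapshot) else np.asarray(pred)
    R = ref.matrix if isinstance(ref, Snapshot) else np.asarray(ref)
    if P.shape != R.shape:
        raise ValueError(f"shape mismatch {P.shape} vs {R.shape}")
    iu = np.triu_indices(P.shape[0], k=1)
    d = P[iu] - R[iu]
    return float(np.abs(d).sum()), float(np.sqrt((d * d).sum()))


def evaluate_sequence(
    model: NdcnModel,
    series: RoiTimeSeries,
    scheme: WindowScheme,
    which: str = "in",
    horizon: int | None = None,
) -> LossReport:
    """Score in- or out-snapshots against reference windows of the series.

    For ``which="out"`` the series must extend past the trained span (only
    possible when the future signal is simulable); ``horizon`` defaults to
    the number of whole volumes available past the span.
    """
    if which not in ("in", "out"):
        raise ValueError("which must be 'in' or 'out'")
    T = series.n_volumes
    if which == "in":
        seq = predict_in_snapshots(model)
    else:
        span_end = model.span[1]
        avail = int(np.floor(T - 1 - span_end))
        if avail < 1:
            raise ValueError(
                "series does not extend past the trained span: reference "
                "windows for out-snapshots are unavailable"
            )
        seq = predict_out_snapshots(model, horizon if horizon is not None else avail)
    per, skipped = [], []
    for snap in seq:
        i = int(round(snap.time_index))
        start = i - _REF_OFFSET
        if start < 0 or start + scheme.window_length > T:
            skipped.append(snap.time_index)
            continue
        ref = reference_window_network(series, i, scheme.window_length)
        l1, l2 = snapshot_loss(snap, ref)
        per.append((snap.time_index, l1, l2))
    if not per:
        raise ValueError("no feasible snapshot/reference pairs")
    if skipped:
        logger.info("skipped %d edge indices without a full reference window",
                    len(skipped))
    l1s = np.array([p[1] for p in per])
    l2s = np.array([p[2] for p in per])
    return LossReport(
        per_snapshot=per,
        mean_l1=float(l1s.mean()),
        mean_l2=float(l2s.mean()),
        sd_l1=float(l1s.std(ddof=1)) if len(per) > 1 else 0.0,
        sd_l2=float(l2s.std(ddof=1)) if len(per) > 1 else 0.0,
        skipped=skipped,
    )


def window_size_sweep(
    series: RoiTimeSeries,
    sizes: list[int],
    config: NdcnConfig | None = None,
    step: int = 5,
    density: float = 0.15,
) -> pd.DataFrame:
    """Refit and score the pipeline per window size; rows (size, mean_l1, mean_l2).

    Duplicate sizes are deduplicated with a warning.  This is the sensitivity
    analysis behind choosing the default window length.
    """
    uniq = sorted(set(sizes))
    if len(uniq) != len(sizes):
        logger.warning("duplicate window sizes removed: %s", sizes)
    rows = []
    for size in uniq:
        scheme = WindowScheme(window_length=size, step=step)
        seq = build_observed_snapshots(series, scheme)
        coupling = build_coupling_graph(seq, density=density)
        model = fit(seq, coupling, config, t_max=series.n_volumes - 1)
        report = evaluate_sequence(model, series, scheme, which="in")
        rows.append((size, report.mean_l1, report.mean_l2))
    return pd.DataFrame(rows, columns=["size", "mean_l1", "mean_l2"])
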