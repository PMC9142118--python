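"""End-to-end per-subject and cohort execution.

One subject runs through: sliding-window snapshots -> static coupling graph
-> dynamics fit -> per-volume in-snapshots and horizon out-snapshots ->
small-world validation -> clustering-coefficient feature vector.  Stage
outputs are flushed to the output directory as they complete, and the
resolved configuration is echoed alongside them.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import graph_metrics, ndcn
from .classify import FeatureTable, extract_features
from .config import PipelineConfig, save_config
from .io import RoiTimeSeries, SubjectManifest, read_roi_series
from .snapshots import SnapshotSequence, WindowScheme, build_observed_snapshots, \
    save_sequence

logger = logging.getLogger("dynbrain")

__all__ = ["SubjectResult", "run_subject", "run_cohort"]


@dataclass
class SubjectResult:
    subject_id: str
    observed: SnapshotSequence
    model: ndcn.NdcnModel
    in_snapshots: SnapshotSequence
    out_snapshots: SnapshotSequence
    features: np.ndarray
    smallworld_in: pd.DataFrame | None = None
    smallworld_out: pd.DataFrame | None = None


def run_subject(
    series: RoiTimeSeries,
    config: PipelineConfig,
    out_dir: str | Path | None = None,
    small_world: bool = False,
) -> SubjectResult:
    """Execute the full per-subject pipeline.

    ``small_world=True`` additionally evaluates every in/out snapshot against
    degree-preserving null models (the expensive validation step); feature
    extraction alone does not need it.
    """
    t_start = time.time()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        save_config(config, out / "config.yaml")

    scheme = WindowScheme(config.window_length, config.window_step)
    observed = build_observed_snapshots(series, scheme)
    if out is not None:
        save_sequence(observed, out / "observed")

    coupling = ndcn.build_coupling_graph(observed, density=config.coupling_density)
    model = ndcn.fit(observed, coupling, config.resolved_ndcn(),
                     t_max=series.n_volumes - 1)
    if out is not None:
        ndcn.save_model(model, out / "model.npz")

    in_snaps = ndcn.predict_in_snapshots(model)
    out_snaps = ndcn.predict_out_snapshots(model, config.horizon)
    in_snaps.subject_id = series.subject_id
    out_snaps.subject_id = series.subject_id
    if out is not None:
        save_sequence(in_snaps, out / "in_snapshots")
        if len(out_snaps):
            save_sequence(out_snaps, out / "out_snapshots")

    sw_in = sw_out = None
    if small_world:
        *_, recs_in = graph_metrics.small_world_fraction(
            in_snaps, density=config.binarize_density,
            n_random=config.n_random, seed=config.seed_metrics,
        )
        sw_in = graph_metrics.records_to_frame(recs_in, in_snaps.times)
        if len(out_snaps):
            *_, recs_out = graph_metrics.small_world_fraction(
                out_snaps, density=config.binarize_density,
                n_random=config.n_random, seed=config.seed_metrics + 500_000,
            )
            sw_out = graph_metrics.records_to_frame(recs_out, out_snaps.times)
        if out is not None:
            sw_in.to_csv(out / "smallworld_in.csv", index=False)
            if sw_out is not None:
                sw_out.to_csv(out / "smallworld_out.csv", index=False)

    features = extract_features(in_snaps, out_snaps if len(out_snaps) else None,
                                density=config.binarize_density)
    if out is not None:
        np.savetxt(out / "features.tsv", features[None, :], delimiter="\t",
                   fmt="%.17g")
        (out / "run_info.json").write_text(json.dumps({
            "subject_id": series.subject_id,
            "n_observed": len(observed),
            "n_in": len(in_snaps),
            "n_out": len(out_snaps),
            "final_training_loss": model.final_loss,
            "seed": config.seed,
            "elapsed_s": round(time.time() - t_start, 2),
        }, indent=2))
    logger.info("subject %s done in %.1fs (%d in, %d out snapshots)",
                series.subject_id, time.time() - t_start,
                len(in_snaps), len(out_snaps))
    return SubjectResult(series.subject_id, observed, model, in_snaps,
                         out_snaps, features, sw_in, sw_out)


def run_cohort(
    manifest: SubjectManifest,
    config: PipelineConfig,
    out_dir: str | Path | None = None,
    small_world: bool = False,
) -> tuple[FeatureTable, FeatureTable, FeatureTable]:
    """Run every manifest subject; returns (in-only, out-only, in+out)
    feature tables for classification and its ablation."""
    t_in, t_out, t_both = FeatureTable(), FeatureTable(), FeatureTable()
    for entry in manifest:
        series = read_roi_series(entry.path)
        series.subject_id = entry.subject_id
        sub_dir = Path(out_dir) / entry.subject_id if out_dir is not None else None
        try:
            res = run_subject(series, config, out_dir=sub_dir,
                              small_world=small_world)
        except Exception as exc:
            raise RuntimeError(
                f"pipeline failed for subject {entry.subject_id}: {exc}"
            ) from exc
        n_in = len(res.in_snapshots)
        t_in.add(entry.subject_id, entry.group_label, res.features[:n_in])
        if len(res.out_snapshots):
            t_out.add(entry.subject_id, entry.group_label, res.features[n_in:])
        t_both.add(entry.subject_id, entry.group_label, res.features)
    if out_dir is not None:
        out = Path(out_dir)
        t_both.to_frame().to_csv(out / "features_both.csv", index=False)
        t_in.to_frame().to_csv(out / "features_in.csv", index=False)
        if t_out.rows:
            t_out.to_frame().to_csv(out / "features_out.csv", index=False)
    return t_in, t_out, t_both
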