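"""Synthetic multi-region BOLD data with known ground truth.

Real resting-state acquisitions (e.g. 264-region atlases, 140 volumes at
TR = 3 s) cannot ship with the package, so every stage is exercised on
simulated data: regional signals drawn from a modular, slowly time-varying
covariance (within-module correlation ``w(t)``, between-module correlation
``b``), plus white observation noise.  Group-level effects shift the
within-module correlation, which moves the clustering coefficient of the
thresholded connectivity graphs — the feature the downstream classifier
consumes.  A separate generator produces matrix-valued graph-diffusion
trajectories with a closed-form (matrix-exponential) evaluator, the oracle
for testing the dynamics model's interpolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable

import numpy as np

from .io import ManifestEntry, RoiTimeSeries, SubjectManifest, write_manifest, \
    write_roi_series
from .snapshots import Snapshot, SnapshotSequence

logger = logging.getLogger("dynbrain")

__all__ = [
    "SyntheticSpec",
    "generate_subject",
    "generate_cohort",
    "generate_dynamics_truth",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the modular BOLD simulator.

    ``drift_model`` controls how the within-module correlation varies over
    the acquisition: ``static`` (constant), ``linear_mixing`` (linear ramp of
    amplitude ``drift_amplitude`` across the series) or ``oscillatory``
    (sinusoid of amplitude ``drift_amplitude`` and period ``drift_period``
    volumes).  ``group_effect`` is added to ``within_corr`` and is the knob
    that separates simulated diagnostic groups.  ``noise_sd`` is the standard
    deviation of additive white noise relative to unit-variance signal, which
    dilutes observed correlations by a factor 1/(1 + noise_sd^2).
    """

    m: int = 30
    T: int = 140
    n_modules: int = 3
    within_corr: float = 0.5
    between_corr: float = 0.1
    drift_model: str = "oscillatory"
    drift_amplitude: float = 0.1
    drift_period: float = 70.0
    group_effect: float = 0.0
    noise_sd: float = 0.3
    tr_seconds: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 2 or self.T < 2 or self.n_modules < 1:
            raise ValueError("m >= 2, T >= 2, n_modules >= 1 required")
        if self.drift_model not in ("static", "linear_mixing", "oscillatory"):
            raise ValueError(f"unknown drift_model {self.drift_model!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for name in ("within_corr", "between_corr"):
            v = getattr(self, name)
            if not -1.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (-1, 1)")


def _module_labels(m: int, n_modules: int) -> np.ndarray:
    return np.array_split(np.arange(m), n_modules)


def _within_at(spec: SyntheticSpec, t: int) -> float:
    w = spec.within_corr + spec.group_effect
    if spec.drift_model == "linear_mixing":
        frac = t / max(spec.T - 1, 1)
        w = w + spec.drift_amplitude * (frac - 0.5)
    elif spec.drift_model == "oscillatory":
        w = w + spec.drift_amplitude * np.sin(2.0 * np.pi * t / spec.drift_period)
    return w


def _covariance(spec: SyntheticSpec, w: float) -> np.ndarray:
    sigma = np.full((spec.m, spec.m), spec.between_corr)
    for idx in _module_labels(spec.m, spec.n_modules):
        sigma[np.ix_(idx, idx)] = w
    np.fill_diagonal(sigma, 1.0)
    return sigma


def _check_psd(spec: SyntheticSpec) -> None:
    ws = {_within_at(spec, t) for t in (0, spec.T // 2, spec.T - 1)}
    ws |= {spec.within_corr + spec.group_effect + s * spec.drift_amplitude
           for s in (-1.0, 1.0)}
    for w in ws:
        if not -1.0 < w < 1.0:
            raise ValueError(
                f"within-module correlation {w:.3f} leaves (-1, 1): adjust "
                "within_corr / group_effect / drift_amplitude"
            )
        ev = np.linalg.eigvalsh(_covariance(spec, w))
        if ev.min() < -1e-10:
            raise ValueError(
                f"non-PSD covariance at within={w:.3f}, "
                f"between={spec.between_corr:.3f} (min eigenvalue {ev.min():.2e})"
            )


def generate_subject(
    spec: SyntheticSpec,
    subject_id: str | None = None,
    rng: np.random.Generator | None = None,
) -> RoiTimeSeries:
    """One subject's m x T BOLD matrix from the time-varying modular covariance."""
    _check_psd(spec)
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    data = np.empty((spec.m, spec.T))
    chol_cache: dict[float, np.ndarray] = {}
    for t in range(spec.T):
        w = round(_within_at(spec, t), 12)
        if w not in chol_cache:
            sigma = _covariance(spec, w)
            # tiny jitter guards exactly-singular corner cases
            chol_cache[w] = np.linalg.cholesky(sigma + 1e-10 * np.eye(spec.m))
        z = rng.standard_normal(spec.m)
        data[:, t] = chol_cache[w] @ z
    if spec.noise_sd > 0:
        data += spec.noise_sd * rng.standard_normal(data.shape)
    return RoiTimeSeries(
        subject_id=subject_id or f"synth-{spec.seed:06d}",
        region_ids=[f"R{i:03d}" for i in range(spec.m)],
        data=data,
        tr_seconds=spec.tr_seconds,
    )


def generate_cohort(
    spec: SyntheticSpec,
    n_per_group: int,
    groups: list[tuple[str, float]],
    out_dir: str | Path,
) -> SubjectManifest:
    """Write per-subject TSVs and a manifest for several diagnostic groups.

    ``groups`` is a list of (label, group_effect) pairs; each subject's seed
    stream is spawned deterministically from the spec's master seed.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for gi, (label, effect) in enumerate(groups):
        gspec = replace(spec, group_effect=effect)
        _check_psd(gspec)
        for si in range(n_per_group):
            rng = np.random.default_rng(
                np.random.SeedSequence([spec.seed, gi, si])
            )
            sid = f"{label}-{si:03d}"
            series = generate_subject(gspec, subject_id=sid, rng=rng)
            path = write_roi_series(series, out_dir / f"{sid}.tsv")
            entries.append(ManifestEntry(sid, label, path))
    manifest = SubjectManifest(entries)
    write_manifest(manifest, out_dir / "manifest.tsv")
    logger.info("cohort: %d subjects x %d groups -> %s",
                n_per_group, len(groups), out_dir)
    return manifest


def generate_dynamics_truth(
    m: int = 5,
    n_obs: int = 10,
    seed: int = 0,
    span: float = 9.0,
    rate: float = 0.25,
) -> tuple[SnapshotSequence, Callable[[float], np.ndarray]]:
    """Snapshots from symmetric graph diffusion with a closed-form evaluator.

    The ground-truth trajectory is the correlation normalization of
    ``M(t) Sigma0 M(t)`` with ``M(t) = expm(-rate * L * t)`` for the
    Laplacian L of a random connected graph: a smooth, exactly known path
    through correlation-matrix space.  Returns ``n_obs`` observed snapshots
    evenly spaced on [0, span] plus ``evaluate(t)`` giving the exact state at
    any time (via the Laplacian eigendecomposition).
    """
    if m < 2:
        raise ValueError("m must be >= 2")
    if n_obs < 2:
        raise ValueError("n_obs must be >= 2")
    rng = np.random.default_rng(seed)
    # random connected graph: spanning tree + extra edges
    A = np.zeros((m, m))
    perm = rng.permutation(m)
    for a, b in zip(perm[:-1], perm[1:]):
        A[a, b] = A[b, a] = 1.0
    iu = np.triu_indices(m, k=1)
    extra = rng.random(len(iu[0])) < 0.3
    A[iu[0][extra], iu[1][extra]] = 1.0
    A = np.maximum(A, A.T)
    L = np.diag(A.sum(axis=1)) - A
    evals, U = np.linalg.eigh(L)

    # modular base correlation matrix
    sigma0 = np.full((m, m), 0.1)
    half = m // 2
    sigma0[:half, :half] = 0.7
    sigma0[half:, half:] = 0.7
    np.fill_diagonal(sigma0, 1.0)

    def evaluate(t: float) -> np.ndarray:
        M = U @ np.diag(np.exp(-rate * evals * t)) @ U.T
        X = M @ sigma0 @ M
        d = 1.0 / np.sqrt(np.diag(X))
        X = X * d[:, None] * d[None, :]
        X = np.clip((X + X.T) / 2.0, -1.0, 1.0)
        np.fill_diagonal(X, 1.0)
        return X

    times = np.linspace(0.0, span, n_obs)
    snaps = [
        Snapshot(time_index=float(t), matrix=evaluate(float(t)), provenance="observed")
        for t in times
    ]
    return SnapshotSequence(subject_id=f"diffusion-{seed}", snapshots=snaps), evaluate
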