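"""Simulated resting-state ROI data with a planted connectivity composite.

Each subject gets voxel-by-time series for five neural regions (amygdala
seed, one positively weighted cluster, three negatively weighted clusters)
plus white-matter and CSF compartments, a 6-parameter motion table and a
global-signal trace.  The five neural mean series realize a target 5x5
correlation matrix whose composite (as computed by the connectivity module,
under the same sign convention) equals the subject's latent
``true_composite_conn``.  Structured nuisance — low-frequency drift, shared
"physiological" components also present in WM/CSF, and motion-locked
intensity spikes — is mixed into the neural series so the denoising stage has
something real to remove.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

ROI_NAMES = (
    "amygdala",
    "cluster_pos",
    "cluster_neg1",
    "cluster_neg2",
    "cluster_neg3",
    "wm",
    "csf",
)
NEURAL_ROIS = ROI_NAMES[:5]

__all__ = ["ScanSpec", "SimulatedScan", "simulate_scan", "ROI_NAMES", "NEURAL_ROIS"]


@dataclass(frozen=True)
class ScanSpec:
    """Acquisition and nuisance parameters of a simulated scan.

    Defaults emulate a 200-volume, TR = 1.5 s resting-state acquisition.
    Amplitudes are relative to the unit-variance latent neural signals.
    """

    n_volumes: int = 200
    tr: float = 1.5
    voxels_per_roi: int = 20
    drift_amplitude: float = 1.0
    spike_rate: float = 0.02
    motion_spike_mm: float = 1.0
    nuisance_amplitude: float = 1.0
    voxel_noise_sd: float = 0.1
    spike_artifact_amplitude: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        if self.tr <= 0:
            raise ValueError("tr must be > 0")
        if self.n_volumes < 2.0 / (self.tr * 0.01):
            raise ValueError(
                "n_volumes too small to resolve the 0.01 Hz band edge at this TR"
            )
        if not 0.0 <= self.spike_rate <= 1.0:
            raise ValueError("spike_rate must lie in [0, 1]")
        if self.voxels_per_roi < 1:
            raise ValueError("voxels_per_roi must be >= 1")


@dataclass
class SimulatedScan:
    roi_ts: dict  # roi name -> (voxels, n_volumes) array
    motion: np.ndarray  # (n_volumes, 6): 3 translations mm, 3 rotations rad
    global_signal: np.ndarray  # (n_volumes,)
    spec: ScanSpec


def target_correlation_matrix(t: float, sign_convention: str = "flip_negative") -> np.ndarray:
    """5x5 correlation target among (amygdala, pos, neg1, neg2, neg3).

    Under ``flip_negative`` the seed correlates +t with the positive cluster
    and -t with each negative cluster, so the sign-flipped composite equals t.
    Under ``raw`` all four seed-cluster correlations equal t.  Cluster-cluster
    correlations are 0; if |t| >= 0.5 the matrix is indefinite and is repaired
    to the nearest positive-definite correlation matrix (the realized
    composite then shrinks accordingly).
    """
    if sign_convention not in ("flip_negative", "raw"):
        raise ValueError(f"unknown sign convention: {sign_convention!r}")
    c = np.eye(5)
    signs = [1.0, -1.0, -1.0, -1.0] if sign_convention == "flip_negative" else [1.0] * 4
    for j, s in enumerate(signs, start=1):
        c[0, j] = c[j, 0] = s * t
    return nearest_positive_definite(c)


def nearest_positive_definite(corr: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Clip negative eigenvalues and renormalize to unit diagonal."""
    vals, vecs = np.linalg.eigh(corr)
    if vals.min() > eps:
        return corr
    vals = np.clip(vals, eps, None)
    fixed = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    return fixed / np.outer(d, d)


def _ar1(rng: np.random.Generator, n: int, phi: float = 0.9) -> np.ndarray:
    innov = rng.standard_normal(n) * np.sqrt(1.0 - phi**2)
    out = np.empty(n)
    out[0] = rng.standard_normal()
    for i in range(1, n):
        out[i] = phi * out[i - 1] + innov[i]
    return out


def simulate_scan(record, spec: ScanSpec, sign_convention: str = "flip_negative") -> SimulatedScan:
    """Simulate one subject's ROI data around ``record.true_composite_conn``.

    Deterministic given ``spec.seed`` and the subject id (a CRC32 of the id
    is folded into the RNG seed so per-subject streams are independent but
    reproducible across runs).
    """
    spec.validate()
    t = float(record.true_composite_conn)
    if not np.isfinite(t) or abs(t) >= 1.0:
        raise ValueError(f"|true_composite_conn| must be < 1, got {t}")

    rng = np.random.default_rng([spec.seed, zlib.crc32(record.subject_id.encode())])
    n, v = spec.n_volumes, spec.voxels_per_roi
    time = np.arange(n) * spec.tr

    # latent unit-variance neural signals with the planted correlation target
    chol = np.linalg.cholesky(target_correlation_matrix(t, sign_convention))
    latent = chol @ rng.standard_normal((5, n))

    # structured nuisance: slow drift + 3 smooth shared components
    drift = spec.drift_amplitude * (
        np.sin(2 * np.pi * 0.005 * time + rng.uniform(0, 2 * np.pi))
        + 0.5 * np.linspace(-1.0, 1.0, n)
    )
    phys = spec.nuisance_amplitude * np.vstack([_ar1(rng, n) for _ in range(3)])

    # motion: gentle random walk plus step jumps at spiked volumes
    motion = np.cumsum(
        rng.normal(0.0, [[0.02] * 3 + [2e-4] * 3], (n, 6)), axis=0
    )
    spikes = rng.random(n) < spec.spike_rate
    spikes[0] = False
    spike_idx = np.flatnonzero(spikes)
    for idx in spike_idx:
        axis = int(rng.integers(0, 3))
        jump = spec.motion_spike_mm * (1.0 + 0.5 * rng.random()) * rng.choice([-1.0, 1.0])
        motion[idx:, axis] += jump
    artifact = np.zeros(n)
    artifact[spike_idx] = spec.spike_artifact_amplitude * rng.choice([-1.0, 1.0], spike_idx.size)

    roi_ts: dict[str, np.ndarray] = {}
    for i, roi in enumerate(NEURAL_ROIS):
        load_d = rng.uniform(0.5, 1.0)
        load_p = rng.uniform(0.5, 1.5, 3)
        base = latent[i] + load_d * drift + load_p @ phys + artifact
        roi_ts[roi] = base + spec.voxel_noise_sd * rng.standard_normal((v, n))
    for roi in ("wm", "csf"):
        loads = rng.uniform(0.5, 1.5, (v, 3))
        base = loads @ phys + rng.uniform(0.2, 0.6, (v, 1)) * drift
        roi_ts[roi] = base + 0.2 * rng.standard_normal((v, n))

    global_signal = np.mean(
        np.concatenate([roi_ts[r] for r in NEURAL_ROIS], axis=0), axis=0
    )
    return SimulatedScan(roi_ts=roi_ts, motion=motion, global_signal=global_signal, spec=spec)
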