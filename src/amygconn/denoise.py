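"""Conn-style nuisance removal for ROI time series.

The stages mirror a standard seed-connectivity cleanup: framewise
displacement and outlier flagging (0.5 mm frame-to-frame displacement or
global-intensity z >= 3), a nuisance GLM with the six motion parameters,
their first-order backward-difference derivatives, the leading principal
components of the white-matter and CSF compartments (aCompCor) and one
indicator ("spike") regressor per flagged volume, followed by an ideal
0.01-0.10 Hz band-pass.

Nuisance design columns are band-pass filtered before the regression so that
regress-then-filter forms a single orthogonal projection: the pair is then
exactly idempotent and the filter cannot reintroduce components of the
regressed-out nuisance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .scans import NEURAL_ROIS, SimulatedScan

__all__ = [
    "DenoiseConfig",
    "FDTrace",
    "OutlierFlags",
    "NuisanceDesign",
    "compute_fd",
    "flag_outlier_volumes",
    "extract_tissue_components",
    "build_nuisance_design",
    "regress_nuisance",
    "bandpass_filter",
    "denoise_series",
    "denoise_scan",
]


@dataclass(frozen=True)
class DenoiseConfig:
    """Denoising parameters; defaults are the analysis' printed settings."""

    n_tissue_components: int = 3
    spike_translation_threshold: float = 0.5  # mm
    spike_global_z_threshold: float = 3.0  # SD units
    band_low: float = 0.01  # Hz
    band_high: float = 0.10  # Hz
    rotation_radius: float = 50.0  # mm, converts radians to arc displacement
    composite_motion: bool = False  # flag on summed displacement instead of per-parameter
    pooled_tissue: bool = False  # pool WM+CSF voxels before PCA

    def validate(self, tr: float | None = None) -> None:
        if not 0.0 <= self.band_low < self.band_high:
            raise ValueError("require 0 <= band_low < band_high")
        if tr is not None and self.band_high > 0.5 / tr + 1e-12:
            raise ValueError(
                f"band_high {self.band_high} Hz exceeds Nyquist {0.5 / tr:.4f} Hz at TR={tr}"
            )
        for name in ("spike_translation_threshold", "spike_global_z_threshold", "rotation_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class FDTrace:
    fd: np.ndarray  # mm per volume; fd[0] = 0 by convention
    mean_fd: float
    median_fd: float
    sd_fd: float


@dataclass
class OutlierFlags:
    flags: np.ndarray  # bool per volume
    reason: list  # per volume: "motion" | "intensity" | "both" | "none"


@dataclass
class NuisanceDesign:
    columns: np.ndarray  # (n_volumes, n_regressors)
    labels: list


def compute_fd(motion: np.ndarray, rotation_radius: float = 50.0) -> FDTrace:
    """Power-style framewise displacement.

    fd[t] = sum |Delta translation_i| + radius * sum |Delta rotation_j| over
    backward differences; summaries are over fd[1:] (the first frame has no
    predecessor).
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion must be a time x 6 array")
    if motion.shape[0] < 2:
        raise ValueError("need at least 2 volumes to compute FD")
    diffs = np.abs(np.diff(motion, axis=0))
    fd_body = diffs[:, :3].sum(axis=1) + rotation_radius * diffs[:, 3:].sum(axis=1)
    fd = np.concatenate([[0.0], fd_body])
    return FDTrace(
        fd=fd,
        mean_fd=float(fd_body.mean()),
        median_fd=float(np.median(fd_body)),
        sd_fd=float(fd_body.std(ddof=1)) if fd_body.size > 1 else 0.0,
    )


def flag_outlier_volumes(
    motion: np.ndarray, global_signal: np.ndarray, config: DenoiseConfig = DenoiseConfig()
) -> OutlierFlags:
    """Artifact-detection flags: frame displacement >= 0.5 mm or |global z| >= 3.

    Motion uses backward differences per parameter (rotations converted to mm
    at ``rotation_radius``); with ``composite_motion`` the six converted
    differences are summed (an FD criterion) instead.  The first volume is
    never motion-flagged.  The global signal is z-scored with the sample SD
    (ddof=1) over all volumes.
    """
    motion = np.asarray(motion, dtype=float)
    gs = np.asarray(global_signal, dtype=float)
    if motion.shape[0] != gs.shape[0]:
        raise ValueError("motion and global_signal lengths differ")
    config.validate()

    diffs = np.abs(np.diff(motion, axis=0))
    diffs[:, 3:] *= config.rotation_radius
    if config.composite_motion:
        exceeded = diffs.sum(axis=1) >= config.spike_translation_threshold
    else:
        exceeded = (diffs >= config.spike_translation_threshold).any(axis=1)
    motion_flag = np.concatenate([[False], exceeded])

    sd = gs.std(ddof=1)
    if sd == 0:
        intensity_flag = np.zeros_like(motion_flag)
    else:
        z = (gs - gs.mean()) / sd
        intensity_flag = np.abs(z) >= config.spike_global_z_threshold

    flags = motion_flag | intensity_flag
    reason = [
        "both" if m and i else "motion" if m else "intensity" if i else "none"
        for m, i in zip(motion_flag, intensity_flag)
    ]
    return OutlierFlags(flags=flags, reason=reason)


def extract_tissue_components(compartment_ts: np.ndarray, k: int) -> np.ndarray:
    """Top-k principal-component time courses of a voxel x time compartment.

    Each voxel's time course is demeaned, then the leading right-singular
    vectors (unit-norm, mutually orthogonal, ordered by explained variance)
    are returned as a (k, time) array.  If the demeaned matrix has rank < k,
    fewer components are returned with a warning.
    """
    x = np.asarray(compartment_ts, dtype=float)
    if x.ndim != 2:
        raise ValueError("compartment_ts must be voxel x time")
    n_vox, n_time = x.shape
    if n_vox < k or n_time < k + 1:
        raise ValueError(f"need >= {k} voxels and >= {k + 1} time points")
    xd = x - x.mean(axis=1, keepdims=True)
    _, s, vt = np.linalg.svd(xd, full_matrices=False)
    tol = s.max(initial=0.0) * max(xd.shape) * np.finfo(float).eps
    rank = int((s > tol).sum())
    if rank < k:
        warnings.warn(
            f"compartment rank {rank} < requested {k} components; returning {rank}",
            stacklevel=2,
        )
        k = rank
    return vt[:k]


def build_nuisance_design(
    motion: np.ndarray,
    wm_comps: np.ndarray,
    csf_comps: np.ndarray,
    flags: np.ndarray,
) -> NuisanceDesign:
    """Assemble motion (6) + derivatives (6) + tissue components + spike indicators."""
    motion = np.asarray(motion, dtype=float)
    wm = np.atleast_2d(np.asarray(wm_comps, dtype=float)) if np.size(wm_comps) else np.empty((0, motion.shape[0]))
    csf = np.atleast_2d(np.asarray(csf_comps, dtype=float)) if np.size(csf_comps) else np.empty((0, motion.shape[0]))
    flags = np.asarray(flags, dtype=bool)
    n = motion.shape[0]
    if motion.shape[1] != 6:
        raise ValueError("motion must have 6 columns")
    for name, arr in (("wm_comps", wm), ("csf_comps", csf)):
        if arr.size and arr.shape[1] != n:
            raise ValueError(f"{name} time length {arr.shape[1]} != {n}")
    if flags.shape[0] != n:
        raise ValueError(f"flags length {flags.shape[0]} != {n}")

    deriv = np.vstack([np.zeros((1, 6)), np.diff(motion, axis=0)])
    cols = [motion, deriv]
    labels = [f"motion_{i + 1}" for i in range(6)]
    labels += [f"motion_derivative_{i + 1}" for i in range(6)]
    if wm.size:
        cols.append(wm.T)
        labels += [f"wm_comp_{i + 1}" for i in range(wm.shape[0])]
    if csf.size:
        cols.append(csf.T)
        labels += [f"csf_comp_{i + 1}" for i in range(csf.shape[0])]
    spike_at = np.flatnonzero(flags)
    if spike_at.size:
        spikes = np.zeros((n, spike_at.size))
        spikes[spike_at, np.arange(spike_at.size)] = 1.0
        cols.append(spikes)
        labels += [f"spike_t{t}" for t in spike_at]
    return NuisanceDesign(columns=np.column_stack(cols), labels=labels)


def regress_nuisance(ts: np.ndarray, design: NuisanceDesign) -> np.ndarray:
    """Least-squares residual of ``ts`` against the design (intercept included).

    Constant-zero columns are dropped; remaining rank deficiency raises an
    error naming the offending columns.
    """
    y = np.asarray(ts, dtype=float)
    x = np.asarray(design.columns, dtype=float)
    if y.shape[0] != x.shape[0]:
        raise ValueError("time series and design lengths differ")
    norms = np.linalg.norm(x, axis=0)
    keep = norms > 1e-12
    x = x[:, keep]
    labels = [l for l, k in zip(design.labels, keep) if k]
    full = np.column_stack([np.ones(y.shape[0]), x / np.linalg.norm(x, axis=0)]) if x.size else np.ones((y.shape[0], 1))

    q, r, piv = scipy.linalg.qr(full, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(full.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank < full.shape[1]:
        offending = sorted(
            ("intercept" if j == 0 else labels[j - 1]) for j in piv[rank:]
        )
        raise ValueError(f"nuisance design is rank deficient; offending columns: {offending}")
    beta, *_ = np.linalg.lstsq(full, y, rcond=None)
    return y - full @ beta


def bandpass_filter(ts: np.ndarray, tr: float, config: DenoiseConfig = DenoiseConfig()) -> np.ndarray:
    """Ideal (rectangular) DFT band-pass keeping frequencies strictly inside the band.

    Fourier coefficients at frequencies <= band_low or >= band_high are
    zeroed (DC always removed), so the output is mean-zero.
    """
    config.validate(tr=tr)
    y = np.asarray(ts, dtype=float)
    n = y.shape[-1]
    freqs = np.fft.rfftfreq(n, d=tr)
    spec = np.fft.rfft(y, axis=-1)
    keep = (freqs > config.band_low) & (freqs < config.band_high)
    spec = np.where(keep, spec, 0.0)
    return np.fft.irfft(spec, n=n, axis=-1)


def denoise_series(
    ts: np.ndarray, design: NuisanceDesign, tr: float, config: DenoiseConfig = DenoiseConfig()
) -> np.ndarray:
    """Full cleanup of one series: regress band-limited nuisance, then filter."""
    filtered_cols = bandpass_filter(design.columns.T, tr, config).T
    norms = np.linalg.norm(filtered_cols, axis=0)
    keep = norms > 1e-10 * (1.0 + np.linalg.norm(design.columns, axis=0))
    banded = NuisanceDesign(
        columns=filtered_cols[:, keep],
        labels=[l for l, k in zip(design.labels, keep) if k],
    )
    resid = regress_nuisance(ts, banded)
    return bandpass_filter(resid, tr, config)


def denoise_scan(scan: SimulatedScan, config: DenoiseConfig = DenoiseConfig()):
    """Denoise every neural ROI mean series of a scan.

    Returns ``(cleaned, log)`` where ``cleaned`` maps ROI name to its cleaned
    mean time series and ``log`` summarizes flags, FD and the design.
    """
    config.validate(tr=scan.spec.tr)
    fd = compute_fd(scan.motion, config.rotation_radius)
    flags = flag_outlier_volumes(scan.motion, scan.global_signal, config)
    k = config.n_tissue_components
    if config.pooled_tissue:
        pooled = np.vstack([scan.roi_ts["wm"], scan.roi_ts["csf"]])
        comps = extract_tissue_components(pooled, k)
        wm_comps, csf_comps = comps, np.empty((0, scan.motion.shape[0]))
    else:
        wm_comps = extract_tissue_components(scan.roi_ts["wm"], k)
        csf_comps = extract_tissue_components(scan.roi_ts["csf"], k)
    design = build_nuisance_design(scan.motion, wm_comps, csf_comps, flags.flags)
    cleaned = {
        roi: denoise_series(scan.roi_ts[roi].mean(axis=0), design, scan.spec.tr, config)
        for roi in NEURAL_ROIS
    }
    log = {
        "n_volumes": int(scan.motion.shape[0]),
        "n_flagged": int(flags.flags.sum()),
        "mean_fd_mm": fd.mean_fd,
        "median_fd_mm": fd.median_fd,
        "band_hz": [config.band_low, config.band_high],
        "design_columns": design.labels,
    }
    return cleaned, log
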