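"""Standard-format I/O: subject tables, ROI/motion tables, NIfTI, configs.

Subject tables are CSV (one row per participant, interim LSAS measures as
``lsas_t1..tk``); ROI voxel time series and motion parameters are TSV; masks
and optional 4D series are NIfTI; configs and provenance records are
YAML/JSON.  Subjects are kept in lexicographic id order everywhere so
cohort-level standardization and permutation seeds reproduce exactly.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .cohort import SubjectRecord
from .scans import ROI_NAMES, SimulatedScan

__all__ = [
    "write_cohort_csv",
    "read_cohort_csv",
    "write_scan_tsv",
    "read_scan_tsv",
    "write_motion_tsv",
    "read_motion_tsv",
    "extract_roi_from_nifti",
    "write_roi_nifti",
    "load_config",
    "write_provenance",
    "write_conn_table",
]


def write_cohort_csv(cohort: list[SubjectRecord], path) -> None:
    rows = []
    for r in cohort:
        row = {
            "subject_id": r.subject_id,
            "group": r.group,
            "sessions_completed": r.sessions_completed,
            "baseline_lsas": r.baseline_lsas,
        }
        for j, v in enumerate(r.lsas_series, start=1):
            row[f"lsas_t{j}"] = v
        row["post_lsas"] = r.post_lsas
        row["delta_lsas"] = r.delta_lsas
        row["true_composite_conn"] = r.true_composite_conn
        rows.append(row)
    pd.DataFrame(rows).sort_values("subject_id").to_csv(path, index=False)


def read_cohort_csv(path) -> list[SubjectRecord]:
    df = pd.read_csv(path)
    required = {"subject_id", "group", "sessions_completed", "baseline_lsas", "post_lsas", "delta_lsas"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"subject table missing columns: {sorted(missing)}")
    dupes = df["subject_id"][df["subject_id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"duplicate subject ids: {sorted(set(dupes))}")
    series_cols = sorted(
        (c for c in df.columns if c.startswith("lsas_t")), key=lambda c: int(c[6:])
    )
    records = []
    for _, row in df.sort_values("subject_id").iterrows():
        records.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                sessions_completed=int(row["sessions_completed"]),
                baseline_lsas=float(row["baseline_lsas"]),
                lsas_series=row[series_cols].to_numpy(dtype=float)
                if series_cols
                else np.array([float(row["post_lsas"])]),
                post_lsas=float(row["post_lsas"]),
                delta_lsas=float(row["delta_lsas"]),
                true_composite_conn=float(row.get("true_composite_conn", np.nan)),
            )
        )
    return records


def write_scan_tsv(scan: SimulatedScan, directory, subject_id: str) -> None:
    """Per-ROI voxel series as one wide TSV (columns ``roi_v<j>``) + motion TSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cols = {}
    for roi in ROI_NAMES:
        for j, voxel in enumerate(scan.roi_ts[roi]):
            cols[f"{roi}_v{j}"] = voxel
    cols["global_signal"] = scan.global_signal
    pd.DataFrame(cols).to_csv(directory / f"{subject_id}_roi.tsv", sep="\t", index=False)
    write_motion_tsv(scan.motion, directory / f"{subject_id}_motion.tsv")


def read_scan_tsv(directory, subject_id: str) -> tuple[dict, np.ndarray, np.ndarray]:
    """Returns (roi_ts dict, motion, global_signal) for one subject."""
    directory = Path(directory)
    df = pd.read_csv(directory / f"{subject_id}_roi.tsv", sep="\t")
    roi_ts = {}
    for roi in ROI_NAMES:
        cols = sorted(
            (c for c in df.columns if c.startswith(f"{roi}_v")), key=lambda c: int(c.rsplit("_v", 1)[1])
        )
        if cols:
            roi_ts[roi] = df[cols].to_numpy(dtype=float).T
    motion = read_motion_tsv(directory / f"{subject_id}_motion.tsv")
    gs = df["global_signal"].to_numpy(dtype=float) if "global_signal" in df else None
    return roi_ts, motion, gs


def write_motion_tsv(motion: np.ndarray, path) -> None:
    cols = ["trans_x_mm", "trans_y_mm", "trans_z_mm", "rot_x_rad", "rot_y_rad", "rot_z_rad"]
    pd.DataFrame(np.asarray(motion), columns=cols).to_csv(path, sep="\t", index=False)


def read_motion_tsv(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] != 6:
        raise ValueError(f"motion table must have 6 columns, found {df.shape[1]}")
    return df.to_numpy(dtype=float)


def extract_roi_from_nifti(image_path, mask_path) -> np.ndarray:
    """Voxel x time matrix of a 4D image under a mask on the identical grid.

    Fails loudly on grid mismatch (shape or affine); no resampling is done.
    """
    img = nib.load(str(image_path))
    mask = nib.load(str(mask_path))
    if img.shape[:3] != mask.shape[:3] or not np.allclose(img.affine, mask.affine, atol=1e-4):
        raise ValueError(
            f"mask {mask_path} is not on the grid of {image_path} "
            f"(shapes {mask.shape[:3]} vs {img.shape[:3]})"
        )
    mask_data = np.asanyarray(mask.dataobj) > 0
    if not mask_data.any():
        raise ValueError(f"mask {mask_path} selects zero voxels")
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"{image_path} is not a 4D image")
    return data[mask_data, :].astype(float)


def write_roi_nifti(scan: SimulatedScan, directory, subject_id: str) -> dict:
    """Pack the ROI voxels of a scan into a small 4D NIfTI plus one mask per ROI.

    Voxels are laid out along the first axis of a (V_total, 1, 1, T) grid so
    masks and data share an identical affine; returns the written paths.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    blocks = [scan.roi_ts[r] for r in ROI_NAMES]
    data = np.concatenate(blocks, axis=0)[:, None, None, :].astype(np.float32)
    affine = np.eye(4)
    img_path = directory / f"{subject_id}_bold.nii"
    nib.Nifti1Image(data, affine).to_filename(str(img_path))
    paths = {"image": img_path}
    offset = 0
    for roi, block in zip(ROI_NAMES, blocks):
        mask = np.zeros(data.shape[:3], dtype=np.uint8)
        mask[offset : offset + block.shape[0], 0, 0] = 1
        offset += block.shape[0]
        mpath = directory / f"{subject_id}_mask_{roi}.nii"
        nib.Nifti1Image(mask, affine).to_filename(str(mpath))
        paths[roi] = mpath
    return paths


def load_config(path) -> dict:
    """YAML or JSON configuration document as a dict."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def write_provenance(path, config: dict, seed: int | None = None, extra: dict | None = None) -> None:
    import amygconn

    record = {
        "package": "amygconn",
        "version": amygconn.__version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": seed,
        "config": config,
    }
    if extra:
        record.update(extra)
    Path(path).write_text(json.dumps(record, indent=2, default=str) + "\n")


def write_conn_table(terms, path, sign_convention: str) -> None:
    df = pd.DataFrame(
        {
            "subject_id": [t.subject_id for t in terms],
            "r_pos": [t.r_pos for t in terms],
            "r_neg1": [t.r_negs[0] for t in terms],
            "r_neg2": [t.r_negs[1] for t in terms],
            "r_neg3": [t.r_negs[2] for t in terms],
            "composite_raw": [t.composite_raw for t in terms],
            "fisher_z": [t.fisher_z for t in terms],
            "cohort_z": [t.cohort_z for t in terms],
        }
    )
    df.attrs["sign_convention"] = sign_convention
    df.to_csv(path, index=False)
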