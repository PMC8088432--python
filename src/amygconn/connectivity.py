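"""Composite amygdala-connectivity predictor from cleaned ROI time series.

The marker correlates the amygdala seed's mean time course with one
positively weighted cluster (subgenual cingulate/caudate/putamen) and three
negatively weighted clusters (left/right central sulcus, right
temporal-occipital), averages the four correlations into a single composite,
Fisher-transforms it, and z-scores the transformed values across the cohort.
Under the default ``flip_negative`` convention the negative-cluster
correlations enter with their sign flipped, so that *reduced* connectivity
with those clusters raises the composite — the direction under which the
frozen positive model coefficient predicts greater treatment response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ClusterSet",
    "ConnectivityProfile",
    "AmygConnTerm",
    "roi_mean_timeseries",
    "seed_cluster_correlations",
    "composite_conn",
    "fisher_z",
    "zscore_across_subjects",
    "build_conn_terms",
]


@dataclass(frozen=True)
class ClusterSet:
    """Fixed cluster roles: exactly one positive and three negative clusters."""

    positive: str = "cluster_pos"
    negatives: tuple = ("cluster_neg1", "cluster_neg2", "cluster_neg3")

    def __post_init__(self) -> None:
        if len(self.negatives) != 3:
            raise ValueError("exactly three negative clusters are required")


@dataclass
class ConnectivityProfile:
    r_pos: float
    r_negs: tuple  # three Pearson r values


@dataclass
class AmygConnTerm:
    subject_id: str
    r_pos: float
    r_negs: tuple
    composite_raw: float  # signed mean of the four correlations
    fisher_z: float  # arctanh(composite_raw)
    cohort_z: float  # standardized across the cohort: the model's amyg_conn


def roi_mean_timeseries(roi_ts: np.ndarray) -> np.ndarray:
    """Unweighted mean across voxels at each time point."""
    x = np.asarray(roi_ts, dtype=float)
    if x.ndim != 2 or x.shape[0] < 1:
        raise ValueError("roi_ts must be a non-empty voxel x time array")
    return x.mean(axis=0)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.shape != b.shape or a.size < 3:
        raise ValueError("series must have equal length >= 3")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance series; correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


def seed_cluster_correlations(amygdala_ts, cluster_ts: dict, clusters: ClusterSet = ClusterSet()) -> ConnectivityProfile:
    """Pearson correlations of the seed mean series with each cluster mean series."""
    seed = np.asarray(amygdala_ts, dtype=float)
    r_pos = _pearson(seed, np.asarray(cluster_ts[clusters.positive], dtype=float))
    r_negs = tuple(
        _pearson(seed, np.asarray(cluster_ts[name], dtype=float)) for name in clusters.negatives
    )
    return ConnectivityProfile(r_pos=r_pos, r_negs=r_negs)


def composite_conn(
    profile: ConnectivityProfile,
    sign_convention: str = "flip_negative",
    two_group_average: bool = False,
) -> float:
    """Signed average of the four seed-cluster correlations.

    ``flip_negative`` negates the negative-cluster correlations before
    averaging; ``raw`` averages the correlations unchanged.  With
    ``two_group_average`` the positive correlation is averaged with the mean
    of the (signed) negative correlations instead of pooling all four.
    """
    if sign_convention == "flip_negative":
        negs = [-r for r in profile.r_negs]
    elif sign_convention == "raw":
        negs = list(profile.r_negs)
    else:
        raise ValueError(f"unknown sign convention: {sign_convention!r}")
    if two_group_average:
        return float((profile.r_pos + np.mean(negs)) / 2.0)
    return float(np.mean([profile.r_pos] + negs))


def fisher_z(r) -> float:
    """Variance-stabilizing Fisher transform arctanh(r); odd and increasing."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        raise ValueError("|r| must be < 1 for the Fisher transform")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def zscore_across_subjects(values) -> np.ndarray:
    """Standardize across the cohort: (x - mean) / sample SD (ddof=1)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 subjects to z-score across the cohort")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant values; cohort z-score undefined")
    return (x - x.mean()) / sd


def build_conn_terms(
    roi_series_by_subject: dict,
    sign_convention: str = "flip_negative",
    clusters: ClusterSet = ClusterSet(),
    two_group_average: bool = False,
    transform_each_r: bool = False,
) -> list[AmygConnTerm]:
    """Per-subject composite terms, Fisher-transformed then cohort z-scored.

    ``roi_series_by_subject`` maps subject id to a dict of mean time series
    (``amygdala`` plus the four cluster names).  By default the four
    correlations are averaged first and the composite is Fisher-transformed
    ("average then transform"); ``transform_each_r`` applies arctanh to each
    correlation before the signed average, for sensitivity analysis.  Subject
    ordering is preserved.
    """
    ids = list(roi_series_by_subject)
    if len(ids) < 2:
        raise ValueError("need >= 2 subjects to build cohort-standardized terms")
    profiles, raws, zs = [], [], []
    for sid in ids:
        series = roi_series_by_subject[sid]
        prof = seed_cluster_correlations(series["amygdala"], series, clusters)
        profiles.append(prof)
        raws.append(composite_conn(prof, sign_convention, two_group_average))
        if transform_each_r:
            tprof = ConnectivityProfile(
                r_pos=fisher_z(prof.r_pos), r_negs=tuple(fisher_z(r) for r in prof.r_negs)
            )
            zs.append(composite_conn(tprof, sign_convention, two_group_average))
        else:
            zs.append(fisher_z(raws[-1]))
    cohort = zscore_across_subjects(zs)
    return [
        AmygConnTerm(
            subject_id=sid,
            r_pos=prof.r_pos,
            r_negs=prof.r_negs,
            composite_raw=raw,
            fisher_z=fz,
            cohort_z=float(cz),
        )
        for sid, prof, raw, fz, cz in zip(ids, profiles, raws, zs, cohort)
    ]
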