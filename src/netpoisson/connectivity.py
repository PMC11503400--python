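"""Network-averaged functional connectivity from ROI time series.

Implements the motion-censoring and featureization stage used for
resting-state fMRI: frames with excessive head motion (framewise
displacement, FD) are censored together with short runs of low-motion
frames, subjects with too few surviving frames are excluded, and the
retained frames are summarized as within- and between-network averages
of Fisher z-transformed Pearson correlations.

With the canonical 12 cortical networks this yields ``12*13/2 = 78``
features per subject, one per unordered network pair (self pairs
included).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Canonical network abbreviations, fixed order used for feature naming.
NETWORKS: tuple[str, ...] = (
    "AD", "CA", "CGC", "DLA", "DT", "FO",
    "RSPLTP", "SA", "SMH", "SMM", "VIS", "VTA",
)

#: Label for ROIs that belong to no network; always excluded.
NONE_LABEL = "none"

#: Clipping bound applied to correlations before atanh.
R_CLIP = 0.999999


def pair_name(a: str, b: str) -> str:
    """Canonical ``"A_B"`` feature name with A <= B lexicographically."""
    return f"{a}_{b}" if a <= b else f"{b}_{a}"


def feature_names(networks: Sequence[str] = NETWORKS) -> list[str]:
    """All unordered network-pair feature names (self pairs included).

    For the 12 canonical networks this is the 78-name inventory, ordered
    lexicographically by (first, second) network.
    """
    nets = sorted(networks)
    out = []
    for i, a in enumerate(nets):
        for b in nets[i:]:
            out.append(f"{a}_{b}")
    return out


@dataclass
class ROITimeSeries:
    """Per-subject ROI signals with motion trace and network labels.

    Parameters
    ----------
    data : (T, R) array
        Frames-by-ROIs signal matrix.
    fd : (T,) array
        Framewise displacement in mm, non-negative.
    labels : sequence of str, length R
        Network assignment per ROI; must come from the canonical network
        set or be ``"none"``.
    """

    data: np.ndarray
    fd: np.ndarray
    labels: Sequence[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.fd = np.asarray(self.fd, dtype=float)
        self.labels = list(self.labels)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D frames-by-ROIs matrix")
        if self.fd.shape != (self.data.shape[0],):
            raise ValueError("fd length must equal the number of frames")
        if len(self.labels) != self.data.shape[1]:
            raise ValueError("one network label required per ROI")
        allowed = set(NETWORKS) | {NONE_LABEL}
        bad = sorted(set(self.labels) - allowed)
        if bad:
            raise ValueError(f"unknown network labels: {bad}")
        if np.any(self.fd < 0):
            raise ValueError("framewise displacement must be non-negative")


@dataclass
class ConnectivityFeatures:
    """Mean Fisher-z connectivity per unordered network pair."""

    values: dict[str, float]
    n_frames_used: int

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, name="fisher_z")


def censor_frames(
    fd: np.ndarray, threshold: float = 0.2, min_run: int = 5
) -> np.ndarray:
    """Boolean retain-mask for motion censoring.

    A frame is retained iff its FD is <= ``threshold`` *and* it belongs
    to a maximal run of sub-threshold frames of length >= ``min_run``.
    Short islands of low motion between spikes are censored along with
    the spikes themselves.
    """
    fd = np.asarray(fd, dtype=float)
    if fd.ndim != 1 or fd.size < 1:
        raise ValueError("fd must be a non-empty 1-D vector")
    if np.any(fd < 0):
        raise ValueError("framewise displacement must be non-negative")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if min_run < 1:
        raise ValueError("min_run must be >= 1")

    below = fd <= threshold
    mask = np.zeros_like(below)
    # scan maximal runs of sub-threshold frames
    t = 0
    T = below.size
    while t < T:
        if not below[t]:
            t += 1
            continue
        start = t
        while t < T and below[t]:
            t += 1
        if t - start >= min_run:
            mask[start:t] = True
    return mask


def qc_pass(mask: np.ndarray, min_frames: int = 350) -> bool:
    """Frame-count quality control: enough retained frames to analyze."""
    return int(np.count_nonzero(mask)) >= min_frames


def network_connectivity(
    ts: ROITimeSeries, mask: np.ndarray | None = None
) -> ConnectivityFeatures:
    """Average Fisher-z correlations for every unordered network pair.

    Within-network values average ``atanh(r)`` over all distinct ROI
    pairs inside the network; between-network values average over all
    cross pairs. Correlations are Pearson correlations computed on the
    retained frames only (means removed over retained frames), clipped
    to ``+/- 0.999999`` before the z-transform. ROIs labelled ``"none"``
    are excluded.
    """
    if mask is None:
        mask = np.ones(ts.data.shape[0], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (ts.data.shape[0],):
        raise ValueError("mask length must equal the number of frames")
    kept = ts.data[mask]
    n_used = kept.shape[0]
    if n_used < 2:
        raise ValueError("need at least 2 retained frames to correlate")

    labels = np.asarray(ts.labels)
    present = sorted(set(labels) - {NONE_LABEL})
    if not present:
        raise ValueError("no ROI belongs to a named network")

    idx = {net: np.flatnonzero(labels == net) for net in present}
    # guard against zero-variance ROIs: corrcoef would emit nan
    sub = kept[:, np.concatenate([idx[n] for n in present])]
    cols = {net: None for net in present}
    pos = 0
    for net in present:
        cols[net] = np.arange(pos, pos + idx[net].size)
        pos += idx[net].size
    sd = sub.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("constant ROI signal on retained frames")
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(sub, rowvar=False)
    corr = np.clip(corr, -R_CLIP, R_CLIP)
    z = np.arctanh(corr)

    values: dict[str, float] = {}
    for i, a in enumerate(present):
        ia = cols[a]
        for b in present[i:]:
            ib = cols[b]
            if a == b:
                if ia.size < 2:
                    raise ValueError(
                        f"within-network feature {a}_{a} undefined: "
                        "network has a single ROI"
                    )
                iu, ju = np.triu_indices(ia.size, k=1)
                vals = z[np.ix_(ia, ia)][iu, ju]
            else:
                vals = z[np.ix_(ia, ib)].ravel()
            values[pair_name(a, b)] = float(vals.mean())
    return ConnectivityFeatures(values=values, n_frames_used=n_used)


# ---------------------------------------------------------------------------
# Cohort-level I/O


def read_subject_timeseries(
    ts_path: str | Path, fd_path: str | Path, labels_path: str | Path
) -> ROITimeSeries:
    """Read one subject's time series (frames x ROIs CSV with ROI-id
    header), FD (one-column CSV) and ROI labels (roi_id, network CSV)."""
    data = pd.read_csv(ts_path)
    fd = pd.read_csv(fd_path).iloc[:, 0].to_numpy(dtype=float)
    lab = pd.read_csv(labels_path)
    label_map: Mapping[str, str] = dict(
        zip(lab.iloc[:, 0].astype(str), lab.iloc[:, 1].astype(str))
    )
    labels = [label_map[str(c)] for c in data.columns]
    return ROITimeSeries(data=data.to_numpy(dtype=float), fd=fd, labels=labels)


def cohort_features(
    subjects: Mapping[str, ROITimeSeries],
    fd_threshold: float = 0.2,
    min_run: int = 5,
    min_frames: int = 350,
    log=None,
) -> pd.DataFrame:
    """Featureize a cohort, dropping subjects that fail frame-count QC.

    Returns one row per passing subject with the 78 canonical columns
    plus ``n_frames_used``; exclusions are reported through ``log``
    (a callable, e.g. ``logging.Logger.info``).
    """
    rows = {}
    for sid, ts in subjects.items():
        mask = censor_frames(ts.fd, threshold=fd_threshold, min_run=min_run)
        if not qc_pass(mask, min_frames=min_frames):
            if log is not None:
                log(
                    f"subject {sid} excluded: {int(mask.sum())} frames "
                    f"after censoring (< {min_frames})"
                )
            continue
        feats = network_connectivity(ts, mask)
        row = dict(feats.values)
        row["n_frames_used"] = feats.n_frames_used
        rows[sid] = row
    cols = feature_names() + ["n_frames_used"]
    df = pd.DataFrame.from_dict(rows, orient="index")
    return df.reindex(columns=cols)
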