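"""Tapered-window correlation graphs and density-normalised degree centrality.

A Gaussian taper W(t) = exp(-t^2 / 2 s^2), t in {-T/2 .. T/2}, s = T/6, is
slid over each node-by-time series in steps of s (window centers s/2 + k*s,
boundary-clipped), which yields eight windows for a 150-volume condition
under the default T = 120, s = 20 geometry. Within each window the taper
acts as observation weights in a weighted Pearson correlation between all
node pairs, giving one signed adjacency matrix per window position. Each
node's weighted degree centrality DC(i) = sum_j a_ij (diagonal excluded,
signed weights retained) is normalised by the network density — the mean
absolute off-diagonal weight — and the subject-wise mean-centred DC vectors
from all windows of the contrasted conditions form the classification
feature set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import ParcellatedTimeSeries

__all__ = [
    "TaperWindow",
    "WindowSegment",
    "AdjacencyStack",
    "CentralityFeatureSet",
    "gaussian_taper",
    "window_series",
    "weighted_correlation_matrix",
    "degree_centrality",
    "density_normalize",
    "compute_adjacency_stack",
    "dc_feature_stack",
    "assemble_features",
    "assemble_ordinal_features",
]

DEFAULT_WINDOW_LENGTH = 120


@dataclass
class TaperWindow:
    """Gaussian taper over integer offsets t in {-T/2 .. T/2}."""

    length_T: int
    s: float
    offsets: np.ndarray
    weights: np.ndarray


@dataclass
class WindowSegment:
    """One boundary-clipped window: retained volume indices plus taper."""

    center: float
    indices: np.ndarray
    weights: np.ndarray


@dataclass
class AdjacencyStack:
    """Per-window N x N weighted correlation graphs for one time series."""

    matrices: np.ndarray  # (K, N, N)
    window_centers: np.ndarray
    node_labels: list[str]

    @property
    def n_windows(self) -> int:
        return self.matrices.shape[0]


def gaussian_taper(length_T: int, s: float | None = None) -> TaperWindow:
    """Taper weights exp(-t^2/(2 s^2)) at offsets t = -T/2 .. T/2.

    ``s`` defaults to T/6. The weight is exactly 1 at the center and
    symmetric about it.
    """
    if length_T < 2:
        raise ValueError(f"length_T must be >= 2, got {length_T}")
    if s is None:
        s = length_T / 6.0
    if not s > 0:
        raise ValueError(f"taper width s must be positive, got {s}")
    half = length_T // 2
    offsets = np.arange(-half, half + 1)
    weights = np.exp(-(offsets.astype(float) ** 2) / (2.0 * s * s))
    return TaperWindow(length_T=length_T, s=float(s), offsets=offsets,
                       weights=weights)


def window_series(
    ts: ParcellatedTimeSeries | np.ndarray,
    length_T: int = DEFAULT_WINDOW_LENGTH,
    s: float | None = None,
) -> list[WindowSegment]:
    """Window positions over a series of length L: K = ceil(L/s) windows with
    centers c_k = s/2 + k*s, each spanning center +/- T/2 and clipped to the
    observed range, the taper truncated with the dropped samples.

    For L = 150, T = 120, s = 20 this yields exactly eight windows.
    """
    data = ts.data if isinstance(ts, ParcellatedTimeSeries) else np.asarray(ts)
    L = data.shape[0]
    if s is None:
        s = length_T / 6.0
    if not s > 0:
        raise ValueError(f"step/width s must be positive, got {s}")
    if L < s:
        raise ValueError(f"series length {L} shorter than window step {s}")
    n_windows = int(np.ceil(L / s))
    half = length_T / 2.0
    segments = []
    for k in range(n_windows):
        center = s / 2.0 + k * s
        lo = int(np.ceil(center - half))
        hi = int(np.floor(center + half))
        idx = np.arange(max(lo, 0), min(hi, L - 1) + 1)
        if idx.size == 0:
            raise ValueError(
                f"window at center {center} lies outside the series"
            )
        offs = idx - center
        weights = np.exp(-(offs**2) / (2.0 * s * s))
        segments.append(WindowSegment(center=center, indices=idx,
                                      weights=weights))
    return segments


def weighted_correlation_matrix(
    segment: np.ndarray, weights: np.ndarray
) -> np.ndarray:
    """Weighted Pearson correlation between all columns of ``segment``.

    The taper values act as observation weights: weighted means are removed,
    the weighted covariance is formed and normalised by the weighted standard
    deviations. The result is symmetric with unit diagonal; a node with zero
    weighted variance is an error naming the node.
    """
    seg = np.asarray(segment, dtype=float)
    w = np.asarray(weights, dtype=float)
    if seg.ndim != 2:
        raise ValueError("segment must be 2-D samples x nodes")
    if w.shape != (seg.shape[0],):
        raise ValueError("one weight per sample required")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if np.count_nonzero(w > 0) < 3:
        raise ValueError("need at least 3 samples with positive weight")
    wsum = w.sum()
    mean = (w @ seg) / wsum
    centered = seg - mean
    cov = (centered * w[:, None]).T @ centered / wsum
    var = np.diag(cov)
    bad = np.flatnonzero(var <= 0)
    if bad.size:
        raise ValueError(f"zero weighted variance at node index {bad[0]}")
    sd = np.sqrt(var)
    corr = cov / np.outer(sd, sd)
    corr = np.clip(corr, -1.0, 1.0)
    corr = 0.5 * (corr + corr.T)
    np.fill_diagonal(corr, 1.0)
    return corr


def degree_centrality(adjacency: np.ndarray) -> np.ndarray:
    """Weighted degree centrality DC(i) = sum_{j != i} a_ij.

    Signed weights are retained; the diagonal is excluded from the sum.
    """
    adj = np.asarray(adjacency, dtype=float)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError(f"adjacency must be square, got shape {adj.shape}")
    return adj.sum(axis=1) - np.diag(adj)


def network_density(adjacency: np.ndarray) -> float:
    """Mean absolute off-diagonal weight of a square matrix."""
    adj = np.asarray(adjacency, dtype=float)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError(f"adjacency must be square, got shape {adj.shape}")
    n = adj.shape[0]
    off = np.abs(adj).sum() - np.abs(np.diag(adj)).sum()
    return off / (n * (n - 1))


def density_normalize(dc: np.ndarray, adjacency: np.ndarray) -> np.ndarray:
    """Divide each node's DC by the graph's density (mean absolute
    off-diagonal weight), removing inter-subject overall-coupling scale."""
    dens = network_density(adjacency)
    if dens <= 0:
        raise ValueError("network density is zero; cannot normalise")
    return np.asarray(dc, dtype=float) / dens


def compute_adjacency_stack(
    ts: ParcellatedTimeSeries,
    length_T: int = DEFAULT_WINDOW_LENGTH,
    s: float | None = None,
) -> AdjacencyStack:
    """All per-window weighted correlation graphs of one time series."""
    segments = window_series(ts, length_T=length_T, s=s)
    mats = np.stack(
        [
            weighted_correlation_matrix(ts.data[seg.indices], seg.weights)
            for seg in segments
        ]
    )
    return AdjacencyStack(
        matrices=mats,
        window_centers=np.array([seg.center for seg in segments]),
        node_labels=list(ts.node_labels),
    )


def dc_feature_stack(stack: AdjacencyStack) -> np.ndarray:
    """Density-normalised DC per window: (K, N) matrix."""
    out = np.empty((stack.n_windows, len(stack.node_labels)))
    for k in range(stack.n_windows):
        adj = stack.matrices[k].copy()
        np.fill_diagonal(adj, 0.0)
        out[k] = density_normalize(degree_centrality(adj), adj)
    return out


@dataclass
class CentralityFeatureSet:
    """Subject-centred DC feature samples with labels and grouping.

    One sample per subject x condition x window. ``labels`` are +1 for
    ``condition_a`` and -1 for ``condition_b``; ``class_index`` carries the
    ordinal class for multi-class sets (binary sets use 0 for the +1 class).
    Per subject, the mean over all of that subject's samples in the
    comparison has been subtracted, so each subject's rows sum to ~0.
    """

    features: np.ndarray
    labels: np.ndarray
    subject_ids: np.ndarray
    conditions: np.ndarray
    window_index: np.ndarray
    node_labels: list[str]
    class_index: np.ndarray | None = None
    contrast: tuple | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        self.subject_ids = np.asarray(self.subject_ids)
        self.conditions = np.asarray(self.conditions)
        self.window_index = np.asarray(self.window_index)
        n = self.features.shape[0]
        for name in ("labels", "subject_ids", "conditions", "window_index"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} must have one entry per sample")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def subjects(self) -> list:
        seen: dict = {}
        for s in self.subject_ids:
            seen.setdefault(s, None)
        return list(seen)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.features, columns=self.node_labels)
        df.insert(0, "subject_id", self.subject_ids)
        df.insert(1, "condition", self.conditions)
        df.insert(2, "window_index", self.window_index)
        df.insert(3, "label", self.labels)
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
        sidecar = {
            "contrast": list(self.contrast) if self.contrast else None,
            "n_nodes": len(self.node_labels),
            "centering": "subject-wise mean over all samples in comparison",
            "density": "mean absolute off-diagonal weight",
        }
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_tsv(cls, path) -> "CentralityFeatureSet":
        df = pd.read_csv(path, sep="\t")
        meta_cols = ["subject_id", "condition", "window_index", "label"]
        node_cols = [c for c in df.columns if c not in meta_cols]
        contrast = None
        sidecar = Path(str(path) + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            if meta.get("contrast"):
                contrast = tuple(meta["contrast"])
        return cls(
            features=df[node_cols].to_numpy(dtype=float),
            labels=df["label"].to_numpy(),
            subject_ids=df["subject_id"].to_numpy(),
            conditions=df["condition"].to_numpy(),
            window_index=df["window_index"].to_numpy(),
            node_labels=node_cols,
            contrast=contrast,
        )


def _center_by_subject(features, subject_ids, center_mask=None):
    """Subtract each subject's mean feature vector (over ``center_mask`` rows,
    default all rows) from all of that subject's rows."""
    features = np.asarray(features, dtype=float).copy()
    subject_ids = np.asarray(subject_ids)
    if center_mask is None:
        center_mask = np.ones(len(subject_ids), dtype=bool)
    for s in np.unique(subject_ids):
        rows = subject_ids == s
        pool = rows & center_mask
        if not pool.any():
            raise ValueError(f"subject {s!r} has no samples in centering pool")
        features[rows] -= features[pool].mean(axis=0)
    return features


def _gather_dc(dc_map, conditions):
    """Validate a {(subject, condition): (K, N) array} mapping and return
    (subjects, window count)."""
    subjects: dict = {}
    for subj, cond in dc_map:
        subjects.setdefault(subj, set()).add(cond)
    missing = [
        (s, c)
        for s, conds in subjects.items()
        for c in conditions
        if c not in conds
    ]
    if missing:
        s, c = missing[0]
        raise ValueError(f"subject {s!r} is missing condition {c!r}")
    k_counts = {
        np.asarray(dc_map[(s, c)]).shape[0]
        for s in subjects
        for c in conditions
    }
    if len(k_counts) != 1:
        raise ValueError(f"unequal window counts across runs: {sorted(k_counts)}")
    return list(subjects), k_counts.pop()


def assemble_features(
    dc_map: dict,
    condition_a: str,
    condition_b: str,
    node_labels,
) -> CentralityFeatureSet:
    """Build the binary classification feature set for one contrast.

    ``dc_map`` maps (subject_id, condition) to a (K, N) stack of
    density-normalised DC vectors. Labels are +1 for ``condition_a`` and -1
    for ``condition_b``; subject-wise centering pools both conditions.
    """
    if condition_a == condition_b:
        raise ValueError("contrast conditions must differ")
    subjects, K = _gather_dc(dc_map, (condition_a, condition_b))
    rows, labels, subj, conds, widx = [], [], [], [], []
    for s in subjects:
        for cond, lab in ((condition_a, 1), (condition_b, -1)):
            dc = np.asarray(dc_map[(s, cond)], dtype=float)
            for k in range(K):
                rows.append(dc[k])
                labels.append(lab)
                subj.append(s)
                conds.append(cond)
                widx.append(k)
    features = _center_by_subject(np.array(rows), np.array(subj))
    return CentralityFeatureSet(
        features=features,
        labels=np.array(labels),
        subject_ids=np.array(subj),
        conditions=np.array(conds),
        window_index=np.array(widx),
        node_labels=list(node_labels),
        contrast=(condition_a, condition_b),
    )


def assemble_ordinal_features(
    dc_map: dict,
    ordered_conditions,
    node_labels,
) -> CentralityFeatureSet:
    """Feature set for ordinal analysis over rank-ordered conditions.

    ``class_index`` runs 0 .. C-1 in the supplied order; subject-wise
    centering pools all C conditions. ``labels`` holds the class index too
    (the +1/-1 encoding has no meaning for C > 2).
    """
    ordered_conditions = list(ordered_conditions)
    if len(set(ordered_conditions)) != len(ordered_conditions):
        raise ValueError("ordered_conditions contains duplicates")
    if len(ordered_conditions) < 2:
        raise ValueError("need at least two ordered conditions")
    subjects, K = _gather_dc(dc_map, ordered_conditions)
    rows, cls, subj, conds, widx = [], [], [], [], []
    for s in subjects:
        for ci, cond in enumerate(ordered_conditions):
            dc = np.asarray(dc_map[(s, cond)], dtype=float)
            for k in range(K):
                rows.append(dc[k])
                cls.append(ci)
                subj.append(s)
                conds.append(cond)
                widx.append(k)
    features = _center_by_subject(np.array(rows), np.array(subj))
    cls = np.array(cls)
    return CentralityFeatureSet(
        features=features,
        labels=cls,
        subject_ids=np.array(subj),
        conditions=np.array(conds),
        window_index=np.array(widx),
        node_labels=list(node_labels),
        class_index=cls,
        contrast=tuple(ordered_conditions),
    )


def assemble_cross_features(
    dc_map: dict,
    condition_a: str,
    condition_b: str,
    condition_c: str,
    node_labels,
) -> tuple[CentralityFeatureSet, CentralityFeatureSet]:
    """Features for classifying a third condition with an (a, b) model.

    Both the (a, b) training samples and the test-only ``condition_c``
    samples are centred with each subject's mean over the a/b pool, so the
    third condition is mapped into the same subject-referenced space.
    """
    if condition_c in (condition_a, condition_b):
        raise ValueError("test condition overlaps the training contrast")
    subjects, K = _gather_dc(
        dc_map, (condition_a, condition_b, condition_c)
    )
    rows, labels, subj, conds, widx, is_train = [], [], [], [], [], []
    for s in subjects:
        for cond, lab in (
            (condition_a, 1), (condition_b, -1), (condition_c, 0)
        ):
            dc = np.asarray(dc_map[(s, cond)], dtype=float)
            for k in range(K):
                rows.append(dc[k])
                labels.append(lab)
                subj.append(s)
                conds.append(cond)
                widx.append(k)
                is_train.append(cond != condition_c)
    rows = np.array(rows)
    subj = np.array(subj)
    is_train = np.array(is_train)
    features = _center_by_subject(rows, subj, center_mask=is_train)
    labels = np.array(labels)
    conds = np.array(conds)
    widx = np.array(widx)

    def _subset(mask, contrast):
        return CentralityFeatureSet(
            features=features[mask],
            labels=labels[mask],
            subject_ids=subj[mask],
            conditions=conds[mask],
            window_index=widx[mask],
            node_labels=list(node_labels),
            contrast=contrast,
        )

    return (
        _subset(is_train, (condition_a, condition_b)),
        _subset(~is_train, (condition_c,)),
    )
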