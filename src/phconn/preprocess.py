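"""Node time-series preprocessing: nuisance regression, band-pass filtering,
and parcellation of 4D images into node time courses.

The pipeline order is nuisance regression first, band-pass second. Nuisance
regression projects each node series onto the orthogonal complement of
[intercept | regressors] by ordinary least squares; the band-pass is an
order-2 Butterworth applied forward-backward (zero phase) over the
0.01–0.1 Hz band by default, retaining low-frequency coherent fluctuations
while suppressing drift and high-frequency physiological signal.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "ParcellatedTimeSeries",
    "NuisanceTable",
    "regress_nuisance",
    "bandpass_filter",
    "parcellate_image",
    "read_timeseries_tsv",
    "write_timeseries_tsv",
]


@dataclass
class ParcellatedTimeSeries:
    """One subject x condition node-by-time matrix.

    Attributes
    ----------
    data : ndarray, shape (n_volumes, n_nodes)
        BOLD-like signal, volumes as rows (arbitrary units).
    tr : float
        Repetition time in seconds.
    node_labels : list of str
        Ordered region names, one per column.
    subject_id : str
    condition : str
    """

    data: np.ndarray
    tr: float
    node_labels: list[str]
    subject_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D volumes x nodes matrix")
        if self.data.shape[0] < 2:
            raise ValueError("need at least 2 volumes")
        if self.data.shape[1] != len(self.node_labels):
            raise ValueError(
                f"node count {self.data.shape[1]} does not match "
                f"{len(self.node_labels)} labels"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time series contains non-finite values")
        if not self.tr > 0:
            raise ValueError("tr must be positive")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]


@dataclass
class NuisanceTable:
    """Nuisance regressors for one run: volumes x k matrix plus names.

    Typical columns are mean CSF signal, mean WM signal and six motion
    parameters (or synthetic stand-ins with the same roles).
    """

    regressors: np.ndarray
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.regressors = np.asarray(self.regressors, dtype=float)
        if self.regressors.ndim != 2:
            raise ValueError("regressors must be a 2-D volumes x k matrix")
        if not self.names:
            self.names = [f"nuis_{i}" for i in range(self.regressors.shape[1])]
        if len(self.names) != self.regressors.shape[1]:
            raise ValueError("names must match regressor columns")

    @property
    def n_volumes(self) -> int:
        return self.regressors.shape[0]


def regress_nuisance(
    ts: ParcellatedTimeSeries, nuis: NuisanceTable
) -> ParcellatedTimeSeries:
    """Regress nuisance signals out of every node series.

    An intercept column is always added to the design, so node means are
    removed along with the supplied regressors. Returns the OLS residuals;
    each residual column has (numerically) zero inner product with every
    design column.
    """
    if nuis.n_volumes != ts.n_volumes:
        raise ValueError(
            f"nuisance table has {nuis.n_volumes} rows but time series has "
            f"{ts.n_volumes} volumes"
        )
    design = np.column_stack([np.ones(ts.n_volumes), nuis.regressors])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError(
            "nuisance design (with intercept) is rank deficient: "
            f"rank {rank} < {design.shape[1]} columns"
        )
    beta, *_ = np.linalg.lstsq(design, ts.data, rcond=None)
    resid = ts.data - design @ beta
    return replace(ts, data=resid)


def bandpass_filter(
    ts: ParcellatedTimeSeries,
    low_hz: float = 0.01,
    high_hz: float = 0.1,
    order: int = 2,
) -> ParcellatedTimeSeries:
    """Zero-phase Butterworth band-pass of every node series.

    Parameters are the band edges in Hz; they must lie strictly inside
    (0, Nyquist) with ``low_hz < high_hz``. Edge transients are controlled by
    mirror (even) padding of one filter settle-length before the
    forward-backward pass; the series length is preserved and the output is
    mean-free per node (DC is outside the pass band).
    """
    nyquist = 1.0 / (2.0 * ts.tr)
    if not (0.0 < low_hz < high_hz < nyquist):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz must satisfy "
            f"0 < low < high < Nyquist ({nyquist:g} Hz for TR={ts.tr:g} s)"
        )
    sos = signal.butter(
        order, [low_hz, high_hz], btype="bandpass", fs=1.0 / ts.tr, output="sos"
    )
    padlen = min(3 * 2 * order * 2, ts.n_volumes - 1)
    filtered = signal.sosfiltfilt(
        sos, ts.data, axis=0, padtype="even", padlen=padlen
    )
    return replace(ts, data=filtered)


def _as_array(img):
    """Accept a nibabel image or a bare ndarray."""
    if hasattr(img, "get_fdata"):
        return np.asanyarray(img.get_fdata())
    return np.asarray(img, dtype=float)


def parcellate_image(
    image, atlas, labels, *, node_names=None, tr: float = 2.0,
    subject_id: str = "", condition: str = "",
) -> ParcellatedTimeSeries:
    """Average a 4D image into node time series using an integer atlas.

    Parameters
    ----------
    image : 4D ndarray or nibabel image, shape (x, y, z, t)
    atlas : 3D ndarray or nibabel image of integer region ids (0 = background)
    labels : ordered sequence of region ids to extract
    node_names : optional region names matching ``labels``

    Each node's value at volume t is the unweighted mean over the voxels
    carrying that region id. Voxels labelled 0 never contribute. Requesting a
    region id absent from the atlas is an error naming the region.
    """
    img = _as_array(image)
    atl = np.asarray(_as_array(atlas)).astype(int)
    if img.ndim != 4:
        raise ValueError("image must be 4-D (x, y, z, t)")
    if atl.shape != img.shape[:3]:
        raise ValueError(
            f"atlas grid {atl.shape} does not match image grid {img.shape[:3]}"
        )
    labels = list(labels)
    if node_names is None:
        node_names = [str(l) for l in labels]
    n_t = img.shape[3]
    out = np.empty((n_t, len(labels)))
    flat_img = img.reshape(-1, n_t)
    flat_atl = atl.reshape(-1)
    for j, lab in enumerate(labels):
        if lab == 0:
            raise ValueError("region id 0 is reserved for background")
        mask = flat_atl == lab
        if not mask.any():
            raise ValueError(f"atlas region {lab!r} is empty")
        out[:, j] = flat_img[mask].mean(axis=0)
    return ParcellatedTimeSeries(
        data=out, tr=tr, node_labels=list(node_names),
        subject_id=subject_id, condition=condition,
    )


def write_timeseries_tsv(ts: ParcellatedTimeSeries, path) -> None:
    """Write a time series as TSV (volumes as rows, header = node labels)."""
    df = pd.DataFrame(ts.data, columns=ts.node_labels)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_timeseries_tsv(
    path, tr: float = 2.0, subject_id: str = "", condition: str = ""
) -> ParcellatedTimeSeries:
    """Read a TSV time-series matrix (gzip tolerated by extension)."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        df = pd.read_csv(fh, sep="\t")
    return ParcellatedTimeSeries(
        data=df.to_numpy(dtype=float),
        tr=tr,
        node_labels=[str(c) for c in df.columns],
        subject_id=subject_id,
        condition=condition,
    )


def read_nuisance_tsv(path) -> NuisanceTable:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        df = pd.read_csv(fh, sep="\t")
    return NuisanceTable(
        regressors=df.to_numpy(dtype=float), names=[str(c) for c in df.columns]
    )


def write_nuisance_tsv(nuis: NuisanceTable, path) -> None:
    pd.DataFrame(nuis.regressors, columns=nuis.names).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )
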