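"""Correlation RDMs, searchlight RDMs, MEG-fMRI fusion, and MDS embedding.

Representational similarity analysis (RSA) abstracts away from the
measurement space: a condition x condition representational dissimilarity
matrix (RDM) summarizes a region's (or a time point's) response geometry,
and geometries from different modalities can be compared directly.  Here
fMRI RDMs are built as 1 - Pearson correlation between condition pattern
vectors, and fusion rank-correlates (Spearman) the time-resolved MEG RDM
with a space-resolved fMRI RDM, yielding a time course of MEG-fMRI
representational similarity per fMRI subject and region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import spearmanr
from sklearn.manifold import smacof

if TYPE_CHECKING:  # pragma: no cover
    from .mvpa import TimeResolvedRDM

__all__ = [
    "ConditionPatternSet",
    "Rdm",
    "FusionSeries",
    "correlation_rdm",
    "searchlight_rdms",
    "fusion_timecourse",
    "mds_embed",
    "lower_triangle",
    "save_mds_coordinates",
    "save_searchlight_rdms",
]


@dataclass
class ConditionPatternSet:
    """Condition x voxel response matrix for one region (or a volume).

    `responses` holds one pattern vector per condition (t-statistic units
    for real fMRI, arbitrary for synthetic). For searchlight use,
    `coordinates` gives each voxel's integer 3-D grid position; only the
    supplied (in-mask) voxels exist.
    """

    responses: np.ndarray  # (n_conditions, n_voxels)
    roi_id: str = ""
    condition_ids: np.ndarray | None = None
    coordinates: np.ndarray | None = None  # (n_voxels, 3) integer grid

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=np.float64)
        if self.responses.ndim != 2:
            raise ValueError("responses must be (n_conditions, n_voxels)")
        if self.responses.shape[0] < 2 or self.responses.shape[1] < 2:
            raise ValueError("need at least 2 conditions and 2 voxels")
        if self.condition_ids is None:
            self.condition_ids = np.arange(self.responses.shape[0])
        else:
            self.condition_ids = np.asarray(self.condition_ids)
        if self.coordinates is not None:
            self.coordinates = np.asarray(self.coordinates)
            if self.coordinates.shape != (self.responses.shape[1], 3):
                raise ValueError("coordinates must be (n_voxels, 3)")
            uniq = np.unique(self.coordinates, axis=0)
            if uniq.shape[0] != self.coordinates.shape[0]:
                raise ValueError("voxel coordinates must be unique")

    @property
    def n_conditions(self) -> int:
        return self.responses.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.responses.shape[1]


@dataclass
class Rdm:
    """Condition x condition dissimilarity matrix (1 - Pearson, in [0, 2])."""

    dissimilarity: np.ndarray
    condition_ids: np.ndarray | None = None
    roi_id: str = ""

    def __post_init__(self) -> None:
        self.dissimilarity = np.asarray(self.dissimilarity, dtype=np.float64)
        d = self.dissimilarity
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("dissimilarity must be square")
        if self.condition_ids is None:
            self.condition_ids = np.arange(d.shape[0])
        else:
            self.condition_ids = np.asarray(self.condition_ids)

    @property
    def n_conditions(self) -> int:
        return self.dissimilarity.shape[0]


@dataclass
class FusionSeries:
    """Spearman rho between a time-resolved MEG RDM and one fMRI RDM."""

    rho: np.ndarray  # (n_times,), NaN where undefined
    time_axis: np.ndarray
    roi_id: str = ""
    subject: int = 0

    n_undefined: int = field(init=False, default=0)

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=np.float64)
        self.time_axis = np.asarray(self.time_axis, dtype=np.float64)
        if self.rho.shape != self.time_axis.shape:
            raise ValueError("rho and time_axis must align")
        self.n_undefined = int(np.isnan(self.rho).sum())


def lower_triangle(matrix: np.ndarray) -> np.ndarray:
    """Strictly-lower-triangle vectorization, row-major with i > j.

    This fixed order is shared by every RDM consumer so serialized
    vectors are bit-stable; rank correlations are order-invariant.
    """
    m = np.asarray(matrix)
    i, j = np.tril_indices(m.shape[0], k=-1)
    return m[i, j]


def correlation_rdm(patterns: ConditionPatternSet) -> Rdm:
    """1 - Pearson correlation between all condition pattern pairs."""
    resp = patterns.responses
    sd = resp.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        ids = patterns.condition_ids[dead]
        raise ValueError(
            f"zero-variance pattern for condition(s) {ids.tolist()}; "
            "correlation dissimilarity is undefined"
        )
    diss = 1.0 - np.corrcoef(resp)
    np.fill_diagonal(diss, 0.0)
    return Rdm(
        dissimilarity=diss,
        condition_ids=patterns.condition_ids,
        roi_id=patterns.roi_id,
    )


def searchlight_rdms(
    volume: ConditionPatternSet, radius: float = 4.0
) -> dict[tuple[int, int, int], Rdm]:
    """Per-voxel correlation RDMs from spherical searchlight neighborhoods.

    For each in-mask voxel v the neighborhood is every in-mask voxel whose
    center-to-center Euclidean distance is <= `radius` (voxel units,
    boundary inclusive); neighborhoods are truncated at mask edges.
    Centers whose neighborhood has fewer than 2 voxels are skipped with a
    warning. Returns a dict keyed by center coordinate.
    """
    if volume.coordinates is None:
        raise ValueError("searchlight requires voxel coordinates")
    coords = volume.coordinates.astype(np.float64)
    tree = cKDTree(coords)
    # tiny epsilon keeps lattice points at exactly `radius` inside the ball
    neighborhoods = tree.query_ball_point(coords, r=radius + 1e-9)
    out: dict[tuple[int, int, int], Rdm] = {}
    skipped = 0
    for center, idx in enumerate(neighborhoods):
        if len(idx) < 2:
            skipped += 1
            continue
        sub = ConditionPatternSet(
            responses=volume.responses[:, sorted(idx)],
            roi_id=volume.roi_id,
            condition_ids=volume.condition_ids,
        )
        key = tuple(int(c) for c in volume.coordinates[center])
        out[key] = correlation_rdm(sub)
    if skipped:
        warnings.warn(
            f"skipped {skipped} searchlight center(s) with a neighborhood "
            "of fewer than 2 voxels",
            stacklevel=2,
        )
    return out


def _spearman(a: np.ndarray, b: np.ndarray) -> float:
    if np.all(a == a[0]) or np.all(b == b[0]):
        return np.nan  # rank correlation undefined for a constant vector
    rho = spearmanr(a, b).statistic
    return float(rho)


def fusion_timecourse(
    meg_rdms: "TimeResolvedRDM",
    fmri_rdm: Rdm,
    subject: int = 0,
) -> FusionSeries:
    """Rank-correlate a time-resolved MEG RDM with one fMRI RDM.

    At each time point both RDMs are vectorized over the strictly-lower
    triangle (diagonal excluded) and compared by Spearman's rho with
    average ranks for ties. Time points where either vector is constant
    (rho undefined) are recorded as NaN; `FusionSeries.n_undefined`
    reports their count.
    """
    if meg_rdms.accuracy.shape[0] != fmri_rdm.n_conditions or not np.array_equal(
        np.asarray(meg_rdms.condition_ids), np.asarray(fmri_rdm.condition_ids)
    ):
        raise ValueError("MEG and fMRI RDMs must share condition ids and order")
    fmri_vec = lower_triangle(fmri_rdm.dissimilarity)
    n_t = meg_rdms.accuracy.shape[2]
    rho = np.empty(n_t)
    for t in range(n_t):
        meg_vec = lower_triangle(meg_rdms.accuracy[:, :, t])
        rho[t] = _spearman(meg_vec, fmri_vec)
    return FusionSeries(
        rho=rho,
        time_axis=meg_rdms.time_axis,
        roi_id=fmri_rdm.roi_id,
        subject=subject,
    )


def _classical_scaling(diss: np.ndarray, n_dims: int) -> np.ndarray:
    d2 = diss**2
    n = diss.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1][:n_dims]
    lam = np.clip(evals[order], 0.0, None)
    return evecs[:, order] * np.sqrt(lam)


def mds_embed(rdm, n_dims: int = 2) -> np.ndarray:
    """Metric MDS embedding of an RDM (or any dissimilarity slice).

    Uses stress majorization (SMACOF) started from the deterministic
    classical-scaling solution, so identical input yields identical
    coordinates. Output is centered at the origin with each axis's sign
    fixed so its largest-magnitude coordinate is positive.
    """
    diss = rdm.dissimilarity if isinstance(rdm, Rdm) else np.asarray(rdm, float)
    if diss.ndim != 2 or diss.shape[0] != diss.shape[1]:
        raise ValueError("dissimilarity must be square")
    if not np.allclose(diss, diss.T):
        raise ValueError("dissimilarity must be symmetric")
    if (diss < 0).any():
        raise ValueError("dissimilarity must be non-negative")
    diss = np.ascontiguousarray((diss + diss.T) / 2.0)
    np.fill_diagonal(diss, 0.0)
    init = _classical_scaling(diss, n_dims)
    if np.allclose(diss, 0.0):
        coords = init  # all conditions coincide; stress is already zero
    else:
        coords, _ = smacof(
            diss,
            metric=True,
            n_components=n_dims,
            init=init,
            n_init=1,
            random_state=0,
            normalized_stress=False,
        )
    coords = coords - coords.mean(axis=0, keepdims=True)
    for dim in range(coords.shape[1]):
        col = coords[:, dim]
        if col.any() and col[np.argmax(np.abs(col))] < 0:
            coords[:, dim] = -col
    return coords


def save_mds_coordinates(path, coords: np.ndarray, condition_ids=None) -> None:
    """Write MDS coordinates as CSV: condition_id, dim1, dim2, ..."""
    import pandas as pd

    coords = np.asarray(coords)
    if condition_ids is None:
        condition_ids = np.arange(coords.shape[0])
    frame = pd.DataFrame(
        coords, columns=[f"dim{i + 1}" for i in range(coords.shape[1])]
    )
    frame.insert(0, "condition_id", np.asarray(condition_ids))
    frame.to_csv(path, index=False)


def save_searchlight_rdms(path, rdms: dict[tuple[int, int, int], Rdm]) -> None:
    """Persist searchlight output as one HDF5 group per center voxel.

    Groups are keyed "x_y_z"; each holds the RDM plus the center
    coordinate, a sparse layout matching the skipped-center semantics.
    """
    import h5py

    with h5py.File(path, "w", track_order=True) as f:
        for (x, y, z), rdm in sorted(rdms.items()):
            grp = f.create_group(f"{x}_{y}_{z}")
            grp.create_dataset(
                "dissimilarity", data=rdm.dissimilarity, track_times=False
            )
            grp.create_dataset(
                "condition_ids", data=rdm.condition_ids, track_times=False
            )
            grp.attrs["center"] = (x, y, z)
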