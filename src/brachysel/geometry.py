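"""Geometric features of the target and organs at risk relative to the applicator.

Twelve per-fraction features drive applicator selection: six HR-CTV geometry
metrics (axis offset, mean/maximum lateral extent orthogonal to the tandem
axis, mean/maximum vertical extent orthogonal to the ring/ovoid plane, and
volume), three organ-at-risk (OAR) volumes, and three OAR-to-target
proximities. All lengths are mm, volumes cm^3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator, TransformerMixin

from .structure_io import ApplicatorFrame, StructureSet, VoxelMask, rasterize

__all__ = [
    "FEATURE_NAMES",
    "HRCTV_FEATURES",
    "OAR_NAMES",
    "DISPLAY_NAMES",
    "FeatureVector",
    "structure_volume",
    "axis_offset",
    "lateral_extent",
    "vertical_extent",
    "oar_proximity",
    "extract_features",
    "GeometricFeatureExtractor",
    "write_feature_table",
]

#: Canonical column order of the feature table.
FEATURE_NAMES = (
    "axis_offset",
    "lateral_mean_extent",
    "lateral_max_extent",
    "vertical_mean_extent",
    "vertical_max_extent",
    "hrctv_volume",
    "rectum_volume",
    "bladder_volume",
    "sigmoid_volume",
    "rectum_proximity",
    "bladder_proximity",
    "sigmoid_proximity",
)

#: The HR-CTV geometry-metric group (the set retained by feature reduction).
HRCTV_FEATURES = FEATURE_NAMES[:6]

OAR_NAMES = ("rectum", "bladder", "sigmoid")

#: Human-readable names used in score reports.
DISPLAY_NAMES = {
    "axis_offset": "Axis Offset",
    "lateral_mean_extent": "Lateral Mean Extent",
    "lateral_max_extent": "Lateral Maximum Extent",
    "vertical_mean_extent": "Vertical Mean Extent",
    "vertical_max_extent": "Vertical Maximum Extent",
    "hrctv_volume": "Volume",
    "rectum_volume": "Rectum Volume",
    "bladder_volume": "Bladder Volume",
    "sigmoid_volume": "Sigmoid Volume",
    "rectum_proximity": "Rectum Proximity",
    "bladder_proximity": "Bladder Proximity",
    "sigmoid_proximity": "Sigmoid Proximity",
}


@dataclass
class FeatureVector:
    """The 12 geometric features for one treatment fraction.

    Absent OARs are flagged with ``None`` (never zero) in both the volume and
    proximity slots.
    """

    axis_offset: float
    lateral_mean_extent: float
    lateral_max_extent: float
    vertical_mean_extent: float
    vertical_max_extent: float
    hrctv_volume: float
    rectum_volume: float | None
    bladder_volume: float | None
    sigmoid_volume: float | None
    rectum_proximity: float | None
    bladder_proximity: float | None
    sigmoid_proximity: float | None

    def __post_init__(self) -> None:
        for name in FEATURE_NAMES:
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"feature {name} must be >= 0, got {v}")
        if self.lateral_max_extent < self.lateral_mean_extent - 1e-9:
            raise ValueError("lateral max extent < lateral mean extent")
        if self.vertical_max_extent < self.vertical_mean_extent - 1e-9:
            raise ValueError("vertical max extent < vertical mean extent")

    @property
    def absent(self) -> tuple[str, ...]:
        return tuple(n for n in FEATURE_NAMES if getattr(self, n) is None)

    def as_series(self) -> pd.Series:
        return pd.Series(
            {n: (np.nan if getattr(self, n) is None else float(getattr(self, n)))
             for n in FEATURE_NAMES}
        )


def structure_volume(mask: VoxelMask) -> float:
    """Structure volume in cm^3: occupied-voxel count times voxel volume."""
    return float(mask.occupancy.sum()) * mask.voxel_volume / 1000.0


def _require_nonempty(mask: VoxelMask, what: str = "mask") -> np.ndarray:
    centers = mask.occupied_centers()
    if centers.shape[0] == 0:
        raise ValueError(f"empty {what}: no occupied voxels")
    return centers


def axis_offset(mask: VoxelMask, frame: ApplicatorFrame) -> float:
    """Perpendicular distance (mm) from the mask centroid to the tandem axis.

    Measures asymmetry of the target about the applicator: the unweighted
    centroid of occupied voxel centers, minus its projection onto the axis.
    """
    centers = _require_nonempty(mask)
    c = centers.mean(axis=0) - frame.tandem_point
    perp = c - np.dot(c, frame.tandem_dir) * frame.tandem_dir
    return float(np.linalg.norm(perp))


def _perp_distances(centers: np.ndarray, frame: ApplicatorFrame) -> np.ndarray:
    rel = centers - frame.tandem_point
    axial = rel @ frame.tandem_dir
    perp = rel - np.outer(axial, frame.tandem_dir)
    return np.linalg.norm(perp, axis=1), axial


def lateral_extent(
    mask: VoxelMask, frame: ApplicatorFrame, mean_mode: str = "slab_max"
) -> tuple[float, float]:
    """Mean and maximum lateral extent (mm) orthogonal to the tandem axis.

    Voxels are binned into axial slabs (width = voxel spacing along the
    axis); each slab contributes its farthest perpendicular reach from the
    axis. The maximum is taken over slabs and, with the default
    ``mean_mode="slab_max"``, the mean over occupied slabs — the reach of the
    target edge from the tandem at each level. ``mean_mode="voxel"`` instead
    averages the perpendicular distance over all occupied voxels (a
    documented alternative reading of "mean extent").
    """
    centers = _require_nonempty(mask)
    dist, axial = _perp_distances(centers, frame)
    if mean_mode == "voxel":
        return float(dist.mean()), float(dist.max())
    if mean_mode != "slab_max":
        raise ValueError(f"unknown mean_mode {mean_mode!r}")
    width = float(np.abs(frame.tandem_dir) @ mask.spacing)
    slab = np.floor(axial / width).astype(int)
    per_slab = pd.Series(dist).groupby(slab).max().to_numpy()
    return float(per_slab.mean()), float(per_slab.max())


def vertical_extent(
    mask: VoxelMask, frame: ApplicatorFrame, mean_mode: str = "cell_max"
) -> tuple[float, float]:
    """Mean and maximum vertical extent (mm) orthogonal to the ring/ovoid plane.

    Signed plane distances are clamped below at 0 (tissue inferior to the
    ring does not contribute negative extent). Voxels are projected onto the
    plane and binned into a 2D grid of in-plane spacing; each occupied cell
    contributes its greatest height above the plane. ``mean_mode="voxel"``
    averages the clamped height over all occupied voxels instead.
    """
    centers = _require_nonempty(mask)
    n = frame.ring_normal
    h = np.clip((centers - frame.ring_point) @ n, 0.0, None)
    if mean_mode == "voxel":
        return float(h.mean()), float(h.max())
    if mean_mode != "cell_max":
        raise ValueError(f"unknown mean_mode {mean_mode!r}")
    # in-plane orthonormal basis
    a = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(n, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    rel = centers - frame.ring_point
    iu = np.floor((rel @ e1) / mask.spacing[0]).astype(int)
    iv = np.floor((rel @ e2) / mask.spacing[1]).astype(int)
    cells = pd.MultiIndex.from_arrays([iu, iv])
    per_cell = pd.Series(h, index=cells).groupby(level=[0, 1]).max().to_numpy()
    return float(per_cell.mean()), float(per_cell.max())


def oar_proximity(
    hrctv: VoxelMask,
    oar: VoxelMask,
    subvolume: float = 1.5,
    direction: str = "oar_side",
) -> float:
    """Mean distance (mm) between the target and the nearest ``subvolume`` cm^3
    of an organ at risk.

    With the default ``direction="oar_side"``, each occupied OAR voxel gets
    the Euclidean distance from its center to the nearest occupied HR-CTV
    voxel center (0 for voxels shared with the target on a common lattice);
    the ``subvolume`` cm^3 of OAR voxels closest to the target are averaged.
    ``direction="hrctv_side"`` averages instead over the HR-CTV voxels
    nearest the OAR (the mirrored reading).
    """
    h_centers = _require_nonempty(hrctv, "HR-CTV mask")
    o_centers = _require_nonempty(oar, "OAR mask")
    if direction == "hrctv_side":
        query, ref, vol = h_centers, o_centers, hrctv.voxel_volume
    elif direction == "oar_side":
        query, ref, vol = o_centers, h_centers, oar.voxel_volume
    else:
        raise ValueError(f"unknown direction {direction!r}")
    m = min(len(query), math.ceil(subvolume * 1000.0 / vol))
    # exact prefilter: a query voxel whose lower-bound distance (to the
    # reference bounding box) exceeds the m-th smallest upper bound (to one
    # reference point) cannot be among the m nearest
    if len(query) > 4 * m:
        lo, hi = ref.min(axis=0), ref.max(axis=0)
        lb = np.linalg.norm(
            np.maximum(np.maximum(lo - query, query - hi), 0.0), axis=1
        )
        p0 = ref[np.argmin(np.linalg.norm(ref - ref.mean(axis=0), axis=1))]
        ub = np.linalg.norm(query - p0, axis=1)
        query = query[lb <= np.partition(ub, m - 1)[m - 1]]
    d, _ = cKDTree(ref).query(query)
    return float(np.sort(d)[:m].mean())


def extract_features(
    struct: StructureSet,
    frame: ApplicatorFrame,
    spacing: Sequence[float] = (1.0, 1.0, 1.0),
    subvolume: float = 1.5,
    lateral_mean_mode: str = "slab_max",
    vertical_mean_mode: str = "cell_max",
    proximity_direction: str = "oar_side",
) -> FeatureVector:
    """Rasterize all available structures and compute the 12 features.

    HR-CTV must be present; absent OARs yield ``None`` entries. All masks
    share a spacing-aligned lattice so center-to-center distances are exact
    where structures overlap.
    """
    hrctv = rasterize(struct, "HR-CTV", spacing=spacing)
    lat_mean, lat_max = lateral_extent(hrctv, frame, mean_mode=lateral_mean_mode)
    vert_mean, vert_max = vertical_extent(hrctv, frame, mean_mode=vertical_mean_mode)
    values: dict[str, float | None] = {
        "axis_offset": axis_offset(hrctv, frame),
        "lateral_mean_extent": lat_mean,
        "lateral_max_extent": lat_max,
        "vertical_mean_extent": vert_mean,
        "vertical_max_extent": vert_max,
        "hrctv_volume": structure_volume(hrctv),
    }
    for oar in OAR_NAMES:
        if oar in struct and struct[oar]:
            mask = rasterize(struct, oar, spacing=spacing)
            values[f"{oar}_volume"] = structure_volume(mask)
            values[f"{oar}_proximity"] = oar_proximity(
                hrctv, mask, subvolume=subvolume, direction=proximity_direction
            )
        else:
            values[f"{oar}_volume"] = None
            values[f"{oar}_proximity"] = None
    return FeatureVector(**values)


class GeometricFeatureExtractor(TransformerMixin, BaseEstimator):
    """Stateless transformer mapping (structure set, applicator frame) pairs
    to the 12-column feature table.

    Parameters
    ----------
    spacing : 3-tuple of float, mm/voxel
        Rasterization grid spacing (default 1 mm isotropic).
    subvolume : float, cm^3
        OAR subvolume used by the proximity metric (default 1.5 cc).
    lateral_mean_mode, vertical_mean_mode, proximity_direction : str
        Alternate metric definitions; see the metric functions.
    """

    def __init__(
        self,
        spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
        subvolume: float = 1.5,
        lateral_mean_mode: str = "slab_max",
        vertical_mean_mode: str = "cell_max",
        proximity_direction: str = "oar_side",
    ):
        self.spacing = spacing
        self.subvolume = subvolume
        self.lateral_mean_mode = lateral_mean_mode
        self.vertical_mean_mode = vertical_mean_mode
        self.proximity_direction = proximity_direction

    def fit(self, X: Iterable, y=None) -> "GeometricFeatureExtractor":
        return self

    def transform(self, X: Iterable) -> pd.DataFrame:
        """X: iterable of ``(StructureSet, ApplicatorFrame)`` pairs, or of
        objects exposing ``structure_set`` and ``frame`` attributes."""
        rows = []
        index = []
        for i, item in enumerate(X):
            if isinstance(item, tuple):
                struct, frame = item
                ident = i
            else:
                struct, frame = item.structure_set, item.frame
                ident = getattr(item, "fraction_id", i)
            fv = extract_features(
                struct,
                frame,
                spacing=self.spacing,
                subvolume=self.subvolume,
                lateral_mean_mode=self.lateral_mean_mode,
                vertical_mean_mode=self.vertical_mean_mode,
                proximity_direction=self.proximity_direction,
            )
            rows.append(fv.as_series())
            index.append(ident)
        return pd.DataFrame(rows, index=pd.Index(index, name="fraction_id"))

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(FEATURE_NAMES, dtype=object)


def write_feature_table(
    features: pd.DataFrame,
    path: str | Path,
    labels: Sequence[str] | None = None,
) -> None:
    """Write a per-fraction feature table as CSV with the canonical 12
    feature columns (display names), the fraction id, and optionally the
    applicator-class label."""
    out = features.loc[:, list(FEATURE_NAMES)].rename(columns=DISPLAY_NAMES)
    if labels is not None:
        out["Applicator Class"] = list(labels)
    out.to_csv(path, index_label="fraction_id")
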