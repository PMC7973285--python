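"""Structure-set I/O, applicator-frame fitting, and contour rasterization.

Anatomy is represented as stacks of planar polygon contours in the DICOM
patient coordinate system (LPS, millimetres), the convention emitted by
brachytherapy treatment-planning systems. The reference on-disk format is a
plain-JSON serialization of the same convention; DICOM RT-STRUCT and RT-PLAN
are supported as optional inputs behind the same contracts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import shapely

__all__ = [
    "ApplicatorClass",
    "PlanarContour",
    "StructureSet",
    "ApplicatorFrame",
    "VoxelMask",
    "MalformedContourError",
    "MissingStructureError",
    "read_structure_set",
    "write_structure_set",
    "read_dicom_rtstruct",
    "derive_applicator_frame",
    "rasterize",
]

#: Structure names the pipeline recognizes. HR-CTV is mandatory; IR-CTV and
#: GTV appear only in dosimetric records, not geometry.
KNOWN_STRUCTURES = ("HR-CTV", "IR-CTV", "GTV", "bladder", "rectum", "sigmoid")


class ApplicatorClass(str, Enum):
    """Applicator type: intracavitary or hybrid intracavitary-interstitial."""

    IC = "IC"
    IS = "IS"


class MalformedContourError(ValueError):
    """A contour violates the polygon contract (e.g. fewer than 3 vertices)."""


class MissingStructureError(KeyError):
    """A required structure (HR-CTV) is absent from the structure set."""


@dataclass(frozen=True)
class PlanarContour:
    """A closed planar polygon on an axial plane.

    Parameters
    ----------
    z : float
        Axial coordinate of the contour plane, mm.
    vertices : (n, 2) ndarray
        Ordered in-plane (x, y) vertices, mm. The polygon closes implicitly
        from the last vertex back to the first.
    """

    z: float
    vertices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise MalformedContourError(
                f"contour vertices must be (n, 2), got shape {v.shape}"
            )
        if v.shape[0] < 3:
            raise MalformedContourError(
                f"malformed contour: {v.shape[0]} vertices (need >= 3)"
            )
        if not (np.isfinite(v).all() and np.isfinite(self.z)):
            raise MalformedContourError("contour coordinates must be finite")
        object.__setattr__(self, "vertices", v)

    def polygon(self) -> shapely.Polygon:
        return shapely.Polygon(self.vertices)


@dataclass
class StructureSet:
    """Named anatomical structures as stacks of planar contours (LPS, mm)."""

    structures: dict[str, list[PlanarContour]]
    frame_of_reference: str = ""

    def __post_init__(self) -> None:
        for name, contours in self.structures.items():
            for i, c in enumerate(contours):
                if not isinstance(c, PlanarContour):
                    raise TypeError(
                        f"structure {name!r} contour {i} is not a PlanarContour"
                    )

    def __getitem__(self, name: str) -> list[PlanarContour]:
        return self.structures[name]

    def __contains__(self, name: str) -> bool:
        return name in self.structures

    @property
    def names(self) -> list[str]:
        return list(self.structures)


@dataclass(frozen=True)
class ApplicatorFrame:
    """Applicator coordinate frame: tandem axis and ring/ovoid plane.

    The tandem axis (point + superior-pointing unit direction) is the
    reference for lateral extent and axis offset; the ring/ovoid plane
    (point + unit normal, oriented along the tandem) is the reference for
    vertical extent.
    """

    tandem_point: np.ndarray
    tandem_dir: np.ndarray
    ring_point: np.ndarray
    ring_normal: np.ndarray
    applicator_class: ApplicatorClass | None = None

    def __post_init__(self) -> None:
        for attr in ("tandem_point", "tandem_dir", "ring_point", "ring_normal"):
            object.__setattr__(self, attr, np.asarray(getattr(self, attr), dtype=float))
        for attr in ("tandem_dir", "ring_normal"):
            n = np.linalg.norm(getattr(self, attr))
            if abs(n - 1.0) > 1e-9:
                raise ValueError(f"{attr} must be a unit vector (|v| = {n:.3g})")


@dataclass
class VoxelMask:
    """Boolean occupancy grid. Voxel (i, j, k) has its center at
    ``origin + (i + 0.5, j + 0.5, k + 0.5) * spacing`` (x, y, z order)."""

    origin: np.ndarray
    spacing: np.ndarray
    occupancy: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        if (self.spacing <= 0).any():
            raise ValueError("voxel spacing components must be > 0")
        if self.occupancy.ndim != 3:
            raise ValueError("occupancy must be a 3D boolean array")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.occupancy.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel, mm^3."""
        return float(np.prod(self.spacing))

    def occupied_centers(self) -> np.ndarray:
        """World coordinates (mm) of the centers of all occupied voxels, (m, 3)."""
        idx = np.argwhere(self.occupancy)
        return self.origin + (idx + 0.5) * self.spacing


# ---------------------------------------------------------------------------
# internal_json format


def write_structure_set(struct: StructureSet, path: str | Path) -> None:
    """Write a structure set to the internal JSON format (vertex-exact)."""
    payload = {
        "frame_of_reference": struct.frame_of_reference,
        "structures": {
            name: [
                {"z": c.z, "vertices": c.vertices.tolist()} for c in contours
            ]
            for name, contours in struct.structures.items()
        },
    }
    Path(path).write_text(json.dumps(payload))


def _structure_set_from_dict(payload: dict, require_hrctv: bool) -> StructureSet:
    structures: dict[str, list[PlanarContour]] = {}
    for name, contours in payload.get("structures", {}).items():
        parsed = []
        for i, c in enumerate(contours):
            try:
                parsed.append(PlanarContour(z=float(c["z"]), vertices=c["vertices"]))
            except MalformedContourError as exc:
                raise MalformedContourError(
                    f"structure {name!r}, contour {i}: {exc}"
                ) from exc
        structures[name] = parsed
    if require_hrctv and "HR-CTV" not in structures:
        raise MissingStructureError(
            "structure set has no HR-CTV; the pipeline cannot proceed"
        )
    return StructureSet(
        structures=structures,
        frame_of_reference=str(payload.get("frame_of_reference", "")),
    )


def read_structure_set(
    path: str | Path,
    format: str = "internal_json",
    require_hrctv: bool = True,
) -> StructureSet:
    """Read a structure set from disk.

    Parameters
    ----------
    path : path
        Input file.
    format : {"internal_json", "dicom_rtstruct"}
        On-disk format. ``internal_json`` is the reference format;
        ``dicom_rtstruct`` reads a DICOM RT Structure Set.
    require_hrctv : bool
        If True (default), a missing HR-CTV structure is a hard error.
    """
    if format == "internal_json":
        payload = json.loads(Path(path).read_text())
        return _structure_set_from_dict(payload, require_hrctv)
    if format == "dicom_rtstruct":
        return read_dicom_rtstruct(path, require_hrctv=require_hrctv)
    raise ValueError(f"unknown structure-set format {format!r}")


def read_dicom_rtstruct(path: str | Path, require_hrctv: bool = True) -> StructureSet:
    """Read a DICOM RT Structure Set into a :class:`StructureSet`.

    ContourData triplets are grouped by ROI; unrecognized ROI names are
    retained under their literal names. Coordinates are kept bit-exact in the
    file's patient coordinate system (LPS, mm).
    """
    import pydicom

    ds = pydicom.dcmread(str(path), force=True)
    roi_names = {
        int(roi.ROINumber): str(roi.ROIName)
        for roi in getattr(ds, "StructureSetROISequence", [])
    }
    structures: dict[str, list[PlanarContour]] = {}
    for roi_contour in getattr(ds, "ROIContourSequence", []):
        name = roi_names.get(int(roi_contour.ReferencedROINumber), "unknown")
        contours = structures.setdefault(name, [])
        for i, item in enumerate(getattr(roi_contour, "ContourSequence", [])):
            pts = np.asarray(item.ContourData, dtype=float).reshape(-1, 3)
            z = float(pts[0, 2])
            try:
                contours.append(PlanarContour(z=z, vertices=pts[:, :2]))
            except MalformedContourError as exc:
                raise MalformedContourError(
                    f"structure {name!r}, contour {i}: {exc}"
                ) from exc
    frame = str(getattr(ds, "FrameOfReferenceUID", ""))
    payload = StructureSet(structures=structures, frame_of_reference=frame)
    if require_hrctv and "HR-CTV" not in payload:
        raise MissingStructureError(
            "structure set has no HR-CTV; the pipeline cannot proceed"
        )
    return payload


# ---------------------------------------------------------------------------
# Applicator frame from dwell positions


def derive_applicator_frame(
    dwell_positions_tandem: Sequence[Sequence[float]],
    dwell_positions_ring: Sequence[Sequence[float]],
    applicator_class: ApplicatorClass | str | None = None,
) -> ApplicatorFrame:
    """Fit the applicator frame from source dwell positions.

    The tandem axis is the total-least-squares line through the tandem dwell
    positions (first principal component), with its sign chosen to point from
    the ring toward the tandem tip (superior). The ring/ovoid plane is the
    least-squares plane through the ring dwell positions, its normal oriented
    to have a positive dot product with the tandem direction.
    """
    tandem = np.asarray(dwell_positions_tandem, dtype=float)
    ring = np.asarray(dwell_positions_ring, dtype=float)
    if tandem.ndim != 2 or tandem.shape[0] < 2 or tandem.shape[1] != 3:
        raise ValueError("need >= 2 tandem dwell positions (3-vectors)")
    if ring.ndim != 2 or ring.shape[0] < 3 or ring.shape[1] != 3:
        raise ValueError("need >= 3 ring dwell positions (3-vectors)")

    t_center = tandem.mean(axis=0)
    _, _, vt = np.linalg.svd(tandem - t_center)
    tandem_dir = vt[0]

    r_center = ring.mean(axis=0)
    _, s, vt = np.linalg.svd(ring - r_center)
    # collinear ring dwells: the second singular value vanishes and the plane
    # through them is not unique
    if s[1] <= 1e-9 * max(s[0], 1.0):
        raise ValueError("degenerate ring plane: ring dwell positions are collinear")
    ring_normal = vt[2]

    if np.dot(tandem_dir, t_center - r_center) < 0:
        tandem_dir = -tandem_dir
    if np.dot(ring_normal, tandem_dir) < 0:
        ring_normal = -ring_normal

    if applicator_class is not None:
        applicator_class = ApplicatorClass(applicator_class)
    return ApplicatorFrame(
        tandem_point=t_center,
        tandem_dir=tandem_dir / np.linalg.norm(tandem_dir),
        ring_point=r_center,
        ring_normal=ring_normal / np.linalg.norm(ring_normal),
        applicator_class=applicator_class,
    )


# ---------------------------------------------------------------------------
# Rasterization


def _slice_gap(z_planes: np.ndarray, default: float) -> float:
    if len(z_planes) < 2:
        return default
    return float(np.median(np.diff(np.sort(np.unique(z_planes)))))


def rasterize(
    struct: StructureSet,
    name: str,
    spacing: Sequence[float] = (1.0, 1.0, 1.0),
    origin: Sequence[float] | None = None,
    pad: float = 1.0,
) -> VoxelMask:
    """Scan-convert one structure's contour stack to a voxel mask.

    A voxel is occupied iff its center lies inside the polygon(s) of the
    nearest contour plane (even-odd rule across polygons sharing a plane) and
    within half the inter-slice gap of that plane's z.

    Parameters
    ----------
    struct : StructureSet
    name : str
        Structure to rasterize; must exist and have >= 1 contour.
    spacing : 3-vector, mm/voxel
        Default 1 mm isotropic.
    origin : 3-vector, optional
        Grid corner. By default the contour bounding box (padded) snapped to
        integer multiples of ``spacing``, so masks rasterized at the same
        spacing share a commensurate, aligned lattice.
    pad : float
        Bounding-box padding, mm.
    """
    if name not in struct or not struct[name]:
        raise MissingStructureError(f"structure {name!r} absent or empty")
    spacing = np.asarray(spacing, dtype=float)
    if (spacing <= 0).any():
        raise ValueError("spacing components must be > 0")
    contours = struct[name]

    z_planes = np.array(sorted({c.z for c in contours}))
    gap = _slice_gap(z_planes, default=float(spacing[2]))
    all_xy = np.vstack([c.vertices for c in contours])
    lo = np.array([all_xy[:, 0].min(), all_xy[:, 1].min(), z_planes.min() - gap / 2])
    hi = np.array([all_xy[:, 0].max(), all_xy[:, 1].max(), z_planes.max() + gap / 2])
    lo -= pad
    hi += pad
    if origin is None:
        origin = np.floor(lo / spacing) * spacing
    else:
        origin = np.asarray(origin, dtype=float)
    shape = np.ceil((hi - origin) / spacing).astype(int)
    shape = np.maximum(shape, 1)

    xs = origin[0] + (np.arange(shape[0]) + 0.5) * spacing[0]
    ys = origin[1] + (np.arange(shape[1]) + 0.5) * spacing[1]
    zs = origin[2] + (np.arange(shape[2]) + 0.5) * spacing[2]
    gx, gy = np.meshgrid(xs, ys, indexing="ij")

    by_plane: dict[float, list[shapely.Polygon]] = {}
    for c in contours:
        by_plane.setdefault(c.z, []).append(c.polygon())
    plane_zs = np.array(sorted(by_plane))

    occ = np.zeros(tuple(shape), dtype=bool)
    plane_cache: dict[float, np.ndarray] = {}
    mid = (plane_zs[:-1] + plane_zs[1:]) / 2.0
    for k, zc in enumerate(zs):
        nearest = plane_zs[int(np.searchsorted(mid, zc, side="right"))]
        # half-open slab [plane - gap/2, plane + gap/2) so abutting slabs
        # tile without double-counting boundary voxels
        if not (-gap / 2 <= zc - nearest < gap / 2):
            continue
        if nearest not in plane_cache:
            inside = np.zeros(gx.shape, dtype=bool)
            for poly in by_plane[nearest]:
                # even-odd: overlapping polygons on one plane carve holes
                inside ^= shapely.contains_xy(poly, gx.ravel(), gy.ravel()).reshape(
                    gx.shape
                )
            plane_cache[nearest] = inside
        occ[:, :, k] = plane_cache[nearest]

    return VoxelMask(origin=origin, spacing=spacing, occupancy=occ)
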