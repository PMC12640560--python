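"""Anatomical data model, standard-format I/O and native<->normative space
machinery.

Structures are binary masks with a NIfTI affine (surface meshes are derived by
marching cubes at the 0.5 level); pathways are bundles of world-space (RAS mm)
polylines with a nominal fiber diameter.  "Normative" space is reached by
applying a smooth displacement field to all geometry; because a physical lead
cannot bend, the warped lead is re-straightened by a total-least-squares line
fit before fields are recomputed around it.

Conventions: 0-based voxel indexing, world RAS mm, the NIfTI affine is
authoritative; masks are warped by inverse-field pull-back with
nearest-neighbor sampling so they stay binary.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from .leads import LeadModel, LeadPlacement, StimSetting

__all__ = [
    "Structure",
    "Pathway",
    "DeformationField",
    "SubjectDataset",
    "FormatError",
    "read_structure",
    "write_structure",
    "read_streamlines",
    "write_streamlines",
    "read_deformation",
    "write_deformation",
    "apply_warp",
    "restraighten_lead",
    "save_subject",
    "load_subject",
]


class FormatError(ValueError):
    """Malformed or unsupported on-disk data."""


@dataclass
class Structure:
    name: str
    mask: np.ndarray  # boolean
    affine: np.ndarray  # 4x4 voxel -> world (RAS mm)
    _mesh: tuple[np.ndarray, np.ndarray] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise FormatError(f"structure mask must be 3-D, got {self.mask.ndim}-D")
        if not self.mask.any():
            raise ValueError(f"structure {self.name!r} is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def surface_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(vertices_world, faces) from marching cubes at the 0.5 level."""
        if self._mesh is None:
            from skimage import measure

            verts, faces, _, _ = measure.marching_cubes(self.mask.astype(np.float32), level=0.5)
            vw = verts @ self.affine[:3, :3].T + self.affine[:3, 3]
            self._mesh = (vw, faces)
        return self._mesh

    def world_points_in_mask(self, points: np.ndarray) -> np.ndarray:
        inv = np.linalg.inv(self.affine)
        vox = np.asarray(points, float) @ inv[:3, :3].T + inv[:3, 3]
        ijk = np.round(vox).astype(int)
        ok = np.all((ijk >= 0) & (ijk < np.asarray(self.mask.shape)), axis=1)
        out = np.zeros(len(points), bool)
        if ok.any():
            s = ijk[ok]
            out[ok] = self.mask[s[:, 0], s[:, 1], s[:, 2]]
        return out

    def resample_to_grid(self, grid) -> np.ndarray:
        """Nearest-neighbor resampling of the mask onto a solver grid."""
        centers = grid.voxel_centers().reshape(-1, 3)
        inv = np.linalg.inv(self.affine)
        vox = centers @ inv[:3, :3].T + inv[:3, 3]
        vals = map_coordinates(self.mask.astype(np.float32), vox.T, order=0, mode="constant", cval=0.0)
        return (vals > 0.5).reshape(grid.shape)


@dataclass
class Pathway:
    name: str
    streamlines: list[np.ndarray]  # world mm polylines, each (N_i, 3)
    fiber_diameter_um: float

    def __post_init__(self) -> None:
        if len(self.streamlines) == 0:
            raise FormatError(f"pathway {self.name!r} has no streamlines")
        for i, sl in enumerate(self.streamlines):
            sl = np.asarray(sl, float)
            if sl.ndim != 2 or sl.shape[1] != 3 or sl.shape[0] < 10:
                raise ValueError(f"streamline {i} must be (>=10, 3)")
            if not np.all(np.isfinite(sl)):
                raise ValueError(f"streamline {i} has non-finite coordinates")
            self.streamlines[i] = sl

    @property
    def n_fibers(self) -> int:
        return len(self.streamlines)


@dataclass
class DeformationField:
    """Dense displacement field d(x) on a regular lattice: phi(x) = x + d(x)."""

    displacement: np.ndarray  # (nx, ny, nz, 3) mm
    affine: np.ndarray  # voxel -> world
    _inverse: "DeformationField | None" = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.displacement.ndim != 4 or self.displacement.shape[-1] != 3:
            raise FormatError("displacement must have shape (nx, ny, nz, 3)")

    @property
    def mean_magnitude(self) -> float:
        return float(np.linalg.norm(self.displacement, axis=-1).mean())

    def _world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        inv = np.linalg.inv(self.affine)
        return np.asarray(points, float) @ inv[:3, :3].T + inv[:3, 3]

    def displacement_at(self, points: np.ndarray) -> np.ndarray:
        vox = self._world_to_voxel(points)
        return np.stack(
            [map_coordinates(self.displacement[..., k], vox.T, order=1, mode="nearest") for k in range(3)],
            axis=-1,
        )

    def displace(self, points: np.ndarray) -> np.ndarray:
        """Map points x -> x + d(x) (trilinear interpolation of d)."""
        points = np.asarray(points, float)
        return points + self.displacement_at(points)

    def scaled(self, factor: float) -> "DeformationField":
        return DeformationField(self.displacement * factor, self.affine.copy())

    def jacobian_determinants(self) -> np.ndarray:
        """det(d phi / dx) on the lattice; all-positive means locally invertible."""
        h = np.abs(np.diag(self.affine[:3, :3]))
        J = np.empty(self.displacement.shape[:3] + (3, 3))
        for k in range(3):
            gx, gy, gz = np.gradient(self.displacement[..., k], *h)
            J[..., k, 0], J[..., k, 1], J[..., k, 2] = gx, gy, gz
        J += np.eye(3)
        return np.linalg.det(J)

    def invert(self, n_iter: int = 20) -> "DeformationField":
        """Fixed-point inversion on the same lattice:
        d_inv(y) <- -d(y + d_inv(y))."""
        if self._inverse is None:
            shape = self.displacement.shape[:3]
            ii = np.indices(shape).reshape(3, -1).T.astype(float)
            y = ii @ self.affine[:3, :3].T + self.affine[:3, 3]
            dinv = np.zeros_like(y)
            for _ in range(n_iter):
                dinv = -self.displacement_at(y + dinv)
            self._inverse = DeformationField(dinv.reshape(shape + (3,)), self.affine.copy())
        return self._inverse


@dataclass
class SubjectDataset:
    """One subject's geometry, settings and evoked-potential amplitudes, all
    in a single consistent space."""

    subject_id: str
    space: str  # "native" | "normative"
    lead_name: str
    placement: LeadPlacement
    structures: dict[str, Structure]
    pathways: dict[str, Pathway]
    settings: list[StimSetting]
    ep_table: pd.DataFrame  # columns: setting_id, EP0_uV, EP1_uV
    deformation: DeformationField | None = None
    truth: pd.DataFrame | None = None  # designated ground-truth activation

    def __post_init__(self) -> None:
        if self.space not in ("native", "normative"):
            raise ValueError(f"unknown space {self.space!r}")
        ids = {s.setting_id for s in self.settings}
        covered = set(self.ep_table["setting_id"])
        if ids - covered:
            raise ValueError(f"ep_table missing settings: {sorted(ids - covered)[:5]} ...")


# ---------------------------------------------------------------------------
# I/O


def read_structure(path: str | Path, name: str | None = None) -> Structure:
    img = nib.load(str(path))
    if img.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D mask volume, got {img.ndim}-D")
    if img.affine is None:
        raise FormatError(f"{path}: missing affine")
    data = np.asanyarray(img.dataobj)
    return Structure(name or Path(path).stem.split(".")[0], data > 0.5, np.asarray(img.affine))


def write_structure(structure: Structure, path: str | Path) -> None:
    img = nib.Nifti1Image(structure.mask.astype(np.uint8), structure.affine)
    nib.save(img, str(path))


def read_streamlines(path: str | Path, name: str | None = None, fiber_diameter_um: float = 1.0) -> Pathway:
    """Read a pathway from TCK/TRK (nibabel, converted to world RAS mm) or a
    CSV polyline table with columns fiber_id, x, y, z."""
    path = Path(path)
    name = name or path.stem.split(".")[0]
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        missing = {"fiber_id", "x", "y", "z"} - set(df.columns)
        if missing:
            raise FormatError(f"{path}: missing columns {sorted(missing)}")
        sls = [g[["x", "y", "z"]].to_numpy(float) for _, g in df.groupby("fiber_id", sort=True)]
        return Pathway(name, sls, fiber_diameter_um)
    try:
        tf = nib.streamlines.load(str(path))
    except Exception as e:  # corrupt header or unknown dialect
        raise FormatError(f"{path}: cannot read streamlines ({e})") from e
    sls = [np.asarray(s, float) for s in tf.tractogram.streamlines]
    if len(sls) == 0:
        raise FormatError(f"{path}: file contains zero streamlines")
    return Pathway(name, sls, fiber_diameter_um)


def write_streamlines(pathway: Pathway, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        rows = []
        for i, sl in enumerate(pathway.streamlines):
            for p in sl:
                rows.append((i, p[0], p[1], p[2]))
        pd.DataFrame(rows, columns=["fiber_id", "x", "y", "z"]).to_csv(path, index=False)
        return
    t = nib.streamlines.Tractogram(pathway.streamlines, affine_to_rasmm=np.eye(4))
    if path.suffix.lower() == ".trk":
        # voxel-order header fields are needed for a valid TRK
        hdr = nib.streamlines.TrkFile.create_empty_header()
        hdr["voxel_to_rasmm"] = np.eye(4)
        hdr["voxel_sizes"] = np.ones(3)
        hdr["dimensions"] = np.array([1, 1, 1])
        hdr["voxel_order"] = b"RAS"
        nib.streamlines.save(t, str(path), header=hdr)
    else:
        nib.streamlines.save(t, str(path))


def read_deformation(path: str | Path) -> DeformationField:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data)  # tolerate (nx, ny, nz, 1, 3) vector volumes
    if data.ndim != 4 or data.shape[-1] != 3:
        raise FormatError(f"{path}: expected a 3-vector displacement volume")
    return DeformationField(np.asarray(data, float), np.asarray(img.affine))


def write_deformation(fieldv: DeformationField, path: str | Path) -> None:
    img = nib.Nifti1Image(fieldv.displacement.astype(np.float32), fieldv.affine)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Warping


def apply_warp(geometry, warp: DeformationField):
    """Warp geometry into the deformed (normative) frame.

    Points and streamlines map forward, ``x -> x + d(x)``; masks are pulled
    back through the numerically inverted field with nearest-neighbor
    sampling so they stay binary.
    """
    if isinstance(geometry, Pathway):
        return Pathway(
            geometry.name,
            [warp.displace(sl) for sl in geometry.streamlines],
            geometry.fiber_diameter_um,
        )
    if isinstance(geometry, Structure):
        inv = warp.invert()
        shape = geometry.mask.shape
        ii = np.indices(shape).reshape(3, -1).T.astype(float)
        world = ii @ geometry.affine[:3, :3].T + geometry.affine[:3, 3]
        src = world + inv.displacement_at(world)
        A = np.linalg.inv(geometry.affine)
        src_vox = src @ A[:3, :3].T + A[:3, 3]
        vals = map_coordinates(
            geometry.mask.astype(np.float32), src_vox.T, order=0, mode="constant", cval=0.0
        )
        warped = (vals > 0.5).reshape(shape)
        return Structure(geometry.name, warped, geometry.affine.copy())
    if isinstance(geometry, np.ndarray):
        return warp.displace(geometry)
    raise TypeError(f"cannot warp {type(geometry).__name__}")


def restraighten_lead(
    warped_points: np.ndarray,
    z_offsets: np.ndarray,
    roll_deg: float = 0.0,
) -> tuple[LeadPlacement, float]:
    """Fit a straight lead to warped tip/contact positions.

    ``warped_points`` are the warped tip (row 0) and contact centers;
    ``z_offsets`` their axial positions in the rigid lead model (tip = 0).
    The axis is the total-least-squares line direction; contact spacing is
    restored by anchoring the rigid offsets at the fitted centroid.  Returns
    the placement and the RMS perpendicular residual of the line fit.
    """
    q = np.asarray(warped_points, float)
    z = np.asarray(z_offsets, float)
    if q.shape[0] < 3:
        raise ValueError("need at least 3 points to re-straighten a lead")
    centroid = q.mean(axis=0)
    _, _, Vt = np.linalg.svd(q - centroid)
    axis = Vt[0]
    if np.dot(axis, q[-1] - q[0]) < 0:
        axis = -axis
    perp = (q - centroid) - np.outer((q - centroid) @ axis, axis)
    residual = float(np.sqrt(np.mean(np.sum(perp**2, axis=1))))
    tip = centroid - z.mean() * axis
    placement = LeadPlacement(tuple(tip), tuple(axis / np.linalg.norm(axis)), roll_deg)
    return placement, residual


def warp_placement(
    lead: LeadModel, placement: LeadPlacement, warp: DeformationField
) -> tuple[LeadPlacement, float]:
    """Warp a placed lead's tip and per-level contact centroids (points on
    the lead axis), then re-straighten."""
    from .leads import lead_to_world

    z = np.concatenate([[0.0], [lead.level_z(k) for k in range(lead.n_levels)]])
    pts_lead = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
    warped = warp.displace(lead_to_world(pts_lead, placement))
    return restraighten_lead(warped, z, placement.roll_deg)


# ---------------------------------------------------------------------------
# Subject manifest I/O


def _setting_to_dict(s: StimSetting) -> dict:
    return dataclasses.asdict(s)


def _setting_from_dict(d: dict) -> StimSetting:
    d = dict(d)
    d["cathodes"] = tuple(d["cathodes"])
    d["anodes"] = tuple(d["anodes"])
    return StimSetting(**d)


def save_subject(subject: SubjectDataset, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "subject_id": subject.subject_id,
        "space": subject.space,
        "lead_name": subject.lead_name,
        "placement": {
            "tip_position": list(subject.placement.tip_position),
            "axis": list(subject.placement.axis),
            "roll_deg": subject.placement.roll_deg,
        },
        "structures": {},
        "pathways": {},
        "settings": [_setting_to_dict(s) for s in subject.settings],
        "ep_table": "ep_table.csv",
    }
    for name, st in subject.structures.items():
        fn = f"structure_{name}.nii"
        write_structure(st, outdir / fn)
        manifest["structures"][name] = fn
    for name, pw in subject.pathways.items():
        fn = f"pathway_{name}.tck"
        write_streamlines(pw, outdir / fn)
        manifest["pathways"][name] = {"file": fn, "fiber_diameter_um": pw.fiber_diameter_um}
    subject.ep_table.to_csv(outdir / "ep_table.csv", index=False)
    if subject.truth is not None:
        subject.truth.to_csv(outdir / "truth_activation.csv", index=False)
        manifest["truth"] = "truth_activation.csv"
    if subject.deformation is not None:
        write_deformation(subject.deformation, outdir / "deformation.nii")
        manifest["deformation"] = "deformation.nii"
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return outdir / "manifest.json"


def load_subject(manifest_path: str | Path) -> SubjectDataset:
    manifest_path = Path(manifest_path)
    d = json.loads(manifest_path.read_text())
    base = manifest_path.parent
    structures = {n: read_structure(base / fn, n) for n, fn in d["structures"].items()}
    pathways = {
        n: read_streamlines(base / e["file"], n, e["fiber_diameter_um"])
        for n, e in d["pathways"].items()
    }
    deformation = None
    if d.get("deformation"):
        deformation = read_deformation(base / d["deformation"])
    truth = None
    if d.get("truth"):
        truth = pd.read_csv(base / d["truth"])
    return SubjectDataset(
        subject_id=d["subject_id"],
        space=d["space"],
        lead_name=d["lead_name"],
        placement=LeadPlacement(
            tuple(d["placement"]["tip_position"]),
            tuple(d["placement"]["axis"]),
            d["placement"]["roll_deg"],
        ),
        structures=structures,
        pathways=pathways,
        settings=[_setting_from_dict(s) for s in d["settings"]],
        ep_table=pd.read_csv(base / d["ep_table"]),
        deformation=deformation,
        truth=truth,
    )
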