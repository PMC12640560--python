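"""Quasi-static volume conductor for placed DBS leads.

Solves ``div(sigma grad phi) = -I`` on a regular grid with a 7-point
finite-difference stencil and harmonic averaging of face conductivities.
Electrode metal is modelled as a high-conductivity inclusion: this enforces
the floating-potential contract for passive contacts (equipotential surface,
zero net current) through the physics of the discretized problem itself, and
keeps the operator linear so superposition across contacts is exact.  The
insulating shaft carries a very low conductivity ("electrode removed").

Two conductivity conventions are supported:

* ``vta_tissue_classes`` — 0.33 S/m inside the supplied gray-matter mask and
  0.14 S/m elsewhere (white matter), electrode removed.
* ``df_homogeneous_scar`` — homogeneous 0.2 S/m bulk with a 0.5 mm
  encapsulation layer at 0.07 S/m hugging the lead surface.

The truncated outer boundary carries Dirichlet values from the monopole
approximation ``I_net/(4 pi sigma r)`` about the active contact, which keeps
mid-range accuracy high on modest boxes; for charge-balanced (bipolar)
superpositions the monopole terms cancel.

Units: mm, mA, S/m, V, V/mm.  The mm/m factors cancel in
``phi = I_mA / (4 pi sigma r_mm)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .leads import LeadModel, LeadPlacement, StimSetting, lead_to_world, world_to_lead

__all__ = [
    "Grid",
    "SolverOptions",
    "CircuitParams",
    "ConductivityMap",
    "FieldSolution",
    "SolverError",
    "point_source_potential",
    "lead_frame_grid",
    "world_grid_for_lead",
    "rasterize_lead",
    "df_conductivity",
    "vta_conductivity",
    "VolumeConductor",
    "solve_static_field",
    "efield_magnitude",
    "temporal_scale",
]


class SolverError(RuntimeError):
    """Linear solve failed to converge; carries the final residual."""


@dataclass(frozen=True)
class Grid:
    """Axis-aligned regular lattice; ``origin`` is the world position of the
    center of voxel (0, 0, 0)."""

    origin: tuple[float, float, float]
    spacing: float
    shape: tuple[int, int, int]

    @property
    def affine(self) -> np.ndarray:
        A = np.eye(4)
        A[:3, :3] *= self.spacing
        A[:3, 3] = self.origin
        return A

    def voxel_centers(self) -> np.ndarray:
        """(nx, ny, nz, 3) world coordinates of voxel centers."""
        axes = [self.origin[i] + self.spacing * np.arange(self.shape[i]) for i in range(3)]
        g = np.meshgrid(*axes, indexing="ij")
        return np.stack(g, axis=-1)

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, float) - np.asarray(self.origin)) / self.spacing

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        return np.asarray(ijk, float) * self.spacing + np.asarray(self.origin)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))


@dataclass(frozen=True)
class SolverOptions:
    spacing: float = 0.5  # mm
    padding: float = 8.0  # mm of tissue around the contact span
    rtol: float = 1e-8
    maxiter: int = 40000
    method: str = "cg"  # "cg" | "direct"
    sigma_metal: float = 1.0e3  # S/m, electrode contacts
    sigma_insulator: float = 1.0e-4  # S/m, lead shaft


@dataclass(frozen=True)
class CircuitParams:
    """1-D equivalent circuit for the separable temporal scaling: series
    access resistance, bulk tissue resistance and electrode double-layer
    capacitance.  Defaults give a scale factor ~0.99 at a 60 us pulse."""

    r_access_ohm: float = 500.0
    r_tissue_ohm: float = 1000.0
    c_dl_farad: float = 3.3e-6

    def __post_init__(self) -> None:
        if min(self.r_access_ohm, self.r_tissue_ohm, self.c_dl_farad) <= 0:
            raise ValueError("equivalent-circuit parameters must be positive")

    def scale(self, pulse_width_us: float) -> float:
        tau = (self.r_access_ohm + self.r_tissue_ohm) * self.c_dl_farad  # seconds
        return float(np.exp(-pulse_width_us * 1e-6 / tau))


@dataclass
class LeadVoxels:
    """Rasterization of a placed lead onto a grid."""

    contact_voxels: dict[int, np.ndarray]  # contact index -> flat voxel indices
    body: np.ndarray  # boolean, lead body (shaft + contacts)
    surface_distance: np.ndarray  # mm from lead surface (negative inside)

    @property
    def all_contact_voxels(self) -> np.ndarray:
        if not self.contact_voxels:
            return np.empty(0, dtype=np.intp)
        return np.unique(np.concatenate(list(self.contact_voxels.values())))


@dataclass
class ConductivityMap:
    grid: Grid
    sigma: np.ndarray  # S/m per voxel
    provenance: str  # "vta_tissue_classes" | "df_homogeneous_scar"
    sigma_far: float  # bulk value used for the open-boundary monopole term
    lead_voxels: LeadVoxels

    def __post_init__(self) -> None:
        if np.any(self.sigma <= 0):
            raise ValueError("conductivity must be positive everywhere")


@dataclass
class FieldSolution:
    grid: Grid
    potential: np.ndarray  # V
    conductivity: ConductivityMap
    contact_currents_mA: dict[int, float]
    temporal_scale: float = 1.0
    _efield: np.ndarray | None = field(default=None, repr=False)

    @property
    def efield_magnitude(self) -> np.ndarray:
        if self._efield is None:
            self._efield = efield_magnitude(self.potential, self.grid.spacing)
        return self._efield

    def sample_potential(self, points_world: np.ndarray) -> np.ndarray:
        """Trilinear interpolation of the potential at world points."""
        from scipy.ndimage import map_coordinates

        vox = self.grid.world_to_voxel(points_world)
        return map_coordinates(self.potential, vox.T, order=1, mode="nearest") * self.temporal_scale


def point_source_potential(current_mA: float, sigma: float, r_mm: np.ndarray | float) -> np.ndarray | float:
    """Potential of a point current source in an infinite homogeneous medium."""
    r = np.asarray(r_mm, float)
    if np.any(r <= 0):
        raise ValueError("r must be positive")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    out = current_mA / (4.0 * np.pi * sigma * r)
    return float(out) if np.isscalar(r_mm) else out


def lead_frame_grid(lead: LeadModel, options: SolverOptions) -> Grid:
    """Grid in the lead frame: x/y symmetric about the axis, z covering the
    tip and contact span plus padding."""
    h = options.spacing
    half = lead.shaft_radius + options.padding
    zlo, zhi = -options.padding, lead.top_z + options.padding
    nxy = int(np.ceil(2 * half / h)) + 1
    if nxy % 2 == 0:
        nxy += 1  # odd count puts a voxel center exactly on the lead axis
    nz = int(np.ceil((zhi - zlo) / h)) + 1
    origin = (-h * (nxy - 1) / 2.0, -h * (nxy - 1) / 2.0, zlo)
    return Grid(origin=origin, spacing=h, shape=(nxy, nxy, nz))


def world_grid_for_lead(lead: LeadModel, placement: LeadPlacement, options: SolverOptions) -> Grid:
    """Axis-aligned world grid covering all contact centers plus padding."""
    from .leads import contact_positions

    pts = contact_positions(lead, placement)
    lo = pts.min(axis=0) - options.padding
    hi = pts.max(axis=0) + options.padding
    h = options.spacing
    shape = tuple(int(np.ceil((hi[i] - lo[i]) / h)) + 1 for i in range(3))
    return Grid(origin=tuple(lo), spacing=h, shape=shape)


def rasterize_lead(lead: LeadModel, grid: Grid, placement: LeadPlacement | None = None) -> LeadVoxels:
    """Classify grid voxels as contact metal / shaft / tissue.

    The lead body is a capsule of radius ``shaft_radius`` whose rounded tip
    apex sits at the lead-frame origin.  A contact claims the body voxels in
    its axial band (and angular sector for segments); sectors that rasterize
    to zero voxels fall back to the voxel nearest their surface centroid so
    every contact is addressable on coarse grids.
    """
    centers = grid.voxel_centers().reshape(-1, 3)
    if placement is not None:
        pl = world_to_lead(centers, placement)
    else:
        pl = centers
    x, y, z = pl[:, 0], pl[:, 1], pl[:, 2]
    rad = np.hypot(x, y)
    R = lead.shaft_radius
    # capsule axis from the dome center to beyond the grid top
    zc = np.clip(z, R, z.max() + R)
    dist_axis = np.sqrt(rad**2 + (z - zc) ** 2)
    surface_distance = dist_axis - R
    body = surface_distance <= 0.0

    # shrink the axial band by half a voxel so metal voxels of neighboring
    # contacts can never be face-adjacent (which would short them)
    h2 = lead.contact_height / 2.0 - grid.spacing / 2.0
    theta = np.rad2deg(np.arctan2(y, x)) % 360.0
    contact_voxels: dict[int, np.ndarray] = {}
    for c in lead.contacts:
        band = body & (np.abs(z - c.z) <= h2 + 1e-9)
        if c.full_ring:
            sel = band
        else:
            s, e = c.angular_span
            in_sector = (theta >= s) & (theta < e)
            # keep a thin insulating core so sectors at one level stay separate
            sel = band & in_sector & (rad >= 0.35 * R)
        idx = np.flatnonzero(sel)
        if idx.size == 0:
            center = np.asarray(c.center, float)
            d2 = np.sum((pl - center) ** 2, axis=1)
            idx = np.array([int(np.argmin(d2))], dtype=np.intp)
        contact_voxels[c.index] = idx
    _separate_contacts(contact_voxels, grid)
    return LeadVoxels(
        contact_voxels=contact_voxels,
        body=body.reshape(grid.shape),
        surface_distance=surface_distance.reshape(grid.shape),
    )


def _separate_contacts(contact_voxels: dict[int, np.ndarray], grid: Grid) -> None:
    """Remove voxels so that no two contacts own face-adjacent voxels (which
    would short them through the metal inclusion).  The contact with more
    voxels yields; a contact is never emptied below one voxel."""
    ny, nz = grid.shape[1], grid.shape[2]
    strides = (ny * nz, nz, 1)
    label = np.full(grid.n_voxels, -1, dtype=np.int64)
    for k, idx in contact_voxels.items():
        label[idx] = k
    for _ in range(16):
        conflict = False
        for k in sorted(contact_voxels):
            idx = contact_voxels[k]
            keep = np.ones(idx.size, bool)
            for pos, v in enumerate(idx):
                for s in strides:
                    for nb in (v - s, v + s):
                        if 0 <= nb < label.size and label[nb] >= 0 and label[nb] != k:
                            other = contact_voxels[label[nb]]
                            if idx.size > 1 and (idx.size >= other.size or other.size == 1):
                                keep[pos] = False
            if not keep.all():
                conflict = True
                label[idx[~keep]] = -1
                contact_voxels[k] = idx[keep]
        if not conflict:
            break


def _apply_lead(sigma: np.ndarray, lv: LeadVoxels, options: SolverOptions) -> None:
    flat = sigma.reshape(-1)
    flat[lv.body.reshape(-1)] = options.sigma_insulator
    for idx in lv.contact_voxels.values():
        flat[idx] = options.sigma_metal


def df_conductivity(
    lead: LeadModel,
    grid: Grid,
    placement: LeadPlacement | None = None,
    sigma_tissue: float = 0.2,
    sigma_scar: float = 0.07,
    scar_thickness: float = 0.5,
    options: SolverOptions = SolverOptions(),
) -> ConductivityMap:
    """Homogeneous bulk + encapsulation-scar conductivity for the driving-force
    branch."""
    if grid.spacing > scar_thickness:
        raise ValueError(
            f"grid spacing {grid.spacing} mm must not exceed the scar thickness {scar_thickness} mm"
        )
    lv = rasterize_lead(lead, grid, placement)
    sigma = np.full(grid.shape, sigma_tissue, float)
    scar = (lv.surface_distance > 0) & (lv.surface_distance <= scar_thickness)
    sigma[scar] = sigma_scar
    _apply_lead(sigma, lv, options)
    return ConductivityMap(grid, sigma, "df_homogeneous_scar", sigma_tissue, lv)


def vta_conductivity(
    lead: LeadModel,
    grid: Grid,
    gray_mask: np.ndarray | None = None,
    placement: LeadPlacement | None = None,
    sigma_gray: float = 0.33,
    sigma_white: float = 0.14,
    options: SolverOptions = SolverOptions(),
) -> ConductivityMap:
    """Gray/white tissue-class conductivity for the VTA branch, electrode
    removed (insulating shaft)."""
    lv = rasterize_lead(lead, grid, placement)
    sigma = np.full(grid.shape, sigma_white, float)
    if gray_mask is not None:
        if gray_mask.shape != grid.shape:
            raise ValueError("gray mask must be resampled to the solver grid")
        sigma[gray_mask.astype(bool)] = sigma_gray
    _apply_lead(sigma, lv, options)
    return ConductivityMap(grid, sigma, "vta_tissue_classes", sigma_white, lv)


def _face_conductance(sigma: np.ndarray, axis: int, h: float) -> np.ndarray:
    """Harmonic-mean face conductance (siemens) between voxel pairs along axis."""
    s0 = np.moveaxis(sigma, axis, 0)[:-1]
    s1 = np.moveaxis(sigma, axis, 0)[1:]
    g = 2.0 * s0 * s1 / (s0 + s1) * h * 1e-3
    return np.moveaxis(g, 0, axis)


class VolumeConductor:
    """Assembled finite-difference operator for one conductivity map.

    The outer one-voxel shell is Dirichlet; the matrix is shared across all
    right-hand sides (one per active contact), so per-contact unit solutions
    are cheap once assembled.
    """

    def __init__(self, cond: ConductivityMap, options: SolverOptions = SolverOptions()):
        self.cond = cond
        self.options = options
        self.grid = cond.grid
        self._assemble()
        self._unit_cache: dict[int, np.ndarray] = {}

    def _assemble(self) -> None:
        grid, sigma = self.grid, self.cond.sigma
        nx, ny, nz = grid.shape
        if min(nx, ny, nz) < 5:
            raise ValueError("grid too small for an interior")
        n = grid.n_voxels
        interior = np.ones(grid.shape, bool)
        interior[0, :, :] = interior[-1, :, :] = False
        interior[:, 0, :] = interior[:, -1, :] = False
        interior[:, :, 0] = interior[:, :, -1] = False
        self.interior = interior
        self.idx_of = -np.ones(n, dtype=np.int64)
        flat_int = np.flatnonzero(interior.reshape(-1))
        self.idx_of[flat_int] = np.arange(flat_int.size)
        self.flat_interior = flat_int
        m = flat_int.size

        diag = np.zeros(m)
        rows, cols, vals = [], [], []
        # boundary coupling: per interior voxel, conductance-weighted sum of
        # Dirichlet neighbor values enters the RHS
        self._bnd_terms: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
        strides = np.array([ny * nz, nz, 1])
        for axis in range(3):
            g = _face_conductance(sigma, axis, grid.spacing)
            # flat indices of the lower voxel of each face along this axis
            shp = list(grid.shape)
            shp[axis] -= 1
            ii = np.indices(shp).reshape(3, -1)
            flat_lo = (ii * strides[:, None]).sum(axis=0)
            flat_hi = flat_lo + strides[axis]
            gval = g.reshape(-1)
            lo_int = self.idx_of[flat_lo]
            hi_int = self.idx_of[flat_hi]
            both = (lo_int >= 0) & (hi_int >= 0)
            np.add.at(diag, lo_int[lo_int >= 0], gval[lo_int >= 0])
            np.add.at(diag, hi_int[hi_int >= 0], gval[hi_int >= 0])
            rows.append(lo_int[both])
            cols.append(hi_int[both])
            vals.append(-gval[both])
            rows.append(hi_int[both])
            cols.append(lo_int[both])
            vals.append(-gval[both])
            # interior-boundary faces
            ib = (lo_int >= 0) & (hi_int < 0)
            self._bnd_terms.append((lo_int[ib], flat_hi[ib], gval[ib]))
            bi = (lo_int < 0) & (hi_int >= 0)
            self._bnd_terms.append((hi_int[bi], flat_lo[bi], gval[bi]))

        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        vals = np.concatenate(vals)
        A = sp.coo_matrix(
            (np.concatenate([vals, diag]), (np.concatenate([rows, np.arange(m)]), np.concatenate([cols, np.arange(m)]))),
            shape=(m, m),
        ).tocsr()
        self.A = A
        self._Minv = 1.0 / A.diagonal()
        self._lu = None

    def _boundary_values(self, source_center: np.ndarray, current_mA: float) -> np.ndarray:
        """Monopole Dirichlet values on the full flat lattice (defined
        everywhere, only boundary-adjacent entries are consumed)."""
        if current_mA == 0.0:
            return np.zeros(self.grid.n_voxels)
        centers = self.grid.voxel_centers().reshape(-1, 3)
        r = np.linalg.norm(centers - source_center, axis=1)
        r = np.maximum(r, self.grid.spacing)
        return current_mA / (4.0 * np.pi * self.cond.sigma_far * r)

    def _solve(self, rhs: np.ndarray, bval: np.ndarray) -> np.ndarray:
        b = rhs.copy()
        for int_idx, bnd_flat, g in self._bnd_terms:
            np.add.at(b, int_idx, g * bval[bnd_flat])
        if self.options.method == "direct":
            if self._lu is None:
                self._lu = spla.splu(self.A.tocsc())
            x = self._lu.solve(b)
        else:
            x, info = spla.cg(
                self.A,
                b,
                rtol=self.options.rtol,
                atol=0.0,
                maxiter=self.options.maxiter,
                M=spla.LinearOperator(self.A.shape, matvec=lambda v: self._Minv * v),
            )
            if info != 0:
                res = np.linalg.norm(self.A @ x - b) / max(np.linalg.norm(b), 1e-300)
                raise SolverError(f"CG did not converge (info={info}, relative residual={res:.2e})")
        phi = bval.copy()
        phi[self.flat_interior] = x
        return phi.reshape(self.grid.shape)

    def unit_solution(self, contact: int) -> np.ndarray:
        """Potential field (V) for +1 mA injected at ``contact``, all other
        contacts floating, open (monopole Dirichlet) outer boundary."""
        if contact not in self._unit_cache:
            vox = self.cond.lead_voxels.contact_voxels.get(contact)
            if vox is None or vox.size == 0:
                raise ValueError(f"contact {contact} has no voxels on this grid")
            rhs = np.zeros(self.flat_interior.size)
            per_voxel = 1e-3 / vox.size  # amperes
            int_idx = self.idx_of[vox]
            if np.any(int_idx < 0):
                raise ValueError("contact voxels touch the Dirichlet boundary; enlarge the grid")
            np.add.at(rhs, int_idx, per_voxel)
            centers = self.grid.voxel_centers().reshape(-1, 3)
            centroid = centers[vox].mean(axis=0)
            bval = self._boundary_values(centroid, 1.0)
            self._unit_cache[contact] = self._solve(rhs, bval)
        return self._unit_cache[contact]

    def setting_potential(self, setting: StimSetting) -> np.ndarray:
        """Superposed potential for a full setting (cathodes negative)."""
        phi = np.zeros(self.grid.shape)
        for c, i_mA in setting.contact_currents_mA.items():
            phi += i_mA * self.unit_solution(c)
        return phi


def solve_static_field(
    lead: LeadModel,
    placement: LeadPlacement,
    setting: StimSetting,
    cond: ConductivityMap,
    options: SolverOptions = SolverOptions(),
    conductor: VolumeConductor | None = None,
) -> FieldSolution:
    """Solve for the potential of one stimulation setting by superposing
    per-contact unit solutions (the operator is linear and the metal
    inclusions are part of the conductivity map, so superposition is exact)."""
    from .leads import contact_positions

    pts = contact_positions(lead, placement)
    lo = grid_min = np.asarray(cond.grid.origin)
    hi = grid_min + cond.grid.spacing * (np.asarray(cond.grid.shape) - 1)
    if np.any(pts < lo + 5.0) or np.any(pts > hi - 5.0):
        raise ValueError("lead must fit inside the grid with >= 5 mm margin")
    vc = conductor if conductor is not None else VolumeConductor(cond, options)
    phi = vc.setting_potential(setting)
    return FieldSolution(
        grid=cond.grid,
        potential=phi,
        conductivity=cond,
        contact_currents_mA=setting.contact_currents_mA,
    )


def efield_magnitude(potential: np.ndarray, spacing: float) -> np.ndarray:
    """|E| in V/mm: central differences in the interior, one-sided at the
    grid faces (numpy gradient convention)."""
    gx, gy, gz = np.gradient(potential, spacing)
    return np.sqrt(gx**2 + gy**2 + gz**2)


def temporal_scale(sol: FieldSolution, circuit: CircuitParams, pulse_width_us: float) -> FieldSolution:
    """Attach the separable equivalent-circuit scaling: the spatial pattern is
    unchanged, only the amplitude factor (in (0, 1]) is updated."""
    s = circuit.scale(pulse_width_us)
    return replace(sol, temporal_scale=sol.temporal_scale * s, _efield=sol._efield)
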