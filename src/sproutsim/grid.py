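"""Cylindrical (z, r) finite-volume mesh and diffusion operators.

The fluid domain is an axisymmetric cylinder of radius ``R_edge`` spanning
``z in [-L, +L]``.  The sprout occupies the innermost radial voxel
(``r < R_sprout``) for ``z < 0`` and is excluded from the fluid domain; its
wall supplies flux boundary conditions through the basement-membrane layer.
Exactly one radial voxel spans ``[0, R_sprout]`` so that the first interior
radial face coincides with the sprout surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .params import Geometry, ValidationError

__all__ = ["Grid", "GridError", "build_grid", "annulus_grid", "diffusion_operator"]


class GridError(ValueError):
    pass


def _segment_faces(a: float, b: float, target: float) -> np.ndarray:
    """Faces from a to b with spacing as close to ``target`` as divides evenly."""
    n = max(1, round((b - a) / target))
    return np.linspace(a, b, n + 1)


@dataclass
class Grid:
    """Finite-volume mesh. Cell (i, j) spans z_faces[i:i+2] x r_faces[j:j+2]."""

    z_faces: np.ndarray
    r_faces: np.ndarray
    geometry: Geometry | None = None
    #: False for cells excluded from the fluid domain (sprout interior)
    active: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.z_faces = np.asarray(self.z_faces, dtype=float)
        self.r_faces = np.asarray(self.r_faces, dtype=float)
        if np.any(np.diff(self.z_faces) <= 0) or np.any(np.diff(self.r_faces) <= 0):
            raise GridError("faces must be strictly ascending")
        if self.nr < 3:
            raise GridError("grid needs at least 3 radial cells")
        if self.nz < 2:
            raise GridError("grid needs at least 2 axial cells")
        if self.active is None:
            self.active = np.ones((self.nz, self.nr), dtype=bool)

    # -- shape ----------------------------------------------------------
    @property
    def nz(self) -> int:
        return len(self.z_faces) - 1

    @property
    def nr(self) -> int:
        return len(self.r_faces) - 1

    @property
    def z_centers(self) -> np.ndarray:
        return 0.5 * (self.z_faces[:-1] + self.z_faces[1:])

    @property
    def r_centers(self) -> np.ndarray:
        return 0.5 * (self.r_faces[:-1] + self.r_faces[1:])

    @property
    def dz(self) -> np.ndarray:
        return np.diff(self.z_faces)

    @property
    def dr(self) -> np.ndarray:
        return np.diff(self.r_faces)

    # -- measures -------------------------------------------------------
    @property
    def ring_areas(self) -> np.ndarray:
        """Cross-sectional (axial-face) area of each radial ring, (nr,)."""
        return np.pi * (self.r_faces[1:] ** 2 - self.r_faces[:-1] ** 2)

    @property
    def cell_volumes(self) -> np.ndarray:
        """(nz, nr) cell volumes in um^3 (inactive cells included)."""
        return np.outer(self.dz, self.ring_areas)

    # -- sprout bookkeeping ---------------------------------------------
    @property
    def has_sprout(self) -> bool:
        return self.geometry is not None and not self.active.all()

    @property
    def sprout_wall_nodes(self) -> np.ndarray:
        """Axial cell indices whose inner radial face is the sprout wall (z<0)."""
        if self.geometry is None:
            return np.array([], dtype=int)
        return np.nonzero(self.z_centers < 0)[0]

    @property
    def tip_wall_nodes(self) -> np.ndarray:
        """Wall nodes covered by the tip cell, z in [-L_tip, 0]."""
        zc = self.z_centers
        return np.nonzero((zc < 0) & (zc > -self.geometry.L_tip))[0]

    @property
    def bm_nodes(self) -> np.ndarray:
        """Axial node set covered by basement membrane (whole sprout wall)."""
        return self.sprout_wall_nodes

    @property
    def cap_cell(self) -> int:
        """Axial index of the fluid cell sitting on the sprout's end cap."""
        return int(np.searchsorted(self.z_faces, 0.0))

    @property
    def axis_mask(self) -> np.ndarray:
        """(nz,) True for axial cells whose j=0 voxel touches r=0 fluid (z>0)."""
        return self.active[:, 0].copy()


def build_grid(geometry: Geometry, spacing_policy: str = "coarse") -> Grid:
    """Mesh the sprout domain.

    ``coarse`` follows the reference discretisation: 8 um axial control
    volumes, one radial voxel for the sprout, 4 um radial spacing near the
    sprout widening to 8 um far from it.  ``fine`` halves every spacing for
    convergence studies.
    """
    if spacing_policy not in ("coarse", "fine"):
        raise GridError(f"unknown spacing policy {spacing_policy!r}")
    half = 2.0 if spacing_policy == "fine" else 1.0
    dz_t, dr_near_t, dr_far_t = 8.0 / half, 4.0 / half, 8.0 / half

    L, R_edge, R_s = geometry.L, geometry.R_edge, geometry.R_sprout
    z_lo = _segment_faces(-L, 0.0, dz_t)
    z_hi = _segment_faces(0.0, L, dz_t)
    if len(z_lo) < 3:
        raise GridError("domain too short: need at least 2 axial cells per half")
    z_faces = np.concatenate([z_lo, z_hi[1:]])

    near_end = min(50.0, R_edge)
    r_parts = [np.array([0.0, R_s]), _segment_faces(R_s, near_end, dr_near_t)[1:]]
    if R_edge > near_end:
        r_parts.append(_segment_faces(near_end, R_edge, dr_far_t)[1:])
    r_faces = np.concatenate(r_parts)

    grid = Grid(z_faces, r_faces, geometry=geometry)
    # carve out the sprout interior: innermost voxel for z < 0
    grid.active[grid.z_centers < 0, 0] = False
    if not np.isclose(r_faces[1], R_s):
        raise GridError("first interior radial face must sit on the sprout surface")
    return grid


def annulus_grid(r_inner: float, r_outer: float, nz: int, nr: int, z_extent: float = 16.0) -> Grid:
    """Annular test mesh with an open inner radial boundary (no sprout),
    used for comparing against closed-form radial solutions."""
    return Grid(
        np.linspace(0.0, z_extent, nz + 1),
        np.linspace(r_inner, r_outer, nr + 1),
    )


def _face_conductances(grid: Grid, D: float):
    """Internal-face conductances g = D*A/dist (um^3/s) acting on bulk
    concentrations; faces touching inactive cells are blocked."""
    zc, rc = grid.z_centers, grid.r_centers
    ring = grid.ring_areas

    g_z = np.zeros((grid.nz + 1, grid.nr))
    dist_z = zc[1:] - zc[:-1]
    g_z[1:-1, :] = D * ring[None, :] / dist_z[:, None]

    g_r = np.zeros((grid.nz, grid.nr + 1))
    dist_r = rc[1:] - rc[:-1]
    area_r = 2.0 * np.pi * np.outer(grid.dz, grid.r_faces[1:-1])
    g_r[:, 1:-1] = D * area_r / dist_r[None, :]

    act = grid.active
    g_z[1:-1, :] *= act[:-1, :] & act[1:, :]
    g_r[:, 1:-1] *= act[:, :-1] & act[:, 1:]
    return g_z, g_r


def _boundary_conductances(grid: Grid, D: float):
    """Conductances from edge-cell centers to the exterior faces, for
    Dirichlet edges. Keys: z_lo, z_hi, r_hi, r_lo (r_lo only if annular)."""
    ring = grid.ring_areas
    zc, rc = grid.z_centers, grid.r_centers
    out = {
        "z_lo": D * ring / (zc[0] - grid.z_faces[0]),
        "z_hi": D * ring / (grid.z_faces[-1] - zc[-1]),
        "r_hi": D * 2.0 * np.pi * grid.r_faces[-1] * grid.dz / (grid.r_faces[-1] - rc[-1]),
    }
    if grid.r_faces[0] > 0:
        out["r_lo"] = D * 2.0 * np.pi * grid.r_faces[0] * grid.dz / (rc[0] - grid.r_faces[0])
    return out


def diffusion_operator(grid: Grid, D: float, dirichlet: dict | None = None):
    """Assemble the conservative FV diffusion operator on bulk concentrations.

    Returns ``(L, b)`` with ``dC/dt = L @ C + b`` for the flattened (nz*nr)
    concentration vector: ``L`` is a CSR sparse matrix in 1/s, ``b`` carries
    Dirichlet boundary contributions (zero with the default all-no-flux
    boundaries).  The axis r=0 is a zero-area face (no flux by symmetry);
    rows of interior nodes sum to zero; inactive (sprout-interior) cells get
    empty rows.

    ``dirichlet`` maps edge names (``z_lo``, ``z_hi``, ``r_hi``, ``r_lo``)
    to bulk boundary values.
    """
    nz, nr = grid.nz, grid.nr
    n = nz * nr
    vol = grid.cell_volumes
    g_z, g_r = _face_conductances(grid, D)

    idx = np.arange(n).reshape(nz, nr)
    rows, cols, vals = [], [], []
    diag = np.zeros((nz, nr))

    def couple(i0, j0, i1, j1, g):
        m = g > 0
        rows.extend([idx[i0, j0][m], idx[i1, j1][m]])
        cols.extend([idx[i1, j1][m], idx[i0, j0][m]])
        vals.extend([g[m], g[m]])
        diag[i0, j0][m] += g[m]
        diag[i1, j1][m] += g[m]

    s = np.s_
    couple(s[:-1], s[:], s[1:], s[:], g_z[1:-1, :])
    couple(s[:], s[:-1], s[:], s[1:], g_r[:, 1:-1])

    b = np.zeros((nz, nr))
    if dirichlet:
        gb = _boundary_conductances(grid, D)
        for edge, value in dirichlet.items():
            if edge not in gb:
                raise GridError(f"edge {edge!r} not available on this grid")
            g = gb[edge]
            if edge == "z_lo":
                diag[0, :] += g
                b[0, :] += g * value
            elif edge == "z_hi":
                diag[-1, :] += g
                b[-1, :] += g * value
            elif edge == "r_hi":
                diag[:, -1] += g
                b[:, -1] += g * value
            else:  # r_lo
                diag[:, 0] += g
                b[:, 0] += g * value
        b[~grid.active] = 0.0

    diag[~grid.active] = 0.0
    rows.append(idx.ravel())
    cols.append(idx.ravel())
    vals.append(-diag.ravel())

    L = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    inv_vol = np.where(grid.active, 1.0 / vol, 0.0).ravel()
    L = sp.diags(inv_vol) @ L
    b = b.ravel() * inv_vol
    return L, b


def bm_interface_flux(
    C_ecm: float,
    C_bm: float,
    D_ecm: float,
    D_bm: float,
    K_ecm: float,
    K_bm: float,
    d_bm: float,
    dr_ecm: float,
):
    """Series two-resistance flux density between a basement-membrane node and
    the adjacent ECM node (planar form), positive from BM into ECM.

    ``C_ecm``/``C_bm`` are bulk molar; the interface enforces continuity of
    interstitial-fluid concentration and of total diffusive flux.  Returns
    mol um^-2 s^-1.  When both materials are identical this reduces to the
    plain two-point FV face flux between centers ``(d_bm + dr_ecm)/2`` apart.
    """
    if d_bm <= 0 or dr_ecm <= 0:
        raise ValidationError("geometric lengths must be positive")
    resistance = d_bm / (2.0 * D_bm * K_bm) + dr_ecm / (2.0 * D_ecm * K_ecm)
    flux_molar_um = (C_bm / K_bm - C_ecm / K_ecm) / resistance  # M um / s
    return flux_molar_um * 1.0e-15  # -> mol um^-2 s^-1
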