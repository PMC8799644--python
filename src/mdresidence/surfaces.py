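"""Ligand surface decomposition: SASA, MolSA, PSA, SAPSA and burial.

Per frame the ligand's solvent-accessible surface area (SASA) is computed
in the context of the full protein-ligand complex (waters excluded from
the occluders — the solvent defines the probe), while the molecular
(solvent-excluded, Connolly) surface area MolSA is computed for the
isolated ligand conformer.  The polar shares PSA and SAPSA count surface
contributed by N and O atoms (and, by default, hydrogens bonded to them).
Derived quantities:

    buried       = MolSA - SASA
    buried_polar = PSA   - SAPSA

SASA uses a deterministic Shrake-Rupley sphere-point method (Fibonacci
lattice) at radius vdW + probe, probe 1.4 A by default.  MolSA uses a
grid level-set: the solvent-excluded volume is the set of points farther
than the probe radius from any probe-accessible position; its boundary is
extracted by marching cubes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt
from scipy.spatial import cKDTree
from skimage.measure import marching_cubes, mesh_surface_area

from .core import Structure, Trajectory

__all__ = [
    "SurfaceAreas",
    "fibonacci_sphere",
    "shrake_rupley",
    "compute_sasa",
    "ses_area",
    "compute_surface_decomposition",
    "surface_trace",
]


@dataclass
class SurfaceAreas:
    frame_index: int
    sasa: float
    molsa: float
    psa: float
    sapsa: float
    probe_radius: float = 1.4

    @property
    def buried(self) -> float:
        return self.molsa - self.sasa

    @property
    def buried_polar(self) -> float:
        return self.psa - self.sapsa


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    golden = np.pi * (1.0 + np.sqrt(5.0))
    theta = golden * i
    return np.column_stack([np.cos(theta) * np.sin(phi),
                            np.sin(theta) * np.sin(phi),
                            np.cos(phi)])


def shrake_rupley(coords: np.ndarray, radii: np.ndarray, probe: float = 1.4,
                  n_points: int = 960,
                  subset: Sequence[int] | None = None) -> np.ndarray:
    """Per-atom accessible surface areas (A^2) in the context of all atoms.

    Returns areas for ``subset`` (default: every atom).  Deterministic for
    a fixed ``n_points``.
    """
    if n_points < 100:
        raise ValueError("n_points must be >= 100")
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if coords.shape[0] == 0:
        raise ValueError("empty atom set")
    subset = np.arange(coords.shape[0]) if subset is None else np.asarray(subset)
    if subset.size == 0:
        raise ValueError("empty atom subset")
    sphere = fibonacci_sphere(n_points)
    expanded = radii + probe
    tree = cKDTree(coords)
    max_r = expanded.max()
    areas = np.zeros(subset.size)
    for out_i, i in enumerate(subset):
        r = expanded[i]
        pts = coords[i] + r * sphere
        neighbor_idx = [j for j in tree.query_ball_point(coords[i], r + max_r)
                        if j != i]
        if neighbor_idx:
            nb = np.asarray(neighbor_idx)
            d2 = ((pts[:, None, :] - coords[nb][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (expanded[nb] ** 2)[None, :] - 1e-12).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[out_i] = frac * 4.0 * np.pi * r * r
    return areas


def compute_sasa(structure: Structure, atom_subset: Sequence[int],
                 probe: float = 1.4, n_points: int = 960,
                 environment: Sequence[int] | None = None):
    """SASA of ``atom_subset`` computed amid ``environment`` occluders
    (default: all non-water atoms).  Returns (per-atom areas, total)."""
    atoms = structure.atoms
    if environment is None:
        environment = [i for i, a in enumerate(atoms)
                       if "water_oxygen" not in a.roles and
                       "water_hydrogen" not in a.roles]
    env = list(dict.fromkeys(list(environment) + list(atom_subset)))
    coords = np.array([atoms[i].position for i in env])
    radii = np.array([atoms[i].vdw_radius for i in env])
    pos_in_env = {g: k for k, g in enumerate(env)}
    sub = np.array([pos_in_env[i] for i in atom_subset])
    areas = shrake_rupley(coords, radii, probe, n_points, subset=sub)
    return areas, float(areas.sum())


def ses_area(coords: np.ndarray, radii: np.ndarray, probe: float = 1.4,
             spacing: float = 0.12, return_assignment: bool = False):
    """Solvent-excluded (molecular) surface area by a grid level set.

    A grid point is probe-accessible when it lies outside every inflated
    sphere (vdW + probe).  The molecular volume is the set of points whose
    Euclidean distance to the accessible region is >= probe; marching
    cubes extracts its boundary.  The raw distance transform measures to
    the nearest accessible *voxel center*, which sits slightly outside the
    true accessible boundary; that offset is corrected per voxel using the
    nearest voxel's analytic clearance min_i(|x - c_i| - R_i).
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if coords.shape[0] == 0:
        raise ValueError("empty atom set")
    inflated = radii + probe
    pad = inflated.max() + probe + 3.0 * spacing
    lo = coords.min(axis=0) - pad
    hi = coords.max(axis=0) + pad
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    axes = [lo[k] + spacing * np.arange(shape[k]) for k in range(3)]

    # clearance g(x) = min_i (|x - c_i| - R_i); accessible iff g > 0
    gx = np.full(shape, np.inf, dtype=np.float32)
    for c, r in zip(coords, inflated):
        i0 = np.maximum(((c - r - lo) / spacing).astype(int) - 1, 0)
        i1 = np.minimum(((c + r - lo) / spacing).astype(int) + 2, shape)
        sub = np.meshgrid(*[axes[k][i0[k]:i1[k]] for k in range(3)], indexing="ij")
        d = np.sqrt((sub[0] - c[0]) ** 2 + (sub[1] - c[1]) ** 2 + (sub[2] - c[2]) ** 2)
        region = (slice(i0[0], i1[0]), slice(i0[1], i1[1]), slice(i0[2], i1[2]))
        gx[region] = np.minimum(gx[region], (d - r).astype(np.float32))
    # distant voxels never touched above: clearance large and positive
    accessible = gx > 0

    dt, (ix, iy, iz) = distance_transform_edt(~accessible, sampling=spacing,
                                              return_indices=True)
    # correct for the nearest accessible voxel's own clearance from the SAS
    correction = np.where(np.isfinite(gx[ix, iy, iz]), gx[ix, iy, iz], 0.0)
    dist_to_accessible = np.maximum(dt - np.clip(correction, 0.0, None), 0.0)
    field = dist_to_accessible.astype(np.float32)
    if not (field > probe).any():
        raise ValueError("no solvent-excluded volume on this grid")
    verts, faces, _, _ = marching_cubes(field, level=probe,
                                        spacing=(spacing, spacing, spacing))
    area = float(mesh_surface_area(verts, faces))
    if not return_assignment:
        return area
    verts_world = verts + lo
    tri = verts_world[faces]
    centroids = tri.mean(axis=1)
    tri_areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
    d_atom = np.linalg.norm(centroids[:, None, :] - coords[None, :, :], axis=2) - \
        radii[None, :]
    owner = d_atom.argmin(axis=1)
    per_atom = np.zeros(coords.shape[0])
    np.add.at(per_atom, owner, tri_areas)
    return area, per_atom


def _polar_indices(structure: Structure, atom_subset: Sequence[int],
                   include_h_on_polar: bool = True) -> set[int]:
    polar = set()
    atoms = structure.atoms
    subset = set(atom_subset)
    for i in atom_subset:
        a = atoms[i]
        el = a.element.upper()
        if el in ("N", "O"):
            polar.add(i)
        elif el == "H" and include_h_on_polar:
            heavies = [n for n in structure.neighbors(a.serial)
                       if n.element.upper() != "H"]
            if heavies and heavies[0].element.upper() in ("N", "O") and \
                    structure.index_of(heavies[0].serial) in subset:
                polar.add(i)
    return polar


def compute_surface_decomposition(frame: Structure, ligand_subset: Sequence[int],
                                  probe: float = 1.4, n_points: int = 960,
                                  grid_spacing: float = 0.12,
                                  include_h_on_polar: bool = True,
                                  frame_index: int = 0) -> SurfaceAreas:
    """Full per-frame decomposition for one ligand.

    SASA/SAPSA in complex; MolSA/PSA on the isolated ligand conformer;
    buried = MolSA - SASA and buried_polar = PSA - SAPSA (reported as
    computed, which may be negative for an isolated molecule).
    """
    ligand_subset = list(ligand_subset)
    if not ligand_subset:
        raise ValueError("empty ligand subset")
    atoms = frame.atoms
    has_no = any(atoms[i].element.upper() in ("N", "O") for i in ligand_subset)
    polar = _polar_indices(frame, ligand_subset, include_h_on_polar)
    if has_no and not polar:
        raise ValueError("ligand polarity annotation missing")

    per_atom, sasa = compute_sasa(frame, ligand_subset, probe, n_points)
    sapsa = float(sum(area for i, area in zip(ligand_subset, per_atom)
                      if i in polar))

    lig_coords = np.array([atoms[i].position for i in ligand_subset])
    lig_radii = np.array([atoms[i].vdw_radius for i in ligand_subset])
    molsa, ses_per_atom = ses_area(lig_coords, lig_radii, probe, grid_spacing,
                                   return_assignment=True)
    psa = float(sum(a for i, a in zip(ligand_subset, ses_per_atom) if i in polar))
    return SurfaceAreas(frame_index=frame_index, sasa=sasa, molsa=molsa,
                        psa=psa, sapsa=sapsa, probe_radius=probe)


def surface_trace(trajectory: Trajectory, ligand_subset: Sequence[int],
                  probe: float = 1.4, n_points: int = 960,
                  grid_spacing: float = 0.12) -> pd.DataFrame:
    """Per-frame surface table (columns mirror the TSV the pipeline writes)."""
    rows = []
    for i, frame in trajectory.iter_frames():
        s = compute_surface_decomposition(frame, ligand_subset, probe, n_points,
                                          grid_spacing, frame_index=i)
        rows.append({"frame": i, "sasa": s.sasa, "molsa": s.molsa, "psa": s.psa,
                     "sapsa": s.sapsa, "buried": s.buried,
                     "buried_polar": s.buried_polar})
    return pd.DataFrame(rows)
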