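"""Hydration sites, ligand displaced-water scoring and pi-weighted averages.

Hydration sites are localized high-occupancy water positions, clustered
from the water-oxygen observations of a restrained-solvent ensemble.
Only waters within an inclusion shell (10.0 A by default) of the ligand
are considered.  Each site carries a free energy relative to bulk water,
either supplied externally (the normal route: site energies are an input
table of x, y, z, dG) or crudely estimated here from excess occupancy.

A ligand displaces a site when its overlap factor exceeds 0.5 strictly;
the ligand score sums -dG over displaced sites, so displacing unstable
(positive-dG) water is favorable (negative score).  Scores evaluated on
metastable-state representative structures are aggregated with the
states' equilibrium probabilities pi_i as weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "HydrationSite",
    "HydrationSiteSet",
    "DisplacementResult",
    "WeightedScore",
    "cluster_hydration_sites",
    "estimate_site_energy",
    "overlap_factor",
    "ligand_displacement_score",
    "weighted_state_score",
    "read_site_table",
    "write_site_table",
]

KT_310K = 0.616  # kcal/mol at 310 K
BULK_WATER_DENSITY = 0.0334  # molecules / A^3


@dataclass
class HydrationSite:
    center: np.ndarray
    occupancy: int
    n_frames: int
    delta_g: float | None = None  # kcal/mol relative to bulk
    source: str = "external"
    member_positions: np.ndarray | None = None

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)


@dataclass
class HydrationSiteSet:
    sites: list
    radius: float
    n_frames: int

    def __len__(self):
        return len(self.sites)

    def __iter__(self):
        return iter(self.sites)


@dataclass
class DisplacementResult:
    overlap_factors: np.ndarray
    displaced: np.ndarray  # boolean, overlap > 0.5 strictly
    score: float           # kcal/mol
    inclusion_shell: float = 10.0


@dataclass
class WeightedScore:
    state_scores: np.ndarray
    weights: np.ndarray
    plain_average: float
    weighted_average: float


def cluster_hydration_sites(water_positions_by_frame: Sequence[np.ndarray],
                            radius: float = 1.0,
                            shell_center: np.ndarray | None = None,
                            shell: float = 10.0,
                            min_occupancy: int = 2) -> HydrationSiteSet:
    """Greedy density clustering of water-oxygen observations.

    Repeatedly takes the observation with the most neighbors within
    ``radius``, founds a site at the member centroid, and removes the
    members, until no remaining observation has at least ``min_occupancy``
    neighbors (itself included).  ``shell_center`` may be a point or an
    array of ligand atom positions; observations farther than ``shell``
    from all of them are excluded up front.
    """
    n_frames = len(water_positions_by_frame)
    if n_frames < 1:
        raise ValueError("need at least one frame")
    frames = [np.asarray(f, dtype=float).reshape(-1, 3)
              for f in water_positions_by_frame]
    points = np.vstack([f for f in frames if len(f)]) if any(len(f) for f in frames) \
        else np.empty((0, 3))
    if shell_center is not None and len(points):
        ref = np.atleast_2d(np.asarray(shell_center, dtype=float))
        d = cKDTree(ref).query(points, k=1)[0]
        points = points[d <= shell + 1e-12]
    sites: list[HydrationSite] = []
    remaining = points
    while len(remaining):
        tree = cKDTree(remaining)
        neighbor_lists = tree.query_ball_point(remaining, radius + 1e-12)
        counts = np.array([len(nl) for nl in neighbor_lists])
        best = int(np.argmax(counts))
        if counts[best] < min_occupancy:
            break
        members = np.array(sorted(neighbor_lists[best]))
        member_pos = remaining[members]
        sites.append(HydrationSite(center=member_pos.mean(axis=0),
                                   occupancy=len(members), n_frames=n_frames,
                                   member_positions=member_pos))
        keep = np.ones(len(remaining), dtype=bool)
        keep[members] = False
        remaining = remaining[keep]
    return HydrationSiteSet(sites=sites, radius=radius, n_frames=n_frames)


def estimate_site_energy(site: HydrationSite, radius: float = 1.0,
                         bulk_density: float = BULK_WATER_DENSITY,
                         kt: float = KT_310K) -> float:
    """Inverse-Boltzmann excess-occupancy estimate of the site free energy.

    dG = -kT ln(rho_site / rho_bulk) with the site volume taken as the
    clustering sphere.  A crude stand-in for proper inhomogeneous
    solvation theory; the site is flagged ``source = "estimated"``.
    """
    if site.occupancy <= 0:
        raise ValueError("site energy undefined for zero occupancy")
    volume = 4.0 / 3.0 * np.pi * radius ** 3
    rho_site = site.occupancy / (site.n_frames * volume)
    dg = -kt * np.log(rho_site / bulk_density)
    site.delta_g = float(dg)
    site.source = "estimated"
    return site.delta_g


def overlap_factor(site: HydrationSite, ligand_positions: np.ndarray,
                   ligand_radii: np.ndarray, probe_offset: float = 1.4) -> float:
    """Fraction of the site's member observations that a bound ligand
    excludes: positions within (vdW radius + probe_offset) of any ligand
    heavy atom could not host a water center."""
    members = site.member_positions
    if members is None or len(members) == 0:
        members = site.center[None, :]
    lig = np.asarray(ligand_positions, dtype=float)
    radii = np.asarray(ligand_radii, dtype=float)
    if len(lig) == 0:
        return 0.0
    d = np.linalg.norm(members[:, None, :] - lig[None, :, :], axis=2)
    inside = (d <= radii[None, :] + probe_offset + 1e-12).any(axis=1)
    return float(inside.mean())


def ligand_displacement_score(sites: HydrationSiteSet | Sequence[HydrationSite],
                              ligand_positions: np.ndarray,
                              ligand_radii: np.ndarray,
                              probe_offset: float = 1.4,
                              inclusion_shell: float = 10.0,
                              displaced_threshold: float = 0.5
                              ) -> DisplacementResult:
    """Displaced-water ligand score: -sum of dG over displaced sites.

    A site is displaced iff overlap factor > ``displaced_threshold``
    strictly; only sites whose center lies within ``inclusion_shell`` of
    the ligand are considered.
    """
    site_list = list(sites)
    lig = np.asarray(ligand_positions, dtype=float)
    missing = [i for i, s in enumerate(site_list) if s.delta_g is None]
    if missing:
        raise ValueError(f"sites without delta_g: {missing}")
    factors = np.zeros(len(site_list))
    in_shell = np.zeros(len(site_list), dtype=bool)
    for i, s in enumerate(site_list):
        d = np.min(np.linalg.norm(lig - s.center, axis=1)) if len(lig) else np.inf
        in_shell[i] = d <= inclusion_shell + 1e-12
        if in_shell[i]:
            factors[i] = overlap_factor(s, lig, ligand_radii, probe_offset)
    displaced = in_shell & (factors > displaced_threshold)
    score = -float(sum(s.delta_g for s, flag in zip(site_list, displaced) if flag))
    return DisplacementResult(overlap_factors=factors, displaced=displaced,
                              score=score, inclusion_shell=inclusion_shell)


def weighted_state_score(scores, equilibrium_probabilities) -> WeightedScore:
    """Equilibrium-probability-weighted aggregate of per-state scores.

    ``scores`` holds one value per metastable state, or a sequence of
    values per state (e.g. one per representative structure), which are
    averaged within the state first.  The weighted average is
    sum(pi_i * s_i) / sum(pi_i); the plain mean is reported alongside.
    """
    pi = np.asarray(equilibrium_probabilities, dtype=float)
    state_scores = np.array([float(np.mean(s)) for s in np.atleast_1d(
        np.asarray(scores, dtype=object))]) if isinstance(scores, (list, tuple)) \
        else np.asarray(scores, dtype=float)
    if state_scores.shape[0] != pi.shape[0]:
        raise ValueError("scores and weights must have equal length")
    if np.any(pi < 0) or pi.sum() == 0:
        raise ValueError("weights must be non-negative and not all zero")
    weighted = float(np.sum(pi * state_scores) / pi.sum())
    plain = float(np.mean(state_scores))
    return WeightedScore(state_scores=state_scores, weights=pi,
                         plain_average=plain, weighted_average=weighted)


# ---------------------------------------------------------------------------
# Site table I/O (TSV: x, y, z, occupancy, delta_g, source)
# ---------------------------------------------------------------------------

def write_site_table(sites: HydrationSiteSet, path) -> None:
    rows = [{"x": s.center[0], "y": s.center[1], "z": s.center[2],
             "occupancy": s.occupancy, "delta_g": s.delta_g, "source": s.source}
            for s in sites]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_site_table(path, n_frames: int = 1) -> HydrationSiteSet:
    df = pd.read_csv(path, sep="\t")
    sites = []
    for _, row in df.iterrows():
        sites.append(HydrationSite(
            center=np.array([row["x"], row["y"], row["z"]]),
            occupancy=int(row.get("occupancy", 1)), n_frames=n_frames,
            delta_g=float(row["delta_g"]) if "delta_g" in row and
            pd.notna(row["delta_g"]) else None,
            source=str(row.get("source", "external"))))
    return HydrationSiteSet(sites=sites, radius=1.0, n_frames=n_frames)
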