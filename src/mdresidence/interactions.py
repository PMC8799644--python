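"""Frame-wise protein-ligand interaction detection and frequency tables.

Detectors implement the standard simulation-interaction-diagram geometric
criteria: hydrogen bonds (hydrogen-to-acceptor 2.5 A, donor angle >= 120
deg, acceptor angle >= 90 deg), pi-cation (charged center to ring centroid
4.5 A), pi-pi stacking (face-to-face / edge-to-face), water bridges
(relaxed H-bond geometry, 2.8 A / 110 deg / 90 deg, one water bonded to
both partners) and salt bridges (charged heavy-atom pair, 4.0 A).  All
cutoffs are inclusive at equality and configurable through
:class:`InteractionCriteria`.

Frequencies follow interaction-fingerprint semantics: a partner pair is
"interacting in a frame" if at least one event of that kind exists in the
frame, and a table row reports n_observed / n_total over frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import Structure

__all__ = [
    "InteractionCriteria",
    "InteractionEvent",
    "detect_hbonds",
    "detect_pication",
    "detect_pipi",
    "detect_waterbridge",
    "detect_saltbridge",
    "detect_all",
    "tabulate_frequencies",
    "trajectory_events",
]


@dataclass
class InteractionCriteria:
    hbond_distance: float = 2.5          # hydrogen -> acceptor, Angstrom
    hbond_donor_angle_min: float = 120.0
    hbond_acceptor_angle_min: float = 90.0
    pication_distance: float = 4.5       # charged center -> ring centroid
    pipi_f2f_centroid_max: float = 4.4
    pipi_f2f_angle_max: float = 30.0
    pipi_e2f_centroid_max: float = 5.5
    pipi_e2f_angle_window: tuple = (60.0, 120.0)
    waterbridge_distance: float = 2.8
    waterbridge_donor_angle_min: float = 110.0
    waterbridge_acceptor_angle_min: float = 90.0
    saltbridge_distance: float = 4.0

    def __post_init__(self):
        for name in ("hbond_distance", "pication_distance", "pipi_f2f_centroid_max",
                     "pipi_e2f_centroid_max", "waterbridge_distance",
                     "saltbridge_distance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("hbond_donor_angle_min", "hbond_acceptor_angle_min",
                     "waterbridge_donor_angle_min", "waterbridge_acceptor_angle_min",
                     "pipi_f2f_angle_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 180.0:
                raise ValueError(f"{name} must lie in [0, 180]")


@dataclass
class InteractionEvent:
    frame_index: int
    kind: str  # hbond | pication | pipi | waterbridge | saltbridge
    partner_a: str
    partner_b: str
    bridging_water: str | None = None
    geometry: str | None = None  # pipi: face_to_face | edge_to_face

    def __post_init__(self):
        if self.partner_a == self.partner_b:
            raise ValueError("interaction partners must be distinct")
        if (self.kind == "waterbridge") != (self.bridging_water is not None):
            raise ValueError("bridging_water present iff kind == waterbridge")


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    v1 = a - b
    v2 = c - b
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


_EPS_D = 1e-9  # inclusive-at-cutoff comparisons, robust to float rounding
_EPS_A = 1e-7


def _hbond_geometry_ok(structure: Structure, h, acceptor, dist_max, donor_min,
                       acceptor_min) -> bool:
    d = np.linalg.norm(h.position - acceptor.position)
    if d > dist_max + _EPS_D:
        return False
    donors = [n for n in structure.neighbors(h.serial) if n.element.upper() != "H"]
    if not donors:
        return False
    donor = donors[0]
    if _angle(donor.position, h.position, acceptor.position) < donor_min - _EPS_A:
        return False
    heavies = [n for n in structure.neighbors(acceptor.serial)
               if n.element.upper() != "H"]
    if not heavies:
        return True  # e.g. water oxygen: acceptor-angle check is vacuous
    return any(_angle(h.position, acceptor.position, x.position)
               >= acceptor_min - _EPS_A for x in heavies)


def _is_water(atom) -> bool:
    return "water_oxygen" in atom.roles or "water_hydrogen" in atom.roles


def detect_hbonds(structure: Structure, criteria: InteractionCriteria | None = None,
                  donor_set: Iterable[int] | None = None,
                  acceptor_set: Iterable[int] | None = None,
                  frame_index: int = 0,
                  include_water: bool = False) -> list[InteractionEvent]:
    """Direct hydrogen bonds between distinct residues.

    ``donor_set`` / ``acceptor_set`` restrict the search to atom indices;
    by default every annotated donor hydrogen and acceptor participates
    (waters excluded unless ``include_water``).
    """
    criteria = criteria or InteractionCriteria()
    atoms = structure.atoms
    hs = donor_set if donor_set is not None else structure.select_role("hbond_hydrogen")
    accs = acceptor_set if acceptor_set is not None else \
        structure.select_role("hbond_acceptor")
    events = []
    for hi in hs:
        h = atoms[hi]
        if "hbond_hydrogen" not in h.roles:
            continue
        if not include_water and _is_water(h):
            continue
        donors = [n for n in structure.neighbors(h.serial) if n.element.upper() != "H"]
        if not donors:
            continue
        donor = donors[0]
        for ai in accs:
            acc = atoms[ai]
            if "hbond_acceptor" not in acc.roles:
                continue
            if not include_water and _is_water(acc):
                continue
            if acc.residue_key == donor.residue_key:
                continue
            if _hbond_geometry_ok(structure, h, acc, criteria.hbond_distance,
                                  criteria.hbond_donor_angle_min,
                                  criteria.hbond_acceptor_angle_min):
                events.append(InteractionEvent(frame_index, "hbond",
                                               donor.describe(), acc.describe()))
    return events


def _ring_centroid_normal(structure: Structure, member_idx: Sequence[int]):
    pos = np.array([structure.atoms[i].position for i in member_idx])
    centroid = pos.mean(axis=0)
    centered = pos - centroid
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return centroid, vt[2]


def detect_pication(structure: Structure, criteria: InteractionCriteria | None = None,
                    frame_index: int = 0) -> list[InteractionEvent]:
    """Charged center within ``pication_distance`` of an aromatic ring centroid."""
    criteria = criteria or InteractionCriteria()
    events = []
    rings = structure.rings()
    for ci in structure.select_role("positive_center"):
        charge = structure.atoms[ci]
        for ring_id, members in rings.items():
            ring_res = structure.atoms[members[0]].residue_key
            if ring_res == charge.residue_key:
                continue
            centroid, _ = _ring_centroid_normal(structure, members)
            if np.linalg.norm(charge.position - centroid) <= \
                    criteria.pication_distance + _EPS_D:
                ring_desc = structure.atoms[members[0]].describe_residue() + \
                    f"/ring{ring_id}"
                events.append(InteractionEvent(frame_index, "pication",
                                               charge.describe(), ring_desc))
    return events


def detect_pipi(structure: Structure, criteria: InteractionCriteria | None = None,
                frame_index: int = 0) -> list[InteractionEvent]:
    """Aromatic stacking, classified face-to-face or edge-to-face.

    The interplanar angle is folded to [0, 90] deg (ring normals have no
    preferred sign).
    """
    criteria = criteria or InteractionCriteria()
    events = []
    rings = structure.rings()
    ring_ids = sorted(rings)
    lo, hi = criteria.pipi_e2f_angle_window
    folded_lo = min(lo, 180.0 - hi)  # window folded onto [0, 90]
    for i, ra in enumerate(ring_ids):
        for rb in ring_ids[i + 1:]:
            res_a = structure.atoms[rings[ra][0]].residue_key
            res_b = structure.atoms[rings[rb][0]].residue_key
            if res_a == res_b:
                continue
            ca, na = _ring_centroid_normal(structure, rings[ra])
            cb, nb = _ring_centroid_normal(structure, rings[rb])
            d = float(np.linalg.norm(ca - cb))
            angle = float(np.degrees(np.arccos(np.clip(abs(np.dot(na, nb)), 0, 1))))
            geometry = None
            if d <= criteria.pipi_f2f_centroid_max + _EPS_D and \
                    angle <= criteria.pipi_f2f_angle_max + _EPS_A:
                geometry = "face_to_face"
            elif d <= criteria.pipi_e2f_centroid_max + _EPS_D and \
                    angle >= folded_lo - _EPS_A:
                geometry = "edge_to_face"
            if geometry:
                desc_a = structure.atoms[rings[ra][0]].describe_residue() + f"/ring{ra}"
                desc_b = structure.atoms[rings[rb][0]].describe_residue() + f"/ring{rb}"
                events.append(InteractionEvent(frame_index, "pipi", desc_a, desc_b,
                                               geometry=geometry))
    return events


def detect_waterbridge(structure: Structure,
                       criteria: InteractionCriteria | None = None,
                       frame_index: int = 0) -> list[InteractionEvent]:
    """One water simultaneously H-bonded (relaxed criteria) to a ligand atom
    and a protein atom; one event per (ligand partner, protein partner, water)."""
    criteria = criteria or InteractionCriteria()
    atoms = structure.atoms
    waters: dict[tuple, dict] = {}
    for i, a in enumerate(atoms):
        if "water_oxygen" in a.roles:
            waters.setdefault(a.residue_key, {})["O"] = i
        elif "water_hydrogen" in a.roles:
            waters.setdefault(a.residue_key, {}).setdefault("H", []).append(i)

    def water_partners(wrec):
        """Non-water atoms H-bonded to this water under relaxed criteria."""
        partners = []
        o = atoms[wrec["O"]]
        # water as donor
        for hi in wrec.get("H", []):
            h = atoms[hi]
            for ai in structure.select_role("hbond_acceptor"):
                acc = atoms[ai]
                if _is_water(acc):
                    continue
                if _hbond_geometry_ok(structure, h, acc,
                                      criteria.waterbridge_distance,
                                      criteria.waterbridge_donor_angle_min,
                                      criteria.waterbridge_acceptor_angle_min):
                    partners.append(acc)
        # water as acceptor
        for hi in structure.select_role("hbond_hydrogen"):
            h = atoms[hi]
            if _is_water(h):
                continue
            if _hbond_geometry_ok(structure, h, o, criteria.waterbridge_distance,
                                  criteria.waterbridge_donor_angle_min,
                                  criteria.waterbridge_acceptor_angle_min):
                donors = [n for n in structure.neighbors(h.serial)
                          if n.element.upper() != "H"]
                if donors:
                    partners.append(donors[0])
        return partners

    events = []
    for wkey, wrec in sorted(waters.items()):
        if "O" not in wrec:
            continue
        partners = water_partners(wrec)
        lig = [p for p in partners if "ligand" in p.roles]
        prot = [p for p in partners if "ligand" not in p.roles]
        water_desc = f"{wkey[0]}/{wkey[2]}{wkey[1]}"
        seen = set()
        for pl in lig:
            for pp in prot:
                key = (pl.serial, pp.serial)
                if key in seen:
                    continue
                seen.add(key)
                events.append(InteractionEvent(frame_index, "waterbridge",
                                               pl.describe(), pp.describe(),
                                               bridging_water=water_desc))
    return events


def detect_saltbridge(structure: Structure,
                      criteria: InteractionCriteria | None = None,
                      frame_index: int = 0) -> list[InteractionEvent]:
    """Charged-group N/O heavy-atom pair within ``saltbridge_distance``."""
    criteria = criteria or InteractionCriteria()
    atoms = structure.atoms
    events = []
    for pi in structure.select_role("positive_center"):
        pos_atom = atoms[pi]
        for ni in structure.select_role("negative_center"):
            neg_atom = atoms[ni]
            if pos_atom.residue_key == neg_atom.residue_key:
                continue
            d = np.linalg.norm(pos_atom.position - neg_atom.position)
            if d <= criteria.saltbridge_distance + _EPS_D:
                events.append(InteractionEvent(frame_index, "saltbridge",
                                               pos_atom.describe(),
                                               neg_atom.describe()))
    return events


_DETECTORS = {
    "hbond": detect_hbonds,
    "pication": detect_pication,
    "pipi": detect_pipi,
    "waterbridge": detect_waterbridge,
    "saltbridge": detect_saltbridge,
}


def detect_all(structure: Structure, criteria: InteractionCriteria | None = None,
               frame_index: int = 0,
               kinds: Sequence[str] = ("hbond", "pication", "pipi", "waterbridge",
                                       "saltbridge")) -> list[InteractionEvent]:
    events = []
    for kind in kinds:
        events.extend(_DETECTORS[kind](structure, criteria, frame_index=frame_index))
    return events


def trajectory_events(trajectory, criteria: InteractionCriteria | None = None,
                      kinds: Sequence[str] = ("hbond", "pication", "pipi",
                                              "waterbridge", "saltbridge")
                      ) -> list[InteractionEvent]:
    events = []
    for i, frame in trajectory.iter_frames():
        events.extend(detect_all(frame, criteria, frame_index=i, kinds=kinds))
    return events


def _residue_part(descriptor: str) -> str:
    parts = descriptor.split("/")
    return "/".join(parts[:2]) if len(parts) >= 2 else descriptor


def tabulate_frequencies(events: Sequence[InteractionEvent], n_frames: int,
                         min_frequency: float | None = None,
                         by_residue: bool = True) -> pd.DataFrame:
    """Interaction frequency table: one row per (kind, partner pair).

    Multiple events of one kind between the same pair in one frame collapse
    to a single observation.  ``min_frequency`` filters strictly (a pair at
    exactly the threshold is dropped), matching the convention that only
    interactions above the threshold are reported.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    frames_seen: dict[tuple, set[int]] = {}
    for ev in events:
        pa = _residue_part(ev.partner_a) if by_residue else ev.partner_a
        pb = _residue_part(ev.partner_b) if by_residue else ev.partner_b
        key = (ev.kind, *sorted((pa, pb)))
        frames_seen.setdefault(key, set()).add(ev.frame_index)
    rows = []
    for (kind, pa, pb), frames in sorted(frames_seen.items()):
        n_obs = len(frames)
        rows.append({"kind": kind, "partner_a": pa, "partner_b": pb,
                     "n_obs": n_obs, "n_total": n_frames,
                     "frequency": n_obs / n_frames})
    table = pd.DataFrame(rows, columns=["kind", "partner_a", "partner_b",
                                        "n_obs", "n_total", "frequency"])
    if min_frequency is not None and len(table):
        table = table[table["frequency"] > min_frequency].reset_index(drop=True)
    return table
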