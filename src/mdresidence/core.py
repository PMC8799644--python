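"""Structures, trajectories, atom annotation and geometric primitives.

Every analysis stage in this package operates on annotated atomic
coordinates.  The central types are :class:`AtomRecord` (one atom with its
chemical roles), :class:`Structure` (an ordered atom collection with
connectivity) and :class:`Trajectory` (frames sharing one topology,
analysed at a fixed stride, 1 ns by default).

Coordinates are in Angstrom throughout.  Distance criteria are inclusive
at the cutoff value.  Residue numbering follows the input PDB verbatim so
that residues like Met109 or Thr175 keep their crystallographic numbers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml
from scipy.spatial import cKDTree

__all__ = [
    "AtomRecord",
    "Structure",
    "Trajectory",
    "PDBParseError",
    "load_structure",
    "write_structure",
    "load_trajectory",
    "write_xyz_trajectory",
    "read_xyz_trajectory",
    "superpose",
    "kabsch",
    "rmsd",
    "measure_ca_distance",
    "mean_ca_distance",
    "default_core_selection",
    "BONDI_RADII",
]

# Bondi van der Waals radii (Angstrom).  A fixed internal table keeps
# surface areas bit-for-bit reproducible across machines.
BONDI_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "K": 2.75, "NA": 2.27, "MG": 1.73, "ZN": 1.39, "SE": 1.90,
}
_DEFAULT_RADIUS = 1.70

WATER_RESNAMES = {"HOH", "WAT", "SPC", "T3P"}

BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT", "H", "H1", "H2", "H3", "HA", "HA2", "HA3"}

# Aromatic ring member names per standard residue.
_RING_TEMPLATES = {
    "PHE": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "TYR": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "TRP": [["CG", "CD1", "NE1", "CE2", "CD2"],
            ["CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"]],
    "HIS": [["CG", "ND1", "CD2", "CE1", "NE2"]],
    "HIE": [["CG", "ND1", "CD2", "CE1", "NE2"]],
    "HID": [["CG", "ND1", "CD2", "CE1", "NE2"]],
}

_POSITIVE_CENTERS = {"LYS": {"NZ"}, "ARG": {"NH1", "NH2", "NE"}, "HIP": {"ND1", "NE2"}}
_NEGATIVE_CENTERS = {"GLU": {"OE1", "OE2"}, "ASP": {"OD1", "OD2"}}


class PDBParseError(ValueError):
    """Raised for malformed PDB records; carries the offending line number."""


@dataclass
class AtomRecord:
    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain: str
    position: np.ndarray
    vdw_radius: float = 0.0
    roles: set = field(default_factory=set)
    ring_id: int | None = None

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.vdw_radius <= 0.0:
            self.vdw_radius = BONDI_RADII.get(self.element.upper(), _DEFAULT_RADIUS)

    @property
    def residue_key(self):
        return (self.chain, self.residue_number, self.residue_name)

    def describe(self) -> str:
        return f"{self.chain}/{self.residue_name}{self.residue_number}/{self.name}"

    def describe_residue(self) -> str:
        return f"{self.chain}/{self.residue_name}{self.residue_number}"


class Structure:
    """Ordered atom collection with connectivity and role annotation."""

    def __init__(self, atoms: Sequence[AtomRecord], bonds: Iterable[tuple[int, int]] = (),
                 title: str = ""):
        self.atoms = list(atoms)
        self.title = title
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            dup = sorted({s for s in serials if serials.count(s) > 1})
            raise ValueError(f"duplicate atom serial(s): {dup[:5]}")
        self._by_serial = {a.serial: i for i, a in enumerate(self.atoms)}
        self.bonds = set()
        for a, b in bonds:
            if a not in self._by_serial or b not in self._by_serial:
                raise ValueError(f"bond references unknown serial ({a}, {b})")
            self.bonds.add((min(a, b), max(a, b)))
        self._neighbors: dict[int, set[int]] = {a.serial: set() for a in self.atoms}
        for a, b in self.bonds:
            self._neighbors[a].add(b)
            self._neighbors[b].add(a)

    # -- basic access -------------------------------------------------
    def __len__(self):
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def set_coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (len(self.atoms), 3):
            raise ValueError(f"coordinate array shape {xyz.shape} does not match "
                             f"{len(self.atoms)} atoms")
        for a, pos in zip(self.atoms, xyz):
            a.position = np.array(pos)

    def with_coords(self, xyz: np.ndarray) -> "Structure":
        new_atoms = [replace(a, position=np.array(p), roles=set(a.roles))
                     for a, p in zip(self.atoms, np.asarray(xyz, dtype=float))]
        return Structure(new_atoms, self.bonds, self.title)

    def copy(self) -> "Structure":
        return self.with_coords(self.coords)

    def atom_by_serial(self, serial: int) -> AtomRecord:
        return self.atoms[self._by_serial[serial]]

    def neighbors(self, serial: int) -> list[AtomRecord]:
        return [self.atom_by_serial(s) for s in sorted(self._neighbors[serial])]

    def index_of(self, serial: int) -> int:
        return self._by_serial[serial]

    # -- selections ---------------------------------------------------
    def select(self, predicate) -> list[int]:
        """Indices of atoms for which ``predicate(atom)`` is true."""
        return [i for i, a in enumerate(self.atoms) if predicate(a)]

    def select_role(self, role: str) -> list[int]:
        return self.select(lambda a: role in a.roles)

    def atom_keys(self) -> dict[tuple, int]:
        """Map (chain, residue_number, name) -> atom index."""
        return {(a.chain, a.residue_number, a.name): i for i, a in enumerate(self.atoms)}

    def residues(self) -> dict[tuple, list[int]]:
        out: dict[tuple, list[int]] = {}
        for i, a in enumerate(self.atoms):
            out.setdefault(a.residue_key, []).append(i)
        return out

    def rings(self) -> dict[int, list[int]]:
        """ring_id -> member atom indices (heavy ring members only)."""
        out: dict[int, list[int]] = {}
        for i, a in enumerate(self.atoms):
            if a.ring_id is not None:
                out.setdefault(a.ring_id, []).append(i)
        return out


@dataclass
class Trajectory:
    """Frames sharing one topology; ``stride_ns`` is the analysis stride."""

    topology: Structure
    xyz: np.ndarray  # (n_frames, n_atoms, 3)
    stride_ns: float = 1.0

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.ndim != 3 or self.xyz.shape[1] != len(self.topology) or \
                self.xyz.shape[2] != 3:
            raise ValueError(f"trajectory shape {self.xyz.shape} inconsistent with "
                             f"{len(self.topology)} topology atoms")
        if self.stride_ns <= 0:
            raise ValueError("stride_ns must be positive")

    @property
    def n_frames(self) -> int:
        return self.xyz.shape[0]

    def __len__(self):
        return self.n_frames

    def frame(self, i: int) -> Structure:
        return self.topology.with_coords(self.xyz[i])

    def iter_frames(self):
        for i in range(self.n_frames):
            yield i, self.frame(i)


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def _parse_pdb_line(line: str, lineno: int) -> AtomRecord:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        resname = line[17:20].strip()
        chain = line[21].strip() or "A"
        resnum = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"line {lineno}: malformed ATOM/HETATM record: {exc}") from exc
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        # fall back to the atom-name convention: first alphabetic character
        stripped = name.lstrip("0123456789")
        element = stripped[:1].upper() if stripped else "C"
        if stripped[:2].upper() in BONDI_RADII and len(stripped) > 1:
            element = stripped[:2].upper()
    return AtomRecord(serial=serial, name=name, element=element,
                      residue_name=resname, residue_number=resnum, chain=chain,
                      position=np.array([x, y, z]))


def _infer_bonds(atoms: list[AtomRecord]) -> set[tuple[int, int]]:
    """Distance-based covalent connectivity (H: 1.25 A; heavy: 1.95/2.1 A)."""
    coords = np.array([a.position for a in atoms])
    if len(atoms) < 2:
        return set()
    tree = cKDTree(coords)
    bonds = set()
    pairs = tree.query_pairs(2.10)
    for i, j in pairs:
        ai, aj = atoms[i], atoms[j]
        d = np.linalg.norm(ai.position - aj.position)
        hi = ai.element.upper() == "H"
        hj = aj.element.upper() == "H"
        if hi and hj:
            continue
        if hi or hj:
            limit = 1.25
        elif "S" in (ai.element.upper(), aj.element.upper()):
            limit = 2.10
        else:
            limit = 1.95
        # never bond across different molecules of solvent
        if ai.residue_key != aj.residue_key and (
                ai.residue_name in WATER_RESNAMES or aj.residue_name in WATER_RESNAMES):
            continue
        if d <= limit:
            bonds.add((min(ai.serial, aj.serial), max(ai.serial, aj.serial)))
    return bonds


_STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "HID", "HIE",
    "HIP", "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


def _check_ring_planarity(atoms: list[AtomRecord], idx: list[int], tol: float = 0.15):
    pos = np.array([atoms[i].position for i in idx])
    centered = pos - pos.mean(axis=0)
    _, s, _ = np.linalg.svd(centered, full_matrices=False)
    rms_out = s[-1] / np.sqrt(len(idx))
    if rms_out > tol:
        raise ValueError(
            f"aromatic ring through {atoms[idx[0]].describe()} is non-planar "
            f"(out-of-plane RMS {rms_out:.3f} A > {tol} A)")


def annotate_roles(structure: Structure, ligand_sidecar: dict | None = None) -> None:
    """Assign chemical roles in place from residue templates.

    Standard amino acids and waters are annotated from templates; HETATM
    residues are annotated from ``ligand_sidecar`` (mapping with keys
    ``roles``: atom name -> list of roles, and ``rings``: list of atom-name
    lists).  Unknown ligands without a sidecar get minimal roles plus a
    warning.
    """
    atoms = structure.atoms
    ring_counter = 0
    residues = structure.residues()

    for reskey, idxs in residues.items():
        chain, resnum, resname = reskey
        names = {atoms[i].name: i for i in idxs}
        is_water = resname in WATER_RESNAMES
        is_protein = resname in _STANDARD_AA

        for i in idxs:
            a = atoms[i]
            el = a.element.upper()
            if is_water:
                if el == "O":
                    a.roles |= {"water_oxygen", "hbond_acceptor", "hbond_donor_heavy",
                                "polar"}
                elif el == "H":
                    a.roles |= {"water_hydrogen", "hbond_hydrogen", "polar"}
                continue
            if is_protein:
                a.roles.add("backbone" if a.name in BACKBONE_NAMES else "sidechain")
            if el in ("N", "O"):
                a.roles.add("polar")
            if el == "H":
                heavies = [n for n in structure.neighbors(a.serial)
                           if n.element.upper() != "H"]
                if heavies and heavies[0].element.upper() in ("N", "O"):
                    a.roles |= {"hbond_hydrogen", "polar"}
                    heavies[0].roles |= {"hbond_donor_heavy", "polar"}
            if el == "O":
                a.roles.add("hbond_acceptor")

        if is_protein:
            # N acceptors: nitrogens with no attached hydrogen (e.g. His NE2/ND1)
            for i in idxs:
                a = atoms[i]
                if a.element.upper() == "N":
                    hs = [n for n in structure.neighbors(a.serial)
                          if n.element.upper() == "H"]
                    if not hs and a.name != "N":
                        a.roles.add("hbond_acceptor")
            for nm in _POSITIVE_CENTERS.get(resname, ()):
                if nm in names:
                    atoms[names[nm]].roles.add("positive_center")
            for nm in _NEGATIVE_CENTERS.get(resname, ()):
                if nm in names:
                    atoms[names[nm]].roles.add("negative_center")
            if "OXT" in names:
                atoms[names["OXT"]].roles.add("negative_center")
                if "O" in names:
                    atoms[names["O"]].roles.add("negative_center")
            for ring_names in _RING_TEMPLATES.get(resname, ()):
                member_idx = [names[n] for n in ring_names if n in names]
                if len(member_idx) >= 5:
                    _check_ring_planarity(atoms, member_idx)
                    for i in member_idx:
                        atoms[i].roles.add("aromatic_ring_member")
                        atoms[i].ring_id = ring_counter
                    ring_counter += 1
        elif not is_water:
            for i in idxs:
                atoms[i].roles.add("ligand")
            if ligand_sidecar is not None:
                role_map = ligand_sidecar.get("roles", {})
                for i in idxs:
                    a = atoms[i]
                    for role in role_map.get(a.name, []):
                        a.roles.add(role)
                    if a.element.upper() in ("N", "O"):
                        a.roles.add("polar")
                    if a.element.upper() == "H":
                        heavies = [n for n in structure.neighbors(a.serial)
                                   if n.element.upper() != "H"]
                        if heavies and heavies[0].element.upper() in ("N", "O"):
                            a.roles |= {"hbond_hydrogen", "polar"}
                            heavies[0].roles.add("hbond_donor_heavy")
                for ring_names in ligand_sidecar.get("rings", []):
                    member_idx = [names[n] for n in ring_names if n in names]
                    if len(member_idx) < 5:
                        raise ValueError(
                            f"sidecar ring {ring_names} has <5 resolvable members")
                    _check_ring_planarity(atoms, member_idx)
                    for i in member_idx:
                        atoms[i].roles.add("aromatic_ring_member")
                        atoms[i].ring_id = ring_counter
                    ring_counter += 1
            else:
                warnings.warn(
                    f"unknown ligand residue {resname} {resnum} without sidecar; "
                    f"roles left minimal", stacklevel=2)
                for i in idxs:
                    a = atoms[i]
                    if a.element.upper() in ("N", "O"):
                        a.roles.add("polar")


def load_structure(path, ligand_sidecar_path=None, infer_connectivity: bool = True
                   ) -> Structure:
    """Read a PDB file into an annotated :class:`Structure`.

    ``ligand_sidecar_path`` points at a small YAML file mapping ligand atom
    names to roles and listing aromatic rings; without it unknown HETATM
    residues keep minimal roles.
    """
    path = Path(path)
    atoms: list[AtomRecord] = []
    conect: set[tuple[int, int]] = set()
    title = ""
    seen_serials: set[int] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec in ("ATOM  ", "HETATM"):
                atom = _parse_pdb_line(line, lineno)
                if atom.serial in seen_serials:
                    raise PDBParseError(
                        f"line {lineno}: duplicate atom serial {atom.serial}")
                seen_serials.add(atom.serial)
                atoms.append(atom)
            elif rec == "TITLE ":
                title += line[10:].strip() + " "
            elif rec == "CONECT":
                fields = line.split()[1:]
                if len(fields) >= 2:
                    base = int(fields[0])
                    for other in fields[1:]:
                        s = int(other)
                        conect.add((min(base, s), max(base, s)))
    bonds = set(conect)
    if infer_connectivity:
        bonds |= _infer_bonds(atoms)
    structure = Structure(atoms, bonds, title.strip() or path.stem)
    sidecar = None
    if ligand_sidecar_path is not None:
        with open(ligand_sidecar_path) as fh:
            sidecar = yaml.safe_load(fh) or {}
    annotate_roles(structure, sidecar)
    return structure


def write_structure(structure: Structure, path) -> None:
    """Write ATOM/HETATM records with standard PDB columns."""
    lines = []
    if structure.title:
        lines.append(f"TITLE     {structure.title}")
    for a in structure.atoms:
        record = "HETATM" if ("ligand" in a.roles or a.residue_name in WATER_RESNAMES
                              or a.residue_name not in _STANDARD_AA) else "ATOM  "
        name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
        x, y, z = a.position
        lines.append(
            f"{record}{a.serial:>5d} {name}{'':1s}{a.residue_name:>3s} "
            f"{a.chain:1s}{a.residue_number:>4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{a.element.upper():>2s}")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Trajectory I/O
# ---------------------------------------------------------------------------

def write_xyz_trajectory(traj: Trajectory, path) -> None:
    """Plain-text multi-frame XYZ dialect used for text fixtures."""
    lines = []
    n = len(traj.topology)
    for i in range(traj.n_frames):
        lines.append(str(n))
        lines.append(f"frame {i} stride_ns {traj.stride_ns}")
        for a, pos in zip(traj.topology.atoms, traj.xyz[i]):
            lines.append(f"{a.element:<2s} {pos[0]:12.5f} {pos[1]:12.5f} {pos[2]:12.5f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_xyz_trajectory(path, topology: Structure, stride_ns: float = 1.0) -> Trajectory:
    lines = Path(path).read_text().splitlines()
    frames = []
    i = 0
    n_atoms = len(topology)
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        if n != n_atoms:
            raise ValueError(f"frame atom count {n} != topology {n_atoms}")
        comment = lines[i + 1]
        if "stride_ns" in comment:
            stride_ns = float(comment.split("stride_ns")[1].split()[0])
        block = lines[i + 2:i + 2 + n]
        xyz = np.array([[float(v) for v in ln.split()[1:4]] for ln in block])
        frames.append(xyz)
        i += 2 + n
    return Trajectory(topology, np.array(frames), stride_ns=stride_ns)


def load_trajectory(path, topology: Structure, topology_path=None,
                    stride_ns: float = 1.0) -> Trajectory:
    """Load frames from XYZ text or binary XTC/DCD (via mdtraj)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".xyz":
        return read_xyz_trajectory(path, topology, stride_ns)
    if suffix in (".xtc", ".dcd"):
        import mdtraj
        if topology_path is None:
            raise ValueError("binary trajectory formats need a topology PDB path")
        mt = mdtraj.load(str(path), top=str(topology_path))
        return Trajectory(topology, mt.xyz * 10.0, stride_ns=stride_ns)  # nm -> A
    raise ValueError(f"unsupported trajectory format: {suffix}")


# ---------------------------------------------------------------------------
# Superposition and distance measurements
# ---------------------------------------------------------------------------

def kabsch(mobile_xyz: np.ndarray, ref_xyz: np.ndarray):
    """Least-squares rigid superposition; returns (rotation, translation, rmsd).

    Applies as ``x @ R.T + t``.
    """
    mobile_xyz = np.asarray(mobile_xyz, dtype=float)
    ref_xyz = np.asarray(ref_xyz, dtype=float)
    if mobile_xyz.shape != ref_xyz.shape or mobile_xyz.shape[0] == 0:
        raise ValueError("superposition needs two equal, non-empty coordinate sets")
    mc = mobile_xyz.mean(axis=0)
    rc = ref_xyz.mean(axis=0)
    a = mobile_xyz - mc
    b = ref_xyz - rc
    h = a.T @ b
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    moved = a @ rot.T
    value = float(np.sqrt(np.mean(np.sum((moved - b) ** 2, axis=1))))
    trans = rc - mc @ rot.T
    return rot, trans, value


def rmsd(a_xyz: np.ndarray, b_xyz: np.ndarray) -> float:
    a_xyz = np.asarray(a_xyz, dtype=float)
    b_xyz = np.asarray(b_xyz, dtype=float)
    return float(np.sqrt(np.mean(np.sum((a_xyz - b_xyz) ** 2, axis=1))))


def _selection_indices(mobile: Structure, reference: Structure,
                       selection: Iterable[tuple] | None):
    mkeys = mobile.atom_keys()
    rkeys = reference.atom_keys()
    if selection is None:
        selection = sorted(set(mkeys) & set(rkeys))
    sel = list(selection)
    if not sel:
        raise ValueError("empty superposition selection")
    midx, ridx = [], []
    for key in sel:
        if key not in mkeys or key not in rkeys:
            raise ValueError(f"selection atom {key} missing from one structure")
        midx.append(mkeys[key])
        ridx.append(rkeys[key])
    return midx, ridx


def superpose(mobile: Structure, reference: Structure,
              selection: Iterable[tuple] | None = None):
    """Superpose ``mobile`` onto ``reference`` over a (chain, resnum, name)
    selection; returns (transformed structure, rmsd over the selection)."""
    midx, ridx = _selection_indices(mobile, reference, selection)
    mob = mobile.coords
    rot, trans, value = kabsch(mob[midx], reference.coords[ridx])
    return mobile.with_coords(mob @ rot.T + trans), value


def default_core_selection(a: Structure, b: Structure,
                           exclude_ranges=((170, 185), (30, 38))):
    """Backbone atoms of residues common to both structures, excluding the
    A-loop (170-185) and G-loop (30-38) by default: a stable reference frame
    against which loop displacements are measured."""
    akeys = set(a.atom_keys())
    bkeys = set(b.atom_keys())
    sel = []
    backbone_core = {"N", "CA", "C", "O"}
    for key in sorted(akeys & bkeys):
        _, resnum, name = key
        if name not in backbone_core:
            continue
        if any(lo <= resnum <= hi for lo, hi in exclude_ranges):
            continue
        sel.append(key)
    return sel


def _find_ca(structure: Structure, residue_number: int, chain: str | None):
    for a in structure.atoms:
        if a.residue_number == residue_number and a.name == "CA":
            if chain is None or a.chain == chain:
                return a
    raise ValueError(f"no CA atom for residue {residue_number}"
                     + (f" in chain {chain}" if chain else ""))


def measure_ca_distance(a: Structure, b: Structure, residue_number: int,
                        chain: str | None = None,
                        selection: Iterable[tuple] | None = None) -> float:
    """Superpose ``b`` onto ``a`` and return the Calpha-Calpha distance for
    one residue (e.g. Thr175 A-loop displacement)."""
    if selection is None:
        selection = default_core_selection(b, a)
    moved, _ = superpose(b, a, selection)
    ca_a = _find_ca(a, residue_number, chain)
    ca_b = _find_ca(moved, residue_number, chain)
    return float(np.linalg.norm(ca_a.position - ca_b.position))


def mean_ca_distance(set_a: Sequence[Structure], set_b: Sequence[Structure],
                     residue_number: int, chain: str | None = None,
                     selection: Iterable[tuple] | None = None) -> float:
    """Average Calpha distance over all cross-pairs of two structure sets."""
    vals = [measure_ca_distance(sa, sb, residue_number, chain, selection)
            for sa in set_a for sb in set_b]
    if not vals:
        raise ValueError("empty structure sets")
    return float(np.mean(vals))
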