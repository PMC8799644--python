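"""Metadynamics collective-variable traces and dissociation counting.

The collective variable is the distance between the mass centers of the
ligand and of the binding-site residues (Val38, Ala51, Leu75, Ile84,
Thr106, Met109 in the kinase application).  A replica counts as fully
dissociated when its CV reaches the threshold (15 A, inclusive) at any
point of the simulation; counts are tabulated per start metastable state
with compound totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import Structure

__all__ = [
    "CVTrace",
    "DissociationTable",
    "DEFAULT_SITE_RESIDUES",
    "compute_cv",
    "classify_dissociation",
    "build_dissociation_table",
    "read_cv_trace",
    "write_cv_trace",
]

DEFAULT_SITE_RESIDUES = (38, 51, 75, 84, 106, 109)

# Standard atomic masses for mass-weighted centroids.
_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
           "P": 30.974, "F": 18.998, "CL": 35.45, "BR": 79.904}


@dataclass
class CVTrace:
    replica_id: str
    start_state: str
    times_ns: np.ndarray
    cv: np.ndarray
    parameters: dict = field(default_factory=lambda: {
        "gaussian_height_kcal": 0.2, "deposition_interval_ps": 1.0,
        "width_angstrom": 0.03, "wall_angstrom": 35.0, "ktemp": 3.4})

    def __post_init__(self):
        self.times_ns = np.asarray(self.times_ns, dtype=float)
        self.cv = np.asarray(self.cv, dtype=float)
        if self.times_ns.shape != self.cv.shape:
            raise ValueError("time and CV series differ in length")
        if len(self.times_ns) and np.any(np.diff(self.times_ns) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.cv < 0):
            raise ValueError("CV distances cannot be negative")


def _mass(atom) -> float:
    return _MASSES.get(atom.element.upper(), 12.011)


def compute_cv(frame: Structure, ligand_indices: Sequence[int],
               site_residues: Sequence[int] = DEFAULT_SITE_RESIDUES,
               chain: str | None = None) -> float:
    """Distance between mass-weighted centroids of the ligand and the
    binding-site residues (all atoms of the listed residues)."""
    atoms = frame.atoms
    if not ligand_indices:
        raise ValueError("empty ligand selection")
    lig_pos = np.array([atoms[i].position for i in ligand_indices])
    lig_m = np.array([_mass(atoms[i]) for i in ligand_indices])
    site_idx = []
    for resnum in site_residues:
        found = [i for i, a in enumerate(atoms)
                 if a.residue_number == resnum and "ligand" not in a.roles and
                 a.residue_name not in ("HOH", "WAT", "SPC", "T3P") and
                 (chain is None or a.chain == chain)]
        if not found:
            raise ValueError(f"binding-site residue {resnum} missing from frame")
        site_idx.extend(found)
    site_pos = np.array([atoms[i].position for i in site_idx])
    site_m = np.array([_mass(atoms[i]) for i in site_idx])
    com_lig = (lig_pos * lig_m[:, None]).sum(axis=0) / lig_m.sum()
    com_site = (site_pos * site_m[:, None]).sum(axis=0) / site_m.sum()
    return float(np.linalg.norm(com_lig - com_site))


def classify_dissociation(trace: CVTrace, threshold: float = 15.0) -> str:
    """'dissociated' iff the CV reached the threshold (inclusive) at any
    time, else 'bound'."""
    if len(trace.cv) == 0:
        raise ValueError("empty CV trace")
    return "dissociated" if float(trace.cv.max()) >= threshold else "bound"


@dataclass
class DissociationTable:
    table: pd.DataFrame  # columns: state, dissociated, bound
    threshold: float

    @property
    def totals(self) -> tuple[int, int]:
        return (int(self.table["dissociated"].sum()),
                int(self.table["bound"].sum()))

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        total = pd.DataFrame([{"state": "total",
                               "dissociated": self.totals[0],
                               "bound": self.totals[1]}])
        pd.concat([out, total], ignore_index=True).to_csv(path, sep="\t",
                                                          index=False)


def build_dissociation_table(traces: Sequence[CVTrace],
                             threshold: float = 15.0,
                             expected_per_state: int | None = None
                             ) -> DissociationTable:
    """Per-start-state dissociated/bound counts plus totals."""
    if not traces:
        raise ValueError("no traces given")
    counts: dict[str, list[int]] = {}
    for tr in traces:
        rec = counts.setdefault(tr.start_state, [0, 0])
        if classify_dissociation(tr, threshold) == "dissociated":
            rec[0] += 1
        else:
            rec[1] += 1
    rows = [{"state": state, "dissociated": d, "bound": b}
            for state, (d, b) in sorted(counts.items())]
    df = pd.DataFrame(rows)
    if expected_per_state is not None:
        off = df[(df["dissociated"] + df["bound"]) != expected_per_state]
        if len(off):
            import warnings
            warnings.warn(f"states with unexpected replica counts: "
                          f"{list(off['state'])}", stacklevel=2)
    return DissociationTable(table=df, threshold=threshold)


# ---------------------------------------------------------------------------
# Trace file dialect: two columns (time_ns, cv_angstrom), '#' comments,
# tolerant of a non-numeric header line.
# ---------------------------------------------------------------------------

def read_cv_trace(path, replica_id: str | None = None,
                  start_state: str = "") -> CVTrace:
    times, cvs = [], []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        try:
            t, v = float(parts[0]), float(parts[1])
        except (ValueError, IndexError):
            continue  # tolerate header lines
        times.append(t)
        cvs.append(v)
    if not times:
        raise ValueError(f"no data rows in CV trace {path}")
    return CVTrace(replica_id=replica_id or Path(path).stem,
                   start_state=start_state, times_ns=np.array(times),
                   cv=np.array(cvs))


def write_cv_trace(trace: CVTrace, path) -> None:
    lines = [f"# replica {trace.replica_id} start_state {trace.start_state}",
             "# time_ns cv_angstrom"]
    lines += [f"{t:.6f} {v:.6f}" for t, v in zip(trace.times_ns, trace.cv)]
    Path(path).write_text("\n".join(lines) + "\n")
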