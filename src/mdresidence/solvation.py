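"""Per-residue sidechain water-exposure traces.

A residue is solvent exposed in a frame when at least one water molecule
lies within the cutoff (3 A by default) of any sidechain heavy atom;
proximity is measured from the water oxygen and counting is per water
molecule, not per contact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import Structure, Trajectory

__all__ = ["ExposureTrace", "count_waters_near_sidechain", "exposure_trace"]


@dataclass
class ExposureTrace:
    residue: tuple  # (chain, residue_number, residue_name)
    cutoff: float
    water_counts: list = field(default_factory=list)

    @property
    def exposed(self) -> list:
        return [c >= 1 for c in self.water_counts]

    @property
    def exposure_fraction(self) -> float:
        return float(np.mean(self.exposed)) if self.water_counts else 0.0

    @property
    def median_count(self) -> float:
        return float(np.median(self.water_counts)) if self.water_counts else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frame": range(len(self.water_counts)),
                             "count": self.water_counts,
                             "exposed": self.exposed})


def _sidechain_heavy(structure: Structure, residue_key) -> np.ndarray:
    idx = [i for i, a in enumerate(structure.atoms)
           if a.residue_key == residue_key and "sidechain" in a.roles and
           a.element.upper() != "H"]
    if not idx:
        chain, num, name = residue_key
        raise ValueError(f"residue {name}{num} chain {chain} has no sidechain "
                         f"heavy atoms")
    return np.array([structure.atoms[i].position for i in idx])


def count_waters_near_sidechain(frame: Structure, residue_key,
                                cutoff: float = 3.0) -> int:
    """Distinct water molecules with oxygen within ``cutoff`` (inclusive) of
    any sidechain heavy atom of the residue."""
    side = _sidechain_heavy(frame, residue_key)
    w_idx = frame.select_role("water_oxygen")
    if not w_idx:
        return 0
    waters = np.array([frame.atoms[i].position for i in w_idx])
    tree = cKDTree(side)
    d, _ = tree.query(waters, k=1)
    return int(np.sum(d <= cutoff + 1e-12))


def exposure_trace(trajectory: Trajectory, residues: Sequence,
                   cutoff: float = 3.0) -> dict:
    """Exposure traces for the requested residues.

    ``residues`` entries may be full residue keys (chain, number, name) or
    (chain, number) pairs, which are resolved against the topology.
    """
    keymap = {}
    for a in trajectory.topology.atoms:
        keymap[(a.chain, a.residue_number)] = a.residue_key
    resolved = []
    for r in residues:
        if len(r) == 3:
            resolved.append(tuple(r))
        else:
            if tuple(r) not in keymap:
                raise ValueError(f"residue {r} not found in topology")
            resolved.append(keymap[tuple(r)])
    traces = {key: ExposureTrace(residue=key, cutoff=cutoff) for key in resolved}
    for _, frame in trajectory.iter_frames():
        for key in resolved:
            traces[key].water_counts.append(
                count_waters_near_sidechain(frame, key, cutoff))
    return traces
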