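"""Contact/non-contact hydropathy averaging over structural segment pairs.

A residue of one segment part is "in contact" with the opposite part when
any of its atoms lies within a distance cutoff (4.5 Å by default) of any
atom of that part.  For each part, the mean hydropathy score of its contact
residues and of its non-contact residues summarises whether the interface
is held together by hydrophobic burial.

Two standard per-residue scales are bundled:

* Kyte–Doolittle (1982, J. Mol. Biol. 157:105) — signed; negative values
  indicate hydrophilicity, positive hydrophobicity.
* Black–Mould (1991, Anal. Biochem. 193:72) — hydrophobic propensity
  normalised to [0, 1]; non-negative by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .model import Trajectory, Topology

__all__ = [
    "HydropathyScale",
    "SegmentPair",
    "PartHydropathy",
    "KYTE_DOOLITTLE",
    "BLACK_MOULD",
    "get_scale",
    "contact_residues",
    "segment_hydropathy",
    "TOP7_SEGMENTS",
]

_KD_SCORES = {
    "ILE": 4.5, "VAL": 4.2, "LEU": 3.8, "PHE": 2.8, "CYS": 2.5,
    "MET": 1.9, "ALA": 1.8, "GLY": -0.4, "THR": -0.7, "SER": -0.8,
    "TRP": -0.9, "TYR": -1.3, "PRO": -1.6, "HIS": -3.2, "GLU": -3.5,
    "GLN": -3.5, "ASP": -3.5, "ASN": -3.5, "LYS": -3.9, "ARG": -4.5,
}

_BM_SCORES = {
    "ALA": 0.616, "ARG": 0.000, "ASN": 0.236, "ASP": 0.028, "CYS": 0.680,
    "GLN": 0.251, "GLU": 0.043, "GLY": 0.501, "HIS": 0.165, "ILE": 0.943,
    "LEU": 0.943, "LYS": 0.283, "MET": 0.738, "PHE": 1.000, "PRO": 0.711,
    "SER": 0.359, "THR": 0.450, "TRP": 0.878, "TYR": 0.880, "VAL": 0.825,
}


@dataclass(frozen=True)
class HydropathyScale:
    name: str
    scores: Mapping[str, float]

    def score(self, residue_name: str) -> float:
        try:
            return self.scores[residue_name.upper()]
        except KeyError:
            raise KeyError(
                f"residue name {residue_name!r} not covered by hydropathy "
                f"scale {self.name!r}"
            ) from None


KYTE_DOOLITTLE = HydropathyScale("kyte_doolittle", _KD_SCORES)
BLACK_MOULD = HydropathyScale("black_mould", _BM_SCORES)


def get_scale(name: str) -> HydropathyScale:
    scales = {s.name: s for s in (KYTE_DOOLITTLE, BLACK_MOULD)}
    if name not in scales:
        raise KeyError(f"unknown hydropathy scale {name!r}; choose from {sorted(scales)}")
    return scales[name]


#: Secondary-structure segments of the Top7 fold (inclusive author ids):
#: five β-strands and two α-helices.
TOP7_SEGMENTS = {
    "strand1": (3, 12),
    "strand2": (15, 25),
    "helix1": (26, 45),
    "strand3": (46, 55),
    "helix2": (56, 75),
    "strand4": (76, 85),
    "strand5": (86, 94),
}


@dataclass(frozen=True)
class SegmentPair:
    """Two disjoint residue-id sets whose interface is analysed."""

    name: str
    part_a: frozenset[int]
    part_b: frozenset[int]

    def __post_init__(self) -> None:
        if not self.part_a or not self.part_b:
            raise ValueError(f"segment pair {self.name!r} has an empty part")
        if self.part_a & self.part_b:
            raise ValueError(f"segment pair {self.name!r} parts overlap")

    @staticmethod
    def from_ranges(
        name: str,
        ranges_a: Sequence[tuple[int, int]],
        ranges_b: Sequence[tuple[int, int]],
    ) -> "SegmentPair":
        expand = lambda rs: frozenset(r for lo, hi in rs for r in range(lo, hi + 1))
        return SegmentPair(name, expand(ranges_a), expand(ranges_b))


def _part_atom_indices(
    top: Topology, part: frozenset[int], include_hydrogens: bool
) -> np.ndarray:
    idx: list[int] = []
    for rid in sorted(part):
        res = top.residue_index_of_id(rid)
        atoms = top.atom_indices_of_residue(res)
        if not include_hydrogens:
            atoms = atoms[~top.is_hydrogen[atoms]]
        idx.extend(int(a) for a in atoms)
    return np.array(idx, dtype=int)


def contact_residues(
    trajectory: Trajectory,
    frame: int,
    pair: SegmentPair,
    cutoff_A: float = 4.5,
    include_hydrogens: bool = False,
) -> tuple[set[int], set[int]]:
    """Residues of each part within ``cutoff_A`` of any atom of the other.

    Any-atom rule: a residue is in contact as soon as one of its (heavy,
    by default) atoms is within the cutoff of the opposite part.
    """
    if cutoff_A <= 0:
        raise ValueError("cutoff must be positive")
    top = trajectory.topology
    x = trajectory.coords[frame]

    def contacts(part: frozenset[int], other_atoms: np.ndarray) -> set[int]:
        out = set()
        for rid in part:
            atoms = _part_atom_indices(top, frozenset([rid]), include_hydrogens)
            d = np.linalg.norm(x[atoms][:, None, :] - x[other_atoms][None, :, :], axis=-1)
            if d.min() <= cutoff_A:
                out.add(rid)
        return out

    atoms_a = _part_atom_indices(top, pair.part_a, include_hydrogens)
    atoms_b = _part_atom_indices(top, pair.part_b, include_hydrogens)
    return contacts(pair.part_a, atoms_b), contacts(pair.part_b, atoms_a)


@dataclass
class PartHydropathy:
    """Mean hydropathy of contact and non-contact residues of one part.

    Means over an empty residue set are undefined and reported as ``None``,
    never as zero.
    """

    part: str
    n_contact: int
    contact_mean: float | None
    n_noncontact: int
    noncontact_mean: float | None


def segment_hydropathy(
    pair: SegmentPair,
    contacts: tuple[set[int], set[int]],
    scale: HydropathyScale,
    topology: Topology,
) -> dict[str, PartHydropathy]:
    """Contact/non-contact mean scores per part plus the pooled means."""

    def resname(rid: int) -> str:
        return topology.residue_name(topology.residue_index_of_id(rid))

    def mean_of(rids: set[int]) -> float | None:
        if not rids:
            return None
        return float(np.mean([scale.score(resname(r)) for r in sorted(rids)]))

    out: dict[str, PartHydropathy] = {}
    pooled_contact: set[int] = set()
    pooled_non: set[int] = set()
    for label, part, contact in (
        ("a", pair.part_a, contacts[0]),
        ("b", pair.part_b, contacts[1]),
    ):
        non = set(part) - contact
        pooled_contact |= contact
        pooled_non |= non
        out[label] = PartHydropathy(
            part=label,
            n_contact=len(contact),
            contact_mean=mean_of(contact),
            n_noncontact=len(non),
            noncontact_mean=mean_of(non),
        )
    out["pooled"] = PartHydropathy(
        part="pooled",
        n_contact=len(pooled_contact),
        contact_mean=mean_of(pooled_contact),
        n_noncontact=len(pooled_non),
        noncontact_mean=mean_of(pooled_non),
    )
    return out
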