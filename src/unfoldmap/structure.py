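"""Conventional trajectory analyses: hydrogen bonds, water shells, angles.

Hydrogen bonds use the geometric criterion of common visualisation tools:
a donor–acceptor heavy-atom distance within a cutoff (3.5 Å by default)
and a donor–hydrogen–acceptor angle within a tolerance of linearity
(45° from 180° by default).  Donors are N/O heavy atoms with a covalently
attached hydrogen (attachment inferred by a D–H distance below 1.2 Å when
no bond table is available); acceptors are N/O heavy atoms.

Water-shell occupancy counts water oxygens within a radius of any atom of
the listed residues; triplet angles are measured at the middle residue's
Cα; and a centred moving average (window 11 by default, shrinking at the
edges) provides the low-pass filtering applied to count series.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .model import Trajectory, Topology, WATER_OXYGEN_NAMES

__all__ = [
    "HBondCriteria",
    "HBondSetDef",
    "TripletDef",
    "HBond",
    "detect_hbonds",
    "count_hbonds_series",
    "moving_average",
    "count_waters_near",
    "triplet_angle_series",
    "TOP7_HBOND_SETS",
]

_DONOR_ACCEPTOR_ELEMENTS = frozenset({"N", "O"})
_COVALENT_DH_CUTOFF = 1.2  # Å


@dataclass(frozen=True)
class HBondCriteria:
    da_cutoff_A: float = 3.5
    angle_tolerance_deg: float = 45.0

    def __post_init__(self) -> None:
        if self.da_cutoff_A <= 0:
            raise ValueError("cutoff must be positive")
        if not 0 < self.angle_tolerance_deg < 90:
            raise ValueError("angle tolerance must lie in (0, 90) degrees")


@dataclass(frozen=True)
class HBondSetDef:
    """A named bond set: donor residue in one range, acceptor in the other.

    Membership is orientation-agnostic (β-sheet bonds alternate direction),
    so a bond belongs to the set when its two residues fall one in each
    range, in either order.  Ranges are inclusive author residue ids.
    """

    name: str
    range_a: tuple[int, int]
    range_b: tuple[int, int]

    def contains(self, res_id_1: int, res_id_2: int) -> bool:
        in_a = lambda r: self.range_a[0] <= r <= self.range_a[1]
        in_b = lambda r: self.range_b[0] <= r <= self.range_b[1]
        return (in_a(res_id_1) and in_b(res_id_2)) or (in_a(res_id_2) and in_b(res_id_1))


#: The four β-sheet hydrogen-bond sets of the Top7 fold, by author numbering.
TOP7_HBOND_SETS = (
    HBondSetDef("set1", (3, 12), (15, 25)),
    HBondSetDef("set2", (3, 12), (46, 55)),
    HBondSetDef("set3", (46, 55), (86, 94)),
    HBondSetDef("set4", (76, 85), (86, 94)),
)


@dataclass(frozen=True)
class TripletDef:
    """Three residue ids; the angle is measured at the middle residue's Cα."""

    residues: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(set(self.residues)) != 3:
            raise ValueError("triplet residues must be distinct")


@dataclass(frozen=True)
class HBond:
    donor: int  # atom indices into the topology
    hydrogen: int
    acceptor: int


def _donor_acceptor_atoms(
    top: Topology,
    donors: Callable[[int], bool] | None,
    acceptors: Callable[[int], bool] | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    heavy_no = np.flatnonzero(
        ~top.is_hydrogen & ~top.is_water & np.isin(top.elements, list(_DONOR_ACCEPTOR_ELEMENTS))
    )
    h_idx = np.flatnonzero(top.is_hydrogen & ~top.is_water)
    don = heavy_no if donors is None else np.array([i for i in heavy_no if donors(i)], dtype=int)
    acc = heavy_no if acceptors is None else np.array([i for i in heavy_no if acceptors(i)], dtype=int)
    return don, acc, h_idx


def detect_hbonds(
    trajectory: Trajectory,
    frame: int,
    criteria: HBondCriteria = HBondCriteria(),
    donors: Callable[[int], bool] | None = None,
    acceptors: Callable[[int], bool] | None = None,
) -> list[HBond]:
    """Geometric hydrogen bonds in one frame.

    A (donor, hydrogen, acceptor) triple is reported when the D–A distance
    is within the cutoff and the D–H–A angle deviates from 180° by at most
    the tolerance.  Intra-residue bonds are excluded.  ``donors`` and
    ``acceptors`` are optional predicates on atom indices restricting the
    default N/O selection.
    """
    top = trajectory.topology
    don, acc, h_idx = _donor_acceptor_atoms(top, donors, acceptors)
    if len(h_idx) == 0:
        raise ValueError(
            "topology contains no hydrogens; geometric hydrogen-bond "
            "criteria cannot be evaluated"
        )
    x = trajectory.coords[frame]
    # Covalent D-H attachment by distance.
    h_tree = cKDTree(x[h_idx])
    dh_pairs: list[tuple[int, int]] = []
    for d in don:
        for k in h_tree.query_ball_point(x[d], _COVALENT_DH_CUTOFF):
            dh_pairs.append((int(d), int(h_idx[k])))
    if not dh_pairs or len(acc) == 0:
        return []
    acc_tree = cKDTree(x[acc])
    min_angle = np.deg2rad(180.0 - criteria.angle_tolerance_deg)
    bonds: list[HBond] = []
    for d, h in dh_pairs:
        for k in acc_tree.query_ball_point(x[d], criteria.da_cutoff_A):
            a = int(acc[k])
            if a == d or top.residue_index[a] == top.residue_index[d]:
                continue
            v1 = x[d] - x[h]
            v2 = x[a] - x[h]
            n1 = np.linalg.norm(v1)
            n2 = np.linalg.norm(v2)
            if n1 == 0 or n2 == 0:
                continue
            cosang = np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0)
            if np.arccos(cosang) >= min_angle:
                bonds.append(HBond(donor=d, hydrogen=h, acceptor=a))
    return bonds


def count_hbonds_series(
    trajectory: Trajectory,
    sets: Sequence[HBondSetDef],
    criteria: HBondCriteria = HBondCriteria(),
) -> dict[str, np.ndarray]:
    """Per-frame bond count for every set; a bond may count in several sets."""
    top = trajectory.topology
    counts = {s.name: np.zeros(trajectory.n_frames, dtype=int) for s in sets}
    for t in range(trajectory.n_frames):
        for bond in detect_hbonds(trajectory, t, criteria):
            rd = top.residue_id(int(top.residue_index[bond.donor]))
            ra = top.residue_id(int(top.residue_index[bond.acceptor]))
            for s in sets:
                if s.contains(rd, ra):
                    counts[s.name][t] += 1
    return counts


def moving_average(series: Sequence[float], window: int = 11) -> np.ndarray:
    """Centred moving average with a shrinking window at the edges.

    The window must be odd; output length equals input length.  At position
    t the mean runs over frames t ± (window−1)/2, clipped to the series.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd positive integer")
    x = np.asarray(series, dtype=float)
    kernel = np.ones(window)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def count_waters_near(
    trajectory: Trajectory,
    residue_ids: Sequence[int],
    radius_A: float = 4.0,
) -> tuple[dict[int, np.ndarray], np.ndarray]:
    """Water oxygens within ``radius_A`` of any atom of each listed residue.

    Returns per-residue count series and an aggregate series in which each
    water is counted once even when it is near several listed residues.
    """
    if radius_A <= 0:
        raise ValueError("radius must be positive")
    top = trajectory.topology
    wat_o = np.flatnonzero(top.is_water & np.isin(top.names, list(WATER_OXYGEN_NAMES)))
    if len(wat_o) == 0:
        raise ValueError("topology contains no water oxygens")
    res_atoms = {
        rid: top.atom_indices_of_residue(top.residue_index_of_id(rid))
        for rid in residue_ids
    }
    T = trajectory.n_frames
    per_res = {rid: np.zeros(T, dtype=int) for rid in residue_ids}
    aggregate = np.zeros(T, dtype=int)
    for t in range(T):
        tree = cKDTree(trajectory.coords[t, wat_o])
        seen: set[int] = set()
        for rid, idx in res_atoms.items():
            hits: set[int] = set()
            for a in idx:
                hits.update(tree.query_ball_point(trajectory.coords[t, a], radius_A))
            per_res[rid][t] = len(hits)
            seen.update(hits)
        aggregate[t] = len(seen)
    return per_res, aggregate


def triplet_angle_series(
    trajectory: Trajectory, triplets: Sequence[TripletDef]
) -> dict[tuple[int, int, int], np.ndarray]:
    """Cα angle at the middle residue of each triplet, per frame, in degrees."""
    top = trajectory.topology
    ca_of: dict[int, int] = {}
    for trip in triplets:
        for rid in trip.residues:
            if rid in ca_of:
                continue
            res = top.residue_index_of_id(rid)
            idx = top.atom_indices_of_residue(res)
            ca = idx[top.names[idx] == "CA"]
            if len(ca) == 0:
                raise ValueError(f"residue {rid} has no CA atom")
            ca_of[rid] = int(ca[0])
    out: dict[tuple[int, int, int], np.ndarray] = {}
    for trip in triplets:
        a, b, c = (trajectory.coords[:, ca_of[r]] for r in trip.residues)
        v1 = a - b
        v2 = c - b
        n1 = np.linalg.norm(v1, axis=1)
        n2 = np.linalg.norm(v2, axis=1)
        bad = np.flatnonzero((n1 == 0) | (n2 == 0))
        if len(bad):
            raise ValueError(
                f"undefined angle for triplet {trip.residues} at frame {int(bad[0])}: "
                "coincident points"
            )
        cosang = np.clip((v1 * v2).sum(axis=1) / (n1 * n2), -1.0, 1.0)
        out[trip.residues] = np.rad2deg(np.arccos(cosang))
    return out
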