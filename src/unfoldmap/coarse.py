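"""Coarse-grained pairwise residue distance time series.

Each protein residue is reduced to a single representative point per frame
(side-chain centroid by default, with a Cα fallback for glycine), and the
Euclidean distance between representatives of every included residue pair
is collected into a ``(P, T)`` array ``X_ij(t)``.  Adjacent pairs up to the
neighbour-exclusion parameter ``excl`` (default 1, i.e. bonded neighbours)
are dropped; an optional finite distance cutoff, evaluated on frame 0,
restricts the pair roster for the whole run.

The absolute forward difference ``|X(t+1) - X(t)|`` of each series is the
rate-of-change input to the activity-based mutual-information heat map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Literal

import numpy as np

from .model import Trajectory

__all__ = [
    "CoarseGrainParams",
    "DistanceSeries",
    "RateSeries",
    "residue_representative",
    "representative_coords",
    "pairwise_distance_series",
    "rate_of_change",
]

Scheme = Literal["side_chain_centroid", "CB_or_CA", "CA"]

# Backbone heavy atoms excluded from the side-chain centroid.
_BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "OXT", "OT1", "OT2"})


@dataclass(frozen=True)
class CoarseGrainParams:
    excl: int = 1
    cutoff: float = math.inf
    scheme: Scheme = "side_chain_centroid"

    def __post_init__(self) -> None:
        if self.excl < 0:
            raise ValueError("excl must be >= 0")
        if not self.cutoff > 0:
            raise ValueError("cutoff must be positive (or infinite)")


@dataclass
class DistanceSeries:
    """Pairwise residue distance series ``X_ij(t)``.

    ``pairs`` holds 0-based protein-residue indices ``(i, j)`` with
    ``i < j``; ``residue_ids`` maps those indices to author numbering.
    """

    pairs: np.ndarray  # (P, 2) int
    values: np.ndarray  # (P, T) float, Å
    residue_ids: np.ndarray  # (n_residues,) author numbering
    frame_dt_ps: float | None = None

    @property
    def n_pairs(self) -> int:
        return self.pairs.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def n_residues(self) -> int:
        return len(self.residue_ids)


@dataclass
class RateSeries:
    """Absolute forward-difference series ``|dX_ij/dt|`` in Å/frame."""

    pairs: np.ndarray
    values: np.ndarray  # (P, T-1), all >= 0
    residue_ids: np.ndarray
    frame_dt_ps: float | None = None

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def n_residues(self) -> int:
        return len(self.residue_ids)


def _residue_atom_groups(trajectory: Trajectory, scheme: Scheme):
    """Per protein residue, the atom indices entering the representative."""
    top = trajectory.topology
    groups: list[np.ndarray] = []
    for res in top.protein_residue_indices:
        idx = top.atom_indices_of_residue(int(res))
        heavy = idx[~top.is_hydrogen[idx]]
        if len(heavy) == 0:
            raise ValueError(
                f"residue {top.residue_name(int(res))} {top.residue_id(int(res))} "
                "has no heavy atoms"
            )
        names = top.names[heavy]
        ca = heavy[names == "CA"]
        if scheme == "CA":
            chosen = ca
        elif scheme == "CB_or_CA":
            cb = heavy[names == "CB"]
            chosen = cb if len(cb) else ca
        else:  # side_chain_centroid
            side = heavy[~np.isin(names, list(_BACKBONE_NAMES))]
            chosen = side if len(side) else ca
        if len(chosen) == 0:
            # No Cα to fall back on: use all heavy atoms rather than fail.
            chosen = heavy
        groups.append(chosen)
    return groups


def representative_coords(trajectory: Trajectory, scheme: Scheme = "side_chain_centroid") -> np.ndarray:
    """Representative point of every protein residue in every frame.

    Returns a ``(T, n_residues, 3)`` array.
    """
    groups = _residue_atom_groups(trajectory, scheme)
    T = trajectory.n_frames
    reps = np.empty((T, len(groups), 3))
    for r, idx in enumerate(groups):
        reps[:, r, :] = trajectory.coords[:, idx, :].mean(axis=1)
    return reps


def residue_representative(trajectory: Trajectory, frame: int, scheme: Scheme = "side_chain_centroid") -> np.ndarray:
    """Representative point of every protein residue in one frame."""
    if not 0 <= frame < trajectory.n_frames:
        raise IndexError(f"frame {frame} out of range [0, {trajectory.n_frames})")
    groups = _residue_atom_groups(trajectory, scheme)
    reps = np.empty((len(groups), 3))
    for r, idx in enumerate(groups):
        reps[r] = trajectory.coords[frame, idx, :].mean(axis=0)
    return reps


def pairwise_distance_series(
    trajectory: Trajectory, params: CoarseGrainParams = CoarseGrainParams()
) -> DistanceSeries:
    """Distance series for every residue pair with ``j - i > excl``.

    With a finite cutoff, the pair roster is fixed on frame 0 (pairs whose
    frame-0 distance exceeds the cutoff are dropped for the whole run).
    """
    reps = representative_coords(trajectory, params.scheme)
    n = reps.shape[1]
    if n < 2:
        raise ValueError("need at least two protein residues")
    pairs = np.array(
        [(i, j) for i, j in combinations(range(n), 2) if j - i > params.excl],
        dtype=int,
    ).reshape(-1, 2)
    if math.isfinite(params.cutoff) and len(pairs):
        d0 = np.linalg.norm(reps[0, pairs[:, 0]] - reps[0, pairs[:, 1]], axis=-1)
        pairs = pairs[d0 <= params.cutoff]
    diffs = reps[:, pairs[:, 0], :] - reps[:, pairs[:, 1], :]  # (T, P, 3)
    values = np.linalg.norm(diffs, axis=-1).T  # (P, T)
    top = trajectory.topology
    residue_ids = top.residue_ids[top.protein_residue_indices]
    return DistanceSeries(
        pairs=pairs,
        values=values,
        residue_ids=residue_ids,
        frame_dt_ps=trajectory.frame_dt_ps,
    )


def rate_of_change(series: DistanceSeries) -> RateSeries:
    """Absolute forward difference per pair; output length is T−1."""
    if series.n_frames < 2:
        raise ValueError("rate of change requires at least two frames")
    values = np.abs(np.diff(series.values, axis=1))
    return RateSeries(
        pairs=series.pairs,
        values=values,
        residue_ids=series.residue_ids,
        frame_dt_ps=series.frame_dt_ps,
    )
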