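"""Synthetic trajectories and geometric fixtures with planted structure.

No forced-unfolding trajectory of the real protein is publicly archived,
so the pipeline is exercised on generated data whose ground truth is known
exactly.  :func:`make_unfolding_trajectory` emulates the phenomenology of a
constant-velocity pulling run: a chain of pseudo-residues (one "CA" plus
one "CB" side-chain atom each, 1.5 Å off the backbone) partitioned into
rigid segments, where every segment at or downstream of a *responsive*
boundary translates along a separation axis by a planted ramp (linear by
default — constant-velocity pulling — or sigmoid), on top of i.i.d.
Gaussian thermal jitter.  All residue pairs spanning a responsive boundary
are recorded in :class:`PlantedTruth` together with the exact ramp series.

The fixtures are geometric, not physical: there is no force field, no
excluded volume during the ramp, and the jitter is white, not an
Ornstein–Uhlenbeck process.

Small deterministic fixtures for the hydrogen-bond and water-shell
analyses are also provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .model import Atom, Topology, Trajectory

__all__ = [
    "Segment",
    "SyntheticSpec",
    "PlantedTruth",
    "make_unfolding_trajectory",
    "make_hbond_fixture",
    "make_solvation_fixture",
]

_AA_CYCLE = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

_CB_OFFSET_A = 1.5  # side-chain pseudo-atom offset, perpendicular to the chain


@dataclass(frozen=True)
class Segment:
    """A residue-index range [start, stop) tagged rigid or responsive.

    A *responsive* segment introduces a responsive boundary at its start:
    it and every downstream segment translate by the ramp.
    """

    start: int
    stop: int
    kind: Literal["rigid", "responsive"]

    def __post_init__(self) -> None:
        if self.stop <= self.start:
            raise ValueError(f"empty segment [{self.start}, {self.stop})")
        if self.kind not in ("rigid", "responsive"):
            raise ValueError(f"unknown segment kind {self.kind!r}")


def _default_segments() -> tuple[Segment, ...]:
    return (Segment(0, 25, "rigid"), Segment(25, 50, "responsive"))


@dataclass(frozen=True)
class SyntheticSpec:
    """Full parameterisation of a planted-event trajectory.

    Defaults emulate a single unfolding event: 50 residues, 1000 frames,
    a 20 Å linear ramp separating the second half of the chain from the
    first, and 0.5 Å isotropic thermal jitter per atom per frame.
    """

    n_residues: int = 50
    n_frames: int = 1000
    segments: tuple[Segment, ...] = field(default_factory=_default_segments)
    ramp: Literal["linear", "sigmoid"] = "linear"
    amplitude_A: float = 20.0
    noise_sigma_A: float = 0.5
    separation_axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    seed: int = 0
    frame_dt_ps: float = 0.5

    def __post_init__(self) -> None:
        segs = sorted(self.segments, key=lambda s: s.start)
        if segs[0].start != 0 or segs[-1].stop != self.n_residues:
            raise ValueError("segments must cover [0, n_residues)")
        for a, b in zip(segs, segs[1:]):
            if a.stop != b.start:
                raise ValueError(
                    f"segments must partition the chain; gap/overlap at {a.stop}/{b.start}"
                )
        if not any(s.kind == "responsive" for s in segs):
            raise ValueError("at least one responsive segment is required")
        if self.noise_sigma_A < 0:
            raise ValueError("noise_sigma_A must be >= 0")
        if np.linalg.norm(self.separation_axis) == 0:
            raise ValueError("separation_axis must be non-zero")


@dataclass
class PlantedTruth:
    """Ground truth of a generated trajectory.

    ``responsive_pairs`` holds every 0-based residue-index pair (i < j)
    whose mutual distance depends on the ramp, i.e. every pair spanning a
    responsive boundary; ``order_parameter`` is the exact ramp series (Å).
    """

    responsive_pairs: set[tuple[int, int]]
    order_parameter: np.ndarray


def _ramp_series(spec: SyntheticSpec) -> np.ndarray:
    s = np.linspace(0.0, 1.0, spec.n_frames)
    if spec.ramp == "linear":
        shape = s
    elif spec.ramp == "sigmoid":
        raw = 1.0 / (1.0 + np.exp(-10.0 * (s - 0.5)))
        shape = (raw - raw[0]) / (raw[-1] - raw[0])
    else:
        raise ValueError(f"unknown ramp {spec.ramp!r}")
    return spec.amplitude_A * shape


def _base_chain(n_residues: int) -> tuple[np.ndarray, np.ndarray]:
    """Backbone positions on a gentle self-avoiding helix + CB offsets."""
    i = np.arange(n_residues, dtype=float)
    ca = np.stack([3.0 * i, 1.8 * np.sin(0.8 * i), 1.8 * np.cos(0.8 * i)], axis=1)
    # Tangent by central difference; CB perpendicular to it.
    tang = np.gradient(ca, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    perp = np.cross(tang, np.array([0.0, 0.0, 1.0]))
    norms = np.linalg.norm(perp, axis=1, keepdims=True)
    fallback = np.tile(np.array([0.0, 1.0, 0.0]), (n_residues, 1))
    perp = np.where(norms > 1e-9, perp / np.where(norms == 0, 1, norms), fallback)
    cb = ca + _CB_OFFSET_A * perp
    return ca, cb


def make_unfolding_trajectory(spec: SyntheticSpec = SyntheticSpec()) -> tuple[Trajectory, PlantedTruth]:
    """Generate a planted-unfolding trajectory and its ground truth.

    Deterministic for a fixed spec (bit-identical repeat runs).  With zero
    noise, every rigid-internal pair distance is exactly constant and every
    responsive pair separates monotonically with a monotone ramp.
    """
    segs = sorted(spec.segments, key=lambda s: s.start)
    ramp = _ramp_series(spec)
    axis = np.asarray(spec.separation_axis, dtype=float)
    axis /= np.linalg.norm(axis)

    # Number of responsive boundaries upstream of (and including) each residue.
    level = np.zeros(spec.n_residues, dtype=int)
    bump = 0
    for s in segs:
        if s.kind == "responsive":
            bump += 1
        level[s.start : s.stop] = bump

    ca0, cb0 = _base_chain(spec.n_residues)
    T = spec.n_frames
    coords = np.empty((T, 2 * spec.n_residues, 3))
    disp = ramp[:, None] * axis[None, :]  # (T, 3) per responsive level
    for r in range(spec.n_residues):
        off = level[r] * disp  # stacked boundaries translate cumulatively
        coords[:, 2 * r, :] = ca0[r] + off
        coords[:, 2 * r + 1, :] = cb0[r] + off
    if spec.noise_sigma_A > 0:
        rng = np.random.default_rng(spec.seed)
        coords = coords + rng.normal(0.0, spec.noise_sigma_A, size=coords.shape)

    atoms = []
    for r in range(spec.n_residues):
        res_name = _AA_CYCLE[r % len(_AA_CYCLE)]
        for name in ("CA", "CB"):
            atoms.append(
                Atom(
                    serial=2 * r + (1 if name == "CA" else 2),
                    name=name,
                    element="C",
                    residue_index=r,
                    residue_name=res_name,
                    residue_id=r + 1,
                    chain="A",
                    is_water=False,
                    is_hydrogen=False,
                )
            )
    traj = Trajectory(topology=Topology(atoms), coords=coords, frame_dt_ps=spec.frame_dt_ps)

    responsive_pairs = {
        (i, j)
        for i in range(spec.n_residues)
        for j in range(i + 1, spec.n_residues)
        if level[i] != level[j]
    }
    return traj, PlantedTruth(responsive_pairs=responsive_pairs, order_parameter=ramp)


def make_hbond_fixture(da_distance_A: float, dha_angle_deg: float) -> Trajectory:
    """Single-frame N–H···O geometry with the exact requested parameters.

    The donor nitrogen sits at the origin with its hydrogen 1.0 Å along x;
    the acceptor oxygen is placed so the donor–acceptor distance equals
    ``da_distance_A`` and the D–H–A angle equals ``dha_angle_deg``.
    """
    if da_distance_A <= 1.2:
        raise ValueError("donor-acceptor distance must exceed 1.2 Å")
    if not 0 < dha_angle_deg <= 180:
        raise ValueError("D-H-A angle must lie in (0, 180] degrees")
    theta = np.deg2rad(dha_angle_deg)
    d = np.zeros(3)
    h = np.array([1.0, 0.0, 0.0])
    v = np.array([-np.cos(theta), np.sin(theta), 0.0])  # direction H -> A
    # Solve |h + L v| = da for L > 0.
    b = float(h @ v)
    disc = b * b - 1.0 + da_distance_A**2
    if disc < 0:
        raise ValueError("infeasible hydrogen-bond geometry")
    L = -b + np.sqrt(disc)
    if L <= 0:
        raise ValueError("infeasible hydrogen-bond geometry")
    a = h + L * v
    atoms = [
        Atom(1, "N", "N", 0, "ALA", 1, "A", False, False),
        Atom(2, "H", "H", 0, "ALA", 1, "A", False, True),
        Atom(3, "O", "O", 1, "ALA", 2, "A", False, False),
    ]
    coords = np.array([[d, h, a]])
    return Trajectory(topology=Topology(atoms), coords=coords)


def make_solvation_fixture(
    schedule: Sequence[int], radius_A: float = 4.0, seed: int = 0
) -> Trajectory:
    """Trajectory whose water-shell count series equals ``schedule`` exactly.

    One protein residue sits at the origin.  In frame t, the first
    ``schedule[t]`` water oxygens are placed uniformly in the shell
    [radius/2, radius] around it and the spares are parked at 10 × radius,
    so counting at ``radius_A`` recovers the schedule for any seed.
    """
    schedule = np.asarray(schedule, dtype=int)
    if np.any(schedule < 0):
        raise ValueError("schedule counts must be >= 0")
    if radius_A <= 0:
        raise ValueError("radius must be positive")
    n_wat = int(schedule.max(initial=0))
    rng = np.random.default_rng(seed)
    T = len(schedule)
    coords = np.zeros((T, 1 + n_wat, 3))
    for t in range(T):
        for w in range(n_wat):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            r = radius_A * (0.5 + 0.5 * rng.random()) if w < schedule[t] else 10.0 * radius_A
            coords[t, 1 + w] = r * u
    atoms = [Atom(1, "CA", "C", 0, "ALA", 1, "A", False, False)]
    for w in range(n_wat):
        atoms.append(Atom(2 + w, "OH2", "O", 1 + w, "HOH", 100 + w, "W", True, False))
    return Trajectory(topology=Topology(atoms), coords=coords)
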