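"""Global activity functions and pulling-schedule arithmetic.

Two scalar summaries of a trajectory are provided:

* ``gaussian_rmsf`` — the root-mean-square fluctuation of Cartesian
  coordinates inside a Gaussian-weighted sliding window of half-width δ
  frames.  This is the "activity function" a(t): quiescent basins give low
  values, transition bursts give peaks.
* ``rmsd_from_initial`` — the RMSD from the frame-0 conformation, the
  natural order parameter of a constant-velocity pulling run (it is shaped
  like a ramp while the molecule extends).

``pulling_schedule`` converts a constant-velocity pulling setup (extension,
spring velocity, integration time step) into a simulation duration and step
count: 1 m/s equals 0.01 Å/ps, so a 50 Å extension at 10 m/s lasts 0.5 ns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.ndimage import convolve1d
from scipy.spatial.transform import Rotation

from .model import Trajectory

__all__ = [
    "RMSFParams",
    "ScalarSeries",
    "PullingSchedule",
    "default_window",
    "gaussian_rmsf",
    "rmsd_from_initial",
    "pulling_schedule",
]

AtomSelection = Literal["CA", "all_protein_heavy"]


@dataclass
class ScalarSeries:
    """One value per frame: an activity function or order parameter."""

    values: np.ndarray
    kind: Literal["rmsf", "rmsd", "external"]
    units: str = "A"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.kind in ("rmsf", "rmsd") and np.any(self.values < 0):
            raise ValueError(f"{self.kind} values must be non-negative")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class RMSFParams:
    """Gaussian sliding-window parameters.

    ``delta`` is the window half-width in frames (weights truncated at ±δ);
    ``sigma_frames`` defaults to δ/2, so the truncation keeps ~95% of the
    Gaussian mass.
    """

    delta: int
    atom_selection: AtomSelection = "CA"
    sigma_frames: float | None = None

    def __post_init__(self) -> None:
        if self.delta < 1:
            raise ValueError("delta must be >= 1")
        if self.sigma_frames is not None and not self.sigma_frames > 0:
            raise ValueError("sigma_frames must be positive")

    @property
    def sigma(self) -> float:
        return self.sigma_frames if self.sigma_frames is not None else self.delta / 2.0


@dataclass(frozen=True)
class PullingSchedule:
    extension_A: float
    velocity_m_per_s: float
    timestep_fs: float
    duration_ns: float
    n_steps: int


def default_window(n_frames: int) -> int:
    """Default δ: 5% of the trajectory length, rounded, at least 1 frame."""
    if n_frames < 20:
        warnings.warn(
            f"trajectory of {n_frames} frames is too short for the 5% window "
            "rule; using delta=1",
            stacklevel=2,
        )
        return 1
    return max(1, round(0.05 * n_frames))


def _select_atoms(trajectory: Trajectory, selection: AtomSelection) -> np.ndarray:
    top = trajectory.topology
    protein = ~top.is_water
    if selection == "CA":
        idx = np.flatnonzero(protein & (top.names == "CA"))
    elif selection == "all_protein_heavy":
        idx = np.flatnonzero(protein & ~top.is_hydrogen)
    else:
        raise ValueError(f"unknown atom selection {selection!r}")
    if len(idx) == 0:
        raise ValueError(f"atom selection {selection!r} matches no atoms")
    return idx


def gaussian_rmsf(trajectory: Trajectory, params: RMSFParams) -> ScalarSeries:
    """Gaussian-windowed RMSF activity function, one value per frame.

    For each frame t, truncated-Gaussian weights w_k ∝ exp(−k²/2σ²) over
    k ∈ [−δ, +δ] (clipped at the trajectory bounds and renormalised) define
    a weighted mean position μ_a(t) per atom, and

        RMSF(t) = sqrt( mean_a Σ_k w_k ‖r_a(t+k) − μ_a(t)‖² ).

    The value is invariant to a time-constant rigid shift of all frames and
    is identically zero on a static trajectory.
    """
    idx = _select_atoms(trajectory, params.atom_selection)
    T = trajectory.n_frames
    if T < 2 * params.delta:
        warnings.warn(
            f"trajectory length {T} is below twice the window half-width "
            f"({params.delta}); edge effects dominate",
            stacklevel=2,
        )
    k = np.arange(-params.delta, params.delta + 1, dtype=float)
    w = np.exp(-(k**2) / (2.0 * params.sigma**2))

    # Center per atom on its frame-0 position: the value is shift-invariant,
    # and centering avoids catastrophic cancellation in the m2 - m1^2 form
    # (a static trajectory then yields exact zeros).
    x = trajectory.coords[:, idx, :]  # (T, A, 3)
    x = x - x[:1]
    ones = np.ones(T)
    norm = convolve1d(ones, w, mode="constant", cval=0.0)  # per-frame weight mass
    m1 = convolve1d(x, w, axis=0, mode="constant", cval=0.0) / norm[:, None, None]
    m2 = convolve1d(x**2, w, axis=0, mode="constant", cval=0.0) / norm[:, None, None]
    var = np.clip(m2 - m1**2, 0.0, None)  # weighted variance per atom/coordinate
    rmsf = np.sqrt(var.sum(axis=2).mean(axis=1))
    return ScalarSeries(values=rmsf, kind="rmsf", units="A")


def rmsd_from_initial(
    trajectory: Trajectory,
    atom_selection: AtomSelection = "CA",
    superpose: bool = False,
) -> ScalarSeries:
    """Per-frame RMSD of the selected atoms from the frame-0 conformation.

    With ``superpose=True`` an optimal least-squares rigid-body
    superposition (Kabsch) is applied before measuring, so pure rigid
    motions give zero; the default measures raw deviation, which tracks the
    stretching itself in a pulling run.
    """
    idx = _select_atoms(trajectory, atom_selection)
    x = trajectory.coords[:, idx, :]
    ref = x[0]
    if not superpose:
        rmsd = np.sqrt(((x - ref) ** 2).sum(axis=2).mean(axis=1))
    else:
        ref_c = ref - ref.mean(axis=0)
        n = len(idx)
        rmsd = np.empty(trajectory.n_frames)
        for t in range(trajectory.n_frames):
            mob = x[t] - x[t].mean(axis=0)
            _, rssd = Rotation.align_vectors(ref_c, mob)
            rmsd[t] = rssd / np.sqrt(n)
    rmsd[0] = 0.0
    return ScalarSeries(values=rmsd, kind="rmsd", units="A")


def pulling_schedule(
    extension_A: float, velocity_m_per_s: float, timestep_fs: float = 1.0
) -> PullingSchedule:
    """Duration and step count of a constant-velocity pulling run.

    1 m/s = 0.01 Å/ps = 10 Å/ns, so duration_ns = extension / (10 × v).
    """
    if extension_A <= 0 or velocity_m_per_s <= 0 or timestep_fs <= 0:
        raise ValueError("extension, velocity and timestep must be positive")
    velocity_A_per_ns = 10.0 * velocity_m_per_s
    duration_ns = extension_A / velocity_A_per_ns
    n_steps = int(round(duration_ns * 1e6 / timestep_fs))
    return PullingSchedule(
        extension_A=extension_A,
        velocity_m_per_s=velocity_m_per_s,
        timestep_fs=timestep_fs,
        duration_ns=duration_ns,
        n_steps=n_steps,
    )
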