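"""Mutual-information heat maps of pairwise residue dynamics.

For every included residue pair the mutual information between its distance
series (or the absolute rate of change of that series) and a global scalar
series is estimated, and the values are assembled into a symmetric
residue × residue matrix R_X,a(i, j):

* rate mode    — I(|dX_ij/dt|, a(t)) with a(t) an activity function (RMSF),
* direct mode  — I(X_ij(t), a(t)) with a(t) an order parameter (RMSD or an
  external series), appropriate when the run undergoes a directional change.

The estimator is a plug-in MI on discretised series.  Continuous series are
discretised with equal-frequency (quantile) bins by default — an adaptive
rule that allocates resolution where the data mass is, and that makes the
direct-mode values invariant to strictly monotone transforms of either
input.  The automatic bin count is clamp(floor(sqrt(T/5)), 4, 16).  Values
are reported in bits.

Matrices are normalised by their global maximum to [0, 1] for display and
selection; pairs exceeding a normalised threshold (0.7 by default, strict
inequality) form the reported selection.  An optional permutation null
(shuffling the scalar series) calibrates the estimator's bias.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .coarse import DistanceSeries, RateSeries
from .activity import ScalarSeries

__all__ = [
    "MIParams",
    "MIMatrix",
    "PairSelection",
    "auto_bins",
    "discretize",
    "mutual_information",
    "permutation_null",
    "mi_matrix_rate",
    "mi_matrix_direct",
    "normalize_matrix",
    "select_pairs",
    "block_scores",
    "write_matrix_tsv",
    "write_selection_tsv",
]

Binning = Literal["equal_frequency", "equal_width"]
MatrixMode = Literal["rate_vs_activity", "direct_vs_order"]


@dataclass(frozen=True)
class MIParams:
    n_bins: int | Literal["auto"] = "auto"
    binning: Binning = "equal_frequency"
    n_permutations: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bins != "auto" and self.n_bins < 2:
            raise ValueError("n_bins must be >= 2 or 'auto'")
        if self.n_permutations < 0:
            raise ValueError("n_permutations must be >= 0")

    def bins_for(self, n_samples: int) -> int:
        if self.n_bins == "auto":
            return auto_bins(n_samples)
        return int(self.n_bins)


def auto_bins(n_samples: int) -> int:
    """Automatic bin count: clamp(floor(sqrt(T/5)), 4, 16)."""
    return int(min(16, max(4, math.floor(math.sqrt(n_samples / 5)))))


def discretize(x: np.ndarray, n_bins: int, binning: Binning = "equal_frequency") -> np.ndarray:
    """Map a series to integer bin labels.

    Equal-frequency binning places bin edges at quantiles (duplicated edges
    from heavy ties simply leave bins empty); equal-width binning spans
    [min, max].  A constant series maps to a single label.
    """
    x = np.asarray(x, dtype=float)
    if x.min() == x.max():
        return np.zeros(len(x), dtype=int)
    if binning == "equal_frequency":
        edges = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    elif binning == "equal_width":
        edges = np.linspace(x.min(), x.max(), n_bins + 1)[1:-1]
    else:
        raise ValueError(f"unknown binning {binning!r}")
    return np.searchsorted(edges, x, side="right")


def _plugin_mi_from_labels(lx: np.ndarray, ly: np.ndarray) -> float:
    """Plug-in MI (bits) of two integer label series via the joint histogram."""
    nx = int(lx.max()) + 1
    ny = int(ly.max()) + 1
    joint = np.bincount(lx * ny + ly, minlength=nx * ny).reshape(nx, ny).astype(float)
    n = joint.sum()
    pj = joint / n
    px = pj.sum(axis=1)
    py = pj.sum(axis=0)
    mask = pj > 0
    outer = px[:, None] * py[None, :]
    # fsum gives a correctly rounded, order-independent total, so the value
    # is exactly symmetric in the arguments.
    mi = math.fsum(pj[mask] * np.log2(pj[mask] / outer[mask]))
    return max(mi, 0.0)  # guard against -0.0 round-off


def mutual_information(
    x: Sequence[float], y: Sequence[float], params: MIParams = MIParams()
) -> float:
    """Plug-in mutual information of two equal-length series, in bits.

    Both series are discretised per ``params``; a constant series yields a
    single bin and hence MI = 0.  The value is symmetric in its arguments
    and non-negative.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"series length mismatch: {x.shape} vs {y.shape}")
    n_bins = params.bins_for(len(x))
    lx = discretize(x, n_bins, params.binning)
    ly = discretize(y, n_bins, params.binning)
    return _plugin_mi_from_labels(lx, ly)


def permutation_null(
    x: Sequence[float], y: Sequence[float], params: MIParams
) -> np.ndarray:
    """MI values of ``x`` against ``params.n_permutations`` shuffles of ``y``.

    The null distribution calibrates the finite-sample bias of the plug-in
    estimator: the observed MI of truly independent series should fall
    inside it.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(params.seed)
    n_bins = params.bins_for(len(x))
    lx = discretize(x, n_bins, params.binning)
    ly = discretize(y, n_bins, params.binning)
    null = np.empty(params.n_permutations)
    for p in range(params.n_permutations):
        null[p] = _plugin_mi_from_labels(lx, rng.permutation(ly))
    return null


@dataclass
class MIMatrix:
    """Symmetric residue × residue heat map of MI values.

    The matrix is indexed by internal residue index; ``residue_ids`` gives
    the author numbering used in all exports.  Diagonal and excluded pairs
    are zero.
    """

    values: np.ndarray  # (n, n) symmetric, >= 0
    residue_ids: np.ndarray
    mode: MatrixMode
    normalized: bool = False

    @property
    def n_residues(self) -> int:
        return self.values.shape[0]


def _scatter_matrix(
    pairs: np.ndarray, mi: np.ndarray, n_residues: int, residue_ids: np.ndarray, mode: MatrixMode
) -> MIMatrix:
    m = np.zeros((n_residues, n_residues))
    m[pairs[:, 0], pairs[:, 1]] = mi
    m[pairs[:, 1], pairs[:, 0]] = mi
    return MIMatrix(values=m, residue_ids=np.asarray(residue_ids), mode=mode)


def _per_pair_mi(values: np.ndarray, scalar: np.ndarray, params: MIParams) -> np.ndarray:
    n_bins = params.bins_for(values.shape[1])
    ls = discretize(scalar, n_bins, params.binning)
    out = np.empty(values.shape[0])
    for p in range(values.shape[0]):
        lx = discretize(values[p], n_bins, params.binning)
        out[p] = _plugin_mi_from_labels(lx, ls)
    return out


def mi_matrix_rate(
    rates: RateSeries, activity: ScalarSeries, params: MIParams = MIParams()
) -> MIMatrix:
    """Rate-mode heat map: I(|dX_ij/dt|, a(t)) per pair.

    The rate series has T−1 samples (forward difference), so the activity
    series is truncated to its first T−1 samples to align the two.
    """
    t = rates.n_frames
    a = np.asarray(activity.values, dtype=float)
    if len(a) < t:
        raise ValueError(
            f"activity length {len(a)} shorter than rate series length {t}"
        )
    mi = _per_pair_mi(rates.values, a[:t], params)
    return _scatter_matrix(rates.pairs, mi, rates.n_residues, rates.residue_ids, "rate_vs_activity")


def mi_matrix_direct(
    distances: DistanceSeries, order: ScalarSeries, params: MIParams = MIParams()
) -> MIMatrix:
    """Direct-mode heat map: I(X_ij(t), a(t)) per pair, equal lengths."""
    a = np.asarray(order.values, dtype=float)
    if len(a) != distances.n_frames:
        raise ValueError(
            f"order parameter length {len(a)} does not match trajectory "
            f"length {distances.n_frames}"
        )
    mi = _per_pair_mi(distances.values, a, params)
    return _scatter_matrix(
        distances.pairs, mi, distances.n_residues, distances.residue_ids, "direct_vs_order"
    )


def normalize_matrix(m: MIMatrix) -> MIMatrix:
    """Divide by the global maximum so the matrix spans [0, 1].

    An all-zero matrix is returned unchanged (flagged normalised); the
    operation is idempotent.
    """
    vmax = m.values.max()
    values = m.values if vmax == 0 else m.values / vmax
    return MIMatrix(values=values, residue_ids=m.residue_ids, mode=m.mode, normalized=True)


@dataclass
class PairSelection:
    """Residue pairs whose normalised MI strictly exceeds the threshold."""

    threshold: float
    pairs: list[tuple[int, int]]  # author residue ids, sorted
    residues: list[int]  # sorted union of pair members


def select_pairs(m: MIMatrix, threshold: float = 0.7) -> PairSelection:
    """Pairs with normalised MI > threshold, in author residue numbering."""
    if not m.normalized:
        raise ValueError("select_pairs requires a normalized matrix")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    iu, ju = np.triu_indices(m.n_residues, k=1)
    keep = m.values[iu, ju] > threshold
    ids = m.residue_ids
    pairs = sorted(
        (int(min(ids[i], ids[j])), int(max(ids[i], ids[j])))
        for i, j in zip(iu[keep], ju[keep])
    )
    residues = sorted({r for p in pairs for r in p})
    return PairSelection(threshold=threshold, pairs=pairs, residues=residues)


def block_scores(m: MIMatrix, boundaries: Sequence[tuple[int, int]]) -> pd.DataFrame:
    """Mean MI per ordered segment pair, for block-structure inspection.

    ``boundaries`` are inclusive author-residue-id ranges that must
    partition the matrix's residue range.  Intra-segment means use the
    upper triangle only (i < j).
    """
    ids = np.asarray(m.residue_ids)
    assigned = np.full(len(ids), -1, dtype=int)
    for s, (lo, hi) in enumerate(boundaries):
        if hi < lo:
            raise ValueError(f"segment ({lo}, {hi}) is empty")
        mask = (ids >= lo) & (ids <= hi)
        if np.any(assigned[mask] >= 0):
            raise ValueError("segments overlap")
        assigned[mask] = s
    if np.any(assigned < 0):
        missing = ids[assigned < 0]
        raise ValueError(f"segments leave residues uncovered: {missing.tolist()}")
    rows = []
    n_seg = len(boundaries)
    for a in range(n_seg):
        for b in range(a, n_seg):
            ia = np.flatnonzero(assigned == a)
            ib = np.flatnonzero(assigned == b)
            if a == b:
                iu, ju = np.meshgrid(ia, ib, indexing="ij")
                mask = iu < ju
                vals = m.values[iu[mask], ju[mask]]
            else:
                vals = m.values[np.ix_(ia, ib)].ravel()
            rows.append(
                {
                    "segment_a": f"{boundaries[a][0]}-{boundaries[a][1]}",
                    "segment_b": f"{boundaries[b][0]}-{boundaries[b][1]}",
                    "mean_mi": float(vals.mean()) if len(vals) else float("nan"),
                    "n_cells": int(len(vals)),
                }
            )
    return pd.DataFrame(rows)


def write_matrix_tsv(m: MIMatrix, path, header_comments: Sequence[str] = ()) -> None:
    """Export a matrix as TSV with author residue ids as header row/column."""
    ids = [str(int(r)) for r in m.residue_ids]
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        fh.write("\t".join(["residue"] + ids) + "\n")
        for i, rid in enumerate(ids):
            row = [rid] + [format(v, ".6g") for v in m.values[i]]
            fh.write("\t".join(row) + "\n")


def write_selection_tsv(sel: PairSelection, path, header_comments: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        fh.write("residue_i\tresidue_j\n")
        for i, j in sel.pairs:
            fh.write(f"{i}\t{j}\n")
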