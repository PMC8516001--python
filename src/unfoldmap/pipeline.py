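"""End-to-end analysis runs: load a trajectory, compute, write TSV outputs.

Every output file carries provenance comment lines (package version, seed,
configuration hash), and a run is fully deterministic: the same
configuration and seed reproduce every output byte.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from . import __version__
from .model import Trajectory, read_multimodel_pdb, read_series_tsv, write_series_tsv
from .coarse import pairwise_distance_series, rate_of_change
from .activity import RMSFParams, ScalarSeries, default_window, gaussian_rmsf, rmsd_from_initial
from .mi import (
    mi_matrix_direct,
    mi_matrix_rate,
    normalize_matrix,
    select_pairs,
    write_matrix_tsv,
    write_selection_tsv,
)
from .structure import count_hbonds_series, count_waters_near, moving_average, triplet_angle_series
from .hydropathy import contact_residues, get_scale, segment_hydropathy
from .config import AnalysisConfig

__all__ = ["run_mi_analysis", "run_structure_analysis", "run_hydropathy_analysis"]

logger = logging.getLogger("unfoldmap")


def _provenance(config: AnalysisConfig, extra: dict | None = None) -> list[str]:
    lines = [
        f"unfoldmap {__version__}",
        f"seed={config.seed}",
        f"config_hash={config.content_hash()}",
    ]
    for k, v in (extra or {}).items():
        lines.append(f"{k}={v}")
    return lines


def _load_trajectory(config: AnalysisConfig) -> Trajectory:
    if config.trajectory is None:
        raise ValueError("no trajectory path configured")
    return read_multimodel_pdb(config.trajectory)


def _activity_series(
    traj: Trajectory, config: AnalysisConfig, delta: int
) -> ScalarSeries:
    if config.activity == "rmsf":
        return gaussian_rmsf(traj, RMSFParams(delta=delta))
    if config.activity == "rmsd":
        return rmsd_from_initial(traj)
    # External order parameter: TSV with a frame column plus one value column.
    cols = read_series_tsv(config.activity)
    name = next(iter(cols))
    return ScalarSeries(values=cols[name], kind="external", units="arbitrary")


def run_mi_analysis(
    config: AnalysisConfig,
    mode: str = "direct",
    deltas: list[int] | None = None,
    out_dir: str | Path = ".",
) -> dict[int, dict[str, Path]]:
    """Compute the MI heat map(s) and write activity/matrix/selection files.

    ``deltas`` lists the RMSF window half-widths to sweep (ignored for an
    rmsd/external scalar, where a single run is performed); the default is
    the 5%-of-frames rule.  Returns the written paths per δ.
    """
    if mode not in ("rate", "direct"):
        raise ValueError(f"mode must be 'rate' or 'direct', got {mode!r}")
    traj = _load_trajectory(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    logger.info(
        "coarse graining: excl=%d cutoff=%s scheme=%s",
        config.coarse_grain.excl, config.coarse_grain.cutoff, config.coarse_grain.scheme,
    )
    distances = pairwise_distance_series(traj, config.coarse_grain)

    if deltas is None:
        deltas = [config.delta if config.delta is not None else default_window(traj.n_frames)]
    if config.activity != "rmsf":
        deltas = deltas[:1]  # no window sweep without an RMSF activity

    outputs: dict[int, dict[str, Path]] = {}
    for delta in deltas:
        scalar = _activity_series(traj, config, delta)
        logger.info("mode=%s activity=%s delta=%d threshold=%.2f bins=%s",
                    mode, config.activity, delta, config.threshold, config.mi.n_bins)
        if mode == "rate":
            rates = rate_of_change(distances)
            matrix = mi_matrix_rate(rates, scalar, config.mi)
        else:
            matrix = mi_matrix_direct(distances, scalar, config.mi)
        norm = normalize_matrix(matrix)
        selection = select_pairs(norm, config.threshold)

        tag = f"{config.out_prefix}_{mode}_d{delta}"
        prov = _provenance(config, {"mode": mode, "delta": delta, "activity": config.activity})
        paths = {
            "activity": out_dir / f"{tag}_activity.tsv",
            "matrix_raw": out_dir / f"{tag}_mi_raw.tsv",
            "matrix_norm": out_dir / f"{tag}_mi_norm.tsv",
            "selection": out_dir / f"{tag}_selection.tsv",
        }
        write_series_tsv(paths["activity"], {scalar.kind: scalar.values}, prov)
        write_matrix_tsv(matrix, paths["matrix_raw"], prov + ["values=bits"])
        write_matrix_tsv(norm, paths["matrix_norm"], prov + ["values=normalized"])
        write_selection_tsv(selection, paths["selection"], prov + [f"threshold={config.threshold}"])
        outputs[delta] = paths
    return outputs


def run_structure_analysis(config: AnalysisConfig, out_dir: str | Path = ".") -> dict[str, Path]:
    """Hydrogen-bond counts, water-shell occupancy and triplet angles."""
    traj = _load_trajectory(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prov = _provenance(config)
    paths: dict[str, Path] = {}

    if config.hbond_sets:
        logger.info(
            "hbond criteria: cutoff=%.2f A tolerance=%.1f deg",
            config.hbond_criteria.da_cutoff_A, config.hbond_criteria.angle_tolerance_deg,
        )
        counts = count_hbonds_series(traj, config.hbond_sets, config.hbond_criteria)
        columns: dict[str, np.ndarray] = {}
        for name, series in counts.items():
            columns[name] = series
            if config.smoothing_window:
                columns[f"{name}_smooth"] = moving_average(series, config.smoothing_window)
        paths["hbonds"] = out_dir / f"{config.out_prefix}_hbonds.tsv"
        write_series_tsv(paths["hbonds"], columns, prov)

    if config.water_residues:
        per_res, aggregate = count_waters_near(traj, config.water_residues, config.water_radius_A)
        columns = {f"res{rid}": series for rid, series in per_res.items()}
        columns["aggregate"] = aggregate
        paths["waters"] = out_dir / f"{config.out_prefix}_waters.tsv"
        write_series_tsv(paths["waters"], columns, prov + [f"radius_A={config.water_radius_A}"])

    if config.triplets:
        angles = triplet_angle_series(traj, config.triplets)
        columns = {"-".join(map(str, trip)): series for trip, series in angles.items()}
        paths["angles"] = out_dir / f"{config.out_prefix}_angles.tsv"
        write_series_tsv(paths["angles"], columns, prov)

    return paths


def run_hydropathy_analysis(
    config: AnalysisConfig, frame: int = 0, out_dir: str | Path = "."
) -> Path:
    """Contact/non-contact hydropathy table over the configured segment pairs."""
    traj = _load_trajectory(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scale = get_scale(config.hydropathy_scale)
    path = out_dir / f"{config.out_prefix}_hydropathy.tsv"
    with open(path, "w") as fh:
        for line in _provenance(config, {"scale": scale.name, "frame": frame}):
            fh.write(f"# {line}\n")
        fh.write("segment\tpart\tn_contact\tcontact_mean\tn_noncontact\tnoncontact_mean\n")
        for pair in config.hydropathy_pairs:
            contacts = contact_residues(traj, frame, pair)
            result = segment_hydropathy(pair, contacts, scale, traj.topology)
            for part in ("a", "b", "pooled"):
                r = result[part]
                fmt = lambda v: "NA" if v is None else format(v, ".6g")
                fh.write(
                    f"{pair.name}\t{part}\t{r.n_contact}\t{fmt(r.contact_mean)}\t"
                    f"{r.n_noncontact}\t{fmt(r.noncontact_mean)}\n"
                )
    return path
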