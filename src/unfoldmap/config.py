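"""YAML analysis configuration with strict validation.

One nested document configures every pipeline stage; unknown keys are
rejected so that a typo never silently falls back to a default.  All
defaults mirror the analysis conventions used throughout the package:
neighbour exclusion 1 with infinite cutoff, δ = 5% of frames, selection
threshold 0.7, hydrogen-bond criteria 3.5 Å / 45°, contact cutoff 4.5 Å,
water-shell radius 4.0 Å, smoothing window 11.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Sequence

import yaml

from .coarse import CoarseGrainParams
from .mi import MIParams
from .structure import HBondCriteria, HBondSetDef, TripletDef
from .hydropathy import SegmentPair

__all__ = ["AnalysisConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """Raised for invalid or unknown configuration content."""


def _check_keys(section: str, mapping: dict, allowed: set[str]) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in {section!r}: {sorted(unknown)}")


@dataclass
class AnalysisConfig:
    """Validated parameters for every stage of the pipeline."""

    trajectory: str | None = None
    coarse_grain: CoarseGrainParams = field(default_factory=CoarseGrainParams)
    activity: str = "rmsf"  # rmsf | rmsd | path to an external TSV
    delta: int | None = None  # None -> 5% of frames
    mi: MIParams = field(default_factory=MIParams)
    threshold: float = 0.7
    hbond_criteria: HBondCriteria = field(default_factory=HBondCriteria)
    hbond_sets: tuple[HBondSetDef, ...] = ()
    water_residues: tuple[int, ...] = ()
    water_radius_A: float = 4.0
    triplets: tuple[TripletDef, ...] = ()
    hydropathy_pairs: tuple[SegmentPair, ...] = ()
    hydropathy_scale: str = "kyte_doolittle"
    smoothing_window: int | None = 11
    seed: int = 0
    out_prefix: str = "unfoldmap"

    def content_hash(self) -> str:
        """Stable hash of the configuration, for provenance headers."""

        def default(o: Any):
            if isinstance(o, (frozenset, set, tuple)):
                return sorted(o) if isinstance(o, (frozenset, set)) else list(o)
            if hasattr(o, "__dict__"):
                return vars(o)
            if isinstance(o, float) and math.isinf(o):
                return "inf"
            return str(o)

        blob = json.dumps(asdict(self), default=default, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


_TOP_KEYS = {
    "trajectory", "coarse_grain", "activity", "delta", "mi", "threshold",
    "hbonds", "waters", "triplets", "hydropathy", "smoothing_window",
    "seed", "out_prefix",
}


def _parse_range(value: Sequence[int], where: str) -> tuple[int, int]:
    if len(value) != 2:
        raise ConfigError(f"{where}: a residue range needs exactly two values, got {value!r}")
    return int(value[0]), int(value[1])


def load_config(path: str | Path) -> AnalysisConfig:
    """Load and validate a YAML analysis configuration file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    _check_keys("top level", raw, _TOP_KEYS)
    cfg = AnalysisConfig()

    cfg.trajectory = raw.get("trajectory", cfg.trajectory)
    cfg.activity = raw.get("activity", cfg.activity)
    cfg.delta = raw.get("delta", cfg.delta)
    cfg.threshold = float(raw.get("threshold", cfg.threshold))
    cfg.seed = int(raw.get("seed", cfg.seed))
    cfg.out_prefix = raw.get("out_prefix", cfg.out_prefix)
    if raw.get("smoothing_window", "unset") != "unset":
        w = raw["smoothing_window"]
        cfg.smoothing_window = None if w is None else int(w)

    if "coarse_grain" in raw:
        sec = raw["coarse_grain"] or {}
        _check_keys("coarse_grain", sec, {"excl", "cutoff", "scheme"})
        cutoff = sec.get("cutoff", math.inf)
        cfg.coarse_grain = CoarseGrainParams(
            excl=int(sec.get("excl", 1)),
            cutoff=math.inf if cutoff in (None, "inf") else float(cutoff),
            scheme=sec.get("scheme", "side_chain_centroid"),
        )

    if "mi" in raw:
        sec = raw["mi"] or {}
        _check_keys("mi", sec, {"n_bins", "binning", "n_permutations", "seed"})
        n_bins = sec.get("n_bins", "auto")
        cfg.mi = MIParams(
            n_bins=n_bins if n_bins == "auto" else int(n_bins),
            binning=sec.get("binning", "equal_frequency"),
            n_permutations=int(sec.get("n_permutations", 0)),
            seed=int(sec.get("seed", cfg.seed)),
        )

    if "hbonds" in raw:
        sec = raw["hbonds"] or {}
        _check_keys("hbonds", sec, {"da_cutoff_A", "angle_tolerance_deg", "sets"})
        cfg.hbond_criteria = HBondCriteria(
            da_cutoff_A=float(sec.get("da_cutoff_A", 3.5)),
            angle_tolerance_deg=float(sec.get("angle_tolerance_deg", 45.0)),
        )
        sets = []
        for entry in sec.get("sets", []):
            _check_keys("hbonds.sets entry", entry, {"name", "range_a", "range_b"})
            sets.append(
                HBondSetDef(
                    name=str(entry["name"]),
                    range_a=_parse_range(entry["range_a"], entry.get("name", "set")),
                    range_b=_parse_range(entry["range_b"], entry.get("name", "set")),
                )
            )
        cfg.hbond_sets = tuple(sets)

    if "waters" in raw:
        sec = raw["waters"] or {}
        _check_keys("waters", sec, {"residues", "radius_A"})
        cfg.water_residues = tuple(int(r) for r in sec.get("residues", []))
        cfg.water_radius_A = float(sec.get("radius_A", 4.0))

    if "triplets" in raw:
        cfg.triplets = tuple(
            TripletDef(residues=tuple(int(r) for r in trip)) for trip in raw["triplets"]
        )

    if "hydropathy" in raw:
        sec = raw["hydropathy"] or {}
        _check_keys("hydropathy", sec, {"scale", "pairs"})
        cfg.hydropathy_scale = sec.get("scale", "kyte_doolittle")
        pairs = []
        for entry in sec.get("pairs", []):
            _check_keys("hydropathy.pairs entry", entry, {"name", "part_a", "part_b"})
            pairs.append(
                SegmentPair.from_ranges(
                    name=str(entry["name"]),
                    ranges_a=[_parse_range(r, entry["name"]) for r in entry["part_a"]],
                    ranges_b=[_parse_range(r, entry["name"]) for r in entry["part_b"]],
                )
            )
        cfg.hydropathy_pairs = tuple(pairs)

    return cfg
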