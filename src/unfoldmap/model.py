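"""Topology and trajectory data model with plain-text readers/writers.

The in-memory containers are deliberately small: a :class:`Topology` is an
ordered list of :class:`Atom` records plus a residue table, and a
:class:`Trajectory` binds a ``(T, N, 3)`` coordinate array (Å) to it.  Author
residue numbering from the source file is preserved in ``Atom.residue_id``
(e.g. 3–94 for an engineered-protein PDB entry), while ``Atom.residue_index``
is the 0-based contiguous internal index every downstream analysis uses.

Multi-model PDB parsing and writing is delegated to :mod:`biotite`; the
functions here only translate its structures into the package's containers
and produce actionable error messages for malformed inputs.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio

__all__ = [
    "Atom",
    "Topology",
    "Trajectory",
    "TrajectoryFormatError",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "read_coord_table",
    "write_series_tsv",
    "read_series_tsv",
    "WATER_RESNAMES",
    "WATER_OXYGEN_NAMES",
]

#: Residue names recognised as water.
WATER_RESNAMES = frozenset({"HOH", "TIP3", "TIP3P", "SPC", "WAT"})
#: Atom names of a water oxygen (CHARMM uses OH2, PDB convention uses O/OW).
WATER_OXYGEN_NAMES = frozenset({"OH2", "O", "OW"})


class TrajectoryFormatError(ValueError):
    """Raised when an input file cannot be interpreted as a trajectory."""


@dataclass(frozen=True)
class Atom:
    """One atom of the topology.

    ``residue_index`` is the 0-based contiguous internal index;
    ``residue_id`` keeps the author numbering of the source file.
    """

    serial: int
    name: str
    element: str
    residue_index: int
    residue_name: str
    residue_id: int
    chain: str
    is_water: bool
    is_hydrogen: bool


def _infer_element(atom_name: str, element: str) -> str:
    if element and element.strip():
        return element.strip().upper()
    # PDB dialect tolerance: leading-character heuristic on the atom name.
    name = atom_name.strip()
    stripped = name.lstrip("0123456789")
    if not stripped:
        return ""
    if stripped[0] in "Hh" or (name and name[0] in "123456789"):
        return "H"
    if len(stripped) >= 2 and stripped[:2].upper() in {"CL", "BR", "NA", "MG", "ZN", "FE", "CA"}:
        # Two-letter elements only occur as full names ("CL"), never as the
        # prefix of a longer protein atom name such as "CA"/"CB"/"NE2".
        if len(stripped) == 2 and stripped.upper() not in {"CA", "CB", "CD", "CE", "CG", "CZ", "ND", "NE", "NH", "NZ", "OD", "OE", "OG", "OH", "SD", "SG"}:
            return stripped[:2].upper()
    return stripped[0].upper()


class Topology:
    """Ordered atom list with a residue table.

    Parameters
    ----------
    atoms
        Atom records in file order.  ``residue_index`` must be contiguous
        and non-decreasing.
    """

    def __init__(self, atoms: Sequence[Atom]):
        self.atoms: tuple[Atom, ...] = tuple(atoms)
        if not self.atoms:
            raise ValueError("topology must contain at least one atom")
        self.residue_index = np.array([a.residue_index for a in self.atoms], dtype=int)
        if np.any(np.diff(self.residue_index) < 0):
            raise ValueError("residue_index must be non-decreasing in atom order")
        self.is_water = np.array([a.is_water for a in self.atoms], dtype=bool)
        self.is_hydrogen = np.array([a.is_hydrogen for a in self.atoms], dtype=bool)
        self.names = np.array([a.name for a in self.atoms])
        self.elements = np.array([a.element for a in self.atoms])

        # Residue table: internal index -> (author id, residue name, is_water)
        n_res = int(self.residue_index.max()) + 1
        self._res_ids = np.zeros(n_res, dtype=int)
        self._res_names = np.empty(n_res, dtype=object)
        self._res_is_water = np.zeros(n_res, dtype=bool)
        for a in self.atoms:
            self._res_ids[a.residue_index] = a.residue_id
            self._res_names[a.residue_index] = a.residue_name
            self._res_is_water[a.residue_index] = a.is_water

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return len(self._res_ids)

    @property
    def protein_residue_indices(self) -> np.ndarray:
        return np.flatnonzero(~self._res_is_water)

    @property
    def n_protein_residues(self) -> int:
        return int(np.count_nonzero(~self._res_is_water))

    def residue_id(self, residue_index: int) -> int:
        return int(self._res_ids[residue_index])

    def residue_name(self, residue_index: int) -> str:
        return str(self._res_names[residue_index])

    @property
    def residue_ids(self) -> np.ndarray:
        """Author residue numbering, one entry per internal residue index."""
        return self._res_ids.copy()

    def residue_index_of_id(self, residue_id: int) -> int:
        """Map an author residue id back to the internal index."""
        hits = np.flatnonzero(self._res_ids == residue_id)
        if len(hits) == 0:
            raise KeyError(f"no residue with author id {residue_id}")
        return int(hits[0])

    def atom_indices_of_residue(self, residue_index: int) -> np.ndarray:
        return np.flatnonzero(self.residue_index == residue_index)


@dataclass
class Trajectory:
    """A ``(T, N, 3)`` coordinate array (Å) bound to a :class:`Topology`."""

    topology: Topology
    coords: np.ndarray
    frame_dt_ps: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (T, N, 3)")
        if self.coords.shape[0] < 1:
            raise ValueError("trajectory must contain at least one frame")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"coordinate atom count {self.coords.shape[1]} does not match "
                f"topology atom count {self.topology.n_atoms}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


# ---------------------------------------------------------------------------
# PDB input/output (via biotite)
# ---------------------------------------------------------------------------

def _diagnose_pdb(path: Path) -> None:
    """Re-scan a PDB file that biotite rejected and raise a targeted error."""
    counts: list[int] = []
    current = 0
    in_model = False
    saw_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                saw_model = True
                in_model = True
                current = 0
            elif rec == "ENDMDL":
                counts.append(current)
                in_model = False
            elif rec in ("ATOM", "HETATM"):
                try:
                    float(line[30:38])
                    float(line[38:46])
                    float(line[46:54])
                except ValueError:
                    raise TrajectoryFormatError(
                        f"unparsable ATOM/HETATM record at line {lineno} of {path}"
                    ) from None
                current += 1
    if saw_model and in_model:
        counts.append(current)
    if counts and len(set(counts)) > 1:
        ref = counts[0]
        bad = next(i for i, c in enumerate(counts, start=1) if c != ref)
        raise TrajectoryFormatError(
            f"atom count mismatch across models in {path}: MODEL {bad} has "
            f"{counts[bad - 1]} atoms, MODEL 1 has {ref}"
        )


def _topology_from_atom_array(arr: struc.AtomArray) -> Topology:
    starts = struc.get_residue_starts(arr)
    res_index = np.zeros(arr.array_length(), dtype=int)
    for i, s in enumerate(starts):
        res_index[s:] = i
    atoms = []
    for k in range(arr.array_length()):
        name = str(arr.atom_name[k])
        res_name = str(arr.res_name[k])
        element = _infer_element(name, str(arr.element[k]) if "element" in arr.get_annotation_categories() else "")
        is_water = res_name in WATER_RESNAMES
        atoms.append(
            Atom(
                serial=k + 1,
                name=name,
                element=element,
                residue_index=int(res_index[k]),
                residue_name=res_name,
                residue_id=int(arr.res_id[k]),
                chain=str(arr.chain_id[k]),
                is_water=is_water,
                is_hydrogen=element == "H",
            )
        )
    return Topology(atoms)


def read_multimodel_pdb(path: str | Path, frame_dt_ps: float | None = None) -> Trajectory:
    """Read a (multi-model) PDB file as a trajectory, one frame per MODEL.

    A file without MODEL records yields a single-frame trajectory.  All
    models must contain the same atoms in the same order; a mismatch raises
    :class:`TrajectoryFormatError` naming the offending model.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        pdb_file = pdbio.PDBFile.read(str(path))
        stack = pdb_file.get_structure(model=None)
    except Exception as exc:
        _diagnose_pdb(path)  # raises a targeted error when it can
        raise TrajectoryFormatError(f"cannot parse PDB file {path}: {exc}") from exc
    if isinstance(stack, struc.AtomArray):  # pragma: no cover - biotite always stacks
        stack = struc.stack([stack])
    topology = _topology_from_atom_array(stack[0])
    coords = np.asarray(stack.coord, dtype=float)
    return Trajectory(topology=topology, coords=coords, frame_dt_ps=frame_dt_ps)


def write_multimodel_pdb(trajectory: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB file (one MODEL per frame)."""
    top = trajectory.topology
    n = top.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = np.zeros((n, 3))
    arr.chain_id = np.array([a.chain for a in top.atoms])
    arr.res_id = np.array([a.residue_id for a in top.atoms], dtype=int)
    arr.res_name = np.array([a.residue_name for a in top.atoms])
    arr.atom_name = np.array([a.name for a in top.atoms])
    arr.element = np.array([a.element for a in top.atoms])
    arr.hetero = np.array([a.is_water for a in top.atoms])
    stack = struc.stack([arr] * trajectory.n_frames)
    stack.coord = np.asarray(trajectory.coords, dtype=np.float32)
    out = pdbio.PDBFile()
    out.set_structure(stack)
    out.write(str(path))


# ---------------------------------------------------------------------------
# Plain-text coordinate tables and series files
# ---------------------------------------------------------------------------

def read_coord_table(path: str | Path, topology: Topology) -> Trajectory:
    """Read a whitespace/tab-delimited table of T rows x 3N columns.

    Columns are frame-major atom (x, y, z) triplets in topology order.
    """
    path = Path(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)  # empty-file warning
            table = np.loadtxt(path, ndmin=2)
    except ValueError as exc:
        raise TrajectoryFormatError(f"cannot parse coordinate table {path}: {exc}") from exc
    if table.size == 0:
        raise TrajectoryFormatError(f"no frames in coordinate table {path}")
    n = topology.n_atoms
    if table.shape[1] != 3 * n:
        raise TrajectoryFormatError(
            f"coordinate table {path} has {table.shape[1]} columns, expected "
            f"{3 * n} for {n} atoms"
        )
    coords = table.reshape(table.shape[0], n, 3)
    return Trajectory(topology=topology, coords=coords)


def write_series_tsv(
    path: str | Path,
    columns: Mapping[str, Sequence[float]],
    header_comments: Iterable[str] = (),
) -> None:
    """Write named per-frame series as a TSV file.

    The first column is the 0-based frame index; ``header_comments`` are
    emitted as ``#``-prefixed lines above the header row.
    """
    names = list(columns)
    arrays = [np.asarray(columns[name]) for name in names]
    lengths = {len(a) for a in arrays}
    if len(lengths) > 1:
        raise ValueError(f"column length mismatch: {sorted(lengths)}")
    n = lengths.pop() if lengths else 0
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        fh.write("\t".join(["frame"] + names) + "\n")
        for t in range(n):
            row = [str(t)] + [format(float(a[t]), ".10g") for a in arrays]
            fh.write("\t".join(row) + "\n")


def read_series_tsv(path: str | Path) -> dict[str, np.ndarray]:
    """Reparse a file written by :func:`write_series_tsv` (frame column dropped)."""
    with open(path) as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    header = lines[0].rstrip("\n").split("\t")
    if not lines[1:]:
        return {name: np.array([]) for name in header[1:]}
    data = np.loadtxt(io.StringIO("".join(lines[1:])), ndmin=2)
    return {name: data[:, i] for i, name in enumerate(header) if i > 0}
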