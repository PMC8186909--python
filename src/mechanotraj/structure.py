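"""Structures, trajectories and named domain selections.

The in-memory model is deliberately small: a :class:`Structure` is a set of
annotated atoms with Angstrom coordinates, a :class:`Trajectory` is an ordered
stack of coordinate frames over a fixed atom list with times in ps, and a
:class:`DomainMap` resolves named regions (TM, LH, TRP, S6, AR1..AR29, the
gate residue...) to atom index sets.  Region definitions are user-supplied
configuration, not hard-coded, because domain boundaries are a modelling
choice that depends on the deposited structure's numbering.

PDB parsing and writing are delegated to :mod:`biotite`; multi-frame data can
also be stored in a columnar ``.npz`` frame store (``times`` in ps, ``coords``
in Angstrom with shape ``(n_frames, n_atoms, 3)``, optional ``box``).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
import biotite.structure as _bts
from biotite.structure.io.pdb import PDBFile
from biotite.structure.info import mass as _element_mass

from .errors import ParseError, SelectionError, AnalysisError

BACKBONE_ATOMS = ("N", "CA", "C", "O")

__all__ = [
    "Structure",
    "Trajectory",
    "DomainMap",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory_pdb",
    "save_frames",
    "load_frames",
    "select",
    "center_of_mass",
    "element_masses",
]


@dataclass
class Structure:
    """Annotated atoms with coordinates in Angstrom."""

    chain_id: np.ndarray
    res_id: np.ndarray
    ins_code: np.ndarray
    res_name: np.ndarray
    atom_name: np.ndarray
    element: np.ndarray
    occupancy: np.ndarray
    coords: np.ndarray
    hetero: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ParseError("non-finite coordinates in structure")
        if self.hetero is None:
            self.hetero = np.zeros(len(self.coords), dtype=bool)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chain_id:
            seen.setdefault(str(c))
        return list(seen)

    def subset(self, indices) -> "Structure":
        idx = np.asarray(indices, dtype=int)
        return Structure(
            chain_id=self.chain_id[idx],
            res_id=self.res_id[idx],
            ins_code=self.ins_code[idx],
            res_name=self.res_name[idx],
            atom_name=self.atom_name[idx],
            element=self.element[idx],
            occupancy=self.occupancy[idx],
            coords=self.coords[idx],
            hetero=self.hetero[idx],
        )

    def with_coords(self, coords: np.ndarray) -> "Structure":
        return replace(self, coords=np.asarray(coords, dtype=float))

    def masses(self) -> np.ndarray:
        return element_masses(self.element)

    # -- biotite interop -------------------------------------------------
    def to_atom_array(self) -> "_bts.AtomArray":
        arr = _bts.AtomArray(self.n_atoms)
        arr.coord = np.asarray(self.coords, dtype=np.float32)
        arr.chain_id = self.chain_id
        arr.res_id = self.res_id
        arr.ins_code = self.ins_code
        arr.res_name = self.res_name
        arr.atom_name = self.atom_name
        arr.element = self.element
        arr.set_annotation("occupancy", np.asarray(self.occupancy, dtype=float))
        arr.hetero = self.hetero
        return arr

    @classmethod
    def from_atom_array(cls, arr) -> "Structure":
        if "occupancy" in arr.get_annotation_categories():
            occ = np.asarray(arr.occupancy, dtype=float)
        else:
            occ = np.ones(arr.array_length(), dtype=float)
        element = np.array(
            [e if e else _infer_element(n) for e, n in zip(arr.element, arr.atom_name)]
        )
        return cls(
            chain_id=np.asarray(arr.chain_id).astype(str),
            res_id=np.asarray(arr.res_id, dtype=int),
            ins_code=np.asarray(arr.ins_code).astype(str),
            res_name=np.asarray(arr.res_name).astype(str),
            atom_name=np.asarray(arr.atom_name).astype(str),
            element=element,
            occupancy=occ,
            coords=np.asarray(arr.coord, dtype=float),
            hetero=np.asarray(arr.hetero, dtype=bool),
        )


def _infer_element(atom_name: str) -> str:
    """Infer the element from a PDB atom name when the element column is blank."""
    name = atom_name.strip()
    if not name:
        raise ParseError("atom with empty name and no element")
    # strip leading digits (e.g. 1HB2); two-letter elements occupy the first
    # two columns of a 4-char name field, single letters are the common case
    stripped = name.lstrip("0123456789")
    if len(name) == 4 and name[0] in "0123456789":
        return stripped[0].upper()
    if stripped[:2].upper() in ("CL", "NA", "MG", "ZN", "FE", "BR", "MN", "CA") and len(
        name
    ) <= 2:
        return stripped[:2].upper()
    return stripped[0].upper()


def element_masses(elements: Iterable[str]) -> np.ndarray:
    """Atomic masses in u for element symbols, via biotite's element table."""
    out = np.empty(len(list(elements)) if not hasattr(elements, "__len__") else len(elements))
    for i, el in enumerate(elements):
        m = _element_mass(str(el).capitalize(), is_residue=False)
        if m is None:
            raise AnalysisError(f"unknown element {el!r}: no mass available")
        out[i] = m
    return out


@dataclass
class Trajectory:
    """Ordered coordinate frames (Angstrom) over a fixed atom list.

    ``times`` are in ps and strictly increasing; ``box`` optionally holds the
    three orthorhombic box lengths (Angstrom) per frame.
    """

    topology: Structure
    coords: np.ndarray  # (n_frames, n_atoms, 3) Angstrom
    times: np.ndarray  # ps
    box: np.ndarray | None = None  # (n_frames, 3) Angstrom

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ParseError(
                f"frame atom count {self.coords.shape[1]} does not match "
                f"topology ({self.topology.n_atoms})"
            )
        if len(self.times) != self.coords.shape[0]:
            raise ValueError("times length must equal frame count")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ParseError("frame times must be strictly increasing")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def frame(self, i: int) -> Structure:
        return self.topology.with_coords(self.coords[i])

    def __iter__(self):
        for i in range(self.n_frames):
            yield self.coords[i]


# ---------------------------------------------------------------------------
# readers / writers


def read_structure(path: str | os.PathLike, format: str = "pdb") -> Structure:
    """Read a single-model structure from a PDB file.

    Altloc records are resolved to the highest-occupancy variant (tie: first
    encountered); insertion codes are preserved; a blank element column is
    inferred from the atom name.
    """
    if format != "pdb":
        raise ParseError(f"unsupported structure format {format!r}")
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if os.path.getsize(path) == 0:
        raise ParseError(f"empty structure file: {path}")
    try:
        pdb = PDBFile.read(path)
        arr = pdb.get_structure(model=1, altloc="occupancy", extra_fields=["occupancy"])
    except Exception as exc:  # biotite raises various error types
        raise ParseError(f"failed to parse PDB {path}: {exc}") from exc
    if arr.array_length() == 0:
        raise ParseError(f"no ATOM/HETATM records in {path}")
    return Structure.from_atom_array(arr)


def write_structure(structure: Structure, path: str | os.PathLike) -> None:
    pdb = PDBFile()
    pdb.set_structure(structure.to_atom_array())
    pdb.write(os.fspath(path))


def read_trajectory(
    paths: str | os.PathLike | Sequence[str | os.PathLike],
    topology: Structure | None = None,
    dt_ps: float = 1.0,
    t0_ps: float = 0.0,
) -> Trajectory:
    """Read a trajectory from one or more multi-model PDB files.

    Files are concatenated in the given order.  Multi-model PDB carries no
    time stamps, so frames are assigned ``t0_ps + i * dt_ps``; frame stores
    written by :func:`save_frames` carry their own times and should be loaded
    with :func:`load_frames`.
    """
    if isinstance(paths, (str, os.PathLike)):
        paths = [paths]
    frames = []
    topo = topology
    for path in paths:
        try:
            pdb = PDBFile.read(os.fspath(path))
            stack = pdb.get_structure(altloc="occupancy", extra_fields=["occupancy"])
        except Exception as exc:
            raise ParseError(f"failed to parse PDB {path}: {exc}") from exc
        if isinstance(stack, _bts.AtomArray):
            stack = _bts.stack([stack])
        if topo is None:
            topo = Structure.from_atom_array(stack[0])
        if stack.array_length() != topo.n_atoms:
            raise ParseError(
                f"{path}: frame atom count {stack.array_length()} does not "
                f"match topology ({topo.n_atoms})"
            )
        frames.append(np.asarray(stack.coord, dtype=float))
    coords = np.concatenate(frames, axis=0)
    times = t0_ps + dt_ps * np.arange(coords.shape[0])
    return Trajectory(topology=topo, coords=coords, times=times)


def write_trajectory_pdb(traj: Trajectory, path: str | os.PathLike) -> None:
    """Write a trajectory as a multi-model PDB."""
    arr = traj.topology.to_atom_array()
    stack = _bts.AtomArrayStack(traj.n_frames, traj.topology.n_atoms)
    for cat in arr.get_annotation_categories():
        stack.set_annotation(cat, arr.get_annotation(cat))
    stack.coord = np.asarray(traj.coords, dtype=np.float32)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(os.fspath(path))


def save_frames(traj: Trajectory, path: str | os.PathLike) -> None:
    """Save to the columnar frame store (.npz): times/coords[/box] arrays."""
    payload = {
        "times": traj.times,
        "coords": traj.coords.astype(np.float32),
    }
    if traj.box is not None:
        payload["box"] = traj.box
    np.savez_compressed(os.fspath(path), **payload)


def load_frames(path: str | os.PathLike, topology: Structure) -> Trajectory:
    with np.load(os.fspath(path)) as data:
        coords = np.asarray(data["coords"], dtype=float)
        times = np.asarray(data["times"], dtype=float)
        box = np.asarray(data["box"], dtype=float) if "box" in data else None
    return Trajectory(topology=topology, coords=coords, times=times, box=box)


# ---------------------------------------------------------------------------
# domain map and selections


@dataclass(frozen=True)
class RegionEntry:
    """One (chain, residue-range) entry of a named region.

    ``chain`` may be ``"*"`` to match every chain; ``backbone_only`` restricts
    the selection to N/CA/C/O.
    """

    chain: str
    start: int
    stop: int  # inclusive
    backbone_only: bool = False

    def __post_init__(self):
        if self.stop < self.start:
            raise ValueError(f"residue range start {self.start} > stop {self.stop}")


@dataclass
class DomainMap:
    """Named region -> residue-range selections, loaded from YAML config."""

    regions: Mapping[str, tuple[RegionEntry, ...]] = field(default_factory=dict)

    def __contains__(self, name: str) -> bool:
        return name in self.regions

    def names(self) -> list[str]:
        return list(self.regions)

    @classmethod
    def from_dict(cls, data: Mapping) -> "DomainMap":
        regions: dict[str, tuple[RegionEntry, ...]] = {}
        for name, entries in data.items():
            parsed = []
            for entry in entries:
                unknown = set(entry) - {"chain", "start", "stop", "backbone_only"}
                if unknown:
                    raise ParseError(
                        f"domain map entry for {name!r} has unknown keys {sorted(unknown)}"
                    )
                parsed.append(
                    RegionEntry(
                        chain=str(entry["chain"]),
                        start=int(entry["start"]),
                        stop=int(entry["stop"]),
                        backbone_only=bool(entry.get("backbone_only", False)),
                    )
                )
            regions[name] = tuple(parsed)
        return cls(regions=regions)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "DomainMap":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ParseError(f"domain map {path} is not a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | os.PathLike) -> None:
        data = {
            name: [
                {
                    "chain": e.chain,
                    "start": e.start,
                    "stop": e.stop,
                    "backbone_only": e.backbone_only,
                }
                for e in entries
            ]
            for name, entries in self.regions.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def select(structure: Structure, domain_map: DomainMap, name: str) -> np.ndarray:
    """Resolve a named region to a sorted array of atom indices.

    Deterministic and pure; raises :class:`SelectionError` for unknown names
    or selections that match no atoms.
    """
    if name not in domain_map:
        raise SelectionError(
            f"region {name!r} not defined in domain map (known: {domain_map.names()})"
        )
    mask = np.zeros(structure.n_atoms, dtype=bool)
    for entry in domain_map.regions[name]:
        m = (structure.res_id >= entry.start) & (structure.res_id <= entry.stop)
        if entry.chain != "*":
            m &= structure.chain_id == entry.chain
        if entry.backbone_only:
            m &= np.isin(structure.atom_name, BACKBONE_ATOMS)
        mask |= m
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise SelectionError(f"region {name!r} selects no atoms in this structure")
    return idx


def center_of_mass(structure: Structure, selection=None) -> np.ndarray:
    """Mass-weighted mean position (Angstrom) of a selection (default: all)."""
    if selection is None:
        sub = structure
    else:
        selection = np.asarray(selection, dtype=int)
        if selection.size == 0:
            raise AnalysisError("empty selection has no center of mass")
        sub = structure.subset(selection)
    m = sub.masses()
    return (sub.coords * m[:, None]).sum(axis=0) / m.sum()


def center_of_mass_coords(coords: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """COM for a bare coordinate block; used on trajectory frames."""
    coords = np.asarray(coords, dtype=float)
    return (coords * masses[:, None]).sum(axis=0) / masses.sum()
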