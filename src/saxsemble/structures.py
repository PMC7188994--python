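"""Structures, ensembles and atom selection, with PDB input/output.

Coordinates are stored column-wise (one numpy array per atom attribute),
which keeps distance-matrix and scattering computations vectorised; the
:class:`AtomRecord` row view exists for inspection and tests.  File parsing
and writing are delegated to :mod:`biotite.structure.io.pdb`; alternate
locations are resolved by keeping the highest-occupancy conformer.

Waters are dropped on reading by default: all downstream analyses concern
the protein together with its cofactor/substrate ligands only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio

from .errors import (
    EmptyStructureError,
    EnsembleConsistencyError,
    StructureIOError,
)

WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})

__all__ = [
    "AtomRecord",
    "AtomSelector",
    "Structure",
    "Ensemble",
    "read_structure",
    "write_ensemble",
    "write_structure",
]


@dataclass(frozen=True)
class AtomRecord:
    """A single atom, as one row of a :class:`Structure`."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    icode: str
    chain_id: str
    coords: np.ndarray
    occupancy: float
    b_factor: float
    is_hetero: bool


@dataclass(frozen=True)
class AtomSelector:
    """Conjunctive atom filter: every non-None criterion must match.

    An empty *result* is valid (distinct from an error); an all-None
    selector matches every atom.
    """

    chain: str | Sequence[str] | None = None
    residue_range: tuple[int, int] | None = None
    residue_numbers: Sequence[int] | None = None
    residue_names: str | Sequence[str] | None = None
    atom_names: str | Sequence[str] | None = None
    hetero: bool | None = None

    def _as_set(self, value) -> frozenset[str] | None:
        if value is None:
            return None
        if isinstance(value, str):
            return frozenset({value})
        return frozenset(value)

    def mask(self, structure: "Structure") -> np.ndarray:
        m = np.ones(len(structure), dtype=bool)
        chains = self._as_set(self.chain)
        if chains is not None:
            m &= np.isin(structure.chain_id, sorted(chains))
        if self.residue_range is not None:
            lo, hi = self.residue_range
            m &= (structure.residue_number >= lo) & (structure.residue_number <= hi)
        if self.residue_numbers is not None:
            m &= np.isin(structure.residue_number, np.asarray(self.residue_numbers))
        res_names = self._as_set(self.residue_names)
        if res_names is not None:
            m &= np.isin(structure.residue_name, sorted(res_names))
        names = self._as_set(self.atom_names)
        if names is not None:
            m &= np.isin(structure.atom_name, sorted(names))
        if self.hetero is not None:
            m &= structure.is_hetero == self.hetero
        return m


CA_SELECTOR = AtomSelector(atom_names="CA", hetero=False)


class Structure:
    """One conformer: parallel per-atom arrays plus free-form metadata."""

    def __init__(
        self,
        *,
        serial: np.ndarray,
        atom_name: np.ndarray,
        element: np.ndarray,
        residue_name: np.ndarray,
        residue_number: np.ndarray,
        icode: np.ndarray,
        chain_id: np.ndarray,
        coords: np.ndarray,
        occupancy: np.ndarray,
        b_factor: np.ndarray,
        is_hetero: np.ndarray,
        model_id: int = 1,
        metadata: Mapping | None = None,
    ) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must be an N x 3 array")
        n = coords.shape[0]
        if n == 0:
            raise EmptyStructureError("a Structure must contain at least one atom")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        self.serial = np.asarray(serial, dtype=int)
        self.atom_name = np.asarray(atom_name, dtype="U6")
        self.element = np.asarray(element, dtype="U4")
        self.residue_name = np.asarray(residue_name, dtype="U5")
        self.residue_number = np.asarray(residue_number, dtype=int)
        self.icode = np.asarray(icode, dtype="U2")
        self.chain_id = np.asarray(chain_id, dtype="U4")
        self.coords = coords
        self.occupancy = np.asarray(occupancy, dtype=float)
        self.b_factor = np.asarray(b_factor, dtype=float)
        self.is_hetero = np.asarray(is_hetero, dtype=bool)
        self.model_id = int(model_id)
        self.metadata = dict(metadata or {})
        for arr in (
            self.serial,
            self.atom_name,
            self.element,
            self.residue_name,
            self.residue_number,
            self.icode,
            self.chain_id,
            self.occupancy,
            self.b_factor,
            self.is_hetero,
        ):
            if arr.shape[0] != n:
                raise ValueError("all per-atom arrays must have equal length")

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_atoms(cls, atoms: Iterable[AtomRecord], model_id: int = 1,
                   metadata: Mapping | None = None) -> "Structure":
        atoms = list(atoms)
        if not atoms:
            raise EmptyStructureError("no atoms given")
        return cls(
            serial=np.array([a.serial for a in atoms]),
            atom_name=np.array([a.name for a in atoms]),
            element=np.array([a.element for a in atoms]),
            residue_name=np.array([a.residue_name for a in atoms]),
            residue_number=np.array([a.residue_number for a in atoms]),
            icode=np.array([a.icode for a in atoms]),
            chain_id=np.array([a.chain_id for a in atoms]),
            coords=np.array([a.coords for a in atoms], dtype=float),
            occupancy=np.array([a.occupancy for a in atoms]),
            b_factor=np.array([a.b_factor for a in atoms]),
            is_hetero=np.array([a.is_hetero for a in atoms]),
            model_id=model_id,
            metadata=metadata,
        )

    @classmethod
    def from_coords(
        cls,
        coords: np.ndarray,
        *,
        atom_name: str | Sequence[str] = "CA",
        residue_name: str | Sequence[str] = "GLY",
        chain_id: str | Sequence[str] = "A",
        element: str | Sequence[str] = "C",
        residue_number: Sequence[int] | None = None,
        is_hetero: bool | Sequence[bool] = False,
        model_id: int = 1,
    ) -> "Structure":
        """Build a minimal (e.g. Cα-trace) structure from bare coordinates."""
        coords = np.asarray(coords, dtype=float)
        n = coords.shape[0]

        def expand(v, dtype=None):
            if isinstance(v, (str, bool, int)):
                return np.full(n, v)
            return np.asarray(v)

        if residue_number is None:
            residue_number = np.arange(1, n + 1)
        return cls(
            serial=np.arange(1, n + 1),
            atom_name=expand(atom_name),
            element=expand(element),
            residue_name=expand(residue_name),
            residue_number=np.asarray(residue_number, dtype=int),
            icode=np.full(n, ""),
            chain_id=expand(chain_id),
            coords=coords,
            occupancy=np.ones(n),
            b_factor=np.zeros(n),
            is_hetero=expand(is_hetero),
            model_id=model_id,
        )

    # -- container protocol ---------------------------------------------------

    def __len__(self) -> int:
        return self.coords.shape[0]

    def __getitem__(self, i: int) -> AtomRecord:
        return AtomRecord(
            serial=int(self.serial[i]),
            name=str(self.atom_name[i]),
            element=str(self.element[i]),
            residue_name=str(self.residue_name[i]),
            residue_number=int(self.residue_number[i]),
            icode=str(self.icode[i]),
            chain_id=str(self.chain_id[i]),
            coords=self.coords[i].copy(),
            occupancy=float(self.occupancy[i]),
            b_factor=float(self.b_factor[i]),
            is_hetero=bool(self.is_hetero[i]),
        )

    def __iter__(self) -> Iterator[AtomRecord]:
        return (self[i] for i in range(len(self)))

    # -- operations -----------------------------------------------------------

    def _subset(self, mask_or_index) -> "Structure":
        return Structure(
            serial=self.serial[mask_or_index],
            atom_name=self.atom_name[mask_or_index],
            element=self.element[mask_or_index],
            residue_name=self.residue_name[mask_or_index],
            residue_number=self.residue_number[mask_or_index],
            icode=self.icode[mask_or_index],
            chain_id=self.chain_id[mask_or_index],
            coords=self.coords[mask_or_index],
            occupancy=self.occupancy[mask_or_index],
            b_factor=self.b_factor[mask_or_index],
            is_hetero=self.is_hetero[mask_or_index],
            model_id=self.model_id,
            metadata=self.metadata,
        )

    def select(self, selector: AtomSelector) -> "Structure | None":
        """Atoms matching *selector*, order preserved; None if empty.

        Returning None (rather than raising) keeps the empty selection
        representable; callers that require atoms raise SelectionError.
        """
        mask = selector.mask(self)
        if not mask.any():
            return None
        return self._subset(mask)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        out = self._subset(slice(None))
        coords = np.asarray(coords, dtype=float)
        if coords.shape != out.coords.shape:
            raise ValueError("replacement coords must keep the shape")
        out.coords = coords
        return out

    def atom_identity(self) -> list[tuple[str, int, str, str]]:
        """(chain, residue_number+icode, atom name) identity, for consistency checks."""
        return list(
            zip(
                self.chain_id.tolist(),
                self.residue_number.tolist(),
                self.icode.tolist(),
                self.atom_name.tolist(),
            )
        )

    def __repr__(self) -> str:
        chains = ",".join(sorted(set(self.chain_id.tolist())))
        return f"<Structure model={self.model_id} atoms={len(self)} chains={chains}>"


class Ensemble:
    """Ordered conformers sharing one atom ordering (the object being clustered)."""

    def __init__(self, frames: Sequence[Structure]) -> None:
        frames = list(frames)
        if not frames:
            raise EnsembleConsistencyError("an Ensemble needs at least one frame")
        ref = frames[0].atom_identity()
        for k, fr in enumerate(frames[1:], start=2):
            if fr.atom_identity() != ref:
                raise EnsembleConsistencyError(
                    f"frame {k} does not share the atom identities/order of frame 1"
                )
        self.frames = frames

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, k: int) -> Structure:
        return self.frames[k]

    def __iter__(self) -> Iterator[Structure]:
        return iter(self.frames)

    @property
    def n_atoms(self) -> int:
        return len(self.frames[0])

    def coords(self) -> np.ndarray:
        """(n_frames, n_atoms, 3) coordinate stack."""
        return np.stack([f.coords for f in self.frames])

    def __repr__(self) -> str:
        return f"<Ensemble frames={len(self)} atoms={self.n_atoms}>"


# -- PDB input/output ---------------------------------------------------------


def _from_atom_array(arr: struc.AtomArray, model_id: int,
                     metadata: Mapping | None = None) -> Structure:
    n = arr.array_length()
    serial = (
        arr.get_annotation("atom_id")
        if "atom_id" in arr.get_annotation_categories()
        else np.arange(1, n + 1)
    )
    occupancy = (
        arr.get_annotation("occupancy")
        if "occupancy" in arr.get_annotation_categories()
        else np.ones(n)
    )
    b_factor = (
        arr.get_annotation("b_factor")
        if "b_factor" in arr.get_annotation_categories()
        else np.zeros(n)
    )
    return Structure(
        serial=serial,
        atom_name=arr.atom_name,
        element=arr.element,
        residue_name=arr.res_name,
        residue_number=arr.res_id,
        icode=arr.ins_code,
        chain_id=arr.chain_id,
        coords=arr.coord,
        occupancy=occupancy,
        b_factor=b_factor,
        is_hetero=arr.hetero,
        model_id=model_id,
        metadata=metadata,
    )


def _to_atom_array(s: Structure) -> struc.AtomArray:
    arr = struc.AtomArray(len(s))
    arr.coord = s.coords.astype(np.float32)
    arr.chain_id = s.chain_id
    arr.res_id = s.residue_number
    arr.ins_code = s.icode
    arr.res_name = s.residue_name
    arr.hetero = s.is_hetero
    arr.atom_name = s.atom_name
    arr.element = s.element
    arr.set_annotation("b_factor", s.b_factor)
    arr.set_annotation("occupancy", s.occupancy)
    arr.set_annotation("atom_id", s.serial)
    return arr


def read_structure(
    path: str | Path,
    model_index: int | str = 1,
    *,
    include_waters: bool = False,
) -> Structure | Ensemble:
    """Read a PDB file into a Structure (one model) or Ensemble ("all").

    Alternate locations keep the highest-occupancy conformer.  A file
    without MODEL records yields exactly one Structure; ``model_index="all"``
    returns an Ensemble with one frame per MODEL block and raises
    EnsembleConsistencyError when the models do not share an atom set.
    """
    path = Path(path)
    try:
        pdb_file = pdbio.PDBFile.read(str(path))
    except (OSError, UnicodeDecodeError) as exc:
        raise StructureIOError(f"cannot read {path}: {exc}") from exc

    extra = ["b_factor", "occupancy", "atom_id"]
    n_models = pdb_file.get_model_count()
    metadata = {"path": str(path), "n_models": n_models}

    def get(model: int) -> Structure:
        try:
            arr = pdb_file.get_structure(
                model=model, altloc="occupancy", extra_fields=extra
            )
        except struc.BadStructureError as exc:
            raise EnsembleConsistencyError(str(exc)) from exc
        if arr.array_length() == 0:
            raise EmptyStructureError(f"{path} model {model} has no atoms")
        s = _from_atom_array(arr, model, metadata)
        if not include_waters:
            keep = ~np.isin(s.residue_name, sorted(WATER_NAMES))
            if not keep.any():
                raise EmptyStructureError(f"{path} contains only waters")
            s = s._subset(keep)
        return s

    if model_index == "all":
        frames = [get(m) for m in range(1, n_models + 1)]
        return Ensemble(frames)
    return get(int(model_index))


def write_ensemble(ensemble: Ensemble | Structure, path: str | Path) -> None:
    """Write frames as MODEL/ENDMDL blocks (also for a single frame).

    Coordinates round-trip to the PDB fixed-width precision of 0.001 Å.
    """
    if isinstance(ensemble, Structure):
        ensemble = Ensemble([ensemble])
    arrays = [_to_atom_array(f) for f in ensemble]
    stack = struc.stack(arrays)
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(stack)
    try:
        pdb_file.write(str(path))
    except OSError as exc:
        raise StructureIOError(f"cannot write {path}: {exc}") from exc


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a single conformer without MODEL records."""
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(_to_atom_array(structure))
    try:
        pdb_file.write(str(path))
    except OSError as exc:
        raise StructureIOError(f"cannot write {path}: {exc}") from exc
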