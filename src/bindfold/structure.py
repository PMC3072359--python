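"""PDB-format structure I/O and Cα extraction.

Coordinates are stored internally in nanometres (PDB files are in Ångström;
the conversion is an exact factor of 0.1).  Parsing and writing are backed by
:mod:`biotite.structure.io.pdb`; this module adapts biotite's flat atom arrays
to the chain → residue → atom hierarchy the rest of the pipeline consumes.

By default HETATM records (waters, carbohydrate moieties, ions, ligands) are
excluded, matching the preparation of the crystal structures this pipeline is
meant to ingest.  Alternate locations are resolved to the highest-occupancy
conformer.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as bts
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "AtomRecord",
    "Structure",
    "CalphaChain",
    "EmptyStructureError",
    "read_pdb",
    "extract_calpha",
    "write_structure",
]

logger = logging.getLogger(__name__)

ANGSTROM_TO_NM = 0.1
NM_TO_ANGSTROM = 10.0

# residue names treated as solvent even when not flagged HETATM
_WATER_NAMES = {"HOH", "WAT", "DOD"}


class EmptyStructureError(ValueError):
    """Raised when a file or selection yields no atoms."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a structure, coordinates in nm."""

    chain_id: str
    residue_index: int
    insertion_code: str
    residue_name: str
    atom_name: str
    element: str
    position: np.ndarray  # shape (3,), nm

    @property
    def residue_key(self) -> tuple[int, str]:
        """Composite residue key: deposited index plus insertion code."""
        return (self.residue_index, self.insertion_code)


@dataclass
class Structure:
    """Chains → residues → atoms, residue order as deposited.

    ``residues_by_chain`` maps chain id to an ordered list of residues, each
    residue being a non-empty list of :class:`AtomRecord`.
    """

    residues_by_chain: dict[str, list[list[AtomRecord]]]
    provenance: dict = field(default_factory=dict)

    @property
    def chain_ids(self) -> list[str]:
        return list(self.residues_by_chain.keys())

    def n_atoms(self, chain_id: str | None = None) -> int:
        chains = [chain_id] if chain_id is not None else self.chain_ids
        return sum(
            len(res)
            for cid in chains
            for res in self.residues_by_chain[cid]
        )

    def atoms(self, chain_id: str | None = None):
        """Iterate AtomRecords in file order."""
        chains = [chain_id] if chain_id is not None else self.chain_ids
        for cid in chains:
            for res in self.residues_by_chain[cid]:
                yield from res

    def coordinates(self, chain_id: str | None = None) -> np.ndarray:
        """(n_atoms, 3) array in nm, file order."""
        pos = [a.position for a in self.atoms(chain_id)]
        if not pos:
            raise EmptyStructureError("structure holds no atoms")
        return np.asarray(pos, dtype=float)


@dataclass
class CalphaChain:
    """One-bead-per-residue representation of a chain."""

    chain_id: str
    positions: np.ndarray  # (n_res, 3), nm
    residue_labels: list[str]
    residue_indices: list[int]

    def __len__(self) -> int:
        return len(self.residue_labels)


def _records_from_atom_array(array: bts.AtomArray, source: str) -> Structure:
    residues_by_chain: dict[str, list[list[AtomRecord]]] = {}
    current_key = None
    for i in range(array.array_length()):
        chain_id = str(array.chain_id[i])
        ins = str(array.ins_code[i]) if "ins_code" in array.get_annotation_categories() else ""
        rec = AtomRecord(
            chain_id=chain_id,
            residue_index=int(array.res_id[i]),
            insertion_code=ins,
            residue_name=str(array.res_name[i]),
            atom_name=str(array.atom_name[i]),
            element=str(array.element[i]),
            position=array.coord[i].astype(float) * ANGSTROM_TO_NM,
        )
        chain = residues_by_chain.setdefault(chain_id, [])
        key = (chain_id, rec.residue_index, rec.insertion_code)
        if key != current_key:
            chain.append([])
            current_key = key
        chain[-1].append(rec)
    return Structure(residues_by_chain=residues_by_chain, provenance={"source": source})


def read_pdb(path: str | os.PathLike, model: int = 1, keep_hetero: bool = False) -> Structure:
    """Read one model of a PDB file into a :class:`Structure`.

    Coordinates are converted from Å to nm.  HETATM records (including
    crystallographic waters and carbohydrate moieties) are dropped unless
    ``keep_hetero`` is set.  Alternate locations are resolved to the
    highest-occupancy conformer; ties keep the first encountered.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"PDB file not found: {path}")
    try:
        pdb_file = PDBFile.read(path)
        array = pdb_file.get_structure(model=model, altloc="occupancy")
    except Exception as exc:  # biotite raises various parse errors
        raise ValueError(f"failed to parse PDB file {path!r}: {exc}") from exc

    mask = np.ones(array.array_length(), dtype=bool)
    if not keep_hetero:
        mask &= ~array.hetero
    mask &= ~np.isin(array.res_name, list(_WATER_NAMES))
    array = array[mask]
    if array.array_length() == 0:
        raise EmptyStructureError(
            f"{path!r} model {model} contains no ATOM records after filtering"
        )
    structure = _records_from_atom_array(array, source=path)
    structure.provenance["model"] = model
    return structure


def extract_calpha(structure: Structure, chains: list[str] | None = None) -> list[CalphaChain]:
    """One Cα bead per residue for each requested chain.

    Residues lacking a Cα atom are dropped with a logged warning; the
    returned chain shrinks accordingly.
    """
    if chains is None:
        chains = structure.chain_ids
    unknown = [c for c in chains if c not in structure.residues_by_chain]
    if unknown:
        raise KeyError(
            f"chain(s) {unknown} not present; available: {structure.chain_ids}"
        )
    out = []
    for cid in chains:
        positions, labels, indices = [], [], []
        dropped = 0
        for residue in structure.residues_by_chain[cid]:
            ca = [a for a in residue if a.atom_name == "CA"]
            if not ca:
                dropped += 1
                continue
            positions.append(ca[0].position)
            labels.append(ca[0].residue_name)
            indices.append(ca[0].residue_index)
        if dropped:
            logger.warning(
                "chain %s: dropped %d residue(s) lacking a Calpha atom", cid, dropped
            )
        out.append(
            CalphaChain(
                chain_id=cid,
                positions=np.asarray(positions, dtype=float).reshape(-1, 3),
                residue_labels=labels,
                residue_indices=indices,
            )
        )
    return out


def _structure_to_atom_array(structure: Structure, coords_nm: np.ndarray | None = None) -> bts.AtomArray:
    records = list(structure.atoms())
    n = len(records)
    array = bts.AtomArray(n)
    array.add_annotation("ins_code", dtype="U1")
    if coords_nm is None:
        coords_nm = np.asarray([r.position for r in records], dtype=float)
    for i, rec in enumerate(records):
        array.chain_id[i] = rec.chain_id
        array.res_id[i] = rec.residue_index
        array.ins_code[i] = rec.insertion_code
        array.res_name[i] = rec.residue_name
        array.atom_name[i] = rec.atom_name
        array.element[i] = rec.element if rec.element else rec.atom_name[0]
        array.hetero[i] = False
    array.coord = coords_nm * NM_TO_ANGSTROM
    return array


def write_structure(
    structure: Structure,
    path: str | os.PathLike,
    frames: np.ndarray | list[np.ndarray] | None = None,
) -> None:
    """Write a structure (or a multi-model trajectory) as PDB.

    ``frames``, if given, is a list/array of per-frame coordinate sets in nm
    matching the structure's atom order; each becomes one MODEL block.
    Round trip preserves identities and coordinates to PDB precision
    (3 decimals in Å, i.e. 1e-4 nm).
    """
    if frames is not None:
        frames = [np.asarray(f, dtype=float) for f in frames]
        if len(frames) == 0:
            raise ValueError("empty frame list")
        for k, f in enumerate(frames):
            if not np.isfinite(f).all():
                bad = np.argwhere(~np.isfinite(f))[0]
                raise ValueError(f"non-finite coordinate in frame {k}, atom {bad[0]}")
        stack = bts.stack(
            [_structure_to_atom_array(structure, f) for f in frames]
        )
        pdb_file = PDBFile()
        pdb_file.set_structure(stack)
        pdb_file.write(os.fspath(path))
        return
    coords = structure.coordinates()
    if not np.isfinite(coords).all():
        bad = np.argwhere(~np.isfinite(coords))[0]
        raise ValueError(f"non-finite coordinate at atom {bad[0]}")
    pdb_file = PDBFile()
    pdb_file.set_structure(_structure_to_atom_array(structure))
    pdb_file.write(os.fspath(path))


def structure_from_calpha(
    chains: dict[str, np.ndarray],
    labels: dict[str, list[str]] | None = None,
    provenance: dict | None = None,
) -> Structure:
    """Build a Cα-only Structure from per-chain coordinate arrays (nm)."""
    residues_by_chain: dict[str, list[list[AtomRecord]]] = {}
    for cid, coords in chains.items():
        coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        chain_labels = labels[cid] if labels else ["GLY"] * len(coords)
        residues_by_chain[cid] = [
            [
                AtomRecord(
                    chain_id=cid,
                    residue_index=i + 1,
                    insertion_code="",
                    residue_name=chain_labels[i],
                    atom_name="CA",
                    element="C",
                    position=coords[i].copy(),
                )
            ]
            for i in range(len(coords))
        ]
    return Structure(residues_by_chain=residues_by_chain, provenance=provenance or {})
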