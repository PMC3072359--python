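"""Native and instantaneous contact analysis.

The native contact map is built with a shadow algorithm: atom pairs within a
distance cutoff are kept as contacts unless a third atom occludes the line of
sight between them (an occluding sphere of configurable radius placed on every
candidate shadowing atom).  Atomic maps are collapsed to residue level, where
a residue pair is native iff at least one atomic contact joins the two
residues and the pair respects the minimum sequence separation (no separation
rule applies across chains).  Native residue pairs carry the Cα–Cα distance
``sigma`` of the reference structure, the length scale of the structure-based
pair potential and of the native-contact-fraction order parameters.

Instantaneous (frame) contacts use a plain distance cutoff, independent of the
native map, and are classified into (interfacial vs intrachain) x (native vs
non-native) cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure import CalphaChain, Structure

__all__ = [
    "ContactPair",
    "ContactMap",
    "shadow_contact_map",
    "residue_native_map",
    "cutoff_contacts",
    "classify_contacts",
]

SPAN_A = "intrachain-A"
SPAN_B = "intrachain-B"
SPAN_INTER = "interfacial"

#: default shadow-map parameters (published shadow-algorithm defaults):
#: 6 Å contact cutoff, 1 Å occluding-sphere radius.
DEFAULT_SCM_CUTOFF_NM = 0.6
DEFAULT_SHADOW_RADIUS_NM = 0.1
#: "separated sequentially by at least three residues" read as |i-j| >= 4
#: (three intervening residues), the common Cα model convention.
DEFAULT_MIN_SEQ_SEP = 4


@dataclass(frozen=True)
class ContactPair:
    """A contact between two participants (atoms or residues), i < j."""

    i: int
    j: int
    chain_span: str
    sigma: float | None = None  # native distance, nm (native pairs only)

    def __post_init__(self):
        if self.i == self.j:
            raise ValueError("contact requires two distinct participants")
        if self.i > self.j:
            object.__setattr__(self, "i", self.j)
            object.__setattr__(self, "j", self.i)
        if self.sigma is not None and not self.sigma > 0:
            raise ValueError("native distance sigma must be positive")

    @property
    def key(self) -> tuple[int, int]:
        return (self.i, self.j)


@dataclass
class ContactMap:
    """Set of contacts plus the indexing metadata to interpret them.

    ``index_info`` has one row per participant global index with columns
    chain_id, residue_index (deposited), residue_ordinal (0-based position of
    the residue inside its chain) and atom_name (empty at residue level).
    """

    level: str  # "atomic" | "residue"
    pairs: list[ContactPair]
    index_info: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        keys = [p.key for p in self.pairs]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate contact pairs")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def pair_keys(self) -> set[tuple[int, int]]:
        return {p.key for p in self.pairs}

    def count_by_span(self) -> dict[str, int]:
        counts = {SPAN_A: 0, SPAN_B: 0, SPAN_INTER: 0}
        for p in self.pairs:
            counts[p.chain_span] += 1
        return counts

    def subset(self, span: str) -> list[ContactPair]:
        return [p for p in self.pairs if p.chain_span == span]

    def to_tsv(self, path) -> None:
        rows = []
        info = self.index_info
        for p in self.pairs:
            ri, rj = info.iloc[p.i], info.iloc[p.j]
            rows.append(
                dict(
                    level=self.level,
                    chain_i=ri.chain_id, res_i=ri.residue_index, atom_i=ri.atom_name,
                    chain_j=rj.chain_id, res_j=rj.residue_index, atom_j=rj.atom_name,
                    sigma_nm="" if p.sigma is None else f"{p.sigma:.6f}",
                    span=p.chain_span,
                    nativeness="native" if p.sigma is not None else "unassigned",
                )
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _span(chain_a: str, chain_b: str, first_chain: str) -> str:
    if chain_a != chain_b:
        return SPAN_INTER
    return SPAN_A if chain_a == first_chain else SPAN_B


def _shadowed(coords: np.ndarray, tree: cKDTree, i: int, j: int, radius: float) -> bool:
    """True if any third atom occludes the segment i-j.

    An atom k occludes when its perpendicular distance to the segment is
    below ``radius`` with its projection strictly between the endpoints, and
    it is closer to both endpoints than they are to each other.
    """
    xi, xj = coords[i], coords[j]
    d = xj - xi
    dij = float(np.linalg.norm(d))
    mid = 0.5 * (xi + xj)
    candidates = tree.query_ball_point(mid, 0.5 * dij + radius)
    for k in candidates:
        if k == i or k == j:
            continue
        v = coords[k] - xi
        t = float(np.dot(v, d)) / (dij * dij)
        if not (0.0 < t < 1.0):
            continue
        perp = np.linalg.norm(v - t * d)
        if perp < radius:
            dik = np.linalg.norm(v)
            djk = np.linalg.norm(coords[k] - xj)
            if dik < dij and djk < dij:
                return True
    return False


def _atom_table(structure: Structure, heavy_only: bool) -> pd.DataFrame:
    rows = []
    for cid in structure.chain_ids:
        for ordinal, residue in enumerate(structure.residues_by_chain[cid]):
            for atom in residue:
                if heavy_only and atom.element.upper() == "H":
                    continue
                rows.append(
                    dict(
                        chain_id=cid,
                        residue_index=atom.residue_index,
                        residue_ordinal=ordinal,
                        atom_name=atom.atom_name,
                        x=atom.position[0], y=atom.position[1], z=atom.position[2],
                    )
                )
    return pd.DataFrame(rows)


def shadow_contact_map(
    structure: Structure,
    cutoff: float = DEFAULT_SCM_CUTOFF_NM,
    shadow_radius: float = DEFAULT_SHADOW_RADIUS_NM,
    min_seq_sep: int = DEFAULT_MIN_SEQ_SEP,
    heavy_only: bool = True,
) -> ContactMap:
    """Atomic-level shadow contact map of a (multi-chain) structure.

    Pairs strictly within ``cutoff`` are retained unless occluded by a third
    atom.  Intrachain pairs between residues closer in sequence than
    ``min_seq_sep`` are excluded (local geometry, not a spatial contact);
    atoms of the same residue never form contacts.  Counts are reported split
    into interfacial and per-chain intrachain classes in ``meta``.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if shadow_radius < 0:
        raise ValueError("shadow_radius must be non-negative")
    info = _atom_table(structure, heavy_only=heavy_only)
    if len(info) < 2:
        raise ValueError("structure must contain at least two atoms")
    coords = info[["x", "y", "z"]].to_numpy()
    first_chain = structure.chain_ids[0]
    tree = cKDTree(coords)
    pairs = []
    for i, j in sorted(tree.query_pairs(cutoff)):
        dij = float(np.linalg.norm(coords[i] - coords[j]))
        if not dij < cutoff:  # strict inequality; ties excluded
            continue
        ci, cj = info.chain_id.iat[i], info.chain_id.iat[j]
        oi, oj = info.residue_ordinal.iat[i], info.residue_ordinal.iat[j]
        if ci == cj and abs(oi - oj) < min_seq_sep:
            continue
        if shadow_radius > 0 and _shadowed(coords, tree, i, j, shadow_radius):
            continue
        pairs.append(
            ContactPair(i=i, j=j, chain_span=_span(ci, cj, first_chain), sigma=dij)
        )
    cmap = ContactMap(
        level="atomic",
        pairs=pairs,
        index_info=info,
        meta=dict(cutoff_nm=cutoff, shadow_radius_nm=shadow_radius,
                  min_seq_sep=min_seq_sep,
                  source=structure.provenance.get("source", "")),
    )
    cmap.meta["counts_by_span"] = cmap.count_by_span()
    return cmap


def residue_native_map(
    atomic_map: ContactMap,
    calpha_chains: list[CalphaChain],
    min_seq_sep: int = DEFAULT_MIN_SEQ_SEP,
) -> ContactMap:
    """Collapse an atomic contact map to a residue-level native map.

    A residue pair is native iff at least one atomic contact joins the two
    residues and — for intrachain pairs — the residues are separated by at
    least ``min_seq_sep`` in sequence (no rule across chains).  ``sigma`` is
    the native Cα–Cα distance.
    """
    if atomic_map.level != "atomic":
        raise ValueError("residue_native_map requires an atomic-level map")
    # global residue indexing: concatenation of the given chains
    offsets: dict[str, int] = {}
    rows = []
    off = 0
    for chain in calpha_chains:
        offsets[chain.chain_id] = off
        for k in range(len(chain)):
            rows.append(
                dict(chain_id=chain.chain_id,
                     residue_index=chain.residue_indices[k],
                     residue_ordinal=k, atom_name="")
            )
        off += len(chain)
    info = pd.DataFrame(rows)
    # map (chain, deposited residue index) -> global residue index
    lookup = {
        (r.chain_id, r.residue_index): gi for gi, r in enumerate(info.itertuples())
    }
    first_chain = calpha_chains[0].chain_id
    coords = np.concatenate([c.positions for c in calpha_chains], axis=0)

    ainfo = atomic_map.index_info
    seen: dict[tuple[int, int], str] = {}
    for p in atomic_map.pairs:
        ai, aj = ainfo.iloc[p.i], ainfo.iloc[p.j]
        key_i = (ai.chain_id, ai.residue_index)
        key_j = (aj.chain_id, aj.residue_index)
        if key_i not in lookup or key_j not in lookup:
            raise ValueError(
                f"atomic contact references residue absent from Calpha chains: "
                f"{key_i if key_i not in lookup else key_j}"
            )
        gi, gj = lookup[key_i], lookup[key_j]
        if gi == gj:
            continue
        if gi > gj:
            gi, gj = gj, gi
        if ai.chain_id == aj.chain_id and abs(
            ai.residue_ordinal - aj.residue_ordinal
        ) < min_seq_sep:
            continue
        seen[(gi, gj)] = _span(ai.chain_id, aj.chain_id, first_chain)
    pairs = [
        ContactPair(i=gi, j=gj, chain_span=span,
                    sigma=float(np.linalg.norm(coords[gi] - coords[gj])))
        for (gi, gj), span in sorted(seen.items())
    ]
    cmap = ContactMap(
        level="residue",
        pairs=pairs,
        index_info=info,
        meta=dict(min_seq_sep=min_seq_sep, offsets=offsets,
                  parent=dict(atomic_map.meta)),
    )
    cmap.meta["counts_by_span"] = cmap.count_by_span()
    return cmap


def cutoff_contacts(
    coords: np.ndarray,
    chain_labels: np.ndarray,
    cutoff: float,
    min_seq_sep: int = DEFAULT_MIN_SEQ_SEP,
    residue_ordinals: np.ndarray | None = None,
) -> list[ContactPair]:
    """All bead pairs strictly within ``cutoff``, independent of the native map.

    ``chain_labels`` assigns each bead to a chain (first distinct label is
    chain A).  Intrachain pairs respect the residue-level minimum sequence
    separation; ``residue_ordinals`` defaults to the bead index within its
    chain.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    coords = np.asarray(coords, dtype=float)
    chain_labels = np.asarray(chain_labels)
    first_chain = chain_labels[0]
    if residue_ordinals is None:
        residue_ordinals = np.zeros(len(coords), dtype=int)
        for lab in np.unique(chain_labels):
            m = chain_labels == lab
            residue_ordinals[m] = np.arange(m.sum())
    tree = cKDTree(coords)
    out = []
    for i, j in sorted(tree.query_pairs(cutoff)):
        if not np.linalg.norm(coords[i] - coords[j]) < cutoff:
            continue
        same = chain_labels[i] == chain_labels[j]
        if same and abs(int(residue_ordinals[i]) - int(residue_ordinals[j])) < min_seq_sep:
            continue
        span = _span(str(chain_labels[i]), str(chain_labels[j]), str(first_chain))
        out.append(ContactPair(i=i, j=j, chain_span=span))
    return out


def classify_contacts(
    frame_contacts: list[ContactPair],
    native_map: ContactMap,
    frame_level: str = "residue",
) -> dict[str, int]:
    """Assign every frame contact to one (span, nativeness) cell.

    Cell totals sum to ``len(frame_contacts)`` by construction.  Frame
    contacts must share the native map's level and global indexing.
    """
    if frame_level != native_map.level:
        raise ValueError(
            f"level mismatch: frame contacts are {frame_level!r}, "
            f"native map is {native_map.level!r}"
        )
    native_keys = native_map.pair_keys
    cells = {
        f"{nat}_{span}": 0
        for nat in ("native", "nonnative")
        for span in (SPAN_INTER, SPAN_A, SPAN_B)
    }
    for p in frame_contacts:
        nat = "native" if p.key in native_keys else "nonnative"
        cells[f"{nat}_{p.chain_span}"] += 1
    return cells
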