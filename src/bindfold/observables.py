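"""Reaction coordinates and structural observables.

Two order parameters drive the analysis: the peptide folding fraction Q_f
(fraction of the peptide's intrachain native contacts formed, a contact
counting as formed when the Cα–Cα distance is strictly below 1.2 times its
native distance) and the chain–chain center-of-mass distance D_com.  The
interfacial native fraction Q_interface is kept as a separate coordinate —
binding and folding are deliberately not mixed into one number.

Also here: Kabsch RMSD, per-residue RMSF about an iteratively superposed
mean structure, and a Cα-geometry helix proxy (a stand-in for hydrogen-bond
based secondary-structure assignment, which a Cα-only model cannot support;
it is never claimed to equal DSSP).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contacts import ContactMap, SPAN_B, SPAN_INTER
from .model import CGTopology, com_separation

__all__ = [
    "OrderParamSeries",
    "ResidueProfile",
    "native_pair_arrays",
    "q_fraction",
    "per_residue_interface_q",
    "com_distance",
    "rmsd_kabsch",
    "rmsf",
    "helix_proxy",
    "compute_series",
]

#: contact-formation threshold: formed iff r < FORMED_FACTOR * sigma
FORMED_FACTOR = 1.2


@dataclass
class OrderParamSeries:
    """Per-frame observables of a trajectory."""

    q_f: np.ndarray
    q_interface: np.ndarray
    d_com: np.ndarray
    potential: np.ndarray
    bias_potential: np.ndarray
    contact_counts: pd.DataFrame | None = None

    def __post_init__(self):
        for name in ("q_f", "q_interface"):
            v = getattr(self, name)
            if len(v) and (v.min() < 0 or v.max() > 1):
                raise ValueError(f"{name} outside [0, 1]")

    def __len__(self) -> int:
        return len(self.d_com)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            dict(Q_f=self.q_f, Q_interface=self.q_interface, D_com=self.d_com,
                 potential=self.potential, bias_potential=self.bias_potential)
        )
        if self.contact_counts is not None:
            df = pd.concat([df, self.contact_counts.reset_index(drop=True)], axis=1)
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class ResidueProfile:
    """Per-residue values over the modeled residues."""

    residue_indices: np.ndarray
    values: np.ndarray
    name: str = "value"
    defined: np.ndarray = None  # False where the quantity has no meaning

    def __post_init__(self):
        if self.defined is None:
            self.defined = np.ones(len(self.values), dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"residue": self.residue_indices, self.name: self.values,
             "defined": self.defined}
        )


def native_pair_arrays(
    native_map: ContactMap, span: str
) -> tuple[np.ndarray, np.ndarray]:
    """(pairs, sigma) arrays of the native contacts with the given span."""
    sel = [p for p in native_map.pairs if p.chain_span == span and p.sigma is not None]
    pairs = np.asarray([[p.i, p.j] for p in sel], dtype=int).reshape(-1, 2)
    sigma = np.asarray([p.sigma for p in sel], dtype=float)
    return pairs, sigma


def _formed(coords, pairs, sigma, factor):
    d = np.linalg.norm(coords[pairs[:, 1]] - coords[pairs[:, 0]], axis=1)
    return d < factor * sigma  # strict: ties are not formed


def q_fraction(
    coords: np.ndarray,
    pairs: np.ndarray,
    sigma: np.ndarray,
    factor: float = FORMED_FACTOR,
) -> float:
    """Fraction of the given native pairs formed in one frame."""
    if len(pairs) == 0:
        raise ValueError("q_fraction is undefined for an empty native pair set")
    if factor <= 0:
        raise ValueError("factor must be positive")
    return float(np.count_nonzero(_formed(coords, pairs, sigma, factor)) / len(pairs))


def per_residue_interface_q(
    coords: np.ndarray,
    pairs: np.ndarray,
    sigma: np.ndarray,
    residue_beads: np.ndarray,
    factor: float = FORMED_FACTOR,
) -> ResidueProfile:
    """Per-residue fraction of formed native interfacial contacts.

    ``residue_beads`` lists the bead indices (typically the peptide chain)
    for which the profile is reported; residues with no native interfacial
    pair are marked undefined (NaN).
    """
    formed = _formed(coords, pairs, sigma, factor) if len(pairs) else np.zeros(0, bool)
    total = np.zeros(len(residue_beads))
    hits = np.zeros(len(residue_beads))
    pos = {b: k for k, b in enumerate(residue_beads)}
    for row, ok in zip(pairs, formed):
        for b in row:
            if b in pos:
                total[pos[b]] += 1
                hits[pos[b]] += ok
    defined = total > 0
    values = np.full(len(residue_beads), np.nan)
    values[defined] = hits[defined] / total[defined]
    return ResidueProfile(
        residue_indices=np.asarray(residue_beads),
        values=values, name="Q_i", defined=defined,
    )


def com_distance(coords: np.ndarray, top: CGTopology) -> float:
    """Euclidean distance between the equal-mass centroids of the two chains."""
    return com_separation(np.asarray(coords, dtype=float), top)


def rmsd_kabsch(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Least-squares superposition RMSD (optimal rotation, no reflection)."""
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"coordinate shapes differ: {a.shape} vs {b.shape}")
    if len(a) < 3:
        raise ValueError("need at least 3 points for superposition")
    a0 = a - a.mean(axis=0)
    b0 = b - b.mean(axis=0)
    h = b0.T @ a0
    u, s, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(u @ vt))
    d = np.diag([1.0, 1.0, sign])
    rot = u @ d @ vt
    diff = b0 @ rot - a0
    return float(np.sqrt((diff**2).sum() / len(a)))


def _superpose_onto(mobile: np.ndarray, ref: np.ndarray) -> np.ndarray:
    m0 = mobile - mobile.mean(axis=0)
    r0 = ref - ref.mean(axis=0)
    u, s, vt = np.linalg.svd(m0.T @ r0)
    sign = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, sign]) @ vt
    return m0 @ rot + ref.mean(axis=0)


def rmsf(
    frames: np.ndarray,
    selection: np.ndarray | None = None,
    max_iter: int = 10,
    tol: float = 1e-6,
) -> ResidueProfile:
    """Per-residue RMS fluctuation about the mean structure.

    Frames are iteratively superposed onto the running mean (Kabsch) until
    the mean structure moves by less than ``tol`` nm RMSD or ``max_iter``
    passes.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or len(frames) < 2:
        raise ValueError("rmsf needs at least two frames of shape (n, 3)")
    if selection is not None:
        frames = frames[:, selection, :]
    aligned = frames.copy()
    mean = aligned[0]
    for _ in range(max_iter):
        aligned = np.stack([_superpose_onto(f, mean) for f in aligned])
        new_mean = aligned.mean(axis=0)
        shift = np.sqrt(((new_mean - mean) ** 2).sum(axis=1).mean())
        mean = new_mean
        if shift < tol:
            break
    fluct = np.sqrt(((aligned - mean) ** 2).sum(axis=2).mean(axis=0))
    idx = np.arange(frames.shape[1]) if selection is None else np.asarray(selection)
    return ResidueProfile(residue_indices=idx, values=fluct, name="rmsf_nm")


def helix_proxy(
    positions: np.ndarray,
    d13_range: tuple[float, float] = (0.47, 0.56),
    d14_range: tuple[float, float] = (0.58, 0.68),
) -> np.ndarray:
    """Cα-geometry α-helix flags for one chain.

    A window starting at residue i is helical when both the Cα(i)–Cα(i+3)
    and Cα(i)–Cα(i+4) distances fall into the canonical α-helix ranges; all
    five residues of a passing window are flagged.
    """
    pos = np.asarray(positions, dtype=float)
    n = len(pos)
    flags = np.zeros(n, dtype=bool)
    if n < 5:
        return flags
    for i in range(n - 4):
        d13 = np.linalg.norm(pos[i + 3] - pos[i])
        d14 = np.linalg.norm(pos[i + 4] - pos[i])
        if d13_range[0] <= d13 <= d13_range[1] and d14_range[0] <= d14 <= d14_range[1]:
            flags[i:i + 5] = True
    return flags


def compute_series(
    frames: np.ndarray,
    top: CGTopology,
    native_map: ContactMap,
    potential: np.ndarray | None = None,
    bias_potential: np.ndarray | None = None,
    factor: float = FORMED_FACTOR,
) -> OrderParamSeries:
    """Per-frame (Q_f, Q_interface, D_com) series for trajectory frames.

    Q_f is computed over the peptide's (second chain's) intrachain native
    pairs; Q_interface over the interfacial native pairs.
    """
    frames = np.asarray(frames, dtype=float)
    fold_pairs, fold_sigma = native_pair_arrays(native_map, SPAN_B)
    int_pairs, int_sigma = native_pair_arrays(native_map, SPAN_INTER)
    nf = len(frames)
    q_f = np.empty(nf)
    q_int = np.empty(nf)
    d_com = np.empty(nf)
    for k in range(nf):
        q_f[k] = q_fraction(frames[k], fold_pairs, fold_sigma, factor)
        q_int[k] = q_fraction(frames[k], int_pairs, int_sigma, factor)
        d_com[k] = com_separation(frames[k], top)
    z = np.zeros(nf)
    return OrderParamSeries(
        q_f=q_f,
        q_interface=q_int,
        d_com=d_com,
        potential=z if potential is None else np.asarray(potential, dtype=float),
        bias_potential=(z if bias_potential is None
                        else np.asarray(bias_potential, dtype=float)),
    )
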