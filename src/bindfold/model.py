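"""Two-chain Cα structure-based (Gō-type) model: topology, energies, forces.

The Hamiltonian is the Clementi-style one-bead-per-residue model: harmonic
bonds and angles, a 1-fold + 3-fold torsion, a 10–12 well for native pairs
(minimum −ε at the native Cα–Cα distance σij) and pure r⁻¹² excluded-volume
repulsion for all remaining nonlocal pairs.  Nonlocal means |i−j| ≥ 4 within
a chain, or any pair across chains; intrachain and interchain nonlocal
interactions carry the same strength.  The native structure is the global
minimum by construction: all bonded terms vanish there and every native pair
sits at the bottom of its well.

A harmonic bias on the chain–chain center-of-mass distance,
``V = ½ k (D_com − D0)²``, can be switched on to make binding/unbinding
transitions more frequent; its energy is bookkept separately so sampling can
be unbiased afterwards.

Energies are in reduced units (ε = 1), lengths in nm; forces are the exact
negative analytic gradient of the reported total (finite-difference checked
in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels as _KERNELS
from .contacts import ContactMap
from .structure import CalphaChain, Structure, extract_calpha

__all__ = [
    "ModelParameters",
    "BiasSpec",
    "CGTopology",
    "EnergyReport",
    "build_topology",
    "energy_forces",
    "bias_energy",
    "com_separation",
    "CGSystem",
]

#: Boltzmann constant in the reduced (Gromacs-like) convention used
#: throughout: energy per kelvin with ε = 1 energy unit.
KB = 0.00831446


@dataclass(frozen=True)
class ModelParameters:
    """Force-field constants of the Cα model (reduced energy units, nm)."""

    kb: float = 100.0        # bond, energy/nm² (E = kb (r-r0)²)
    ka: float = 20.0         # angle, energy/rad²
    kd1: float = 1.0         # 1-fold torsion strength
    kd3: float = 0.5         # 3-fold torsion strength
    eps_native: float = 1.0  # native-pair well depth
    eps_nn: float = 1.0      # non-native repulsion strength
    sigma_nn: float = 0.4    # excluded-volume radius, nm
    cutoff: float = 3.0      # nonbonded cutoff, nm

    def __post_init__(self):
        for name in ("kb", "ka", "kd1", "kd3", "eps_native", "eps_nn",
                     "sigma_nn", "cutoff"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class BiasSpec:
    """Harmonic center-of-mass-distance bias ``½ k (D_com − D0)²``."""

    k: float = 0.0    # energy/nm²
    d0: float = 0.0   # nm
    enabled: bool = False

    def __post_init__(self):
        if self.k < 0:
            raise ValueError("bias force constant must be non-negative")

    def potential(self, d_com: np.ndarray | float) -> np.ndarray | float:
        if not self.enabled:
            return np.zeros_like(np.asarray(d_com, dtype=float))
        return 0.5 * self.k * (np.asarray(d_com, dtype=float) - self.d0) ** 2


@dataclass
class CGTopology:
    """Bead topology with native equilibrium geometry baked in."""

    n_beads: int
    chain_of_bead: np.ndarray            # str labels, len n_beads
    chain_slices: dict[str, slice]       # contiguous bead ranges per chain
    bonds: np.ndarray                    # (nb, 2) int
    bond_r0: np.ndarray                  # (nb,) nm
    angles: np.ndarray                   # (na, 3) int
    angle_theta0: np.ndarray             # (na,) rad
    torsions: np.ndarray                 # (nt, 4) int
    torsion_phi0: np.ndarray             # (nt,) rad
    native_pairs: np.ndarray             # (np, 2) int
    native_sigma: np.ndarray             # (np,) nm
    native_span: list[str]               # span label per native pair
    masses: np.ndarray = None            # (n_beads,), default 1.0
    position_restraints: list[tuple[int, np.ndarray, float]] = field(
        default_factory=list
    )  # (bead, x0 (nm), kappa (energy/nm²))
    native_coords: np.ndarray = None     # (n_beads, 3) reference geometry

    def __post_init__(self):
        if self.masses is None:
            self.masses = np.ones(self.n_beads)
        self._nonnative_mask = None

    @property
    def chain_ids(self) -> list[str]:
        return list(self.chain_slices.keys())

    def partition(self) -> tuple[np.ndarray, np.ndarray]:
        """Bead indices of the two chains (receptor first)."""
        ids = self.chain_ids
        if len(ids) != 2:
            raise ValueError(f"expected exactly two chains, got {ids}")
        a = np.arange(self.n_beads)[self.chain_slices[ids[0]]]
        b = np.arange(self.n_beads)[self.chain_slices[ids[1]]]
        if len(a) == 0 or len(b) == 0:
            raise ValueError("empty chain partition")
        return a, b

    def nonnative_indices(self, min_seq_sep: int = 4) -> tuple[np.ndarray, np.ndarray]:
        """Cached (i, j) index arrays of the non-native nonlocal pairs."""
        if getattr(self, "_nn_idx", None) is None:
            ii, jj = np.nonzero(self.nonnative_mask(min_seq_sep))
            self._nn_idx = (np.ascontiguousarray(ii), np.ascontiguousarray(jj))
        return self._nn_idx

    def nonnative_mask(self, min_seq_sep: int = 4) -> np.ndarray:
        """Upper-triangular boolean mask of non-native nonlocal pairs."""
        if self._nonnative_mask is not None:
            return self._nonnative_mask
        n = self.n_beads
        mask = np.zeros((n, n), dtype=bool)
        iu = np.triu_indices(n, k=1)
        mask[iu] = True
        # exclude local intrachain pairs (covered by bonded terms)
        ordinal = np.zeros(n, dtype=int)
        for cid, sl in self.chain_slices.items():
            ordinal[sl] = np.arange(sl.stop - sl.start)
        same_chain = self.chain_of_bead[:, None] == self.chain_of_bead[None, :]
        close = np.abs(ordinal[:, None] - ordinal[None, :]) < min_seq_sep
        mask &= ~(same_chain & close)
        mask[self.native_pairs[:, 0], self.native_pairs[:, 1]] = False
        self._nonnative_mask = mask
        return mask


@dataclass
class EnergyReport:
    """Per-term energies plus forces; total is the exact sum of terms."""

    terms: dict[str, float]
    forces: np.ndarray  # (n_beads, 3), energy/nm
    meta: dict = field(default_factory=dict)

    @property
    def total(self) -> float:
        return float(sum(self.terms.values()))


def build_topology(
    native: Structure | list[CalphaChain],
    residue_map: ContactMap,
    params: ModelParameters,
) -> CGTopology:
    """Assemble the CG topology from the native complex and its residue map.

    Equilibrium bond lengths, angles, torsions and native σij are read off
    the native geometry, so the native coordinates are a stationary point of
    the bonded + native-pair energy.
    """
    if residue_map.level != "residue":
        raise ValueError("build_topology requires a residue-level contact map")
    if isinstance(native, Structure):
        chains = extract_calpha(native)
    else:
        chains = native
    coords = np.concatenate([c.positions for c in chains], axis=0)
    n = len(coords)
    if len(residue_map.index_info) != n:
        raise ValueError(
            f"residue map indexes {len(residue_map.index_info)} residues but the "
            f"native structure provides {n} beads"
        )
    chain_of_bead = np.concatenate(
        [np.full(len(c), c.chain_id, dtype=object) for c in chains]
    )
    chain_slices = {}
    off = 0
    for c in chains:
        chain_slices[c.chain_id] = slice(off, off + len(c))
        off += len(c)

    bonds, angles, torsions = [], [], []
    for c in chains:
        sl = chain_slices[c.chain_id]
        idx = np.arange(sl.start, sl.stop)
        bonds += [(idx[k], idx[k + 1]) for k in range(len(idx) - 1)]
        angles += [(idx[k], idx[k + 1], idx[k + 2]) for k in range(len(idx) - 2)]
        torsions += [tuple(idx[k:k + 4]) for k in range(len(idx) - 3)]
    bonds = np.asarray(bonds, dtype=int).reshape(-1, 2)
    angles = np.asarray(angles, dtype=int).reshape(-1, 3)
    torsions = np.asarray(torsions, dtype=int).reshape(-1, 4)

    native_pairs, native_sigma, native_span = [], [], []
    for p in residue_map.pairs:
        if p.sigma is None:
            continue
        if p.i >= n or p.j >= n:
            raise ValueError(f"native pair ({p.i},{p.j}) references a missing bead")
        native_pairs.append((p.i, p.j))
        native_sigma.append(p.sigma)
        native_span.append(p.chain_span)

    top = CGTopology(
        n_beads=n,
        chain_of_bead=chain_of_bead,
        chain_slices=chain_slices,
        bonds=bonds,
        bond_r0=_bond_lengths(coords, bonds),
        angles=angles,
        angle_theta0=_angles(coords, angles),
        torsions=torsions,
        torsion_phi0=_dihedrals(coords, torsions),
        native_pairs=np.asarray(native_pairs, dtype=int).reshape(-1, 2),
        native_sigma=np.asarray(native_sigma, dtype=float),
        native_span=native_span,
        native_coords=coords.copy(),
    )
    return top


# ---------------------------------------------------------------- geometry

def _bond_lengths(coords, bonds):
    if len(bonds) == 0:
        return np.zeros(0)
    d = coords[bonds[:, 1]] - coords[bonds[:, 0]]
    return np.linalg.norm(d, axis=1)


def _angles(coords, angles):
    if len(angles) == 0:
        return np.zeros(0)
    u = coords[angles[:, 0]] - coords[angles[:, 1]]
    v = coords[angles[:, 2]] - coords[angles[:, 1]]
    cosang = np.einsum("ij,ij->i", u, v) / (
        np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
    )
    return np.arccos(np.clip(cosang, -1.0, 1.0))


def _dihedrals(coords, torsions):
    if len(torsions) == 0:
        return np.zeros(0)
    b1 = coords[torsions[:, 1]] - coords[torsions[:, 0]]
    b2 = coords[torsions[:, 2]] - coords[torsions[:, 1]]
    b3 = coords[torsions[:, 3]] - coords[torsions[:, 2]]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = b2 / np.linalg.norm(b2, axis=1)[:, None]
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", np.cross(n1, n2), b2n)
    return np.arctan2(y, x)


# ---------------------------------------------------------------- energies

def com_separation(coords: np.ndarray, top: CGTopology) -> float:
    """Center-of-mass distance between the two chains (equal bead masses)."""
    a, b = top.partition()
    return float(np.linalg.norm(coords[a].mean(axis=0) - coords[b].mean(axis=0)))


def bias_energy(
    coords: np.ndarray, top: CGTopology, bias: BiasSpec
) -> tuple[float, np.ndarray]:
    """Bias energy and its per-bead forces via the chain rule through the COMs."""
    forces = np.zeros_like(coords)
    if not bias.enabled or bias.k == 0.0:
        return 0.0, forces
    a, b = top.partition()
    com_a, com_b = coords[a].mean(axis=0), coords[b].mean(axis=0)
    delta = com_a - com_b
    d = float(np.linalg.norm(delta))
    energy = 0.5 * bias.k * (d - bias.d0) ** 2
    if d > 1e-12:
        dv = bias.k * (d - bias.d0) * delta / d  # dV/d(com_a)
        forces[a] -= dv / len(a)
        forces[b] += dv / len(b)
    return float(energy), forces


def energy_forces(
    top: CGTopology,
    coords: np.ndarray,
    params: ModelParameters,
    bias: BiasSpec | None = None,
) -> EnergyReport:
    """Evaluate all energy terms and the exact negative gradient.

    Reported terms: bond, angle, torsion, native, nonnative, restraint, bias.
    A bead overlap that drives the repulsion non-finite is flagged in
    ``meta['overlap_pair']`` with the total reported as +inf.  The inner
    loops run through the compiled kernel when numba is available; the numpy
    path below is the reference implementation.
    """
    coords = np.asarray(coords, dtype=float).reshape(top.n_beads, 3)
    if not np.isfinite(coords).all():
        raise ValueError("non-finite coordinates")
    meta = {}
    if _KERNELS.HAVE_NUMBA:
        forces = np.zeros_like(coords)
        nn_i, nn_j = top.nonnative_indices()
        e_bond, e_angle, e_torsion, e_native, e_nn = _KERNELS.cg_energy_forces(
            coords,
            top.bonds, top.bond_r0, params.kb,
            top.angles, top.angle_theta0, params.ka,
            top.torsions, top.torsion_phi0, params.kd1, params.kd3,
            top.native_pairs, top.native_sigma, params.eps_native,
            nn_i, nn_j, params.eps_nn, params.sigma_nn,
            params.cutoff,
            forces,
        )
        terms = dict(bond=e_bond, angle=e_angle, torsion=e_torsion,
                     native=e_native, nonnative=e_nn)
        if not np.isfinite(e_nn):
            d = coords[nn_j] - coords[nn_i]
            r2 = np.einsum("ij,ij->i", d, d)
            worst = int(np.argmin(r2))
            meta["overlap_pair"] = (int(nn_i[worst]), int(nn_j[worst]))
    else:
        terms, forces = _energy_forces_numpy(top, coords, params, meta)
    return _finish_report(top, coords, terms, forces, bias, meta)


def _finish_report(top, coords, terms, forces, bias, meta):
    e_res = 0.0
    for bead, x0, kappa in top.position_restraints:
        dx = coords[bead] - np.asarray(x0, dtype=float)
        e_res += 0.5 * kappa * float(np.dot(dx, dx))
        forces[bead] -= kappa * dx
    terms["restraint"] = e_res
    if bias is not None and bias.enabled:
        e_bias, f_bias = bias_energy(coords, top, bias)
        terms["bias"] = e_bias
        forces += f_bias
    else:
        terms["bias"] = 0.0
    return EnergyReport(terms=terms, forces=forces, meta=meta)


def _energy_forces_numpy(top, coords, params, meta):
    forces = np.zeros_like(coords)
    terms = {}

    # bonds: E = kb (r - r0)^2
    if len(top.bonds):
        d = coords[top.bonds[:, 1]] - coords[top.bonds[:, 0]]
        r = np.linalg.norm(d, axis=1)
        dr = r - top.bond_r0
        terms["bond"] = float(params.kb * np.dot(dr, dr))
        f = (2.0 * params.kb * dr / r)[:, None] * d  # dE/d r_j
        np.add.at(forces, top.bonds[:, 0], f)
        np.add.at(forces, top.bonds[:, 1], -f)
    else:
        terms["bond"] = 0.0

    # angles: E = ka (theta - theta0)^2
    if len(top.angles):
        i, j, k = top.angles.T
        u = coords[i] - coords[j]
        v = coords[k] - coords[j]
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        uh, vh = u / nu[:, None], v / nv[:, None]
        cosang = np.clip(np.einsum("ij,ij->i", uh, vh), -1.0, 1.0)
        theta = np.arccos(cosang)
        sin = np.sqrt(np.clip(1.0 - cosang**2, 1e-12, None))
        dth = theta - top.angle_theta0
        terms["angle"] = float(params.ka * np.dot(dth, dth))
        dEdth = 2.0 * params.ka * dth
        dth_di = (cosang[:, None] * uh - vh) / (nu * sin)[:, None]
        dth_dk = (cosang[:, None] * vh - uh) / (nv * sin)[:, None]
        np.add.at(forces, i, -dEdth[:, None] * dth_di)
        np.add.at(forces, k, -dEdth[:, None] * dth_dk)
        np.add.at(forces, j, dEdth[:, None] * (dth_di + dth_dk))
    else:
        terms["angle"] = 0.0

    # torsions: E = kd1 (1 - cos(phi - phi0)) + kd3 (1 - cos 3(phi - phi0))
    if len(top.torsions):
        ti, tj, tk, tl = top.torsions.T
        b1 = coords[tj] - coords[ti]
        b2 = coords[tk] - coords[tj]
        b3 = coords[tl] - coords[tk]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        nb2 = np.linalg.norm(b2, axis=1)
        x = np.einsum("ij,ij->i", n1, n2)
        y = np.einsum("ij,ij->i", np.cross(n1, n2), b2 / nb2[:, None])
        phi = np.arctan2(y, x)
        dphi = phi - top.torsion_phi0
        terms["torsion"] = float(
            params.kd1 * np.sum(1.0 - np.cos(dphi))
            + params.kd3 * np.sum(1.0 - np.cos(3.0 * dphi))
        )
        dEdphi = params.kd1 * np.sin(dphi) + 3.0 * params.kd3 * np.sin(3.0 * dphi)
        n1sq = np.einsum("ij,ij->i", n1, n1)
        n2sq = np.einsum("ij,ij->i", n2, n2)
        dphi_di = (-nb2 / n1sq)[:, None] * n1
        dphi_dl = (nb2 / n2sq)[:, None] * n2
        t = np.einsum("ij,ij->i", b1, b2) / nb2**2
        s = np.einsum("ij,ij->i", b3, b2) / nb2**2
        dphi_dj = -(1.0 + t)[:, None] * dphi_di + s[:, None] * dphi_dl
        dphi_dk = t[:, None] * dphi_di - (1.0 + s)[:, None] * dphi_dl
        np.add.at(forces, ti, -dEdphi[:, None] * dphi_di)
        np.add.at(forces, tj, -dEdphi[:, None] * dphi_dj)
        np.add.at(forces, tk, -dEdphi[:, None] * dphi_dk)
        np.add.at(forces, tl, -dEdphi[:, None] * dphi_dl)
    else:
        terms["torsion"] = 0.0

    # native pairs: E = eps [5 (sig/r)^12 - 6 (sig/r)^10], truncated at cutoff
    if len(top.native_pairs):
        d = coords[top.native_pairs[:, 1]] - coords[top.native_pairs[:, 0]]
        r = np.linalg.norm(d, axis=1)
        within = r < params.cutoff
        sr = np.where(within, top.native_sigma / np.maximum(r, 1e-6), 0.0)
        sr10 = sr**10
        sr12 = sr**12
        e = params.eps_native * (5.0 * sr12 - 6.0 * sr10)
        terms["native"] = float(e.sum())
        # dE/dr = eps (-60 sr12 + 60 sr10) / r
        dEdr = params.eps_native * 60.0 * (sr10 - sr12) / np.maximum(r, 1e-6)
        f = (dEdr / np.maximum(r, 1e-6))[:, None] * d
        np.add.at(forces, top.native_pairs[:, 0], f)
        np.add.at(forces, top.native_pairs[:, 1], -f)
    else:
        terms["native"] = 0.0

    # non-native: E = eps_nn (sigma_nn / r)^12 over all remaining nonlocal pairs
    mask = top.nonnative_mask()
    ii, jj = np.nonzero(mask)
    if len(ii):
        d = coords[jj] - coords[ii]
        r2 = np.einsum("ij,ij->i", d, d)
        near = r2 < params.cutoff**2
        ii, jj, d, r2 = ii[near], jj[near], d[near], r2[near]
        if len(ii):
            r2 = np.maximum(r2, 1e-4)  # clamp deep overlaps (matches kernel)
            sr12 = (params.sigma_nn**2 / r2) ** 6
            e = params.eps_nn * sr12
            if not np.isfinite(e).all():
                worst = int(np.argmax(~np.isfinite(e)))
                meta["overlap_pair"] = (int(ii[worst]), int(jj[worst]))
                e = np.where(np.isfinite(e), e, np.inf)
            terms["nonnative"] = float(e.sum())
            dEdr_over_r = -12.0 * params.eps_nn * sr12 / r2
            f = dEdr_over_r[:, None] * d
            np.add.at(forces, ii, f)
            np.add.at(forces, jj, -f)
        else:
            terms["nonnative"] = 0.0
    else:
        terms["nonnative"] = 0.0

    return terms, forces


class CGSystem:
    """Potential-interface wrapper: (topology, parameters, bias) → U, forces.

    The same object serves the Langevin sampler and the path optimizer; with
    unit bead masses the mass-weighted and Cartesian coordinates coincide.
    """

    def __init__(self, top: CGTopology, params: ModelParameters,
                 bias: BiasSpec | None = None):
        self.top = top
        self.params = params
        self.bias = bias if bias is not None else BiasSpec()

    @property
    def n_dof(self) -> int:
        return self.top.n_beads * 3

    def energy_forces(self, coords: np.ndarray) -> EnergyReport:
        return energy_forces(self.top, coords, self.params, self.bias)

    def energy_gradient(self, x_flat: np.ndarray) -> tuple[float, np.ndarray]:
        rep = self.energy_forces(x_flat.reshape(-1, 3))
        return rep.total, -rep.forces.ravel()

    def unbiased(self) -> "CGSystem":
        return CGSystem(self.top, self.params, BiasSpec())

    def with_bias(self, bias: BiasSpec) -> "CGSystem":
        return CGSystem(self.top, self.params, bias)
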