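"""Synthetic inputs: toy receptor–peptide complexes, unfolded ensembles,
and analytic 2-D benchmark surfaces with known critical points.

The toy complex emulates the geometry class of a helical inhibitor peptide
lying in the groove of a folded receptor: the peptide is an ideal Cα helix,
the receptor a deterministic compact scaffold (four serpentine strands
forming a channel that encloses one helix face).  The defining property,
mirrored from the real system, is that the interfacial native-contact
network is much larger than the peptide's intrachain one — binding is
energetically dominant over folding.  A "balanced" control spec is provided
so the mechanism-ordering tests do not pass vacuously.

Everything is deterministic under its seed and requires no downloads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contacts import (ContactMap, ContactPair, SPAN_A, SPAN_INTER,
                       residue_native_map, shadow_contact_map)
from .model import BiasSpec, CGSystem, CGTopology, ModelParameters, build_topology
from .observables import native_pair_arrays, q_fraction, rmsd_kabsch
from .sampler import SamplerConfig, run_langevin
from .structure import Structure, structure_from_calpha

__all__ = [
    "ToyComplexSpec",
    "make_toy_complex",
    "toy_native_map",
    "build_toy_system",
    "make_unfolded_ensemble",
    "AnalyticSurface2D",
    "analytic_surface",
    "balanced_control_spec",
]

CA_SPACING = 0.38  # nm, consecutive Cα distance

#: residue-level contact cutoff used for toy native maps (Cα-only beads);
#: typical Cα Gō-model convention.
TOY_RESIDUE_CUTOFF = 0.8


@dataclass(frozen=True)
class ToyComplexSpec:
    receptor_length: int = 40
    peptide_length: int = 12
    groove_depth: float = 0.6         # nm below the helix axis
    groove_half_width: float | None = None  # nm; default: helix radius + 0.45
    helix_rise: float = 0.15          # nm per residue
    helix_turn_deg: float = 100.0     # degrees per residue
    helix_radius: float = 0.23        # nm
    interfacial_contact_target: int = 48
    intrachain_contact_target: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.receptor_length < 5 or self.peptide_length < 5:
            raise ValueError("chains must have at least 5 residues")
        if self.interfacial_contact_target < 1 or self.intrachain_contact_target < 1:
            raise ValueError("contact targets must be >= 1")
        if self.interfacial_contact_target <= self.intrachain_contact_target:
            raise ValueError(
                "interfacial contact target must exceed the intrachain target "
                "(binding-dominant energy balance)"
            )

    @property
    def wall_offset(self) -> float:
        if self.groove_half_width is not None:
            if self.groove_half_width <= self.helix_radius:
                raise ValueError("groove narrower than the helix radius")
            return self.groove_half_width
        return self.helix_radius + 0.45


def balanced_control_spec(seed: int = 0) -> ToyComplexSpec:
    """Control with interfacial barely above intrachain (weak imbalance)."""
    return ToyComplexSpec(interfacial_contact_target=9,
                          intrachain_contact_target=8, seed=seed)


def ideal_helix(n: int, rise: float = 0.15, turn_deg: float = 100.0,
                radius: float = 0.23) -> np.ndarray:
    """Ideal α-helix Cα trace along the x axis, centered at the origin."""
    i = np.arange(n)
    theta = np.deg2rad(turn_deg) * i
    x = rise * i
    coords = np.column_stack([x, radius * np.cos(theta), radius * np.sin(theta)])
    return coords - coords.mean(axis=0)


def make_toy_complex(spec: ToyComplexSpec = ToyComplexSpec()) -> Structure:
    """Two-chain native bound pose: receptor chain R, peptide chain P.

    The peptide helix axis runs along x in a groove formed by four receptor
    strands (two floor strands below, two wall strands at the sides); the
    groove is open toward +z.  A 0.01 nm seeded jitter on receptor beads
    breaks exact symmetry deterministically.
    """
    rng = np.random.Generator(np.random.Philox(spec.seed))
    pep = ideal_helix(spec.peptide_length, spec.helix_rise,
                      spec.helix_turn_deg, spec.helix_radius)

    w = spec.wall_offset
    depth = spec.groove_depth
    # (y, z) of the strand axes plus the pleat direction of each strand;
    # the pleat keeps consecutive beads off a straight line (angles and
    # dihedrals of a Cα chain are degenerate on collinear geometry).
    # Lines are packed ~0.55-0.75 nm apart so every receptor bead carries
    # several intrachain native contacts: the scaffold must stay folded at
    # temperatures where the free peptide helix melts.
    lines = [
        ((-w, 0.0), (-1.0, 0.0)),             # left wall, pleats outward in y
        ((-0.44 * w, -depth), (0.0, -1.0)),   # left floor
        ((0.0, -depth - 0.5), (0.0, -1.0)),   # core, gives the scaffold bulk
        ((0.44 * w, -depth), (0.0, -1.0)),    # right floor
        ((w, 0.0), (1.0, 0.0)),               # right wall
    ]
    pleat = 0.08
    n = spec.receptor_length
    per = [n // 5 + (1 if k < n % 5 else 0) for k in range(5)]
    xs_extent = (max(per) - 1) * CA_SPACING
    beads = []
    for k, (((y, z), (py, pz)), m) in enumerate(zip(lines, per)):
        xs = np.arange(m) * CA_SPACING - xs_extent / 2
        if k % 2 == 1:
            xs = xs[::-1]  # serpentine: keep consecutive strand ends close
        for idx, x in enumerate(xs):
            wiggle = pleat * (1 if idx % 2 == 0 else -1)
            beads.append((x, y + wiggle * py, z + wiggle * pz))
    receptor = np.asarray(beads, dtype=float)
    receptor += 0.01 * rng.standard_normal(receptor.shape)

    return structure_from_calpha(
        {"R": receptor, "P": pep},
        labels={"R": ["ALA"] * len(receptor), "P": ["ALA"] * len(pep)},
        provenance={"source": f"toy_complex(seed={spec.seed})"},
    )


def toy_native_map(structure: Structure, spec: ToyComplexSpec = ToyComplexSpec(),
                   min_seq_sep: int = 4) -> ContactMap:
    """Residue-level native map of a toy complex, tuned toward the requested contact targets.

    Intrachain pairs come from the shadow map at the standard Cα cutoff.
    The interfacial cutoff is then searched (coarse grid, deterministic) so
    the interfacial count lands as close to ``interfacial_contact_target``
    as the geometry permits.
    """
    from .structure import extract_calpha

    chains = extract_calpha(structure)
    base = residue_native_map(
        shadow_contact_map(structure, cutoff=TOY_RESIDUE_CUTOFF,
                           shadow_radius=0.1, min_seq_sep=min_seq_sep),
        chains, min_seq_sep=min_seq_sep,
    )
    intall = [p for p in base.pairs if p.chain_span != SPAN_INTER]

    coords = np.concatenate([c.positions for c in chains], axis=0)
    n_a = len(chains[0])
    # candidate interfacial pairs ranked by native distance
    cand = []
    for i in range(n_a):
        for j in range(n_a, len(coords)):
            d = float(np.linalg.norm(coords[i] - coords[j]))
            cand.append((d, i, j))
    cand.sort()
    best_cut, best_err = TOY_RESIDUE_CUTOFF, None
    for cut in np.arange(0.45, 1.2001, 0.01):
        count = sum(1 for d, _, _ in cand if d < cut)
        err = abs(count - spec.interfacial_contact_target)
        if best_err is None or err < best_err:
            best_err, best_cut = err, float(cut)
    inter = [
        ContactPair(i=i, j=j, chain_span=SPAN_INTER, sigma=d)
        for d, i, j in cand if d < best_cut
    ]
    cmap = ContactMap(
        level="residue",
        pairs=sorted(intall + inter, key=lambda p: p.key),
        index_info=base.index_info,
        meta={**base.meta, "interfacial_cutoff_nm": best_cut,
              "spec_targets": (spec.interfacial_contact_target,
                               spec.intrachain_contact_target)},
    )
    cmap.meta["counts_by_span"] = cmap.count_by_span()
    return cmap


def build_toy_system(
    spec: ToyComplexSpec = ToyComplexSpec(),
    params: ModelParameters = ModelParameters(),
    bias: BiasSpec | None = None,
) -> tuple[Structure, ContactMap, CGTopology, CGSystem]:
    """Convenience: structure, native map, topology and potential in one call."""
    structure = make_toy_complex(spec)
    nmap = toy_native_map(structure, spec)
    top = build_topology(structure, nmap, params)
    return structure, nmap, top, CGSystem(top, params, bias)


def _peptide_subtopology(top: CGTopology) -> CGTopology:
    """Topology of the isolated peptide chain (second chain)."""
    ids = top.chain_ids
    sl = top.chain_slices[ids[1]]
    off = sl.start
    npep = sl.stop - sl.start
    sel = lambda arr: arr[(arr >= off).all(axis=1) & (arr < sl.stop).all(axis=1)] - off
    bonds = sel(top.bonds)
    angles = sel(top.angles)
    torsions = sel(top.torsions)
    keep = [(k, (i, j)) for k, (i, j) in enumerate(top.native_pairs)
            if i >= off and j >= off]
    pairs = np.asarray([p for _, p in keep], dtype=int).reshape(-1, 2) - off
    sigma = top.native_sigma[[k for k, _ in keep]]
    return CGTopology(
        n_beads=npep,
        chain_of_bead=np.full(npep, ids[1], dtype=object),
        chain_slices={ids[1]: slice(0, npep)},
        bonds=bonds, bond_r0=_match(top.bonds, top.bond_r0, off, sl.stop),
        angles=angles, angle_theta0=_match(top.angles, top.angle_theta0, off, sl.stop),
        torsions=torsions, torsion_phi0=_match(top.torsions, top.torsion_phi0, off, sl.stop),
        native_pairs=pairs, native_sigma=sigma,
        native_span=[SPAN_A] * len(pairs),
        native_coords=top.native_coords[sl] if top.native_coords is not None else None,
    )


def _match(terms, values, lo, hi):
    mask = (terms >= lo).all(axis=1) & (terms < hi).all(axis=1)
    return values[mask]


def _random_rotation(rng) -> np.ndarray:
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def make_unfolded_ensemble(
    top: CGTopology,
    params: ModelParameters,
    n: int = 9,
    temperature_factor: float = 3.0,
    seed: int = 0,
    base_temperature: float = 176.0,
    spread_threshold: float = 0.3,
    start_distance: float = 3.0,
    max_steps: int = 400_000,
) -> list[np.ndarray]:
    """Thermally unfolded peptide conformations placed at the start distance.

    The isolated peptide is run at ``temperature_factor`` times the base
    temperature; frames are accepted when unfolded (Q_f < 0.5 against the
    native map) and mutually spread (pairwise Cα RMSD >= ``spread_threshold``
    nm).  Each accepted conformation is placed, randomly oriented, with its
    COM at ``start_distance`` nm from the receptor COM, on the open (+z)
    side of the groove.  Deterministic under ``seed``.
    """
    if temperature_factor <= 1:
        raise ValueError("temperature_factor must exceed 1 (high-T unfolding)")
    pep_top = _peptide_subtopology(top)
    pep_system = CGSystem(pep_top, params)
    start = pep_top.native_coords.copy()
    cfg = SamplerConfig(
        temperature=base_temperature * temperature_factor,
        time_step=0.002, drag_coefficient=1.0,
        n_steps=max_steps, save_every=500, seed=seed,
    )
    traj = run_langevin(pep_system, start, cfg)
    pairs, sigma = native_pair_arrays_from_topology(pep_top)

    rng = np.random.Generator(np.random.Philox(seed + 1))
    accepted: list[np.ndarray] = []
    for frame in traj.coords.astype(float):
        if len(pairs) and q_fraction(frame, pairs, sigma) >= 0.5:
            continue
        if any(rmsd_kabsch(frame, prev) < spread_threshold for prev in accepted):
            continue
        accepted.append(frame)
        if len(accepted) == n:
            break
    if len(accepted) < n:
        raise RuntimeError(
            f"found only {len(accepted)} of {n} spread unfolded conformations; "
            "increase max_steps or lower the spread threshold"
        )

    a, b = top.partition()
    receptor = top.native_coords[a]
    com_r = receptor.mean(axis=0)
    placed = []
    for pep in accepted:
        rot = _random_rotation(rng)
        pep_rot = (pep - pep.mean(axis=0)) @ rot.T
        direction = rng.standard_normal(3)
        direction[2] = abs(direction[2]) + 0.5  # bias toward the open groove side
        direction /= np.linalg.norm(direction)
        frame = np.vstack([receptor, pep_rot + com_r + start_distance * direction])
        placed.append(frame)
    return placed


def native_pair_arrays_from_topology(top: CGTopology):
    return top.native_pairs, top.native_sigma


# ------------------------------------------------------------- 2-D surfaces

@dataclass
class AnalyticSurface2D:
    """Closed-form 2-D benchmark energy with registered critical points."""

    name: str
    _energy: callable
    _gradient: callable
    minima: list[np.ndarray]
    saddles: list[np.ndarray]

    def energy(self, xy: np.ndarray) -> float:
        return float(self._energy(np.asarray(xy, dtype=float)))

    def gradient(self, xy: np.ndarray) -> np.ndarray:
        return np.asarray(self._gradient(np.asarray(xy, dtype=float)), dtype=float)

    # PotentialInterface contract
    def energy_gradient(self, x_flat: np.ndarray) -> tuple[float, np.ndarray]:
        xy = np.asarray(x_flat, dtype=float).ravel()
        return self.energy(xy), self.gradient(xy)


def _newton_polish(surface_grad, surface_hess, x0, tol=1e-12):
    x = np.asarray(x0, dtype=float)
    for _ in range(50):
        g = surface_grad(x)
        if np.linalg.norm(g) < tol:
            break
        x = x - np.linalg.solve(surface_hess(x), g)
    return x


_REGISTRY = {}


def _register(name, energy, gradient, hessian, minima, saddles):
    polished_minima = [_newton_polish(gradient, hessian, m) for m in minima]
    polished_saddles = [_newton_polish(gradient, hessian, s) for s in saddles]
    for pt in polished_minima + polished_saddles:
        if np.linalg.norm(gradient(pt)) >= 1e-8:
            raise RuntimeError(f"critical point of {name} failed to polish: {pt}")
    _REGISTRY[name] = AnalyticSurface2D(
        name=name, _energy=energy, _gradient=gradient,
        minima=polished_minima, saddles=polished_saddles,
    )


def _dw_energy(p):
    x, y = p
    return (x**2 - 1.0) ** 2 + y**2


def _dw_grad(p):
    x, y = p
    return np.array([4.0 * x * (x**2 - 1.0), 2.0 * y])


def _dw_hess(p):
    x, y = p
    return np.array([[12.0 * x**2 - 4.0, 0.0], [0.0, 2.0]])


def _adw_energy(p):
    x, y = p
    return (x**2 - 1.0) ** 2 + 0.3 * x + y**2


def _adw_grad(p):
    x, y = p
    return np.array([4.0 * x * (x**2 - 1.0) + 0.3, 2.0 * y])


def _adw_hess(p):
    x, y = p
    return np.array([[12.0 * x**2 - 4.0, 0.0], [0.0, 2.0]])


def _chan_energy(p):
    x, y = p
    return (x**2 - 1.0) ** 2 + y**2 * (1.0 + 2.0 * x**2)


def _chan_grad(p):
    x, y = p
    return np.array([4.0 * x * (x**2 - 1.0) + 4.0 * x * y**2,
                     2.0 * y * (1.0 + 2.0 * x**2)])


def _chan_hess(p):
    x, y = p
    return np.array([
        [12.0 * x**2 - 4.0 + 4.0 * y**2, 8.0 * x * y],
        [8.0 * x * y, 2.0 + 4.0 * x**2],
    ])


_register("double_well", _dw_energy, _dw_grad, _dw_hess,
          minima=[np.array([-1.0, 0.0]), np.array([1.0, 0.0])],
          saddles=[np.array([0.0, 0.0])])
_register("asym_double_well", _adw_energy, _adw_grad, _adw_hess,
          minima=[np.array([-1.02, 0.0]), np.array([0.98, 0.0])],
          saddles=[np.array([0.04, 0.0])])
_register("entropic_channel", _chan_energy, _chan_grad, _chan_hess,
          minima=[np.array([-1.0, 0.0]), np.array([1.0, 0.0])],
          saddles=[np.array([0.0, 0.0])])


def analytic_surface(name: str) -> AnalyticSurface2D:
    """Look up a registered analytic benchmark surface."""
    if name not in _REGISTRY:
        raise KeyError(f"unknown surface {name!r}; registry: {sorted(_REGISTRY)}")
    return _REGISTRY[name]
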