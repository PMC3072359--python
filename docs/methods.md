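# Methods

## The model

Each residue is one bead at its Cα position. For a two-chain complex
(receptor R, peptide P) the potential energy is

```
U = Σ_bonds    kb (r − r0)²
  + Σ_angles   ka (θ − θ0)²
  + Σ_torsions kd1 [1 − cos(φ − φ0)] + kd3 [1 − cos 3(φ − φ0)]
  + Σ_native   ε [5 (σij/r)¹² − 6 (σij/r)¹⁰]
  + Σ_nonnat   ε_nn (σ_nn/r)¹²
```

with all equilibrium values (r0, θ0, φ0, σij) taken from the native
complex, so the native structure is the global minimum by construction.
Nonbonded pairs are those separated by at least three intervening
residues within a chain (|i−j| ≥ 4, configurable down to ≥ 3) or on
different chains; native pairs are the residue-level native contact map,
everything else is pure excluded volume. Intrachain and interchain native
contacts carry the same well depth ε — the energetic asymmetry between
binding and folding enters only through how many contacts of each class
the native structure has. Enhanced sampling adds a harmonic bias on the
chain–chain center-of-mass distance, V = ½ k (D_com − D0)², bookkept
separately per frame so it can be removed exactly afterwards.

Assumptions worth stating: topological frustration only (no energetic
heterogeneity, no sequence dependence), no electrostatics or desolvation
barriers, equal unit bead masses (so mass-weighted and Cartesian
coordinates coincide), open boundaries (no periodic box — the bias keeps
the pair together).

### Parameters

| parameter | default | units | role |
|---|---|---|---|
| kb | 100 | ε/nm² | bond stiffness (E = kb Δr², no ½) |
| ka | 20 | ε/rad² | angle stiffness |
| kd1, kd3 | 1, 0.5 | ε | torsion barriers |
| ε (native) | 1 | ε | native-pair well depth, all classes |
| ε_nn, σ_nn | 1, 0.4 | ε, nm | excluded volume |
| cutoff | 3.0 | nm | nonbonded truncation (no shift; the 10–12 well is ~10⁻⁹ ε there) |
| bias k, D0 | 1.0, 2.0 | ε/nm², nm | COM-distance bias of the campaign |
| kB | 0.00831446 | ε/K | reduced Boltzmann constant |

The reduced-unit convention mirrors the Gromacs-style structure-based
models this Hamiltonian comes from: ε = 1 energy unit, temperatures
quoted in kelvin-like numbers through kB above. The campaign default is
T = 115 (kBT ≈ 0.96 ε), chosen for the synthetic complex by the same rule
the original study states for its system: below the binding transition
(the complex is stable and the receptor folded, receptor Q ≈ 0.85–0.9)
but above the free peptide's helix melting point (the unbound peptide
spends most of its time below half its native intrachain contacts —
the disordered-when-free premise). A small system with ~2 intrachain
contacts per receptor bead has its transitions at lower reduced
temperatures than a real enzyme with ~3 heavy-atom-derived contacts per
residue; the temperature is a property of the system, not a universal
constant.

## Sampling

BAOAB-splitting Langevin dynamics (friction 1.0 /τ, step 0.005 τ,
velocity randomization from a counter-based Philox stream keyed by the
run seed, so campaigns are reproducible run-by-run and bitwise under
rerun). The configurational accuracy of the integrator is verified by
equipartition in a harmonic well (variance = kBT/κ within 5%) and by
recovering the Boltzmann profile of a 1-D double well to < 0.3 kBT.

The campaign runs 9 trajectories of 250 000 steps (frames every 125
steps): a third from the native complex, the rest from thermally
unfolded peptide conformations (high-temperature run of the isolated
peptide at 3× the campaign temperature, subsampled at mutual Cα-RMSD
≥ 0.3 nm and Q_f < 0.5) placed 3 nm from the receptor at random
orientations. These sizes are the package's desk-scale defaults; they
give ~18 000 frames, enough for the ordering analyses below.

## Free-energy surfaces and the mechanism test

Free energies are F = −ln P in kBT, lowest sampled bin set to zero,
bins with fewer than 5 samples masked (never reported as zero). The
campaign grid is fixed: Q_f on [0, 1] with 20 bins (0.5 is exactly a bin
edge, so "above half" is bin-faithful for a peptide whose Q_f is a
multiple of 1/8) and D_com on [0, 3.6] nm with 40 bins — separations
beyond ~3.5 nm are unbound and excluded from the analysis window.

A single harmonic bias is removed analytically,
F_unb(x) = F_b(x) − V(D_com)/kBT + C, which is exact only when the
binned coordinates contain D_com (enforced). Runs at unequal biases are
combined by self-consistent WHAM with the bias evaluated at bin centers
(the classic bin-based formulation; the single-window case then reduces
exactly to the analytic transform).

The binding-before-folding check works on the unbiased (Q_f, D_com)
surface. For each D_com bin it asks whether the folded population
(Q_f bins lying entirely above 0.5) outnumbers the unfolded one, and it
locates the free-energy barrier of the D_com marginal between the bound
basin and the unbound end. The signature holds when the folded
population is a minority everywhere from the unbound end through the
barrier, becomes the majority only past it, and dominates the bound
basin itself. Two estimator choices matter and are deliberate: (a)
bin-faithful thresholding — a Q_f bin straddling 0.5 is not evidence of
folding; (b) marginalization over Q_f within each D_com bin rather than
an argmin over individual (Q_f, D_com) bins, because with O(10–30)
counts per 2-D bin the argmin flips on Poisson noise while the
marginal population ratio does not. With the default campaign the folded
majority appears only at D_com ≤ ~0.77 nm, past the barrier at
~0.9–1.0 nm, with the bound state at 0.46 nm: the route binds, crosses
the transition region unfolded, and folds during the final descent.

The transition-state ensemble is extracted by closed coordinate ranges
(defaults Q_f ∈ [0.3, 0.5], D_com ∈ [2.2, 2.5] nm — the published window
for the real enzyme–inhibitor system; for the toy campaign the window is
config-exposed) and profiled with the plain cutoff contact algorithm,
independent of the native map, giving per-receptor-residue mean
interfacial contact counts and a pair-frequency map annotated by
nativeness.

## Minimum-action paths

A path is N conformations between fixed endpoints. The action of a most
probable Brownian trajectory is discretized as

```
S = Σ_i exp((U(X_i) + U(X_{i+1})) / 2γ) · |X_{i+1} − X_i| ,
```

γ > 0 playing the role of a thermal energy: γ → ∞ gives the straight
chord (linear interpolation is then optimal — unit-tested), γ → 0 the
steepest-descent limit hugging the minimum-energy valley through the
saddle. What is minimized (Polak–Ribière conjugate gradient over the
interior grids, endpoints immutable) is T = S + ρ Σ (Δlᵢ − ⟨Δl⟩)² + C,
with C a soft Gaussian repulsion between non-adjacent grids that keeps
configurations spread along the pathway. Exponents are clipped at 600
with a matching zero derivative, keeping value and gradient consistent.
If the converged spacing deviation exceeds tolerance (15% relative), ρ is
increased tenfold and minimization continues (up to three rounds).

Initial guesses are linear interpolation followed by a short
clash-removing pre-relaxation (capped per-grid gradient descent with
periodic equal-arc-length reparametrization) — a cheap stand-in for a
self-penalty-walk initial guess; straight-line interpolation between a
coil 3 nm away and the bound complex otherwise drives beads through each
other. For paths on the CG complex γ defaults to 25 ε, on the scale of
half the interfacial binding energy: small enough that the path hugs the
energy valley, large enough that the exponential weights stay in a
numerically meaningful range over the ~140 ε energy span of the binding
funnel.

Correctness anchors: the target gradient matches central finite
differences to < 10⁻⁵; on a 2-D double well the optimized action is
within 5% of an exhaustive Dijkstra shortest path over a 21×21 lattice
with the same edge action, and the path passes within 0.05 of the
independently (Newton) located saddle.

Per-grid profiles report Q_f, Q_interface, receptor Q, cutoff-contact
class counts and helix-proxy flags; the backtracking report lists every
native contact or helical residue that forms, breaks and re-forms along
the grid sequence with its grid intervals.

### Known limitation: path-level ordering

On this potential the optimized kinetic paths fold the peptide before
docking it (Q_f crosses 0.5 near grid 5–8 of 40; Q_interface near grid
32–35), whereas the free-energy route binds first. This is a real
property of minimum-action paths on a structure-based potential, not an
optimizer artifact: folding is unconditionally downhill (−1 ε per
intrachain contact, available anywhere in space) while interfacial
attractions vanish beyond contact range, so at every γ — including the
steepest-descent limit, where the only downhill direction far from the
receptor is folding — the action favors folding during the approach.
The ingredients that delay folding in the real system are configurational
entropy (present in the thermodynamic arm, which accordingly shows
binding first) and attractive non-native interactions (absent from a
Gō-type Hamiltonian, whose non-native term is excluded volume only).
The package reports both arms side by side; the disagreement between
them is itself the informative result at this scale.

## Synthetic systems

The toy complex is deterministic under its seed: the peptide an ideal
α-helix (rise 0.15 nm, 100°/residue, radius 0.23 nm), the receptor five
serpentine strands — two walls, two floor strands and a core — packed
0.55–0.75 nm apart so every receptor bead carries ~2 intrachain contacts
(the scaffold must stay folded at temperatures where the free helix
melts), each strand pleated by ±0.08 nm because a Cα chain's angles and
dihedrals are degenerate on collinear geometry. A 0.01 nm seeded jitter
breaks residual symmetry. The native map takes intrachain pairs from the
shadow map at the 0.8 nm Cα cutoff and selects the interfacial cutoff so
the interfacial count lands on the requested target (default 48 vs 8 peptide
intrachain — the ~6:1 imbalance of the real complex's atomic counts). A
`balanced_control_spec` (9:8) is provided so the ordering tests cannot
pass vacuously.

What the toy does **not** emulate: sequence heterogeneity, side chains,
solvent, electrostatics, the receptor's true size (331 vs 40 residues —
which is why its reduced transition temperatures sit below the real
system's 176 K), and attractive non-native interactions. Tests passing on
the toy therefore validate the machinery and the entropic
binding-before-folding mechanism, not force-field realism.

Analytic 2-D surfaces (`double_well`, `asym_double_well`,
`entropic_channel`) are registered with Newton-polished critical points
(|∇U| < 10⁻⁸) and serve as ground truth for the path optimizer and the
free-energy code.

## Numerical choices and degenerate inputs

- Contact formation and membership use strict inequalities; ties at the
  cutoff or at 1.2 σᵢⱼ count as not formed.
- Altlocs resolve to the highest-occupancy conformer; residues lacking a
  Cα are dropped with a logged warning; HETATM/water/carbohydrate records
  are excluded on reading.
- Å↔nm conversion is the exact factor 0.1.
- Deep bead overlaps (only reachable through pathological inputs such as
  unrelaxed interpolated paths) clamp the repulsion at r² = 10⁻⁴ nm²
  rather than overflowing; a non-finite repulsion is reported as +inf
  with the offending pair.
- The numba kernel and the numpy reference implementation agree to
  10⁻⁹ ε and are interchangeable.
- RMSF uses iterative mean-structure superposition (10 iterations or
  mean shift < 10⁻⁶ nm). With few anchor atoms the least-squares fit
  absorbs part of a single atom's fluctuation; closed-form checks need
  ~dozens of anchors.
- WHAM iterates window shifts to 10⁻⁷; non-overlapping windows trigger a
  warning naming the gap.
- The helix proxy (Cα i→i+3 ∈ [0.47, 0.56] nm and i→i+4 ∈ [0.58, 0.68]
  nm over 5-residue windows) is a geometric stand-in for hydrogen-bond
  based assignment, which a Cα model cannot support; it is never claimed
  to match DSSP.

## Problem sizes

Default desk-scale sizes, chosen once: 52-bead complex; 9 × 250 000
sampling steps; 20 × 40 surface grid with min-count 5; 3 paths of 40
grids; 21×21 lattice oracle; 2–2.5 M steps for the 1-D statistical
checks. The acceptance script re-runs all of it from one seed in a few
minutes on a single CPU.
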