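# bindfold

Coupled binding and folding of an intrinsically disordered peptide at its
receptor, analyzed at two levels with one package: equilibrium
thermodynamics from coarse-grained Langevin sampling, and kinetics from
discrete minimum-action paths.

## The problem

Many regulatory proteins are disordered in isolation and fold only upon
binding their partner. The classic example treated here is the yeast
proteinase-A inhibitor: a peptide that is a random coil free in solution
but folds into an amphipathic α-helix lying in the groove of its target
enzyme. The mechanistic question is one of order: does the peptide fold
first and then dock (conformational selection), or does it bind first and
fold inside the groove (induced fit)?

`bindfold` implements the full analysis chain needed to answer that
question for a two-chain receptor–peptide complex:

- **Structure I/O** (`bindfold.structure`): PDB reading/writing (nm units
  internally), Cα extraction, multi-model trajectory export.
- **Contacts** (`bindfold.contacts`): shadow contact maps (distance cutoff
  plus occluding-sphere line-of-sight test), residue-level native maps
  with the |i−j| ≥ 4 sequence-separation rule, plain cutoff contacts, and
  native/non-native × interfacial/intrachain classification.
- **Model** (`bindfold.model`): a two-chain Cα structure-based (Gō-type)
  Hamiltonian — harmonic bonds/angles, 1-fold+3-fold torsions, a 10–12
  well of depth ε at the native distance σᵢⱼ for every native pair, r⁻¹²
  excluded volume for everything else, and a harmonic center-of-mass
  distance bias ½k(D_com−D₀)² for enhanced sampling. Analytic forces
  (numba-compiled inner loops, numpy reference path).
- **Sampling** (`bindfold.sampler`): BAOAB Langevin dynamics, bitwise
  reproducible under a seed, with per-frame bias-energy bookkeeping.
- **Order parameters** (`bindfold.observables`): folding fraction Q_f
  (peptide intrachain native contacts formed, r < 1.2 σᵢⱼ), interface
  fraction Q_interface, D_com, Kabsch RMSD, iteratively superposed RMSF,
  and a Cα-geometry helix proxy.
- **Free energy** (`bindfold.fes`): F = −ln P surfaces in kBT, analytic
  removal of the harmonic bias (exact whenever the binned coordinates
  contain D_com), multi-window WHAM, transition-state-ensemble extraction
  and interfacial contact profiling, minimum-free-energy routes, and the
  binding-before-folding ordering check.
- **Kinetic paths** (`bindfold.paths`): discrete minimum-action paths
  between fixed endpoints, S = Σᵢ exp((Uᵢ+Uᵢ₊₁)/2γ)·Δlᵢ, minimized by
  conjugate gradient with a spacing restraint and a self-avoidance term;
  per-grid structural profiles and backtracking (form–break–reform)
  detection.
- **Synthetic systems** (`bindfold.synthetic`): a deterministic toy
  receptor–peptide complex (ideal Cα helix in a five-strand groove
  scaffold) whose interfacial native-contact network dominates the
  peptide's intrachain one, thermally generated unfolded-peptide
  ensembles, and analytic 2-D benchmark surfaces with registered critical
  points.
- **Pipeline/CLI** (`bindfold.pipeline`, `bindfold` command): both study
  arms from a YAML config with manifests and full seed provenance.

## Worked example

```python
from bindfold import build_toy_system, com_distance

structure, native_map, topology, system = build_toy_system()
counts = native_map.meta["counts_by_span"]
print(f"chains: {structure.chain_ids}, beads: {topology.n_beads}")
print(f"native contacts  interfacial: {counts['interfacial']}  "
      f"peptide intrachain: {counts['intrachain-B']}  "
      f"receptor intrachain: {counts['intrachain-A']}")
print(f"bound-state COM distance: "
      f"{com_distance(topology.native_coords, topology):.3f} nm")
report = system.energy_forces(topology.native_coords)
print(f"native-state energy: {report.total:.2f} eps "
      f"(native pair term {report.terms['native']:.1f})")
```

prints

```
chains: ['R', 'P'], beads: 52
native contacts  interfacial: 48  peptide intrachain: 8  receptor intrachain: 82
bound-state COM distance: 0.462 nm
native-state energy: -137.97 eps (native pair term -138.0)
```

The 48:8 interfacial:intrachain imbalance is the defining feature of the
synthetic complex — the interface is worth six times the peptide's own
folding energy, the regime in which binding can drive folding. Each native
pair contributes −1 ε at the bound pose, so the native energy is (minus)
the total contact count; the bound chains sit 0.462 nm apart by their
centers of mass.

Running the full thermodynamics arm (`run_thermo`, nine biased Langevin
runs started from the native complex and from unfolded conformations
placed 3 nm away) produces an unbiased free-energy surface over
(Q_f, D_com) whose minimum-free-energy route shows the mechanism: the
folded population becomes the majority only at D_com ≈ 0.77 nm, after the
route has crossed its free-energy barrier at D_com ≈ 0.9–1.0 nm — the
peptide binds before it folds. The kinetics arm (`run_paths`) optimizes
minimum-action paths from each unfolded start to the bound complex and
tabulates, for every path, the grids where Q_interface and Q_f first cross
0.5, plus all backtracking events along the way.

From the shell:

```bash
bindfold toy --seed 0 --out toy.pdb
bindfold sample --seed 1 --steps 100000 --out traj.h5
bindfold thermo --config campaign.yaml --out results/thermo
bindfold paths  --config campaign.yaml --out results/paths
```

For analyses of the deposited enzyme–inhibitor crystal complex, place the
PDB entry `1DP5` at `data/1DP5.pdb`; the structure checks in the test
suite (chain–chain COM distance, shadow-map contact counts) read it from
there.

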