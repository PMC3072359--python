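"""Constant-temperature Langevin (stochastic) dynamics.

The integrator is the BAOAB splitting of underdamped Langevin dynamics,
chosen for its accurate configurational (Boltzmann) sampling at practical
step sizes.  Works on any system exposing ``energy_forces(coords) ->
EnergyReport`` (the CG model, or analytic test systems), with unit masses
unless the system's topology says otherwise.

Reduced units: energies in ε, lengths in nm, kB = 0.00831446 ε/K so that a
temperature printed in kelvin-like numbers matches the Gromacs-style
convention of the structure-based model.  Randomness comes from a
counter-based (Philox) generator keyed by the run seed, so multi-run
campaigns are reproducible run by run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import h5py
import numpy as np

from .model import KB, BiasSpec

__all__ = ["SamplerConfig", "Trajectory", "run_langevin"]


@dataclass(frozen=True)
class SamplerConfig:
    temperature: float = 176.0      # reduced kelvin (kBT = KB * T in ε)
    time_step: float = 0.005        # reduced time
    drag_coefficient: float = 1.0   # 1/time
    n_steps: int = 1000
    save_every: int = 100
    seed: int = 0
    bias: BiasSpec = field(default_factory=BiasSpec)

    def __post_init__(self):
        if self.time_step <= 0:
            raise ValueError("time_step must be positive")
        if self.n_steps < 1 or self.save_every < 1:
            raise ValueError("n_steps and save_every must be >= 1")
        if self.temperature < 0:
            raise ValueError("temperature must be non-negative")

    @property
    def kbt(self) -> float:
        return KB * self.temperature


@dataclass
class Trajectory:
    """Saved frames with per-frame energy bookkeeping."""

    coords: np.ndarray        # (n_frames, n_beads, 3) float32, nm
    times: np.ndarray         # (n_frames,) reduced time
    potential: np.ndarray     # (n_frames,) unbiased potential energy
    bias_potential: np.ndarray  # (n_frames,) bias energy (0 if no bias)
    config: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite coordinates in trajectory")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def save(self, path) -> None:
        with h5py.File(path, "w") as h5:
            h5.create_dataset("coords", data=self.coords.astype(np.float32))
            h5.create_dataset("times", data=self.times.astype(np.float64))
            h5.create_dataset("potential", data=self.potential.astype(np.float64))
            h5.create_dataset("bias_potential",
                              data=self.bias_potential.astype(np.float64))
            for key, val in self.config.items():
                h5.attrs[key] = val

    @classmethod
    def load(cls, path) -> "Trajectory":
        with h5py.File(path, "r") as h5:
            return cls(
                coords=h5["coords"][...],
                times=h5["times"][...],
                potential=h5["potential"][...],
                bias_potential=h5["bias_potential"][...],
                config=dict(h5.attrs),
            )


def _flat_config(cfg: SamplerConfig) -> dict:
    d = asdict(cfg)
    b = d.pop("bias")
    d.update({f"bias_{k}": v for k, v in b.items()})
    return d


def run_langevin(system, start: np.ndarray, cfg: SamplerConfig) -> Trajectory:
    """BAOAB Langevin trajectory of ``system`` from ``start`` coordinates.

    ``system`` must provide ``energy_forces(coords) -> EnergyReport`` whose
    terms include a ``bias`` entry (zero when unbiased); if it has a ``top``
    with masses those are used, else unit masses.  Identical (seed, config,
    start) gives a bitwise-identical trajectory.
    """
    x = np.array(start, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3:
        raise ValueError("start coordinates must have shape (n_beads, 3)")
    n = x.shape[0]
    top = getattr(system, "top", None)
    if top is not None and top.n_beads != n:
        raise ValueError(
            f"start has {n} beads but topology expects {top.n_beads}"
        )
    masses = (top.masses if top is not None else np.ones(n)).reshape(n, 1)

    dt = cfg.time_step
    kbt = cfg.kbt
    rng = np.random.Generator(np.random.Philox(cfg.seed))
    c1 = np.exp(-cfg.drag_coefficient * dt)
    c2 = np.sqrt(max(0.0, 1.0 - c1 * c1))
    sigma_v = np.sqrt(kbt / masses)

    v = rng.standard_normal(x.shape) * sigma_v if kbt > 0 else np.zeros_like(x)
    rep = system.energy_forces(x)
    f = rep.forces

    n_saved = cfg.n_steps // cfg.save_every
    coords = np.empty((n_saved, n, 3), dtype=np.float32)
    times = np.empty(n_saved)
    potential = np.empty(n_saved)
    bias_potential = np.empty(n_saved)
    k = 0
    for step in range(1, cfg.n_steps + 1):
        v += 0.5 * dt * f / masses
        x += 0.5 * dt * v
        if kbt > 0:
            v = c1 * v + c2 * sigma_v * rng.standard_normal(x.shape)
        else:
            v = c1 * v
        x += 0.5 * dt * v
        rep = system.energy_forces(x)
        f = rep.forces
        if not np.isfinite(x).all() or not np.isfinite(f).all():
            fmax = float(np.nanmax(np.abs(f)))
            raise FloatingPointError(
                f"integration diverged at step {step}; largest |force| {fmax:.3e}"
            )
        v += 0.5 * dt * f / masses
        if step % cfg.save_every == 0:
            coords[k] = x
            times[k] = step * dt
            bias_potential[k] = rep.terms.get("bias", 0.0)
            potential[k] = rep.total - bias_potential[k]
            k += 1
    return Trajectory(
        coords=coords,
        times=times,
        potential=potential,
        bias_potential=bias_potential,
        config=_flat_config(cfg),
    )
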