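"""Campaign orchestration: thermodynamics arm and kinetics arm.

``run_thermo`` runs the biased multi-start Langevin campaign on a complex,
reconstructs the biased and unbiased (Q_f, D_com) free-energy surfaces,
and characterizes the transition-state ensemble.  ``run_paths`` optimizes
one minimum-action path per unfolded start and profiles each along its
grids.  Every artifact is listed in a manifest keyed by a config hash, and
all randomness flows from the seeds recorded in the config, so reruns are
bitwise reproducible.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fes import (TSERegion, biased_surface, extract_tse,
                  minimum_free_energy_route, tse_contact_profile, unbias_surface)
from .model import KB, BiasSpec, CGSystem, ModelParameters
from .observables import compute_series, rmsf
from .paths import (PathSpec, init_path_linear, optimize_sdp,
                    prerelax_path, profile_path)
from .sampler import SamplerConfig, run_langevin
from .structure import write_structure
from .synthetic import (ToyComplexSpec, build_toy_system, make_unfolded_ensemble)

__all__ = ["RunConfig", "run_thermo", "run_paths"]


@dataclass
class RunConfig:
    """Inputs and knobs of one campaign (toy-complex input source)."""

    toy: ToyComplexSpec = field(default_factory=ToyComplexSpec)
    params: ModelParameters = field(default_factory=ModelParameters)
    bias: BiasSpec = field(default_factory=lambda: BiasSpec(k=1.0, d0=2.0, enabled=True))
    temperature: float = 115.0
    time_step: float = 0.005
    drag_coefficient: float = 1.0
    n_runs: int = 9
    n_steps: int = 250_000
    save_every: int = 125
    base_seed: int = 0
    bins: int = 40
    q_edges: tuple = (0.0, 1.0 + 1e-9, 20)   # 0.5 falls exactly on a bin edge
    d_edges: tuple = (0.0, 3.6, 40)          # region of interest; > 3.5 nm is unbound
    min_count: int = 5
    tse_region: dict = field(default_factory=lambda: {"Q_f": (0.3, 0.5),
                                                      "D_com": (2.2, 2.5)})
    contact_cutoff: float = 0.8
    n_paths: int = 3
    path_grids: int = 40
    path_gamma: float = 25.0   # action energy scale ~ half the binding energy
    path_rho: float = 100.0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "toy" in raw:
            kwargs["toy"] = ToyComplexSpec(**raw.pop("toy"))
        if "params" in raw:
            kwargs["params"] = ModelParameters(**raw.pop("params"))
        if "bias" in raw:
            kwargs["bias"] = BiasSpec(**raw.pop("bias"))
        kwargs.update(raw)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    @property
    def kbt(self) -> float:
        return KB * self.temperature

    @property
    def gamma(self) -> float:
        return self.path_gamma


def _manifest(config: RunConfig, outputs: dict, outdir, arm: str) -> dict:
    manifest = dict(
        tool="bindfold", version=__version__, arm=arm,
        config=config.to_dict(), config_hash=config.digest(),
        seeds=[config.base_seed + i for i in range(config.n_runs)],
        outputs=outputs,
    )
    with open(os.path.join(outdir, f"manifest_{arm}.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def run_thermo(config: RunConfig, outdir: str) -> dict:
    """Thermodynamics arm: sample → surfaces → TSE report.

    Returns a bundle dict with the trajectories, series, surfaces, TSE
    indices/profile and manifest; files are written under ``outdir``.
    """
    os.makedirs(outdir, exist_ok=True)
    structure, nmap, top, system = build_toy_system(
        config.toy, config.params, config.bias
    )
    native = top.native_coords
    starts = [native.copy()]
    n_unbound = max(config.n_runs - max(config.n_runs // 3, 1), 0)
    if n_unbound:
        ensemble = make_unfolded_ensemble(
            top, config.params, n=n_unbound, temperature_factor=3.0,
            seed=config.base_seed + 1000, base_temperature=config.temperature,
        )
        starts += ensemble
    while len(starts) < config.n_runs:
        starts.append(native.copy())
    starts = starts[: config.n_runs]

    trajectories, series_list = [], []
    outputs = {"series": [], "trajectories": []}
    for i, start in enumerate(starts):
        cfg = SamplerConfig(
            temperature=config.temperature, time_step=config.time_step,
            drag_coefficient=config.drag_coefficient, n_steps=config.n_steps,
            save_every=config.save_every, seed=config.base_seed + i,
            bias=config.bias,
        )
        traj = run_langevin(system, start, cfg)
        series = compute_series(traj.coords.astype(float), top, nmap,
                                potential=traj.potential,
                                bias_potential=traj.bias_potential)
        tsv = os.path.join(outdir, f"series_run{i}.tsv")
        series.to_tsv(tsv)
        outputs["series"].append(tsv)
        h5 = os.path.join(outdir, f"traj_run{i}.h5")
        traj.save(h5)
        outputs["trajectories"].append(h5)
        trajectories.append(traj)
        series_list.append(series)

    grid = [np.linspace(*config.q_edges[:2], int(config.q_edges[2]) + 1),
            np.linspace(*config.d_edges[:2], int(config.d_edges[2]) + 1)]
    surf_b = biased_surface(series_list, names=["Q_f", "D_com"],
                            edges=grid, min_count=config.min_count)
    surf_u = unbias_surface(surf_b, config.bias, config.temperature)
    for tag, surf in (("biased", surf_b), ("unbiased", surf_u)):
        tsv = os.path.join(outdir, f"surface_{tag}.tsv")
        surf.to_tsv(tsv)
        surf.plot(os.path.join(outdir, f"surface_{tag}.png"))
        outputs[f"surface_{tag}"] = tsv

    region = TSERegion(ranges=config.tse_region)
    all_frames = np.concatenate([t.coords.astype(float) for t in trajectories])
    pooled = pd.concat([s.to_frame() for s in series_list], ignore_index=True)
    tse_idx = extract_tse(pooled, region)
    profile, freq = tse_contact_profile(
        all_frames[tse_idx] if len(tse_idx) else all_frames[:1],
        top, config.contact_cutoff, nmap,
    )
    profile.to_csv(os.path.join(outdir, "tse_contact_profile.tsv"),
                   sep="\t", index=False)
    freq.to_csv(os.path.join(outdir, "tse_pair_frequency.tsv"),
                sep="\t", index=False)
    a, _ = top.partition()
    receptor_rmsf = rmsf(all_frames, selection=a)
    receptor_rmsf.to_frame().to_csv(os.path.join(outdir, "receptor_rmsf.tsv"),
                                    sep="\t", index=False)
    outputs["tse"] = dict(n_frames=int(len(tse_idx)))

    manifest = _manifest(config, outputs, outdir, "thermo")
    return dict(
        structure=structure, native_map=nmap, topology=top,
        trajectories=trajectories, series=series_list,
        surface_biased=surf_b, surface_unbiased=surf_u,
        route=minimum_free_energy_route(surf_u),
        tse_indices=tse_idx, tse_profile=profile, tse_pairs=freq,
        receptor_rmsf=receptor_rmsf, manifest=manifest,
    )


def _first_crossing(values: np.ndarray, threshold: float = 0.5) -> int | None:
    above = np.nonzero(np.asarray(values) > threshold)[0]
    return int(above[0]) if len(above) else None


def run_paths(config: RunConfig, outdir: str) -> dict:
    """Kinetics arm: one optimized minimum-action path per unfolded start."""
    os.makedirs(outdir, exist_ok=True)
    structure, nmap, top, _ = build_toy_system(config.toy, config.params)
    system = CGSystem(top, config.params)  # unbiased potential for paths
    native = top.native_coords
    starts = make_unfolded_ensemble(
        top, config.params, n=config.n_paths, temperature_factor=3.0,
        seed=config.base_seed + 2000, base_temperature=config.temperature,
    )
    spec = PathSpec(n_grids=config.path_grids, gamma=config.gamma,
                    rho=config.path_rho)
    outputs = {"paths": []}
    results, summary = [], []
    for k, start in enumerate(starts):
        init = init_path_linear(start.ravel(), native.ravel(), spec.n_grids)
        init = prerelax_path(init, system, u_stop=50.0)
        status = "ok"
        try:
            path = optimize_sdp(init, system, spec)
        except RuntimeError as exc:
            status = f"failed: {exc}"
            path = init
        prof, backtrack = profile_path(path, top, nmap, potential=system,
                                       cutoff=config.contact_cutoff)
        base = os.path.join(outdir, f"path{k}")
        prof.to_csv(base + "_profile.tsv", sep="\t", index=False)
        backtrack.to_csv(base + "_backtracking.tsv", sep="\t", index=False)
        write_structure(structure, base + ".pdb",
                        frames=path.grids.reshape(path.n_grids, -1, 3))
        outputs["paths"].append(base + "_profile.tsv")
        summary.append(dict(
            path=k, status=status,
            q_interface_crossing=_first_crossing(prof["Q_interface"]),
            q_f_crossing=_first_crossing(prof["Q_f"]),
        ))
        results.append(dict(path=path, profile=prof, backtracking=backtrack,
                            status=status))
    summary_df = pd.DataFrame(summary)
    summary_df.to_csv(os.path.join(outdir, "path_summary.tsv"),
                      sep="\t", index=False)
    manifest = _manifest(config, outputs, outdir, "paths")
    return dict(structure=structure, native_map=nmap, topology=top,
                paths=results, summary=summary_df, manifest=manifest)
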