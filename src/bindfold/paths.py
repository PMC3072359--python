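"""Discrete minimum-action ("steepest descent") kinetic paths.

A path between two fixed endpoint conformations is a grid of N conformations
X_0 … X_{N-1} in mass-weighted coordinates (unit bead masses here, so
Cartesian and mass-weighted coincide).  The action of a most probable
Brownian trajectory is discretized as

    S = sum_i exp( (U(X_i) + U(X_{i+1})) / (2 gamma) ) * |X_{i+1} - X_i| ,

with gamma a positive energy parameter playing the role of a thermal
energy: for gamma -> infinity every segment weight tends to one and the
optimum is the straight line (shortest path, i.e. the linear
interpolation); for gamma -> 0 the optimum approaches the steepest-descent
path hugging the minimum-energy valley through the saddle.

What is minimized is the target function

    T = S + rho * sum_i (dl_i - <dl>)^2 + C ,

where the rho term restrains every step length to the average length and C
is a soft repulsion between non-adjacent grids that keeps configurations
distributed along the pathway instead of clumping.  Minimization is
conjugate-gradient over the interior grids; the endpoints never move.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "PathSpec",
    "DiscretePath",
    "validate_potential",
    "init_path_linear",
    "action",
    "target",
    "optimize_sdp",
    "prerelax_path",
    "reparametrize_equal",
    "profile_path",
    "detect_backtracking",
]

logger = logging.getLogger(__name__)

#: exponent clip: beyond this the segment weight saturates (and its
#: energy-derivative is zero, keeping value and gradient consistent)
EXP_CLIP = 600.0


@dataclass(frozen=True)
class PathSpec:
    n_grids: int = 100
    gamma: float = 1.0          # action energy parameter, > 0
    rho: float = 100.0          # spacing-penalty strength
    c_repulsion: float = 0.01   # strength of the non-adjacent-grid restraint
    max_iter: int = 2000
    grad_tol: float = 1e-6
    spacing_tol: float = 0.15   # relative spacing deviation accepted

    def __post_init__(self):
        if self.n_grids < 3:
            raise ValueError("need at least 3 grids")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.rho < 0 or self.c_repulsion < 0:
            raise ValueError("restraint strengths must be non-negative")


@dataclass
class DiscretePath:
    """Ordered grid of conformations with immutable endpoints."""

    grids: np.ndarray  # (N, dof)

    def __post_init__(self):
        self.grids = np.asarray(self.grids, dtype=float)
        if self.grids.ndim != 2 or len(self.grids) < 3:
            raise ValueError("path must be (N >= 3, dof)")

    @property
    def n_grids(self) -> int:
        return len(self.grids)

    @property
    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.grids, axis=0), axis=1)

    @property
    def spacing_deviation(self) -> float:
        dl = self.segment_lengths
        mean = dl.mean()
        if mean == 0:
            return 0.0
        return float(np.max(np.abs(dl - mean)) / mean)

    def reversed(self) -> "DiscretePath":
        return DiscretePath(self.grids[::-1].copy())


def validate_potential(potential, x0: np.ndarray, rel_tol: float = 1e-4) -> None:
    """Check gradient/energy consistency by central finite differences."""
    x0 = np.asarray(x0, dtype=float).ravel()
    _, g = potential.energy_gradient(x0)
    h = 1e-6
    num = np.empty_like(g)
    for k in range(len(x0)):
        xp, xm = x0.copy(), x0.copy()
        xp[k] += h
        xm[k] -= h
        num[k] = (potential.energy_gradient(xp)[0]
                  - potential.energy_gradient(xm)[0]) / (2 * h)
    scale = max(np.abs(num).max(), 1.0)
    if np.abs(num - g).max() > rel_tol * scale:
        raise ValueError("potential gradient inconsistent with energy")


def init_path_linear(x_start: np.ndarray, x_end: np.ndarray, n: int) -> DiscretePath:
    """Linear-interpolation initial path with exactly uniform spacing."""
    a = np.asarray(x_start, dtype=float).ravel()
    b = np.asarray(x_end, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("endpoint dimensionality mismatch")
    if n < 3:
        raise ValueError("need at least 3 grids")
    t = np.linspace(0.0, 1.0, n)[:, None]
    return DiscretePath(a[None, :] * (1 - t) + b[None, :] * t)


def _grid_energies(path: DiscretePath, potential) -> tuple[np.ndarray, np.ndarray]:
    u = np.empty(path.n_grids)
    grads = np.empty_like(path.grids)
    for i, x in enumerate(path.grids):
        try:
            u[i], grads[i] = potential.energy_gradient(x)
        except Exception as exc:
            raise RuntimeError(f"potential evaluation failed at grid {i}: {exc}")
    return u, grads


def _segment_weights(u: np.ndarray, gamma: float) -> tuple[np.ndarray, np.ndarray]:
    """exp((U_i + U_{i+1}) / 2 gamma) per segment, with saturating clip."""
    expo = (u[:-1] + u[1:]) / (2.0 * gamma)
    clipped = expo > EXP_CLIP
    w = np.exp(np.minimum(expo, EXP_CLIP))
    dw_du = np.where(clipped, 0.0, w / (2.0 * gamma))  # dw/dU_i = dw/dU_{i+1}
    return w, dw_du


def action(path: DiscretePath, potential, gamma: float) -> float:
    """Discretized most-probable-Brownian-path action S."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    u, _ = _grid_energies(path, potential)
    w, _ = _segment_weights(u, gamma)
    return float(np.dot(w, path.segment_lengths))


def target(
    path: DiscretePath, potential, spec: PathSpec
) -> tuple[float, np.ndarray]:
    """Target function T = S + spacing penalty + C and its full gradient.

    The gradient is with respect to every grid; rows 0 and N-1 are zeroed —
    endpoints are not degrees of freedom.
    """
    x = path.grids
    n, dof = x.shape
    u, du = _grid_energies(path, potential)
    diffs = np.diff(x, axis=0)
    dl = np.linalg.norm(diffs, axis=1)
    dl_safe = np.maximum(dl, 1e-300)
    unit = diffs / dl_safe[:, None]
    mean = dl.mean()
    m = len(dl)

    w, dw_du = _segment_weights(u, spec.gamma)
    s_val = float(np.dot(w, dl))

    grad = np.zeros_like(x)
    # dS through segment lengths
    seg_pref = w[:, None] * unit
    grad[:-1] -= seg_pref
    grad[1:] += seg_pref
    # dS through grid energies: U_i enters segments i-1 and i
    coeff = np.zeros(n)
    coeff[:-1] += dw_du * dl
    coeff[1:] += dw_du * dl
    grad += coeff[:, None] * du

    # spacing penalty: rho * sum (dl_i - mean)^2 ; d/d dl_k = 2 rho (dl_k - mean)
    pen = float(spec.rho * np.sum((dl - mean) ** 2))
    dpen_dl = 2.0 * spec.rho * (dl - mean)
    pen_pref = dpen_dl[:, None] * unit
    grad[:-1] -= pen_pref
    grad[1:] += pen_pref

    # C: repulsion between non-adjacent grids, scaled by the mean spacing
    c_val = 0.0
    if spec.c_repulsion > 0 and mean > 0:
        ii, jj = np.triu_indices(n, k=2)
        d = x[ii] - x[jj]
        dist2 = np.einsum("ij,ij->i", d, d)
        e = np.exp(-dist2 / mean**2)
        c_val = float(spec.c_repulsion * e.sum())
        pref = spec.c_repulsion * e * (-2.0 / mean**2)
        np.add.at(grad, ii, pref[:, None] * d)
        np.add.at(grad, jj, -pref[:, None] * d)
        # chain rule through the mean spacing
        dc_dmean = float(spec.c_repulsion * np.sum(e * 2.0 * dist2 / mean**3))
        dmean_pref = (dc_dmean / m) * unit
        grad[:-1] -= dmean_pref
        grad[1:] += dmean_pref

    grad[0] = 0.0
    grad[-1] = 0.0
    return s_val + pen + c_val, grad


def optimize_sdp(path: DiscretePath, potential, spec: PathSpec) -> DiscretePath:
    """Conjugate-gradient minimization of T over the interior grids.

    The endpoints are never touched.  If the optimized spacing deviation
    exceeds ``spec.spacing_tol`` the spacing penalty is strengthened and
    minimization continues from the current path (up to three rounds).
    """
    x0, x_end = path.grids[0].copy(), path.grids[-1].copy()
    n, dof = path.grids.shape
    t_init, _ = target(path, potential, spec)

    def pack(grids):
        return grids[1:-1].ravel()

    def unpack(z):
        return np.vstack([x0, z.reshape(n - 2, dof), x_end])

    current = path.grids.copy()
    spec_round = spec
    for round_ in range(3):
        def fun(z):
            t, g = target(DiscretePath(unpack(z)), potential, spec_round)
            return t, g[1:-1].ravel()

        res = optimize.minimize(
            fun, pack(current), jac=True, method="CG",
            options=dict(maxiter=spec_round.max_iter, gtol=spec_round.grad_tol),
        )
        current = unpack(res.x)
        out = DiscretePath(current)
        if out.spacing_deviation <= spec.spacing_tol:
            break
        spec_round = replace(spec_round, rho=spec_round.rho * 10.0)
        logger.info("spacing deviation %.3f > tol; raising rho to %.1f",
                    out.spacing_deviation, spec_round.rho)
    t_final, _ = target(out, potential, spec)
    if t_final > t_init + 1e-9 * max(abs(t_init), 1.0):
        raise RuntimeError(
            f"path optimization diverged: T rose from {t_init:.6g} to {t_final:.6g}"
        )
    return out


def reparametrize_equal(path: DiscretePath) -> DiscretePath:
    """Resample the piecewise-linear path at uniform arc-length fractions."""
    x = path.grids
    dl = path.segment_lengths
    s = np.concatenate([[0.0], np.cumsum(dl)])
    total = s[-1]
    if total == 0:
        return DiscretePath(x.copy())
    targets = np.linspace(0.0, total, path.n_grids)
    out = np.empty_like(x)
    out[0], out[-1] = x[0], x[-1]
    for k in range(1, path.n_grids - 1):
        j = int(np.searchsorted(s, targets[k], side="right") - 1)
        j = min(j, path.n_grids - 2)
        t = (targets[k] - s[j]) / max(s[j + 1] - s[j], 1e-300)
        out[k] = (1 - t) * x[j] + t * x[j + 1]
    return DiscretePath(out)


def prerelax_path(
    path: DiscretePath,
    potential,
    n_iter: int = 300,
    step: float = 2e-4,
    force_cap: float = 1e3,
    reparam_every: int = 10,
    u_stop: float | None = None,
) -> DiscretePath:
    """Clash-removing pre-relaxation of an initial path.

    Linear interpolation between distant endpoints routinely drives beads
    through each other; before the action is meaningful those overlaps must
    be relaxed away.  Each interior grid takes capped gradient-descent steps
    on the bare potential while the path is periodically reparametrized to
    equal spacing — a cheap stand-in for a self-penalty-walk initial guess.
    Endpoints never move.
    """
    x = path.grids.copy()
    n = len(x)
    for it in range(n_iter):
        u_max = -np.inf
        for i in range(1, n - 1):
            u, g = potential.energy_gradient(x[i])
            u_max = max(u_max, u)
            gn = float(np.sqrt(np.sum(np.square(np.minimum(np.abs(g), 1e150)))))
            if not np.isfinite(gn) or gn == 0.0:
                continue
            if gn > force_cap:
                g = g * (force_cap / gn)
            x[i] = x[i] - step * g
        if (it + 1) % reparam_every == 0:
            x = reparametrize_equal(DiscretePath(x)).grids
        if u_stop is not None and u_max < u_stop:
            break
    return reparametrize_equal(DiscretePath(x))


def detect_backtracking(formed: dict[str, np.ndarray]) -> pd.DataFrame:
    """Form–break–reform events along the grid sequence.

    ``formed`` maps a label (one native contact or one helix flag) to a
    boolean per-grid series.  Every maximal True run that is followed, after
    a gap, by another True run is one backtracking event; the reported
    interval is (formation grid, last grid before breaking, re-formation
    grid).
    """
    rows = []
    for label, series in formed.items():
        series = np.asarray(series, dtype=bool)
        runs = []
        start = None
        for g, val in enumerate(series):
            if val and start is None:
                start = g
            elif not val and start is not None:
                runs.append((start, g - 1))
                start = None
        if start is not None:
            runs.append((start, len(series) - 1))
        for (s0, e0), (s1, _) in zip(runs[:-1], runs[1:]):
            rows.append(dict(label=label, formed_at=s0, broken_after=e0,
                             reformed_at=s1))
    return pd.DataFrame(rows, columns=["label", "formed_at", "broken_after",
                                       "reformed_at"])


def profile_path(
    path: DiscretePath,
    top,
    native_map,
    potential=None,
    cutoff: float | None = None,
    helix_chain: str | None = None,
    factor: float = 1.2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-grid structural profile of a path over the CG system.

    Returns (profile table, backtracking report).  The profile has one row
    per grid with Q_f (peptide intrachain), Q_interface, Q_receptor,
    contact-class counts from the cutoff algorithm, helical residue count
    of the peptide, and the potential energy when a potential is supplied.
    """
    from .contacts import SPAN_A, SPAN_B, SPAN_INTER, cutoff_contacts, classify_contacts
    from .observables import helix_proxy, native_pair_arrays, q_fraction

    frames = path.grids.reshape(path.n_grids, -1, 3)
    pairs_b, sig_b = native_pair_arrays(native_map, SPAN_B)
    pairs_a, sig_a = native_pair_arrays(native_map, SPAN_A)
    pairs_i, sig_i = native_pair_arrays(native_map, SPAN_INTER)
    if cutoff is None:
        cutoff = 0.8
    chain_ids = top.chain_ids
    pep = top.chain_slices[chain_ids[1]]

    rows = []
    formed_series: dict[str, np.ndarray] = {}
    all_native = np.vstack([pairs_b, pairs_i]) if len(pairs_i) else pairs_b
    all_sigma = np.concatenate([sig_b, sig_i]) if len(pairs_i) else sig_b
    contact_tracks = np.zeros((path.n_grids, len(all_native)), dtype=bool)
    helix_tracks = np.zeros((path.n_grids, pep.stop - pep.start), dtype=bool)

    for g, frame in enumerate(frames):
        row = dict(grid=g)
        row["Q_f"] = q_fraction(frame, pairs_b, sig_b, factor) if len(pairs_b) else np.nan
        row["Q_interface"] = q_fraction(frame, pairs_i, sig_i, factor) if len(pairs_i) else np.nan
        row["Q_receptor"] = q_fraction(frame, pairs_a, sig_a, factor) if len(pairs_a) else np.nan
        fc = cutoff_contacts(frame, top.chain_of_bead, cutoff)
        cells = classify_contacts(fc, native_map)
        row.update(cells)
        hel = helix_proxy(frame[pep])
        helix_tracks[g] = hel
        row["helix_residues"] = int(hel.sum())
        if potential is not None:
            row["U"], _ = potential.energy_gradient(frame.ravel())
        rows.append(row)
        if len(all_native):
            d = np.linalg.norm(frame[all_native[:, 1]] - frame[all_native[:, 0]], axis=1)
            contact_tracks[g] = d < factor * all_sigma

    for k, (i, j) in enumerate(all_native):
        formed_series[f"contact_{i}-{j}"] = contact_tracks[:, k]
    for r in range(helix_tracks.shape[1]):
        formed_series[f"helix_res_{pep.start + r}"] = helix_tracks[:, r]
    report = detect_backtracking(formed_series)
    return pd.DataFrame(rows), report
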