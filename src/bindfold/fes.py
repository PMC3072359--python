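"""Free-energy reconstruction from (possibly biased) sampling.

Free energies are in kBT units: ``F = -ln P`` of the normalized histogram,
shifted so the lowest sampled bin is zero.  Unsampled (or under-sampled)
bins are masked, never reported as zero.  A harmonic center-of-mass bias is
removed analytically,

    F_unbiased(x) = F_biased(x) - V_bias(D_com) / kBT + C,

which is exact only when the binning coordinates contain D_com — the bias
depends on nothing else; this validity condition is enforced.  Runs at
unequal biases are combined by the standard self-consistent WHAM iteration.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contacts import cutoff_contacts, ContactMap
from .model import KB, BiasSpec, CGTopology

__all__ = [
    "FESurface",
    "TSERegion",
    "biased_surface",
    "unbias_surface",
    "wham_surface",
    "extract_tse",
    "tse_contact_profile",
    "minimum_free_energy_route",
]

logger = logging.getLogger(__name__)

DEFAULT_BINS = 40
DEFAULT_MIN_COUNT = 5
RANGE_PAD = 0.05


@dataclass
class FESurface:
    """Histogram-based free-energy surface over one or two coordinates."""

    names: list[str]
    edges: list[np.ndarray]
    free_energy: np.ndarray   # kBT; NaN on masked bins
    counts: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        sampled = ~np.isnan(self.free_energy)
        if sampled.any():
            m = float(np.nanmin(self.free_energy))
            if abs(m) > 1e-9:
                self.free_energy = self.free_energy - m

    @property
    def centers(self) -> list[np.ndarray]:
        return [0.5 * (e[1:] + e[:-1]) for e in self.edges]

    @property
    def mask(self) -> np.ndarray:
        """True where the bin is unsampled / not reportable."""
        return np.isnan(self.free_energy)

    def rezero(self) -> "FESurface":
        return FESurface(self.names, self.edges, self.free_energy.copy(),
                         self.counts.copy(), dict(self.meta))

    def to_frame(self) -> pd.DataFrame:
        grids = np.meshgrid(*self.centers, indexing="ij")
        data = {n: g.ravel() for n, g in zip(self.names, grids)}
        data["F_kBT"] = self.free_energy.ravel()
        data["count"] = self.counts.ravel()
        return pd.DataFrame(data)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def plot(self, path) -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        if len(self.names) == 1:
            ax.plot(self.centers[0], self.free_energy, "-o", ms=3)
            ax.set_xlabel(self.names[0])
            ax.set_ylabel("F (kBT)")
        else:
            x, y = self.centers
            im = ax.pcolormesh(
                self.edges[0], self.edges[1],
                np.ma.masked_invalid(self.free_energy).T,
                shading="auto",
            )
            fig.colorbar(im, ax=ax, label="F (kBT)")
            ax.set_xlabel(self.names[0])
            ax.set_ylabel(self.names[1])
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


@dataclass(frozen=True)
class TSERegion:
    """Closed coordinate ranges delimiting the transition-state ensemble.

    Defaults are the saddle region of the real system: Q_f in [0.3, 0.5],
    D_com in [2.2, 2.5] nm.
    """

    ranges: dict = None

    def __post_init__(self):
        if self.ranges is None:
            object.__setattr__(
                self, "ranges", {"Q_f": (0.3, 0.5), "D_com": (2.2, 2.5)}
            )
        for name, (lo, hi) in self.ranges.items():
            if not lo <= hi:
                raise ValueError(f"empty range for {name}: ({lo}, {hi})")


def _auto_edges(values: list[np.ndarray], bins: int) -> np.ndarray:
    lo = min(float(v.min()) for v in values)
    hi = max(float(v.max()) for v in values)
    pad = RANGE_PAD * (hi - lo if hi > lo else max(abs(hi), 1.0))
    return np.linspace(lo - pad, hi + pad, bins + 1)


def _gather(series_list, names):
    cols = {}
    frames = [s.to_frame() if hasattr(s, "to_frame") else pd.DataFrame(s)
              for s in series_list]
    for name in names:
        cols[name] = [f[name].to_numpy(dtype=float) for f in frames]
    return cols


def biased_surface(
    series_list,
    names: list[str] = ("Q_f", "D_com"),
    bins: int | list[int] = DEFAULT_BINS,
    edges: list[np.ndarray] | None = None,
    min_count: int = DEFAULT_MIN_COUNT,
    weights: list[np.ndarray] | None = None,
) -> FESurface:
    """F = -ln(normalized histogram) of pooled series, min over sampled bins 0.

    All series are assumed to share one bias and temperature (pooling rule);
    use :func:`wham_surface` for unequal biases.  ``weights`` is used
    internally for reweighted histograms.
    """
    names = list(names)
    if not 1 <= len(names) <= 2:
        raise ValueError("one or two coordinates required")
    cols = _gather(series_list, names)
    n_samples = sum(len(v) for v in cols[names[0]])
    if n_samples == 0:
        raise ValueError("no samples supplied")
    if isinstance(bins, int):
        bins = [bins] * len(names)
    if edges is None:
        edges = [_auto_edges(cols[n], b) for n, b in zip(names, bins)]
    sample = np.column_stack([np.concatenate(cols[n]) for n in names])
    w = None if weights is None else np.concatenate(weights)
    hist, _ = np.histogramdd(sample, bins=edges, weights=w)
    counts, _ = np.histogramdd(sample, bins=edges)
    if hist.sum() == 0:
        raise ValueError("empty histogram: samples fall outside the grid")
    prob = hist / hist.sum()
    with np.errstate(divide="ignore"):
        free = -np.log(prob)
    free[counts < min_count] = np.nan
    return FESurface(
        names=names, edges=[np.asarray(e) for e in edges],
        free_energy=free, counts=counts,
        meta=dict(min_count=min_count, n_samples=int(n_samples)),
    )


def unbias_surface(
    biased: FESurface, bias: BiasSpec, temperature: float
) -> FESurface:
    """Remove a harmonic D_com bias analytically and re-zero.

    Raises if the surface lacks a D_com coordinate: the transformation has
    an explicit expression only when the binned coordinates contain the
    biased one.
    """
    if "D_com" not in biased.names:
        raise ValueError(
            "unbiasing is exact only over coordinates containing D_com; "
            f"surface has {biased.names}"
        )
    kbt = KB * temperature
    axis = biased.names.index("D_com")
    centers = biased.centers[axis]
    v = np.asarray(bias.potential(centers), dtype=float) / kbt
    shape = [1] * len(biased.names)
    shape[axis] = len(centers)
    free = biased.free_energy - v.reshape(shape)
    return FESurface(
        names=list(biased.names), edges=[e.copy() for e in biased.edges],
        free_energy=free, counts=biased.counts.copy(),
        meta={**biased.meta, "unbiased_from": repr(bias)},
    )


def wham_surface(
    series_list,
    bias_list: list[BiasSpec],
    temperature: float,
    names: list[str] = ("Q_f", "D_com"),
    bins: int | list[int] = DEFAULT_BINS,
    edges: list[np.ndarray] | None = None,
    min_count: int = DEFAULT_MIN_COUNT,
    tol: float = 1e-7,
    max_iter: int = 100000,
) -> FESurface:
    """Unbiased surface from windows at unequal harmonic D_com biases (WHAM).

    The bias of a sample is evaluated at the center of its D_com bin (the
    classic bin-based formulation, which makes the single-window case reduce
    exactly to biased_surface followed by unbias_surface).  The window
    free-energy shifts f_k are iterated to self-consistency (tolerance
    ``tol``); each sample then carries the weight
    1 / sum_k N_k exp(-beta (V_k - f_k)) and the weighted histogram over
    ``names`` gives the unbiased free energy.
    """
    if len(series_list) != len(bias_list):
        raise ValueError("one bias spec per series required")
    kbt = KB * temperature
    beta = 1.0 / kbt
    d = [
        (s.to_frame() if hasattr(s, "to_frame") else pd.DataFrame(s))["D_com"]
        .to_numpy(dtype=float)
        for s in series_list
    ]
    n_k = np.array([len(x) for x in d], dtype=float)
    d_all = np.concatenate(d)
    lo, hi = d_all.min(), d_all.max()
    if len(series_list) > 1:
        for k, dk in enumerate(d):
            if dk.min() > hi or dk.max() < lo:
                warnings.warn(f"window {k} does not overlap the pooled D_com range")
    # snap every sample to its D_com bin center before evaluating the bias
    if edges is not None:
        d_edges = np.asarray(edges[list(names).index("D_com")])
    else:
        if isinstance(bins, int):
            bins_list = [bins] * len(names)
        else:
            bins_list = list(bins)
        d_edges = _auto_edges([d_all], bins_list[list(names).index("D_com")])
        edges_built = []
        for nm, b in zip(names, bins_list):
            if nm == "D_com":
                edges_built.append(d_edges)
            else:
                cols = _gather(series_list, [nm])[nm]
                edges_built.append(_auto_edges(cols, b))
        edges = edges_built
    d_centers = 0.5 * (d_edges[1:] + d_edges[:-1])
    idx = np.clip(np.digitize(d_all, d_edges) - 1, 0, len(d_centers) - 1)
    d_snap = d_centers[idx]
    # bias energy of every sample under every window: (K, N)
    v = np.stack([np.asarray(b.potential(d_snap), dtype=float) for b in bias_list])
    f_k = np.zeros(len(bias_list))
    for _ in range(max_iter):
        # denominators: sum_k N_k exp(-beta (V_k(x_n) - f_k))
        log_den = _logsumexp(
            np.log(n_k)[:, None] - beta * (v - f_k[:, None]), axis=0
        )
        # new shifts: f_k = -kbt ln sum_n exp(-beta V_k(x_n)) / den_n
        log_num = _logsumexp(-beta * v - log_den[None, :], axis=1)
        f_new = -kbt * log_num
        f_new -= f_new[0]
        if np.max(np.abs(f_new - f_k)) < tol:
            f_k = f_new
            break
        f_k = f_new
    log_w = -_logsumexp(np.log(n_k)[:, None] - beta * (v - f_k[:, None]), axis=0)
    log_w -= log_w.max()
    w_all = np.exp(log_w)
    weights, start = [], 0
    for x in d:
        weights.append(w_all[start:start + len(x)])
        start += len(x)
    surf = biased_surface(series_list, names=names, bins=bins, edges=edges,
                          min_count=min_count, weights=weights)
    surf.meta.update(window_shifts_kbt=(f_k / kbt).tolist(), method="wham")
    return surf


def _logsumexp(a, axis):
    m = np.max(a, axis=axis, keepdims=True)
    return (m + np.log(np.sum(np.exp(a - m), axis=axis, keepdims=True))).squeeze(axis)


def extract_tse(series, region: TSERegion | None = None) -> np.ndarray:
    """Indices of frames inside the closed TSE coordinate ranges."""
    region = region or TSERegion()
    df = series.to_frame() if hasattr(series, "to_frame") else pd.DataFrame(series)
    keep = np.ones(len(df), dtype=bool)
    for name, (lo, hi) in region.ranges.items():
        v = df[name].to_numpy(dtype=float)
        keep &= (v >= lo) & (v <= hi)
    idx = np.nonzero(keep)[0]
    if len(idx) == 0:
        warnings.warn("no frames fall inside the TSE region")
    return idx


def tse_contact_profile(
    frames: np.ndarray,
    top: CGTopology,
    cutoff: float,
    native_map: ContactMap | None = None,
):
    """Interfacial contact statistics over an ensemble of frames.

    Returns (per-receptor-residue mean interfacial contact count,
    pair-frequency DataFrame annotated with nativeness when a native map is
    given).  Contacts use the plain cutoff algorithm, independent of the
    native map.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    if len(frames) == 0:
        raise ValueError("at least one frame required")
    a, b = top.partition()
    chain_labels = top.chain_of_bead
    counts = np.zeros(len(a))
    freq: dict[tuple[int, int], int] = {}
    for frame in frames:
        for p in cutoff_contacts(frame, chain_labels, cutoff):
            if p.chain_span != "interfacial":
                continue
            recep = p.i if p.i in a else p.j
            counts[recep - a[0]] += 1
            freq[p.key] = freq.get(p.key, 0) + 1
    counts /= len(frames)
    native_keys = native_map.pair_keys if native_map is not None else set()
    rows = [
        dict(i=i, j=j, frequency=c / len(frames),
             native=(i, j) in native_keys)
        for (i, j), c in sorted(freq.items())
    ]
    profile = pd.DataFrame({"receptor_residue": a, "mean_contacts": counts})
    return profile, pd.DataFrame(rows, columns=["i", "j", "frequency", "native"])


def minimum_free_energy_route(surface: FESurface) -> pd.DataFrame:
    """Minimum-F value of the first coordinate at each sampled bin of the second.

    For a (Q_f, D_com) surface this traces the binding route: for every
    D_com bin the Q_f bin of lowest free energy.  Rows are ordered from the
    largest D_com (unbound) down to the smallest (bound).
    """
    if len(surface.names) != 2:
        raise ValueError("route extraction requires a 2-D surface")
    qc, dc = surface.centers
    q_edges, d_edges = surface.edges
    rows = []
    for j in range(len(dc) - 1, -1, -1):
        col = surface.free_energy[:, j]
        if np.all(np.isnan(col)):
            continue
        i = int(np.nanargmin(col))
        rows.append({
            surface.names[1]: dc[j], surface.names[0]: qc[i],
            f"{surface.names[0]}_low": q_edges[i],
            f"{surface.names[0]}_high": q_edges[i + 1],
            f"{surface.names[1]}_low": d_edges[j],
            f"{surface.names[1]}_high": d_edges[j + 1],
            "F_kBT": col[i],
        })
    return pd.DataFrame(rows)


def binding_precedes_folding(surface: FESurface, d_bound: float,
                             threshold: float = 0.5,
                             min_count: int = DEFAULT_MIN_COUNT) -> dict:
    """Ordering check on an unbiased (Q_f, D_com) free-energy surface.

    The binding-before-folding signature: traversing the binding coordinate
    from the unbound end, the population with folding fraction above
    ``threshold`` stays the minority everywhere on the unbound side of the
    free-energy barrier of the D_com marginal, becomes the majority only
    after the barrier (binding and folding couple only past the transition
    state), and dominates in the bound basin itself.

    Folded/unfolded assignment is bin-faithful (a Q_f bin counts as folded
    only when its entire range exceeds the threshold) and marginalizes the
    sample counts over Q_f within each D_com bin, so the verdict rests on
    the full population at each separation rather than on single-bin
    minima.  Returns a dict with ``holds`` plus barrier/crossing locations.
    """
    if len(surface.names) != 2 or surface.names != ["Q_f", "D_com"]:
        raise ValueError("expects a surface over (Q_f, D_com)")
    q_edges, d_edges = surface.edges
    d_centers = 0.5 * (d_edges[1:] + d_edges[:-1])
    counts = surface.counts  # (nq, nd)
    folded_q = q_edges[:-1] > threshold  # whole bin above threshold
    n_folded = counts[folded_q, :].sum(axis=0)
    n_total = counts.sum(axis=0)
    sampled = n_total >= min_count
    if sampled.sum() < 3:
        raise ValueError("too few sampled D_com bins to locate a barrier")
    with np.errstate(divide="ignore"):
        f_d = -np.log(n_total / n_total.sum())
    f_d[~sampled] = np.nan

    bound_bins = np.nonzero(sampled & (d_edges[:-1] <= d_bound))[0]
    reaches_bound = len(bound_bins) > 0
    folded_majority = sampled & (n_folded > n_total - n_folded)
    if not reaches_bound:
        return dict(holds=False, reaches_bound=False, barrier_d=None,
                    fold_crossing_d=None)
    i_bound = int(bound_bins[np.nanargmin(f_d[bound_bins])])
    i_unbound = int(np.nonzero(sampled)[0].max())
    seg = slice(i_bound, i_unbound + 1)
    i_barrier = i_bound + int(np.nanargmax(f_d[seg]))
    fold_idx = np.nonzero(folded_majority)[0]
    fold_crossing = int(fold_idx.max()) if len(fold_idx) else None
    holds = bool(
        reaches_bound
        and folded_majority[i_bound]                  # bound basin is folded
        and not folded_majority[i_barrier:].any()     # unfolded up to barrier
        and fold_crossing is not None
        and fold_crossing < i_barrier                 # folding past the barrier
    )
    return dict(
        holds=holds,
        reaches_bound=reaches_bound,
        barrier_d=float(d_centers[i_barrier]),
        barrier_f=float(f_d[i_barrier] - np.nanmin(f_d)),
        bound_d=float(d_centers[i_bound]),
        fold_crossing_d=(None if fold_crossing is None
                         else float(d_centers[fold_crossing])),
    )
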