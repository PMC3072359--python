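"""Free-energy reconstruction: histograms, unbiasing, WHAM, TSE tools."""

import numpy as np
import pandas as pd
import pytest

from bindfold import (
    TSERegion,
    biased_surface,
    extract_tse,
    tse_contact_profile,
    unbias_surface,
    wham_surface,
)
from bindfold.fes import FESurface, minimum_free_energy_route
from bindfold.model import KB, BiasSpec

TEMP = 120.0
KBT = KB * TEMP


def series_from_x(x):
    """Wrap raw samples of the biased coordinate as an order-parameter table."""
    return pd.DataFrame({"D_com": x, "Q_f": np.zeros_like(x)})


def rejection_sample_double_well(n, a, kbt, rng, lim=1.8):
    x = rng.uniform(-lim, lim, size=4 * n)
    u = a * (x**2 - 1) ** 2
    keep = rng.random(4 * n) < np.exp(-u / kbt)
    out = x[keep]
    assert len(out) >= n
    return out[:n]


class TestBiasedSurface:
    def test_known_double_well_density(self, rng):
        a = 1.0
        x = rejection_sample_double_well(10**6, a, KBT, rng)
        surf = biased_surface([series_from_x(x)], names=["D_com"], bins=30,
                              min_count=100)
        centers = surf.centers[0]
        ok = ~surf.mask
        f_ref = a * (centers[ok] ** 2 - 1) ** 2 / KBT
        f_ref -= f_ref.min()
        assert np.abs(surf.free_energy[ok] - f_ref).max() < 0.2

    def test_uniform_samples_flat(self, rng):
        x = rng.uniform(0, 1, size=10**6)
        surf = biased_surface([series_from_x(x)], names=["D_com"],
                              edges=[np.linspace(0, 1, 21)])
        f = surf.free_energy[~surf.mask]
        assert f.max() - f.min() < 0.1

    def test_pooling_equals_concatenation(self, rng):
        x1 = rng.standard_normal(5000)
        x2 = rng.standard_normal(5000)
        edges = [np.linspace(-4, 4, 31)]
        a = biased_surface([series_from_x(x1), series_from_x(x2)],
                           names=["D_com"], edges=edges)
        b = biased_surface([series_from_x(np.concatenate([x1, x2]))],
                           names=["D_com"], edges=edges)
        np.testing.assert_array_equal(a.counts, b.counts)
        np.testing.assert_allclose(a.free_energy, b.free_energy, equal_nan=True)

    def test_min_of_sampled_bins_is_zero(self, rng):
        surf = biased_surface([series_from_x(rng.standard_normal(10000))],
                              names=["D_com"], bins=20)
        assert np.nanmin(surf.free_energy) == pytest.approx(0.0, abs=1e-12)

    def test_unsampled_bins_masked_not_zero(self, rng):
        x = np.concatenate([rng.normal(-2, 0.1, 5000), rng.normal(2, 0.1, 5000)])
        surf = biased_surface([series_from_x(x)], names=["D_com"],
                              edges=[np.linspace(-3, 3, 40)])
        mid = np.argmin(np.abs(surf.centers[0]))
        assert np.isnan(surf.free_energy[mid])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            biased_surface([series_from_x(np.zeros(0))], names=["D_com"])


class TestUnbiasSurface:
    def test_disabled_bias_is_identity(self, rng):
        surf = biased_surface([series_from_x(rng.standard_normal(20000))],
                              names=["D_com"], bins=25)
        out = unbias_surface(surf, BiasSpec(k=0.0, enabled=False), TEMP)
        np.testing.assert_allclose(out.free_energy, surf.free_energy,
                                   equal_nan=True, atol=1e-12)

    def test_harmonic_plus_bias_gaussian_algebra(self, rng):
        # U = 1/2 x^2 biased by 1/2 k (x - x0)^2: the biased density is the
        # exact Gaussian with kappa_b = 1 + k, mean k x0 / (1 + k)
        k, x0 = 2.0, 0.8
        kappa_b = 1.0 + k
        mean_b = k * x0 / kappa_b
        x = rng.normal(mean_b, np.sqrt(KBT / kappa_b), size=10**6)
        surf = biased_surface([series_from_x(x)], names=["D_com"], bins=35,
                              min_count=200)
        out = unbias_surface(surf, BiasSpec(k=k, d0=x0, enabled=True), TEMP)
        centers = out.centers[0]
        ok = ~out.mask
        f = out.free_energy[ok]
        c = centers[ok]
        # recovered F should be 1/2 x^2 / kbt up to a constant
        coeffs = np.polyfit(c, f, 2)
        assert coeffs[0] == pytest.approx(0.5 / KBT, rel=0.10)
        assert abs(-coeffs[1] / (2 * coeffs[0])) < (c[1] - c[0])  # min within 1 bin

    def test_requires_dcom_coordinate(self, rng):
        x = rng.standard_normal(1000)
        surf = biased_surface([pd.DataFrame({"Q_f": x, "D_com": x})],
                              names=["Q_f"], bins=10)
        with pytest.raises(ValueError, match="D_com"):
            unbias_surface(surf, BiasSpec(k=1.0, enabled=True), TEMP)

    def test_rezero_constant_invariance(self, rng):
        surf = biased_surface([series_from_x(rng.standard_normal(10000))],
                              names=["D_com"], bins=20)
        shifted = FESurface(surf.names, surf.edges, surf.free_energy + 3.7,
                            surf.counts)
        np.testing.assert_allclose(shifted.free_energy, surf.free_energy,
                                   equal_nan=True, atol=1e-12)


class TestWham:
    def test_single_window_reduces_to_composition(self, rng):
        k, x0 = 1.5, 0.5
        kappa_b = 1.0 + k
        x = rng.normal(k * x0 / kappa_b, np.sqrt(KBT / kappa_b), size=50000)
        bias = BiasSpec(k=k, d0=x0, enabled=True)
        edges = [np.linspace(-2, 2, 30)]
        direct = unbias_surface(
            biased_surface([series_from_x(x)], names=["D_com"], edges=edges),
            bias, TEMP,
        )
        via_wham = wham_surface([series_from_x(x)], [bias], TEMP,
                                names=["D_com"], edges=edges)
        ok = ~direct.mask & ~via_wham.mask
        np.testing.assert_allclose(via_wham.free_energy[ok],
                                   direct.free_energy[ok], atol=1e-6)

    def test_multi_window_recovers_harmonic(self, rng):
        # three umbrella windows on U = 1/2 x^2; each window's biased density
        # is an exact Gaussian, so samples can be drawn directly
        windows = [BiasSpec(k=3.0, d0=c, enabled=True) for c in (-1.0, 0.0, 1.0)]
        series = []
        for b in windows:
            kappa = 1.0 + b.k
            series.append(series_from_x(
                rng.normal(b.k * b.d0 / kappa, np.sqrt(KBT / kappa), size=80000)
            ))
        edges = [np.linspace(-1.8, 1.8, 37)]
        surf = wham_surface(series, windows, TEMP, names=["D_com"], edges=edges)
        centers = surf.centers[0]
        ok = ~surf.mask
        f_ref = 0.5 * centers[ok] ** 2 / KBT
        f_ref -= f_ref.min()
        assert np.abs(surf.free_energy[ok] - f_ref).max() < 0.3


class TestTse:
    def test_full_domain_region_keeps_all(self):
        df = pd.DataFrame({"Q_f": [0.1, 0.4, 0.9], "D_com": [0.5, 2.3, 3.0]})
        region = TSERegion(ranges={"Q_f": (0, 1), "D_com": (0, 10)})
        assert len(extract_tse(df, region)) == 3

    def test_disjoint_region_warns_empty(self):
        df = pd.DataFrame({"Q_f": [0.1], "D_com": [0.5]})
        region = TSERegion(ranges={"Q_f": (0.9, 1.0), "D_com": (5, 6)})
        with pytest.warns(UserWarning):
            idx = extract_tse(df, region)
        assert len(idx) == 0

    def test_default_region_membership(self):
        df = pd.DataFrame({
            "Q_f": [0.35, 0.45, 0.2, 0.4, 0.6],
            "D_com": [2.3, 2.4, 2.3, 3.0, 2.3],
        })
        idx = extract_tse(df)  # defaults: Q_f in [0.3, 0.5], D_com in [2.2, 2.5]
        assert list(idx) == [0, 1]

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            TSERegion(ranges={"Q_f": (0.5, 0.3)})


class TestTseContactProfile:
    def test_separated_chains_zero(self, toy_topology):
        coords = toy_topology.native_coords.copy()
        _, pep = toy_topology.partition()
        coords[pep] += np.array([0.0, 0.0, 50.0])
        profile, freq = tse_contact_profile(coords[None], toy_topology, 0.8)
        assert profile["mean_contacts"].sum() == 0
        assert len(freq) == 0

    def test_brute_force_average(self, toy_topology, toy_native_map_fixture, rng):
        frames = toy_topology.native_coords[None] + 0.15 * rng.standard_normal(
            (20,) + toy_topology.native_coords.shape
        )
        cutoff = 0.8
        profile, freq = tse_contact_profile(frames, toy_topology, cutoff,
                                            toy_native_map_fixture)
        a, b = toy_topology.partition()
        expected = np.zeros(len(a))
        for frame in frames:
            for i in a:
                for j in b:
                    if np.linalg.norm(frame[i] - frame[j]) < cutoff:
                        expected[i] += 1
        expected /= len(frames)
        np.testing.assert_allclose(profile["mean_contacts"].to_numpy(), expected)
        assert (freq["frequency"] > 0).all()


def _mechanism_surface(rng, binding_first=True):
    """Synthetic (Q_f, D_com) sample with folding late (or early)."""
    qs, ds = [], []
    # unbound basin: disordered peptide far away
    qs.append(rng.uniform(0.1, 0.45, 6000))
    ds.append(rng.uniform(2.0, 3.2, 6000))
    # corridor
    q_corr = rng.uniform(0.1, 0.45, 1500) if binding_first \
        else rng.uniform(0.55, 0.95, 1500)
    qs.append(q_corr)
    ds.append(rng.uniform(0.9, 2.0, 1500))
    # bound basin: folded
    qs.append(rng.uniform(0.8, 1.0, 8000))
    ds.append(rng.uniform(0.35, 0.7, 8000))
    df = pd.DataFrame({"Q_f": np.concatenate(qs), "D_com": np.concatenate(ds)})
    return biased_surface([df], names=["Q_f", "D_com"],
                          edges=[np.linspace(0, 1.0001, 21),
                                 np.linspace(0, 3.6, 41)], min_count=5)


def test_binding_precedes_folding_detects_both_orders(rng):
    from bindfold.fes import binding_precedes_folding

    good = binding_precedes_folding(_mechanism_surface(rng, True), 0.5)
    assert good["holds"], good
    bad = binding_precedes_folding(_mechanism_surface(rng, False), 0.5)
    assert not bad["holds"], bad


def test_route_orders_from_unbound_to_bound(rng):
    q = np.concatenate([rng.uniform(0, 0.4, 4000), rng.uniform(0.8, 1.0, 4000)])
    d = np.concatenate([rng.uniform(2.5, 3.0, 4000), rng.uniform(0.4, 0.6, 4000)])
    surf = biased_surface([pd.DataFrame({"Q_f": q, "D_com": d})],
                          names=["Q_f", "D_com"], bins=15, min_count=2)
    route = minimum_free_energy_route(surf)
    assert route["D_com"].is_monotonic_decreasing
    assert route["Q_f"].iloc[0] < 0.5 and route["Q_f"].iloc[-1] > 0.5
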