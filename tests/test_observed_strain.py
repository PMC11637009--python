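"""Observed strains from stage pairs, bootstrap CIs, profile mapping."""

import numpy as np
import pandas as pd
import pytest

from shapeprog.observed_strain import (bootstrap_profile, combine_anisotropic,
                                       map_profile_to_lattice, strain_from_area,
                                       strain_from_elongation,
                                       strain_from_rearrangements)
from shapeprog.strain_frames import assign_regions_and_frames


def rings_table(delta_N, area=None, L=None):
    df = pd.DataFrame({"k": np.arange(len(delta_N)), "delta_N": delta_N})
    df["N"] = df["delta_N"].cumsum()
    df["area_mean"] = 1.0 if area is None else area
    df["L_mean"] = 1.0 if L is None else L
    return df


class TestAreaStrain:
    def test_equal_areas(self):
        t = rings_table([1, 6, 12], area=[2.0, 2.0, 2.0])
        assert np.allclose(strain_from_area(t, t), 1.0)

    @pytest.mark.parametrize("a0, a1, expected", [
        (1.0, 4.0, 2.0),
        (2.0, 1.0, 1 / np.sqrt(2)),
    ])
    def test_sqrt_ratio(self, a0, a1, expected):
        t = rings_table([1, 6], area=[a0, a0])
        later = rings_table([1, 6], area=[a1, a1])
        assert strain_from_area(t, later)[1] == pytest.approx(expected)

    def test_nonpositive_area_rejected(self):
        t = rings_table([1, 6], area=[1.0, 0.0])
        with pytest.raises(ValueError):
            strain_from_area(t, t)

    def test_terminal_bins_dropped_with_warning(self):
        t = rings_table([1, 6, 12])
        later = rings_table([1, 6])
        with pytest.warns(RuntimeWarning):
            out = strain_from_area(t, later)
        assert np.isnan(out[-1])
        assert np.isfinite(out[:-1]).all()


class TestElongationStrain:
    def test_identical(self):
        t = rings_table([1, 6], L=[1.1, 1.2])
        assert np.allclose(strain_from_elongation(t, t), 1.0)

    @pytest.mark.parametrize("q0, q1", [(0.0, 0.2), (0.1, -0.1)])
    def test_exponential_ratio(self, q0, q1):
        t = rings_table([1, 6], L=np.exp([q0, q0]))
        later = rings_table([1, 6], L=np.exp([q1, q1]))
        assert strain_from_elongation(t, later)[1] == pytest.approx(np.exp(q1 - q0))


class TestRearrangementStrain:
    def test_identity(self):
        t = rings_table([1, 6, 12, 18])
        assert np.allclose(strain_from_rearrangements(t, t), 1.0)

    def test_ring_spread_over_two(self):
        """One ring's cells occupying two later rings give strain 2."""
        t = rings_table([1, 6, 12])
        later = rings_table([1, 6, 6, 6])
        assert strain_from_rearrangements(t, later)[2] == pytest.approx(2.0)

    def test_two_rings_merge(self):
        t = rings_table([1, 6, 6, 6])
        later = rings_table([1, 6, 12])
        out = strain_from_rearrangements(t, later)
        assert out[2] == pytest.approx(0.5)
        assert out[3] == pytest.approx(0.5)


class TestCombine:
    def test_product_per_bin(self):
        lq = np.array([1.0, 1.1, 0.9])
        lr = np.array([1.0, 1.2, 2.0])
        out = combine_anisotropic(lq, lr)
        assert np.array_equal(out, lq * lr)
        assert out[1] == pytest.approx(1.32)
        assert out[2] == pytest.approx(1.8)


class TestBootstrap:
    def test_constant_values_zero_width(self):
        out = bootstrap_profile({0: np.full(20, 3.0)}, seed=1, repeats=200)
        assert out["ci_low"].item() == out["ci_high"].item() == 3.0

    def test_seed_determinism(self):
        vals = {0: np.arange(30.0), 1: np.arange(10.0)}
        a = bootstrap_profile(vals, seed=7, repeats=500)
        b = bootstrap_profile(vals, seed=7, repeats=500)
        pd.testing.assert_frame_equal(a, b)

    def test_weighted_mean_statistic(self):
        vals = {0: np.array([1.0, 3.0])}
        w = {0: np.array([3.0, 1.0])}
        out = bootstrap_profile(vals, seed=0, repeats=100, weights_by_bin=w)
        assert out["stat"].item() == pytest.approx(1.5)

    def test_coverage_of_percentile_interval(self, rng):
        """The 95% CI covers the true mean at roughly nominal rate."""
        hits = 0
        n_rep = 120
        for _ in range(n_rep):
            sample = rng.normal(loc=2.0, scale=1.0, size=200)
            out = bootstrap_profile({0: sample}, seed=int(rng.integers(2**31)),
                                    repeats=600)
            hits += out["ci_low"].item() <= 2.0 <= out["ci_high"].item()
        assert 0.88 <= hits / n_rep <= 0.99

    def test_empty_bin_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_profile({0: np.empty(0)}, seed=0)


@pytest.fixture(scope="module")
def frame(cap_f5):
    return assign_regions_and_frames(cap_f5, w_DV=0.0)


class TestProfileMapping:
    def test_constant_profile_uniform_field(self, frame):
        prof = pd.DataFrame({"region": "outDVB", "coordinate": [0.0, 1.0],
                             "lambda_A": [1.2, 1.2], "lambda_R": [1.1, 1.1]})
        f = map_profile_to_lattice(prof, frame, iso_col="lambda_A",
                                   aniso_col="lambda_R")
        assert np.allclose(f.lam, 1.2)
        assert np.allclose(f.lam_t[~frame.singular], 1.1)

    def test_rearrangement_scenario_keeps_iso_unity(self, frame):
        """The {1, lambda_R*} scenario programs no area change."""
        prof = pd.DataFrame({"region": "outDVB", "coordinate": [0.0, 1.0],
                             "lambda_R": [1.0, 1.4]})
        f = map_profile_to_lattice(prof, frame, iso_col=None, aniso_col="lambda_R")
        assert np.array_equal(f.lam, np.ones(frame.n))

    def test_sampled_roundtrip(self, frame):
        xs = np.linspace(0, 1, 11)
        prof = pd.DataFrame({"region": "outDVB", "coordinate": xs,
                             "lambda_A": 1 + 0.3 * xs})
        f = map_profile_to_lattice(prof, frame, iso_col="lambda_A")
        assert np.abs(f.lam - (1 + 0.3 * frame.coord)).max() < 1e-12

    def test_missing_region_rejected(self, frame):
        prof = pd.DataFrame({"region": "DVB", "coordinate": [0.0, 1.0],
                             "lambda_A": [1.0, 1.0]})
        with pytest.raises(ValueError):
            map_profile_to_lattice(prof, frame, iso_col="lambda_A")


class TestEndToEndRecovery:
    def test_profiles_invariant_under_rigid_motion(self):
        from scipy.spatial.transform import Rotation

        from shapeprog.cell_network import CellNetwork
        from shapeprog.pipeline import extract_strains
        from shapeprog.synth import (RingCapConfig, apply_stage_transition,
                                     generate_ring_cap, ring_boundaries_for)

        counts = np.array([1, 6, 12, 18, 24])
        cfg1 = RingCapConfig(20.0, counts, ring_boundaries_for(20.0, 0.8, counts))
        cfg2, _ = apply_stage_transition(cfg1, area_factor=1.1)
        net1, net2 = generate_ring_cap(cfg1), generate_ring_cap(cfg2)
        prof0, _ = extract_strains(net1, net2)
        R3 = Rotation.from_euler("xyz", [0.3, 0.1, -0.2]).as_matrix()
        m1 = CellNetwork(net1.vertices @ R3.T + [1, 2, 3],
                         [c.copy() for c in net1.cells], region=net1.region)
        m2 = CellNetwork(net2.vertices @ R3.T + [1, 2, 3],
                         [c.copy() for c in net2.cells], region=net2.region)
        prof1, _ = extract_strains(m1, m2)
        for col in ("lambda_A", "lambda_Q", "lambda_R"):
            assert np.allclose(prof0[col], prof1[col], atol=1e-9, equal_nan=True)

    def test_combined_total_identity(self):
        from shapeprog.pipeline import extract_strains
        from shapeprog.synth import standard_stage_pair

        net1, _, net2, _, _ = standard_stage_pair("area", n_rings=12)
        prof, _ = extract_strains(net1, net2)
        ok = prof["lambda_total"].notna()
        assert np.array_equal(prof.loc[ok, "lambda_total"],
                              prof.loc[ok, "lambda_Q"] * prof.loc[ok, "lambda_R"])
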