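"""Packaging simulator: fragment laws, closed-form coverage, fixtures."""

import numpy as np
import pytest

from transductomics.simulate import (
    FragmentSet,
    GenomeModel,
    GTAParams,
    PacSite,
    ProphageElement,
    expected_coverage,
    fragments_to_coverage,
    make_fixture,
    simulate_fragments,
    simulate_wgs_track,
)


def gta_model(L=1_000_000, F=13_000, circular=True, bias=None):
    return GenomeModel(
        genome_length=L, circular=circular,
        gta=GTAParams(fragment_size=F, rate=1.0, bias_field=bias),
    )


class TestSimulateFragments:
    def test_gta_fragments_have_fixed_size(self):
        frags = simulate_fragments(gta_model(), n_particles=1000, seed=0)
        assert len(frags) == 1000
        assert np.all(frags.lengths() == 13_000)
        assert frags.lengths().sum() == 13_000_000

    def test_headful_counts_follow_geometric_law(self):
        q, H, n = 0.5, 40_000, 10_000
        m = GenomeModel(
            genome_length=2_000_000, circular=True,
            pac_sites=[PacSite(position=0, headful=H, continuation_prob=q)],
        )
        frags = simulate_fragments(m, n, seed=1)
        k = frags.starts // H + 1
        for kk in range(1, 6):
            p = q ** (kk - 1) * (1 - q)
            observed = int((k == kk).sum())
            sd = np.sqrt(n * p * (1 - p))
            assert abs(observed - n * p) <= 3 * sd

    def test_pure_prophage_particles_match_interval(self):
        m = GenomeModel(
            genome_length=200_000,
            prophages=[ProphageElement(start=50_000, end=90_000, specialized_rate=0.0)],
        )
        frags = simulate_fragments(m, 500, seed=2)
        assert np.all(frags.starts == 50_000)
        assert np.all(frags.ends == 90_000)
        assert set(frags.labels) == {"phage:prophage"}

    def test_seed_determinism(self):
        m = gta_model()
        a = simulate_fragments(m, 5_000, seed=7)
        b = simulate_fragments(m, 5_000, seed=7)
        np.testing.assert_array_equal(a.starts, b.starts)
        np.testing.assert_array_equal(a.ends, b.ends)

    def test_linear_truncation_at_ends(self):
        m = gta_model(L=100_000, circular=False)
        frags = simulate_fragments(m, 5_000, seed=3)
        assert frags.ends.max() <= 100_000
        assert np.all(frags.lengths() <= 13_000)

    def test_invalid_models_rejected(self):
        with pytest.raises(ValueError, match="outside genome"):
            GenomeModel(genome_length=1000, pac_sites=[PacSite(position=5000)])
        with pytest.raises(ValueError, match="continuation_prob"):
            PacSite(position=0, continuation_prob=1.0)
        with pytest.raises(ValueError):
            simulate_fragments(gta_model(), 0, seed=0)


class TestExpectedCoverage:
    def test_single_pac_closed_form(self):
        # per-particle headful law: coverage in headful k is n * q^(k-1) * (1-q);
        # with 2000 particles at q = 0.5 the first-headful rate is 1000 and the
        # third headful (position 100 kbp) carries 1000 * 0.5^2 = 250
        q, H = 0.5, 40_000
        m = GenomeModel(
            genome_length=2_000_000, circular=False,
            pac_sites=[PacSite(position=0, headful=H, continuation_prob=q)],
        )
        exp = expected_coverage(m, 2_000, bin_size=100)
        assert exp.depths[100_000 // 100] == pytest.approx(250.0)
        assert exp.depths[0] == pytest.approx(1000.0)

    def test_specialized_ratio_single_vs_double_sided(self):
        kw = dict(start=100_000, end=148_500, induction_rate=1.0,
                  specialized_rate=1e-4, capsid_capacity=48_500, max_flank=25_000)
        for side_bias, ratio in [(0.5, 20_000), (0.0, 10_000)]:
            m = GenomeModel(
                genome_length=300_000,
                prophages=[ProphageElement(side_bias=side_bias, **kw)],
            )
            exp = expected_coverage(m, 1_000_000, bin_size=100)
            plateau = exp.depths[1_100]
            flank_max = exp.depths[1_485]  # right flank, first bin
            assert plateau / flank_max == pytest.approx(ratio, rel=0.02)

    def test_empty_model_all_zero(self):
        m = GenomeModel(genome_length=50_000)
        exp = expected_coverage(m, 1_000, bin_size=100)
        assert np.all(exp.depths == 0)

    def test_monte_carlo_agreement_all_modes(self):
        m = GenomeModel(
            genome_length=500_000, circular=True,
            prophages=[ProphageElement(
                start=100_000, end=140_000, induction_rate=1.0,
                specialized_rate=0.05, max_flank=20_000, side_bias=0.5,
                lateral_rate=0.5, lateral_direction="right", continuation_prob=0.6,
            )],
            pac_sites=[PacSite(position=300_000, headful=40_000, continuation_prob=0.5)],
            gta=GTAParams(fragment_size=13_000, rate=1.0),
        )
        n = 100_000
        mc = fragments_to_coverage(simulate_fragments(m, n, seed=5), bin_size=100)
        exp = expected_coverage(m, n, bin_size=100)
        sel = exp.depths >= 10
        z = (mc.depths[sel] - exp.depths[sel]) / np.sqrt(exp.depths[sel])
        assert np.abs(z).max() <= 5.0

    def test_staircase_monotone_and_constant_within_headful(self):
        m = GenomeModel(
            genome_length=1_000_000, circular=False,
            pac_sites=[PacSite(position=0, headful=40_000, continuation_prob=0.7)],
        )
        exp = expected_coverage(m, 10_000, bin_size=100)
        assert np.all(np.diff(exp.depths) <= 1e-9)
        first = exp.depths[: 40_000 // 100]
        assert np.ptp(first) == pytest.approx(0.0)


class TestFragmentsToCoverage:
    def test_single_fragment(self):
        frags = FragmentSet(10_000, False, [0], [1_000], ["x"])
        cov = fragments_to_coverage(frags, bin_size=100)
        np.testing.assert_allclose(cov.depths[:10], 1.0)
        assert cov.depths[10:].sum() == 0

    def test_wrapped_fragment_on_circular_genome(self):
        frags = FragmentSet(10_000, True, [9_500], [10_500], ["x"])
        cov = fragments_to_coverage(frags, bin_size=100)
        np.testing.assert_allclose(cov.depths[:5], 1.0)
        np.testing.assert_allclose(cov.depths[-5:], 1.0)
        assert cov.depths[5:-5].sum() == 0

    def test_matches_bruteforce_overlap_count(self):
        rng = np.random.default_rng(4)
        L, n = 30_000, 800
        starts = rng.integers(0, L, size=n)
        ends = starts + rng.integers(200, 5_000, size=n)
        frags = FragmentSet(L, True, starts, ends, np.array(["x"] * n))
        cov = fragments_to_coverage(frags, bin_size=100)
        per_base = np.zeros(L)
        for s, e in zip(starts, ends):
            if e <= L:
                per_base[s:e] += 1
            else:
                per_base[s:] += 1
                per_base[: e - L] += 1
        np.testing.assert_allclose(cov.depths, per_base.reshape(-1, 100).mean(axis=1))

    def test_mass_conservation(self):
        frags = simulate_fragments(gta_model(), 20_000, seed=6)
        cov = fragments_to_coverage(frags, bin_size=100)
        assert cov.base_mass() == pytest.approx(float(frags.lengths().sum()))


class TestWgsTrack:
    def test_flat_without_noise(self):
        t = simulate_wgs_track(100_000, 50.0, ori_gradient=1.0, noise=False)
        np.testing.assert_allclose(t.depths, 50.0)

    def test_gradient_fold_exact(self):
        t = simulate_wgs_track(
            1_000_000, 100.0, ori_gradient=2.0, ori_position=0,
            circular=True, noise=False,
        )
        ori = t.depths[0]
        terminus = t.depths[t.n_bins // 2]
        assert ori / terminus == pytest.approx(2.0, rel=1e-3)
        assert t.mean_depth() == pytest.approx(100.0, rel=1e-6)

    def test_poisson_noise_variance_matches_mean(self):
        t = simulate_wgs_track(2_000_000, 100.0, noise=True, seed=8)
        var = t.depths.var()
        n = t.n_bins
        # chi-square bounds on the sample variance of Poisson(100)
        assert 100 * (1 - 4 / np.sqrt(n)) < var < 100 * (1 + 4 / np.sqrt(n))

    def test_invalid_gradient(self):
        with pytest.raises(ValueError):
            simulate_wgs_track(10_000, 10.0, ori_gradient=0.5)


class TestFixtures:
    def test_lambda_expected_ratio_and_flanks(self, lambda_fixture):
        pair, truth, _ = lambda_fixture
        el = truth.elements[0]
        assert el["mode"] == "specialized"
        assert el["frequency_ratio"] == pytest.approx(10_000, rel=0.01)
        assert el["max_flank"] == 25_000

    def test_p22_truth_pac_count(self, p22_fixture):
        _, truth = p22_fixture
        el = next(e for e in truth.elements if e["mode"] == "generalized")
        assert len(el["pac_positions"]) in (5, 6)
        assert el["headful"] == 44_000

    def test_community_all_rates_zero_is_all_standard(self):
        counts = {"standard": 6, "contamination": 0, "induction": 0,
                  "specialized": 0, "lateral": 0, "generalized": 0, "gta_like": 0}
        pairs, truths = make_fixture("community_like", seed=3, counts=counts)
        assert len(pairs) == 6
        assert all(t.mode == "standard" for t in truths)

    def test_community_size_and_mode_mix(self, community):
        pairs, truths = community
        assert len(pairs) >= 50
        modes = {t.mode for t in truths}
        assert {"standard", "induction", "specialized", "lateral",
                "generalized", "gta_like"} <= modes
        assert any(t.contamination for t in truths)
        lengths = [p.wgs.contig_length for p in pairs]
        assert min(lengths) >= 40_000

    def test_unknown_fixture_name(self):
        with pytest.raises(ValueError, match="unknown fixture"):
            make_fixture("nonexistent")

    def test_gta_flat_bias_coverage_uniform(self):
        n = 200_000
        frags = simulate_fragments(gta_model(), n, seed=9)
        cov = fragments_to_coverage(frags, bin_size=100)
        sm = np.convolve(cov.depths, np.ones(100) / 100, mode="valid")
        assert sm.max() / sm.min() < 1.25
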