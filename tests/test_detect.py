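"""Pattern detector: features, pac/headful estimation, classification."""

import numpy as np
import pytest

from transductomics import (
    DetectorParams,
    PairedCoverage,
    call_pac_sites,
    call_patterns,
    contig_baseline,
    edge_sharpness,
    estimate_headful_size,
    estimate_transduction_frequency,
    fit_decay_slope,
    normalize_track,
    segment_log_coverage,
    unevenness_ratio,
    wgs_evenness,
)
from transductomics.simulate import (
    GenomeModel,
    PacSite,
    ProphageElement,
    expected_coverage,
    fragments_to_coverage,
    simulate_fragments,
    simulate_wgs_track,
)

from conftest import make_track


def staircase_track(r=1000.0, q=0.5, H=40_000, L=400_000, pac_at=0):
    """Noise-free geometric packaging staircase as a closed-form track."""
    m = GenomeModel(
        genome_length=L, circular=False,
        pac_sites=[PacSite(position=pac_at, headful=H, continuation_prob=q)],
    )
    n = r / (1 - q)
    return expected_coverage(m, n, bin_size=100, total_mapped=1e6)


class TestBaseline:
    def test_constant(self):
        assert contig_baseline(make_track([10.0] * 100)) == pytest.approx(10.0)

    def test_mixture_with_induced_prophage(self):
        depths = np.ones(2000)
        depths[950:1050] = 10_000.0
        assert contig_baseline(make_track(depths)) == pytest.approx(1.0)

    def test_all_zero(self):
        assert contig_baseline(make_track([0.0] * 50)) == 0.0


class TestEvenness:
    def test_constant_passes(self):
        rep = wgs_evenness(make_track([100.0] * 500, source="whole"))
        assert rep.cv == 0.0 and rep.passed

    def test_chimeric_halfdepth_fails(self):
        depths = np.concatenate([np.full(1000, 10.0), np.full(1000, 1000.0)])
        rep = wgs_evenness(make_track(depths, source="whole"))
        # analytic CV of {10, 1000} half/half is ~0.98
        assert rep.cv == pytest.approx(0.98, abs=0.02)
        assert not rep.passed

    def test_poisson_noise_passes(self):
        t = simulate_wgs_track(500_000, 100.0, noise=True, seed=1)
        assert wgs_evenness(t).passed


class TestSegmentation:
    def test_piecewise_constant_breakpoints(self):
        depths = np.concatenate([
            np.ones(1000), np.full(200, 100.0), np.ones(1000)
        ])
        segs = segment_log_coverage(make_track(depths))
        assert len(segs) == 3
        assert abs(segs[0].end_bin - 1000) <= 2
        assert abs(segs[1].end_bin - 1200) <= 2
        assert segs[-1].end == 220_000
        # segments tile the contig
        assert segs[0].start == 0
        for a, b in zip(segs, segs[1:]):
            assert a.end == b.start

    def test_constant_single_segment(self):
        segs = segment_log_coverage(make_track([5.0] * 800))
        assert len(segs) == 1

    def test_lambda_plateau_recovered(self, lambda_fixture):
        pair, truth, _ = lambda_fixture
        el = truth.elements[0]
        segs = segment_log_coverage(normalize_track(pair.vlp))
        match = [
            s for s in segs
            if abs(s.start - el["start"]) <= 200 and abs(s.end - el["end"]) <= 200
        ]
        assert match, [(s.start, s.end) for s in segs]


class TestEdgeSharpness:
    def test_step(self):
        depths = np.concatenate([np.ones(100), np.full(100, 100.0)])
        fold, trunc = edge_sharpness(make_track(depths), 10_000, 500)
        assert fold == pytest.approx(101 / 2, rel=0.01)
        assert not trunc

    def test_slow_ramp_is_not_sharp(self):
        depths = np.linspace(10, 100, 500)  # 50 kbp ramp
        fold, _ = edge_sharpness(make_track(depths), 25_000, 500)
        assert fold < 1.2

    def test_boundary_at_contig_end_truncated(self):
        fold, trunc = edge_sharpness(make_track([5.0] * 100), 9_900, 500)
        assert trunc
        assert np.isfinite(fold)


class TestDecaySlope:
    def test_geometric_staircase_slope(self):
        t = staircase_track(q=0.5, H=40_000)
        slope, r2 = fit_decay_slope(t, (0, 320_000))
        # one halving per 40 kbp = -0.25 log2-fold per 10 kbp
        assert slope == pytest.approx(-0.25, abs=0.03)
        assert r2 > 0.9

    def test_constant_zero_slope(self):
        slope, r2 = fit_decay_slope(make_track([7.0] * 200), (0, 20_000))
        assert slope == 0.0

    def test_exact_log_linear_decay(self):
        x = np.arange(300) * 100.0
        depths = 2 ** (8 - x / 10_000) - 1  # exactly linear in log2(depth + 1)
        slope, r2 = fit_decay_slope(make_track(depths), (0, 30_000))
        assert slope == pytest.approx(-1.0, rel=1e-6)
        assert r2 == pytest.approx(1.0)

    def test_all_zero_flagged(self):
        slope, r2 = fit_decay_slope(make_track([0.0] * 100), (0, 10_000))
        assert np.isnan(slope) and np.isnan(r2)


class TestPacSites:
    def test_closed_form_single_site(self):
        t = staircase_track(pac_at=100_000, L=500_000)
        sites = call_pac_sites(t)
        assert len(sites) == 1
        assert abs(sites[0] - 100_000) <= 100

    def test_constant_track_no_sites(self):
        assert call_pac_sites(make_track([50.0] * 2000)) == []

    def test_p22_fixture_all_sites_recovered(self, p22_fixture):
        pair, truth = p22_fixture
        true_sites = next(
            e for e in truth.elements if e["mode"] == "generalized"
        )["pac_positions"]
        called = call_pac_sites(normalize_track(pair.vlp))
        assert len(called) == len(true_sites)
        for ts in true_sites:
            assert min(abs(c - ts) for c in called) <= 200


class TestHeadful:
    def test_noise_free_staircase(self):
        t = staircase_track(q=0.7, H=40_000, L=600_000)
        h = estimate_headful_size(t, (0, 600_000))
        assert abs(h - 40_000) <= 100

    def test_p22_fixture_within_ten_percent(self, p22_fixture):
        pair, _ = p22_fixture
        call = call_patterns(pair)
        assert call.headful_estimate == pytest.approx(44_000, rel=0.10)

    def test_constant_track_undefined(self):
        h = estimate_headful_size(make_track([20.0] * 3000), (0, 300_000))
        assert np.isnan(h)


class TestFrequency:
    @pytest.mark.parametrize(
        "plateau,flank,expected",
        [(10_000.0, 1.0, 10_000.0), (5.0, 5.0, 1.0), (12_345.0, 1.0, 12_000.0)],
    )
    def test_ratio_and_rounding(self, plateau, flank, expected):
        assert estimate_transduction_frequency(plateau, flank) == expected

    def test_zero_flank_rejected(self):
        with pytest.raises(ValueError):
            estimate_transduction_frequency(10.0, 0.0)

    @pytest.mark.parametrize("f_spec", [1e-2, 1e-3, 1e-4])
    def test_recovery_single_sided(self, f_spec):
        m = GenomeModel(
            genome_length=300_000,
            prophages=[ProphageElement(
                start=125_000, end=173_500, induction_rate=1.0,
                specialized_rate=f_spec, capsid_capacity=48_500,
                max_flank=25_000, side_bias=0.0,
            )],
        )
        frags = simulate_fragments(m, 3_000_000, seed=13)
        vlp = fragments_to_coverage(frags, bin_size=100, total_mapped=1e6)
        wgs = simulate_wgs_track(300_000, 200.0, seed=13)
        call = call_patterns(PairedCoverage(vlp.contig_id, wgs=wgs, vlp=vlp))
        assert call.mode == "specialized"
        truth = 1.0 / f_spec
        assert truth / 2 <= call.frequency_ratio <= truth * 2


class TestUnevenness:
    def test_constant_is_one(self):
        assert unevenness_ratio(make_track([30.0] * 1000)) == pytest.approx(1.0)

    def test_pbsx_configured_bias_recovered(self, pbsx_fixture):
        pair, truth = pbsx_fixture
        fold = next(e["bias_fold"] for e in truth.elements if e["mode"] == "gta_like")
        assert unevenness_ratio(normalize_track(pair.vlp)) == pytest.approx(fold, rel=0.2)

    def test_weak_generalized_below_strong(self, p1_fixture, p22_fixture):
        u_p1 = unevenness_ratio(normalize_track(p1_fixture[0].vlp))
        u_p22 = unevenness_ratio(normalize_track(p22_fixture[0].vlp))
        assert u_p1 <= 10.0
        assert u_p1 <= u_p22


class TestCallPatterns:
    def test_lambda_specialized_with_both_flanks(self, lambda_fixture):
        pair, truth, _ = lambda_fixture
        call = call_patterns(pair)
        el_truth = truth.elements[0]
        assert call.mode == "specialized"
        (el,) = call.elements
        assert abs(el.start - el_truth["start"]) <= 200
        assert abs(el.end - el_truth["end"]) <= 200
        sides = {f["side"]: f["extent"] for f in el.flanks}
        assert set(sides) == {"left", "right"}
        for extent in sides.values():
            assert extent == pytest.approx(25_000, abs=3_000)
        assert call.frequency_ratio == pytest.approx(10_000, rel=0.5)
        assert call.confident

    def test_flat_low_vlp_is_standard(self):
        wgs = simulate_wgs_track(200_000, 150.0, seed=2)
        rng = np.random.default_rng(3)
        vlp = make_track(rng.poisson(2.0, size=2000).astype(float),
                         contig_id="contig")
        call = call_patterns(PairedCoverage("contig", wgs=wgs, vlp=vlp))
        assert call.mode == "standard"

    def test_faecalis_two_laterals_and_island(self, faecalis_fixture):
        pair, truth = faecalis_fixture
        call = call_patterns(pair)
        assert call.mode == "lateral"
        kinds = sorted(e.kind for e in call.elements)
        assert kinds == ["induction", "lateral", "lateral"]
        ratios = sorted(e.frequency_ratio for e in call.elements if e.kind == "lateral")
        truth_ratios = sorted(
            e["frequency_ratio"] for e in truth.elements if e["mode"] == "lateral"
        )
        for est, tr in zip(ratios, truth_ratios):
            assert tr / 2 <= est <= tr * 2

    def test_scale_invariance_of_modes(self, community):
        pairs, _ = community
        for pair in pairs[:12]:
            ref = call_patterns(pair).mode
            for c in (0.037, 29.0):
                scaled = PairedCoverage(
                    pair.contig_id,
                    wgs=make_track(
                        pair.wgs.depths * c, total_mapped=pair.wgs.total_mapped * c,
                        contig_id=pair.contig_id, source="whole",
                        contig_length=pair.wgs.contig_length,
                    ),
                    vlp=make_track(
                        pair.vlp.depths * c, total_mapped=pair.vlp.total_mapped * c,
                        contig_id=pair.contig_id, source="vlp",
                        contig_length=pair.vlp.contig_length,
                    ),
                )
                assert call_patterns(scaled).mode == ref

    def test_community_macro_recall(self, community, community_calls):
        pairs, truths = community
        by_mode: dict[str, list[bool]] = {}
        for t, c in zip(truths, community_calls):
            by_mode.setdefault(t.mode, []).append(c.mode == t.mode)
        for mode, hits in by_mode.items():
            assert np.mean(hits) >= 0.9, (mode, hits)

    def test_truncated_lateral_flagged(self):
        # prophage near the left end, staircase running off the right end
        m = GenomeModel(
            genome_length=250_000, circular=False,
            prophages=[ProphageElement(
                start=20_000, end=60_000, induction_rate=1.0,
                capsid_capacity=40_000, lateral_rate=0.01,
                lateral_direction="right", continuation_prob=0.7,
            )],
        )
        frags = simulate_fragments(m, 200_000, seed=21)
        vlp = fragments_to_coverage(frags, bin_size=100, total_mapped=1e6)
        wgs = simulate_wgs_track(250_000, 100.0, seed=21)
        call = call_patterns(PairedCoverage(vlp.contig_id, wgs=wgs, vlp=vlp))
        assert call.mode == "lateral"
        assert "truncated_at_end" in call.qc_flags
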