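"""Fragment simulation, the deamination channel, trimming and profiling."""

import numpy as np
import pytest

import paleoimpute as pi
from paleoimpute.ancient_reads import (
    BASE_CODE,
    BASES,
    DamageModelParams,
    ReadSet,
    estimate_damage_profile,
    fit_damage_model,
    params_for_pmd,
)


@pytest.fixture(scope="module")
def dense_panel():
    """High SNP density so distance-resolved damage cells are well populated."""
    return pi.simulate_panel(1, 20, 12_000, 200_000, ts_fraction=0.3,
                             maf_min=0.05, seed=21)


@pytest.fixture(scope="module")
def dense_individual(dense_panel):
    return pi.sample_individual(dense_panel, "pop0", copy_error=0.0, seed=22)


class TestDamageModel:
    def test_closed_form(self):
        d = DamageModelParams(overhang_p=0.36, deam_ds=0.0097, deam_ss=0.42)
        dist = np.arange(1, 6)
        expected = 0.0097 + (0.42 - 0.0097) * 0.64 ** (dist - 1)
        assert np.allclose(d.delta(dist), expected)
        assert d.delta5_at_1() == pytest.approx(0.42)

    def test_udg_scales_channel(self):
        d = DamageModelParams(deam_ss=0.4, udg_factor=0.25)
        assert d.delta5_at_1() == pytest.approx(0.1)

    def test_params_for_pmd(self):
        d = params_for_pmd(0.42)
        assert d.delta5_at_1() == pytest.approx(0.42)
        tiny = params_for_pmd(0.001)
        assert tiny.deam_ds <= tiny.deam_ss

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            DamageModelParams(deam_ss=1.5)


class TestSimulateReads:
    def test_no_damage_no_error_reads_truth(self, dense_panel, dense_individual,
                                            no_damage):
        rs = pi.simulate_reads(dense_individual, dense_panel, 2.0, no_damage, seed=1)
        ref = np.array([BASE_CODE[b] for b in dense_panel.ref_base])
        alt = np.array([BASE_CODE[b] for b in dense_panel.alt_base])
        # every observed base must equal one of the individual's two alleles
        a1 = np.where(dense_individual.hap1[rs.obs_site] == 0,
                      ref[rs.obs_site], alt[rs.obs_site])
        a2 = np.where(dense_individual.hap2[rs.obs_site] == 0,
                      ref[rs.obs_site], alt[rs.obs_site])
        assert np.all((rs.obs_base == a1) | (rs.obs_base == a2))

    def test_realized_coverage(self, clean_error_only):
        panel = pi.simulate_panel(1, 20, 10_000, 5_000_000, seed=30)
        ind = pi.sample_individual(panel, "pop0", seed=31)
        rs = pi.simulate_reads(ind, panel, 30.0, clean_error_only, seed=32)
        assert abs(rs.realized_coverage - 30.0) / 30.0 < 0.05

    def test_determinism(self, dense_panel, dense_individual, clean_error_only):
        a = pi.simulate_reads(dense_individual, dense_panel, 1.0,
                              clean_error_only, seed=9)
        b = pi.simulate_reads(dense_individual, dense_panel, 1.0,
                              clean_error_only, seed=9)
        assert np.array_equal(a.obs_base, b.obs_base)
        assert np.array_equal(a.frag_start, b.frag_start)

    def test_fragment_length_bounds(self, dense_panel, dense_individual,
                                    clean_error_only):
        rs = pi.simulate_reads(dense_individual, dense_panel, 1.0,
                               clean_error_only, seed=3)
        lengths = rs.frag_end - rs.frag_start + 1
        assert lengths.min() >= 30 and lengths.max() <= 150

    def test_nick_freq_warns(self, dense_panel, dense_individual):
        damage = DamageModelParams(nick_freq=0.024, seq_error=0.0)
        with pytest.warns(UserWarning, match="nick_freq"):
            pi.simulate_reads(dense_individual, dense_panel, 0.5, damage, seed=4)

    def test_zero_fragments_warns(self, dense_panel, dense_individual, no_damage):
        with pytest.warns(UserWarning, match="zero fragments|no fragment"):
            rs = pi.simulate_reads(dense_individual, dense_panel, 1e-7,
                                   no_damage, seed=5)
        assert rs.n_obs == 0


class TestDownsample:
    def test_identity_at_current_coverage(self, dense_panel, dense_individual,
                                          clean_error_only):
        rs = pi.simulate_reads(dense_individual, dense_panel, 2.0,
                               clean_error_only, seed=6)
        same = pi.downsample_reads(rs, rs.realized_coverage, seed=1)
        assert same.n_fragments == rs.n_fragments

    def test_kept_fraction(self, clean_error_only):
        panel = pi.simulate_panel(1, 20, 5_000, 2_000_000, seed=33)
        ind = pi.sample_individual(panel, "pop0", seed=34)
        rs = pi.simulate_reads(ind, panel, 30.0, clean_error_only, seed=35)
        ds = pi.downsample_reads(rs, 1.0, seed=36)
        frac = ds.n_fragments / rs.n_fragments
        p = 1.0 / rs.realized_coverage
        se = np.sqrt(p * (1 - p) / rs.n_fragments)
        assert abs(frac - p) <= 3 * se

    def test_determinism_and_rejects_upsample(self, dense_panel,
                                              dense_individual, clean_error_only):
        rs = pi.simulate_reads(dense_individual, dense_panel, 2.0,
                               clean_error_only, seed=7)
        a = pi.downsample_reads(rs, 0.5, seed=2)
        b = pi.downsample_reads(rs, 0.5, seed=2)
        assert np.array_equal(a.obs_site, b.obs_site)
        with pytest.raises(ValueError):
            pi.downsample_reads(rs, 10.0)


class TestTrim:
    def test_k0_identity(self, dense_panel, dense_individual, clean_error_only):
        rs = pi.simulate_reads(dense_individual, dense_panel, 1.0,
                               clean_error_only, seed=8)
        assert pi.trim_reads(rs, 0) is rs

    def test_coverage_strictly_decreasing_in_k(self, dense_panel,
                                               dense_individual, clean_error_only):
        rs = pi.simulate_reads(dense_individual, dense_panel, 2.0,
                               clean_error_only, seed=9)
        c0 = pi.trim_reads(rs, 0).realized_coverage
        c5 = pi.trim_reads(rs, 5).realized_coverage
        c10 = pi.trim_reads(rs, 10).realized_coverage
        assert c0 > c5 > c10

    def test_full_trim_empties(self, dense_panel, dense_individual,
                               clean_error_only):
        rs = pi.simulate_reads(dense_individual, dense_panel, 1.0,
                               clean_error_only, seed=10)
        assert pi.trim_reads(rs, 75).n_obs == 0

    def test_trimmed_obs_far_from_ends(self, dense_panel, dense_individual,
                                       clean_error_only):
        rs = pi.simulate_reads(dense_individual, dense_panel, 1.0,
                               clean_error_only, seed=11)
        t = pi.trim_reads(rs, 10)
        start = t.frag_start[t.obs_frag]
        end = t.frag_end[t.obs_frag]
        dmin = np.minimum(t.obs_pos - start + 1, end - t.obs_pos + 1)
        assert dmin.min() > 10


class TestDamageProfile:
    def test_zero_damage_monomorphic_background(self, dense_panel,
                                                dense_individual, no_damage):
        rs = pi.simulate_reads(dense_individual, dense_panel, 5.0, no_damage,
                               seed=12)
        prof = estimate_damage_profile(rs, dense_panel, k_max=15)
        # ambiguous sites are excluded and there is no error channel, so
        # every informative cell must be exactly zero
        finite = prof.d5_ct[np.isfinite(prof.d5_ct)]
        assert np.all(finite == 0.0)

    def test_recovers_headline_rate(self, dense_panel, dense_individual):
        damage = params_for_pmd(0.42, seq_error=0.001)
        damage = DamageModelParams(**{**damage.__dict__, "nick_freq": 0.0})
        rs = pi.simulate_reads(dense_individual, dense_panel, 30.0, damage,
                               seed=13)
        prof = estimate_damage_profile(rs, dense_panel, k_max=15)
        assert prof.n5[0] > 400
        assert abs(prof.pmd_headline - 0.42) <= 0.03
        # profile non-increasing within binomial noise (3 pooled-se slack)
        for d in range(1, 10):
            se = np.sqrt(0.3 / prof.n5[d])
            assert prof.d5_ct[d] <= prof.d5_ct[d - 1] + 3 * se

    def test_strand_symmetry_double_strand(self, dense_panel, dense_individual):
        damage = DamageModelParams(nick_freq=0.0, deam_ss=0.3, seq_error=0.0)
        rs = pi.simulate_reads(dense_individual, dense_panel, 30.0, damage,
                               seed=14)
        prof = estimate_damage_profile(rs, dense_panel, k_max=10)
        # C->T at 5' and G->A at 3' are mirror images of one channel
        for d in range(5):
            se = np.sqrt(0.25 * (1 / prof.n5[d] + 1 / prof.n3[d]))
            assert abs(prof.d5_ct[d] - prof.d3_ga[d]) <= 4 * se

    def test_single_strand_library_ct_both_ends(self, dense_panel,
                                                dense_individual):
        damage = DamageModelParams(nick_freq=0.0, deam_ss=0.3, seq_error=0.0,
                                   library="single_strand")
        rs = pi.simulate_reads(dense_individual, dense_panel, 10.0, damage,
                               seed=15)
        prof = estimate_damage_profile(rs, dense_panel, k_max=10,
                                       library="single_strand")
        # in ss mode the 3' tally is also C->T and must show elevation
        assert prof.d3_ga[0] > 0.15
        ds_prof = estimate_damage_profile(rs, dense_panel, k_max=10,
                                          library="double_strand")
        assert ds_prof.d3_ga[0] < 0.05  # no true G->A channel in ss libraries

    def test_fit_damage_model_recovers_parameters(self, dense_panel,
                                                  dense_individual):
        damage = DamageModelParams(nick_freq=0.0, overhang_p=0.36,
                                   deam_ds=0.0097, deam_ss=0.42, seq_error=0.0)
        rs = pi.simulate_reads(dense_individual, dense_panel, 30.0, damage,
                               seed=16)
        prof = estimate_damage_profile(rs, dense_panel, k_max=20)
        fit = fit_damage_model(prof)
        assert abs(fit.deam_ss - 0.42) < 0.05
        assert abs(fit.overhang_p - 0.36) < 0.15

    def test_empty_input_rejected(self, dense_panel):
        with pytest.raises(ValueError):
            estimate_damage_profile(ReadSet.empty(dense_panel.n_sites),
                                    dense_panel)


class TestReadSetTsv:
    def test_round_trip_exact(self, dense_panel, dense_individual,
                              clean_error_only, tmp_path):
        rs = pi.simulate_reads(dense_individual, dense_panel, 0.5,
                               clean_error_only, seed=17)
        path = tmp_path / "reads.tsv"
        rs.to_tsv(path, chrom=dense_panel.chrom)
        back = ReadSet.from_tsv(path, dense_panel)
        assert np.array_equal(back.obs_site, rs.obs_site)
        assert np.array_equal(back.obs_base, rs.obs_base)
        assert np.array_equal(back.frag_start, rs.frag_start)
        assert np.array_equal(back.frag_strand, rs.frag_strand)
        assert back.realized_coverage == rs.realized_coverage

    def test_non_panel_position_rejected(self, dense_panel, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "frag\tchrom\tstart\tend\tstrand\tsource\tsite_pos\tobs_base\tqual\n"
            "0\t1\t10\t70\t+\tendogenous\t99999999\tA\t30\n"
        )
        with pytest.raises(ValueError, match="row 2"):
            ReadSet.from_tsv(path, dense_panel)
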