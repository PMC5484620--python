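import math

import numpy as np
import pytest
from scipy import stats as sps

from larpclip.model import UTR3, UTR5, TranscriptModel
from larpclip.seqstats import (
    bound_vs_unbound_composition,
    classify_top,
    enriched_hexamers,
    g_fraction,
    max_pyrimidine_run,
    positional_pyrimidine_profile,
    pyrimidine_fraction,
    site_sequences,
    summarize_runs,
    top_overlap,
    welch_t_test,
)
from larpclip.sitecall import BindingSite


class TestPyrimidineFraction:
    @pytest.mark.parametrize(
        "seq,expected",
        [("CCTTCC", 1.0), ("GAGA", 0.0), ("CTGA", 0.5), ("CTNN", 1.0)],
    )
    def test_examples(self, seq, expected):
        assert pyrimidine_fraction(seq) == pytest.approx(expected)

    def test_all_n_undefined(self):
        with pytest.raises(ValueError):
            pyrimidine_fraction("NNN")

    def test_pyrimidine_plus_purine_is_one(self, rng):
        for _ in range(100):
            seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 50))))
            purine = sum(1 for b in seq if b in "AG") / len(seq)
            assert pyrimidine_fraction(seq) + purine == pytest.approx(1.0)


class TestWelch:
    def test_identical_groups(self):
        ct = welch_t_test([0.5, 0.6, 0.7], [0.5, 0.6, 0.7])
        assert ct.t == pytest.approx(0.0)
        assert ct.p == pytest.approx(1.0)

    def test_frozen_closed_form_oracle(self):
        # hand-computed from the Welch formulas before implementation:
        # a=(0.8,0.9,0.85), b=(0.5,0.55,0.6) -> t=7.34846922834954,
        # df=4.0, p=0.0018262606682599785
        ct = welch_t_test([0.8, 0.9, 0.85], [0.5, 0.55, 0.6])
        assert ct.t == pytest.approx(7.34846922834954, abs=1e-10)
        assert ct.df == pytest.approx(4.0, abs=1e-10)
        assert ct.p == pytest.approx(0.0018262606682599785, abs=1e-12)

    def test_swap_negates_t_preserves_p(self):
        a, b = [0.8, 0.9, 0.85], [0.5, 0.55, 0.6]
        ct, tc = welch_t_test(a, b), welch_t_test(b, a)
        assert tc.t == pytest.approx(-ct.t)
        assert tc.p == pytest.approx(ct.p)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0], [0.5, 0.6])

    def test_zero_variance_equal_means_convention(self):
        ct = welch_t_test([0.5, 0.5], [0.5, 0.5])
        assert ct.p == 1.0 and ct.t == 0.0

    def test_agrees_with_independent_implementation(self, rng):
        """200 random inputs vs scipy's Welch test, tolerance 1e-10."""
        for _ in range(200):
            na, nb = int(rng.integers(2, 30)), int(rng.integers(2, 30))
            a = rng.normal(0, 1, size=na)
            b = rng.normal(0.3, 2, size=nb)
            ct = welch_t_test(a, b)
            ref = sps.ttest_ind(a, b, equal_var=False)
            assert ct.t == pytest.approx(ref.statistic, abs=1e-10)
            assert ct.p == pytest.approx(ref.pvalue, abs=1e-10)


class TestRuns:
    @pytest.mark.parametrize(
        "seq,expected", [("GGCCTTTCG", 6), ("AAAA", 0), ("CTCTCT", 6)]
    )
    def test_examples(self, seq, expected):
        assert max_pyrimidine_run(seq) == expected

    def test_matches_linear_scan_oracle(self, rng):
        for _ in range(200):
            seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 80))))
            best = cur = 0
            for b in seq:
                cur = cur + 1 if b in "CT" else 0
                best = max(best, cur)
            assert max_pyrimidine_run(seq) == best


def mktx(seq, tid="T0", u5=None, cat="RP"):
    u5 = u5 if u5 is not None else len(seq) // 4
    cds = len(seq) // 2
    u3 = len(seq) - u5 - cds
    return TranscriptModel(tid, f"G_{tid}", cat, seq, u5, cds, u3)


def mksite(tid, start, end, region):
    return BindingSite(tid, start, end, read_count=5, conversion_read_count=1,
                       rpm=2.0, norm_score=10.0, region=region)


class TestTop:
    def test_top_positive_call(self):
        t = mktx("CTTTCTGGC" + "A" * 91)
        (call,) = classify_top([t], min_run=4)
        assert call.is_top
        assert call.top_run_length >= 5

    def test_must_start_with_c(self):
        t = mktx("ATTTT" + "A" * 95)
        (call,) = classify_top([t], min_run=4)
        assert not call.is_top

    def test_site_away_from_top_does_not_overlap(self):
        seq = "CTTTTTTT" + "G" * 192 + "A" * 300 + "G" * 100
        t = mktx(seq, u5=200)
        calls = classify_top([t], min_run=4)
        frac, n = top_overlap([mksite("T0", 180, 200, UTR5)], calls)
        assert n == 1 and frac == 0.0

    def test_site_at_cap_overlaps(self):
        seq = "CTTTTTTT" + "G" * 192 + "A" * 300 + "G" * 100
        t = mktx(seq, u5=200)
        calls = classify_top([t], min_run=4)
        frac, _ = top_overlap([mksite("T0", 0, 20, UTR5)], calls)
        assert frac == 1.0


class TestBoundVsUnbound:
    def test_single_transcript_rejected(self):
        t = mktx("C" * 100 + "A" * 200 + "G" * 100, u5=100)
        with pytest.raises(ValueError):
            bound_vs_unbound_composition([mksite("T0", 0, 20, UTR5)], [t], UTR5)

    def test_detects_planted_pyrimidine_contrast(self):
        # bound segments all-pyrimidine, remainder all-purine
        txs, sites = [], []
        for i in range(20):
            tid = f"T{i}"
            seq = "A" * 80 + "CT" * 10 + "A" * 200 + "G" * 100  # PES at 80-100
            txs.append(TranscriptModel(tid, f"G{i}", "RP", seq, 100, 200, 100))
            sites.append(mksite(tid, 80, 100, UTR5))
        ct = bound_vs_unbound_composition(sites, txs, UTR5)
        assert ct.mean_a == pytest.approx(1.0)
        assert ct.mean_b == pytest.approx(0.0)
        assert ct.p < 1e-6

    def test_utr3_scope_uses_g_fraction(self):
        txs, sites = [], []
        for i in range(10):
            tid = f"T{i}"
            seq = "A" * 100 + "C" * 200 + "G" * 30 + "ATAT" * 17 + "AT"
            txs.append(TranscriptModel(tid, f"G{i}", "non_TR", seq, 100, 200, 100))
            sites.append(mksite(tid, 300, 330, UTR3))
        ct = bound_vs_unbound_composition(sites, txs, UTR3)
        assert ct.mean_a == pytest.approx(1.0)  # bound segment pure G
        assert ct.mean_b == pytest.approx(0.0)


class TestPositionalProfile:
    def test_uniform_sequence_both_windows_one(self):
        seqs = ["C" * 100, "C" * 100]
        res = positional_pyrimidine_profile(seqs, ["A" * 60 + "C" * 40] * 3, window=25)
        assert np.allclose(res["five_prime"].group_a, 1.0)
        assert np.allclose(res["three_prime"].group_a, 1.0)

    def test_short_utrs_excluded_and_all_short_rejected(self):
        with pytest.raises(ValueError):
            positional_pyrimidine_profile(["CCC"], ["C" * 100] * 2, window=25)

    def test_three_prime_contrast_detected(self, rng):
        # group A pyrimidine-rich only at the 3' end; group B uniform
        ga = ["".join(rng.choice(list("ACGT"), size=75)) + "CT" * 13 for _ in range(15)]
        gb = ["".join(rng.choice(list("ACGT"), size=101)) for _ in range(15)]
        res = positional_pyrimidine_profile(ga, gb, window=25)
        assert res["three_prime"].p < 0.01
        assert res["five_prime"].p > 0.05


def test_site_sequences_extension_clipped(small_data):
    transcripts, truth, _ = small_data
    sites = [
        mksite(s.transcript_id, s.start, s.end, s.region)
        for s in truth.planted_sites[:5]
    ]
    pairs = site_sequences(sites, transcripts, extend=15)
    for site, seq in pairs:
        assert len(seq) >= (site.end - site.start)
        assert len(seq) <= (site.end - site.start) + 30


def test_summarize_runs_on_pure_pes():
    txs, sites = [], []
    for i in range(8):
        tid = f"T{i}"
        seq = "A" * 80 + "CT" * 10 + "A" * 200 + "G" * 100
        txs.append(TranscriptModel(tid, f"G{i}", "RP", seq, 100, 200, 100))
        sites.append(mksite(tid, 80, 100, UTR5))
    frac, n = summarize_runs(sites, txs, k=6, extend=15, region=UTR5)
    assert n == 8 and frac == 1.0


def test_enriched_hexamers_finds_planted_motif(rng):
    seqs = []
    for _ in range(30):
        bg = "".join(rng.choice(list("ACGT"), size=40))
        seqs.append(bg[:17] + "CTTTCC" + bg[23:])
    top = enriched_hexamers(seqs, seed=0, top=5)
    assert "CTTTCC" in {k for k, _ in top}
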