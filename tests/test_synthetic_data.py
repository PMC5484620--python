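import dataclasses
import math

import numpy as np
import pytest

from larpclip.alignment_io import make_aligned_read
from larpclip.model import CDS, UTR3, UTR5, write_fasta, write_region_tsv
from larpclip.synthetic_data import (
    SimulationSpec,
    estimate_conversion_rate,
    generate_transcriptome,
    simulate_mrnaseq,
    simulate_parclip,
    synthetic_go_annotation,
)


def tiny(**over):
    defaults = dict(n_transcripts=30, mrnaseq_reads=10_000, seed=5)
    defaults.update(over)
    return SimulationSpec(**defaults)


class TestSpecValidation:
    def test_bad_probability_rejected(self):
        with pytest.raises(ValueError, match="conversion_rate"):
            tiny(conversion_rate=1.5).validate()

    def test_fractions_must_fit(self):
        with pytest.raises(ValueError, match="fraction"):
            tiny(fraction_rp=0.7, fraction_tr_other=0.5).validate()

    def test_short_region_names_region(self):
        with pytest.raises(ValueError, match="5'UTR"):
            generate_transcriptome(tiny(utr5_len=(10, 20)))
        with pytest.raises(ValueError, match="3'UTR"):
            generate_transcriptome(tiny(utr3_len=(5, 10)))


class TestTranscriptome:
    def test_deterministic_outputs_byte_identical(self, tmp_path):
        spec = tiny(seed=1)
        files = []
        for run in ("a", "b"):
            tx, _ = generate_transcriptome(spec)
            fa = tmp_path / f"{run}.fa"
            tsv = tmp_path / f"{run}.tsv"
            write_fasta(fa, tx)
            write_region_tsv(tsv, tx)
            files.append((fa.read_bytes(), tsv.read_bytes()))
        assert files[0] == files[1]

    def test_category_counts_exact(self):
        tx, _ = generate_transcriptome(tiny(n_transcripts=100, fraction_rp=0.2))
        assert sum(t.category == "RP" for t in tx) == 20

    def test_pure_pes_when_rate_one(self):
        spec = tiny(pes_pyrimidine_rate=1.0)
        tx, truth = generate_transcriptome(spec)
        for s in truth.planted_sites:
            if s.region == UTR5:
                seq = tx[int(s.transcript_id[2:])].seq[s.start : s.end]
                assert all(b in "CT" for b in seq)

    def test_planted_sites_inside_their_region(self, small_data):
        transcripts, truth, _ = small_data
        by_tid = {t.transcript_id: t for t in transcripts}
        for s in truth.planted_sites:
            lo, hi = by_tid[s.transcript_id].region_bounds()[s.region]
            assert lo <= s.start < s.end <= hi

    def test_rp_transcripts_start_with_top(self, small_data):
        transcripts, _, spec = small_data
        for t in transcripts:
            if t.category == "RP":
                assert t.seq[0] == "C"
                assert all(b in "CT" for b in t.seq[1 : 1 + spec.top_run_len])

    def test_footprint_layout_by_category(self, small_data):
        transcripts, truth, _ = small_data
        regions = {}
        for s in truth.planted_sites:
            regions.setdefault(s.category, set()).add(s.region)
        assert regions["RP"] == {UTR5, UTR3}
        assert regions["TR_other"] == {UTR5, UTR3}
        assert regions["non_TR"] == {CDS, UTR3}

    def test_utr5_footprints_active_only_when_mtor_off(self, small_data):
        _, truth, _ = small_data
        for s in truth.planted_sites:
            if s.region == UTR5:
                assert s.active_in == ("mTOR_off",)
            else:
                assert set(s.active_in) == {"mTOR_on", "mTOR_off"}


def _aligned(records, transcripts):
    by_tid = {t.transcript_id: t.seq for t in transcripts}
    return [make_aligned_read(r, by_tid[r.transcript_id]) for r in records]


class TestParclip:
    def test_no_conversions_when_rate_zero(self):
        spec = tiny(conversion_rate=0.0, seq_error_rate=0.0)
        tx, truth = generate_transcriptome(spec)
        reads = _aligned(simulate_parclip(tx, truth, spec), tx)
        assert all(r.t_to_c_count == 0 for r in reads)

    def test_conversion_rate_recovered_within_3se(self):
        spec = tiny(n_transcripts=100)
        tx, truth = generate_transcriptome(spec)
        reads = _aligned(simulate_parclip(tx, truth, spec), tx)
        est, n = estimate_conversion_rate(reads, truth, tx, spec.condition)
        assert n >= 1000
        se = math.sqrt(spec.conversion_rate * (1 - spec.conversion_rate) / n)
        assert abs(est - spec.conversion_rate) <= 3 * se

    def test_mtor_on_silences_rp_utr5_footprints(self):
        spec = tiny(condition="mTOR_on", background_read_rate=0.0)
        tx, truth = generate_transcriptome(spec)
        reads = simulate_parclip(tx, truth, spec)
        utr5_sites = [s for s in truth.planted_sites if s.region == UTR5]
        for r in reads:
            mid = r.start + len(r.seq) // 2
            for s in utr5_sites:
                assert not (
                    r.transcript_id == s.transcript_id and s.start <= mid < s.end
                )

    def test_footprint_reads_overlap_their_site(self):
        spec = tiny(background_read_rate=0.0, multimap_fraction=0.0)
        tx, truth = generate_transcriptome(spec)
        reads = simulate_parclip(tx, truth, spec)
        active = truth.active_sites(spec.condition)
        for r in reads:
            assert any(
                r.transcript_id == s.transcript_id
                and max(r.start, s.start) < min(r.start + len(r.seq), s.end)
                for s in active
            )

    def test_deterministic(self):
        spec = tiny()
        tx1, tr1 = generate_transcriptome(spec)
        tx2, tr2 = generate_transcriptome(spec)
        assert simulate_parclip(tx1, tr1, spec) == simulate_parclip(tx2, tr2, spec)

    def test_empty_truth_gives_no_reads(self):
        spec = tiny(background_read_rate=0.0)
        tx, truth = generate_transcriptome(spec)
        truth.planted_sites.clear()
        assert simulate_parclip(tx, truth, spec) == []


class TestMrnaseq:
    def test_zero_reads_requested_rejected(self, small_data):
        transcripts, truth, spec = small_data
        bad = dataclasses.replace(spec, mrnaseq_reads=0)
        with pytest.raises(ValueError):
            simulate_mrnaseq(transcripts, truth, bad)

    def test_single_transcript_takes_all_reads(self):
        spec = tiny(n_transcripts=1, fraction_rp=0.0, fraction_tr_other=0.0,
                    multimap_fraction=0.0, mrnaseq_reads=500)
        tx, truth = generate_transcriptome(spec)
        (lib,) = simulate_mrnaseq(tx, truth, dataclasses.replace(spec, n_replicates=1))
        assert len(lib) == 500
        assert {r.transcript_id for r in lib} == {tx[0].transcript_id}

    def test_doubled_abundance_doubles_expected_count(self):
        spec = tiny(n_transcripts=2, fraction_rp=0.0, fraction_tr_other=0.0,
                    multimap_fraction=0.0, mrnaseq_reads=200_000, n_replicates=1,
                    utr5_len=(100, 100), cds_len=(400, 400), utr3_len=(200, 200))
        tx, truth = generate_transcriptome(spec)
        a, b = (t.transcript_id for t in tx)
        truth.true_abundance = {a: 2 / 3, b: 1 / 3}
        (lib,) = simulate_mrnaseq(tx, truth, spec)
        counts = {a: 0, b: 0}
        for r in lib:
            counts[r.transcript_id] += 1
        ratio = counts[a] / counts[b]
        # multinomial sampling noise at this depth is well under 5%
        assert ratio == pytest.approx(2.0, rel=0.05)

    def test_replicates_differ_but_same_marginals(self, small_data):
        transcripts, truth, spec = small_data
        libs = simulate_mrnaseq(transcripts, truth, spec)
        assert len(libs) == spec.n_replicates
        assert libs[0] != libs[1]


def test_multimap_reads_emitted_once_per_cassette_copy(small_data):
    transcripts, truth, spec = small_data
    assert len(truth.multimap_copies) >= 2
    libs = simulate_mrnaseq(transcripts, truth, spec)
    by_id: dict[str, int] = {}
    for r in libs[0]:
        by_id[r.read_id] = by_id.get(r.read_id, 0) + 1
    ks = set(by_id.values())
    assert ks == {1, len(truth.multimap_copies)}


def test_go_annotation_reflects_categories(small_data):
    transcripts, _, spec = small_data
    ann = synthetic_go_annotation(transcripts, spec)
    for t in transcripts:
        if t.category == "RP":
            assert "GO:0003735" in ann[t.gene_id]
        if t.category in ("RP", "TR_other"):
            assert "GO:0006412" in ann[t.gene_id]
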