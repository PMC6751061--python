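import math

import pytest

from rendscope import synthetic as syn
from rendscope.peaks import Peak
from rendscope.regulon import (
    PromoterCall,
    RegulonParams,
    build_regulon_table,
    call_induced_promoters,
    fold_change_track,
    infer_operon,
    merge_nearby_peaks,
    upstream_window,
)
from rendscope.tracks import EndTrack

SIGN_41MER = "TTTTCGTTTACGTTTCTATTTCTCTAGATAAAATCATTAAG"


def _t5(counts, normalized=True, strand="+"):
    return EndTrack("ref1", strand, "5p", 10_000, dict(counts),
                    normalized=normalized, scale_factor=1.0 if normalized else None)


def _peak(pos, count=50.0, strand="+", end="5p"):
    return Peak("ref1", strand, end, pos, count, 0.1, count / 0.25)


class TestFoldChange:
    def test_identical_tracks_fc_one(self):
        counts = {100: 5.0, 200: 9.0}
        fc = fold_change_track(_t5(counts), _t5(counts))
        assert set(fc) and all(v == pytest.approx(1.0) for v in fc.values())

    def test_stated_pseudocount_arithmetic(self):
        # windowed induced sum 100, control 0, pseudocount 0.5 -> 100.5/0.5 = 201
        fc = fold_change_track(_t5({100: 100.0}), _t5({}))
        assert fc[100] == pytest.approx(201.0)

    def test_both_zero_positions_omitted(self):
        fc = fold_change_track(_t5({100: 1.0}), _t5({100: 1.0}))
        assert 500 not in fc

    def test_window_sums_absorb_jitter(self):
        params = RegulonParams()
        fc = fold_change_track(_t5({100: 60.0, 101: 40.0}), _t5({99: 5.0}), params)
        # at i=100 the +/-2 window captures all induced and control signal
        assert fc[100] == pytest.approx((100.0 + 0.5) / (5.0 + 0.5))

    def test_mismatched_tracks_rejected(self):
        with pytest.raises(ValueError):
            fold_change_track(_t5({1: 1.0}), _t5({1: 1.0}, strand="-"))
        with pytest.raises(ValueError, match="normalized"):
            fold_change_track(_t5({1: 1.0}, normalized=False), _t5({1: 1.0}))

    def test_planted_induction_measured_near_truth(self):
        # one 100-fold induced TU against a strong constitutive background:
        # the normalized ratio lands within a factor of two of the plant
        g = syn.make_genome(
            n_refs=1, ref_lengths=30_000, n_tus=4,
            tu_spec=[
                {"length": 2000, "strand": "+", "abundance": {"WT": 0.05, "ind": 5.0}},
                {"length": 2000, "strand": "+", "abundance": {"WT": 5.0, "ind": 5.0}},
                {"length": 2000, "strand": "-", "abundance": {"WT": 5.0, "ind": 5.0}},
                {"length": 2000, "strand": "+", "abundance": {"WT": 5.0, "ind": 5.0}},
            ],
            seed=51,
        )
        from rendscope.align import align_reads, reassign_all
        from rendscope.tracks import count_ends, count_nonribo, normalize_tracks

        tracks = {}
        for i, cond in enumerate(("WT", "ind")):
            params = syn.SimulatorParams(depth=50_000, seed=60 + i)
            reads, _ = syn.simulate_reads(g, params, cond)
            recs = reassign_all(align_reads(reads, g))
            tracks[cond] = normalize_tracks(count_ends(recs, g), count_nonribo(recs, g))
        tu = g.planted_tus[0]
        fc = fold_change_track(
            tracks["ind"].get("ref1", "+", "5p"), tracks["WT"].get("ref1", "+", "5p")
        )
        assert 50.0 <= fc[tu.tss] <= 200.0


class TestCallPromoters:
    def test_threshold_boundary_inclusive(self):
        peaks = [_peak(100), _peak(300)]
        fc = {100: 10.0, 300: 9.99}
        calls = call_induced_promoters(fc, peaks)
        assert [c.tss for c in calls] == [100]

    def test_no_peaks_empty(self):
        assert call_induced_promoters({100: 50.0}, []) == []

    def test_nearby_peaks_merge_to_higher(self):
        peaks = [_peak(100, 40.0), _peak(103, 90.0), _peak(200, 50.0)]
        merged = merge_nearby_peaks(peaks, within=5)
        assert [p.position for p in merged] == [103, 200]

    def test_only_5prime_peaks_considered(self):
        calls = call_induced_promoters({100: 50.0}, [_peak(100, end="3p")])
        assert calls == []


@pytest.fixture(scope="module")
def embedded():
    return syn.make_genome(
        n_refs=1, ref_lengths=10_000, n_tus=1,
        tu_spec=[{"tss": 5000, "length": 2000, "strand": "+", "embed": SIGN_41MER}],
        seed=2,
    )


class TestUpstreamWindow:
    def test_recovers_embedded_window(self, embedded):
        assert upstream_window(embedded, "ref1", 5000, "+") == SIGN_41MER

    def test_minus_strand_mirror_symmetry(self, embedded):
        from rendscope._seq import revcomp

        g = embedded
        seq = g.sequences["ref1"]
        mirrored = syn.AnnotatedGenome(sequences={"ref1": revcomp(seq)})
        n = len(seq)
        assert upstream_window(g, "ref1", 5000, "+") == upstream_window(
            mirrored, "ref1", n - 5000 + 1, "-"
        )

    @pytest.mark.parametrize("tss", [41, 500, 9959])
    def test_length_always_41(self, embedded, tss):
        assert len(upstream_window(embedded, "ref1", tss, "+")) == 41

    def test_out_of_bounds_on_linear_ref(self, embedded):
        with pytest.raises(ValueError, match="bounds"):
            upstream_window(embedded, "ref1", 10, "+")


class TestInferOperon:
    def _genes(self):
        return [
            syn.Gene("g1", "ref1", 1100, 1600, "+"),
            syn.Gene("g2", "ref1", 1650, 2200, "+"),
            syn.Gene("g3", "ref1", 5000, 5400, "+"),
            syn.Gene("gm", "ref1", 1100, 1600, "-"),
        ]

    def _call(self, tss=1000):
        return PromoterCall("orphan:%d" % tss, "ref1", "+", tss, 50.0)

    def test_two_gene_operon(self):
        done = infer_operon(self._call(), [_peak(2300, end="3p")], self._genes())
        assert done.operon_genes == ("g1", "g2")
        assert done.name == "g1"
        assert done.transcript_end3 == 2300

    def test_end_before_first_gene_is_orphan(self):
        done = infer_operon(self._call(), [_peak(1050, end="3p")], self._genes())
        assert done.operon_genes == ()
        assert done.name == "orphan:1000"

    def test_nearest_downstream_end_wins(self):
        done = infer_operon(
            self._call(), [_peak(2300, end="3p"), _peak(6000, end="3p")], self._genes()
        )
        assert done.transcript_end3 == 2300

    def test_no_peak_within_scan_absent_end(self):
        params = RegulonParams(max_operon_scan=500)
        done = infer_operon(self._call(), [_peak(2300, end="3p")], self._genes(), params)
        assert done.transcript_end3 is None

    def test_partial_overlap_threshold(self):
        # g2 (1650-2200) only half-covered by a transcript ending at 1925
        done = infer_operon(self._call(), [_peak(1926, end="3p")], self._genes())
        assert done.operon_genes == ("g1", "g2")
        done2 = infer_operon(self._call(), [_peak(1900, end="3p")], self._genes())
        assert done2.operon_genes == ("g1",)

    def test_synthetic_three_gene_operon_recovered(self, std_run):
        result, _ = std_run
        three = [
            tu for tu in result.genome.planted_tus
            if tu.abundance["induced"] / max(tu.abundance["WT"], 1e-9) >= 10
        ]
        by_tss = {c.tss: c for c in result.calls}
        for tu in three:
            call = by_tss.get(tu.tss)
            assert call is not None
            expected = tuple(
                g.name for g in result.genome.genes if g.name.startswith(tu.name + "_")
            )
            assert call.operon_genes == expected


class TestRegulonTable:
    def test_empty_calls_header_only(self):
        df = build_regulon_table([])
        assert len(df) == 0
        assert list(df.columns)[:4] == ["promoter", "sequence", "operon", "fold_change"]

    def test_fold_change_formatting(self):
        calls = [
            PromoterCall("a", "r", "+", 10, 101.0, "A" * 41),
            PromoterCall("b", "r", "+", 20, 152.5, "A" * 41),
            PromoterCall("c", "r", "+", 30, math.nan, "", source="predicted"),
        ]
        df = build_regulon_table(calls)
        assert list(df["fold_change"]) == ["101", "152.5", ""]

    def test_row_count_matches_planted_induced(self, std_run, induced_truth):
        result, _ = std_run
        rendseq_rows = result.table[result.table["source"] == "rendseq"]
        assert len(rendseq_rows) == len(induced_truth)

    def test_upstream41_reextraction_invariant(self, std_run):
        result, _ = std_run
        for c in result.calls:
            assert len(c.upstream41) == 41
            assert upstream_window(result.genome, c.ref_id, c.tss, c.strand) == c.upstream41
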