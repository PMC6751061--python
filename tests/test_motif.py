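import numpy as np
import pytest

from helpers import oracle_inverted_repeats
from rendscope.motif import (
    IUPACPattern,
    PWM,
    build_pwm,
    consensus_string,
    discover_motif,
    find_inverted_repeat,
    scan_genome,
    write_meme_minimal,
)
from rendscope.promoters_pbs32 import (
    PBS32_PROMOTERS,
    all_windows,
    embedded_promoter_genome,
    rendseq_detected,
)
from rendscope.synthetic import AnnotatedGenome


class TestBuildPwm:
    def test_single_sequence_indicator_columns(self):
        pwm = build_pwm(["ACGT"], pseudocount=0.0)
        assert np.array_equal(pwm.probs, np.eye(4)[[0, 1, 2, 3]])

    def test_hand_tallied_frequencies(self):
        # col0: A,A,C -> (2/3, 1/3, 0, 0); col1: C,C,C -> (0,1,0,0)
        pwm = build_pwm(["AC", "AC", "CC"], pseudocount=0.0)
        assert pwm.probs[0] == pytest.approx([2 / 3, 1 / 3, 0, 0])
        assert pwm.probs[1] == pytest.approx([0, 1, 0, 0])

    def test_columns_sum_to_one_with_pseudocount(self):
        pwm = build_pwm(["ACGTAC", "TTGACA"], width=4, offsets=[1, 2], pseudocount=0.7)
        assert pwm.probs.sum(axis=1) == pytest.approx(np.ones(4))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_pwm([])


class TestDiscoverMotif:
    def test_identical_sequences_full_information(self):
        model = discover_motif(["GATTACAGAT"] * 20, width=6, pseudocount=1e-9)
        assert model.total_ic == pytest.approx(12.0, abs=1e-3)
        assert consensus_string(model.pwm) == "GATTAC"

    def test_planted_motif_recovered_at_random_offsets(self):
        rng = np.random.default_rng(11)
        planted = "TTGACACG"
        seqs = []
        for _ in range(20):
            bg = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 50)])
            off = int(rng.integers(0, 50 - len(planted)))
            seqs.append(bg[:off] + planted + bg[off + len(planted):])
        model = discover_motif(seqs, width=8)
        assert consensus_string(model.pwm).upper() == planted
        for s, o in zip(seqs, model.offsets):
            assert s[o : o + 8] == planted

    def test_deterministic(self):
        seqs = all_windows()
        a = discover_motif(seqs, width=30)
        b = discover_motif(seqs, width=30)
        assert a.offsets == b.offsets
        assert np.array_equal(a.pwm.probs, b.pwm.probs)

    def test_ic_trajectory_never_decreases(self):
        model = discover_motif(all_windows(), width=30)
        traj = model.ic_trajectory
        assert all(b >= a - 1e-9 for a, b in zip(traj, traj[1:]))

    def test_width_wider_than_shortest_rejected(self):
        with pytest.raises(ValueError):
            discover_motif(["ACGTACGT", "ACG"], width=6)

    def test_published_windows_consensus_blocks(self):
        model = discover_motif(all_windows(), width=30)
        cons = consensus_string(model.pwm).upper()
        assert "TTTACG" in cons
        assert "GATA" in cons

    def test_occurrences_cover_promoter_elements(self):
        # every assigned occurrence must span both the -35-like and -10-like
        # conserved blocks of its promoter window
        model = discover_motif(all_windows(), width=30)
        for entry, off in zip(PBS32_PROMOTERS, model.offsets):
            occ = entry.window41[off : off + 30]
            assert "TTAC" in occ and "GATA" in occ, entry.name


class TestConsensusString:
    def test_indicator_pwm_uppercase(self):
        pwm = build_pwm(["TTGACA"], pseudocount=0.0)
        assert consensus_string(pwm) == "TTGACA"

    def test_uniform_column_is_n(self):
        pwm = PWM(probs=np.full((1, 4), 0.25))
        assert consensus_string(pwm) == "n"

    def test_minority_base_lowercase(self):
        pwm = PWM(probs=np.array([[0.45, 0.35, 0.1, 0.1]]))
        assert consensus_string(pwm) == "a"


class TestScanGenome:
    def test_infinite_threshold_no_hits(self):
        genome = AnnotatedGenome(sequences={"r": "ACGT" * 50})
        pwm = build_pwm(["ACGTACGT"], pseudocount=0.5)
        assert scan_genome(pwm, genome, float("inf")) == []

    def test_training_windows_rediscovered_at_threshold(self):
        model = discover_motif(all_windows(), width=30)
        for seq, off, score in zip(all_windows(), model.offsets, model.train_scores):
            genome = AnnotatedGenome(sequences={"w": seq})
            hits = scan_genome(model.pwm, genome, model.min_train_score)
            assert any(h.motif_start == off + 1 and h.strand == "+" for h in hits)
            # scorer/trainer consistency
            assert model.pwm.score(seq, off) == pytest.approx(score)

    def test_planted_sites_recovered_exactly(self):
        rng = np.random.default_rng(13)
        model = discover_motif(all_windows(), width=30)
        site = "AATTTACGTTTTCCAAGAACCAGATATAAA"  # a strong training occurrence
        bg = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 6000)])
        positions = [500, 2500, 4500]
        seq = list(bg)
        for p in positions:
            seq[p : p + 30] = site
        genome = AnnotatedGenome(sequences={"r": "".join(seq)})
        hits = scan_genome(model.pwm, genome, model.min_train_score)
        assert sorted(h.motif_start for h in hits) == [p + 1 for p in positions]

    def test_two_predicted_targets_on_embedded_plasmid(self):
        from rendscope.motif import predict_promoters

        detected = rendseq_detected()
        model = discover_motif([p.window41 for p in detected], width=30)
        genome, tss = embedded_promoter_genome(seed=0)
        hits = predict_promoters(model, genome)
        training_windows = [(tss[p.name] - 41, tss[p.name]) for p in detected]
        new = [
            h for h in hits
            if not any(lo <= h.motif_start <= hi for lo, hi in training_windows)
        ]
        assert len(new) == 2
        assert {h.nearest_downstream_gene for h in new} == {"zpbQ_orf", "zpcR_orf"}


class TestInvertedRepeat:
    def test_constructed_exact_site(self):
        seq = "GGGG" + "CGAACATATGTTCG" + "GGGG"
        pat = IUPACPattern("CGAAC", 4, 4, 0)
        (m,) = find_inverted_repeat(seq, pat)
        assert (m.start, m.spacer) == (5, 4)

    def test_half_site_mutation_abolishes_match(self):
        # GAAC>TTAC knocks out the left half-site
        seq = "GGGG" + "CTTACATATGTTCG" + "GGGG"
        pat = IUPACPattern("CGAAC", 4, 4, 0)
        assert find_inverted_repeat(seq, pat) == []

    def test_mismatch_budget_restores_match(self):
        seq = "GGGG" + "CTAACATATGTTCG" + "GGGG"
        assert find_inverted_repeat(seq, IUPACPattern("CGAAC", 4, 4, 1))

    def test_iupac_degeneracy(self):
        pat = IUPACPattern("CRAAC", 3, 5, 0)  # R = A/G
        seq = "TTCAAACTTTGTTTGTT"
        hits = find_inverted_repeat(seq, pat)
        assert [(m.start, m.spacer) for m in hits] == [(3, 3)]

    def test_matches_exhaustive_enumerator(self):
        rng = np.random.default_rng(17)
        pat = IUPACPattern("CGAACR", 2, 6, 1)
        for _ in range(20):
            seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 1000)])
            ours = [(m.start, m.spacer) for m in find_inverted_repeat(seq, pat)]
            oracle = oracle_inverted_repeats(seq, "CGAACR", 2, 6, 1)
            assert sorted(ours) == sorted(oracle)


class TestMemeSerialization:
    def test_writes_probability_matrix(self, tmp_path):
        pwm = build_pwm(["TTGACA", "TTGACT"], pseudocount=0.5)
        path = tmp_path / "motif.txt"
        write_meme_minimal(pwm, path, nsites=2)
        text = path.read_text()
        assert "MEME version 4" in text
        assert "letter-probability matrix: alength= 4 w= 6" in text
        rows = [l for l in text.splitlines() if l.startswith(" ") and "." in l]
        vals = np.array([[float(x) for x in r.split()] for r in rows])
        assert np.allclose(vals, pwm.probs, atol=1e-6)
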