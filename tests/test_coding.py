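"""ORF scanning, TESTCODE and hexamer features, scorer training, thresholds."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from noveltx.coding import (
    AMBIGUOUS, CODING, INCONSISTENT, NONCODING,
    CodingAssessment, CodingThresholds, HexamerModel,
    classify_tool_score, consensus_category, fickett_position_value,
    fickett_score, find_orfs, hexamer_llr, longest_orf, sequence_features,
    train_coding_model,
)
from noveltx.simulate import make_coding_sequence, make_noncoding_sequence

from .oracles import fickett_oracle, hexamer_oracle, longest_orf_oracle


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestFindOrfs:
    def test_simple_atg_orf(self):
        (orf,) = find_orfs("ATGAAATAG")
        assert orf.length_nt == 9 and orf.has_start and orf.has_stop

    def test_no_atg_gives_empty(self):
        assert find_orfs("CCCCCC") == []

    def test_too_short(self):
        assert find_orfs("AT") == []

    def test_trailing_orf_without_stop(self):
        (orf,) = find_orfs("ATGAAAAAA")
        assert orf.has_start and not orf.has_stop and orf.length_nt == 9

    def test_stop_to_stop_mode_reports_atg_free_span(self):
        # polypeptide-like span with no ATG anywhere
        seq = "TAA" + "CCTCCTCCTCCTCCT" + "TGA"
        orfs = find_orfs(seq, mode="stop_to_stop")
        assert any(o.length_nt >= 15 and not o.has_start for o in orfs)

    def test_both_strands_finds_antisense_orf(self):
        sense = "ATGAAAAAATAG"
        from Bio.Seq import Seq
        anti = str(Seq(sense).reverse_complement())
        assert find_orfs(anti, strands="sense") == []
        best = longest_orf(anti, strands="both")
        assert best.strand == "-" and best.length_nt == 12

    @pytest.mark.parametrize("length", [9, 18, 30, 200, 600])
    def test_matches_exhaustive_scan_oracle(self, rng, length):
        for _ in range(120):
            seq = _random_seq(rng, length)
            got = longest_orf(seq)
            assert (got.length_nt if got else 0) == longest_orf_oracle(seq)

    def test_orfs_sorted_longest_first(self, rng):
        for _ in range(20):
            lens = [o.length_nt for o in find_orfs(_random_seq(rng, 300))]
            assert lens == sorted(lens, reverse=True)


class TestFickett:
    def test_homopolymer_values(self):
        # equal per-position counts (4,4,4): published position value
        # max/(min+1) = 0.8; content of A is trivially 1.0
        seq = "A" * 12
        assert fickett_position_value(seq, "A") == pytest.approx(0.8)
        assert seq.count("A") / len(seq) == 1.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            fickett_score("")

    @given(st.text(alphabet="ACGT", min_size=6, max_size=60))
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_content_parameters_invariant_under_duplication(self, seq):
        for base in "ACGT":
            assert seq.count(base) / len(seq) == pytest.approx(
                (seq + seq).count(base) / (2 * len(seq))
            )

    def test_matches_independent_table_transcription(self, rng):
        for _ in range(10):
            seq = _random_seq(rng, 300)
            assert fickett_score(seq) == pytest.approx(fickett_oracle(seq))

    def test_score_range(self, rng):
        scores = [fickett_score(_random_seq(rng, 120)) for _ in range(50)]
        assert all(0.0 < s < 1.95 for s in scores)


class TestHexamer:
    def test_identical_tables_score_zero(self, rng):
        seqs = [_random_seq(rng, 120) for _ in range(10)]
        model = HexamerModel.train(seqs, seqs, coding_step=1, noncoding_step=1)
        assert hexamer_llr(_random_seq(rng, 200), model) == pytest.approx(0.0)

    def test_single_best_hexamer_scores_max_ratio(self, corpora):
        coding, noncoding = corpora
        model = HexamerModel.train(coding, noncoding)
        best = max(model.log_ratio, key=model.log_ratio.get)
        assert hexamer_llr(best, model) == pytest.approx(model.log_ratio[best])

    def test_untrained_model_rejected(self):
        with pytest.raises(ValueError):
            hexamer_llr("ACGTACGT", HexamerModel())

    def test_matches_brute_force_summation(self, rng, corpora):
        model = HexamerModel.train(*corpora)
        for _ in range(30):
            seq = _random_seq(rng, int(rng.integers(6, 400)))
            for start in (None, 0, 2):
                assert hexamer_llr(seq, model, frame_start=start) == pytest.approx(
                    hexamer_oracle(seq, model.log_ratio, start)
                )


class TestTraining:
    def test_separable_classes_reach_perfect_training_accuracy(self, corpora):
        coding, noncoding = corpora
        scorer = train_coding_model(coding, noncoding, seed=11)
        preds = [scorer.predict_proba(s) >= 0.5 for s in coding[:25]]
        preds += [scorer.predict_proba(s) < 0.5 for s in noncoding[:25]]
        assert np.mean(preds) == 1.0

    def test_probability_bounded(self, cpat_scorer, rng):
        for _ in range(10):
            p = cpat_scorer.predict_proba(_random_seq(rng, int(rng.integers(60, 900))))
            assert 0.0 <= p <= 1.0

    def test_single_class_rejected(self, corpora):
        with pytest.raises(ValueError):
            train_coding_model(corpora[0], [], seed=0)

    def test_label_permutation_destroys_signal(self, corpora):
        rng = np.random.default_rng(11)
        coding, noncoding = corpora
        pool = list(coding[:30]) + list(noncoding[:30])
        accs = []
        for _ in range(20):
            perm = rng.permutation(len(pool))
            fake_coding = [pool[i] for i in perm[:30]]
            fake_noncoding = [pool[i] for i in perm[30:]]
            scorer = train_coding_model(
                fake_coding[:15], fake_noncoding[:15], seed=int(rng.integers(1e6))
            )
            correct = [scorer.predict_proba(s) >= 0.5 for s in fake_coding[15:]]
            correct += [scorer.predict_proba(s) < 0.5 for s in fake_noncoding[15:]]
            accs.append(np.mean(correct))
        assert 0.3 < np.mean(accs) < 0.7

    def test_consensus_recovers_planted_composition_labels(
        self, cpat_scorer, cpc_scorer
    ):
        rng = np.random.default_rng(1100)
        n = 40
        seqs = {}
        labels = {}
        for i in range(n):
            L = int(rng.integers(250, 1200))
            seqs[f"c{i}"] = make_coding_sequence(rng, L, bias=1.0)
            labels[f"c{i}"] = CODING
            seqs[f"n{i}"] = make_noncoding_sequence(rng, L)
            labels[f"n{i}"] = NONCODING
        hits = 0
        for tid, seq in seqs.items():
            cat = CodingAssessment.from_scores(
                tid, cpc_scorer.log_odds(seq), cpat_scorer.predict_proba(seq)
            ).consensus
            hits += cat == labels[tid]
        assert hits / (2 * n) >= 0.95


class TestThresholds:
    @pytest.mark.parametrize(
        "score,tool,expected",
        [
            (-1.06, "cpc", NONCODING),   # printed conserved-noncoding locus
            (0.01, "cpat", NONCODING),
            (1.22, "cpc", CODING),       # printed coding candidate
            (0.53, "cpat", CODING),
            (0.0, "cpc", AMBIGUOUS),
            (0.3, "cpat", AMBIGUOUS),
            (1.0, "cpc", CODING),        # cut inclusive per printed inequality
            (-0.5, "cpc", NONCODING),
            (0.5, "cpat", CODING),
            (0.02, "cpat", AMBIGUOUS),   # noncoding is strictly < 0.02
            (-0.15, "cpc", AMBIGUOUS),   # lies between the printed CPC cuts
        ],
    )
    def test_printed_threshold_decisions(self, score, tool, expected):
        assert classify_tool_score(score, tool) == expected

    def test_unknown_tool_rejected(self):
        with pytest.raises(ValueError):
            classify_tool_score(0.5, "orf-finder")

    def test_invalid_threshold_ordering_rejected(self):
        with pytest.raises(ValueError):
            CodingThresholds(cpc_coding=-1.0, cpc_noncoding=0.0)

    def test_monotone_through_categories(self):
        order = {NONCODING: 0, AMBIGUOUS: 1, CODING: 2}
        for tool, scores in (
            ("cpc", np.linspace(-3, 3, 61)),
            ("cpat", np.linspace(0, 1, 51)),
        ):
            ranks = [order[classify_tool_score(float(s), tool)] for s in scores]
            assert ranks == sorted(ranks)


class TestConsensus:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (CODING, CODING, CODING),
            (NONCODING, NONCODING, NONCODING),
            (AMBIGUOUS, AMBIGUOUS, AMBIGUOUS),
            (AMBIGUOUS, NONCODING, INCONSISTENT),
            (NONCODING, CODING, INCONSISTENT),
        ],
    )
    def test_intersection_rule(self, a, b, expected):
        assert consensus_category(a, b) == expected

    @given(
        st.sampled_from([CODING, NONCODING, AMBIGUOUS]),
        st.sampled_from([CODING, NONCODING, AMBIGUOUS]),
    )
    @settings(derandomize=True, deadline=None)
    def test_symmetric(self, a, b):
        assert consensus_category(a, b) == consensus_category(b, a)

    def test_worked_score_pairs(self):
        assert CodingAssessment.from_scores("x", 1.22, 0.53).consensus == CODING
        assert CodingAssessment.from_scores("x", -1.06, 0.01).consensus == NONCODING
        # CPC -0.31 is ambiguous, CPAT 0 noncoding: inconsistent pair
        assert CodingAssessment.from_scores("x", -0.31, 0.0).consensus == INCONSISTENT


def test_feature_vector_shape_and_coverage(cpat_scorer, rng):
    seq = make_coding_sequence(rng, 600)
    f = sequence_features(seq, cpat_scorer.hexamer_model)
    assert f.shape == (4,)
    assert 0 <= f[1] <= 1.0 and f[0] <= len(seq)
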