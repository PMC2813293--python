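"""Clone caller: alignment scores vs brute-force DP, classification, calls."""

import numpy as np
import pytest
from Bio.Seq import reverse_complement

from tph2_isoedit import (
    GenerationParams,
    align_clone,
    annotate_clone,
    apply_variants,
    call_library,
    call_variants,
    classify_splice_isoform,
    generate_clone_library,
    generate_individual,
    qc_filter,
)
from tph2_isoedit.calling import PairwiseAlignment, shift_gaps_3prime
from tph2_isoedit.reference import InvalidSequenceError

OPEN, EXT = 5.0, 1.0


def gotoh_score(a: str, b: str) -> float:
    """Independent exhaustive affine-gap global alignment (three-state DP)."""
    def sub(x, y):
        if "N" in (x, y):
            return 0.0
        return 1.0 if x == y else -1.0

    NEG = float("-inf")
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b
    Y = np.full((n + 1, m + 1), NEG)  # gap in a
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -OPEN - EXT * (i - 1)
    for j in range(1, m + 1):
        Y[0, j] = -OPEN - EXT * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + sub(
                a[i - 1], b[j - 1]
            )
            X[i, j] = max(M[i - 1, j] - OPEN, X[i - 1, j] - EXT, Y[i - 1, j] - OPEN)
            Y[i, j] = max(M[i, j - 1] - OPEN, Y[i, j - 1] - EXT, X[i, j - 1] - OPEN)
    return float(max(M[n, m], X[n, m], Y[n, m]))


def _mutate(seq: str, rng) -> str:
    """Random substitutions/indels for oracle comparison instances."""
    s = list(seq)
    for _ in range(rng.integers(0, 4)):
        op = rng.integers(3)
        pos = int(rng.integers(len(s))) if s else 0
        if op == 0 and s:
            s[pos] = "ACGT"[rng.integers(4)]
        elif op == 1 and len(s) > 2:
            del s[pos]
        else:
            s.insert(pos, "ACGT"[rng.integers(4)])
    return "".join(s) or "A"


class TestAlignClone:
    def test_identical_sequences_score_length(self):
        aln = align_clone("ACGTACGT", "ACGTACGT")
        assert aln.score == 8 and "-" not in aln.query_aln

    def test_single_mismatch_scores_len_minus_2(self):
        aln = align_clone("ACGTACGT", "ACGAACGT")
        assert aln.score == 6

    def test_insertion_yields_single_6_column_gap(self, model):
        aln = align_clone(model.transcript_b, model.transcript_a)
        gaps = aln.gaps()
        assert gaps == [("ins", len(model.utr5_seq) + 439, 6)]
        assert aln.score == len(model.transcript_a) - (OPEN + 5 * EXT)

    def test_empty_or_invalid_sequences_rejected(self):
        with pytest.raises(InvalidSequenceError):
            align_clone("", "ACGT")
        with pytest.raises(InvalidSequenceError):
            align_clone("ACGT", "ACXT")

    def test_scores_match_bruteforce_dp_on_small_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(40):
            n = int(rng.integers(5, 30))
            ref = "".join("ACGT"[i] for i in rng.integers(0, 4, n))
            qry = _mutate(ref, rng)
            assert align_clone(qry, ref).score == pytest.approx(gotoh_score(qry, ref))

    def test_n_bases_score_zero(self):
        assert align_clone("ACNT", "ACGT").score == 3.0
        assert gotoh_score("ACNT", "ACGT") == 3.0

    def test_gap_canonicalization_shifts_3prime(self):
        # the gap in AA[--]AA vs AAAA-like repeats must sit 3'-most
        q, r = shift_gaps_3prime("A--AA", "AAAAA")
        assert (q, r) == ("AAA--", "AAAAA")


class TestClassifyIsoform:
    def test_error_free_clones_called_correctly(self, model):
        call_a = classify_splice_isoform(model.transcript_a, model)
        call_b = classify_splice_isoform(model.transcript_b, model)
        assert call_a.isoform == "a" and call_b.isoform == "b"
        assert call_a.margin >= 3 and call_b.margin >= 3

    def test_truncated_clone_unclassified(self, model):
        truncated = model.transcript_a[: model.c_to_index(400, "a")]
        res = classify_splice_isoform(truncated, model)
        assert res.isoform == "unclassified" and res.reason == "no_coverage"

    def test_corrupted_insertion_window_not_called_b(self, model):
        seq = list(model.transcript_b)
        ins_start = len(model.utr5_seq) + 439
        seq[ins_start] = "T"  # GCAAGG -> TCAAGG
        res = classify_splice_isoform("".join(seq), model)
        assert res.isoform != "b"

    def test_reverse_complement_clone_recovered(self, model):
        ann = annotate_clone("rc", reverse_complement(model.transcript_b), model)
        assert ann.isoform == "b" and not ann.variant_calls


class TestCallVariants:
    def test_inverse_of_apply_variants(self, model):
        for iso, indices in (("a", (1, 2, 3, 4)), ("b", (2, 3, 4)), ("a", ()), ("b", (1,))):
            variants = [model.variant(iso, i) for i in indices]
            seq = apply_variants(model, iso, variants)
            aln = PairwiseAlignment(seq, model.transcript(iso), 0.0)
            calls = call_variants(aln, model, iso)
            assert {(c.c_pos, c.observed_base) for c in calls} == {
                (v.c_pos, v.alt_base) for v in variants
            }
            assert all(c.in_catalogue for c in calls)

    def test_random_error_yields_noncatalogue_call(self, model):
        seq = list(model.transcript_a)
        idx = model.c_to_index(600, "a")
        original = seq[idx]
        seq[idx] = {"A": "C", "C": "A", "G": "C", "T": "G"}[original]
        ann = annotate_clone("e", "".join(seq), model)
        assert ann.isoform == "a"
        assert ann.n_noncatalogue_mismatches == 1
        assert ann.variant_calls[0].c_pos == 600

    def test_qc_filter_threshold(self):
        assert qc_filter(0)
        assert qc_filter(5)
        assert not qc_filter(6)

    def test_qc_pass_rate_with_sanger_error_rate(self, model):
        # ~1.5 kb at 1e-3/base: expected <2 errors, QC (<=5) passes >95%
        prof = generate_individual("i", "control", {"rs4290270": {"TT": 1.0}}, model, seed=1)
        params = GenerationParams(
            n_clones=400, splice_fraction_b=0.5,
            editing_probs={"a": (0.0,) * 4, "b": (0.5,) * 4},
            error_rate=1e-3, seed=2,
        )
        recs, _, _ = generate_clone_library(model, prof, "amygdala", params)
        anns, _ = call_library(recs, model)
        pass_rate = sum(a.qc_pass for a in anns) / len(anns)
        assert pass_rate > 0.95


class TestTruthRoundTrip:
    def test_error_free_pipeline_recovers_generator_truth(self, model):
        prof = generate_individual(
            "i", "control", {"rs4290270": {"AT": 1.0}, "rs7305115": {"AG": 1.0}},
            model, seed=21,
        )
        params = GenerationParams(
            n_clones=400, splice_fraction_b=0.5,
            editing_probs={"a": (0.4, 0.3, 0.2, 0.5), "b": (0.78, 0.96, 0.96, 0.96)},
            gating=True, permissive_allele="T", error_rate=0.0, seed=22,
        )
        recs, _, truth = generate_clone_library(model, prof, "amygdala", params)
        anns, _ = call_library(recs, model)
        truth = truth.set_index("clone_id")
        assert len(anns) == 400
        for ann in anns:
            assert ann.isoform == truth.loc[ann.clone_id, "isoform"]
            assert ann.rs4290270_base == truth.loc[ann.clone_id, "allele_origin"]
            edited = {
                c.catalogue_entry.editing_index
                for c in ann.variant_calls
                if c.in_catalogue and c.catalogue_entry.site_class == "editing_candidate"
                and c.catalogue_entry.isoform_scope == f"{ann.isoform}-only"
            }
            want = set(map(int, str(truth.loc[ann.clone_id, "edited_indices"]) or ""))
            assert edited == want
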