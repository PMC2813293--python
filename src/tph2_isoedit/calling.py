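"""Clone alignment, splice-isoform classification, and variant calling.

Each sequenced cDNA clone is compared against both isoform references
(TPH2a and TPH2b transcripts).  Classification is by dual-reference scoring:
the clone is assigned to the higher-scoring isoform when the score margin
reaches a threshold *and*, for a TPH2b call, the six insertion columns read
GCAAGG.  Substitution columns against the called isoform's reference become
variant calls, looked up in the model's catalogue.

Scoring scheme (global, affine gaps): match +1, mismatch -1, gap open -5,
gap extend -1, where a length-k gap costs 5 + (k-1).  N scores 0 against
anything and never yields a variant call.

Full-length global alignment of ~1.6 kb clones is exact but costly, so the
caller takes a provably equivalent shortcut on the dominant case: when the
clone's length equals one isoform transcript exactly, the optimal alignment
against that transcript is gapless and the optimal alignment against the
other differs only by the canonical 6-column insertion gap (substitutions
cannot pay for an extra indel pair under this scheme at the error rates
involved).  Anything else - indels, truncations, reverse-complemented
inserts - falls back to the exact affine aligner, with a reverse-complement
retry when the forward score is poor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import reverse_complement

from .reference import (
    InvalidSequenceError,
    ParameterError,
    ReferenceModel,
    VariantSpec,
)

MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 1.0, -1.0, -5.0, -1.0
ALPHABET = "ACGTN"


def _aligner() -> Align.PairwiseAligner:
    mat = substitution_matrices.Array(alphabet=ALPHABET, dims=2)
    for x in ALPHABET:
        for y in ALPHABET:
            if "N" in (x, y):
                mat[x, y] = 0.0
            else:
                mat[x, y] = MATCH if x == y else MISMATCH
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = mat
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


_ALIGNER = _aligner()


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global alignment as gapped strings plus the score."""

    query_aln: str
    ref_aln: str
    score: float

    def __post_init__(self) -> None:
        if len(self.query_aln) != len(self.ref_aln):
            raise ParameterError("gapped strings must have equal length")

    @property
    def query(self) -> str:
        return self.query_aln.replace("-", "")

    @property
    def ref(self) -> str:
        return self.ref_aln.replace("-", "")

    def ref_to_query(self) -> dict[int, int]:
        """Monotone projection of ungapped reference positions onto the query."""
        out: dict[int, int] = {}
        qi = ri = 0
        for q, r in zip(self.query_aln, self.ref_aln):
            if q != "-" and r != "-":
                out[ri] = qi
            if q != "-":
                qi += 1
            if r != "-":
                ri += 1
        return out

    def gaps(self) -> list[tuple[str, int, int]]:
        """Gap runs as (kind 'ins'|'del' relative to reference, ref_pos, length)."""
        runs: list[tuple[str, int, int]] = []
        qi = ri = 0
        i = 0
        n = len(self.query_aln)
        while i < n:
            if self.ref_aln[i] == "-":
                j = i
                while j < n and self.ref_aln[j] == "-":
                    j += 1
                runs.append(("ins", ri, j - i))
                qi += j - i
                i = j
            elif self.query_aln[i] == "-":
                j = i
                while j < n and self.query_aln[j] == "-":
                    j += 1
                runs.append(("del", ri, j - i))
                ri += j - i
                i = j
            else:
                qi += 1
                ri += 1
                i += 1
        return runs


def _validate_seq(seq: str, what: str) -> str:
    if not seq:
        raise InvalidSequenceError(f"{what} sequence is empty")
    seq = seq.upper()
    if set(seq) - set(ALPHABET):
        raise InvalidSequenceError(
            f"{what} contains non-ACGTN symbols: {sorted(set(seq) - set(ALPHABET))}"
        )
    return seq


def shift_gaps_3prime(query_aln: str, ref_aln: str) -> tuple[str, str]:
    """Canonicalize equivalent gap placements to the 3'-most position.

    Repeated-context insertions (e.g. GCAAGG next to an identical hexamer)
    admit several equal-scoring alignments; the HGVS convention names the
    3'-most, which keeps catalogue comparison stable.
    """
    q, r = list(query_aln), list(ref_aln)
    moved = True
    while moved:
        moved = False
        for row, other in ((q, r), (r, q)):
            i = 0
            n = len(row)
            while i < n:
                if row[i] == "-":
                    j = i
                    while j < n and row[j] == "-":
                        j += 1
                    # slide the whole gap run right while the flanking base matches
                    while j < n and row[j] != "-" and other[j] == other[i] and row[j] != "-":
                        row[i] = row[j]
                        row[j] = "-"
                        i += 1
                        j += 1
                        moved = moved or True
                    i = j
                else:
                    i += 1
    return "".join(q), "".join(r)


def align_clone(clone_seq: str, ref_seq: str) -> PairwiseAlignment:
    """Exact global affine-gap alignment of a clone against a reference."""
    clone_seq = _validate_seq(clone_seq, "clone")
    ref_seq = _validate_seq(ref_seq, "reference")
    alns = _ALIGNER.align(clone_seq, ref_seq)
    best = alns[0]
    q, r = str(best[0]), str(best[1])
    q, r = shift_gaps_3prime(q, r)
    return PairwiseAlignment(query_aln=q, ref_aln=r, score=float(best.score))


def _to_bytes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _gapless_score(a: np.ndarray, b: np.ndarray) -> tuple[float, int]:
    """(score, mismatches) for a same-length gapless comparison; N scores 0."""
    n_mask = (a == ord("N")) | (b == ord("N"))
    diff = (a != b) & ~n_mask
    n_diff = int(diff.sum())
    n_n = int(n_mask.sum())
    score = (a.size - n_diff - n_n) * MATCH + n_diff * MISMATCH
    return float(score), n_diff


def _gap_cost(k: int) -> float:
    return -(abs(GAP_OPEN) + (k - 1) * abs(GAP_EXTEND))


@dataclass(frozen=True)
class IsoformCall:
    isoform: str  # 'a' | 'b' | 'unclassified'
    margin: float
    score_a: float
    score_b: float
    reverse_complemented: bool = False
    reason: str = ""


# clones differing from a transcript by more than this many substitutions do
# not take the gapless shortcut and are re-examined by the exact aligner
FAST_PATH_MAX_MISMATCHES = 40


def classify_splice_isoform(
    clone_seq: str,
    model: ReferenceModel,
    margin_threshold: float = 3.0,
) -> IsoformCall:
    """Dual-reference isoform classification with score margin.

    A TPH2b call additionally requires the six clone bases in the canonical
    insertion window to read GCAAGG.  Clones not covering the insertion
    window (c.430-c.450) are unclassified with reason 'no_coverage'.
    """
    clone_seq = _validate_seq(clone_seq, "clone")
    tr_a, tr_b = model.transcript_a, model.transcript_b
    ins_start = len(model.utr5_seq) + model.insertion.after_c_pos
    ins_seq = model.insertion.inserted_seq

    def finish(sa: float, sb: float, window_ok: bool, rc: bool) -> IsoformCall:
        margin = abs(sa - sb)
        if margin < margin_threshold:
            return IsoformCall("unclassified", margin, sa, sb, rc, "low_margin")
        if sb > sa and not window_ok:
            return IsoformCall("unclassified", margin, sa, sb, rc, "insertion_window_mismatch")
        return IsoformCall("a" if sa > sb else "b", margin, sa, sb, rc)

    clone_b = _to_bytes(clone_seq)
    if len(clone_seq) == len(tr_a):
        sa, ma = _gapless_score(clone_b, _to_bytes(tr_a))
        if ma <= FAST_PATH_MAX_MISMATCHES:
            # optimal vs TPH2b: same columns plus the canonical 6-col deletion
            sb = sa + _gap_cost(len(ins_seq))
            return finish(sa, sb, window_ok=False, rc=False)
    elif len(clone_seq) == len(tr_b):
        sb, mb = _gapless_score(clone_b, _to_bytes(tr_b))
        if mb <= FAST_PATH_MAX_MISMATCHES:
            without_ins = clone_seq[:ins_start] + clone_seq[ins_start + len(ins_seq):]
            sa, _ = _gapless_score(_to_bytes(without_ins), _to_bytes(tr_a))
            sa += _gap_cost(len(ins_seq))
            window_ok = clone_seq[ins_start : ins_start + len(ins_seq)] == ins_seq
            return finish(sa, sb, window_ok, rc=False)

    return _classify_slow(clone_seq, model, margin_threshold)


def _covers_window(aln: PairwiseAlignment, model: ReferenceModel, isoform: str) -> bool:
    proj = aln.ref_to_query()
    lo = model.c_to_index(430, isoform)
    hi = model.c_to_index(450, isoform)
    return all(p in proj for p in (lo, hi))


def _classify_slow(clone_seq, model, margin_threshold) -> IsoformCall:
    tr_a, tr_b = model.transcript_a, model.transcript_b
    rc = False
    aln_a = align_clone(clone_seq, tr_a)
    aln_b = align_clone(clone_seq, tr_b)
    best = max(aln_a.score, aln_b.score)
    if best < 0.5 * len(clone_seq):
        rc_seq = reverse_complement(clone_seq)
        aln_a_rc = align_clone(rc_seq, tr_a)
        aln_b_rc = align_clone(rc_seq, tr_b)
        if max(aln_a_rc.score, aln_b_rc.score) > best:
            aln_a, aln_b, rc = aln_a_rc, aln_b_rc, True
    sa, sb = aln_a.score, aln_b.score
    if not (_covers_window(aln_a, model, "a") and _covers_window(aln_b, model, "b")):
        return IsoformCall("unclassified", abs(sa - sb), sa, sb, rc, "no_coverage")
    window_ok = False
    if sb >= sa:
        proj = aln_b.ref_to_query()
        ins_start = len(model.utr5_seq) + model.insertion.after_c_pos
        idx = [proj.get(ins_start + k) for k in range(len(model.insertion.inserted_seq))]
        if all(i is not None for i in idx):
            observed = "".join(aln_b.query[i] for i in idx)  # type: ignore[index]
            window_ok = observed == model.insertion.inserted_seq
    margin = abs(sa - sb)
    if margin < margin_threshold:
        return IsoformCall("unclassified", margin, sa, sb, rc, "low_margin")
    if sb > sa and not window_ok:
        return IsoformCall("unclassified", margin, sa, sb, rc, "insertion_window_mismatch")
    return IsoformCall("a" if sa > sb else "b", margin, sa, sb, rc)


@dataclass(frozen=True)
class VariantCall:
    """A substitution column: observed base differs from the reference."""

    c_pos: int
    ref_base: str
    observed_base: str
    in_catalogue: bool
    catalogue_entry: Optional[VariantSpec] = None


def call_variants(
    alignment: PairwiseAlignment, model: ReferenceModel, isoform: str
) -> list[VariantCall]:
    """Emit every substitution column of an alignment to the isoform reference.

    Positions are c. coordinates on the called isoform's track; catalogue
    membership is looked up by (position, observed base).  Gap columns are
    never variant calls (the splice insertion is encoded in the isoform call)
    and N observations are skipped.
    """
    lookup = model.catalogue_lookup(isoform)
    calls: list[VariantCall] = []
    ri = 0
    for q, r in zip(alignment.query_aln, alignment.ref_aln):
        if r == "-":
            continue
        if q not in ("-", "N") and r != "N" and q != r:
            c_pos = model.index_to_c(ri, isoform)
            entry = lookup.get((c_pos, q))
            calls.append(VariantCall(c_pos, r, q, entry is not None, entry))
        ri += 1
    return calls


@dataclass(frozen=True)
class CloneAnnotation:
    """Per-clone result of the caller stage."""

    clone_id: str
    isoform: str
    margin: float
    variant_calls: tuple[VariantCall, ...]
    rs4290270_base: Optional[str]
    n_noncatalogue_mismatches: int
    qc_pass: bool
    reason: str = ""


def qc_filter(n_noncatalogue_mismatches: int, max_noncatalogue: int = 5) -> bool:
    """QC pass when the clone's non-catalogue substitutions stay within bounds."""
    return n_noncatalogue_mismatches <= max_noncatalogue


def annotate_clone(
    clone_id: str,
    clone_seq: str,
    model: ReferenceModel,
    margin_threshold: float = 3.0,
    max_noncatalogue: int = 5,
) -> CloneAnnotation:
    """Classify one clone and call its variants against the winning reference."""
    clone_seq = _validate_seq(clone_seq, "clone")
    iso = classify_splice_isoform(clone_seq, model, margin_threshold)
    if iso.isoform == "unclassified":
        return CloneAnnotation(clone_id, "unclassified", iso.margin, (), None, 0, False,
                               iso.reason)
    isoform = iso.isoform
    seq = reverse_complement(clone_seq) if iso.reverse_complemented else clone_seq
    ref = model.transcript(isoform)
    if len(seq) == len(ref):
        aln = PairwiseAlignment(seq, ref, iso.score_a if isoform == "a" else iso.score_b)
    else:
        aln = align_clone(seq, ref)
    calls = call_variants(aln, model, isoform)
    rs_pos = model.scoped_pos(
        next(v for v in model.variant_catalogue if v.rs_id == "rs4290270"), isoform
    )
    proj = aln.ref_to_query()
    rs_idx = proj.get(model.c_to_index(rs_pos, isoform))
    rs_base = aln.query[rs_idx] if rs_idx is not None else None
    n_bad = sum(1 for c in calls if not c.in_catalogue)
    return CloneAnnotation(
        clone_id, isoform, iso.margin, tuple(calls), rs_base, n_bad,
        qc_filter(n_bad, max_noncatalogue),
    )


def call_library(
    records: Sequence[tuple[str, str]],
    model: ReferenceModel,
    margin_threshold: float = 3.0,
    max_noncatalogue: int = 5,
) -> tuple[list[CloneAnnotation], pd.DataFrame]:
    """Annotate a whole clone library; also return the flat calls table."""
    annotations = [
        annotate_clone(cid, seq, model, margin_threshold, max_noncatalogue)
        for cid, seq in records
    ]
    rows = []
    for ann in annotations:
        if not ann.variant_calls:
            rows.append(
                {"clone_id": ann.clone_id, "isoform": ann.isoform, "margin": ann.margin,
                 "c_pos": None, "ref": None, "obs": None, "in_catalogue": None,
                 "rs4290270": ann.rs4290270_base, "qc": ann.qc_pass}
            )
        for c in ann.variant_calls:
            rows.append(
                {"clone_id": ann.clone_id, "isoform": ann.isoform, "margin": ann.margin,
                 "c_pos": c.c_pos, "ref": c.ref_base, "obs": c.observed_base,
                 "in_catalogue": c.in_catalogue, "rs4290270": ann.rs4290270_base,
                 "qc": ann.qc_pass}
            )
    return annotations, pd.DataFrame(rows)
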