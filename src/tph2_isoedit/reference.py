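"""Coding-sequence model of the two human TPH2 splice isoforms.

The human tryptophan hydroxylase 2 gene is alternatively spliced at intron 3:
the canonical (non-canonical GC) splice donor yields the short isoform TPH2a,
while a GT donor 6 nt downstream yields TPH2b, which carries a 6 bp in-frame
insertion (c.439_440insGCAAGG, adding Gly-Lys after residue 146).  Each isoform
carries four isoform-specific RNA-editing positions plus two genuine genomic
SNPs (rs7305115 c.936A>G, rs4290270 c.1125A>T).

No public reference sequence is bundled; instead a *surrogate* reference is
generated deterministically under the full set of printed base and codon
constraints, so that every catalogued variant behaves exactly as described
(e.g. c.385C>T creates a stop in codon 129 of TPH2b) while all unconstrained
bases are arbitrary.

Coordinates are HGVS-like c. positions: c.1 is the A of the start codon,
negative positions count backward through the 5'-UTR.  Positions of variants
restricted to TPH2b are expressed on the TPH2b CDS (insertion included);
all other positions are on the TPH2a track.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from Bio.Seq import Seq

BASES = "ACGT"
STOP_CODONS = {"TAA", "TAG", "TGA"}


class Tph2Error(Exception):
    """Base class for package errors."""


class ConstraintConflictError(Tph2Error):
    """Two incompatible reference-base constraints at the same position."""


class MutualExclusivityError(Tph2Error):
    """A variant was applied to an isoform outside its scope."""


class ReferenceMismatchError(Tph2Error):
    """A variant's stated reference base disagrees with the model sequence."""


class InvalidSequenceError(Tph2Error):
    """A sequence contains symbols outside the expected alphabet."""


class ParameterError(Tph2Error):
    """An operation received an out-of-domain parameter."""


@dataclass(frozen=True)
class InsertionSpec:
    """The alternative-splice insertion: ``inserted_seq`` after c.``after_c_pos``."""

    after_c_pos: int = 439
    inserted_seq: str = "GCAAGG"

    def __post_init__(self) -> None:
        if len(self.inserted_seq) != 6:
            raise ParameterError("splice insertion must be 6 nt")


@dataclass(frozen=True)
class VariantSpec:
    """One catalogued sequence variant.

    ``c_pos`` is signed (negative = 5'-UTR).  For ``isoform_scope='b-only'``
    the position is on the TPH2b CDS; otherwise on TPH2a.
    ``site_class`` separates RNA-editing candidates (which carry an
    ``editing_index`` 1-4) from genuine genomic SNPs.
    """

    c_pos: int
    ref_base: str
    alt_base: str
    isoform_scope: str  # 'a-only' | 'b-only' | 'both'
    site_class: str  # 'editing_candidate' | 'genomic_snp'
    editing_index: Optional[int] = None
    rs_id: Optional[str] = None
    protein_consequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.isoform_scope not in ("a-only", "b-only", "both"):
            raise ParameterError(f"bad isoform_scope {self.isoform_scope!r}")
        if self.site_class == "editing_candidate" and self.editing_index is None:
            raise ParameterError("editing candidates need an editing_index")
        if self.site_class == "genomic_snp" and self.editing_index is not None:
            raise ParameterError("genomic SNPs carry no editing_index")
        for b in (self.ref_base, self.alt_base):
            if b not in BASES:
                raise InvalidSequenceError(f"bad base {b!r}")


#: The eight isoform-dependent editing positions (4 per isoform, mutually
#: exclusive) and the two genomic SNPs, as printed.
DEFAULT_CATALOGUE: tuple[VariantSpec, ...] = (
    VariantSpec(-42, "T", "C", "a-only", "editing_candidate", 1),
    VariantSpec(711, "A", "G", "a-only", "editing_candidate", 2),
    VariantSpec(1297, "A", "G", "a-only", "editing_candidate", 3),
    VariantSpec(1322, "G", "A", "a-only", "editing_candidate", 4),
    VariantSpec(385, "C", "T", "b-only", "editing_candidate", 1),
    VariantSpec(804, "A", "G", "b-only", "editing_candidate", 2),
    VariantSpec(830, "C", "T", "b-only", "editing_candidate", 3),
    VariantSpec(1403, "A", "G", "b-only", "editing_candidate", 4),
    VariantSpec(936, "A", "G", "both", "genomic_snp", rs_id="rs7305115"),
    VariantSpec(1125, "A", "T", "both", "genomic_snp", rs_id="rs4290270"),
)

#: Codon-context constraints (1-based codon index on the TPH2a CDS -> codon)
#: that make the catalogued variants reproduce their printed consequences:
#: Q129X nonsense, R237 synonymous, K268 synonymous, P277L, R433G, R441H,
#: Q468R, plus the NdeI design around rs4290270 (codon 375 CAA / codon 376 ATG
#: so the T allele completes CA^TATG) and the Gly context at c.439 that makes
#: the 6 nt insertion read Gly-Lys.
DEFAULT_CODON_CONSTRAINTS: Mapping[int, str] = {
    129: "CAA",  # Gln; c.385C>T -> TAA stop (b-scope position 385 < insertion)
    237: "CGA",  # Arg; c.711A>G synonymous
    266: "AAA",  # Lys; b c.804A>G synonymous (a codon 266 = b codon 268)
    275: "CCT",  # Pro; b c.830C>T -> Leu (a codon 275 = b codon 277)
    312: "CCA",  # Pro; rs7305115 c.936A>G synonymous
    375: "CAA",  # Gln; rs4290270 c.1125A>T; with ATG at 376, T allele => CATATG
    376: "ATG",
    433: "AGA",  # Arg; c.1297A>G -> Gly
    441: "CGT",  # Arg; c.1322G>A -> His
    466: "CAA",  # Gln; b c.1403A>G -> Arg (a codon 466 = b codon 468)
}

#: NdeI recognition sequence (cut CA^TATG).
NDEI_SITE = "CATATG"


def c_to_codon(c_pos: int) -> tuple[int, int]:
    """Map a positive coding position to (1-based codon index, offset 1-3)."""
    if c_pos < 1:
        raise ParameterError("UTR positions have no codon")
    return math.ceil(c_pos / 3), (c_pos - 1) % 3 + 1


@dataclass(frozen=True)
class ReferenceModel:
    """Dual-isoform TPH2 reference: 5'-UTR, TPH2a CDS, insertion, catalogue."""

    utr5_seq: str
    cds_a: str
    insertion: InsertionSpec = field(default_factory=InsertionSpec)
    intron3_context: str = "GCAAGGGTAAGTATCT"
    variant_catalogue: tuple[VariantSpec, ...] = DEFAULT_CATALOGUE

    def __post_init__(self) -> None:
        if len(self.cds_a) % 3 != 0:
            raise InvalidSequenceError("TPH2a CDS length must be divisible by 3")
        if len(self.utr5_seq) < 42:
            raise InvalidSequenceError("5'-UTR must reach c.-42")
        if len(self.intron3_context) < 8:
            raise InvalidSequenceError("intron 3 context must be >= 8 nt")
        for v in self.variant_catalogue:
            if self.base_at(v.c_pos, "b" if v.isoform_scope == "b-only" else "a") != v.ref_base:
                raise ReferenceMismatchError(
                    f"reference base at c.{v.c_pos} ({v.isoform_scope}) != {v.ref_base}"
                )

    # -- derived sequences -------------------------------------------------
    @property
    def cds_b(self) -> str:
        ins = self.insertion
        return self.cds_a[: ins.after_c_pos] + ins.inserted_seq + self.cds_a[ins.after_c_pos :]

    @property
    def transcript_a(self) -> str:
        return self.utr5_seq + self.cds_a

    @property
    def transcript_b(self) -> str:
        return self.utr5_seq + self.cds_b

    def transcript(self, isoform: str) -> str:
        return self.transcript_a if isoform == "a" else self.transcript_b

    # -- coordinate arithmetic --------------------------------------------
    def c_to_index(self, c_pos: int, isoform: str = "a") -> int:
        """0-based index in the isoform transcript (UTR + CDS) of c.``c_pos``."""
        utr = len(self.utr5_seq)
        if c_pos == 0:
            raise ParameterError("c.0 does not exist")
        if c_pos < 0:
            idx = utr + c_pos
            if idx < 0:
                raise ParameterError(f"c.{c_pos} lies before the modelled UTR")
            return idx
        cds_len = len(self.cds_a) if isoform == "a" else len(self.cds_b)
        if c_pos > cds_len:
            raise ParameterError(f"c.{c_pos} beyond CDS of isoform {isoform}")
        return utr + c_pos - 1

    def index_to_c(self, idx: int, isoform: str = "a") -> int:
        utr = len(self.utr5_seq)
        if idx < utr:
            return idx - utr
        return idx - utr + 1

    def a_to_b_pos(self, c_pos: int) -> int:
        """Project a TPH2a coding position onto the TPH2b CDS."""
        if c_pos < 0 or c_pos <= self.insertion.after_c_pos:
            return c_pos
        return c_pos + len(self.insertion.inserted_seq)

    def b_to_a_pos(self, c_pos: int) -> Optional[int]:
        """Project a TPH2b coding position onto TPH2a (None inside the insertion)."""
        ins = self.insertion
        if c_pos < 0 or c_pos <= ins.after_c_pos:
            return c_pos
        if c_pos <= ins.after_c_pos + len(ins.inserted_seq):
            return None
        return c_pos - len(ins.inserted_seq)

    def scoped_pos(self, variant: VariantSpec, isoform: str) -> int:
        """The variant's c. position expressed on ``isoform``'s transcript."""
        if variant.isoform_scope == "b-only":
            if isoform == "b":
                return variant.c_pos
            a = self.b_to_a_pos(variant.c_pos)
            assert a is not None
            return a
        return variant.c_pos if isoform == "a" else self.a_to_b_pos(variant.c_pos)

    def base_at(self, c_pos: int, isoform: str = "a") -> str:
        return self.transcript(isoform)[self.c_to_index(c_pos, isoform)]

    # -- catalogue lookups --------------------------------------------------
    def catalogue_by_index(self, isoform: str) -> dict[int, VariantSpec]:
        """Editing catalogue entries in scope of ``isoform``, keyed by index."""
        scope = f"{isoform}-only"
        return {
            v.editing_index: v
            for v in self.variant_catalogue
            if v.site_class == "editing_candidate" and v.isoform_scope == scope
        }

    def catalogue_lookup(self, isoform: str) -> dict[tuple[int, str], VariantSpec]:
        """All catalogue entries keyed by (position on ``isoform`` track, alt)."""
        out: dict[tuple[int, str], VariantSpec] = {}
        for v in self.variant_catalogue:
            if v.isoform_scope == "a-only" and isoform == "b":
                pos = self.a_to_b_pos(v.c_pos)  # cross-scope site, still locatable
            elif v.isoform_scope == "b-only" and isoform == "a":
                pos = self.b_to_a_pos(v.c_pos)
                if pos is None:
                    continue
            else:
                pos = self.scoped_pos(v, isoform)
            out[(pos, v.alt_base)] = v
        return out

    def variant(self, isoform: str, editing_index: int) -> VariantSpec:
        return self.catalogue_by_index(isoform)[editing_index]


def _apply_constraints(
    catalogue: Sequence[VariantSpec],
    insertion: InsertionSpec,
    utr5_len: int,
) -> dict[int, str]:
    """Collapse catalogue ref-base requirements to TPH2a-track constraints.

    Returns a map of 0-based transcript-a index -> base; raises on conflict.
    """
    constraints: dict[int, str] = {}

    def put(idx: int, base: str, what: str) -> None:
        if constraints.get(idx, base) != base:
            raise ConstraintConflictError(
                f"conflicting reference bases at transcript index {idx} ({what})"
            )
        constraints[idx] = base

    for v in catalogue:
        pos = v.c_pos
        if v.isoform_scope == "b-only":
            if pos > insertion.after_c_pos + len(insertion.inserted_seq):
                pos -= len(insertion.inserted_seq)
            elif pos > insertion.after_c_pos:
                continue  # lies inside the insertion itself
        if pos < 0:
            idx = utr5_len + pos
        else:
            idx = utr5_len + pos - 1
        put(idx, v.ref_base, f"c.{v.c_pos}")
    return constraints


def build_reference(
    catalogue: Optional[Iterable[VariantSpec]] = None,
    *,
    utr5_len: int = 60,
    n_codons: int = 491,
    seed: int = 20100129,
    codon_constraints: Optional[Mapping[int, str]] = None,
    insertion: Optional[InsertionSpec] = None,
    intron3_context: str = "GCAAGGGTAAGTATCT",
) -> ReferenceModel:
    """Generate the deterministic surrogate reference.

    All catalogue reference bases and the codon-context constraints are honored
    simultaneously; every other base is drawn from a fixed-seed RNG.  The CDS
    starts with ATG, ends with a single stop codon, contains no internal stop,
    and carries no accidental NdeI site (so the designed rs4290270 site is the
    only one in play for the RFLP).
    """
    catalogue = tuple(DEFAULT_CATALOGUE if catalogue is None else catalogue)
    ins = insertion or InsertionSpec()
    if codon_constraints is None:
        codon_constraints = DEFAULT_CODON_CONSTRAINTS if catalogue == DEFAULT_CATALOGUE else {}

    rng = np.random.default_rng(seed)
    utr = list(rng.choice(list(BASES), size=utr5_len))
    codons: list[str] = ["ATG"]
    non_stop = [c for c in ("".join(t) for t in _all_codons()) if c not in STOP_CODONS]
    for i in range(2, n_codons):
        codons.append(non_stop[rng.integers(len(non_stop))])
    codons.append("TAA")

    for codon_idx, codon in codon_constraints.items():
        if not 1 <= codon_idx <= n_codons:
            raise ParameterError(f"codon constraint {codon_idx} outside CDS")
        codons[codon_idx - 1] = codon
    # the insertion context: base right before the insertion point must make
    # the inserted 6-mer read in frame as Gly-Lys and leave flanks intact
    cds = list("".join(codons))
    cds[ins.after_c_pos - 1] = "G"

    base_constraints = _apply_constraints(catalogue, ins, utr5_len)
    seq = utr + cds  # transcript-a track
    for idx, base in base_constraints.items():
        if idx >= len(seq):
            raise ParameterError(f"catalogue position at index {idx} outside model")
        here = seq[idx]
        constrained = (
            idx >= utr5_len
            and ((idx - utr5_len) // 3 + 1) in codon_constraints
        ) or idx == utr5_len + ins.after_c_pos - 1
        if constrained and here != base:
            raise ConstraintConflictError(
                f"catalogue base at transcript index {idx} conflicts with codon context"
            )
        seq[idx] = base
    utr, cds = seq[:utr5_len], seq[utr5_len:]

    _scrub(cds, utr5_len, base_constraints, codon_constraints, ins, catalogue, rng)

    model = ReferenceModel(
        utr5_seq="".join(utr),
        cds_a="".join(cds),
        insertion=ins,
        intron3_context=intron3_context,
        variant_catalogue=catalogue,
    )
    return model


def _all_codons():
    for a in BASES:
        for b in BASES:
            for c in BASES:
                yield a + b + c


def _scrub(cds, utr5_len, base_constraints, codon_constraints, ins, catalogue, rng):
    """Re-roll unconstrained bases that create internal stops or stray NdeI sites."""
    fixed = {i - utr5_len for i in base_constraints if i >= utr5_len}
    for ci in codon_constraints:
        fixed.update(range(3 * (ci - 1), 3 * ci))
    fixed.add(ins.after_c_pos - 1)
    fixed.update({0, 1, 2, len(cds) - 3, len(cds) - 2, len(cds) - 1})

    def stop_free(i0: int) -> bool:
        return "".join(cds[i0 : i0 + 3]) not in STOP_CODONS

    for _ in range(200):
        dirty = False
        for i0 in range(3, len(cds) - 3, 3):
            if not stop_free(i0):
                free = [j for j in range(i0, i0 + 3) if j not in fixed]
                if not free:
                    raise ConstraintConflictError("constrained codon is a stop codon")
                j = free[0]
                cds[j] = rng.choice([b for b in BASES if b != cds[j]])
                dirty = True
        s = "".join(cds)
        # forbid accidental NdeI sites anywhere except via the designed T allele
        hit = s.find(NDEI_SITE)
        while hit != -1:
            free = [j for j in range(hit, hit + 6) if j not in fixed]
            if not free:
                raise ConstraintConflictError("constrained region forms an NdeI site")
            j = free[0]
            cds[j] = rng.choice([b for b in BASES if b != cds[j]])
            dirty = True
            s = "".join(cds)
            hit = s.find(NDEI_SITE)
        if not dirty:
            return
    raise Tph2Error("could not satisfy sequence constraints")  # pragma: no cover


def apply_variants(
    model: ReferenceModel, isoform: str, variants: Iterable[VariantSpec]
) -> str:
    """Return the ``isoform`` transcript (UTR + CDS) with ``variants`` applied.

    Raises :class:`MutualExclusivityError` if a variant's scope excludes the
    isoform and :class:`ReferenceMismatchError` if a stated reference base
    disagrees with the model.
    """
    if isoform not in ("a", "b"):
        raise ParameterError(f"unknown isoform {isoform!r}")
    seq = list(model.transcript(isoform))
    seen: set[int] = set()
    for v in variants:
        if v.isoform_scope != "both" and v.isoform_scope != f"{isoform}-only":
            raise MutualExclusivityError(
                f"variant c.{v.c_pos} ({v.isoform_scope}) applied to isoform {isoform}"
            )
        idx = model.c_to_index(v.c_pos, isoform)
        if seq[idx] != v.ref_base:
            raise ReferenceMismatchError(f"c.{v.c_pos}: expected {v.ref_base}, found {seq[idx]}")
        if idx in seen:
            raise ParameterError(f"two variants at c.{v.c_pos}")
        seen.add(idx)
        seq[idx] = v.alt_base
    return "".join(seq)


def translate_cds(cds: str) -> tuple[str, Optional[int]]:
    """Translate a CDS; return (protein up to first stop, premature stop codon index).

    The index is 1-based and reported only when the first in-frame stop
    precedes the final codon; a clean terminal stop (or no stop) yields None.
    """
    if len(cds) % 3 != 0:
        raise InvalidSequenceError("CDS length not divisible by 3")
    if set(cds) - set(BASES):
        raise InvalidSequenceError(f"non-ACGT symbols: {sorted(set(cds) - set(BASES))}")
    aa = str(Seq(cds).translate())
    stop = aa.find("*")
    n_codons = len(cds) // 3
    if stop == -1:
        return aa, None
    premature = stop + 1 if stop + 1 < n_codons else None
    return aa[:stop], premature


def scan_donor_sites(intron3_context: str) -> dict[str, Optional[object]]:
    """Report the intron's first dinucleotide and any nearby downstream GT.

    For the human TPH2 intron 3 context (``GCAAGG GT...``) this returns
    ``{'primary_dinucleotide': 'GC', 'alternative_gt_offset': 6}``: a
    non-canonical GC donor with an alternative GT donor 6 nt downstream.
    A canonical GT primary donor reports offset None.
    """
    if len(intron3_context) < 8:
        raise InvalidSequenceError("need >= 8 nt of intron context")
    primary = intron3_context[:2]
    if primary == "GT":
        return {"primary_dinucleotide": "GT", "alternative_gt_offset": None}
    offset: Optional[int] = None
    for i in range(1, 7):
        if intron3_context[i : i + 2] == "GT":
            offset = i
            break
    return {"primary_dinucleotide": primary, "alternative_gt_offset": offset}


def catalogue_to_frame(model: ReferenceModel):
    """Serialize the variant catalogue as a pandas DataFrame (TSV schema)."""
    import pandas as pd

    rows = []
    for v in model.variant_catalogue:
        rows.append(
            {
                "c_pos": v.c_pos,
                "ref": v.ref_base,
                "alt": v.alt_base,
                "scope": v.isoform_scope,
                "class": v.site_class,
                "editing_index": v.editing_index,
                "rs_id": v.rs_id,
                "consequence": v.protein_consequence,
            }
        )
    return pd.DataFrame(rows)


def catalogue_from_frame(df) -> tuple[VariantSpec, ...]:
    def _opt(x):
        return None if x is None or (isinstance(x, float) and math.isnan(x)) or x == "." else x

    out = []
    for _, r in df.iterrows():
        ei = _opt(r["editing_index"])
        out.append(
            VariantSpec(
                c_pos=int(r["c_pos"]),
                ref_base=str(r["ref"]),
                alt_base=str(r["alt"]),
                isoform_scope=str(r["scope"]),
                site_class=str(r["class"]),
                editing_index=int(ei) if ei is not None else None,
                rs_id=_opt(r["rs_id"]),
            )
        )
    return tuple(out)
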