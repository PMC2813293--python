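"""SNP-versus-RNA-edit discrimination and editing-pattern assignment.

A substitution seen in a cDNA clone is a posttranscriptional RNA edit only if
the individual's genomic DNA is homozygous for the reference base at that
site; if the observed base is present among the genomic alleles it is a
genomic allele (a heterozygous carrier expressing the alt allele cannot be
distinguished from editing without phasing, so it is conservatively called
genomic); anything else is discordant.

Verified edits at catalogued positions are folded into the isoform's
mutually exclusive editing pattern ("TPH2a 1234", "TPH2b 234", ...); an edit
at a catalogue site of the *other* isoform's pattern raises the exclusivity
violation flag.  Editing chemistry is reported on the mRNA sense strand with
A>G labelled A>I and C>T labelled C>U, per convention; across the default
catalogue all four mammalian chemistries (A>I, C>U, U>C, G>A) occur.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .calling import CloneAnnotation, VariantCall
from .reference import ParameterError, ReferenceModel, c_to_codon

CHEMISTRY = {("A", "G"): "A>I", ("C", "T"): "C>U", ("T", "C"): "U>C", ("G", "A"): "G>A"}


class MissingGenomicDataError(ParameterError):
    """No genomic genotype is available for a site that needs one."""


@dataclass(frozen=True)
class SiteClassification:
    c_pos: int
    verdict: str  # 'rna_edit' | 'genomic_allele' | 'discordant'
    genomic_genotype: tuple[str, str]
    chemistry: str
    observed_base: str = "N"


def genomic_genotype_at(
    haplotypes: tuple[str, str], model: ReferenceModel, c_pos: int, isoform: str
) -> tuple[str, str]:
    """The individual's genomic base pair at a transcript position.

    Haplotype sequences are on the TPH2a exon track; TPH2b positions are
    projected back (positions inside the splice insertion have no genomic
    counterpart on this track and raise).
    """
    a_pos = c_pos if isoform == "a" else model.b_to_a_pos(c_pos)
    if a_pos is None:
        raise MissingGenomicDataError(f"b c.{c_pos} lies inside the splice insertion")
    idx = model.c_to_index(a_pos, "a")
    return haplotypes[0][idx], haplotypes[1][idx]


def classify_site(
    call: VariantCall, genomic_genotype: Optional[tuple[str, str]]
) -> SiteClassification:
    """Decide RNA edit vs genomic allele for one substitution call."""
    if genomic_genotype is None:
        raise MissingGenomicDataError(f"no genomic genotype for c.{call.c_pos}")
    g = tuple(genomic_genotype)
    chem = CHEMISTRY.get((call.ref_base, call.observed_base), "other")
    if g == (call.ref_base, call.ref_base):
        verdict = "rna_edit"
    elif call.observed_base in g:
        verdict = "genomic_allele"
    else:
        verdict = "discordant"
    return SiteClassification(call.c_pos, verdict, g, chem, call.observed_base)


@dataclass(frozen=True)
class EditingPattern:
    isoform: str
    edited_indices: frozenset[int]
    label: str
    exclusivity_violation: bool


def pattern_label(isoform: str, indices: frozenset[int]) -> str:
    if not indices:
        return f"TPH2{isoform} unedited"
    return f"TPH2{isoform} " + "".join(str(i) for i in sorted(indices))


def assign_pattern(
    annotation: CloneAnnotation,
    site_classifications: Mapping[int, SiteClassification],
    model: ReferenceModel,
) -> EditingPattern:
    """Fold verified edits into the clone's mutually exclusive pattern.

    ``site_classifications`` is keyed by the call's c. position on the called
    isoform's track.  Only catalogue editing sites in the isoform's own scope,
    observed with the catalogue's edited base, contribute indices; a verified
    edit at a cross-scope catalogue site sets ``exclusivity_violation``.
    Non-catalogue edits never join a pattern.
    """
    if annotation.isoform not in ("a", "b"):
        raise ParameterError("cannot assign a pattern without an isoform call")
    isoform = annotation.isoform
    own = {
        (model.scoped_pos(v, isoform), v.alt_base): v.editing_index
        for v in model.catalogue_by_index(isoform).values()
    }
    other_iso = "b" if isoform == "a" else "a"
    cross = set()
    for v in model.catalogue_by_index(other_iso).values():
        # position of the cross-scope site expressed on *this* isoform's track
        if v.isoform_scope == "b-only":
            mapped = v.c_pos if isoform == "b" else model.b_to_a_pos(v.c_pos)
        else:
            mapped = v.c_pos if isoform == "a" else model.a_to_b_pos(v.c_pos)
        if mapped is not None:
            cross.add((mapped, v.alt_base))
    indices: set[int] = set()
    violation = False
    for c_pos, sc in site_classifications.items():
        if sc.verdict != "rna_edit":
            continue
        key = (c_pos, sc.observed_base)
        if key in own:
            indices.add(own[key])
        elif key in cross:
            violation = True
    idx = frozenset(indices)
    return EditingPattern(isoform, idx, pattern_label(isoform, idx), violation)


def annotate_consequence(
    variant, model: ReferenceModel, isoform: Optional[str] = None
) -> tuple[str, Optional[str]]:
    """Consequence class of a variant, derived by codon substitution.

    Accepts a catalogue :class:`VariantSpec` or a :class:`VariantCall` (with
    ``observed_base`` as alt); for a bare call, ``isoform`` says which CDS
    track the position lives on.  Returns (kind, protein change), where kind
    is 'utr', 'synonymous', 'missense' or 'nonsense'.  b-only positions are
    read on the TPH2b CDS; everything else defaults to TPH2a.
    """
    c_pos = variant.c_pos
    alt = getattr(variant, "alt_base", None) or variant.observed_base
    if isoform is None:
        scope = getattr(variant, "isoform_scope", "both")
        isoform = "b" if scope == "b-only" else "a"
    if c_pos < 0:
        return "utr", None
    cds = model.cds_a if isoform == "a" else model.cds_b
    codon_idx, offset = c_to_codon(c_pos)
    codon = list(cds[3 * (codon_idx - 1) : 3 * codon_idx])
    codon_ref = "".join(codon)
    codon[offset - 1] = alt
    codon_alt = "".join(codon)
    aa_ref = _aa(codon_ref)
    aa_alt = _aa(codon_alt)
    if aa_alt == aa_ref:
        return "synonymous", f"p.{aa_ref}{codon_idx}"
    if aa_alt == "*":
        return "nonsense", f"p.{aa_ref}{codon_idx}X"
    return "missense", f"p.{aa_ref}{codon_idx}{aa_alt}"


def _aa(codon: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(codon).translate())


def discriminate_library(
    annotations: Sequence[CloneAnnotation],
    haplotypes_by_individual: Mapping[str, tuple[str, str]],
    manifest: pd.DataFrame,
    model: ReferenceModel,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run site classification and pattern assignment over a called library.

    Returns (patterns table, sites table).  Clones without an isoform call or
    failing QC are carried in the patterns table with an empty label so the
    tabulation stage can count them separately.
    """
    meta = manifest.set_index("clone_id")
    pattern_rows, site_rows = [], []
    for ann in annotations:
        ind = meta.loc[ann.clone_id, "individual"]
        haps = haplotypes_by_individual.get(ind)
        if haps is None:
            raise MissingGenomicDataError(f"no genomic sequences for individual {ind!r}")
        row = {
            "clone_id": ann.clone_id,
            "individual": ind,
            "group": meta.loc[ann.clone_id, "group"],
            "region": meta.loc[ann.clone_id, "region"],
            "isoform": ann.isoform,
            "rs4290270": ann.rs4290270_base,
            "qc": ann.qc_pass,
        }
        if ann.isoform == "unclassified":
            pattern_rows.append({**row, "label": ".", "indices": ".", "violation": False})
            continue
        classifications: dict[int, SiteClassification] = {}
        for call in ann.variant_calls:
            gt = genomic_genotype_at(haps, model, call.c_pos, ann.isoform)
            sc = classify_site(call, gt)
            classifications[call.c_pos] = sc
            if call.catalogue_entry is not None:
                kind, pchange = annotate_consequence(call.catalogue_entry, model)
            else:
                kind, pchange = annotate_consequence(call, model, isoform=ann.isoform)
            site_rows.append(
                {
                    "clone_id": ann.clone_id,
                    "c_pos": call.c_pos,
                    "ref": call.ref_base,
                    "obs": call.observed_base,
                    "in_catalogue": call.in_catalogue,
                    "verdict": sc.verdict,
                    "chemistry": sc.chemistry,
                    "consequence": kind,
                    "protein_change": pchange,
                }
            )
        pattern = assign_pattern(ann, classifications, model)
        pattern_rows.append(
            {
                **row,
                "label": pattern.label,
                "indices": "".join(str(i) for i in sorted(pattern.edited_indices)),
                "violation": pattern.exclusivity_violation,
            }
        )
    return pd.DataFrame(pattern_rows), pd.DataFrame(site_rows)
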