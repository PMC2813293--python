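"""Synthetic clone libraries, genomic haplotypes, kinetic assays and cohorts.

This module emulates the study design the analysis assumes: per-individual
cDNA clone libraries from brain regions, with diploid rs7305115/rs4290270
genotypes, allele-gated alternative splicing and editing, per-position
editing probabilities per stratum, Sanger-scale sequencing error, noisy
saturation-kinetics curves, and genotype cohorts for association testing.
Every generated object comes with an exhaustive truth table.

The gating rule ("splicing to TPH2b and RNA editing occur only on transcripts
from the permissive rs4290270 allele") follows the running text, under which
the T allele is permissive.  The printed frequency table labels the edited
strata with the opposite allele; the permissive allele is therefore a
parameter (``permissive_allele``) so either convention can be generated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .kinetics import KineticDataset, michaelis_menten, substrate_inhibition
from .reference import BASES, ParameterError, ReferenceModel

GROUPS = ("control", "drug_abuse", "suicide", "schizophrenia")


@dataclass(frozen=True)
class IndividualProfile:
    """One (synthetic) subject: group, diploid SNP genotypes, and the two
    genomic haplotype sequences on the TPH2a exon track (UTR + CDS)."""

    id: str
    group: str
    genotypes: Mapping[str, tuple[str, str]]  # rs id -> unordered allele pair
    haplotypes: tuple[str, str]

    def genotype(self, rs_id: str) -> tuple[str, str]:
        return tuple(sorted(self.genotypes[rs_id]))  # type: ignore[return-value]


@dataclass(frozen=True)
class GenerationParams:
    """Knobs of the clone-library generator.

    ``editing_probs`` maps (region, isoform) -> per-index probabilities
    (editing indices 1-4); a plain isoform key acts as a region-independent
    fallback.  ``splice_fraction_b`` is the probability that a transcript from
    the permissive allele is spliced to TPH2b.  ``error_rate`` is a uniform
    per-base substitution rate (default 1e-3, Sanger scale).
    """

    n_clones: int = 50
    splice_fraction_b: float = 0.5
    editing_probs: Mapping[object, Sequence[float]] = field(
        default_factory=lambda: {"a": (0.0, 0.0, 0.0, 0.0), "b": (0.9, 0.9, 0.9, 0.9)}
    )
    gating: bool = True
    permissive_allele: str = "T"
    error_rate: float = 1e-3
    seed: int = 0

    def probs_for(self, region: str, isoform: str) -> Sequence[float]:
        probs = self.editing_probs.get((region, isoform), self.editing_probs.get(isoform))
        if probs is None:
            raise ParameterError(f"no editing probabilities for {(region, isoform)}")
        if len(probs) != 4 or any(not 0.0 <= p <= 1.0 for p in probs):
            raise ParameterError("editing probabilities must be four values in [0,1]")
        return probs

    def __post_init__(self) -> None:
        if not 0.0 <= self.splice_fraction_b <= 1.0:
            raise ParameterError("splice_fraction_b must be in [0,1]")
        if not 0.0 <= self.error_rate < 1.0:
            raise ParameterError("error_rate must be in [0,1)")
        if self.permissive_allele not in ("A", "T"):
            raise ParameterError("permissive allele must be A or T (rs4290270)")


def generate_individual(
    ind_id: str,
    group: str,
    genotype_freqs: Mapping[str, Mapping[str, float]],
    model: ReferenceModel,
    seed: int,
) -> IndividualProfile:
    """Draw diploid genotypes and build the matching genomic haplotypes.

    ``genotype_freqs`` maps each rs id to genotype probabilities, e.g.
    ``{"rs4290270": {"AA": 0.25, "AT": 0.5, "TT": 0.25}}``.  Haplotype
    sequences carry the drawn alleles at the SNP positions and reference
    bases at every editing-candidate position (edits are never genomic).
    """
    if group not in GROUPS:
        raise ParameterError(f"unknown group {group!r}")
    rng = np.random.default_rng(seed)
    snps = {v.rs_id: v for v in model.variant_catalogue if v.site_class == "genomic_snp"}
    genotypes: dict[str, tuple[str, str]] = {}
    hap = [list(model.transcript_a), list(model.transcript_a)]
    for rs_id, spec in snps.items():
        freqs = genotype_freqs.get(rs_id, {spec.ref_base * 2: 1.0})
        labels = list(freqs)
        p = np.asarray([freqs[g] for g in labels], dtype=float)
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ParameterError(f"genotype frequencies for {rs_id} must sum to 1")
        gt = labels[rng.choice(len(labels), p=p)]
        if len(gt) != 2 or set(gt) - {spec.ref_base, spec.alt_base}:
            raise ParameterError(f"genotype {gt!r} incompatible with {rs_id} alleles")
        genotypes[rs_id] = (gt[0], gt[1])
        idx = model.c_to_index(spec.c_pos, "a")
        hap[0][idx] = gt[0]
        hap[1][idx] = gt[1]
    return IndividualProfile(
        id=ind_id,
        group=group,
        genotypes=genotypes,
        haplotypes=("".join(hap[0]), "".join(hap[1])),
    )


def _transcript_from_haplotype(model: ReferenceModel, hap: str, isoform: str) -> str:
    if isoform == "a":
        return hap
    cut = len(model.utr5_seq) + model.insertion.after_c_pos
    return hap[:cut] + model.insertion.inserted_seq + hap[cut:]


def generate_clone_library(
    model: ReferenceModel,
    profile: IndividualProfile,
    region: str,
    params: GenerationParams,
) -> tuple[list[tuple[str, str]], pd.DataFrame, pd.DataFrame]:
    """Simulate one clone library: (records, manifest, truth table).

    Each clone: (i) pick an allele of origin 50/50 from the diploid
    rs4290270 genotype, (ii) apply the gating rule if enabled (blocked allele
    => TPH2a, no editing), (iii) sample the splice isoform, (iv) sample each
    in-scope editing index independently with its stratum probability,
    (v) apply uniform sequencing errors.  Records are (id, sequence).
    """
    rng = np.random.default_rng(params.seed)
    gt = profile.genotype("rs4290270")
    records: list[tuple[str, str]] = []
    manifest_rows, truth_rows = [], []
    for k in range(params.n_clones):
        clone_id = f"{profile.id}_{region}_c{k:05d}"
        hap_idx = int(rng.integers(2))
        allele = gt[hap_idx]
        blocked = params.gating and allele != params.permissive_allele
        if blocked:
            isoform, edited = "a", frozenset()
        else:
            isoform = "b" if rng.random() < params.splice_fraction_b else "a"
            probs = params.probs_for(region, isoform)
            edited = frozenset(
                i + 1 for i, p in enumerate(probs) if rng.random() < p
            )
        seq = list(_transcript_from_haplotype(model, profile.haplotypes[hap_idx], isoform))
        for i in sorted(edited):
            v = model.variant(isoform, i)
            seq[model.c_to_index(v.c_pos, isoform)] = v.alt_base
        n_err = int(rng.binomial(len(seq), params.error_rate))
        err_pos = rng.choice(len(seq), size=n_err, replace=False) if n_err else []
        for j in err_pos:
            seq[j] = BASES[(BASES.index(seq[j]) + int(rng.integers(1, 4))) % 4]
        records.append((clone_id, "".join(seq)))
        manifest_rows.append(
            {"clone_id": clone_id, "individual": profile.id, "group": profile.group,
             "region": region}
        )
        truth_rows.append(
            {
                "clone_id": clone_id,
                "individual": profile.id,
                "group": profile.group,
                "region": region,
                "allele_origin": allele,
                "isoform": isoform,
                "edited_indices": "".join(str(i) for i in sorted(edited)),
                "n_seq_errors": n_err,
            }
        )
    return records, pd.DataFrame(manifest_rows), pd.DataFrame(truth_rows)


#: The published stratified editing-frequency rows used as generator scenarios:
#: (region, isoform, rs4290270 stratum allele, clone count, per-index
#: probabilities).  Strata labels follow the printed table, under which the
#: permissive allele is A.
TABLE1_ROWS: tuple[tuple[str, str, str, int, tuple[float, float, float, float]], ...] = (
    ("amygdala", "a", "A", 48, (0.33, 0.31, 0.33, 0.33)),
    ("amygdala", "a", "T", 17, (0.0, 0.0, 0.0, 0.0)),
    ("amygdala", "b", "A", 27, (0.78, 0.96, 0.96, 0.96)),
    ("other", "a", "A", 8, (0.0, 0.0, 0.0, 0.0)),
    ("other", "a", "T", 19, (0.0, 0.0, 0.0, 0.0)),
    ("other", "b", "A", 11, (1.0, 1.0, 1.0, 1.0)),
)


def generate_table1_libraries(
    model: ReferenceModel,
    seed: int,
    rows=TABLE1_ROWS,
    error_rate: float = 0.0,
) -> tuple[list[tuple[str, str]], pd.DataFrame, pd.DataFrame, dict[str, IndividualProfile]]:
    """Build clone libraries mimicking the published stratified clone sets.

    One homozygous synthetic individual per stratum allele carries the
    stratum's clones; isoform composition and editing probabilities are forced
    to the row's values.  Uses the printed table's allele convention
    (permissive allele = A).
    """
    rng = np.random.default_rng(seed)
    records: list[tuple[str, str]] = []
    manifests, truths = [], []
    profiles: dict[str, IndividualProfile] = {}
    for i, (region, isoform, allele, n, probs) in enumerate(rows):
        ind_id = f"tbl_{region}_{isoform}{allele}"
        profile = generate_individual(
            ind_id,
            "control",
            {"rs4290270": {allele * 2: 1.0}, "rs7305115": {"AA": 1.0}},
            model,
            seed=int(rng.integers(2**31 - 1)),
        )
        profiles[ind_id] = profile
        params = GenerationParams(
            n_clones=n,
            splice_fraction_b=1.0 if isoform == "b" else 0.0,
            editing_probs={(region, isoform): tuple(probs)},
            gating=True,
            permissive_allele="A",
            error_rate=error_rate,
            seed=int(rng.integers(2**31 - 1)),
        )
        recs, man, tru = generate_clone_library(model, profile, region, params)
        records.extend(recs)
        manifests.append(man)
        truths.append(tru)
    return records, pd.concat(manifests, ignore_index=True), pd.concat(
        truths, ignore_index=True
    ), profiles


def generate_kinetic_dataset(
    model_kind: str,
    km: float,
    vmax: float,
    substrate_grid: Sequence[float],
    noise_cv: float,
    n_replicates: int,
    seed: int,
    ki: Optional[float] = None,
    variant: str = "synthetic",
    cofactor: str = "6MPH4",
    cofactor_um: float = 300.0,
) -> KineticDataset:
    """Simulate substrate-velocity observations from MM or Haldane kinetics.

    Each observation is the model velocity times multiplicative lognormal
    noise with coefficient of variation ``noise_cv`` (unit mean).
    """
    if model_kind not in ("MM", "SI"):
        raise ParameterError("model_kind must be 'MM' or 'SI'")
    if km <= 0 or vmax <= 0:
        raise ParameterError("Km and Vmax must be positive")
    grid = np.asarray(substrate_grid, dtype=float)
    if (grid <= 0).any():
        raise ParameterError("substrate concentrations must be positive")
    if model_kind == "SI":
        if ki is None:
            raise ParameterError("substrate-inhibition model needs Ki")
        if ki <= 0:
            raise ParameterError("Ki must be positive")
        mean_v = substrate_inhibition(grid, km, vmax, ki)
    else:
        mean_v = michaelis_menten(grid, km, vmax)
    rng = np.random.default_rng(seed)
    S = np.tile(grid, n_replicates)
    mu = np.tile(mean_v, n_replicates)
    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv**2))
        noise = rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=S.size)
    else:
        noise = np.ones_like(S)
    rep = np.repeat(np.arange(n_replicates), grid.size)
    return KineticDataset(
        variant=variant,
        cofactor=cofactor,
        cofactor_um=cofactor_um,
        S=S,
        v=mu * noise,
        replicate=rep,
    )


def generate_genotype_cohort(
    allele_freq_p: float,
    n: int,
    seed: int,
    hwe: bool = True,
    genotype_probs: Optional[Sequence[float]] = None,
    label: str = "cohort",
):
    """Draw a diploid genotype cohort (counts of AA / AT / TT).

    Under ``hwe=True`` genotypes are multinomial(p^2, 2p(1-p), (1-p)^2) where
    p is the frequency of the first allele; otherwise ``genotype_probs``
    supplies the three probabilities directly.
    """
    from .cohort import GenotypeCounts

    if not 0.0 <= allele_freq_p <= 1.0:
        raise ParameterError("allele frequency must lie in [0,1]")
    if hwe:
        p = allele_freq_p
        probs = np.array([p * p, 2 * p * (1 - p), (1 - p) * (1 - p)])
    else:
        if genotype_probs is None:
            raise ParameterError("genotype_probs required when hwe=False")
        probs = np.asarray(genotype_probs, dtype=float)
        if probs.shape != (3,) or (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
            raise ParameterError("genotype_probs must be three values summing to 1")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n, probs)
    return GenotypeCounts(label=label, n_AA=int(counts[0]), n_AT=int(counts[1]),
                          n_TT=int(counts[2]))
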