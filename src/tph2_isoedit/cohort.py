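"""Stratified editing-frequency tables, group comparisons, HWE/association
tests, and the in-silico NdeI RFLP for rs4290270 genotyping.

The frequency table mirrors the published layout: rows keyed by
(region, isoform, rs4290270 allele observed in the transcript), with the
clone count and, for each editing index 1-4, the percent of QC-passing
clones carrying that edit.  Group comparisons use per-individual edited
fractions as the unit of replication (a t-test on pooled clone indicators
would be pseudo-replication) with Welch's unequal-variance two-tailed test,
the two-sample reading of a spreadsheet "type 3" t-test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .reference import NDEI_SITE, ParameterError

EDITING_INDICES = (1, 2, 3, 4)


@dataclass(frozen=True)
class GenotypeCounts:
    """Diploid genotype tallies for one cohort (biallelic SNP)."""

    label: str
    n_AA: int
    n_AT: int
    n_TT: int

    @property
    def n(self) -> int:
        return self.n_AA + self.n_AT + self.n_TT

    def as_array(self) -> np.ndarray:
        return np.array([self.n_AA, self.n_AT, self.n_TT], dtype=float)


def editing_frequency_table(
    patterns: pd.DataFrame,
    strata: Sequence[str] = ("region", "isoform", "rs4290270"),
) -> pd.DataFrame:
    """Count edited clones per stratum and editing index.

    ``patterns`` needs one row per clone with the strata columns, ``qc``,
    ``isoform`` and the edited ``indices`` string (e.g. "234").  Denominators
    are QC-passing clones with an isoform call in the stratum; percentages are
    NaN (undefined, not 0) for empty strata.
    """
    missing = [c for c in (*strata, "qc", "indices") if c not in patterns.columns]
    if missing:
        raise ParameterError(f"patterns table lacks columns {missing}")
    usable = patterns[(patterns["qc"]) & (patterns["isoform"].isin(["a", "b"]))]
    rows = []
    for key, grp in usable.groupby(list(strata), dropna=False):
        key = key if isinstance(key, tuple) else (key,)
        n = len(grp)
        row = dict(zip(strata, key))
        row["n_clones"] = n
        for i in EDITING_INDICES:
            edited = grp["indices"].fillna("").astype(str).str.contains(str(i)).sum()
            row[f"n_edited_{i}"] = int(edited)
            row[f"percent_{i}"] = 100.0 * edited / n if n else float("nan")
        rows.append(row)
    out = pd.DataFrame(rows)
    return out.sort_values(list(strata)).reset_index(drop=True) if len(out) else out


def per_individual_fractions(
    patterns: pd.DataFrame, isoform: str, editing_index: int
) -> pd.Series:
    """Edited fraction at one position per individual (QC-passing clones)."""
    sub = patterns[(patterns["qc"]) & (patterns["isoform"] == isoform)]
    edited = sub["indices"].fillna("").astype(str).str.contains(str(editing_index))
    return edited.groupby(sub["individual"]).mean()


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p: float
    flags: tuple[str, ...] = ()


def compare_editing(group_a: Sequence[float], group_b: Sequence[float]) -> TestResult:
    """Welch two-sample, two-tailed t-test on per-individual edited fractions."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("need >= 2 individuals per group")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if a.mean() == b.mean():
            return TestResult(0.0, float("nan"), 1.0, ("degenerate_zero_variance",))
        return TestResult(float("inf"), float("nan"), 0.0, ("degenerate_zero_variance",))
    res = stats.ttest_ind(a, b, equal_var=False)
    return TestResult(float(res.statistic), float(res.df), float(res.pvalue))


def hwe_test(counts: GenotypeCounts) -> TestResult:
    """Pearson chi-square test for Hardy-Weinberg equilibrium (df = 1)."""
    n = counts.n
    if n <= 0:
        raise ParameterError("empty cohort")
    obs = counts.as_array()
    p = (2 * counts.n_AA + counts.n_AT) / (2.0 * n)
    exp = n * np.array([p * p, 2 * p * (1 - p), (1 - p) * (1 - p)])
    flags: tuple[str, ...] = ()
    if (exp == 0).any():
        # a fixed allele: observed must equal expected where defined
        flags = ("zero_expected_cell",)
        with np.errstate(invalid="ignore", divide="ignore"):
            terms = np.where(exp > 0, (obs - exp) ** 2 / np.where(exp > 0, exp, 1.0), 0.0)
        chi2 = float(terms.sum())
    else:
        chi2 = float(((obs - exp) ** 2 / exp).sum())
    return TestResult(chi2, 1.0, float(stats.chi2.sf(chi2, 1)), flags)


def genotype_association(
    case_counts: GenotypeCounts,
    control_counts: GenotypeCounts,
    mode: str = "AA_vs_rest",
) -> TestResult:
    """Pearson chi-square for genotype-disease association.

    ``AA_vs_rest`` collapses to a 2x2 table (df 1); ``full_2x3`` keeps all
    three genotypes (df 2).  No continuity correction.
    """
    if case_counts.n == 0 or control_counts.n == 0:
        raise ParameterError("both cohorts must be non-empty")
    if mode == "AA_vs_rest":
        table = np.array(
            [
                [case_counts.n_AA, case_counts.n - case_counts.n_AA],
                [control_counts.n_AA, control_counts.n - control_counts.n_AA],
            ],
            dtype=float,
        )
    elif mode == "full_2x3":
        table = np.vstack([case_counts.as_array(), control_counts.as_array()])
    else:
        raise ParameterError(f"unknown association mode {mode!r}")
    col_sums = table.sum(axis=0)
    keep = col_sums > 0
    flags: tuple[str, ...] = ()
    if not keep.all():
        table = table[:, keep]
        flags = ("empty_margin_dropped",)
    if table.shape[1] < 2:
        return TestResult(float("nan"), float("nan"), float("nan"), ("undefined",))
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return TestResult(float(chi2), float(df), float(p), flags)


@dataclass(frozen=True)
class RflpResult:
    """In-silico restriction digest of one amplicon."""

    allele: str
    fragments: tuple[int, ...]
    cut: bool


def ndel_rflp(amplicon_seq: str, allele: str = ".") -> RflpResult:
    """Digest an amplicon with NdeI (CA^TATG, cut between bases 2 and 3).

    Fragments are returned 5'->3' and always sum to the amplicon length.
    """
    if not amplicon_seq:
        raise ParameterError("empty amplicon")
    seq = amplicon_seq.upper()
    cuts = []
    start = 0
    while True:
        hit = seq.find(NDEI_SITE, start)
        if hit == -1:
            break
        cuts.append(hit + 2)
        start = hit + 1
    bounds = [0, *cuts, len(seq)]
    fragments = tuple(b - a for a, b in zip(bounds, bounds[1:]) if b > a)
    return RflpResult(allele=allele, fragments=fragments, cut=len(fragments) >= 2)


def rs4290270_amplicons(model, flank: int = 80) -> dict[str, str]:
    """Synthetic genotyping amplicons around rs4290270 for both alleles.

    The surrogate reference is built so the T allele completes the NdeI site.
    """
    spec = next(v for v in model.variant_catalogue if v.rs_id == "rs4290270")
    idx = model.c_to_index(spec.c_pos, "a")
    tr = model.transcript_a
    lo, hi = max(0, idx - flank), min(len(tr), idx + flank + 1)
    out = {}
    for allele in (spec.ref_base, spec.alt_base):
        s = tr[lo:idx] + allele + tr[idx + 1 : hi]
        out[allele] = s
    return out
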