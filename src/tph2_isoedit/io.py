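"""Shared file formats and run configuration.

Tabular interchange is TSV (UTF-8, header row, '.' for missing); nested
statistics go to JSON; sequences to FASTA wrapped at 60 columns.  Variant
tables use HGVS-like c. labels (no genomic assembly exists for the surrogate
reference, so VCF export is future work).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .reference import InvalidSequenceError, ParameterError

log = logging.getLogger("tph2_isoedit")

IUPAC_NT = set("ACGTURYSWKMBDHVN")


def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA records as (id, uppercase sequence) pairs.

    Duplicate ids and non-IUPAC characters raise; lowercase input is
    uppercased and logged.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise InvalidSequenceError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        raw = str(rec.seq)
        if raw != raw.upper():
            log.warning("record %s: lowercase bases uppercased on read", rec.id)
        seq = raw.upper()
        bad = set(seq) - IUPAC_NT
        if bad:
            raise InvalidSequenceError(
                f"record {rec.id!r} has non-IUPAC characters {sorted(bad)}"
            )
        records.append((rec.id, seq))
    return records


def write_fasta(records: Sequence[tuple[str, str]], path) -> None:
    """Write (id, sequence) pairs as FASTA, 60 columns per line."""
    seen: set[str] = set()
    recs = []
    for rid, seq in records:
        if rid in seen:
            raise InvalidSequenceError(f"duplicate FASTA id {rid!r}")
        seen.add(rid)
        recs.append(SeqRecord(Seq(seq), id=rid, description=""))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(recs)


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=".")


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["."], keep_default_na=True)


@dataclass
class RunConfig:
    """Everything one pipeline run needs, serializable to/from YAML."""

    seed: int = 1
    out_dir: str = "tph2_run"
    # generation
    n_individuals_per_group: int = 2
    n_clones: int = 30
    regions: tuple[str, ...] = ("amygdala",)
    splice_fraction_b: float = 0.5
    editing_probs_a: tuple[float, float, float, float] = (0.33, 0.31, 0.33, 0.33)
    editing_probs_b: tuple[float, float, float, float] = (0.78, 0.96, 0.96, 0.96)
    gating: bool = True
    permissive_allele: str = "T"
    error_rate: float = 1e-3
    genotype_freqs_rs4290270: Mapping[str, float] = field(
        default_factory=lambda: {"AA": 0.25, "AT": 0.5, "TT": 0.25}
    )
    genotype_freqs_rs7305115: Mapping[str, float] = field(
        default_factory=lambda: {"AA": 0.25, "AG": 0.5, "GG": 0.25}
    )
    # caller
    margin_threshold: float = 3.0
    max_noncatalogue: int = 5
    # statistics
    association_mode: str = "AA_vs_rest"
    bonferroni: bool = False
    # kinetics
    kinetics_model: str = "MM"
    kinetics_method: str = "nls"
    inverse_v2_weighting: bool = False

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["regions"] = list(self.regions)
        d["editing_probs_a"] = list(self.editing_probs_a)
        d["editing_probs_b"] = list(self.editing_probs_b)
        d["genotype_freqs_rs4290270"] = dict(self.genotype_freqs_rs4290270)
        d["genotype_freqs_rs7305115"] = dict(self.genotype_freqs_rs7305115)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(data)
        for key in ("regions", "editing_probs_a", "editing_probs_b"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]
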