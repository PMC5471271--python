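"""Classification and filtering of annotated somatic variant tables.

Consumes the tabular output of an upstream somatic caller + effect
annotator (MuTect / Variant Effect Predictor style) in a five-column TSV
dialect — symbol, description, allele_freq, base_change ("X/Y"
nucleotides), aa_change ("A/B" residues, "stop" or "*" marking a gained
stop codon) — classifies each variant as stop-gain / missense /
synonymous / other, filters by class and allele frequency, and summarises
allele frequencies.

The published table of mutations private to the bone-metastasis-derived
cell line ships as package data (``table1_path()``): 4 stop-gains (GRM3,
BHMT2, REXO1L1P, FCGR1A) and 21 amino-acid substitutions.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

REQUIRED_COLUMNS = ["symbol", "description", "allele_freq", "base_change", "aa_change"]
STOP_TOKENS = {"stop", "*"}
_NUCLEOTIDES = set("ACGT")


class VariantClass(str, Enum):
    STOP_GAIN = "stop_gain"
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


@dataclass
class VariantRecord:
    """One annotated exonic variant (one table row)."""

    symbol: str
    description: str
    allele_freq: float
    base_change: str
    aa_change: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.allele_freq <= 1.0:
            raise ValueError(
                f"allele_freq {self.allele_freq} outside [0, 1]"
            )
        parts = self.base_change.split("/")
        if len(parts) != 2 or not all(p in _NUCLEOTIDES for p in parts):
            raise ValueError(f"malformed base_change {self.base_change!r}")
        if len(self.aa_change.split("/")) != 2:
            raise ValueError(f"malformed aa_change {self.aa_change!r}")


def table1_path() -> Path:
    """Path to the packaged published mutation table."""
    return Path(
        importlib.resources.files("bonemet") / "data" / "table1_bmd_mutations.tsv"
    )


def read_variant_table(path: str | Path) -> list[VariantRecord]:
    """Read a variant TSV, validating every row.

    Malformed rows raise a ValueError naming the (1-based, header-excluded)
    row number.
    """
    df = pd.read_csv(path, sep="\t", dtype={"allele_freq": float})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            records.append(
                VariantRecord(
                    symbol=str(row.symbol),
                    description=str(row.description),
                    allele_freq=float(row.allele_freq),
                    base_change=str(row.base_change),
                    aa_change=str(row.aa_change),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"row {i}: {exc}") from exc
    return records


def classify_variant(rec: VariantRecord) -> VariantClass:
    """Stop-gain if the new residue is the stop token; synonymous if the
    residues match; missense if two distinct ordinary residues."""
    ref_aa, alt_aa = (p.strip() for p in rec.aa_change.split("/"))
    if not ref_aa or not alt_aa:
        raise ValueError(f"unparseable aa_change {rec.aa_change!r}")
    if alt_aa.lower() in STOP_TOKENS:
        return VariantClass.STOP_GAIN
    if ref_aa.lower() in STOP_TOKENS:
        return VariantClass.OTHER  # stop-loss etc.
    if ref_aa == alt_aa:
        return VariantClass.SYNONYMOUS
    return VariantClass.MISSENSE


def filter_and_count(
    records: Sequence[VariantRecord],
    classes: Iterable[VariantClass | str],
    min_af: float = 0.0,
) -> tuple[list[VariantRecord], dict[str, int]]:
    """Keep records of the requested classes with allele_freq >= min_af.

    Returns the filtered records in input order plus per-class counts of
    the kept records.
    """
    wanted = {VariantClass(c) for c in classes}
    kept: list[VariantRecord] = []
    counts = {c.value: 0 for c in VariantClass}
    for rec in records:
        cls = classify_variant(rec)
        if cls in wanted and rec.allele_freq >= min_af:
            kept.append(rec)
            counts[cls.value] += 1
    return kept, counts


def af_summary(records: Sequence[VariantRecord]) -> tuple[float, float, float]:
    """(min, max, mean) of allele frequency over the given records."""
    if not records:
        raise ValueError("empty record list")
    afs = [r.allele_freq for r in records]
    return min(afs), max(afs), sum(afs) / len(afs)


def truncation_length(stop_codon_position: int, wildtype_length: int) -> int:
    """Residues translated before a premature stop at a 1-based position."""
    if not 1 <= stop_codon_position <= wildtype_length:
        raise ValueError(
            f"stop position {stop_codon_position} outside "
            f"[1, {wildtype_length}]"
        )
    return stop_codon_position - 1


def records_to_frame(records: Sequence[VariantRecord]) -> pd.DataFrame:
    """Tabular view of variant records (columns in the TSV dialect order)."""
    return pd.DataFrame(
        [
            {
                "symbol": r.symbol,
                "description": r.description,
                "allele_freq": r.allele_freq,
                "base_change": r.base_change,
                "aa_change": r.aa_change,
            }
            for r in records
        ],
        columns=REQUIRED_COLUMNS,
    )


def read_variant_vcf(path: str | Path) -> list[VariantRecord]:
    """Minimal VCF reader mapping annotated records into VariantRecord.

    Expects uncompressed VCF 4.x with INFO keys ``SYMBOL`` (gene),
    ``AF`` (allele frequency) and ``AA`` (amino-acid change "A/B", "*"
    accepted as the stop token); REF/ALT give the base change.  Anything
    richer (multi-allelic records, transcript-level consequences) is out
    of scope.
    """
    from cyvcf2 import VCF

    records = []
    for v in VCF(str(path)):
        symbol = v.INFO.get("SYMBOL")
        af = v.INFO.get("AF")
        aa = v.INFO.get("AA")
        if symbol is None or af is None or aa is None:
            raise ValueError(
                f"VCF record {v.CHROM}:{v.POS} lacks SYMBOL/AF/AA INFO keys"
            )
        records.append(
            VariantRecord(
                symbol=str(symbol),
                description=str(v.INFO.get("DESC", "")),
                allele_freq=float(af),
                base_change=f"{v.REF}/{v.ALT[0]}",
                aa_change=str(aa),
            )
        )
    return records
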