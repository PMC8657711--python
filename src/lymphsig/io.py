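"""Readers and writers for the formats the pipeline consumes and emits.

Conventions enforced here, and only here:

* VCF positions are 1-based; all interval files (BED) are 0-based
  half-open.  Internal record tables carry the 1-based VCF position.
* Context/count/signature matrices travel as TSV with the 96 canonical
  row labels (``A[C>A]A`` ...) in the first column.
* The catalog reader accepts any TSV whose first column holds the 96
  canonical labels in any order -- including the public COSMIC v3.2 SBS
  layout -- and reorders rows into the canonical layout.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .categories import CATEGORY_LABELS, label_to_index

RECORD_COLUMNS = ["sample", "chrom", "pos", "ref", "alt", "vaf"]

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class MutationRecord:
    """One somatic SNV: sample, contig, 1-based position, ref/alt, VAF."""

    sample: str
    chrom: str
    pos: int
    ref: str
    alt: str
    vaf: float | None = None

    def __post_init__(self):
        if self.ref not in _VALID_BASES or self.alt not in _VALID_BASES:
            raise ValueError(f"ref/alt must be A/C/G/T: {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref equals alt at {self.chrom}:{self.pos}")


def records_to_frame(records: Iterable[MutationRecord]) -> pd.DataFrame:
    rows = [(r.sample, r.chrom, r.pos, r.ref, r.alt,
             np.nan if r.vaf is None else r.vaf) for r in records]
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


# ---------------------------------------------------------------------------
# FASTA

def load_genome(path: str | os.PathLike) -> dict[str, str]:
    """Load a FASTA into an in-memory dict of uppercase sequences."""
    from pyfaidx import Fasta

    fa = Fasta(str(path), sequence_always_upper=True)
    genome = {name: str(fa[name][:]) for name in fa.keys()}
    fa.close()
    return genome


def write_fasta(genome: Mapping[str, str], path: str | os.PathLike,
                width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# VCF

VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=VAF,Number=1,Type=Float,Description="Variant allele frequency">
"""


def write_vcf(records: pd.DataFrame, path: str | os.PathLike,
              contig_lengths: Mapping[str, int] | None = None) -> None:
    """Write a minimal sorted single-sample VCF v4.2 (SNVs only)."""
    df = records.sort_values(["chrom", "pos"], kind="mergesort")
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        if contig_lengths:
            for name, length in contig_lengths.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in df.itertuples(index=False):
            info = "." if pd.isna(row.vaf) else f"VAF={row.vaf:.4f}"
            fh.write(f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}"
                     f"\t.\tPASS\t{info}\n")


def read_vcf(path: str | os.PathLike, sample: str | None = None) -> pd.DataFrame:
    """Read somatic SNVs from a VCF into a record table.

    Multi-allelic rows are split into one record per alternate allele;
    non-SNV alleles (indels, symbolic) are dropped.  The sample name
    defaults to the file's basename without extension.
    """
    from cyvcf2 import VCF

    if sample is None:
        base = os.path.basename(str(path))
        for ext in (".vcf.gz", ".vcf"):
            if base.endswith(ext):
                base = base[: -len(ext)]
                break
        sample = base
    rows = []
    vcf = VCF(str(path))
    try:
        for var in vcf:
            ref = var.REF.upper()
            if len(ref) != 1 or ref not in _VALID_BASES:
                continue
            vaf = var.INFO.get("VAF")
            for alt in var.ALT:
                alt = alt.upper()
                if len(alt) != 1 or alt not in _VALID_BASES or alt == ref:
                    continue
                rows.append((sample, var.CHROM, var.POS, ref, alt,
                             np.nan if vaf is None else float(vaf)))
    finally:
        vcf.close()
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def read_vcf_cohort(paths: Iterable[str | os.PathLike]) -> pd.DataFrame:
    frames = [read_vcf(p) for p in paths]
    if not frames:
        return pd.DataFrame(columns=RECORD_COLUMNS)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# BED (0-based half-open)

def read_bed(path: str | os.PathLike, label_column: bool = True) -> pd.DataFrame:
    """Read a BED file; columns chrom/start/end plus optional label."""
    names = ["chrom", "start", "end"] + (["label"] if label_column else [])
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=range(len(names)), names=names,
                     float_precision="round_trip")
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    if (df["end"] <= df["start"]).any():
        raise ValueError(f"BED with non-positive interval length: {path}")
    return df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def write_bed(intervals: pd.DataFrame, path: str | os.PathLike) -> None:
    cols = [c for c in ("chrom", "start", "end", "label", "name")
            if c in intervals.columns]
    intervals[cols].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# 96-row matrices (context counts, signature catalogs, exposures)

def _roundtrip_float(v: float) -> str:
    """Shortest decimal string that parses back to the same double."""
    return repr(float(v))


def write_matrix(matrix: pd.DataFrame, path: str | os.PathLike) -> None:
    matrix.to_csv(path, sep="\t", index=True, index_label="Type",
                  float_format=_roundtrip_float)


def read_context_matrix(path: str | os.PathLike) -> pd.DataFrame:
    df = read_catalog(path, normalize=False)
    return df


def read_catalog(path: str | os.PathLike, normalize: bool = True) -> pd.DataFrame:
    """Read a 96-row table keyed by canonical category labels.

    Accepts the COSMIC v3.2 SBS TSV layout (``Type`` column with labels
    like ``A[C>A]A``) or any TSV with those labels in the first column;
    rows are reordered into the canonical order and a header check
    rejects tables that do not cover all 96 categories exactly once.
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    df = df.set_index(df.columns[0])
    labels = list(df.index)
    if sorted(labels) != sorted(CATEGORY_LABELS):
        missing = set(CATEGORY_LABELS) - set(labels)
        raise ValueError(
            f"table at {path} is not a 96-category SBS table; "
            f"missing/unknown labels (showing up to 5): {sorted(missing)[:5]}")
    order = np.argsort([label_to_index(l) for l in labels])
    df = df.iloc[order]
    df.index.name = "Type"
    if normalize:
        sums = df.sum(axis=0)
        if (sums <= 0).any():
            raise ValueError(f"catalog at {path} has a non-positive column")
        df = df / sums
    return df


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def write_table(df: pd.DataFrame, path: str | os.PathLike,
                index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_roundtrip_float)
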