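"""Trinucleotide-context classification and mutation-burden summaries.

Every somatic SNV is classified into one of the 96 pyrimidine-normalized
trinucleotide categories: when the reference base is a purine, the
substitution and both flanking bases are complemented and the flanks
swap sides, so each mutated base pair is counted exactly once regardless
of the strand the caller reported.  Records whose context cannot be
extracted (contig edge, ambiguous base) are skipped and tallied, never
silently dropped; a reference-base mismatch is treated as corrupt input
and raised.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .categories import (CATEGORY_LABELS, ContextCategory, SUBSTITUTIONS,
                         encode_sequence, normalize_substitution)
from .errors import DataIntegrityError
from .intervals import covered_mask


@dataclass
class SkipTally:
    """Counts of records excluded from classification, by reason."""

    edge: int = 0
    ambiguous: int = 0

    @property
    def total(self) -> int:
        return self.edge + self.ambiguous

    def __add__(self, other: "SkipTally") -> "SkipTally":
        return SkipTally(self.edge + other.edge, self.ambiguous + other.ambiguous)


def classify_context(record, genome: Mapping[str, str]) -> ContextCategory | None:
    """Classify one SNV; None if the context is unavailable (edge / N).

    Raises :class:`DataIntegrityError` when the genome base at the
    record's position disagrees with the record's REF allele.
    """
    seq = genome[record.chrom]
    pos0 = record.pos - 1
    if pos0 < 1 or pos0 >= len(seq) - 1:
        return None
    ref_genome = seq[pos0].upper()
    if ref_genome != record.ref:
        raise DataIntegrityError(
            f"sample {record.sample}: genome has {ref_genome} at "
            f"{record.chrom}:{record.pos}, record says {record.ref}")
    f5, f3 = seq[pos0 - 1].upper(), seq[pos0 + 1].upper()
    if any(b not in "ACGT" for b in (f5, f3)):
        return None
    return normalize_substitution(record.ref, record.alt, f5, f3)


# substitution-class lookup in code space: row = pyrimidine ref code (C=1,T=3),
# col = alt code; -1 marks impossible (ref == alt)
_SUB_CODE = np.full((4, 4), -1, dtype=np.int64)
_SUB_CODE[1, 0], _SUB_CODE[1, 2], _SUB_CODE[1, 3] = 0, 1, 2   # C>A, C>G, C>T
_SUB_CODE[3, 0], _SUB_CODE[3, 1], _SUB_CODE[3, 2] = 3, 4, 5   # T>A, T>C, T>G


def classify_records(records: pd.DataFrame, genome: Mapping[str, str]
                     ) -> tuple[np.ndarray, SkipTally]:
    """Vectorized classification of a record table.

    Returns (category indices in [0, 96), -1 where skipped; tally of
    skipped records).
    """
    n = len(records)
    cats = np.full(n, -1, dtype=np.int64)
    tally = SkipTally()
    if n == 0:
        return cats, tally
    chroms = records["chrom"].to_numpy()
    pos0 = records["pos"].to_numpy(dtype=np.int64) - 1
    ref_codes = encode_sequence("".join(records["ref"]))
    alt_codes = encode_sequence("".join(records["alt"]))
    for chrom in pd.unique(chroms):
        seq = genome[chrom]
        codes = encode_sequence(seq)
        sel = np.flatnonzero(chroms == chrom)
        p = pos0[sel]
        inside = (p >= 1) & (p < len(seq) - 1)
        tally.edge += int((~inside).sum())
        sel, p = sel[inside], p[inside]
        c = codes[p]
        mism = c != ref_codes[sel]
        if mism.any():
            i = sel[mism][0]
            raise DataIntegrityError(
                f"sample {records['sample'].iloc[i]}: genome base at "
                f"{chrom}:{records['pos'].iloc[i]} is not {records['ref'].iloc[i]}")
        f5 = codes[p - 1]
        f3 = codes[p + 1]
        ok = (f5 >= 0) & (f3 >= 0)
        tally.ambiguous += int((~ok).sum())
        sel, c, f5, f3 = sel[ok], c[ok], f5[ok], f3[ok]
        alt = alt_codes[sel]
        purine = (c == 0) | (c == 2)
        c2 = np.where(purine, 3 - c, c)
        alt2 = np.where(purine, 3 - alt, alt)
        f5c, f3c = np.where(purine, 3 - f3, f5), np.where(purine, 3 - f5, f3)
        cats[sel] = _SUB_CODE[c2, alt2] * 16 + f5c * 4 + f3c
    return cats, tally


def build_context_matrix(records: pd.DataFrame, genome: Mapping[str, str],
                         regions: pd.DataFrame | None = None,
                         samples: list[str] | None = None
                         ) -> tuple[pd.DataFrame, SkipTally]:
    """Build the 96 x S count matrix over samples.

    ``regions``, when given, restricts counting to records overlapping
    the 0-based half-open intervals (e.g. IG loci for localized
    catalogs).  Columns follow ``samples`` when given, else the sorted
    distinct sample names.  An empty record set yields a valid all-zero
    matrix.
    """
    if samples is None:
        samples = sorted(records["sample"].unique())
    if regions is not None and len(records):
        inside = covered_mask(regions, records["chrom"].to_numpy(),
                              records["pos"].to_numpy(dtype=np.int64) - 1)
        records = records.loc[inside]
    cats, tally = classify_records(records, genome)
    counts = np.zeros((96, len(samples)), dtype=np.int64)
    col = {s: j for j, s in enumerate(samples)}
    keep = cats >= 0
    if keep.any():
        sample_idx = records["sample"].map(col).to_numpy(dtype=np.int64)[keep]
        np.add.at(counts, (cats[keep], sample_idx), 1)
    matrix = pd.DataFrame(counts, index=list(CATEGORY_LABELS), columns=samples)
    matrix.index.name = "Type"
    return matrix, tally


@dataclass
class SpectrumSummary:
    """Six-class substitution fractions with CpG and Ti/Tv breakdown."""

    fractions: pd.Series
    cpg_fraction_of_ct: float
    titv: float
    titv_infinite: bool = False
    total: int = 0


def substitution_spectrum(matrix: pd.DataFrame) -> SpectrumSummary:
    """Summarize a context matrix (or single column) into the six
    substitution-class fractions, the share of C>T at CpG sites, and the
    transition/transversion ratio (C>T + T>C over the four transversion
    classes)."""
    counts = matrix.to_numpy().sum(axis=1).astype(float)
    total = counts.sum()
    if total == 0:
        raise ValueError("empty context matrix: no classified mutations")
    by_sub = counts.reshape(6, 16).sum(axis=1)
    fractions = pd.Series(by_sub / total, index=list(SUBSTITUTIONS))
    ct = by_sub[2]
    # C>T rows 32..47; 3' flank G = offset 2 within each flank-4 block
    ct_cpg = counts[32:48].reshape(4, 4)[:, 2].sum()
    cpg_fraction = float(ct_cpg / ct) if ct > 0 else float("nan")
    transitions = by_sub[2] + by_sub[4]
    transversions = by_sub[0] + by_sub[1] + by_sub[3] + by_sub[5]
    if transversions == 0:
        return SpectrumSummary(fractions, cpg_fraction, float("inf"), True,
                               int(total))
    return SpectrumSummary(fractions, cpg_fraction,
                           float(transitions / transversions), False, int(total))


def summarize_burden(records: pd.DataFrame, target_size_mb: float,
                     groups: Mapping[str, str] | None = None
                     ) -> tuple[pd.DataFrame, dict | None]:
    """Per-sample mutation counts, rates per Mb and VAF summaries.

    ``target_size_mb`` is the size of the sequenced territory the rates
    are normalized to (for exomes, the capture-design size; it is an
    explicit parameter because it is a property of the assay, not of the
    VCF).  With a two-group ``groups`` mapping, counts are compared by a
    two-sided t-test and per-sample median VAFs by a two-sided rank-sum
    test.
    """
    if target_size_mb <= 0:
        raise ValueError("target_size_mb must be positive")
    per = records.groupby("sample").agg(
        n_mutations=("pos", "size"), median_vaf=("vaf", "median"))
    per["rate_per_mb"] = per["n_mutations"] / target_size_mb
    per = per.reset_index()
    if groups is not None:
        per["group"] = per["sample"].map(groups)
    tests = None
    if groups is not None:
        labels = sorted(set(groups.values()))
        if len(labels) == 2:
            a = per[per["group"] == labels[0]]
            b = per[per["group"] == labels[1]]
            t_stat, t_p = stats.ttest_ind(a["n_mutations"], b["n_mutations"])
            tests = {"groups": labels,
                     "count_t_stat": float(t_stat), "count_p": float(t_p)}
            if a["median_vaf"].notna().any() and b["median_vaf"].notna().any():
                z, p = stats.ranksums(a["median_vaf"].dropna(),
                                      b["median_vaf"].dropna())
                tests["vaf_ranksum_stat"] = float(z)
                tests["vaf_p"] = float(p)
    return per, tests
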