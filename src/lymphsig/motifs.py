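"""Tracing somatic mutations to AID target motifs.

Activation-induced cytidine deaminase (AID) prefers distinct sequence
contexts: canonical AID causes C>T/C>G changes inside WRCY motifs,
polymerase-eta-associated (non-canonical) AID causes A>C transversions
at WA dinucleotides, and a third pattern shows C>T transitions in RCG
motifs (IUPAC: W = A/T, R = A/G, Y = C/T).  Because AID deaminates
cytosine on either strand, every motif is matched on the plus strand and
on the reverse complement (e.g. WRCY on the minus strand appears as RGYW
on the plus strand with a mutated G).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from .categories import COMPLEMENT, reverse_complement

IUPAC = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"), "W": frozenset("AT"), "R": frozenset("AG"),
    "Y": frozenset("CT"), "N": frozenset("ACGT"),
}


@dataclass(frozen=True)
class MotifDefinition:
    """An AID motif: IUPAC pattern, index of the mutated base within it,
    and the substitutions AID is reported to cause at that base."""

    name: str
    pattern: str
    mutated_offset: int
    allowed_substitutions: frozenset[str]

    def __post_init__(self):
        if any(ch not in IUPAC for ch in self.pattern):
            raise ValueError(f"pattern {self.pattern!r} has non-IUPAC symbols")
        if not 0 <= self.mutated_offset < len(self.pattern):
            raise ValueError("mutated_offset outside pattern")


# The substitution sets follow the reported AID chemistry: C>T/C>G at
# WRCY, A>C at WA, C>T at RCG; all are user-overridable.
DEFAULT_MOTIFS: tuple[MotifDefinition, ...] = (
    MotifDefinition("WRCY", "WRCY", 2, frozenset({"C>T", "C>G"})),
    MotifDefinition("WA", "WA", 1, frozenset({"A>C"})),
    MotifDefinition("RCG", "RCG", 1, frozenset({"C>T"})),
)

DEFAULT_PRIORITY: tuple[str, ...] = ("WRCY", "RCG", "WA")


def motifs_from_config(entries: Iterable[Mapping]) -> tuple[MotifDefinition, ...]:
    """Build motif definitions from config dicts
    (name/pattern/mutated_offset/allowed_substitutions)."""
    return tuple(
        MotifDefinition(e["name"], e["pattern"], int(e["mutated_offset"]),
                        frozenset(e["allowed_substitutions"]))
        for e in entries)


def _window_matches(window: str, pattern: str) -> bool:
    return len(window) == len(pattern) and all(
        b in IUPAC[p] for b, p in zip(window, pattern))


def match_motif(record, genome: Mapping[str, str],
                motif: MotifDefinition) -> bool:
    """True iff the record's substitution sits in the motif on either
    strand.  Windows running off the contig edge do not match."""
    seq = genome[record.chrom]
    pos0 = record.pos - 1
    L = len(motif.pattern)
    off = motif.mutated_offset

    # plus strand: pattern laid 5'->3' with the mutated base at `off`
    start = pos0 - off
    if 0 <= start and start + L <= len(seq):
        window = seq[start:start + L].upper()
        if (f"{record.ref}>{record.alt}" in motif.allowed_substitutions
                and _window_matches(window, motif.pattern)):
            return True

    # minus strand: the motif on the reverse complement; the mutated base
    # of the pattern aligns to pos0, so the plus-strand window extends
    # `off` bases 3' and L-1-off bases 5' of it
    start = pos0 - (L - 1 - off)
    if 0 <= start and start + L <= len(seq):
        window = reverse_complement(seq[start:start + L].upper())
        sub = f"{COMPLEMENT[record.ref]}>{COMPLEMENT[record.alt]}"
        if (sub in motif.allowed_substitutions
                and _window_matches(window, motif.pattern)):
            return True
    return False


@dataclass
class MotifCallSummary:
    """Cohort-level motif attribution in both counting modes.

    In *exclusive* mode each mutation is assigned to at most one motif by
    a fixed priority, so per-motif fractions sum to the combined
    fraction; in *overlapping* mode a mutation counts once per motif it
    matches.
    """

    total: int
    exclusive_counts: dict = field(default_factory=dict)
    overlapping_counts: dict = field(default_factory=dict)
    priority: tuple[str, ...] = DEFAULT_PRIORITY

    @property
    def exclusive_fractions(self) -> dict:
        return {k: v / self.total for k, v in self.exclusive_counts.items()}

    @property
    def overlapping_fractions(self) -> dict:
        return {k: v / self.total for k, v in self.overlapping_counts.items()}

    @property
    def combined_count(self) -> int:
        return sum(self.exclusive_counts.values())

    @property
    def combined_fraction(self) -> float:
        return self.combined_count / self.total


def trace_cohort(records: pd.DataFrame, genome: Mapping[str, str],
                 motifs: tuple[MotifDefinition, ...] = DEFAULT_MOTIFS,
                 priority: tuple[str, ...] = DEFAULT_PRIORITY
                 ) -> MotifCallSummary:
    """Match every record against every motif and summarize the cohort."""
    if len(records) == 0:
        raise ValueError("empty cohort")
    by_name = {m.name: m for m in motifs}
    order = [by_name[n] for n in priority if n in by_name]
    order += [m for m in motifs if m.name not in priority]
    exclusive = {m.name: 0 for m in motifs}
    overlapping = {m.name: 0 for m in motifs}
    for rec in records.itertuples(index=False):
        matches = [m.name for m in order if match_motif(rec, genome, m)]
        for name in matches:
            overlapping[name] += 1
        if matches:
            exclusive[matches[0]] += 1
    return MotifCallSummary(len(records), exclusive, overlapping,
                            tuple(m.name for m in order))


def compare_cohorts_chi2(summary_a: MotifCallSummary,
                         summary_b: MotifCallSummary,
                         correction: bool = False) -> tuple[float, float]:
    """Pearson chi-squared on the 2x2 motif/non-motif x cohort table."""
    table = [
        [summary_a.combined_count, summary_a.total - summary_a.combined_count],
        [summary_b.combined_count, summary_b.total - summary_b.combined_count],
    ]
    col_sums = [table[0][0] + table[1][0], table[0][1] + table[1][1]]
    if 0 in col_sums or summary_a.total == 0 or summary_b.total == 0:
        raise ValueError("a margin of the 2x2 table is zero; "
                         "use Fisher's exact test instead")
    stat, p, _, _ = stats.chi2_contingency(table, correction=correction)
    return float(stat), float(p)
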