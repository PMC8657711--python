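"""DNA-repair pathway mutation prevalence analysis.

Variants are mapped onto repair-gene intervals, each sample is flagged
per pathway (BER, MMR, FA, DDR by default) when it carries at least one
variant in a member gene, and pathway prevalence is compared between two
cohorts with a two-sided Fisher exact test (point-probability rule,
computed by exact hypergeometric enumeration) under Benjamini-Hochberg
correction across pathways.  Somatic novelty filtering (germline or
prior-biopsy subtraction) is assumed done upstream; an optional
exclusion list of prior variants is honoured.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import overlapping_hits

DEFAULT_PATHWAYS = ("BER", "MMR", "FA", "DDR")


@dataclass
class PathwayCatalog:
    """Gene intervals plus gene -> pathway memberships."""

    genes: pd.DataFrame        # chrom, start, end, name (0-based half-open)
    membership: pd.DataFrame   # gene, pathway

    def __post_init__(self):
        self.genes = self.genes.sort_values(
            ["chrom", "start"], kind="mergesort").reset_index(drop=True)
        if len(self.membership) == 0:
            raise ValueError("pathway membership table is empty")
        counts = self.membership.groupby("pathway").size()
        empty = [p for p in self.pathways if counts.get(p, 0) == 0]
        if empty:
            raise ValueError(f"pathways without genes: {empty}")
        if (self.genes["end"] <= self.genes["start"]).any():
            raise ValueError("gene intervals must be half-open with end > start")

    @property
    def pathways(self) -> list[str]:
        return sorted(self.membership["pathway"].unique())

    def pathways_of(self, gene: str) -> list[str]:
        return list(self.membership.loc[
            self.membership["gene"] == gene, "pathway"])


def map_variants_to_genes(records: pd.DataFrame, catalog: PathwayCatalog,
                          exclude: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-variant gene hits by interval overlap.

    A variant inside several (possibly overlapping) genes yields one row
    per gene; unmapped variants yield no rows.  ``exclude`` (same record
    schema) drops previously observed variants before mapping.
    """
    if exclude is not None and len(exclude):
        key = records[["chrom", "pos", "ref", "alt"]].apply(tuple, axis=1)
        bad = set(exclude[["chrom", "pos", "ref", "alt"]].apply(tuple, axis=1))
        records = records[~key.isin(bad)]
    rows = []
    genes = catalog.genes
    for rec in records.itertuples(index=False):
        for row_idx in overlapping_hits(genes, rec.chrom, rec.pos - 1):
            rows.append({"sample": rec.sample, "chrom": rec.chrom,
                         "pos": rec.pos, "gene": genes.loc[row_idx, "name"]})
    return pd.DataFrame(rows, columns=["sample", "chrom", "pos", "gene"])


def build_pathway_table(hits: pd.DataFrame, catalog: PathwayCatalog,
                        samples: list[str]) -> pd.DataFrame:
    """Sample x pathway variant counts and mutated flags.

    A gene belonging to several pathways increments each of them.
    Returns a tidy table indexed by sample with ``<pathway>_count`` and
    ``<pathway>`` (boolean flag) columns.
    """
    pathways = catalog.pathways
    counts = pd.DataFrame(0, index=samples, columns=pathways, dtype=int)
    for hit in hits.itertuples(index=False):
        for pw in catalog.pathways_of(hit.gene):
            counts.loc[hit.sample, pw] += 1
    out = pd.DataFrame(index=pd.Index(samples, name="sample"))
    for pw in pathways:
        out[f"{pw}_count"] = counts[pw]
        out[pw] = counts[pw] >= 1
    return out


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher exact test on [[a, b], [c, d]].

    The p-value follows the point-probability rule: the sum of the
    probabilities of all tables with the same margins whose probability
    does not exceed the observed table's.  Computed by enumerating the
    hypergeometric support, which is exact for any desk-scale margins.
    The odds ratio uses the Haldane-Anscombe 0.5 correction only when a
    zero cell would otherwise make it undefined.
    """
    n = a + b + c + d
    row1, col1 = a + b, a + c
    kmin = max(0, row1 + col1 - n)
    kmax = min(row1, col1)
    support = np.arange(kmin, kmax + 1)
    pmf = stats.hypergeom.pmf(support, n, col1, row1)
    p_obs = pmf[support == a][0]
    p = float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())
    p = min(1.0, p)
    if 0 in (a, b, c, d):
        a2, b2, c2, d2 = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        a2, b2, c2, d2 = a, b, c, d
    return (a2 * d2) / (b2 * c2), p


def fisher_pathway_prevalence(table: pd.DataFrame, groups: dict[str, str]
                              ) -> pd.DataFrame:
    """Per-pathway prevalence comparison between two groups.

    ``table`` is the output of :func:`build_pathway_table`; ``groups``
    maps sample -> group label (exactly two labels).  Reports mutated /
    total counts per group, odds ratio, raw two-sided Fisher p and its
    Benjamini-Hochberg adjustment across pathways.
    """
    labels = sorted(set(groups.values()))
    if len(labels) != 2:
        raise ValueError("exactly two groups are required")
    g = pd.Series({s: groups[s] for s in table.index})
    sizes = g.value_counts()
    if (sizes.reindex(labels).fillna(0) == 0).any():
        raise ValueError("a group has zero samples")
    pathways = [c for c in table.columns if not c.endswith("_count")]
    rows = []
    for pw in pathways:
        flags = table[pw]
        a = int((flags & (g == labels[0])).sum())     # mutated, group 1
        b = int((~flags & (g == labels[0])).sum())
        c = int((flags & (g == labels[1])).sum())
        d = int((~flags & (g == labels[1])).sum())
        oddsratio, p = fisher_exact_2x2(a, b, c, d)
        rows.append({"pathway": pw,
                     f"mutated_{labels[0]}": a, f"total_{labels[0]}": a + b,
                     f"mutated_{labels[1]}": c, f"total_{labels[1]}": c + d,
                     "odds_ratio": float(oddsratio), "p_raw": p})
    out = pd.DataFrame(rows)
    out["p_bh"] = multipletests(out["p_raw"], method="fdr_bh")[1]
    return out


def upset_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Counts of samples per non-empty pathway combination.

    Each sample contributes to exactly one combination (the set of all
    pathways it is flagged in), so the counts sum to the number of
    samples with at least one flag.
    """
    pathways = [c for c in table.columns if not c.endswith("_count")]
    combos: dict[tuple[str, ...], int] = {}
    for _, row in table[pathways].iterrows():
        combo = tuple(pw for pw in pathways if row[pw])
        if combo:
            combos[combo] = combos.get(combo, 0) + 1
    rows = [{"combination": "+".join(combo), "n_pathways": len(combo),
             "count": count}
            for combo, count in sorted(combos.items(),
                                       key=lambda kv: (-kv[1], kv[0]))]
    return pd.DataFrame(rows, columns=["combination", "n_pathways", "count"])
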