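"""Self-contained synthetic cohort generator.

Emulates the statistical structure the downstream analysis assumes: two
disease-like cohorts (FL-like and CLL-like) with group-specific signature
exposures, compartment-differential activity in one group (injected as a
log-odds shift of the exposure vector between the A and B compartments),
AID-motif-concentrated signature activity, and planted DNA-repair-pathway
mutations with differential prevalence.  Everything is generated from one
seed: genome (FASTA), per-sample somatic SNVs (VCF v4.2), an A/B
compartment track and gene intervals (BED), a signature catalog and truth
tables (TSV).

Mutations are placed by (i) sampling a compartment by territory share,
(ii) sampling a signature from the compartment-adjusted exposures,
(iii) sampling one of the 96 categories from that signature, and
(iv) drawing a genomic site whose reference context matches the category,
with the mutated strand chosen uniformly.  Repair-gene territory is
reserved for planted pathway variants so pathway flags are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .categories import CATEGORY_LABELS, category_from_index, encode_sequence
from .errors import ConfigurationError
from .intervals import assign_nonoverlapping

_BASES = np.array(list("ACGT"))

PRESET_NAMES = (
    "spontaneous-deamination-like",
    "flat-like",
    "canonical-AID-like",
    "noncanonical-AID-like",
    "MMR-failure-like",
)


# ---------------------------------------------------------------------------
# Configuration


def _default_groups() -> dict:
    return {"FL-like": 33, "CLL-like": 30}


def _default_exposures() -> dict:
    # the three processes the cohorts share: AID activity, spontaneous
    # deamination, and failing DNA repair; concentrated spectra keep the
    # mixture identifiable at desk scale (a near-flat signature is not
    # reliably extractable from ~230 mutations/sample)
    return {
        "FL-like": {"canonical-AID-like": 0.45,
                    "spontaneous-deamination-like": 0.25,
                    "MMR-failure-like": 0.30},
        "CLL-like": {"canonical-AID-like": 0.10,
                     "spontaneous-deamination-like": 0.30,
                     "MMR-failure-like": 0.60},
    }


def _default_shift() -> dict:
    # FL-like canonical-AID activity enriched in the active compartment
    return {"FL-like": {"canonical-AID-like": 1.0}, "CLL-like": {}}


def _default_prevalence() -> dict:
    return {
        "FL-like": {"BER": 0.30, "MMR": 0.10, "FA": 0.36, "DDR": 0.20},
        "CLL-like": {"BER": 0.03, "MMR": 0.10, "FA": 0.10, "DDR": 0.33},
    }


def _default_vaf() -> dict:
    return {"FL-like": (7.0, 13.0), "CLL-like": (9.0, 11.0)}


@dataclass
class SyntheticConfig:
    """Study conditions of the synthetic cohort.

    Defaults reproduce the desk-scale design used throughout the test
    suite: 33 + 30 samples, ~230 mutations each (negative binomial),
    three well-separated generating signatures, a +1 log-odds shift of
    canonical-AID exposure toward compartment A in the FL-like group, and
    BER prevalence 0.30 vs 0.03.
    """

    n_samples_per_group: dict = field(default_factory=_default_groups)
    mutations_per_sample: float = 230.0
    mutation_dispersion: float | None = 20.0   # NB size; None = fixed count
    group_exposures: dict = field(default_factory=_default_exposures)
    compartment_shift: dict = field(default_factory=_default_shift)
    contig_lengths: list = field(default_factory=lambda: [150_000, 150_000])
    contig_names: list | None = None
    a_fraction: float = 0.5
    compartment_tile: int = 10_000
    gc_content: float = 0.45
    pathway_prevalence: dict = field(default_factory=_default_prevalence)
    vaf_beta: dict = field(default_factory=_default_vaf)
    exposure_concentration: float = 50.0
    seed: int = 0

    def __post_init__(self):
        if not self.contig_lengths or any(l < 1000 for l in self.contig_lengths):
            raise ConfigurationError("every contig must be at least 1000 bp")
        if not 0 < self.a_fraction < 1:
            raise ConfigurationError("a_fraction must lie in (0, 1)")
        if not 0 < self.gc_content < 1:
            raise ConfigurationError("gc_content must lie in (0, 1)")
        for group, expo in self.group_exposures.items():
            w = np.array(list(expo.values()), dtype=float)
            if (w < 0).any() or abs(w.sum() - 1) > 1e-9:
                raise ConfigurationError(
                    f"exposures of group {group} must be a probability vector")
        for group, per in self.pathway_prevalence.items():
            for pw, p in per.items():
                if not 0 <= p <= 1:
                    raise ConfigurationError(
                        f"prevalence of {pw} in {group} outside [0, 1]")
        if self.contig_names is None:
            self.contig_names = [f"chr{i + 1}"
                                 for i in range(len(self.contig_lengths))]

    @property
    def groups(self) -> list:
        return list(self.n_samples_per_group)

    @property
    def sample_names(self) -> list:
        names = []
        for group, n in self.n_samples_per_group.items():
            tag = "".join(ch for ch in group if ch.isalnum())[:3].upper()
            names += [f"{tag}{i + 1:03d}" for i in range(n)]
        return names

    @property
    def sample_groups(self) -> dict:
        out = {}
        for group, n in self.n_samples_per_group.items():
            tag = "".join(ch for ch in group if ch.isalnum())[:3].upper()
            for i in range(n):
                out[f"{tag}{i + 1:03d}"] = group
        return out


# ---------------------------------------------------------------------------
# Genome and compartment track


def generate_genome(config: SyntheticConfig,
                    rng: np.random.Generator | None = None) -> dict[str, str]:
    """Random i.i.d. genome with the configured GC content.

    Independent sampling realizes every trinucleotide, so each of the 96
    categories has sites to mutate.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    gc = config.gc_content
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    genome = {}
    for name, length in zip(config.contig_names, config.contig_lengths):
        codes = rng.choice(4, size=length, p=probs)
        genome[name] = "".join(_BASES[codes])
    return genome


def generate_compartment_track(config: SyntheticConfig,
                               genome: Mapping[str, str]) -> pd.DataFrame:
    """Deterministic alternating A/B tiling with A share ~ a_fraction.

    Tiles of ``compartment_tile`` bp are labeled by a Bresenham-style
    allocation so the A share converges to ``a_fraction``; adjacent
    equal-label tiles merge.  The tiles partition each contig exactly.
    """
    a = config.a_fraction
    rows = []
    for name in config.contig_names:
        length = len(genome[name])
        n_tiles = max(1, length // config.compartment_tile)
        bounds = [i * config.compartment_tile for i in range(n_tiles)] + [length]
        labels = ["A" if int((i + 1) * a) > int(i * a) else "B"
                  for i in range(n_tiles)]
        start = bounds[0]
        for i in range(n_tiles):
            if i + 1 < n_tiles and labels[i + 1] == labels[i]:
                continue
            rows.append({"chrom": name, "start": start,
                         "end": bounds[i + 1], "label": labels[i]})
            start = bounds[i + 1]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])


def generate_ig_regions(config: SyntheticConfig) -> pd.DataFrame:
    """An arbitrary interval set standing in for the IG loci, used by the
    localized (region-restricted) catalog builders."""
    name = config.contig_names[0]
    length = config.contig_lengths[0]
    start = length // 4
    return pd.DataFrame([{"chrom": name, "start": start,
                          "end": start + max(10_000, length // 10),
                          "label": "IG"}])


# ---------------------------------------------------------------------------
# Signature presets


def _preset_vector(core: dict[int, float], background: float) -> np.ndarray:
    v = np.full(96, background / (96 - len(core)))
    for idx, mass in core.items():
        v[idx] = mass
    return v / v.sum()


def _cat_indices(subs, five, three) -> list[int]:
    from .categories import category_index
    return [category_index(s, f5, f3) for s in subs for f5 in five
            for f3 in three]


def generate_signature_set(kind: str = "presets") -> pd.DataFrame:
    """The five named preset signatures as a 96 x 5 column-stochastic
    table (also the bundled stand-in reference catalog for tests).

    Presets: spontaneous deamination (CpG C>T), near-flat, canonical AID
    (C>T/C>G at WRC with a pyrimidine 3' flank), non-canonical AID
    (T>G/T>C followed by A/T, i.e. WA on the purine strand), and
    MMR-failure-like (non-CpG C>T with pyrimidine 5' flank).  Distinct
    presets have pairwise cosine similarity < 0.8.
    """
    if kind != "presets":
        raise ValueError(
            f"unknown preset set {kind!r}; valid: 'presets' "
            f"(signatures {PRESET_NAMES})")
    cols = {}
    idx = _cat_indices(["C>T"], "ACGT", "G")
    cols["spontaneous-deamination-like"] = _preset_vector(
        {i: 0.85 / len(idx) for i in idx}, 0.15)
    cols["flat-like"] = np.full(96, 1 / 96)
    idx = _cat_indices(["C>T", "C>G"], "AG", "CT")
    cols["canonical-AID-like"] = _preset_vector(
        {i: 0.80 / len(idx) for i in idx}, 0.20)
    core = {i: 0.60 / 8 for i in _cat_indices(["T>G"], "ACGT", "AT")}
    core.update({i: 0.20 / 8 for i in _cat_indices(["T>C"], "ACGT", "AT")})
    cols["noncanonical-AID-like"] = _preset_vector(core, 0.20)
    idx = _cat_indices(["C>T"], "CT", "ACT")
    cols["MMR-failure-like"] = _preset_vector(
        {i: 0.80 / len(idx) for i in idx}, 0.20)
    df = pd.DataFrame(cols, index=list(CATEGORY_LABELS))
    df.index.name = "Type"
    return df


# ---------------------------------------------------------------------------
# Site index: genomic positions by (compartment, normalized context)


class SiteIndex:
    """Positions grouped by compartment label and pyrimidine-normalized
    trinucleotide context (32 classes: center C/T x 16 flank pairs),
    split by which strand carries the pyrimidine."""

    def __init__(self, genome: Mapping[str, str], track: pd.DataFrame,
                 exclude: pd.DataFrame | None = None):
        self.contigs = list(genome)
        buckets: dict[tuple, list] = {}
        for ci, name in enumerate(self.contigs):
            codes = encode_sequence(genome[name])
            n = len(codes)
            if n < 3:
                continue
            pos0 = np.arange(1, n - 1)
            c = codes[1:-1]
            f5, f3 = codes[:-2], codes[2:]
            valid = (c >= 0) & (f5 >= 0) & (f3 >= 0)
            purine = (c == 0) | (c == 2)
            cn = np.where(purine, 3 - c, c)
            f5n = np.where(purine, 3 - f3, f5)
            f3n = np.where(purine, 3 - f5, f3)
            ctx = (cn == 3).astype(np.int64) * 16 + f5n * 4 + f3n
            chroms = np.full(n - 2, name, dtype=object)
            comp_rows = assign_nonoverlapping(track, chroms, pos0)
            labels = np.where(comp_rows >= 0,
                              track["label"].reindex(
                                  np.clip(comp_rows, 0, None)).to_numpy(),
                              "")
            if exclude is not None and len(exclude):
                from .intervals import covered_mask
                drop = covered_mask(exclude, chroms, pos0)
                valid &= ~drop
            for label in ("A", "B"):
                mask_lab = valid & (labels == label)
                for strand, smask in (("pyr", ~purine), ("pur", purine)):
                    m = mask_lab & smask
                    if not m.any():
                        continue
                    for ctx_id in np.unique(ctx[m]):
                        mm = m & (ctx == ctx_id)
                        key = (label, int(ctx_id), strand)
                        buckets.setdefault(key, []).append(
                            np.stack([np.full(mm.sum(), ci), pos0[mm]], axis=1))
        self._index = {k: np.concatenate(v) for k, v in buckets.items()}

    def sample_site(self, label: str, category_idx: int,
                    rng: np.random.Generator) -> tuple[str, int, str, str]:
        """Draw (chrom, 1-based pos, ref, alt) for a 96-category mutation
        within the given compartment, strand chosen uniformly."""
        cat = category_from_index(category_idx)
        pyr, alt = cat.substitution.split(">")
        ctx_id = ((1 if pyr == "T" else 0) * 16
                  + "ACGT".index(cat.five_prime) * 4
                  + "ACGT".index(cat.three_prime))
        strand = "pyr" if rng.random() < 0.5 else "pur"
        sites = self._index.get((label, ctx_id, strand))
        if sites is None:
            strand = "pur" if strand == "pyr" else "pyr"
            sites = self._index.get((label, ctx_id, strand))
        if sites is None:
            raise ConfigurationError(
                f"no genomic site realizes category {cat.label} "
                f"in compartment {label}")
        ci, pos0 = sites[rng.integers(len(sites))]
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        if strand == "pyr":
            ref_out, alt_out = pyr, alt
        else:
            ref_out, alt_out = comp[pyr], comp[alt]
        return self.contigs[ci], int(pos0) + 1, ref_out, alt_out


# ---------------------------------------------------------------------------
# Cohort simulation


def _shifted_exposure(expo: np.ndarray, shift: np.ndarray, side: float
                      ) -> np.ndarray:
    """Apply half the log-odds shift toward one compartment and
    renormalize, so the full A-vs-B log-odds difference equals ``shift``."""
    w = expo * np.exp(side * shift / 2.0)
    return w / w.sum()


@dataclass
class SimulatedCohort:
    records: pd.DataFrame            # all samples, sorted
    sample_table: pd.DataFrame       # sample, group, n_mutations, exposures
    compartment_truth: pd.DataFrame  # sample x compartment expected exposures
    signature_names: list


def simulate_cohort(config: SyntheticConfig, genome: Mapping[str, str],
                    track: pd.DataFrame, signatures: pd.DataFrame,
                    rng: np.random.Generator | None = None,
                    site_index: SiteIndex | None = None) -> SimulatedCohort:
    """Draw per-sample somatic SNVs from the configured exposure mixture."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if site_index is None:
        site_index = SiteIndex(genome, track)
    signames = list(signatures.columns)
    sig_probs = {s: signatures[s].to_numpy(dtype=float) for s in signames}
    for group, expo in config.group_exposures.items():
        unknown = set(expo) - set(signames)
        if unknown:
            raise ConfigurationError(
                f"group {group} references unknown signatures {sorted(unknown)}")
    # compartment choice by analyzable territory share
    lengths = track.groupby("label").apply(
        lambda g: (g["end"] - g["start"]).sum(), include_groups=False)
    p_a = float(lengths.get("A", 0)) / float(lengths.sum())

    rec_rows, samp_rows, comp_rows = [], [], []
    for group, n_samples in config.n_samples_per_group.items():
        base = np.array([config.group_exposures[group].get(s, 0.0)
                         for s in signames])
        shift = np.array([config.compartment_shift.get(group, {}).get(s, 0.0)
                          for s in signames])
        tag = "".join(ch for ch in group if ch.isalnum())[:3].upper()
        va, vb = config.vaf_beta.get(group, (8.0, 12.0))
        for i in range(n_samples):
            sample = f"{tag}{i + 1:03d}"
            pos_mask = base > 0
            alpha = base[pos_mask] * config.exposure_concentration
            expo = np.zeros_like(base)
            expo[pos_mask] = rng.dirichlet(alpha)
            expo_by_comp = {
                "A": _shifted_exposure(expo, shift, +1.0),
                "B": _shifted_exposure(expo, shift, -1.0),
            }
            if config.mutation_dispersion is None:
                n_mut = int(round(config.mutations_per_sample))
            else:
                r = config.mutation_dispersion
                p = r / (r + config.mutations_per_sample)
                n_mut = int(rng.negative_binomial(r, p))
            taken = set()
            for _ in range(n_mut):
                comp = "A" if rng.random() < p_a else "B"
                sig = rng.choice(len(signames), p=expo_by_comp[comp])
                cat_idx = int(rng.choice(96, p=sig_probs[signames[sig]]))
                for attempt in range(1000):
                    chrom, pos, ref, alt = site_index.sample_site(
                        comp, cat_idx, rng)
                    if (chrom, pos) not in taken:
                        break
                else:
                    raise ConfigurationError(
                        f"could not place category "
                        f"{category_from_index(cat_idx).label} after 1000 tries")
                taken.add((chrom, pos))
                vaf = float(rng.beta(va, vb))
                rec_rows.append((sample, chrom, pos, ref, alt, vaf,
                                 comp, signames[sig],
                                 CATEGORY_LABELS[cat_idx]))
            samp_row = {"sample": sample, "group": group, "n_mutations": n_mut}
            samp_row.update({f"exposure_{s}": expo[j]
                             for j, s in enumerate(signames)})
            samp_rows.append(samp_row)
            for comp in ("A", "B"):
                row = {"sample": sample, "group": group, "compartment": comp}
                row.update({s: expo_by_comp[comp][j]
                            for j, s in enumerate(signames)})
                comp_rows.append(row)

    records = pd.DataFrame(rec_rows, columns=[
        "sample", "chrom", "pos", "ref", "alt", "vaf",
        "true_compartment", "true_signature", "true_category"])
    records = records.sort_values(["sample", "chrom", "pos"],
                                  kind="mergesort").reset_index(drop=True)
    return SimulatedCohort(records, pd.DataFrame(samp_rows),
                           pd.DataFrame(comp_rows), signames)


# ---------------------------------------------------------------------------
# Repair-pathway tables and planted mutations


_PATHWAY_GENES = {
    "BER": ["UNG", "POLE", "POLB", "XRCC1", "NEIL1", "OGG1"],
    "MMR": ["MSH2", "MSH6", "MLH1", "PMS2"],
    "FA": ["FANCD2", "FANCA", "FANCC", "FANCI", "BRCA2"],
    "DDR": ["TP53", "ATM", "HUS1", "CHEK2", "ATR"],
}

GENE_LENGTH = 2000


def generate_gene_intervals(config: SyntheticConfig) -> tuple[pd.DataFrame,
                                                              pd.DataFrame]:
    """Deterministic non-overlapping repair-gene intervals plus the
    pathway membership table."""
    genes = [(g, pw) for pw, gl in _PATHWAY_GENES.items() for g in gl]
    n = len(genes)
    rows, members = [], []
    per_contig = int(np.ceil(n / len(config.contig_names)))
    gi = 0
    for name, length in zip(config.contig_names, config.contig_lengths):
        spacing = length // (per_contig + 1)
        if spacing <= GENE_LENGTH:
            raise ConfigurationError("contigs too short for gene placement")
        for slot in range(per_contig):
            if gi >= n:
                break
            gene, pw = genes[gi]
            start = (slot + 1) * spacing
            rows.append({"chrom": name, "start": start,
                         "end": start + GENE_LENGTH, "name": gene})
            members.append({"gene": gene, "pathway": pw})
            gi += 1
    if gi < n:
        raise ConfigurationError("not enough contig space for all genes")
    return (pd.DataFrame(rows, columns=["chrom", "start", "end", "name"]),
            pd.DataFrame(members, columns=["gene", "pathway"]))


def plant_pathway_mutations(config: SyntheticConfig,
                            genome: Mapping[str, str],
                            genes: pd.DataFrame, membership: pd.DataFrame,
                            rng: np.random.Generator,
                            existing: pd.DataFrame | None = None
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plant >= 1 variant per flagged (sample, pathway) at the configured
    prevalence.  Returns (planted records, truth flag table)."""
    by_pathway = {pw: membership.loc[membership["pathway"] == pw, "gene"].tolist()
                  for pw in membership["pathway"].unique()}
    gene_rows = genes.set_index("name")
    taken = set()
    if existing is not None:
        taken |= set(zip(existing["sample"], existing["chrom"],
                         existing["pos"]))
    rec_rows, flag_rows = [], []
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for sample, group in config.sample_groups.items():
        prevs = config.pathway_prevalence.get(group, {})
        flags = {"sample": sample, "group": group}
        for pw in sorted(by_pathway):
            prev = prevs.get(pw, 0.0)
            hit = rng.random() < prev
            flags[pw] = bool(hit)
            if not hit:
                continue
            n_var = 1 + int(rng.integers(0, 2))
            for _ in range(n_var):
                gene = by_pathway[pw][rng.integers(len(by_pathway[pw]))]
                row = gene_rows.loc[gene]
                for _ in range(1000):
                    pos0 = int(rng.integers(row["start"], row["end"]))
                    key = (sample, row["chrom"], pos0 + 1)
                    ref = genome[row["chrom"]][pos0].upper()
                    if key not in taken and ref in "ACGT":
                        break
                else:
                    raise ConfigurationError(
                        f"could not place a variant in gene {gene}")
                taken.add(key)
                alts = [b for b in "ACGT" if b != ref]
                alt = alts[rng.integers(3)]
                rec_rows.append((sample, row["chrom"], pos0 + 1, ref, alt,
                                 float(rng.beta(8, 12)), "", "planted:" + pw,
                                 ""))
        flag_rows.append(flags)
    planted = pd.DataFrame(rec_rows, columns=[
        "sample", "chrom", "pos", "ref", "alt", "vaf",
        "true_compartment", "true_signature", "true_category"])
    return planted, pd.DataFrame(flag_rows)


# ---------------------------------------------------------------------------
# One-call generator


@dataclass
class CohortData:
    """Everything the pipeline consumes, plus the generating truth."""

    config: SyntheticConfig
    genome: dict
    track: pd.DataFrame
    signatures: pd.DataFrame
    ig_regions: pd.DataFrame
    records: pd.DataFrame
    sample_table: pd.DataFrame
    compartment_truth: pd.DataFrame
    pathway_genes: pd.DataFrame
    pathway_membership: pd.DataFrame
    pathway_flags: pd.DataFrame

    @property
    def sample_groups(self) -> dict:
        return dict(zip(self.sample_table["sample"], self.sample_table["group"]))


def generate_cohort(config: SyntheticConfig | None = None) -> CohortData:
    """Generate the full synthetic study from one seed."""
    if config is None:
        config = SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    genome_rng, cohort_rng, pathway_rng = rng.spawn(3)
    genome = generate_genome(config, genome_rng)
    track = generate_compartment_track(config, genome)
    signatures = generate_signature_set()
    used = sorted({s for e in config.group_exposures.values() for s in e})
    signatures_used = signatures[[c for c in signatures.columns if c in used]]
    genes, membership = generate_gene_intervals(config)
    index = SiteIndex(genome, track, exclude=genes)
    cohort = simulate_cohort(config, genome, track, signatures_used,
                             rng=cohort_rng, site_index=index)
    planted, flags = plant_pathway_mutations(
        config, genome, genes, membership, pathway_rng,
        existing=cohort.records)
    if len(planted):
        records = pd.concat([cohort.records, planted], ignore_index=True)
    else:
        records = cohort.records.copy()
    records = records.sort_values(["sample", "chrom", "pos"],
                                  kind="mergesort").reset_index(drop=True)
    return CohortData(config, genome, track, signatures_used,
                      generate_ig_regions(config), records,
                      cohort.sample_table, cohort.compartment_truth,
                      genes, membership, flags)


def write_cohort(data: CohortData, outdir) -> dict:
    """Persist a generated cohort as FASTA / per-sample VCF / BED / TSV.

    Returns a manifest of the written paths.  Outputs are byte-identical
    across runs with the same configuration and seed.
    """
    import os

    from . import io

    os.makedirs(outdir, exist_ok=True)
    manifest = {}
    fasta = os.path.join(outdir, "genome.fa")
    io.write_fasta(data.genome, fasta)
    manifest["genome"] = fasta
    contig_lengths = {n: len(s) for n, s in data.genome.items()}
    vcf_dir = os.path.join(outdir, "vcf")
    os.makedirs(vcf_dir, exist_ok=True)
    manifest["vcf"] = []
    plain = data.records[["sample", "chrom", "pos", "ref", "alt", "vaf"]]
    for sample in data.sample_table["sample"]:
        path = os.path.join(vcf_dir, f"{sample}.vcf")
        io.write_vcf(plain[plain["sample"] == sample], path, contig_lengths)
        manifest["vcf"].append(path)
    for key, df, name in (
            ("compartments", data.track, "compartments.bed"),
            ("ig_regions", data.ig_regions, "ig_regions.bed"),
            ("genes", data.pathway_genes, "repair_genes.bed")):
        path = os.path.join(outdir, name)
        io.write_bed(df, path)
        manifest[key] = path
    for key, df, name, index in (
            ("catalog", data.signatures, "signatures.tsv", True),
            ("sample_truth", data.sample_table, "truth_samples.tsv", False),
            ("compartment_truth", data.compartment_truth,
             "truth_compartments.tsv", False),
            ("pathway_membership", data.pathway_membership,
             "pathways.tsv", False),
            ("pathway_truth", data.pathway_flags,
             "truth_pathways.tsv", False)):
        path = os.path.join(outdir, name)
        if index:
            io.write_matrix(df, path)
        else:
            io.write_table(df, path)
        manifest[key] = path
    return manifest


def simulate_counts(signatures: pd.DataFrame, exposure: np.ndarray,
                    n_mutations: int, rng: np.random.Generator) -> np.ndarray:
    """Draw a 96-count vector from a signature mixture (multinomial).

    Count-level shortcut used for statistical tests that do not need
    genomic coordinates.
    """
    p = signatures.to_numpy(dtype=float) @ np.asarray(exposure, dtype=float)
    p = p / p.sum()
    return rng.multinomial(int(n_mutations), p)
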