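"""The synthetic cohort generator: genome, track, presets, simulation,
pathway planting, determinism and truth recovery."""

import hashlib
import os

import numpy as np
import pandas as pd
import pytest

import lymphsig as ls
from lymphsig.categories import CATEGORY_LABELS, category_index
from lymphsig.errors import ConfigurationError
from lymphsig.pathways import PathwayCatalog, build_pathway_table, \
    map_variants_to_genes
from lymphsig.synthetic import (SyntheticConfig, generate_cohort,
                                generate_compartment_track,
                                generate_gene_intervals, generate_genome,
                                generate_signature_set,
                                plant_pathway_mutations, simulate_cohort,
                                simulate_counts, write_cohort)


def _cfg(**kw):
    base = dict(n_samples_per_group={"g": 2}, mutations_per_sample=100,
                mutation_dispersion=None, contig_lengths=[10_000],
                compartment_tile=1_000, pathway_prevalence={},
                compartment_shift={},
                group_exposures={"g": {"flat-like": 1.0}})
    base.update(kw)
    return SyntheticConfig(**base)


def test_genome_length_alphabet_and_determinism(tmp_path):
    cfg = _cfg(seed=1)
    g1 = generate_genome(cfg)
    g2 = generate_genome(cfg)
    assert len(g1["chr1"]) == 10_000
    assert set(g1["chr1"]) <= set("ACGT")
    assert g1 == g2


def test_genome_gc_content_targeted():
    cfg = _cfg(contig_lengths=[100_000], gc_content=0.6, seed=2)
    g = generate_genome(cfg)
    gc = sum(b in "GC" for b in g["chr1"]) / 100_000
    assert abs(gc - 0.6) <= 0.02


def test_short_contig_rejected():
    with pytest.raises(ConfigurationError):
        _cfg(contig_lengths=[500])


def test_bad_a_fraction_rejected():
    with pytest.raises(ConfigurationError):
        _cfg(a_fraction=1.0)


def test_track_tiling_half_and_half():
    cfg = _cfg(a_fraction=0.5)
    genome = generate_genome(cfg)
    track = generate_compartment_track(cfg, genome)
    assert len(track) == 10                      # alternating, no merges
    a_len = (track.loc[track.label == "A", "end"]
             - track.loc[track.label == "A", "start"]).sum()
    assert a_len == 5_000


def test_track_partitions_contig_without_gaps():
    cfg = _cfg(a_fraction=0.7, contig_lengths=[25_500])
    genome = generate_genome(cfg)
    track = generate_compartment_track(cfg, genome)
    assert track["start"].iloc[0] == 0
    assert track["end"].iloc[-1] == 25_500
    for i in range(len(track) - 1):
        assert track["end"].iloc[i] == track["start"].iloc[i + 1]


def test_track_a_share_tracks_a_fraction():
    cfg = _cfg(a_fraction=0.9, contig_lengths=[100_000])
    genome = generate_genome(cfg)
    track = generate_compartment_track(cfg, genome)
    lengths = track.assign(w=track.end - track.start).groupby("label")["w"].sum()
    share = lengths["A"] / lengths.sum()
    assert 0.85 <= share <= 0.95


def test_presets_are_probability_vectors(presets):
    assert list(presets.index) == list(CATEGORY_LABELS)
    assert np.allclose(presets.sum(axis=0), 1.0, atol=1e-9)
    assert (presets.to_numpy() >= 0).all()


def test_flat_preset_is_near_uniform(presets):
    v = presets["flat-like"].to_numpy()
    assert (v >= 0.5 / 96).all() and (v <= 2.0 / 96).all()


def test_canonical_aid_preset_mass_on_wrc(presets):
    v = presets["canonical-AID-like"]
    mass = sum(v.iloc[category_index(sub, f5, f3)]
               for sub in ("C>T", "C>G") for f5 in "AG" for f3 in "ACGT")
    assert mass >= 0.70


def test_preset_pairwise_separation(presets):
    import itertools
    for a, b in itertools.combinations(presets.columns, 2):
        assert ls.cosine_similarity(presets[a].to_numpy(),
                                    presets[b].to_numpy()) < 0.8


def test_unknown_preset_kind_lists_valid():
    with pytest.raises(ValueError, match="flat-like"):
        generate_signature_set("other")


def test_fixed_count_simulation_and_unique_positions(presets):
    cfg = _cfg(seed=9)
    genome = generate_genome(cfg)
    track = generate_compartment_track(cfg, genome)
    cohort = simulate_cohort(cfg, genome, track, presets[["flat-like"]])
    sizes = cohort.records.groupby("sample").size()
    assert (sizes == 100).all()
    dup = cohort.records.groupby(["sample", "chrom", "pos"]).size()
    assert (dup == 1).all()
    # VCF invariants: 1-based positions inside the contig, ref != alt
    assert cohort.records["pos"].between(1, 10_000).all()
    assert (cohort.records["ref"] != cohort.records["alt"]).all()


def test_roundtrip_every_record_reclassifies_to_sampled_category(small_cohort):
    data = small_cohort
    recs = data.records[data.records["true_category"] != ""]
    cats, tally = ls.classify_records(recs, data.genome)
    idx = {lab: i for i, lab in enumerate(CATEGORY_LABELS)}
    truth = recs["true_category"].map(idx).to_numpy()
    assert tally.total == 0
    assert (cats == truth).all()


def test_single_signature_spectrum_cosine(presets):
    cfg = _cfg(seed=4, mutations_per_sample=1000,
               n_samples_per_group={"g": 1}, contig_lengths=[100_000],
               group_exposures={"g": {"canonical-AID-like": 1.0}})
    genome = generate_genome(cfg)
    track = generate_compartment_track(cfg, genome)
    cohort = simulate_cohort(cfg, genome, track,
                             presets[["canonical-AID-like"]])
    m, _ = ls.build_context_matrix(cohort.records, genome)
    assert ls.cosine_similarity(
        m.to_numpy().ravel(),
        presets["canonical-AID-like"].to_numpy()) >= 0.98


def test_exposure_recovery_within_five_points(presets):
    """Fitting the generating signatures to >= 1000-mutation samples
    recovers each true exposure within 0.05, averaged over 20
    replicates."""
    basis = presets[["canonical-AID-like", "spontaneous-deamination-like",
                     "MMR-failure-like"]]
    rng = np.random.default_rng(17)
    errs = []
    for _ in range(20):
        truth = rng.dirichlet([5, 5, 5])
        counts = simulate_counts(basis, truth, 1200, rng)
        matrix = pd.DataFrame({"s": counts}, index=list(CATEGORY_LABELS))
        expo, _, _ = ls.fit_exposures(matrix, basis, cutoff=0.0)
        errs.append(np.abs(expo["s"].to_numpy() - truth))
    assert np.mean(errs) <= 0.05


def test_pathway_prevalence_zero_plants_nothing():
    cfg = _cfg(seed=3, pathway_prevalence={"g": {"BER": 0.0, "MMR": 0.0,
                                                 "FA": 0.0, "DDR": 0.0}},
               contig_lengths=[60_000, 60_000])
    genome = generate_genome(cfg)
    genes, membership = generate_gene_intervals(cfg)
    planted, flags = plant_pathway_mutations(
        cfg, genome, genes, membership, np.random.default_rng(0))
    assert len(planted) == 0
    assert not flags[["BER", "MMR", "FA", "DDR"]].to_numpy().any()


def test_pathway_planting_matches_binomial_rate():
    """33 samples at prevalence 0.3: planted BER-flag count within 3
    standard deviations of Binomial(33, 0.3)."""
    cfg = SyntheticConfig(
        n_samples_per_group={"FL-like": 33}, mutations_per_sample=10,
        mutation_dispersion=None, contig_lengths=[100_000, 100_000],
        group_exposures={"FL-like": {"flat-like": 1.0}},
        compartment_shift={},
        pathway_prevalence={"FL-like": {"BER": 0.3}}, seed=21)
    genome = generate_genome(cfg)
    genes, membership = generate_gene_intervals(cfg)
    total = 0
    for rep in range(10):
        _, flags = plant_pathway_mutations(
            cfg, genome, genes, membership, np.random.default_rng(rep))
        total += int(flags["BER"].sum())
    mean, sd = 10 * 33 * 0.3, np.sqrt(10 * 33 * 0.3 * 0.7)
    assert abs(total - mean) <= 3 * sd


def test_planted_flags_roundtrip_through_pathway_analysis(small_cohort):
    """Truth flags equal the flags recomputed from the VCF records."""
    data = small_cohort
    catalog = PathwayCatalog(data.pathway_genes, data.pathway_membership)
    hits = map_variants_to_genes(data.records, catalog)
    samples = list(data.sample_table["sample"])
    table = build_pathway_table(hits, catalog, samples)
    truth = data.pathway_flags.set_index("sample")
    for pw in ("BER", "MMR", "FA", "DDR"):
        assert (table[pw] == truth.loc[samples, pw]).all()


def test_written_outputs_byte_identical_across_runs(tmp_path):
    cfg = _cfg(seed=13, pathway_prevalence={"g": {"BER": 0.5}},
               contig_lengths=[40_000, 40_000])

    def digest(outdir):
        data = generate_cohort(cfg)
        write_cohort(data, outdir)
        h = hashlib.sha256()
        for root, _, files in sorted(os.walk(outdir)):
            for f in sorted(files):
                h.update(f.encode())
                h.update(open(os.path.join(root, f), "rb").read())
        return h.hexdigest()

    assert digest(tmp_path / "a") == digest(tmp_path / "b")


def test_cohort_mutation_totals_match_truth_table(small_cohort):
    data = small_cohort
    truth = data.sample_table.set_index("sample")["n_mutations"]
    planted = data.records["true_signature"].str.startswith("planted")
    observed = data.records[~planted].groupby("sample").size()
    assert (observed == truth.loc[observed.index]).all()
    assert len(data.records) == truth.sum() + planted.sum()


def test_unknown_signature_in_exposures_rejected(presets):
    cfg = _cfg(group_exposures={"g": {"no-such-signature": 1.0}})
    genome = generate_genome(cfg)
    track = generate_compartment_track(cfg, genome)
    with pytest.raises(ConfigurationError, match="no-such-signature"):
        simulate_cohort(cfg, genome, track, presets)
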