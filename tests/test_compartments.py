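"""A/B compartment annotation, eigenvector calling and A-vs-B tests."""

import numpy as np
import pandas as pd
import pytest

import lymphsig as ls
from lymphsig.compartments import (annotate_variants,
                                   call_compartments_from_contacts,
                                   compare_compartments, fit_by_compartment)
from lymphsig.io import MutationRecord, records_to_frame


def _track(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])


def test_annotation_containment_and_boundary():
    track = _track([("c", 100, 200, "A"), ("c", 200, 300, "B")])
    recs = records_to_frame([
        MutationRecord("s", "c", 150, "A", "C"),   # inside [100,200)
        MutationRecord("s", "c", 200, "A", "C"),   # pos0=199 -> A
        MutationRecord("s", "c", 201, "A", "C"),   # pos0=200 -> B
        MutationRecord("s", "c", 301, "A", "C"),   # past the track
    ])
    out = annotate_variants(recs, track)
    assert list(out["compartment"]) == ["A", "A", "B", "unassigned"]


def test_annotation_unknown_contig_warns_unassigned():
    track = _track([("c", 0, 100, "A")])
    recs = records_to_frame([MutationRecord("s", "other", 5, "A", "C")])
    with pytest.warns(UserWarning, match="absent"):
        out = annotate_variants(recs, track)
    assert list(out["compartment"]) == ["unassigned"]


def test_annotation_matches_linear_scan_oracle(rng):
    rows = []
    pos = 0
    for i in range(30):
        gap = int(rng.integers(0, 50))
        length = int(rng.integers(10, 100))
        rows.append(("c", pos + gap, pos + gap + length,
                     "A" if rng.random() < 0.5 else "B"))
        pos += gap + length
    track = _track(rows)
    recs = records_to_frame([
        MutationRecord("s", "c", int(rng.integers(1, pos + 100)), "A", "C")
        for _ in range(300)])
    out = annotate_variants(recs, track)
    for _, rec in out.iterrows():
        expected = "unassigned"
        for r in rows:
            if r[1] <= rec["pos"] - 1 < r[2]:
                expected = r[3]
                break
        assert rec["compartment"] == expected


def test_partition_conservation(small_cohort):
    out = annotate_variants(small_cohort.records, small_cohort.track)
    counts = out.groupby(["sample", "compartment"]).size().unstack(fill_value=0)
    totals = out.groupby("sample").size()
    assert (counts.sum(axis=1) == totals).all()


def test_overlapping_track_rejected():
    track = _track([("c", 0, 100, "A"), ("c", 50, 150, "B")])
    recs = records_to_frame([MutationRecord("s", "c", 10, "A", "C")])
    with pytest.raises(ValueError, match="overlap"):
        annotate_variants(recs, track)


# ---------------------------------------------------------------------------
# Eigenvector caller


def _block_matrix(sizes, within=2.0, between=0.5, noise=0.0, seed=0):
    labels = np.concatenate([[i % 2] * s for i, s in enumerate(sizes)])
    n = len(labels)
    M = np.where(np.equal.outer(labels, labels), within, between)
    if noise:
        rng = np.random.default_rng(seed)
        E = rng.uniform(0, noise, size=(n, n))
        M = M + (E + E.T) / 2
    return M, labels


def test_eigenvector_recovers_two_blocks():
    M, labels = _block_matrix([10, 10], noise=0.05)
    orientation = (labels == 0).astype(float)   # block 0 is the active one
    track = call_compartments_from_contacts(M, 1000, orientation)
    # reconstruct per-bin labels
    out = np.empty(20, dtype=object)
    for r in track.itertuples():
        out[r.start // 1000: r.end // 1000] = r.label
    assert (out[labels == 0] == "A").all()
    assert (out[labels == 1] == "B").all()


@pytest.mark.parametrize("sizes", [(3, 3), (5, 3), (4, 7, 4), (3, 8, 3, 6)])
def test_eigenvector_block_recovery_any_sizes(sizes):
    """Alternating A/B blocks of any sizes >= 3 bins are recovered."""
    M, labels = _block_matrix(list(sizes), noise=0.02, seed=1)
    orientation = (labels == 0).astype(float)
    track = call_compartments_from_contacts(M, 10, orientation)
    out = np.empty(len(labels), dtype=object)
    for r in track.itertuples():
        out[r.start // 10: r.end // 10] = r.label
    assert (out == np.where(labels == 0, "A", "B")).all()


def test_eigenvector_degenerate_matrix_raises():
    with pytest.raises(ValueError):
        call_compartments_from_contacts(np.ones((10, 10)), 10, np.ones(10))


def test_eigenvector_rejects_asymmetric():
    M = np.ones((5, 5))
    M[0, 1] = 5
    with pytest.raises(ValueError, match="symmetric"):
        call_compartments_from_contacts(M, 10, np.ones(5))


def test_eigenvector_empty_bins_become_gaps():
    M, labels = _block_matrix([5, 5], noise=0.02)
    M[3, :] = 0
    M[:, 3] = 0
    orientation = (labels == 0).astype(float)
    with pytest.warns(UserWarning, match="empty"):
        track = call_compartments_from_contacts(M, 10, orientation)
    covered = sum(r.end - r.start for r in track.itertuples())
    assert covered == 90  # one 10-bp bin dropped


# ---------------------------------------------------------------------------
# Per-compartment fitting and testing


def test_all_mutations_in_one_compartment_flags_other(presets):
    genome = {"c": "ACGT" * 500}
    track = _track([("c", 0, 1000, "A"), ("c", 1000, 2000, "B")])
    recs = records_to_frame([
        MutationRecord("s1", "c", int(p), "A", "C")
        for p in np.arange(5, 900, 4)])
    basis = presets.iloc[:, :2]
    out = fit_by_compartment(recs, track, basis, genome)
    a = out[(out["sample"] == "s1") & (out["compartment"] == "A")].iloc[0]
    b = out[(out["sample"] == "s1") & (out["compartment"] == "B")].iloc[0]
    assert a["fitted"]
    assert not b["fitted"]
    assert b["n_mutations"] == 0


def test_no_shift_yields_small_mean_difference(presets):
    """Null simulation: without a planted compartment shift the mean
    per-signature |A - B| exposure difference stays <= 0.05 over 20
    seeds."""
    import lymphsig
    diffs = []
    for seed in range(20):
        cfg = lymphsig.SyntheticConfig(
            n_samples_per_group={"g": 6}, mutations_per_sample=400,
            mutation_dispersion=None, contig_lengths=[60_000],
            compartment_tile=5_000, compartment_shift={},
            pathway_prevalence={}, seed=300 + seed,
            group_exposures={"g": {"canonical-AID-like": 0.5,
                                   "spontaneous-deamination-like": 0.5}})
        data = lymphsig.generate_cohort(cfg)
        out = fit_by_compartment(data.records, data.track, data.signatures,
                                 data.genome)
        a = out[out["compartment"] == "A"].set_index("sample")
        b = out[out["compartment"] == "B"].set_index("sample")
        for sig in data.signatures.columns:
            diffs.append((a[sig] - b[sig]).mean())
    assert np.abs(np.mean(diffs)) <= 0.05
    assert np.mean(np.abs(diffs)) <= 0.05


def test_planted_shift_raises_a_exposure(small_cohort):
    """The default design plants a +1 log-odds canonical-AID shift toward
    compartment A in the FL-like group: the fitted A exposure exceeds the
    B exposure in >= 90% of fitted FL-like samples."""
    data = small_cohort
    out = fit_by_compartment(data.records, data.track, data.signatures,
                             data.genome)
    fl = {s for s, g in data.sample_groups.items() if g == "FL-like"}
    sub = out[out["sample"].isin(fl) & out["fitted"]]
    a = sub[sub["compartment"] == "A"].set_index("sample")
    b = sub[sub["compartment"] == "B"].set_index("sample")
    common = a.index.intersection(b.index)
    sig = "canonical-AID-like"
    frac = (a.loc[common, sig].to_numpy() >
            b.loc[common, sig].to_numpy()).mean()
    assert frac >= 0.9


def _per_comp_frame(a_expo, b_expo, signames):
    rows = []
    for i, (ea, eb) in enumerate(zip(a_expo, b_expo)):
        for comp, e in (("A", ea), ("B", eb)):
            row = {"sample": f"s{i}", "compartment": comp,
                   "n_mutations": 100, "fitted": True}
            row.update({sig: e[j] for j, sig in enumerate(signames)})
            rows.append(row)
    return pd.DataFrame(rows)


def test_identical_exposures_give_p_one():
    rng = np.random.default_rng(0)
    expo = rng.dirichlet([3, 3, 3], size=10)
    table = compare_compartments(_per_comp_frame(expo, expo, list("xyz")))
    assert (table["p_raw"] == 1.0).all()
    assert (table["p_bonferroni"] == 1.0).all()
    assert table["all_ties"].all()


def test_bonferroni_is_raw_times_m(rng):
    a = rng.dirichlet([3, 3, 3], size=12)
    b = rng.dirichlet([3, 3, 3], size=12)
    table = compare_compartments(_per_comp_frame(a, b, list("xyz")))
    m = len(table)
    for _, row in table.iterrows():
        assert row["p_bonferroni"] == pytest.approx(
            min(1.0, row["p_raw"] * m))


def test_relabeling_compartments_preserves_p(rng):
    a = rng.dirichlet([5, 3], size=10)
    b = rng.dirichlet([3, 5], size=10)
    t1 = compare_compartments(_per_comp_frame(a, b, list("xy")))
    t2 = compare_compartments(_per_comp_frame(b, a, list("xy")))
    assert np.allclose(t1["p_raw"], t2["p_raw"])


def test_too_few_paired_samples_raises():
    rng = np.random.default_rng(1)
    expo = rng.dirichlet([3, 3], size=4)
    with pytest.raises(ValueError, match="at least 6"):
        compare_compartments(_per_comp_frame(expo, expo, list("xy")))
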