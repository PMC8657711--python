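"""NMF extraction, NNLS matching and exposure fitting."""

import numpy as np
import pandas as pd
import pytest

import lymphsig as ls
from lymphsig.categories import CATEGORY_LABELS
from lymphsig.signatures import kl_nmf
from lymphsig.synthetic import simulate_counts


def test_cosine_closed_forms():
    u = np.zeros(96)
    u[0] = 1
    assert ls.cosine_similarity(u, u) == pytest.approx(1.0)
    v = np.zeros(96)
    v[1] = 1
    assert ls.cosine_similarity(u, v) == pytest.approx(0.0)
    w = np.zeros(96)
    w[0] = w[1] = 1
    assert ls.cosine_similarity(u, w) == pytest.approx(1 / np.sqrt(2))
    with pytest.raises(ValueError):
        ls.cosine_similarity(u, np.zeros(96))


def test_nmf_objective_non_increasing(rng):
    V = rng.poisson(5, size=(96, 10)).astype(float)
    _, _, _, trace = kl_nmf(V, 3, rng, max_iter=200, track_objective=True)
    diffs = np.diff(trace)
    assert (diffs <= 1e-9 * np.maximum(1, np.abs(trace[:-1]))).all()


def test_nnls_exact_cone_membership(presets):
    cat = presets
    s1 = cat.iloc[:, 0].to_numpy()
    entry = ls.nnls_decompose(s1, cat)
    assert entry.weights.iloc[0] == pytest.approx(1.0, abs=1e-9)
    assert entry.cosine == pytest.approx(1.0, abs=1e-9)
    assert entry.residual == pytest.approx(0.0, abs=1e-9)
    mix = 0.6 * cat.iloc[:, 0].to_numpy() + 0.4 * cat.iloc[:, 2].to_numpy()
    entry = ls.nnls_decompose(mix, cat)
    assert entry.weights.iloc[0] == pytest.approx(0.6, abs=1e-6)
    assert entry.weights.iloc[2] == pytest.approx(0.4, abs=1e-6)
    assert entry.cosine == pytest.approx(1.0, abs=1e-9)
    assert set(entry.retained.index) == {cat.columns[0], cat.columns[2]}


def test_nnls_flags_novel_signature(presets):
    """A probability vector far from the catalog cone is flagged novel
    (cosine < 0.85), mirroring the novelty call for unexplained
    germinal-center signatures."""
    novel = np.zeros(96)
    novel[48] = 1.0  # pure T>A peak; no preset concentrates there
    entry = ls.nnls_decompose(novel, presets)
    assert entry.cosine < 0.85
    assert not entry.matched


def test_fit_single_source_recovery(presets, rng):
    basis = presets.iloc[:, :3]
    counts = simulate_counts(basis, [0, 1, 0], 500, rng)
    matrix = pd.DataFrame({"s": counts}, index=list(CATEGORY_LABELS))
    expo, err, unfit = ls.fit_exposures(matrix, basis)
    assert expo.loc[basis.columns[1], "s"] == pytest.approx(1.0)
    assert not unfit


def test_fit_mixture_recovery_mae(presets, rng):
    """70/30 mixture at n=1000: mean absolute exposure error <= 0.05
    over 20 replicates."""
    basis = presets[["canonical-AID-like", "spontaneous-deamination-like"]]
    truth = np.array([0.7, 0.3])
    errs = []
    for _ in range(20):
        counts = simulate_counts(basis, truth, 1000, rng)
        matrix = pd.DataFrame({"s": counts}, index=list(CATEGORY_LABELS))
        expo, _, _ = ls.fit_exposures(matrix, basis)
        errs.append(np.abs(expo["s"].to_numpy() - truth).mean())
    assert np.mean(errs) <= 0.05


def test_fit_cutoff_zeroes_small_weights(presets):
    basis = presets.iloc[:, :3]
    p = 0.97 * basis.iloc[:, 0] + 0.03 * basis.iloc[:, 1]
    matrix = pd.DataFrame({"s": (p * 100000).round()},
                          index=list(CATEGORY_LABELS))
    expo, _, _ = ls.fit_exposures(matrix, basis, cutoff=0.06)
    assert expo.loc[basis.columns[1], "s"] == 0.0
    assert expo["s"].sum() == pytest.approx(1.0)


def test_fit_zero_sample_flagged(presets):
    matrix = pd.DataFrame({"s": np.zeros(96, dtype=int)},
                          index=list(CATEGORY_LABELS))
    expo, _, unfit = ls.fit_exposures(matrix, presets.iloc[:, :2])
    assert unfit == ["s"]
    assert (expo["s"] == 0).all()


def test_fit_agrees_with_simplex_grid_oracle(rng):
    """On a 6-channel toy with k=3, exhaustive grid search over the
    exposure simplex (step 0.01) reaches the same SSE within 1e-4."""
    B = np.array([[0.5, 0.1, 0.0],
                  [0.3, 0.1, 0.1],
                  [0.1, 0.4, 0.1],
                  [0.05, 0.2, 0.2],
                  [0.03, 0.1, 0.3],
                  [0.02, 0.1, 0.3]])
    basis = pd.DataFrame(B, columns=list("xyz"))
    for trial in range(3):
        w_true = rng.dirichlet([2, 2, 2])
        p = B @ w_true + rng.normal(0, 0.01, size=6)
        p = np.clip(p, 0, None)
        p = p / p.sum()
        matrix = pd.DataFrame({"s": (p * 10000).round()})
        expo, sse, _ = ls.fit_exposures(matrix, basis, cutoff=0.0)
        pn = matrix["s"].to_numpy() / matrix["s"].sum()
        best = np.inf
        grid = np.arange(0, 101)
        for i in grid:
            for j in range(0, 101 - i):
                w = np.array([i, j, 100 - i - j]) / 100
                r = pn - B @ w
                best = min(best, float(r @ r))
        assert sse["s"] <= best + 1e-4


def test_fit_scale_invariance(presets, rng):
    basis = presets.iloc[:, :3]
    counts = simulate_counts(basis, [0.5, 0.3, 0.2], 800, rng)
    m1 = pd.DataFrame({"s": counts}, index=list(CATEGORY_LABELS))
    m7 = pd.DataFrame({"s": counts * 7}, index=list(CATEGORY_LABELS))
    e1, _, _ = ls.fit_exposures(m1, basis)
    e7, _, _ = ls.fit_exposures(m7, basis)
    assert np.abs(e1.to_numpy() - e7.to_numpy()).max() <= 1e-3


def test_fit_column_permutation_equivariance(presets, rng):
    basis = presets.iloc[:, :3]
    cols = {f"s{i}": simulate_counts(basis, rng.dirichlet([3, 3, 3]),
                                     500, rng) for i in range(5)}
    matrix = pd.DataFrame(cols, index=list(CATEGORY_LABELS))
    perm = ["s3", "s0", "s4", "s2", "s1"]
    e1, _, _ = ls.fit_exposures(matrix, basis)
    e2, _, _ = ls.fit_exposures(matrix[perm], basis)
    assert np.allclose(e1[perm].to_numpy(), e2.to_numpy())


def test_reconstruct_spectrum_properties(presets, rng):
    basis = presets.iloc[:, :3]
    e = np.array([0.0, 1.0, 0.0])
    rec = ls.reconstruct_spectrum(basis, e, 500)
    assert np.allclose(rec, 500 * basis.iloc[:, 1].to_numpy())
    e = rng.dirichlet([1, 1, 1])
    rec = ls.reconstruct_spectrum(basis, e, 321)
    assert rec.sum() == pytest.approx(321, abs=1e-6)


def test_fitted_solution_beats_single_signature_fits(presets, rng):
    """Optimality spot-check: the fitted SSE never exceeds the SSE of the
    best single-signature reconstruction."""
    basis = presets.iloc[:, :3]
    counts = simulate_counts(basis, [0.5, 0.25, 0.25], 1000, rng)
    matrix = pd.DataFrame({"s": counts}, index=list(CATEGORY_LABELS))
    _, sse, _ = ls.fit_exposures(matrix, basis, cutoff=0.0)
    p = counts / counts.sum()
    singles = []
    for j in range(3):
        r = p - basis.iloc[:, j].to_numpy()
        singles.append(float(r @ r))
    assert sse["s"] <= min(singles) + 1e-12


def test_extract_identical_columns_selects_rank_one(presets, rng):
    """S identical columns: rank 1 is selected and the signature equals
    the common normalized spectrum."""
    spectrum = (0.5 * presets.iloc[:, 0] + 0.5 * presets.iloc[:, 2])
    col = (spectrum * 2000).round().astype(int)
    matrix = pd.DataFrame({f"s{i}": col for i in range(12)},
                          index=list(CATEGORY_LABELS))
    res = ls.extract_denovo(matrix, rank_range=range(1, 4), n_bootstrap=10,
                            n_restarts=2, seed=3)
    assert res.report.selected_rank == 1
    cos = ls.cosine_similarity(res.signatures.iloc[:, 0].to_numpy(),
                               spectrum.to_numpy())
    assert cos >= 0.999


def test_extract_recovers_two_well_separated_signatures(presets, rng):
    """Noiseless 2-signature mixture over 60 samples x 500 mutations:
    rank 2 selected, both signatures recovered at cosine >= 0.95."""
    basis = presets[["canonical-AID-like", "spontaneous-deamination-like"]]
    B = basis.to_numpy()
    cols = {}
    for i in range(60):
        w = np.array([i / 59, 1 - i / 59])
        cols[f"s{i}"] = np.round(500 * (B @ w)).astype(int)
    matrix = pd.DataFrame(cols, index=list(CATEGORY_LABELS))
    res = ls.extract_denovo(matrix, rank_range=range(1, 5), n_bootstrap=15,
                            n_restarts=2, seed=5)
    assert res.report.selected_rank == 2
    for c in res.signatures.columns:
        best = max(ls.cosine_similarity(res.signatures[c].to_numpy(),
                                        basis[t].to_numpy())
                   for t in basis.columns)
        assert best >= 0.95


def test_extract_rejects_degenerate_input():
    zero = pd.DataFrame(np.zeros((96, 5)), index=list(CATEGORY_LABELS))
    with pytest.raises(ValueError):
        ls.extract_denovo(zero)


def test_pairwise_nnls_restricts_to_best_pair(presets):
    """Exhaustive pairwise search finds the generating pair exactly when
    the signature is a two-component cone member."""
    mix = 0.7 * presets.iloc[:, 2] + 0.3 * presets.iloc[:, 4]
    entry = ls.nnls_decompose(mix.to_numpy(), presets, pairwise=True)
    support = entry.weights[entry.weights > 1e-9]
    assert set(support.index) == {presets.columns[2], presets.columns[4]}
    assert entry.cosine == pytest.approx(1.0, abs=1e-9)
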