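"""A/B chromatin-compartment annotation and compartment-stratified fitting.

Variants are labeled A (active/open chromatin) or B (inactive) by
interval containment against a compartment track (BED, 0-based
half-open).  When only a dense Hi-C contact matrix is available, a
classical eigenvector caller provides the track: observed/expected
normalization by diagonal distance, Pearson correlation matrix, leading
eigenvector, sign oriented by an external activity score (e.g. gene
density or GC content).

Per-sample exposures are then re-fitted independently within each
compartment and compared signature-by-signature with a paired Wilcoxon
signed-rank test, Bonferroni-corrected over the signatures tested.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import assign_nonoverlapping
from .signatures import fit_exposures


def validate_track(track: pd.DataFrame) -> pd.DataFrame:
    """Sort and sanity-check a compartment track (labels A/B, no overlap)."""
    track = track.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    if not set(track["label"]).issubset({"A", "B"}):
        raise ValueError("compartment labels must be A or B")
    for _, grp in track.groupby("chrom"):
        if (grp["start"].to_numpy()[1:] < grp["end"].to_numpy()[:-1]).any():
            raise ValueError("compartment intervals overlap")
    return track


def annotate_variants(records: pd.DataFrame, track: pd.DataFrame) -> pd.DataFrame:
    """Return records with a ``compartment`` column (A / B / unassigned)."""
    track = validate_track(track)
    records = records.copy()
    if len(records) == 0:
        records["compartment"] = pd.Series(dtype=object)
        return records
    known = set(track["chrom"])
    unknown = set(records["chrom"]) - known
    if unknown:
        warnings.warn(f"contigs absent from compartment track: {sorted(unknown)}")
    rows = assign_nonoverlapping(track, records["chrom"].to_numpy(),
                                 records["pos"].to_numpy(dtype=np.int64) - 1)
    labels = np.where(rows >= 0,
                      track["label"].reindex(np.clip(rows, 0, None)).to_numpy(),
                      "unassigned")
    records["compartment"] = labels
    return records


# ---------------------------------------------------------------------------
# Fallback eigenvector compartment caller


def call_compartments_from_contacts(contacts: np.ndarray, bin_size: int,
                                    orientation: np.ndarray,
                                    chrom: str = "chr1",
                                    symmetry_tol: float = 1e-8
                                    ) -> pd.DataFrame:
    """Call A/B compartments from a dense intra-chromosomal contact matrix.

    ``orientation`` is a per-bin activity score (gene density, GC ...);
    the eigenvector sign is chosen so the A side has the higher mean
    score.  Bins with no contacts are dropped and appear as gaps.
    """
    M = np.asarray(contacts, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("contact matrix must be square")
    if np.abs(M - M.T).max() > symmetry_tol * max(1.0, np.abs(M).max()):
        raise ValueError("contact matrix is not symmetric")
    if (M < 0).any():
        raise ValueError("contact matrix has negative entries")
    n = M.shape[0]
    orientation = np.asarray(orientation, dtype=float)
    if orientation.shape[0] != n:
        raise ValueError("orientation track length must equal bin count")

    keep = M.sum(axis=1) > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} empty bin(s)")
    Mk = M[np.ix_(keep, keep)]
    nk = Mk.shape[0]
    if nk < 3:
        raise ValueError("too few informative bins")

    # observed / expected by diagonal distance
    idx = np.abs(np.subtract.outer(np.arange(nk), np.arange(nk)))
    expected = np.array([Mk[idx == d].mean() for d in range(nk)])
    expected[expected == 0] = np.nan
    OE = Mk / expected[idx]
    OE = np.nan_to_num(OE, nan=0.0)

    with np.errstate(invalid="ignore"):
        C = np.corrcoef(OE)
    if not np.isfinite(C).all():
        raise ValueError("degenerate contact matrix: no compartment structure")
    evals, evecs = np.linalg.eigh(C)
    ev = evecs[:, -1]
    if (ev >= 0).all() or (ev <= 0).all():
        raise ValueError("leading eigenvector does not change sign: "
                         "no compartment structure detected")
    score = orientation[keep]
    pos_mean = score[ev > 0].mean() if (ev > 0).any() else -np.inf
    neg_mean = score[ev < 0].mean() if (ev < 0).any() else -np.inf
    if neg_mean > pos_mean:
        ev = -ev

    labels_full = np.full(n, "", dtype=object)
    labels_full[np.flatnonzero(keep)] = np.where(ev > 0, "A", "B")
    rows = []
    current = None
    for i in range(n):
        lab = labels_full[i]
        if lab == "":
            current = None
            continue
        if current is not None and current["label"] == lab:
            current["end"] = (i + 1) * bin_size
        else:
            current = {"chrom": chrom, "start": i * bin_size,
                       "end": (i + 1) * bin_size, "label": lab}
            rows.append(current)
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])


# ---------------------------------------------------------------------------
# Per-compartment exposure fitting and testing


def fit_by_compartment(records: pd.DataFrame, track: pd.DataFrame,
                       basis: pd.DataFrame, genome: Mapping[str, str],
                       cutoff: float = 0.06, min_mutations: int = 10
                       ) -> pd.DataFrame:
    """Split each sample's mutations by compartment and fit exposures
    independently per (sample, compartment).

    Returns a tidy table: sample, compartment, n_mutations, fitted flag,
    one column per basis signature.  Compartments with fewer than
    ``min_mutations`` classified mutations are flagged unfitted and
    excluded from downstream tests.
    """
    from .contexts import build_context_matrix

    annotated = records if "compartment" in records.columns else \
        annotate_variants(records, track)
    signames = list(basis.columns)
    rows = []
    samples = sorted(annotated["sample"].unique())
    for comp in ("A", "B"):
        sub = annotated[annotated["compartment"] == comp]
        matrix, _ = build_context_matrix(sub, genome, samples=samples)
        expo, _, unfit = fit_exposures(matrix, basis, cutoff=cutoff)
        for s in samples:
            n = int(matrix[s].sum())
            fitted = n >= min_mutations and s not in unfit
            row = {"sample": s, "compartment": comp, "n_mutations": n,
                   "fitted": fitted}
            for sig in signames:
                row[sig] = float(expo.loc[sig, s]) if fitted else 0.0
            rows.append(row)
    return pd.DataFrame(rows)


def compare_compartments(per_compartment: pd.DataFrame,
                         signatures: list[str] | None = None,
                         paired: bool = True) -> pd.DataFrame:
    """Per-signature A-vs-B test across samples fitted in both
    compartments: two-sided paired Wilcoxon signed-rank on the (A - B)
    exposure differences (or unpaired rank-sum with ``paired=False``),
    Bonferroni-adjusted over the signatures tested."""
    if signatures is None:
        meta = {"sample", "compartment", "n_mutations", "fitted"}
        signatures = [c for c in per_compartment.columns if c not in meta]
    fitted = per_compartment[per_compartment["fitted"]]
    a = fitted[fitted["compartment"] == "A"].set_index("sample")
    b = fitted[fitted["compartment"] == "B"].set_index("sample")
    common = a.index.intersection(b.index)
    if len(common) < 6:
        raise ValueError(
            f"only {len(common)} samples fitted in both compartments; "
            "need at least 6")
    m = len(signatures)
    rows = []
    for sig in signatures:
        xa = a.loc[common, sig].to_numpy(dtype=float)
        xb = b.loc[common, sig].to_numpy(dtype=float)
        tie = False
        if paired:
            diff = xa - xb
            if np.allclose(diff, 0):
                stat, p, tie = 0.0, 1.0, True
            else:
                stat, p = stats.wilcoxon(xa, xb, alternative="two-sided")
        else:
            stat, p = stats.mannwhitneyu(xa, xb, alternative="two-sided")
        rows.append({"signature": sig, "n_pairs": len(common),
                     "mean_A": float(xa.mean()), "mean_B": float(xb.mean()),
                     "statistic": float(stat), "p_raw": float(p),
                     "p_bonferroni": float(min(1.0, p * m)),
                     "all_ties": tie})
    return pd.DataFrame(rows)
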