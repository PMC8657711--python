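"""End-to-end orchestration: contexts -> motifs -> extraction ->
similarity -> fitting -> compartments -> clustering -> pathways.

Every stage writes its result as plain TSV under the output directory,
the run configuration is echoed verbatim, and a manifest records the
package version, seed and per-stage record counts.  Each stage can also
run independently on the intermediates a previous invocation persisted
(see :mod:`lymphsig.cli`); because a stage that is missing in-memory
state reloads exactly what the earlier stage wrote, chaining single
stages reproduces ``run_pipeline`` bit for bit.
"""

from __future__ import annotations

import dataclasses
import glob as globmod
import json
import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from . import io
from .clustering import diana_clustering, hopkins_statistic, pca_projection, \
    silhouette_widths
from .compartments import annotate_variants, compare_compartments, \
    fit_by_compartment
from .contexts import build_context_matrix, substitution_spectrum, \
    summarize_burden
from .errors import ConfigurationError, LymphsigError
from .motifs import compare_cohorts_chi2, trace_cohort
from .pathways import PathwayCatalog, build_pathway_table, \
    fisher_pathway_prevalence, map_variants_to_genes, upset_counts
from .signatures import extract_denovo, fit_exposures, match_catalog

logger = logging.getLogger("lymphsig.pipeline")

STAGES = ("contexts", "motifs", "extract", "similarity", "fit",
          "compartments", "cluster", "pathways", "report")


class StageError(LymphsigError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Paths and stage parameters for one pipeline run."""

    genome: str
    vcf_glob: str
    compartments: str
    catalog: str
    genes: str
    pathway_membership: str
    groups: str                      # TSV with sample / group columns
    outdir: str
    regions: str | None = None       # optional BED for localized catalogs
    seed: int = 0
    target_size_mb: float = 50.0
    rank_min: int = 1
    rank_max: int = 6
    n_bootstrap: int = 50
    n_restarts: int = 3
    stability_threshold: float = 0.8
    fit_cutoff: float = 0.06
    min_compartment_mutations: int = 10
    cluster_k: int = 3
    hopkins_fraction: float = 0.1

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    def validate(self) -> None:
        missing = []
        for key in ("genome", "compartments", "catalog", "genes",
                    "pathway_membership", "groups", "regions"):
            path = getattr(self, key)
            if path is not None and not os.path.exists(path):
                missing.append(f"{key}: {path}")
        if not globmod.glob(self.vcf_glob):
            missing.append(f"vcf_glob matched no file: {self.vcf_glob}")
        if missing:
            raise ConfigurationError(
                "missing inputs:\n  " + "\n  ".join(missing))


def _out(config: RunConfig, name: str) -> str:
    return os.path.join(config.outdir, name)


# --- lazy state: each key either set by an earlier in-process stage or
# reloaded from the TSV that stage persisted ---------------------------------


def _load_fitted(path: str) -> pd.DataFrame:
    df = io.read_table(path).set_index("sample")
    df = df.drop(columns=["reconstruction_sse"], errors="ignore")
    return df.T


_LOADERS = {
    "matrix": lambda c: io.read_context_matrix(os.path.join(c.outdir,
                                                            "context_matrix.tsv")),
    "denovo_signatures": lambda c: io.read_catalog(
        os.path.join(c.outdir, "denovo_signatures.tsv"), normalize=False),
    "similarity": lambda c: io.read_table(os.path.join(c.outdir,
                                                       "similarity.tsv")),
    "basis": lambda c: io.read_catalog(os.path.join(c.outdir,
                                                    "fitting_basis.tsv"),
                                       normalize=False),
    "fitted": lambda c: _load_fitted(os.path.join(c.outdir,
                                                  "fitted_exposures.tsv")),
}


def _ensure(config: RunConfig, state: dict, *keys: str) -> None:
    for key in keys:
        if key in state:
            continue
        if key in _LOADERS:
            state[key] = _LOADERS[key](config)
        elif key in ("genome", "records", "groups", "track", "catalog"):
            _load_inputs(config, state)
        else:  # pragma: no cover - programming error
            raise KeyError(key)


def _load_inputs(config: RunConfig, state: dict) -> None:
    if "records" in state:
        return
    state["genome"] = io.load_genome(config.genome)
    state["records"] = io.read_vcf_cohort(sorted(globmod.glob(config.vcf_glob)))
    groups_df = io.read_table(config.groups)
    state["groups"] = dict(zip(groups_df["sample"], groups_df["group"]))
    state["track"] = io.read_bed(config.compartments)
    state["catalog"] = io.read_catalog(config.catalog)


# --- stages -----------------------------------------------------------------


def stage_contexts(config: RunConfig, state: dict, manifest: dict) -> str:
    _ensure(config, state, "records")
    matrix, tally = build_context_matrix(state["records"], state["genome"])
    state["matrix"] = matrix
    io.write_matrix(matrix, _out(config, "context_matrix.tsv"))
    if config.regions:
        regions = io.read_bed(config.regions)
        local, _ = build_context_matrix(state["records"], state["genome"],
                                        regions=regions)
        io.write_matrix(local, _out(config, "context_matrix_localized.tsv"))
    spectrum = substitution_spectrum(matrix)
    spec_df = spectrum.fractions.rename("fraction").to_frame().reset_index(
        names="substitution")
    io.write_table(spec_df, _out(config, "substitution_spectrum.tsv"))
    burden, tests = summarize_burden(state["records"], config.target_size_mb,
                                     state["groups"])
    io.write_table(burden, _out(config, "burden.tsv"))
    summary = pd.DataFrame([{
        "n_records": len(state["records"]),
        "n_classified": int(matrix.to_numpy().sum()),
        "skipped_edge": tally.edge, "skipped_ambiguous": tally.ambiguous,
        "titv": spectrum.titv,
        "cpg_fraction_of_ct": spectrum.cpg_fraction_of_ct,
        "burden_count_p": tests["count_p"] if tests else np.nan,
        "burden_vaf_p": tests.get("vaf_p", np.nan) if tests else np.nan,
    }])
    io.write_table(summary, _out(config, "contexts_summary.tsv"))
    manifest["stages"]["contexts"] = {
        "records_in": len(state["records"]),
        "classified": int(matrix.to_numpy().sum()),
        "skipped": tally.total}
    return _out(config, "context_matrix.tsv")


def stage_motifs(config: RunConfig, state: dict, manifest: dict) -> str:
    _ensure(config, state, "records")
    records, groups = state["records"], state["groups"]
    rows = []
    summaries = {}
    for group in sorted(set(groups.values())):
        samples = {s for s, g in groups.items() if g == group}
        cohort = records[records["sample"].isin(samples)]
        summary = trace_cohort(cohort, state["genome"])
        summaries[group] = summary
        for motif in summary.exclusive_counts:
            rows.append({
                "group": group, "motif": motif,
                "exclusive_count": summary.exclusive_counts[motif],
                "exclusive_fraction": summary.exclusive_fractions[motif],
                "overlapping_count": summary.overlapping_counts[motif],
                "overlapping_fraction": summary.overlapping_fractions[motif],
                "combined_fraction": summary.combined_fraction,
                "total": summary.total})
    table = pd.DataFrame(rows)
    names = sorted(summaries)
    if len(names) == 2:
        stat, p = compare_cohorts_chi2(summaries[names[0]], summaries[names[1]])
        table["chi2_stat"] = stat
        table["chi2_p"] = p
    io.write_table(table, _out(config, "motif_summary.tsv"))
    manifest["stages"]["motifs"] = {"groups": len(names),
                                    "records_in": len(records)}
    return _out(config, "motif_summary.tsv")


def stage_extract(config: RunConfig, state: dict, manifest: dict) -> str:
    _ensure(config, state, "matrix")
    result = extract_denovo(
        state["matrix"], rank_range=range(config.rank_min, config.rank_max + 1),
        n_bootstrap=config.n_bootstrap, n_restarts=config.n_restarts,
        seed=config.seed, stability_threshold=config.stability_threshold)
    state["denovo_signatures"] = result.signatures
    io.write_matrix(result.signatures, _out(config, "denovo_signatures.tsv"))
    io.write_table(result.exposures.T.reset_index(names="sample"),
                   _out(config, "denovo_exposures.tsv"))
    io.write_table(result.report.table, _out(config, "rank_selection.tsv"))
    manifest["stages"]["extract"] = {
        "selected_rank": result.report.selected_rank,
        "n_bootstrap": config.n_bootstrap}
    return _out(config, "denovo_signatures.tsv")


def stage_similarity(config: RunConfig, state: dict, manifest: dict) -> str:
    _ensure(config, state, "catalog", "denovo_signatures")
    report = match_catalog(state["denovo_signatures"], state["catalog"])
    state["similarity"] = report
    io.write_table(report, _out(config, "similarity.tsv"))
    manifest["stages"]["similarity"] = {
        "n_signatures": len(report),
        "n_novel": int((~report["matched"]).sum())}
    return _out(config, "similarity.tsv")


def stage_fit(config: RunConfig, state: dict, manifest: dict) -> str:
    _ensure(config, state, "catalog", "matrix", "denovo_signatures",
            "similarity")
    basis = state["catalog"].copy()
    # unmatched (novel) de novo signatures join the fitting basis as-is
    for _, row in state["similarity"][~state["similarity"]["matched"]].iterrows():
        basis[f"novel_{row['signature']}"] = \
            state["denovo_signatures"][row["signature"]]
    exposures, errors, unfit = fit_exposures(state["matrix"], basis,
                                             cutoff=config.fit_cutoff)
    state["basis"] = basis
    state["fitted"] = exposures
    io.write_matrix(basis, _out(config, "fitting_basis.tsv"))
    out = exposures.T.reset_index(names="sample")
    out["reconstruction_sse"] = errors.to_numpy()
    io.write_table(out, _out(config, "fitted_exposures.tsv"))
    manifest["stages"]["fit"] = {"n_samples": exposures.shape[1],
                                 "n_signatures": exposures.shape[0],
                                 "unfit": len(unfit)}
    return _out(config, "fitted_exposures.tsv")


def stage_compartments(config: RunConfig, state: dict, manifest: dict) -> str:
    _ensure(config, state, "records", "basis")
    records = annotate_variants(state["records"], state["track"])
    counts = records["compartment"].value_counts()
    per_comp = fit_by_compartment(records, state["track"], state["basis"],
                                  state["genome"], cutoff=config.fit_cutoff,
                                  min_mutations=config.min_compartment_mutations)
    io.write_table(per_comp, _out(config, "compartment_exposures.tsv"))
    tests = []
    for group in sorted(set(state["groups"].values())):
        samples = {s for s, g in state["groups"].items() if g == group}
        sub = per_comp[per_comp["sample"].isin(samples)]
        try:
            table = compare_compartments(sub)
        except ValueError:
            continue
        table.insert(0, "group", group)
        tests.append(table)
    test_table = pd.concat(tests, ignore_index=True) if tests else \
        pd.DataFrame(columns=["group", "signature", "p_raw", "p_bonferroni"])
    io.write_table(test_table, _out(config, "compartment_tests.tsv"))
    manifest["stages"]["compartments"] = {
        "A": int(counts.get("A", 0)), "B": int(counts.get("B", 0)),
        "unassigned": int(counts.get("unassigned", 0))}
    return _out(config, "compartment_tests.tsv")


def stage_cluster(config: RunConfig, state: dict, manifest: dict) -> str:
    _ensure(config, state, "records", "fitted")
    expo = state["fitted"]
    X = expo.T.to_numpy(dtype=float)
    samples = list(expo.columns)
    h = hopkins_statistic(X, sample_fraction=config.hopkins_fraction,
                          seed=config.seed)
    tree = diana_clustering(X)
    k = min(config.cluster_k, len(samples))
    labels = tree.cut(k)
    widths, mean_width = silhouette_widths(X, labels)
    scores, evr = pca_projection(X, n_components=min(2, *X.shape))
    assign = pd.DataFrame({"sample": samples, "cluster": labels,
                           "silhouette": widths,
                           "group": [state["groups"].get(s) for s in samples]})
    for i in range(scores.shape[1]):
        assign[f"PC{i + 1}"] = scores[:, i]
    io.write_table(assign, _out(config, "clusters.tsv"))
    with open(_out(config, "diana_tree.nwk"), "w") as fh:
        fh.write(tree.newick(samples) + "\n")
    summary = pd.DataFrame([{
        "hopkins": h, "k": k, "mean_silhouette": mean_width,
        "pc1_variance": evr[0] if len(evr) else np.nan,
        "pc2_variance": evr[1] if len(evr) > 1 else np.nan}])
    io.write_table(summary, _out(config, "cluster_summary.tsv"))
    manifest["stages"]["cluster"] = {"k": k, "hopkins": round(h, 4),
                                     "mean_silhouette": round(mean_width, 4)}
    return _out(config, "cluster_summary.tsv")


def stage_pathways(config: RunConfig, state: dict, manifest: dict) -> str:
    _ensure(config, state, "records")
    genes = pd.read_csv(config.genes, sep="\t", header=None,
                        names=["chrom", "start", "end", "name"])
    membership = io.read_table(config.pathway_membership)
    catalog = PathwayCatalog(genes, membership)
    hits = map_variants_to_genes(state["records"], catalog)
    samples = sorted(state["records"]["sample"].unique())
    table = build_pathway_table(hits, catalog, samples)
    io.write_table(table.reset_index(), _out(config, "pathway_table.tsv"))
    tests = fisher_pathway_prevalence(table, state["groups"])
    io.write_table(tests, _out(config, "pathway_tests.tsv"))
    upset = upset_counts(table)
    io.write_table(upset, _out(config, "pathway_upset.tsv"))
    manifest["stages"]["pathways"] = {"n_hits": len(hits),
                                      "n_flagged": int(upset["count"].sum())
                                      if len(upset) else 0}
    return _out(config, "pathway_tests.tsv")


def stage_report(config: RunConfig, state: dict, manifest: dict) -> str:
    return _write_manifest(config, manifest)


_STAGE_FN = {
    "contexts": stage_contexts, "motifs": stage_motifs,
    "extract": stage_extract, "similarity": stage_similarity,
    "fit": stage_fit, "compartments": stage_compartments,
    "cluster": stage_cluster, "pathways": stage_pathways,
    "report": stage_report,
}


def _new_manifest(config: RunConfig) -> dict:
    manifest = {"seed": config.seed, "stages": {}}
    try:
        from importlib.metadata import version
        manifest["lymphsig_version"] = version("lymphsig")
    except Exception:
        manifest["lymphsig_version"] = "unknown"
    return manifest


def run_stage(config: RunConfig, name: str, state: dict | None = None,
              manifest: dict | None = None) -> str:
    """Run one stage, reloading any missing inputs from the outdir.

    The on-disk manifest is updated after the stage so that chained
    single-stage invocations accumulate the same record counts as a full
    pipeline run.
    """
    if name not in _STAGE_FN:
        raise ConfigurationError(f"unknown stage {name!r}; valid: {STAGES}")
    os.makedirs(config.outdir, exist_ok=True)
    state = {} if state is None else state
    if manifest is None:
        manifest_path = _out(config, "manifest.json")
        if os.path.exists(manifest_path):
            with open(manifest_path) as fh:
                manifest = json.load(fh)
        else:
            manifest = _new_manifest(config)
    out = _STAGE_FN[name](config, state, manifest)
    logger.info("stage %s: %s", name, manifest["stages"].get(name, {}))
    _write_manifest(config, manifest)
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order; returns {stage: primary output path}.

    Inputs are validated before any computation; a stage failure raises
    :class:`StageError` naming the stage, with the outputs of completed
    stages left on disk.
    """
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    config.to_yaml(_out(config, "config.yaml"))
    manifest = _new_manifest(config)
    state: dict = {}
    outputs = {}
    for name in STAGES:
        try:
            outputs[name] = _STAGE_FN[name](config, state, manifest)
            logger.info("stage %s: %s", name, manifest["stages"].get(name, {}))
        except Exception as exc:
            _write_manifest(config, manifest)
            raise StageError(name, exc) from exc
    return outputs


def _write_manifest(config: RunConfig, manifest: dict) -> str:
    path = _out(config, "manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
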