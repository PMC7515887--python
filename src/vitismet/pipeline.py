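"""End-to-end orchestration of the two-armed analysis, with a run manifest.

``run_pipeline`` executes: simulate (or load) -> align -> occurrence
filter -> impute -> internal-standard normalize -> glog -> Pareto ->
{PCA, hierarchical clustering, OPLS-DA CV (+ optional permutation
test)} -> univariate selection -> (optional) annotation and pathway
mapping -> qPCR stability ranking and GOI tests.  Every stage writes a
TSV and the manifest records every parameter that influences any
reported number, so the same config and seed reproduce identical
outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotate import annotate_mz, load_compound_table, map_to_pathways, unique_annotated_masses
from .multivariate import hierarchical_cluster, pca, permutation_test, stratified_cv
from .peaks import (FeatureMatrix, PeakList, preprocess_chain, read_peaklist,
                    validate_metadata, write_feature_matrix, write_peaklist)
from .qpcr import goi_group_tests, normalize_goi, stability_report
from .simulate import (DEFAULT_STANDARD_MZ, GroundTruth, SimulationConfig,
                       generate_cq_table, generate_peak_experiment)
from .univariate import select_discriminatory, summarize, univariate_stats


@dataclass
class RunConfig:
    """Parameters of a full pipeline run.

    When ``peaklist_dir`` is None the profiling inputs are simulated
    from ``simulation`` (likewise the Cq table when ``cq_path`` is
    None); otherwise TSV inputs are loaded from the given paths.
    """

    out_dir: str = "vitismet_run"
    seed: int = 0
    # profiling arm inputs
    peaklist_dir: str | None = None
    metadata_path: str | None = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    # parameters (printed study defaults)
    ppm_align: float = 1.0
    ppm_annotate: float = 2.0
    occurrence_fraction: float = 2 / 3
    strict_occurrence: bool = False
    standard_mz: float | None = DEFAULT_STANDARD_MZ
    fdr_alpha: float = 0.01
    fc_cut: float = 1.0
    cv_folds: int = 7
    n_orthogonal: int = 1
    n_permutations: int = 1000
    run_permutation: bool = True
    pca_variance_threshold: float = 0.95
    clip: float = 5.0
    # annotation arm inputs (skipped when absent)
    compound_table_path: str | None = None
    pathway_table_path: str | None = None
    # qPCR arm
    cq_path: str | None = None
    efficiency_path: str | None = None
    goi_alpha: float = 0.05
    n_reference_genes: int = 10
    n_goi: int = 7
    ref_stability_sds: tuple = (0.1, 0.15, 0.2, 0.3, 0.4, 0.5, 0.6, 0.8, 1.0, 1.2)
    goi_shifts: tuple = (-3.0, -2.0, -1.0, 0.0, 0.0, 0.5, 1.0)

    def __post_init__(self) -> None:
        for name in ("ppm_align", "ppm_annotate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("fdr_alpha", "goi_alpha"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in (0, 1)")


def _write_tsv(df: pd.DataFrame, path: Path, float_format="%.6g", index=False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=float_format)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the manifest dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            k: v for k, v in asdict(config).items()
            if k not in ("simulation",)
        },
        "simulation": asdict(config.simulation),
        "stages": {},
    }

    # ----- inputs: simulate or load ---------------------------------------
    truth: GroundTruth | None = None
    if config.peaklist_dir is None:
        lists, meta, truth = generate_peak_experiment(config.simulation)
        (out / "peaklists").mkdir(exist_ok=True)
        for pl in lists:
            write_peaklist(pl, out / "peaklists" / f"{pl.sample_id}.tsv")
        _write_tsv(meta, out / "metadata.tsv")
        with open(out / "ground_truth.json", "w") as fh:
            json.dump(truth.to_json_dict(), fh, indent=1)
        standard_mz = config.simulation.internal_standard_mz
    else:
        if config.metadata_path is None:
            raise FileNotFoundError("metadata_path required when loading peak lists")
        meta = pd.read_csv(config.metadata_path, sep="\t")
        lists = [
            read_peaklist(p, sample_id=p.stem)
            for p in sorted(Path(config.peaklist_dir).glob("*.tsv"))
        ]
        if not lists:
            raise FileNotFoundError(f"no peak-list TSVs in {config.peaklist_dir}")
        standard_mz = config.standard_mz
    meta = validate_metadata(meta, [pl.sample_id for pl in lists])

    # ----- preprocessing chain --------------------------------------------
    stages = preprocess_chain(
        lists, meta,
        ppm_align=config.ppm_align,
        occurrence_fraction=config.occurrence_fraction,
        strict_occurrence=config.strict_occurrence,
        standard_mz=standard_mz,
    )
    for name, m in stages.items():
        write_feature_matrix(m, out / f"matrix_{name}.tsv")
        manifest["stages"][name] = {"features": m.n_features, "samples": m.n_samples}
    (out / "processing_log.txt").write_text(
        "\n".join(stages["pareto"].events) + "\n"
    )

    # ----- unsupervised + classifier ---------------------------------------
    pca_res = pca(stages["pareto"], variance_threshold=config.pca_variance_threshold)
    scores = pd.DataFrame(
        pca_res.scores[:, : pca_res.n_retained],
        index=pca_res.sample_ids,
        columns=[f"PC{i + 1}" for i in range(pca_res.n_retained)],
    )
    scores.index.name = "sample_id"
    _write_tsv(scores, out / "pca_scores.tsv", index=True)
    _write_tsv(
        pd.DataFrame({
            "component": np.arange(1, pca_res.explained_variance_fraction.size + 1),
            "explained_variance_fraction": pca_res.explained_variance_fraction,
        }),
        out / "pca_explained_variance.tsv",
    )
    manifest["pca_components_retained"] = pca_res.n_retained

    tree = hierarchical_cluster(stages["pareto"])
    (out / "dendrogram.nwk").write_text(tree.to_newick() + "\n")

    x = stages["glog"].data.to_numpy().T
    y = meta.set_index("sample_id").loc[stages["glog"].sample_ids, "group"].to_numpy()
    cv = stratified_cv(x, y, k=config.cv_folds, n_orthogonal=config.n_orthogonal,
                       seed=config.seed, scale="pareto")
    cv_report = pd.DataFrame([{
        "accuracy": cv.accuracy, "r2y": cv.r2y, "q2y": cv.q2y, "k": cv.k,
        "n_orthogonal": config.n_orthogonal,
    }])
    _write_tsv(cv_report, out / "oplsda_cv.tsv")
    manifest["oplsda"] = {"accuracy": cv.accuracy, "r2y": cv.r2y, "q2y": cv.q2y,
                          "k": int(cv.k)}

    if config.run_permutation:
        perm = permutation_test(
            x, y, k=config.cv_folds, n_orthogonal=config.n_orthogonal,
            n_permutations=config.n_permutations, seed=config.seed, scale="pareto",
        )
        _write_tsv(pd.DataFrame({"permuted_accuracy": perm.permuted_accuracies}),
                   out / "permutation_distribution.tsv")
        manifest["permutation"] = {
            "observed_accuracy": perm.observed_accuracy,
            "p_value": round(perm.p_value, 3),
            "n_permutations": perm.n_permutations,
        }

    # ----- univariate selection --------------------------------------------
    stats_df = univariate_stats(stages["normalized"], stages["glog"], meta,
                                alpha=config.fdr_alpha, fc_cut=config.fc_cut)
    _write_tsv(stats_df, out / "feature_stats.tsv")
    disc = select_discriminatory(stats_df, alpha=config.fdr_alpha, fc_cut=config.fc_cut)
    _write_tsv(disc, out / "discriminatory_features.tsv")
    manifest["univariate"] = summarize(stats_df, alpha=config.fdr_alpha,
                                       fc_cut=config.fc_cut)

    # ----- annotation + pathways (only with a compound table) --------------
    if config.compound_table_path is not None:
        table = load_compound_table(config.compound_table_path)
        mode = stages["aligned"].ionization_mode
        hits, unannotated = annotate_mz(disc["feature_mz"].tolist(), table, mode,
                                        ppm_tol=config.ppm_annotate)
        _write_tsv(hits, out / "annotation_hits.tsv")
        _write_tsv(pd.DataFrame({"unannotated_mz": unannotated}),
                   out / "annotation_unmatched.tsv")
        manifest["annotation"] = {
            "hits": int(len(hits)),
            "unique_annotated_masses": unique_annotated_masses(hits),
        }
        if config.pathway_table_path is not None:
            pathways = pd.read_csv(config.pathway_table_path, sep="\t", dtype=str)
            report = map_to_pathways(hits, stats_df, table, pathways,
                                     clip=config.clip)
            _write_tsv(report.summary, out / "pathway_summary.tsv")
            _write_tsv(report.members, out / "pathway_members.tsv")
            manifest["pathways"] = dict(zip(report.summary["pathway_id"],
                                            report.summary["n_compounds"].astype(int)))

    # ----- qPCR arm ---------------------------------------------------------
    if config.cq_path is None:
        cq, eff, cq_truth = generate_cq_table(
            config.n_reference_genes, config.n_goi, meta,
            stability_sds=list(config.ref_stability_sds),
            goi_shifts=list(config.goi_shifts),
            seed=config.seed,
        )
        cq.to_csv(out / "cq_table.tsv", sep="\t", float_format="%.4f")
        eff.to_frame().to_csv(out / "efficiencies.tsv", sep="\t")
        ref_genes = [g for g in cq.index if g.startswith("REF")]
        goi_genes = [g for g in cq.index if g.startswith("GOI")]
    else:
        cq = pd.read_csv(config.cq_path, sep="\t", index_col=0)
        if config.efficiency_path is not None:
            eff = pd.read_csv(config.efficiency_path, sep="\t",
                              index_col=0).iloc[:, 0]
        else:
            eff = 2.0
        ref_genes = [g for g in cq.index if not g.startswith("GOI")]
        goi_genes = [g for g in cq.index if g.startswith("GOI")]

    groups = meta.set_index("sample_id")["group"].reindex(cq.columns)
    report = stability_report(cq.loc[ref_genes], eff if np.isscalar(eff)
                              else eff.loc[ref_genes], groups=groups)
    report.table.to_csv(out / "stability_report.tsv", sep="\t",
                        float_format="%.4f")
    report.pairwise_v.to_frame().to_csv(out / "genorm_pairwise_v.tsv", sep="\t",
                                        float_format="%.4f")
    best_refs = report.table.index[:3].tolist()
    manifest["qpcr"] = {"best_reference_genes": best_refs,
                        "genorm_optimal_n": report.optimal_n}

    if goi_genes:
        normalized = normalize_goi(cq.loc[goi_genes], cq.loc[best_refs])
        normalized.to_csv(out / "goi_normalized.tsv", sep="\t",
                          float_format="%.4f")
        goi = goi_group_tests(normalized, groups, alpha=config.goi_alpha)
        goi.to_csv(out / "goi_tests.tsv", sep="\t", float_format="%.4g")
        manifest["qpcr"]["reliable_goi"] = goi.index[goi["reliable"]].tolist()

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
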