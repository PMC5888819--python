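"""End-to-end orchestration: normalize, filter, DE, associate, seed-match.

The stages mirror the analysis this package implements:

1. 75th-percentile scaling normalization of miRNA signals;
2. expression filter (miRNAs detected in >20% of normal mucosa samples);
3. paired negative-binomial differential expression of the pathway genes,
   overall and within MSI/MSS subgroups, BH-adjusted, classified by fold
   change (>1.50 up, <0.67 down at FDR < 0.05);
4. the same fold-change screen applied to miRNA mean signals;
5. covariate-adjusted OLS association of paired differences for every
   dysregulated gene x dysregulated miRNA, residual-bootstrap p values,
   BH within gene;
6. seed extraction (6/7/8-mers), 3'UTR scanning, and direct/indirect calls
   for the significant associations.

Every stage records its settings and dimensions in a run log so a run is
reproducible from its output directory.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .association import BootstrapSpec, association_screen
from .de import de_table, subgroup_de
from .errors import ConfigurationError, SubgroupSizeError
from .io import (PairedStudy, ReferenceTables, read_fasta, read_study,
                 utrs_by_gene)
from .mirna import expression_filter, scale_normalize
from .seeds import (classify_interaction, extract_seeds, scan_gene,
                    summarize_by_mirna)


@dataclass
class PipelineConfig:
    """Declarative configuration of a full pipeline run."""

    bundle_path: str
    output_dir: str
    gene_list: list[str] | None = None  # None: every gene in the count matrix
    fdr: float = 0.05
    fc_up: float = 1.50
    fc_down: float = 0.67
    min_normal_fraction: float = 0.20
    bootstrap: BootstrapSpec = field(default_factory=BootstrapSpec)
    subgroups: tuple[str, ...] = ("MSI", "MSS")
    mirna_screen: str = "dysregulated"  # or "all": every filtered miRNA
    zero_fraction_cutoff: float = 0.90
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        if self.gene_list is not None and len(self.gene_list) == 0:
            raise ConfigurationError("gene_list is empty")
        if not (0 < self.fdr < 1):
            raise ConfigurationError("fdr must lie in (0, 1)")
        if not (0 < self.fc_down < 1 < self.fc_up):
            raise ConfigurationError("need fc_down < 1 < fc_up, both positive")
        if self.mirna_screen not in ("dysregulated", "all"):
            raise ConfigurationError(f"unknown mirna_screen {self.mirna_screen!r}")
        return self


@dataclass
class PipelineResult:
    de_tables: dict[str, pd.DataFrame]       # subgroup -> DE table
    mirna_table: pd.DataFrame                # per-miRNA FC screen
    associations: pd.DataFrame
    seed_matches: pd.DataFrame
    interaction_calls: pd.DataFrame
    summary: dict
    run_log: list[dict]


def _mirna_fc_table(signals: pd.DataFrame, study: PairedStudy) -> pd.DataFrame:
    tumor = study.samples_for("tumor")
    normal = study.samples_for("normal")
    t_mean = signals[tumor].mean(axis=1)
    n_mean = signals[normal].mean(axis=1)
    fc = t_mean / n_mean.where(n_mean > 0)
    return pd.DataFrame({
        "mirna": signals.index,
        "tumor_mean": t_mean.to_numpy(),
        "normal_mean": n_mean.to_numpy(),
        "fold_change": fc.to_numpy(),
    })


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage and write result tables under ``config.output_dir``."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []

    def stage(name, **info):
        log.append({"stage": name, "time": time.strftime("%Y-%m-%dT%H:%M:%S"),
                    **info})

    bundle = Path(config.bundle_path)
    study = read_study(bundle)
    utrs = utrs_by_gene(read_fasta(bundle / "utrs.fasta")) \
        if (bundle / "utrs.fasta").exists() else {}
    matures = read_fasta(bundle / "mirnas.fasta", rna=True) \
        if (bundle / "mirnas.fasta").exists() else {}
    stage("read_study", n_subjects=len(study.subjects),
          n_genes=int(study.mrna_counts.shape[0]),
          n_mirnas=int(study.mirna_signals.shape[0]))

    normalized = scale_normalize(study.mirna_signals)
    stage("scale_normalize",
          reference_quantile=normalized.reference_quantile)

    kept_mirnas = expression_filter(normalized.matrix,
                                    study.samples_for("normal"),
                                    config.min_normal_fraction)
    stage("expression_filter", min_normal_fraction=config.min_normal_fraction,
          filter_applied_after_normalization=True,
          n_retained=len(kept_mirnas))

    genes = config.gene_list
    de_tables = {"overall": de_table(
        study, genes, fdr_cut=config.fdr, up_cut=config.fc_up,
        down_cut=config.fc_down, zero_fraction_cutoff=config.zero_fraction_cutoff)}
    for sub in config.subgroups:
        try:
            de_tables[sub] = subgroup_de(
                study, sub, genes=genes, fdr_cut=config.fdr,
                up_cut=config.fc_up, down_cut=config.fc_down,
                zero_fraction_cutoff=config.zero_fraction_cutoff)
        except SubgroupSizeError as exc:
            stage("subgroup_de_skipped", subgroup=sub, reason=str(exc))
    stage("differential_expression", model="paired NB, subject intercepts, "
          "Cox-Reid dispersion, LRT", subgroups=list(de_tables))

    dysregulated_genes: list[str] = []
    for table in de_tables.values():
        for gene in table.loc[table["direction"] != "none", "gene"]:
            if gene not in dysregulated_genes:
                dysregulated_genes.append(gene)

    mirna_table = _mirna_fc_table(normalized.matrix.loc[kept_mirnas], study)
    mirna_table["dysregulated"] = (
        (mirna_table["fold_change"] > config.fc_up)
        | (mirna_table["fold_change"] < config.fc_down)
    )
    if config.mirna_screen == "dysregulated":
        screen_mirnas = list(mirna_table.loc[mirna_table["dysregulated"], "mirna"])
    else:
        screen_mirnas = kept_mirnas
    stage("dysregulation_screen", fc_up=config.fc_up, fc_down=config.fc_down,
          n_dysregulated_genes=len(dysregulated_genes),
          n_screen_mirnas=len(screen_mirnas))

    empty_assoc = pd.DataFrame(columns=["gene", "mirna", "beta", "f_observed",
                                        "p_raw", "p_fdr", "n_subjects",
                                        "significant"])
    if dysregulated_genes and screen_mirnas:
        associations = association_screen(
            study, dysregulated_genes, screen_mirnas, config.bootstrap,
            normalized_signals=normalized.matrix, fdr_cut=config.fdr)
    else:
        associations = empty_assoc
    stage("association_screen", n_tests=len(associations),
          bootstrap_resamples=config.bootstrap.n_resamples,
          bootstrap_seed=config.bootstrap.seed,
          n_significant=int(associations["significant"].sum())
          if len(associations) else 0)

    significant = associations[associations["significant"]] \
        if len(associations) else empty_assoc
    match_rows = []
    calls = []
    seed_sets = {m: extract_seeds(m, matures[m])
                 for m in significant["mirna"].unique() if m in matures}
    for _, row in significant.iterrows():
        matches = []
        if row["mirna"] in seed_sets and row["gene"] in utrs:
            matches = scan_gene(utrs[row["gene"]], seed_sets[row["mirna"]],
                                row["gene"])
        for m in matches:
            match_rows.append({"mirna": m.mirna, "gene": m.gene,
                               "seed_length": m.seed_length,
                               "utr_start": m.utr_start, "utr_end": m.utr_end})
        calls.append(classify_interaction(row["gene"], row["mirna"],
                                          row["beta"], matches))
    seed_matches = pd.DataFrame(
        match_rows, columns=["mirna", "gene", "seed_length", "utr_start", "utr_end"])
    interaction_calls = pd.DataFrame(
        [{"gene": c.gene, "mirna": c.mirna, "beta": c.beta,
          "has_seed_match": c.has_seed_match, "call": c.call} for c in calls],
        columns=["gene", "mirna", "beta", "has_seed_match", "call"])
    stage("seed_matching", n_matches=len(seed_matches),
          n_direct=int((interaction_calls["call"] == "direct").sum())
          if len(interaction_calls) else 0)

    summary = {
        "n_subjects": len(study.subjects),
        "n_genes_tested": int(len(de_tables["overall"])),
        "n_dysregulated_genes": len(dysregulated_genes),
        "n_mirnas_retained": len(kept_mirnas),
        "n_mirnas_screened": len(screen_mirnas),
        "n_association_tests": int(len(associations)),
        "n_significant_associations": int(associations["significant"].sum())
        if len(associations) else 0,
        "n_direct": int((interaction_calls["call"] == "direct").sum())
        if len(interaction_calls) else 0,
        "mirna_summary": summarize_by_mirna(calls),
    }

    float_fmt = "%.6g"
    for name, table in de_tables.items():
        table.to_csv(outdir / f"de_{name}.tsv", sep="\t", index=False,
                     float_format=float_fmt)
    mirna_table.to_csv(outdir / "mirna_screen.tsv", sep="\t", index=False,
                       float_format=float_fmt)
    associations.to_csv(outdir / "associations.tsv", sep="\t", index=False,
                        float_format=float_fmt)
    seed_matches.to_csv(outdir / "seed_matches.tsv", sep="\t", index=False)
    interaction_calls.to_csv(outdir / "interaction_calls.tsv", sep="\t",
                             index=False, float_format=float_fmt)
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1,
                                                    sort_keys=True))
    run_settings = {
        "version": __version__,
        "seed": config.seed,
        "fdr": config.fdr, "fc_up": config.fc_up, "fc_down": config.fc_down,
        "min_normal_fraction": config.min_normal_fraction,
        "bootstrap_resamples": config.bootstrap.n_resamples,
        "bootstrap_seed": config.bootstrap.seed,
        "mirna_screen": config.mirna_screen,
        "zero_fraction_cutoff": config.zero_fraction_cutoff,
        "stages": log,
    }
    (outdir / "run_log.json").write_text(json.dumps(run_settings, indent=1))

    return PipelineResult(de_tables=de_tables, mirna_table=mirna_table,
                          associations=associations, seed_matches=seed_matches,
                          interaction_calls=interaction_calls, summary=summary,
                          run_log=log)


def acceptance_report(fixtures: ReferenceTables) -> dict:
    """Counts and arithmetic checks recomputed from the reference tables.

    Everything here is derived at call time from the packaged tables and
    the package's own classification rules; nothing is hard-coded.
    """
    t1, t2, t3 = fixtures.table1, fixtures.table2, fixtures.table3
    report: dict[str, float] = {}

    report["table2_n_genes"] = int(len(t2))
    report["table2_n_down"] = int((t2["fold_change"] < 0.67).sum())
    report["table2_n_up"] = int((t2["fold_change"] > 1.50).sum())
    from .de import classify_dysregulation
    recls = [classify_dysregulation(fc, q)
             for fc, q in zip(t2["fold_change"], t2["p_adjusted"])]
    report["table2_direction_agreement"] = float(
        (pd.Series(recls).to_numpy() == t2["direction"].to_numpy()).mean())

    report["table3_n_rows"] = int(len(t3))
    report["table3_n_genes"] = int(t3["gene"].nunique())
    direct = t3["seed_match"] & (t3["beta"] < 0)
    report["table3_n_direct"] = int(direct.sum())
    report["table3_n_seed_matches"] = int(t3["seed_match"].sum())
    report["table3_fdr_ge_raw_fraction"] = float(
        (t3["p_fdr"] >= t3["p_raw"]).mean())

    site = t1[(t1["section"] == "site")].set_index("item")["value"]
    report["table1_colon_count"] = int(site["Colon"])
    report["table1_colon_pct"] = round(
        100 * site["Colon"] / (site["Colon"] + site["Rectal"]), 1)

    sub = fixtures.subgroup_only
    union = set(t2["gene"]) | set(sub["gene"])
    report["union_n_dysregulated"] = int(len(union))

    def mean_ratio(frame, gene_col, gene, t_col, n_col):
        row = frame[frame[gene_col] == gene].iloc[0]
        return round(float(row[t_col] / row[n_col]), 2)

    report["fgf9_fc_from_means"] = mean_ratio(t2, "gene", "FGF9",
                                              "tumor_mean", "normal_mean")
    report["myc_fc_from_means"] = mean_ratio(t2, "gene", "MYC",
                                             "tumor_mean", "normal_mean")
    mir203a = t3[t3["mirna"] == "hsa-miR-203a"].iloc[0]
    report["mir203a_fc_from_means"] = round(
        float(mir203a["mirna_tumor_mean"] / mir203a["mirna_normal_mean"]), 2)
    report["mir203a_paired_diff"] = round(
        float(mir203a["mirna_tumor_mean"] - mir203a["mirna_normal_mean"]), 2)
    report["myc_n_mirnas"] = int((t3["gene"] == "MYC").sum())
    return report
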