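"""Covariate-adjusted miRNA:mRNA association tests with bootstrap p values.

For each candidate pair, the subject-level paired differential expression of
the gene (tumor minus normal RPMPCG) is regressed by ordinary least squares
on the paired differential expression of the miRNA, adjusting for age
(years, untransformed) and sex (single indicator):

    mRNA_diff_i = b0 + beta * miRNA_diff_i + b_age * age_i + b_sex * I(sex_i=M) + e_i

The test of ``beta = 0`` uses the F statistic comparing this model with the
null model without the miRNA term. Its p value is Monte Carlo: residuals of
the *null* model are resampled with replacement, added back to the null
fitted values, both models are refit on each resampled response, and the
observed F is ranked in the resulting null F distribution with the
(1 + count) / (B + 1) correction, so p is never exactly zero. Multiplicity
is adjusted at the gene level: Benjamini-Hochberg across the miRNAs tested
against each gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import de, mirna as mirna_mod
from .errors import CollinearityError, GroupingError, SizeError, SpecError
from .io import PairedStudy


@dataclass
class BootstrapSpec:
    """Plan for the residual-bootstrap null distribution of F."""

    n_resamples: int = 10_000
    seed: int = 0
    covariates: tuple[str, ...] = ("age", "sex")

    def __post_init__(self):
        if self.n_resamples < 1:
            raise SpecError("n_resamples must be at least 1")


@dataclass
class AssociationFit:
    """An OLS fit of mRNA diff on miRNA diff plus covariates.

    Holds the design and null-model residuals needed by
    :func:`bootstrap_pvalue`; ``f_observed`` is computed once, here.
    """

    beta: float
    f_observed: float
    n_subjects: int
    x_full: np.ndarray = field(repr=False)
    x_null: np.ndarray = field(repr=False)
    null_fitted: np.ndarray = field(repr=False)
    null_residuals: np.ndarray = field(repr=False)


def _rss_projector(x: np.ndarray) -> np.ndarray:
    q, _ = np.linalg.qr(x)
    return q


def _f_from_rss(rss_null, rss_full, df_resid_full, q: int = 1):
    return ((rss_null - rss_full) / q) / (rss_full / df_resid_full)


def fit_association(mrna_diff: pd.Series, mirna_diff: pd.Series,
                    age: pd.Series, sex: pd.Series) -> AssociationFit:
    """OLS of gene differential expression on miRNA differential expression.

    All four inputs are indexed by subject; the fit uses the subjects of
    ``mrna_diff``'s index, which must have complete covariates.
    """
    subjects = mrna_diff.index
    y = mrna_diff.to_numpy(float)
    x = mirna_diff.reindex(subjects).to_numpy(float)
    a = age.reindex(subjects).to_numpy(float)
    s = (sex.reindex(subjects).astype(str) == "M").to_numpy(float)
    if np.isnan(x).any() or np.isnan(a).any() or np.isnan(y).any():
        raise SizeError("missing values among subjects passed to fit_association")
    n = y.size
    x_null = np.column_stack([np.ones(n), a, s])
    x_full = np.column_stack([x_null, x])
    if n < x_full.shape[1] + 1:
        raise SizeError(f"{n} subjects cannot support {x_full.shape[1]} coefficients")
    if np.linalg.matrix_rank(x_full) < x_full.shape[1]:
        raise CollinearityError("rank-deficient design (constant or collinear predictor)")

    full = sm.OLS(y, x_full).fit()
    null = sm.OLS(y, x_null).fit()
    f_obs = float(_f_from_rss(null.ssr, full.ssr, full.df_resid))
    return AssociationFit(
        beta=float(full.params[-1]),
        f_observed=f_obs,
        n_subjects=n,
        x_full=x_full,
        x_null=x_null,
        null_fitted=null.fittedvalues,
        null_residuals=null.resid,
    )


def bootstrap_pvalue(fit: AssociationFit, spec: BootstrapSpec) -> float:
    """Residual-bootstrap p value for the miRNA term of a fitted association.

    Resamples the null-model residuals with replacement, rebuilds the
    response around the null fitted values, refits full and null models on
    every resample, and ranks the observed F in the B resampled F values:
    ``p = (1 + #{F_b >= F_obs}) / (B + 1)``. Deterministic given the seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = fit.null_fitted.size
    b = spec.n_resamples
    q_full = _rss_projector(fit.x_full)
    q_null = _rss_projector(fit.x_null)
    df_resid_full = n - fit.x_full.shape[1]

    f_stats = np.empty(b)
    # blocks bound peak memory at ~n x 4000 doubles
    block = max(1, min(b, 4000))
    done = 0
    while done < b:
        m = min(block, b - done)
        idx = rng.integers(0, n, size=(n, m))
        ystar = fit.null_fitted[:, None] + fit.null_residuals[idx]
        r_full = ystar - q_full @ (q_full.T @ ystar)
        r_null = ystar - q_null @ (q_null.T @ ystar)
        rss_full = np.einsum("ij,ij->j", r_full, r_full)
        rss_null = np.einsum("ij,ij->j", r_null, r_null)
        f_stats[done:done + m] = _f_from_rss(rss_null, rss_full, df_resid_full)
        done += m
    return float((1 + np.sum(f_stats >= fit.f_observed)) / (b + 1))


def gene_level_fdr(results: pd.DataFrame) -> pd.DataFrame:
    """Fill ``p_fdr`` by BH across one gene's miRNA tests.

    All rows must share the same gene; raises GroupingError otherwise.
    """
    if results["gene"].nunique() > 1:
        raise GroupingError("gene_level_fdr received rows from multiple genes")
    out = results.copy()
    out["p_fdr"] = de.bh_adjust(out["p_raw"].to_numpy())
    return out


def association_screen(study: PairedStudy, dysregulated_genes,
                       dysregulated_mirnas, spec: BootstrapSpec,
                       normalized_signals: pd.DataFrame | None = None,
                       fdr_scope: str = "gene",
                       fdr_cut: float = 0.05) -> pd.DataFrame:
    """Cross every dysregulated gene with every dysregulated miRNA.

    Subject-level paired differences (RPMPCG for genes; normalized signals
    for miRNAs) are tested pairwise with age/sex-adjusted OLS and
    residual-bootstrap p values; ``p_fdr`` is BH-adjusted within each gene
    (``fdr_scope="gene"``) or across all tests (``fdr_scope="global"``).
    Subjects with missing age or sex are dropped. Per-test bootstrap seeds
    are spawned deterministically from ``spec.seed``.
    """
    genes = list(dysregulated_genes)
    mirnas = list(dysregulated_mirnas)
    if not genes or not mirnas:
        raise SpecError("association_screen needs nonempty gene and miRNA lists")
    if fdr_scope not in ("gene", "global"):
        raise SpecError(f"unknown fdr_scope {fdr_scope!r}")

    signals = study.mirna_signals if normalized_signals is None else normalized_signals
    expr = de.rpmpcg_matrix(study.mrna_counts.loc[genes], study.total_pc_counts)
    mrna_diffs = mirna_mod.paired_diff_matrix(expr, study.sample_map)
    mirna_diffs = mirna_mod.paired_diff_matrix(signals.loc[mirnas], study.sample_map)

    covars = study.subjects[["age", "sex"]]
    complete = covars.index[covars["age"].notna() & covars["sex"].isin(["M", "F"])]
    keep = [s for s in mrna_diffs.columns if s in set(complete)]
    age = study.subjects.loc[keep, "age"]
    sex = study.subjects.loc[keep, "sex"]

    child_seeds = np.random.SeedSequence(spec.seed).generate_state(len(genes) * len(mirnas))
    rows = []
    k = 0
    for gene in genes:
        y = mrna_diffs.loc[gene, keep]
        for mir in mirnas:
            fit = fit_association(y, mirna_diffs.loc[mir, keep], age, sex)
            pair_spec = BootstrapSpec(
                n_resamples=spec.n_resamples,
                seed=int(child_seeds[k] % (2**31 - 1)),
                covariates=spec.covariates,
            )
            p = bootstrap_pvalue(fit, pair_spec)
            rows.append({"gene": gene, "mirna": mir, "beta": fit.beta,
                         "f_observed": fit.f_observed, "p_raw": p,
                         "n_subjects": fit.n_subjects})
            k += 1
    table = pd.DataFrame(rows)
    if fdr_scope == "gene":
        table = (
            table.groupby("gene", sort=False, group_keys=False)[table.columns]
            .apply(gene_level_fdr)
            .reset_index(drop=True)
        )
    else:
        table["p_fdr"] = de.bh_adjust(table["p_raw"].to_numpy())
    table["significant"] = table["p_fdr"] < fdr_cut
    order = ["gene", "mirna", "beta", "f_observed", "p_raw", "p_fdr",
             "n_subjects", "significant"]
    return table[order]
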