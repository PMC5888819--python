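"""Paired tumor/normal differential expression of mRNA counts.

Model
-----
For gene *g*, the count of sample *j* (subject *i(j)*, tissue *t(j)*) is
negative binomial,

    y_j ~ NB(mu_j, alpha_g),    log mu_j = a_i(j) + beta_t * t(j) + log T_j,

with a per-subject intercept ``a_i`` absorbing the paired design, a tissue
indicator ``t`` (1 = carcinoma, 0 = normal mucosa), and the log of the
sample's total protein-coding count ``T_j`` as offset, so the model works on
relative expression. The tumor/normal fold change is ``exp(beta_t)``.

The per-gene dispersion ``alpha_g`` (variance ``mu + alpha mu^2``) is
estimated by maximizing the Cox-Reid adjusted profile likelihood; the
adjustment (-0.5 log det X'WX) compensates for the many subject intercepts,
which would otherwise bias the dispersion low in a two-observations-per-
subject design. The tissue effect is tested by a likelihood-ratio test with
the dispersion held at its full-model estimate.

Expression is summarized as RPMPCG (reads per million protein-coding
genes): a gene's count divided by the sample's total protein-coding count,
times 1e6. Reported tumor/normal means are arithmetic means of per-sample
RPMPCG; the ratio of those means is reported alongside the model fold
change (the two nearly coincide in balanced designs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .errors import (DegenerateSampleError, FitError, SizeError,
                     SubgroupSizeError)
from .io import PairedStudy

MIN_DISPERSION = 1e-8
MAX_DISPERSION = 20.0

#: classification thresholds: FDR < 0.05 and fold change > 1.50 or < 0.67
FDR_CUT = 0.05
FC_UP = 1.50
FC_DOWN = 0.67


def rpmpcg(gene_count, total_pc_count):
    """Reads per million protein-coding genes: 1e6 * count / total."""
    total = np.asarray(total_pc_count, dtype=float)
    if np.any(total <= 0):
        raise DegenerateSampleError("non-positive protein-coding total")
    return 1e6 * np.asarray(gene_count, dtype=float) / total


def rpmpcg_matrix(counts: pd.DataFrame, totals: pd.Series) -> pd.DataFrame:
    """Column-wise RPMPCG of a genes x samples count matrix."""
    return pd.DataFrame(
        rpmpcg(counts.to_numpy(), totals[counts.columns].to_numpy()[None, :]),
        index=counts.index, columns=counts.columns,
    )


@dataclass
class NBFit:
    """Result of one paired negative-binomial fit."""

    fold_change: float
    p_raw: float
    beta: float
    dispersion: float
    llr: float
    converged: bool


_MAX_BETA = 30.0  # |log FC| clamp against separation-driven divergence


def _nb_loglik(y, mu, alpha):
    if alpha < 1e-10:
        return float(np.sum(y * np.log(mu) - mu - special.gammaln(y + 1)))
    inv = 1.0 / alpha
    return float(np.sum(
        special.gammaln(y + inv) - special.gammaln(inv) - special.gammaln(y + 1)
        + y * np.log(alpha * mu / (1.0 + alpha * mu))
        - inv * np.log1p(alpha * mu)
    ))


def _paired_irls(y, tumor_pos, pair_of, offset, alpha, with_tissue,
                 start=None, max_iter=60, tol=1e-10):
    """IRLS for the paired NB log-link model, exploiting design structure.

    The design is [subject one-hot block | tissue indicator]; its normal
    equations have an arrow shape (diagonal plus one border row/column),
    so each iteration is O(n) via the Schur complement instead of a dense
    solve over n+1 coefficients.

    Returns (subject intercepts a, tissue coefficient b, loglik, logdet of
    X'WX at the optimum, converged flag).
    """
    n_obs = y.size
    n_subj = pair_of.max() + 1
    tissue = np.zeros(n_obs)
    tissue[tumor_pos] = 1.0
    if start is None:
        tot_y = np.bincount(pair_of, weights=y, minlength=n_subj)
        tot_e = np.bincount(pair_of, weights=np.exp(offset), minlength=n_subj)
        a = np.log((tot_y + 0.5) / tot_e)
        b = 0.0
    else:
        a, b = start[0].copy(), float(start[1])
    converged = False
    for _ in range(max_iter):
        eta = a[pair_of] + b * tissue + offset
        mu = np.exp(np.clip(eta, -300, 300))
        mu = np.maximum(mu, 1e-12)
        w = mu / (1.0 + alpha * mu)
        z = (eta - offset) + (y - mu) / mu
        wz = w * z
        d = np.bincount(pair_of, weights=w, minlength=n_subj)
        r1 = np.bincount(pair_of, weights=wz, minlength=n_subj)
        if with_tissue:
            c = np.bincount(pair_of, weights=w * tissue, minlength=n_subj)
            s = float(np.sum(w * tissue))
            r2 = float(np.sum(wz * tissue))
            denom = s - float(np.sum(c * c / d))
            if denom <= 0:
                break
            b_new = (r2 - float(np.sum(c * r1 / d))) / denom
            b_new = float(np.clip(b_new, -_MAX_BETA, _MAX_BETA))
            a_new = (r1 - c * b_new) / d
        else:
            b_new = 0.0
            a_new = r1 / d
        delta = max(np.max(np.abs(a_new - a)), abs(b_new - b))
        a, b = a_new, b_new
        if delta < tol:
            converged = True
            break
    eta = a[pair_of] + b * tissue + offset
    mu = np.maximum(np.exp(np.clip(eta, -300, 300)), 1e-12)
    w = mu / (1.0 + alpha * mu)
    d = np.bincount(pair_of, weights=w, minlength=n_subj)
    if with_tissue:
        c = np.bincount(pair_of, weights=w * tissue, minlength=n_subj)
        s = float(np.sum(w * tissue))
        logdet = float(np.sum(np.log(d)) + np.log(max(s - np.sum(c * c / d), 1e-300)))
    else:
        logdet = float(np.sum(np.log(d)))
    return a, b, _nb_loglik(y, mu, alpha), logdet, converged


def fit_paired_nb(counts, tissue, subject_ids, log_total, gene: str = "") -> NBFit:
    """Fit the paired NB model for one gene and test the tissue effect.

    Parameters
    ----------
    counts : per-sample counts (length 2n).
    tissue : indicator, 1 for carcinoma and 0 for normal mucosa.
    subject_ids : subject label per sample (each appearing exactly twice).
    log_total : offset, the log total protein-coding count per sample.

    The dispersion maximizes the Cox-Reid adjusted profile likelihood of
    the full model; the tissue coefficient is then tested by a
    likelihood-ratio chi-square with one degree of freedom, holding the
    dispersion fixed.
    """
    y = np.asarray(counts, dtype=float)
    tissue = np.asarray(tissue, dtype=float)
    offset = np.asarray(log_total, dtype=float)
    subjects, codes = np.unique(np.asarray(subject_ids), return_inverse=True)
    if subjects.size < 2:
        raise SizeError(f"need at least 2 pairs to fit gene {gene or '?'}")
    if not np.any(y > 0):
        raise FitError(f"gene {gene or '?'} has no nonzero counts", gene=gene)
    tumor_pos = np.flatnonzero(tissue == 1)

    state = {"start": None}

    def neg_apl(log_alpha):
        alpha = float(np.exp(log_alpha))
        a, b, ll, logdet, _conv = _paired_irls(
            y, tumor_pos, codes, offset, alpha, with_tissue=True,
            start=state["start"])
        state["start"] = (a, b)
        return -(ll - 0.5 * logdet)

    opt = optimize.minimize_scalar(
        neg_apl,
        bounds=(np.log(MIN_DISPERSION), np.log(MAX_DISPERSION)),
        method="bounded",
        options={"xatol": 0.01, "maxiter": 60},
    )
    alpha = float(np.exp(opt.x))
    _a, beta, ll_full, _ld, conv_full = _paired_irls(
        y, tumor_pos, codes, offset, alpha, with_tissue=True,
        start=state["start"])
    _a0, _b0, ll_null, _ld0, conv_null = _paired_irls(
        y, tumor_pos, codes, offset, alpha, with_tissue=False)
    if not np.isfinite(beta) or not np.isfinite(ll_full):
        raise FitError(f"NB fit diverged for gene {gene or '?'}", gene=gene)

    llr = max(0.0, 2.0 * (ll_full - ll_null))
    p_raw = float(stats.chi2.sf(llr, df=1))
    return NBFit(fold_change=float(np.exp(beta)), p_raw=p_raw, beta=float(beta),
                 dispersion=alpha, llr=llr, converged=bool(conv_full and conv_null))


def fit_paired_conditional(counts, tissue, subject_ids, log_total,
                           gene: str = "") -> NBFit:
    """Paired tissue effect via the conditional (binomial) formulation.

    Conditioning each pair's tumor count on the pair total turns the
    Poisson version of the paired model into a binomial regression whose
    intercept-free logit is ``beta_t + log(T_tumor/T_normal)``, eliminating
    the subject intercepts exactly. Used as an independent cross-check of
    :func:`fit_paired_nb`; it ignores extra-Poisson dispersion.
    """
    y = np.asarray(counts, dtype=float)
    tissue = np.asarray(tissue, dtype=float)
    offset = np.asarray(log_total, dtype=float)
    subjects, codes = np.unique(np.asarray(subject_ids), return_inverse=True)
    n = subjects.size
    yt = np.zeros(n)
    yn = np.zeros(n)
    off = np.zeros(n)
    for j in range(y.size):
        if tissue[j] == 1:
            yt[codes[j]] = y[j]
            off[codes[j]] += offset[j]
        else:
            yn[codes[j]] = y[j]
            off[codes[j]] -= offset[j]
    keep = (yt + yn) > 0
    if keep.sum() < 2:
        raise SizeError(f"fewer than 2 informative pairs for gene {gene or '?'}")
    endog = np.column_stack([yt[keep], yn[keep]])
    X = np.ones((keep.sum(), 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(endog, X, family=sm.families.Binomial(), offset=off[keep])
        full = model.fit()
        null_ll = float(model.loglike(np.array([0.0])))
    beta = float(full.params[0])
    llr = max(0.0, 2.0 * (full.llf - null_ll))
    p_raw = float(stats.chi2.sf(llr, df=1))
    return NBFit(fold_change=float(np.exp(beta)), p_raw=p_raw, beta=beta,
                 dispersion=0.0, llr=llr, converged=bool(full.converged))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (order preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_dysregulation(fold_change: float, p_adjusted: float,
                           fdr_cut: float = FDR_CUT, up_cut: float = FC_UP,
                           down_cut: float = FC_DOWN) -> str:
    """Classify a gene as up, down, or none (strict inequalities)."""
    if fold_change <= 0:
        raise ValueError("fold change must be positive")
    if p_adjusted < fdr_cut and fold_change > up_cut:
        return "up"
    if p_adjusted < fdr_cut and fold_change < down_cut:
        return "down"
    return "none"


def de_table(study: PairedStudy, genes=None, *, fdr_cut: float = FDR_CUT,
             up_cut: float = FC_UP, down_cut: float = FC_DOWN,
             zero_fraction_cutoff: float = 0.90,
             subgroup: str = "overall") -> pd.DataFrame:
    """Differential-expression table for a study (one row per tested gene).

    Genes with zero counts in more than ``zero_fraction_cutoff`` of samples
    are excluded as unexpressed. Columns follow the reporting convention
    tumor mean / normal mean / fold change / p value / adjusted p value,
    plus the mean-ratio fold change and the dysregulation class.
    """
    counts = study.mrna_counts if genes is None else study.mrna_counts.loc[list(genes)]
    totals = study.total_pc_counts
    expr = rpmpcg_matrix(counts, totals)
    tumor_samples = study.samples_for("tumor")
    normal_samples = study.samples_for("normal")
    tissue = (study.sample_map.loc[counts.columns, "tissue"] == "tumor").to_numpy(float)
    subject_ids = study.sample_map.loc[counts.columns, "subject"].to_numpy()
    log_total = np.log(totals[counts.columns].to_numpy(float))

    zero_frac = (counts == 0).mean(axis=1)
    tested = counts.index[zero_frac <= zero_fraction_cutoff]

    rows = []
    for gene in tested:
        fit = fit_paired_nb(counts.loc[gene].to_numpy(), tissue, subject_ids,
                            log_total, gene=gene)
        rows.append({
            "gene": gene,
            "tumor_mean": float(expr.loc[gene, tumor_samples].mean()),
            "normal_mean": float(expr.loc[gene, normal_samples].mean()),
            "fold_change": fit.fold_change,
            "p_value": fit.p_raw,
            "fc_mean_ratio": float(
                expr.loc[gene, tumor_samples].mean()
                / max(expr.loc[gene, normal_samples].mean(), np.finfo(float).tiny)
            ),
            "dispersion": fit.dispersion,
        })
    table = pd.DataFrame(rows)
    if len(table):
        table["p_adjusted"] = bh_adjust(table["p_value"].to_numpy())
        table["direction"] = [
            classify_dysregulation(fc, q, fdr_cut, up_cut, down_cut)
            for fc, q in zip(table["fold_change"], table["p_adjusted"])
        ]
    else:
        table = pd.DataFrame(columns=["gene", "tumor_mean", "normal_mean",
                                      "fold_change", "p_value", "fc_mean_ratio",
                                      "dispersion", "p_adjusted", "direction"])
    table["subgroup"] = subgroup
    order = ["gene", "tumor_mean", "normal_mean", "fold_change", "p_value",
             "p_adjusted", "direction", "fc_mean_ratio", "dispersion", "subgroup"]
    return table[order]


def subgroup_de(study: PairedStudy, subgroup: str, **kwargs) -> pd.DataFrame:
    """Differential expression restricted to MSI or MSS subjects."""
    if subgroup not in ("MSI", "MSS"):
        raise ValueError(f"subgroup must be MSI or MSS, got {subgroup!r}")
    members = study.subjects.index[study.subjects["msi_status"] == subgroup]
    if len(members) < 2:
        raise SubgroupSizeError(
            f"subgroup {subgroup} has {len(members)} subjects; need at least 2"
        )
    return de_table(study.restrict_subjects(members), subgroup=subgroup, **kwargs)
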