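"""OLS association fits, residual-bootstrap p values, gene-level FDR."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import mirpair as mp
from mirpair.errors import CollinearityError, GroupingError, SpecError


def make_series(values, subjects=None):
    if subjects is None:
        subjects = [f"s{i}" for i in range(len(values))]
    return pd.Series(np.asarray(values, float), index=subjects)


@pytest.fixture()
def covariates():
    rng = np.random.default_rng(2)
    n = 40
    subjects = [f"s{i}" for i in range(n)]
    age = make_series(rng.normal(65, 10, n), subjects)
    sex = pd.Series(rng.choice(["M", "F"], n), index=subjects)
    return subjects, age, sex


def test_exact_linear_relationship_recovers_slope(covariates):
    subjects, age, sex = covariates
    x = make_series(np.linspace(-3, 3, len(subjects)), subjects)
    y = -0.3 * x + 2.0
    fit = mp.fit_association(y, x, age, sex)
    assert fit.beta == pytest.approx(-0.3, abs=1e-9)
    assert fit.f_observed > 1e10


def test_constant_mirna_is_a_collinearity_error(covariates):
    subjects, age, sex = covariates
    x = make_series(np.zeros(len(subjects)), subjects)
    y = make_series(np.random.default_rng(0).normal(size=len(subjects)), subjects)
    with pytest.raises(CollinearityError):
        mp.fit_association(y, x, age, sex)


def test_six_subject_toy_matches_normal_equations():
    subjects = [f"s{i}" for i in range(6)]
    x = make_series([1.0, 2.0, 3.0, 4.0, 5.0, 6.0], subjects)
    age = make_series([61.0, 70.0, 58.0, 66.0, 73.0, 65.0], subjects)
    sex = pd.Series(["M", "F", "M", "F", "M", "F"], index=subjects)
    y = make_series([2.0, 1.0, 4.0, 3.0, 6.0, 5.0], subjects)
    design = np.column_stack([np.ones(6), age, (sex == "M").astype(float), x])
    beta_hand = np.linalg.solve(design.T @ design, design.T @ y.to_numpy())
    fit = mp.fit_association(y, x, age, sex)
    assert fit.beta == pytest.approx(beta_hand[-1], abs=1e-10)


def test_bootstrap_p_is_deterministic_given_seed(covariates):
    subjects, age, sex = covariates
    rng = np.random.default_rng(4)
    x = make_series(rng.normal(size=len(subjects)), subjects)
    y = make_series(0.3 * x.to_numpy() + rng.normal(size=len(subjects)), subjects)
    fit = mp.fit_association(y, x, age, sex)
    spec = mp.BootstrapSpec(n_resamples=777, seed=11)
    assert mp.bootstrap_pvalue(fit, spec) == mp.bootstrap_pvalue(fit, spec)


def test_strong_effect_reaches_the_monte_carlo_floor(covariates):
    subjects, age, sex = covariates
    rng = np.random.default_rng(5)
    x = make_series(rng.normal(0, 5, len(subjects)), subjects)
    y = make_series(-2.0 * x.to_numpy() + rng.normal(0, 0.1, len(subjects)),
                    subjects)
    fit = mp.fit_association(y, x, age, sex)
    b = 2000
    p = mp.bootstrap_pvalue(fit, mp.BootstrapSpec(n_resamples=b, seed=3))
    assert p <= 2.0 / (b + 1)


def test_bootstrap_converges_to_classical_f_test():
    rng = np.random.default_rng(12)
    n = 150
    subjects = [f"s{i}" for i in range(n)]
    age = make_series(rng.normal(65, 10, n), subjects)
    sex = pd.Series(rng.choice(["M", "F"], n), index=subjects)
    x = make_series(rng.normal(size=n), subjects)
    y = make_series(0.15 * x.to_numpy() + rng.normal(size=n), subjects)
    fit = mp.fit_association(y, x, age, sex)
    p_boot = mp.bootstrap_pvalue(fit, mp.BootstrapSpec(n_resamples=20_000, seed=9))
    p_f = stats.f.sf(fit.f_observed, 1, n - 4)
    assert p_boot == pytest.approx(p_f, abs=0.01)


def test_beta_invariant_to_affine_age_rescaling(covariates):
    subjects, age, sex = covariates
    rng = np.random.default_rng(7)
    x = make_series(rng.normal(size=len(subjects)), subjects)
    y = make_series(0.4 * x.to_numpy() + 0.05 * age.to_numpy()
                    + rng.normal(size=len(subjects)), subjects)
    fit1 = mp.fit_association(y, x, age, sex)
    fit2 = mp.fit_association(y, x, 10.0 * age + 3.0, sex)
    assert fit1.beta == pytest.approx(fit2.beta, abs=1e-10)
    assert fit1.f_observed == pytest.approx(fit2.f_observed, rel=1e-9)


def test_invalid_bootstrap_spec():
    with pytest.raises(SpecError):
        mp.BootstrapSpec(n_resamples=0)


class TestGeneLevelFDR:
    def test_single_mirna_unchanged(self):
        df = pd.DataFrame({"gene": ["g"], "mirna": ["m"], "p_raw": [0.004]})
        assert mp.gene_level_fdr(df)["p_fdr"].tolist() == [0.004]

    def test_two_mirna_example(self):
        df = pd.DataFrame({"gene": ["g", "g"], "mirna": ["m1", "m2"],
                           "p_raw": [0.0002, 0.0001]})
        assert np.allclose(mp.gene_level_fdr(df)["p_fdr"], [0.0002, 0.0002])

    def test_mixed_genes_rejected(self):
        df = pd.DataFrame({"gene": ["g1", "g2"], "p_raw": [0.1, 0.2]})
        with pytest.raises(GroupingError):
            mp.gene_level_fdr(df)

    def test_reference_table_fdr_never_below_raw(self, reference_tables):
        t3 = reference_tables.table3
        assert (t3["p_fdr"] >= t3["p_raw"]).all()


def test_screen_adjusts_within_gene_and_flags_significance(small_study):
    study = small_study.study
    norm = mp.scale_normalize(study.mirna_signals)
    table = mp.association_screen(
        study, ["GENE0001", "GENE0002"], ["mir-0001", "mir-0002", "mir-0003"],
        mp.BootstrapSpec(n_resamples=199, seed=5),
        normalized_signals=norm.matrix)
    assert len(table) == 6
    for _gene, grp in table.groupby("gene"):
        assert np.allclose(grp["p_fdr"], mp.bh_adjust(grp["p_raw"].to_numpy()))
    assert (table["p_fdr"] >= table["p_raw"] - 1e-12).all()
    assert ((table["p_raw"] > 0) & (table["p_raw"] <= 1)).all()
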