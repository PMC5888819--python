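"""Paired NB differential expression: estimates, tests, BH, classification."""

import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import mirpair as mp
from mirpair.de import FC_DOWN, FC_UP
from mirpair.errors import (DegenerateSampleError, FitError,
                            SubgroupSizeError)


def bh_oracle(p):
    """Brute-force BH step-up with explicit monotonicity enforcement."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adj, 0, 1)
    return out


def paired_arrays(n, tumor, normal):
    y = np.empty(2 * n)
    y[0::2] = tumor
    y[1::2] = normal
    tissue = np.tile([1.0, 0.0], n)
    subj = np.repeat([f"s{i}" for i in range(n)], 2)
    return y, tissue, subj


class TestRpmpcg:
    def test_unit_total(self):
        assert mp.rpmpcg(10, 1_000_000) == 10.0

    def test_zero_count(self):
        assert mp.rpmpcg(0, 123456) == 0.0

    def test_scale_invariance(self):
        assert mp.rpmpcg(14, 2_000_000) == mp.rpmpcg(28, 4_000_000)

    def test_zero_total_rejected(self):
        with pytest.raises(DegenerateSampleError):
            mp.rpmpcg(5, 0)


class TestPairedNB:
    def test_null_data_gives_unit_fold_change(self):
        rng = np.random.default_rng(0)
        base = rng.poisson(500, 80)
        y, tissue, subj = paired_arrays(80, base, base)
        fit = mp.fit_paired_nb(y, tissue, subj, np.zeros(160))
        assert fit.fold_change == pytest.approx(1.0, abs=1e-6)
        assert fit.p_raw > 0.99

    def test_planted_halving_recovered(self):
        cfg = mp.SyntheticConfig(
            n_subjects=200, n_genes=2, n_mirnas=2, seed=8,
            planted_gene_log_fc={"GENE0001": np.log(0.5)})
        study, _ = mp.generate_study(cfg)
        tissue = (study.sample_map["tissue"] == "tumor").to_numpy(float)
        subj = study.sample_map["subject"].to_numpy()
        off = np.log(study.total_pc_counts.to_numpy(float))
        fit = mp.fit_paired_nb(study.mrna_counts.loc["GENE0001"].to_numpy(),
                               tissue, subj, off)
        assert 0.45 <= fit.fold_change <= 0.55

    def test_model_fc_close_to_mean_ratio_on_balanced_data(self, small_study):
        table = mp.de_table(small_study.study)
        ratio = table["fold_change"] / table["fc_mean_ratio"]
        assert ((ratio - 1).abs() < 0.15).all()

    def test_agrees_with_reference_glm_at_fixed_dispersion(self):
        # independent route: statsmodels GLM with explicit subject dummies
        cfg = mp.SyntheticConfig(n_subjects=40, n_genes=1, n_mirnas=2, seed=13,
                                 planted_gene_log_fc={"GENE0001": 0.4})
        study, _ = mp.generate_study(cfg)
        y = study.mrna_counts.loc["GENE0001"].to_numpy(float)
        tissue = (study.sample_map["tissue"] == "tumor").to_numpy(float)
        subj = study.sample_map["subject"].to_numpy()
        off = np.log(study.total_pc_counts.to_numpy(float))
        fit = mp.fit_paired_nb(y, tissue, subj, off)
        _, codes = np.unique(subj, return_inverse=True)
        X = np.zeros((y.size, codes.max() + 2))
        X[np.arange(y.size), codes] = 1.0
        X[:, -1] = tissue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=sm.families.NegativeBinomial(
                alpha=max(fit.dispersion, 1e-8)), offset=off).fit(
                maxiter=200, tol=1e-10)
        assert fit.beta == pytest.approx(res.params[-1], abs=1e-5)

    def test_agrees_with_conditional_formulation_when_poisson(self):
        # at negligible dispersion the conditional binomial is an exact
        # reformulation of the paired count model
        cfg = mp.SyntheticConfig(n_subjects=150, n_genes=1, n_mirnas=2,
                                 seed=21, nb_dispersion=1e-13,
                                 planted_gene_log_fc={"GENE0001": np.log(1.6)})
        study, _ = mp.generate_study(cfg)
        y = study.mrna_counts.loc["GENE0001"].to_numpy(float)
        tissue = (study.sample_map["tissue"] == "tumor").to_numpy(float)
        subj = study.sample_map["subject"].to_numpy()
        off = np.log(study.total_pc_counts.to_numpy(float))
        nb = mp.fit_paired_nb(y, tissue, subj, off)
        cond = mp.fit_paired_conditional(y, tissue, subj, off)
        assert nb.beta == pytest.approx(cond.beta, abs=5e-3)

    def test_all_zero_gene_raises_fit_error_with_gene_id(self):
        y, tissue, subj = paired_arrays(5, np.zeros(5), np.zeros(5))
        with pytest.raises(FitError, match="deadgene"):
            mp.fit_paired_nb(y, tissue, subj, np.zeros(10), gene="deadgene")


class TestBH:
    def test_single_p_unchanged(self):
        assert mp.bh_adjust([0.03]).tolist() == [0.03]

    def test_equally_spaced_example(self):
        adj = mp.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_ties_unchanged(self):
        assert np.allclose(mp.bh_adjust([0.2, 0.2, 0.2]), 0.2)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            mp.bh_adjust([0.5, 1.2])

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            p = rng.random(rng.integers(1, 40))
            assert np.allclose(mp.bh_adjust(p), bh_oracle(p))


class TestClassify:
    def test_reference_examples(self):
        assert mp.classify_dysregulation(0.18, 6.44e-29) == "down"
        assert mp.classify_dysregulation(3.70, 6.94e-53) == "up"

    def test_strict_boundaries(self):
        assert mp.classify_dysregulation(1.50, 1e-10) == "none"
        assert mp.classify_dysregulation(0.67, 1e-10) == "none"
        assert mp.classify_dysregulation(2.0, 0.05) == "none"

    def test_monotone_in_adjusted_p(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            fc = float(rng.uniform(0.05, 6.0))
            p_hi = float(rng.uniform(0, 1))
            p_lo = p_hi * rng.uniform(0, 1)
            hi = mp.classify_dysregulation(fc, p_hi)
            lo = mp.classify_dysregulation(fc, p_lo)
            if hi in ("up", "down"):
                assert lo == hi


class TestSubgroups:
    def test_single_status_subgroup_equals_overall(self):
        cfg = mp.SyntheticConfig(n_subjects=30, n_genes=4, n_mirnas=2,
                                 seed=6, frac_msi=0.0,
                                 planted_gene_log_fc={"GENE0002": np.log(2.2)})
        study, _ = mp.generate_study(cfg)
        overall = mp.de_table(study)
        mss = mp.subgroup_de(study, "MSS")
        for col in ("fold_change", "p_value", "p_adjusted", "direction"):
            assert (overall[col] == mss[col]).all()

    def test_msi_only_effect_found_in_msi_not_mss(self):
        cfg = mp.SyntheticConfig(
            n_subjects=160, n_genes=3, n_mirnas=2, seed=14, frac_msi=0.5,
            planted_subgroup_log_fc={("GENE0001", "MSI"): np.log(2.5)})
        study, _ = mp.generate_study(cfg)
        msi = mp.subgroup_de(study, "MSI").set_index("gene")
        mss = mp.subgroup_de(study, "MSS").set_index("gene")
        assert msi.loc["GENE0001", "direction"] == "up"
        assert mss.loc["GENE0001", "direction"] == "none"

    def test_empty_subgroup_raises(self):
        cfg = mp.SyntheticConfig(n_subjects=10, n_genes=2, n_mirnas=2,
                                 seed=1, frac_msi=0.0)
        study, _ = mp.generate_study(cfg)
        with pytest.raises(SubgroupSizeError):
            mp.subgroup_de(study, "MSI")


def test_de_table_excludes_mostly_zero_genes(small_study):
    study = small_study.study
    counts = study.mrna_counts.copy()
    dead = pd.Series(0, index=counts.columns, name="DEADGENE")
    counts = pd.concat([counts, dead.to_frame().T])
    study2 = mp.PairedStudy(study.subjects, counts, study.mirna_signals,
                            study.sample_map, study.total_pc_counts)
    table = mp.de_table(study2)
    assert "DEADGENE" not in set(table["gene"])
    assert (table["p_adjusted"] >= table["p_value"] - 1e-15).all()
    assert (FC_DOWN < 1 < FC_UP)  # thresholds wired as documented
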