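import numpy as np
import pandas as pd
import pytest

from coexmerge.eb_dc import (
    EBInputs,
    EBModel,
    biweight_midcorrelation,
    crit_fun,
    default_patterns,
    eb_pairs,
    fit_em,
    initialize_hyperparameters,
    make_d_matrix,
)
from coexmerge.preprocess import zscore_merge
from coexmerge.synthetic_data import SimulationConfig, simulate_studies

from conftest import make_study


def _inputs_from_z(z: np.ndarray) -> EBInputs:
    """EBInputs whose Fisher-z-transformed D equals z (2 conditions)."""
    d = np.tanh(z)
    pairs = [(f"a{i}", f"b{i}") for i in range(len(d))]
    return EBInputs(
        d=pd.DataFrame(d, columns=["1", "2"], index=[f"a{i}|b{i}" for i in range(len(d))]),
        pairs=pairs,
        patterns=default_patterns(2),
    )


class TestBiweightMidcorrelation:
    def test_perfectly_correlated(self):
        x = np.array([1.0, 2.0, 3.0, 5.0, 8.0])
        assert biweight_midcorrelation(x, x) == pytest.approx(1.0)

    def test_perfectly_anticorrelated(self):
        x = np.array([1.0, 2.0, 3.0, 5.0, 8.0])
        assert biweight_midcorrelation(x, -x) == pytest.approx(-1.0)

    def test_close_to_pearson_on_clean_gaussian(self):
        rng = np.random.default_rng(0)
        z = rng.standard_normal(200)
        x = np.sqrt(0.7) * z + np.sqrt(0.3) * rng.standard_normal(200)
        y = np.sqrt(0.7) * z + np.sqrt(0.3) * rng.standard_normal(200)
        pearson = np.corrcoef(x, y)[0, 1]
        assert abs(biweight_midcorrelation(x, y) - pearson) < 0.1

    def test_zero_mad_falls_back_to_pearson(self):
        x = np.array([1.0, 1.0, 1.0, 1.0, 9.0])  # MAD = 0
        y = np.array([0.5, 1.5, 2.0, 3.0, 4.0])
        with pytest.warns(UserWarning, match="zero MAD"):
            r = biweight_midcorrelation(x, y)
        assert r == pytest.approx(np.corrcoef(x, y)[0, 1])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            biweight_midcorrelation([1.0, 2.0], [1.0, 2.0])


class TestMakeDMatrix:
    def test_pair_count_formula(self, merged_planted):
        inputs = make_d_matrix(merged_planted, list(merged_planted.gene_ids[:3]))
        assert inputs.n_pairs == 3
        assert inputs.d.shape == (3, 2)

    def test_identical_condition_submatrices_give_identical_columns(self):
        rng = np.random.default_rng(1)
        half = rng.normal(size=(4, 6))
        merged = zscore_merge([make_study(np.hstack([half, half]), 6, 6)])
        inputs = make_d_matrix(merged, [f"g{i}" for i in range(4)])
        assert np.allclose(inputs.d.iloc[:, 0], inputs.d.iloc[:, 1])

    def test_entries_match_elementwise_oracle(self, merged_planted):
        genes = sorted(merged_planted.gene_ids[:4])
        inputs = make_d_matrix(merged_planted, genes)
        case_cols = merged_planted.samples_of("case")
        row = 0
        for i in range(4):
            for j in range(i + 1, 4):
                x = merged_planted.expr.loc[genes[i], case_cols].to_numpy()
                y = merged_planted.expr.loc[genes[j], case_cols].to_numpy()
                assert inputs.d.iloc[row]["case"] == pytest.approx(
                    biweight_midcorrelation(x, y), abs=1e-12
                )
                row += 1


class TestInitialization:
    def test_degenerate_single_value(self):
        z = np.full((12, 2), 0.3)
        model = initialize_hyperparameters(_inputs_from_z(np.arctanh(z)))
        assert len(model.means) == 1
        assert model.means_corr[0] == pytest.approx(0.3, abs=1e-6)

    def test_bimodal_mixture_recovery(self):
        rng = np.random.default_rng(2)
        flat = np.where(
            rng.random(2000) < 0.5,
            rng.normal(0.0, 0.05, 2000),
            rng.normal(0.8, 0.05, 2000),
        )
        model = initialize_hyperparameters(_inputs_from_z(np.arctanh(np.clip(flat.reshape(1000, 2), -0.999, 0.999))), seed=0)
        means = np.sort(model.means_corr)
        # two dominant components near 0 and 0.8
        assert min(abs(means - 0.0)) < 0.05
        assert min(abs(means - 0.8)) < 0.05
        assert model.bic_by_k[2] < model.bic_by_k[1]


class TestEM:
    def test_zero_dc_prior_forces_zero_posterior(self):
        rng = np.random.default_rng(3)
        z = rng.normal(0, 0.3, size=(50, 2))
        inputs = _inputs_from_z(z)
        init = EBModel(
            means=np.array([0.0]),
            sds=np.array([0.3]),
            weights=np.array([1.0]),
            pattern_priors=np.array([1.0, 0.0]),
        )
        model = fit_em(inputs, init, variant="zero-step")
        assert np.allclose(model.posterior_dc.to_numpy(), 0.0)

    def test_full_em_loglik_monotone(self):
        rng = np.random.default_rng(4)
        n = 400
        ec = rng.normal(0.0, 0.2, size=(n, 1)) + rng.normal(0, 0.05, size=(n, 2))
        dc = np.column_stack([rng.normal(1.0, 0.2, 60), rng.normal(0.0, 0.2, 60)])
        z = np.vstack([ec, dc])
        inputs = _inputs_from_z(z)
        init = initialize_hyperparameters(inputs, seed=0)
        model = fit_em(inputs, init, variant="full")
        ll = np.array(model.loglik_trace)
        assert np.all(np.diff(ll) > -1e-6)

    def test_dc_prior_weight_recovered(self):
        rng = np.random.default_rng(5)
        p = 3000
        is_dc = rng.random(p) < 0.10
        comp_means = np.array([0.0, 1.0])
        ec_comp = rng.integers(0, 2, p)
        z = np.empty((p, 2))
        z[:, 0] = rng.normal(comp_means[ec_comp], 0.15)
        z[:, 1] = rng.normal(comp_means[ec_comp], 0.15)
        flip = is_dc  # DC rows: second condition from the other component
        z[flip, 1] = rng.normal(comp_means[1 - ec_comp[flip]], 0.15)
        inputs = _inputs_from_z(z)
        init = initialize_hyperparameters(inputs, seed=0)
        model = fit_em(inputs, init, variant="full")
        dc_prior = 1.0 - model.pattern_priors[0]
        assert abs(dc_prior - 0.10) < 0.05

    def test_unknown_variant_rejected(self):
        inputs = _inputs_from_z(np.zeros((12, 2)))
        init = initialize_hyperparameters(inputs)
        with pytest.raises(ValueError, match="variant"):
            fit_em(inputs, init, variant="two-step")


class TestCritFun:
    def test_two_confident_pairs_called(self):
        cutoff, called = crit_fun(np.array([1.0, 1.0, 0.0]), target_fdr=0.05)
        assert called.sum() == 2

    def test_uninformative_posteriors_give_empty_set(self):
        cutoff, called = crit_fun(np.full(10, 0.5), target_fdr=0.05)
        assert called.sum() == 0 and np.isinf(cutoff)

    def test_enumerated_cutoff_example(self):
        # running means of (1-pp): 0.01, 0.02, 0.0467, 0.16 -> cutoff at 0.90
        pp = np.array([0.99, 0.97, 0.90, 0.50])
        cutoff, called = crit_fun(pp, target_fdr=0.05)
        assert cutoff == pytest.approx(0.90)
        assert called.sum() == 3

    def test_posterior_fdr_controlled_on_every_run(self, merged_planted, planted_sim):
        _, _, truth = planted_sim
        genes = sorted(truth.de_genes)[:20]
        inputs = make_d_matrix(merged_planted, genes)
        init = initialize_hyperparameters(inputs, seed=0)
        model = fit_em(inputs, init, variant="one-step")
        pairs, table = eb_pairs(inputs, model, target_fdr=0.05)
        called = table["called"]
        if called.any():
            assert (1.0 - table.loc[called, "posterior_dc"]).mean() <= 0.05

    def test_invalid_posterior_rejected(self):
        with pytest.raises(ValueError):
            crit_fun(np.array([0.5, 1.2]))


def test_planted_pairs_get_high_posterior(merged_planted, planted_sim):
    _, _, truth = planted_sim
    genes = sorted(truth.de_genes)
    inputs = make_d_matrix(merged_planted, genes)
    init = initialize_hyperparameters(inputs, seed=0)
    model = fit_em(inputs, init, variant="one-step")
    pairs, table = eb_pairs(inputs, model, target_fdr=0.05)
    called = {tuple(sorted(p)) for p in pairs.pairs}
    overlap = called & truth.pair_set
    assert len(overlap) >= 8  # most planted pairs called
    realized_fdr = 1 - len(overlap) / max(len(called), 1)
    assert realized_fdr <= 0.2
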