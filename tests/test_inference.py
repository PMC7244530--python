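"""Tests for the statistical layer: trees, classical tests, the Gibbs LMM."""

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from patternspectra import inference, synth
from patternspectra.errors import ConfigurationError, DataError
from patternspectra.inference import (
    ModelSpec,
    dic,
    fit_mcmc_lmm,
    hpd_interval,
    one_way_anova,
    phylo_covariance,
    pmcmc,
    read_newick,
    sex_deviation_model,
    two_sample_t,
)


def brownian_tip_covariance(phylo, taxa_order, n_reps, seed):
    """Independent oracle: simulate Brownian motion along the tree edges."""
    rng = np.random.default_rng(seed)
    values = {}
    for node in phylo.tree.preorder_node_iter():
        parent = node.parent_node
        base = values[id(parent)] if parent is not None else np.zeros(n_reps)
        length = node.edge.length or 0.0
        values[id(node)] = base + np.sqrt(length) * rng.standard_normal(n_reps)
    leaves = {leaf.taxon.label: values[id(leaf)] for leaf in phylo.tree.leaf_node_iter()}
    tips = np.array([leaves[t] for t in taxa_order])
    return np.cov(tips)


def random_ultrametric_newick(rng, n_taxa):
    labels = [f"t{i}" for i in range(n_taxa)]

    def sub(labs, parent_h):
        if len(labs) == 1:
            return f"{labs[0]}:{parent_h:.6f}"
        k = int(rng.integers(1, len(labs)))
        node_h = float(rng.uniform(0, parent_h))
        left = sub(labs[:k], node_h)
        right = sub(labs[k:], node_h)
        return f"({left},{right}):{parent_h - node_h:.6f}"

    root_h = 1.0
    k = int(rng.integers(1, n_taxa)) if n_taxa > 1 else 1
    return f"({sub(labels[:k], root_h)},{sub(labels[k:], root_h)});"


class TestNewick:
    def test_two_taxon_tree(self):
        t = read_newick("(A:1,B:1);")
        assert set(t.taxa) == {"A", "B"}
        c = phylo_covariance(t, ["A", "B"])
        assert np.allclose(np.diag(c), 1.0)

    def test_nested_tree_shared_paths(self):
        t = read_newick("((A:1,B:1):1,C:2);")
        c = phylo_covariance(t, ["A", "B", "C"])
        assert np.allclose(c, [[2, 1, 0], [1, 2, 0], [0, 0, 2]])

    def test_malformed_newick_rejected(self):
        with pytest.raises(DataError, match="parse"):
            read_newick("(A:1,(B:1);")

    def test_duplicate_taxa_rejected(self):
        with pytest.raises(DataError, match="duplicate"):
            read_newick("(A:1,A:1);")

    def test_missing_branch_length_rejected(self):
        with pytest.raises(DataError, match="branch length"):
            read_newick("(A:1,B);")

    def test_round_trip_preserves_structure(self):
        t = read_newick("((A:1,B:1):1,C:2);")
        t2 = read_newick(t.write_newick())
        assert np.allclose(
            phylo_covariance(t, ["A", "B", "C"]),
            phylo_covariance(t2, ["A", "B", "C"]),
        )


class TestPhyloCovariance:
    def test_star_tree_gives_identity(self):
        t = read_newick("(A:1,B:1,C:1,D:1);")
        assert np.allclose(phylo_covariance(t, list("ABCD")), np.eye(4))

    def test_unknown_taxon_rejected(self):
        t = read_newick("(A:1,B:1);")
        with pytest.raises(DataError, match="not present"):
            phylo_covariance(t, ["A", "Z"])

    def test_matches_brownian_simulation_oracle(self):
        t = read_newick("((A:1,B:1):1,C:2);")
        sim = brownian_tip_covariance(t, ["A", "B", "C"], n_reps=20_000, seed=0)
        # MC standard error of each entry is about sqrt(5/n) ~ 0.016
        assert np.allclose(sim, [[2, 1, 0], [1, 2, 0], [0, 0, 2]], atol=0.08)

    def test_random_ultrametric_trees_are_psd_and_unit_diagonal(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            n = int(rng.integers(3, 11))
            t = read_newick(random_ultrametric_newick(rng, n))
            c = phylo_covariance(t, [f"t{i}" for i in range(n)], normalize=True)
            assert np.allclose(c, c.T)
            assert np.allclose(np.diag(c), 1.0)
            assert np.linalg.eigvalsh(c).min() > -1e-9


class TestClassicalTests:
    def test_two_group_anova_closed_form(self):
        res = one_way_anova([[1, 2, 3], [4, 5, 6]])
        assert res.f_stat == pytest.approx(13.5)
        assert (res.df_between, res.df_within) == (1, 4)

    def test_two_group_f_equals_squared_t(self):
        rng = np.random.default_rng(4)
        a, b = rng.standard_normal(12), 0.5 + rng.standard_normal(15)
        f = one_way_anova([a, b])
        t = two_sample_t(a, b)
        assert t.t_stat**2 == pytest.approx(f.f_stat, rel=1e-12)
        assert t.p_value == pytest.approx(f.p_value, rel=1e-9)

    def test_identical_samples_give_t_zero_p_one(self):
        rng = np.random.default_rng(5)
        a = rng.standard_normal(10)
        res = two_sample_t(a, a)
        assert res.t_stat == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_swapping_samples_flips_sign_only(self):
        rng = np.random.default_rng(6)
        a, b = rng.standard_normal(8), 1 + rng.standard_normal(9)
        r1, r2 = two_sample_t(a, b), two_sample_t(b, a)
        assert r1.t_stat == pytest.approx(-r2.t_stat)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DataError):
            one_way_anova([[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(DataError):
            two_sample_t([2.0, 2.0], [2.0, 2.0])
        with pytest.raises(ConfigurationError):
            one_way_anova([[1.0, 2.0]])

    def test_anova_type_i_error_is_calibrated(self):
        """Null rejection rate at alpha = 0.05 over 1000 simulations."""
        rng = np.random.default_rng(7)
        rejections = 0
        for _ in range(1000):
            groups = rng.standard_normal((4, 25))
            if one_way_anova(list(groups)).p_value < 0.05:
                rejections += 1
        assert 0.035 <= rejections / 1000 <= 0.065


class TestPosteriorSummaries:
    def test_pmcmc_floor_for_one_sided_chain(self):
        assert pmcmc(np.ones(1000)) == pytest.approx(0.002)

    def test_pmcmc_balanced_chain_is_one(self):
        d = np.concatenate([np.ones(500), -np.ones(500)])
        assert pmcmc(d) == pytest.approx(1.0)

    def test_pmcmc_arithmetic(self):
        d = np.concatenate([np.ones(900), -np.ones(100)])
        assert pmcmc(d) == pytest.approx(0.2)

    def test_hpd_of_constant_draws_is_degenerate(self):
        lo, hi = hpd_interval(np.full(50, 3.25))
        assert (lo, hi) == (3.25, 3.25)

    def test_hpd_of_uniform_integers_matches_window_search(self):
        draws = np.arange(1, 101, dtype=float)
        lo, hi = hpd_interval(draws, 0.95)
        assert hi - lo == pytest.approx(94.0)
        # exhaustive window search oracle
        k = 95
        widths = [draws[i + k - 1] - draws[i] for i in range(len(draws) - k + 1)]
        assert hi - lo == pytest.approx(min(widths))

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(shift=st.floats(-100, 100))
    def test_hpd_is_shift_equivariant(self, shift):
        rng = np.random.default_rng(8)
        draws = rng.standard_normal(200)
        lo, hi = hpd_interval(draws)
        lo2, hi2 = hpd_interval(draws + shift)
        assert lo2 == pytest.approx(lo + shift, abs=1e-9)
        assert hi2 == pytest.approx(hi + shift, abs=1e-9)


class TestMixedModel:
    def _noise_free_table(self, study_sim_config, tree, b=0.5, seed=0):
        cfg = study_sim_config(
            intercept_b0=0.1, effect_b=b, sigma_phylo=0.0, sigma_site=0.0,
            sigma_resid=0.0, seed=seed,
        )
        return synth.generate_study_dataset(cfg, tree)

    def test_degenerate_noise_recovers_fixed_effect(self, study_sim_config, default_tree):
        """With zero noise and strong signal the effect is pinned to truth."""
        table = self._noise_free_table(study_sim_config, default_tree)
        # add minute jitter so the residual variance is positive but tiny
        rng = np.random.default_rng(0)
        table = table.assign(slope=table["slope"] + 1e-4 * rng.standard_normal(len(table)))
        spec = ModelSpec(
            response="slope", fixed=("habitat_slope",), random=(),
            iterations=22_000, burn_in=2_000, thin=10, seed=1,
        )
        post = fit_mcmc_lmm(table, spec)
        row = post.summaries.set_index("parameter").loc["habitat_slope"]
        assert abs(row["mean"] - 0.5) < 0.02
        assert row["pmcmc"] <= 0.001

    def test_same_seed_gives_identical_draws(self, study_sim_config, default_tree):
        cfg = study_sim_config(sigma_phylo=0.2, sigma_site=0.1, sigma_resid=0.2, seed=3)
        table = synth.generate_study_dataset(cfg, default_tree)
        spec = ModelSpec(response="slope", fixed=("habitat_slope",),
                         iterations=4_000, burn_in=500, thin=5, seed=11)
        p1 = fit_mcmc_lmm(table, spec, default_tree)
        p2 = fit_mcmc_lmm(table, spec, default_tree)
        assert np.array_equal(p1.theta_draws, p2.theta_draws)
        assert p1.dic == p2.dic
        assert dic(p1) == pytest.approx(p1.dic, rel=1e-12)

    def test_draw_count_matches_chain_settings(self, study_sim_config, default_tree):
        cfg = study_sim_config(sigma_resid=0.2, seed=4)
        table = synth.generate_study_dataset(cfg, default_tree)
        spec = ModelSpec(response="slope", fixed=("habitat_slope",),
                         iterations=5_000, burn_in=1_000, thin=20, seed=0)
        post = fit_mcmc_lmm(table, spec, default_tree)
        assert post.theta_draws.shape[0] == (5_000 - 1_000) // 20
        for name in ("sigma2_phylo", "sigma2_site", "sigma2_resid"):
            assert np.all(post.draws[name] > 0)

    def test_vague_prior_without_random_terms_matches_ols(self, study_sim_config, default_tree):
        cfg = study_sim_config(effect_b=0.7, sigma_resid=0.3, seed=5)
        table = synth.generate_study_dataset(cfg, default_tree)
        spec = ModelSpec(response="slope", fixed=("habitat_slope",), random=(),
                         iterations=20_000, burn_in=2_000, thin=10, seed=2)
        post = fit_mcmc_lmm(table, spec)
        x = np.column_stack([np.ones(len(table)), table["habitat_slope"]])
        ols = np.linalg.lstsq(x, table["slope"].to_numpy(), rcond=None)[0]
        row = post.summaries.set_index("parameter")
        assert row.loc["(Intercept)", "mean"] == pytest.approx(ols[0], abs=0.02)
        assert row.loc["habitat_slope", "mean"] == pytest.approx(ols[1], abs=0.02)

    def test_chain_is_stationary_on_default_study(self, study_sim_config, default_tree):
        """Split-half mean difference within 3 Monte-Carlo standard errors."""
        import arviz

        cfg = study_sim_config(effect_b=0.5, sigma_phylo=0.2, sigma_site=0.1,
                               sigma_resid=0.2, seed=6)
        table = synth.generate_study_dataset(cfg, default_tree)
        spec = ModelSpec(response="slope", fixed=("habitat_slope",),
                         iterations=20_000, burn_in=2_000, thin=10, seed=3)
        post = fit_mcmc_lmm(table, spec, default_tree)
        d = post.draws["habitat_slope"]
        half = len(d) // 2
        ess = float(arviz.ess(d))
        mcse = d.std() / np.sqrt(ess)
        assert abs(d[:half].mean() - d[half:].mean()) < 3 * mcse

    def test_species_tree_mismatch_rejected(self, study_sim_config, default_tree):
        cfg = study_sim_config(sigma_resid=0.1, seed=7)
        table = synth.generate_study_dataset(cfg, default_tree)
        small = read_newick("(E_zonale:1,E_swaini:1);")
        spec = ModelSpec(response="slope", fixed=("habitat_slope",),
                         iterations=2_000, burn_in=500, thin=5)
        with pytest.raises(DataError, match="absent"):
            fit_mcmc_lmm(table, spec, small)

    def test_non_ultrametric_tree_requires_scaling_opt_out(self):
        t = read_newick("((A:1,B:1):1,C:2.5);")
        import pandas as pd

        table = pd.DataFrame({
            "species": list("AABBCC") * 4,
            "site": [s + "1" for s in list("AABBCC") * 4],
            "slope": np.random.default_rng(0).standard_normal(24),
        })
        spec = ModelSpec(response="slope", fixed=(), random=("phylo",),
                         iterations=2_000, burn_in=500, thin=5)
        with pytest.raises(DataError, match="ultrametric"):
            fit_mcmc_lmm(table, spec, t)
        spec2 = ModelSpec(response="slope", fixed=(), random=("phylo",),
                          iterations=2_000, burn_in=500, thin=5, scale_phylo=False)
        post = fit_mcmc_lmm(table, spec2, t)
        assert np.all(post.draws["sigma2_phylo"] > 0)


class TestDic:
    def test_noise_predictor_costs_a_positive_penalty(self, study_sim_config, default_tree):
        """Adding a pure-noise fixed effect raises DIC in the median."""
        deltas = []
        for rep in range(12):
            cfg = study_sim_config(effect_b=0.5, sigma_phylo=0.15, sigma_site=0.05,
                                   sigma_resid=0.2, seed=300 + rep)
            table = synth.generate_study_dataset(cfg, default_tree)
            table = table.assign(
                noise=np.random.default_rng(rep).standard_normal(len(table))
            )
            base = ModelSpec(response="slope", fixed=("habitat_slope",),
                             iterations=10_000, burn_in=1_000, thin=5, seed=rep)
            bigger = ModelSpec(response="slope", fixed=("habitat_slope", "noise"),
                               iterations=10_000, burn_in=1_000, thin=5, seed=rep)
            d0 = fit_mcmc_lmm(table, base, default_tree).dic
            d1 = fit_mcmc_lmm(table, bigger, default_tree).dic
            deltas.append(d1 - d0)
        assert np.median(deltas) > 0


class TestSexDeviationModel:
    def _deviation_table(self, study_sim_config, tree, sex_effect, seed):
        cfg = study_sim_config(
            sites_per_species=2, fish_per_site=20, intercept_b0=0.5, effect_b=0.0,
            sigma_phylo=0.05, sigma_site=0.02, sigma_resid=0.1,
            sex_effect=sex_effect, seed=seed,
        )
        table = synth.generate_study_dataset(cfg, tree)
        return table.rename(columns={"slope": "deviation"})

    def test_recovers_negative_sex_effect(self, study_sim_config, default_tree):
        table = self._deviation_table(study_sim_config, default_tree, -0.12, seed=21)
        spec = ModelSpec(response="deviation", fixed=("is_female",),
                         iterations=20_000, burn_in=2_000, thin=10, seed=5)
        post = sex_deviation_model(table, default_tree, spec)
        row = post.summaries.set_index("parameter").loc["is_female"]
        assert row["mean"] < 0
        assert row["hpd_lo"] <= -0.12 <= row["hpd_hi"]

    def test_null_sex_effect_is_rarely_significant(self, study_sim_config, default_tree):
        hits = 0
        n_reps = 20
        for rep in range(n_reps):
            table = self._deviation_table(study_sim_config, default_tree, 0.0,
                                          seed=400 + rep)
            spec = ModelSpec(response="deviation", fixed=("is_female",),
                             iterations=6_000, burn_in=1_000, thin=10, seed=rep)
            post = sex_deviation_model(table, default_tree, spec)
            p = post.summaries.set_index("parameter").loc["is_female", "pmcmc"]
            hits += p < 0.05
        assert hits <= 3  # >= 85% of replicates non-significant

    def test_missing_deviation_rejected(self, study_sim_config, default_tree):
        cfg = study_sim_config(seed=1)
        table = synth.generate_study_dataset(cfg, default_tree)
        with pytest.raises(DataError, match="deviation"):
            sex_deviation_model(table, default_tree)
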