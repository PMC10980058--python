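import math

import numpy as np
import pandas as pd
import pytest
import tskit
from hypothesis import given, settings
from hypothesis import strategies as st

import argtrait
from argtrait.effect_sim import (
    choose_causal_allele,
    scale_effect,
    select_causal_sites,
    sim_trait,
)

from argtrait.fixtures import FixtureSpec, random_arg

from conftest import make_random_arg


class TestSiteSelection:
    def test_default_is_one_site(self, fig1, fixed_model):
        effects = sim_trait(fig1, fixed_model, random_seed=3)
        assert effects["site_id"].nunique() == 1

    def test_all_eligible_sites_any_seed(self):
        ts = make_random_arg(5)
        eligible = set(ts.tables.mutations.site)
        for seed in (0, 1, 99):
            chosen = select_causal_sites(ts, len(eligible), np.random.default_rng(seed))
            assert sorted(chosen) == sorted(eligible)

    def test_mutation_free_sites_never_selected(self, fig1):
        tc = fig1.dump_tables()
        tc.sites.add_row(position=0.8, ancestral_state="C")  # no mutations
        ts = tc.tree_sequence()
        for seed in range(50):
            assert select_causal_sites(ts, rng=np.random.default_rng(seed)) == [0]
        with pytest.raises(ValueError, match="exceeds"):
            select_causal_sites(ts, 2, np.random.default_rng(0))

    def test_selection_is_uniform(self):
        # 3 eligible sites, 10^4 single-site draws: each ~1/3
        ts = random_arg(FixtureSpec(n_individuals=4, n_sites=3, seed=40))
        eligible = sorted(set(ts.tables.mutations.site))
        assert len(eligible) == 3
        rng = np.random.default_rng(2024)
        counts = pd.Series(
            [select_causal_sites(ts, 1, rng)[0] for _ in range(10_000)]
        ).value_counts(normalize=True)
        for site in eligible:
            assert abs(counts[site] - 1 / 3) < 0.02

    def test_returned_in_position_order(self):
        ts = make_random_arg(8, max_sites=15)
        chosen = select_causal_sites(
            ts, len(set(ts.tables.mutations.site)), np.random.default_rng(1)
        )
        positions = [ts.site(s).position for s in chosen]
        assert positions == sorted(positions)


class TestCausalAllele:
    def test_fig1_only_t_is_eligible(self, fig1):
        # derived states are {T, A}; the back mutation to A is silent
        for seed in range(20):
            assert choose_causal_allele(fig1, 0, np.random.default_rng(seed)) == "T"

    def test_single_candidate(self):
        tc = tskit.TableCollection(sequence_length=1.0)
        tc.individuals.add_row()
        n0 = tc.nodes.add_row(flags=tskit.NODE_IS_SAMPLE, time=0, individual=0)
        tc.sites.add_row(position=0.5, ancestral_state="A")
        tc.mutations.add_row(site=0, node=n0, derived_state="G")
        ts = tc.tree_sequence()
        assert choose_causal_allele(ts, 0, np.random.default_rng(0)) == "G"

    def test_two_candidates_uniform(self):
        tc = tskit.TableCollection(sequence_length=1.0)
        tc.individuals.add_row()
        n0 = tc.nodes.add_row(flags=tskit.NODE_IS_SAMPLE, time=0, individual=0)
        n1 = tc.nodes.add_row(flags=tskit.NODE_IS_SAMPLE, time=0, individual=0)
        tc.sites.add_row(position=0.5, ancestral_state="A")
        tc.mutations.add_row(site=0, node=n0, derived_state="C")
        tc.mutations.add_row(site=0, node=n1, derived_state="G")
        ts = tc.tree_sequence()
        rng = np.random.default_rng(5)
        draws = [choose_causal_allele(ts, 0, rng) for _ in range(10_000)]
        frac_c = draws.count("C") / len(draws)
        assert abs(frac_c - 0.5) < 0.02

    def test_all_silent_mutations_error(self):
        tc = tskit.TableCollection(sequence_length=1.0)
        tc.individuals.add_row()
        n0 = tc.nodes.add_row(flags=tskit.NODE_IS_SAMPLE, time=0, individual=0)
        tc.sites.add_row(position=0.5, ancestral_state="A")
        tc.mutations.add_row(site=0, node=n0, derived_state="A")
        ts = tc.tree_sequence()
        with pytest.raises(ValueError, match="no derived allele"):
            choose_causal_allele(ts, 0, np.random.default_rng(0))


class TestScaleEffect:
    def test_alpha_zero_is_identity(self):
        for beta in (-2.0, 0.0, 0.7):
            for p in (0.0, 0.1, 0.5, 1.0):  # p unconstrained when alpha = 0
                assert scale_effect(beta, p, 0.0) == beta

    def test_printed_formula(self):
        # (2 * 0.5 * 0.5)^(-1/2) = sqrt(2)
        assert scale_effect(1.0, 0.5, -1.0) == pytest.approx(math.sqrt(2), rel=1e-12)
        assert scale_effect(2.0, 0.1, 1.0) == pytest.approx(
            2.0 * (2 * 0.1 * 0.9) ** 0.5, rel=1e-12
        )

    def test_rarer_allele_larger_effect(self):
        assert abs(scale_effect(2.0, 0.1, -1.0)) > abs(scale_effect(2.0, 0.4, -1.0))

    @pytest.mark.parametrize("p", [0.0, 1.0])
    def test_degenerate_frequency_rejected(self, p):
        with pytest.raises(ValueError, match="0 < p < 1"):
            scale_effect(1.0, p, -1.0)

    @given(
        beta=st.floats(-10, 10, allow_nan=False),
        p1=st.floats(0.001, 0.999),
        p2=st.floats(0.001, 0.999),
        alpha=st.floats(-3, -0.01),
    )
    @settings(derandomize=True, max_examples=200)
    def test_magnitude_monotone_in_heterozygosity(self, beta, p1, p2, alpha):
        h1, h2 = p1 * (1 - p1), p2 * (1 - p2)
        s1 = abs(scale_effect(beta, p1, alpha))
        s2 = abs(scale_effect(beta, p2, alpha))
        if h1 < h2:
            assert s1 >= s2
        elif h1 > h2:
            assert s1 <= s2


class TestSimTrait:
    def test_fig1_fixed_effect(self, fig1, fixed_model):
        effects = sim_trait(fig1, fixed_model, random_seed=0)
        assert len(effects) == 1
        row = effects.iloc[0]
        assert row["causal_allele"] == "T"
        assert row["beta_raw"] == 0.05
        assert row["beta_scaled"] == 0.05
        assert row["allele_freq"] == 0.5

    def test_multivariate_row_count(self):
        ts = make_random_arg(6, max_sites=10)
        model = argtrait.trait_model(
            "multivariate_normal", mean=[0, 0], cov=np.eye(2)
        )
        n = min(3, len(set(ts.tables.mutations.site)))
        effects = sim_trait(ts, model, num_causal=n, random_seed=1)
        assert len(effects) == 2 * n
        assert set(effects["trait_id"]) == {0, 1}

    def test_rows_ordered_by_position_then_trait(self):
        ts = make_random_arg(9, max_sites=12)
        model = argtrait.trait_model(
            "multivariate_normal", mean=[0, 0], cov=np.eye(2)
        )
        n = min(4, len(set(ts.tables.mutations.site)))
        effects = sim_trait(ts, model, num_causal=n, random_seed=1)
        assert effects.equals(
            effects.sort_values(["position", "trait_id"], ignore_index=True)
        )

    def test_explicit_betas_pass_through(self, fig1):
        model = argtrait.trait_model("normal")
        causal = pd.DataFrame(
            {"site_id": [0], "causal_allele": ["T"], "beta_raw": [0.7]}
        )
        effects = sim_trait(fig1, model, causal_sites=causal, alpha=-1.0, random_seed=4)
        assert effects.loc[0, "beta_raw"] == 0.7
        assert effects.loc[0, "beta_scaled"] == pytest.approx(
            0.7 * (2 * 0.5 * 0.5) ** -0.5, rel=1e-12
        )

    def test_explicit_by_position(self, fig1, fixed_model):
        causal = pd.DataFrame({"position": [0.5]})
        effects = sim_trait(fig1, fixed_model, causal_sites=causal, random_seed=1)
        assert effects.loc[0, "site_id"] == 0

    def test_explicit_errors(self, fig1, fixed_model):
        with pytest.raises(ValueError, match="does not exist"):
            sim_trait(fig1, fixed_model, causal_sites=pd.DataFrame({"site_id": [5]}))
        with pytest.raises(ValueError, match="not a segregating"):
            sim_trait(
                fig1,
                fixed_model,
                causal_sites=pd.DataFrame(
                    {"site_id": [0], "causal_allele": ["G"]}
                ),
            )
        with pytest.raises(ValueError, match="mutually exclusive"):
            sim_trait(
                fig1,
                fixed_model,
                num_causal=1,
                causal_sites=pd.DataFrame({"site_id": [0]}),
            )

    def test_causal_csv_file(self, fig1, fixed_model, tmp_path):
        path = tmp_path / "causal.csv"
        pd.DataFrame({"site_id": [0], "causal_allele": ["T"]}).to_csv(
            path, index=False
        )
        effects = sim_trait(fig1, fixed_model, causal_sites=path, random_seed=1)
        assert effects.loc[0, "causal_allele"] == "T"

    @pytest.mark.parametrize("seed", [0, 123])
    def test_deterministic_given_seed(self, seed):
        ts = make_random_arg(2, max_sites=10)
        model = argtrait.trait_model("normal")
        n = min(3, len(set(ts.tables.mutations.site)))
        a = sim_trait(ts, model, num_causal=n, alpha=-0.5, random_seed=seed)
        b = sim_trait(ts, model, num_causal=n, alpha=-0.5, random_seed=seed)
        pd.testing.assert_frame_equal(a, b)

    def test_alpha_zero_scaled_equals_raw(self):
        ts = make_random_arg(12, max_sites=15)
        model = argtrait.trait_model("normal")
        n = len(set(ts.tables.mutations.site))
        effects = sim_trait(ts, model, num_causal=n, random_seed=8)
        assert (effects["beta_scaled"] == effects["beta_raw"]).all()
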