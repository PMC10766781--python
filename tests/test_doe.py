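"""ANOVA decomposition, Tukey comparisons, and condition recommendation."""

import numpy as np
import pandas as pd
import pytest

import oxsel as ox
from oxsel.design import FACTOR_CODES


def make_records(design, y, replicates=2):
    """Replicate-level records with a supplied response vector y (len 81*r)."""
    rows = []
    i = 0
    for run in range(1, design.n_runs + 1):
        for rep in range(1, replicates + 1):
            rows.append(
                {"condition_set": run, "replicate": rep, "selectivity": y[i]}
            )
            i += 1
    return pd.DataFrame(rows)


def planted_response(design, rng, effect_a=(0.0, 0.0, 0.0), noise=1.0, replicates=2):
    """Response with an additive factor-A effect plus iid Gaussian noise."""
    y = []
    for run in design.levels:
        for _ in range(replicates):
            y.append(effect_a[run[0]] + rng.normal(0, noise))
    return np.array(y)


class TestFitAnova:
    def test_term_structure_and_ss_identity(self, design):
        rng = np.random.default_rng(0)
        recs = make_records(design, rng.normal(10, 2, 162))
        fit = ox.fit_anova(recs, design)
        assert len(fit.table) == 15
        assert set(fit.table["df"]) == {2.0, 4.0}
        total_ss = fit.table["sum_sq"].sum() + fit.residual_ss
        y = fit.data["y"].to_numpy()
        assert total_ss == pytest.approx(((y - y.mean()) ** 2).sum(), rel=1e-9)
        assert fit.residual_df == 162 - 1 - 50

    def test_main_effect_ss_matches_closed_form(self, design):
        # balanced-design oracle: between-level SS with 54 observations/level
        rng = np.random.default_rng(1)
        recs = make_records(design, rng.normal(0, 1, 162))
        fit = ox.fit_anova(recs, design)
        df = fit.data
        grand = df["y"].mean()
        for j, code in enumerate(FACTOR_CODES):
            means = df.groupby(f"f{code}")["y"].mean()
            counts = df.groupby(f"f{code}")["y"].size()
            ss = float((counts * (means - grand) ** 2).sum())
            got = float(fit.table.set_index("term").loc[code, "sum_sq"])
            assert got == pytest.approx(ss, rel=1e-9)

    def test_planted_additive_effect_detected(self, design):
        hits_a, hits_e = 0, 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            y = planted_response(design, rng, effect_a=(0.0, 2.0, 1.0), noise=1.0)
            fit = ox.fit_anova(make_records(design, y), design)
            sig = set(fit.significant_terms(0.05))
            hits_a += "A" in sig
            hits_e += "E" in sig
        assert hits_a >= 18
        assert hits_e <= 4

    def test_constant_response_all_ss_zero(self, design):
        recs = make_records(design, np.full(162, 3.0))
        fit = ox.fit_anova(recs, design)
        assert np.allclose(fit.table["sum_sq"], 0.0, atol=1e-18)

    def test_run_reordering_invariance(self, design):
        rng = np.random.default_rng(2)
        recs = make_records(design, rng.normal(0, 1, 162))
        shuffled = recs.sample(frac=1.0, random_state=5).reset_index(drop=True)
        a = ox.fit_anova(recs, design).table["sum_sq"].to_numpy()
        b = ox.fit_anova(shuffled, design).table["sum_sq"].to_numpy()
        np.testing.assert_allclose(a, b, rtol=1e-9)

    def test_log_transform(self, design):
        rng = np.random.default_rng(3)
        y = np.exp(rng.normal(0, 0.5, 162))
        fit = ox.fit_anova(make_records(design, y), design, transform="log")
        np.testing.assert_allclose(fit.data["y"], np.log(y))

    def test_saturated_model_rejected(self, design):
        # 41 single-replicate runs cannot support the 50-df two-way model
        sub = ox.DesignTable(levels=design.levels[::2], generator=design.generator)
        recs = make_records(sub, np.ones(sub.n_runs), replicates=1)
        with pytest.raises(ValueError, match="saturated|residual"):
            ox.fit_anova(recs, sub)

    def test_unknown_condition_rejected(self, design):
        recs = pd.DataFrame({"condition_set": [999], "selectivity": [1.0]})
        with pytest.raises(ValueError, match="unknown condition"):
            ox.fit_anova(recs, design)

    def test_nonfinite_records_excluded(self, design):
        rng = np.random.default_rng(4)
        y = rng.normal(0, 1, 162)
        y[5] = np.nan
        fit = ox.fit_anova(make_records(design, y), design)
        assert fit.n_excluded == 1
        assert fit.residual_df == 161 - 1 - 50


class TestTukey:
    def test_planted_difference_significant(self, design):
        rng = np.random.default_rng(6)
        y = planted_response(design, rng, effect_a=(0.0, 5.0, 5.0), noise=0.5)
        fit = ox.fit_anova(make_records(design, y), design)
        tk = ox.tukey_comparisons(fit, "A")
        t01 = tk.table[(tk.table.level_a == 0) & (tk.table.level_b == 1)].iloc[0]
        assert t01["significant"]
        assert t01["lo"] > 0  # interval excludes zero

    def test_two_tied_levels_one_apart(self, design):
        rng = np.random.default_rng(7)
        y = planted_response(design, rng, effect_a=(0.0, 0.0, 8.0), noise=0.5)
        fit = ox.fit_anova(make_records(design, y), design)
        tk = ox.tukey_comparisons(fit, "A")
        assert int(tk.table["significant"].sum()) == 2
        assert set(tk.winners()) == {2}

    def test_identical_level_means_not_significant(self, design):
        y = np.tile([1.0, 2.0], 81)  # replicate scatter, no level structure
        fit = ox.fit_anova(make_records(design, y), design)
        tk = ox.tukey_comparisons(fit, "A")
        assert (tk.table["p_adj"] > 0.999).all()

    def test_alpha_validated(self, design):
        rng = np.random.default_rng(8)
        fit = ox.fit_anova(make_records(design, rng.normal(0, 1, 162)), design)
        with pytest.raises(ValueError):
            ox.tukey_comparisons(fit, "A", alpha=1.5)
        with pytest.raises(ValueError):
            ox.tukey_comparisons(fit, "Q")


@pytest.fixture(scope="module")
def planted_campaign(design, oil_dist, ooo_na_pair):
    spec = ox.CampaignSpec(design=design, composition=oil_dist, seed=11)
    manifest, spectra = ox.simulate_campaign(spec, ox.default_model(noise_cv=0.05))
    per_rep = ox.batch_selectivity(
        manifest, oil_dist, targets=[ooo_na_pair], spectra=spectra, aggregate=False
    )
    agg = ox.batch_selectivity(
        manifest, oil_dist, targets=[ooo_na_pair], spectra=spectra
    )
    return per_rep, agg


class TestRecommendation:
    def test_planted_optimum_recovered(self, design, planted_campaign, conditions):
        per_rep, agg = planted_campaign
        fit = ox.fit_anova(per_rep, design, transform="log")
        rec = ox.recommend_conditions({"oil/OOO/3": fit}, agg)
        assert conditions[rec.best_condition - 1].levels == (1, 1, 1, 2, 2)
        assert rec.factor_levels["A"] == [1]  # sodium acetate
        assert rec.factor_levels["D"] == [2]  # high capillary voltage

    def test_single_response_reduces_to_argmax(self, planted_campaign, design):
        per_rep, agg = planted_campaign
        fit = ox.fit_anova(per_rep, design, transform="log")
        rec = ox.recommend_conditions({"r": fit}, agg)
        argmax = int(agg.loc[agg["selectivity"].idxmax(), "condition_set"])
        assert rec.best_condition == argmax

    def test_flat_response_flagged(self, design):
        rng = np.random.default_rng(9)
        recs = make_records(design, rng.normal(0, 1, 162))
        fit = ox.fit_anova(recs, design)
        agg = pd.DataFrame(
            {
                "sample": "oil",
                "species": "OOO",
                "ox_degree": "3",
                "condition_set": np.arange(1, 82),
                "selectivity": np.ones(81),
                "sd": np.zeros(81),
            }
        )
        rec = ox.recommend_conditions({"r": fit}, agg)
        assert "no discrimination" in rec.flags

    def test_empty_fits_rejected(self, design):
        with pytest.raises(ValueError):
            ox.recommend_conditions({}, pd.DataFrame())
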