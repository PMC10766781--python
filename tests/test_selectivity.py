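"""The normalized ionization-selectivity factor at both stages."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oxsel as ox
from oxsel.selectivity import INFINITE_SELECTIVITY

from conftest import ammoniated_ion, sodiated_ion


def ammoniated_only_model(**kwargs):
    """Generator emitting pure ammoniated adducts for every additive.

    Keeps all generated sticks inside the printed oil windows up to 4ox, so
    window-level selectivity has no mass-range truncation.
    """
    weights = {a: {"[M+NH4]+": 1.0} for a in ("NH4Fo", "NaOAc", "NaI")}
    return ox.IonizationModel(adduct_weights=weights, **kwargs)


class TestSelectivityFactor:
    def test_identity(self):
        assert ox.selectivity_factor(5.0, 5.0, 0.3, 0.3) == pytest.approx(1.0)

    def test_double_area(self):
        assert ox.selectivity_factor(10.0, 5.0, 0.3, 0.3) == pytest.approx(2.0)

    def test_normalization(self):
        # ox species at half the composition fraction ionizing equally well
        assert ox.selectivity_factor(1.0, 1.0, 0.25, 0.5) == pytest.approx(2.0)

    def test_infinite_sentinel(self):
        with pytest.warns(UserWarning, match="no signal"):
            assert ox.selectivity_factor(1.0, 0.0, 0.3, 0.6) == INFINITE_SELECTIVITY

    def test_zero_fraction_rejected(self):
        with pytest.raises(ox.NormalizationUndefinedError):
            ox.selectivity_factor(1.0, 1.0, 0.0, 0.5)

    @settings(derandomize=True, max_examples=100)
    @given(
        st.floats(0.0, 1e6),
        st.floats(1e-6, 1e6),
        st.floats(1e-6, 1.0),
        st.floats(1e-6, 1.0),
        st.floats(1e-6, 1e6),
    )
    def test_rescaling_both_areas_leaves_factor_unchanged(self, a, b, fa, fb, c):
        s = ox.selectivity_factor(a, b, fa, fb)
        assert ox.selectivity_factor(c * a, c * b, fa, fb) == pytest.approx(
            s, rel=1e-9
        )

    def test_role_swap_inverts(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a, b = rng.uniform(0.1, 10, 2)
            fa, fb = rng.uniform(0.01, 0.9, 2)
            s = ox.selectivity_factor(a, b, fa, fb)
            assert ox.selectivity_factor(b, a, fb, fa) == pytest.approx(1 / s)

    def test_scale_invariance(self, conditions, oil_dist):
        s = ox.simulate_spectrum(conditions[41], ox.default_model(0.0), oil_dist, seed=9)
        windows = ox.default_windows("oil")
        base = ox.stage1_selectivity(s, windows, oil_dist).selectivity
        for c in (1e-3, 7.0, 1e4):
            scaled = ox.stage1_selectivity(s.scaled(c), windows, oil_dist).selectivity
            assert scaled == pytest.approx(base, rel=1e-12)


class TestStage1:
    def test_all_intensity_in_ox_window_is_infinite(self, oil_dist):
        s = ox.Spectrum(np.array([920.0, 950.0]), np.array([5.0, 5.0]), sample="oil")
        with pytest.warns(UserWarning):
            rec = ox.stage1_selectivity(s, ox.default_windows("oil"), oil_dist)
        assert math.isinf(rec.selectivity)
        assert "infinite" in rec.flags

    def test_unit_efficiencies_give_unit_selectivity(self, conditions, oil_dist):
        model = ammoniated_only_model()
        for cond in (conditions[0], conditions[41], conditions[80]):
            s = ox.simulate_spectrum(cond, model, oil_dist, seed=0, max_ox=4)
            rec = ox.stage1_selectivity(
                s, ox.default_windows("oil"), oil_dist, ox_degrees=(1, 2, 3, 4)
            )
            assert rec.selectivity == pytest.approx(1.0, rel=1e-9)

    def test_leakage_monotonically_lowers_selectivity(self, conditions, oil_dist):
        prev = math.inf
        for f in (0.0, 0.1, 0.2, 0.4, 0.6):
            model = ammoniated_only_model(leakage=f)
            s = ox.simulate_spectrum(conditions[41], model, oil_dist, seed=0, max_ox=4)
            rec = ox.stage1_selectivity(s, ox.default_windows("oil"), oil_dist)
            assert rec.selectivity < prev
            prev = rec.selectivity

    def test_window_roles_required(self, oil_dist):
        s = ox.Spectrum(np.array([900.0]), np.array([1.0]))
        with pytest.raises(ValueError, match="window"):
            ox.stage1_selectivity(s, ox.default_windows("oil")[:1], oil_dist)


class TestStage2:
    def test_planted_ratio_recovered_exactly(self, conditions, oil_dist):
        # oxidized species ionizing 120x better than its non-ox form
        model = ox.IonizationModel(base={("OOO", 3): 120.0})
        s = ox.simulate_spectrum(conditions[41], model, oil_dist, seed=4)
        rec = ox.stage2_selectivity(
            s, sodiated_ion(ox.OOO, 3), sodiated_ion(ox.OOO, 0), oil_dist
        )
        assert rec.selectivity == pytest.approx(120.0, rel=1e-9)

    def test_missing_ox_peak_is_zero(self, oil_dist):
        ion0 = sodiated_ion(ox.OOO, 0)
        s = ox.Spectrum(np.array([ion0.mz]), np.array([10.0]), sample="oil")
        rec = ox.stage2_selectivity(s, sodiated_ion(ox.OOO, 3), ion0, oil_dist)
        assert rec.selectivity == 0.0

    def test_mismatched_ions_rejected(self, oil_dist):
        s = ox.Spectrum(np.array([900.0]), np.array([1.0]))
        with pytest.raises(ValueError, match="adduct"):
            ox.stage2_selectivity(
                s, sodiated_ion(ox.OOO, 3), ammoniated_ion(ox.OOO, 0), oil_dist
            )
        with pytest.raises(ValueError, match="species"):
            ox.stage2_selectivity(
                s, sodiated_ion(ox.OOL, 3), sodiated_ion(ox.OOO, 0), oil_dist
            )


@pytest.fixture(scope="module")
def campaign(design, oil_dist):
    spec = ox.CampaignSpec(design=design, composition=oil_dist, seed=5)
    return ox.simulate_campaign(spec, ox.default_model(noise_cv=0.0))


class TestBatch:
    def test_table_shape(self, campaign, oil_dist, design, ooo_na_pair):
        manifest, spectra = campaign
        table = ox.batch_selectivity(
            manifest, oil_dist, targets=[ooo_na_pair], spectra=spectra
        )
        assert len(table) == 81
        assert set(table["condition_set"]) == set(range(1, 82))
        assert (table["n_replicates"] == 2).all()

    def test_zero_noise_zero_sd(self, campaign, oil_dist, ooo_na_pair):
        manifest, spectra = campaign
        table = ox.batch_selectivity(
            manifest, oil_dist, targets=[ooo_na_pair], spectra=spectra
        )
        assert np.allclose(table["sd"], 0.0)

    def test_argmax_recovers_planted_optimum(self, campaign, oil_dist, ooo_na_pair, conditions):
        manifest, spectra = campaign
        table = ox.batch_selectivity(
            manifest, oil_dist, targets=[ooo_na_pair], spectra=spectra
        )
        best = int(table.loc[table["selectivity"].idxmax(), "condition_set"])
        assert conditions[best - 1].levels == (1, 1, 1, 2, 2)

    def test_missing_replicate_flagged_not_dropped(self, campaign, oil_dist, ooo_na_pair):
        manifest, spectra = campaign
        manifest = manifest.copy()
        manifest.loc[0, "path"] = "does_not_exist.csv"
        table = ox.batch_selectivity(
            manifest, oil_dist, targets=[ooo_na_pair], spectra=spectra
        )
        cond1 = table[table["condition_set"] == 1].iloc[0]
        assert cond1["n_replicates"] == 1
        assert len(table) == 81

    def test_per_replicate_rows(self, campaign, oil_dist, ooo_na_pair):
        manifest, spectra = campaign
        table = ox.batch_selectivity(
            manifest, oil_dist, targets=[ooo_na_pair], spectra=spectra, aggregate=False
        )
        assert len(table) == 162
        assert set(table["replicate"]) == {1, 2}
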