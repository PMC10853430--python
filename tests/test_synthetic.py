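"""Ground-truth generator: class fidelity, noise guarantees, determinism."""

import numpy as np
import pandas as pd
import pytest

from domforge.assignment import AssignmentParams, Peak, assign_peaklist, enumerate_candidates
from domforge.chemodiversity import compare_two, composition
from domforge.formulas import MolecularFormula, exact_neutral_mass, neutral_mass_from_mz
from domforge.network import spearman_pair
from domforge.synthetic import (
    CONDITIONS,
    DEFAULT_CLASS_MIXTURES,
    ScenarioConfig,
    generate_sample,
    generate_study,
    pearson_for_spearman,
    sample_formula_in_class,
    sample_formulas_in_class,
    simulate_coupled_pair,
    study_feature_matrix,
)
from domforge.vankrevelen import SEVEN_CLASSES, CompoundClass, classify_formula, classify_table

SMALL = ScenarioConfig(seed=11, formulas_per_sample=300)


@pytest.fixture(scope="module")
def small_study():
    return generate_study(SMALL)


class TestFormulaSampler:
    @pytest.mark.parametrize("cls", SEVEN_CLASSES)
    def test_round_trip_classification(self, cls, rng):
        rows = sample_formulas_in_class(cls, 300, rng)
        for row in rows:
            f = MolecularFormula(*(int(v) for v in row))
            assert classify_formula(f) == cls

    def test_carbohydrate_box_margin(self, rng):
        rows = sample_formulas_in_class(CompoundClass.CARBOHYDRATES, 300, rng)
        oc = rows[:, 2] / rows[:, 0]
        hc = rows[:, 1] / rows[:, 0]
        assert oc.min() >= 0.68 - 1e-9 and oc.max() <= 1.19 + 1e-9
        assert hc.min() >= 1.51 - 1e-9 and hc.max() <= 2.29 + 1e-9

    def test_mass_window_respected(self, rng):
        rows = sample_formulas_in_class(
            CompoundClass.LIGNIN_CRAM, 200, rng, mass_window=(300.0, 600.0)
        )
        for row in rows:
            m = exact_neutral_mass(MolecularFormula(*(int(v) for v in row)))
            assert 300.0 <= m <= 600.0

    def test_single_draw_wrapper(self, rng):
        f = sample_formula_in_class(CompoundClass.TANNINS, (200.0, 1000.0), rng)
        assert classify_formula(f) == CompoundClass.TANNINS

    def test_unclassified_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_formulas_in_class(CompoundClass.UNCLASSIFIED, 1, rng)


class TestGenerateSample:
    def test_noiseless_errorless_sample_fully_recovered(self):
        cfg = ScenarioConfig(seed=5, formulas_per_sample=150,
                             mass_error_ppm_sd=0.0, noise_fraction=0.0,
                             snr_below_frac=0.0)
        rng = np.random.default_rng(5)
        peaks, truth = generate_sample(0, cfg, rng)
        assigned = assign_peaklist(
            [Peak(*t) for t in peaks.itertuples(index=False)], AssignmentParams()
        )
        got = {a.formula.as_tuple() for a in assigned if a.formula}
        want = {tuple(int(v) for v in row) for row in truth[["C", "H", "O", "N", "S"]].to_numpy()}
        assert got == want

    def test_low_snr_fraction_filtered(self):
        cfg = ScenarioConfig(seed=6, formulas_per_sample=400, snr_below_frac=0.10,
                             noise_fraction=0.0)
        rng = np.random.default_rng(6)
        peaks, _ = generate_sample(0, cfg, rng)
        frac = (peaks["snr"] < 4).mean()
        assert frac == pytest.approx(0.10, abs=0.05)

    def test_noise_peaks_are_unassignable(self, small_study):
        """Every generated noise m/z has no valid formula within 2 ppm."""
        check = AssignmentParams(tol_ppm=2.0)
        peaks = small_study.peak_tables["CC1Y_r1"]
        truth = small_study.truth.formula_tables["CC1Y_r1"]
        noise_mzs = set(peaks["mz"]) - set(truth["mz_observed"])
        assert len(noise_mzs) == small_study.truth.noise_counts["CC1Y_r1"]
        for mz in noise_mzs:
            assert enumerate_candidates(neutral_mass_from_mz(mz), check) == []

    def test_signal_peaks_assignable_at_1ppm(self, small_study):
        """0.3 ppm mass-error sd leaves ~all signal peaks inside 1 ppm."""
        truth = small_study.truth.formula_tables["CC1Y_r1"]
        err = 1e6 * (truth["mz_observed"] - truth["mz_exact"]) / truth["mz_exact"]
        assert (err.abs() <= 1.0).mean() >= 0.99


class TestGenerateStudy:
    def test_same_seed_identical(self):
        a = generate_study(SMALL)
        b = generate_study(SMALL)
        for sid in a.peak_tables:
            pd.testing.assert_frame_equal(a.peak_tables[sid], b.peak_tables[sid])
        pd.testing.assert_frame_equal(a.chemistry, b.chemistry)
        pd.testing.assert_frame_equal(a.genera, b.genera)

    def test_shapes_and_labels(self, small_study):
        assert list(small_study.peak_tables) == SMALL.sample_ids()
        assert len(small_study.peak_tables) == 12
        assert small_study.chemistry.shape[0] == 12
        assert small_study.genera.columns.tolist() == SMALL.sample_ids()

    def test_genus_columns_are_relative_abundance(self, small_study):
        np.testing.assert_allclose(small_study.genera.sum(axis=0), 100.0)

    def test_conditions_share_and_differ(self, small_study):
        """First vs last condition yields non-empty D/R/P blocks."""
        ann = {
            sid: classify_table(
                t.rename(columns=str)[["C", "H", "O", "N", "S"]].astype("Int64")
            )
            for sid, t in small_study.truth.formula_tables.items()
        }
        a = pd.concat([ann[f"CC1Y_r{i}"] for i in (1, 2, 3)])
        b = pd.concat([ann[f"CC7Y_r{i}"] for i in (1, 2, 3)])
        res = compare_two(a, b)
        assert len(res.degraded) > 0
        assert len(res.remaining) > 0
        assert len(res.produced) > 0
        assert sum(res.overall_pct.values()) == pytest.approx(100, abs=0.1)

    def test_class_mixture_recovery_single_seed(self):
        cfg = ScenarioConfig(seed=42)
        study = generate_study(cfg)
        for k, cond in enumerate(CONDITIONS):
            est = np.mean(
                [
                    (study.truth.formula_tables[f"{cond}_r{r}"]["compound_class"] == "tannins").mean()
                    for r in (1, 2, 3)
                ]
            ) * 100
            assert est == pytest.approx(DEFAULT_CLASS_MIXTURES["tannins"][k], abs=1.5)

    def test_chemistry_trends(self, small_study):
        cond_means = small_study.chemistry.groupby(
            small_study.chemistry.index.str.split("_").str[0]
        ).mean().loc[list(CONDITIONS)]
        assert cond_means["TN"].is_monotonic_decreasing
        assert cond_means["OM"].is_monotonic_decreasing
        assert cond_means["C/N"].iloc[-1] > cond_means["C/N"].iloc[0]
        # DOC V-shape: dips then partially recovers
        doc = cond_means["DOC"].to_numpy()
        assert doc[0] > doc.min() and doc[-1] > doc.min()

    def test_structural_absences(self, small_study):
        g = small_study.genera
        cc1 = [c for c in g.columns if c.startswith("CC1Y_")]
        cc7 = [c for c in g.columns if c.startswith("CC7Y_")]
        assert (g.loc["wb1-P19", cc7] == 0).all()
        assert (g.loc["wb1-P19", cc1] > 0).all()
        assert (g.loc["Aquabacterium", cc1] == 0).all()
        assert (g.loc["Nocardioides"] > 0).all()

    def test_feature_matrix_assembly(self, small_study):
        matrix, cats = study_feature_matrix(small_study)
        assert matrix.shape[0] == 12
        assert set(cats.values()) == {"compound_class", "element_group", "chemistry", "genus"}
        assert "tannins" in matrix.columns and "Methylobacter" in matrix.columns
        assert not matrix.isna().any().any()


class TestCopulaCoupling:
    def test_pearson_for_spearman_inverse(self):
        # rho_s = (6/pi) arcsin(r/2) evaluated back
        for rho_s in (0.3, 0.6, 0.95):
            r = pearson_for_spearman(rho_s)
            assert 6 / np.pi * np.arcsin(r / 2) == pytest.approx(rho_s, abs=1e-12)

    def test_coupled_pair_hits_target_rank_correlation(self, rng):
        """Average sample Spearman over many replicates approaches 0.95."""
        rhos = []
        for _ in range(300):
            x, y = simulate_coupled_pair(0.95, 30, rng)
            rhos.append(spearman_pair(x, y, method="asymptotic")[0])
        assert np.mean(rhos) == pytest.approx(0.95, abs=0.02)


class TestConfigValidation:
    def test_mixtures_must_sum_to_100(self):
        bad = dict(DEFAULT_CLASS_MIXTURES)
        bad["tannins"] = (30.0, 30.0, 30.0, 30.0)
        with pytest.raises(ValueError):
            ScenarioConfig(class_mixtures=bad)

    def test_mixture_length_must_match_conditions(self):
        bad = dict(DEFAULT_CLASS_MIXTURES)
        bad["tannins"] = (18.13, 13.95)
        with pytest.raises(ValueError):
            ScenarioConfig(class_mixtures=bad)

    def test_config_hash_stable_and_sensitive(self):
        a, b = ScenarioConfig(seed=1), ScenarioConfig(seed=1)
        c = ScenarioConfig(seed=2)
        assert a.config_hash() == b.config_hash()
        assert a.config_hash() != c.config_hash()
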