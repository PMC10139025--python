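"""Synthetic-data generators: ground-truth behavior and determinism."""

import numpy as np
import pytest
from scipy import stats

from cellmech.errors import InvalidConfigError
from cellmech.physics import ProbeSpec
from cellmech.simgen import (
    CurveSimConfig,
    PopulationSpec,
    gen_cell_image,
    gen_expression_table,
    gen_force_curve,
    gen_population,
    gen_viability,
    write_curve_tsv,
)
from cellmech.forcecurve import read_curve_tsv


class TestForceCurveGeneration:
    def test_noiseless_baseline_identically_zero(self, probe):
        cfg = CurveSimConfig(noise_sd=0.0, baseline_slope=0.0)
        curve = gen_force_curve(cfg, probe)
        pre = curve.z < cfg.contact_z
        np.testing.assert_array_equal(curve.deflection[pre], 0.0)

    def test_post_contact_force_matches_hertz(self, probe):
        # force at the deepest point of a noiseless curve agrees with the
        # closed form evaluated at the realized indentation
        cfg = CurveSimConfig(true_modulus=1.0, noise_sd=0.0)
        curve = gen_force_curve(cfg, probe)
        from cellmech.physics import hertz_force

        delta = (curve.z - cfg.contact_z) * 1e3 - curve.deflection
        f_model = hertz_force(delta[-1], 1.0, probe)
        assert curve.force[-1] == pytest.approx(f_model, rel=1e-9)

    def test_truncated_at_trigger_force(self, probe):
        cfg = CurveSimConfig(true_modulus=5.0, noise_sd=0.0)  # stiff: hits 2 nN
        curve = gen_force_curve(cfg, probe)
        assert curve.force.max() <= probe.trigger_force + 1e-9
        assert curve.z[-1] < cfg.z_range[1]

    def test_z_range_must_contain_contact(self):
        with pytest.raises(InvalidConfigError):
            CurveSimConfig(contact_z=10.0, z_range=(3.5, 6.0))

    def test_determinism_bit_identical(self, probe):
        cfg = CurveSimConfig(noise_sd=1.0, seed=42)
        c1 = gen_force_curve(cfg, probe)
        c2 = gen_force_curve(cfg, probe)
        np.testing.assert_array_equal(c1.deflection, c2.deflection)

    def test_tsv_roundtrip(self, probe, tmp_path):
        cfg = CurveSimConfig(noise_sd=1.0, seed=3)
        curve = gen_force_curve(cfg, probe, cell_id="c1", curve_id="k0")
        path = write_curve_tsv(curve, tmp_path / "curve.tsv")
        back = read_curve_tsv(path)
        np.testing.assert_allclose(back.deflection, curve.deflection, atol=1e-9)
        assert back.probe == probe
        assert back.truth["E_kPa"] == cfg.true_modulus


class TestPopulationGeneration:
    def test_degenerate_mixture_all_equal(self):
        spec = PopulationSpec(
            component_means=(0.4,), component_sds=(0.0,), n_cells=5, curves_per_cell=5
        )
        cells = gen_population(spec, seed=0, within_cell_cv=0.0)
        assert all(c.true_modulus == 0.4 for c in cells)

    def test_zero_weight_component_never_drawn(self):
        spec = PopulationSpec(
            component_means=(0.3, 0.9),
            component_sds=(0.05, 0.05),
            component_weights=(1.0, 0.0),
            n_cells=50,
            curves_per_cell=5,
        )
        cells = gen_population(spec, seed=1)
        assert all(c.component == 0 for c in cells)

    def test_component_means_within_three_se(self):
        spec = PopulationSpec(
            component_means=(0.3, 0.9),
            component_sds=(0.08, 0.15),
            component_weights=(0.5, 0.5),
            n_cells=400,
            curves_per_cell=5,
        )
        cells = gen_population(spec, seed=7)
        for k, (mu, sd) in enumerate(zip(spec.component_means, spec.component_sds)):
            draws = np.array([c.true_modulus for c in cells if c.component == k])
            se = sd / np.sqrt(draws.size)
            assert abs(draws.mean() - mu) < 3 * se

    def test_mixture_weights_chi_squared(self):
        # empirical component counts consistent with the spec weights
        spec = PopulationSpec(
            component_means=(0.3, 0.9),
            component_sds=(0.0, 0.0),
            component_weights=(0.35, 0.65),
            n_cells=10_000,
            curves_per_cell=5,
        )
        from cellmech.simgen import sample_cell_moduli

        moduli, components = sample_cell_moduli(spec, 10_000, np.random.default_rng(11))
        counts = np.bincount(components, minlength=2)
        res = stats.chisquare(counts, f_exp=np.array([0.35, 0.65]) * 10_000)
        assert res.pvalue > 0.01
        assert set(np.unique(moduli)) == {0.3, 0.9}  # sd 0: draws equal the means

    def test_determinism(self):
        spec = PopulationSpec(
            component_means=(0.5,), component_sds=(0.1,), n_cells=3, curves_per_cell=5
        )
        a = gen_population(spec, seed=5)
        b = gen_population(spec, seed=5)
        for ca, cb in zip(a, b):
            assert ca.true_modulus == cb.true_modulus
            np.testing.assert_array_equal(ca.curves[0].deflection, cb.curves[0].deflection)

    def test_curves_per_cell_minimum(self):
        with pytest.raises(InvalidConfigError):
            PopulationSpec(component_means=(0.5,), component_sds=(0.1,), curves_per_cell=4)


class TestViability:
    def test_midpoint_is_fifty(self):
        table = gen_viability(10.0, 1.5, [1, 2, 4, 10, 20, 40, 80], noise_sd=0.0)
        at_ic50 = table.loc[table.concentration_uM == 10.0, "viability_pct"].iloc[0]
        assert at_ic50 == pytest.approx(50.0)

    def test_steep_hill_approaches_step(self):
        table = gen_viability(10.0, 50.0, [1, 2, 4, 20, 40, 80], noise_sd=0.0)
        v = table.viability_pct.to_numpy()
        assert np.all(v[:3] > 99.0)
        assert np.all(v[3:] < 1.0)

    def test_clipping_bounds(self):
        table = gen_viability(10.0, 1.0, [1, 2, 4, 10, 20, 40, 80], noise_sd=50.0, seed=0)
        assert table.viability_pct.between(0, 110).all()


class TestCellImage:
    def test_uniform_profile_constant_inside(self):
        img, mask = gen_cell_image(intensity_profile="uniform", noise_sd=0.0)
        assert np.ptp(img[mask]) == 0.0

    def test_center_weighted_brighter_at_centroid(self):
        img, mask = gen_cell_image(intensity_profile="center-weighted", noise_sd=0.0)
        h, w = img.shape
        center_val = img[h // 2, w // 2]
        rim = img[mask].min()
        assert center_val > rim

    def test_axes_give_expected_aspect_ratio(self):
        from cellmech.morpho_imaging import shape_metrics

        _, mask = gen_cell_image(axes=(50, 10), intensity_profile="uniform")
        sm = shape_metrics(mask)
        assert sm.aspect_ratio == pytest.approx(5.0, rel=0.03)

    def test_axes_must_fit(self):
        with pytest.raises(InvalidConfigError):
            gen_cell_image(axes=(200, 100), size=(128, 128))


class TestExpressionTable:
    def test_no_effects_equal_group_means(self):
        expr, groups = gen_expression_table(300, {}, n_reps=30, seed=0)
        log2 = np.log2(expr)
        diff = (
            log2.loc[:, groups == "B"].mean(axis=1)
            - log2.loc[:, groups == "A"].mean(axis=1)
        )
        assert abs(diff.mean()) < 0.05

    def test_fold_change_recovered(self):
        expr, groups = gen_expression_table(
            50, {"GENE0001": 4.0}, n_reps=200, seed=1
        )
        log2 = np.log2(expr.loc["GENE0001"])
        lfc = log2[groups == "B"].mean() - log2[groups == "A"].mean()
        assert lfc == pytest.approx(2.0, abs=0.15)

    def test_housekeeping_never_affected(self):
        expr, groups = gen_expression_table(
            20, {"HPRT1": 8.0, "HMBS": 8.0}, n_reps=100, seed=2
        )
        for g in ("HPRT1", "HMBS", "PPIB"):
            log2 = np.log2(expr.loc[g])
            lfc = log2[groups == "B"].mean() - log2[groups == "A"].mean()
            assert abs(lfc) < 0.3  # fold change ~1 despite requested effects
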