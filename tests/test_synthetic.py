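"""Phantom geometry, quantile sampling, and cohort generation."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from asphere.response import classify_table
from asphere.shape import measure_voi
from asphere.synthetic import (
    ASP_SUMMARIES,
    NRL_ASP_SUMMARY,
    RL_ASP_SUMMARY,
    CohortSpec,
    FiveNumberSummary,
    PhantomSpec,
    ShapeSpec,
    analytic_metrics,
    ellipsoid_metrics,
    make_phantom,
    quantile_model_auc,
    sample_cohort,
    sample_from_summary,
    union_of_spheres_metrics,
)
from asphere.grids import split_seed


def ellipsoid_area_quadrature(a, b, c):
    """Independent surface-area oracle: direct quadrature of the area element."""

    def integrand(theta, phi):
        st, ct = np.sin(theta), np.cos(theta)
        sp, cp = np.sin(phi), np.cos(phi)
        # |r_theta x r_phi| for r = (a st cp, b st sp, c ct)
        e = (b * c * st**2 * cp) ** 2 + (a * c * st**2 * sp) ** 2 + (a * b * st * ct) ** 2
        return np.sqrt(e)

    val, _ = integrate.dblquad(integrand, 0, 2 * np.pi, 0, np.pi, epsabs=1e-8)
    return val


class TestAnalyticShapes:
    def test_sphere_is_the_asp_reference(self):
        m = analytic_metrics(ShapeSpec("sphere", (10.0, 10.0, 10.0)))
        assert m["ASP_percent"] == pytest.approx(0.0, abs=1e-9)
        assert m["V_ml"] == pytest.approx(4.0 / 3.0 * np.pi, rel=1e-12)

    @pytest.mark.parametrize(
        "axes", [(20, 10, 10), (10, 10, 5), (18, 12, 7), (30, 10, 10)]
    )
    def test_ellipsoid_surface_matches_quadrature(self, axes):
        _, S = ellipsoid_metrics(*axes)
        assert S == pytest.approx(ellipsoid_area_quadrature(*axes), rel=1e-6)

    def test_prolate_asp_from_closed_form(self):
        # exact prolate-spheroid area 2*pi*b^2*(1 + (a/(b e)) arcsin e)
        a, b = 20.0, 10.0
        e = np.sqrt(1 - b**2 / a**2)
        S = 2 * np.pi * b**2 * (1 + (a / (b * e)) * np.arcsin(e))
        m = analytic_metrics(ShapeSpec("ellipsoid", (a, b, b)))
        assert m["S_mm2"] == pytest.approx(S, rel=1e-12)
        assert m["ASP_percent"] == pytest.approx(7.673, abs=0.01)

    def test_rotation_leaves_analytic_metrics_unchanged(self):
        base = analytic_metrics(ShapeSpec("ellipsoid", (20, 10, 10)))
        rot = analytic_metrics(ShapeSpec("ellipsoid", (20, 10, 10), orientation=(0.3, 1.0, 2.2)))
        assert rot == base

    def test_two_lobe_union_against_grid_oracle(self):
        lobes = (((0.0, 0.0, 0.0), 12.0), ((15.0, 0.0, 0.0), 10.0))
        V, S = union_of_spheres_metrics(lobes)
        # volume oracle: fine-grid voxel count
        from asphere.synthetic import rasterize

        mask = rasterize(
            ShapeSpec("lobulated", lobes=lobes), (140, 100, 100), (0.5, 0.5, 0.5)
        )
        assert V == pytest.approx(mask.sum() * 0.125, rel=0.01)
        # union area must be below the sum of the two sphere areas and
        # above that of the larger sphere alone
        assert 4 * np.pi * 144 < S < 4 * np.pi * (144 + 100)

    def test_lobulated_requires_overlap_and_pairwise_only(self):
        with pytest.raises(ValueError, match="connected"):
            union_of_spheres_metrics((((0, 0, 0), 5.0), ((30, 0, 0), 5.0)))
        with pytest.raises(ValueError, match="triple"):
            union_of_spheres_metrics(
                (((0, 0, 0), 10.0), ((8, 0, 0), 10.0), ((4, 6, 0), 10.0))
            )
        with pytest.raises(ValueError, match="contained"):
            union_of_spheres_metrics((((0, 0, 0), 10.0), ((1, 0, 0), 3.0)))


class TestMakePhantom:
    def test_shape_exceeding_grid_names_the_axis(self):
        spec = PhantomSpec(
            shape=ShapeSpec("sphere", (30.0, 30.0, 30.0)),
            grid_shape=(32, 64, 64),
            spacing_mm=(2.0, 2.0, 2.0),
        )
        with pytest.raises(ValueError, match="axis x"):
            make_phantom(spec)

    def test_activity_levels_and_truth_mask(self, sphere_phantom_sharp):
        grid, truth, metrics = sphere_phantom_sharp
        assert grid.values[truth.mask].min() == pytest.approx(10.0)
        assert grid.values[~truth.mask].max() == pytest.approx(1.0)
        assert metrics["ASP_percent"] == pytest.approx(0.0, abs=1e-9)

    def test_poisson_noise_is_seeded(self):
        spec = PhantomSpec(
            shape=ShapeSpec("sphere", (10.0, 10.0, 10.0)),
            grid_shape=(40, 40, 40),
            spacing_mm=(2.0, 2.0, 2.0),
            lesion_activity=50.0,
            background_activity=5.0,
            noise="poisson",
            seed=11,
        )
        g1, _, _ = make_phantom(spec)
        g2, _, _ = make_phantom(spec)
        assert np.array_equal(g1.values, g2.values)
        assert not np.array_equal(g1.values, make_phantom(spec.__class__(**{**spec.__dict__, "seed": 12}))[0].values)

    def test_self_consistency_of_truth_mask_metrics(self):
        """Measuring the rasterized truth reproduces analytic V and ASP at fine spacing."""
        shapes = [
            ShapeSpec("sphere", (12.0, 12.0, 12.0)),
            ShapeSpec("ellipsoid", (20.0, 10.0, 10.0), orientation=(0.5, 0.3, 0.9)),
            ShapeSpec("lobulated", lobes=(((0, 0, 0), 12.0), ((15.0, 0, 0), 10.0))),
        ]
        for shape in shapes:
            spec = PhantomSpec(
                shape=shape, grid_shape=(150, 150, 150), spacing_mm=(0.5, 0.5, 0.5),
                psf_fwhm_mm=6.0,
            )
            grid, truth, analytic = make_phantom(spec)
            measured = measure_voi(truth, grid)
            assert measured.V_ml == pytest.approx(analytic["V_ml"], rel=0.02)
            assert measured.ASP_percent == pytest.approx(analytic["ASP_percent"], abs=2.0)


class TestQuantileSampling:
    def test_degenerate_summary_returns_constants(self):
        s = FiveNumberSummary(0, 0, 0, 0, 0)
        assert np.all(sample_from_summary(s, 5, np.random.default_rng(0)) == 0.0)

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ValueError, match="non-decreasing"):
            FiveNumberSummary(1.0, 0.5, 2.0, 3.0, 4.0)

    def test_pd_summary_quartiles_recovered(self):
        s = ASP_SUMMARIES["PD"]  # median 11.3, IQR 8.5-15.5, range 2.4-21.3
        x = sample_from_summary(s, 10**5, np.random.default_rng(1))
        assert np.median(x) == pytest.approx(11.3, abs=0.2)
        assert np.percentile(x, 25) == pytest.approx(8.5, abs=0.2)
        assert np.percentile(x, 75) == pytest.approx(15.5, abs=0.2)
        assert x.min() >= 2.4 and x.max() <= 21.3

    @pytest.mark.parametrize("cls", list(ASP_SUMMARIES))
    def test_samples_bounded_and_quartiles_within_2pct(self, cls):
        s = ASP_SUMMARIES[cls]
        x = sample_from_summary(s, 2 * 10**4, np.random.default_rng(3))
        assert x.min() >= s.minimum - 1e-12 and x.max() <= s.maximum + 1e-12
        scale = s.maximum - s.minimum
        for q, target in ((25, s.q1), (50, s.median), (75, s.q3)):
            assert abs(np.percentile(x, q) - target) <= 0.02 * scale

    def test_truncated_sampling_respects_lower_bound(self):
        s = FiveNumberSummary(10.0, 13.7, 19.2, 33.3, 100.0)
        x = sample_from_summary(s, 5000, np.random.default_rng(5), lower_bound=15.0)
        assert x.min() >= 15.0
        assert x.max() <= 100.0

    def test_model_auc_exact_vs_monte_carlo(self, rng):
        auc = quantile_model_auc(RL_ASP_SUMMARY, NRL_ASP_SUMMARY)
        neg = sample_from_summary(RL_ASP_SUMMARY, 10**5, rng)
        pos = sample_from_summary(NRL_ASP_SUMMARY, 10**5, rng)
        from scipy.stats import rankdata

        ranks = rankdata(np.concatenate([neg, pos]))
        u = ranks[len(neg):].sum() - len(pos) * (len(pos) + 1) / 2
        assert u / (len(neg) * len(pos)) == pytest.approx(auc, abs=0.005)

    def test_model_auc_of_identical_summaries_is_half(self):
        assert quantile_model_auc(RL_ASP_SUMMARY, RL_ASP_SUMMARY) == pytest.approx(0.5, abs=1e-12)


class TestCohort:
    def test_closed_loop_labels(self):
        table = sample_cohort(CohortSpec(seed=4))
        for tp in ("4m", "12m"):
            labeled = classify_table(table, tp)
            assert (labeled[f"recist_{tp}"] == labeled["true_class"]).all()

    def test_single_class_cohort(self):
        spec = CohortSpec(n_per_class={"CR": 0, "PR": 0, "SD": 0, "PD": 27}, seed=2)
        table = sample_cohort(spec)
        assert len(table) == 27
        labeled = classify_table(table, "12m")
        assert (labeled["recist_12m"] == "PD").all()
        assert (labeled["group_12m"] == "NRL").all()

    def test_paper_matched_group_sizes(self):
        table = sample_cohort(CohortSpec(seed=9))
        labeled = classify_table(table, "12m")
        assert (labeled["group_12m"] == "RL").sum() == 104
        assert (labeled["group_12m"] == "NRL").sum() == 27

    def test_determinism_and_seed_sensitivity(self):
        t1 = sample_cohort(CohortSpec(seed=5))
        t2 = sample_cohort(CohortSpec(seed=5))
        pd.testing.assert_frame_equal(t1, t2)
        t3 = sample_cohort(CohortSpec(seed=6))
        assert not t1["asp_percent"].equals(t3["asp_percent"])

    def test_patient_packing_respects_selection_rules(self):
        table = sample_cohort(CohortSpec(seed=8))
        per_patient = table.groupby("patient_id").size()
        assert per_patient.max() <= 5
        per_organ = table.groupby(["patient_id", "organ"]).size()
        assert per_organ.max() <= 2

    def test_diameters_respect_eligibility(self):
        table = sample_cohort(CohortSpec(seed=10))
        nodes = table[table["organ"] == "lymph_node"]
        others = table[table["organ"] != "lymph_node"]
        assert (nodes["diameter_baseline_mm"] >= 15.0).all()
        assert (others["diameter_baseline_mm"] >= 10.0).all()

    def test_seed_splitting_is_stable_across_processes(self):
        # crc32-based tag hashing: the stream must not depend on interpreter state
        assert split_seed(1, "cohort", "asp", "PD").integers(0, 2**16) == \
            split_seed(1, "cohort", "asp", "PD").integers(0, 2**16)
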