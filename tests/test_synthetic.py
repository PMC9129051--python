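"""Seeded cohort generation: planted structure, panels, outcomes, bundles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from kneephen.biclustering import msr
from kneephen.synthetic import (
    FeatureKind,
    OutcomeParams,
    PlantedBicluster,
    SyntheticSpec,
    TrajGroup,
    default_spec,
    generate_clinical_matrix,
    generate_longitudinal_panel,
    generate_outcomes,
    read_fixture_bundle,
    recovery_benchmark_spec,
    two_group_panel,
    write_fixture_bundle,
)


class TestSpecValidation:
    def test_overlapping_planted_rows_rejected(self):
        spec = recovery_benchmark_spec(seed=0)
        bad = spec.planted_biclusters[0]
        spec.planted_biclusters.append(
            PlantedBicluster(rows=bad.rows[:5], cols=(0, 1), mu=1.0, row_scale=0.5, col_scale=0.5)
        )
        with pytest.raises(ValueError, match="overlap"):
            spec.validate()

    def test_mixing_proportions_must_sum_to_one(self):
        spec = recovery_benchmark_spec(seed=0)
        spec.traj_groups = [TrajGroup(pi=0.5, coef=(0.0,), sigma=1.0)]
        with pytest.raises(ValueError, match="sum"):
            spec.validate()

    def test_noise_sd_positive(self):
        spec = recovery_benchmark_spec(seed=0)
        spec.noise_sd = 0.0
        with pytest.raises(ValueError):
            spec.validate()

    def test_spec_json_roundtrip(self):
        spec = default_spec(seed=3, n_rows=50, n_cols=20)
        back = SyntheticSpec.from_dict(spec.to_dict())
        assert back.to_dict() == spec.to_dict()


class TestClinicalMatrix:
    def test_determinism_by_seed(self):
        spec = default_spec(seed=7, n_rows=60, n_cols=20)
        t1, _, _ = generate_clinical_matrix(spec)
        t2, _, _ = generate_clinical_matrix(spec)
        pd.testing.assert_frame_equal(t1, t2)

    def test_different_seed_differs(self):
        a, _, _ = generate_clinical_matrix(default_spec(seed=1, n_rows=60, n_cols=20))
        b, _, _ = generate_clinical_matrix(default_spec(seed=2, n_rows=60, n_cols=20))
        assert not a.equals(b)

    def test_dimensions_and_kinds(self):
        spec = default_spec(seed=5, n_rows=80, n_cols=20)
        table, truth, metadata = generate_clinical_matrix(spec)
        assert table.shape == (80, 20)
        assert len(metadata) == 20
        assert truth.latent.shape == (80, 20)

    def test_noiseless_block_has_zero_residue(self):
        spec = recovery_benchmark_spec(seed=0)
        spec.noise_sd = 1e-9
        _, truth, _ = generate_clinical_matrix(spec)
        blk = spec.planted_biclusters[0]
        h, _, _ = msr(truth.latent, blk.rows, blk.cols)
        assert h < 1e-6

    def test_block_msr_matches_theory(self):
        # an additive block plus iid noise has expected residue
        # sigma^2 (m-1)(n-1)/(m n) on the latent scale
        hs = []
        for seed in range(30):
            spec = recovery_benchmark_spec(seed=seed)
            spec.noise_sd = 0.3
            _, truth, _ = generate_clinical_matrix(spec)
            blk = spec.planted_biclusters[0]
            hs.append(msr(truth.latent, blk.rows, blk.cols)[0])
        m, n = 80, 14
        expected = 0.3**2 * (m - 1) * (n - 1) / (m * n)
        se = np.std(hs, ddof=1) / np.sqrt(len(hs))
        assert abs(np.mean(hs) - expected) < 3 * se

    def test_row_membership_unique(self):
        spec = default_spec(seed=2, n_rows=100, n_cols=20)
        _, truth, _ = generate_clinical_matrix(spec)
        counts = {}
        for blk_id in truth.row_membership.values():
            if blk_id is not None:
                counts[blk_id] = counts.get(blk_id, 0) + 1
        planted = {i: len(b.rows) for i, b in enumerate(spec.planted_biclusters)}
        assert counts == planted


class TestPanel:
    def test_group_sizes_within_binomial_bounds(self):
        panel, truth = two_group_panel(seed=1, n=500)
        sizes = np.bincount([g for g in truth.traj_group.values()], minlength=2)
        lo, hi = stats.binom.ppf([0.005, 0.995], 500, 0.7)
        assert lo <= sizes[0] <= hi

    def test_no_dropout_gives_all_visits(self):
        panel, _ = two_group_panel(seed=2, n=100)
        counts = panel.groupby("knee_id")["month"].count()
        assert (counts == 7).all()

    def test_month_zero_change_is_zero(self):
        panel, _ = two_group_panel(seed=3, n=50)
        assert (panel.loc[panel["month"] == 0, "value"] == 0.0).all()

    def test_dropout_is_monotone(self):
        spec = default_spec(seed=4, n_rows=300, n_cols=20)
        _, truth, _ = generate_clinical_matrix(spec)
        panel = generate_longitudinal_panel(spec, truth)
        months = [0, 12, 24, 36, 48, 72, 96]
        for _, sub in panel.groupby("knee_id"):
            got = sorted(sub["month"])
            assert got == months[: len(got)]  # a prefix: once gone, always gone

    def test_dropout_rate_matches_hazard(self):
        spec = default_spec(seed=6, n_rows=2000, n_cols=4)
        spec.planted_biclusters = []
        spec.dropout_hazard = {12: 0.2}
        _, truth, _ = generate_clinical_matrix(spec)
        panel = generate_longitudinal_panel(spec, truth)
        has12 = panel[panel["month"] == 12]["knee_id"].nunique()
        lo, hi = stats.binom.ppf([0.005, 0.995], 2000, 0.8)
        assert lo <= has12 <= hi


class TestOutcomes:
    def test_klg_monotone_over_time(self):
        spec = default_spec(seed=8, n_rows=150, n_cols=10)
        _, truth, _ = generate_clinical_matrix(spec)
        out = generate_outcomes(spec, truth)
        for _, sub in out.groupby("knee_id"):
            klg = sub.sort_values("month")["klg"].to_numpy()
            assert np.all(np.diff(klg) >= 0)
            assert klg.min() >= 0 and klg.max() <= 4

    def test_linear_qjsw_with_zero_noise(self):
        spec = recovery_benchmark_spec(seed=0)
        spec.outcome_params = {
            "background": OutcomeParams(
                qjsw_baseline_mean=(4.0, 4.0),
                qjsw_baseline_sd=0.0,
                qjsw_slope_mean=(-1.0 / 96, -1.0 / 96),
                qjsw_slope_sd=0.0,
                qjsw_noise_sd=0.0,
            )
        }
        spec.planted_biclusters = []
        _, truth, _ = generate_clinical_matrix(spec)
        out = generate_outcomes(spec, truth)
        at96 = out[out["month"] == 96]
        np.testing.assert_allclose(at96["qjsw_medial"], 3.0, atol=1e-12)

    def test_zero_tka_probability(self):
        spec = recovery_benchmark_spec(seed=1)
        spec.outcome_params = {"background": OutcomeParams(tka_prob=0.0)}
        spec.planted_biclusters = []
        _, truth, _ = generate_clinical_matrix(spec)
        out = generate_outcomes(spec, truth)
        assert (out["tka"] == 0).all()


class TestBundle:
    def test_roundtrip_cell_for_cell(self, tmp_path):
        spec = default_spec(seed=9, n_rows=40, n_cols=12)
        write_fixture_bundle(tmp_path, spec)
        bundle = read_fixture_bundle(tmp_path)
        table, truth, _ = generate_clinical_matrix(spec)
        pd.testing.assert_frame_equal(
            bundle["baseline"], table, check_dtype=False
        )
        assert bundle["spec"].to_dict() == spec.to_dict()

    def test_regeneration_from_stored_spec(self, tmp_path):
        spec = default_spec(seed=10, n_rows=30, n_cols=10)
        write_fixture_bundle(tmp_path / "a", spec)
        stored = read_fixture_bundle(tmp_path / "a")["spec"]
        write_fixture_bundle(tmp_path / "b", stored)
        for name in ("baseline.csv", "panel.csv", "outcomes.csv"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()
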