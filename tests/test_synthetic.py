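"""Dose-dependent generator: response model, metric tables, renders."""

import numpy as np
import pandas as pd
import pytest

from sproutassay.synthetic import (
    ChipGeometry,
    PlateLayout,
    SproutingModelParams,
    expected_response,
    generate_dose_response_dataset,
    render_chip_stack,
    simulate_metric_table,
)


class TestExpectedResponse:
    def test_vehicle_returns_control_distance(self):
        p = SproutingModelParams(D0=321.0)
        assert expected_response(0.0, p) == 321.0

    def test_half_maximal_at_ic50(self):
        p = SproutingModelParams(D0=200.0, Imax=1.0, ic50=20.0)
        assert expected_response(20.0, p) == pytest.approx(100.0)

    def test_hand_evaluated_point(self):
        # 250 * (1 - 80/100) at c=80, IC50=20, hill=1, full inhibition
        p = SproutingModelParams(D0=250, Imax=1.0, ic50=20.0, hill=1.0)
        assert expected_response(80.0, p) == pytest.approx(50.0)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            expected_response(-1.0, SproutingModelParams())

    @pytest.mark.parametrize("imax,hill", [(1.0, 1.0), (0.6, 0.8), (1.0, 2.5)])
    def test_monotone_non_increasing_and_bounded(self, imax, hill):
        p = SproutingModelParams(D0=250, Imax=imax, ic50=30.0, hill=hill)
        grid = np.logspace(-2, 4, 200)
        vals = np.array([expected_response(c, p) for c in grid])
        assert np.all(np.diff(vals) <= 1e-9)
        assert np.all(vals <= p.D0 + 1e-9)
        assert np.all(vals >= p.D0 * (1 - p.Imax) - 1e-9)

    def test_param_validation(self):
        with pytest.raises(ValueError):
            SproutingModelParams(D0=-5)
        with pytest.raises(ValueError):
            SproutingModelParams(Imax=1.5)
        with pytest.raises(ValueError):
            SproutingModelParams(hill=0)


class TestPlateLayout:
    def test_control_plate_mirrors_characterisation_design(self):
        layout = PlateLayout.control_plate(n_max=15, n_min=14)
        df = layout.to_frame()
        assert (df.role == "max_control").sum() == 15
        assert (df.role == "min_control").sum() == 14
        assert (df.loc[df.role == "max_control", "concentration_nM"] == 0).all()

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            PlateLayout((("a", "x", 0.0, "test"), ("a", "x", 1.0, "test")))

    def test_bad_role_rejected(self):
        with pytest.raises(ValueError):
            PlateLayout((("a", "x", 0.0, "vehicle"),))

    def test_csv_round_trip(self, tmp_path):
        layout = PlateLayout.control_plate(3, 2)
        path = tmp_path / "layout.csv"
        layout.to_frame().to_csv(path, index=False)
        assert PlateLayout.from_csv(path) == layout


class TestSimulateMetricTable:
    def test_zero_noise_reproduces_expectation(self):
        p = SproutingModelParams(cv_chip=0.0, D0=250)
        layout = PlateLayout.control_plate(5, 5, min_conc=1e6)
        df = simulate_metric_table(layout, p, seed=0)
        assert np.allclose(
            df.loc[df.role == "max_control", "distance_um"], 250.0
        )

    def test_one_row_per_chip(self):
        layout = PlateLayout.control_plate(15, 14)
        df = simulate_metric_table(layout, SproutingModelParams(), seed=1)
        assert len(df) == 29
        assert df.chip_id.is_unique

    def test_law_of_large_numbers_at_vehicle(self):
        p = SproutingModelParams(D0=250, cv_chip=0.13)
        layout = PlateLayout((("c0", "veh", 0.0, "max_control"),))
        df = simulate_metric_table(layout, p, replicates=10_000, seed=2)
        se = 0.13 * 250 / np.sqrt(len(df))
        assert abs(df.distance_um.mean() - 250) < 3 * se

    def test_group_sd_scales_with_cv(self):
        layout = PlateLayout.control_plate(200, 2)
        sds = []
        for cv in (0.05, 0.10):
            p = SproutingModelParams(cv_chip=cv)
            df = simulate_metric_table(layout, p, seed=3)
            sds.append(df.loc[df.role == "max_control", "distance_um"].std())
        assert sds[1] / sds[0] == pytest.approx(2.0, rel=0.2)

    def test_seeded_determinism(self):
        layout = PlateLayout.control_plate(6, 6)
        p = SproutingModelParams()
        a = simulate_metric_table(layout, p, seed=9)
        b = simulate_metric_table(layout, p, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_layout_rejected(self):
        with pytest.raises(ValueError):
            simulate_metric_table(PlateLayout(()), SproutingModelParams())


class TestDoseResponseDataset:
    def test_requires_four_concentrations(self):
        with pytest.raises(ValueError):
            generate_dose_response_dataset([0, 10, 100], SproutingModelParams())

    def test_screening_series_shape(self):
        df = generate_dose_response_dataset(
            [0, 1, 10, 50, 100, 1000], SproutingModelParams(), n_per_conc=4, seed=0
        )
        assert len(df) == 24
        assert set(df.concentration_nM) == {0, 1, 10, 50, 100, 1000}

    def test_saturating_dose_suppresses_response(self):
        p = SproutingModelParams(Imax=1.0, ic50=20.0, cv_chip=0.05)
        df = generate_dose_response_dataset(
            [0, 1, 10, 1e6], p, n_per_conc=6, seed=4
        )
        high = df.loc[df.concentration_nM == 1e6, "distance_um"]
        assert high.max() < 0.05 * p.D0


class TestRenderChipStack:
    def test_seeded_determinism_bit_identical(self, default_params):
        geom = ChipGeometry(shape_px=(128, 128), n_z=3)
        p = SproutingModelParams(D0=80, baseline_y=100, sprouts_per_chip=2)
        a, _ = render_chip_stack(p, geom, seed=5)
        b, _ = render_chip_stack(p, geom, seed=5)
        for name in a.channels:
            assert np.array_equal(a.channels[name], b.channels[name])
            assert a.channels[name].dtype == np.uint16

    def test_zero_sprouts_background_only_beyond_baseline(self):
        p = SproutingModelParams(seed=6)
        stack, truth = render_chip_stack(p, n_sprouts=0, seed=6, noise=False)
        baseline_px = int(round(p.baseline_y / 2.7))
        gel = stack.channels["factin"][:, baseline_px + 5:, :]
        assert gel.max() <= 110  # background offset only
        assert truth.true_distance == 0.0
        assert truth.true_nuclei_in_sprouts == 0

    def test_ground_truth_consistency(self, rendered_chip, default_params):
        _, truth = rendered_chip
        assert truth.true_distance >= 0
        assert truth.true_area > 0
        pos = truth.nuclei_positions
        assert (pos[:, 0] >= 0).all() and (pos[:, 1] >= 0).all()
        # sprout nuclei beyond the baseline count matches the stored total
        beyond = truth.sprout_nuclei[:, 1] > default_params.baseline_y
        assert truth.true_nuclei_in_sprouts == int(beyond.sum())

    def test_out_of_frame_nuclei_clipped_with_warning(self):
        geom = ChipGeometry(shape_px=(96, 96), n_z=2)  # 259 µm frame
        p = SproutingModelParams(D0=400, baseline_y=100, cv_chip=0.0,
                                 sprouts_per_chip=3)
        with pytest.warns(RuntimeWarning, match="clipped"):
            _, truth = render_chip_stack(p, geom, seed=8)
        assert (truth.nuclei_positions[:, 1] < geom.height_um).all()
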