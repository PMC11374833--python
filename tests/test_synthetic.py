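import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cortexmx import synthetic as syn
from cortexmx.geometry import layer_area


class TestGenerateField:
    def test_fixed_count_matches_density_times_area(self):
        pop = syn.PopulationSpec(
            densities={"Neuron": {"L2/3": 200.0}}, count_mode="fixed",
            confusable_fraction=0.0,
        )
        spec = syn.FieldSpec(seed=1)
        fd = syn.generate_field(spec, pop)
        area = layer_area(fd.layer_model, "L2/3")
        assert len(fd.cells) == round(200.0 * area)

    def test_all_zero_densities_give_empty_tables(self):
        pop = syn.PopulationSpec(
            densities={c: {} for c in syn.CLASSES}, confusable_fraction=0.0,
            vessels_per_mm2=0.0,
        )
        fd = syn.generate_field(syn.FieldSpec(seed=2), pop)
        assert fd.cells.empty
        assert fd.ground_truth.empty

    def test_determinism(self):
        pop = syn.population_preset("A46").scaled(0.2, 0.0)
        a = syn.generate_field(syn.FieldSpec(seed=5), pop)
        b = syn.generate_field(syn.FieldSpec(seed=5), pop)
        pd.testing.assert_frame_equal(a.cells, b.cells)
        pd.testing.assert_frame_equal(a.ground_truth, b.ground_truth)

    def test_ground_truth_closure(self, small_field):
        """Every cell has exactly one truth row and sits inside its layer."""
        cells, truth = small_field.cells, small_field.ground_truth
        assert len(cells) == len(truth)
        assert (cells["object_id"].to_numpy() == truth["object_id"].to_numpy()).all()
        model = small_field.layer_model
        for layer in truth["true_layer"].unique():
            top, bottom = model.layer_interval(layer)
            depths = cells.loc[
                truth.index[truth["true_layer"] == layer], "centroid_y_um"
            ]
            assert ((depths >= top) & (depths < bottom)).all()

    def test_cell_table_dialect(self, small_field):
        cols = small_field.cells.columns
        assert cols[0] == "object_id"
        assert {"centroid_x_um", "centroid_y_um"} <= set(cols)
        assert "HuD_Cell_mean" in cols
        assert "Olig2_Nucleus_mean" in cols
        assert "GFAP_Cytoplasm_mean" in cols

    def test_log_normality_of_intensities(self):
        """ln(raw+1) for one homogeneous (class, marker) stratum passes
        Shapiro–Wilk at α=0.01 in ≥95% of seeds (Olig2 is positive in every
        oligodendrocyte, so the stratum is a single log-normal)."""
        rejections = 0
        n_seeds = 40
        for seed in range(n_seeds):
            pop = syn.PopulationSpec(
                densities={"Oligodendrocyte": {"L6": 3600.0}},
                confusable_fraction=0.0,
            )
            fd = syn.generate_field(syn.FieldSpec(seed=seed), pop)
            raw = fd.cells["Olig2_Nucleus_mean"].to_numpy()[:500]
            assert len(raw) == 500
            _, p = sps.shapiro(np.log(raw + 1))
            rejections += p < 0.01
        assert rejections / n_seeds <= 0.05

    def test_planted_density_ratio_recoverable_from_truth(self):
        ratios = []
        for seed in range(5):
            a46 = syn.generate_field(
                syn.FieldSpec(area_label="A46", seed=seed),
                syn.population_preset("A46", count_mode="poisson").scaled(0.3, 0),
            )
            a17 = syn.generate_field(
                syn.FieldSpec(area_label="A17", seed=seed + 100),
                syn.population_preset("A17", count_mode="poisson").scaled(0.3, 0),
            )
            dens = []
            for fd in (a46, a17):
                t = fd.ground_truth
                n = (
                    (t["true_class"] == "Neuron")
                    & t["true_layer"].isin(["L2/3", "L4", "L5", "L6"])
                ).sum()
                area = sum(
                    layer_area(fd.layer_model, l) for l in ("L2/3", "L4", "L5", "L6")
                )
                dens.append(n / area)
            ratios.append(dens[1] / dens[0])
        assert np.mean(ratios) == pytest.approx(2.0, abs=0.15)

    def test_placement_failure_is_diagnosed(self):
        pop = syn.PopulationSpec(
            densities={"Neuron": {"L2/3": 20000.0}}, confusable_fraction=0.0
        )
        with pytest.raises(syn.PlacementError, match="separation"):
            syn.generate_field(
                syn.FieldSpec(seed=3), pop, render_channels=["DAPI"]
            )

    def test_rendered_nuclei_do_not_overlap(self, rendered_field):
        xy = rendered_field.cells[["centroid_x_um", "centroid_y_um"]].to_numpy()
        from scipy.spatial.distance import pdist

        min_sep = 2 * 4.0 + 1.0
        assert pdist(xy).min() >= min_sep - 1e-9


class TestGenerateCohort:
    def test_default_seven_cases_give_eleven_fields(self):
        fields, manifest = syn.generate_cohort(
            n_cases=7, seed=1, count_mode="fixed",
        )
        assert len(fields) == 11
        areas = [f.spec.area_label for f in fields]
        assert areas.count("A46") == 6
        assert areas.count("A17") == 5
        assert len(manifest["fields"]) == 11

    def test_single_case_degenerates_to_unit_effect(self):
        fields, manifest = syn.generate_cohort(n_cases=1, seed=4, count_mode="fixed")
        assert len(fields) == 2  # one field per preset
        for f in manifest["fields"]:
            assert f["density_factor"] == 1.0
            assert f["intensity_shift"] == 0.0

    def test_zero_random_effect_gives_identical_expected_densities(self):
        fields, manifest = syn.generate_cohort(
            n_cases=3, seed=9, case_effect_sd=0.0, count_mode="fixed"
        )
        factors = {f["density_factor"] for f in manifest["fields"]}
        assert factors == {1.0}
        a46 = [len(f.cells) for f in fields if f.spec.area_label == "A46"]
        assert len(set(a46)) == 1  # fixed counts, equal effects → equal sizes

    def test_invalid_case_count_rejected(self):
        with pytest.raises(ValueError):
            syn.generate_cohort(n_cases=0, seed=1)


class TestPopulationSpec:
    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            syn.PopulationSpec(densities={"Neuron": {"L1": -5.0}})

    def test_scaled_compounds_factors(self):
        pop = syn.PopulationSpec().scaled(0.5, 0.1).scaled(0.5, 0.1)
        assert pop.density_scale == pytest.approx(0.25)
        assert pop.intensity_shift == pytest.approx(0.2)
        assert pop.densities["Neuron"]["L2/3"] == pytest.approx(400.0)
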