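import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cortexmx.composition import (
    compare_groups,
    composition_ratios,
    count_cells,
    density_by_layer,
    laminar_distribution,
    sidak_adjust,
    within_layer_proportions,
)


class TestDensity:
    def test_count_over_area(self):
        counts = pd.DataFrame({"layer": ["L4"], "count": [20]})
        out = density_by_layer(counts, {"L4": 0.1})
        assert out["density_per_mm2"].iloc[0] == 200.0

    def test_zero_count_zero_density(self):
        counts = pd.DataFrame({"layer": ["L4"], "count": [0]})
        assert density_by_layer(counts, {"L4": 0.1})["density_per_mm2"].iloc[0] == 0.0

    def test_zero_area_rejected(self):
        counts = pd.DataFrame({"layer": ["L4"], "count": [5]})
        with pytest.raises(ValueError):
            density_by_layer(counts, {"L4": 0.0})

    def test_missing_layer_area_rejected(self):
        counts = pd.DataFrame({"layer": ["L9"], "count": [5]})
        with pytest.raises(KeyError):
            density_by_layer(counts, {"L4": 0.1})

    def test_unit_invariance(self):
        counts = pd.DataFrame({"layer": ["L4"], "count": [20]})
        d1 = density_by_layer(counts, {"L4": 0.1})["density_per_mm2"].iloc[0]
        # same area expressed via µm²→mm² conversion of a 400×250 µm rectangle
        d2 = density_by_layer(counts, {"L4": 400 * 250 / 1e6})["density_per_mm2"].iloc[0]
        assert d1 == d2


class TestRatios:
    def test_printed_non_neuronal_ratios(self):
        r46 = composition_ratios({"Neuron": 57, "Astrocyte": 43})
        assert r46.non_neuronal_to_neuron == pytest.approx(43 / 57)
        assert r46.display["non_neuronal_to_neuron"] == 0.75
        r17 = composition_ratios({"Neuron": 73, "Astrocyte": 27})
        assert r17.display["non_neuronal_to_neuron"] == 0.37

    def test_printed_gnr(self):
        r = composition_ratios(
            {"Neuron": 57, "Astrocyte": 20, "Oligodendrocyte": 9,
             "Microglia": 3, "Endothelial": 11}
        )
        assert r.glia_to_neuron == pytest.approx(32 / 57)
        assert r.display["glia_to_neuron"] == 0.56

    def test_ei_from_inhibitory_fraction(self):
        r = composition_ratios(
            {"Neuron": 100}, inhibitory_neurons=20, neurons_l23_l6=100
        )
        assert r.excitatory_to_inhibitory == 4.0

    def test_zero_denominator_flagged_not_raised(self):
        r = composition_ratios({"Astrocyte": 10})
        assert r.non_neuronal_to_neuron is None
        assert r.display["non_neuronal_to_neuron"] is None

    @given(p=st.floats(0.01, 0.99))
    @settings(max_examples=50, deadline=None)
    def test_ratio_identity(self, p):
        """non-neuronal:neuron = (1−p)/p for any neuron proportion p."""
        n = 10_000
        r = composition_ratios(
            {"Neuron": p * n, "Endothelial": (1 - p) * n}
        )
        assert r.non_neuronal_to_neuron == pytest.approx((1 - p) / p, rel=1e-9)


class TestLaminarDistribution:
    def test_single_layer_concentration(self):
        counts = pd.DataFrame(
            {"cell_class": ["Neuron"] * 5,
             "layer": ["L1", "L2/3", "L4", "L5", "L6"],
             "count": [0, 10, 0, 0, 0]}
        )
        out = laminar_distribution(counts)
        assert out["fraction"].tolist() == [0, 1, 0, 0, 0]

    def test_uniform_counts(self):
        counts = pd.DataFrame(
            {"cell_class": ["Neuron"] * 5,
             "layer": ["L1", "L2/3", "L4", "L5", "L6"],
             "count": [7] * 5}
        )
        assert laminar_distribution(counts)["fraction"].tolist() == [0.2] * 5

    def test_wm_excluded_and_fractions_sum_to_one(self, annotated_cohort):
        cells, _, _ = annotated_cohort
        keep = (~cells["cell_class"].isin(["Other", "Multiple"])) & (
            cells["layer"] != "excluded"
        )
        counts = count_cells(cells[keep], by=("area", "layer", "cell_class"))
        out = laminar_distribution(counts)
        assert "WM" not in out["layer"].values
        sums = out.groupby(["area", "cell_class"])["fraction"].sum()
        assert np.allclose(sums, 1.0)

    def test_within_layer_proportions_sum_to_one(self, annotated_cohort):
        cells, _, _ = annotated_cohort
        keep = (~cells["cell_class"].isin(["Other", "Multiple"])) & (
            cells["layer"] != "excluded"
        )
        counts = count_cells(cells[keep], by=("layer", "cell_class"))
        out = within_layer_proportions(counts)
        sums = out.groupby("layer")["proportion"].sum()
        assert np.allclose(sums, 1.0)

    def test_count_conservation(self, annotated_cohort):
        cells, _, _ = annotated_cohort
        keep = (~cells["cell_class"].isin(["Other", "Multiple"])) & (
            cells["layer"] != "excluded"
        )
        counts = count_cells(cells[keep])
        assert counts["count"].sum() == keep.sum()


def _simulate(rng, effect=1.0, n_per=8, subject_sd=0.1, noise_sd=0.1, log_scale=True):
    layers = ["L1", "L2/3", "L4", "L5", "L6"]
    rows = []
    for area in ("A46", "A17"):
        for i in range(n_per):
            b = rng.normal(0, subject_sd)
            for l in layers:
                mu = effect if area == "A17" else 1.0
                y = mu * np.exp(b) * np.exp(rng.normal(0, noise_sd))
                rows.append(
                    {"area": area, "case": f"{area}{i}", "layer": l,
                     "density": np.log(y) if log_scale else y}
                )
    return pd.DataFrame(rows)


class TestCompareGroups:
    def test_planted_area_effect_detected(self, rng):
        df = _simulate(rng, effect=2.0)
        res = compare_groups(df, "density")
        anova = res["anova"].set_index("factor")
        assert anova.loc["area", "p"] < 0.001
        assert anova.loc["area", "error_stratum"] == "subjects"
        assert anova.loc["layer", "error_stratum"] == "residual"

    def test_null_is_not_rejected_most_of_the_time(self, rng):
        rejections = sum(
            compare_groups(_simulate(rng), "density")["anova"]
            .set_index("factor")
            .loc["area", "p"]
            < 0.05
            for _ in range(40)
        )
        assert rejections <= 6

    def test_one_subject_per_group_refused(self, rng):
        df = _simulate(rng, n_per=1)
        with pytest.raises(ValueError, match="subject"):
            compare_groups(df, "density")

    def test_single_level_factor_refused(self, rng):
        df = _simulate(rng)
        df["area"] = "A46"
        with pytest.raises(ValueError):
            compare_groups(df, "density")

    def test_contrasts_are_sidak_adjusted(self, rng):
        df = _simulate(rng, effect=2.0)
        res = compare_groups(df, "density")
        c = res["contrasts"]
        layer_c = c[c["factor"] == "layer"]
        assert len(layer_c) == 10  # 5 choose 2
        assert (layer_c["p_sidak"] >= layer_c["p_raw"] - 1e-12).all()

    def test_sidak_adjustment_formula(self):
        assert sidak_adjust(np.array([0.01]), 5) == pytest.approx(
            1 - 0.99**5
        )
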