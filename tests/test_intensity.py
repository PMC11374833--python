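import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cortexmx.intensity import (
    DegenerateInputError,
    GateSpec,
    call_positive,
    gates_from_reference,
    log_z_normalize,
    measure_compartments,
    normalize_cell_table,
    segment_nuclei,
    trim_extremes,
)
from cortexmx.panel import MarkerPanel


class TestLogZNormalize:
    def test_two_point_hand_example(self):
        # raw {0, e²−1} → ln+1 {0, 2} → z = ∓1/√2 with sample s.d.
        out = log_z_normalize([0.0, math.e**2 - 1])
        assert out == pytest.approx([-1 / math.sqrt(2), 1 / math.sqrt(2)])

    def test_three_point_hand_example(self):
        out = log_z_normalize([0.0, math.e - 1, math.e**3 - 1])
        assert out == pytest.approx([-0.8729, -0.2182, 1.0911], abs=1e-4)

    @given(
        st.lists(st.floats(0, 1e6, allow_nan=False), min_size=2, max_size=200).filter(
            lambda v: np.std(np.log(np.asarray(v) + 1), ddof=1) > 1e-12
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_output_standardized(self, values):
        out = log_z_normalize(values)
        assert abs(out.mean()) < 1e-9
        assert out.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_log_shift_invariance(self):
        # multiplying (raw+1) by a constant shifts ln by a constant,
        # which the z-score removes exactly
        raw = np.array([0.0, 10.0, 100.0, 1000.0])
        scaled = (raw + 1) * 7.0 - 1
        assert log_z_normalize(raw) == pytest.approx(
            log_z_normalize(scaled), abs=1e-12
        )

    def test_constant_input_raises(self):
        with pytest.raises(DegenerateInputError):
            log_z_normalize([5.0, 5.0, 5.0])

    def test_single_value_raises(self):
        with pytest.raises(DegenerateInputError):
            log_z_normalize([1.0])


class TestTrimExtremes:
    @pytest.mark.parametrize(
        "n,frac,expected_kept",
        [(1000, 0.002, 996), (100, 0.01, 98), (50, 0.0, 50)],
    )
    def test_kept_counts(self, n, frac, expected_kept, rng):
        values = rng.normal(size=n)
        keep = trim_extremes(values, frac, frac)
        assert keep.sum() == expected_kept

    def test_drops_the_extremes_not_the_middle(self, rng):
        values = np.arange(1000.0)
        keep = trim_extremes(values, 0.002, 0.002)
        assert not keep[0] and not keep[1]
        assert not keep[-1] and not keep[-2]
        assert keep[2:-2].all()

    def test_ties_broken_stably(self):
        values = np.zeros(10)
        keep = trim_extremes(values, 0.1, 0.0)
        assert not keep[0] and keep[1:].all()

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            trim_extremes([1.0, 2.0], 0.6, 0.0)


class TestGating:
    def test_equality_is_negative(self):
        gate = GateSpec("HuD", "Cell", "Neuron", "fixed", 1.0)
        assert not call_positive(1.0, gate)
        assert call_positive(1.0 + 1e-12, gate)

    def test_quantile_gate_median(self):
        gate = GateSpec("HuD", "Cell", "Neuron", "quantile-of-reference", 0.5)
        gate.resolve(np.array([-1.0, 0.0, 1.0]))
        assert gate.threshold == 0.0
        assert call_positive(1.0, gate)
        assert not call_positive(0.0, gate)

    def test_unresolved_threshold_raises(self):
        gate = GateSpec("HuD", "Cell", "Neuron", "quantile-of-reference", 0.5)
        with pytest.raises(ValueError):
            call_positive(1.0, gate)

    def test_recovers_planted_positivity(self, small_field):
        """With ≥3-s.d. separation from the gate, calls match ground truth ≥99%."""
        panel = MarkerPanel.default()
        cells = normalize_cell_table(small_field.cells, panel)
        gates = gates_from_reference(cells, small_field.ground_truth, panel)
        correct = total = 0
        for name, gate in gates.items():
            col = f"{name}_{gate.compartment}_mgi"
            calls = call_positive(cells[col].to_numpy(), gate)
            truth = small_field.ground_truth[f"pos_{name}"].to_numpy()
            correct += (calls == truth).sum()
            total += len(calls)
        assert correct / total >= 0.99


class TestSegmentation:
    def test_blank_image_yields_zero_nuclei(self):
        labels, table = segment_nuclei(np.zeros((50, 50)), 1.0)
        assert labels.max() == 0
        assert table.empty

    def test_counts_match_rendered_ground_truth(self, rendered_field):
        px = rendered_field.spec.pixel_size
        labels, table = segment_nuclei(
            rendered_field.image["DAPI"], px, intensity_floor=100.0, min_area_um2=10.0
        )
        assert len(table) == len(rendered_field.cells)

    def test_min_area_filter_uses_disc_area(self):
        # a radius-4 µm disc has area π·16 ≈ 50.3 µm² < 60 → rejected
        img = np.zeros((40, 40))
        yy, xx = np.mgrid[0:40, 0:40]
        img[(yy - 20) ** 2 + (xx - 20) ** 2 <= 16] = 200.0  # r=4 px at 1 µm/px
        _, kept = segment_nuclei(img, 1.0, 100.0, min_area_um2=60.0)
        assert kept.empty
        _, kept = segment_nuclei(img, 1.0, 100.0, min_area_um2=40.0)
        assert len(kept) == 1


class TestCompartments:
    @pytest.fixture()
    def one_nucleus(self):
        labels = np.zeros((20, 20), dtype=int)
        labels[8:12, 8:12] = 1
        return labels

    def test_uniform_channel_gives_constant_means(self, one_nucleus):
        out = measure_compartments(one_nucleus, {"HuD": np.full((20, 20), 7.0)}, 1.0)
        assert out["HuD_Nucleus_mean"].iloc[0] == 7.0
        assert out["HuD_Cell_mean"].iloc[0] == 7.0
        assert out["HuD_Cytoplasm_mean"].iloc[0] == 7.0

    def test_nucleus_only_signal_leaves_cytoplasm_zero(self, one_nucleus):
        channel = np.where(one_nucleus > 0, 50.0, 0.0)
        out = measure_compartments(one_nucleus, {"NeuN": channel}, 1.0)
        assert out["NeuN_Cytoplasm_mean"].iloc[0] == 0.0
        assert out["NeuN_Nucleus_mean"].iloc[0] == 50.0

    def test_two_pixel_nucleus_mean(self):
        labels = np.zeros((5, 5), dtype=int)
        labels[2, 2] = labels[2, 3] = 1
        channel = np.zeros((5, 5))
        channel[2, 2], channel[2, 3] = 10.0, 20.0
        out = measure_compartments(labels, {"HuD": channel}, 1.0)
        assert out["HuD_Nucleus_mean"].iloc[0] == 15.0

    def test_compartment_partition_invariants(self, one_nucleus):
        from skimage import segmentation as sks

        expanded = sks.expand_labels(one_nucleus, 2)
        nucleus = one_nucleus > 0
        cell = expanded > 0
        cyto = cell & ~nucleus
        assert (nucleus & ~cell).sum() == 0  # Nucleus ⊆ Cell
        assert (cyto & nucleus).sum() == 0
        assert ((cyto | nucleus) == cell).all()

    def test_unknown_channel_rejected(self, one_nucleus):
        with pytest.raises(KeyError, match="NotAMarker"):
            measure_compartments(one_nucleus, {"NotAMarker": np.zeros((20, 20))}, 1.0)

    def test_rendered_field_roundtrip(self, rendered_field):
        """Compartment means recovered from rendered images agree with the table."""
        px = rendered_field.spec.pixel_size
        labels, table = segment_nuclei(
            rendered_field.image["DAPI"], px, intensity_floor=100.0
        )
        out = measure_compartments(labels, {"NeuN": rendered_field.image["NeuN"]}, px)
        # NeuN-positive nuclei should read far brighter than negatives
        truth = rendered_field.ground_truth
        pos_frac = truth["pos_NeuN"].mean()
        measured_hi = (out["NeuN_Nucleus_mean"] > 100).mean()
        assert measured_hi == pytest.approx(pos_frac, abs=0.05)
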