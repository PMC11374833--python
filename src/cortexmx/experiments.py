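"""Reusable desk-scale experiments: worked examples, planted-parameter
recovery, statistical calibration, and multivariate planted-structure
checks.

These are the computations the analysis drivers and the acceptance
script execute.  Everything is seeded; simulation sizes are chosen so a
full run completes in minutes on one CPU (per-field densities are scaled
to about a third of the full template where only a ratio or rate — not
an absolute count — is being estimated).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import composition as comp
from . import multivariate as mv
from . import pipeline as pl
from . import synthetic as syn
from .geometry import layer_area
from .intensity import call_positive, gates_from_reference, normalize_cell_table
from .panel import MarkerPanel
from .phenotyping import filter_for_analysis
from .synthetic import _MIX
from .vessels import polygon_metrics, vessel_metrics

SAMPLED_LAYERS = ("L2/3", "L4", "L5", "L6")


# ---------------------------------------------------------------------------
# worked examples from printed compositions


def printed_ratio_examples() -> dict[str, float]:
    """Headline ratios recomputed from the printed cell-class proportions.

    Inputs are the published pooled percentages: 57% neurons with 32%
    glia in the prefrontal area, 73% neurons with 18% glia in the primary
    visual area, and a 20% GABAergic fraction of prefrontal neurons.
    """
    a46 = comp.composition_ratios(
        {"Neuron": 57, "Astrocyte": 20, "Oligodendrocyte": 9,
         "Microglia": 3, "Endothelial": 11},
        inhibitory_neurons=20, neurons_l23_l6=100,
    )
    a17 = comp.composition_ratios(
        {"Neuron": 73, "Astrocyte": 12, "Oligodendrocyte": 5,
         "Microglia": 1, "Endothelial": 9},
    )
    return {
        "nn_neuron_ratio_a46": a46.non_neuronal_to_neuron,
        "nn_neuron_ratio_a17": a17.non_neuronal_to_neuron,
        "gnr_a46": a46.glia_to_neuron,
        "gnr_a17": a17.glia_to_neuron,
        "ei_ratio_a46": a46.excitatory_to_inhibitory,
    }


# ---------------------------------------------------------------------------
# planted-parameter recovery


def _annotated_field(area: str, seed: int, scale: float = 0.3,
                     pop: syn.PopulationSpec | None = None) -> tuple:
    pop = pop or syn.population_preset(area, count_mode="poisson").scaled(scale, 0.0)
    fd = syn.generate_field(syn.FieldSpec(area_label=area, seed=seed), pop)
    cells = pl.annotate_cohort([fd])
    return fd, cells


def neuron_density_ratio(seed: int, scale: float = 0.3) -> float:
    """A17:A46 neuron-density ratio over L2/3–L6, one seed, full pipeline."""
    dens = {}
    for i, area in enumerate(("A46", "A17")):
        fd, cells = _annotated_field(area, seed * 2 + i + 1, scale)
        retained, _ = filter_for_analysis(cells)
        n = (
            (retained["cell_class"] == "Neuron")
            & retained["layer"].isin(SAMPLED_LAYERS)
        ).sum()
        area_mm2 = sum(layer_area(fd.layer_model, l) for l in SAMPLED_LAYERS)
        dens[area] = n / area_mm2
    return dens["A17"] / dens["A46"]


def density_ratio_recovery(n_seeds: int = 20, seed: int = 0, scale: float = 0.3):
    ratios = [neuron_density_ratio(seed * 1000 + k, scale) for k in range(n_seeds)]
    return float(np.mean(ratios)), ratios


def gating_accuracy(seed: int = 0, scale: float = 0.3) -> float:
    """Positive-call accuracy vs ground truth over every gated marker."""
    panel = MarkerPanel.default()
    pop = syn.population_preset("A46", count_mode="poisson").scaled(scale, 0.0)
    fd = syn.generate_field(syn.FieldSpec(seed=seed), pop)
    cells = normalize_cell_table(fd.cells, panel)
    gates = gates_from_reference(cells, fd.ground_truth, panel)
    correct = total = 0
    for name, gate in gates.items():
        col = f"{name}_{gate.compartment}_mgi"
        calls = call_positive(cells[col].to_numpy(), gate)
        truth = fd.ground_truth[f"pos_{name}"].to_numpy()
        correct += int((calls == truth).sum())
        total += len(calls)
    return correct / total


# ---------------------------------------------------------------------------
# statistical calibration of the group-comparison contract


def _mixed_design_sample(rng, effect: float = 1.0, n_per_arm: int = 10,
                         subject_sd: float = 0.1, noise_sd: float = 0.1):
    """Split-plot sample: area (between) × layer (within), multiplicative
    subject effect and noise; analysed on the log scale."""
    layers = ["L1", "L2/3", "L4", "L5", "L6"]
    rows = []
    for area in ("A46", "A17"):
        mu = effect if area == "A17" else 1.0
        for i in range(n_per_arm):
            b = rng.normal(0, subject_sd)
            for l in layers:
                y = mu * np.exp(b) * np.exp(rng.normal(0, noise_sd))
                rows.append(
                    {"area": area, "case": f"{area}{i}", "layer": l,
                     "log_density": np.log(y)}
                )
    return pd.DataFrame(rows)


def anova_calibration(n_null: int = 1000, n_power: int = 100, seed: int = 0):
    """Type-I rate under the null and power at a planted ×2 area effect."""
    rng = np.random.default_rng(seed)

    def _area_p(df):
        res = comp.compare_groups(df, "log_density")
        return res["anova"].set_index("factor").loc["area", "p"]

    type1 = float(
        np.mean([_area_p(_mixed_design_sample(rng)) < 0.05 for _ in range(n_null)])
    )
    power = float(
        np.mean(
            [_area_p(_mixed_design_sample(rng, effect=2.0)) < 0.05
             for _ in range(n_power)]
        )
    )
    return type1, power


# ---------------------------------------------------------------------------
# multivariate planted structure


def manova_informative_feature(seed: int = 0, n_per_group: int = 20, p: int = 5):
    """One informative feature (group means 0 vs 5, s.d. 1): is c1
    significant and is that feature's |coefficient| the largest?"""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(2 * n_per_group, p))
    g = np.repeat([0, 1], n_per_group)
    X[g == 1, 2] += 5.0
    res = mv.manova_canonical(X, g, [f"f{i}" for i in range(p)])
    return {
        "c1_p": float(res.p_values[0]),
        "top_feature_correct": res.coefficients["c1"].abs().idxmax() == "f2",
    }


def manova_permutation_fp(n_perm: int = 100, seed: int = 0,
                          n_per_group: int = 20, p: int = 5) -> float:
    """Fraction of label permutations with any significant canonical dim."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(2 * n_per_group, p))
    base = np.repeat([0, 1], n_per_group)
    fp = 0
    for _ in range(n_perm):
        res = mv.manova_canonical(X, rng.permutation(base))
        fp += (res.p_values < 0.05).any()
    return fp / n_perm


def neuronal_only_cohort(seed: int = 0, n_cases: int = 6, scale: float = 0.3):
    """Cohort whose areas differ only in neuronal co-expression mixtures.

    Glial mixtures, all densities and pathology offsets are shared, so any
    area signal in glial features would be an artifact.
    """
    rng = np.random.default_rng(seed)
    fields = []
    for area in ("A46", "A17"):
        mix = dict(_MIX[area])
        for k in ("astro", "astro_olig2", "oligo"):
            mix[k] = _MIX["A46"][k]
        for i in range(n_cases):
            pop = syn.population_preset(
                "A46", count_mode="poisson", mix=mix, pathology_offsets={}
            ).scaled(scale, 0.0)
            spec = syn.FieldSpec(
                case_id=f"case{i + 1}", area_label=area,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            fields.append(syn.generate_field(spec, pop))
    return fields


def scheme_contrast(seed: int = 0) -> dict[str, float]:
    """Area-separation p-values of the neuronal vs glial MANOVA schemes on
    a cohort with structure planted only in neuronal features."""
    fields = neuronal_only_cohort(seed)
    cells = pl.annotate_cohort(fields)
    retained, _ = filter_for_analysis(cells)
    retained = retained[retained["layer"] != "excluded"]
    manifests = mv.default_manifests()
    out = {}
    for name, classes in (
        ("neuronal_8", ("Neuron",)),
        ("glial", ("Astrocyte", "Oligodendrocyte", "Microglia")),
    ):
        manifest = manifests[name]
        table = mv.build_feature_table(retained, manifest, class_filter=classes)
        res = mv.manova_canonical(table[manifest.columns], table["area"])
        out[name] = float(res.p_values[0])
    return {"neuronal_p": out["neuronal_8"], "glial_p": out["glial"]}


# ---------------------------------------------------------------------------
# morphometry identities


def morphometry_identities() -> dict[str, float]:
    """Circularity of a rasterized circle at 0.5 µm/px, the square-outline
    closed form, and the shoelace area of the unit square."""
    px, r = 0.5, 20.0
    n = int(2 * r / px) + 20
    yy, xx = np.mgrid[0:n, 0:n]
    c = n / 2
    mask = ((yy + 0.5 - c) ** 2 + (xx + 0.5 - c) ** 2) <= (r / px) ** 2
    circ = float(vessel_metrics(mask, px)["circularity"].iloc[0])
    square = polygon_metrics([(0, 0), (30, 0), (30, 30), (0, 30)])
    from .geometry import polygon_area

    return {
        "circle_circularity": circ,
        "square_circularity": float(square["circularity"]),
        "unit_square_area": polygon_area([(0, 0), (1, 0), (1, 1), (0, 1)]),
    }
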