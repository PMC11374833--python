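"""Synthetic cortical fields with known ground truth.

Generates the inputs the analysis pipeline consumes — per-cell intensity
tables in the QuPath-export dialect, layer-boundary records, and optional
multichannel images — for a 400-µm-wide region of interest running from
the pia through 100 µm of white matter at 5-µm section thickness.

Two area presets are provided.  The prefrontal-like preset ("A46") has a
thin homogeneous L4; the primary-visual-like preset ("A17") has an
expanded L4 (subdivided 4A/4B/4Cα/4Cβ) and roughly twice the neuron
density of the prefrontal preset in L2/3–L6.  Per-cell marker intensities
are drawn log-normally conditional on the cell's class and subtype, with
positive populations separated from negative ones by a configurable
number of log-scale standard deviations.  Subtype co-expression mixtures
(pan-neuronal HuD/NeuN, GABAergic GAD65/GAD67 with PV/CB, astrocytic
GFAP/ALDH1L1, oligodendroglial Olig2/CNPase/BCAS1) follow the published
proportions for the two areas.

Cells are placed uniformly at random within their layer's rectangle —
the downstream statistics use only counts and depths, so no spatial
interaction is modelled.  Marker bleed-through and autofluorescence are
not simulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import (
    LAYERS,
    WM,
    LayerModel,
    SublayerPartition,
    assign_layers,
    layer_area,
)
from .panel import MarkerPanel

CLASSES = ("Neuron", "Astrocyte", "Microglia", "Oligodendrocyte", "Endothelial")
ALL_LAYER_BINS = LAYERS + (WM,)

_DEFAULT_THICKNESS = {
    "A46": {"L1": 150.0, "L2/3": 700.0, "L4": 200.0, "L5": 300.0, "L6": 350.0},
    "A17": {"L1": 120.0, "L2/3": 500.0, "L4": 400.0, "L5": 250.0, "L6": 330.0},
}

# planar densities, cells/mm²; qualitative laminar template (absolute values
# are round numbers of the right magnitude for primate neocortex)
_BASE_DENSITY = {
    "Neuron": {"L1": 100, "L2/3": 1600, "L4": 1600, "L5": 1600, "L6": 1600, "WM": 50},
    "Astrocyte": {"L1": 600, "L2/3": 400, "L4": 400, "L5": 400, "L6": 400, "WM": 450},
    "Microglia": {"L1": 120, "L2/3": 60, "L4": 70, "L5": 60, "L6": 80, "WM": 130},
    "Oligodendrocyte": {"L1": 150, "L2/3": 300, "L4": 400, "L5": 500, "L6": 600, "WM": 1200},
    "Endothelial": {"L1": 400, "L2/3": 350, "L4": 350, "L5": 350, "L6": 350, "WM": 250},
}

# co-expression mixtures per area (printed overall proportions)
_MIX = {
    "A46": {
        "pan_neuron": {"HuD+/NeuN+": 0.96, "HuD+ only": 0.01, "NeuN+ only": 0.03},
        "gaba": {"GAD67+ only": 0.08, "GAD65+ only": 0.07, "GAD65+/GAD67+": 0.05},
        "kv31_in_gad67": 0.43,
        "astro": {"GFAP+/ALDH1L1+": 0.76, "ALDH1L1+ only": 0.23, "GFAP+ only": 0.01},
        "astro_olig2": 0.04,
        "oligo": {
            "Olig2+ only": 0.78,
            "Olig2+/CNPase+": 0.19,
            "Olig2+/BCAS1+": 0.02,
            "Olig2+/CNPase+/BCAS1+": 0.01,
        },
    },
    "A17": {
        "pan_neuron": {"HuD+/NeuN+": 0.91, "HuD+ only": 0.04, "NeuN+ only": 0.05},
        "gaba": {"GAD67+ only": 0.05, "GAD65+ only": 0.03, "GAD65+/GAD67+": 0.04},
        "kv31_in_gad67": 0.56,
        "astro": {"GFAP+/ALDH1L1+": 0.78, "ALDH1L1+ only": 0.18, "GFAP+ only": 0.04},
        "astro_olig2": 0.34,
        "oligo": {
            "Olig2+ only": 0.69,
            "Olig2+/CNPase+": 0.25,
            "Olig2+/BCAS1+": 0.04,
            "Olig2+/CNPase+/BCAS1+": 0.02,
        },
    },
}

# PV/CB categorical mix among GAD67-containing interneurons
_PVCB = {"PV+ only": 0.20, "CB+ only": 0.12, "PV+/CB+": 0.03, "none": 0.65}

# small class-conditional log-mean offsets (in s.d. units) for pathology
# markers, giving the multivariate stage realistic area/class structure
_PATHOLOGY_OFFSET = {
    ("Neuron", "A46"): 0.5,
    ("Neuron", "A17"): 0.0,
}
_PATHOLOGY_MARKERS = ("Abeta", "pTau", "CC3", "S6", "TSPO", "3NT", "TDP43")


class PlacementError(RuntimeError):
    """Non-overlapping nucleus placement failed after bounded retries."""


@dataclass
class FieldSpec:
    """Geometry and identity of one synthetic field."""

    case_id: str = "case1"
    area_label: str = "A46"
    roi_width: float = 400.0
    layer_thicknesses: dict[str, float] | None = None
    wm_sample_depth: float = 100.0
    pixel_size: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.area_label not in ("A46", "A17"):
            raise ValueError("area_label must be 'A46' or 'A17'")
        if self.roi_width <= 0 or self.pixel_size <= 0 or self.wm_sample_depth <= 0:
            raise ValueError("roi_width, pixel_size and wm_sample_depth must be > 0")
        if self.layer_thicknesses is None:
            self.layer_thicknesses = dict(_DEFAULT_THICKNESS[self.area_label])
        if any(t <= 0 for t in self.layer_thicknesses.values()):
            raise ValueError("layer thicknesses must be positive")

    def layer_model(self) -> LayerModel:
        edges = np.cumsum([self.layer_thicknesses[l] for l in LAYERS])
        return LayerModel(
            boundaries=tuple(edges),
            wm_sample_depth=self.wm_sample_depth,
            roi_width=self.roi_width,
            area_label=self.area_label,
            sublayers=SublayerPartition(),
        )


@dataclass
class PopulationSpec:
    """Cell densities and the class-conditional intensity model.

    ``separation_sd`` is the log-scale gap between positive and negative
    marker populations in units of ``log_sigma``; the default of 6 puts
    each class mean 3 s.d. from a midpoint gate.
    """

    densities: dict[str, dict[str, float]] = field(
        default_factory=lambda: {c: dict(v) for c, v in _BASE_DENSITY.items()}
    )
    log_mu_neg: float = math.log(50.0)
    log_sigma: float = 0.4
    separation_sd: float = 6.0
    count_mode: str = "fixed"  # "fixed" | "poisson"
    confusable_fraction: float = 0.04
    nucleus_radius_um: float = 4.0
    vessels_per_mm2: float = 60.0
    density_scale: float = 1.0
    intensity_shift: float = 0.0  # additive log-scale per-case effect
    mix: dict | None = None  # override of the area's co-expression mixtures
    pathology_offsets: dict | None = None  # override of class log-mean offsets

    def __post_init__(self) -> None:
        if self.count_mode not in ("fixed", "poisson"):
            raise ValueError("count_mode must be 'fixed' or 'poisson'")
        if self.log_sigma <= 0:
            raise ValueError("log_sigma must be positive")
        if any(
            d < 0 for per_layer in self.densities.values() for d in per_layer.values()
        ):
            raise ValueError("densities must be non-negative")

    @property
    def log_mu_pos(self) -> float:
        return self.log_mu_neg + self.separation_sd * self.log_sigma

    def scaled(self, density_factor: float, intensity_shift: float) -> "PopulationSpec":
        dens = {
            c: {l: d * density_factor for l, d in per.items()}
            for c, per in self.densities.items()
        }
        return replace(
            self,
            densities=dens,
            density_scale=self.density_scale * density_factor,
            intensity_shift=self.intensity_shift + intensity_shift,
        )


def population_preset(area_label: str, **overrides) -> PopulationSpec:
    """Density preset for an area.  A17 neurons are 2× A46 in L2/3–L6."""
    pop = PopulationSpec(**overrides)
    if area_label == "A17":
        for layer in ("L2/3", "L4", "L5", "L6"):
            pop.densities["Neuron"][layer] *= 2.0
    return pop


@dataclass
class FieldData:
    """One generated field: cell table, laminar model, truth, optional image."""

    spec: FieldSpec
    cells: pd.DataFrame
    layer_model: LayerModel
    ground_truth: pd.DataFrame
    vessels: pd.DataFrame | None = None
    image: dict[str, np.ndarray] | None = None


def _categorical(rng, n, mix: dict[str, float]) -> np.ndarray:
    labels = list(mix)
    probs = np.array([mix[k] for k in labels], dtype=float)
    rest = 1.0 - probs.sum()
    if rest > 1e-12:
        labels.append("none")
        probs = np.append(probs, rest)
    probs = probs / probs.sum()
    return rng.choice(labels, size=n, p=probs)


def _subtype_flags(
    cls: str, area: str, n: int, rng, mix: dict | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-cell marker positivity flags and a subtype label for one class."""
    mix = mix if mix is not None else _MIX[area]
    flags = {m: np.zeros(n, dtype=bool) for m in MarkerPanel.default().names}
    subtype = np.full(n, "", dtype=object)
    if cls == "Neuron":
        pan = _categorical(rng, n, mix["pan_neuron"])
        flags["HuD"] = pan != "NeuN+ only"
        flags["NeuN"] = pan != "HuD+ only"
        gaba = _categorical(rng, n, mix["gaba"])
        flags["GAD67"] = np.isin(gaba, ["GAD67+ only", "GAD65+/GAD67+"])
        flags["GAD65"] = np.isin(gaba, ["GAD65+ only", "GAD65+/GAD67+"])
        pvcb = _categorical(rng, n, _PVCB)
        has67 = flags["GAD67"]
        flags["PV"] = has67 & np.isin(pvcb, ["PV+ only", "PV+/CB+"])
        flags["CB"] = has67 & np.isin(pvcb, ["CB+ only", "PV+/CB+"])
        flags["Kv3.1"] = has67 & (rng.random(n) < mix["kv31_in_gad67"])
        flags["MAP2"] = rng.random(n) < 0.90
        subtype = pan
    elif cls == "Astrocyte":
        sub = _categorical(rng, n, mix["astro"])
        flags["GFAP"] = sub != "ALDH1L1+ only"
        flags["ALDH1L1"] = sub != "GFAP+ only"
        flags["Olig2"] = rng.random(n) < mix["astro_olig2"]
        subtype = sub
    elif cls == "Microglia":
        flags["Iba1"][:] = True
        subtype[:] = "Iba1+"
    elif cls == "Oligodendrocyte":
        sub = _categorical(rng, n, mix["oligo"])
        flags["Olig2"][:] = True
        flags["CNPase"] = np.isin(sub, ["Olig2+/CNPase+", "Olig2+/CNPase+/BCAS1+"])
        flags["BCAS1"] = np.isin(sub, ["Olig2+/BCAS1+", "Olig2+/CNPase+/BCAS1+"])
        subtype = sub
    elif cls == "Endothelial":
        flags["CollagenIV"][:] = True
        flags["Vimentin"][:] = True
        subtype[:] = "CollagenIV+/Vimentin+"
    elif cls == "Multiple":
        # genuine conflict: neuronal and microglial defining markers together
        flags["HuD"][:] = True
        flags["NeuN"][:] = True
        flags["Iba1"][:] = True
        subtype[:] = "conflict"
    # "Other": everything stays negative
    return pd.DataFrame({f"pos_{m}": v for m, v in flags.items()}), subtype


def _draw_intensities(
    positivity: pd.DataFrame,
    pop: PopulationSpec,
    panel: MarkerPanel,
    rng,
    area: str,
    classes: np.ndarray,
) -> pd.DataFrame:
    """Log-normal raw intensities per marker × compartment.

    The marker's measured compartment carries the class-conditional signal;
    the complementary compartment carries background; ``Cell`` is a
    0.4/0.6 nucleus/cytoplasm mixture.
    """
    n = len(positivity)
    out = {}
    for m in panel:
        pos = positivity[f"pos_{m.name}"].to_numpy()
        mu_sig = np.where(pos, pop.log_mu_pos, pop.log_mu_neg).astype(float)
        if m.name in _PATHOLOGY_MARKERS:
            offsets = (
                pop.pathology_offsets
                if pop.pathology_offsets is not None
                else _PATHOLOGY_OFFSET
            )
            off = np.zeros(n)
            for cls in np.unique(classes):
                key = (cls, area)
                if key in offsets:
                    off[classes == cls] = offsets[key] * pop.log_sigma
            mu_sig = mu_sig + off
        mu_sig = mu_sig + pop.intensity_shift
        mu_bg = pop.log_mu_neg + pop.intensity_shift
        sig = pop.log_sigma
        if m.compartment == "Nucleus":
            nuc = np.exp(rng.normal(mu_sig, sig))
            cyt = np.exp(rng.normal(mu_bg, sig, n))
        elif m.compartment == "Cytoplasm":
            nuc = np.exp(rng.normal(mu_bg, sig, n))
            cyt = np.exp(rng.normal(mu_sig, sig))
        else:  # Cell: signal in both compartments
            nuc = np.exp(rng.normal(mu_sig, sig))
            cyt = np.exp(rng.normal(mu_sig, sig))
        out[f"{m.name}_Nucleus_mean"] = nuc
        out[f"{m.name}_Cytoplasm_mean"] = cyt
        out[f"{m.name}_Cell_mean"] = 0.4 * nuc + 0.6 * cyt
    return pd.DataFrame(out)


def _place_nonoverlapping(
    n: int,
    x_range,
    depth_range,
    min_sep: float,
    rng,
    max_retries: int = 200,
    grid: dict | None = None,
):
    """Uniform placement with a minimum pairwise separation (grid-hashed).

    ``grid`` carries accepted positions across calls so separate
    class/layer blocks of the same field cannot overlap each other.
    """
    cell = max(min_sep, 1e-6)
    if grid is None:
        grid = {}
    xs, ys = np.empty(n), np.empty(n)
    for i in range(n):
        for _ in range(max_retries):
            x = rng.uniform(*x_range)
            y = rng.uniform(*depth_range)
            gx, gy = int(x // cell), int(y // cell)
            ok = True
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for (px, py) in grid.get((gx + dx, gy + dy), ()):
                        if (px - x) ** 2 + (py - y) ** 2 < min_sep**2:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if ok:
                grid.setdefault((gx, gy), []).append((x, y))
                xs[i], ys[i] = x, y
                break
        else:
            raise PlacementError(
                f"could not place nucleus {i + 1}/{n} with separation "
                f"{min_sep:.1f} µm after {max_retries} retries; density too "
                f"high for non-overlapping rendering in depth band "
                f"{depth_range[0]:.0f}–{depth_range[1]:.0f} µm"
            )
    return xs, ys


def generate_field(
    spec: FieldSpec,
    pop: PopulationSpec | None = None,
    render_channels: list[str] | None = None,
    panel: MarkerPanel | None = None,
) -> FieldData:
    """Generate one synthetic field.

    Parameters
    ----------
    spec, pop
        Geometry/identity and population model; ``pop`` defaults to the
        area preset for ``spec.area_label``.
    render_channels
        If given, a multichannel image is rendered for these channel names
        ("DAPI" plus marker names).  Rendering switches cell placement to
        non-overlapping discs (retry-with-jitter), so the cell table is
        consistent with the image.

    Identical ``(spec, pop)`` (including ``spec.seed``) yields byte-identical
    cell tables.
    """
    panel = panel or MarkerPanel.default()
    pop = pop or population_preset(spec.area_label)
    rng = np.random.default_rng(spec.seed)
    model = spec.layer_model()
    # rendered nuclei must stay ≥2 px apart after rasterization or adjacent
    # discs merge into one connected component
    min_sep = (
        2 * pop.nucleus_radius_um + 1.0 + 2 * spec.pixel_size
        if render_channels
        else None
    )
    placement_grid: dict = {}

    blocks, gt_blocks = [], []
    for layer in ALL_LAYER_BINS:
        top, bottom = model.layer_interval(layer)
        area_mm2 = layer_area(model, layer)
        for cls in CLASSES:
            dens = pop.densities.get(cls, {}).get(layer, 0.0)
            mean_n = dens * area_mm2
            n = int(rng.poisson(mean_n)) if pop.count_mode == "poisson" else round(mean_n)
            if n == 0:
                continue
            if min_sep is None:
                xs = rng.uniform(0, spec.roi_width, n)
                ys = rng.uniform(top, bottom, n)
            else:
                xs, ys = _place_nonoverlapping(
                    n, (0, spec.roi_width), (top, bottom), min_sep, rng,
                    grid=placement_grid,
                )
            flags, subtype = _subtype_flags(cls, spec.area_label, n, rng, pop.mix)
            blocks.append(
                pd.DataFrame(
                    {"centroid_x_um": xs, "centroid_y_um": ys, "_class": cls}
                )
            )
            gt_blocks.append(
                pd.concat(
                    [
                        pd.DataFrame(
                            {
                                "true_class": cls,
                                "true_subtype": subtype,
                                "true_layer": layer,
                            }
                        ),
                        flags,
                    ],
                    axis=1,
                )
            )

    # planted confusables (Other/Multiple), uniform over the sampled depth
    n_real = sum(len(b) for b in blocks)
    n_conf = round(pop.confusable_fraction * n_real)
    if n_conf:
        half = n_conf // 2
        for cls, n in (("Other", n_conf - half), ("Multiple", half)):
            if n == 0:
                continue
            if min_sep is None:
                xs = rng.uniform(0, spec.roi_width, n)
                ys = rng.uniform(0, model.max_depth, n)
            else:
                xs, ys = _place_nonoverlapping(
                    n, (0, spec.roi_width), (0, model.max_depth), min_sep, rng,
                    grid=placement_grid,
                )
            flags, subtype = _subtype_flags(cls, spec.area_label, n, rng, pop.mix)
            layers = assign_layers(ys, model)
            blocks.append(
                pd.DataFrame(
                    {"centroid_x_um": xs, "centroid_y_um": ys, "_class": cls}
                )
            )
            gt_blocks.append(
                pd.concat(
                    [
                        pd.DataFrame(
                            {
                                "true_class": cls,
                                "true_subtype": subtype,
                                "true_layer": layers,
                            }
                        ),
                        flags,
                    ],
                    axis=1,
                )
            )

    if blocks:
        cells = pd.concat(blocks, ignore_index=True)
        truth = pd.concat(gt_blocks, ignore_index=True)
    else:
        cells = pd.DataFrame(columns=["centroid_x_um", "centroid_y_um", "_class"])
        truth = pd.DataFrame(columns=["true_class", "true_subtype", "true_layer"])

    classes = cells.pop("_class").to_numpy() if len(cells) else np.array([])
    intensities = _draw_intensities(
        truth if len(truth) else pd.DataFrame(
            {f"pos_{m}": pd.Series(dtype=bool) for m in panel.names}
        ),
        pop,
        panel,
        rng,
        spec.area_label,
        classes,
    )
    cells = pd.concat([cells, intensities], axis=1)
    cells.insert(0, "object_id", np.arange(len(cells)))
    truth.insert(0, "object_id", np.arange(len(truth)))

    vessels = _generate_vessels(spec, pop, model, rng)
    image = None
    if render_channels:
        image = _render(spec, pop, model, cells, truth, vessels, render_channels, panel, rng)
    return FieldData(spec, cells, model, truth, vessels, image)


def _generate_vessels(spec, pop, model, rng) -> pd.DataFrame:
    """Elliptical vessel profiles with a per-layer budget."""
    rows = []
    for layer in ALL_LAYER_BINS:
        top, bottom = model.layer_interval(layer)
        n = round(pop.vessels_per_mm2 * layer_area(model, layer))
        for _ in range(n):
            a = rng.uniform(4.0, 22.0)  # semi-axes, µm
            b = a * rng.uniform(0.6, 1.0)
            margin = a + 2
            rows.append(
                {
                    "center_x_um": rng.uniform(margin, spec.roi_width - margin),
                    "center_y_um": rng.uniform(
                        min(top + margin, bottom), max(bottom - margin, top)
                    ),
                    "semi_major_um": a,
                    "semi_minor_um": b,
                    "angle_rad": rng.uniform(0, math.pi),
                    "layer": layer,
                    "sma_positive": bool(rng.random() < 0.3),
                }
            )
    df = pd.DataFrame(rows)
    if len(df):
        a, b = df["semi_major_um"], df["semi_minor_um"]
        df["area_um2"] = math.pi * a * b
        # Ramanujan perimeter approximation
        h = ((a - b) / (a + b)) ** 2
        df["perimeter_um"] = math.pi * (a + b) * (1 + 3 * h / (10 + np.sqrt(4 - 3 * h)))
    return df


def _paint_disc(img, cx, cy, r, value, px):
    h, w = img.shape
    ci, cj = cy / px, cx / px
    rp = r / px
    i0, i1 = max(0, int(ci - rp) - 1), min(h, int(ci + rp) + 2)
    j0, j1 = max(0, int(cj - rp) - 1), min(w, int(cj + rp) + 2)
    if i0 >= i1 or j0 >= j1:
        return
    ii, jj = np.mgrid[i0:i1, j0:j1]
    mask = (ii + 0.5 - ci) ** 2 + (jj + 0.5 - cj) ** 2 <= rp**2
    img[i0:i1, j0:j1][mask] = value


def _fiber_profile(marker: str, depth_norm: np.ndarray, model: LayerModel) -> np.ndarray:
    """Mean raw intensity of a fibrillar channel versus normalized depth."""
    d = np.clip(depth_norm, 0, 120)
    base = 20.0 + 1.6 * d  # myelin/axonal markers rise toward WM
    if marker == "MAP2":
        l4_top, l4_bot = model.layer_interval("L4")
        c = 100.0 * 0.5 * (l4_top + l4_bot) / model.wm_line
        w = 100.0 * (l4_bot - l4_top) / (2 * model.wm_line)
        return 120.0 - 50.0 * np.exp(-((d - c) ** 2) / (2 * w**2))
    if marker == "npNF":
        return 40.0 + 0.6 * d
    if marker in ("MBP", "CNPase", "BCAS1") and model.area_label == "A17":
        l4_top, l4_bot = model.layer_interval("L4")
        c = 100.0 * 0.5 * (l4_top + l4_bot) / model.wm_line
        w = 100.0 * (l4_bot - l4_top) / (2 * model.wm_line)
        base = base + 90.0 * np.exp(-((d - c) ** 2) / (2 * w**2))
    return base


def _render(spec, pop, model, cells, truth, vessels, channels, panel, rng):
    px = spec.pixel_size
    h = int(math.ceil(model.max_depth / px))
    w = int(math.ceil(spec.roi_width / px))
    image = {}
    r_nuc = pop.nucleus_radius_um
    r_cell = r_nuc + 2.0
    fibrillar = set(panel.fibrillar) | {"BCAS1", "CNPase"}
    for name in channels:
        img = np.full((h, w), 5.0, dtype=np.float32)
        img += rng.normal(0, 1.0, (h, w)).astype(np.float32)
        if name in fibrillar and name != "DAPI":
            depth_norm = 100.0 * (np.arange(h) + 0.5) * px / model.wm_line
            prof = _fiber_profile(name, depth_norm, model)
            img += (prof[:, None] * np.exp(
                rng.normal(0, 0.15, (h, w))
            )).astype(np.float32)
        if name == "DAPI":
            for _, c in cells.iterrows():
                _paint_disc(img, c.centroid_x_um, c.centroid_y_um, r_nuc, 200.0, px)
        elif name in ("CollagenIV", "Vimentin", "SMA"):
            pass  # vascular channels carry vessel outlines only (below)
        elif name in panel.names:
            m = panel.get(name)
            for (_, c), (_, t) in zip(cells.iterrows(), truth.iterrows()):
                if not t[f"pos_{name}"]:
                    continue
                if m.compartment == "Nucleus":
                    _paint_disc(img, c.centroid_x_um, c.centroid_y_um, r_nuc,
                                c[f"{name}_Nucleus_mean"], px)
                else:
                    _paint_disc(img, c.centroid_x_um, c.centroid_y_um, r_cell,
                                c[f"{name}_{m.compartment}_mean"], px)
                    if m.compartment == "Cytoplasm":
                        _paint_disc(img, c.centroid_x_um, c.centroid_y_um, r_nuc, 5.0, px)
        if name in ("CollagenIV", "Vimentin", "SMA") and vessels is not None:
            for _, v in vessels.iterrows():
                if name == "SMA" and not v.sma_positive:
                    continue
                _paint_ellipse_ring(img, v, px, value=180.0, thickness=2.0)
        image[name] = img
    return image


def _paint_ellipse_ring(img, v, px, value, thickness):
    h, w = img.shape
    a, b = v.semi_major_um, v.semi_minor_um
    ci, cj = v.center_y_um / px, v.center_x_um / px
    ext = (a + thickness) / px
    i0, i1 = max(0, int(ci - ext) - 1), min(h, int(ci + ext) + 2)
    j0, j1 = max(0, int(cj - ext) - 1), min(w, int(cj + ext) + 2)
    if i0 >= i1 or j0 >= j1:
        return
    ii, jj = np.mgrid[i0:i1, j0:j1]
    y = (ii + 0.5 - ci) * px
    x = (jj + 0.5 - cj) * px
    ca, sa = math.cos(v.angle_rad), math.sin(v.angle_rad)
    u = x * ca + y * sa
    t = -x * sa + y * ca
    rin = (u / max(a - thickness, 1.0)) ** 2 + (t / max(b - thickness, 1.0)) ** 2
    rout = (u / a) ** 2 + (t / b) ** 2
    ring = (rout <= 1.0) & (rin >= 1.0)
    img[i0:i1, j0:j1][ring] = value


def generate_cohort(
    n_cases: int = 7,
    presets: tuple[str, ...] = ("A46", "A17"),
    seed: int = 0,
    case_effect_sd: float = 0.10,
    count_mode: str = "fixed",
    density_overrides: dict[str, PopulationSpec] | None = None,
    membership: dict[str, list[int]] | None = None,
    **field_kwargs,
) -> tuple[list[FieldData], dict]:
    """Generate a multi-case cohort of fields with per-case random effects.

    Each case receives one multiplicative log-normal scaling of densities
    and one additive log-scale intensity shift, shared by all its fields —
    this is the "subject" random blocking factor downstream statistics
    account for.  With seven cases the default membership mirrors a
    6-field prefrontal / 5-field visual design; otherwise every case
    contributes every preset.

    Returns the fields and a YAML-able manifest.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    rng = np.random.default_rng(seed)
    if membership is None:
        if n_cases == 7 and set(presets) == {"A46", "A17"}:
            membership = {
                "A46": [0, 1, 2, 3, 4, 5],
                "A17": [0, 2, 3, 5, 6],
            }
        else:
            membership = {a: list(range(n_cases)) for a in presets}

    effects = {
        i: (
            float(np.exp(rng.normal(0, case_effect_sd))) if n_cases > 1 else 1.0,
            float(rng.normal(0, case_effect_sd)) if n_cases > 1 else 0.0,
        )
        for i in range(n_cases)
    }
    fields, manifest_fields = [], []
    for area in presets:
        for i in membership.get(area, []):
            dens_f, int_s = effects[i]
            base = (
                density_overrides[area]
                if density_overrides and area in density_overrides
                else population_preset(area, count_mode=count_mode)
            )
            pop = base.scaled(dens_f, int_s)
            spec = FieldSpec(
                case_id=f"case{i + 1}",
                area_label=area,
                seed=int(rng.integers(0, 2**31 - 1)),
                **field_kwargs,
            )
            fields.append(generate_field(spec, pop))
            manifest_fields.append(
                {
                    "case_id": spec.case_id,
                    "area_label": area,
                    "seed": spec.seed,
                    "density_factor": dens_f,
                    "intensity_shift": int_s,
                    "n_cells": int(len(fields[-1].cells)),
                }
            )
    manifest = {
        "n_cases": n_cases,
        "presets": list(presets),
        "seed": seed,
        "case_effect_sd": case_effect_sd,
        "fields": manifest_fields,
    }
    return fields, manifest
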