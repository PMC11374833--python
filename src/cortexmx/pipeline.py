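"""End-to-end orchestration of the analysis stages.

``run`` executes generate/ingest → normalize → gate → phenotype →
laminar assignment → composition (+ statistics) → fiber profiles →
vessel morphometry → multivariate clustering, writing every stage's
tables under an output directory together with a JSON run manifest
(config hash, seeds, versions).  Identical config + seeds yield an
identical bundle.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import composition as comp
from . import fibers as fib
from . import intensity as inten
from . import multivariate as mv
from . import phenotyping as pheno
from . import synthetic as syn
from . import vessels as ves
from .geometry import LAYERS, WM, assign_layers, layer_area
from .io import write_cell_table, write_layer_boundaries, write_manifest
from .panel import MarkerPanel

log = logging.getLogger(__name__)

FIBER_MARKERS = ("BCAS1", "CNPase", "MBP", "MAP2", "pan-pNF", "npNF")
VESSEL_MARKERS = ("CollagenIV", "Vimentin", "SMA")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    mode: str = "synthetic"  # synthetic | cell-table
    out_dir: str = "results/run"
    seed: int = 0
    n_cases: int = 7
    presets: tuple[str, ...] = ("A46", "A17")
    case_effect_sd: float = 0.10
    count_mode: str = "poisson"
    density_scale: float = 1.0  # global density multiplier (demo runs)
    use_sublayers: bool = True
    wm_sample_depth: float = 100.0
    trim_frac: float = 0.002
    trim_frac_microglia: float = 0.01
    feature_manifest: str = "total"
    perplexity: float = 15.0
    pixel_size: float = 2.0
    render_fields: int = 1  # image-based stages run on this many fields/area
    cell_tables: list[str] = field(default_factory=list)
    gate_file: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        cfg = cls(**known)
        cfg.presets = tuple(cfg.presets)
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


class StageError(RuntimeError):
    pass


def save_fields(fields: list[syn.FieldData], out_dir) -> None:
    """Write each field's cell table, layer boundaries and ground truth."""
    from .io import write_layer_boundaries as _wlb

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for fd in fields:
        stem = f"{fd.spec.case_id}_{fd.spec.area_label}"
        write_cell_table(fd.cells, out / f"{stem}_cells.csv")
        _wlb(fd.layer_model, out / f"{stem}_layers.csv")
        fd.ground_truth.to_csv(out / f"{stem}_truth.csv", index=False)


def load_fields(sim_dir) -> list[syn.FieldData]:
    """Rebuild fields from the per-field CSVs written by :func:`save_fields`."""
    from .io import read_cell_table, read_layer_boundaries

    sim = Path(sim_dir)
    fields = []
    for cells_path in sorted(sim.glob("*_cells.csv")):
        stem = cells_path.name[: -len("_cells.csv")]
        case_id, area = stem.rsplit("_", 1)
        cells = read_cell_table(cells_path)
        model = read_layer_boundaries(sim / f"{stem}_layers.csv")
        model.area_label = area
        truth = pd.read_csv(sim / f"{stem}_truth.csv")
        spec = syn.FieldSpec(case_id=case_id, area_label=area)
        fields.append(syn.FieldData(spec, cells, model, truth))
    return fields


def _annotate_field(fd: syn.FieldData, panel: MarkerPanel, use_sublayers: bool):
    """Normalize, gate, phenotype and laminar-assign one field's cells."""
    cells = inten.normalize_cell_table(fd.cells, panel)
    gates = inten.gates_from_reference(cells, fd.ground_truth, panel)
    cells = inten.apply_gates(cells, gates, panel)
    cells["cell_class"] = pheno.classify_cells(cells)
    cells["layer"] = assign_layers(
        cells["centroid_y_um"].to_numpy(), fd.layer_model, use_sublayers=False
    )
    if use_sublayers and fd.spec.area_label == "A17":
        cells["sublayer"] = assign_layers(
            cells["centroid_y_um"].to_numpy(), fd.layer_model, use_sublayers=True
        )
    cells["case"] = fd.spec.case_id
    cells["area"] = fd.spec.area_label
    cells["layer_area_mm2"] = [
        layer_area(fd.layer_model, l) if l != "excluded" else np.nan
        for l in cells["layer"]
    ]
    return cells, gates


def annotate_cohort(fields, panel=None, use_sublayers=True) -> pd.DataFrame:
    panel = panel or MarkerPanel.default()
    parts = []
    for fd in fields:
        cells, _ = _annotate_field(fd, panel, use_sublayers)
        parts.append(cells)
    return pd.concat(parts, ignore_index=True)


def composition_stage(cells: pd.DataFrame, models: dict[str, object]) -> dict:
    """Counts, densities, distributions and headline ratios per area."""
    retained, retained_fraction = pheno.filter_for_analysis(cells)
    retained = retained[retained["layer"] != "excluded"]
    counts = comp.count_cells(retained)
    dens_parts = []
    for area, model in models.items():
        sub = counts[counts["area"] == area]
        dens_parts.append(comp.density_by_layer(sub, model))
    densities = pd.concat(dens_parts, ignore_index=True)

    ratios = {}
    for area in sorted(retained["area"].unique()):
        sub = retained[(retained["area"] == area) & (retained["layer"] != WM)]
        class_counts = sub["cell_class"].value_counts().to_dict()
        neurons = sub[sub["cell_class"] == "Neuron"]
        n_l23_l6 = neurons[neurons["layer"] != "L1"]
        inhib = int(
            (n_l23_l6["pos_GAD67"] | n_l23_l6["pos_GAD65"]).sum()
        ) if "pos_GAD67" in sub else None
        ratios[area] = comp.composition_ratios(
            class_counts,
            inhibitory_neurons=inhib,
            neurons_l23_l6=len(n_l23_l6) if inhib is not None else None,
        )
    laminar = comp.laminar_distribution(counts)
    return {
        "counts": counts,
        "densities": densities,
        "laminar": laminar,
        "ratios": ratios,
        "retained_fraction": retained_fraction,
    }


def fiber_stage(fd: syn.FieldData, pixel_size: float) -> pd.DataFrame:
    profiles = []
    for m in FIBER_MARKERS:
        profiles.append(
            fib.tile_profile(
                fd.image[m], fd.layer_model, pixel_size,
                marker=m, field_id=f"{fd.spec.case_id}:{fd.spec.area_label}",
            )
        )
    return pd.concat(profiles, ignore_index=True)


def vessel_stage(fd: syn.FieldData, pixel_size: float) -> dict:
    masks = {m: ves.classify_pixels(fd.image[m], threshold=100.0)
             for m in VESSEL_MARKERS}
    table = ves.vessel_metrics(masks["CollagenIV"], pixel_size, masks)
    table = ves.assign_vessel_layers(table, fd.layer_model)
    table["field"] = f"{fd.spec.case_id}:{fd.spec.area_label}"
    occ = ves.layer_occupancy(masks["CollagenIV"], fd.layer_model, pixel_size, masks)
    occ["field"] = f"{fd.spec.case_id}:{fd.spec.area_label}"
    return {"vessels": table, "occupancy": occ}


def multivariate_stage(
    cells: pd.DataFrame, manifest_name: str, perplexity: float, seed: int
) -> dict:
    retained, _ = pheno.filter_for_analysis(cells)
    retained = retained[retained["layer"] != "excluded"]
    manifest = mv.default_manifests()[manifest_name]
    table = mv.build_feature_table(retained, manifest)
    X = table[manifest.columns].to_numpy()
    scores, ratio, k = mv.pca_variance_cut(X)
    coords = mv.embed(X, perplexity=perplexity, seed=seed)
    group = table["area"].astype(str) + " " + table["layer"].astype(str)
    counts = group.value_counts()
    ok = group.isin(counts[counts >= 2].index)
    result = mv.manova_canonical(
        table.loc[ok, manifest.columns], group[ok], manifest.columns
    )
    return {
        "features": table,
        "pca_k": k,
        "explained": ratio,
        "tsne": coords,
        "manova": result,
    }


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the result bundle in memory."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel = MarkerPanel.default()
    bundle: dict = {}
    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "stages": [],
    }

    try:
        if config.mode != "synthetic":
            raise StageError(
                "only synthetic mode is wired through run(); use the library "
                "API to analyze externally produced cell tables"
            )
        overrides = None
        if config.density_scale != 1.0:
            overrides = {
                a: syn.population_preset(a, count_mode=config.count_mode).scaled(
                    config.density_scale, 0.0
                )
                for a in config.presets
            }
        fields, cohort_manifest = syn.generate_cohort(
            n_cases=config.n_cases,
            presets=config.presets,
            seed=config.seed,
            case_effect_sd=config.case_effect_sd,
            count_mode=config.count_mode,
            density_overrides=overrides,
            wm_sample_depth=config.wm_sample_depth,
            pixel_size=config.pixel_size,
        )
        sim_dir = out / "fields"
        sim_dir.mkdir(exist_ok=True)
        for fd in fields:
            stem = f"{fd.spec.case_id}_{fd.spec.area_label}"
            write_cell_table(fd.cells, sim_dir / f"{stem}_cells.csv")
            write_layer_boundaries(fd.layer_model, sim_dir / f"{stem}_layers.csv")
        write_manifest(cohort_manifest, out / "cohort.yaml")
        manifest["stages"].append("simulate")

        cells = annotate_cohort(fields, panel, config.use_sublayers)
        cells.to_csv(out / "cells_annotated.csv", index=False)
        manifest["stages"].append("annotate")

        models = {a: next(f.layer_model for f in fields
                          if f.spec.area_label == a)
                  for a in config.presets}
        bundle["composition"] = composition_stage(cells, models)
        bundle["composition"]["counts"].to_csv(out / "composition_counts.csv", index=False)
        bundle["composition"]["densities"].to_csv(out / "composition_densities.csv", index=False)
        bundle["composition"]["laminar"].to_csv(out / "laminar_distribution.csv", index=False)
        ratio_rows = [
            {"area": a, **{k: v for k, v in r.display.items()}}
            for a, r in bundle["composition"]["ratios"].items()
        ]
        pd.DataFrame(ratio_rows).to_csv(out / "ratios.csv", index=False)
        manifest["stages"].append("composition")

        # density statistics: neuron density per case × area × layer
        retained, _ = pheno.filter_for_analysis(cells)
        retained = retained[(retained["layer"] != "excluded")]
        neuron = retained[retained["cell_class"] == "Neuron"]
        dens = (
            neuron.groupby(["case", "area", "layer"], observed=True)
            .agg(count=("object_id", "size"), area_mm2=("layer_area_mm2", "first"))
            .reset_index()
        )
        dens["log_density"] = np.log(dens["count"] / dens["area_mm2"])
        try:
            # cases contribute fields in both areas → area is within-subject
            bundle["stats"] = comp.compare_groups(
                dens, "log_density", between=(), within=("area", "layer"),
                subject="case",
            )
            bundle["stats"]["anova"].to_csv(out / "anova_neuron_density.csv", index=False)
            bundle["stats"]["contrasts"].to_csv(out / "contrasts_neuron_density.csv", index=False)
            manifest["stages"].append("statistics")
        except ValueError as e:
            log.warning("skipping group statistics: %s", e)

        # image-based stages on a subset of fields per area
        fiber_parts, vessel_parts, occ_parts = [], [], []
        for area in config.presets:
            area_fields = [f for f in fields if f.spec.area_label == area]
            for fd in area_fields[: config.render_fields]:
                rendered = syn.generate_field(
                    fd.spec,
                    syn.population_preset(
                        area, count_mode="fixed",
                        vessels_per_mm2=60.0,
                    ).scaled(0.12, 0.0),  # sparse cells: rendering needs non-overlap
                    render_channels=list(FIBER_MARKERS + VESSEL_MARKERS),
                )
                fiber_parts.append(fiber_stage(rendered, config.pixel_size))
                v = vessel_stage(rendered, config.pixel_size)
                vessel_parts.append(v["vessels"])
                occ_parts.append(v["occupancy"])
        bundle["fibers"] = pd.concat(fiber_parts, ignore_index=True)
        bundle["fibers"].to_csv(out / "fiber_profiles.csv", index=False)
        fib.laminar_fiber_summary(bundle["fibers"]).to_csv(
            out / "fiber_laminar_summary.csv", index=False
        )
        bundle["vessels"] = pd.concat(vessel_parts, ignore_index=True)
        bundle["vessels"].to_csv(out / "vessel_table.csv", index=False)
        pd.concat(occ_parts, ignore_index=True).to_csv(
            out / "vessel_occupancy.csv", index=False
        )
        manifest["stages"].extend(["fibers", "vessels"])

        bundle["multivariate"] = multivariate_stage(
            cells, config.feature_manifest, config.perplexity, config.seed
        )
        bundle["multivariate"]["features"].to_csv(out / "field_features.csv", index=False)
        np.savetxt(out / "tsne_coords.csv", bundle["multivariate"]["tsne"],
                   delimiter=",", header="tsne1,tsne2", comments="")
        bundle["multivariate"]["manova"].coefficients.to_csv(
            out / "canonical_coefficients.csv"
        )
        (out / "group_dendrogram.nwk").write_text(
            bundle["multivariate"]["manova"].newick + "\n"
        )
        manifest["stages"].append("multivariate")
    finally:
        manifest["elapsed_s"] = round(time.time() - t0, 2)
        write_manifest(manifest, out / "run_manifest.yaml")
    return bundle
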