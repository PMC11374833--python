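"""Cellular composition: counts, densities, within-layer proportions,
laminar distributions, headline ratios (non-neuronal:neuron, GNR, E:I),
and the area × layer split-plot ANOVA of log neuron density with case as
the random block."""

from pathlib import Path

import numpy as np
import pandas as pd

from cortexmx import composition as comp
from cortexmx.phenotyping import filter_for_analysis
from cortexmx.pipeline import composition_stage, load_fields

OUT = Path("results/analysis")


def main() -> None:
    fields = load_fields(OUT / "fields")
    cells = pd.read_csv(OUT / "cells_annotated.csv", low_memory=False)
    models = {
        a: next(f.layer_model for f in fields if f.spec.area_label == a)
        for a in ("A46", "A17")
    }
    stage = composition_stage(cells, models)
    stage["counts"].to_csv(OUT / "composition_counts.csv", index=False)
    stage["densities"].to_csv(OUT / "composition_densities.csv", index=False)
    stage["laminar"].to_csv(OUT / "laminar_distribution.csv", index=False)

    print(f"retained fraction after Other/Multiple exclusion: "
          f"{stage['retained_fraction']:.3f}")
    for area, r in sorted(stage["ratios"].items()):
        d = r.display
        print(f"  {area}: non-neuronal:neuron {d['non_neuronal_to_neuron']}, "
              f"GNR {d['glia_to_neuron']}, "
              f"E:I {d['excitatory_to_inhibitory']}")

    # split-plot ANOVA of log neuron density (case = random block)
    retained, _ = filter_for_analysis(cells)
    retained = retained[retained["layer"] != "excluded"]
    neurons = retained[retained["cell_class"] == "Neuron"]
    dens = (
        neurons.groupby(["case", "area", "layer"], observed=True)
        .agg(count=("object_id", "size"), area_mm2=("layer_area_mm2", "first"))
        .reset_index()
    )
    dens["log_density"] = np.log(dens["count"] / dens["area_mm2"])
    # most cases contribute both areas, so area is a within-subject factor
    res = comp.compare_groups(dens, "log_density",
                              between=(), within=("area", "layer"), subject="case")
    res["anova"].to_csv(OUT / "anova_neuron_density.csv", index=False)
    res["contrasts"].to_csv(OUT / "contrasts_neuron_density.csv", index=False)
    a = res["anova"].set_index("factor")
    print(f"  neuron log-density ANOVA: area F={a.loc['area', 'F']:.1f} "
          f"(p={a.loc['area', 'p']:.2e}), layer F={a.loc['layer', 'F']:.1f} "
          f"(p={a.loc['layer', 'p']:.2e})")


if __name__ == "__main__":
    main()
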