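"""Simulate the study cohort: 7 cases, 6 prefrontal (A46) and 5 primary
visual (A17) fields, with per-case random effects on densities and
intensities.  Writes per-field cell tables, layer boundaries and ground
truth under results/analysis/fields/."""

from pathlib import Path

from cortexmx import synthetic as syn
from cortexmx.io import write_manifest
from cortexmx.pipeline import save_fields

OUT = Path("results/analysis")
SEED = 20240628


def main() -> None:
    fields, manifest = syn.generate_cohort(
        n_cases=7, seed=SEED, count_mode="poisson", case_effect_sd=0.10
    )
    save_fields(fields, OUT / "fields")
    write_manifest(manifest, OUT / "cohort.yaml")
    n_cells = sum(len(f.cells) for f in fields)
    by_area = {
        a: sum(len(f.cells) for f in fields if f.spec.area_label == a)
        for a in ("A46", "A17")
    }
    print(f"simulated {len(fields)} fields from {manifest['n_cases']} cases")
    print(f"  total cells: {n_cells} (A46 {by_area['A46']}, A17 {by_area['A17']})")
    print(f"  wrote {OUT / 'fields'} and {OUT / 'cohort.yaml'}")


if __name__ == "__main__":
    main()
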