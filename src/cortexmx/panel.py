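"""The marker panel: names, measurement compartments, reference cell types.

The default panel mirrors a 28-marker iterative multiplexed-IF experiment:
11 cell-type markers, 4 fibrillar markers (myelin and neurofilaments),
3 vascular markers and 10 intracellular / oxidative-stress / misfolded-
protein markers.  Per-cell gating operates on the 21 non-fiber, non-vessel
markers; fibrillar markers are profiled on a tile grid and vascular markers
pixel-wise within vessel objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

COMPARTMENTS = ("Cell", "Cytoplasm", "Nucleus")

# marker -> (category, compartment of measurement, reference cell class)
_DEFAULT_PANEL = {
    # cellular (11)
    "HuD": ("cellular", "Cell", "Neuron"),
    "NeuN": ("cellular", "Nucleus", "Neuron"),
    "GAD67": ("cellular", "Cytoplasm", "Neuron"),
    "GAD65": ("cellular", "Cytoplasm", "Neuron"),
    "PV": ("cellular", "Cell", "Neuron"),
    "CB": ("cellular", "Cell", "Neuron"),
    "ALDH1L1": ("cellular", "Cell", "Astrocyte"),
    "GFAP": ("cellular", "Cytoplasm", "Astrocyte"),
    "Iba1": ("cellular", "Cell", "Microglia"),
    "Olig2": ("cellular", "Nucleus", "Oligodendrocyte"),
    "CNPase": ("cellular", "Cytoplasm", "Oligodendrocyte"),
    # fibrillar (4) — tile-profiled, excluded from per-cell gating feature set
    "MBP": ("fibrillar", "Cell", None),
    "MAP2": ("fibrillar", "Cytoplasm", "Neuron"),
    "pan-pNF": ("fibrillar", "Cell", None),
    "npNF": ("fibrillar", "Cell", None),
    # vascular (3)
    "CollagenIV": ("vascular", "Cell", "Endothelial"),
    "Vimentin": ("vascular", "Cell", "Endothelial"),
    "SMA": ("vascular", "Cell", "Endothelial"),
    # other intracellular / pathology (10)
    "BCAS1": ("other", "Cytoplasm", "Oligodendrocyte"),
    "Kv3.1": ("other", "Cell", "Neuron"),
    "CR": ("other", "Cell", "Neuron"),
    "Abeta": ("other", "Cell", None),
    "pTau": ("other", "Cell", None),
    "CC3": ("other", "Cell", None),
    "S6": ("other", "Cell", None),
    "TSPO": ("other", "Cell", None),
    "3NT": ("other", "Cell", None),
    "TDP43": ("other", "Cell", None),
}


@dataclass(frozen=True)
class MarkerSpec:
    name: str
    category: str  # cellular | fibrillar | vascular | other
    compartment: str  # compartment on which gating/statistics operate
    reference_class: str | None = None

    def __post_init__(self):
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.compartment!r}")


@dataclass
class MarkerPanel:
    markers: list[MarkerSpec] = field(default_factory=list)

    @classmethod
    def default(cls) -> "MarkerPanel":
        return cls(
            [MarkerSpec(n, *spec) for n, spec in _DEFAULT_PANEL.items()]
        )

    def __iter__(self):
        return iter(self.markers)

    def __len__(self):
        return len(self.markers)

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.markers]

    def get(self, name: str) -> MarkerSpec:
        for m in self.markers:
            if m.name == name:
                return m
        raise KeyError(f"marker {name!r} not in panel")

    def by_category(self, *categories: str) -> list[str]:
        return [m.name for m in self.markers if m.category in categories]

    @property
    def fibrillar(self) -> list[str]:
        return self.by_category("fibrillar")

    @property
    def vascular(self) -> list[str]:
        return self.by_category("vascular")

    @property
    def gating_markers(self) -> list[str]:
        """The 21 non-fiber, non-vessel markers used for per-cell analyses."""
        return self.by_category("cellular", "other")

    def column(self, marker: str, compartment: str | None = None) -> str:
        """Cell-table column name for a marker's raw mean intensity."""
        comp = compartment or self.get(marker).compartment
        return f"{marker}_{comp}_mean"

    def mgi_column(self, marker: str, compartment: str | None = None) -> str:
        comp = compartment or self.get(marker).compartment
        return f"{marker}_{comp}_mgi"

    def to_yaml(self, path) -> None:
        data = [
            {
                "name": m.name,
                "category": m.category,
                "compartment": m.compartment,
                "reference_class": m.reference_class,
            }
            for m in self.markers
        ]
        with open(path, "w") as fh:
            yaml.safe_dump({"markers": data}, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "MarkerPanel":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(
            [
                MarkerSpec(
                    d["name"],
                    d["category"],
                    d["compartment"],
                    d.get("reference_class"),
                )
                for d in data["markers"]
            ]
        )
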