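"""Laminar geometry of a cortical field.

A *field* is a 400-µm-wide region of interest running from the pial surface
down through the cortical depth and 100 µm into the white matter (WM).
Depth is measured in µm from the pia at the nucleus centroid, increasing
downward (pia at the top of the image).  Layer membership uses half-open
``[top, bottom)`` intervals so every depth maps to exactly one label.

Layers are L1, L2/3 (never split), L4, L5, L6 and WM.  In primary-visual-
style fields L4 is subdivided into 4A, 4B, 4Cα and 4Cβ occupying fixed
fractions of the L4 depth (defaults 10%, 20%, 20%, 50%).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon

LAYERS = ("L1", "L2/3", "L4", "L5", "L6")
SUBLAYER_NAMES = ("L4A", "L4B", "L4Ca", "L4Cb")
WM = "WM"
EXCLUDED = "excluded"

#: boundary names, in depth order, for the layer-boundary CSV
BOUNDARY_NAMES = ("L1/L2-3", "L2-3/L4", "L4/L5", "L5/L6", "L6/WM")


@dataclass(frozen=True)
class SublayerPartition:
    """Fractions of L4 depth allocated to 4A, 4B, 4Cα, 4Cβ (top to bottom)."""

    fractions: tuple[float, float, float, float] = (0.10, 0.20, 0.20, 0.50)

    def __post_init__(self) -> None:
        if len(self.fractions) != 4:
            raise ValueError("exactly four sublayer fractions required")
        if any(f <= 0 for f in self.fractions):
            raise ValueError("sublayer fractions must be positive")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("sublayer fractions must sum to 1")


@dataclass
class LayerModel:
    """Ordered laminar boundary depths for one field.

    Parameters
    ----------
    boundaries
        Depths in µm from the pia of the five boundaries
        L1/L2-3, L2-3/L4, L4/L5, L5/L6 and L6/WM, strictly increasing.
    wm_sample_depth
        How far into the white matter the field is sampled (µm).
    roi_width
        Lateral width of the field (µm).
    l1_polygon
        Optional vertex list (µm) outlining L1 when the pial surface is
        curved; used only for the L1 area.
    """

    boundaries: tuple[float, float, float, float, float]
    wm_sample_depth: float = 100.0
    roi_width: float = 400.0
    l1_polygon: list[tuple[float, float]] | None = None
    area_label: str = "A46"
    sublayers: SublayerPartition = field(default_factory=SublayerPartition)

    def __post_init__(self) -> None:
        b = tuple(float(x) for x in self.boundaries)
        if len(b) != 5:
            raise ValueError("five boundary depths required")
        if any(b2 <= b1 for b1, b2 in zip(b, b[1:])) or b[0] <= 0:
            raise ValueError("boundary depths must be strictly increasing and positive")
        if self.wm_sample_depth <= 0:
            raise ValueError("wm_sample_depth must be positive")
        if self.roi_width <= 0:
            raise ValueError("roi_width must be positive")
        self.boundaries = b

    @property
    def wm_line(self) -> float:
        """Depth of the gray/white matter boundary (µm)."""
        return self.boundaries[4]

    @property
    def max_depth(self) -> float:
        return self.wm_line + self.wm_sample_depth

    def layer_interval(self, layer: str) -> tuple[float, float]:
        """Half-open depth interval ``[top, bottom)`` of a layer or sublayer."""
        tops = (0.0,) + self.boundaries
        table = dict(zip(LAYERS + (WM,), zip(tops, self.boundaries + (self.max_depth,))))
        if layer in table:
            return table[layer]
        if layer in SUBLAYER_NAMES:
            l4_top, l4_bottom = table["L4"]
            return subdivide_layer4(l4_top, l4_bottom, self.sublayers)[layer]
        raise KeyError(f"unknown layer label: {layer!r}")


def subdivide_layer4(
    l4_top: float, l4_bottom: float, partition: SublayerPartition | None = None
) -> dict[str, tuple[float, float]]:
    """Split the L4 depth interval into 4A/4B/4Cα/4Cβ half-open bands.

    The bands are contiguous and cover ``[l4_top, l4_bottom)`` with widths
    proportional to the partition fractions; the bottom edge is pinned to
    ``l4_bottom`` exactly.
    """
    if l4_bottom <= l4_top:
        raise ValueError("degenerate L4 interval")
    partition = partition or SublayerPartition()
    width = l4_bottom - l4_top
    edges = l4_top + width * np.cumsum((0.0,) + partition.fractions)
    edges[-1] = l4_bottom
    return {
        name: (float(edges[i]), float(edges[i + 1]))
        for i, name in enumerate(SUBLAYER_NAMES)
    }


def assign_layer(
    depth: float,
    model: LayerModel,
    use_sublayers: bool = False,
) -> str:
    """Map a depth (µm from pia) to its layer label.

    Depths in ``[wm_line, wm_line + wm_sample_depth)`` are "WM"; anything
    deeper (or negative) is "excluded".  With ``use_sublayers`` the four L4
    sublayers are reported instead of "L4".
    """
    if depth < 0 or depth >= model.max_depth:
        return EXCLUDED
    tops = (0.0,) + model.boundaries
    for name, top, bottom in zip(
        LAYERS + (WM,), tops, model.boundaries + (model.max_depth,)
    ):
        if top <= depth < bottom:
            if name == "L4" and use_sublayers:
                for sub, (lo, hi) in subdivide_layer4(
                    top, bottom, model.sublayers
                ).items():
                    if lo <= depth < hi:
                        return sub
            return name
    return EXCLUDED  # pragma: no cover


def assign_layers(
    depths: np.ndarray, model: LayerModel, use_sublayers: bool = False
) -> np.ndarray:
    """Vectorized :func:`assign_layer`."""
    depths = np.asarray(depths, dtype=float)
    return np.array(
        [assign_layer(d, model, use_sublayers) for d in depths], dtype=object
    )


def polygon_area(vertices) -> float:
    """Area of a simple polygon from its vertex list (shoelace)."""
    return float(Polygon(vertices).area)


def layer_area(model: LayerModel, layer: str) -> float:
    """Area of a layer in mm².

    Rectangular (width × thickness) for every layer except L1, which uses
    the supplied outline polygon when present — the pial surface is curved
    in real sections, so L1 is annotated rather than assumed rectangular.
    """
    if layer == "L1" and model.l1_polygon is not None:
        return polygon_area(model.l1_polygon) / 1e6
    top, bottom = model.layer_interval(layer)
    return model.roi_width * (bottom - top) / 1e6


def normalized_depth(depth, model: LayerModel):
    """Linear pia-to-white-matter depth scale: pia = 0, WM line = 100.

    Values above 100 are legitimate for the sampled WM band.
    """
    return 100.0 * np.asarray(depth, dtype=float) / model.wm_line


def boundary_table(model: LayerModel):
    """(boundary_name, depth_um) rows for the layer-boundary CSV."""
    return list(zip(BOUNDARY_NAMES, model.boundaries))
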