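"""Intensity measurement, normalization and threshold gating.

Raw per-cell mean intensities are log-normally distributed, so the
working scale — mean grayscale intensity (MGI) — is ``z(ln(raw + 1))``
with the z-score taken over all cells of one tissue section, separately
per marker × compartment (the scale on which gate thresholds are
defined).  The z-score uses the sample (n−1) standard deviation.

A marker gate compares a cell's MGI against a threshold derived from a
reference cell type; calls are strictly "above threshold ⇒ positive", so
equality is negative.

An intentionally simple nucleus segmenter (global threshold + connected
components + area filter) is included so the synthetic image path is
exercisable end-to-end; the pipeline's contract is the cell table, and
externally produced exports can be substituted at that boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure, segmentation

from .panel import COMPARTMENTS, MarkerPanel


class DegenerateInputError(ValueError):
    """Raised when a z-score is requested for constant (s.d. 0) input."""


def log_z_normalize(raw: np.ndarray) -> np.ndarray:
    """MGI transform: ``z(ln(raw + 1))`` with sample (ddof=1) s.d.

    Output has sample mean 0 and sample s.d. 1 (to numerical precision).
    Constant input or n < 2 raises :class:`DegenerateInputError`.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size < 2:
        raise DegenerateInputError("need at least two values to z-score")
    if np.any(raw < 0):
        raise ValueError("raw intensities must be non-negative")
    logged = np.log(raw + 1.0)
    # ptp guard: the mean of n identical floats can differ from them by one
    # ulp, giving a spurious tiny s.d. instead of exactly zero
    if np.ptp(logged) == 0:
        raise DegenerateInputError("constant input: standard deviation is zero")
    sd = logged.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("constant input: standard deviation is zero")
    return (logged - logged.mean()) / sd


def trim_extremes(
    values: np.ndarray, lower_frac: float = 0.002, upper_frac: float = 0.002
) -> np.ndarray:
    """Keep mask dropping ``ceil(frac·n)`` values from each requested tail.

    Stable order breaks ties, so the mask is deterministic.  The defaults
    are the 0.2% used for most cell types; sparse populations (microglia)
    use 1% per tail.
    """
    values = np.asarray(values, dtype=float)
    if not (0 <= lower_frac < 0.5 and 0 <= upper_frac < 0.5):
        raise ValueError("tail fractions must lie in [0, 0.5)")
    n = values.size
    keep = np.ones(n, dtype=bool)
    if n == 0:
        return keep
    order = np.argsort(values, kind="stable")
    n_lo = math.ceil(lower_frac * n) if lower_frac > 0 else 0
    n_hi = math.ceil(upper_frac * n) if upper_frac > 0 else 0
    if n_lo:
        keep[order[:n_lo]] = False
    if n_hi:
        keep[order[n - n_hi:]] = False
    return keep


@dataclass
class GateSpec:
    """Positivity gate for one marker, defined on the MGI scale."""

    marker: str
    compartment: str
    reference_class: str | None = None
    method: str = "fixed"  # "fixed" | "quantile-of-reference"
    value: float | None = None  # threshold (fixed) or quantile in (0,1)
    threshold: float | None = None  # resolved threshold

    def __post_init__(self):
        if self.method not in ("fixed", "quantile-of-reference"):
            raise ValueError(f"unknown gate method {self.method!r}")
        if self.method == "fixed":
            if self.value is None:
                raise ValueError("fixed gate requires a threshold value")
            self.threshold = float(self.value)
        else:
            if self.value is None or not (0 < self.value < 1):
                raise ValueError("quantile gate requires a quantile in (0,1)")

    def resolve(self, reference_mgis: np.ndarray) -> "GateSpec":
        """Resolve a quantile gate against the reference cell type's MGIs."""
        if self.method == "quantile-of-reference":
            self.threshold = float(np.quantile(reference_mgis, self.value))
        return self


def call_positive(mgi, gate: GateSpec):
    """Strictly-above-threshold positivity call (equality ⇒ negative)."""
    if gate.threshold is None:
        raise ValueError(
            f"gate for {gate.marker!r} has no resolved threshold; call resolve()"
        )
    return np.asarray(mgi, dtype=float) > gate.threshold


def default_gates(panel: MarkerPanel | None = None, threshold: float = 1.5) -> dict:
    """Uniform fixed gates for every gating marker (config stand-in)."""
    panel = panel or MarkerPanel.default()
    return {
        m: GateSpec(
            m,
            panel.get(m).compartment,
            panel.get(m).reference_class,
            "fixed",
            threshold,
        )
        for m in panel.gating_markers
    }


def gates_from_reference(
    cells: pd.DataFrame,
    reference_positivity: pd.DataFrame,
    panel: MarkerPanel | None = None,
) -> dict[str, GateSpec]:
    """Fixed gates at the midpoint between reference-positive and -negative MGIs.

    This is the in-silico analogue of setting each marker's threshold
    manually in its reference cell type: ``reference_positivity`` holds
    boolean ``pos_{marker}`` columns for a reference population with known
    labels, and the threshold is placed halfway between the mean MGI of
    the positive and negative groups.  Markers with no positive reference
    cells gate everything negative (+inf threshold).
    """
    panel = panel or MarkerPanel.default()
    gates = {}
    # every marker is gated per-cell: vascular markers feed endothelial
    # classification and MAP2 feeds neuronal subtype densities, even though
    # both are excluded from the 21-marker feature set
    for name in panel.names:
        spec = panel.get(name)
        col = f"{name}_{spec.compartment}_mgi"
        flag = f"pos_{name}"
        if col not in cells.columns or flag not in reference_positivity.columns:
            continue
        mgi = cells[col].to_numpy()
        pos = reference_positivity[flag].to_numpy().astype(bool)
        if pos.any() and (~pos).any():
            thr = 0.5 * (mgi[pos].mean() + mgi[~pos].mean())
        elif pos.any():
            thr = -np.inf
        else:
            thr = np.inf
        gates[name] = GateSpec(
            name, spec.compartment, spec.reference_class, "fixed", thr
        )
    return gates


def load_gates(path) -> dict[str, GateSpec]:
    """Read gate specs from YAML: a list of {marker, compartment,
    reference_class, method, value} mappings."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh)
    gates = {}
    for d in data["gates"]:
        gates[d["marker"]] = GateSpec(
            d["marker"],
            d["compartment"],
            d.get("reference_class"),
            d.get("method", "fixed"),
            d["value"],
        )
    return gates


def save_gates(gates: dict[str, GateSpec], path) -> None:
    import yaml

    data = [
        {
            "marker": g.marker,
            "compartment": g.compartment,
            "reference_class": g.reference_class,
            "method": g.method,
            "value": None if g.value is None else float(g.value),
        }
        for g in gates.values()
    ]
    with open(path, "w") as fh:
        yaml.safe_dump({"gates": data}, fh, sort_keys=False)


def normalize_cell_table(
    cells: pd.DataFrame, panel: MarkerPanel | None = None
) -> pd.DataFrame:
    """Append MGI columns for every marker × compartment of one section."""
    panel = panel or MarkerPanel.default()
    out = cells.copy()
    for m in panel:
        for comp in COMPARTMENTS:
            col = f"{m.name}_{comp}_mean"
            if col in out.columns:
                out[f"{m.name}_{comp}_mgi"] = log_z_normalize(out[col].to_numpy())
    return out


def apply_gates(
    cells: pd.DataFrame, gates: dict[str, GateSpec], panel: MarkerPanel | None = None
) -> pd.DataFrame:
    """Positivity calls for every gated marker; adds ``pos_{marker}`` columns."""
    panel = panel or MarkerPanel.default()
    out = cells.copy()
    for name, gate in gates.items():
        col = f"{name}_{gate.compartment}_mgi"
        if col not in out.columns:
            raise KeyError(f"MGI column missing for marker {name!r}: {col}")
        out[f"pos_{name}"] = call_positive(out[col].to_numpy(), gate)
    return out


def segment_nuclei(
    dapi: np.ndarray,
    pixel_size: float,
    intensity_floor: float = 50.0,
    min_area_um2: float = 10.0,
):
    """Segment nuclei from a DAPI channel.

    Global threshold at ``intensity_floor``, 8-connected components, then
    an area filter in µm².  Returns (label image, centroid table in µm).
    An empty image yields zero nuclei, which is not an error.
    """
    dapi = np.asarray(dapi)
    if dapi.ndim != 2:
        raise ValueError("DAPI channel must be a single 2-D image")
    mask = dapi > intensity_floor
    labels = measure.label(mask, connectivity=2)
    min_px = min_area_um2 / pixel_size**2
    rows = []
    keep = np.zeros(labels.max() + 1, dtype=bool)
    for p in measure.regionprops(labels):
        if p.area >= min_px:
            keep[p.label] = True
            rows.append(
                {
                    "label": p.label,
                    "centroid_x_um": (p.centroid[1] + 0.5) * pixel_size,
                    "centroid_y_um": (p.centroid[0] + 0.5) * pixel_size,
                    "area_um2": p.area * pixel_size**2,
                }
            )
    labels = np.where(keep[labels], labels, 0)
    labels, _, _ = segmentation.relabel_sequential(labels)
    for new, row in enumerate(rows, start=1):
        row["label"] = new
    return labels, pd.DataFrame(rows)


def measure_compartments(
    labels: np.ndarray,
    channels: dict[str, np.ndarray],
    pixel_size: float,
    expansion_um: float = 2.0,
    panel: MarkerPanel | None = None,
) -> pd.DataFrame:
    """Per-cell raw mean intensities in Nucleus / Cell / Cytoplasm.

    The Cell mask is the nucleus dilated by ``expansion_um``, clipped at
    the image border and at neighbouring cells (nearest-label tie-break,
    via :func:`skimage.segmentation.expand_labels`); Cytoplasm is Cell
    minus Nucleus, so Nucleus ⊆ Cell and the two sub-compartments
    partition it.
    """
    panel = panel or MarkerPanel.default()
    labels = np.asarray(labels)
    n = int(labels.max())
    expanded = segmentation.expand_labels(labels, distance=expansion_um / pixel_size)
    cyto = np.where(labels > 0, 0, expanded)
    idx = np.arange(1, n + 1)
    out = {"label": idx}
    for name, img in channels.items():
        if name == "DAPI":
            continue
        if name not in panel.names:
            raise KeyError(f"channel {name!r} is not a marker in the panel")
        img = np.asarray(img, dtype=float)
        if img.shape != labels.shape:
            raise ValueError(f"channel {name!r} does not match label geometry")
        nuc = ndimage.mean(img, labels, idx)
        cell = ndimage.mean(img, expanded, idx)
        cyt_counts = ndimage.sum(np.ones_like(img), cyto, idx)
        cyt = np.where(
            cyt_counts > 0, ndimage.mean(img, cyto, idx), 0.0
        )
        out[f"{name}_Nucleus_mean"] = nuc
        out[f"{name}_Cell_mean"] = cell
        out[f"{name}_Cytoplasm_mean"] = cyt
    return pd.DataFrame(out)
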