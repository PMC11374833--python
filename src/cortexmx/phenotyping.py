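"""Cell classification from marker positivity, and subtype gating.

Each segmented object is assigned exactly one of Neuron, Astrocyte,
Microglia, Oligodendrocyte, Endothelial, Other or Multiple.  A class is
*hit* when any (or, for endothelial cells, all) of its defining markers
is positive.  Tolerated exceptions handle known cross-class expression —
e.g. Olig2 in a subset of astrocytes — without triggering "Multiple";
genuine conflicts (defining markers of two classes, after exceptions)
are "Multiple", and cells hitting no class are "Other".  Other and
Multiple are excluded before any statistics.

Within classes, co-expression subtypes are gated from ordered positivity
flags (HuD/NeuN; GAD67/GAD65 with PV/CB; GFAP/ALDH1L1; Olig2/CNPase/
BCAS1), mutually exclusive and exhaustive by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

CLASS_LABELS = (
    "Neuron",
    "Astrocyte",
    "Microglia",
    "Oligodendrocyte",
    "Endothelial",
    "Other",
    "Multiple",
)


@dataclass(frozen=True)
class ClassRule:
    """Defining markers of one cell class.

    ``mode`` is "any" (one defining marker suffices) or "all";
    ``exceptions`` lists markers from *other* classes whose positivity is
    tolerated in this class.
    """

    name: str
    defining: tuple[str, ...]
    mode: str = "any"
    exceptions: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if not self.defining:
            raise ValueError(f"class {self.name!r} needs at least one defining marker")
        if self.mode not in ("any", "all"):
            raise ValueError("mode must be 'any' or 'all'")

    def hit(self, pos: dict[str, bool]) -> bool:
        values = [bool(pos.get(m, False)) for m in self.defining]
        return all(values) if self.mode == "all" else any(values)


def default_class_rules() -> list[ClassRule]:
    return [
        ClassRule("Neuron", ("HuD", "NeuN")),
        ClassRule("Astrocyte", ("ALDH1L1", "GFAP"), exceptions=frozenset({"Olig2"})),
        ClassRule("Microglia", ("Iba1",)),
        ClassRule("Oligodendrocyte", ("Olig2",)),
        # endothelial calls require both vascular markers (or vessel
        # containment, handled by the caller via `in_vessel`)
        ClassRule("Endothelial", ("CollagenIV", "Vimentin"), mode="all"),
    ]


def classify_cell(
    positivity: dict[str, bool],
    rules: list[ClassRule] | None = None,
    in_vessel: bool = False,
) -> str:
    """Assign one class from per-marker positivity.

    Hits from a class whose defining markers are all tolerated exceptions
    of another hit class are suppressed before conflict resolution, so the
    result does not depend on rule or marker ordering.
    """
    rules = rules if rules is not None else default_class_rules()
    hits = {r.name for r in rules if r.hit(positivity)}
    if in_vessel:
        hits.add("Endothelial")
    by_name = {r.name: r for r in rules}
    suppressed = set()
    for a in hits:
        for b in hits:
            if a == b or b in suppressed:
                continue
            rb = by_name.get(b)
            if rb is None:
                continue
            hit_markers = {m for m in rb.defining if positivity.get(m, False)}
            if hit_markers and hit_markers <= by_name[a].exceptions:
                suppressed.add(b)
    hits -= suppressed
    if not hits:
        return "Other"
    if len(hits) > 1:
        return "Multiple"
    return hits.pop()


def classify_cells(
    cells: pd.DataFrame,
    rules: list[ClassRule] | None = None,
    in_vessel: np.ndarray | None = None,
) -> pd.Series:
    """Vector version over a cell table with ``pos_{marker}`` columns."""
    rules = rules if rules is not None else default_class_rules()
    markers = sorted(
        {m for r in rules for m in r.defining}
        | {m for r in rules for m in r.exceptions}
    )
    cols = {m: cells[f"pos_{m}"].to_numpy() for m in markers if f"pos_{m}" in cells}
    iv = in_vessel if in_vessel is not None else np.zeros(len(cells), dtype=bool)
    out = [
        classify_cell({m: v[i] for m, v in cols.items()}, rules, bool(iv[i]))
        for i in range(len(cells))
    ]
    return pd.Series(out, index=cells.index, name="cell_class")


def filter_for_analysis(cells: pd.DataFrame, class_col: str = "cell_class"):
    """Drop Other/Multiple cells; returns (retained, retained_fraction)."""
    keep = ~cells[class_col].isin(["Other", "Multiple"])
    fraction = float(keep.mean()) if len(cells) else 1.0
    retained = cells.loc[keep].copy()
    if len(cells) and retained.empty:
        log.warning("all cells classified Other/Multiple; nothing retained")
    return retained, fraction


@dataclass(frozen=True)
class SubtypeScheme:
    """Ordered marker tuple defining co-expression subtypes in one class."""

    cell_class: str
    markers: tuple[str, ...]
    style: str = "combo"  # "combo" | "gaba"


PAN_NEURON = SubtypeScheme("Neuron", ("HuD", "NeuN"))
GABA = SubtypeScheme("Neuron", ("GAD67", "GAD65", "PV", "CB"), style="gaba")
ASTRO = SubtypeScheme("Astrocyte", ("GFAP", "ALDH1L1"))
OLIGO = SubtypeScheme("Oligodendrocyte", ("Olig2", "CNPase", "BCAS1"))


def _combo_label(flags: tuple[bool, ...], markers: tuple[str, ...]) -> str:
    on = [m for m, f in zip(markers, flags) if f]
    if not on:
        return "negative"
    if len(on) == 1:
        return f"{on[0]}+ only"
    return "/".join(f"{m}+" for m in on)


def _gaba_label(g67: bool, g65: bool, pv: bool, cb: bool) -> str:
    if not (g67 or g65):
        return "non-GABAergic"
    if g67 and g65:
        base = "GAD65+/GAD67+"
    elif g67:
        base = "GAD67-only"
    else:
        base = "GAD65-only"
    if pv and cb:
        return f"{base}, PV+/CB+"
    if pv:
        return f"{base}, PV+"
    if cb:
        return f"{base}, CB+"
    return base


def gate_subtypes(
    cells: pd.DataFrame,
    scheme: SubtypeScheme,
    class_col: str = "cell_class",
    layer_col: str = "layer",
    area_col: str = "area",
) -> tuple[pd.Series, pd.DataFrame]:
    """Subtype labels for all cells of the scheme's class.

    Returns (labels indexed like the class subset, contingency counts per
    layer × area when those columns are present, else overall).
    """
    subset = cells[cells[class_col] == scheme.cell_class]
    missing = [m for m in scheme.markers if f"pos_{m}" not in cells.columns]
    if missing:
        raise KeyError(f"no positivity gate for marker(s): {missing}")
    flags = {m: subset[f"pos_{m}"].to_numpy().astype(bool) for m in scheme.markers}
    if scheme.style == "gaba":
        labels = [
            _gaba_label(*(flags[m][i] for m in ("GAD67", "GAD65", "PV", "CB")))
            for i in range(len(subset))
        ]
    else:
        labels = [
            _combo_label(tuple(flags[m][i] for m in scheme.markers), scheme.markers)
            for i in range(len(subset))
        ]
    labels = pd.Series(labels, index=subset.index, name="subtype")
    group_cols = [c for c in (area_col, layer_col) if c in subset.columns]
    tab = (
        pd.DataFrame({"subtype": labels, **{c: subset[c] for c in group_cols}})
        .groupby(group_cols + ["subtype"], observed=True)
        .size()
        .rename("count")
        .reset_index()
    )
    return labels, tab
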