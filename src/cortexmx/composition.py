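"""Counts, densities, proportions, headline ratios, and group comparisons.

Composition is tabulated per (case, area, layer, class-or-subtype):
counts, planar densities (cells/mm²), within-layer proportions, and the
across-layer relative distribution of each class (white matter excluded,
because only a 100-µm WM band is sampled rather than its full extent).

Headline ratios: non-neuronal:neuron, glia:neuron (GNR — astrocytes +
oligodendrocytes + microglia over neurons), and the excitatory:inhibitory
neuron ratio (E:I) computed over layers 2/3–6 from GAD gating.  Stored
values are unrounded; a 2-dp display form mirrors how such ratios are
conventionally printed.

Group comparisons follow a split-plot mixed-design ANOVA with subject as
the random blocking factor: between-subject factors (brain area) are
tested against the subject-within-group mean square, within-subject
factors (layer, subtype) and interactions against the residual.  Post-hoc
pairwise contrasts of estimated marginal means use the Šidák adjustment
within a family, with a Bonferroni correction available across families.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .geometry import LAYERS, WM, LayerModel, layer_area

GLIA = ("Astrocyte", "Oligodendrocyte", "Microglia")
NON_NEURONAL = GLIA + ("Endothelial",)


def density_by_layer(
    counts: pd.DataFrame,
    areas_mm2: dict[str, float] | LayerModel,
    layer_col: str = "layer",
    count_col: str = "count",
) -> pd.DataFrame:
    """Planar densities (cells/mm²) from per-layer counts and layer areas."""
    if isinstance(areas_mm2, LayerModel):
        model = areas_mm2
        areas_mm2 = {l: layer_area(model, l) for l in LAYERS + (WM,)}
    out = counts.copy()
    areas = out[layer_col].map(areas_mm2)
    if areas.isna().any():
        missing = sorted(out.loc[areas.isna(), layer_col].unique())
        raise KeyError(f"no area for layer(s): {missing}")
    if (areas <= 0).any():
        raise ValueError("layer areas must be positive")
    out["area_mm2"] = areas
    out["density_per_mm2"] = out[count_col] / areas
    return out


def count_cells(
    cells: pd.DataFrame,
    by=("case", "area", "layer", "cell_class"),
) -> pd.DataFrame:
    """Tidy per-group cell counts."""
    return (
        cells.groupby(list(by), observed=True).size().rename("count").reset_index()
    )


@dataclass
class RatioReport:
    """Headline composition ratios.  ``None`` marks an undefined ratio."""

    non_neuronal_to_neuron: float | None
    glia_to_neuron: float | None
    excitatory_to_inhibitory: float | None = None

    @staticmethod
    def _disp(x):
        return None if x is None else round(x, 2)

    @property
    def display(self) -> dict:
        return {
            "non_neuronal_to_neuron": self._disp(self.non_neuronal_to_neuron),
            "glia_to_neuron": self._disp(self.glia_to_neuron),
            "excitatory_to_inhibitory": self._disp(self.excitatory_to_inhibitory),
        }


def _safe_ratio(num: float, den: float) -> float | None:
    return None if den == 0 else num / den


def composition_ratios(
    class_counts: dict[str, float],
    inhibitory_neurons: float | None = None,
    neurons_l23_l6: float | None = None,
) -> RatioReport:
    """Headline ratios from pooled class counts (L1–L6).

    ``inhibitory_neurons`` and ``neurons_l23_l6`` — GAD+ neuron count and
    total neuron count over L2/3–L6 — enable the E:I ratio; E:I is only
    defined on that laminar span.
    """
    neurons = float(class_counts.get("Neuron", 0))
    non_neuronal = float(sum(class_counts.get(c, 0) for c in NON_NEURONAL))
    glia = float(sum(class_counts.get(c, 0) for c in GLIA))
    ei = None
    if inhibitory_neurons is not None and neurons_l23_l6 is not None:
        excitatory = neurons_l23_l6 - inhibitory_neurons
        ei = _safe_ratio(excitatory, inhibitory_neurons)
    return RatioReport(
        non_neuronal_to_neuron=_safe_ratio(non_neuronal, neurons),
        glia_to_neuron=_safe_ratio(glia, neurons),
        excitatory_to_inhibitory=ei,
    )


def laminar_distribution(
    counts: pd.DataFrame,
    class_col: str = "cell_class",
    layer_col: str = "layer",
    count_col: str = "count",
    exclude_wm: bool = True,
) -> pd.DataFrame:
    """Across-layer relative distribution of each class (fractions sum to 1)."""
    df = counts.copy()
    if exclude_wm:
        df = df[df[layer_col] != WM]
    # normalize within every non-layer key present (case, area, class, ...)
    keys = [c for c in df.columns if c not in (layer_col, count_col)]
    totals = df.groupby(keys, observed=True)[count_col].transform("sum")
    df["fraction"] = np.where(totals > 0, df[count_col] / totals, 0.0)
    return df


def within_layer_proportions(
    counts: pd.DataFrame,
    class_col: str = "cell_class",
    layer_col: str = "layer",
    count_col: str = "count",
) -> pd.DataFrame:
    """Class proportions within each layer (sum to 1 per layer)."""
    df = counts.copy()
    keys = [c for c in df.columns if c not in (class_col, count_col)]
    totals = df.groupby(keys, observed=True)[count_col].transform("sum")
    df["proportion"] = np.where(totals > 0, df[count_col] / totals, 0.0)
    return df


# ---------------------------------------------------------------------------
# group comparisons


def sidak_adjust(p: np.ndarray, m: int | None = None) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    m = m or p.size
    return 1.0 - (1.0 - p) ** m


def bonferroni_families(p: np.ndarray, n_families: int) -> np.ndarray:
    return np.minimum(np.asarray(p, dtype=float) * n_families, 1.0)


def compare_groups(
    data: pd.DataFrame,
    response: str,
    between: tuple[str, ...] = ("area",),
    within: tuple[str, ...] = ("layer",),
    subject: str = "case",
    alpha: float = 0.05,
) -> dict:
    """Mixed-design (split-plot) ANOVA with subject as the random block.

    Between-subject factors are tested against the subject-within-groups
    stratum; within-subject factors and all interactions against the
    residual.  With ``between=()`` (every factor varies within subject, as
    when each case contributes both brain areas) the subject stratum is
    the deviation of subject means from the grand mean — a standard
    repeated-measures decomposition.  Returns ``{"anova": DataFrame,
    "contrasts": DataFrame}`` where contrasts are Šidák-adjusted pairwise
    comparisons of estimated marginal means per factor.
    """
    factors = tuple(between) + tuple(within)
    for f in factors + (subject, response):
        if f not in data.columns:
            raise KeyError(f"column {f!r} missing from data")
    for f in factors:
        if data[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs at least 2 levels")
    if between:
        subj_per_cell = data.groupby(list(between), observed=True)[subject].nunique()
        crossed = data.groupby(subject, observed=True)[list(between)].nunique()
        if (crossed > 1).any(axis=None):
            raise ValueError(
                "a subject appears at several levels of a between-subject "
                "factor; model that factor as within-subject instead"
            )
        if data[subject].nunique() < 2 or (subj_per_cell < 2).any():
            raise ValueError(
                "random-effect fit requires at least two subjects per "
                "between-subject group; got a degenerate design"
            )
    elif data[subject].nunique() < 2:
        raise ValueError("random-effect fit requires at least two subjects")

    fixed = " * ".join(f"C(Q('{f}'))" for f in factors)
    formula = f"Q('{response}') ~ {fixed}"
    fit = smf.ols(formula, data=data).fit()
    table = anova_lm(fit, typ=2)

    def _term(*fs):
        return ":".join(f"C(Q('{f}'))" for f in fs)

    # subject stratum: extra sum of squares of C(subject) after the fixed
    # factors.  For a balanced nested design this is exactly the classical
    # subjects-within-groups stratum; the extra-SS form also stays valid
    # for unbalanced or partially crossed membership.
    fit_full = smf.ols(formula + f" + C(Q('{subject}'))", data=data).fit()
    subj_ss = float(fit.ssr - fit_full.ssr)
    subj_df = float(fit.df_resid - fit_full.df_resid)
    if subj_df <= 0:
        raise ValueError(
            "random-effect fit requires more subjects than between-subject "
            "groups; got a degenerate design"
        )
    resid_ss = float(fit_full.ssr)
    resid_df = float(fit_full.df_resid)
    if resid_df <= 0:
        raise ValueError("no residual degrees of freedom for within-subject tests")

    rows = []
    for k in range(1, len(factors) + 1):
        for combo in itertools.combinations(factors, k):
            term = _term(*combo)
            if term not in table.index:
                continue
            ss, df = table.loc[term, "sum_sq"], table.loc[term, "df"]
            purely_between = all(f in between for f in combo)
            if purely_between:
                err_ss, err_df, stratum = subj_ss, subj_df, "subjects"
            else:
                err_ss, err_df, stratum = resid_ss, resid_df, "residual"
            ms, err_ms = ss / df, err_ss / err_df
            F = ms / err_ms
            p = float(sps.f.sf(F, df, err_df))
            rows.append(
                {
                    "factor": " x ".join(combo),
                    "sum_sq": ss,
                    "df": df,
                    "err_df": err_df,
                    "error_stratum": stratum,
                    "F": F,
                    "p": p,
                    "significant": p < alpha,
                }
            )
    anova = pd.DataFrame(rows)

    contrasts = []
    for f in factors:
        emm = data.groupby(f, observed=True)[response].mean()
        counts = data.groupby(f, observed=True)[response].size()
        if f in between:
            err_ss, err_df = subj_ss, subj_df
        else:
            err_ss, err_df = resid_ss, resid_df
        err_ms = err_ss / err_df
        pairs = list(itertools.combinations(emm.index, 2))
        praw, rows_f = [], []
        for a, b in pairs:
            diff = emm[a] - emm[b]
            se = np.sqrt(err_ms * (1 / counts[a] + 1 / counts[b]))
            t = diff / se
            p = float(2 * sps.t.sf(abs(t), err_df))
            praw.append(p)
            rows_f.append(
                {"factor": f, "level_a": a, "level_b": b, "estimate": diff,
                 "se": se, "t": t, "p_raw": p}
            )
        adj = sidak_adjust(np.array(praw), len(pairs)) if pairs else []
        for r, pa in zip(rows_f, adj):
            r["p_sidak"] = float(pa)
            r["significant"] = pa < alpha
        contrasts.extend(rows_f)

    return {"anova": anova, "contrasts": pd.DataFrame(contrasts)}
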