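"""Per-field feature vectors and multivariate field clustering.

Fields (one per layer × area × case, optionally per cell type) are
summarized as vectors of mean marker MGIs, optionally concatenated with
cell densities, each variable z-scored across fields.  Downstream:

* PCA retaining the smallest number of components whose cumulative
  explained variance reaches a target (default 80%);
* t-SNE embedding of a Euclidean or squared-Euclidean distance matrix
  (perplexity 15, seeded — embeddings are only reproducible for a fixed
  seed and perplexity, which are recorded with the result);
* one-way MANOVA supervised clustering: canonical variables from the
  between/within scatter eigenproblem, Bartlett's sequential Wilks-Λ
  chi-square test per canonical dimension, feature influence ranked by
  absolute canonical coefficient, and an average-linkage dendrogram of
  group means in canonical space (Newick text).

Feature manifests are config-driven: the default "methods" manifest uses
21 intensity + 16 density variables, with a narrower 21 + 14 variant, a
neuronal scheme (15 intensity + 9 density; 8-density variant) and a
glial scheme (13 intensity + 6 density) shipped as presets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .panel import MarkerPanel

log = logging.getLogger(__name__)

NEURONAL_INTENSITY = (
    "HuD", "NeuN", "GAD67", "GAD65", "PV", "CB", "Kv3.1", "MAP2",
    "Abeta", "pTau", "CC3", "S6", "TSPO", "3NT", "TDP43",
)  # 15
NEURONAL_DENSITY_9 = (
    "HuD", "NeuN", "GAD67", "GAD65", "PV", "CB", "Kv3.1", "MAP2", "CR",
)
NEURONAL_DENSITY_8 = NEURONAL_DENSITY_9[:8]
GLIAL_INTENSITY = (
    "GFAP", "ALDH1L1", "Iba1", "Olig2", "CNPase", "BCAS1",
    "Abeta", "pTau", "CC3", "S6", "TSPO", "3NT", "TDP43",
)  # 13
GLIAL_DENSITY = ("GFAP", "ALDH1L1", "Iba1", "Olig2", "CNPase", "BCAS1")  # 6


@dataclass(frozen=True)
class FeatureManifest:
    """Which variables enter the field feature vector."""

    name: str
    intensity_markers: tuple[str, ...]
    density_markers: tuple[str, ...] = ()

    @property
    def columns(self) -> list[str]:
        return [f"mgi_{m}" for m in self.intensity_markers] + [
            f"density_{m}" for m in self.density_markers
        ]


def default_manifests(panel: MarkerPanel | None = None) -> dict[str, FeatureManifest]:
    panel = panel or MarkerPanel.default()
    gating = tuple(panel.gating_markers)  # the 21 non-fiber/non-vessel markers
    return {
        # 21 intensity + 16 density (methods-style) and + 14 (results-style)
        "total": FeatureManifest("total", gating, gating[:16]),
        "total_14": FeatureManifest("total_14", gating, gating[:14]),
        "intensity_only": FeatureManifest("intensity_only", gating),
        "neuronal": FeatureManifest("neuronal", NEURONAL_INTENSITY, NEURONAL_DENSITY_9),
        "neuronal_8": FeatureManifest(
            "neuronal_8", NEURONAL_INTENSITY, NEURONAL_DENSITY_8
        ),
        "glial": FeatureManifest("glial", GLIAL_INTENSITY, GLIAL_DENSITY),
    }


def build_feature_table(
    cells: pd.DataFrame,
    manifest: FeatureManifest,
    by_cell_type: bool = False,
    key_cols: tuple[str, ...] = ("case", "area", "layer"),
    class_col: str = "cell_class",
    area_col_mm2: str | None = "layer_area_mm2",
    panel: MarkerPanel | None = None,
    zscore: bool = True,
    class_filter: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """One feature vector per field key.

    Intensity features are means of per-cell MGIs over the field (per
    cell type when ``by_cell_type``); density features are counts of
    marker-positive cells divided by the field's layer area (requires an
    ``area_col_mm2`` column).  Keys with zero cells simply do not appear;
    keys with missing features are dropped with a log entry.  Finally
    every variable is z-scored across fields.
    """
    panel = panel or MarkerPanel.default()
    if class_filter is not None:
        cells = cells[cells[class_col].isin(class_filter)]
    keys = list(key_cols) + ([class_col] if by_cell_type else [])
    groups = cells.groupby(keys, observed=True)
    rows = []
    for key, g in groups:
        key = key if isinstance(key, tuple) else (key,)
        row = dict(zip(keys, key))
        for m in manifest.intensity_markers:
            col = panel.mgi_column(m)
            row[f"mgi_{m}"] = g[col].mean() if col in g else np.nan
        for m in manifest.density_markers:
            flag = f"pos_{m}"
            if flag in g and area_col_mm2 in g:
                row[f"density_{m}"] = g[flag].sum() / g[area_col_mm2].iloc[0]
            else:
                row[f"density_{m}"] = np.nan
        row["n_cells"] = len(g)
        rows.append(row)
    table = pd.DataFrame(rows)
    feat = manifest.columns
    bad = table[feat].isna().any(axis=1)
    if bad.any():
        log.info("dropping %d field vector(s) with missing features", int(bad.sum()))
        table = table.loc[~bad].reset_index(drop=True)
    if zscore:
        if len(table) < 2:
            raise ValueError("cross-field z-scoring needs at least two fields")
        for c in feat:
            sd = table[c].std(ddof=1)
            if sd == 0:
                log.info("feature %s constant across fields; set to 0", c)
                table[c] = 0.0
            else:
                table[c] = (table[c] - table[c].mean()) / sd
    return table


def pca_variance_cut(features: np.ndarray, variance_target: float = 0.80):
    """Scores of the fewest leading PCs reaching the variance target.

    Returns ``(scores, explained_variance_ratio, k)``.
    """
    X = np.asarray(features, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least two observations")
    pca = PCA()
    scores = pca.fit_transform(X)
    ratio = pca.explained_variance_ratio_
    k = int(np.searchsorted(np.cumsum(ratio), variance_target - 1e-12) + 1)
    k = min(k, scores.shape[1])
    return scores[:, :k], ratio, k


def embed(
    features: np.ndarray,
    method: str = "tsne",
    distance: str = "euclidean",
    perplexity: float = 15.0,
    seed: int = 0,
) -> np.ndarray:
    """2-D t-SNE of the pairwise distance matrix; deterministic per seed."""
    if method != "tsne":
        raise ValueError(f"unknown embedding method {method!r}")
    X = np.asarray(features, dtype=float)
    n = X.shape[0]
    if distance == "euclidean":
        d = squareform(pdist(X))
    elif distance == "squared-euclidean":
        d = squareform(pdist(X, "sqeuclidean"))
    else:
        raise ValueError(f"unknown distance {distance!r}")
    if not np.isfinite(d).all() or n < 3:
        raise ValueError("degenerate distance matrix")
    if perplexity >= n:
        new_p = max((n - 1) / 3, 1.0)
        warnings.warn(
            f"perplexity {perplexity} too large for n={n}; reduced to {new_p:.1f}"
        )
        perplexity = new_p
    ts = TSNE(
        n_components=2,
        metric="precomputed",
        perplexity=perplexity,
        init="random",
        random_state=seed,
    )
    return ts.fit_transform(d)


@dataclass
class CanonicalResult:
    coefficients: pd.DataFrame  # features × canonical variables
    scores: np.ndarray  # observations × canonical variables
    eigenvalues: np.ndarray
    p_values: np.ndarray  # sequential Wilks/Bartlett test per dimension
    group_means: pd.DataFrame  # groups × canonical variables
    newick: str
    ridge: float = 0.0

    @property
    def n_significant(self) -> int:
        return int((self.p_values < 0.05).sum())

    def top_features(self, dim: int = 0, k: int = 5) -> pd.DataFrame:
        coef = self.coefficients.iloc[:, dim].abs().sort_values(ascending=False)
        return coef.head(k)


def _linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    tree = hierarchy.to_tree(Z)

    def rec(node, parent_dist):
        length = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        return (
            f"({rec(node.left, node.dist)},{rec(node.right, node.dist)})"
            f":{length:.6g}"
        )

    return f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)});"


def manova_canonical(
    features: np.ndarray | pd.DataFrame,
    groups,
    feature_names: list[str] | None = None,
    alpha: float = 0.05,
) -> CanonicalResult:
    """One-way MANOVA with canonical variables.

    Solves the between/within scatter generalized eigenproblem
    ``B v = λ W v``; canonical coefficients are scaled so canonical
    scores have unit pooled within-group variance.  Per-dimension
    significance uses Bartlett's chi-square approximation to the
    sequential Wilks Λ.  A singular within scatter is ridge-regularized
    with a warning.  The group means in canonical space are clustered by
    average-linkage on Euclidean distances and returned as Newick text.
    """
    if isinstance(features, pd.DataFrame):
        feature_names = feature_names or list(features.columns)
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        feature_names = feature_names or [f"x{i}" for i in range(X.shape[1])]
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    g, n, p = len(labels), X.shape[0], X.shape[1]
    if g < 2:
        raise ValueError("need at least two groups")
    if (counts < 2).any():
        raise ValueError("every group needs at least two observations")

    grand = X.mean(axis=0)
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    means = np.empty((g, p))
    for i, lab in enumerate(labels):
        Xi = X[groups == lab]
        mi = Xi.mean(axis=0)
        means[i] = mi
        W += (Xi - mi).T @ (Xi - mi)
        B += len(Xi) * np.outer(mi - grand, mi - grand)

    ridge = 0.0
    cond = np.linalg.cond(W)
    if not np.isfinite(cond) or cond > 1e12:
        ridge = 1e-8 * np.trace(W) / p if np.trace(W) > 0 else 1e-8
        W = W + ridge * np.eye(p)
        warnings.warn("within-group scatter singular; ridge-regularized")

    from scipy.linalg import eigh

    evals, evecs = eigh(B, W)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    m = min(g - 1, p)
    evals = np.clip(evals[:m], 0, None)
    evecs = evecs[:, :m]
    # scale: unit pooled within-group variance of canonical scores
    dfw = n - g
    for j in range(m):
        s = evecs[:, j] @ (W / dfw) @ evecs[:, j]
        if s > 0:
            evecs[:, j] = evecs[:, j] / np.sqrt(s)

    # Bartlett's sequential test of dimensions k..m-1
    pvals = np.empty(m)
    for k in range(m):
        lam = np.prod(1.0 / (1.0 + evals[k:]))
        chi2 = -(n - 1 - (p + g) / 2) * np.log(max(lam, np.finfo(float).tiny))
        df = (p - k) * (g - k - 1)
        pvals[k] = float(sps.chi2.sf(chi2, df)) if df > 0 else 1.0

    scores = (X - grand) @ evecs
    gm = (means - grand) @ evecs
    group_means = pd.DataFrame(
        gm, index=[str(l) for l in labels],
        columns=[f"c{j + 1}" for j in range(m)],
    )
    coefficients = pd.DataFrame(
        evecs, index=feature_names, columns=[f"c{j + 1}" for j in range(m)]
    )
    if g > 2:
        Z = hierarchy.linkage(gm, method="average", metric="euclidean")
        newick = _linkage_to_newick(Z, [str(l) for l in labels])
    else:
        newick = f"({labels[0]},{labels[1]});"
    return CanonicalResult(
        coefficients, scores, evals, pvals, group_means, newick, ridge
    )
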