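"""Cluster-purity evaluation of activity matrices on annotated cell mixtures.

Do pathway/TF activity matrices retain cell-type structure?  The evaluation
embeds a features × cells matrix into 2-D (UMAP), assigns each cell the
cluster label of its annotated type at a chosen granularity of the cell-type
hierarchy, and measures purity with silhouette widths in the embedded space:
s = (b − a) / max(a, b), with a the mean intra-cluster distance and b the
smallest mean distance to a foreign cluster.  Global purity is the unweighted
mean of per-cluster mean widths.

Positive/negative controls use highly variable genes (HVG): the positive
control is the expression matrix of the top-n HVGs; the negative control uses
n genes sampled at random from the top 2000 HVGs — matching feature counts so
purity differences reflect information content, not dimensionality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.nonparametric.smoothers_lowess import lowess


class PurityError(ValueError):
    pass


# ---------------------------------------------------------------------------
# highly variable genes (vst-style)
# ---------------------------------------------------------------------------

class HVGSelector(BaseEstimator, TransformerMixin):
    """Variance-stabilizing (vst-style) highly-variable-gene selection.

    Per gene of a raw count matrix, the expected variance is fit as a smooth
    local-regression function of the mean on log10 scale; each observation is
    standardized by the fitted sd and clipped at sqrt(n_cells); genes are
    ranked by the variance of the standardized values.

    Parameters
    ----------
    n : int
        Genes to keep, default 2000.
    span : float
        Lowess span of the mean–variance trend fit, default 0.3.

    Attributes
    ----------
    genes_ : pd.Index
        Selected genes, most variable first.
    standardized_variance_ : pd.Series
        Ranking statistic for every input gene.
    """

    def __init__(self, n: int = 2000, span: float = 0.3):
        self.n = n
        self.span = span

    def fit(self, X: pd.DataFrame, y=None):
        if X.shape[1] < 3:
            raise PurityError("need at least 3 cells for the variance trend")
        values = X.to_numpy(dtype=float)
        n_cells = values.shape[1]
        mean = values.mean(axis=1)
        var = values.var(axis=1, ddof=1)
        usable = (mean > 0) & (var > 0)
        std_var = np.zeros(values.shape[0])
        if usable.sum() >= 2:
            lx = np.log10(mean[usable])
            ly = np.log10(var[usable])
            fit = lowess(ly, lx, frac=self.span, return_sorted=False)
            sd_exp = np.sqrt(10.0 ** fit)
            z = (values[usable] - mean[usable, None]) / sd_exp[:, None]
            z = np.clip(z, -np.sqrt(n_cells), np.sqrt(n_cells))
            std_var[usable] = z.var(axis=1, ddof=1)
        self.standardized_variance_ = pd.Series(std_var, index=X.index)
        order = self.standardized_variance_.sort_values(ascending=False, kind="stable")
        n = self.n
        if n > len(order):
            warnings.warn(
                f"requested {n} HVGs but only {len(order)} genes present; returning all",
                stacklevel=2,
            )
            n = len(order)
        self.genes_ = order.index[:n]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X.loc[self.genes_]


def select_hvgs(expr: pd.DataFrame, n: int = 2000, span: float = 0.3) -> pd.Index:
    """Top-``n`` highly variable genes of a raw count matrix (most variable first)."""
    return HVGSelector(n=n, span=span).fit(expr).genes_


def make_controls(
    expr: pd.DataFrame, hvgs, n_features: int, seed: int = 0, pool: int = 2000
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Positive/negative HVG control matrices with ``n_features`` rows each.

    Positive control: the top ``n_features`` HVGs.  Negative control: a
    seeded uniform sample of ``n_features`` genes from the top ``pool``
    (default 2000) HVGs.  Typical feature counts are 14 (pathway case) and
    113 (TF case).
    """
    hvgs = pd.Index(hvgs)
    if n_features > pool:
        raise PurityError(f"n_features must be <= {pool}")
    if n_features > len(hvgs):
        raise PurityError("n_features exceeds the number of HVGs supplied")
    positive = expr.loc[hvgs[:n_features]]
    rng = np.random.default_rng(seed)
    sample = rng.choice(min(pool, len(hvgs)), size=n_features, replace=False)
    negative = expr.loc[hvgs[:pool][np.sort(sample)]]
    return positive, negative


# ---------------------------------------------------------------------------
# cell-type hierarchy
# ---------------------------------------------------------------------------

#: Default PBMC + HEK cell-line hierarchy, level 0 (every type its own
#: cluster) through level 4 (PBMC vs cell line).
DEFAULT_HIERARCHY: dict[int, dict[str, str]] = {
    0: {t: t for t in (
        "CD4 T cells", "CD8 T cells", "NK cells", "B cells",
        "CD14+ monocytes", "FCGR3A+ monocytes", "dendritic cells", "HEK cells",
    )},
    1: {
        "CD4 T cells": "T cells", "CD8 T cells": "T cells",
        "NK cells": "NK cells", "B cells": "B cells",
        "CD14+ monocytes": "CD14+ monocytes",
        "FCGR3A+ monocytes": "FCGR3A+ monocytes",
        "dendritic cells": "dendritic cells", "HEK cells": "HEK cells",
    },
    2: {
        "CD4 T cells": "T/NK cells", "CD8 T cells": "T/NK cells",
        "NK cells": "T/NK cells", "B cells": "B cells",
        "CD14+ monocytes": "monocytic cells",
        "FCGR3A+ monocytes": "monocytic cells",
        "dendritic cells": "monocytic cells", "HEK cells": "HEK cells",
    },
    3: {
        "CD4 T cells": "lymphoid cells", "CD8 T cells": "lymphoid cells",
        "NK cells": "lymphoid cells", "B cells": "lymphoid cells",
        "CD14+ monocytes": "myeloid cells",
        "FCGR3A+ monocytes": "myeloid cells",
        "dendritic cells": "myeloid cells", "HEK cells": "HEK cells",
    },
    4: {
        "CD4 T cells": "PBMC", "CD8 T cells": "PBMC", "NK cells": "PBMC",
        "B cells": "PBMC", "CD14+ monocytes": "PBMC",
        "FCGR3A+ monocytes": "PBMC", "dendritic cells": "PBMC",
        "HEK cells": "HEK cells",
    },
}


def relabel_hierarchy(cell_types: pd.Series, mapping: dict[str, str] | int) -> pd.Series:
    """Map per-cell types to cluster labels at a hierarchy level.

    ``mapping`` is either an explicit {cell_type: cluster} dict or an integer
    level into :data:`DEFAULT_HIERARCHY`.
    """
    if isinstance(mapping, int):
        if mapping not in DEFAULT_HIERARCHY:
            raise PurityError(f"unknown hierarchy level {mapping}")
        mapping = DEFAULT_HIERARCHY[mapping]
    unmapped = sorted(set(cell_types) - set(mapping))
    if unmapped:
        raise PurityError(f"cell type(s) missing from hierarchy map: {unmapped}")
    return cell_types.map(mapping)


# ---------------------------------------------------------------------------
# embedding and silhouette purity
# ---------------------------------------------------------------------------

def embed_2d(features: pd.DataFrame, seed: int = 0, n_neighbors: int = 15,
             min_dist: float = 0.1) -> pd.DataFrame:
    """UMAP projection of a features × cells matrix to 2-D (cells × [x, y]).

    Deterministic under a fixed seed (single-threaded exact mode).
    """
    import umap

    values = features.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise PurityError("feature matrix contains non-finite values")
    if features.shape[0] < 2 or features.shape[1] < 10:
        raise PurityError("need >= 2 features and >= 10 cells")
    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=min(n_neighbors, features.shape[1] - 1),
        min_dist=min_dist,
        random_state=seed,
        n_jobs=1,
    )
    coords = reducer.fit_transform(values.T)
    return pd.DataFrame(coords, index=features.columns, columns=["x", "y"])


@dataclass
class SilhouetteReport:
    """Per-cell silhouette widths and their cluster/global aggregates."""

    cells: pd.DataFrame  # columns: cluster, a, b, s
    cluster_means: pd.Series
    global_purity: float  # unweighted mean of cluster means (primary)
    cell_weighted_purity: float  # plain mean over cells (secondary)


def silhouette_purity(coords: pd.DataFrame, labels: pd.Series) -> SilhouetteReport:
    """Silhouette-width cluster purity in the embedded space.

    Per cell: a = mean distance to same-cluster cells, b = smallest mean
    distance to any foreign cluster, s = (b − a)/max(a, b) ∈ [−1, 1];
    cells in singleton clusters carry s = 0.  Global purity aggregates the
    per-cluster mean widths with an unweighted mean.
    """
    labels = pd.Series(labels).reindex(coords.index) if not isinstance(labels, pd.Series) \
        else labels.reindex(coords.index)
    if labels.isna().any():
        raise PurityError("every cell needs a cluster label")
    uniq = labels.unique()
    if len(uniq) < 2:
        raise PurityError("silhouette needs at least 2 clusters")
    X = coords.to_numpy(dtype=float)
    D = cdist(X, X)
    lab = labels.to_numpy()
    masks = {c: lab == c for c in uniq}
    a = np.zeros(len(X))
    b = np.zeros(len(X))
    s = np.zeros(len(X))
    for i in range(len(X)):
        own = masks[lab[i]]
        n_own = own.sum()
        foreign_means = [D[i, m].mean() for c, m in masks.items() if c != lab[i]]
        b[i] = min(foreign_means)
        if n_own == 1:  # singleton: silhouette defined as 0
            a[i] = 0.0
            s[i] = 0.0
        else:
            a[i] = D[i, own].sum() / (n_own - 1)
            s[i] = (b[i] - a[i]) / max(a[i], b[i])
    cells = pd.DataFrame({"cluster": lab, "a": a, "b": b, "s": s}, index=coords.index)
    cluster_means = cells.groupby("cluster")["s"].mean()
    return SilhouetteReport(
        cells=cells,
        cluster_means=cluster_means,
        global_purity=float(cluster_means.mean()),
        cell_weighted_purity=float(cells["s"].mean()),
    )


def cross_protocol_consistency(per_protocol: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Pairwise Pearson correlation of per-cell-type mean activities.

    ``per_protocol`` maps a protocol name to a features × cell-types matrix
    of mean activities.  Pairs sharing fewer than 3 features are skipped with
    a warning.  Returns a tidy table (protocol_a, protocol_b, r) with the
    median correlation in ``.attrs["median"]``.
    """
    names = sorted(per_protocol)
    if len(names) < 2:
        raise PurityError("need at least 2 protocols")
    rows = []
    for i, pa in enumerate(names):
        for pb in names[i + 1:]:
            A, B = per_protocol[pa], per_protocol[pb]
            feats = A.index.intersection(B.index)
            cols = A.columns.intersection(B.columns)
            if len(feats) < 3:
                warnings.warn(
                    f"protocols {pa!r}/{pb!r} share {len(feats)} features; pair skipped",
                    stacklevel=2,
                )
                continue
            x = A.loc[feats, cols].to_numpy(dtype=float).ravel()
            y = B.loc[feats, cols].to_numpy(dtype=float).ravel()
            r = float(np.corrcoef(x, y)[0, 1])
            rows.append((pa, pb, r))
    out = pd.DataFrame(rows, columns=["protocol_a", "protocol_b", "r"])
    out.attrs["median"] = float(out["r"].median()) if len(out) else np.nan
    return out
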