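"""Activity statistics over footprint and regulon gene sets.

Five statistics, each exposed as a scikit-learn style transformer plus a thin
module-level function:

============================  =============================================
:class:`FootprintScorer`      weighted sum of logFC/expression × footprint
                              weight (linear-model pathway score)
:class:`RegulonScorer`        analytic rank-quantile normalized enrichment
                              score (NES) over a signed regulon
:class:`ConsensusRegulonScorer`  NES integrated across several networks
                              (squared-NES self-weighted average)
:class:`AUCellScorer`         area under the top-quantile recovery curve on
                              ranked raw counts (rank-only, weight-free)
:class:`GSEAScorer`           weighted running-sum enrichment score with a
                              gene-label permutation null
============================  =============================================

Transformers take genes × samples (or genes × contrasts) DataFrames — the
transcriptomics convention, transposed relative to the sklearn norm — and
return features × samples activity DataFrames.  A column is a *gene
signature*: one cell/sample of normalized expression, or one contrast of
logFC values.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .genesets import FootprintModel, RegulonNetwork, prune_min_targets, subset_footprint


class ScoringError(ValueError):
    pass


def _check_frame(X, min_cols: int = 1) -> pd.DataFrame:
    if not isinstance(X, pd.DataFrame):
        raise ScoringError("expected a genes x samples DataFrame")
    if X.shape[1] < min_cols:
        raise ScoringError(f"need at least {min_cols} column(s), got {X.shape[1]}")
    if not np.isfinite(X.to_numpy(dtype=float)).all():
        raise ScoringError("input matrix contains non-finite values")
    return X


# ---------------------------------------------------------------------------
# gene-wise scaling
# ---------------------------------------------------------------------------

def scale_gene_wise(matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale each gene row to mean 0, sd 1 (sample sd) across columns.

    Constant rows are set to all-zero with a warning; a single-column matrix
    is rejected because the sample sd is undefined.
    """
    matrix = _check_frame(matrix, min_cols=2)
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} constant gene row(s) set to zero during scaling",
            stacklevel=2,
        )
    sd[sd == 0] = 1.0
    out = (values - mean) / sd
    out[flat, :] = 0.0
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


# ---------------------------------------------------------------------------
# footprint (PROGENy-style) weighted sum
# ---------------------------------------------------------------------------

class FootprintScorer(BaseEstimator, TransformerMixin):
    """Pathway activity as a weighted sum of expression × footprint weight.

    Parameters
    ----------
    model
        Footprint model (pathway, gene, weight, responsiveness rank).
    top_n
        Per-pathway footprint size: keep the ``top_n`` most responsive genes,
        or ``"all"``.  Larger footprints trade specificity for robustness to
        low gene coverage.
    scale
        If True each pathway row of the activity matrix is standardized to
        mean 0, sd 1 across samples; rows with zero spread are dropped with a
        warning.

    Attributes
    ----------
    model_ : FootprintModel
        The subsetted model actually scored.
    pathways_ : list[str]
        Pathways retained after intersecting with the measured genes.
    """

    def __init__(self, model: FootprintModel, top_n="all", scale: bool = True):
        self.model = model
        self.top_n = top_n
        self.scale = scale

    def fit(self, X: pd.DataFrame, y=None):
        X = _check_frame(X)
        self.model_ = subset_footprint(self.model, self.top_n)
        measured = set(X.index)
        kept = []
        for pathway, sub in self.model_.entries.groupby("pathway"):
            if measured & set(sub["gene"]):
                kept.append(pathway)
            else:
                warnings.warn(
                    f"pathway {pathway!r} shares no gene with the signature; skipped",
                    stacklevel=2,
                )
        self.pathways_ = kept
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = _check_frame(X)
        entries = self.model_.entries
        scores = {}
        for pathway in self.pathways_:
            sub = entries[entries["pathway"] == pathway]
            common = X.index.intersection(sub["gene"])
            if len(common) == 0:
                warnings.warn(f"pathway {pathway!r} not covered; entry absent", stacklevel=2)
                continue
            w = sub.set_index("gene")["weight"].reindex(common)
            scores[pathway] = w.to_numpy() @ X.loc[common].to_numpy(dtype=float)
        out = pd.DataFrame(scores, index=X.columns).T
        if self.scale and out.shape[1] >= 2:
            out = _scale_rows_drop_flat(out)
        out.attrs["statistic"] = "footprint_sum"
        return out


def _scale_rows_drop_flat(out: pd.DataFrame) -> pd.DataFrame:
    values = out.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(
            f"dropped {int(flat.sum())} zero-variance activity row(s) during scaling",
            stacklevel=3,
        )
    values = (values - values.mean(axis=1, keepdims=True)) / np.where(flat, 1.0, sd)[:, None]
    return pd.DataFrame(values[~flat], index=out.index[~flat], columns=out.columns)


def footprint_scores(
    signatures: pd.DataFrame, model: FootprintModel, scale: bool = True, top_n="all"
) -> pd.DataFrame:
    """Functional wrapper over :class:`FootprintScorer`."""
    return FootprintScorer(model, top_n=top_n, scale=scale).fit(signatures).transform(signatures)


# ---------------------------------------------------------------------------
# analytic rank-quantile NES (VIPER-style regulon enrichment)
# ---------------------------------------------------------------------------

def _signature_quantiles(values: np.ndarray) -> np.ndarray:
    """Map signature values to standard-normal quantiles via average ranks."""
    n = values.shape[0]
    ranks = stats.rankdata(values, method="average")
    return stats.norm.ppf(ranks / (n + 1))


def regulon_nes(
    signature: pd.Series, net: RegulonNetwork, min_targets: int = 4
) -> pd.Series:
    """Normalized enrichment score per TF for one gene signature.

    Genes are ranked by signature value and mapped to standard-normal
    quantiles q_g = Φ⁻¹(rank/(n+1)); then

        NES(tf) = Σ_targets mode·likelihood·q_g / sqrt(Σ likelihood²)

    over the targets present in the signature.  Under an exchangeable null the
    statistic is asymptotically standard normal, so scores are comparable
    across TFs with different regulon sizes.  TFs with fewer than
    ``min_targets`` targets in the signature receive no score.
    """
    values = signature.to_numpy(dtype=float)
    if values.shape[0] < 2:
        raise ScoringError("signature needs at least 2 genes")
    if not np.isfinite(values).all():
        raise ScoringError("signature contains non-finite values")
    q = pd.Series(_signature_quantiles(values), index=signature.index)
    out = {}
    for tf, sub in net.edges.groupby("tf"):
        hit = sub[sub["target"].isin(signature.index)]
        if hit["target"].nunique() < min_targets:
            continue
        qs = q.reindex(hit["target"]).to_numpy()
        mode = hit["mode"].to_numpy(dtype=float)
        lik = hit["likelihood"].to_numpy(dtype=float)
        out[tf] = float((mode * lik * qs).sum() / math.sqrt((lik**2).sum()))
    return pd.Series(out, dtype=float).sort_index()


class RegulonScorer(BaseEstimator, TransformerMixin):
    """TF activity as the analytic rank-quantile NES, column by column.

    Parameters
    ----------
    network
        Signed, likelihood-weighted regulon network.
    min_targets
        TFs with fewer measured targets are discarded (default 4).
    scale_genes
        Gene-wise standardize the input matrix before ranking (the standard
        preprocessing for single-sample matrices; contrasts of logFCs are
        typically scored unscaled).

    Attributes
    ----------
    network_ : RegulonNetwork
        The network pruned against the measured genes.
    features_ : list[str]
        TFs that can receive a score.
    """

    def __init__(self, network: RegulonNetwork, min_targets: int = 4, scale_genes: bool = False):
        self.network = network
        self.min_targets = min_targets
        self.scale_genes = scale_genes

    def fit(self, X: pd.DataFrame, y=None):
        X = _check_frame(X)
        pruned = prune_min_targets(self.network, X.index, self.min_targets)
        if pruned is None:
            raise ScoringError("no TF retains enough measured targets")
        self.network_ = pruned
        self.features_ = pruned.tfs
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = _check_frame(X)
        if self.scale_genes and X.shape[1] >= 2:
            X = scale_gene_wise(X)
        values = X.to_numpy(dtype=float)
        n = values.shape[0]
        # column-wise average ranks -> standard-normal quantiles
        ranks = stats.rankdata(values, method="average", axis=0)
        q = stats.norm.ppf(ranks / (n + 1))
        gene_pos = {g: i for i, g in enumerate(X.index)}
        rows, index = [], []
        for tf, sub in self.network_.edges.groupby("tf"):
            hit = sub[sub["target"].isin(gene_pos)]
            if hit["target"].nunique() < self.min_targets:
                continue
            pos = np.array([gene_pos[g] for g in hit["target"]])
            w = hit["mode"].to_numpy(dtype=float) * hit["likelihood"].to_numpy(dtype=float)
            denom = math.sqrt(float((hit["likelihood"].to_numpy(dtype=float) ** 2).sum()))
            rows.append(w @ q[pos, :] / denom)
            index.append(tf)
        out = pd.DataFrame(np.asarray(rows), index=index, columns=X.columns)
        out.attrs["statistic"] = "nes"
        return out


# ---------------------------------------------------------------------------
# multi-network consensus NES (metaVIPER-style)
# ---------------------------------------------------------------------------

def consensus_nes(per_network) -> pd.Series:
    """Integrate per-network NES values into one consensus score per TF.

    ``per_network`` is an iterable of ``(network_name, Series tf -> NES)``.
    The consensus is the squared-NES self-weighted average

        consensus(tf) = Σ_k NES_k² · NES_k / Σ_k NES_k²

    over the networks reporting that TF, which favours networks making a
    confident (large-magnitude) call in either direction.  A TF whose every
    NES is 0 gets consensus 0; a TF absent from all networks is absent.
    """
    pooled: dict[str, list[float]] = {}
    for _name, scores in per_network:
        for tf, v in scores.items():
            pooled.setdefault(tf, []).append(float(v))
    out = {}
    for tf, vals in pooled.items():
        arr = np.asarray(vals, dtype=float)
        denom = (arr**2).sum()
        out[tf] = float((arr**3).sum() / denom) if denom > 0 else 0.0
    return pd.Series(out, dtype=float).sort_index()


class ConsensusRegulonScorer(BaseEstimator, TransformerMixin):
    """NES consensus across several regulon networks (e.g. tissue-specific).

    Each network is scored independently with :class:`RegulonScorer`; per-TF
    scores are integrated with :func:`consensus_nes`.  A network in which a
    TF fails the minimum-target filter simply does not vote for that TF.
    """

    def __init__(self, networks, min_targets: int = 4, scale_genes: bool = False):
        self.networks = networks
        self.min_targets = min_targets
        self.scale_genes = scale_genes

    def fit(self, X: pd.DataFrame, y=None):
        X = _check_frame(X)
        self.scorers_ = []
        for net in self.networks:
            try:
                scorer = RegulonScorer(net, self.min_targets, self.scale_genes).fit(X)
            except ScoringError:
                continue
            self.scorers_.append(scorer)
        if not self.scorers_:
            raise ScoringError("no network retains any scorable TF")
        self.features_ = sorted({tf for s in self.scorers_ for tf in s.features_})
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = _check_frame(X)
        per_net = [(s.network_.name, s.transform(X)) for s in self.scorers_]
        cols = {}
        for c in X.columns:
            cols[c] = consensus_nes(
                (name, frame[c].dropna()) for name, frame in per_net
            )
        out = pd.DataFrame(cols)
        out.attrs["statistic"] = "consensus_nes"
        return out


# ---------------------------------------------------------------------------
# AUCell-style recovery-curve AUC
# ---------------------------------------------------------------------------

def _recovery_auc(positions: np.ndarray, k: int, set_size: int) -> float:
    """Area under the step recovery curve, normalized to the attainable max.

    ``positions`` are 1-based ranks of gene-set members that landed inside
    the top-``k`` window.  Area = Σ_{i=1..k} (#members among top i); maximum
    area puts all m = min(set_size, k) members at ranks 1..m.
    """
    area = float(np.sum(k - positions + 1))
    m = min(set_size, k)
    max_area = float(sum(min(i, m) for i in range(1, k + 1)))
    return area / max_area


class AUCellScorer(BaseEstimator, TransformerMixin):
    """Gene-set enrichment in the top quantile of a cell's count ranking.

    Per cell, genes are sorted by decreasing raw count (ties broken by input
    row order — a fixed, seed-independent rule) and the enrichment of a gene
    set is the area under its recovery curve within the top
    ``ceil(quantile · n_genes)`` ranks, divided by the maximum attainable
    area, giving a score in [0, 1].  Ranks only: modes, likelihoods and
    footprint weights are ignored, and scores are invariant to any monotone
    transform of the counts within a cell.

    Parameters
    ----------
    gene_sets
        A RegulonNetwork, FootprintModel, or mapping name → member genes.
    quantile
        Fraction of the ranking forming the top window (default 0.05).
    """

    def __init__(self, gene_sets, quantile: float = 0.05):
        self.gene_sets = gene_sets
        self.quantile = quantile

    def _memberships(self) -> dict[str, list[str]]:
        if isinstance(self.gene_sets, (RegulonNetwork, FootprintModel)):
            return self.gene_sets.to_gene_sets()
        return {k: list(v) for k, v in self.gene_sets.items()}

    def fit(self, X: pd.DataFrame, y=None):
        X = _check_frame(X)
        if not (0 < self.quantile <= 1):
            raise ScoringError("quantile must lie in (0, 1]")
        measured = set(X.index)
        self.sets_ = {}
        for name, members in self._memberships().items():
            inside = [g for g in dict.fromkeys(members) if g in measured]
            if inside:
                self.sets_[name] = inside
            else:
                warnings.warn(f"gene set {name!r} has no measured member; skipped", stacklevel=2)
        if not self.sets_:
            raise ScoringError("no gene set overlaps the measured genes")
        self.features_ = sorted(self.sets_)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = _check_frame(X)
        counts = X.to_numpy(dtype=float)
        if (counts < 0).any():
            raise ScoringError("counts must be non-negative")
        n_genes = X.shape[0]
        k = math.ceil(self.quantile * n_genes)
        # stable mergesort on -counts keeps input row order on ties
        order = np.argsort(-counts, axis=0, kind="stable")
        rank_of = np.empty_like(order)
        rows = np.arange(n_genes)[:, None]
        np.put_along_axis(rank_of, order, rows + 1, axis=0)  # 1-based ranks
        gene_pos = {g: i for i, g in enumerate(X.index)}
        out = np.zeros((len(self.features_), X.shape[1]))
        for i, name in enumerate(self.features_):
            idx = np.array([gene_pos[g] for g in self.sets_[name]])
            ranks = rank_of[idx, :]  # (set_size, n_cells)
            for j in range(X.shape[1]):
                pos = ranks[:, j]
                out[i, j] = _recovery_auc(pos[pos <= k], k, len(idx))
        result = pd.DataFrame(out, index=self.features_, columns=X.columns)
        result.attrs["statistic"] = "auc"
        return result


def aucell_scores(counts: pd.DataFrame, gene_sets, quantile: float = 0.05) -> pd.DataFrame:
    """Functional wrapper over :class:`AUCellScorer`."""
    return AUCellScorer(gene_sets, quantile).fit(counts).transform(counts)


# ---------------------------------------------------------------------------
# permutation GSEA
# ---------------------------------------------------------------------------

def _running_es(stat_sorted: np.ndarray, member_mask: np.ndarray) -> float:
    """Signed maximum deviation of the weighted KS running sum (exponent 1)."""
    n = stat_sorted.shape[0]
    n_mem = int(member_mask.sum())
    hit = np.where(member_mask, np.abs(stat_sorted), 0.0)
    nr = hit.sum()
    hit = hit / nr if nr > 0 else np.where(member_mask, 1.0 / max(n_mem, 1), 0.0)
    n_miss = n - n_mem
    miss = np.where(member_mask, 0.0, 1.0 / n_miss) if n_miss > 0 else np.zeros(n)
    running = np.cumsum(hit - miss)
    return float(running[np.argmax(np.abs(running))])


def gsea_scores(
    contrast: pd.Series,
    gene_sets: dict,
    n_permutations: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation GSEA of unsigned gene sets against one logFC contrast.

    The enrichment score (ES) is the maximum deviation from zero of the
    weighted running sum (gene statistic = logFC, weight exponent 1).  The
    null is built from ``n_permutations`` gene-label shuffles; NES = ES
    divided by the mean |ES| of same-sign permutation scores, and p is the
    same-sign permutation tail fraction (with add-one smoothing).

    Returns a DataFrame indexed by set name with columns es, nes, pval, size.
    """
    if n_permutations < 1:
        raise ScoringError("n_permutations must be >= 1")
    values = contrast.to_numpy(dtype=float)
    order = np.argsort(-values, kind="stable")
    stat_sorted = values[order]
    genes_sorted = contrast.index[order]
    pos_of = {g: i for i, g in enumerate(genes_sorted)}
    rng = np.random.default_rng(seed)
    n = len(values)
    rows = []
    for name, members in gene_sets.items():
        inside = [pos_of[g] for g in dict.fromkeys(members) if g in pos_of]
        if not inside:
            warnings.warn(f"gene set {name!r} shares no gene with the contrast; skipped",
                          stacklevel=2)
            continue
        mask = np.zeros(n, dtype=bool)
        mask[inside] = True
        es = _running_es(stat_sorted, mask)
        m = len(inside)
        perm = np.empty(n_permutations)
        pmask = np.zeros(n, dtype=bool)
        for b in range(n_permutations):
            pmask[:] = False
            pmask[rng.choice(n, size=m, replace=False)] = True
            perm[b] = _running_es(stat_sorted, pmask)
        same = perm[np.sign(perm) == np.sign(es)] if es != 0 else perm
        if len(same) == 0:
            nes = np.nan
            p = 1.0 / (n_permutations + 1)
        else:
            nes = es / np.mean(np.abs(same))
            p = (1 + int(np.sum(np.abs(same) >= abs(es)))) / (1 + len(same))
        rows.append((name, es, nes, p, m))
    return pd.DataFrame(rows, columns=["set", "es", "nes", "pval", "size"]).set_index("set")


def write_activity_tsv(activity: pd.DataFrame, path) -> None:
    """Write an activity matrix as TSV with a statistic-tag header line."""
    with open(path, "w") as fh:
        fh.write(f"# statistic: {activity.attrs.get('statistic', 'unknown')}\n")
        activity.to_csv(fh, sep="\t")


def read_activity_tsv(path) -> pd.DataFrame:
    """Read an activity matrix written by :func:`write_activity_tsv`."""
    with open(path) as fh:
        header = fh.readline().strip()
        out = pd.read_csv(fh, sep="\t", index_col=0)
    if header.startswith("# statistic:"):
        out.attrs["statistic"] = header.split(":", 1)[1].strip()
    return out


class GSEAScorer(BaseEstimator, TransformerMixin):
    """Permutation-GSEA NES per gene set, applied contrast by contrast."""

    def __init__(self, gene_sets: dict, n_permutations: int = 1000, seed: int = 0):
        self.gene_sets = gene_sets
        self.n_permutations = n_permutations
        self.seed = seed

    def fit(self, X: pd.DataFrame, y=None):
        X = _check_frame(X)
        measured = set(X.index)
        self.sets_ = {
            name: members
            for name, members in self.gene_sets.items()
            if measured & set(members)
        }
        if not self.sets_:
            raise ScoringError("no gene set overlaps the measured genes")
        self.features_ = sorted(self.sets_)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = _check_frame(X)
        cols = {}
        for c in X.columns:
            table = gsea_scores(X[c], self.sets_, self.n_permutations, self.seed)
            cols[c] = table["nes"]
        out = pd.DataFrame(cols)
        out.attrs["statistic"] = "gsea_nes"
        return out
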