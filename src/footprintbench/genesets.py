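"""Gene-set resources: signed TF regulon networks and pathway footprint models.

Two resource shapes feed every activity statistic in this package:

* a :class:`RegulonNetwork` — signed, likelihood-weighted TF→target edges with
  curated A–E confidence grades (the DoRothEA/GTEx resource shape);
* a :class:`FootprintModel` — pathway→(gene, weight, responsiveness rank)
  tables supporting top-N subsetting of the most perturbation-responsive
  footprint genes (the PROGENy resource shape).

Gene identifiers are opaque, case-sensitive strings; no symbol/ID mapping is
performed here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONFIDENCE_LEVELS = ("A", "B", "C", "D", "E")

EDGE_COLUMNS = ("tf", "target", "mode", "likelihood")
FOOTPRINT_COLUMNS = ("pathway", "gene", "weight", "responsiveness_rank")


class GeneSetError(ValueError):
    """Malformed or unusable gene-set resource."""


class EmptyNetworkError(GeneSetError):
    """A filter removed every TF; downstream benchmarks cannot proceed."""


@dataclass(frozen=True)
class RegulonNetwork:
    """Signed TF→target network.

    Parameters
    ----------
    edges
        DataFrame with columns ``tf, target, mode, likelihood, confidence``;
        mode ∈ {−1, +1}, likelihood ∈ (0, 1], confidence ∈ A–E.
    name
        Label, e.g. a tissue name when several networks feed a consensus score.
    tf_confidence
        Optional per-TF summary confidence. When absent, the summary level of
        a TF is the best (closest to A) confidence among its edges.
    """

    edges: pd.DataFrame
    name: str = "network"
    tf_confidence: dict[str, str] | None = field(default=None)

    def __post_init__(self) -> None:
        edges = self.edges
        missing = [c for c in (*EDGE_COLUMNS, "confidence") if c not in edges.columns]
        if missing:
            raise GeneSetError(f"network table is missing column(s): {missing}")
        if len(edges) == 0:
            raise EmptyNetworkError("regulon network has no edges")
        bad_mode = ~edges["mode"].isin([-1, 1])
        if bad_mode.any():
            raise GeneSetError(
                f"mode must be -1 or +1; offending rows: {edges.index[bad_mode].tolist()[:5]}"
            )
        lik = edges["likelihood"].to_numpy(dtype=float)
        if np.any(~np.isfinite(lik)) or np.any(lik <= 0) or np.any(lik > 1):
            raise GeneSetError("likelihood must lie in (0, 1]")
        bad_conf = ~edges["confidence"].isin(CONFIDENCE_LEVELS)
        if bad_conf.any():
            raise GeneSetError(
                f"confidence must be one of {CONFIDENCE_LEVELS}; got "
                f"{sorted(edges.loc[bad_conf, 'confidence'].unique())}"
            )
        dup = edges.duplicated(subset=["tf", "target"])
        if dup.any():
            pairs = edges.loc[dup, ["tf", "target"]].itertuples(index=False, name=None)
            raise GeneSetError(f"duplicate (tf, target) pairs: {sorted(set(pairs))}")

    @property
    def tfs(self) -> list[str]:
        return sorted(self.edges["tf"].unique())

    @property
    def n_tfs(self) -> int:
        return self.edges["tf"].nunique()

    def regulon(self, tf: str) -> pd.DataFrame:
        """Edges of a single TF."""
        return self.edges[self.edges["tf"] == tf]

    def summary_confidence(self) -> pd.Series:
        """Per-TF summary confidence level.

        Uses the supplied per-TF level when available, otherwise the leading
        (best) confidence level among the TF's interactions.
        """
        best = self.edges.groupby("tf")["confidence"].min()
        if self.tf_confidence is not None:
            supplied = pd.Series(self.tf_confidence)
            best.update(supplied[supplied.index.isin(best.index)])
        return best

    def to_gene_sets(self) -> dict[str, list[str]]:
        """Unsigned membership view (used by AUCell-style scoring)."""
        return {tf: sub["target"].tolist() for tf, sub in self.edges.groupby("tf")}


@dataclass(frozen=True)
class FootprintModel:
    """Pathway footprint model: per-pathway weighted, responsiveness-ranked genes."""

    entries: pd.DataFrame

    def __post_init__(self) -> None:
        entries = self.entries
        missing = [c for c in FOOTPRINT_COLUMNS if c not in entries.columns]
        if missing:
            raise GeneSetError(f"footprint table is missing column(s): {missing}")
        if len(entries) == 0:
            raise GeneSetError("footprint model has no entries")
        w = entries["weight"].to_numpy(dtype=float)
        if np.any(~np.isfinite(w)):
            raise GeneSetError("footprint weights must be finite")
        ranks = entries["responsiveness_rank"]
        if (ranks < 1).any():
            raise GeneSetError("responsiveness_rank must be >= 1")
        dup = entries.duplicated(subset=["pathway", "responsiveness_rank"])
        if dup.any():
            raise GeneSetError("responsiveness_rank must be unique within a pathway")

    @property
    def pathways(self) -> list[str]:
        return sorted(self.entries["pathway"].unique())

    def to_gene_sets(self) -> dict[str, list[str]]:
        return {p: sub["gene"].tolist() for p, sub in self.entries.groupby("pathway")}


def load_regulon_network(path, name: str | None = None) -> RegulonNetwork:
    """Read a regulon network from a tab-separated table.

    Required columns: ``tf, target, mode, likelihood``; ``confidence`` is
    optional (default E) and ``likelihood`` values left blank default to 1.
    """
    edges = pd.read_csv(path, sep="\t")
    missing = [c for c in ("tf", "target", "mode") if c not in edges.columns]
    if missing:
        raise GeneSetError(f"network table {path} is missing column(s): {missing}")
    if "likelihood" not in edges.columns:
        edges["likelihood"] = 1.0
    edges["likelihood"] = edges["likelihood"].fillna(1.0)
    if "confidence" not in edges.columns:
        edges["confidence"] = "E"
    edges["confidence"] = edges["confidence"].fillna("E")
    return RegulonNetwork(edges=edges.reset_index(drop=True), name=name or str(path))


def load_footprint_model(path) -> FootprintModel:
    """Read a footprint model from a tab-separated table."""
    entries = pd.read_csv(path, sep="\t")
    return FootprintModel(entries=entries.reset_index(drop=True))


def load_gmt(path, name: str | None = None) -> RegulonNetwork:
    """Read unsigned gene sets in GMT format (set, description, members...).

    Members become mode=+1, likelihood=1 edges so that unsigned collections
    plug into the same scoring surface as curated regulons.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            set_name, _desc, *members = parts
            for g in members:
                if g:
                    rows.append((set_name, g, 1, 1.0, "E"))
    if not rows:
        raise GeneSetError(f"no gene sets found in {path}")
    edges = pd.DataFrame(rows, columns=[*EDGE_COLUMNS, "confidence"])
    return RegulonNetwork(edges=edges, name=name or str(path))


def filter_by_confidence(net: RegulonNetwork, levels) -> RegulonNetwork:
    """Keep only TFs whose summary confidence is in ``levels`` (e.g. {"A","B"}).

    Confidence combinations act at the TF level: a TF's summary level is the
    supplied per-TF grade when present, else its best edge grade.
    """
    levels = set(levels)
    if not levels or not levels <= set(CONFIDENCE_LEVELS):
        raise GeneSetError(f"levels must be a non-empty subset of {CONFIDENCE_LEVELS}")
    summary = net.summary_confidence()
    keep_tfs = summary.index[summary.isin(levels)]
    edges = net.edges[net.edges["tf"].isin(keep_tfs)].reset_index(drop=True)
    if len(edges) == 0:
        raise EmptyNetworkError(
            f"no TF in network {net.name!r} has confidence in {sorted(levels)}"
        )
    return RegulonNetwork(edges=edges, name=net.name, tf_confidence=net.tf_confidence)


def prune_min_targets(
    net: RegulonNetwork, measured_genes, min_targets: int = 4
) -> RegulonNetwork | None:
    """Drop TFs with fewer than ``min_targets`` targets among measured genes.

    Edges to unmeasured genes are retained for surviving TFs — pruning decides
    TF inclusion only; each scorer intersects with its signature again.
    Returns None when every TF is pruned away.
    """
    measured = set(measured_genes)
    if not measured:
        raise GeneSetError("measured_genes must be non-empty")
    counts = (
        net.edges[net.edges["target"].isin(measured)].groupby("tf")["target"].nunique()
    )
    keep = counts.index[counts >= min_targets]
    edges = net.edges[net.edges["tf"].isin(keep)].reset_index(drop=True)
    if len(edges) == 0:
        return None
    return RegulonNetwork(edges=edges, name=net.name, tf_confidence=net.tf_confidence)


def subset_footprint(model: FootprintModel, top_n) -> FootprintModel:
    """Per pathway, keep the ``top_n`` most perturbation-responsive genes.

    ``top_n="all"`` is the identity; pathways with fewer entries than
    ``top_n`` are returned whole.
    """
    if top_n == "all":
        return model
    top_n = int(top_n)
    if top_n < 1:
        raise GeneSetError("top_n must be >= 1 or 'all'")
    entries = model.entries[model.entries["responsiveness_rank"] <= top_n]
    return FootprintModel(entries=entries.reset_index(drop=True))
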