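"""Perturbation-recovery benchmark: contrasts, coverage masking, ROC/PR.

A perturbation compendium is summarized into a genes × contrasts matrix of
logFC values (perturbed-group mean minus control-group mean of normalized
log expression).  A logFC of exactly 0 encodes a gene that is *not covered*
by the experiment, which is what lets gene coverage be lowered artificially:
:func:`mask_coverage` zeroes random positions until a target number of
covered genes per contrast remains.

Activity scores are evaluated for perturbation recovery by orienting scores
(inhibition/knockdown contrasts are sign-flipped so the perturbed feature
should always score highest), labelling the perturbed feature of each
contrast as the positive class and every other feature–contrast score as
negative, and summarizing with ROC and precision-recall curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn import metrics as skm


class BenchmarkError(ValueError):
    pass


@dataclass(frozen=True)
class PerturbationRecord:
    """One perturbation experiment: its target, direction and sample groups."""

    contrast_id: str
    target: str
    direction: int  # +1 activation, -1 inhibition/knockdown
    kind: str = "tf"  # "tf" or "pathway"
    perturbed_samples: tuple = ()
    control_samples: tuple = ()

    def __post_init__(self):
        if self.direction not in (-1, 1):
            raise BenchmarkError(f"direction must be -1 or +1, got {self.direction}")
        if self.perturbed_samples or self.control_samples:
            if not self.perturbed_samples or not self.control_samples:
                raise BenchmarkError(
                    f"contrast {self.contrast_id}: both sample groups must be non-empty"
                )
            if set(self.perturbed_samples) & set(self.control_samples):
                raise BenchmarkError(
                    f"contrast {self.contrast_id}: sample groups overlap"
                )


def load_perturbation_metadata(path) -> list[PerturbationRecord]:
    """Read perturbation metadata from CSV.

    Expected columns: ``id, target, direction, kind, sample_id, group`` with
    group in {perturbed, control} — one row per sample, mirroring compendium
    metadata tables that annotate each GEO sample with its experiment,
    perturbation target and direction.
    """
    df = pd.read_csv(path)
    required = {"id", "target", "direction", "sample_id", "group"}
    missing = required - set(df.columns)
    if missing:
        raise BenchmarkError(f"metadata table is missing column(s): {sorted(missing)}")
    records = []
    for cid, sub in df.groupby("id", sort=False):
        pert = tuple(sub.loc[sub["group"] == "perturbed", "sample_id"])
        ctrl = tuple(sub.loc[sub["group"] == "control", "sample_id"])
        records.append(
            PerturbationRecord(
                contrast_id=str(cid),
                target=str(sub["target"].iloc[0]),
                direction=int(sub["direction"].iloc[0]),
                kind=str(sub["kind"].iloc[0]) if "kind" in sub.columns else "tf",
                perturbed_samples=pert,
                control_samples=ctrl,
            )
        )
    return records


def write_perturbation_metadata(records, path) -> None:
    rows = []
    for r in records:
        for s in r.perturbed_samples:
            rows.append((r.contrast_id, r.target, r.direction, r.kind, s, "perturbed"))
        for s in r.control_samples:
            rows.append((r.contrast_id, r.target, r.direction, r.kind, s, "control"))
    pd.DataFrame(
        rows, columns=["id", "target", "direction", "kind", "sample_id", "group"]
    ).to_csv(path, index=False)


def expand_records_to_cells(records, cell_ids) -> list[PerturbationRecord]:
    """Rewrite sample groups of bulk-level records to simulated-cell ids.

    Simulated cells are named ``<bulk sample>|cell<i>`` (see
    :func:`footprintbench.simulate.simulate_compendium_cells`); each record's
    sample groups are replaced by the cells originating from them.  Records
    whose groups end up empty (all their cells were filtered) are dropped.
    """
    by_origin: dict[str, list[str]] = {}
    for cid in cell_ids:
        origin = str(cid).rsplit("|", 1)[0]
        by_origin.setdefault(origin, []).append(cid)
    out = []
    for r in records:
        pert = tuple(c for s in r.perturbed_samples for c in by_origin.get(s, []))
        ctrl = tuple(c for s in r.control_samples for c in by_origin.get(s, []))
        if pert and ctrl:
            out.append(
                PerturbationRecord(r.contrast_id, r.target, r.direction, r.kind, pert, ctrl)
            )
    return out


def coverage(contrasts: pd.DataFrame) -> pd.Series:
    """Covered (nonzero-logFC) gene count per contrast column."""
    return (contrasts != 0).sum(axis=0)


def _group_means(expr: pd.DataFrame, record: PerturbationRecord) -> pd.Series:
    for s in (*record.perturbed_samples, *record.control_samples):
        if s not in expr.columns:
            raise BenchmarkError(
                f"contrast {record.contrast_id}: sample {s!r} missing from matrix"
            )
    pert = expr[list(record.perturbed_samples)].mean(axis=1)
    ctrl = expr[list(record.control_samples)].mean(axis=1)
    return pert - ctrl


def build_expression_contrasts(expr: pd.DataFrame, records) -> pd.DataFrame:
    """Genes × contrasts logFC matrix from normalized log expression.

    logFC(g, contrast) = mean over perturbed samples − mean over controls.
    """
    cols = {r.contrast_id: _group_means(expr, r) for r in records}
    return pd.DataFrame(cols)


def build_activity_contrasts(activities: pd.DataFrame, records) -> pd.DataFrame:
    """Feature-wise perturbed-minus-control mean difference of activity scores."""
    return build_expression_contrasts(activities, records)


def mask_coverage(
    contrasts: pd.DataFrame, target: int, n_reps: int = 25, seed: int = 0
) -> list[pd.DataFrame]:
    """Randomly zero logFC entries until each contrast covers ``target`` genes.

    Positions to keep are drawn uniformly and independently per contrast and
    per replicate; surviving values are never altered, only positions are
    zeroed.  Returns ``n_reps`` masked copies.
    """
    nz_per_contrast = coverage(contrasts)
    short = nz_per_contrast[nz_per_contrast < target]
    if len(short):
        raise BenchmarkError(
            f"coverage target {target} exceeds available covered genes in "
            f"contrast(s) {short.index.tolist()[:5]}"
        )
    rng = np.random.default_rng(seed)
    reps = []
    values = contrasts.to_numpy(dtype=float)
    for _ in range(n_reps):
        masked = np.zeros_like(values)
        for j in range(values.shape[1]):
            nz = np.flatnonzero(values[:, j])
            keep = rng.choice(nz, size=target, replace=False)
            masked[keep, j] = values[keep, j]
        reps.append(pd.DataFrame(masked, index=contrasts.index, columns=contrasts.columns))
    return reps


def _records_by_contrast(records) -> dict[str, PerturbationRecord]:
    return {r.contrast_id: r for r in records}


def orient_scores(activity_contrasts: pd.DataFrame, records) -> pd.DataFrame:
    """Sign-flip columns of inhibition/knockdown contrasts (direction −1).

    After orientation the perturbed feature should, for an ideal scorer, carry
    the highest activity change in its own contrast regardless of the
    perturbation's direction.
    """
    by_id = _records_by_contrast(records)
    out = activity_contrasts.copy()
    for c in out.columns:
        if c not in by_id:
            raise BenchmarkError(f"contrast {c!r} has no perturbation record")
        if by_id[c].direction == -1:
            out[c] = -out[c]
    return out


def qc_filter_perturbations(contrasts: pd.DataFrame, records) -> list[PerturbationRecord]:
    """Drop knockdown records whose target gene's own logFC is positive.

    A knockdown that failed to lower the target's own expression is an
    implausible experiment.  Applies only to direction −1 records; a record
    whose target gene is unmeasured is kept with a warning.  The boundary
    logFC = 0 is kept (strict > 0 drops).
    """
    kept = []
    for r in records:
        if r.direction != -1:
            kept.append(r)
            continue
        if r.contrast_id not in contrasts.columns or r.target not in contrasts.index:
            warnings.warn(
                f"contrast {r.contrast_id}: target {r.target!r} not measured; kept",
                stacklevel=2,
            )
            kept.append(r)
            continue
        if contrasts.at[r.target, r.contrast_id] > 0:
            continue
        kept.append(r)
    return kept


@dataclass
class BenchmarkResult:
    """Scores/labels of one benchmark replicate plus its ROC/PR summaries."""

    scores: np.ndarray
    labels: np.ndarray
    auroc: float
    auprc: float
    roc_points: pd.DataFrame
    pr_points: pd.DataFrame
    tf_coverage: int
    excluded_contrasts: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)


def evaluate_recovery(oriented: pd.DataFrame, records, meta: dict | None = None) -> BenchmarkResult:
    """ROC/PR evaluation of perturbation recovery.

    For each contrast whose perturbed target is among the scored features,
    the target's score is a positive-class observation and every other
    feature's score in that contrast is negative.  Contrasts whose target is
    not scored are excluded and reported; ``tf_coverage`` counts the distinct
    perturbed features that *are* scored.  AUROC is trapezoidal (equivalently
    pairwise concordance with ties counted ½); AUPRC is step-integrated
    (average precision).
    """
    by_id = _records_by_contrast(records)
    scores, labels = [], []
    covered_targets, excluded = set(), []
    for c in oriented.columns:
        r = by_id.get(c)
        if r is None:
            raise BenchmarkError(f"contrast {c!r} has no perturbation record")
        col = oriented[c].dropna()
        if r.target not in col.index:
            excluded.append(c)
            continue
        covered_targets.add(r.target)
        scores.extend(col.to_numpy(dtype=float))
        labels.extend((col.index == r.target).astype(int))
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if labels.sum() == 0 or labels.sum() == len(labels):
        raise BenchmarkError("need both positive and negative observations")
    fpr, tpr, roc_thr = skm.roc_curve(labels, scores)
    prec, rec, pr_thr = skm.precision_recall_curve(labels, scores)
    return BenchmarkResult(
        scores=scores,
        labels=labels,
        auroc=float(skm.auc(fpr, tpr)),
        auprc=float(skm.average_precision_score(labels, scores)),
        roc_points=pd.DataFrame({"fpr": fpr, "tpr": tpr}),
        pr_points=pd.DataFrame({"recall": rec, "precision": prec}),
        tf_coverage=len(covered_targets),
        excluded_contrasts=excluded,
        meta=dict(meta or {}),
    )


def results_to_frame(results) -> pd.DataFrame:
    """Tidy one-row-per-result table (metadata columns + auroc/auprc)."""
    rows = []
    for r in results:
        row = dict(r.meta)
        row.update(auroc=r.auroc, auprc=r.auprc, tf_coverage=r.tf_coverage)
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_grid(
    results,
    group_keys=("mu", "n_cells", "setting"),
    replicate_key: str = "replicate",
    bulk_key: str = "is_bulk",
) -> pd.DataFrame:
    """Mean/sd AUROC per parameter-grid cell, plus single-cell − bulk deltas.

    ``results`` is a collection of :class:`BenchmarkResult` (their ``meta``
    dicts supply the grid coordinates) or an equivalent tidy DataFrame.  Rows
    flagged by ``bulk_key`` provide the bulk baseline for their ``setting``;
    grid cells without a bulk baseline report a missing difference.
    """
    df = results if isinstance(results, pd.DataFrame) else results_to_frame(results)
    if df.empty:
        raise BenchmarkError("no results to summarize")
    keys = [k for k in group_keys if k in df.columns]
    if bulk_key in df.columns:
        sc = df[~df[bulk_key].astype(bool)]
        bulk = df[df[bulk_key].astype(bool)]
    else:
        sc, bulk = df, df.iloc[0:0]
    grouped = sc.groupby(keys, dropna=False)["auroc"]
    summary = grouped.agg(mean_auroc="mean", sd_auroc="std", n_replicates="count")
    summary = summary.reset_index()
    if len(bulk):
        bulk_keys = [k for k in keys if k not in ("mu", "n_cells")]
        baseline = bulk.groupby(bulk_keys, dropna=False)["auroc"].mean() if bulk_keys \
            else pd.Series({(): bulk["auroc"].mean()})
        if bulk_keys:
            summary = summary.merge(
                baseline.rename("bulk_auroc").reset_index(), on=bulk_keys, how="left"
            )
        else:
            summary["bulk_auroc"] = bulk["auroc"].mean()
        summary["mean_diff_vs_bulk"] = summary["mean_auroc"] - summary["bulk_auroc"]
    else:
        summary["bulk_auroc"] = np.nan
        summary["mean_diff_vs_bulk"] = np.nan
    # best setting per remaining grid cell
    cell_keys = [k for k in keys if k != "setting"]
    if "setting" in keys and cell_keys:
        best = summary.loc[summary.groupby(cell_keys)["mean_auroc"].idxmax(),
                           cell_keys + ["setting"]]
        best = best.rename(columns={"setting": "best_setting"})
        summary = summary.merge(best, on=cell_keys, how="left")
    return summary
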