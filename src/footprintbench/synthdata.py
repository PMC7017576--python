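"""Ground-truth-bearing synthetic inputs for every benchmark stage.

Three generators with a shared configuration:

* :func:`generate_regulons` — a random signed TF→target network and the
  paired pathway footprint model (same memberships, weight = mode);
* :func:`generate_perturbation_compendium` — bulk perturbation experiments
  (negative-binomial counts; perturbed profiles shift the target's direct
  regulon by a known log2 effect) plus per-experiment metadata records;
* :func:`generate_mixture_population` — a multi-cell-type single-cell count
  matrix in which each type's active TFs shift their regulons, with cell
  annotations ready for hierarchy relabelling.

Effects apply to direct targets only, so the ground truth for recovery
metrics is unambiguous.  Generators are fully determined by their seed and
write the same plain-text formats the rest of the package reads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .benchmark import PerturbationRecord
from .genesets import CONFIDENCE_LEVELS, FootprintModel, RegulonNetwork
from .simulate import draw_library_sizes


class SynthError(ValueError):
    pass


@dataclass(frozen=True)
class SynthConfig:
    """Synthetic-study conditions.

    effect is the multiplicative shift of a direct target's mean on log2
    scale: a perturbed target's mean is multiplied by 2^(effect·mode·direction).
    baseline_mean/dispersion parametrize the negative-binomial bulk counts
    (var = m + dispersion·m²).
    """

    n_genes: int = 2000
    n_tfs: int = 20
    targets_per_tf: int = 25
    activating_fraction: float = 0.75
    effect: float = 2.0
    baseline_mean: float = 50.0
    dispersion: float = 0.2
    n_experiments: int = 30
    direction_mix: float = 0.5
    samples_per_group: int = 3
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.activating_fraction <= 1:
            raise SynthError("activating_fraction must lie in [0, 1]")
        if self.effect < 0:
            raise SynthError("effect must be >= 0")
        if self.dispersion <= 0:
            raise SynthError("dispersion must be > 0")
        if self.targets_per_tf < 1:
            raise SynthError("targets_per_tf must be >= 1")
        if not 0 <= self.direction_mix <= 1:
            raise SynthError("direction_mix must lie in [0, 1]")


@dataclass
class GroundTruth:
    """What the generators injected: per-experiment and per-cell-type truth."""

    experiments: list[dict] = field(default_factory=list)
    cell_types: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {"experiments": self.experiments, "cell_types": self.cell_types},
                indent=2,
            )
            + "\n"
        )


def _gene_names(n: int) -> list[str]:
    return [f"g{i:05d}" for i in range(n)]


def generate_regulons(cfg: SynthConfig) -> tuple[RegulonNetwork, FootprintModel]:
    """Random signed regulon network plus the paired footprint model.

    Each of the ``n_tfs`` TFs receives ``targets_per_tf`` distinct targets
    (TFs may share targets); mode is +1 with probability
    ``activating_fraction``; likelihood is 1; each TF's confidence grade is
    uniform over A–E.  The footprint model reuses the memberships with
    weight = mode and responsiveness rank following draw order.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_names(cfg.n_genes)
    if cfg.targets_per_tf > cfg.n_genes:
        raise SynthError("targets_per_tf cannot exceed n_genes")
    rows, fp_rows = [], []
    for t in range(cfg.n_tfs):
        tf = f"TF{t:03d}"
        conf = CONFIDENCE_LEVELS[rng.integers(len(CONFIDENCE_LEVELS))]
        targets = rng.choice(cfg.n_genes, size=cfg.targets_per_tf, replace=False)
        modes = np.where(rng.random(cfg.targets_per_tf) < cfg.activating_fraction, 1, -1)
        for rank, (gi, mode) in enumerate(zip(targets, modes), start=1):
            rows.append((tf, genes[gi], int(mode), 1.0, conf))
            fp_rows.append((tf, genes[gi], float(mode), rank))
    net = RegulonNetwork(
        edges=pd.DataFrame(rows, columns=["tf", "target", "mode", "likelihood", "confidence"]),
        name="synthetic",
    )
    model = FootprintModel(
        entries=pd.DataFrame(fp_rows, columns=["pathway", "gene", "weight", "responsiveness_rank"])
    )
    return net, model


def _nb_draw(rng, mean: np.ndarray, dispersion: float, size=None) -> np.ndarray:
    """Negative binomial with var = m + dispersion·m² (gamma-Poisson)."""
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean / shape, size=size if size is not None else mean.shape)
    return rng.poisson(lam)


def generate_perturbation_compendium(
    net: RegulonNetwork, cfg: SynthConfig
) -> tuple[pd.DataFrame, list[PerturbationRecord], GroundTruth]:
    """Bulk perturbation compendium with metadata and ground truth.

    Per experiment a target TF is chosen (cycling through the network so all
    TFs are exercised), a direction is drawn (−1 with probability
    ``direction_mix``), and control/perturbed bulk profiles are sampled from
    the negative binomial; in perturbed samples each direct target's mean is
    multiplied by 2^(effect·mode·direction).
    """
    if cfg.n_experiments < 1:
        raise SynthError("n_experiments must be >= 1")
    rng = np.random.default_rng(cfg.seed + 1)
    genes = _gene_names(cfg.n_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    # gene-specific baseline means (lognormal spread around baseline_mean)
    base = cfg.baseline_mean * rng.lognormal(mean=0.0, sigma=0.7, size=cfg.n_genes)
    tfs = net.tfs
    columns, names = [], []
    records: list[PerturbationRecord] = []
    truth = GroundTruth()
    for e in range(cfg.n_experiments):
        target = tfs[e % len(tfs)]
        direction = -1 if rng.random() < cfg.direction_mix else 1
        regulon = net.regulon(target)
        pert_mean = base.copy()
        idx = np.array([gene_pos[g] for g in regulon["target"]])
        pert_mean[idx] = base[idx] * 2.0 ** (
            cfg.effect * regulon["mode"].to_numpy(dtype=float) * direction
        )
        ctrl_ids, pert_ids = [], []
        for s in range(cfg.samples_per_group):
            columns.append(_nb_draw(rng, base, cfg.dispersion))
            names.append(f"e{e:03d}_ctrl{s}")
            ctrl_ids.append(names[-1])
        for s in range(cfg.samples_per_group):
            columns.append(_nb_draw(rng, pert_mean, cfg.dispersion))
            names.append(f"e{e:03d}_pert{s}")
            pert_ids.append(names[-1])
        records.append(
            PerturbationRecord(
                contrast_id=f"e{e:03d}",
                target=target,
                direction=direction,
                kind="tf",
                perturbed_samples=tuple(pert_ids),
                control_samples=tuple(ctrl_ids),
            )
        )
        truth.experiments.append(
            {
                "contrast_id": f"e{e:03d}",
                "target": target,
                "direction": direction,
                "shifted_genes": regulon["target"].tolist(),
            }
        )
    bulk = pd.DataFrame(np.stack(columns, axis=1), index=genes, columns=names)
    return bulk, records, truth


def generate_mixture_population(
    net: RegulonNetwork,
    cell_types: dict[str, list[str]],
    cells_per_type: int,
    cfg: SynthConfig,
    mu: float = 5000.0,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Mixed-cell-type single-cell counts with annotations and ground truth.

    Each cell type gets a mean profile (baseline with its active TFs' direct
    targets shifted by 2^(effect·mode)); cells are then sampled with the
    bulk→single-cell multinomial model at mean library size ``mu``.
    Returns (genes × cells counts, annotation table, ground truth).
    """
    rng = np.random.default_rng(cfg.seed + 2)
    genes = _gene_names(cfg.n_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    known = set(net.tfs)
    for ct, active in cell_types.items():
        unknown = sorted(set(active) - known)
        if unknown:
            raise SynthError(f"cell type {ct!r} lists unknown TF(s): {unknown}")
    base = cfg.baseline_mean * rng.lognormal(mean=0.0, sigma=0.7, size=cfg.n_genes)
    blocks, ann_rows = [], []
    truth = GroundTruth(cell_types={ct: list(a) for ct, a in cell_types.items()})
    for ct, active in cell_types.items():
        mean = base.copy()
        for tf in active:
            regulon = net.regulon(tf)
            idx = np.array([gene_pos[g] for g in regulon["target"]])
            mean[idx] = mean[idx] * 2.0 ** (
                cfg.effect * regulon["mode"].to_numpy(dtype=float)
            )
        p = mean / mean.sum()
        libs = draw_library_sizes(mu, cells_per_type, rng)
        libs = np.maximum(libs, 1)  # keep the requested cell count
        cells = np.stack([rng.multinomial(int(L), p) for L in libs], axis=1)
        ids = [f"{ct}|cell{i}" for i in range(cells_per_type)]
        blocks.append(pd.DataFrame(cells, index=genes, columns=ids))
        ann_rows.extend((cid, ct) for cid in ids)
    counts = pd.concat(blocks, axis=1)
    annotations = pd.DataFrame(ann_rows, columns=["cell_id", "cell_type"])
    return counts, annotations, truth


def write_compendium(out_dir, bulk: pd.DataFrame, records, truth: GroundTruth,
                     net: RegulonNetwork, model: FootprintModel) -> None:
    """Write a compendium in the formats the reader modules consume."""
    from .benchmark import write_perturbation_metadata

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bulk.to_csv(out / "bulk_counts.tsv", sep="\t")
    write_perturbation_metadata(records, out / "metadata.csv")
    net.edges.to_csv(out / "network.tsv", sep="\t", index=False)
    model.entries.to_csv(out / "footprints.tsv", sep="\t", index=False)
    truth.to_json(out / "ground_truth.json")
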