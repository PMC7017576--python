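"""Simulate homogeneous single cells from a bulk RNA-seq profile.

The probability model: a bulk count vector C is converted to TPM (B), and the
relative TPM of each gene becomes its sampling probability P = B / |B|.  A
simulated cell is L with-replacement draws from P — realized as one
multinomial(L, P) draw, which has the identical distribution — where the
library size L is itself drawn from Normal(μ, sd=μ/2), rounded and truncated
at zero.  Cells whose total count falls below ``min_library`` (default 100)
are discarded before normalization.  The model preserves the bulk sample's
information while introducing the hallmark single-cell artifacts: drop-outs
(P(zero | L) = (1 − P_g)^L), small libraries, and many cells.

Only homogeneous populations can be simulated from one bulk sample; mixtures
are composed from several bulk profiles (see :mod:`footprintbench.synthdata`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the bulk→single-cell sampler.

    mu
        Desired mean library size (total counts per cell); the per-cell
        library is drawn from Normal(mu, sd=mu/2).
    n_cells
        Cells to simulate per bulk sample.  The study grid is
        1, 10, 20, 30, 50, 100 — small values deliberately discard
        information from the bulk template.
    n_reps
        Independent simulation repetitions (default 25).
    min_library
        Cells with fewer total counts are dropped (default 100, strict <).
    """

    mu: float = 5000.0
    n_cells: int = 10
    n_reps: int = 25
    seed: int = 0
    min_library: int = 100

    def __post_init__(self):
        if self.mu <= 0:
            raise SimulationError("mu must be > 0")
        if self.n_cells < 1 or self.n_reps < 1:
            raise SimulationError("n_cells and n_reps must be >= 1")


def bulk_to_probabilities(
    counts: pd.Series, lengths: pd.Series | None = None
) -> tuple[pd.Series, pd.Series]:
    """TPM values and gene sampling probabilities from a bulk count vector.

    B_g = (C_g/length_g) / Σ_h (C_h/length_h) · 1e6 and P_g = B_g / Σ B.
    Without gene lengths, TPM degenerates to CPM (all lengths equal).
    """
    c = counts.to_numpy(dtype=float)
    if c.sum() <= 0:
        raise SimulationError("bulk profile has no counts")
    if (c < 0).any():
        raise SimulationError("bulk counts must be non-negative")
    if lengths is None:
        rate = c
    else:
        ln = lengths.reindex(counts.index).to_numpy(dtype=float)
        if np.any(~np.isfinite(ln)) or np.any(ln <= 0):
            raise SimulationError("every counted gene needs a positive length")
        rate = c / ln
    tpm = rate / rate.sum() * 1e6
    p = tpm / tpm.sum()
    return (
        pd.Series(tpm, index=counts.index, name="tpm"),
        pd.Series(p, index=counts.index, name="p"),
    )


def draw_library_sizes(mu: float, n: int, rng) -> np.ndarray:
    """Draw n library sizes from Normal(mu, sd=mu/2), rounded, floored at 0."""
    if n < 1:
        raise SimulationError("n must be >= 1")
    rng = np.random.default_rng(rng)
    draws = rng.normal(loc=mu, scale=mu / 2.0, size=n)
    return np.maximum(np.rint(draws), 0).astype(np.int64)


def simulate_cells(
    counts: pd.Series,
    cfg: SimulationConfig,
    lengths: pd.Series | None = None,
    rng=None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Simulate ``cfg.n_cells`` cells from one bulk profile.

    Returns the genes × kept-cells count matrix and the boolean keep mask over
    all drawn cells (cells with library < ``cfg.min_library`` are dropped).
    Column sums of kept cells equal their drawn library sizes.
    """
    _, p = bulk_to_probabilities(counts, lengths)
    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    libs = draw_library_sizes(cfg.mu, cfg.n_cells, rng)
    cells = np.stack([rng.multinomial(int(L), p.to_numpy()) for L in libs], axis=1)
    keep = cells.sum(axis=0) >= cfg.min_library
    if not keep.any():
        raise SimulationError(
            f"all {cfg.n_cells} simulated cells fell below the library "
            f"threshold {cfg.min_library}"
        )
    kept = cells[:, keep]
    columns = [f"cell{i}" for i in np.flatnonzero(keep)]
    return pd.DataFrame(kept, index=counts.index, columns=columns), keep


def normalize_cells(counts: pd.DataFrame) -> pd.DataFrame:
    """Size-factor log-normalization of a single-cell count matrix.

    Size factor = library size / geometric mean of library sizes; the
    normalized value is log2(count / size_factor + 1).  Cells with zero
    library must have been filtered before calling.
    """
    values = counts.to_numpy(dtype=float)
    libs = values.sum(axis=0)
    if (libs <= 0).any():
        raise SimulationError("zero-library cell present; filter before normalizing")
    geo = np.exp(np.mean(np.log(libs)))
    sf = libs / geo
    return pd.DataFrame(
        np.log2(values / sf[None, :] + 1.0), index=counts.index, columns=counts.columns
    )


def simulate_compendium_cells(
    bulk: pd.DataFrame,
    cfg: SimulationConfig,
    lengths: pd.Series | None = None,
    rng=None,
) -> pd.DataFrame:
    """Simulate cells from every column of a bulk matrix.

    Cell ids encode the bulk sample of origin (``<sample>|cell<i>``) so that
    perturbation metadata written against bulk sample ids can be expanded to
    the simulated cells.
    """
    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    blocks = []
    for sample in bulk.columns:
        cells, _ = simulate_cells(bulk[sample], cfg, lengths, rng)
        cells.columns = [f"{sample}|{c}" for c in cells.columns]
        blocks.append(cells)
    return pd.concat(blocks, axis=1)


def write_simulation(out_dir, counts: pd.DataFrame, cfg: SimulationConfig) -> None:
    """Write a simulated count matrix as MTX + index files + config sidecar."""
    from scipy import io as sio
    from scipy import sparse

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sio.mmwrite(out / "matrix.mtx", sparse.csr_matrix(counts.to_numpy()))
    (out / "genes.tsv").write_text("\n".join(map(str, counts.index)) + "\n")
    (out / "barcodes.tsv").write_text("\n".join(map(str, counts.columns)) + "\n")
    (out / "config.json").write_text(json.dumps(asdict(cfg), indent=2) + "\n")


def read_simulation(out_dir) -> tuple[pd.DataFrame, SimulationConfig]:
    from scipy import io as sio

    out = Path(out_dir)
    mat = sio.mmread(out / "matrix.mtx").toarray()
    genes = (out / "genes.tsv").read_text().splitlines()
    barcodes = (out / "barcodes.tsv").read_text().splitlines()
    cfg = SimulationConfig(**json.loads((out / "config.json").read_text()))
    return pd.DataFrame(mat, index=genes, columns=barcodes), cfg
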