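import numpy as np
import pandas as pd
import pytest

from footprintbench.genesets import FootprintModel, RegulonNetwork


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_network():
    """Three TFs with 4-6 targets each over a 30-gene universe."""
    genes = [f"g{i}" for i in range(30)]
    rows = []
    rng = np.random.default_rng(7)
    for t, (tf, size, conf) in enumerate(
        [("TFA", 6, "A"), ("TFB", 5, "B"), ("TFC", 4, "C")]
    ):
        targets = rng.choice(30, size=size, replace=False)
        for g in targets:
            mode = 1 if rng.random() < 0.7 else -1
            rows.append((tf, genes[g], mode, 1.0, conf))
    edges = pd.DataFrame(rows, columns=["tf", "target", "mode", "likelihood", "confidence"])
    return RegulonNetwork(edges=edges, name="toy")


@pytest.fixture
def small_footprint():
    """Two pathways, 5 weighted genes each, responsiveness-ranked."""
    rows = []
    for p, signs in [("P1", [1, 1, -1, 1, -1]), ("P2", [-1, 1, 1, -1, 1])]:
        for rank, s in enumerate(signs, start=1):
            rows.append((p, f"g{(rank * 3) % 30}" if p == "P1" else f"g{(rank * 5) % 30}",
                         s * (1.0 + rank / 10), rank))
    entries = pd.DataFrame(rows, columns=["pathway", "gene", "weight", "responsiveness_rank"])
    return FootprintModel(entries=entries)


@pytest.fixture
def signature(rng):
    genes = [f"g{i}" for i in range(30)]
    return pd.Series(rng.normal(size=30), index=genes)
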