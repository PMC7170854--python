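from pathlib import Path

import numpy as np
import pytest

from hetmda import hetnet


@pytest.fixture
def toy_edge_files(tmp_path: Path) -> dict[str, Path]:
    """Hand-enumerable 6-node toy: 2 miRNAs, 2 diseases, 1 protein, 1 lncRNA.

    Edges (5): m1-p1, m2-p1, m1-d1, l1-d2, p1-d1.
    Hand-counted degrees: m1=2, m2=1, d1=2, d2=1, p1=3, l1=1.
    """
    files = {}

    def write(cls: str, rows: list[tuple[str, str]]) -> None:
        path = tmp_path / f"{cls}.tsv"
        path.write_text("".join(f"{a}\t{b}\n" for a, b in rows))
        files[cls] = path

    write("mirna-protein", [("m1", "p1"), ("m2", "p1")])
    write("mirna-disease", [("m1", "d1")])
    write("lncrna-disease", [("l1", "d2")])
    write("protein-disease", [("p1", "d1")])
    return files


@pytest.fixture
def toy_net(toy_edge_files) -> hetnet.HeteroNetwork:
    return hetnet.load_edge_lists(toy_edge_files)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_symmetric_adjacency(n: int, p: float, rng: np.random.Generator) -> np.ndarray:
    """Random undirected graph adjacency with no isolated-node guarantee."""
    upper = rng.random((n, n)) < p
    adj = np.triu(upper, k=1).astype(float)
    return adj + adj.T
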