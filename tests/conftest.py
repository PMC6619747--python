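"""Shared fixtures: a small deterministic gene and sequence sets."""

from __future__ import annotations

import numpy as np
import pytest

from tauscan.seq_model import Exon, GeneModel
from tauscan.synthetic import make_background


@pytest.fixture(scope="session")
def toy_gene() -> GeneModel:
    """3-exon gene with fixed coordinates for coordinate arithmetic tests.

    Exons: E9=(11,60), E10=(101,193), E11=(241,290); introns between them.
    """
    seq = make_background(300, seed=1234)
    return GeneModel(
        gene_id="toy",
        sequence=seq,
        exons=(Exon("E9", 11, 60), Exon("E10", 101, 193), Exon("E11", 241, 290)),
    )


@pytest.fixture(scope="session")
def oracle_sequences() -> list[str]:
    """Short random sequences (8-18 nt) for enumeration-oracle comparisons."""
    rng = np.random.default_rng(20240917)
    seqs = []
    for _ in range(60):
        n = int(rng.integers(8, 19))
        seqs.append("".join(rng.choice(list("ACGU"), n)))
    # a few adversarial cases: GC-rich, wobble-rich, unpairable
    seqs += ["GGGGCCCCGGCC", "GUGUGUGUGUGUGU", "AAAAAAAAAAAA", "GGGAAACCCAAAGGGUUUCCC"[:18]]
    return seqs
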