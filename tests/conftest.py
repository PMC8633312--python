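"""Shared fixtures: one seeded synthetic dataset and its derived layers.

The session-scoped dataset is the generator's default study conditions
(5 stages x 3 replicates, 200 circRNAs / 150 miRNAs / 500 genes) so the
recovery tests all score the same simulated experiment.
"""

from __future__ import annotations

import warnings

import pandas as pd
import pytest

import circregnet as cr
from circregnet.diffexp import de_all_contrasts

SEED = 1


@pytest.fixture(scope="session")
def dataset():
    return cr.simulate_dataset(seed=SEED)


@pytest.fixture(scope="session")
def normalized(dataset):
    """SRPBM / TPM / FPKM matrices for the three layers."""
    circ_s = cr.srpbm(dataset.circ_counts, dataset.mapped_reads)
    mir_t = cr.tpm(dataset.mir_counts,
                   {m: len(s) for m, s in dataset.mir_seqs.items()})
    gene_f = cr.fpkm(dataset.gene_counts,
                     {g: max(len(s), 1) for g, s in dataset.utr_seqs.items()})
    return {"circ": circ_s, "mir": mir_t, "gene": gene_f}


@pytest.fixture(scope="session")
def de_sets(normalized):
    """Union-of-contrasts differential feature ids per layer."""
    _, circ_de = de_all_contrasts(normalized["circ"], "circRNA")
    _, mir_de = de_all_contrasts(normalized["mir"], "miRNA")
    _, gene_de = de_all_contrasts(normalized["gene"], "gene")
    return {"circ": circ_de, "mir": mir_de, "gene": gene_de}


@pytest.fixture(scope="session")
def fitted_network(normalized, dataset):
    """Signed co-expression network over all circRNAs + genes."""
    combined = pd.concat(
        [normalized["circ"].log2p1(), normalized["gene"].log2p1()]
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        net = cr.CoexpressionNetwork(power=12, log_transform=False).fit(combined)
    net.design_ = dataset.design
    return net
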