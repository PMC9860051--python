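"""Shared fixtures and toy-genome builders."""

from __future__ import annotations

import pytest

from pulcascade.core import NONE, AnnotationCall, Gene


def build_toy_genome(labels, strands=None, contig="ctg01"):
    """Genes + annotations from a flat list of labels.

    Labels are annotation labels (``GH26``, ``SUSC``, ``SUSD``, ``GT``,
    ``NONE``); ``NONE`` genes carry no call.
    """
    strands = strands or ["+"] * len(labels)
    genes = [
        Gene(
            contig_id=contig,
            order_index=i,
            gene_id=f"{contig}_g{i:04d}",
            start=i * 1000 + 1,
            end=i * 1000 + 900,
            strand=strands[i],
        )
        for i in range(len(labels))
    ]
    annotations = {}
    for g, label in zip(genes, labels):
        if label == NONE:
            annotations[g.gene_id] = frozenset()
        else:
            annotations[g.gene_id] = frozenset({AnnotationCall(g.gene_id, label)})
    return genes, annotations


@pytest.fixture
def toy_genome():
    return build_toy_genome


@pytest.fixture
def zero_noise_assembly():
    """A two-PUL, three-decoy assembly with noise-free hit tables."""
    from pulcascade import synthetic

    truth = synthetic.generate_genome(
        n_contigs=2, n_genes_per_contig=60, n_puls=2, n_decoys=3, seed=11
    )
    domain, search, intents = synthetic.generate_hit_tables(
        truth, synthetic.NoiseConfig(seed=12)
    )
    return truth, domain, search, intents
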