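"""Core domain objects shared across the pipeline.

The pipeline operates on ordered protein-coding genes along contigs; the
genomic unit of interest is the polysaccharide utilization locus (PUL): a
contiguous run of genes anchored on a tandem SusC/SusD transporter pair and
carrying carbohydrate-active enzyme (CAZyme) genes for one substrate class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

#: Special (non-CAZy-family) annotation labels.
SUSC = "SUSC"
SUSD = "SUSD"
GT = "GT"
NONE = "NONE"

SPECIAL_LABELS = frozenset({SUSC, SUSD, GT, NONE})


def is_cazyme_label(label: str) -> bool:
    """True for CAZy family labels that count as degradative CAZymes.

    Glycosyl transferases (``GT``) are deliberately excluded: they are
    biosynthetic and never extend a degradative locus.
    """
    return label not in SPECIAL_LABELS


@dataclass(frozen=True, order=True)
class Gene:
    """A protein-coding feature on a contig.

    ``order_index`` is the 0-based rank of the gene along its contig;
    neighborhood rules downstream count genes, not base pairs.
    """

    contig_id: str
    order_index: int
    gene_id: str
    start: int
    end: int
    strand: str
    locus_tag: Optional[str] = None

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")


@dataclass(frozen=True)
class AnnotationCall:
    """A per-protein functional label with its evidence provenance.

    ``label`` is a CAZy family string (``GH26``, ``GH5_26``, ``CE2`` ...) or
    one of the special labels ``SUSC``, ``SUSD``, ``GT``. ``evidence`` records
    which route(s) support the call: profile-HMM hits (``HMM``) and/or
    pairwise sequence search (``SEARCH``).
    """

    protein_id: str
    label: str
    evidence: frozenset = frozenset({"HMM"})

    @property
    def is_cazyme(self) -> bool:
        return is_cazyme_label(self.label)


#: Annotations for one assembly: gene id -> set of AnnotationCall.
Annotations = dict


def labels_of(annotations: Annotations, gene_id: str) -> frozenset:
    return frozenset(c.label for c in annotations.get(gene_id, ()))


@dataclass
class PUL:
    """A polysaccharide utilization locus.

    The span is a closed interval of contig order indices. ``family_set``
    excludes GT labels by construction; ``cazyme_calls`` preserves gene order
    along the locus.
    """

    contig_id: str
    span: tuple  # (left order_index, right order_index), inclusive
    anchors: list  # list of (susC Gene, susD Gene); >1 after a merge
    genes: list = field(default_factory=list)  # Gene objects inside the span
    cazyme_calls: list = field(default_factory=list)  # ordered (gene_id, family)
    provenance: dict = field(default_factory=dict)

    @property
    def family_set(self) -> frozenset:
        return frozenset(fam for _, fam in self.cazyme_calls)

    @property
    def anchor(self):
        """Primary (left-most) SusC/D anchor pair."""
        return self.anchors[0]

    @property
    def n_genes(self) -> int:
        return self.span[1] - self.span[0] + 1

    def __post_init__(self):
        left, right = self.span
        if left > right:
            raise ValueError(f"invalid span {self.span}")
        for susc, susd in self.anchors:
            for g in (susc, susd):
                if not (left <= g.order_index <= right):
                    raise ValueError(
                        f"anchor gene {g.gene_id} outside span {self.span}"
                    )


def genes_by_contig(genes: Sequence[Gene]) -> dict:
    """Group genes per contig, sorted by order index, with sanity checks."""
    by_contig: dict = {}
    for g in genes:
        by_contig.setdefault(g.contig_id, []).append(g)
    for contig, glist in by_contig.items():
        glist.sort(key=lambda g: g.order_index)
        prev = None
        for g in glist:
            if prev is not None:
                if g.order_index == prev.order_index:
                    raise ValueError(
                        f"duplicate order_index {g.order_index} on {contig}"
                    )
                if g.start <= prev.start:
                    raise ValueError(
                        f"order_index not increasing with start on {contig} "
                        f"at {g.gene_id}"
                    )
            prev = g
    return by_contig
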