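"""PUL detection: SusC/D anchor pairing, gene-context extension, screening.

The locus model follows the screen used for the *Muricauda*-type beta-mannan
loci: a tandem SusC/SusD pair anchors the locus; its boundaries are grown by
scanning a seven-gene frame beyond the current edge for further degradative
CAZyme genes (glycosyl transferases never count); assemblies are kept when a
locus carries at least one GH26 endo-mannanase together with the SusC/D pair.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import (
    GT,
    SUSC,
    SUSD,
    PUL,
    genes_by_contig,
    is_cazyme_label,
    labels_of,
)


@dataclass(frozen=True)
class MineParams:
    """Tunable parameters of the mining stage."""

    frame: int = 7  # gene-count window scanned beyond each locus edge
    max_gap: int = 1  # max intervening genes inside a SusC/D pair
    require_same_strand: bool = True
    window_mode: str = "iterative"  # 'iterative' | 'fixed'
    require_gh26: bool = True
    gh26_scope: str = "cluster"  # 'cluster' | 'assembly'

    def __post_init__(self):
        if self.frame < 1:
            raise ValueError("frame must be >= 1")
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")
        if self.window_mode not in ("iterative", "fixed"):
            raise ValueError(f"unknown window_mode {self.window_mode!r}")
        if self.gh26_scope not in ("cluster", "assembly"):
            raise ValueError(f"unknown gh26_scope {self.gh26_scope!r}")


def find_suscd_pairs(
    genes,
    annotations: dict,
    max_gap: int = 1,
    require_same_strand: bool = True,
) -> list:
    """Locate tandem SusC/D anchor pairs.

    A pair is a SUSC and a SUSD gene on one contig, in either order, with at
    most ``max_gap`` intervening genes (same strand when required). Genes are
    used in at most one pair: candidates are taken greedily left to right,
    closest pair first on ties.

    Returns a list of ``(susC Gene, susD Gene)`` tuples.
    """
    pairs = []
    for contig, glist in sorted(genes_by_contig(genes).items()):
        marks = []
        for pos, g in enumerate(glist):
            labels = labels_of(annotations, g.gene_id)
            if SUSC in labels:
                marks.append((pos, SUSC, g))
            elif SUSD in labels:
                marks.append((pos, SUSD, g))
        candidates = []
        for i in range(len(marks)):
            for j in range(i + 1, len(marks)):
                pi, li, gi = marks[i]
                pj, lj, gj = marks[j]
                if li == lj:
                    continue
                if pj - pi - 1 > max_gap:
                    continue
                if require_same_strand and gi.strand != gj.strand:
                    continue
                susc, susd = (gi, gj) if li == SUSC else (gj, gi)
                candidates.append((pi, pj - pi, susc, susd))
        candidates.sort(key=lambda c: (c[0], c[1]))
        used = set()
        for pi, _, susc, susd in candidates:
            if susc.gene_id in used or susd.gene_id in used:
                continue
            used.update((susc.gene_id, susd.gene_id))
            pairs.append((susc, susd))
    return pairs


def extend_span(is_caz, left: int, right: int, frame: int, iterative: bool = True):
    """Grow a closed index span over a contig by the gene-frame rule.

    ``is_caz`` is an indexable of booleans (True where the gene carries a
    degradative, non-GT CAZyme call). From each side of the span the next
    ``frame`` genes are examined; if any is a CAZyme the boundary jumps to
    the farthest such gene. In ``iterative`` mode (the default) the scan
    repeats from the new boundary until a window holds no CAZyme or the
    contig ends; in fixed mode each side is scanned exactly once.
    """
    n = len(is_caz)
    while True:
        hi = min(right + frame, n - 1)
        new_right = right
        for j in range(hi, right, -1):
            if is_caz[j]:
                new_right = j
                break
        moved = new_right != right
        right = new_right
        if not (iterative and moved):
            break
    while True:
        lo = max(left - frame, 0)
        new_left = left
        for j in range(lo, left):
            if is_caz[j]:
                new_left = j
                break
        moved = new_left != left
        left = new_left
        if not (iterative and moved):
            break
    return left, right


def trim_span(keep, left: int, right: int):
    """Shrink a span so each terminus is terminus-eligible (``keep`` True)."""
    while left < right and not keep[left]:
        left += 1
    while right > left and not keep[right]:
        right -= 1
    return left, right


def _gene_flags(glist, annotations):
    is_caz = []
    keep = []
    for g in glist:
        labels = labels_of(annotations, g.gene_id)
        caz = any(is_cazyme_label(l) for l in labels - {GT})
        is_caz.append(caz)
        keep.append(caz or SUSC in labels or SUSD in labels)
    return is_caz, keep


def extract_pul(
    anchor,
    genes,
    annotations: dict,
    frame: int = 7,
    window_mode: str = "iterative",
) -> PUL:
    """Extract the locus around one SusC/D anchor.

    The anchor span is extended by :func:`extend_span` and trimmed so both
    termini are CAZyme, SusC or SusD genes. Genes labelled only GT never
    extend the span and are trimmed off the termini.
    """
    susc, susd = anchor
    contig = susc.contig_id
    glist = genes_by_contig(genes)[contig]
    pos = {g.gene_id: i for i, g in enumerate(glist)}
    left = min(pos[susc.gene_id], pos[susd.gene_id])
    right = max(pos[susc.gene_id], pos[susd.gene_id])

    is_caz, keep = _gene_flags(glist, annotations)
    left, right = extend_span(
        is_caz, left, right, frame, iterative=(window_mode == "iterative")
    )
    left, right = trim_span(keep, left, right)

    span_genes = glist[left : right + 1]
    cazyme_calls = []
    for g in span_genes:
        for fam in sorted(labels_of(annotations, g.gene_id)):
            if is_cazyme_label(fam) and fam != GT:
                cazyme_calls.append((g.gene_id, fam))
    return PUL(
        contig_id=contig,
        span=(glist[left].order_index, glist[right].order_index),
        anchors=[(susc, susd)],
        genes=span_genes,
        cazyme_calls=cazyme_calls,
        provenance={"frame": frame, "window_mode": window_mode},
    )


def screen_filter(puls, require_family: str = "GH26"):
    """Keep loci whose family profile contains the screen family (GH26 by
    default; any subfamily such as ``GH26_1`` counts).

    Returns ``(kept, summary)`` where summary records the keep/drop tally.
    """
    kept, dropped = [], []
    for pul in puls:
        if any(
            fam == require_family or fam.startswith(require_family + "_")
            for fam in pul.family_set
        ):
            kept.append(pul)
        else:
            dropped.append(pul)
    summary = {
        "n_candidates": len(puls),
        "n_kept": len(kept),
        "n_dropped": len(dropped),
        "required_family": require_family,
    }
    return kept, summary


def _merge_overlapping(puls):
    """Merge loci on one contig whose spans intersect (shared anchors after a
    noisy double-pairing, or tandem loci grown into each other)."""
    merged = []
    for pul in sorted(puls, key=lambda p: (p.contig_id, p.span)):
        last = merged[-1] if merged else None
        if (
            last is not None
            and last.contig_id == pul.contig_id
            and pul.span[0] <= last.span[1]
        ):
            genes = {g.gene_id: g for g in last.genes + pul.genes}
            span_genes = sorted(genes.values(), key=lambda g: g.order_index)
            calls = list(
                dict.fromkeys([*last.cazyme_calls, *pul.cazyme_calls])
            )
            calls.sort(key=lambda c: genes[c[0]].order_index)
            merged[-1] = PUL(
                contig_id=last.contig_id,
                span=(last.span[0], max(last.span[1], pul.span[1])),
                anchors=last.anchors + pul.anchors,
                genes=span_genes,
                cazyme_calls=calls,
                provenance={**last.provenance, "merged": True},
            )
        else:
            merged.append(pul)
    return merged


def mine_assembly(genes, annotations: dict, params: MineParams = MineParams()) -> list:
    """Full mining pass over one assembly.

    Anchors are paired, each is extended into a locus, intersecting loci are
    merged (recorded in provenance), and the GH26 screen filter is applied.
    Deterministic; loci are reported in contig/coordinate order.
    """
    anchors = find_suscd_pairs(
        genes,
        annotations,
        max_gap=params.max_gap,
        require_same_strand=params.require_same_strand,
    )
    puls = [
        extract_pul(a, genes, annotations, params.frame, params.window_mode)
        for a in anchors
    ]
    puls = _merge_overlapping(puls)
    if params.require_gh26:
        if params.gh26_scope == "assembly":
            assembly_has = any(
                fam == "GH26" or fam.startswith("GH26_")
                for calls in annotations.values()
                for fam in (c.label for c in calls)
            )
            if not assembly_has:
                puls = []
        else:
            puls, _ = screen_filter(puls)
    puls.sort(key=lambda p: (p.contig_id, p.span))
    return puls
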