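"""Comparative analysis of mined loci against the reference beta-mannan PUL.

Covers modularity classification (is a locus's CAZyme family profile the
same as the reference?), family co-occurrence across a screened set,
family-set intersection counts (UpSet-style input), whole-genome repertoire
matching for MAGs, and reciprocal-best-hit synteny maps between loci.
"""

from __future__ import annotations

import re
from bisect import bisect_left
from dataclasses import dataclass, field

import pandas as pd

from .core import SUSC, SUSD

_SUBFAMILY = re.compile(r"^((?:GH|PL|CE|CBM|AA|GT)\d+)_\d+$")


def collapse_subfamily(family: str) -> str:
    """Collapse a CAZy subfamily label to its family (``GH5_26`` -> ``GH5``)."""
    m = _SUBFAMILY.match(family)
    return m.group(1) if m else family


@dataclass(frozen=True)
class ReferenceModule:
    """The reference locus content: the *Muricauda*-type beta-mannan PUL
    carries GH26 mannanases, a GH5 glucanase, a GH27 alpha-galactosidase, a
    GH130 phosphorylase and a CE2 esterase next to its SusC/D pair."""

    families: frozenset = frozenset({"GH26", "GH5", "GH27", "GH130", "CE2"})
    components: frozenset = frozenset({SUSC, SUSD})

    def __post_init__(self):
        if not self.families:
            raise ValueError("reference family set must be non-empty")
        if "GH26" not in {collapse_subfamily(f) for f in self.families}:
            raise ValueError("reference must include GH26")


def same_modularity(pul, reference: ReferenceModule = ReferenceModule(), mode: str = "exact") -> bool:
    """Compare a locus's family profile with the reference.

    Subfamilies are collapsed before comparison; multiplicity is ignored.
    ``exact`` demands set equality (extra families disqualify), ``superset``
    only containment of the reference families.
    """
    if mode not in ("exact", "superset"):
        raise ValueError(f"unknown mode {mode!r}")
    fams = frozenset(collapse_subfamily(f) for f in pul.family_set)
    ref = frozenset(collapse_subfamily(f) for f in reference.families)
    return fams == ref if mode == "exact" else fams >= ref


def cooccurrence(puls, min_fraction: float = 0.05) -> pd.DataFrame:
    """Per-family presence fractions over a set of loci.

    Returns the full table (family, count, fraction, retained) where
    ``retained`` marks rows at or above ``min_fraction`` (inclusive, per the
    "at least 5%" screen wording).
    """
    n = len(puls)
    counts: dict = {}
    for pul in puls:
        for fam in pul.family_set:
            counts[fam] = counts.get(fam, 0) + 1
    rows = [
        {
            "family": fam,
            "count": c,
            "fraction": c / n,
            "retained": c / n >= min_fraction,
        }
        for fam, c in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["family", "count", "fraction", "retained"])


def intersection_counts(puls) -> pd.DataFrame:
    """Counts of distinct family sets (the numbers behind an UpSet plot).

    The rows partition the input: counts sum to the number of loci.
    """
    counts: dict = {}
    for pul in puls:
        key = tuple(sorted(pul.family_set))
        counts[key] = counts.get(key, 0) + 1
    rows = [
        {"family_set": ";".join(key), "count": c}
        for key, c in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["family_set", "count"])


def mag_repertoire_match(
    annotations: dict, reference: ReferenceModule = ReferenceModule()
) -> dict:
    """Whole-genome repertoire screen, regardless of genetic context.

    ``minimal``: the genome encodes at least one SusC, one SusD and one GH26
    anywhere. ``full``: every reference family is present anywhere.
    """
    labels = {
        collapse_subfamily(c.label)
        for calls in annotations.values()
        for c in calls
    }
    ref = {collapse_subfamily(f) for f in reference.families}
    minimal = SUSC in labels and SUSD in labels and "GH26" in labels
    return {"minimal": minimal, "full": ref <= labels}


@dataclass
class SyntenyMap:
    """Reciprocal-best-hit gene correspondence between two loci."""

    pairs: list = field(default_factory=list)  # [(ref gene id, target gene id)]
    conservation: float = 0.0  # matched fraction of reference genes
    order_score: float = 0.0  # LCS fraction of matched pairs


def _best_hits(hits: pd.DataFrame, queries, subjects, e_max: float) -> dict:
    """Best subject per query among passing hits, ties broken by (e-value,
    subject id)."""
    best: dict = {}
    if hits.empty:
        return best
    for _, row in hits.iterrows():
        q, s = row["query_id"], row["subject_id"]
        if q not in queries or s not in subjects:
            continue
        if row["e_value"] > e_max:
            continue
        key = (row["e_value"], s)
        if q not in best or key < best[q]:
            best[q] = key
    return {q: s for q, (_, s) in best.items()}


def _lis_length(seq) -> int:
    """Longest strictly increasing subsequence (patience sorting)."""
    tails: list = []
    for x in seq:
        i = bisect_left(tails, x)
        if i == len(tails):
            tails.append(x)
        else:
            tails[i] = x
    return len(tails)


def synteny_map(
    pul_ref,
    pul_target,
    hits_ab: pd.DataFrame,
    hits_ba: pd.DataFrame,
    e_max: float = 1e-5,
) -> SyntenyMap:
    """Reciprocal-best-hit synteny between a reference locus and a target.

    Matched pairs are reciprocal best hits at e-value <= ``e_max``;
    conservation is the matched fraction of reference genes; the order score
    is the fraction of matched pairs lying on a longest common subsequence
    of the target's gene order read along the reference.
    """
    ref_ids = [g.gene_id for g in pul_ref.genes]
    tgt_ids = [g.gene_id for g in pul_target.genes]
    fwd = _best_hits(hits_ab, set(ref_ids), set(tgt_ids), e_max)
    rev = _best_hits(hits_ba, set(tgt_ids), set(ref_ids), e_max)
    pairs = [(a, b) for a, b in fwd.items() if rev.get(b) == a]
    order = {gid: i for i, gid in enumerate(ref_ids)}
    pairs.sort(key=lambda ab: order[ab[0]])
    if not pairs:
        return SyntenyMap([], 0.0, 0.0)
    tgt_order = {gid: i for i, gid in enumerate(tgt_ids)}
    lcs = _lis_length([tgt_order[b] for _, b in pairs])
    return SyntenyMap(
        pairs=pairs,
        conservation=len(pairs) / len(ref_ids),
        order_score=lcs / len(pairs),
    )
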