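"""Dual-evidence functional annotation of proteins.

Raw evidence comes in two tables: profile-HMM domain hits against a
dbCAN-style family database (HMMER3 ``domtblout`` dialect) and pairwise
protein-search hits against a CAZy-sequence database (BLAST tabular dialect
with a subject-family column). The annotation route is:

1. :func:`filter_domain_hits` — the dbCAN parser rules: an e-value below
   1e-5 for alignments longer than 80 residues (1e-3 otherwise), profile
   coverage above 0.30, and per-protein resolution of overlapping hits by
   the lower e-value.
2. :func:`classify_sus` — SusC (TIGR04056) and SusD (PF12741/PF12771/
   PF14322/PF07980) transporter-component calls from the filtered hits.
3. :func:`label_gt` — glycosyl-transferase families are collapsed to the
   ``GT`` label so downstream neighborhood scans never count them as
   degradative CAZymes.
4. :func:`confirm_calls` — a CAZy-family call survives only if a search hit
   of the same family passes e-value <= 1e-20, query coverage >= 40% and
   identity >= 30% ("confirmed" mode); an HMM-only mode bypasses this.

All thresholds are inclusive at the boundary and configurable.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace

import pandas as pd

from .core import GT, SUSC, SUSD, AnnotationCall, Gene

log = logging.getLogger(__name__)

#: Profile names recognized as SusC / SusD components (version suffix ignored).
SUSC_PROFILES = frozenset({"TIGR04056"})
SUSD_PROFILES = frozenset({"PF12741", "PF12771", "PF14322", "PF07980"})

_VERSION_SUFFIX = re.compile(r"\.\d+$")

DOMAIN_HIT_COLUMNS = [
    "protein_id",
    "profile_name",
    "e_value",
    "alignment_length",
    "profile_coverage",
    "env_start",
    "env_end",
]

SEARCH_HIT_COLUMNS = [
    "query_id",
    "subject_id",
    "subject_family",
    "percent_identity",
    "query_coverage",
    "e_value",
]


def strip_version(profile_name: str) -> str:
    """Drop a trailing Pfam/TIGRFAM version suffix (``PF12741.10`` -> ``PF12741``)."""
    return _VERSION_SUFFIX.sub("", profile_name)


@dataclass(frozen=True)
class FilterRules:
    """dbCAN-parser style thresholds for domain hits (all inclusive-exclusive
    as documented per field)."""

    #: e-value must be strictly below this for alignments longer than `long_alignment`
    e_value_long: float = 1e-5
    #: e-value must be strictly below this for alignments of <= `long_alignment` residues
    e_value_short: float = 1e-3
    #: alignment length (residues) above which the stringent e-value applies
    long_alignment: int = 80
    #: profile coverage must be strictly above this fraction
    min_coverage: float = 0.30
    #: two hits on one protein overlap when shared length > this fraction of the shorter
    overlap_fraction: float = 0.5


@dataclass(frozen=True)
class ConfirmRules:
    """Search-confirmation thresholds; boundary values pass."""

    max_e_value: float = 1e-20
    min_query_coverage: float = 40.0
    min_identity: float = 30.0
    #: 'family' requires the search hit to carry the same family label as the
    #: HMM call; 'protein' accepts any passing hit for the protein.
    scope: str = "family"


def _validate_domain_hits(hits: pd.DataFrame) -> None:
    missing = [c for c in DOMAIN_HIT_COLUMNS[:5] if c not in hits.columns]
    if missing:
        raise ValueError(f"domain-hit table lacks columns {missing}")
    bad_rows = []
    for idx, row in hits.iterrows():
        ok = (
            row["e_value"] > 0
            and 0 <= row["profile_coverage"] <= 1
            and row["alignment_length"] > 0
        )
        if ok and {"env_start", "env_end"} <= set(hits.columns):
            ok = row["env_start"] <= row["env_end"]
        if not ok:
            bad_rows.append(idx)
    if bad_rows:
        raise ValueError(f"malformed domain-hit rows: {bad_rows}")


def filter_domain_hits(hits: pd.DataFrame, rules: FilterRules = FilterRules()) -> pd.DataFrame:
    """Apply threshold and overlap-resolution rules to raw domain hits.

    Overlapping hits on the same protein (shared envelope length exceeding
    ``rules.overlap_fraction`` of the shorter alignment) are resolved by
    keeping the hit with the lower e-value. Idempotent.
    """
    if hits.empty:
        return hits.copy()
    _validate_domain_hits(hits)

    long_aln = hits["alignment_length"] > rules.long_alignment
    e_ok = (long_aln & (hits["e_value"] < rules.e_value_long)) | (
        ~long_aln & (hits["e_value"] < rules.e_value_short)
    )
    cov_ok = hits["profile_coverage"] > rules.min_coverage
    kept = hits[e_ok & cov_ok]

    if {"env_start", "env_end"} - set(kept.columns):
        return kept.reset_index(drop=True)

    rows = []
    for _, group in kept.groupby("protein_id", sort=False):
        chosen: list = []
        for _, row in group.sort_values(
            ["e_value", "profile_name"], kind="mergesort"
        ).iterrows():
            clash = False
            for kept_row in chosen:
                shared = min(row["env_end"], kept_row["env_end"]) - max(
                    row["env_start"], kept_row["env_start"]
                ) + 1
                shorter = min(
                    row["env_end"] - row["env_start"] + 1,
                    kept_row["env_end"] - kept_row["env_start"] + 1,
                )
                if shared > rules.overlap_fraction * shorter:
                    clash = True
                    break
            if not clash:
                chosen.append(row)
        rows.extend(chosen)
    if not rows:
        return kept.iloc[0:0].reset_index(drop=True)
    out = pd.DataFrame(rows).sort_index(kind="mergesort")
    return out.reset_index(drop=True)


def classify_sus(hits: pd.DataFrame) -> list:
    """SusC/SusD component calls from (already filtered) domain hits.

    A protein matching both SusC and SusD profiles is flagged and resolved
    in favor of the lower e-value.
    """
    calls = []
    if hits.empty:
        return calls
    for protein_id, group in hits.groupby("protein_id", sort=False):
        best = {}  # label -> best e-value
        for _, row in group.iterrows():
            name = strip_version(str(row["profile_name"]))
            if name in SUSC_PROFILES:
                label = SUSC
            elif name in SUSD_PROFILES:
                label = SUSD
            else:
                continue
            e = float(row["e_value"])
            if label not in best or e < best[label]:
                best[label] = e
        if not best:
            continue
        if len(best) == 2:
            log.warning(
                "protein %s matches both SusC and SusD profiles; keeping the "
                "lower e-value call",
                protein_id,
            )
            label = min(best, key=lambda k: (best[k], k))
            best = {label: best[label]}
        (label,) = best
        calls.append(AnnotationCall(protein_id, label, frozenset({"HMM"})))
    return calls


def domain_calls(hits: pd.DataFrame) -> list:
    """CAZy-family calls (HMM evidence) from filtered domain hits.

    SusC/SusD profiles are excluded here (see :func:`classify_sus`); unknown
    non-CAZy profile names are ignored with a log record. One call per
    (protein, family).
    """
    calls = []
    seen = set()
    if hits.empty:
        return calls
    for _, row in hits.iterrows():
        name = strip_version(str(row["profile_name"]))
        if name in SUSC_PROFILES or name in SUSD_PROFILES:
            continue
        if not re.match(r"^(GH|GT|PL|CE|CBM|AA)\d", name):
            log.info("ignoring unrecognized profile name %r", row["profile_name"])
            continue
        family = name.removesuffix(".hmm")
        key = (row["protein_id"], family)
        if key in seen:
            continue
        seen.add(key)
        calls.append(AnnotationCall(row["protein_id"], family, frozenset({"HMM"})))
    return calls


def label_gt(calls: list) -> list:
    """Collapse glycosyl-transferase family calls to the ``GT`` label."""
    out = []
    seen = set()
    for call in calls:
        if call.label.startswith("GT"):
            call = replace(call, label=GT)
        key = (call.protein_id, call.label)
        if key in seen:
            continue
        seen.add(key)
        out.append(call)
    return out


def _search_hit_passes(row, rules: ConfirmRules) -> bool:
    return (
        row["e_value"] <= rules.max_e_value
        and row["query_coverage"] >= rules.min_query_coverage
        and row["percent_identity"] >= rules.min_identity
    )


def confirm_calls(
    calls: list,
    search_hits: pd.DataFrame,
    rules: ConfirmRules = ConfirmRules(),
) -> list:
    """Keep CAZy-family calls backed by a passing sequence-search hit.

    SusC/SusD/GT calls pass through unchanged (they are not part of the
    CAZyme confirmation screen). Confirmed calls gain ``SEARCH`` evidence.
    """
    passing: dict = {}  # protein -> set of passing families ('*' = any)
    if not search_hits.empty:
        for _, row in search_hits.iterrows():
            if not _search_hit_passes(row, rules):
                continue
            fams = passing.setdefault(row["query_id"], set())
            fams.add(str(row["subject_family"]))
    out = []
    for call in calls:
        if call.label in (SUSC, SUSD, GT):
            out.append(call)
            continue
        fams = passing.get(call.protein_id)
        if fams is None:
            continue
        if rules.scope == "protein" or call.label in fams:
            out.append(replace(call, evidence=call.evidence | {"SEARCH"}))
    return out


def annotate_genome(
    genes,
    domain_hits: pd.DataFrame,
    search_hits: pd.DataFrame,
    mode: str = "confirmed",
    filter_rules: FilterRules = FilterRules(),
    confirm_rules: ConfirmRules = ConfirmRules(),
) -> dict:
    """Full annotation of an assembly: gene id -> frozenset of calls.

    ``mode='confirmed'`` applies the dual-evidence rule to CAZy families;
    ``mode='hmm-only'`` keeps every filtered HMM call. Total over genes:
    genes without evidence map to an empty set.
    """
    if mode not in ("confirmed", "hmm-only"):
        raise ValueError(f"unknown annotation mode {mode!r}")
    gene_ids = {g.gene_id if isinstance(g, Gene) else g for g in genes}
    offenders = sorted(
        set(domain_hits["protein_id"]) - gene_ids if not domain_hits.empty else set()
    )
    if not search_hits.empty:
        offenders = sorted(set(offenders) | (set(search_hits["query_id"]) - gene_ids))
    if offenders:
        raise ValueError(f"hit tables reference unknown proteins: {offenders}")

    filtered = filter_domain_hits(domain_hits, filter_rules)
    calls = classify_sus(filtered) + label_gt(domain_calls(filtered))
    if mode == "confirmed":
        calls = confirm_calls(calls, search_hits, confirm_rules)

    annotations = {gid: set() for gid in gene_ids}
    for call in calls:
        annotations[call.protein_id].add(call)
    return {gid: frozenset(v) for gid, v in annotations.items()}
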