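"""Domain-hit filtering, SusC/D classification and the dual-evidence
confirmation rule, including exact threshold-boundary semantics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pulcascade import annotation as ann
from pulcascade import io
from pulcascade.annotation import (
    AnnotationCall,
    ConfirmRules,
    FilterRules,
    classify_sus,
    confirm_calls,
    filter_domain_hits,
    label_gt,
)
from pulcascade.core import GT, SUSC, SUSD


def hit(pid="p1", profile="GH26", e=1e-10, aln=120, cov=0.5, start=1):
    return {
        "protein_id": pid,
        "profile_name": profile,
        "e_value": e,
        "alignment_length": aln,
        "profile_coverage": cov,
        "env_start": start,
        "env_end": start + aln - 1,
    }


def frame(*hits):
    return pd.DataFrame(list(hits))


@pytest.mark.parametrize(
    "e,aln,cov,kept",
    [
        (1e-6, 120, 0.5, True),  # long alignment, stringent e-value met
        (1e-4, 120, 0.5, False),  # long alignment needs e < 1e-5
        (1e-4, 60, 0.5, True),  # short alignment relaxes to e < 1e-3
        (1e-6, 120, 0.25, False),  # coverage must exceed 0.30
        (1e-3, 60, 0.5, False),  # e == threshold fails (strict <)
    ],
)
def test_domain_filter_thresholds(e, aln, cov, kept):
    out = filter_domain_hits(frame(hit(e=e, aln=aln, cov=cov)))
    assert (len(out) == 1) == kept


def test_overlapping_hits_resolved_by_lower_evalue():
    hits = frame(
        hit(profile="GH26", e=1e-10, start=1),
        hit(profile="GH5", e=1e-8, start=10),  # ~90% overlap with the first
    )
    out = filter_domain_hits(hits)
    assert list(out["profile_name"]) == ["GH26"]


def _overlap_oracle(h1, h2, rules=FilterRules()):
    """Brute-force two-hit overlap decision: keep both iff the shared
    envelope is at most half the shorter alignment, else the lower e-value."""
    shared = min(h1["env_end"], h2["env_end"]) - max(h1["env_start"], h2["env_start"]) + 1
    shorter = min(
        h1["env_end"] - h1["env_start"] + 1, h2["env_end"] - h2["env_start"] + 1
    )
    if shared > rules.overlap_fraction * shorter:
        return [min((h1, h2), key=lambda h: h["e_value"])["profile_name"]]
    return sorted([h1["profile_name"], h2["profile_name"]])


@pytest.mark.parametrize("start2", [1, 5, 30, 61, 100, 121])
@pytest.mark.parametrize("e2", [1e-12, 1e-7])
def test_overlap_resolution_matches_enumerated_oracle(start2, e2):
    h1 = hit(profile="GH26", e=1e-10, aln=120, start=1)
    h2 = hit(profile="GH5", e=e2, aln=120, start=start2)
    out = filter_domain_hits(frame(h1, h2))
    assert sorted(out["profile_name"]) == sorted(_overlap_oracle(h1, h2))


def test_filter_is_idempotent():
    rng = np.random.default_rng(0)
    hits = frame(
        *[
            hit(
                pid=f"p{rng.integers(3)}",
                profile=f"GH{rng.integers(1, 30)}",
                e=10.0 ** -rng.uniform(1, 12),
                aln=int(rng.integers(40, 200)),
                cov=float(rng.uniform(0.1, 0.9)),
                start=int(rng.integers(1, 50)),
            )
            for _ in range(40)
        ]
    )
    once = filter_domain_hits(hits)
    twice = filter_domain_hits(once)
    pd.testing.assert_frame_equal(once, twice)


def test_malformed_rows_reported_with_row_number():
    bad = frame(hit(), hit(e=-1.0))
    with pytest.raises(ValueError, match=r"\[1\]"):
        filter_domain_hits(bad)


def test_sus_classification():
    hits = frame(
        hit(pid="c", profile="TIGR04056"),
        hit(pid="d", profile="PF14322.9"),
        hit(pid="x", profile="GH26"),
    )
    calls = {c.protein_id: c.label for c in classify_sus(hits)}
    assert calls == {"c": SUSC, "d": SUSD}


def test_sus_conflict_resolved_by_lower_evalue():
    hits = frame(
        hit(pid="p", profile="TIGR04056", e=1e-30),
        hit(pid="p", profile="PF12741.10", e=1e-10),
    )
    (call,) = classify_sus(hits)
    assert call.label == SUSC


def test_gt_labeling():
    calls = [
        AnnotationCall("a", "GT2"),
        AnnotationCall("b", "GH26"),
        AnnotationCall("c", "CE2"),
    ]
    labelled = {c.protein_id: c.label for c in label_gt(calls)}
    assert labelled == {"a": GT, "b": "GH26", "c": "CE2"}
    assert ann.AnnotationCall("c", "CE2").is_cazyme  # esterases count as CAZymes


def search_hit(q="p1", fam="GH26", e=1e-25, qcov=50.0, pid=40.0):
    return {
        "query_id": q,
        "subject_id": f"db|{fam}|1",
        "subject_family": fam,
        "percent_identity": pid,
        "query_coverage": qcov,
        "e_value": e,
    }


def test_confirmation_passes_and_fails():
    call = [AnnotationCall("p1", "GH26")]
    assert confirm_calls(call, frame(search_hit(e=1e-25)))  # passing hit
    assert not confirm_calls(call, frame(search_hit(e=1e-19)))  # fails e-value
    assert not confirm_calls(call, frame(search_hit(fam="GH5")))  # family mismatch


def test_confirmation_boundary_is_inclusive():
    call = [AnnotationCall("p1", "GH26")]
    exact = search_hit(e=1e-20, qcov=40.0, pid=30.0)
    assert confirm_calls(call, frame(exact))
    up = np.nextafter
    assert not confirm_calls(call, frame(search_hit(e=up(1e-20, 1), qcov=40, pid=30)))
    assert not confirm_calls(call, frame(search_hit(e=1e-20, qcov=up(40, -1), pid=30)))
    assert not confirm_calls(call, frame(search_hit(e=1e-20, qcov=40, pid=up(30, -1))))
    assert confirm_calls(call, frame(search_hit(e=up(1e-20, 0), qcov=up(40, 41), pid=up(30, 31))))


def test_protein_scope_ignores_family_agreement():
    call = [AnnotationCall("p1", "GH26")]
    hits = frame(search_hit(fam="GH5"))
    assert not confirm_calls(call, hits)  # default per-family
    assert confirm_calls(call, hits, ConfirmRules(scope="protein"))


def test_sus_and_gt_pass_through_confirmation():
    calls = [
        AnnotationCall("c", SUSC),
        AnnotationCall("d", SUSD),
        AnnotationCall("g", GT),
    ]
    assert confirm_calls(calls, pd.DataFrame(columns=ann.SEARCH_HIT_COLUMNS)) == calls


@settings(derandomize=True, max_examples=40)
@given(
    d_e=st.floats(min_value=0.0, max_value=10.0),
    d_cov=st.floats(min_value=0.0, max_value=40.0),
    d_pid=st.floats(min_value=0.0, max_value=30.0),
)
def test_tightening_confirmation_never_adds_calls(d_e, d_cov, d_pid):
    rng = np.random.default_rng(7)
    calls = [AnnotationCall(f"p{i}", "GH26") for i in range(20)]
    hits = frame(
        *[
            search_hit(
                q=f"p{i}",
                e=10.0 ** -rng.uniform(10, 30),
                qcov=rng.uniform(20, 80),
                pid=rng.uniform(20, 60),
            )
            for i in range(20)
        ]
    )
    base = ConfirmRules()
    tight = ConfirmRules(
        max_e_value=base.max_e_value * 10.0**-d_e,
        min_query_coverage=base.min_query_coverage + d_cov,
        min_identity=base.min_identity + d_pid,
    )
    loose_ids = {c.protein_id for c in confirm_calls(calls, hits, base)}
    tight_ids = {c.protein_id for c in confirm_calls(calls, hits, tight)}
    assert tight_ids <= loose_ids


def test_confirmed_mode_is_subset_of_hmm_only(zero_noise_assembly):
    from pulcascade.synthetic import NoiseConfig, generate_hit_tables

    truth, *_ = zero_noise_assembly
    domain, search, _ = generate_hit_tables(
        truth, NoiseConfig(fp_rate=0.4, near_threshold_fraction=0.5, seed=5)
    )
    confirmed = ann.annotate_genome(truth.genes, domain, search, mode="confirmed")
    hmm_only = ann.annotate_genome(truth.genes, domain, search, mode="hmm-only")
    for gid in confirmed:
        got = {c.label for c in confirmed[gid]}
        sup = {c.label for c in hmm_only[gid]}
        assert got <= sup


def test_empty_tables_give_empty_annotation(toy_genome):
    genes, _ = toy_genome(["NONE", "NONE"])
    out = ann.annotate_genome(
        genes,
        pd.DataFrame(columns=ann.DOMAIN_HIT_COLUMNS),
        pd.DataFrame(columns=ann.SEARCH_HIT_COLUMNS),
    )
    assert all(v == frozenset() for v in out.values())


def test_unresolvable_protein_ids_error(toy_genome):
    genes, _ = toy_genome(["NONE"])
    with pytest.raises(ValueError, match="ghost"):
        ann.annotate_genome(
            genes,
            frame(hit(pid="ghost")),
            pd.DataFrame(columns=ann.SEARCH_HIT_COLUMNS),
        )


def test_hit_table_io_roundtrip(tmp_path, zero_noise_assembly):
    """Writing and re-reading the HMMER/BLAST dialects must preserve every
    filtering decision."""
    truth, domain, search, _ = zero_noise_assembly
    io.write_domtbl(domain, tmp_path / "hits.domtbl")
    io.write_search_table(search, tmp_path / "hits.blast.tsv")
    domain2 = io.read_domtbl(tmp_path / "hits.domtbl")
    search2 = io.read_search_table(tmp_path / "hits.blast.tsv")
    a1 = ann.annotate_genome(truth.genes, domain, search)
    a2 = ann.annotate_genome(truth.genes, domain2, search2)
    assert {
        (g, c.label) for g, calls in a1.items() for c in calls
    } == {(g, c.label) for g, calls in a2.items() for c in calls}
    assert np.allclose(
        sorted(domain["profile_coverage"]), sorted(domain2["profile_coverage"])
    )
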