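"""Anchor pairing, frame-based locus extension (against a brute-force
fixed-point oracle), merging, screening and full-assembly closure."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pulcascade import synthetic
from pulcascade.annotation import annotate_genome
from pulcascade.core import GT, NONE, SUSC, SUSD
from pulcascade.mining import (
    MineParams,
    extend_span,
    extract_pul,
    find_suscd_pairs,
    mine_assembly,
    screen_filter,
)

from conftest import build_toy_genome


# ------------------------------------------------------------ anchor pairing
def test_adjacent_pair_found(toy_genome):
    genes, annot = toy_genome([NONE, SUSC, SUSD, NONE])
    pairs = find_suscd_pairs(genes, annot)
    assert [(c.gene_id, d.gene_id) for c, d in pairs] == [
        ("ctg01_g0001", "ctg01_g0002")
    ]


def test_pair_respects_max_gap(toy_genome):
    genes, annot = toy_genome([SUSC, NONE, NONE, NONE, SUSD])
    assert find_suscd_pairs(genes, annot, max_gap=1) == []
    assert len(find_suscd_pairs(genes, annot, max_gap=3)) == 1


def test_pair_either_order_and_strand_rule(toy_genome):
    genes, annot = toy_genome([SUSD, SUSC], strands=["+", "+"])
    (pair,) = find_suscd_pairs(genes, annot)
    assert pair[0].gene_id == "ctg01_g0001"  # susC listed first
    genes, annot = toy_genome([SUSC, SUSD], strands=["+", "-"])
    assert find_suscd_pairs(genes, annot) == []
    assert len(find_suscd_pairs(genes, annot, require_same_strand=False)) == 1


def test_tandem_run_gives_two_disjoint_pairs(toy_genome):
    genes, annot = toy_genome([SUSC, SUSD, SUSC, SUSD])
    pairs = find_suscd_pairs(genes, annot)
    assert len(pairs) == 2
    used = [g.gene_id for p in pairs for g in p]
    assert len(used) == len(set(used))


def _pairing_oracle(labels, max_gap=1):
    """Independent greedy pairing: left-to-right, closest pair first, each
    gene used once."""
    marks = [(i, l) for i, l in enumerate(labels) if l in (SUSC, SUSD)]
    cands = []
    for (i, li), (j, lj) in itertools.combinations(marks, 2):
        if li != lj and j - i - 1 <= max_gap:
            cands.append((i, j - i, i if li == SUSC else j, j if li == SUSC else i))
    cands.sort(key=lambda c: (c[0], c[1]))
    used, out = set(), []
    for _, _, ci, di in cands:
        if ci in used or di in used:
            continue
        used.update((ci, di))
        out.append((ci, di))
    return out


def test_pairing_matches_bruteforce_on_all_arrangements():
    for labels in itertools.product([NONE, SUSC, SUSD], repeat=6):
        genes, annot = build_toy_genome(list(labels))
        got = [
            (c.order_index, d.order_index)
            for c, d in find_suscd_pairs(genes, annot)
        ]
        assert got == _pairing_oracle(labels), labels


# -------------------------------------------------------- locus extension
CAZ = "GH26"


def anchored(labels_left, labels_right):
    """Build a toy contig <left> SUSC SUSD <right> and return pieces."""
    labels = list(labels_left) + [SUSC, SUSD] + list(labels_right)
    genes, annot = build_toy_genome(labels)
    anchor = (genes[len(labels_left)], genes[len(labels_left) + 1])
    return labels, genes, annot, anchor


def test_upstream_cazyme_within_frame_extends_span():
    _, genes, annot, anchor = anchored([CAZ, NONE, NONE], [])
    pul = extract_pul(anchor, genes, annot)
    assert pul.span == (0, 4)
    assert pul.family_set == {CAZ}


def test_cazyme_outside_frame_ignored():
    _, genes, annot, anchor = anchored([], [NONE] * 7 + [CAZ])
    pul = extract_pul(anchor, genes, annot, frame=7)
    assert pul.span == (0, 1)


def test_gt_only_neighbor_never_extends():
    _, genes, annot, anchor = anchored([], [NONE, GT])
    pul = extract_pul(anchor, genes, annot)
    assert pul.span == (0, 1)
    assert pul.family_set == frozenset()


def test_iterative_window_chains_beyond_one_frame():
    # CAZymes at +3 and +9: the second is reachable only after the window
    # advances to the first.
    _, genes, annot, anchor = anchored([], [NONE, NONE, CAZ, NONE, NONE, NONE, NONE, NONE, CAZ])
    assert extract_pul(anchor, genes, annot, frame=7).span == (0, 10)
    assert extract_pul(anchor, genes, annot, frame=7, window_mode="fixed").span == (0, 4)


def _fixed_point_oracle(caz, keep, left, right, frame):
    """Least fixed point of 'absorb any CAZyme within ``frame`` genes of the
    span', then trim to terminus-eligible genes."""
    changed = True
    while changed:
        changed = False
        for j, c in enumerate(caz):
            if c and (left - frame <= j < left or right < j <= right + frame):
                left, right = min(left, j), max(right, j)
                changed = True
    while left < right and not keep[left]:
        left += 1
    while right > left and not keep[right]:
        right -= 1
    return left, right


def _flags(labels):
    caz = [l not in (NONE, GT, SUSC, SUSD) for l in labels]
    keep = [c or l in (SUSC, SUSD) for c, l in zip(caz, labels)]
    return caz, keep


@pytest.mark.parametrize("frame", [1, 2, 7])
def test_extraction_matches_oracle_on_random_full_alphabet(frame):
    rng = np.random.default_rng(2024)
    alphabet = [NONE, CAZ, "CE2", GT, SUSC, SUSD]
    for _ in range(800):
        n_left = int(rng.integers(0, 7))
        n_right = int(rng.integers(0, 7))
        left_labels = [alphabet[i] for i in rng.integers(0, len(alphabet), n_left)]
        right_labels = [alphabet[i] for i in rng.integers(0, len(alphabet), n_right)]
        labels = list(left_labels) + [SUSC, SUSD] + list(right_labels)
        genes, annot = build_toy_genome(labels)
        anchor = (genes[n_left], genes[n_left + 1])
        pul = extract_pul(anchor, genes, annot, frame=frame)
        caz, keep = _flags(labels)
        want = _fixed_point_oracle(caz, keep, n_left, n_left + 1, frame)
        assert pul.span == want, labels


@settings(derandomize=True, max_examples=200)
@given(
    codes=st.lists(st.integers(0, 2), min_size=0, max_size=12),
    split=st.integers(0, 12),
    frame=st.integers(1, 8),
)
def test_frame_monotonicity(codes, split, frame):
    """A larger frame never shrinks the extended span."""
    split = min(split, len(codes))
    caz = [c == 1 for c in codes[:split]] + [False, False] + [c == 1 for c in codes[split:]]
    l0, r0 = split, split + 1
    a = extend_span(caz, l0, r0, frame)
    b = extend_span(caz, l0, r0, frame + 1)
    assert b[0] <= a[0] and a[1] <= b[1]


# ------------------------------------------------- screening, merge, closure
def test_screen_filter_requires_gh26():
    from types import SimpleNamespace

    def fake(fams):
        return SimpleNamespace(family_set=frozenset(fams))

    kept, summary = screen_filter([fake({"GH26", "GH27"}), fake({"GH5", "GH27"}), fake(set())])
    assert len(kept) == 1 and summary["n_dropped"] == 2
    kept, _ = screen_filter([fake({"GH26_3"})])  # subfamilies count
    assert len(kept) == 1


def test_overlapping_anchor_spans_merge():
    labels = [CAZ, SUSC, SUSD, NONE, CAZ, NONE, SUSC, SUSD, CAZ]
    genes, annot = build_toy_genome(labels)
    puls = mine_assembly(genes, annot)
    assert len(puls) == 1
    assert puls[0].span == (0, 8)
    assert len(puls[0].anchors) == 2
    assert puls[0].provenance.get("merged")


def test_mine_zero_noise_recovers_planted_spans():
    truth = synthetic.generate_genome(2, 40, 2, n_decoys=0, seed=7)
    domain, search, _ = synthetic.generate_hit_tables(truth, synthetic.NoiseConfig(seed=7))
    annotations = annotate_genome(truth.genes, domain, search)
    puls = mine_assembly(truth.genes, annotations)
    got = {(p.contig_id, *p.span) for p in puls}
    want = {(p.contig_id, p.start_index, p.end_index) for p in truth.planted_puls}
    assert got == want


def test_decoy_only_genome_yields_nothing():
    truth = synthetic.generate_genome(1, 60, 0, n_decoys=3, seed=3)
    domain, search, _ = synthetic.generate_hit_tables(truth, synthetic.NoiseConfig(seed=3))
    annotations = annotate_genome(truth.genes, domain, search)
    assert mine_assembly(truth.genes, annotations) == []


def test_mine_params_validation():
    with pytest.raises(ValueError):
        MineParams(frame=0)
    with pytest.raises(ValueError):
        MineParams(window_mode="sideways")
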