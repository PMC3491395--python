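import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from psidr.parent import (
    AlignmentPair,
    GAP_EXTEND,
    GAP_OPEN,
    MATCH,
    MISMATCH,
    align_pair,
    assign_parent,
    cds_identity,
    classify_identity_group,
    utr3_window_identity,
)
from psidr.simulate import SimulationConfig, simulate_annotation, simulate_sequences


# ------------------------------------------------------------ parent choice


@pytest.mark.parametrize(
    "candidates, expected",
    [
        ({"manual": "P1", "automated": "P2"}, ("P1", "manual")),
        ({"alignment": "P3"}, ("P3", "alignment")),
        ({"automated": "P4", "alignment": "P3", "manual": "P1"}, ("P1", "manual")),
        ({"automated": "P4", "alignment": "P3"}, ("P3", "alignment")),
        ({}, (None, "none")),
    ],
)
def test_assign_parent_priority(candidates, expected):
    assert assign_parent(candidates) == expected


# ---------------------------------------------------------------- alignment


def _gotoh_score(a, b):
    """Independent affine-gap global alignment score (Gotoh DP); a gap of
    length k costs GAP_OPEN + (k-1)*GAP_EXTEND."""
    n, m = len(a), len(b)
    NEG = -1e9
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b (consume a)
    Y = np.full((n + 1, m + 1), NEG)  # gap in a (consume b)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = GAP_OPEN + (i - 1) * GAP_EXTEND
    for j in range(1, m + 1):
        Y[0, j] = GAP_OPEN + (j - 1) * GAP_EXTEND
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + GAP_OPEN, X[i - 1, j] + GAP_EXTEND)
            Y[i, j] = max(M[i, j - 1] + GAP_OPEN, Y[i, j - 1] + GAP_EXTEND)
    return max(M[n, m], X[n, m], Y[n, m])


def test_align_identical_sequences_all_match():
    seq = "ACGTACGTACGT" * 5
    pair = align_pair(seq, seq)
    assert pair.columns["CDS"] == "M" * len(seq)
    assert cds_identity(pair) == 100.0


def test_single_substitution_identity():
    parent = "A" * 50 + "C" + "A" * 49
    pseudo = "A" * 100
    pair = align_pair(pseudo, parent)
    assert cds_identity(pair) == 99.0


def test_alignment_score_matches_gotoh_oracle_on_short_sequences():
    rng = np.random.default_rng(11)
    bases = np.array(list("ACGT"))
    for _ in range(40):
        a = "".join(rng.choice(bases, size=int(rng.integers(3, 13))))
        b = "".join(rng.choice(bases, size=int(rng.integers(3, 13))))
        assert align_pair(a, b).score == pytest.approx(_gotoh_score(a, b))


def test_empty_sequence_rejected():
    with pytest.raises(ValueError):
        align_pair("", "ACGT")


def test_region_split_by_parent_cds_length():
    parent = "ACGTACGTAC" + "TTTTTGGGGG"  # CDS 10 | UTR 10
    pair = align_pair(parent, parent, parent_cds_len=10)
    assert len(pair.columns["CDS"]) == 10
    assert len(pair.columns["UTR3"]) == 10


# -------------------------------------------------------------- identities


def test_hand_counted_toy_alignment():
    # 20 columns: 15 M, 3 X, 2 G -> identity 75%
    pair = AlignmentPair("p", "q", {"CDS": "MMMMMXMMMXMMMMGXMMGM", "UTR3": ""}, 0.0)
    assert cds_identity(pair) == 75.0


def test_all_gap_identity_zero():
    pair = AlignmentPair("p", "q", {"CDS": "G" * 30, "UTR3": ""}, 0.0)
    assert cds_identity(pair) == 0.0


def test_identity_undefined_on_empty_region():
    pair = AlignmentPair("p", "q", {"CDS": "", "UTR3": ""}, 0.0)
    with pytest.raises(ValueError):
        cds_identity(pair)


def _brute_window_identity(cols, window=100):
    if len(cols) <= window:
        return 100.0 * cols.count("M") / len(cols)
    return max(
        100.0 * cols[i : i + window].count("M") / window
        for i in range(len(cols) - window + 1)
    )


def test_window_identity_matches_brute_force_on_random_alignments():
    rng = np.random.default_rng(5)
    states = np.array(list("MXG"))
    for _ in range(200):
        cols = "".join(rng.choice(states, size=500, p=[0.6, 0.3, 0.1]))
        pair = AlignmentPair("p", "q", {"CDS": "", "UTR3": cols}, 0.0)
        assert utr3_window_identity(pair) == pytest.approx(_brute_window_identity(cols))


def test_window_identity_finds_perfect_island():
    cols = "X" * 150 + "M" * 100 + "X" * 150
    pair = AlignmentPair("p", "q", {"CDS": "", "UTR3": cols}, 0.0)
    assert utr3_window_identity(pair) == 100.0


def test_short_region_scored_whole():
    pair = AlignmentPair("p", "q", {"CDS": "", "UTR3": "MMMX"}, 0.0)
    assert utr3_window_identity(pair) == 75.0


# ----------------------------------------------------------- classification


@pytest.mark.parametrize(
    "cds, utr, group",
    [
        (85, 55, "highCDS-lowUTR"),
        (55, 85, "lowCDS-highUTR"),
        (60, 80, "midCDS-midUTR"),  # closed mid bin at both edges
        (59.999, 80.001, "lowCDS-highUTR"),
        (100, 0, "highCDS-lowUTR"),
    ],
)
def test_classify_identity_group(cds, utr, group):
    assert classify_identity_group(cds, utr).group == group


@settings(derandomize=True, max_examples=200)
@given(
    st.floats(min_value=0, max_value=100, allow_nan=False),
    st.floats(min_value=0, max_value=100, allow_nan=False),
)
def test_classification_is_total(cds, utr):
    group = classify_identity_group(cds, utr).group
    parts = group.split("-")
    assert parts[0][:-3] in {"low", "mid", "high"} and parts[1][:-3] in {"low", "mid", "high"}


def test_classify_rejects_out_of_range():
    with pytest.raises(ValueError):
        classify_identity_group(101, 50)


# ------------------------------------------------ simulated sequence recovery


def test_simulated_identities_recovered_within_two_points():
    cfg = SimulationConfig(seed=9, n_pseudogenes=40, n_coding_genes=12, n_near_coding=2)
    _, _, manual, *_ = simulate_annotation(cfg)
    targets = {manual[0].id: (100.0, 100.0), manual[1].id: (85.0, 55.0)}
    sequences, used = simulate_sequences(manual, cfg, targets)
    for pg in manual[:20]:
        pseudo, parent, cds_len = sequences[pg.id]
        pair = align_pair(pseudo, parent, cds_len)
        t_cds, t_utr = used[pg.id]
        assert cds_identity(pair) == pytest.approx(t_cds, abs=2.0)
        assert utr3_window_identity(pair) == pytest.approx(t_utr, abs=2.0)
    # perfect-identity pair is exactly the parent
    pseudo, parent, _ = sequences[manual[0].id]
    assert pseudo == parent


def test_simulated_target_out_of_range_rejected():
    cfg = SimulationConfig(seed=9, n_pseudogenes=10, n_coding_genes=6, n_near_coding=1)
    _, _, manual, *_ = simulate_annotation(cfg)
    with pytest.raises(ValueError):
        simulate_sequences(manual, cfg, {manual[0].id: (120.0, 50.0)})
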