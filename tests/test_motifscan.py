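"""PWM construction, exact score distributions, scanning, background, chi2."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest

from coopenh import motifscan
from coopenh.intervals import GenomicInterval
from coopenh.motifscan import (
    benjamini_hochberg,
    pwm_from_counts,
    regulon_overrepresentation,
    reverse_complement,
    scan,
    score_distribution,
    shuffle_background,
    tf_enrichment,
)


def _sharp_pwm(consensus: str, name: str = "TF") -> motifscan.PWM:
    counts = np.zeros((len(consensus), 4))
    for j, b in enumerate(consensus):
        counts[j, "ACGT".index(b)] = 12
    return pwm_from_counts(name, counts)


# ---------------------------------------------------------------------------
# PWM construction


def test_pwm_probabilities_with_pseudocount():
    counts = np.array([[100, 0, 0, 0]] * 4)
    pwm = pwm_from_counts("t", counts, pseudocount=0.5)
    assert pwm.probs[0, 0] == pytest.approx(100.5 / 102)
    assert pwm.probs.sum(axis=1) == pytest.approx(np.ones(4), abs=1e-12)


def test_flat_counts_give_zero_log_odds():
    pwm = pwm_from_counts("t", np.full((5, 4), 3.0))
    assert np.allclose(pwm.log_odds, 0.0)


def test_pwm_rejects_bad_input():
    with pytest.raises(ValueError):
        pwm_from_counts("t", np.zeros((4, 4)))  # all-zero position
    with pytest.raises(ValueError):
        pwm_from_counts("t", np.ones((3, 4)))  # width < 4
    with pytest.raises(ValueError):
        pwm_from_counts("t", -np.ones((4, 4)))


def test_jaspar_round_trip(tmp_path):
    counts = {"TFA": np.array([[12, 0, 0, 0]] * 6), "TFB": np.array([[0, 9, 3, 0]] * 5)}
    path = tmp_path / "pwms.jaspar"
    motifscan.write_jaspar(counts, path)
    pwms = motifscan.read_jaspar(path)
    assert [p.name for p in pwms] == ["TFA", "TFB"]
    assert pwms[0].consensus == "AAAAAA"


# ---------------------------------------------------------------------------
# exact score distribution


def test_width1_like_distribution_is_base_distribution():
    # Minimal allowed width is 4; a PWM informative at one position only has
    # a 4-outcome distribution shifted by the flat positions (score 0 there).
    counts = np.vstack([[12, 0, 0, 0], np.full((3, 4), 3.0)])
    pwm = pwm_from_counts("t", counts)
    dist = score_distribution(pwm)
    support = np.flatnonzero(dist.pmf)
    assert support.size == 2  # A vs non-A at the informative position
    probs = dist.pmf[support]
    assert probs == pytest.approx([0.75, 0.25])


def test_distribution_mass_and_enumeration_oracle():
    rng = np.random.default_rng(3)
    counts = rng.integers(0, 13, size=(4, 4)).astype(float) + 0.2
    pwm = pwm_from_counts("t", counts)
    dist = score_distribution(pwm, granularity=1e-4)
    assert dist.pmf.sum() == pytest.approx(1.0, abs=1e-9)
    # enumerate all 256 windows with the same integerised scores
    tail = {}
    for window in itertools.product(range(4), repeat=4):
        s = int(sum(dist.int_log_odds[j, b] for j, b in enumerate(window)))
        tail[s] = tail.get(s, 0.0) + 0.25 ** 4
    for s, mass in tail.items():
        expected_sf = sum(v for k, v in tail.items() if k >= s)
        assert dist.p_value(np.array([s]))[0] == pytest.approx(expected_sf, abs=1e-6)


def test_max_score_has_positive_p():
    pwm = _sharp_pwm("ACGTAC")
    dist = score_distribution(pwm)
    top = dist.min_score + dist.pmf.size - 1
    p = dist.p_value(np.array([top]))[0]
    assert 0 < p <= 0.25 ** 5  # at most P(consensus window)


# ---------------------------------------------------------------------------
# scanning


def test_scan_finds_planted_consensus():
    rng = np.random.default_rng(1)
    bases = np.array(list("ACGT"))
    seq = "".join(rng.choice(bases, 400))
    pwm = _sharp_pwm("ACGTACGTGG")
    planted = seq[:200] + pwm.consensus + seq[210:]
    hits = scan({"region": planted}, pwm, q_threshold=0.5)
    best = min(hits, key=lambda h: h.p_value)
    assert best.interval.start == 200
    assert best.strand == "+"


def test_scan_reverse_complement_symmetry():
    rng = np.random.default_rng(2)
    seq = "".join(np.random.default_rng(2).choice(list("ACGT"), 300))
    pwm = _sharp_pwm("ACGTACGT")
    fwd = scan({"s": seq}, pwm, q_threshold=0.9)
    rev = scan({"s": reverse_complement(seq)}, pwm, q_threshold=0.9)
    L, w = len(seq), pwm.width
    mirrored = {(L - w - h.interval.start, {"+": "-", "-": "+"}[h.strand],
                 round(h.score, 6)) for h in rev}
    assert {(h.interval.start, h.strand, round(h.score, 6)) for h in fwd} == mirrored


def test_scan_matches_brute_force_on_toy_sequence():
    rng = np.random.default_rng(5)
    seq = "".join(rng.choice(list("ACGT"), 60))
    counts = rng.integers(0, 13, size=(4, 4)).astype(float) + 0.2
    pwm = pwm_from_counts("t", counts)
    dist = score_distribution(pwm)
    hits = scan({"s": seq}, pwm, q_threshold=1.0, dist=dist)
    enc = [int("ACGT".index(b)) for b in seq]
    for h in [h for h in hits if h.strand == "+"]:
        s = sum(
            dist.int_log_odds[j, enc[h.interval.start + j]] for j in range(4)
        )
        assert h.score == pytest.approx(s * dist.granularity)
        assert h.p_value == pytest.approx(dist.p_value(np.array([s]))[0])


def test_scan_skips_windows_with_n():
    pwm = _sharp_pwm("ACGT")
    hits = scan({"s": "ACGTN" + "ACGT"}, pwm, q_threshold=1.0)
    starts = {h.interval.start for h in hits if h.strand == "+"}
    assert 0 in starts and 5 in starts
    assert not {1, 2, 3, 4} & starts  # every window crossing the N is skipped


def test_scan_short_sequence_yields_nothing():
    assert scan({"s": "ACG"}, _sharp_pwm("ACGTAC")) == []


# ---------------------------------------------------------------------------
# shuffled background


def test_shuffle_background_contract():
    region = GenomicInterval("chr1", 400_000, 401_000)
    (bg,) = shuffle_background([region], {"chr1": 1_000_000}, seed=0)
    assert bg.chrom == "chr1"
    assert len(bg) == 1000
    assert not bg.overlaps(region)


def test_shuffle_background_forced_slot():
    # exclude everything except one 1 kb window; rejection sampling must hit
    # the single valid start, so allow it a generous number of tries
    excl = [GenomicInterval("chr1", 0, 50_000), GenomicInterval("chr1", 51_000, 100_000)]
    region = GenomicInterval("chr1", 10_000, 11_000)
    (bg,) = shuffle_background([region], {"chr1": 100_000},
                               seed=3, excluded=excl, max_tries=2_000_000)
    assert (bg.start, bg.end) == (50_000, 51_000)


def test_shuffle_background_reports_infeasible_chromosome():
    region = GenomicInterval("chr1", 0, 900)
    excl = [GenomicInterval("chr1", 0, 1000)]
    with pytest.raises(RuntimeError, match="chr1"):
        shuffle_background([region], {"chr1": 1000}, seed=0, excluded=excl,
                           max_tries=50)


def test_shuffle_background_deterministic():
    regions = [GenomicInterval("chr1", i * 10_000, i * 10_000 + 500) for i in range(10)]
    a = shuffle_background(regions, {"chr1": 500_000}, seed=42)
    b = shuffle_background(regions, {"chr1": 500_000}, seed=42)
    assert a == b


# ---------------------------------------------------------------------------
# enrichment statistics


def test_tf_enrichment_equal_fractions_not_selected():
    rec, = tf_enrichment({"t": [True] * 5 + [False] * 5},
                         {"t": [True] * 5 + [False] * 5})
    assert rec.chi2_stat == 0.0
    assert rec.p_value == 1.0
    assert not rec.selected


def test_tf_enrichment_hand_computed_chi2():
    re_flags = [True] * 90 + [False] * 10
    bg_flags = [True] * 10 + [False] * 90
    (rec,) = tf_enrichment({"t": re_flags}, {"t": bg_flags})
    assert rec.chi2_stat == pytest.approx(128.0)
    assert rec.binding_difference == pytest.approx(80.0)
    assert rec.selected


def test_tf_enrichment_direction_filter():
    # strongly depleted in REs: tiny p but negative difference -> not selected
    (rec,) = tf_enrichment({"t": [False] * 90 + [True] * 10},
                           {"t": [True] * 90 + [False] * 10})
    assert rec.p_value < 1e-10
    assert rec.binding_difference < 0
    assert not rec.selected


def test_tf_enrichment_requires_regions():
    with pytest.raises(ValueError):
        tf_enrichment({"t": []}, {"t": [True]})


def test_tf_enrichment_ranked_by_binding_difference():
    records = tf_enrichment(
        {"a": [True] * 3 + [False] * 7, "b": [True] * 8 + [False] * 2},
        {"a": [False] * 10, "b": [False] * 10},
    )
    assert [r.tf for r in records] == ["b", "a"]


# ---------------------------------------------------------------------------
# Benjamini-Hochberg


def test_bh_single_p():
    assert benjamini_hochberg([0.03]) == pytest.approx([0.03])


def test_bh_step_up_hand_example():
    q = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
    assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])


def test_bh_monotone_and_order_invariant():
    rng = np.random.default_rng(0)
    p = rng.uniform(1e-6, 1, 100)
    q = benjamini_hochberg(p)
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-12).all()
    perm = rng.permutation(100)
    assert benjamini_hochberg(p[perm]) == pytest.approx(q[perm])
    assert (q >= p).all()


def test_bh_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(4)
    p = rng.uniform(1e-8, 1, 250)
    q = benjamini_hochberg(p)
    _, q_sm, _, _ = multipletests(p, method="fdr_bh")
    assert q == pytest.approx(q_sm)


def test_bh_rejects_invalid_p():
    with pytest.raises(ValueError):
        benjamini_hochberg([0.0, 0.5])


# ---------------------------------------------------------------------------
# regulon over-representation


def test_regulon_subset_of_targets_selected():
    universe = {f"g{i}" for i in range(500)}
    targets = {f"g{i}" for i in range(40)}
    regulons = {"TF1": {f"g{i}" for i in range(10)}}  # fully inside targets
    df = regulon_overrepresentation(targets, regulons, universe)
    assert df.loc[0, "selected"]
    assert df.loc[0, "p_value"] < 1e-9


def test_regulon_disjoint_gives_p_one():
    universe = {f"g{i}" for i in range(100)}
    df = regulon_overrepresentation(
        {f"g{i}" for i in range(10)},
        {"TF1": {f"g{i}" for i in range(50, 60)}},
        universe,
    )
    assert df.loc[0, "p_value"] == pytest.approx(1.0)


def test_regulon_empty_universe_rejected():
    with pytest.raises(ValueError):
        regulon_overrepresentation(set(), {"TF": set()}, set())


def test_regulon_matches_exact_enumeration():
    # 20-gene toy universe: exact hypergeometric tail by rational arithmetic
    universe = {f"g{i}" for i in range(20)}
    targets = {f"g{i}" for i in range(8)}
    regulon = {f"g{i}" for i in range(5, 12)}  # overlap k = 3
    df = regulon_overrepresentation(targets, {"TF": regulon}, universe)
    N, K, n, k = 20, 7, 8, 3
    tail = sum(
        Fraction(math.comb(K, i) * math.comb(N - K, n - i), math.comb(N, n))
        for i in range(k, min(K, n) + 1)
    )
    assert df.loc[0, "p_value"] == pytest.approx(float(tail), abs=1e-12)
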