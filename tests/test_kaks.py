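import math
import random

import pytest

from oracles import (
    oracle_pair_differences,
    oracle_site_counts,
    oracle_two_codon_kaks,
    random_sense_codon,
)
from iqdfam.io import IqdfamError
from iqdfam.kaks import (
    SENSE_CODONS,
    CodonAlignment,
    classify_selection,
    date_divergence,
    kaks_estimate,
    ng86_pair_differences,
    ng86_site_counts,
    sliding_window_kaks,
)
from iqdfam.simulate import gen_diverged_cds_pair


def _pair_alignment(a: str, b: str) -> CodonAlignment:
    return CodonAlignment(
        [(a[i:i + 3], b[i:i + 3]) for i in range(0, len(a), 3)]
    )


@pytest.mark.parametrize(
    "codon,n,s",
    [
        ("TTT", 8 / 3, 1 / 3),   # only TTT->TTC is synonymous among 9 mutants
        ("ATG", 3.0, 0.0),       # Met has no synonym
        ("TAT", 2.0, 1.0),       # third position: TAA/TAG are stops, TAC syn
    ],
)
def test_site_counts_hand_enumerated(codon, n, s):
    got_n, got_s = ng86_site_counts(codon)
    assert got_n == pytest.approx(n, abs=1e-12)
    assert got_s == pytest.approx(s, abs=1e-12)


def test_site_counts_match_oracle_for_all_sense_codons():
    for codon in SENSE_CODONS:
        n, s = ng86_site_counts(codon)
        on, os_ = oracle_site_counts(codon)
        assert n == pytest.approx(on, abs=1e-12)
        assert s == pytest.approx(os_, abs=1e-12)
        assert n + s == pytest.approx(3.0, abs=1e-12)


@pytest.mark.parametrize(
    "a,b,nd,sd",
    [
        ("GGT", "GGC", 0.0, 1.0),    # Gly->Gly single step
        ("AAA", "AAA", 0.0, 0.0),
        ("TTT", "GTA", 1.5, 0.5),    # two pathways, averaged
    ],
)
def test_pair_differences_hand_enumerated(a, b, nd, sd):
    assert ng86_pair_differences(a, b) == pytest.approx((nd, sd), abs=1e-12)


def test_pair_differences_match_oracle_on_random_pairs():
    rng = random.Random(21)
    for _ in range(500):
        a, b = random_sense_codon(rng), random_sense_codon(rng)
        try:
            want = oracle_pair_differences(a, b)
        except AssertionError:
            continue
        got = ng86_pair_differences(a, b)
        assert got == pytest.approx(want, abs=1e-12)
        k = sum(x != y for x, y in zip(a, b))
        assert got[0] + got[1] == pytest.approx(k, abs=1e-12)


def test_estimate_identical_and_pure_synonymous():
    cds = "ATGGCTGCTAAGCGTTTCGAACTGGGTATG" * 6
    res = kaks_estimate(_pair_alignment(cds, cds))
    assert res.ka == 0.0 and res.ks == 0.0 and res.ratio is None
    a, b, truth = gen_diverged_cds_pair(seed=2, n_codons=100, target_ks=0.3, omega=0.0)
    assert truth.realized_nd == 0
    res = kaks_estimate(_pair_alignment(a, b))
    assert res.ka == 0.0
    assert res.ks is not None and res.ks > 0


def test_two_codon_alignments_match_exhaustive_oracle():
    rng = random.Random(33)
    for _ in range(200):
        cols = (
            (random_sense_codon(rng), random_sense_codon(rng)),
            (random_sense_codon(rng), random_sense_codon(rng)),
        )
        try:
            N, S, Nd, Sd, ka, ks = oracle_two_codon_kaks(*cols)
        except AssertionError:
            continue
        res = kaks_estimate(CodonAlignment(list(cols)))
        assert res.N == pytest.approx(N, abs=1e-12)
        assert res.S == pytest.approx(S, abs=1e-12)
        assert res.Nd == pytest.approx(Nd, abs=1e-12)
        assert res.Sd == pytest.approx(Sd, abs=1e-12)
        for got, want, p in ((res.ka, ka, res.pn), (res.ks, ks, res.ps)):
            if (want is None) != (got is None):
                # saturation threshold reached by one summation order only
                assert abs(p - 0.75) < 1e-9
            elif want is not None:
                assert got == pytest.approx(want, abs=1e-9)


def test_gapped_columns_skipped_and_empty_alignment_errors():
    aln = CodonAlignment([("ATG", "ATG"), ("---", "GGG"), ("AAA", "AAG")])
    res = kaks_estimate(aln)
    assert res.N + res.S == pytest.approx(6.0)  # two comparable codons
    with pytest.raises(IqdfamError, match="no comparable"):
        kaks_estimate(CodonAlignment([("---", "ATG")]))


def test_window_count_and_homogeneity():
    a, b, _ = gen_diverged_cds_pair(seed=5, n_codons=100, target_ks=0.1, omega=0.5)
    track = sliding_window_kaks(_pair_alignment(a[:300], b[:300]))
    assert len(track.windows) == 17  # floor((300-150)/9) + 1
    assert [w[0] for w in track.windows] == [9 * i for i in range(17)]
    assert all(w[1] - w[0] == 150 for w in track.windows)


def test_window_shorter_than_alignment_warns():
    a, b, _ = gen_diverged_cds_pair(seed=6, n_codons=60, target_ks=0.1, omega=0.5)
    sub = _pair_alignment(a[:120], b[:120])
    with pytest.warns(UserWarning, match="shorter than window"):
        track = sliding_window_kaks(sub)
    assert len(track.windows) == 1 and track.windows[0][1] == 120


def test_window_localizes_planted_positive_selection():
    # omega >> 1 in a 150 bp core, strong purifying elsewhere
    rng = random.Random(8)
    flank_a, flank_b, _ = gen_diverged_cds_pair(seed=71, n_codons=100, target_ks=0.25, omega=0.05)
    core_a, core_b, _ = gen_diverged_cds_pair(seed=72, n_codons=50, target_ks=0.25, omega=3.0)
    a = flank_a + core_a + flank_a
    b = flank_b + core_b + flank_b
    track = sliding_window_kaks(_pair_alignment(a, b))
    ratios = [
        (start, res.ratio) for start, _, res in track.windows if res.ratio is not None
    ]
    best_start = max(ratios, key=lambda t: t[1])[0]
    core_span = (300, 450)
    assert best_start < core_span[1] and best_start + 150 > core_span[0]


def test_dating_formula_and_linearity():
    res = date_divergence(0.15)
    assert res.t_mya == 11.54 and res.t_mya_nearest == 12
    assert date_divergence(0.0).t_years == 0.0
    assert date_divergence(0.13).t_mya == pytest.approx(10.0)
    assert date_divergence(0.30).t_years == pytest.approx(2 * date_divergence(0.15).t_years)
    assert date_divergence(0.15, 1.3e-8).t_years == pytest.approx(res.t_years / 2)
    with pytest.raises(IqdfamError):
        date_divergence(-0.1)
    with pytest.raises(IqdfamError):
        date_divergence(math.nan)


@pytest.mark.parametrize(
    "ratio,label",
    [(1.5, "positive"), (0.3, "purifying"), (1.0, "neutral"), (None, "undefined")],
)
def test_selection_classification(ratio, label):
    assert classify_selection(ratio) == label


def test_site_count_invariant_on_simulated_sequences():
    a, b, truth = gen_diverged_cds_pair(seed=9, n_codons=200, target_ks=0.15, omega=0.3)
    total = sum(sum(ng86_site_counts(a[i:i + 3])) for i in range(0, len(a), 3))
    assert total == pytest.approx(3 * 200, abs=1e-9)
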