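import random

import pytest

from oracles import brute_force_domain_triples, brute_force_motif_starts
from iqdfam.family import (
    classify_family,
    compute_protein_stats,
    find_iq67_domains,
    isoelectric_point,
    remove_redundant,
    scan_iq_motifs,
    scan_secondary_motifs,
    verify_phase0_boundary,
)
from iqdfam.io import GeneModel, IqdfamError, SequenceRecord
from iqdfam.simulate import gen_iq67_protein

PEIQD2_PEPTIDE = "SAIKIQSAFRSYLARKALCA"    # predicted CaM-binding string, residue 130
PEIQD20_PEPTIDE = "AAVMIQKAFRGYLARKALRA"   # predicted CaM-binding string, residue 8


def test_relaxed_scan_on_printed_peptide():
    hits = scan_iq_motifs(PEIQD2_PEPTIDE, "relaxed")
    assert [(h.start, h.matched) for h in hits] == [(4, "IQSAFRSYLAR")]
    # this peptide's motif is not strict-form (position 7 is S, not G)
    assert scan_iq_motifs(PEIQD2_PEPTIDE, "strict") == []


def test_strict_scan_on_printed_peptide():
    hits = scan_iq_motifs(PEIQD20_PEPTIDE, "strict")
    assert [(h.start, h.matched) for h in hits] == [(4, "IQKAFRGYLAR")]


def test_no_hits_in_polyA():
    assert scan_iq_motifs("A" * 30, "strict") == []
    assert scan_iq_motifs("A" * 30, "relaxed") == []


@pytest.mark.parametrize("mode,kind", [("strict", "strict"), ("relaxed", "relaxed")])
def test_scanner_matches_bruteforce_oracle(mode, kind):
    rng = random.Random(99)
    for _ in range(300):
        protein = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWYX") for _ in range(200))
        got = [h.start for h in scan_iq_motifs(protein, mode)]
        assert got == brute_force_motif_starts(protein, kind)


def test_strict_hits_subset_of_relaxed():
    rng = random.Random(5)
    for _ in range(200):
        protein = "".join(rng.choice("IQRGKLAV") for _ in range(80))
        strict = {h.start for h in scan_iq_motifs(protein, "strict")}
        relaxed = {h.start for h in scan_iq_motifs(protein, "relaxed")}
        assert strict <= relaxed


def test_scan_rejects_bad_input():
    with pytest.raises(IqdfamError, match="empty"):
        scan_iq_motifs("")
    with pytest.raises(IqdfamError, match="position 2"):
        scan_iq_motifs("MKB*Z")


def test_secondary_motif_minimal_anchor_and_oracle():
    hits = scan_secondary_motifs("LAAALAAAAL", (0, 10))
    assert [(h.kind, h.start) for h in hits] == [("m1_5_10", 0)]
    assert scan_secondary_motifs("G" * 40, (0, 40)) == []
    rng = random.Random(7)
    for _ in range(100):
        protein = "".join(rng.choice("FILVWAG") for _ in range(60))
        got = sorted(
            (h.kind, h.start) for h in scan_secondary_motifs(protein, (0, len(protein)))
        )
        want = sorted(
            [("m1_5_10", s) for s in brute_force_motif_starts(protein, "m1_5_10")]
            + [("m1_8_14", s) for s in brute_force_motif_starts(protein, "m1_8_14")]
        )
        assert got == want


def test_domain_assembly_recovers_planted_and_matches_triples():
    rec, truth = gen_iq67_protein(seed=1, n_domains=1)
    domains = find_iq67_domains(rec.residues)
    assert len(domains) == 1
    d = domains[0]
    start, end, spacers = truth.planted_domains[rec.id][0]
    assert d.span == (start, end)
    assert (d.spacer1_len, d.spacer2_len) == spacers == (11, 15)
    assert d.span[1] - d.span[0] == 59


def test_two_motifs_do_not_make_a_domain():
    protein = "IQAAARGAAAR" + "A" * 11 + "IQAAARGAAAR" + "A" * 40
    assert len(scan_iq_motifs(protein, "strict")) == 2
    assert find_iq67_domains(protein) == []


def test_domain_sets_match_exhaustive_triple_enumeration():
    # dense IQ-motif soup: every greedy domain must be the first available
    # triple of the brute-force enumeration
    rng = random.Random(17)
    for _ in range(200):
        protein = "".join(rng.choice("IQRAK") for _ in range(150))
        domains = find_iq67_domains(protein)
        triples = brute_force_domain_triples(protein)
        starts = {t[0] for t in triples}
        for d in domains:
            a, b, c = (h.start for h in d.iq_hits)
            assert (a, b, c) in triples
        if triples and not domains:
            raise AssertionError("scanner missed an available triple")
        if domains:
            assert domains[0].iq_hits[0].start == min(starts)


def test_planted_domain_recovery_across_500_seeds():
    for seed in range(500):
        rec, truth = gen_iq67_protein(seed=seed, length=250, n_domains=2,
                                      decoy_motifs=(seed % 2 == 0))
        found = [(d.span[0], d.span[1]) for d in find_iq67_domains(rec.residues)]
        assert found == [(s, e) for s, e, _ in truth.planted_domains[rec.id]]


def test_classify_family_counts_and_redundancy(make_records):
    positives = [gen_iq67_protein(seed=s, length=200)[0] for s in range(10)]
    decoys = [gen_iq67_protein(seed=100 + s, length=200, n_domains=0,
                               decoy_motifs=True)[0] for s in range(10)]
    for i, r in enumerate(positives + decoys):
        r.id = f"p{i}"
    report = classify_family(positives + decoys)
    assert report["n_members"] == 10
    # a duplicated positive record is counted once
    dup = SequenceRecord("dup", "dup", positives[0].residues)
    assert classify_family(positives + [dup])["n_members"] == 10
    assert classify_family([])["n_members"] == 0


def test_remove_redundant_rules(make_records):
    a, b = make_records(["MKKK", "MKKK"])
    assert [r.id for r in remove_redundant([a, b])] == ["s0"]
    long, short = make_records(["M" * 400, "M" * 300 + "K" * 0])
    kept = remove_redundant([long, short], locus_tags={"s0": "L1", "s1": "L1"})
    assert [r.id for r in kept] == ["s0"]
    uniq = make_records(["MA", "MC", "MD"])
    assert remove_redundant(uniq) == uniq


def _model(intron_after_codons: int | None, phase: int = 0, n_codons: int = 70):
    total = 3 * n_codons
    if intron_after_codons is None:
        return GeneModel("g", "c", "+", [(0, total)], [(0, total, 0)])
    cut = 3 * intron_after_codons
    return GeneModel(
        "g", "c", "+",
        exons=[(0, cut), (cut + 500, cut + 500 + total - cut)],
        cds_segments=[(0, cut, 0), (cut + 500, cut + 500 + total - cut, phase)],
    )


def test_phase0_boundary_hallmark():
    assert verify_phase0_boundary(_model(16, phase=0), 0) is True
    assert verify_phase0_boundary(_model(16, phase=1), 0) is False
    assert verify_phase0_boundary(_model(None), 0) is False
    with pytest.raises(IqdfamError, match="past the CDS"):
        verify_phase0_boundary(_model(16, n_codons=30), 0)


def test_protein_stats_examples():
    g = compute_protein_stats("G")
    assert g.mw_da == pytest.approx(75.07, abs=0.01)
    assert isoelectric_point("DD") < 7 < isoelectric_point("KK")
    prot = "M" + "A" * 189
    cds = "ATG" + "GCT" * 189 + "TAA"
    st = compute_protein_stats(prot, cds)
    assert (st.length_aa, st.orf_length_bp) == (190, 573)
    assert st.orf_length_bp == 3 * (st.length_aa + 1)
    with pytest.raises(IqdfamError, match="translate"):
        compute_protein_stats("MK", "ATGATG")
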