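"""Pairwise alignment and paralog/ortholog detection rules.

Paralogs (within species): global alignment, shorter sequence covering
> 70% of the longer and >= 70% identity over gapless columns.
Orthologs (cross species): reciprocal best hits under local (Smith-Waterman)
score with > 300 aligned (gapless) nucleotide columns.

Alignment itself is delegated to Biopython's PairwiseAligner; a gap of
length k costs open + k*extend (protein 10 + 0.5k against BLOSUM62;
nucleotide match 2 / mismatch -3, gap 5 + 2k).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .io import IqdfamError, SequenceRecord
from .kaks import CodonAlignment

logger = logging.getLogger(__name__)

PROTEIN_GAP_OPEN = 10.0
PROTEIN_GAP_EXTEND = 0.5
NUC_MATCH = 2.0
NUC_MISMATCH = -3.0
NUC_GAP_OPEN = 5.0
NUC_GAP_EXTEND = 2.0


@dataclass
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float
    identity_pct: float
    coverage_pct: float
    aligned_residue_pairs: int
    aligned_bp: int


@dataclass
class HomologPair:
    id_a: str
    id_b: str
    relation: str  # "paralog" | "ortholog"
    alignment: AlignmentResult


def _aligner(alphabet: str, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    if alphabet == "protein":
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        open_, ext = PROTEIN_GAP_OPEN, PROTEIN_GAP_EXTEND
    elif alphabet == "nucleotide":
        aligner.match_score = NUC_MATCH
        aligner.mismatch_score = NUC_MISMATCH
        open_, ext = NUC_GAP_OPEN, NUC_GAP_EXTEND
    else:
        raise IqdfamError(f"unknown alphabet {alphabet!r}")
    # Biopython charges open_gap_score for the first gap position and
    # extend_gap_score for each further one; with these values a length-k
    # gap costs open + k*extend.
    aligner.open_gap_score = -(open_ + ext)
    aligner.extend_gap_score = -ext
    return aligner


def _result(aln, len_a: int, len_b: int) -> AlignmentResult:
    a, b = str(aln[0]), str(aln[1])
    pairs = ident = 0
    for x, y in zip(a, b):
        if x != "-" and y != "-":
            pairs += 1
            if x == y:
                ident += 1
    longer = max(len_a, len_b)
    return AlignmentResult(
        aligned_a=a, aligned_b=b, score=float(aln.score),
        identity_pct=100.0 * ident / pairs if pairs else 0.0,
        coverage_pct=100.0 * pairs / longer if longer else 0.0,
        aligned_residue_pairs=pairs, aligned_bp=pairs,
    )


def global_align(a: str, b: str, alphabet: str = "protein") -> AlignmentResult:
    """Optimal global (Needleman-Wunsch, affine gap) alignment.

    identity_pct is over gapless columns; coverage_pct is gapless columns
    over the longer input's length.
    """
    if not a or not b:
        raise IqdfamError("cannot align an empty sequence")
    aligner = _aligner(alphabet, "global")
    aln = aligner.align(a.upper(), b.upper())[0]
    return _result(aln, len(a), len(b))


def local_align(a: str, b: str, alphabet: str = "nucleotide") -> AlignmentResult:
    """Optimal local (Smith-Waterman) alignment under the nucleotide params."""
    if not a or not b:
        raise IqdfamError("cannot align an empty sequence")
    aligner = _aligner(alphabet, "local")
    alns = aligner.align(a.upper(), b.upper())
    aln = alns[0]
    return _result(aln, len(a), len(b))


COVERAGE_MIN = 70.0  # strict: "covers over 70%"
IDENTITY_MIN = 70.0  # inclusive: "minimum identity ... is 70%"


def find_paralog_pairs(
    genes: Sequence[SequenceRecord], alphabet: str = "nucleotide"
) -> list[HomologPair]:
    """All within-species pairs with coverage > 70% and identity >= 70%."""
    if len(genes) < 2:
        return []
    pairs: list[HomologPair] = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            res = global_align(genes[i].residues, genes[j].residues, alphabet)
            if res.coverage_pct > COVERAGE_MIN and res.identity_pct >= IDENTITY_MIN:
                pairs.append(HomologPair(genes[i].id, genes[j].id, "paralog", res))
    return pairs


ALIGNED_BP_MIN = 300  # strict: "more than 300 bp ... aligned"


def reciprocal_best_hits(
    set_a: Sequence[SequenceRecord], set_b: Sequence[SequenceRecord]
) -> list[HomologPair]:
    """Cross-species orthologs: mutual best local-alignment hits with
    > 300 gapless aligned bp.  Score ties break to the lexicographically
    smaller partner id (logged)."""
    if not set_a or not set_b:
        raise IqdfamError("both sequence sets must be non-empty")
    scores: dict[tuple[str, str], AlignmentResult] = {}
    for ra in set_a:
        for rb in set_b:
            scores[(ra.id, rb.id)] = local_align(ra.residues, rb.residues)

    def best(partner_ids, fixed_id, key):
        ranked = sorted(
            partner_ids,
            key=lambda pid: (-scores[key(fixed_id, pid)].score, pid),
        )
        top = ranked[0]
        tied = [p for p in ranked if scores[key(fixed_id, p)].score == scores[key(fixed_id, top)].score]
        if len(tied) > 1:
            logger.info("best-hit tie for %s among %s; keeping %s", fixed_id, tied, top)
        return top

    ids_a = [r.id for r in set_a]
    ids_b = [r.id for r in set_b]
    best_in_b = {a: best(ids_b, a, lambda x, y: (x, y)) for a in ids_a}
    best_in_a = {b: best(ids_a, b, lambda x, y: (y, x)) for b in ids_b}
    out: list[HomologPair] = []
    for a in ids_a:
        b = best_in_b[a]
        if best_in_a[b] == a and scores[(a, b)].aligned_bp > ALIGNED_BP_MIN:
            out.append(HomologPair(a, b, "ortholog", scores[(a, b)]))
    return out


def codon_align(
    protein_alignment: AlignmentResult, cds_a: str, cds_b: str
) -> CodonAlignment:
    """Back-translate a protein alignment onto the two CDS.

    Each protein column becomes a codon column; protein gaps become ``---``
    triplets; a trailing stop codon on either CDS is trimmed.  The CDS must
    translate to the ungapped proteins.
    """
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    cods = []
    for cds, aligned in ((cds_a, protein_alignment.aligned_a), (cds_b, protein_alignment.aligned_b)):
        if len(cds) % 3 != 0:
            raise IqdfamError("CDS length is not a multiple of 3")
        codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
        prot = aligned.replace("-", "")
        if codons and codons[-1] in ("TAA", "TAG", "TGA"):
            codons = codons[:-1]
        if len(codons) != len(prot):
            raise IqdfamError(
                f"CDS has {len(codons)} codons but protein has {len(prot)} residues"
            )
        for idx, (cod, res) in enumerate(zip(codons, prot)):
            trans = str(Seq(cod).translate())
            if trans != res.upper():
                raise IqdfamError(
                    f"codon {idx} ({cod} -> {trans}) does not encode residue {res!r}"
                )
        cods.append(codons)
    columns: list[tuple[str, str]] = []
    ia = ib = 0
    for ca, cb in zip(protein_alignment.aligned_a, protein_alignment.aligned_b):
        if ca == "-":
            codon_a = "---"
        else:
            codon_a = cods[0][ia]
            ia += 1
        if cb == "-":
            codon_b = "---"
        else:
            codon_b = cods[1][ib]
            ib += 1
        columns.append((codon_a, codon_b))
    return CodonAlignment(columns)
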