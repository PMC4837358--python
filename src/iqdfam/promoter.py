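"""Promoter extraction and cis-element counting.

Promoters are the 2000 bp upstream of the transcription start site,
strand-aware (reverse-complemented for minus-strand genes, truncated with a
warning at contig boundaries).  Elements are IUPAC consensus strings scanned
exhaustively at every offset on the promoter and, by default, its reverse
complement; all overlapping occurrences count, so a palindromic consensus
yields two hits per site when both strands are scanned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io import GeneModel, IqdfamError, SequenceRecord

IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T", "N"},  # unconstrained: matches anything
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class CisElement:
    element_id: str
    consensus: str
    description: str = ""

    def __post_init__(self) -> None:
        self.consensus = self.consensus.upper()
        if not self.consensus:
            raise IqdfamError(f"element {self.element_id}: empty consensus")
        for ch in self.consensus:
            if ch not in IUPAC:
                raise IqdfamError(
                    f"element {self.element_id}: invalid IUPAC character {ch!r}"
                )


def load_library(entries: Iterable[Mapping[str, str]]) -> list[CisElement]:
    return [
        CisElement(e["element_id"], e["consensus"], e.get("description", ""))
        for e in entries
    ]


@dataclass
class PromoterRegion:
    gene_id: str
    contig: str
    strand: str
    start: int
    end: int
    sequence: str


@dataclass
class ElementHit:
    gene_id: str
    element_id: str
    offset: int
    strand: str


def extract_upstream(
    genome: Mapping[str, str] | Sequence[SequenceRecord],
    gene_model: GeneModel,
    length: int = 2000,
) -> PromoterRegion:
    """The ``length`` bp upstream of the gene's TSS, on the gene's strand."""
    if not isinstance(genome, Mapping):
        genome = {r.id: r.residues for r in genome}
    if gene_model.contig not in genome:
        raise IqdfamError(f"contig {gene_model.contig!r} absent from genome")
    contig_seq = genome[gene_model.contig].upper()
    tss = gene_model.tss
    if gene_model.strand == "+":
        start, end = max(0, tss - length), tss
        seq = contig_seq[start:end]
    else:
        start, end = tss, min(len(contig_seq), tss + length)
        seq = reverse_complement(contig_seq[start:end])
    if end - start < length:
        warnings.warn(
            f"promoter of {gene_model.gene_id} truncated to {end - start} bp at contig boundary"
        )
    return PromoterRegion(
        gene_id=gene_model.gene_id, contig=gene_model.contig,
        strand=gene_model.strand, start=start, end=end, sequence=seq,
    )


def _matches_at(seq: str, consensus: str, offset: int) -> bool:
    for i, ch in enumerate(consensus):
        if seq[offset + i] not in IUPAC[ch]:
            return False
    return True


def scan_sequence(seq: str, consensus: str) -> list[int]:
    """Offsets of all (overlapping) consensus occurrences in ``seq``."""
    seq = seq.upper()
    L, m = len(seq), len(consensus)
    return [off for off in range(L - m + 1) if _matches_at(seq, consensus, off)]


def scan_elements(
    region: PromoterRegion,
    library: Sequence[CisElement],
    both_strands: bool = True,
) -> list[ElementHit]:
    """All element occurrences in a promoter, one hit per (offset, strand).

    Reverse-strand hits are found by scanning the element against the
    reverse complement of the region; their offsets are reported on the
    region's forward coordinate system (offset of the match's left end).
    """
    hits: list[ElementHit] = []
    L = len(region.sequence)
    for elem in library:
        for off in scan_sequence(region.sequence, elem.consensus):
            hits.append(ElementHit(region.gene_id, elem.element_id, off, "+"))
        if both_strands:
            rc = reverse_complement(region.sequence)
            m = len(elem.consensus)
            for off in scan_sequence(rc, elem.consensus):
                hits.append(
                    ElementHit(region.gene_id, elem.element_id, L - off - m, "-")
                )
    return hits


@dataclass
class CountSummary:
    counts: dict[tuple[str, str], int]
    gene_totals: dict[str, int]
    element_totals: dict[str, int]
    argmax_gene: dict[str, str | None]


def summarize_counts(hits: Iterable[ElementHit]) -> CountSummary:
    """Per-(gene, element) counts with totals and the max-bearing gene per
    element."""
    counts: dict[tuple[str, str], int] = {}
    for h in hits:
        counts[(h.gene_id, h.element_id)] = counts.get((h.gene_id, h.element_id), 0) + 1
    gene_totals: dict[str, int] = {}
    element_totals: dict[str, int] = {}
    for (g, e), c in counts.items():
        gene_totals[g] = gene_totals.get(g, 0) + c
        element_totals[e] = element_totals.get(e, 0) + c
    argmax: dict[str, str | None] = {}
    for e in element_totals:
        best = max(
            ((g2, c) for (g2, e2), c in counts.items() if e2 == e),
            key=lambda t: (t[1], t[0]),
            default=(None, 0),
        )
        argmax[e] = best[0]
    return CountSummary(counts, gene_totals, element_totals, argmax)
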