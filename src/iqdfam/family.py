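"""IQ67-domain identification by motif grammar, plus per-protein statistics.

The plant-specific IQ67 calmodulin-recruitment domain is built from three
IQ-motif copies with fixed inter-motif spacers of 11 and 15 residues.  The
scanner here implements that grammar literally: position-class patterns for
the IQ motif (strict ``IQxxxRGxxxR`` and relaxed ``[ILV]QxxxRxxxx[RK]``
forms) and for the hydrophobic-anchor 1-5-10 and 1-8-14 motifs, exhaustive
overlapping scans, and assembly of motif triples whose spacers match 11/15
within a configurable tolerance.

The grammar arithmetic gives a 59-residue core span (11+11+11+15+11); the
conventional "67-residue" figure is exposed as an optional fixed window from
the first IQ position (``extended_span_67``) since the grammar itself does
not place the extra residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from .io import GeneModel, IqdfamError, SequenceRecord

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")
# X is tolerated in input but never satisfies a constrained position class.
SCAN_ALPHABET = PROTEIN_ALPHABET | {"X"}

#: Position-class patterns, 0-based position -> allowed residue set.
#: Unconstrained positions are simply absent.
IQ_STRICT = {"length": 11, "classes": {0: {"I"}, 1: {"Q"}, 5: {"R"}, 6: {"G"}, 10: {"R"}}}
IQ_RELAXED = {"length": 11, "classes": {0: set("ILV"), 1: {"Q"}, 5: {"R"}, 10: set("RK")}}
HYDRO = set("FILVW")
M_1_5_10 = {"length": 10, "classes": {0: HYDRO, 4: set("FILV"), 9: HYDRO}}
M_1_8_14 = {"length": 14, "classes": {0: HYDRO, 7: set("FAILVW"), 13: HYDRO}}

PATTERNS = {
    "IQ_strict": IQ_STRICT,
    "IQ_relaxed": IQ_RELAXED,
    "m1_5_10": M_1_5_10,
    "m1_8_14": M_1_8_14,
}

SPACER1 = 11
SPACER2 = 15
DOMAIN_SPAN = 3 * IQ_STRICT["length"] + SPACER1 + SPACER2  # 59 aa


@dataclass(frozen=True)
class MotifHit:
    kind: str
    start: int
    end: int
    matched: str


@dataclass
class Iq67Domain:
    iq_hits: tuple[MotifHit, MotifHit, MotifHit]
    spacer1_len: int
    spacer2_len: int
    span: tuple[int, int]
    secondary_hits: list[MotifHit] = field(default_factory=list)
    extended_span_67: tuple[int, int] | None = None


def _check_protein(protein: str) -> str:
    if not protein:
        raise IqdfamError("empty protein sequence")
    protein = protein.upper()
    for i, ch in enumerate(protein):
        if ch not in SCAN_ALPHABET:
            raise IqdfamError(f"non-alphabet character {ch!r} at position {i}")
    return protein


def _scan(protein: str, kind: str) -> list[MotifHit]:
    pat = PATTERNS[kind]
    length, classes = pat["length"], pat["classes"]
    hits = []
    for start in range(len(protein) - length + 1):
        if all(protein[start + pos] in allowed for pos, allowed in classes.items()):
            hits.append(MotifHit(kind, start, start + length, protein[start:start + length]))
    return hits


def scan_iq_motifs(protein: str, mode: str = "relaxed") -> list[MotifHit]:
    """All overlapping IQ-motif occurrences, sorted by start.

    ``strict`` matches ``IQxxxRGxxxR``; ``relaxed`` the bracketed consensus
    ``[ILV]QxxxRxxxx[RK]``.  Every strict hit is also a relaxed hit.
    """
    protein = _check_protein(protein)
    if mode not in ("strict", "relaxed"):
        raise IqdfamError(f"unknown scan mode {mode!r}")
    return _scan(protein, "IQ_strict" if mode == "strict" else "IQ_relaxed")


def scan_secondary_motifs(protein: str, span: tuple[int, int]) -> list[MotifHit]:
    """1-5-10 and 1-8-14 motif occurrences whose interval intersects ``span``."""
    protein = _check_protein(protein)
    lo, hi = span
    if not (0 <= lo <= hi <= len(protein)):
        raise IqdfamError(f"span {span} outside protein of length {len(protein)}")
    hits = _scan(protein, "m1_5_10") + _scan(protein, "m1_8_14")
    return sorted(
        (h for h in hits if h.start < hi and h.end > lo), key=lambda h: (h.start, h.kind)
    )


def find_iq67_domains(
    protein: str, spacer_tolerance: int = 0, mode: str = "relaxed"
) -> list[Iq67Domain]:
    """Assemble IQ-motif triples with 11/15-residue spacers into domains.

    Every ordered hit triple with ``|spacer1 - 11| <= tol`` and
    ``|spacer2 - 15| <= tol`` is a candidate; non-overlapping candidates are
    selected greedily left to right.  Overlapping 1-5-10 / 1-8-14 hits are
    attached to each accepted domain.
    """
    protein = _check_protein(protein)
    hits = scan_iq_motifs(protein, mode=mode)
    candidates = []
    for i, a in enumerate(hits):
        for j in range(i + 1, len(hits)):
            b = hits[j]
            s1 = b.start - a.end
            if abs(s1 - SPACER1) > spacer_tolerance:
                continue
            for k in range(j + 1, len(hits)):
                c = hits[k]
                s2 = c.start - b.end
                if abs(s2 - SPACER2) > spacer_tolerance:
                    continue
                candidates.append(((a, b, c), s1, s2))
    candidates.sort(key=lambda t: (t[0][0].start, t[0][2].end))
    domains: list[Iq67Domain] = []
    cursor = -1
    for (a, b, c), s1, s2 in candidates:
        if a.start <= cursor:
            continue
        span = (a.start, c.end)
        ext = (a.start, a.start + 67) if a.start + 67 <= len(protein) else None
        domains.append(
            Iq67Domain(
                iq_hits=(a, b, c), spacer1_len=s1, spacer2_len=s2, span=span,
                secondary_hits=scan_secondary_motifs(protein, span),
                extended_span_67=ext,
            )
        )
        cursor = c.end - 1
    return domains


def remove_redundant(
    records: Sequence[SequenceRecord],
    locus_tags: Mapping[str, str] | None = None,
) -> list[SequenceRecord]:
    """Collapse exact duplicate sequences (first id kept) and, when locus
    tags are supplied, isoforms of one locus (longest kept)."""
    seen_seq: dict[str, str] = {}
    out: list[SequenceRecord] = []
    for rec in records:
        if rec.residues in seen_seq:
            continue
        seen_seq[rec.residues] = rec.id
        out.append(rec)
    if locus_tags:
        best: dict[str, SequenceRecord] = {}
        order: list[str] = []
        untagged: list[SequenceRecord] = []
        for rec in out:
            tag = locus_tags.get(rec.id)
            if tag is None:
                untagged.append(rec)
                continue
            if tag not in best:
                order.append(tag)
                best[tag] = rec
            elif len(rec.residues) > len(best[tag].residues):
                best[tag] = rec
        kept = untagged + [best[t] for t in order]
        kept.sort(key=lambda r: [x.id for x in out].index(r.id))
        out = kept
    return out


def classify_family(
    records: Sequence[SequenceRecord],
    spacer_tolerance: int = 0,
    mode: str = "relaxed",
    locus_tags: Mapping[str, str] | None = None,
) -> dict:
    """Family membership report: records carrying >=1 IQ67 domain after
    redundancy removal, with per-member domain coordinates."""
    unique = remove_redundant(records, locus_tags)
    members = []
    for rec in unique:
        domains = find_iq67_domains(rec.residues, spacer_tolerance, mode)
        if domains:
            members.append(
                {
                    "id": rec.id,
                    "n_domains": len(domains),
                    "domains": [
                        {
                            "start": d.span[0], "end": d.span[1],
                            "spacer1": d.spacer1_len, "spacer2": d.spacer2_len,
                            "n_1_5_10": sum(h.kind == "m1_5_10" for h in d.secondary_hits),
                            "n_1_8_14": sum(h.kind == "m1_8_14" for h in d.secondary_hits),
                        }
                        for d in domains
                    ],
                }
            )
    return {"n_members": len(members), "members": members}


def verify_phase0_boundary(gene_model: GeneModel, domain_start_codon: int) -> bool:
    """True iff an intron interrupts the domain between its 16th and 17th
    codons and the downstream CDS segment starts in phase 0.

    This exon-intron boundary is the structural hallmark of the domain: the
    intron sits exactly between two codons (phase 0), 16 codons into the
    domain.
    """
    segments = sorted(gene_model.cds_segments)
    if gene_model.strand == "-":
        segments = segments[::-1]
    total = sum(e - s for s, e, _ in segments)
    if 3 * (domain_start_codon + DOMAIN_SPAN) > total:
        raise IqdfamError("domain extends past the CDS")
    boundary_nt = 3 * (domain_start_codon + 16)
    offset = 0
    for idx, (s, e, _phase) in enumerate(segments[:-1]):
        offset += e - s
        if offset == boundary_nt:
            return segments[idx + 1][2] == 0
        if offset > boundary_nt:
            return False
    return False


# EMBOSS pKa set used for the isoelectric point (net-charge bisection).
_PKA_POSITIVE = {"Nterm": 8.6, "K": 10.8, "R": 12.5, "H": 6.5}
_PKA_NEGATIVE = {"Cterm": 3.6, "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1}


def net_charge(protein: str, ph: float) -> float:
    """Henderson-Hasselbalch net charge at ``ph`` under the EMBOSS pKa set."""
    pos = 1.0 / (1.0 + 10 ** (ph - _PKA_POSITIVE["Nterm"]))
    neg = 1.0 / (1.0 + 10 ** (_PKA_NEGATIVE["Cterm"] - ph))
    for res in protein:
        if res in ("K", "R", "H"):
            pos += 1.0 / (1.0 + 10 ** (ph - _PKA_POSITIVE[res]))
        elif res in ("D", "E", "C", "Y"):
            neg += 1.0 / (1.0 + 10 ** (_PKA_NEGATIVE[res] - ph))
    return pos - neg


def isoelectric_point(protein: str, tol: float = 1e-3) -> float:
    """pI by bisection of the net-charge function on [0, 14]."""
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if net_charge(protein, mid) > 0:
            lo = mid
        else:
            hi = mid
    return round((lo + hi) / 2.0, 2)


@dataclass
class ProteinStats:
    length_aa: int
    orf_length_bp: int
    mw_da: float
    pi: float


def compute_protein_stats(protein: str, cds: str | None = None) -> ProteinStats:
    """Length, ORF length, average molecular weight and pI for one protein.

    When a CDS is supplied it must translate (standard code, stop trimmed)
    to the protein; the ORF length is then the CDS length, which equals
    3 x (aa + 1) for a stop-terminated CDS.  MW is the sum of average
    residue masses plus one water (Biopython's ProtParam convention).
    """
    protein = _check_protein(protein)
    if cds is not None:
        cds = cds.upper()
        if len(cds) % 3 != 0:
            raise IqdfamError("CDS length is not a multiple of 3")
        translated = str(Seq(cds).translate())
        if translated.endswith("*"):
            translated = translated[:-1]
        if translated != protein:
            raise IqdfamError("CDS does not translate to the given protein")
        orf = len(cds)
    else:
        orf = 3 * (len(protein) + 1)
    mw = ProteinAnalysis(protein).molecular_weight()
    return ProteinStats(
        length_aa=len(protein), orf_length_bp=orf,
        mw_da=round(mw, 2), pi=isoelectric_point(protein),
    )
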