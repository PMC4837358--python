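"""Synthetic-data generators with recorded ground truth.

Every downstream stage (domain scanning, homolog detection, Ka/Ks
estimation, promoter counting, expression quantification) can be scored
against the truth objects emitted here, without any external data.  All
generators are fully deterministic in their seed.

Design notes: protein backgrounds exclude glutamine so no accidental IQ
motif can arise outside planted coordinates (both IQ-motif forms require Q
at their second position); CDS evolution is i.i.d. per site with stop
codons rejected, matching the assumptions of the pathway-counting Ka/Ks
estimator it feeds; promoter backgrounds are repaired by rejection until
the planted element occurrences are the only matches on either strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import GeneModel, IqdfamError, SequenceRecord
from .kaks import SENSE_CODONS, STOP_CODONS, CODON_TABLE, ng86_site_counts
from .promoter import CisElement, ElementHit, IUPAC, PromoterRegion, reverse_complement, scan_elements

# background alphabet: 20 standard residues minus Q (see module docstring)
_BG_RESIDUES = np.array(list("ACDEFGHIKLMNPRSTVWY"))
_BASES = np.array(list("ACGT"))

IQ_LEN = 11
SPACER1 = 11
SPACER2 = 15
DOMAIN_LEN = 3 * IQ_LEN + SPACER1 + SPACER2  # 59


@dataclass
class SimTruth:
    planted_domains: dict[str, list[tuple[int, int, tuple[int, int]]]] = field(default_factory=dict)
    decoy_motifs: dict[str, list[int]] = field(default_factory=dict)
    paralog_pairs: set[frozenset[str]] = field(default_factory=set)
    ortholog_pairs: set[frozenset[str]] = field(default_factory=set)
    realized_ks: float | None = None
    realized_ka: float | None = None
    realized_sd: int = 0
    realized_nd: int = 0
    ancestor_S: float | None = None
    ancestor_N: float | None = None
    planted_element_counts: dict[tuple[str, str], int] = field(default_factory=dict)
    planted_element_hits: list[ElementHit] = field(default_factory=list)
    true_folds: dict[tuple[str, str], float] = field(default_factory=dict)


def _bg(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BG_RESIDUES, size=n)) if n else ""


def _iq_motif(rng: np.random.Generator) -> str:
    """A strict-form IQ motif instance with background free positions."""
    return "IQ" + _bg(rng, 3) + "RG" + _bg(rng, 3) + "R"


def gen_iq67_protein(
    seed: int,
    length: int = 300,
    n_domains: int = 1,
    decoy_motifs: bool = False,
    n_decoys: int = 2,
) -> tuple[SequenceRecord, SimTruth]:
    """A protein with ``n_domains`` planted IQ67 domains among Q-free
    background, optionally with isolated single-IQ-motif decoys.

    Planted domains follow the grammar exactly (IQ motif, 11-aa spacer, IQ
    motif, 15-aa spacer, IQ motif); decoy placement is resampled until no
    unintended motif triple satisfies the 11/15 spacing.
    """
    rng = np.random.default_rng(seed)
    n_dec = n_decoys if decoy_motifs else 0
    if length < n_domains * DOMAIN_LEN + 20:
        raise IqdfamError(
            f"length {length} infeasible for {n_domains} domains (needs >= {n_domains * DOMAIN_LEN + 20})"
        )
    item_lens = [DOMAIN_LEN] * n_domains + [IQ_LEN] * n_dec
    free = length - sum(item_lens)
    if free < 0:
        raise IqdfamError("length infeasible for requested domains and decoys")

    for _attempt in range(200):
        # split the free residues into len(items)+1 gaps
        cuts = np.sort(rng.integers(0, free + 1, size=len(item_lens))) if item_lens else []
        gaps = np.diff(np.concatenate(([0], cuts, [free]))) if item_lens else [free]
        order = rng.permutation(len(item_lens))
        starts: list[tuple[int, int]] = []  # (start, item_index)
        pos = 0
        for gi, idx in enumerate(order):
            pos += int(gaps[gi])
            starts.append((pos, int(idx)))
            pos += item_lens[idx]
        # IQ-motif start coordinates implied by the layout
        motif_starts: list[int] = []
        domain_spans: list[tuple[int, int]] = []
        decoy_starts: list[int] = []
        for s, idx in starts:
            if idx < n_domains:
                motif_starts += [s, s + IQ_LEN + SPACER1, s + 2 * IQ_LEN + SPACER1 + SPACER2]
                domain_spans.append((s, s + DOMAIN_LEN))
            else:
                motif_starts.append(s)
                decoy_starts.append(s)
        motif_starts.sort()
        planted_triples = {
            (a, a + IQ_LEN + SPACER1, a + 2 * IQ_LEN + SPACER1 + SPACER2)
            for a, _ in domain_spans
        }
        ok = True
        for i, a in enumerate(motif_starts):
            for j in range(i + 1, len(motif_starts)):
                b = motif_starts[j]
                if b - (a + IQ_LEN) != SPACER1:
                    continue
                for k in range(j + 1, len(motif_starts)):
                    c = motif_starts[k]
                    if c - (b + IQ_LEN) == SPACER2 and (a, b, c) not in planted_triples:
                        ok = False
        if ok:
            break
    else:
        raise IqdfamError("could not place decoys without creating a spurious domain")

    seq = list(_bg(rng, length))
    for s, idx in starts:
        if idx < n_domains:
            block = (
                _iq_motif(rng) + _bg(rng, SPACER1) + _iq_motif(rng)
                + _bg(rng, SPACER2) + _iq_motif(rng)
            )
        else:
            block = _iq_motif(rng)
        seq[s:s + len(block)] = block
    gene_id = f"synt_iq67_{seed}"
    truth = SimTruth(
        planted_domains={gene_id: [(a, b, (SPACER1, SPACER2)) for a, b in sorted(domain_spans)]},
        decoy_motifs={gene_id: sorted(decoy_starts)},
    )
    return SequenceRecord(gene_id, gene_id, "".join(seq)), truth


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    return "".join(rng.choice(SENSE_CODONS, size=n_codons))


def _classify_mutation(codon: str, pos: int, base: str) -> str | None:
    """'syn' / 'nonsyn' for a single-base change, None if it creates a stop."""
    mutant = codon[:pos] + base + codon[pos + 1:]
    if mutant in STOP_CODONS:
        return None
    return "syn" if CODON_TABLE[mutant] == CODON_TABLE[codon] else "nonsyn"


def gen_diverged_cds_pair(
    seed: int, n_codons: int = 300, target_ks: float = 0.2, omega: float = 0.2
) -> tuple[str, str, SimTruth]:
    """An ancestor CDS and a derived copy with controlled divergence.

    The ancestor is codon-uniform over the 61 sense codons.  Substitution
    counts are Poisson with means ``target_ks * S`` (synonymous) and
    ``omega * target_ks * N`` (nonsynonymous), where N and S are the
    ancestor's pathway-method site counts; each event is a uniformly chosen
    single-base change of the required class, stop-creating changes
    rejected.  Realized tallies (and per-site rates) go into the truth.
    """
    if n_codons < 50:
        raise IqdfamError("n_codons must be >= 50")
    if target_ks < 0 or omega < 0:
        raise IqdfamError("target_ks and omega must be non-negative")
    rng = np.random.default_rng(seed)
    ancestor = _random_cds(rng, n_codons)
    counts = [ng86_site_counts(ancestor[i:i + 3]) for i in range(0, 3 * n_codons, 3)]
    N = sum(n for n, _ in counts)
    S = sum(s for _, s in counts)
    n_syn = int(rng.poisson(target_ks * S))
    n_nonsyn = int(rng.poisson(omega * target_ks * N))

    derived = list(ancestor)
    events = ["syn"] * n_syn + ["nonsyn"] * n_nonsyn
    rng.shuffle(events)
    sd = nd = 0
    for wanted in events:
        while True:
            ci = int(rng.integers(0, n_codons))
            pos = int(rng.integers(0, 3))
            base = str(rng.choice(_BASES))
            codon = "".join(derived[3 * ci:3 * ci + 3])
            if base == codon[pos]:
                continue
            kind = _classify_mutation(codon, pos, base)
            if kind != wanted:
                continue
            derived[3 * ci + pos] = base
            break
        if wanted == "syn":
            sd += 1
        else:
            nd += 1
    truth = SimTruth(
        realized_sd=sd, realized_nd=nd, ancestor_S=S, ancestor_N=N,
        realized_ks=sd / S if S else 0.0, realized_ka=nd / N if N else 0.0,
    )
    return ancestor, "".join(derived), truth


def _mutate_cds(rng: np.random.Generator, cds: str, p_sub: float) -> str:
    """Per-site substitutions at rate p_sub, stop codons rejected."""
    seq = list(cds)
    for i in range(len(seq)):
        if rng.random() >= p_sub:
            continue
        codon_start = 3 * (i // 3)
        choices = [b for b in "ACGT" if b != seq[i]]
        rng.shuffle(choices)
        for b in choices:
            codon = seq[codon_start:codon_start + 3]
            codon[i - codon_start] = b
            if "".join(codon) not in STOP_CODONS:
                seq[i] = b
                break
    return "".join(seq)


def gen_family_fixture(
    seed: int = 3,
    n_species: int = 2,
    genes_per_species: int = 5,
    duplication_events: int = 2,
    n_codons: int = 250,
    ortholog_divergence: float = 0.015,
    paralog_divergence: float = 0.08,
) -> tuple[dict[str, list[SequenceRecord]], list[GeneModel], SimTruth]:
    """Multi-species CDS sets with known ortholog/paralog truth.

    Each of ``genes_per_species`` unrelated ancestors seeds a one-to-one
    ortholog in every species (low divergence from the ancestor); each
    duplication event copies one species' gene with extra divergence,
    creating a within-species paralog pair.  The duplicate is strictly more
    diverged than any ortholog, so reciprocal-best-hit recovery of the
    ortholog truth is exact by construction.
    """
    if duplication_events > genes_per_species:
        raise IqdfamError("duplication_events must not exceed genes_per_species")
    rng = np.random.default_rng(seed)
    ancestors = [_random_cds(rng, n_codons) for _ in range(genes_per_species)]
    species: dict[str, list[SequenceRecord]] = {}
    copies: dict[tuple[int, int], str] = {}
    for s in range(n_species):
        name = f"sp{s}"
        recs = []
        for g, anc in enumerate(ancestors):
            cds = _mutate_cds(rng, anc, ortholog_divergence)
            copies[(s, g)] = cds
            recs.append(SequenceRecord(f"sp{s}_g{g}", f"sp{s}_g{g}", cds))
        species[name] = recs

    truth = SimTruth()
    dup_parents = rng.choice(genes_per_species, size=duplication_events, replace=False)
    for g in dup_parents:
        s = int(rng.integers(0, n_species))
        parent_id = f"sp{s}_g{g}"
        dup_id = f"sp{s}_g{g}d"
        dup = _mutate_cds(rng, copies[(s, int(g))], paralog_divergence)
        species[f"sp{s}"].append(SequenceRecord(dup_id, dup_id, dup))
        truth.paralog_pairs.add(frozenset({parent_id, dup_id}))
    for g in range(genes_per_species):
        for s1 in range(n_species):
            for s2 in range(s1 + 1, n_species):
                truth.ortholog_pairs.add(frozenset({f"sp{s1}_g{g}", f"sp{s2}_g{g}"}))

    models = []
    for name, recs in species.items():
        offset = 0
        for rec in recs:
            L = len(rec.residues)
            models.append(
                GeneModel(
                    gene_id=rec.id, contig=f"{name}_contig", strand="+",
                    exons=[(offset, offset + L)], cds_segments=[(offset, offset + L, 0)],
                )
            )
            offset += L + 100
    return species, models, truth


def _realize(rng: np.random.Generator, consensus: str) -> str:
    return "".join(
        str(rng.choice(sorted(IUPAC[ch] - {"N"}))) for ch in consensus
    )


def gen_promoters(
    seed: int,
    planted_counts: Mapping[str, Mapping[str, int]],
    motif_library: Sequence[CisElement],
    length: int = 2000,
    plant_reverse: bool = True,
) -> tuple[dict[str, str], list[GeneModel], SimTruth]:
    """Synthetic contigs whose promoters carry exact planted element counts.

    ``planted_counts`` maps gene id -> {element_id: copies}.  Copies are
    non-overlapping (separated by at least the longest library motif) on a
    random strand; the background is mutated until the planted occurrences
    are the only matches of any library element on either strand, making
    the counts exact ground truth.  Each gene sits on its own contig with
    the promoter immediately upstream of the annotated TSS (genes alternate
    strands so strand-aware extraction is exercised).
    """
    rng = np.random.default_rng(seed)
    lib = {e.element_id: e for e in motif_library}
    maxlen = max(len(e.consensus) for e in motif_library)
    genome: dict[str, str] = {}
    models: list[GeneModel] = []
    truth = SimTruth()
    body = 300

    for gi, (gene, wants) in enumerate(sorted(planted_counts.items())):
        total_copies = sum(wants.values())
        need = total_copies * 2 * maxlen
        if need > length:
            raise IqdfamError(
                f"{gene}: {total_copies} copies do not fit in {length} bp"
            )
        # choose non-overlapping slots, each maxlen wide with maxlen spacing
        n_slots = length // (2 * maxlen)
        slot_ids = rng.choice(n_slots, size=total_copies, replace=False)
        placements = []  # (offset, element_id, strand, instance)
        copy_elems = [e for e, c in sorted(wants.items()) for _ in range(c)]
        for slot, elem_id in zip(slot_ids, copy_elems):
            elem = lib[elem_id]
            off = int(slot) * 2 * maxlen + int(rng.integers(0, maxlen - len(elem.consensus) + 1))
            strand = "-" if (plant_reverse and rng.random() < 0.5) else "+"
            inst = _realize(rng, elem.consensus)
            placements.append((off, elem_id, strand, inst))

        promoter = list("".join(rng.choice(_BASES, size=length)))
        planted_intervals = []
        for off, elem_id, strand, inst in placements:
            ins = inst if strand == "+" else reverse_complement(inst)
            promoter[off:off + len(ins)] = ins
            planted_intervals.append((off, off + len(ins)))
        planted_set = {
            (e, off, strand) for off, e, strand, _ in placements
        }

        region = PromoterRegion(gene, f"ctg_{gene}", "+", 0, length, "".join(promoter))
        for _ in range(500):
            hits = scan_elements(region, motif_library, both_strands=True)
            extra = [
                h for h in hits
                if (h.element_id, h.offset, h.strand) not in planted_set
            ]
            if not extra:
                break
            h = extra[0]
            m = len(lib[h.element_id].consensus)
            positions = [
                p for p in range(h.offset, h.offset + m)
                if not any(a <= p < b for a, b in planted_intervals)
            ]
            if not positions:
                raise IqdfamError(
                    "library elements collide inside planted copies; "
                    "use mutually non-matching consensi"
                )
            p = positions[int(rng.integers(0, len(positions)))]
            promoter[p] = str(rng.choice([b for b in "ACGT" if b != promoter[p]]))
            region = PromoterRegion(gene, f"ctg_{gene}", "+", 0, length, "".join(promoter))
        else:
            raise IqdfamError("promoter background repair did not converge")

        # verify the planted set is exactly recovered
        final = {(h.element_id, h.offset, h.strand) for h in
                 scan_elements(region, motif_library, both_strands=True)}
        assert final == planted_set

        gene_strand = "+" if gi % 2 == 0 else "-"
        body_seq = "".join(rng.choice(_BASES, size=body))
        if gene_strand == "+":
            contig = "".join(promoter) + body_seq
            exons = [(length, length + body)]
        else:
            contig = body_seq + reverse_complement("".join(promoter))
            exons = [(0, body)]
        genome[f"ctg_{gene}"] = contig
        models.append(
            GeneModel(gene_id=gene, contig=f"ctg_{gene}", strand=gene_strand,
                      exons=exons, cds_segments=[(exons[0][0], exons[0][1], 0)])
        )
        for e, c in wants.items():
            truth.planted_element_counts[(gene, e)] = c
        truth.planted_element_hits += [
            ElementHit(gene, e, off, strand) for off, e, strand, _ in placements
        ]
    return genome, models, truth


def gen_ct_table(
    seed: int,
    genes: Sequence[str],
    conditions: Sequence[str],
    true_folds: Mapping[tuple[str, str], float],
    ct_noise_sd: float = 0.0,
    n_reps: int = 3,
    reference_gene: str = "TIP41",
    control_condition: str = "0h",
) -> tuple[pd.DataFrame, SimTruth]:
    """Replicate Ct tables with known fold changes.

    The reference gene's Ct is constant across conditions; each target
    gene's Ct in a condition is its control Ct minus log2(true fold) plus
    i.i.d. Gaussian noise per replicate.  The control condition's true fold
    is 1 by definition.
    """
    rng = np.random.default_rng(seed)
    all_conditions = [control_condition] + [c for c in conditions if c != control_condition]
    rows = []
    for rep in range(1, n_reps + 1):
        for cond in all_conditions:
            rows.append((reference_gene, cond, rep, 20.0))
    truth = SimTruth()
    for gene in genes:
        base_ct = float(rng.uniform(22.0, 28.0))
        for cond in all_conditions:
            fold = 1.0 if cond == control_condition else float(true_folds[(gene, cond)])
            if fold <= 0:
                raise IqdfamError(f"true fold for ({gene}, {cond}) must be positive")
            truth.true_folds[(gene, cond)] = fold
            mean_ct = base_ct - np.log2(fold)
            for rep in range(1, n_reps + 1):
                noise = float(rng.normal(0.0, ct_noise_sd)) if ct_noise_sd > 0 else 0.0
                rows.append((gene, cond, rep, mean_ct + noise))
    df = pd.DataFrame(rows, columns=["gene", "condition", "replicate", "ct"])
    return df, truth
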