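"""Nei-Gojobori (1986) Ka/Ks estimation, sliding windows, and Ks dating.

The pathway-counting estimator: per-codon synonymous/nonsynonymous *site*
counts are fractions of single-nucleotide mutants (stop mutants excluded
from the denominator), *difference* counts between two codons are averaged
over all orderings of the differing positions, skipping orderings that pass
through a stop codon.  Proportions are Jukes-Cantor corrected,
``d = -(3/4) ln(1 - (4/3) p)``; ``p >= 3/4`` is reported as saturated.

Divergence dating uses the molecular-clock relation ``T = Ks / (2 lambda)``
with a default synonymous rate of 6.5e-9 substitutions per site per year.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations

from Bio.Data.CodonTable import standard_dna_table

from .io import IqdfamError

CODON_TABLE = dict(standard_dna_table.forward_table)
STOP_CODONS = set(standard_dna_table.stop_codons)
SENSE_CODONS = sorted(CODON_TABLE)
BASES = "ACGT"

DEFAULT_LAMBDA = 6.5e-9  # synonymous substitutions / site / year
WINDOW_BP = 150
STEP_BP = 9


@dataclass
class CodonAlignment:
    """Paired codon columns; ``---`` marks a gapped codon."""

    codon_columns: list[tuple[str, str]]

    def __len__(self) -> int:
        return len(self.codon_columns)

    @property
    def length_bp(self) -> int:
        return 3 * len(self.codon_columns)


@dataclass
class KaKsResult:
    N: float
    S: float
    Nd: float
    Sd: float
    pn: float
    ps: float
    ka: float | None
    ks: float | None
    ratio: float | None
    ka_saturated: bool = False
    ks_saturated: bool = False
    skipped_codons: int = 0


@lru_cache(maxsize=None)
def ng86_site_counts(codon: str) -> tuple[float, float]:
    """(n, s) for one sense codon.

    At each position the synonymous fraction is (synonymous single-nucleotide
    mutants) / (non-stop single-nucleotide mutants); n accumulates the
    complement, so n + s = 3 whenever every position has a non-stop mutant
    (true for all 61 sense codons of the standard code).
    """
    codon = codon.upper()
    if codon in STOP_CODONS or codon not in CODON_TABLE:
        raise IqdfamError(f"not a sense codon: {codon!r}")
    aa = CODON_TABLE[codon]
    s = 0.0
    n = 0.0
    for pos in range(3):
        syn = 0
        legal = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1:]
            if mutant in STOP_CODONS:
                continue
            legal += 1
            if CODON_TABLE[mutant] == aa:
                syn += 1
        if legal:
            frac = syn / legal
            s += frac
            n += 1.0 - frac
    return n, s


@lru_cache(maxsize=None)
def ng86_pair_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(nd, sd) between two sense codons, averaged over mutational pathways.

    For k differing positions, every ordering of the k single-nucleotide
    steps defines a pathway; pathways whose intermediates are stop codons
    are excluded.  If no legal pathway exists the pair contributes nothing
    (caller also drops its site counts).
    """
    codon_a, codon_b = codon_a.upper(), codon_b.upper()
    for c in (codon_a, codon_b):
        if c in STOP_CODONS or c not in CODON_TABLE:
            raise IqdfamError(f"not a sense codon: {c!r}")
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return 0.0, 0.0
    nd_total = sd_total = 0.0
    n_paths = 0
    for order in permutations(diff):
        cur = codon_a
        nd = sd = 0
        legal = True
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                legal = False
                break
            if CODON_TABLE[nxt] == CODON_TABLE[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if legal:
            nd_total += nd
            sd_total += sd
            n_paths += 1
    if n_paths == 0:
        raise _NoLegalPathway(codon_a, codon_b)
    return nd_total / n_paths, sd_total / n_paths


class _NoLegalPathway(Exception):
    def __init__(self, a: str, b: str):
        super().__init__(f"no stop-free pathway between {a} and {b}")
        self.pair = (a, b)


def jukes_cantor(p: float) -> tuple[float | None, bool]:
    """JC69 multiple-hit correction; returns (d, saturated)."""
    if p < 0:
        raise IqdfamError("negative proportion")
    if p >= 0.75:
        return None, True
    return -0.75 * math.log1p(-4.0 * p / 3.0), False


def kaks_estimate(alignment: CodonAlignment) -> KaKsResult:
    """NG86 Ka/Ks over a codon alignment.

    Site counts are averaged over the two sequences; gapped columns and
    codon pairs with no stop-free pathway are skipped (the latter with a
    warning).  ``ratio`` is None when ks is 0 or saturated.
    """
    n_a = s_a = n_b = s_b = 0.0
    nd = sd = 0.0
    compared = 0
    skipped = 0
    for ca, cb in alignment.codon_columns:
        if "-" in ca or "-" in cb:
            continue
        try:
            dnd, dsd = ng86_pair_differences(ca, cb)
        except _NoLegalPathway:
            warnings.warn(f"no stop-free pathway between {ca} and {cb}; codon pair skipped")
            skipped += 1
            continue
        na, sa = ng86_site_counts(ca)
        nb, sb = ng86_site_counts(cb)
        n_a += na
        s_a += sa
        n_b += nb
        s_b += sb
        nd += dnd
        sd += dsd
        compared += 1
    if compared == 0:
        raise IqdfamError("no comparable codon columns")
    N = (n_a + n_b) / 2.0
    S = (s_a + s_b) / 2.0
    pn = nd / N if N > 0 else 0.0
    ps = sd / S if S > 0 else 0.0
    ka, ka_sat = jukes_cantor(pn)
    ks, ks_sat = jukes_cantor(ps)
    if ka is None or ks is None or ks == 0.0:
        ratio = None
    else:
        ratio = ka / ks
    return KaKsResult(
        N=N, S=S, Nd=nd, Sd=sd, pn=pn, ps=ps, ka=ka, ks=ks, ratio=ratio,
        ka_saturated=ka_sat, ks_saturated=ks_sat, skipped_codons=skipped,
    )


@dataclass
class WindowTrack:
    window_bp: int
    step_bp: int
    windows: list[tuple[int, int, KaKsResult]] = field(default_factory=list)


def sliding_window_kaks(
    alignment: CodonAlignment, window_bp: int = WINDOW_BP, step_bp: int = STEP_BP
) -> WindowTrack:
    """Per-window Ka/Ks along the alignment (defaults 150 bp / 9 bp step).

    Window coordinates are gapped-alignment nucleotide offsets; gapped
    columns inside a window are skipped during counting.  Only full windows
    are emitted: floor((L - window)/step) + 1 of them.  An alignment shorter
    than one window yields a single full-length window with a warning.
    """
    if window_bp % 3 or step_bp % 3:
        raise IqdfamError("window and step must be codon multiples (bp divisible by 3)")
    L = alignment.length_bp
    track = WindowTrack(window_bp=window_bp, step_bp=step_bp)
    if L < window_bp:
        warnings.warn(f"alignment ({L} bp) shorter than window ({window_bp} bp)")
        track.windows.append((0, L, kaks_estimate(alignment)))
        return track
    wc = window_bp // 3
    sc = step_bp // 3
    for start_codon in range(0, len(alignment) - wc + 1, sc):
        sub = CodonAlignment(alignment.codon_columns[start_codon:start_codon + wc])
        track.windows.append((3 * start_codon, 3 * start_codon + window_bp, kaks_estimate(sub)))
    return track


@dataclass
class DatingResult:
    ks: float
    lambda_: float
    t_years: float
    t_mya: float
    t_mya_nearest: int


def date_divergence(ks: float, lambda_: float = DEFAULT_LAMBDA) -> DatingResult:
    """Molecular-clock divergence date T = Ks / (2 lambda)."""
    if not math.isfinite(ks) or ks < 0:
        raise IqdfamError(f"invalid ks for dating: {ks}")
    t_years = ks / (2.0 * lambda_)
    t_mya = t_years / 1e6
    return DatingResult(
        ks=ks, lambda_=lambda_, t_years=t_years,
        t_mya=round(t_mya, 2), t_mya_nearest=round(t_mya),
    )


def classify_selection(ratio: float | None, tolerance: float = 1e-9) -> str:
    """Ka/Ks > 1: positive, < 1: purifying, == 1 (within tol): neutral."""
    if ratio is None:
        return "undefined"
    if ratio > 1.0 + tolerance:
        return "positive"
    if ratio < 1.0 - tolerance:
        return "purifying"
    return "neutral"
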