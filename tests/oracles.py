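"""Independent reference computations used to check the implementation.

Everything here is deliberately written from first principles (enumeration,
brute-force DP, closed forms) and shares no code path with the package.
"""

from __future__ import annotations

import itertools
import random
from functools import lru_cache

from Bio.Seq import Seq

# ---------------------------------------------------------------- motifs

IQ_STRICT_SPEC = {0: "I", 1: "Q", 5: "R", 6: "G", 10: "R"}
IQ_RELAXED_SPEC = {0: "ILV", 1: "Q", 5: "R", 10: "RK"}
M_1_5_10_SPEC = {0: "FILVW", 4: "FILV", 9: "FILVW"}
M_1_8_14_SPEC = {0: "FILVW", 7: "FAILVW", 13: "FILVW"}
PATTERN_LEN = {"strict": 11, "relaxed": 11, "m1_5_10": 10, "m1_8_14": 14}
PATTERN_SPEC = {
    "strict": IQ_STRICT_SPEC, "relaxed": IQ_RELAXED_SPEC,
    "m1_5_10": M_1_5_10_SPEC, "m1_8_14": M_1_8_14_SPEC,
}


def brute_force_motif_starts(protein: str, kind: str) -> list[int]:
    """Check every offset position-by-position against the allowed letters."""
    spec, L = PATTERN_SPEC[kind], PATTERN_LEN[kind]
    out = []
    for off in range(len(protein) - L + 1):
        window = protein[off:off + L]
        if all(window[pos] in allowed for pos, allowed in spec.items()):
            out.append(off)
    return out


def brute_force_domain_triples(protein: str, tol: int = 0) -> list[tuple[int, int, int]]:
    """All IQ-hit triples (relaxed) with spacers 11/15 within tolerance."""
    starts = brute_force_motif_starts(protein, "relaxed")
    triples = []
    for a, b, c in itertools.combinations(starts, 3):
        if abs((b - (a + 11)) - 11) <= tol and abs((c - (b + 11)) - 15) <= tol:
            triples.append((a, b, c))
    return triples


# ---------------------------------------------------------------- NG86

_STOPS = {"TAA", "TAG", "TGA"}


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def oracle_site_counts(codon: str) -> tuple[float, float]:
    s = 0.0
    for pos in range(3):
        mutants = [codon[:pos] + b + codon[pos + 1:] for b in "ACGT" if b != codon[pos]]
        legal = [m for m in mutants if m not in _STOPS]
        syn = [m for m in legal if _aa(m) == _aa(codon)]
        if legal:
            s += len(syn) / len(legal)
    return 3.0 - s, s  # (n, s)


def oracle_pair_differences(a: str, b: str) -> tuple[float, float]:
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0
    results = []
    for order in itertools.permutations(diff):
        cur, nd, sd, legal = a, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            if nxt in _STOPS:
                legal = False
                break
            if _aa(nxt) == _aa(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if legal:
            results.append((nd, sd))
    assert results, "no legal pathway"
    return (
        sum(r[0] for r in results) / len(results),
        sum(r[1] for r in results) / len(results),
    )


def oracle_two_codon_kaks(col1: tuple[str, str], col2: tuple[str, str]):
    """From-scratch NG86 + JC on a two-codon alignment."""
    import math

    cols = [col1, col2]
    N = S = Nd = Sd = 0.0
    for ca, cb in cols:
        na, sa = oracle_site_counts(ca)
        nb, sb = oracle_site_counts(cb)
        N += (na + nb) / 2
        S += (sa + sb) / 2
        nd, sd = oracle_pair_differences(ca, cb)
        Nd += nd
        Sd += sd
    pn, ps = Nd / N, Sd / S
    ka = None if pn >= 0.75 else -0.75 * math.log(1 - 4 * pn / 3)
    ks = None if ps >= 0.75 else -0.75 * math.log(1 - 4 * ps / 3)
    return N, S, Nd, Sd, ka, ks


def random_sense_codon(rng: random.Random) -> str:
    while True:
        c = "".join(rng.choice("ACGT") for _ in range(3))
        if c not in _STOPS:
            return c


# ---------------------------------------------------------------- alignment

def gotoh_global_score(
    a: str, b: str, score_fn, gap_open: float, gap_extend: float
) -> float:
    """Three-state affine-gap global DP; gap of length k costs open + k*extend."""
    NEG = float("-inf")
    n, m = len(a), len(b)
    first = gap_open + gap_extend  # cost of the first gap position
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(gap_open + gap_extend * i)
    for j in range(1, m + 1):
        Y[0][j] = -(gap_open + gap_extend * j)
    for i in range(n + 1):
        for j in range(m + 1):
            if i > 0 and j > 0:
                best = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
                M[i][j] = best + score_fn(a[i - 1], b[j - 1])
            if i > 0 and (i, j) != (n + 1, 0):
                X[i][j] = max(
                    X[i][j],
                    X[i - 1][j] - gap_extend,
                    max(M[i - 1][j], Y[i - 1][j]) - first,
                )
            if j > 0:
                Y[i][j] = max(
                    Y[i][j],
                    Y[i][j - 1] - gap_extend,
                    max(M[i][j - 1], X[i][j - 1]) - first,
                )
    return max(M[n][m], X[n][m], Y[n][m])


def exhaustive_global_score(a: str, b: str, score_fn, gap_open, gap_extend) -> float:
    """Enumerate every alignment (tiny inputs only)."""
    best = [float("-inf")]

    def go(i, j, score, state):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            go(i + 1, j + 1, score + score_fn(a[i], b[j]), "M")
        if i < len(a):
            cost = gap_extend if state == "X" else gap_open + gap_extend
            go(i + 1, j, score - cost, "X")
        if j < len(b):
            cost = gap_extend if state == "Y" else gap_open + gap_extend
            go(i, j + 1, score - cost, "Y")

    go(0, 0, 0.0, "M")
    return best[0]


# ---------------------------------------------------------------- trees

class SimpleNode:
    def __init__(self, name=None, children=(), length=0.0):
        self.name = name
        self.children = list(children)
        self.length = length

    def leaves(self):
        if not self.children:
            return [self]
        out = []
        for c in self.children:
            out += c.leaves()
        return out


def random_additive_tree(rng: random.Random, n_taxa: int):
    """A random binary tree with positive branch lengths; returns
    (labels, distance matrix, true bipartition set, total length)."""
    nodes = [SimpleNode(name=f"t{i}", length=rng.uniform(0.1, 1.0)) for i in range(n_taxa)]
    total = sum(n.length for n in nodes)
    while len(nodes) > 3:
        i, j = sorted(rng.sample(range(len(nodes)), 2), reverse=True)
        a, b = nodes.pop(i), nodes.pop(j)
        parent = SimpleNode(children=[a, b], length=rng.uniform(0.1, 1.0))
        total += parent.length
        nodes.append(parent)
    root = SimpleNode(children=nodes)
    total -= 0.0

    labels = sorted(l.name for l in root.leaves())
    import itertools as it

    # leaf-to-leaf path distances via each leaf's root path
    anc_path = {}

    def collect(node, path):
        path = path + [(id(node), node.length)]
        if not node.children:
            anc_path[node.name] = path
            return
        for c in node.children:
            collect(c, path)

    collect(root, [])
    import numpy as np

    n = len(labels)
    d = np.zeros((n, n))
    for x, y in it.combinations(range(n), 2):
        px = anc_path[labels[x]]
        py = anc_path[labels[y]]
        ids_x = {i for i, _ in px}
        ids_y = {i for i, _ in py}
        dist = sum(l for i, l in px if i not in ids_y) + sum(
            l for i, l in py if i not in ids_x
        )
        d[x, y] = d[y, x] = dist

    universe = frozenset(labels)
    bips = set()

    def clades(node):
        for c in node.children:
            side = frozenset(l.name for l in c.leaves())
            if 1 < len(side) < len(universe) - 1:
                other = universe - side
                bips.add(min(side, other, key=lambda s: (len(s), sorted(s))))
            clades(c)

    clades(root)
    return labels, d, bips, total
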