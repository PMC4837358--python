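# Methods

This note records the models, conventions and numerical choices behind
`iqdfam`, and what the synthetic-data generators do and do not emulate.

## Motif grammar and domain assembly

The IQ67 domain is treated as a deterministic position-class grammar, not a
probabilistic profile. Patterns are ordered sets of allowed-residue
classes:

| pattern | length | constrained positions (1-based) |
|---|---|---|
| IQ strict | 11 | 1 I, 2 Q, 6 R, 7 G, 11 R |
| IQ relaxed | 11 | 1 [ILV], 2 Q, 6 R, 11 [RK] |
| 1–5–10 | 10 | 1 [FILVW], 5 [FILV], 10 [FILVW] |
| 1–8–14 | 14 | 1 [FILVW], 8 [FAILVW], 14 [FILVW] |

The "×n" in the conventional 1–5–10 / 1–8–14 notation is read as n
unconstrained residues between anchors, which reproduces the stated anchor
positions. `X` in input never satisfies a constrained class (conservative
matching); any other non-standard character is an error. Scans are
exhaustive over all offsets and return all overlapping occurrences.

A domain is any ordered triple of IQ hits whose spacers satisfy
|spacer₁ − 11| ≤ t and |spacer₂ − 15| ≤ t (default tolerance t = 0,
relaxed mode). Non-overlapping domains are chosen greedily left to right.
The grammar arithmetic gives a 59-residue core (11+11+11+15+11); the
conventional 67-residue figure does not follow from the stated spacing, so
it is exposed only as an optional fixed window (`extended_span_67`) from
the first IQ position rather than silently reconciled.

The structural hallmark check (`verify_phase0_boundary`) requires an
exon–exon junction exactly 16 codons into the domain with the downstream
CDS segment in phase 0.

Protein statistics: molecular weight is the sum of average residue masses
plus one water (Biopython's ProtParam table); the isoelectric point is
found by bisection of the Henderson–Hasselbalch net-charge function on
pH ∈ [0, 14] to 10⁻³ pH, using the EMBOSS pKa set (N-term 8.6, C-term 3.6;
K 10.8, R 12.5, H 6.5, D 3.9, E 4.1, C 8.5, Y 10.1), reported to two
decimals. Parity with any specific web tool is not promised; determinism
is. For a stop-terminated CDS the ORF length is 3 × (aa + 1).

## Alignment conventions

Alignment is delegated to Biopython's `PairwiseAligner`. A gap of length k
costs `open + k·extend`: protein 10 + 0.5k against BLOSUM62; nucleotide
gap 5 + 2k with match +2 / mismatch −3. Global mode implements
Needleman–Wunsch, local mode Smith–Waterman; at equal score the aligner's
first reported alignment is used, which is deterministic for fixed inputs.
Identity is computed over gapless columns only; coverage is gapless
columns over the longer input's length; `aligned_bp` counts gapless
nucleotide columns of the local alignment.

Homology rules follow their wording asymmetry deliberately: coverage
strictly > 70 %, identity ≥ 70 % for paralogs; aligned bp strictly > 300
for reciprocal best hits. Best-hit ties break to the lexicographically
smaller id and are logged. The paralog rule is applied to nucleotide
alignments by default (configurable to protein).

## NG86 Ka/Ks

Site counts per sense codon: at each of the three positions, the
synonymous fraction is (synonymous single-nucleotide mutants)/(non-stop
single-nucleotide mutants); the nonsynonymous fraction is its complement,
so n + s = 3 for every sense codon of the standard code. Differences
between two codons are averaged over all orderings of the differing
positions, excluding orderings that traverse a stop codon; a pair with no
stop-free pathway is skipped with a warning and contributes neither sites
nor differences. Sites are averaged across the two sequences. Proportions
pₙ = Nd/N and pₛ = Sd/S receive the Jukes–Cantor correction
d = −(3/4)·ln(1 − (4/3)p); p ≥ 3/4 is reported as a flagged saturated
value, never silently propagated as NaN. The ratio ω = Ka/Ks is undefined
when Ks = 0 or saturated. Selection classes: ω > 1 positive, ω < 1
purifying, ω = 1 (within 10⁻⁹) neutral.

Sliding windows use alignment (gapped) nucleotide coordinates with
defaults window 150 bp, step 9 bp (both codon multiples); only full
windows are emitted — `floor((L − 150)/9) + 1` of them — and gapped
columns inside a window are skipped in counting. Alignments shorter than
one window fall back to a single full-length window with a warning.

Divergence dating: T = Ks/(2λ) with default
λ = 6.5 × 10⁻⁹ synonymous substitutions per site per year, reported in
years and MY (two decimals, plus a nearest-integer convenience field).
The same clock is applied to paralog and ortholog pairs.

## Neighbour joining

Saitou–Nei agglomeration on the Q-criterion with deterministic tie-breaks:
each cluster is labelled by its smallest leaf name and ties take the
lexicographically smallest label pair. Branch lengths come from the
standard two-point formulas; negative estimates are clamped to zero and
logged. The final three clusters join at a trifurcating root, so the tree
is unrooted. Distances are p-distances (mismatches over compared columns,
pairwise deletion of gapped columns) on a supplied alignment — the package
does not perform multiple alignment. Bootstrap support resamples columns
with replacement (seeded NumPy generator) and reports the percentage of
replicates containing each internal bipartition.

Subfamily assignment treats either side of any edge as a clade (the tree
is unrooted): a query leaf takes the subfamily of the smallest side
containing it and at least one anchor, provided that side's anchors are of
one subfamily and no equally small side disagrees; otherwise it is
unresolved. Four subfamily labels (I–IV) are conventional for this family.

## Promoters

The promoter is the 2000 bp upstream of the transcription start (5′-most
annotated coordinate on +, 3′-most on −; mRNA start, falling back to CDS
start), reverse-complemented for minus-strand genes and truncated with a
warning at contig edges. Scanning is position-exhaustive under IUPAC
classes; all overlapping occurrences count, both strands by default, one
hit per (offset, strand) — a palindromic consensus therefore scores twice
per site. `N` in a promoter never matches a constrained class; `N` in a
consensus is unconstrained. The packaged element library ships the PLACE
identifiers reported for drought- and wound-stress elements with
placeholder consensi explicitly marked user-supplied: the survey this
package operationalises prints only the element IDs, and inventing motif
sequences would manufacture results.

## Expression

Replicate Cts are arithmetically averaged before ΔCt (standard Livak
procedure), ΔCt subtracts the reference gene per condition, ΔΔCt subtracts
the control condition, fold = 2^−ΔΔCT; the control column is exactly 1 and
log₂ fold = −ΔΔCt identically. The reference gene is a required parameter
rather than a hard-coded name. Response classes over a treatment series
(default threshold 2-fold): up if any fold ≥ 2 and none ≤ 0.5, down
mirrored, both → mixed, neither → flat. Heatmap ordering uses
average-linkage clustering of log₂-fold rows under Euclidean distance,
rows pre-sorted by label so equal-distance merges are deterministic; a
constant matrix yields a valid all-zero-height dendrogram.

## Synthetic data: what it emulates and what it does not

- `gen_iq67_protein` plants grammar-exact domains in a background drawn
  from the 19 non-glutamine residues, so no accidental IQ motif can span a
  planted boundary (both IQ forms require Q at position 2); decoy single
  motifs are placed only where they complete no 11/15-spaced triple.
  Planted recovery is therefore exact by construction — it validates the
  scanner, not the realism of protein composition.
- `gen_diverged_cds_pair` draws a codon-uniform stop-free ancestor and
  applies Poisson numbers of synonymous and nonsynonymous single-base
  events (means Ks·S and ω·Ks·N over the ancestor's NG86 site counts),
  rejecting stop-creating changes, i.i.d. across sites. Realized tallies
  are recorded, so estimator checks compare against what was actually
  applied. No codon-usage bias, rate heterogeneity, indels or
  transition/transversion bias — deliberately matching the assumptions of
  the NG86/JC estimator under test. Default study conditions for parameter
  recovery: 1000 codons, Ks 0.2, ω 0.2, 100 seeds.
- `gen_family_fixture` builds unrelated random ancestors (positional
  identity ≈ 25 %), per-species orthologous copies at 1.5 % divergence and
  within-species duplicates at 8 % extra divergence (≈ 92 % identity, well
  inside the 70/70 rule; duplicates strictly more diverged than any
  ortholog so reciprocal-best-hit truth recovery is exact by
  construction). Defaults: 2 species × 5 genes of 250 codons, 2
  duplications.
- `gen_promoters` places non-overlapping element copies (random strand,
  random realization of degenerate positions) separated by at least the
  longest library motif, then mutates background bases until the planted
  occurrences are the only matches on either strand; it refuses libraries
  whose elements collide inside planted copies (e.g. palindromes planted
  on the reverse strand), keeping counts exact truth.
- `gen_ct_table` holds the reference gene's Ct constant, sets each
  target's condition Ct to its control Ct − log₂(fold), and adds i.i.d.
  Gaussian replicate noise (default 3 replicates, study noise level
  σ = 0.2 cycles). Amplification-efficiency variation and technical/
  biological replicate structure are not modelled.

Passing the truth-recovery suites therefore demonstrates correctness of
the computations under their own model assumptions, not performance on
real genomes — real proteins contain Q-rich regions, real promoters repeat
elements in biased contexts, and real qPCR noise is not Gaussian-constant.

## Problem sizes

The shipped drivers and test suites use desk-scale inputs chosen to make
every check exact or tightly toleranced: 100 × 1000-codon pairs for rate
recovery, 50 random 6–10-taxon additive matrices for NJ consistency, 20
fixture seeds for homolog F1, 100 seeds for promoter count recovery, 200
genes for expression recovery, 200–1000 bootstrap replicates for trees.

## Known limitations

- No profile-HMM search; the explicit grammar replaces it, so divergent
  domains that violate the exact 11/15 spacing require a spacer tolerance.
- No multiple sequence alignment, synteny analysis, ML codon models, or
  amplification-efficiency correction.
- The cis-element library requires user-supplied consensi for the PLACE
  identifiers; packaged entries are placeholders by design.
- `DistanceMatrix` requires finite entries, so saturated/undefined
  distances must be resolved upstream.
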