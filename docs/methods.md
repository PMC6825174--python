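# Methods

This note documents the models, conventions and defaults behind each stage,
the design choices made where several reasonable options existed, and what
the synthetic-data generators do and do not emulate.

## Sequence comparison and phylogeny (`seqalign`)

Pairwise global alignment uses Needleman–Wunsch with affine gaps
(BLOSUM62, gap open −10, gap extend −1; a gap of length k costs
open + (k−1)·extend). We deliberately use *pairwise* alignment rather than a
multiple sequence alignment: distances, relative-selection and ZOOPS motif
discovery all operate on unaligned or pairwise-aligned inputs, so an MSA
subsystem would add nothing downstream. Percent identity is computed over
aligned columns with at least one residue; the p-distance is
1 − identity/100, so distances live in [0, 1].

Neighbor joining is the standard Saitou–Nei agglomeration on the Q-matrix.
Properties relied on elsewhere: on an additive (tree-metric) input the
reconstructed path-length metric reproduces the input exactly (checked to
1e−9), and ties in Q are broken deterministically by label pair. Negative
branch-length estimates — possible on non-additive inputs — are clamped to
zero with a warning, the common convention. Trees are unrooted (internal
nodes of degree 3) and serialized to Newick by rooting arbitrarily at an
internal node.

`select_relatives` sorts by distance to the focal sequence with
lexicographic tie-breaks and takes either the k closest (focal included) or
all within a distance ceiling. No default k or ceiling is asserted: how many
relatives to use is a per-study decision, so exactly one of the two modes
must be given explicitly.

## Motif discovery (`motifs`)

The ZOOPS model: sequence i of length L_i either contains no site (prior
1 − γ) or one site at a uniformly chosen admissible offset (prior γ/m_i,
m_i = L_i − w + 1 valid windows). Site columns are emitted by a w × 20 PWM,
everything else by a fixed background estimated once from residue
frequencies (Laplace-floored). EM alternates posterior site
responsibilities with PWM/γ re-estimation; M-steps add a Dirichlet
pseudocount of 0.01·background per PWM row. Because of the pseudocounts the
provably monotone objective is the MAP-penalized log-likelihood
(log-likelihood + pseudocount prior term); that is the quantity recorded in
`ll_history` and asserted non-decreasing (tolerance 1e−9). Convergence:
|Δ objective| < 1e−6, max 200 iterations.

Seeding is MEME-like and deterministic: PWMs are initialized from observed
w-mers (probability 0.7 on the seen residue), up to 200 evenly spaced seed
sites per width are screened with two EM iterations, and the best few
(default 5) run to convergence.

**Width selection.** Candidate models across widths 6–10 are compared by
floor-penalized total information, ic_bits − c·w with c = 1.0 bit/column
(the same floor used for early stopping). We do not use per-column
information ic/w: every sub-window of a conserved motif has nearly the same
per-column information as the full motif, so ic/w cannot identify the true
width — the penalized total, by contrast, grows only while added columns
carry more than c bits. MEME's E-value machinery is out of scope; the floor
is a declared, overridable convention.

Multiple motifs are found sequentially with hard erasing: accepted
occurrence positions are masked with a character excluded from all counts,
which guarantees occurrence intervals of different motifs never overlap.
Occurrences are called per sequence when the posterior probability of
carrying a site exceeds 0.5, at the argmax offset. `scan` places a fitted
PWM on arbitrary sequences by log2-odds thresholding.

A caveat observed during development: with few sequences (n ≈ 6–12),
empirical per-column information of *any* gapless alignment is inflated by
small-sample bias, so the 1.0-bit floor does not by itself stop discovery on
pure background; γ and occurrence counts are the informative signals there.

## Primer design (`primers`)

The nucleotide consensus is built from what is *observed*: motif
occurrences are mapped codon-wise onto each species' CDS (aa offset a ↦ nt
[3a, 3a+3w)), the 3w-nt substrings are stacked, and each column becomes the
IUPAC code for the union of observed bases (template N ignored; an all-N
column is an error). Observed-union consensus, not codon-table
back-translation, is what keeps degeneracy low — a published 18-mer with a
single W is reproducible this way, while full back-translation of six codons
would often exceed 256-fold degeneracy.

Window selection enumerates all 18–22-nt windows of the consensus
(reverse-complemented first for reverse primers) and discards windows whose
last two positions are degenerate (3′ polymerase-extension rule), whose
degeneracy exceeds 64, or whose Wallace Tm range (2(A+T) + 4(G+C), computed
from the min/max GC count over expansions) leaves [45, 65] °C. Survivors are
ranked by (degeneracy, Tm spread, leftmost start), lexicographically. An
infeasible consensus yields a typed no-primer result carrying per-constraint
elimination counts rather than an exception. No GC-clamp is required
(published degenerate primers frequently end in A/T).

Pair enumeration takes every ordered motif pair on the reference transcript
(upstream motif → forward primer, downstream motif → reverse primer) and
keeps pairs whose product, measured footprint-inclusively (5′ of the forward
site to 5′ of the reverse site, i.e. rev-5′ − fwd-5′ + 1), lies in
[80, 300] bp by default. Pairs are scored ascending by
1.0·(combined degeneracy) + 0.1·|amplicon − 150| + 1.0·|ΔTm|; the weights
and the 150-bp target are declared conventions, overridable in
`DesignConfig`. Coordinates are 0-based half-open internally; reports are
1-based inclusive.

## IUPAC algebra, QC and in-silico PCR (`iupac`, `ispcr`)

The 15 ambiguity codes biject with the non-empty subsets of {A,C,G,T};
complementation is the induced involution (R↔Y, K↔M, S, W, N self).
Degeneracy is the product of per-position subset sizes; `expand` is the
sorted Cartesian product. QC reports GC and Wallace-Tm ranges over
expansions, the longest achievable mononucleotide run, and the longest
self-complementary stretch (exhaustive antiparallel substring check with
set-intersection pairing).

The binding-site scanner matches primer codes against concrete template
bases (a position matches when the template base is in the code's set;
template N never matches — conservative), with a mismatch budget and a
mismatch-free 3′ anchor of 3 positions by default, mirroring polymerase
extension sensitivity. Products are all (forward +strand, reverse −strand)
site combinations with positive footprint-inclusive length up to 3000 bp.
This local scanner is the in-repo specificity surrogate; it does not query
any remote database, and reports label it accordingly.

## Co-expression networks and key genes (`keygenes`)

Networks come from user data only: |Pearson r| of (optionally
log2(x+1)-transformed) expression rows, thresholded. Zero-variance genes
have undefined correlation and are excluded. Database-derived composite
networks are out of scope.

Centralities use unweighted shortest paths by default (edge weights can be
used as 1/w distances behind a flag). Formulas, per connected component of
size n_c and diameter Δ_c:

* degree — edge count;
* betweenness — Brandes pair-dependency sum (each unordered pair counted
  once);
* stress — raw count of shortest paths through the node,
  Σ_{s<t} σ_st(v);
* closeness — (n_c − 1) / Σ_w d(v, w);
* radiality — Σ_w (Δ_c + 1 − d(v, w)) / (n_c − 1);
* eigenvector — principal adjacency eigenvector by power iteration on
  A + I (the shift breaks the ±λ oscillation of bipartite spectra without
  changing eigenvectors), normalized to max 1.

Singletons get 0 for all distance-based measures, with an `isolated` flag.
Hub–bottleneck selection flags genes strictly above the mean in both degree
and betweenness (the usual screening convention; the cut is a parameter) and
ranks by the product of degree and betweenness percentile ranks, ties
lexicographic. Hierarchical clustering is average-linkage on 1 − r with
genes pre-sorted by id so flat partitions are reproducible under input
reordering.

## qPCR and metabolite correlation (`qpcr`)

2^−ΔΔCt with 100% assumed amplification efficiency. Averaging order is
declared: technical replicates first, then ΔCt = Ct_gene − Ct_reference per
(tissue, biological replicate), then ΔΔCt against the gene's mean calibrator
ΔCt, then mean ± SD of 2^−ΔΔCt over biological replicates. The calibrator
tissue is a required argument — no silent default. Its mean is exactly 1 in
the noiseless case; with replicate noise it stays centred on 1 up to the
(small) Jensen bias of exponentiating per-replicate values. ΔΔCt is
invariant to any additive shift applied to all Ct values of a (tissue,
replicate) pair. Expression–metabolite correlation is plain Pearson over
tissue means, tissues matched by id, dropped pairwise with n reported;
fewer than 3 shared tissues is an error, zero variance yields a missing
value.

## Synthetic data (`simulate`)

**Families.** An ancestral protein (uniform residue composition) evolves
down a star phylogeny with per-species substitution rates; planted motifs
are drawn per column at a stated conservation toward a fixed consensus, at
the same offset in every species (no indels). CDSs are built per residue;
with `synonymous_wobble` codons are drawn uniformly *within the canonical
codon box* (same first two bases), so planted variation is third-position
only — the regime in which degenerate primer design is informative. The
demo family (`demo_family_spec`) plants three fully conserved motifs built
from amino acids with 1–2-fold codon boxes (M, W, D, E, Y, C, F, N, K, Q,
H), the composition that keeps 18–22-mer windows under the 64-fold cap;
motif spacings put all pairwise products inside 80–300 bp on the 600-nt
CDS. Motif-recovery fixtures use background rate 0.95 (effectively i.i.d.
residues), so only planted columns carry signal.

**Expression.** A latent-factor model: module genes load √ρ on their
module's factor (ρ = target within-module correlation, default 0.8) plus
independent noise; hub genes load h/√M on every one of the M module factors
(default h = 0.9, M = 2), bridging the modules; remaining genes are pure
noise. Factor sample vectors are orthogonalized against the constant vector
and each other and standardized, so the planted structure (between-module
r = 0, within-module ρ) holds *in-sample*, not just in expectation — with
30 samples, raw i.i.d. factors can correlate at ±0.4 and silently destroy
the bridge. Hub–module correlation is h·√(ρ/2) ≈ 0.57 (its structural
ceiling is 1/√2, since squared correlations with orthogonal factors sum to
at most 1); the hub-recovery experiment therefore thresholds the network at
0.45, between the between-module (~0) and hub–module (~0.57) levels. Values
are 2^(8+z), positive and log2-recoverable.

**Ct tables.** Generated by inverting the 2^−ΔΔCt formula around a baseline
(reference 20 cycles, target 24 at the calibrator), with Gaussian
per-measurement noise; planted fold changes are exactly recoverable at zero
noise. All generators are pure functions of their spec: one explicit RNG
stream per spec, byte-identical reruns.

What the generators do *not* emulate: indels and alignment uncertainty,
realistic codon-usage bias or residue composition, tree-structured (rather
than star) divergence within a fixture, count-based RNA-seq noise, and
amplification-efficiency variation in qPCR. Passing tests therefore
demonstrate correctness of the algorithms under their stated models, not
robustness to those real-data complications.

## Problem sizes and determinism

Test and acceptance runs use desk-scale inputs chosen to exercise every
code path: 20 × 200-aa families for motif recovery, 6-species families for
end-to-end design, 40-gene/30-sample networks (100 replicates for the hub
experiment), graphs of n ≤ 8 against the exhaustive path-enumeration
oracle (50 replicates). All randomness flows from explicit integer seeds;
`scripts/acceptance.py` derives every stream from its `--seed` argument.

## Known limitations

* Motif discovery has no E-value significance machinery; the IC floor does
  not reliably stop discovery on pure background at small n (see above).
* The in-silico PCR scanner is quadratic and intended for transcript-scale
  templates, not genomes.
* Eigenvector centrality on a disconnected graph reflects the spectrally
  dominant component; other components' values decay toward 0.
* Exact numeric concordance with any particular published qPCR figure is
  not claimed: the calibrator tissue choice is a required user input.
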