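# phyloprimer

Phylogeny-guided design of taxa-specific degenerate primers for plant
biosynthetic gene families, with co-expression-network key-gene
prioritization and qPCR analysis.

## The problem

Cloning a biosynthetic gene (say, squalene epoxidase or an oxidosqualene
cyclase of the triterpenic-acid pathway) from a non-model plant usually
starts from homologs in related species. The workflow this package
implements:

1. **Select close relatives.** Homologous protein sequences are aligned
   pairwise (Needleman–Wunsch, BLOSUM62, affine gaps), a p-distance matrix
   (1 − fractional identity) is computed, a neighbor-joining tree is built,
   and the species closest to the focal taxon are kept.
2. **Find conserved blocks.** Ungapped protein motifs (width 6–10) are
   discovered by ZOOPS expectation–maximization — the "zero or one
   occurrence per sequence" model popularized by MEME: each sequence carries
   at most one site of a width-w position weight matrix against a background
   distribution; discovered sites are erased before the next motif is
   sought.
3. **Design degenerate primers.** Each protein motif occurrence is mapped
   codon-wise onto its coding sequence; the per-column union of observed
   bases across species becomes an IUPAC consensus (this keeps degeneracy
   far below codon-table back-translation when variation is synonymous).
   Primer windows of 18–22 nt are selected under a degeneracy cap (≤64),
   a Wallace-rule Tm range (2(A+T) + 4(G+C), 45–65 °C) and a non-degenerate
   3′ end; all ordered motif pairs are enumerated under amplicon-size
   constraints (default 80–300 bp) and ranked.
4. **Validate in silico.** A local in-silico PCR scanner matches degenerate
   primers against template sequences under IUPAC set semantics (template N
   never matches) with a mismatch budget and a mismatch-free 3′ anchor, and
   predicts product sizes.
5. **Prioritize key genes.** From an expression matrix (or an edge list), a
   co-expression network is built by thresholding |Pearson r|; degree,
   betweenness, closeness, stress, radiality and max-normalized eigenvector
   centrality are computed, and hub–bottleneck genes (above-mean degree AND
   betweenness) are flagged. Expression profiles are hierarchically
   clustered (average linkage, distance 1 − r).
6. **Quantify and correlate.** Relative expression from Ct tables by the
   2^−ΔΔCt method (reference gene + calibrator tissue), and tissue-wise
   Pearson correlation of expression against metabolite content.

Every stage has a deterministic synthetic-data generator
(`phyloprimer.simulate`) that records ground truth (planted motif
positions, module/hub memberships, fold changes), so the whole pipeline is
testable without downloads.

## Worked example

Simulate a six-species homolog family (three fully conserved planted
motifs, third-position codon wobble) and design primers on the first
species' transcript:

```sh
$ phyloprimer simulate family --out demo --seed 7
$ phyloprimer design-primers --proteins demo/proteins.fa --cds demo/cds.fa \
      --reference sp00 --gene-name FAM --n-motifs 3 --seed 1
gene_name  primer        sequence_5to3  amplicon_bp  degeneracy  tm_min_c  tm_max_c  gc_min_pct  gc_max_pct
      FAM  FAMFwd ATGTGGGAYGARTAYTGYTT          138          16      52.0      60.0        30.0        50.0
      FAM  FAMRev   YTTRTTYTGRTGCATCCA          138          16      46.0      54.0        27.8        50.0
      FAM FAMFwd2 TGGATGCAYCARAAYAARGA          168          16      52.0      60.0        30.0        50.0
      FAM FAMRev2   CATYTTRTGRTCRTTCCA          168          16      46.0      54.0        27.8        50.0
      ...
```

Each primer is one IUPAC string standing for a set of concrete oligos
(degeneracy 16 = four 2-fold positions), with Tm/GC ranges over all
expansions; `amplicon_bp` is the footprint-inclusive product length on the
reference. The degenerate codes sit on third codon positions only, because
between-species variation in the fixture is synonymous. Verify the top pair
amplifies every species:

```sh
$ phyloprimer ispcr --fwd ATGTGGGAYGARTAYTGYTT --rev YTTRTTYTGRTGCATCCA \
      --templates demo/cds.fa
template  start  end  length_bp  fwd_mismatches  rev_mismatches
sp00      91     228  138        0               0
...                                    # one 138-bp product per species
```

Rank genes from an expression matrix (here: simulated, with a planted
hub-bridge gene):

```sh
$ phyloprimer simulate expression --out demo-expr --seed 2
$ phyloprimer rank-genes --expr demo-expr/expression.tsv --threshold 0.45
```

The top-ranked gene is the planted hub (`truth.json` records it), flagged
`hub_bottleneck=True` because it exceeds the network mean in both degree and
betweenness.

The same operations are available as a library
(`phyloprimer.seqalign`, `.motifs`, `.primers`, `.ispcr`, `.keygenes`,
`.qpcr`, `.simulate`); see `docs/methods.md` for models, conventions and
parameter defaults.

A published six-gene Lamiaceae primer panel (FDS, SQS, SQE, LUS, BAS, MFAS)
ships in `phyloprimer.panel` as a reference input for the IUPAC algebra and
design-rule checks. To check that panel against real transcripts, download a
rosemary transcriptome assembly and run `phyloprimer ispcr` with each pair
against it (network access required; not part of the test suite).

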