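# Methods

`aarscan` analyses tandem amino acid repeats (AARs, homopeptides) in
protein-coding genes: detection and repeat-content statistics, coupling of
repeat content to coding GC, conservation of repeats in ortholog alignments,
the evolutionary rate of repeat flanks, structural-disorder enrichment, and
transcript-level regulation of repeat-containing proteins (RCPs).  Because
the corresponding genome-scale observations require external proteomes,
expression arrays and third-party disorder predictors, the package is
validated against synthetic data whose generative structure is known — every
claim the pipeline can make is checked as either an exact worked example, an
oracle equivalence, or a parameter-recovery/calibration experiment.

## Definitions and statistics

**AAR.** An uninterrupted run of `min_len` (default 4) or more identical
amino acids.  Runs are maximal and non-overlapping.  `X` or any non-standard
letter breaks a run and never seeds one: an ambiguous residue cannot be
asserted identical to its neighbours.  Coordinates are 0-based half-open in
the library and 1-based inclusive in written tables (stated in headers).

**RRPK** (repeated residues per kilo amino acids): total AAR residues
divided by protein (or segment) length, times 1000.  The 15-residue peptide
`QQQQQSTWQQQQAAE` carries two runs totalling 9 residues, RRPK
= 9/15 × 1000 = 600.  A protein with at least one AAR is an RCP.

**GC content** is computed over unambiguous A/C/G/T only; IUPAC ambiguity
codes are excluded from numerator and denominator.  Regional GC projects
each residue's codon (positions 3i..3i+2) onto the residue's region.

**Thirds partition.**  For length n = 3q + r the remainder is given to the
N-terminal side (first r segments get q+1 residues).  A repeat spanning a
boundary contributes its residues to each side, which keeps
Σ(segment length × segment RRPK)/1000 exactly equal to the total repeat
residue count.

**GC-rich-codon repeats** are alanine, glycine and proline runs (the three
residues encoded exclusively by GC-rich codons).

## Conservation in ortholog alignments

A repeat is mapped to the minimal alignment-column span whose ungapped focal
content is the repeat tract.  It *fails to align* when every other member's
gap fraction over that span strictly exceeds 0.5 (configurable; the
strictest reading — entirely gap-filled — corresponds to threshold 1 minus
epsilon, but partial gap fill is common, so the threshold is exposed and
logged).  A *conserved long* repeat has length ≥ 8 and at least 8 other
members whose region identity — the fraction of span columns carrying the
repeat's amino acid, gaps counting as mismatches — is at least 0.5.  This is
the simplest reading of "alignment identity" for a homopolymer block; no
requirement is placed on the taxonomic spread of the supporters.

**Flanking regions** extend up to 33 residues on each side of a repeat,
truncated at the protein ends and at adjacent repeats; the region between
two repeats closer than 66 residues is shared by both, and flank spans are
merged per protein before any rate estimation so no codon is counted twice.

## dN/dS (NG86)

The estimator is Nei–Gojobori (1986) counting with Jukes–Cantor correction,
chosen over ML codon models because it is self-contained and verifiable by
exhaustive enumeration at the single-codon scale:

* synonymous *site* counts use the fractional method per codon position;
  single-nucleotide changes to stop codons are excluded from both numerator
  and denominator of the fraction (site counts per codon sum to 3);
* *differences* between two codons average the synonymous/nonsynonymous
  step classifications over all orderings of the differing positions;
  pathways through intermediate stop codons are discarded unless every
  pathway is;
* pS = Sd/S and pN = Nd/N are corrected by d = −(3/4)·ln(1 − 4p/3);
  p ≥ 3/4 is flagged saturated, dS = 0 with dN > 0 flags an
  infinite/undefined ratio.

Counting tables over the 61 sense codons are precomputed, so estimation on
long sequences is integer table lookup.  Under a neutral mutation model
(every nucleotide substitution equally likely, stop-creating changes
redrawn) the mean dN/dS over replicate pairs at ~10% site divergence centres
on 1 (measured 0.99), the estimator's basic unbiasedness check.

**Per-protein aggregation.**  A protein-region's dN/dS across its ortholog
pairs is computed by *pooling* the site and difference counts over all
pairs and forming a single ratio.  Averaging per-pair ratios instead
(the obvious alternative) inflates the expectation of short regions by
approximately CV²(dS) ≈ 1/Sd — a ~25% upward bias for a 66-residue flank at
moderate divergence versus ~7% for a whole protein — which manufactures a
spurious flank-vs-whole difference under identical evolution.  Pooling
keeps both region classes nearly unbiased at the default divergence
(pairwise dS ≈ 0.3, giving pooled Sd of order 10² per region).  An explicit
delta-method correction was evaluated and rejected: at these counts it
overcorrects.

**Flank vs whole comparison.**  For each repeat-containing member the
pipeline computes pooled dN/dS over (a) the merged flank spans and (b) the
whole protein *excluding the repeat tracts themselves* — a maintained
homopolymer is nonsynonymously invariant by construction, so including it
would depress the baseline irrespective of flank evolution.  Per species,
flank and whole values are compared with a two-sided Mann–Whitney U test;
each group contributes one protein per species, so the observations within
a sample are independent (the additionally reported pooled-species row
mixes up to ten correlated members per group and is labelled accordingly).
The fraction of flank values above 1 is reported as the positive-selection
candidate rate.

## Disorder

A repeat is *fully disordered* when every residue in its window carries a
disordered call in a per-residue binary annotation (two independent tracks
may be supplied and are never reconciled).  Enrichment is tested against a
random-segment null: in each of `n_trials` (default 1000) trials, every
repeat is matched by one segment of identical length placed uniformly
inside a uniformly chosen RCP (restricted to RCPs long enough to host the
segment; a same-protein sampling mode is available, pooled sampling is the
default as the simplest reading of "random segments in RCPs").  The
empirical p is the add-one estimator (b+1)/(n+1), so zero exceedances in
1000 trials yields p = 1/1001 < 0.001 and p is never exactly 0.  With a
fixed seed the whole null distribution is reproducible.  Calibration: when
disorder is assigned i.i.d. per residue independently of repeats, the
empirical p is approximately uniform over replications (KS test); ties
between the observed fraction and null draws make it slightly conservative,
which shrinks as the number of repeats grows.

## Regulation statistics

**Expression normalization**: log2-transform present (above-background)
values, subtract each tissue's mean, add the grand mean of all present log
values; absent calls stay masked.  Column means are equal afterwards.

**Tissue-specificity index**: TSI = Σᵢ(1 − xᵢ/x_max)/(N − 1) over the N
usable tissues; 0 means uniform expression, 1 single-tissue expression.
Computed on normalized log values (following the stated normalization
order); negative normalized values are floored at 0 first (the index
assumes nonnegative input; flooring is flagged per gene), and genes with
fewer than 2 usable tissues or x_max ≤ 0 are flagged undefined.  Probe-level
values are averaged per locus (unweighted).

**Half-lives**: Welch's unequal-variance t-test of RCP vs non-RCP
transcript half-lives, with per-locus probe averaging.

**Splice classes**: an exon (by exact genomic interval) is constitutive iff
the identical interval occurs in every model of its gene; single-model
genes are all-constitutive.  Protein residues map to the exon containing
the first base of their codon (junction codons go to the upstream/5' exon —
deterministic and consistent with first-base conventions).  Per-segment
RRPK values are pooled across genes and compared alternative vs
constitutive with Welch's t-test.

**Hotspot neighbours**: a gene neighbours a recombination hotspot iff its
interval overlaps a hotspot interval by ≥ 1 bp (0-based half-open, shared
chromosome naming); the RCP × neighbouring 2×2 table is tested with the
two-sided Fisher's exact test.  Hotspot inference itself is out of scope;
intervals are inputs.

## Statistical tests

Pearson (t-based p), Welch's t and the asymptotic Mann–Whitney U (midranks,
tie-corrected variance, continuity correction) delegate to scipy, which
implements exactly these formulas; Fisher's exact 2×2 (own log-gamma
hypergeometric summation of tables no more probable than observed),
Grubbs's single-outlier test (G = max|xᵢ−x̄|/s with the t-distribution
relation t² = G²n(n−2)/((n−1)² − nG²), p = min(1, 2n·P(T₍ₙ₋₂₎ > t))) and
the add-one empirical p are implemented in-repo.  `mann_whitney_u` defaults
to exact enumeration when both samples have ≤ 8 observations: the normal
approximation is intrinsically coarse there (deviations up to ~0.04 from
the exact p at n = 3); from sample sizes of 5 upwards it is within 0.02.
All tests are two-sided unless configured otherwise and every resampling
procedure takes a mandatory seed.

## Synthetic data

The generator emits every input the pipeline reads, in standard formats,
with ground-truth labels written alongside so tests never re-derive truth by
a second method.  Identical seed and config give a byte-identical bundle.

**Proteomes.**  Ten species (default) with GC targets evenly spaced on
0.38–0.62 and 200 proteins each of length 120–300.  Amino acids are drawn
i.i.d. from a fixed background composition; repeat tracts (lengths 4 + a
truncated geometric, mean ≈ 5.8; residues drawn from a disorder-promoting
set: S, Q, A, G, P, E...) are seeded so that the expected repeat residues
per protein equal `base + β·GC` (defaults 0.5 + 12·GC, giving species mean
RRPK of order 20–40 and RCP fractions of 0.55–0.75 — a deliberately higher
repeat density than real proteomes so that per-species means are estimable
from 200-protein samples).  Coding sequences choose synonymous codons with
weight g^nGC·(1−g)^(3−nGC) toward the species target g, so coding GC varies
across species while the protein-level repeat process depends on GC *only*
through β: at β = 0 repeat content and GC are independent by construction,
making the no-coupling null exact.  Seeded tracts are reconciled with the
final sequence (expanded to the maximal run, merged) before the truth table
is written.

A single generative procedure in which species GC targets biased nucleotide
proposals during evolution was rejected: GC-biased proposals shift amino
acid composition toward alanine/glycine/proline and would couple repeat
content to GC even at β = 0, destroying the null the calibration
experiments require.  The proteome and ortholog sub-generators are
therefore separate, composed by `generate_bundle`.

**Ortholog groups.**  Forty groups (default) descend from a group ancestor
on a star phylogeny (the analyses are pairwise/column-wise; a star keeps
alignment-by-construction exact).  Each ancestor carries one seeded tract:
*conserved* (probability 0.3; length 8–12, kept intact by every member) or
*lineage-specific* (length 4–8, kept only by the first member; others
retain 0–3 residues, the remainder becoming codon-sized gaps).  Sites
mutate with per-codon proposal probability 0.3 per branch; nonsynonymous
proposals are accepted with probability 0.25 genome-wide, ×`flank_relaxation`
(capped at 1) within 33 residues of the tract, and 0 inside the tract
(the repeat is maintained; its synonymous sites evolve at the background
proposal rate, so tract columns are not a rate anomaly).  Stop-creating
proposals are rejected.  Indels occur only inside tracts, so alignment
columns are placed without an aligner and every row ungaps to its member's
exact sequence.

**Disorder tracks.**  Two Bernoulli pseudo-tracks with different
sensitivity/specificity trade-offs (defaults 0.90/0.30 and 0.60/0.12
inside-repeat/background, window ±10 residues), emulating predictors that
disagree on absolute fractions while both being repeat-enriched.

**Regulation inputs.**  Log-normal expression over 6 tissues with a
configurable fraction of tissue-specific RCPs (one dominant tissue),
~20% of loci carrying two probes, 4% absent calls; exponential half-lives
with RCP mean multiplied by 0.6; gene models with 1–5 coding exons whose
boundaries need not be codon-aligned, 15% of genes receiving a second model
that drops (preferentially) the most repeat-rich exon; gene and hotspot
intervals on one chromosome with hotspots anchored on RCP genes at 3×
probability.

**What the generator does not emulate** — real codon-usage tables, genome
sizes, phylogenetic tree structure, microarray noise models, linked hotspot
inference — bounds what passing tests show: the pipeline detects the
effects this structure encodes and stays calibrated when they are absent;
agreement with any particular real proteome's numbers is not claimed.

## Experiment problem sizes

The repeat-seed experiments (`aarscan.experiments`) use: 100/600 seeds for
the RRPK–GC coupling power/null at 10 species × 200 proteins per seed
(power ≥ 90% at the default β; null type-I within [0.03, 0.07]); 50/100
seeds for flank relaxation power/null at 40 groups × 10 members; 200
replications × 200 trials for the permutation-null uniformity check; and
200 pairs × 300 codons for the neutral dN/dS limit.  These sizes keep the
full suite deskable while leaving the binomial noise of each measured rate
well inside its acceptance band.

## Known limitations

* NG86 is a counting estimator: absolute dN/dS values differ from ML
  estimates (yn00/codeml); all conclusions here are comparative
  (neutral-limit, rank-order, calibration).
* The flank-vs-whole comparison shares sites between the two samples of the
  Mann–Whitney test (flanks are part of the protein); within a species the
  observations are independent across groups, but the pairing makes the
  test mildly conservative under the null.
* The random-segment empirical p is conservative in the presence of ties
  with the observed fraction (discrete statistic); uniformity holds to KS
  resolution at ~200+ repeats.
* Grubbs's p uses the classical t-relation bound, accurate for the single
  most extreme point only.
* The exon mapper assumes the representative model's coding exons partition
  the CDS exactly; genes violating this are rejected with an error.
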