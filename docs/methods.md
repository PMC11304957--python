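# Methods

## The screen and its statistic

The package analyses saturation selection screens over the CXXX motif
space: all 8,000 four-residue C-terminal motifs with a fixed cysteine and
three variable residues, encoded by a 9-nt variable region. A reporter
couples motif modifiability to growth; sequencing the variable region
before (naive) and after selection yields per-variant frequencies

f(v) = (reads of v summed over all replicates) / (all accepted reads),

and the enrichment score E(v) = f_selected(v) / f_naive(v).

Two analysis conventions are deliberate:

* **No pseudocounts.** Scores are raw ratios; a variant absent after
  selection scores exactly 0. A zero *naive* frequency makes the ratio
  undefined; such variants are flagged (`status = "undefined"`) and
  excluded from rankings with a logged warning, never smoothed.
* **Denominator = accepted reads only.** Reads rejected during processing
  (missing anchors, wrong insert length, stop codons, out-of-library
  translations) are tallied per reason and excluded from frequency
  denominators, so accepted + rejected always equals reads processed.

The permissive-temperature (25 °C) library is computed and exported but
never used as an E-Score denominator; only the naive library serves as
reference, because a grown permissive culture adds its own selection noise
to the denominator.

## Motif classification

Classification is driven by configurable residue sets with these defaults:

| flag | rule | default sets |
|---|---|---|
| `x_consensus` | terminal X compatible with modification | X ∈ {L,F,I,M,V} |
| `a2_bca` | a2 is branched-chain aliphatic | a2 ∈ {V,I,L} |
| `canonical_cleavable` | `a2_bca` ∧ `x_consensus` | Cx[V/I/L][L/F/I/M/V] |
| `restrictive` | residues blocking modification | a2 ∈ {D,E,K,R} ∨ X ∈ {K,R,P} |

`canonical_cleavable` is keyed on a2 and X only — a1 is unconstrained — so
sequences like CAIL count as canonical. This matches the de-enriched
profile the screen itself produces; an a1-restricted definition can be
supplied through the ruleset configuration.

For logo rendering the twenty residues partition into five classes:
cysteine (blue), branched-chain aliphatic V/I/L (red), charged K/R/H/D/E
(green), polar uncharged S/Q/T/N (black), other hydrophobic A/G/P/F/W/Y/M
(purple).

## The synthetic-data generator

The simulator reproduces the statistical structure of the screen, stage by
stage, under one seed (all stages consume child streams spawned from it):

1. **Library abundance.** One symmetric Dirichlet draw (concentration
   α = 5 per variant) gives the library-wide abundance vector. α = 5
   produces the right qualitative picture — several-fold spread between
   rare and common variants with no variant absent — without modelling the
   cause of the unevenness. Every variant has nonzero abundance.
2. **Colony sampling.** Each replicate of each condition draws
   multinomial(150,000 CFUs) colonies from that vector; 10 replicates per
   condition by default.
3. **Growth.** N_i′ = N_i · 2^(f_i·D) with D = 8 doublings — the simplest
   law consistent with growth "rounds of population doubling". Relative
   growth rates f ∈ [0,1] come from a motif-category rule table.
4. **Sequencing.** multinomial(depth) reads per replicate proportional to
   grown abundances, default depth 100,000 reads/replicate (a desk-scale
   choice; real per-replicate depths are screen-specific), then a uniform
   substitution-error channel at 0.001/base.

**Fitness calibration.** The rule tables are the generator's ground truth,
a calibration rather than measured values:

| category | definition | f at 42 °C | f at 37 °C |
|---|---|---|---|
| shunted | x_consensus ∧ ¬a2_bca ∧ ¬restrictive (n = 1,300) | 1.00 | 1.00 |
| other ("unmodified") | ¬x_consensus ∧ ¬restrictive (n = 3,840) | 0.25 | 0.75 |
| canonical | a2_bca ∧ x_consensus (n = 300) | 0.15 | 0.10 |
| restrictive | a2 ∈ DEKR ∨ X ∈ KRP (n = 2,560) | 0.05 | 0.70 |

The strict ordering encodes three qualitative facts the screen must
reproduce: shunted motifs dominate the enriched tail; canonically modified
motifs underperform even the unmodified reporter; and at the harsher
temperature the de-enriched tail is majority-restrictive (which requires
restrictive < canonical there — with the two tied, restrictive motifs
would be only ~40% of the bottom tail, since they are 32% of the library).
At 37 °C the spread is smaller and canonical motifs are the most impaired,
so the strongly de-enriched subset at that temperature is essentially the
canonical Cx[V/I/L][L/F/I/M/V] class. 25 °C is neutral (all f = 1), so
only sampling noise separates it from the naive library.

**Error channel.** FASTQ materialisation applies independent per-base
substitutions over the whole read (anchors included). The count-level fast
path applies the statistically matched channel per variant: each read
mutates with probability 1 − (1−e)^9 over its variable bases and is
reassigned along a uniformly chosen single-base substitution of the
variant's fixed coding 9-mer (reads acquiring ≥ 2 errors — < 0.01% of
reads at e = 0.001 — are approximated as single-error). Mutants that
translate through a stop codon are tallied as rejected reads.

**Amplicon layout.** Reads are `anchor_left + 9-mer + anchor_right` with
fixed synthetic 20-nt anchors and a constant quality string; real amplicon
structure, primer positions and quality profiles are not modelled. Each
variant uses a fixed coding DNA (lexicographically first codons) in the
sequencing screen; synonymous-codon diversity appears only where it
matters, in the colony-screen mode.

**Colony-screen mode.** The viability reporter treats shunted and
canonical motifs as viable and everything else as inviable. Colony picks
are parent DNA with probability 83/200 (gene conversion), repeats of an
earlier pick with probability 5/117 (double-picked colonies), and
otherwise random synonymous codon encodings of uniformly drawn viable
variants; the parent's CVLL coding DNA is a fixed synthetic choice
(GTT-TTG-TTG). These fractions calibrate the expected deduplication ladder
to 200 → 117 → 112 unique DNA sequences.

## What passing tests do and do not show

The simulator emulates sampling structure, not biology: fitness values are
calibrated, not measured; abundance unevenness is Dirichlet by fiat; PCR
jackpots, quality-score structure, chimeric reads and
transformation-efficiency bias are absent; colony picks are uniform over
viable variants, so the cross-reference fractions (share of colony hits
with E > 2, etc.) reflect that uniformity rather than a real screen's hit
spectrum. Passing recovery tests therefore demonstrates that the analysis
pipeline — counting, normalisation, scoring, subset selection, motif
summarisation — correctly recovers a known ground truth through realistic
sampling noise, not that any particular enzyme has a particular
specificity.

## Numerical and design choices

* **Coverage.** Expected coverage is `1 − (1 − 1/L)^n` via `log1p`/`expm1`.
  The probability of complete coverage uses inclusion–exclusion,
  Σ_j (−1)^j C(L,j)(1 − j/L)^n, with log-space terms and a signed
  log-sum-exp so alternating terms cancel stably; library sizes are capped
  at 10⁶. Both definitions are exposed because coverage calculators differ
  in which they report; for the study conditions (L = 8,000, n = 150,000)
  both exceed 0.999. `required_sample_size` binary-searches the monotone
  coverage function. An optional Monte-Carlo mode quantifies the coverage
  cost of Dirichlet-uneven abundances.
* **Ranking determinism.** Subset selections sort by score with
  lexicographic tie-breaks on the variant string, so top-N/bottom-N sets
  are stable across runs and platforms.
* **Anchored extraction** allows substitutions only (≤ 1 per anchor by
  default), no indels — deterministic and fast; reads are not
  reverse-complement searched by default (the simulator emits forward
  reads; a flag enables RC search for real data). No quality filter is
  applied by default; a mean-Phred threshold is available.
* **Degenerate inputs.** All-zero count tables, empty subsets, ragged
  sequence lengths, zero/negative sample sizes and unreachable coverage
  targets raise errors rather than propagating NaNs; untranslatable colony
  sequences are excluded from the deduplication ladder and listed as
  rejects.
* **Determinism.** The pipeline writes no timestamps; the run manifest
  records the config, seed, version and SHA-256 of every artifact, so two
  replays with one seed are byte-identical directory trees.

## Test problem sizes

The suite exercises full-library (8,000-variant) screens at 100k
reads/replicate for the recovery properties, and smaller sub-libraries
(50–400 variants) where the property under test is scale-free (round
trips, determinism, pipeline artifacts). The neutral-selection control
runs on a 100-variant sub-library at otherwise default conditions: the
mean-E-Score-equals-1 property concerns estimator bias, and the frequency
ratio's Jensen bias (≈ K·α/(α−1)·Σ 1/N over the denominator's sampling
stages, for K variants) must sit well below the cross-variant standard
error for the check to be informative; at K = 100 the bias-to-SE ratio is
≈ 0.1, while at K = 8,000 the colony bottleneck alone pushes it past the
3-SE band for any feasible depth. The colony-screen ladder is averaged
over 100 seeds.

## Known limitations

* Enrichment scores carry no variance model, confidence intervals or
  significance tests; they are point ratios.
* The coverage model assumes equal abundances except in the Monte-Carlo
  mode; transformation-efficiency bias between host libraries is not
  modelled.
* The indel-free anchor matcher will reject reads with insertions or
  deletions inside the anchors; real data with indel-prone chemistry needs
  upstream trimming.
* UMIs, paired-end merging and alignment to the full reporter plasmid are
  out of scope.
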