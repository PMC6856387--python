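# Methods

## Scoring model

A sample's carbohydrate-processing potential is read out from shotgun
sequence data in four stages: predict protein fragments from merged reads,
scan them against a catalog of carbohydrate-active-domain profile HMMs,
accept hits under dbCAN-style criteria, and integrate the accepted hits'
HMM-coverage fractions into per-family scores.

The per-family score is

    DFPMAA_250(h) = 10^6 × Σ_i cov_i(h) / N_aa

with cov_i = (hmm_to − hmm_from + 1) / hmm_len the fraction of model *h*'s
match states covered by hit *i* and N_aa the total amino acids of all
fragments submitted to scanning. The underlying assumption is that enzyme
(domain) copy number is the limiting factor of a community's carbohydrate
turnover, so integrated domain counts per unit of coding sequence are a
meaningful capability readout. Being a ratio of two extensive quantities,
the score is invariant under duplication of the read set and stable in
sequencing depth once all families are sampled.

### The role of "250"

The 250 in the score's name is treated as the reference read length (nt)
at which the score is calibrated, recorded as metadata — not as an extra
divisor. The ratio itself is read-length-neutral above the coverage
threshold; the documented read-length sensitivity enters only through the
0.3-coverage acceptance rule (below). An opt-in
`rescale_to_reference=True` multiplies scores by 250/mean-read-length for
users who prefer an explicit rescale; the default applies no such factor.

### Acceptance rules and their constants

`FilterConfig` holds the dbCAN parser's published defaults, applied in the
parser's order: overlap resolution first, then the E-value tier, then
coverage.

| parameter | default | meaning |
|---|---|---|
| `overlap_frac` | 0.5 | same-sequence hits conflict when alignment overlap exceeds this fraction of the shorter alignment; the lower i-Evalue wins (ties → higher bit score → smaller start) |
| `evalue_long` / `long_aa` | 1e-5 / 80 aa | i-Evalue ceiling for alignments longer than 80 aa |
| `evalue_short` | 1e-3 | ceiling for alignments ≤ 80 aa |
| `min_cov` | 0.3 | minimal covered fraction of HMM match states |

The filtering statistic is the independent per-domain E-value (i-Evalue),
not the full-sequence E-value: per-domain decisions require the
per-domain statistic. Coverage uses HMMER's inclusive coordinates
(`to − from + 1`); the alternative exclusive convention would differ by at
most 1/hmm_len.

Overlap resolution is implemented as greedy elimination by ascending
i-Evalue with pairwise conflict checks, which for this conflict relation
yields the same kept set as exhaustive pairwise elimination; the test
suite checks equivalence against a direct rule-enumeration oracle on
random instances.

A read-length gate at 187.6 nt mean merged-read length flags datasets
whose scores are systematically underestimated by the coverage rule
(most known protein domains are under 200 aa, so ~190 nt of coding
sequence is about the minimum that can cover 30% of a typical model).
Scores remain computable below the gate; only cross-dataset comparability
is flagged.

## Fragment prediction

The six-frame translator is a deliberately naive stand-in for
indel-aware fragment gene predictors (FragGeneScan and kin), adequate for
error-free synthetic reads: translate all six frames with the bacterial
genetic code (table 11), split at stops, keep maximal stop-free fragments
of ≥ 20 residues (`min_aa`). Fragments need not start with methionine —
shotgun reads are random genome windows. Codons containing N translate to
X. N_aa counts exactly the residues of the fragments handed to scanning,
keeping numerator and denominator consistent.

## Diversity and rarefaction

Hill numbers D_q = (Σ f^q)^(1/(1−q)) are computed over normalized
frequencies of "species equivalents" — OTUs or per-family scores. q = 0
counts nonzero entries (the alpha-diversity convention used throughout),
q = 1 is evaluated by its analytic limit exp(−Σ f ln f) rather than by
numerical approach (a 1e-3 continuity band at q = 1 is asserted, never
used in computation), and zero frequencies are excluded at every q.
Per-family scores are normalized to frequencies before profiling; raw hit
counts would weight large families differently, and the normalized choice
makes profiles comparable across samples with different N_aa.

Rarefaction subsamples counts **without replacement** (multivariate
hypergeometric): subsets of observed reads are draws from those reads, and
the hypergeometric expectation gives the tests an exact oracle. Output
totals equal the requested depth exactly; saturation curves average
nonzero-feature counts over replicate subsamples per depth.

## Comparison statistics

Group contrasts from published summaries use t statistics reconstructed
from (mean, SEM, n): Welch's form by default — group sizes and variances
differ in the motivating contrasts — with Satterthwaite degrees of freedom
recovered via s_i² = n_i·SEM_i²; a pooled Student option is provided.
When both SEMs are zero the p-value degenerates to 1 (equal means) or 0.

The paired bootstrap resamples paired differences with replacement B times
(default 10,000) and reports p = (1 + #{resample mean ≤ 0})/(B + 1); the
add-one correction keeps p strictly positive. What is resampled (patients,
rarefactions, reads) is the caller's choice of input vector. PCA is
delegated to scikit-learn after column centering, with a fixed sign
convention (largest-magnitude loading positive) so decompositions are
reproducible; community profiles are Hellinger-transformed (square roots
of relative abundances) beforehand, giving unit-norm rows suitable for
Euclidean ordination.

The consensus-selection rule keeps a feature iff the two classifiers
(pluggable callables, by default tagged "svc" and "lr") both selected it
in at least `min_frac` (default 0.5, "at least half") of the rarefied data
sets; agreement in exactly half selects. The classifiers themselves are
external; only the agreement rule is implemented here.

## Synthetic data: what it emulates, and what it does not

The generator builds a toy HMM catalog (CAZy-style names; the default
class mix roughly follows the dbCAN catalog's balance of GH/GT/CBM/CE/PL/
AA plus a small "other" share; signature lengths uniform on 30–300 aa,
40–200 in the test fixtures so the coverage gate bites), plants
reverse-translated signatures (one fixed codon per residue) into genomes
separated by stop-rich spacers on random strands, and simulates
uniform-coverage, error-free reads. The scanner seeds exact 8-mers against
the signatures and extends each fragment/signature diagonal to its maximal
end-trimmed window with ≥ 90% identity and ≥ 10 aa, emitting hits with
monotone pseudo-statistics (i-Evalue 10^(−matched/2), bit score =
matched residues).

Passing tests therefore demonstrate the pipeline's accounting and
filtering logic — coverage fractions, normalization, depth invariance,
density recovery, read-length threshold behaviour — under clean
conditions. They do not demonstrate robustness to sequencing error,
probabilistic HMM scoring, indel-containing gene fragments, GC or
coverage bias, or paired-end merging artifacts: real data should go
through real upstream tools (PEAR, FragGeneScan, hmmsearch with the
database size set to the number of HMMs) and enter this package at the
domtblout stage.

## Problem sizes and numerical choices

The heavy properties run at desk scale, chosen to keep Monte-Carlo error
well inside the asserted bands: depth stability uses a 30-family registry
(two planted copies each, ~32 kb genome) at depths 10³/10⁴/10⁵ reads × 5
replicate seeds, asserting < 10% relative SD per depth and < 10% drift of
the mean across depths; density recovery compares equal-length genomes
(spacer lengths compensate planted-copy number) at densities 1:2:4 under
50× coverage, asserting ratios within 10%; read-length degradation trims
300-nt reads to 250/190/150/120 nt over 5 seeds and asserts monotone
decline. Score tables serialize floats with shortest-round-trip repr so
read∘write is exact; all stochastic steps take explicit integer seeds and
are bit-reproducible.

## Known limitations

- The scanner's end-trimmed identity windows can include a few
  chance-matching flanking residues, inflating coverage fractions by a
  couple of residues per hit; this cancels in the ratio properties and is
  irrelevant to real HMMER input.
- The density-recovery ratios run a few percent above nominal because
  spacer-derived junk residues dilute N_aa slightly differently across
  densities; the effect is well inside the 10% band.
- `trim_reads` assigns each read a deterministic total trim (its length
  minus the target), randomizing only the 5′/3′ split; read sets with
  heterogeneous lengths shorter than the target keep those reads intact
  and may land slightly under the target mean.
- Six-frame translation over-counts N_aa relative to single-strand gene
  callers (both strands contribute fragments); this is consistent between
  numerator and denominator and across samples scored the same way, but
  absolute scores are not comparable to pipelines using a different gene
  caller.
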