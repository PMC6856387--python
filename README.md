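# dfpmaa

Carbohydrate-active domain scoring for shotgun sequence data.

Gut microbiomes are metabolic organs, but taxonomic profiles alone say
little about what a community can metabolize. `dfpmaa` quantifies a
community's (or a single genome's) carbohydrate-processing potential
directly from shotgun reads by counting carbohydrate-active protein
domains — CAZyme families such as glycoside hydrolases (GH),
glycosyltransferases (GT), polysaccharide lyases (PL), carbohydrate
esterases (CE), carbohydrate-binding modules (CBM) and auxiliary
activities (AA) — found by scanning predicted protein fragments against a
collection of profile HMMs.

## The score

For an HMM *h* with accepted hits *i*, each hit contributes its **domain
fraction** — the share of the model's match states it covers,
(hmm_to − hmm_from + 1) / hmm_len — and the per-family score is

```
DFPMAA_250(h) = 10^6 · Σᵢ covᵢ(h) / N_aa
```

where `N_aa` is the total number of amino acids submitted to scanning
("domain fractions per million amino acids", calibrated at a 250-nt
reference read length). The sum over all families, **∑DFPMAA_250**, is the
sample-level readout of overall carbohydrate-processing capability, and
per-class aggregation profiles how it is distributed across GH/GT/PL/CE/
CBM/AA.

Hits are accepted under dbCAN-style rules: overlapping same-sequence hits
are resolved in favour of the lower independent E-value, alignments longer
than 80 aa need i-Evalue < 1e-5 (else < 1e-3), and a hit must cover at
least 30% of the HMM. The coverage rule makes the score sensitive to read
length below roughly 190 nt, so datasets with mean merged-read lengths
under 187.6 nt are flagged as not cross-comparable.

Around the score the package provides Hill-number diversity profiles
D_q = (Σ f^q)^(1/(1−q)) over OTUs or per-family scores, rarefaction by
hypergeometric subsampling, saturation curves, and the comparison
statistics used with such scores (t tests from summary statistics, Pearson
correlation, a seeded paired bootstrap, Hellinger transform + PCA, and a
two-model rarefaction-consensus feature-selection rule). A synthetic-data
module generates toy HMM catalogs, genomes with planted domain-coding
segments, simulated reads, and ground-truth hit tables in HMMER3
`--domtblout` format, so the entire pipeline can be exercised and tested
without any downloads.

## Worked example

Score a synthetic community end to end (simulate → six-frame translate →
scan → filter → score):

```python
from dfpmaa import make_registry, make_toy_genome, simulate_reads, hill_number
from dfpmaa.diversity import AbundanceVector
from dfpmaa.pipeline import score_reads

registry = make_registry(10, seed=4, length_range=(60, 150))
genome, annotation = make_toy_genome(registry, n_segments_per_hmm=2, seed=5)
reads = simulate_reads(genome, 5000, 250, seed=6)

table = score_reads(reads, registry)
print(f"sum DFPMAA_250     = {table.sum():.2f}")
print(f"domains detected   = {len(table.scores)} of {len(registry)} planted")
for cls, share in sorted(table.class_proportions().items(), key=lambda kv: kv[0].value):
    print(f"  {cls.value:<5} {100 * share:5.1f}%")
av = AbundanceVector.from_scores(table.scores)
print(f"Hill D0 = {hill_number(av, 0):.0f}, D1 = {hill_number(av, 1):.2f}")
```

prints

```
sum DFPMAA_250     = 1075.96
domains detected   = 10 of 10 planted
  CBM    10.0%
  CE     10.2%
  GH     60.5%
  GT     19.3%
Hill D0 = 10, D1 = 9.98
```

All 10 planted domain families are recovered (richness D0 = 10); the
near-equal D1 says their scores are close to evenly distributed, and the
class shares reflect the registry's composition. With real data you would
instead feed an existing `hmmsearch --domtblout` table and the scanned
protein FASTA to `dfpmaa.pipeline.score_domtblout` (or `dfpmaa score
--domtblout ... --proteins ...` on the command line).

The same functionality is exposed as a CLI — `dfpmaa score | sum | classes
| diversity | rarefy | trim | compare | select | simulate | selftest` —
where every run records its parameters and seed in a provenance JSON next
to its output. `dfpmaa selftest --seed 7` runs the synthetic end-to-end
pipeline and prints a pass/fail line per invariant.

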