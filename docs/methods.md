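# Methods

## Pooling model

The canonical design (`canonical384`) arrays 384 lines on four 96-well
plates and forms 12 pools of 96 lines in three dimensions: column
blocks {1–3}, {4–6}, {7–9}, {10–12} across all plates (pools 1–4), row
pairs {A,B}, {C,D}, {E,F}, {G,H} across all plates (pools 5–8), and
whole plates 1–4 (pools 9–12). Every line then belongs to exactly one
pool per dimension, each dimension partitions the population, and each
of the 4³ = 64 full triples intersects in exactly 2 rows × 3 columns on
one plate — six wells. `validate_design` checks all of these by brute
force enumeration.

Designs are data, not code: any layout can be registered from a JSON
file of explicit well lists (`register_scheme_from_config`). This
matters in practice because real screens sometimes rotate the
column/row colouring from plate to plate; one published validation-well
list in the packaged NGS-trial table (position 1477) follows such a
rotated layout while the other ten rows follow the canonical one, and
the package ships the canonical layout plus the config hook rather than
guessing the rotation.

`decode_pools` with fewer than three pools returns the (larger)
intersection instead of raising, so partial evidence — e.g. a
substitution significant in only two pools — can still be localised for
review. Two pools from the same dimension are rejected as an impossible
signature for a single carrier.

## Signal model and the caller

A diploid pool of s lines carries 2s alleles; a heterozygous carrier
contributes 1 allele (expected alt fraction 1/(2s), i.e. 1/192 ≈ 0.52%
at s = 96) and a homozygote 2 alleles (≈ 1.04%). Sequencing error adds
a floor of `error_rate`/3 per non-reference base. Homeologous
variation — fixed differences between the amplified locus and its
homeologous copy co-amplified at some level — appears at a similar
fraction (default 0.5) in **every** pool, which is what makes it
separable from single-line mutations.

### Background estimation

The error background is estimated separately per pool and per
substitution type (ref→alt pair): the frequencies of that substitution
at all other positions in the same pool carrying the same reference
base, excluding homeolog-flagged positions and the focal position
itself (leave-one-out, computed in closed form). Separating by
substitution type reflects the fact that miscall rates are
base-context dependent; pooling types would let a high-error context
mask a low-error one.

### The test

The focal frequency is compared with the background distribution by a
one-sided, prediction-interval-style Student t-test:

    t = (f − μ̂) / ( σ̂′ · √(1 + 1/n) ),   df = n − 1,
    σ̂′ = max(σ̂, 1/(2·depth))

The √(1+1/n) factor accounts for the focal observation being a new
draw from the background rather than its mean. The floor on σ̂′ is one
read of resolution at the position's filtered depth: with an all-zero
background the statistic would otherwise be infinite, and no frequency
estimate can be more precise than half a read pair. The upper-tail
p-value comes from the t distribution (`scipy.stats.t.sf`); tests
verify it against an independent incomplete-beta tail evaluation to
1e-10.

### Candidate rule

A substitution at a position becomes a candidate iff:

1. its p-value is ≤ α (default 0.05) in a set of pools containing a
   **full triple** (one pool per dimension);
2. each such pool's frequency lies in the expected single-carrier band:
   ≥ `min_candidate_freq` (default 0.002) and < `homeolog_min_freq`
   (default 0.2);
3. the position has filtered depth ≥ `min_depth` (default 100) in the
   tested pools;
4. the position is not homeolog-flagged (frequency ≥ 0.2 in ≥ 90% of
   pools with data).

The decoded line set attached to a candidate is the union of the
decodes of every triple contained in the significant pool set (six
wells when the set is exactly one triple); sets larger than one triple
are emitted with a `needs_review` flag rather than suppressed, since
two carriers of the same substitution produce exactly that pattern.
Candidates are annotated — not filtered — by the EMS signature
(G→A/C→T); `ems_only` enables filtering.

**Why the band has a lower edge.** With raw per-pool p ≤ 0.05 the
triple-coincidence rule alone leaves a per-substitution false-call
probability of about [1−(1−α)⁴]³ ≈ 0.6%: marginally elevated error
counts are "significant" in ~5% of pools by construction, and over
thousands of tested substitutions dozens of spurious triples would
survive. Real single-carrier signals cannot fall far below the 0.52%
heterozygote expectation, so requiring each positive pool's frequency
to exceed 0.002 (~40% of that expectation, >5 binomial standard
deviations below it at 5,000×) removes the noise triples without
costing sensitivity to one heterozygote per pool. No additional
multiple-testing correction is applied by default: the three-pool
coincidence plus the band is the error control, which matches how this
class of screen is operated.

### Numerical/degenerate-input choices

* Zero-depth positions are flagged `no_data` and never divided or
  tested. Positions below `min_depth` are excluded from significance.
* Background groups with fewer than 3 usable positions are not tested
  (p = NaN, never significant).
* Homeolog-flagged positions are excluded from background fits but
  still receive a (full-background) p-value for reporting.
* All randomness in the simulator flows from one integer seed;
  per-pool streams are derived as `default_rng([seed, 2, pool_id])`,
  so adding a pool does not perturb the others.

## The pileup reader

SAMtools mpileup text is consumed with the full base-column grammar:
`.`/`,` as reference (strand collapsed), `^X`/`$` read boundaries,
`+N…`/`-N…` indel insertions consumed without counting, `*`/`#`, `>`/`<`
and `N` consuming a quality character but excluded from both numerator
and filtered depth. Base qualities are Phred+33 by default
(configurable offset) and the filter is strictly "Phred > cutoff"
(default 20). Only base quality is filtered; mapping quality is assumed
handled upstream by the aligner. The simulator writes the same dialect,
and write→read round trips are byte-exact, which the tests use as the
reader's oracle.

## Effect annotation

Classification against an exon/CDS gene model in amplicon coordinates:
splice if within the first or last 2 intronic bases of a junction (the
canonical GT–AG dinucleotides; a deliberately narrow window — effect
predictors differ between 2 and ~10 bp here); otherwise nonsense /
missense / silent by translating the affected codon (standard nuclear
code, strand-aware for minus-strand CDS); noncoding for UTRs and intron
interiors. Start-codon changes are classified by their codon effect
(missense unless a stop arises). For summary reporting the five classes
collapse to three groups — {nonsense, splice}, {missense}, {silent,
noncoding} — with percentages to one decimal.

## Population statistics

* **Density.** Screened bp per amplicon = lines × (size − 200 bp): the
  ~100 bp nearest each primer cannot be scored, so they are excluded.
  Per-amplicon density is reported as "1/N kb" with N the
  nearest-integer kb; the aggregate divides total screened bp by total
  mutations. On the packaged 26-amplicon survey this yields 47,202,048
  bp, 432 mutations, 1/109 kb aggregate and ≈10,400 mutations per
  genome at 1,132 Mb (rounded to the nearest hundred). Note the
  packaged survey's printed density column itself mixes conventions:
  23 of 26 rows match nearest-integer rounding, while three (bn4
  112.62 → "112", bn19 143.52 → "143", bn21 150.68 → "150") were
  evidently truncated in print; no single rounding rule reproduces all
  26, and the package implements nearest-integer.
* **Spectrum.** Substitutions are strand-collapsed into six classes
  plus indels; the headline figure is percent G/C→A/T (integer-rounded),
  ≈99% for an EMS population.
* **Per-line distribution.** Histogram of mutations per line plus the
  count of lines with ≥1. When an independent unique-mutation total is
  supplied, any difference from the histogram's Σ k·n_k assignments is
  reported as a bookkeeping discrepancy rather than reconciled (the
  packaged survey shows 414 assignments vs 432 unique mutations; lines
  sharing a mutation and unscreened carriers are counted differently by
  the two tallies).

## Simulator scope

`synthdata` emulates exactly the structure the caller assumes: Poisson
planting per line (density per kb per line, default 1/109), an
EMS-dominated spectrum (`spectrum_fraction` 0.99 of planted changes are
G→A/C→T), heterozygous fraction 317/432 (the het:hom split observed in
a large screened population), per-pool multinomial counts at fixed
depth (default 5,000×), uniform error 5×10⁻⁴, and homeolog SNPs at 0.5
in all pools. It does **not** model read-level artefacts: insert-size
and read-length structure, position- or context-dependent quality
decay, PCR duplicates and jackpot amplification, alignment errors near
indels, or pool-to-pool depth imbalance (real screens ranged over an
order of magnitude in per-amplicon depth). Passing recovery tests
therefore demonstrate the statistical machinery under the stated noise
model, not robustness to those artefacts; the quality filter and
per-pool backgrounds are the hooks that absorb them on real data.

The standard recovery experiment used in the tests and the acceptance
script is one 1,600 bp amplicon across the canonical 384-line design —
12 pools × 1,600 positions at 5,000× (~96 M simulated bases), 10
planted mutations, 3 homeolog positions — which runs in roughly a
second and exercises ~4,700 tested substitutions against ~1,600-point
backgrounds.

## Known limitations

* Candidates resolve to six wells, not one; final resolution is by
  per-well Sanger sequencing, outside this package's scope.
* Indels are out of scope for the caller (the pileup reader consumes
  indel markup without counting it); the spectrum summary accepts
  indel records supplied from external validation.
* The homeolog rule assumes the homeologous copy is co-amplified at a
  roughly constant share across pools; a homeolog amplified in only a
  subset of pools would evade the ≥90%-of-pools criterion.
* With more than ~2 carriers of the same substitution the significant
  pool set decodes to a rapidly growing well union; such positions are
  flagged for review rather than resolved.
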