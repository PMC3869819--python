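# scampr

Detection of rare induced point mutations in a mutagenised plant
population by deep sequencing of pooled amplicons ("sequencing candidate
amplicons in multiple parallel reactions"), with the supporting
combinatorics and population statistics of a TILLING screen.

**Who it is for.** Reverse-genetics groups running EMS-mutagenised
populations (including allopolyploids such as *Brassica napus*) who
amplify a target gene from tri-dimensionally pooled DNA, sequence the
pools, and need to (i) find the handful of true single-line mutations
hidden at ~0.5% allele frequency, (ii) resolve each one to a small set
of candidate wells for Sanger validation, and (iii) report the
population's mutation density, spectrum and predicted allele effects.

## The method

A population of 384 M₂ lines arrayed on four 96-well plates is combined
into 12 pools of 96 lines along three dimensions — four column-block
pools, four row-pair pools, four plate pools — so every line lies in
exactly one pool per dimension. A mutation carried by a single line
surfaces in exactly one pool **triple**, whose intersection contains
six wells.

Per pool, reads are summarised as quality-filtered base counts (Phred
> 20) at each amplicon position, giving substitution frequencies
f = n_alt / depth. One heterozygote among 96 diploid lines contributes
1 of 192 alleles, an expected signal of 1/192 ≈ 0.5% — well above
sequencing noise (< 0.05%) at depth. For each pool and substitution
type, the sequencing-error background is estimated from all other
positions with the same reference base, and the focal frequency is
tested one-sided against it:

    t = (f − μ̂_bg) / ( max(σ̂_bg, 1/(2·depth)) · √(1 + 1/n) ),  df = n − 1

A substitution is called a candidate EMS mutation when a full pool
triple is significant at α = 0.05 and the per-pool frequency lies in
the expected single-carrier band. Fixed differences between homeologous
gene copies — which appear at high frequency in *every* pool — are
recognised by that pattern and excluded. Candidates are annotated for
the EMS signature (G→A / C→T on the reference strand) and decoded to
their six candidate wells.

Population statistics follow the field's conventions: mutation density
is kb of screened DNA per mutation with a 200 bp amplicon-edge
exclusion, extrapolated to mutations per genome; the substitution
spectrum is strand-collapsed; effects on the gene product are classed
nonsense / splice / missense / silent / noncoding from an exon–CDS gene
model and the standard genetic code.

A built-in simulator generates the whole data structure — planted
mutations with realistic zygosity and spectrum, homeologous SNPs,
multinomial sequencing noise, per-pool counts and mpileup text — so the
entire pipeline is testable without external sequencing data.

## Worked example

Simulate a 384-line screen over a 1,600 bp amplicon (12 pools at
5,000× with 5×10⁻⁴ error, 4 planted mutations, 2 homeolog positions),
then call candidates:

```
$ scampr simulate --length 1600 --n-mutations 4 --n-homeologs 2 \
      --depth 5000 --seed 11 --out demo
planted 4 mutations, 2 homeolog positions -> demo (27 files)

$ scampr call --design demo/design.json --counts 'demo/pool*.counts.tsv' \
      --reference demo/amplicons.fasta --out out
4 candidates -> out/candidates.tsv
```

`out/candidates.tsv` (abridged):

```
position  mutation  positive_pools  wells_to_validate                mean_positive_freq
334       G>A       2,6,10          plate 2 - C4 ... plate 2 - D6    0.012067
1508      C>T       2,8,9           plate 1 - G4 ... plate 1 - H6    0.005200
```

Position 334 is a homozygote (expected 2/192 ≈ 1.04%; observed 1.21%),
position 1508 a heterozygote (expected 1/192 ≈ 0.52%; observed 0.52%).
Each candidate's pool triple decodes to six wells — the carrier's well
plus its five pool-mates — which is the set one would Sanger-sequence
to pin down the line; the two homeolog positions (frequency ≈ 0.5 in
all 12 pools) are correctly excluded. The same calls are written as
VCF with POOLS/PVALS/LINESET/EMS INFO fields, and a frequency-profile
plot per substitution type.

Decoding on its own:

```
$ scampr design decode --pools 2,7,12
plate 4 - E4
...
plate 4 - F6
```

Population statistics from the packaged 26-amplicon survey:

```
$ scampr stats density
...
total mutations: 432
aggregate density: 1/109 kb
mutations per genome (~1132 Mb): 10400
```

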