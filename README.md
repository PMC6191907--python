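# rifdecay

Genome-wide mRNA half-life estimation from rifampicin-chase two-color
microarray experiments, plus coverage-based detection of rRNA
fragmentation regions — built for bacterial transcriptome studies in
which rRNA is too unstable to serve as a normalization anchor (the
motivating case is the acetic acid bacterium *Gluconobacter oxydans*,
whose 23S rRNA is naturally cleaved into fragments).

## The model

Rifampicin blocks transcription initiation, so after addition at t = 0
each transcript decays exponentially with half-life t½:

    N(t) = N(0) · 2^(−t/t½)

Two-color arrays compare RNA at t = 2, 5, 10, 15 min against the
pre-rifampicin reference. Per hybridization, spots are kept if
Flags ≥ 0 and signal/noise ≥ 3 in either channel; every ratio of
medians r is rescaled by f = 2^(−mean log₂ r) over the 1:1 spike-in
control spots (32 spots each for `(+)E1A_r60_1` and `(+)E1A_r60_a20`),
which centers the controls' mean log₂ ratio at 0. Averaged replicate
log₂ ratios y_t = log₂(N(t)/N(0)) are fitted by ordinary least squares;
a gene is accepted when R² > 0.7, first on all four time points, then —
because short-lived transcripts hit the detection floor before 15 min —
on t ∈ {2, 5, 10} alone. The half-life is t½ = −1/slope. Accepted
half-lives are averaged per operon, tested per functional category
(one-way ANOVA, post-hoc one-sample t-test against the global mean,
Bonferroni-corrected), and correlated with transcript abundance
(FPKM = count · 10⁹ / (length · library size)) and ORF length.

Separately, reads from ribosome-derived RNA are mapped to the rRNA gene
copies full length at ≥ 99% identity (brute-force naive mapper, seeded
random tie-breaking between identical copies); intervals whose per-base
coverage is below 5% of the locus-mean coverage are called as
fragmentation regions and compared across gene copies (matching within
2 nt).

Every input the pipeline consumes can be simulated with known ground
truth: spot tables with planted decay, dye swaps, bad spots and spike-in
controls; rRNA read sets with planted zero-coverage gaps; fragment count
tables.

## Worked example

```sh
rifdecay simulate-decay --n-genes 300 --seed 1 --out-dir sim
rifdecay normalize --samplesheet sim/samplesheet.tsv --out profiles.tsv
rifdecay halflife --profiles profiles.tsv --out half_lives.tsv --summary summary.json
```

prints

```
wrote 12 arrays to sim
300 gene profiles -> profiles.tsv; diagnostics -> profiles.diagnostics.tsv
299 of 300 genes passed the R² gate -> half_lives.tsv
mean 6.0 min, median 5.6 min -> summary.json
```

12 arrays are 4 time points × 3 replicates (replicate 2 dye-swapped).
With the default multiplicative noise (0.15 on the log₂ ratio), 299 of
300 genes pass the R² > 0.7 gate, and the recovered global mean and
median (6.0 / 5.6 min) sit close to the simulated truth (half-lives
log-normal with median 5.7 min). `half_lives.tsv` holds one row per
gene:

```
gene_id    slope      intercept  r_squared  n_points  half_life_min  status
GENE0001   -0.146939  -0.051544  0.962130   4         6.8            ok_4pt
```

The rRNA side, with two planted cleavage gaps:

```sh
rifdecay simulate-rrna --gap 1140:1159 --gap 1456:1465 --n-reads 2000 --seed 1 --out-dir rrna
rifdecay fragments --ref rrna/reference.fasta --reads rrna/reads.fastq --seed 1 --out-dir frag
```

calls regions at 1138–1164 and 1452–1474 — the planted gaps widened by
the coverage ramp where reads cannot span into a gap — plus short
sampling ramps at the locus ends.

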