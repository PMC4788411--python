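# plastidkit

Toolkit for adapting reporter genes to AT-rich chloroplast genomes and
quantifying their output.

Chloroplast genomes — the liverwort *Marchantia polymorpha* plastome is the
archetype — are strongly AT-rich, and genes written in GC-rich codon styles
(such as standard fluorescent-protein ORFs) express poorly from them.
`plastidkit` covers the full desk-side workflow around a codon-optimized
plastid reporter:

* **Codon-usage tables** from plastome GenBank records or FASTA CDS sets:
  per-triplet counts and synonym-relative frequencies
  `f(c) = n(c) / n(family)` under translation table 11.
* **Per-gene diagnostics** against a table: GC3 (fraction of codons with
  G/C third base), optimal codons (family maximum), rare codons
  (`f ≤ 0.10`, inclusive), the mean codon frequency difference
  (four selectable definitions), and synonymous-change accounting between
  two recodings (total and per 80-codon segment).
* **Codon optimization** toward a table (`max`, frequency-`match`, or
  `threshold` strategies), translation-preserving, with optional forbidden
  motifs.
* **Normalized chloroplast fluorescence**: mask plastids on the
  autofluorescence channel (rolling-ball background subtraction, automatic
  threshold, watershed), then ratio mean reporter intensity to mean
  autofluorescence per particle to cancel tissue depth; aggregate
  mean ± SD across thallus sections and fold change versus a reference.
* **In-gel densitometry**: OLS standard curve from serial dilutions,
  inversion of unknown band densities with propagated uncertainty, and
  conversion to ng protein per mg tissue fresh weight.
* **Seeded synthetic data** for every stage (CDS sets with controlled
  codon profiles and GC3, plastome-like GenBank records, two-channel
  plastid scenes with known per-particle ratios, gel dilution series),
  with ground truth returned alongside.

See `docs/methods.md` for the definitions, defaults and their rationale.

## Worked example

Build a usage table from a (here: simulated) plastome, score a GC-rich
gene against it, and recode the gene:

```bash
plastidkit simulate plastome -o plastome.gb --n-cds 94 --seed 11
plastidkit usage-table plastome.gb -o usage.tsv --report extraction.tsv
# -> extracted 94 CDS (2 rejected)        # the 2 are inverted-repeat duplicates

plastidkit simulate cds -o gene.fasta --n-cds 1 --mean-length 240 --gc3 0.96 --seed 3
plastidkit diagnose gene.fasta usage.tsv
```

```
gene          : syn_000
codons        : 214
GC3           : 98.13%
optimal       : 24 (11.21%)
rare          : 189 (88.32%)
mean codon frequency difference (position): 65.51%
```

The gene is badly adapted: 98 % of its third bases are G/C against a
plastome whose CDS sit near 12 %, and 88 % of its codons are rare in the
reference. Recode it and re-score:

```bash
plastidkit optimize gene.fasta usage.tsv -o gene_opt.fasta --strategy max
plastidkit diagnose gene_opt.fasta usage.tsv
plastidkit compare gene.fasta gene_opt.fasta
```

```
gene          : syn_000|max
codons        : 214
GC3           : 9.81%
optimal       : 214 (100.00%)
rare          : 0 (0.00%)
mean codon frequency difference (position): 26.88%

codons changed: 190 / 214
per 80-codon segment: [72, 70, 48]
```

190 of 214 codons changed, spread evenly across the gene; the recoded GC3
(9.8 %) now matches the reference. Note the `position` variant of the
frequency difference does not reach zero for a fully optimal gene (it
compares usage *distributions*); the `deficit` variant ranks adaptation
monotonically and does:

```bash
plastidkit diagnose gene.fasta     usage.tsv --variant deficit   # -> 60.59%
plastidkit diagnose gene_opt.fasta usage.tsv --variant deficit   # -> 0.00%
```

The first few rows of the table (`usage.tsv`) show the AT bias directly:

```
codon  amino_acid  count  freq_among_synonyms  is_optimal  is_rare
AAA    K           1130   0.9767               True        False
AAC    N           26     0.0211               False       True
AAG    K           27     0.0233               False       True
AAT    N           1207   0.9789               True        False
```

The same library surface is importable (`plastidkit.build_usage_table`,
`plastidkit.diagnose`, `plastidkit.optimize`,
`plastidkit.normalized_fluorescence`, `plastidkit.fit_standard_curve`, …),
and `plastidkit imquant` / `plastidkit gelquant` run the imaging and gel
pipelines from TIFF/CSV inputs.

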