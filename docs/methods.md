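# Methods

## Scope and model

`plastidkit` quantifies how well a coding sequence matches the codon usage
of an AT-rich chloroplast genome, recodes genes toward that usage, and
measures reporter output downstream of such a recoding by two independent
assays: ratiometric two-channel fluorescence microscopy of plastids, and
in-gel densitometry against a dilution standard curve. The motivating use
case is a cyan fluorescent reporter recoded for expression from a liverwort
plastome, but nothing in the package is specific to one gene or organism.

## Codon-usage statistics

A **codon usage table** holds, for each of the 64 triplets, its raw count
over a reference CDS set and its frequency *among synonyms*:
`f(c) = count(c) / count(family(c))` under a fixed genetic code
(NCBI translation table 11 by default; configurable everywhere). Families
with zero observations get `f = 0` for all members and are flagged rather
than silently dropped. Input sequences are upper-cased; any non-ACGT symbol
is a hard error, because every downstream statistic is count-exact and
silent N-skipping would shift the denominators.

Per-gene statistics include the stop codon when the sequence carries one,
so a 239-residue protein plus terminator is 240 codons; this keeps
whole-gene counts consistent with how recoded reporters are usually
described. Table construction exposes `include_stops` separately.

* **GC3** — fraction of codons whose third base is G or C. For an AT-rich
  plastome this is the single most informative adaptation proxy: almost all
  synonym families offer an A/T-ending alternative.
* **Optimal codon** — the most frequent triplet within its family in the
  reference set. Ties at the maximum are broken lexicographically and the
  family is flagged (`tied_families`), so classification is deterministic
  and auditable. Single-codon families (Met, Trp) are always optimal.
* **Rare codon** — reference frequency ≤ 0.10, boundary inclusive.
  Optimal takes precedence in the degenerate case where a family maximum
  lies at or below the threshold.
* **Synonymous change accounting** — positionwise codon differences between
  two sequences that must translate identically (a non-synonymous
  difference is an error carrying the offending positions). Differences are
  also binned into consecutive windows of 80 codons (1-based:
  codons 1–80, 81–160, …) to show how evenly a recoding is spread.

### Mean codon frequency difference

The aggregate distance between a gene's codon usage and the reference table
has no single canonical definition, so four are implemented and selectable;
all work on synonym-relative frequencies and are reported as percentages:

| variant | definition |
|---|---|
| `position` (default) | mean over codon positions of abs(f_gene(c) − f_ref(c)), equivalently the occurrence-weighted mean over triplets |
| `triplet_uniform` | unweighted mean of abs(f_gene − f_ref) over all 64 triplets |
| `gene_present` | unweighted mean over the distinct triplets the gene uses |
| `deficit` | mean over positions of f_ref(family optimum) − f_ref(c): the shortfall of each used codon relative to the preferred synonym |

`position` is the default because it is zero exactly when the gene's
synonymous usage matches the reference and it weights codons by how often
the gene actually uses them. Note an asymmetry worth knowing: a *fully
optimal* gene concentrates all its usage on one codon per family
(`f_gene = 1`), which under `position` can sit farther from a spread-out
reference than a mixed gene does — so optimal recoding does not always
decrease `position`. It always decreases (to exactly zero) under
`deficit`, which is the variant to use when ranking genes by adaptation;
the package's optimizer monotonicity guarantee is stated for `deficit`.

## Codon optimization

Recoding preserves the translation exactly and never touches single-codon
families. Strategies:

* `max` — every codon becomes its family optimum (lexicographic tie-break);
  output is 100 % optimal and idempotent under re-optimization. The stop is
  recoded to the optimal stop.
* `match` — codons are drawn per family proportional to the reference
  frequencies. Reproducible across platforms: NumPy `default_rng` (PCG64)
  with a required caller-supplied seed.
* `threshold` — codons at or below `rare_ceiling` (default 0.10) are
  promoted to the family optimum; everything else is kept.

Optional forbidden motifs (e.g. a restriction site used for vector
linearization) are removed by a greedy synonymous re-choice pass over the
codons overlapping each occurrence, preferring the most frequent
alternative synonym; occurrences that no synonymous change can remove
(e.g. motifs spanning Met/Trp codons) are reported, never silently kept.
No attempt is made to reproduce any particular synthesized gene
base-for-base: deposited commercial designs are typically only ~70 %
optimal and their objective functions are unpublished, so the deposited
sequence is a diagnostics input, not a target.

## CDS extraction

GenBank CDS features are extracted with Biopython's location machinery, so
`join(...)` splicing and `complement(...)` strand resolution follow the
flat-file conventions exactly (1-based inclusive printed coordinates,
0-based half-open internally). The acceptance policy drops, with a logged
reason rather than an exception: `/pseudo` features, frame violations,
non-ACGT sequences, internal stops, and sub-minimum lengths. Genes
annotated twice in the plastome's inverted repeat (same gene name,
identical sequence) are counted once by default so they do not
double-weight the usage table; the toggle is exposed because conventions
differ between published tables.

## Fluorescence quantification

Per thallus section, given a reporter channel (CFP, emission 465–495 nm
role) and a chlorophyll autofluorescence channel (610–700 nm role):

1. **Background subtraction** on the autofluorescence channel for mask
   construction: rolling-ball, radius 5 px default. Background is defined
   as the grayscale *opening* of the intensity surface by a ball — the
   upper envelope of every position of the ball rolled under the surface
   (erosion then dilation with the non-flat ball-cap structuring element,
   computed by `scipy.ndimage.grey_opening`). This is the mathematically
   crisp definition; historical sliding-paraboloid implementations differ
   by small amounts. The channel is first smoothed with a 1 px Gaussian
   (exposed as `smooth_sigma`): morphological background estimation rides
   on noise minima, and without smoothing the positive noise residue
   destroys the threshold's bimodality at realistic noise levels.
2. **Binary transformation**: automatic global threshold, IsoData
   iterative intermeans by default, Otsu between-class-variance as the
   alternative. A constant image yields an empty mask with a warning.
3. **Watershed**: touching particles are split along ridges of the
   Euclidean distance transform, seeds from its local maxima at ≥ 2 px
   separation, 8-connected flooding, labels consecutive from 1.
4. **Per-particle ratio**: mean reporter intensity over the particle's
   pixels divided by mean autofluorescence intensity, which normalizes out
   tissue depth (both channels attenuate together). Intensities are
   measured on the *raw* channels minus a flat per-channel background
   offset (median intensity outside the mask). The rolling-ball output is
   deliberately not used for measurement: a 5 px ball is narrower than a
   typical plastid, so the opening tracks and flattens particle plateaus —
   harmless for masking, fatal for intensities. Particles with zero mean
   autofluorescence are excluded and reported; fragments below 4 px are
   dropped as segmentation shards.
5. **Aggregation**: mean of per-particle ratios within a section, then
   mean ± SD *across sections* (error bars describe biological variation
   between tissue sections, not pixel statistics; SD is NaN for a single
   section). Fold change is the ratio of section-level means between a
   sample and a reference (e.g. wild type), in which residual
   segmentation biases largely cancel.

Pixel intensities are treated as linear; no gamma correction.

## Gel densitometry

Replicate band densities (mean gray value over a fixed ROI) of a serial
dilution are averaged per point and fitted by ordinary least squares,
`density = slope · ng + intercept` (unweighted by default; inverse-variance
weighting and a through-origin mode are exposed — the free intercept is the
default because forcing the origin is an assumption the data should earn).
Unknowns are inverted through the line; the reported SD propagates the
slope/intercept covariance and the measurement SD by the delta method, and
negative estimates are flagged below-detection with the raw value
retained. The tissue-level result is
`ng/mg = amount · (buffer volume / loaded volume) · dilution / fresh weight`,
with every factor explicit in an `ExtractionContext` rather than hard-coded.

## Synthetic data and what it does (not) show

All generators use NumPy `default_rng` (PCG64) and are bit-reproducible for
a fixed seed.

* **CDS sets** — codons drawn per family from a stated frequency profile;
  ATG start, exactly one terminal stop, Poisson lengths. The
  GC3-targeted profile splits each family's mass between G/C-ending and
  A/T-ending codons, compensating for the forced G-ending Met/Trp codons
  so the expected CDS-wide GC3 hits the target (realized GC3 is within
  ~0.02 at plastome scale). Default study condition: 94 CDS of mean length
  250 codons at target GC3 0.121, the scale of a liverwort plastome coding
  complement.
* **Plastome-like GenBank records** — generated CDS placed in AT-rich
  spacers, ~40 % on the minus strand, ~10 % split in two exons, plus two
  verbatim duplicate genes emulating the inverted repeat.
* **Synonymous pairs / composition fixtures** — a gene and a recoding with
  an exactly known number and placement of synonymous changes; genes with
  exactly known third-base or optimal/rare/intermediate composition
  against a given table. These make whole-gene accounting testable to the
  integer.
* **Two-channel scenes** — disc particles (radius 3–4.5 px default, kept
  below the 5 px ball radius so the masking step preserves them) with
  Gaussian edge falloff (σ = 1 px); the reporter channel is an exact
  per-particle multiple of the autofluorescence foreground before
  backgrounds (5/10 counts) and i.i.d. Gaussian noise are added; truth
  labels extend to the half-maximum contour. Default contrast condition:
  ratio 4.0 over a ratio-1.0 background line, amplitude 200, noise SD 20
  (SNR 10), 8 particles per 160×160 section, a quarter of them in touching
  pairs, three sections per line. Under these conditions the pipeline
  recovers the configured fold change within ~1 % (worst case over 20
  seeds ≤ 5 %). The scenes deliberately omit PSF blur, depth attenuation,
  spectral bleed-through and structured background — passing tests show
  the measurement chain is correct on known ground truth, not that it is
  robust to every artifact of real confocal data.
* **Gel series** — densities on a known line with additive Gaussian noise;
  the default design is a ten-point two-fold dilution from 1000 ng with
  three replicates. At 2 % noise (relative to the top density) the slope
  is recovered within 5 % on every one of 100 seeds.

## Problem sizes and numerical choices

The test suite and the acceptance script run everything at the sizes above
(94×250-codon plastomes, 240-codon reporters, 160×160 px scenes ×3
sections ×20 seeds, 10-point gel series ×100 seeds); the whole suite
completes in well under a minute on one core. Tolerances: family
frequencies sum to 1 within 1e-12; GC3 oracle agreement to 1e-15;
watershed uses 8-connectivity throughout; the rare threshold is inclusive;
optimal-codon ties are lexicographic and flagged.

## Known limitations

* The mean-codon-frequency-difference default is a declared convention
  among several defensible ones; compare variants before quoting absolute
  values across publications.
* The image pipeline is 2-D; z-stacks must be projected or sliced first.
* Thresholding is a global method per section; strongly uneven
  illumination beyond what the rolling ball removes will bias masks.
* Gel quantification takes band densities as input; band detection on gel
  images is out of scope.
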