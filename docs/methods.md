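# Methods

## Coordinate frame and conventions

All coordinates are 0-based, half-open `[start, end)`. A TA site is
identified by the forward-strand position of its T; TA is its own reverse
complement, so one index serves both strands (site *p* maps to *L* − 2 − *p*
under reflection). Genes plus constructed intergenic regions tile the
genome exactly, and an insertion belongs to the feature containing the T of
its TA site — a single-base rule that prevents double assignment at feature
boundaries. Annotated genes that overlap are made disjoint by truncating
the later-starting gene to begin at the earlier gene's end; genes fully
contained in another are dropped with a warning. This policy is a design
choice: the tiling invariant is what makes the Dval normalisation exact
(see below), and it has to be restored somehow when annotations overlap.
Only `type=gene` GFF3 records are used; multi-chromosome genomes are out of
scope.

## Generative model of the screen

The simulator is a standard hierarchical counting chain with one noise
process per wet-lab stage:

1. **Library.** Each TA site independently carries an insertion clone with
   probability `saturation` (default 0.63, the saturation of a deeply
   constructed mariner library). Orientation is uniform. Initial clone
   abundances are log-normal with σ = 0.5 on the natural log around a
   common mean of 100 cells per clone — enough that selection and the
   colony bottleneck, not initial cell counts, dominate the noise, while
   still giving realistic several-fold abundance spread between clones.
2. **Selection (3-h treatment).** Expected post-treatment abundance is
   `abundance × 20` for the control arm (net growth) and
   `abundance × survival × multiplier(feature)` for treated arms
   (survival 0.17 sub-bactericidal, 0.005 bactericidal). Realised
   abundances are Poisson about the expectation, independently per
   replicate. `survival × multiplier` is clipped at 1 — a clone cannot
   out-survive certainty — which caps the effective enrichment of strong
   resistance determinants under milder doses.
3. **Colony bottleneck.** Survivors are plated and a fixed number of
   colonies pooled: a multinomial draw of 100,000 / 8,000 / 230 colonies
   (control / sub / bactericidal) with probabilities proportional to
   post-selection abundance. This is the dominant noise source in the
   bactericidal arm: with 230 colonies, even a strongly resistant clone
   class can miss the pool in one replicate.
4. **Sequencing.** Reads are drawn multinomially over clones proportional
   to abundance (default 200,000 per sample at desk scale; real depth is
   not published for this design, so it is configurable). Each read is
   `barcode ++ tag`: one 6-bp barcode per experimental group with pairwise
   Hamming distance ≥ 3, replicates as separate files. The genomic tag of
   a (+) clone at TA position *p* is `genome[p : p+16]`; for a (−) clone,
   the reverse complement of `genome[p+2−16 : p+2]` — either way the
   sequenced tag begins with the TA of its site. The 16-bp default
   reflects the short genomic fragments that restriction-based junction
   protocols (MmeI-class) capture; the chemistry itself (digestion,
   adaptor ligation, size selection) is deliberately not modelled, because
   the tag carries exactly the information those steps exist to produce:
   site and orientation. Substitution errors at a configurable per-base
   rate (default 0); no indels, PCR duplicates or circular-genome
   wraparound.

Everything is deterministic given the seed, to the byte, including FASTQ
output.

### What the simulator does not emulate

Real libraries have insertion-site bias beyond the TA requirement, hot and
cold spots, PCR jackpots, batch effects between replicates, and reads whose
quality degrades along the cycle. Passing tests on this generator therefore
demonstrates that the pipeline's bookkeeping and statistics are correct
under the stated stochastic model — not that the statistics are robust to
artefacts the model excludes.

## Read processing

Demultiplexing assigns a read to the unique barcode within
`max_mismatches` (default 1; barcodes must be separated by more than twice
that distance). Tags are then mapped by **exact** lookup against a
two-strand index of every TA-anchored tag in the genome — a desk-scale
replacement for seed-and-extend alignment. Error tolerance comes from
discarding, not mismatch search: reads whose tag matches nowhere are
dropped as unmapped, and tags matching more than one (site, orientation)
pair are dropped as ambiguous; both are always counted in the mapping
summary, never silently. The one intrinsic ambiguity worth naming: a
reverse-complement-palindromic window makes the (+) tag of one TA site
identical to the (−) tag of a nearby site (probability ≈ 4⁻⁸ per random
16-mer window), and no aligner can resolve it either. Counts are raw reads
per (site, orientation), collapsed onto the position for the statistics;
no duplicate collapsing, since the ratio statistic uses read numbers
directly.

## Statistics

`predicted = T·len/L` makes Σ predicted = Σ actual over a tiling catalog,
which forces the length-weighted mean raw Dval to be exactly 1 in every
sample and makes raw Dval (and hence SI) invariant to sequencing depth.
Choices made where the design was genuinely open:

* **Per-replicate SI, geometric mean.** SI is computed within each
  replicate and combined as exp(mean(ln SI)), consistent with testing on
  the log scale. (Pooling reads across replicates before one SI is the
  other defensible reading; the per-replicate route is the one that
  supports a replicate-level significance test.)
* **Significance.** A two-tailed one-sample *t*-test of ln SI against 0,
  the paired-test equivalent on log Dvals. SI is a ratio, so the log
  transform symmetrises it. Zero-variance cases are flagged: p = 1 when
  the mean is also 0, p reported as 0 (below machine resolution) and
  annotated otherwise. Two finite replicates are the minimum.
* **Pseudocount 0.5** added to both actual and predicted reads when
  forming the Dvals used for SI and testing. Without it, any feature with
  zero treated reads — common after 99.5% kill plus a 230-colony
  bottleneck — would have SI undefined or 0 exactly. For a well-covered
  feature (predicted reads in the hundreds) the perturbation is < 1%.
  Raw pseudocount-0 Dvals are reported in the same table.
* **≥ 3 insertion sites** (inclusive) across the union of all compared
  samples, the closest observable proxy for "the library contains ≥ 3
  independent mutants of this feature". Features below the threshold are
  reported but not tested.
* **No multiple-testing correction** in the headline hit call (raw
  P ≤ 0.05, matching the screen's original decision rule); BH q-values
  are computed over the tested set and reported alongside.
* **Hit ranking** by geometric-mean SI, descending for resistant hits.

## Validation experiments and problem sizes

The screen-level test suite (`tests/test_acceptance.py`, driven by
`tnscreen.experiments`) runs at sizes chosen to keep the full suite in the
minutes range while leaving each check statistically meaningful:

* Neutral-SI identity: algebraic, any size.
* Saturation recovery: 100-kb genome (~6,250 TA sites), 200,000 error-free
  reads through the full FASTQ pipeline; accepted within the exact
  binomial 99% interval around 0.63.
* Dval centering to 1e-9 and round-trip count exactness (10 seeds, 30-kb
  genomes): exact checks of the bookkeeping.
* Null calibration: 500 all-neutral screens on a 40-kb / 60-gene
  reference, sub-bactericidal arm (17% survival, 8,000-colony bottleneck)
  so per-feature counts stay in the regime where the log-ratio *t*
  approximation holds; empirical type-I rate required in [0.03, 0.07].
  Under the bactericidal arm's 230-colony bottleneck the treated counts
  are too discrete for a 3-replicate *t*-test to be exactly calibrated —
  that regime is exercised by the recovery test instead.
* Planted recovery: 50 screens, each a fresh ~200-kb / 300-gene reference
  (~26 clones per gene at 63% saturation — the density of a saturated
  mariner library), 5 genes planted at multiplier 30, bactericidal
  conditions; all 5 must reach the resistant list at P ≤ 0.05 with mean
  SI > 5 in ≥ 95% of screens. The occasional failure mode is real: a
  low-abundance resistant gene can draw zero of the 230 colonies in one
  replicate, which wrecks that replicate's ln SI.
* Closed-form SI expectation: for a rare resistant class at frequency *f*
  with multiplier *m*, E[SI] ≈ m / (1 + f(m−1)) (= 29.15 at f = 0.001,
  m = 30); checked by 10,000-draw Monte Carlo within 3 SE.

## Known limitations

Single chromosome only; exact tag matching tolerates no sequencing error
inside the tag (each 1%-per-base error removes ~15% of 16-bp tags from the
mapped pool — unbiased loss under the error model, but loss); the
significance test assumes approximate normality of ln SI across three
replicates, which degrades for features whose treated counts are nearly
all zero; and the simulator's neutrality of intergenic insertions (default
multiplier 1) is an assumption, not a finding.
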