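# Methods

## The detection problem

Cell-free DNA in plasma is overwhelmingly wild-type; in localized breast
cancer the tumor-derived fraction routinely sits below 0.1% VAF. At such
fractions the raw sequencing error rate (~10⁻³ per base) produces more
spurious mutant reads than real ones, so detection hinges on two
orthogonal devices: (i) molecular consensus over UMI families, which
removes errors introduced during amplification and sequencing, and
(ii) statistical comparison against a pool of control plasmas sequenced
identically, which absorbs the residual, position-specific error floor.
This package implements both, plus the bookkeeping that turns per-variant
detections into cohort-level diagnostics.

## Molecular consensus

Reads are grouped by **exact** UMI string identity plus fragment
coordinates and strand orientation. Identity matching (rather than
edit-distance clustering) is deliberate: the library chemistry uses fully
degenerate barcodes, so two UMIs one mismatch apart are far more likely to
be two molecules than one molecule with a sequencing error in the barcode;
the fragment coordinates in the key resolve the residual collisions.

Consensus is per position: among member bases with quality ≥ 30, the
winning base must hold a strict majority of the qualifying votes; ties or
positions with no qualifying vote become N. The consensus quality is the
qualifying agreeing quality mass minus the disagreeing mass, floored at 2
and capped at 60 — a deliberately simple score standing in for a full
error-model calibration; positions whose consensus quality falls below the
threshold are masked to N. N bases never enter pileups. Mate overlaps are
clipped so that each original fragment contributes at most once per
reference position (the overlap is kept on the mate with the higher mean
quality; ties go to read 1).

Family-size minima are mode-specific and intentional: the tumor arm keeps
only consensus molecules built from ≥3 reads (a somatic reference set
should not rest on singletons), while the plasma arm keeps singletons
(min 1) because at 0.03% VAF every molecule is evidence and the
downstream duplex and statistical filters carry the specificity burden.

Reads are modeled as gapless, reference-positioned base vectors; CIGAR
interpretation is the SAM reader's job. Indel and splice alleles are not
modeled inside reads: they enter as pre-called single-token alleles ("*")
keyed to the variant's leftmost position, which the simulator can spike
and the pileup counts like any other allele. This mirrors the practical
reality that automated callers struggle with low-VAF indels, which is
precisely what the rescue path exists for.

## Candidate calling and coverage QC

The built-in caller is a frequency caller: one candidate per site and
non-reference allele with at least `min_alt_fragments` supporting
consensus fragments, emitted in deterministic (chrom, pos, alt) order.
It deliberately does no local assembly or realignment — the pipeline's
discriminating power lives in the filters, and externally produced VCFs
can be substituted for the built-in caller at the same interface.

A region fails coverage QC when strictly more than 10% of its bases sit
below 100× consensus depth ("exactly 10% low" passes); median coverage is
computed over panel bases only.

## The two detection modes

**Tumor-informed.** Tumor candidates pass iff VAF > 0.05 (fresh-frozen)
or > 0.2 (FFPE — fixation artifacts inflate low-VAF calls) *and* the
variant is in COSMIC or TCGA (either set). Thresholds are strict
inequalities, mirroring how they are stated. The paired plasma is then
interrogated for exactly this reference set. The caller path requires ≥2
supporting fragments at ≥2 distinct start coordinates (the built-in
frequency caller is far more permissive than a production somatic caller,
so the coordinate rule is applied on this path too rather than trusting
a bare single-fragment call). Variants the caller path misses go to the
rescue test.

**Rescue.** At each caller-missed site the mutant/wild-type consensus
counts are tallied in the patient plasma and in every control plasma; a
one-sided Fisher exact test compares the patient's 2×2 table against the
pooled control counts. One-sidedness is a design choice the source
material leaves open: the alternative of interest is *excess* mutant
allele in the case, and the one-sided test is uniformly more powerful for
it while remaining conservative under the null; the two-sided variant is
available by configuration. The default pool is healthy donors only —
pooling mutation-negative patients is supported as a sensitivity analysis
but adds noise, since patient cfDNA can carry trace true signal. A rescue
additionally requires ≥2 mutant fragments at ≥2 distinct genomic start
coordinates ("duplex configuration"): PCR copies of one errored molecule
share a start coordinate, so this rule is a cheap, powerful guard against
clustered artifacts. α is fixed at 0.05. No multiplicity correction gates
the decision — matching the analysed workflow — but a Benjamini–Hochberg
column is attached as supplementary output.

**Tumor-naive.** No VAF floor at all. A plasma variant counts as
tumor-shed iff it is exonic, present in both COSMIC and TCGA-BC, and
duplex-supported. Two written statements of the database rule conflict
(one adds the TCGA all-cancers set); the two-database version is the
default and `require_tcga_all=True` restores the stricter reading. The
exonic criterion is read as exonic-or-splice, because the published call
set itself contains splice-site variants. Controls run through the
identical code path.

## Cohort statistics

Confidence intervals for sensitivity, specificity and PPV are exact
Clopper–Pearson (beta-quantile) intervals — the choice is verified against
the printed interval for 19/22 controls, which matches this method to four
decimals. Zero-denominator metrics are reported as undefined rather than
crashing.

The cohort's raw positive count (25/74 samples) and the operative
confusion table behind the printed metrics (TP = 23) differ by two; the
package computes and reports both rather than hiding the discrepancy:
`positivity_table` returns raw counts, and `diagnostic_metrics` accepts
whatever confusion table the analyst designates as operative.

Association screens select their test explicitly: categorical×categorical
pairs use the Fisher exact test when any expected cell is ≤ 5 and the
chi-square test otherwise (the boundary is inclusive so that borderline
tables get the exact test); continuous×categorical pairs use the Wilcoxon
rank-sum test. Constant columns are skipped with a reason. Significance is
judged at p < 0.05 unadjusted, with a BH column as supplementary output.

## The synthetic-data generator

The generator emulates the study conditions, not generic sequencing:

| parameter | default | rationale |
|---|---|---|
| consensus depth | 2,500 fragments/site | published post-UMI plasma median (~2,525×; tumor ~1,698×) |
| family size | 1 + Poisson(λ=6) | reproduces the ~15,000–17,700× raw → ~1,700–2,500× consensus collapse (ratio ≈7) |
| pre-consensus error | 10⁻³/base | typical raw short-read substitution rate |
| UMI length | 10 nt | degenerate-barcode regime; collisions resolved by fragment coordinates |
| tumor spike VAF | U(0.03, 0.8) | span of the published tumor VAFs |
| plasma spike VAF | log-U(10⁻⁴, 5×10⁻²) | span of the published plasma detections |
| read length | 25 bp/site window | sites are simulated as independent windows; consensus, pileup and testing are position-local, so a short window exercises the full path at a fraction of the cost |

Errors are injected per read copy, *after* family replication, so
consensus genuinely suppresses them; a "polymerase" mode injects errors
before replication (shared by the whole family, consensus-proof) to
stress-test the Fisher screen. All randomness flows through one seeded
generator per call; the same seed reproduces byte-identical reads. Each
patient in a simulated cohort derives its seeds from the master seed via
`SeedSequence`, so cohorts are reproducible sample-by-sample and samples
can be regenerated lazily.

What the generator does **not** emulate: cfDNA fragment-length
distributions, GC and mappability bias, strand-specific damage, CHIP
mutations, and germline contamination. Passing tests therefore demonstrate
the correctness and calibration of the *pipeline machinery* under the
stated noise model, not performance on real plasma libraries.

## Validation choices and problem sizes

- The detection-limit study runs 200 seeded replicates at consensus depth
  10,000 with one variant spiked at VAF 3×10⁻⁴, against a fixed pool of
  22 mutation-free control plasmas at depth 2,500 (simulated once — the
  same donors back every patient). A replicate counts as duplex-eligible
  when ≥2 mutant fragments at ≥2 distinct coordinates were realized
  (≈80% of replicates at mean 3 mutant molecules); detection is assessed
  end-to-end (grouping → consensus → pileup → caller/rescue) over eligible
  replicates. With a 22×2,500 pool, a 2-fragment signal at depth 10,000
  reaches p ≈ 0.024 — the pool size is what makes the claimed limit
  attainable.
- Type-I control of the rescue screen is simulated at the allele-count
  level (2,000 sites, case and controls at the same post-consensus error
  rate 3×10⁻⁴): the screen itself is the unit under test there, and the
  one-sided exact test plus the coordinate rule keep the empirical
  rejection rate at or below the nominal 5%.
- Consensus error suppression is measured on 10⁵ single-base families per
  family size k ∈ {1,3,5,7} at an exaggerated per-read error of 5%
  (at 10⁻³ the k ≥ 5 rates are indistinguishable from zero at any feasible
  Monte-Carlo size); an N consensus counts as an error.
- Unit-level simulations (VAF recovery, binomial consistency) use reduced
  depths (100–500) and 200–500 replicates — enough for 3-standard-error
  assertions while keeping the default test run fast.

## Numerical and degenerate-input conventions

- VAF at zero depth is undefined (`None`), never silently 0/0.
- An all-zero Fisher table has p = 1 and never passes.
- Consensus ties break to N, never to an arbitrary base.
- Pileups exclude N bases from both numerator and denominator.
- BED is 0-based half-open externally and internally; VCF positions are
  emitted 1-based; fixture percent columns convert to fractions on load.
- Table fixtures are validated at load (61 rows/40 samples and
  16 rows/14 samples); corruption fails fast.

## Known limitations

- The read model is substitution-only; real indel support depends on an
  external caller or the simulator's allele tokens.
- The built-in frequency caller is not a substitute for a somatic caller
  with realignment and error models; it exists so the filters and tests
  can be exercised hermetically, and external VCFs slot in at the same
  interface.
- Duplex configuration is operationalized as distinct fragment start
  coordinates, the weaker of the two published readings; true
  strand-paired duplex consensus is out of scope (an optional stricter
  mode additionally requires both strand orientations).
- The cohort fixture reconstructs per-sample covariates from published
  marginal counts only; joint covariate structure in it is synthetic, so
  association screens on it are exercises of machinery, not of biology.
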