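# Methods

This note records the models, parameter choices and numerical
conventions behind `nrykit`, and what the simulation-based tests do and
do not demonstrate about real data.

## Coordinates and formats

BED intervals are 0-based half-open; SNP catalogue positions are
1-based. The single conversion point is `TargetRegions.contains`: a SNP
at 1-based p lies in (start, end) iff start ≤ p−1 < end. The reference
coordinate space is fixed (hs37d5 chrY); no liftover is attempted.
Pileup base columns are strand-folded (upper/lower case merged) because
haplogroup-SNP catalogues are strandless; deamination orientation is
recovered from the allele pair itself (C→T or G→A), not from strand.
Pileups are stored column-wise (`PileupTable`: positions, an n×4 count
matrix, and a CSR layout of read-end offsets) so whole-chromosome
operations stay vectorised; per-site `SitePileup` views are
materialised on demand through the mapping interface.

## Probe-window geometry

A SNP-panel probe set effectively recovers flanking sequence around
each targeted variant. `expand_windows(snps, window_bp)` gives each SNP
at p the inclusive range [p − w/2, p + w/2] — w+1 positions before
merging — with w configurable and defaulting to 120 bp, a reasonable
average ancient-DNA read length. The inclusive reading (121 positions
at the default) was chosen over the half-open alternative; the
parameter absorbs the ambiguity and window 0 degenerates to the SNP
positions alone.

## Enrichment statistics

Sites/SNPs covered are normalised per five million mapped endogenous
reads before any cross-library comparison, and libraries with shotgun
endogenous DNA ≤ 0.1% are excluded from empirical comparisons. The
fold-increase location test is a one-sample t-test on log fold
increases against zero (log scale makes folds symmetric under the
null); the endogenous-DNA association is a Pearson product-moment
correlation with a rank-based alternative available. Degenerate inputs
(identical folds, zero-variance responses) are handled explicitly:
identical unit folds give p = 1, identical non-unit folds give p = 0
rather than an undefined t statistic.

## Haplogroup calling

For each covered catalogue SNP the caller records derived, ancestral
and other read counts and the signed difference (derived − ancestral).
**Positive difference = evidence for the derived allele**; per-clade
support is the summed difference over that clade's SNPs, and the call
is the deepest node reachable from the root along branches whose
aggregate support ≥ `min_support` (default 1 read). Ties between
equally deep paths break on cumulative support, then label order.
Clades whose SNPs mix positive and negative differences are reported
as conflicts — a transitional form or an artefact worth review — but
do not block the call, mirroring a manual-review workflow. Two report
files are written: positive-difference SNPs only (the readable
root-to-terminal path) and all covered SNPs (for checking basal
branches and spotting conflicts); the first is always a subset of the
second, and both carry the raw counts so either sign convention is
recoverable. Damage triage (`flag_damage_suspects`) lists calls with a
deamination-mimicking allele pair, fewer derived reads than a floor,
and a derived read close to a read terminus.

## Contamination screen

Heterozygosity is the fraction of covered sites (depth ≥ `min_depth`,
default 1 — every covered site is assessed) with ≥ 2 distinct bases;
the default pass threshold is 0.1%. The literal one-read criterion is
the default; an optional stricter mode requires ≥ 2 reads of the minor
base to damp single-read damage. Note that mixture alone between two
human Y lineages produces modest heterozygosity (2·μ·T of discordant
sites — about 0.03% for a 200 ky split at 50/50 mixing); observed
values of ~1% in real contaminated libraries additionally reflect
error and damage, which the screen does not need to model to be
useful as a monotone indicator.

## Consensus and alignment

Consensus calls require depth ≥ 2 and minor-allele fraction strictly
below 10% (a 9:1 site is masked; ties are masked). The minor-fraction
comparison is done on integer counts (minor ≥ 0.1·depth masks) to
avoid float rounding at the 9:1 boundary. The alignment keeps
segregating sites (≥ 2 distinct called bases) covered in ≥ 2 samples
and samples covering ≥ `min_seg_sites` (default 1100) segregating
sites; the two filters interact, so they are iterated to a fixed
point, and the segregating-site count is taken after the ≥ 2-sample
site filter. Maximum-likelihood tree search, substitution-model
selection and bootstrapping are delegated to external phylogenetics
software via the exported FASTA (+ sidecar table mapping columns to
chromosome positions); the built-in neighbour-joining tree on pairwise
mismatch proportions is a deterministic internal sanity check only.

## Diagnostic SNPs

The four rules (no ancestral ingroup sample; > 1 ingroup sample
covered; no derived outgroup sample; > 1 outgroup sample covered) are
evaluated on a 3-state matrix polarised against the reference; "more
than one" means ≥ 2. Novel C→T / G→A sites are excluded as probable
damage unless previously catalogued (matching on position + allele
pair; polarity flips relative to the catalogue are annotated, never
silently corrected). Because rule 1 forbids ancestral ingroup
observations, "x/N derived" reports imply the other N−x samples are
missing, and the missingness report includes the ancestral count so
this is checkable. Summary tables report raw counts; percentages are
left to the reader to recompute.

## TMRCA estimation

Two haploid lineages split T years ago accumulate differences
independently, so E[d] = 2·μ·n·T over n jointly called sites and
TMRCA = c · d/(2n) with all rate assumptions absorbed into the
calibration constant c (years per unit relative divergence). c is
fitted so the mean calibrated TMRCA over outgroup anchor pairs equals
the anchor split time exactly; the default anchor is 161,300 years
(haplogroup A0 against all else; ~163 ky also circulates for this
split, so the value is a parameter, not a constant). CIs transform the
exact (Garwood) Poisson interval on d through the same linear map, so
pairs with fewer overlapping sites naturally get wider intervals. Pairs
of samples from the same sampling site can be excluded from clade
summaries (close kin bias splits downward), and SNP-panel-derived
consensuses are refused by default because a panel targeting known
segregating sites enriches d but not n, biasing the implied rate
upward. A transversions-only sensitivity mode drops C↔T / G↔A
mismatches from both d and n.

## The simulator

`simulate` generates a Kingman-style random binary genealogy rescaled
to a chosen root age, places mutations per branch as
Poisson(μ·L·duration) with positions uniform without replacement
(infinite sites — appropriate because the catalogue framework treats
each SNP as a single ancestral→derived event), and emits per-sample
pileups with Poisson read depth, per-site drop-out, per-read
orientation-symmetric deamination (C→T and G→A at equal rate), optional
contamination drawn from another leaf's haplotype, and uniform
read-end offsets. Defaults: μ = 8.0 × 10⁻¹⁰ substitutions/site/year
(inside the published NRY range), L configurable up to the ~10.4 Mb
mappable NRY and down to ~10⁵ bp for fast tests; every stochastic
operation takes an explicit seed. Haplogroup labels encode the binary
topology (root `HG`, children append `0`/`1`), so the label set is
itself a valid haplogroup hierarchy with known truth per leaf.

What the simulator does **not** model: sequencing error beyond
deamination, the end-concentration of real deamination damage (offsets
are uniform, so offset-based damage triage is exercised but not
calibrated), fragment-length variation, mapping artefacts, and
reference bias. Passing tests therefore demonstrate the correctness of
the statistical machinery under its stated assumptions, not robustness
to every artefact of real ancient-DNA libraries.

## Test and acceptance problem sizes

The suite runs everything at reduced scale: 8-leaf trees over the full
10.4 Mb length for caller/alignment checks, 200 leaves for the
recovery rates (clean: 100% agreement with a path-tracing oracle —
the deepest truth-path clade whose every branch has a covered defining
SNP; 5% damage at depth 10: ≥ 99%), 200 random 20×200 matrices for the
diagnostic-rule oracle, and 300 two-leaf replicates per split time for
CI coverage. For the coverage runs the sequence length is scaled down
per split time (1 Mb at 10 ky, 200 kb at 50 ky, 70 kb at 150 ky) to
hold the expected difference count near 16: this preserves the count
regime the estimator operates in on real data (hundreds of
differences), whereas a uniform tiny length would push the smallest
setting into the λ ≈ 1 regime where exact Poisson intervals are
degenerate-conservative and coverage saturates near 100%.

## Known limitations

* The caller's resolution is bounded by the catalogue: branches
  without covered defining SNPs stop the descent, so calls are
  ancestors of the true terminal clade when coverage is sparse.
* Calibration transfers rate uncertainty into a point constant; no
  uncertainty in c is propagated into the CIs.
* The heterozygosity screen detects male contamination only through
  allele mixtures at divergent sites; female contamination is
  invisible to it.
* Back mutation and saturation are excluded by construction
  (infinite sites), consistent with catalogue-based Y analysis but
  not with deep-time mtDNA-style saturation regimes.
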