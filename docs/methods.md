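# Methods

`flockscan` implements a complete within-population genomic analysis for
SNP-array data from structured livestock populations: call-rate quality
control, runs of homozygosity (ROH) and four genomic inbreeding
coefficients, pairwise Weir–Cockerham F_ST, LD-decay historical effective
population size (N_e), five single-population selection statistics, and
their decorrelated composite (DCMS). A forward Wright–Fisher simulator
generates array-like multi-population data so that every stage is testable
without external downloads. This note records the models, the parameter
choices that matter, and the limits of what the synthetic data can show.

## Genotype model and quality control

Genotypes are diploid allele-count codes x ∈ {0, 1, 2} against a per-variant
reference allele a2 (a1 is the minor allele for PED/MAP text input, or the
first BIM allele for binary input), with −1 for missing. QC removes samples
with call rate below 1 − `sample_max_missing` (default 0.10) first, then
variants with missingness above `variant_max_missing` (default 0.05)
*among the retained samples*, then non-autosomal variants (autosomes 1–26,
the sheep karyotype, configurable). The order matters in edge cases: a
variant that fails only because of a bad sample survives once that sample
is gone. All missingness denominators exclude already-removed entities.

LD pruning is greedy within sliding SNP windows (defaults 50 SNPs, step 5,
r² > 0.2), with r² the squared Pearson correlation of genotype codes
(composite LD — the phase-free quantity PLINK's `--r2` reports). When a
pair exceeds the threshold the lower-MAF member is dropped; equal MAF drops
the later map position, making the result deterministic for a given input
order. Relatedness filtering uses the off-diagonal of the within-population
variance-standardized (Yang) genomic relationship matrix with threshold
0.25; the member of a flagged pair with more flagged partners goes first
(ties remove the later sample). With tens of samples per population the
off-diagonals shrink toward −1/n plus sampling noise, so estimated
parent–offspring coefficients sit slightly below the pedigree 0.5 but well
above the cut.

## ROH and inbreeding

ROH detection reconstructs the PLINK `--homozyg` scan. Defaults: minimum
run length 1,000 kb, maximum inter-SNP gap 1,000 kb, at most 0 heterozygous
and 1 missing call per scanning window, density at most 150 kb per SNP.
The scanning window (50 SNPs) and hit-proportion threshold (0.05) are not
implied by those flags, so both are explicit parameters: a window is a
"hit" when it satisfies the het/missing tolerances, a SNP is ROH-eligible
when at least 5% of the windows covering it are hits, and maximal runs of
consecutive eligible non-heterozygous SNPs are then filtered on count,
length, density and gaps. A consequence worth knowing: run edges are
trimmed by a couple of SNPs relative to the underlying homozygous tract,
because edge SNPs are covered mostly by windows that straddle flanking
heterozygotes. Chromosomes shorter than the scanning window are scanned
with a single truncated window rather than skipped.

The per-run minimum SNP count defaults to the false-positive-controlled
value L = ceil( log(α / (n_SNPs · n_individuals)) / log(1 − het) ),
clamped at ≥ 2, with α = 0.05: the expected number of chance runs of L
homozygous SNPs over all SNP × individual start points is bounded by α.
At 50K-array scale (39,685 SNPs, 238 samples, mean heterozygosity 0.35)
this gives L = 45.

Per individual the package reports:

- **F_ROH** — summed ROH length over the SNP-covered autosomal length,
  where covered length is Σ over chromosomes of (last − first + 1) bp.
  Both numerator and denominator use inclusive spans, so runs that tile
  the covered genome give exactly 1.
- **F_GRM** — mean over polymorphic SNPs of (x − 2p)² / (2p(1−p)) minus 1,
  the diagonal of the Yang GRM minus one. Negative when an individual is
  more heterozygous than the reference frequencies predict.
- **F_HOM** — (O_hom − E_hom) / (m − E_hom) with E_hom = Σ (1 − 2p(1−p)),
  the excess-homozygosity form.
- **F_IS** — 1 − mean(H_O)/mean(H_E) at the population level (an
  individual-level variant is a documented alternative; the population
  form is reported because H_E is a population quantity). Populations of
  one sample get NaN, flagged in the log.

Allele frequencies for the frequency-dependent estimators are computed
within each sample's population; monomorphic markers are excluded (their
standardized deviations are undefined). ROH length classes are [1,5),
[5,10), [10,15), [15,20) and ≥20 Mb, left-closed, so class totals conserve
the summed length.

## F_ST and LD-decay N_e

Pairwise F_ST uses the Weir & Cockerham (1984) method-of-moments variance
components a, b, c with the two-population sample-size and heterozygosity
terms; the multi-locus estimate is the ratio of sums Σa / Σ(a+b+c). SNPs
monomorphic across both populations, or with fewer than two genotyped
samples in either, are skipped. Negative estimates arise from sampling
noise; both the per-SNP values and the mean are clamped at zero *for
reporting* while raw values are retained in the result object, so the
clamping never silently biases a downstream computation.

The N_e trajectory bins within-chromosome SNP pairs by physical distance
(50 kb bins from 50 kb to 4 Mb), averages composite r² per bin, subtracts
the sample-size term 1/(βn) (β = 2 for unphased genotype r², 1 for
haplotype r²), maps distance to recombination rate c, and inverts

    N_e(c) = (1 / (4 f(c))) · (1 / r²_adj − α),      t ≈ 1 / (2 f(c)),

with mutation parameter α = 2 by default. The mapping is pluggable:
`linear` (c = d in Morgans at 1 cM/Mb, the default used for every number
in this repository) and `sved_feldman` (c = d/(1+2d), a drift-based
correction that compresses large distances). No sheep genetic map is
shipped, so cM/Mb is a constant (1.0, configurable). Bins with no pairs or
with r²_adj too small to support a positive N_e are emitted with NaN and
flagged rather than dropped, so the distance axis stays complete. With the
linear map the most distant bin (4 Mb) probes t ≈ 13 generations ago and
the closest (50 kb) about 990 — larger distances inform more recent
epochs.

Because the simulator has no mutation, its equilibrium LD follows
E[r²] ≈ 1/(1 + 4Nc) rather than the mutation-drift 1/(2 + 4Nc); inverting
with α = 2 therefore biases N_e down by 1/(4c), about 12% at c = 0.01 for
N = 200. The ±35% recovery check on mid-distance (1–2 Mb) bins absorbs
this known, signed, and small effect; the bottleneck scenario is assessed
on the *shape* (recent bins below older bins), which the bias does not
affect.

## Selection statistics

All five statistics are computed within one population.

- **EHH / iHS** (phased haplotypes). EHH at distance x from a focal allele
  is the probability that two random carrier gametes are identical from
  the focal SNP through x, computed by haplotype-group splitting
  (equivalently Σ C(n_k,2)/C(n_core,2)). iHH integrates EHH over physical
  distance by trapezoid until EHH falls below 0.05; sites whose profile
  reaches a chromosome end above the cutoff are treated as missing, as are
  sites with minor-allele frequency below 0.05 or singleton alleles.
  Raw iHS = ln(iHH_ancestral / iHH_derived) is z-scored within
  derived-allele-frequency bins of width 0.05 per chromosome. Arrays carry
  no ancestral-state annotation, so the dataset-wide major allele stands
  in for the ancestral allele; this affects only the sign of iHS, and the
  composite uses |iHS|. The inner loop is a numba kernel; a pure-numpy
  implementation of the same profile (`ehh_decay`) serves readable
  reference duty and the test suite checks both against an O(n²)
  pairwise-identity oracle.
- **H12** (phased): sum of squared haplotype frequencies with the two most
  common haplotypes pooled, in 25-SNP windows stepping 1 SNP.
- **ZHp** (genotypes): pooled heterozygosity 2·Σn_MAJ·Σn_MIN/(Σn_MAJ+Σn_MIN)²
  per 200 kb window stepping 100 kb (50% overlap), z-scored over all
  windows genome-wide. Identical Hp in every window makes the z-score
  undefined and raises an explicit error.
- **π and Tajima's D** (genotypes): per-site π = 2j(N−j)/(N(N−1)) from
  alternate-allele count j among N non-missing allele copies — an
  allele-count form that serves phased and unphased input identically;
  window π divides the per-site sum by the 300 kb window span. D uses the
  standard a1…e2 constants at the window's rounded mean N. Windows with
  fewer than 10 SNPs are excluded; the same floor is reused for ZHp.
  π/D windows are non-overlapping.

## DCMS composite

Native-resolution scores are assigned to non-overlapping 500 kb grid
windows by midpoint (half-open [k·500kb, (k+1)·500kb); a midpoint exactly
on a boundary belongs to the right window) and averaged; |iHS| is median-
smoothed (width 3) along each chromosome first to damp single-SNP spikes.
Per statistic, grid values become empirical p-values by average rank:
right tail p = (N − rank + 1)/(N + 1) for |iHS| and H12 (high = candidate),
left tail p = rank/(N + 1) for ZHp, π and Tajima's D (low = candidate).
Rank p-values are strictly inside (0,1) and, at N windows, bounded below by
1/(N+1) — a resolution limit that matters at reduced genome sizes (below).

The tail choice for π deliberately deviates from treating high diversity
as a candidate signal: sweeps *remove* diversity, and with a right-tailed
π the composite demotes exactly the windows a sweep produces (verified on
simulated sweeps, where detection fails outright). All tail directions are
configurable per statistic.

The composite for window j is DCMS_j = Σ_i w_i · log10((1 − p_ij)/p_ij)
with w_i = 1/Σ_k |r_ik|, where r is the Pearson correlation matrix of the
p-value columns over pairwise-complete windows and the sum includes
k = i. Five perfectly correlated statistics thus each get weight 1/5 and
the composite equals the single-statistic score — correlated signals share
one vote. Windows missing components (an undefined D, an iHS-free region)
are scored when at least 3 of 5 statistics are present, with weights
recomputed from the correlation submatrix of the available statistics, so
a lone statistic carries weight 1. Fewer than 10 scored windows refuse
calibration.

Scores are compared to a Gaussian with the sample mean and standard
deviation of the population's own windows (upper tail), and
Benjamini–Hochberg step-up marks windows with q < 0.05. Significant
windows, extended by ±500 kb, are exported as merged 0-based half-open BED
records for downstream annotation.

## The synthetic-data generator

A forward Wright–Fisher engine: discrete generations, diploid populations
with size schedules (bottlenecks), Poisson-crossover recombination at
1 cM/Mb, optional directional selection at one site (fitness 1 : 1+s :
1+2s), island-model migration, and a small-flock mating mode that
partitions a population into persistent flocks with within-flock parent
choice — the mechanism behind recent autozygosity in smallholder herds.
Founder haplotypes are drawn site-independently from a U-shaped Beta(0.5,
0.5) frequency density clipped to MAF ≥ 0.02, modelling the ascertainment
of a chip designed on a broad discovery panel; LD then accrues by drift
over the burn-in generations. Markers that later fix in a population stay
in the output as monomorphic genotypes, exactly as a real chip behaves.
Scalar migration follows the Wright convention (each gamete drawn from a
metapopulation-wide pool, including the source deme, with probability m),
so the classic F_ST = 1/(4Nm + 1) is the correct two-deme reference; a
matrix gives explicit per-pair rates instead. Sweeps are seeded as a
standing variant on a *single* ancestral haplotype block (carriers copy
one origin gamete's surroundings): a shared allele without shared ancestry
produces no hitchhiking and no footprint. A sweep allele that is lost
restarts the run from a derived seed up to a retry cap, then is reported
as lost. Identical config + seed reproduces byte-identical output.

What the generator does *not* emulate: mutation (timescales are tens to
hundreds of generations), gene conversion, a real recombination map,
genotyping error, and realistic sheep demographic history. Three
consequences show up in the tests and are worth restating:

- **Tajima's D is shifted positive (~ +1.4) genome-wide on the generator's
  neutral output.** MAF ascertainment deletes rare variants, inflating π
  relative to Watterson's θ. This is a faithful property of array data,
  not an artifact to fix; within-genome *ranks* — all the composite uses —
  are unaffected. The neutrality calibration of D (mean within ±0.5) is
  therefore checked on a direct neutral-SFS fixture instead.
- **Completed sweeps leave recombination remnants at intermediate
  frequency**, so without mutational input D can turn *positive* at a
  fixed sweep site. The bundled sweep panel stops selection at frequency
  0.95 so the site stays segregating, matching the near-fixation scenario
  the composite is calibrated for.
- **Rank-p resolution.** At the bundled panel's ~80 grid windows the
  smallest attainable component p is 1/81, capping DCMS around 3 and BH q
  around 0.04–0.15 even at a perfect sweep window. The sweep is therefore
  assessed by localization — does the sweep-containing window attain the
  genome-wide maximum DCMS — rather than by crossing the q < 0.05 line,
  which at full 2.5-Gb genome scale (~4,900 windows) is not similarly
  capped. Localization itself has an intrinsic granularity limit: an
  s = 0.05 footprint (~±0.8 Mb) spans about three 500 kb windows, so when
  the strict single-window maximum misses, it lands in the window adjacent
  to the sweep essentially every time. The replicated localization rate at
  these conditions sits right at the 80% mark, and the dedicated
  acceptance test documents (and may fail at) exactly that boundary.

### Problem sizes used by the test suite and acceptance script

Simulated scenarios run at reduced genome size: 2–4 chromosomes of 10–20 Mb
at 1 SNP per ~4–20 kb, populations of 50–1,000 diploids, 20–800
generations, 10–100 sampled individuals. The denser-than-50K marker
spacing keeps ≥ 10 SNPs in every 200–300 kb statistic window at these
genome sizes, preserving each estimator's operating regime. The sweep
panel is one swept plus one neutral 20 Mb chromosome, N = 500, s = 0.05
from a standing variant at 10% frequency on a single 500 kb ancestral
block, with selection switched off at frequency 0.85 so the site is
sampled in the late-sweep regime where haplotype and frequency statistics
are jointly informative; 60 individuals are sampled because the window
statistics' rank noise at 30 samples drowns part of the localization
signal. These sizes are the package's own study conditions; all scale
linearly if larger runs are wanted.

## Numerical conventions and degenerate inputs

Coordinates are 1-based inclusive bp except where a format dictates
otherwise (BED output is 0-based half-open; the DCMS grid is half-open).
Ties: LD pruning drops the later position at equal MAF; kin filtering
removes the later sample at equal degree; rank p-values average tied
ranks; a frequency tie makes the lexicographically smaller allele the
minor allele on text load. Monomorphic markers are excluded wherever a
2p(1−p) denominator appears. Empty windows and undefined statistics
propagate as NaN with a log record, never as silent zeros; operations that
cannot return a meaningful value on degenerate input (all samples removed
by QC, zero Hp variance, zero DCMS variance, monomorphic-only kinship)
raise explicit errors.

## Known limitations

Only biallelic autosomal variants are handled; X-chromosome inbreeding,
multi-allelic sites and pedigree semantics beyond sample identifiers are
out of scope, as are phasing (phased VCF is an input contract), gene
annotation and enrichment analysis. cM/Mb is constant in both simulator
and N_e inversion, so map-rate variation is invisible. The L-parameter and
ROH scan reconstruct PLINK's documented behaviour but are not bit-for-bit
PLINK; the hit-proportion internals PLINK leaves unstated are explicit
parameters here.
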