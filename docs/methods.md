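# Methods

This note documents the statistical models, estimator dialects, numerical
conventions and deliberate design choices behind `popsig`, and what the
synthetic-data tests do and do not establish about real data.

## Genotype model and coordinates

Genotypes are unordered diploid classes {hom-ref, het, hom-alt, missing};
phasing is discarded because no implemented statistic uses it. Positions
are 1-based VCF coordinates. All windows are half-open `[start,
start + window)` with starts at `k*step + 1`; per chromosome the grid runs
from the earliest step-aligned window containing the first SNP to the last
window starting at or before the last SNP, so every SNP is covered by the
full complement of overlapping windows. Missing genotypes are excluded
site-wise from every frequency denominator (the usual VCFtools/PLINK
behavior). Multiallelic and indel records are skipped on input with a
logged count; duplicate (chrom, pos) records are an error.

## Diversity panel

* **Pn** — fraction of sites with minor allele frequency strictly
  greater than 0.01, computed per population from that population's own
  frequencies.
* **Ho** — per sample, het calls / non-missing calls; population values
  are mean ± SD over samples. All mean ± SD summaries in the package use
  the sample SD (n−1), matching how cohort tables are usually reported.
* **He** — mean of 2p(1−p) over sites polymorphic within the population.
  This is the standard expected heterozygosity; with n diploids the site
  mean of 2p̂(1−p̂) carries the usual (1 − 1/2n) sampling factor, which the
  calibration test accounts for explicitly.
* **π** — the VCFtools windowed dialect: per-site unbiased estimator
  2p(1−p)·m/(m−1) with m called alleles, summed over the window and
  divided by the nominal window length in bp (monomorphic positions count
  in the denominator; trailing partial windows still divide by the nominal
  length, which only affects edge windows).
* **D** — per pair at mutually called sites, IBS2 = identical genotype
  classes, IBS0 = opposite homozygotes, IBS1 = remainder;
  DST = (IBS2 + 0.5·IBS1)/N and D = 1 − DST. This parenthesization is the
  standard PLINK `--genome` DST and is the only reading that keeps
  DST ∈ [0, 1].

## Runs of homozygosity

Detection is the PLINK `--homozyg` two-phase scheme: 50-SNP scanning
windows *hit* when they contain at most `max_het_per_window` (default 1)
heterozygous and `max_missing_per_window` (default 1) missing calls; a SNP
is *in* a run when ≥ `window_hit_threshold` (default 0.05, the PLINK
default) of the windows covering it hit; maximal *in* stretches are split
at gaps > 1 Mb and filtered by ≥50 SNPs, ≥100 kb, and segment-average
density ≥ 1 SNP/100 kb. The "≤1 het / ≤1 missing" thresholds are applied
per scanning window, the only reading under which a homozygous-run
definition is self-consistent. One refinement beyond the classic recipe:
final segments are trimmed so both endpoints are homozygous non-missing
calls — a run delimited by a heterozygous or missing call is not a
meaningful ROH boundary, and the trim makes planted-tract recovery exact
to one SNP. Segment coordinates are first/last SNP positions, length =
end − start + 1.

Length classes partition (100 kb, ∞) at 150/250/400 kb with the boundary
in the lower class ("100–150" then ">150–250"). F_ROH divides total ROH
length by L_auto, default 2.4 Gb (the caprine autosome length); for
synthetic genomes the pipeline uses the actually covered span instead,
which is essential for the identity tests.

The brute-force oracle in the test suite is an independent plain-loop
implementation of the same documented contract, and the two agree exactly
on hundreds of random genomes across widely varied thresholds.

## Selection scans and the FST dialects

Per-site two-population FST is computed as
1 − (p₁q₁ + p₂q₂)/(2p̄q̄) with p̄ the unweighted mean frequency —
algebraically (p₁−p₂)²/(4p̄q̄), hence bounded in [0, 1]. The window value
is the unweighted mean of per-site values over windows with ≥30
informative SNPs (the default dialect, matching how the scan statistic is
usually printed).

Two further dialects matter for *estimation*. For two demes each drifted
with Balding–Nichols parameter F, the statistic above is the two-deme
G_ST, whose ratio-of-expectations is F/(2−F) ≈ F/2 — plus a finite-sample
inflation of order 1/(4n) from sampling noise in (p̂₁−p̂₂)². It is a valid
scan statistic but **not** a calibrated estimator of the drift parameter.
The Weir–Cockerham ratio-of-sums (`dialect="wc"`, the estimator VCFtools
computes as "weighted FST") and the sample-size-corrected Hudson
ratio-of-sums (`dialect="hudson"`) are nearly unbiased for F; the
parameter-recovery checks therefore use the `wc` dialect, and recover
F ∈ {0.01, 0.05, 0.1} within a few percent on 40k-SNP cohorts with no
calibration knobs. WC/Hudson window values can be slightly negative by
construction; the default dialect cannot.

Pooled heterozygosity uses per-SNP major/minor **allele counts** (not
frequencies): Hp = 2·ΣnMaj·ΣnMin/(ΣnMaj + ΣnMin)². Counts keep the
statistic robust to per-site missingness; with frequencies every SNP
would contribute identically regardless of how many genotypes support it.
Ties at p = 0.5 are irrelevant because Hp is symmetric in the two sums.
Hp ∈ [0, 0.5], with 0.5 iff the two sums are equal.

Both scans are Z-standardized genome-wide per comparison/population with
the sample SD; a constant scan is a hard error. Outlier calling selects
ceil(tail·N) windows per tail (ties broken by deterministic (chrom, start)
order), intersects by exact window identity, and union-merges overlapping
or abutting selected windows into candidate regions. The FST and Hp grids
can differ slightly (windows are dropped by different informativeness
rules), so the pipeline intersects over shared windows; strict grid
checking is available and is the library default.

## f-statistics

f3 and f4 are plain site means of (a−b)(a−c) and (a−b)(c−d) over sites
with defined frequencies in every involved population (listwise
deletion); blocks of 500 retained SNPs (trailing partial merged into the
last full block) feed a weighted delete-one jackknife (Busing form, which
reduces to the standard formula for equal blocks). No finite-sample bias
correction is applied by default — the statistics are used for their
sign/Z contract — but `correct_target_het=True` subtracts the unbiased
within-target sampling-variance term â(1−â)/(2n−1), which removes the
positive O(het/2n) bias of f3 with small samples.

## Synthetic cohorts

The Balding–Nichols generator is chosen over a coalescent because the
closed-form frequency moments make every calibration analytic, and no
implemented statistic needs linkage. Defaults: 3 populations × 10
samples, 2 × 10 Mb chromosomes, 40,000 SNPs (2 SNPs/kb), ancestral
Beta(1, 1) (E[He] = 1/3, in the range of outbred livestock), drift
F = 0.05, missing rate 1%. SNP positions are uniform without replacement.

Planted features are registered against the realized SNP coordinates:

* **Sweeps** redraw the target population's frequencies inside the window
  with minor allele frequency ~ U(0, ceiling) toward the ancestral major
  allele (default ceiling 0.02), giving depleted Hp and elevated FST.
* **Autozygous tracts** force one sample homozygous for the
  population-major allele across the span. The two SNPs immediately
  outside each end are forced heterozygous, and planted calls are exempt
  from missingness masking: without these the detected run would extend
  stochastically into the (often homozygous) background and the planted
  extent would not be identifiable. With them, detection under default
  parameters lands deterministically one SNP inside each planted
  boundary, so F_ROH matches the planted fraction to one inter-SNP
  spacing per boundary.

What the simulations do **not** model: linkage disequilibrium, mutation
spectra, sequencing/calling error, non-equilibrium demography, and
relatedness within populations. Passing tests therefore establish the
correctness of the estimators and the detectability of idealized signals,
not the power or false-discovery behavior on real resequencing data,
where LD correlates neighboring windows and genotype error inflates
heterozygosity inside true ROH.

## Problem sizes and determinism

Test and acceptance workloads use cohorts of 16k–67k SNPs and up to 5,400
scan windows — sizes chosen so the full pipeline runs in seconds while
every window/tail computation still operates in its intended regime
(thousands of windows, ≥30 SNPs each). All stochastic tests fix seeds;
the pipeline is byte-deterministic given a seed, and the acceptance
script derives all sub-seeds from its single `--seed` argument.
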