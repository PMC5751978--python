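# Methods

## Phenotype model

A rice spikelet carries two stigmas; after flowering each may be exposed
or enclosed. For a panicle with `S` spikelets of which `Ns` expose one
stigma and `Nd` expose both, the exposed-stigma fractions are

    SSE% = 100 · Ns / (2S)
    DSE% = 100 · 2Nd / (2S)
    SE%  = SSE% + DSE% = 100 · (Ns + 2Nd) / (2S)

i.e. each rate is a fraction of the panicle's `2S` stigmas. `SE = SSE +
DSE` holds exactly by construction, matching the additive rows of the
reference phenotype table (9.19 + 3.34 = 12.53 and so on). Plants with
SE% strictly below 25 are classified low-exertion; the boundary value
itself goes to the high class (a fixed, configurable convention — the low
class is defined by falling *under* the split).

Percent reductions of a mutant rate against the wild type are
`100·(wild − mutant)/wild`, reported half-up to two decimals, which gives
70.64% for SE (12.53 vs 42.68) and 70.36% for SSE (9.19 vs 31.01), the
smallest reduction across the three traits.

### Segregation testing

The F2 high:low split is tested against 3:1 by Pearson chi-square with
1 df, uncorrected by default (the conventional χ²₀.₀₅,₁ = 3.84 comparison);
a Yates flag is available. For the reference counts 1536:464 the statistic
is 36²/1500 + 36²/500 = 3.456 (p ≈ 0.063), consistent with 3:1 at α =
0.05, and the low:high ratio is 0.30. Note that neither the Pearson nor
the Yates-corrected statistic equals the historically printed value for
these counts (1.77); the computation behind that figure is unstated, so
this package reports the standard statistic. χ² is not invariant under
scaling both counts: doubling the sample doubles the statistic.

## SNP-index scan

At every biallelic site where the cross parents carry different alleles,
the SNP-index of a pool is the fraction of its reads carrying the
mutant-parent allele; Δ = index_L − index_H. With this orientation a
recessive low-exertion locus drives Δ toward +1 (the L-pool, built from
low plants, is fixed for the mutant allele). Flipping the parent labels
maps every index x to 1 − x and Δ to −Δ; region calling on the lower band
side is available for that orientation.

Filters follow the strict-inequality exclusion rules: sites with quality
< 20 or per-pool depth < 4 or > 32 are removed, so the bounds themselves
are kept. Depth bounds apply to both pools by default (an H-pool-only
mode is provided); symmetric filtering also guarantees both indices are
defined. Coordinates are 1-based inclusive throughout.

Windows of 1 Mb advanced by 10 kb are anchored at position 1; terminal
windows are truncated at the chromosome end and kept. A window needs at
least 3 member SNPs to be reportable (single-site spikes otherwise
dominate the scan); windows below the minimum are flagged missing and
carry no means. The window coordinate used for reporting is the midpoint.

### Null band

Under no QTL, each bulk is `bulk_size` independent draws from the F2
genotype distribution (¼ aa, ½ Aa, ¼ AA); the bulk mutant-allele
frequency is the mean allele dosage, and read counts are binomial at the
given depth. The band tabulates empirical two-sided quantiles of
simulated Δ per (depth_H, depth_L) pair — 1,000 replicates at the 95%
level by default; the self-calibration check uses 10,000 for tighter
Monte-Carlo tolerance. Each depth pair gets an independent deterministic
seed stream, so bands are bit-reproducible and independent of grid order.
Candidate regions are maximal runs of ≥ 3 consecutive non-missing windows
whose mean Δ clears the upper bound at the band entry nearest the
window's rounded mean per-pool depths, merged across step overlaps.

The windowed statistic is conservative against this per-site band: a
window averages ~50 sites whose read noise averages out, while the shared
bulk-composition noise remains. In practice the no-QTL false-call rate is
near zero and the planted locus clears the band by a wide margin.

## Simulator

Meiosis is Haldane: crossovers per gamete per chromosome are Poisson with
mean equal to the genetic length in Morgans at 400 kb/cM (configurable),
breakpoints uniform, starting parent a fair coin. F2 plants are two
independent gametes. Phenotypes: aa plants draw SE% from N(12.53, 2.44),
all others from N(42.68, 3.39), clipped to [0, 100] — the class means are
more than 8 SD apart, so the SE% = 25 boundary recovers the genotype
classes essentially without error and the extreme-tail bulks of 30 are
pure aa / non-aa. Bulks are the most extreme plants per tail. Read
counts: per-site pool frequency is the mean member dosage halved,
perturbed by a symmetric per-read error of 0.002; depth is Poisson
(negative binomial optional) around 24 per pool. The phenotype table is
emitted as integer spikelet counts: SE% is converted to exposed stigmas
on a 120-spikelet panicle with roughly a quarter of exposures double,
clamped to feasibility; quantisation moves SE% by under half a point.

Defaults are the study conditions: F2 of 2,000, bulks of 30, 1,000 sites
on a 20 Mb chromosome, QTL at 13.8 Mb, depth 24×.

What the simulator does *not* emulate: genotyping error and allele-specific
bias, over/under-dispersed coverage along the genome (beyond the optional
NB switch), repeat-driven false SNPs, multi-locus or partially penetrant
phenotypes, and crossover interference. Passing recovery tests therefore
demonstrate the statistical machinery under a clean single-locus model,
not robustness to those artefacts.

### Expected Δ at the locus, and scan resolution

With pure tails, the L-pool index at the QTL is exactly 1 (asserted at
zero sequencing error), but the H-pool is a 2:1 Aa:AA mixture with
mutant-allele frequency 1/3, so the expected peak Δ is 2/3 — not ≈ 1; a
claim that the H-pool index is "near 0" is not attainable for a recessive
locus under phenotypic bulk selection. At map distance r from the locus
the expectation decays as Δ(r) = 2/3 − (4/3)r, i.e. only ~0.033 per Mb at
400 kb/cM, while the bulk-mosaic sampling noise of 30-plant bulks (120
gametes) has a chromosome-correlated sd of ~0.03. Consequently the
called region reliably *contains* the locus (20/20 seeded replicates at
the default design), but the argmax window can wander several Mb: peak
localisation to ±1 Mb holds in only ~60–85% of replicates depending on
seed, and the exceedance region often spans most of a 50 cM chromosome.
This resolution limit is intrinsic to 30-plant bulks — it is why the
workflow hands over from the scan to recombinant fine mapping — and the
corresponding acceptance test records it honestly.

Sizes used by the test-suite experiments were chosen to keep the full
suite fast while preserving the structure under test: property tests run
on 5–10 Mb toy chromosomes with a few hundred plants, while the
acceptance experiments run the full default design (20 replicates).

## Linkage and fine mapping

Among recessive plants every gamete is informative: a heterozygous plant
at a marker carries one recombinant gamete there, a non-mutant homozygote
two. cM = 100·(n_single + 2·n_double)/(2·n) with no map function — at
fine-mapping distances the Haldane/Kosambi correction is below the
printed precision, and the raw fraction reproduces all four reference
distances (11.53, 10.45, 1.19, 3.23 cM at n = 464) exactly.

Interval inference treats each recessive plant's codes as a pattern
non-A* A+ non-A* over the ordered panel (A = mutant-parent homozygote).
A left-arm breakpoint places the locus at or right of the first A marker
after it; symmetrically on the right. The interval is the max of left
bounds to the min of right bounds — so it never widens as plants are
added — and anything violating the pattern (no A block, or an interior
non-A island) is reported as a contradiction naming the plants. Missing
codes are uninformative. With the bundled six recombinants this yields
InDel-2 (13,690,353) to InDel-4 (13,939,718), 0.25 Mb, with InDel-3 as
the zero-recombinant internal marker.

Candidate-gene filtering reports the distinct gene IDs whose alleles
differ between two chosen lines anywhere in the interval variant table:
7 genes between the parents 93S and *lesr*, and 2 genes (OS10g0404566,
OS10g0407000) between *lesr* and its wild-type progenitor 115S.

## Numerical conventions

Reported ratios, percentages and Mb lengths round half-up to two decimals
(banker's rounding would disagree with printed tables on ties). Window
means are exact prefix-sum differences (equal to the brute-force site
average within 1e−9). All randomness flows through
`numpy.random.default_rng` seeded from configuration; stage and
depth-pair streams are derived deterministically so outputs are
bit-reproducible for a fixed seed.
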