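# Methods

`sweetsim` is a forward-in-time stochastic simulator of a hybrid sweet corn
breeding program: a public program developing inbred parents for testcross
hybrids, with a four-fold larger private program running alongside to supply
the elite tester inbreds. This note documents the models, the parameters
that matter, the numerical choices, and what the reduced-scale experiments
do and do not show.

## Founder genomes

Genomes are fully synthetic and biallelic (0/1), tracked only at the causal
QTN and the neutral SNP markers. The default genome has 10 chromosome pairs,
each 2.0 Morgans of genetic map (physical coordinates, 2x10^8 bp with
per-bp recombination 1.25x10^-8 and mutation 2.5x10^-8, are used only by
the coalescent founder path); 300 QTN and 3,000 SNPs per chromosome (33,000
sites genome-wide).

Founders emulate the historical public/private split of US sweet corn
germplasm: a panmictic Hardy-Weinberg base of 100 individuals is divided
into a public and a private pool of 50, which then random-mate independently
for 30 Wright-Fisher generations (constant size, selfing allowed, no further
mutation). Two base generators are provided and pass the same invariant
suite:

- **coalescent** (default): per-chromosome neutral coalescent haplotypes via
  msprime (population size 100, binary mutation model), giving a realistic
  frequency spectrum and background linkage disequilibrium;
- **beta**: independent sites with ancestral frequencies from
  Beta(0.5, 0.5), sampled into Hardy-Weinberg genotypes. Cheaper, no base
  LD; useful for fast tests and drift oracles.

QTN and SNP coordinates are chosen *after* the split-and-drift phase, from
candidate sites still segregating in the combined 100 founders: each QTN is
the segregating site nearest to an evenly spaced grid point on the genetic
map, and SNPs are drawn at random from the remaining segregating sites
(QTN and SNP sets are disjoint, so prediction never sees causal sites
directly). Selecting sites post-drift conditions on segregation the same way
coalescent-based founder pipelines do; committing to fixed positions before
30 generations of drift would lose a fraction of all sites with certainty at
genome scale. If a chromosome cannot supply enough segregating candidates,
the whole generation is retried with a fresh seed (5 attempts) before
failing.

## Transmission

Meiosis uses the Haldane model: crossovers per chromosome are
Poisson(length in Morgans) with breakpoints uniform on the map, no
interference and no obligate chiasma; the starting haplotype is a fair coin.
Crossing draws one independent gamete per parent; selfing draws two
independent gametes from the same parent; a doubled haploid duplicates a
single gamete into both haplotypes (heterozygosity exactly zero). There is
no mutation after the founder stage, no sex, and no structural variation.
The inner copy loop is a numba kernel; all randomness stays in numpy
Generators so that a fixed seed reproduces populations bit-exactly.

## Trait model

One quantitative trait with additive, dominance and genotype-by-environment
(GE) components. Per QTN i, with genotype coding x_i in {-1, 0, +1} and
heterozygote indicator h_i:

    G = mu + sum_i x_i a_i + sum_i h_i d_i,      d_i = delta_i |a_i|

Raw additive effects a_i are standard normal, jointly rescaled (with mu)
so the *founder* additive mean and variance are exactly 150 and 30
(population variance on the founder set; rescaling is idempotent).
Dominance degrees delta_i ~ Normal(0.93, 0.3) give strong directional
dominance: outbred material carries a heterosis premium, and inbred lines
express inbreeding depression. This matters when reading outputs: parental
genetic means of inbred lines can sit below the founder mean of 150 even
after sustained selection, because the additive gains and the loss of the
dominance premium move in opposite directions. Selection response is
therefore best read from the additive component or from hybrid means.

GE interaction is a linear reaction norm: an independent standard-normal
slope is drawn per QTN and the slope score sum_i x_i s_i is scaled so its
founder variance equals `ge_var_multiplier` x 30 (multiplier 0 or 10) at a
unit-variance environmental covariate. The yearly covariate (EC) is drawn
once per (year, season) as a quantile mapped through the standard-normal
inverse CDF: target-season quantiles ~ Normal(0.5, 0.03) (EC near 0,
year-to-year weather wobble) and off-season quantiles ~ Normal(0.1 or 0.9,
a fair coin per year; 0.03) (EC near -1.28 or +1.28, a genuinely different
environment). The quantile reading makes the base covariate mean-0,
variance-1 across typical years while keeping the two seasons' stated
intensities. Consequence: with multiplier 10, off-season selection is
heavily GE-confounded (deviation sd ~ 22 at |EC| = 1.28) while target-season
trials are only mildly so — which is precisely why marker-based off-season
selection helps.

Phenotypes are entry means: G + GE deviation + error with variance
sigma2_res / n_reps, where n_reps is the stage's trial count (1 nursery row;
2, 5, 20 trials at testcross stages TC1-TC3). sigma2_res is 60
(high-heritability trait) or 240 (low).

## Breeding programs

Five public-program variants share one calendar engine. All stages are
occupied every year (overlapping cohorts), so the shipped per-year budgets
are true annual costs and the genomic-selection training window receives
records yearly. Parental substitution, line release, and private tester
turnover happen once per completed recurrent-selection cycle: 5 years for
Conv/GSTC/GSF1 (4 cycles in the 20 evaluation years, 2 releases each = 8
lines) and 4 years for DH/DHGS (5 cycles, 10 lines).

- **Conv** - cohort ages: Y1 cross (50 F1, off-season); Y2 self to an F2
  nursery (10 progeny per family, 500 rows), phenotypic truncation to 150
  lines; Y3 TC1 (1 tester, 2 trials) on 150, advance 100; Y4 TC2 (3
  testers, 5 trials), advance 15; Y5 TC3 (5 testers, 20 trials), top 2
  eligible for release. Parent candidates: top 50 of the TC2-ranked lines.
- **GSTC** - same calendar; the nursery step is ranked by GEBV (no
  phenotyped nursery plots) and parent candidates by GEBV; testcross
  advancement stays GCA-based. Training: each stage-year's testcross GCAs
  (150 + 100 + 15 records per year) in a 4-year sliding window
  (steady state 1,060 records).
- **GSF1** - as GSTC, but trained on 800 F1 families crossed from the
  current block each year and phenotyped (one trial) in the target
  environment.
- **DH** - Y1 cross and induce 800 DH lines (16 per family); Y2 TC1 on all
  800, advance 200; Y3 TC2, advance 100; Y4 TC3, top 2 released. Parents
  recycle from the TC2 ranking - a 4-year cycle.
- **DHGS** - as DH with GSTC-style training on its larger testcross
  populations (800/200/100 records per year); crossing-block candidates are
  the newest (year-1) DH lines ranked by GEBV - early recycling is the
  scenario's defining advantage.

Crossing plans are random: each cross draws two distinct parents from the
block at random, so contributions are unequal and the block's effective
size is below its census size (balanced contribution schemes would mute the
diversity loss that full parental replacement causes). The substitution
ratio (old:new in {3:1, 1:1, 1:3, 0:1}) composes each new block from
floor(slots x old fraction) top-ranked parents of the previous cycle plus
top-ranked new candidates, ids breaking ties. During the burn-in and in the
private program the ratio is fixed at 1:1, so every scenario and every
ratio variant under study starts from a bit-identical burn-in state for a
given seed.

The private program mirrors the conventional calendar at four-fold stage
sizes with purely phenotypic per-se line trials (1/2/5/20 replicates by
stage). Its top five finished lines become the tester set at each 5-year
boundary. Per-se trials stand in for the private program's own testcross
network, which the simulation cannot represent without circularity (the
private program is itself the source of testers).

A 15-year conventional burn-in precedes every scenario. 20 evaluation years
follow. Per evaluation year the program records the crossing block's
genetic mean and variance (additive + dominance, no residual), the genetic
mean of the year's TC3 hybrids, cumulative cost (years x the scenario's
annual budget), and cumulative releases; a year-0 baseline row captures the
burn-in endpoint.

## Genomic prediction

The marker model is ridge-regression BLUP, y = 1 mu + Z u + e with
u ~ N(0, I sigma2_m), e ~ N(0, I sigma2_e), fitted by REML on the single
ratio lambda = sigma2_e / sigma2_m. One eigendecomposition of the centred
kernel yields a cheap 1-D restricted-likelihood profile in lambda,
optimized by a coarse log-grid (41 points on [1e-5, 1e5]) followed by
bounded Brent search (tolerance 1e-8 on log10 lambda). The decomposition is
taken on whichever side is smaller - the m x m marker Gram matrix Zc'Zc
(cost independent of training-set size; per-year Gram blocks are cached as
the window slides) or the n x n record kernel Zc Zc' (needed at full scale,
where markers number 30,000). Both paths produce identical estimates; at
the optimum, effects and intercept equal the exact mixed-model-equation
solution (verified against a dense MME oracle in the tests). Genotypes are
centred by training-set allele frequency; a constant response returns a
flagged degenerate fit (effects zero, prediction = mean).

Testcross GCA is the parent main effect of a two-way (parent + tester)
least-squares fit with sum-to-zero constraints; in balanced layouts this is
the parent's mean across testers minus the grand mean (closed form used
when the layout is balanced), and with one tester the testcross mean minus
the grand mean. Training records keep one row per parent per stage-year;
rows older than the 4-year window are dropped.

## Budgets and efficiency

Per-year plot counts and dollar costs for all ten scenario/size
combinations are shipped as configuration; their per-category composition
is not derivable from cohort sizes alone, so `itemized_cost` (unit costs:
inbred plot $12, testcross plot $8, genotyping $10/sample, phenotyping
$4/plot, DH line $20) supports forward costing of user-defined programs
instead. Cost efficiency is reported under both circulating conventions -
relative gain per relative cost, and relative cost per relative gain
(exact reciprocals) - with the conventional program normalized to 1.00.

## Reduced problem sizes

The desk preset shrinks the genome to 3 chromosomes with 50 QTN and 500
SNPs each (1,650 sites) while leaving every program size, trial count and
calendar untouched; tiny single-chromosome genomes are used where only
bookkeeping is under test. These sizes keep the full test suite and the
acceptance script within routine desk budgets. What transfers across scale:
calendars, release counts, budget arithmetic, Mendelian/crossover/selfing
statistics, trait scaling, marker-model algebra, and the direction of the
headline scenario contrasts (DH+GS recycling beats the conventional
program; full parental replacement erodes genetic variance). What does not:
absolute genetic means/variances after 20 years, which depend on genome
size, founder spectrum and maintained diversity, and are therefore not
compared numerically anywhere. Selection in a 50-parent program is strongly
drift-affected at any scale; paired-seed designs (shared founders, burn-in
and yearly environments) are used throughout for scenario contrasts.

## Known limitations

- One trait; no selection indices, no epistasis, no correlated traits.
- The private program is phenotypic-only and per-se evaluated; reciprocal
  improvement of the tester pool by GS/DH is out of scope.
- Plot-level spatial field structure is not modelled; trial replication
  enters only through the entry-mean error variance.
- Costs are static configuration; no discounting or personnel modelling.
- The GE reaction norm is linear with a single environmental covariate per
  (year, season).
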