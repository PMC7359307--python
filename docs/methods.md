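# Methods

`selsweep` implements the standard three-way scan for recent positive
selection in closely related domesticated populations, together with the
simulation machinery needed to validate every stage against known ground
truth. This note records the models, the defaults and the reasoning behind
the open design choices.

## The scan statistics

**EHH and iHH.** For a core SNP and core allele, the extended haplotype
homozygosity at a site `s` is the probability that two randomly drawn
carrier chromosomes are identical at every SNP between the core and `s`:

    EHH(s) = Σ_h C(n_h, 2) / C(n_c, 2)

where `n_c` counts carriers and `n_h` the members of each distinct
haplotype class over the interval. EHH equals 1 at the core and is
non-increasing outward (haplotype classes only split). iHH is the
trapezoidal integral of EHH over physical distance, both directions
summed, truncated where EHH first drops below a cutoff (default 0.05,
with the interpolated crossing point included). A curve that reaches the
chromosome end while still above the cutoff is *edge-censored*: its
integral is a biased underestimate, so the site is excluded from
standardization. Distances are physical base pairs throughout — the
panels this package targets have no genetic map, and position-based
integration is the reference behaviour of haplotype-scan tools when no
map is supplied.

**iHS.** The unstandardized statistic is `ln(iHH_A / iHH_D)` (ancestral
over derived). Because its null expectation depends strongly on the
derived-allele frequency, scores are standardized — mean subtracted, SD
divided — within derived-frequency bins of width 0.05; bins with fewer
than 10 scored sites are merged into their right neighbour (the last bin
merges leftward) so that the bin moments stay estimable at desk scale.
The population (divide-by-n) SD is used. Within each bin the standardized
scores have mean 0 and SD 1 by construction. Ancestral alleles are taken
from the simulator's founder coding or the VCF `INFO/AA` key; sites
without polarity are skipped by default (`require_ancestral=True`), or
the reference allele can be treated as ancestral, with a loud warning,
since flipped polarity only flips the sign of individual scores.

**EHHS, iES and Rsb.** EHHS pools both alleles: the haplotype
homozygosity across *all* chromosomes over the interval, normalized to 1
at the core (it is a convex combination of the two allele-specific EHH
curves, a property the tests check by enumeration). iES integrates EHHS
with the same cutoff rule. Rsb compares one site's iES between two
populations, `ln(iES_pop1 / iES_pop2)`, standardized genome-wide in a
single bin — Rsb requires no ancestral/derived polarity, so there is no
frequency axis to bin on. Positive standardized Rsb marks longer
haplotypes, hence candidate selection, in pop1; negative in pop2; the
scan is antisymmetric under swapping the populations.

**p-values.** Both standardized scores are treated as approximately
standard normal and reported as `-log10(2(1 - Φ(|z|)))`. The genome-wide
significance line is the Bonferroni value `-log10(α/M)`; for α = 0.05 and
M = 1.3 × 10⁶ SNPs this is 7.4, the conventional line for resequencing
panels of that size. Candidate SNPs must exceed the line strictly.

**Weir–Cockerham F_ST.** Per-SNP variance components a (among
populations), b (among individuals within populations) and c (within
individuals) follow the 1984 estimator for two populations, computed from
per-population sample sizes, allele frequencies and heterozygote
fractions; θ = a/(a+b+c), undefined (NaN) where the site is monomorphic
overall. Windows use the weighted ratio-of-sums estimator
`Σa / Σ(a+b+c)`; negative per-SNP components are retained so window sums
stay unbiased. Sliding windows are 1-based inclusive, anchored at
position 1, truncated at the chromosome end: 250 kb / 25 kb step for
F_ST, 250 kb / 10 kb for π.

## Quality control

The site filters run in a fixed order — indels, >2 alleles, QUAL < 30,
site call rate < 0.90, mitochondrial contigs (label list, default
`MT`), Hardy–Weinberg exact p < 1e-9, MAF < 0.05 — with the last two
evaluated within each population and a site surviving only if it passes
in *every* population. Each removed site is charged to the first filter
it fails, so the report reconciles exactly with input/output counts. All
thresholds are strict inequalities: boundary values pass. Missing QUAL
(`.`) passes the QUAL filter; whether QUAL means site quality or genotype
GQ is ambiguous in this kind of pipeline description — site QUAL is
assumed.

The Hardy–Weinberg test is the exact conditional test (Wigginton-style):
conditioning on the observed allele counts, the null probability of each
possible heterozygote count (same parity) is computed and the p-value
sums all outcomes no more probable than the observed one. This is the
standard genotype-QC test and is exactly checkable by enumeration, which
the tests do exhaustively for all count triples with n ≤ 30.

Sample-level QC removes individuals with genotype call rate below 0.80,
then prunes relatives: method-of-moments P(IBD=0/1/2) per pair from
identity-by-state counts versus their expectations under pooled allele
frequencies (the PLINK `--genome` construction, probabilities clamped to
[0,1] and renormalised), PI_HAT = P(IBD=2) + P(IBD=1)/2. Pairs exceeding
PI_HAT 0.5 are resolved greedily from the highest PI_HAT down, removing
the lower-call-rate member (ties: lexicographically later id). Greedy
removal does not guarantee a minimum vertex cover — a triangle of three
mutually related samples loses two members — which matches how
relatedness pruning is done in practice. Pairs with fewer than 50
informative SNPs are flagged unstable rather than dropped.

Haplotype scans require phased, fully called genotypes. The pipeline
imputes nothing: phasing is an upstream precondition on real data (the
simulator emits phased, complete haplotypes), and the scan stage errors
on unphased input rather than guessing.

## The simulator

A discrete-generation forward Wright–Fisher model on binary haplotypes,
chosen over a coalescent because hard sweeps with selection are simplest
to condition forward in time. Each generation, every offspring draws a
parent for each gamete through a cumulative-weight inverse-CDF (uniform
weights when neutral — so the neutral and s = 0 paths consume the RNG
identically and are exactly comparable); each gamete is a
single-crossover recombinant with probability `min(1, r·L)`, breakpoint
uniform — adequate to produce the rapid r² decay over tens of kb that
these panels show, at desk scale (N ≤ 500, L ≤ 2 Mb). Mutations are
infinite-sites: `Poisson(2NLμ)` new derived alleles per generation at
unused positions; the founder allele is ancestral by construction, so
simulated panels always carry polarity (`ancestral_known`). Monomorphic
sites are dropped at emission, matching the shape of post-QC input.

Burn-in is 4N generations from monomorphic founders, which brings
pairwise diversity to ≈ (1 − e⁻²) ≈ 86% of the 4Nμ equilibrium — the
tests budget for this. Defaults (N = 200, μ = 1.25e-6/bp, r = 1e-6/bp,
L = 1 Mb, 60 sampled diploids per population — within the 56–124 range
typical of per-strain resequencing panels) put π near 8.6 × 10⁻⁴ and
decay r² to background well inside 100 kb, the magnitudes typical of
recently diverged farmed-fish strains; a split of 18 generations at
N = 200 gives pairwise F_ST ≈ 1 − e^(−t/2N) ≈ 0.045.

Sweeps inject the derived allele on haplotype row 0 (exchangeable, no RNG
consumed) at the configured site right after burn-in and evolve it with
multiplicative fitness (1+s) per copy until its frequency reaches
`sweep_target_freq` (default 0.8); runs that lose the allele restart from
the injection snapshot with a fresh RNG stream, up to 1,000 restarts
(unbiased enough at s ≥ 0.1, bounded runtime). In multi-population mode
the burn-in pool is split first and the sweep runs in one population
while the others drift in lock-step, which yields the pop1-versus-pop2
contrast Rsb is designed for; the realized frequency, generation count
and restart count are returned as ground truth. Splits with no sweep
evolve each daughter population independently for `split_generations`
generations with no migration; an optional pre-split snapshot panel is
available as a stand-in for a wild reference, though no analysis here
uses one.

What the simulator does **not** emulate: migration and admixture between
strains, multiple origins (the real strains are composites of several
GIFT-derived lineages), genotyping error, missing data, multi-chromosome
linkage (one chromosome per run; concatenate runs for more), or variable
recombination. Passing tests therefore demonstrate correctness of the
statistics and the detectability of clean hard sweeps on neutral
backgrounds — not robustness to admixture or data artefacts in real
panels.

## Candidate regions and genes

Scan SNPs above the threshold seed intervals of 250 kb total width
(±125 kb — the "250 kb around each SNP" convention is read as total
width, consistent with the 250 kb LD-derived window used for the
statistics; the ±250 kb reading is selectable). Intervals merge within a
method + population, never across methods, so cross-method agreement is
computed on gene sets (7-cell Venn counts), not intervals. F_ST
candidates are the top 0.5% of defined windows (ties at the cutoff all
included, ceil rounding) merged into regions, attributed to the
population *pair* — the F_ST contrast cannot say which member is under
selection. Genes intersect a region on ≥ 1 bp closed-interval overlap
(adjacency is not overlap). Variant effects use three interval classes
only — exonic, intronic (in gene, outside exons), intergenic — ignoring
strand and UTR subtypes.

## Numerical and scale choices

* EHH kernels are numba-compiled; haplotype classes are tracked as
  integer labels refined site by site, so a full scan is
  O(sites × carriers × decay length).
* Tie-breaks are all deterministic (documented above), and every pipeline
  output is written with fixed float formatting, so a rerun with the same
  seed is byte-identical.
* Windows with no polymorphic SNPs are NaN and excluded from ranking;
  monomorphic sites give He = Ho = 0, π = 0, and are skipped in LD pairs.
* PCA mean-imputes missing genotypes per site (that operation only),
  centres at 2p̂ and scales by √(p̂(1−p̂)).
* Test problem sizes are desk-scale by design: neutral calibration panels
  of ≥ 20k SNPs (N = 100, 100 diploids), sweep-detection replicates at
  N = 200 with s = 0.5 (a 500 kb sweep chromosome concatenated with
  neutral chromosomes of identical demography, so the standardization
  bins are dominated by neutral sites as they would be on a genome-scale
  panel; r = 2e-6 keeps rL = 1, the single-crossover model's domain, and
  the hitchhiking footprint inside the ±50 kb localisation window), and
  split recovery at t/2N = 0.045. The package's statistics are exact
  (oracle-checked to 1e-12); only the simulation-based properties carry
  Monte-Carlo variability.
* Method-of-moments IBD on a single short chromosome is high-variance
  (few independent genealogies), so desk-scale demos prune noticeably
  more "relatives" than a genome-scale panel would; PI_HAT is reliable
  in the regime it is used for in practice — many SNPs across many
  chromosomes.

## Known limitations

* The iHS null at desk-scale sample sizes is only approximately normal;
  occasional genealogical outliers (an old, unbroken haplotype at modest
  derived frequency) can exceed any fixed line — see the calibration
  test for how this is bounded.
* No interval estimation for F_ST (the bootstrap CI of the windowed
  estimator is omitted rather than guessed).
* No genetic-map support, no XP-EHH/nSL, no multi-allelic cores, no
  imputation/phasing, no admixture modelling.
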