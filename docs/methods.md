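# Methods

## Data model

A band matrix holds binary presence calls for N accessions at L scored
fragment positions (loci), each locus belonging to exactly one primer.
Missing calls are permitted on input (tokens `.`, `NA`, empty) and are
excluded locus-wise from frequency computations; `--require-complete`
rejects incomplete matrices instead. Loci whose band appears in no
accession (monomorphic-absent) are retained in the matrix and count
toward the locus total, but are not treated as "bands of the primer" in
the per-primer statistics; this distinction is what lets population-level
allele numbers fall below 1 for band-poor groups (see below).

## Marker informativeness

For band frequency f at a locus (the fraction of non-missing accessions
carrying the band): PIC = 2f(1−f), which is the two-state gene diversity
and is capped at 0.5; a primer's PIC is the unweighted mean over its
amplified loci. The effective multiplex ratio is EMR = n·β with
β = PB/(PB+MB). The definition of n ("mean number of fragments amplified
per primer") is ambiguous across the literature; the default takes n as
the primer's own fragment count (making EMR = PB), and
`emr_n="global_mean"` switches to the matrix-wide mean fragment count
per primer. MI = EMR·PIC exactly. RP sums Ib = 1 − 2|0.5 − p| over the
primer's bands. The band-state allele statistics treat each locus as a
two-state system with frequencies (p, 1−p): Na is 2 for polymorphic and
1 for monomorphic loci — hence the identity Na = (2·PB + MB)/(PB + MB)
per primer — Ne = 1/(p² + q²), H = 2pq, I = −(p ln p + q ln q).

Allele frequencies default to the raw band-state ("phenotypic")
estimator. The Hardy–Weinberg dominant-marker estimator
p = 1 − √(1 − p_band) is available (`estimator="sqrt"`), but published
dominant-panel tables are numerically consistent with the phenotypic
convention (a locus at band frequency 0.5 printing H = 0.50 is possible
only under it), so it is the default.

## Population diversity

Within a group, each locus contributes by its within-group band
frequency p. The zero-allele convention governs loci whose band the
group lacks entirely: Na contribution 0 (2 if polymorphic, 1 if fixed
present), Ne contribution 0, He and I contribute 0. Group values are
means over **all** loci in the dataset, so a group carrying few of the
panel's bands can show Na well below 1 — the behaviour published
dominant-marker diversity tables exhibit. The Ne convention for
all-absent loci is not standardized across programs (a contribution of 1
is equally defensible and matches some published tables more closely);
we report Ne under the zero convention and treat published Ne columns as
approximate. Private bands (Pb) are bands present in a group and absent
in all others, computed on the full locus set; genotype-specific loci
are the individual-level analogue (band carried, or lacked, by exactly
one accession).

## Distances and trees

Nei's standard genetic identity between frequency profiles counts both
band states: Jxy = mean(x·y + (1−x)(1−y)) and D = −ln(Jxy/√(Jx·Jy)).
Individual accessions enter with their raw 0/1 vectors as frequency
profiles, the convention that makes an accession-level Nei matrix well
defined for dominant data (a presence-only variant is available;
both-states is the default). The band-mismatch (squared Euclidean)
distance Σ(x−y)² is the AMOVA/PCoA input. With missing calls, pairs use
pairwise-complete loci rescaled by L/L_complete. UPGMA is size-weighted
average linkage (via scipy's `linkage(method="average")`); node height
is half the merge distance, so trees are exactly ultrametric, and
Newick export carries branch lengths.

## AMOVA and PhiPT

One-level AMOVA partitions pairwise squared distances:
SS_total = Σ_{i<j} d²_ij/N, SS_within = Σ_g Σ_{i<j∈g} d²_ij/n_g — the
standard identity equating these to centroid sums of squares is the test
oracle. df = (G−1, N−G), n0 = (N − Σn_g²/N)/(G−1),
Va = (MS_among − MS_within)/n0 (negative values truncated to 0 with a
warning), Vw = MS_within, ΦPT = Va/(Va+Vw). Significance: free
permutation of individuals among groups with sizes fixed (999 by
default) and the add-one estimate p = (1 + #{Φ* ≥ Φ})/(1 + P). Because
Va is truncated at 0, permuted and observed statistics tie at 0 under
weak structure, making the test slightly conservative (measured type-I
error ≈ 0.03–0.05 at α = 0.05).

## PCoA

Classical metric scaling: B = −½·J·D²·J with the centering matrix J,
eigendecomposition of the symmetrized B, coordinates scaled by √λ for
eigenvalues above a relative tolerance of 1e−9. When the input matrix
carries the `squared-euclidean` tag its entries are used as D² directly
(the band-mismatch matrix is already squared). Negative eigenvalues are
counted and excluded from the percent-variance denominator; axis signs
are fixed by making the largest-magnitude loading positive.

## Admixture model

Haploid binary-locus mixture: q_i ~ Dirichlet(α,…,α) over K clusters,
f_kl ~ Beta(λ, λ), z_il ~ Categorical(q_i), x_il ~ Bernoulli(f_{z_il,l});
α = λ = 1 fixed. Bands are modelled as haploid phenotypes rather than
through a diploid dominant/recessive layer — the matrix is scored as
phenotypes, and for mixed-ploidy germplasm a diploid model would be no
less wrong. The Gibbs sampler updates z, then f (Beta conjugacy), then
q (Dirichlet conjugacy) each sweep; the numba-compiled kernel records
the data log-likelihood Σ_il ln Σ_k q_ik·f^x(1−f)^{1−x} each post-burn-in
sweep, and Q and F are posterior means over recorded sweeps. Missing
calls contribute nothing to f updates or the likelihood.

Chains are initialized from a seeded k-means++ clustering of the band
profiles (missing values imputed to locus means), with initial cluster
frequencies taken from the assigned counts; `init="random"` assigns each
accession to a uniform random cluster instead. Symmetry breaking at
initialization matters: started from uniform ancestry and i.i.d. random
frequencies, all clusters are statistically identical and the sampler
can sit on that saddle for thousands of sweeps.

Two properties of this model are worth knowing when reading results.
First, posterior-mean ancestry of even a perfectly pure individual does
not reach 1: Dirichlet smoothing and loci that are uninformative between
clusters leave a shrinkage floor (about 0.07 mean absolute error at
Balding–Nichols divergence 0.4 with ~100 loci). Second, clusters
represented by very few accessions are identifiable only at high
divergence: with frequencies integrated out exactly, the marginal
likelihood of the ten-group panel design prefers merging the 2–4-member
groups below divergence ≈ 0.4 and separates all five clusters at 0.5.
Both statements are asserted by tests against exact or fixed-point
oracles.

Defaults scale the classical run design down to desk scale: burn-in
5,000 + 5,000 recorded sweeps, 5 runs per K, grid K = 2–8; the classical
100,000-iteration design is reachable through the same flags. Evanno's
ΔK = |L(K+1) − 2L(K) + L(K−1)| / sd(L(K)) uses the per-run posterior-mean
log-likelihood as L(K); with zero run-to-run sd, ΔK is reported missing
rather than infinite, so deterministic toy fixtures do not produce a
spurious best K. Multi-run Q matrices are aggregated by greedy
column-correlation matching to the first run. Accessions with maximum
ancestry below the threshold (default 0.6, boundary inclusive) are
called admixed.

ΔK carries its well-documented bias toward the dominant hierarchical
level on unbalanced designs: the second difference of L(K) peaks at the
last *large* likelihood jump, and per-split likelihood gains scale with
the splitting group's size and tightness. On the ten-group panel
simulation (group masses 17, 8, 6, 4, 2 with clonal groups), ΔK
therefore selects K = 3 or 4 — the levels separating the largest,
tightest blocks — rather than the generative K = 5, even though the
K = 5 mode has higher posterior support and truth-initialized chains
stay in it. The
two-cluster benchmark, where gains are balanced, recovers K and Q
cleanly. Readers applying ΔK to designs with highly unequal group sizes
should expect the same behaviour on real data.

## Synthetic data generator

Cluster band frequencies follow the Balding–Nichols form: ancestral
frequencies p̄_l from a Beta prior (uniform by default), per-cluster
frequencies from Beta(p̄(1−d)/d, (1−p̄)(1−d)/d) so the divergence knob d
acts like an F_ST between clusters. An accession with ancestry vector q
shows a band with probability Σ_k q_k f_kl; clonal groups copy one drawn
parent genotype; symmetric per-call flip noise (default 0.01) emulates
scoring error. One seeded generator stream drives everything, so
fixtures are bit-reproducible.

`rose_panel_config()` emulates a 38-accession oil-bearing rose panel:
ten groups of sizes 8, 5, 9, 4, 2, 2, 2, 2, 2, 2; fifteen primers with
band counts summing to 238; five ancestral clusters (an unidentified
clonal population, R. gallica, a heterogeneous R. damascena breeding
population sharing its cluster with four clonal cultivar pairs, R. alba,
R. centifolia) and one hybrid group with ancestry split 50/50 between
the damascena and gallica clusters. The default divergence is 0.5 —
species-level, inside the regime where the admixture model can identify
even the 2-member groups (see above). What the generator does **not**
reproduce about real dominant-marker panels: ascertainment of reliably
scorable bands (real panels have many fully monomorphic bands, which a
symmetric flip-noise model at any nonzero rate makes vanishingly rare
across 38 accessions), real within-clone somaclonal variation (published
clone pairs differ at 8–12% of loci — under this generator that would
have to be booked as scoring noise), linkage between bands, and
gel-artifact structure. Passing parameter-recovery tests on these
simulations therefore demonstrates correctness of the estimators, not
that any particular real panel satisfies the model.

## Numerical conventions

Frequencies in the generator are clipped to (1e−4, 1−1e−4) so truth
objects satisfy 0 < f < 1. PCoA uses a relative eigenvalue tolerance of
1e−9; UPGMA inherits scipy's deterministic tie handling; Nei identity on
identical inputs returns exactly 0 and raises when a profile has zero
homozygosity sum (identity undefined) or the identity is 0 (infinite
distance). The Gibbs kernel adds 1e−12 to gamma draws to keep sampled
frequencies and ancestries strictly interior. Permutation p-values use
the add-one convention, so the smallest attainable p at 999 permutations
is 0.001. All run seeds derive from user seeds via `SeedSequence` and
stay below 2³¹.

## Problem sizes used in tests

Unit tests run on matrices from 2×1 up to the 38×238 panel. The
acceptance layer uses: 400 null panels (30 accessions, 50 loci, 99
permutations) for the type-I error of the ΦPT test; three seeds of the
two-cluster benchmark (20 accessions, 120 loci, 5,000+5,000 sweeps) for
Q recovery; and five repetitions of the Evanno experiment on the full
panel simulation (K = 2–8, 5 runs × 5,000+5,000 sweeps). These sizes
were chosen so the whole suite runs on a laptop-class single core in
well under half an hour.
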