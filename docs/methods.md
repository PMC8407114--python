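# Methods

## Scope and model

symbionet infers candidate hosts/partners for a focal, uncultivable
microbe (prototypically an ultra-small DPANN archaeon) by combining two
statistically independent evidence lines computed from the same community
data: a compositionality-aware co-occurrence network over marker-gene OTUs,
and a scan for recently transferred genes (xenologs) between the focal
genome and the community's other genomes. Neither line is decisive alone —
co-occurrence is correlational, and a single near-identical gene pair can
be contamination — so hypotheses are ranked lexicographically, dual-evidence
candidates first. We deliberately do not fuse the two signals into one
score: any weighting would be an assertion the data cannot calibrate.

## Basis correlations (SparCC-type estimator)

Sequencing depths are closed (per-sample totals are arbitrary), so Pearson
correlations of raw depths are biased. Let `f_ij` be component *i*'s
fraction in sample *j*. The observable log-ratio variance
`t_ik = Var_j[log(f_ij/f_kj)]` decomposes as
`t_ik = ω_i² + ω_k² − 2 ρ_ik ω_i ω_k` in terms of latent (basis) variances
and correlations. Under sparsity (most pairs uncorrelated), summing over
partners gives a linear system for the `ω_i²`:

    t_i = n_i ω_i² + Σ_{k ∈ kept(i)} ω_k²,

solved exactly by `numpy.linalg.solve`; with no exclusions this reduces to
the familiar closed form `ω_i² = (t_i − W)/(D−2)`, `W = Σ t_i / (2(D−1))`,
which the tests verify on a constructed case. Strong pairs violate
sparsity, so the currently strongest pair with |ρ| above 0.1 is excluded
and the system re-solved, one pair per iteration, up to 10 iterations; a
pair is never excluded if it would leave a component with fewer than two
partners. Negative variance estimates are floored at 1e-12 with a warning;
ρ is clipped to [−1, 1].

Numerical/estimation choices that matter:

* **Fractions.** Point estimate `(count + 1)` column-normalized; optionally
  20 per-sample Dirichlet(count + 1) posterior draws, with t and ρ averaged
  over draws (the default in the pipeline).
* **Structural zeros.** The community generator's zeros mean "organism
  absent", not "sampled zero". A log-ratio is undefined when either member
  is absent, so each pair's `t_ik` is computed over co-observed samples
  only (falling back to all samples below 3 co-observations). Without this,
  pseudocounted absences swamp the signal: in our occupancy-0.8 benchmark
  the planted ρ = 0.9 estimate collapses from ~0.9 to ~0.1.
* **Identifiability.** The variance system needs D ≥ 4 components; the
  estimator refuses smaller tables. Small D remains the fragile regime —
  the default scenario uses 12 OTUs for this reason.

**Significance.** Pseudo-*p* values: each OTU's depths are permuted across
samples independently, the full estimator (including exclusions) is
recomputed, and the two-sided `p_ik` is the fraction of permutations with
`|ρ_null| ≥ |ρ_obs|`, at resolution 1/n_permutations (default 100; p may be
exactly 0). A sanity switch includes the identity permutation, bounding
every p away from 0. Edges require |ρ| strictly > 0.6 (an `inclusive`
switch gives ≥) and p < 0.05. Modules are Louvain communities (resolution
1.0) on |ρ|-weighted edges with a fixed node ordering and seed; the
two-triangle test pins the partition to the exhaustive-search optimum.

## Marker profiling

One rpS3 marker per genome is clustered at 95% global nucleotide identity
by greedy centroid clustering: sequences sorted by decreasing length (ties:
id), each joins the first centroid at or above the threshold, centroids
never reassigned — so clustering is independent of input file order.
Identity counts gap columns in the denominator (match +1/mismatch −1, gap
open −5 for the first gap base, −2 per extension). OTU depth is the sum of
member depths; OTUs observed (depth > 0) in fewer than 6 samples are
dropped before network inference. "Observed" means strictly positive depth,
consistent with structural zeros.

## Alignment kernel

Biopython's `PairwiseAligner` supplies optimal global (Needleman–Wunsch)
and local (Smith–Waterman) alignments: BLOSUM62 with affine gaps (−11 first
residue, −1 extension) for proteins; +1/−1 with −5/−2 gaps for
nucleotides. Identity is computed over all alignment columns including gaps
(the convention BLAST reports as `pident`, which the 70% and 95% thresholds
presuppose). Global alignments are computed in a canonical sequence
orientation so identity(a,b) = identity(b,a) even when co-optimal
alignments place gaps differently. Homology search is exhaustive
(every query against every subject — no heuristic seeding at desk scale)
and reports `score(q,s)/score(q,q)`, a database-size-independent normalized
score in (0, 1]; raw scores below 70 are discarded in the directional
detector, roughly E < 1e-3 under Karlin–Altschul statistics at the database
sizes used here. Without this floor, the dozens of weak random local hits
any protein accrues inflate the group sums and blur the native/transferred
separation. A pure-Python affine-gap dynamic program serves as the oracle
for local scores in the tests.

## Directional HGT calls

For each focal gene, hits are grouped by subject taxonomy: *self* (the
recipient's own lineage labels; dropped), *close* (the designated clade,
e.g. DPANN), *distal* (everything else). Close and distal groups are
summarized as sums of normalized scores over at most 50 hits each. A gene
is called transferred when its close sum is at or below τ_close and its
distal sum at or above τ_distal, and the best distal hit's phylum differs
from the recipient's ("interphylum"); missing phylum labels map to
"unclassified" and never produce calls. Thresholds are fitted per genome
from the score distributions: Gaussian KDE (Silverman bandwidth, 512-point
grid), τ = the density minimum between the first two modes; unimodal
distributions fall back to the 25th (close) / 75th (distal) percentile and
degenerate ones to the constant, with the method recorded in the fit. This
valley rule is this package's own declared procedure — reference tools do
not publish theirs — and is flagged as such in outputs. A descriptive OLS
of transfer count on gene count (with R²) is provided for cross-genome
summaries.

## Recent-transfer (xenolog) scan

Focal proteins are searched against all community genomes outside the close
clade. A pair is a candidate recent transfer when identity ≥ 70% and the
aligned region ≥ 100 amino acids. Two artefact guards: genes on scaffolds
shorter than 5 kb are ineligible, and genes that are first or last on their
scaffold are discarded (mis-assembled or chimeric bin edges mimic
xenologs). Both guards are independent switches; every examined pair above
a 30%-identity reporting floor is returned with explicit reason codes
(LOW_IDENTITY, SHORT_ALIGNMENT, TERMINAL_GENE, …) so filter behaviour is
auditable. An "ancient" transfer planted at 58% divergence is never
retained; that invariant is tested.

## Partner ranking

Candidates are the union of the focal OTU's network neighbours and the OTUs
of genomes contributing passing xenolog pairs (genomes without a marker
cannot enter via the network and appear with transfer-only evidence). Sort
key, descending: (dual evidence, number of passing pairs, |ρ|, best pair
identity), with OTU id as the deterministic tie-break. Each hypothesis also
carries the Pearson r and r² of the two OTUs' depths over co-observed
samples (an `all`-samples mode is available; the two agree at full
occupancy) and the candidate's abundance rank in the focal OTU's best
sample — reported, but never used in ranking, since its evidential status
is unclear.

## Synthetic data: what it emulates, and what it does not

`generate_community` draws log-abundances from a multivariate normal whose
correlation matrix carries the planted pairs (a Gaussian copula on the log
scale; non-PSD plants are rejected with a diagnostic), applies independent
per-OTU occupancy draws (structural absences), closes each sample to
fractions, and scales to counts by a multinomial at the configured read
depth. Defaults mirror the target study design: 88 samples, occupancy 0.8,
read depth 1e5, one strong planted pair (0.9) plus a weaker decoy (0.8,
with the implied third correlation 0.72 to keep the matrix consistent).

`generate_genomes` lays genes left-to-right with a configurable overlap
fraction, plants the 54 single-copy markers as reference proteins mutated
at 35% per genome (so shared markers sit far below the 70% xenolog
threshold, as real inter-phylum orthologs do), one rpS3 nucleotide gene per
genome (group-wise references; within-group copies ~99% identical, between
groups far below 95%), and HGT events by copying a donor protein and
substituting exactly `round(L·divergence)` positions, never back to the
original residue — so expected identity is analytic (202 residues at
divergence 22/202 give exactly 180/202 = 89.1%). All randomness flows from
one master seed through named substreams; identical configs are
byte-identical.

Not emulated: read-level noise (FASTQ), assembly/binning errors, GC or
codon structure in coding regions, within-population strain variation,
phylogenetic signal in protein sequences (random proteins have no shared
ancestry, so the detector benchmark is easier than real data on the
"native gene" side), and depth estimation error from read mapping. Passing
tests therefore demonstrate correctness of the inference machinery under
the stated generative model, not performance on real assemblies.

## Problem sizes and defaults

The packaged study conditions: default scenario with 12 genomes
(~30–45 genes each), 88 samples, 100 permutations, 20 Dirichlet resamples;
detector benchmark with a 100-gene focal genome, 10 planted transfers at
15% divergence, and a 400-protein reference. Replicate-level checks run 20
seeds. These sizes keep a full test run in a few minutes on one core while
leaving every estimator in its intended regime.

## Known limitations

* The valley-rule threshold fit assumes at least 20 genes and separable
  score modes; genomes whose transferred fraction approaches 50% would
  blur the valley.
* Pseudo-*p* resolution is 1/n_permutations; at 100 permutations the
  0.05 threshold sits at 5 discrete null exceedances, so borderline edges
  flicker between seeds.
* The basis estimator remains noisy for D below ~10 components and can
  produce clipped |ρ| = 1 under permutation at very small D.
* Genome→OTU mapping requires the marker to survive the occurrence filter;
  a host absent from the marker table can only ever appear with
  transfer-only evidence.
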