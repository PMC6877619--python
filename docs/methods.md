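# Methods

`hicarch` implements a comparative analysis of binned Hi-C contact maps as
used to contrast the three-dimensional architecture of a dosage-compensated
X chromosome between sexes in *Drosophila*: matrix balancing and
downsampling, interaction-decay statistics, a non-parametric comparison of
top-scoring interactions, a trans-contact propensity null model, the Local
Score Differentiator (LSD) boundary caller with a boundary-class comparison,
insulation scores, and feature/insulator enrichment and pile-up analyses.
A synthetic contact-map generator with known ground truth provides the test
surface for every stage.

## Contact matrices and balancing

Matrices are stored as upper-triangle triplets over a dense genome-wide bin
table (0-based half-open intervals; the last bin of a chromosome may be
short). Iterative correction assumes factorizable per-bin biases
(`balanced = raw / (bias_i * bias_j)`) and equalizes per-bin marginals,
either per chromosome on cis blocks only or genome-wide including trans
blocks. Defaults follow common practice for fly Hi-C at these resolutions:
bins with a marginal below 40 counts are masked, the two shortest-range
diagonals (distances 0 and 1 bin, dominated by self-ligation and re-ligation
artefacts) are zeroed before balancing, and iteration stops at tolerance
1e-2. The convergence metric is the relative spread `(max - min) / mean` of
unmasked marginals, checked before each update, so a matrix already at
tolerance is a fixed point; the iteration cap is 1000, exceeded only on
pathological input (then an error reports the last spread). Masking uses the
marginals of the matrix actually balanced, i.e. after removing the excluded
diagonals.

Degenerate-input remark: a block whose *off-diagonal* entries are all equal
is **not** a fixed point when short-range diagonals are excluded, because
edge rows lose fewer excluded cells than interior rows and therefore start
with larger marginals; only a fully uniform block with no exclusions is.
Relatedly, balancing raises the values of the first and last few bins of a
chromosome (their raw marginals lack short-range partners beyond the
chromosome end); on the short chromosomes used in simulation studies this
edge inflation is a visible artefact (see "Top-scoring interactions" below).

Two downsampling procedures mirror the two coverage-matching strategies
used when comparing sexes: independent binomial thinning of every count
(default p = 0.5, emulating a halved copy number) and per-chromosome
matched thinning of cis counts to a reference sample's cis totals
(chromosomes already at or below the reference are left unchanged). Both
are reproducible from a seed.

## Decay of contact frequency with distance

Per chromosome, the decay curve is the median normalized value at each
diagonal from 2 to 100 bins. Structurally absent sparse cells count as
zeros, extending the convention that non-finite values are set to 0; this
makes sparse and dense inputs agree exactly. Balanced values are converted
to contact frequencies by dividing each chromosome's cis entries by its own
median value at 2-bin distance (the first informative diagonal), anchoring
the frequency scale at 1 there. The decay slope is an ordinary
least-squares fit of log10(median) on log10(distance in bp) over 2-15 bins,
the range where the decay is close to linear in the log-log plot; zero
medians are dropped with a warning, and the fit needs at least three
positive points. Pairwise slope differences Δ(a, b) = slope_a − slope_b
form an antisymmetric table; the chrX-vs-autosome contrast is a two-sided
rank-sum test (Mann-Whitney U, exact for small tie-free samples) of
{Δ(chrX, autosome)} against {Δ(autosome, autosome)} over unordered pairs.
Cumulative decay curves (cumulative sum of median frequencies divided by
its final value) are compared by Kuiper's statistic
`V = max(cdf_a − cdf_b) + max(cdf_b − cdf_a)`, with each maximum floored at
0 so that one-sided dominance yields the single-sided gap.

## Top-scoring interactions

For each cis diagonal at distance ≥ 2 bins, cells strictly above the
diagonal's 95th percentile (linear-interpolation convention, computed over
the full diagonal including implicit zeros) are selected. Being
per-diagonal and rank-based, the selection is invariant to the decay curve
and to global coverage. Strictly-greater thresholding means constant
(e.g. all-zero) diagonals select nothing. Selected points are single-linkage
clustered under Euclidean distance in bin coordinates scaled by the bin
size; at the default 25-kb link distance and 25-kb bins only immediate
neighbours link. The summary statistic is the fraction of points in
clusters of size ≥ 2, and differences of this fraction between samples.

Parameter-recovery tests of this stage run on the generator's output used
directly as normalized signal: synthetic maps carry no bin biases by
construction, and running iterative correction on a short synthetic
chromosome would only inject the edge-inflation artefact described above
(edge bins receive ~1.4-fold corrections and then deterministically top
every diagonal, swamping the planted structure). Real data, with genuine
biases and thousands of bins per chromosome, is balanced first as usual.

## Trans-contact propensity

Counting each read pair once per involved chromosome, the expected trans
contacts from origin a to target b under the uniform null are

    E(a, b) = (c_b * l_b) / sum_{b' != a} (c_b' * l_b') * T_a

with c the copy number, l the chromosome length and T_a the observed trans
total of a. Row sums of the expectation reproduce the observed totals
exactly. The propensity table is log2(observed / expected); it need not be
symmetric, because the normalizing denominator depends on the origin.
Zero observed counts yield a −inf sentinel plus an explicit flag.

## LSD boundary calling

The directionality index (DI) per bin contrasts the summed contact signal
over 10 bins upstream (A) versus downstream (B): with E = (A + B)/2,
DI = sign(B − A) * ((A − E)² + (B − E)²) / E, zero when A = B and undefined
when E = 0 or the window leaves the chromosome. Forward and backward first
differences of DI capture changes of direction. Within a sliding window of
±25 bins, Tukey fences select local outliers: a domain start requires a
finite DI, ΔDI_forward ≤ Q25 − 1.5·IQR of the window's forward deltas, and
ΔDI_forward ≤ DI; a domain end symmetrically with the backward deltas and
the upper fence. Quantiles use linear interpolation; windows truncate at
chromosome ends. When a window is perfectly tied (IQR = 0) the fences
degenerate to the tied value and the printed inequalities would fire on
constant tracks, so a call then additionally requires a strictly negative
forward delta (starts) or strictly positive backward delta (ends). The
optional strict mode adds DI ≤ 0 at starts and DI ≥ 0 at ends; the optional
gap filling moves the start of the following domain to end + 1; both are
off by default.

Unique domain-end bins, extended half a bin to each side across the
junction to the following bin, give one-bin-wide boundary regions; a
boundary's identity is its junction bin. Because the backward-delta outlier
peaks where DI jumps from negative to positive — the first bin of the
downstream domain — called junctions typically sit one bin downstream of
the physical junction; the shift is consistent across samples, so exact
junction matching between samples remains meaningful, and recovery against
simulation truth is scored within ±1 bin. Two samples' boundary sets are
compared by exact junction match: present in both = same, male-only =
appearing, female-only = disappearing; the non-matching fraction is
1 − |same| / |union|. The three classes partition the union by
construction.

The insulation score per bin is the mean of the 10×10 square of values
between the 10 bins upstream and the 10 bins downstream (all at distance
≥ 2, so excluded diagonals never contribute), skipping 10 bins at each
chromosome end, normalized by the chromosome mean; a boundary's score is
the mean of the two bins flanking its junction.

## Feature analyses

Point features are assigned to the bin containing their midpoint.
Enrichment around boundary classes uses windows of up to 15 bins per side
centred on the junction coordinate, with the intervening region split
equally at the midpoint between neighbouring boundaries so windows are
disjoint; the null expects N/L sites per bin (N sites on the chromosome, L
its length in bins) and the result is log2(observed density / expected).
Insulator combinatorics take the maximum 99th-percentile-scaled ChIP signal
within each boundary region as that factor's summit (callers comparing two
sexes pass the per-interval maximum of the two samples), threshold at 0.5 —
the midpoint between the modes of the bimodal summit distribution — and
classify: (i) BEAF-32 high with CP190 or Chromator high; (ii) exactly one
side high, including the case of both CP190 and Chromator high without
BEAF-32; (iii) all low.

Aggregate pairwise (pile-up) profiles average, over anchor pairs (i, j)
satisfying n ≤ i ≤ D−1−n and i + 2n < j ≤ D−1−n (0-based, default n = 20),
the (2n+1)² window around (i, j) divided by the mean of its (2(n+1)+1)²
background window, log2-transformed. The background window is deliberately
only one bin larger per side, as specified for this procedure; a
config-level override is available. Cells that are zero before the log2
become −inf and are set to 0, extending the non-finite-to-zero convention;
a constant matrix therefore yields an identically zero profile.

4C fragment values are binarized (1 if any replicate has a read) after a
probe-level QC pre-filter on a read-count manifest (≥ 2-fold replicate
depth difference discards the probe; > 1.5-fold cross-sample difference
likewise). The enrichment at fragment midpoint m is
log10(Σ v in ±20 kb / Σ v in ±600 kb + 1), defined for midpoints at least
600 kb from either chromosome end; a zero background sum leaves the value
undefined and flagged. Boundary metaprofiles map fragments to contact-map
bins (bin value = mean enrichment of its fragments), re-index by offset
from the bin containing each junction, and average per offset across the
boundaries of a class, with a ±35 kb (or ±7 kb) scalar summary.

TSS-boundary association maps every gene — active or not — to its nearest
boundary junction, drops pairs at ≥ 10 kb, keeps per boundary only the
closest gene, and removes low/no-expression genes last, so inactive genes
take part in the nearest-neighbour competition and cannot be displaced by a
more distant active gene.

## Synthetic data generator

The generator emulates the regimes the analyses are designed for. Expected
cis intensity is λ(i, j) ∝ d^α (distances 0 and 1 bin set to 0, mirroring
the analysis-side exclusion) times a TAD factor: pairs within one effective
TAD receive `intra_tad_boost`, pairs crossing boundaries are attenuated by
the product of (1 − strength) over crossed junctions. A strength-0 boundary
does not segment TADs and leaves the intensity untouched, so strength 0
means fully open and strength 1 full block separation. Boundaries are
recorded at bin junctions (between bin b and b + 1), matching the boundary
caller's convention. Counts are Poisson — the minimal noise model; an
overdispersion knob is left as a configuration extension — with the
chromosome total scaled to `coverage * copy_number / 2`, i.e. `coverage` is
the expected cis total at the diploid state and a single-copy chromosome
receives half of it. Trans counts are Poisson, uniform over trans bin pairs
weighted by the product of copy numbers, with total set by the trans
fraction. Feature tracks place a chosen fraction of site midpoints within a
maximal offset of randomly chosen true junctions and the rest uniformly.
The matched sex pair re-draws the female spec with chrX at copy number 1, a
chrX decay exponent shifted by a chosen delta, and selected boundary
strengths set to 0; autosomes are statistically identical. All generators
are pure functions of (spec, seed).

What the generator does not emulate: fragment-level biases (GC,
mappability, restriction-site density) — so balancing on synthetic maps
corrects only edge effects; focal loop/peak anchors — top-scoring
clustering contrast arises from boundary-crossing intensity contrast, not
from planted loops; overdispersed noise; and polymer-physics realism
(homolog pairing, compartments). Passing tests therefore demonstrate
correctness of the statistics and recovery of planted decay/boundary/
coverage parameters, not robustness to every artefact of real libraries.

## Problem sizes and default study conditions

Parameter-recovery checks use sizes at which every stage's behaviour is
already asymptotic while the whole suite stays interactive: decay-slope
recovery on a 200-bin (5 Mb at 25 kb) chromosome at 5×10^5 cis pairs,
exponents {−0.8, −1.0, −1.2}, three seeds each, recovered within ±0.05;
the sex-pair contrast on five 200-bin arms with a +0.11 chrX exponent
shift, recovering the mean chrX-vs-autosome delta within [0.06, 0.16] with
rank-sum p < 0.05; LSD recovery on a 140-bin (3.5-kb) chromosome with 10
planted boundaries at strength 0.8, boost 2.0 and 250 reads/bin, five
seeds, scoring TPR ≥ 0.8 at FDR ≤ 0.2 within ±1 bin; enrichment
calibration on a 2000-bin chromosome with 10 boundaries, 200-400 sites and
a 200-shuffle permutation null.

## Known limitations

- The DI-based end calls carry the one-bin downstream shift described
  above; absolute junction coordinates are conventional, comparisons
  between samples are not affected.
- Exact-match boundary comparison is deliberately strict: one-bin jitter
  between samples produces an appearing/disappearing pair rather than a
  match, as in the original exact-intersection definition.
- Iterative correction near chromosome ends inflates edge bins; analyses on
  very short chromosomes should mask or disregard the first and last few
  bins.
- Balancing is dense per chromosome internally; genome-wide scope builds
  the full dense matrix and is intended for genomes up to a few thousand
  bins per run, ample for the simulation scales above.
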