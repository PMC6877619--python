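# hicarch

Comparative Hi-C architecture toolkit: quantify how two samples — typically
male and female *Drosophila*, where dosage compensation leaves the single
male X chromosome structurally distinct — differ in contact-decay
behaviour, interaction patterning, trans-contact propensity, and structural
domain boundaries, at desk scale and with synthetic ground truth for every
stage.

It is aimed at chromatin-architecture researchers who work with binned
contact matrices (triplet TSV + bin table) and point/signal feature tracks
(BED / bedGraph), and who need copy-number-robust statistics rather than
genome-wide-thresholded TAD callers.

## What it computes

- **Balancing and downsampling** — chromosome-wise or genome-wide iterative
  correction (marginal equalization under `balanced = raw / (bias_i bias_j)`;
  marginal floor 40, first two diagonals excluded, tolerance 1e-2), binomial
  thinning (p = 0.5 emulates a halved copy number) and per-chromosome
  matched thinning to a reference sample's cis totals.
- **Decay statistics** — per-distance median contact frequency, log-log
  slope over 2-15 bins, pairwise slope deltas Δ(a,b) = slope_a − slope_b, a
  rank-sum test of chrX-vs-autosome deltas against autosome-pair deltas,
  cumulative decay curves and Kuiper's statistic
  V = max(cdf_a − cdf_b) + max(cdf_b − cdf_a).
- **Top-scoring interactions** — per-diagonal 95th-percentile selection
  (coverage- and decay-invariant), single-linkage clustering at a 25-kb
  link distance, and the clustered-fraction difference between samples.
- **Trans propensity** — E(a,b) = (c_b l_b) / Σ_{b'≠a}(c_b' l_b') · T_a and
  the log2 observed/expected table.
- **LSD boundary calling** — directionality index (window 10 bins), its
  forward/backward differences, Tukey-fence outliers in a ±25-bin local
  window, boundary regions at domain-end junctions, same / appearing /
  disappearing classification by exact junction match, and Crane-style
  insulation scores (10-bin square window, chromosome-mean normalized).
- **Feature analyses** — site enrichment around boundary classes under a
  uniform null, combinatorial insulator classes (BEAF-32 × CP190/Chromator
  at a 0.5 scaled-signal cutoff), aggregate pairwise pile-up profiles, 4C
  window enrichment (±20 kb over ±600 kb, log10 with pseudocount), and
  TSS-to-boundary association.
- **Synthetic maps** — power-law decay with planted TAD boundaries of
  tunable insulation strength, copy-number-scaled Poisson coverage, uniform
  trans contacts, co-located feature tracks, and matched female/male map
  pairs — all pure functions of (spec, seed).

See `docs/methods.md` for the full model descriptions and conventions.

## Worked example

Simulate a small two-chromosome genome with three planted boundaries on X,
balance it, and run the decay and boundary analyses:

```python
import hicarch as h

g = h.GenomeModel([("2L", 3_500_000, 2), ("X", 3_500_000, 2)], bin_size=25_000)
spec = h.SimSpec(genome=g, decay_exponent=-1.0, coverage=3e5,
                 tad_boundaries={"X": [(30, 0.8), (60, 0.8), (100, 0.8)]},
                 intra_tad_boost=2.0, trans_fraction=0.05, seed=3)
mat, truth = h.simulate_contact_map(spec)

bal = h.ice_balance(mat)                      # chromosome-wise ICE
freq = h.to_contact_frequency(bal)
fits = {c: h.fit_decay_slope(cv) for c, cv in h.decay_curve(freq).items()}
print({c: round(f.slope, 3) for c, f in fits.items()})
# {'2L': -0.992, 'X': -1.046}

bounds = h.call_domains(bal)["X"]
print(bounds.junctions)
# [ 31  61 101]
```

The fitted slopes recover the planted decay exponent −1.0 (the X estimate
is pulled slightly by its TAD structure), and the called boundary junctions
sit at the planted junctions 30/60/100 — the delta-DI outlier localizes at
the first bin of the downstream domain, one bin after the physical
junction, consistently across samples.

The same pipeline is scriptable from the shell:

```sh
hicarch simulate --config sim.json --seed 3 --prefix sim
hicarch balance --matrix sim.triplets.tsv --bins sim.bins.tsv --out bal.tsv
hicarch lsd --matrix bal.tsv --bins sim.bins.tsv --out boundaries.tsv
hicarch compare --female boundaries_f.tsv --male boundaries_m.tsv --bin-size 25000
```

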