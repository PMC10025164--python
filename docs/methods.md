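# Methods

This note documents the statistical model, the processing rules, the
defaults and the numerical choices implemented in `lysoenrich`, and what the
synthetic-data tests do and do not demonstrate.

## Input model

One quantification observation is a (protein, cell line, replicate) row
carrying a SILAC heavy/light ratio (or an already-oriented SPIONs/control
ratio), an iBAQ intensity and a unique-peptide count. The study design says
which SILAC channel received SPIONs in each replicate; label switching
(SPIONs in the light channel for half the replicates) cancels labelling
bias. Sentinel ratios — by default 100 and 0.01 — are arbitrary codes for
proteins detected in only one channel, not measurements, and are treated as
such throughout.

## Ratio processing

1. **Orientation.** SPIONs/control = H/L in heavy-SPIONs replicates and
   1/(H/L) in light-SPIONs replicates. Already-oriented reported ratios pass
   through unchanged. Sentinels remain codes: a heavy/light sentinel in a
   light-SPIONs replicate swaps direction (high ↔ low); for the default
   reciprocal sentinel pair this coincides with exact reciprocal arithmetic.
2. **Normalization.** Ratios are log2-transformed and the median of the
   valid values of each (cell line, replicate) column is subtracted.
   Sentinels and missing cells are excluded from the median: sentinel codes
   carry no magnitude information. After normalization the per-column median
   of valid values is 0 — exactly for odd column sizes, to one floating-point
   ulp (~1e-16) for even sizes, where the median is the mean of the middle
   pair.
3. **Pooling.** Per (protein, cell line), the median across replicates
   (configurable to the mean; the median was chosen for robustness and
   consistency with the other medians in the procedure). Proteins need at
   least `min_valid_replicates` (default 3) valid values; failing that, a
   protein with that many same-direction sentinel observations is tagged
   extreme HIGH/LOW, and anything else is dropped with a logged reason.
   Mixed finite/sentinel proteins fall back to their finite values whenever
   those alone satisfy the filter — sentinel codes never override actual
   measurements.
4. **Extreme substitution.** Per cell line, extreme-HIGH proteins receive
   the maximum finite pooled ratio of that cell line and extreme-LOW the
   minimum ("most extreme value observed in the dataset", interpreted per
   cell line because all downstream statistics are per cell line). Tags are
   retained so the scoring stage can force posteriors.

## Mixture model and enrichment calls

Pooled non-extreme values of one cell line are modelled as a two-component
univariate normal mixture fitted by EM. Starting values expand the published
scalar settings to two components: μ = (0, 0.5), σ = (1.1, 1.1),
λ = (0.5, 0.5); the E-step uses λ-weighted densities (computed in log space
with log-sum-exp), the M-step uses weighted moments, iteration stops when
the absolute log-likelihood change drops below 1e-8 (default) or after 1000
iterations. Standard deviations are clamped at `sigma_floor` (1e-6); a clamp
active at exit marks the fit non-converged. Components are relabelled after
fitting so that the enriched component has the larger mean (ties broken by
the larger σ). The log-likelihood trace is retained; EM theory guarantees it
is nondecreasing, and tests assert this with 1e-10 slack for accumulated
rounding.

The per-protein posterior is the unweighted density ratio
φ₂/(φ₁ + φ₂) — deliberately ignoring the mixing weights, which matches the
procedure this package re-implements; the λ-weighted responsibility is
available via `weighted=True`. The quantity fed to Benjamini–Hochberg is
p = 1 − posterior by default, keeping the posterior as the single ranking
statistic; the upper-tail probability under the background component
(`p_mode="background_tail"`), which is a calibrated p-value under the
background null, is available as an alternative. Enrichment is called at
q ≤ α (default 0.05, inclusive; a strict `<` comparison is available).
Extreme-tagged proteins are excluded from both the fit and the BH input;
their posterior/p/q are forced to 1/0/0 (HIGH) or 0/1/1 (LOW), and their
enriched flag is forced accordingly even at degenerate α.

Note that 1 − posterior is not uniformly distributed for background
proteins, so the BH-adjusted q values control a ranking-based criterion
rather than a frequentist FDR in the strict sense; with the default
parameters this makes the call threshold conservative (the effective
posterior cutoff lands near 0.995). This is a property of the published
procedure itself, preserved here by design.

## iBAQ abundance profiles

Raw iBAQ intensities are incomparable across replicates because lysosome
yield varies. Each replicate's intensities are divided by the median iBAQ of
the qualifying V-ATPase reference subunits of that replicate (qualification:
≥ `min_unique_peptides`, default 10, evaluated per replicate — the
normalization itself is per replicate, so the qualification is too). The
eight reference accessions are configuration, not code: they depend on
species and annotation source. Per (protein, cell line) the median
normalized value across replicates is reported, and a protein passes the
presence filter when it has values in ≥ 3 replicates in each of ≥ 2 cell
lines; failing proteins are flagged, not deleted. Normalization is exactly
scale-invariant per replicate whenever the rescaling factor is exactly
representable (e.g. powers of two); otherwise to ~1 ulp.

Functional-class sums add the passing putative-lysosomal proteins' medians
per (cell line, class); the classes are treated as a partition (at most one
class per protein, at most 32 declared classes), and declared-but-empty
classes are reported with sum 0. The whole-cell-lysate comparison reports
per-protein log2(enriched/lysate) for proteins passing both filters plus a
per-line Pearson correlation of log10 abundances, flagging proteins
relatively more abundant in the lysate.

## Cross-line frequency analysis

Membership matrices code presence (or significant enrichment) as 1/0 per
(protein, cell line); exact-intersection counts (each protein counted once
under its full pattern) feed UpSet-style summaries. The frequency table
counts identified/enriched lines per protein; the candidate list keeps
proteins enriched in ≥ `candidate_threshold` lines (default 5) that are not
previously reported as lysosomal. Compartment-percentage profiles report,
for every threshold k, the percentage of proteins present in ≥ k lines
assigned to each compartment, normalized to the k = 1 baseline; proteins
with several compartments count once per compartment, and zero-baseline
categories are reported missing. Frequency thresholds use ≥ k; exact-k
tallies are emitted separately. Pearson matrices use pairwise-complete
observations with a minimum overlap (default 10 proteins); pairs below it
are reported missing. When cell lines use different accession spaces
(e.g. mixed human and mouse lines), the pipeline can join on gene symbol
instead of accession (`join_key="gene_symbol"`); this is a pragmatic
stand-in for proper ortholog mapping.

## Synthetic studies

The generator emulates: 6 cell lines × 4 replicates with label switching
(replicates 1–2 light-SPIONs, 3–4 heavy); per-(protein, line) latent log2
ratios from N(0, 0.6) for the 1700 background proteins and N(2.2, 0.7) for
the 300 lysosomal proteins (~15% lysosomal); replicate noise sd 0.3; 10%
missing cells; 5% of lysosomal proteins emitted as sentinel-high in all
detected replicates; lognormal iBAQ (ln-mean 16, ln-sd 2, replicate ln-sd
0.2); 8 reference subunits with ≥ 10 unique peptides (all other proteins
< 10); half the lysosomal proteins shared by all lines ("core"), the rest
present in 2 to 5 random lines, background proteins in 1 to 6 random lines;
60% of lysosomal proteins marked previously reported; and a whole-cell-lysate
companion in which background proteins are boosted by 1.5 natural-log units.
A single seeded generator is consumed in a fixed documented order, so equal
configurations give byte-identical tables.

What the generator does **not** emulate: peptide-level effects and
peptide-to-protein rollup, intensity-dependent missingness (missingness here
is uniform), correlated replicate errors, contaminants, shared peptides
between orthologs, or search-engine-specific quirks beyond the sentinel
codes. Passing the end-to-end tests therefore shows that the statistical
machinery recovers a truth of the assumed shape, not that any particular
real dataset satisfies these assumptions.

With the default generator and scoring settings, per-line sensitivity at
q ≤ 0.05 is modest by construction (the two components overlap
substantially), while the across-lines union recovers ≥ 90% of non-sentinel
lysosomal proteins with a sub-percent background false-call rate — the
multi-line design, not the single-line test, carries the discovery power,
which is precisely the rationale for the frequency analysis.

## Problem sizes and numerical choices

Simulated studies used in tests and in `scripts/acceptance.py` are ~2000
proteins × 6 lines × 4 replicates; mixture-recovery checks use 5000-point
samples, sizes at which the EM estimates are stable and every check runs in
seconds. Determinism: all randomness flows through seeded
`numpy.random.default_rng` streams; outputs are written with fixed float
formatting and fixed sort orders, so reruns are byte-identical. Degenerate
inputs (fewer than 10 finite values, zero variance, all-extreme pooled sets,
no qualifying reference subunit, empty profile intersections) raise typed
errors naming the offending entity rather than producing silent NaNs.
Unimodal input data is not an error: the two components simply collapse
toward each other (or one weight shrinks), which the fit diagnostics expose.
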