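# Methods

`teametab` re-implements an untargeted flow-infusion electrospray MS
(FIE-MS) fingerprinting analysis for ordered manufacturing processes —
the motivating system is tea manufacture, where leaf samples are taken at
successive stages (picking, withering, fixation/rolling, oxidation,
roasting) and the chemistry of each stage is read from binned mass
fingerprints. This note records the models, the defaults and why, the
numerical choices, and what the synthetic-data tests do and do not
establish.

## Spectral binning

FIE-MS acquires a few minutes of scans without chromatographic
separation; the informative part of the run is the infusion plateau. The
default scan window keeps the contiguous run of scans around the TIC
maximum whose TIC is ≥ 50% of that maximum (per polarity); a fixed
window override is available. Peaks are assigned to 0.01 Da bins by
half-up rounding to two decimals, per-scan bin intensities are summed,
and the feature value is the mean of per-scan sums across retained scans
(scans lacking the bin contribute zero). Positive- and negative-mode
scans from the same run coexist in one matrix via a `p`/`n` id prefix.

Bin ids are 0.01 Da coarse — ±17 ppm at m/z 289 — which is useless for
3 ppm formula assignment, so every feature also carries an
intensity-weighted mean of its contributing peak m/z values
("accurate m/z"); assignment works from that value.

Filtering follows standard post-acquisition practice: a feature is kept
if detected in ≥ 2/3 of the samples of at least one class (stage or
stage-arm), and dropped if its relative standard deviation across pooled
QC injections exceeds 0.5 or its QC occupancy falls below 2/3. Both
thresholds are declared assumptions (the conventions for 3-replicate
designs), configurable and logged in the matrix provenance.

## Weight/moisture normalisation

Samples differ in mass and moisture, so intensities are scaled to a
common dry-mass basis: moisture is measured destructively on one
replicate per sample type and propagated; each sample's dry-mass
equivalent is d = extract_weight × (1 − moisture); intensities are
multiplied by min(d)/d, leaving the lowest-weight sample unchanged.
"Lowest weight" is interpreted as lowest *dry-mass equivalent* because
the procedure adjusts for weight and moisture together; a raw-weight
mode is available by flag.

Trend profiles are computed on per-stage replicate means and expressed
as percentage relative abundance (stage means scaled to sum to 100 per
feature). Percentages are taken over stages, not samples; this is a
documented interpretation choice — it is the form in which per-stage
trend plots are drawn.

## Formula assignment and consensus classification

Ionisation rules are data (TSV): name, polarity, multimer count n,
charge z, mass delta, required elements, required mobile-phase ion. The
default set covers [M+H]+, [M+Na]+, [M+K]+, [M+NH4]+, [2M+H]+,
[M+H−H2O]+, [M+H−NH3]+, [M−H]−, [M+Cl]−, [M+HCOO]−, [2M−H]−. Rules
needing a mobile-phase ion (NH4+, HCOO−) apply only when the run context
declares it; rules needing an element (N for ammonia loss, O for water
loss) are pruned per formula. The proton mass used for charge
bookkeeping is 1.007276 Da.

For a feature, every polarity-matching applicable rule is inverted to a
neutral mass and all CHNOPS formulas within the ppm tolerance are
enumerated by depth-first search (heaviest element first, mass-window
pruning, ≤ 10⁶ candidate budget), subject to RDBE ≥ 0 and integer RDBE
(even-electron neutrals). The default tolerance is 3 ppm (instrument
accuracy 3 ± 1 ppm; presets 2/4). A 10⁻⁹ Da window floor keeps
zero-tolerance queries numerically meaningful. Candidates are sorted by
|ppm| of the observed against the theoretical ion m/z.

Compound matching is tiered: primary-tier (KEGG-style snapshot) matches
shadow fallback-tier (PubChem-style) matches. Consensus classification
descends the matched compounds' taxonomy paths level by level, keeping
the modal label iff its frequency over *all* matched compounds is ≥ 0.66
(the stricter reading of "consensus among the matched compounds"); a
modal tie stops the descent rather than make an arbitrary class claim. A
feature's consensus comes from its best candidate (lowest |ppm|) with at
least one compound match. Cross-feature adduct/isotope grouping is
deliberately not implemented; each feature is assigned independently.

## Random-forest stage modelling

Stages are encoded as equally spaced ordinal integers (0 for picking).
A regression forest is fit on the feature matrix; model quality is the
out-of-bag R² (per-sample OOB predictions averaged over the trees for
which the sample was out of bag). Feature importance is %IncMSE: the
percentage increase in OOB MSE when a feature's values are permuted,
aggregated at the forest level over per-tree OOB squared-error sums,
with unpermuted error substituted for trees that never split on the
feature (such features get exactly 0).

Significance comes from refitting the forest under permuted responses:
the model p-value is (1 + #{null R² ≥ observed R²})/(n_perm + 1), and
each feature's p-value compares its observed importance against its own
importances in those same refits. Defaults: 1000 trees, mtry = ⌊p/3⌋,
3000 permutations with refits at a reduced 200 trees
(`n_trees_null`); set `n_trees_null = n_trees` when observed and null
importances must be exchangeable (calibration studies). Permutation
p-values can never be zero (add-one form). All forests are pure
functions of (data, parameters, seed).

The forest engine is a small numba-compiled CART implementation
specialised for tens of samples: general-purpose libraries provide
neither OOB permutation importance nor the fit throughput the
permutation scheme needs (~10⁴ refits per calibration study). Per tree,
importance is evaluated only for features the tree actually splits on —
permuting a feature a tree never consults cannot change its predictions.
scikit-learn's forest serves as an independent cross-check of OOB R² in
the tests, never as the implementation.

Known limitations. (i) With many mutually correlated informative
features, permutation importance shares credit among them (masking), so
per-feature recovery saturates below 100% even for univariately strong
trends; at a planted trend spanning 3 noise SDs the measured recovery is
≈ 0.87–0.92. (ii) %IncMSE carries a point mass at exactly zero —
features the forest never splits on (split choice concentrates on
features that chance-correlate with the response, so the mass does not
vanish with more trees; ~15% at 500 features × 18 samples). Such
features cannot be selected under the add-one ≥ rule, which leaves the
per-feature permutation p-values exactly calibrated at moderate
thresholds (measured 0.098 at nominal 0.099, 0.199 at 0.198) but
slightly conservative in the extreme tail (0.047–0.048 selected at
nominal 0.0495).

## Trend clustering

K-means (Lloyd, k-means++ initialisation, best of 25 restarts by WCSS,
tol 10⁻⁶) on raw percentage profiles — percentages already share a
0–100 scale, so no z-scoring by default (a z-score option exists).
Cluster ids are renumbered by descending size for stable reports.
k-selection diagnostics report mean silhouette and WCSS over a k range
and recommend the silhouette argmax; the final k remains an analyst
choice (the emulated analyses fixed k = 15).

## Enrichment

Functional enrichment diffuses from the compounds matched to an affected
feature set over a typed knowledge graph (compound–reaction–enzyme–
module–pathway, undirected) by personalized PageRank: the fixed point of
s = (1−d)·r + d·Wᵀs with damping d = 0.85, row-normalised adjacency W,
restart vector r uniform on the seed compounds, dangling mass
redistributed via r, power iteration to L1 tolerance 10⁻¹⁰. Node
significance is an empirical p-score, (1 + #{null ≥ observed})/(n_null+1)
over n_null = 1000 random same-size compound seed sets — a
simulation-style null standing in for the cited tool's internal null,
which is not published; p-scores are reported unadjusted, as that tool
does. Pathway and module nodes at p ≤ 0.05 are reported per cluster.

Structural enrichment is one-sided Fisher over-representation of
consensus classes at a chosen taxonomy level (default 2, the superclass
level), cluster against the rest of the background, BH-corrected across
the classes of one run. Features whose consensus does not reach the
level are excluded from both margins.

Differential testing between process arms uses two-sided Welch t-tests
per feature (Welch–Satterthwaite df) with BH FDR control; direction is
the sign of the arm-B minus arm-A mean. Degenerate inputs are explicit:
two zero-variance groups with equal means give p = 1; with unequal means
the feature is flagged rather than tested.

## Synthetic data

The study's raw data are not publicly deposited, so a seeded generator
provides every input with ground truth: an ordered design (6 green
stages or 7 black stages × 3 replicates, the black design branching into
4 h/overnight arms at oxidation and roasting, plus 3 pooled-QC
injections); ~2000 polarity-tagged features (post-binning dimensionality
is unreported anywhere, so 2000 is a free choice at the scale typical of
0.01 Da FIE-MS matrices); multiplicative log-normal noise (σ = 0.2,
~20% CV, matching routine technical+biological variation); a minority of
informative features whose log-intensities follow per-stage cluster
templates (monotone up/down, peak/valley at rolling, late rise, early
fall; default amplitude 1.0 log unit, within the several-fold stage
changes reported for real tea constituents); per-scan mass jitter at
3 ppm (1σ) matching instrument accuracy; and intensities proportional to
each sample's dry-mass equivalent, so that weight normalisation removes
a real planted effect rather than injecting noise (disable with
`weight_effect=False` to get the pure template world).

Planted features sit at the exact [M−H]−/[M+H]+ ion m/z of compounds
wired to one planted pathway of the synthetic knowledge graph and share
a flavan-3-ol-style consensus class, so formula assignment, functional
and structural enrichment all have recoverable ground truth. The
compound snapshot shares formulas among compounds (including one
three-compound formula agreeing only to taxonomy depth 2) to exercise
consensus logic.

Spectra are emitted so that re-binning reproduces the matrix: each
feature's per-scan intensities are its matrix value times weights with
mean exactly 1 across the flat infusion plateau (8 scans per polarity).
This realises the scan-level partition of a sample's signal in the form
the mean-aggregating binning inverts; with zero jitter the round trip is
exact to ~10⁻¹².

Not simulated: chromatographic carryover, isotope envelopes, in-source
fragmentation, batch drift beyond QC noise, and real taxonomies or
pathway topologies. A green test therefore establishes internal
correctness of the pipeline's statistics and plumbing, not performance
on real instrument data.

## Numerical and reporting choices

- Half-up rounding is computed as ⌊mz/width + 0.5⌋; values whose decimal
  representation sits exactly on a bin edge follow their binary float
  representation.
- Most-abundant-isotope masses are tabulated to 10⁻⁶ Da.
- Reports are TSV with fixed `%.8g` float formatting and stable sort
  orders, so reruns under one seed are byte-identical; every run writes
  a JSON report with per-step feature counts (monotone through filters),
  parameters, manifest and seed.
- Seeds are mandatory for every stochastic step; child streams are
  derived via `SeedSequence` so components are individually reproducible
  and mutually independent.
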