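# Methods

This note records the models, parameter choices, numerical decisions and
known limitations behind the package, in the order data flows through it.

## Geodesy and solar timing

Distances between roosts are loxodrome (constant compass bearing) lengths on
a sphere of radius 6371 km. A spherical datum is used deliberately: the
ellipsoidal correction is a few parts in 10³, far below the 19/40/50-km
decision thresholds the distances feed. The rhumb formulas use the Mercator
latitude with the standard parallel-limit guard (`q → cos φ` as Δψ → 0);
poles with differing longitudes are rejected as the loxodrome is undefined
there. Sunrise and sunset come from the NOAA low-precision solar position
series at a sun-centre altitude of −0.833° (refraction plus solar radius),
evaluated at each day's median position; day boundaries sit at local solar
midnight (UTC shifted by longitude/15 h). Polar day/night degrade to the
full or empty civil day.

## Track segmentation

Fixes are subsampled to one per interval slot (default 60 min) between
sunrise and sunset, nearest-in-slot within half an interval. The roosting
sites of a day are its first and last retained daylight fixes. Turning angle
is the absolute circular difference of consecutive daily azimuths (in
[0°, 180°]); a zero-displacement day has no azimuth and hence no turning
angle. Classification is a pure threshold rule — migratory iff total daily
path > 40 km and/or roost-to-roost beeline > 19 km — so permuting days
permutes labels.

Endpoint detection resolves each track to exactly one of three fates:

* **arrival** — the first day whose beeline is ≤ 50 km (or whose azimuth
  leaves the north-crossing sector (270°, 360°) ∪ [0°, 90°)) *and* whose
  turning angle exceeds 100°, provided no northern-sector > 50-km beeline
  day occurs within the following lookahead window (default 5 days). The
  lookahead makes the rule fully automatic where a human would otherwise
  confirm by inspecting the track. The > 50-km cessation criterion is
  evaluated on the daily *beeline*, parallel to the directional criterion it
  is paired with.
* **death** — the first instant opening a window (default 24 h) in which all
  accelerometer variances stay below `death_acc_epsilon` (default 0.01, i.e.
  ~1% of a migratory-day level in the generator's units) and displacement
  stays below 0.5 km. A window that the fix stream cannot cover is never
  called death. ACC units are tag-specific, so all three thresholds are
  configuration, not constants.
* **loss** — neither rule fires before the stream ends.

If both rules fire, the earlier date wins and ties resolve to death (a dead
bird trivially satisfies the low-movement half of the arrival rule, not the
reverse). Post-stopover migration distance sums daily total path over
migratory days strictly before the endpoint, computed from the subsampled
hourly track; total migration distance is the sum of two rhumb beelines
(wintering → stopover → breeding) and is only defined when both remote sites
are known.

## Body condition

`SMI_i = M_i (L0/L_i)^b` with `L0` the arithmetic mean wing length and `b`
the standardized major axis slope of ln M on ln L, computed as the OLS slope
divided by the Pearson correlation (equivalently sign(r)·sd(lnM)/sd(lnL)).
The index is computed strictly within sex — raptor sexual size dimorphism
makes a pooled allometry meaningless — and mixed-sex input is refused. SMI
is equivariant to rescaling mass and invariant to the wing-length unit. When
every wing equals the reference length the index degenerates to the raw mass
(the exponent base is 1), which is returned without estimating `b`.

## Community preprocessing

The ladder runs: contaminant flagging → control removal → taxonomy filter →
depth floor → rarefaction. Contaminant flagging follows the prevalence
logic: for each taxon a presence/absence 2×2 table (controls vs true
samples) is scored with the Pearson chi-square p-value, falling back to the
one-sided Fisher exact (control-enrichment alternative) whenever an expected
cell drops below 5; only taxa proportionally more prevalent in controls are
candidates, and a score below 0.5 flags them. The taxonomy filter removes
taxa not assigned to Bacteria, mitochondrial or chloroplast sequences, and
taxa unresolved at phylum. The depth floor removes samples with fewer than
10,000 reads, retention inclusive at the boundary. Rarefaction is a
multivariate-hypergeometric subsample per sample (without replacement) to a
common depth — by default the post-filter minimum — under a fixed seed
(default 999); taxa left with zero total are dropped. Re-running the ladder
on its own output is a no-op.

## Diversity and ordination

Shannon uses natural logs; Chao1 is the bias-corrected form
S + F₁(F₁−1)/(2(F₂+1)); Faith's PD sums branch lengths of the subtree
spanning present taxa and the root. Normality transforms used downstream:
log₁₀ for Shannon, reciprocal for Faith's PD, identity for Chao1. Jaccard is
computed on presence/absence by default (a quantitative Ružička variant sits
behind a flag) since it is grouped with the unweighted metrics; weighted
UniFrac is non-normalized by default, the common toolchain default, with the
normalized variant available. Both choices are configuration because the
source analyses do not pin them. Unweighted UniFrac is unique/covered branch
length; edges with no observed taxa never contribute, so tree tips absent
from the table are inert.

PCoA is classical scaling of the Gower-centred squared-distance matrix;
raw eigenvalues (possibly negative) are reported, and coordinates use
positive axes only. PERMANOVA partitions the same Gower matrix with
least-squares projections of the dummy-coded design; marginal mode compares
the full model against the model dropping each term, sequential mode adds
terms in order (whose R² then telescope to 1 with the residual). p-values
use the unbiased permutation estimator (1 + #{F* ≥ F})/(1 + n_perm) with
9999 permutations by default, permuting sample identities; small designs can
enumerate every relabelling, in which case the plain proportion is reported.
Ties between permuted and observed F are counted with a relative slack of
1e-6 because the trace partition carries ~1e-7 relative noise on strongly
separated data. The dispersion test measures each sample's distance to its
group's spatial median (geometric median, Weiszfeld iteration) in the full
PCoA space with the negative-eigenvalue correction (imaginary-axis squared
distances subtracted, floored at zero); the group F is referred to a
permutation distribution of the distances. The spatial medians of the real
and imaginary subspaces are fit separately, a simplification of the mixed
L1 problem that is exact whenever the distance matrix is Euclidean.

## Differential abundance

The model is `log(count + 1) = sample offset + taxon intercept +
taxon coefficient × covariate`. Offsets (sampling fractions) and per-taxon
regressions are alternated; the offset update combines (i) the across-taxon
*median of the fitted coefficients* — the consensus shift that a per-sample
sampling fraction would induce in every taxon, whose removal from the
coefficients is the bias correction — with (ii) the per-sample median
residual. A naive update using the median residual alone accumulates any
systematic skew of the residual distribution into an unbounded drift along
the design span (log counts with zeros are left-skewed, so the drift is
generic); folding the coefficient median into the offsets quotients that
direction out and the iteration converges in a handful of steps. Offsets
are pinned to mean zero (the constant is absorbed by intercepts). W is the
corrected coefficient over its OLS standard error, p from the standard
normal, q by Benjamini–Hochberg; a taxon is selected when q < 0.01 *and*
|W| reaches the 85th percentile of |W| within the analysed taxon set
(recomputed per analysis, before the q filter). The percentile is taken on
|W|; both choices are documented rather than inferred. Counts are
aggregated to phylum or genus before fitting, and only taxa present in more
than 10% of samples are tested. The estimator is invariant to per-sample
depth rescaling up to the pseudocount's effect on zeros.

## Association layer

All two-sample comparisons use the Welch unequal-variance form with
Satterthwaite degrees of freedom (the fractional df the analyses report make
the pooled form inapplicable). Model sets are OLS fits ranked by
AICc = −2logL + 2k + 2k(k+1)/(n−k−1), with k counting coefficients plus the
residual variance; models within 2 of the minimum form the supported set,
and Akaike weights are reported. Numeric explanatory variables are centred
and scaled before fitting, which changes coefficients but not ranks, ΔAICc
or p-values. The Scheirer–Ray–Hare test midranks the pooled response and
forms H = SS_term/MS_total from a two-way ANOVA on ranks (Type II sums of
squares, which coincide with the classical sequential form on the balanced
designs intended here), referred to chi-square; midranking makes MS_total
self-correcting for ties, and a design collapsed to a single level of one
factor reduces exactly to Kruskal–Wallis. Pearson chi-square is reported
without the Yates correction by default (a toggle restores it). Adjusted
p-values within a declared family use Benjamini–Hochberg; the family
membership is explicit configuration and is echoed in every output row,
since which tests share a family is an analysis decision, not a statistical
fact.

## Synthetic data

The generator's defaults mirror the study system: a cohort of 36 females
and 18 males captured over 30 April days at the Eilat stopover (29.55°N,
34.95°E); female mass 629 ± 77 g and male 518 ± 60 g, produced by sex-specific
wing-length draws with an allometric mass ∝ wing² power law and lognormal
noise calibrated to those moments; tracks of ~150 km daily rhumb steps on a
15° heading with stopover runs interleaved; Dirichlet-multinomial
communities at sequencing depths spanning the observed 14,523–76,393 reads,
with three negative controls. Tracks are simulated by rhumb-line destination
steps so the analyzer's beeline recomputation is exact by construction;
within-day fixes add lateral jitter, so total path ≥ beeline holds
identically. Accelerometer summaries are per-burst variance scalars in
arbitrary units with flatline meaning < 1% of the migratory-day level.

Planted effects act on per-sample log abundances before the softmax:
sex-effect taxa shift by a log-fold change in males; the designated
pathogen-like taxon shifts by slope × standardized condition; capture date
scales the Dirichlet concentration as exp(slope × (date − mean)), so a
negative slope lowers expected evenness (Shannon) for late birds — a
concentration effect, not a composition effect. With every effect at zero
the samples are exchangeable, which the calibration tests rely on.
Contaminants are guaranteed present in every control (counts floored at 1)
and rare in true samples; negative controls are contaminant-dominated with
faint cross-talk from real taxa. The random phylogeny is a bifurcating tree
from random pairwise joins with exponential branch lengths.

What the generator does *not* emulate: spatial autocorrelation of real GPS
error, tag battery-driven sampling gaps, wind or thermal structure in daily
step lengths, phylogenetic signal in the planted effects (effect taxa are
chosen independently of the tree), and zero-inflation beyond what the
Dirichlet-multinomial induces. Passing tests therefore demonstrate the
statistical machinery recovers what this model plants — not that the model
captures every feature of field data.

A note on scenario geometry: the arrival detector's lookahead (default
5 days) assumes mid-migration stopover runs shorter than the lookahead and
daily beelines comfortably above 50 km; the bundled scenarios use runs of
1–4 days and steps of 100–250 km. Longer stopovers with slow travel would
require a longer lookahead, as in real tracks.

## Problem sizes

Simulation-based checks use sizes chosen to make binomial error bands tight
while keeping the suite quick: 100 seeded tracks for segmentation recovery,
200 replicates for PERMANOVA type-I calibration (12 samples, 99 permutations
each), 100 replicates each for differential-abundance null/power (40
samples × 30 taxa) and for slope-sign recovery (24 samples × 40 taxa). The
acceptance script reruns all of these from scratch.

## Known limitations

* Arrival/death rules are threshold heuristics; they are calibrated to the
  generator's clean tracks, and real tracks with long pre-breeding
  wanderings would need the lookahead and thresholds revisited.
* The differential-abundance fit handles a single covariate (numeric or
  two-level), no random effects and no structural-zero detection.
* PERMANOVA permutes raw sample identities (no restricted permutation
  blocks).
* The decontamination score is the contingency p-value form of the
  prevalence method; frequency-based scores are not implemented.
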