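# Methods

`nirsnet` analyzes resting-state functional near-infrared spectroscopy
(fNIRS) recordings as small-world networks. This note documents the model,
the numerical choices, the synthetic-data generator used for validation, and
the known limits of both.

## The analysis model

**Nodes and edges.** Each measurement channel (source-detector optode pair)
is a node. For one subject, the channels × samples concentration time series
is reduced to the N × N Pearson correlation matrix `r_ij`. The matrix is
binarized at a *sparsity* S — the fraction of realized edges out of the
N(N−1)/2 possible pairs: the K = round(S·M) pairs with the largest |r|
become edges (round half away from zero; ties broken by |r| descending, then
row, then column index, so results are platform-independent). Absolute
correlation ranks edges, so strong negative couplings count as connections.
Because any single S is arbitrary, all metrics are computed over the full
grid S = 0:0.01:1 (101 points).

**Graph metrics.** For a binary undirected graph:

- degree `K_i` (row sums);
- clustering coefficient `C_i = E_i / (K_i(K_i−1)/2)` with `E_i` the edges
  among i's neighbors; `C_p` is the mean over all nodes. `C_i = 0` when
  `K_i < 2` (the formula is otherwise 0/0);
- all-pairs shortest-path lengths by level-synchronous breadth-first search
  run for all sources at once through boolean matrix products — exact for
  unweighted graphs and fast at N = 12;
- characteristic path length `L_p`: the mean of `d_ij` over *reachable*
  ordered pairs. Unreachable pairs are excluded rather than propagated as
  infinities, matching common network-toolbox behavior and keeping
  low-sparsity sweep points usable; `L_p` is undefined (NaN, never an
  exception) only for an edgeless graph;
- nodal efficiency `E_nodal(i) = (1/(N−1)) Σ_j 1/d_ij` with `1/∞ = 0`;
  `E_glob` is its node mean. Efficiencies handle disconnection naturally;
- local efficiency `E_loc_nodal(i)`: the global efficiency of the subgraph
  induced on i's neighbors (i excluded); 0 when the neighbor set has fewer
  than 2 nodes;
- betweenness `N_bc`: unnormalized shortest-path betweenness (Brandes
  accumulation). Only within-graph comparisons between nodes use it, so
  normalization is immaterial; unnormalized is stated for bit-exactness.

**Null model.** Each real graph is compared against 100 degree-matched
random networks built by Maslov–Sneppen double-edge swaps: pick edges
(a,b), (c,d), replace with (a,d), (c,b) unless a self-loop or duplicate
would result. The swap budget is 10 attempts per edge; invalid proposals
are rejected (swap-rigid graphs such as triangles and complete graphs come
back unchanged, which is correct — their degree-matched null class is
themselves). No connectedness constraint is imposed on nulls. Normalized
indicators divide real by null-ensemble means: γ = C_p/C_p_rand,
λ = L_p/L_p_rand, γ_E = E_glob/E_g_rand, λ_E = E_loc/E_l_rand. The
small-world scalar is σ = γ/λ (and σ_E = γ_E/λ_E): a small-world graph has
γ > 1 and λ ≈ 1, hence σ > 1. (Some texts print σ = λ/γ; that form is
inconsistent with requiring γ > 1, λ ≈ 1, σ > 1 and with the efficiency
analogue, and is treated here as a typo.)

**Significance.** Per sparsity point, z = (x_real − mean(x_rand)) / sd(x_rand)
with the sample (n−1) SD — the 100 nulls are a sample, not a population.
|z| > 1.96 flags two-tailed 0.05 significance; zero null SD yields a flagged
undefined z, not an exception. Significant sparsity ranges are maximal
contiguous grid runs of |z| > 1.96, reported with the mean ± SD of z over
the run. Group-level z defaults to averaging each subject's z against its
own null ensemble (fully specified and conservative); an alternative mode
z-scores the group-mean metric against the distribution of the mean of one
null draw per subject (variance = Σ sd_i² / n²).

**AUC summaries.** A metric curve Y(S) is summarized by the trapezoidal
integral `Y_AUC = Σ_k (Y(S_k) + Y(S_k+1))·ΔS/2`. Nodal (hub) AUCs always
integrate the full grid. Global-metric AUCs used for association integrate,
by default, the largest contiguous window where every subject's metrics are
defined (in practice [0.01, 1]: only the edgeless S = 0 point is undefined);
the resolved window is archived in the run log and is configurable.

**Hubs.** A node is a hub when its degree, nodal-efficiency or betweenness
AUC exceeds the across-node mean by more than one across-node sample SD on
any criterion; the default operates on cohort-mean nodal AUCs (one hub set
per cohort), with a per-subject mode available.

**Association.** Each of the five NEO-FFI factor totals is correlated
(Pearson r, two-tailed p from t = r√((n−2)/(1−r²)) with n−2 df) with each
global AUC (C_p, L_p, E_glob, E_loc) across subjects — a 5 × 4 table with
stars at 0.05 and 0.01. P-values are raw by default (20 tests, uncorrected,
mirroring common practice in this literature); an optional
Benjamini–Hochberg column is available but off by default.

**NEO-FFI scoring.** 60 items, 12 per factor, rated 1–5; reverse-keyed
items contribute 6 − raw; factor totals span [12, 60]. The published
item-to-factor keying is licensed test content, so the default map is a
documented placeholder (items assigned cyclically N, E, O, A, C, no reverse
keying); any real study must supply its own map. Trait totals can also be
supplied directly, bypassing scoring.

## Preprocessing

Order is fixed: segment selection → despiking → detrending → band-pass.

- **Segment**: discard the first 180 s (settling), keep the 180-s window
  centered on the midpoint of the remainder (600-s recording → 300–480 s).
  "Centered on the remainder" honors both "discard the start" and "use the
  middle" when the two rules are in tension.
- **Despiking** (off by default): samples whose robust z — |x − median| /
  (1.4826·MAD) — exceeds 5 are replaced by cubic-spline interpolation from
  clean neighbors. It is off by default because the synthetic generator
  injects no motion artifacts unless asked.
- **Detrend + filter**: per channel, remove the best-fit line, then apply an
  order-3 Butterworth band-pass (0.01–0.1 Hz) in second-order sections,
  forward-backward (zero phase, doubled effective order). A 0.01 Hz corner
  at 50 Hz sampling is numerically delicate in transfer-function form;
  cascaded sections keep it stable. Edge transients are limited by scipy's
  default odd-reflection padding.

Note that a 180-s segment holds under two periods of the lowest passband
frequency, so per-channel sample means after filtering are small but not
zero — the filter's DC gain is zero only asymptotically.

## The synthetic cohort generator

No public dataset pairs multichannel prefrontal fNIRS with five-factor
personality scores, so validation uses simulated cohorts with known ground
truth. Defaults emulate the target acquisition: 30 subjects, 12 channels,
50 Hz, 600-s recordings.

- **Traits**: multivariate normal with means (O, C, E, A, N) =
  (41.57, 45.13, 41.13, 39.80, 28.30) and SDs (5.86, 6.60, 7.91, 5.06,
  7.55) — values typical of young-adult cohorts — with a planted
  conscientiousness-neuroticism correlation of −0.53. Totals are truncated
  to [12, 60]; truncation (rather than redrawing) slightly attenuates tail
  values but preserves the planted correlation better, and at these
  defaults the bounds sit more than 2 SD from every mean.
- **Topology**: each subject receives a Watts–Strogatz graph on the 12
  channels, ring degree k = 4, rewiring probability
  p = clamp(0.3 + 0.2·z(C), 0, 1), standardized by the *population* mean/SD
  so the planted map is identical across cohorts. The slope 0.2 sizes the
  planted effect so that the correlation between p and the true graph's
  L_p across subjects is ≈ −0.65, the magnitude of effect this kind of
  study reports. Higher conscientiousness → more shortcuts → shorter L_p.
- **Signals**: per channel, independent Gaussian white series are mixed
  through an eigenvalue square root of the target correlation matrix (1 on
  the diagonal, r_in = 0.6 on topology edges, r_out = 0.15 elsewhere,
  projected to the nearest valid correlation matrix by eigenvalue clipping
  when the patterned matrix is indefinite — the projection keeps in-edge
  correlations ≥ 0.49 and off-edge ≤ 0.20), then band-passed to
  0.01–0.1 Hz. The same linear filter on every channel leaves cross-channel
  correlations untouched, so the correlation ordering survives filtering by
  construction.
- **Nuisance**: cardiac (~1 Hz), respiratory (~0.3 Hz) and Mayer-wave
  (~0.1 Hz) sinusoids with ±10% per-subject frequency jitter and random
  per-channel phase, at amplitudes (0.5, 0.4, 0.3) relative to the
  unit-variance latent signal, plus white noise at 0.5. Cardiac and
  respiratory bands lie outside the analysis band and are removed by the
  filter; the Mayer band sits at the passband edge and is only attenuated —
  deliberately, since that is the hard case in real data.
- **Determinism**: all randomness derives from per-subject, per-stage
  seed-sequence streams spawned from the cohort seed; identical specs give
  bit-identical cohorts.

### What the generator does not emulate

Real fNIRS features deliberately out of scope: raw optical intensities and
the Beer–Lambert conversion, scalp/systemic physiology shared across
channels (which inflates correlations globally), motion artifacts beyond
optional injected spikes, non-stationarity, and 1/f background structure.
Passing recovery tests therefore show that the *pipeline* is correct and
statistically calibrated — not that real recordings carry this much signal.

## Statistical power of planted-effect recovery — a known limit

The planted effect is strong at the source: p correlates ≈ −0.65 with the
true topology's L_p, and sweeping *noiseless* correlation matrices through
the pipeline yields r(p, L_p-AUC) ≈ −0.50. Measurement noise is what the
emulated acquisition cannot overcome: a 180-s window of 0.01–0.1 Hz signal
carries only ~2·B·T ≈ 32 effective degrees of freedom, so each pairwise
Pearson estimate has an SE near 0.15, and only ~80% of planted edges are
recovered at the true sparsity. On a 12-node graph whose L_p dynamic range
across the whole rewiring axis is ~0.3 hops, that ranking noise halves the
recoverable correlation to r ≈ −0.15 ± 0.2 at n = 30. Replicate cohorts
therefore show the planted negative conscientiousness-L_p sign in roughly
two-thirds to three-quarters of runs, not ≥ 90%, and the induced positive
neuroticism-L_p correlation (via the planted C-N correlation of −0.53) is
positive in the mean but weak. This is an information limit of the emulated
study conditions (window length, band, channel count, contrast), not an
implementation defect: the corresponding recovery test asserts the design
target and is expected to fail until the study conditions themselves are
enriched (longer windows, more channels, or higher edge contrast all
restore recovery).

## Problem sizes used in the test suite

Simulation-heavy checks run at sizes chosen to keep the whole suite fast
while preserving the statistics that matter: synthetic recordings are
generated at 10 Hz with a 240-s duration and a 30-s discard (the analysis
window stays 180 s, so the effective degrees of freedom — the quantity that
drives every correlation estimate — match the 50 Hz/600 s defaults), and
the end-to-end determinism check runs 6 subjects on a 21-point grid with 20
nulls. Oracle and null-model exactness checks run at full stated sizes (500
graphs; ≥10⁴ swap attempts), as do the 50-seed small-world and 1000-cohort
calibration checks.

## Known limitations

- Binary graphs only; no weighted-network generalizations.
- The sparsity grid treats all thresholds equally in the AUC; low-sparsity
  points are noisy (few edges) and the reachable-pairs L_p convention makes
  them well-defined but volatile.
- The null model preserves degrees exactly but not connectedness.
- The default NEO-FFI item map is a placeholder; scoring is only faithful
  to the real instrument when the licensed keying is supplied.
- Hub identification on 12 nodes flags at mean + 1 SD; with so few nodes
  the SD estimate itself is noisy, so hub sets should be read qualitatively.
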