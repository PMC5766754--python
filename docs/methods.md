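# Methods

## Cluster segmentation

Licks are segmented greedily left to right: a new cluster begins at the
first lick and at every lick whose gap from its predecessor exceeds the
threshold. The split is strict — an interlick interval (ILI) exactly
equal to the threshold stays within a cluster — because the defining
convention is "no ILI *greater than* 500 ms". The result is an
exhaustive, non-overlapping partition, so cluster sizes always sum to
the lick total and segmentation is invariant to shifting all timestamps
by a constant. Single licks count as clusters of size 1 (minimum run
length is not part of the definition); an optional `min_cluster_size`
filter and an optional low-ILI artifact floor (`min_ili`, for
near-coincident contact bounces) are provided but off by default, since
the standard analysis applies neither.

The 0.5 s threshold is a parameter everywhere, never a constant: burst
(~0.25 s) and bout (~1 s) analyses are the same computation at another
threshold. Raising the threshold can only merge clusters, so cluster
count is non-increasing and mean cluster size non-decreasing in the
threshold — a property the test suite checks on random trains, alongside
exact agreement with an independently coded brute-force segmenter.

Because clusters are defined purely by gaps, a session boundary can
truncate the last cluster but never create an ambiguous one; no
truncate-vs-drop policy is needed (it would matter only for rate-based
burst statistics, which this package does not compute).

## Metrics

- **Licks per cluster** (palatability): total licks / number of
  clusters, per (rat, session, bottle). Undefined (NaN, never 0) for an
  empty train.
- **Cluster number** (motivation/satiation): count of clusters.
- **Preference**: casein licks / total licks on the two-bottle day.
  A rat with zero total licks yields NaN with a warning and is excluded
  from the group test — the t statistic's df then visibly drops, so
  exclusions can never be silent.

## Time courses

Lick counts fall into half-open uniform bins `[kw, (k+1)w)`; a lick at
exactly the session end joins the final bin, and licks beyond the
session window are clipped into it with a warning. The default width is
60 s — the finest scale at which hour-long curves remain readable — and
halving the width and re-summing adjacent pairs reproduces the coarser
counts exactly. Group curves are across-rat mean ± SEM (sample SD / √n);
SEM for a single rat is reported missing. Epoch summaries use fixed
windows: early = first 20 min, late = final 40 min of a 1-h session.
The cumulative path interleaves both bottles' licks in time and plots
running casein count against running maltodextrin count; simultaneous
cross-bottle timestamps (possible only in merged or resampled data) are
ordered casein-first and logged.

## Split-plot statistics

The two-way mixed ANOVA is computed from first principles via the
stratum decomposition. With subjects nested in diet groups (between
factor A, a levels, n_j subjects each) and every subject measured at all
b within levels:

- between-subjects stratum: `SS_A = b Σ_j n_j (ȳ_j − ȳ)²` tested against
  subjects-within-groups (`df = N − a`);
- within-subjects stratum: responses are subject-centered, then the
  within main effect and interaction come from within-level and
  group×level cell means; the residual (subject × within) is the error
  term with `df = (N − a)(b − 1)`.

On balanced designs this equals the textbook Type I/II/III decomposition
(the suite verifies the sums of squares against a hand-written oracle to
1e-10 and against an independent mixed-ANOVA implementation); unbalanced
group sizes give the marginal-means (Type II style) decomposition with a
logged note. No sphericity correction is applied: the headline designs
have two within levels, where sphericity is vacuous, and repeated-day
factors deliberately keep uncorrected df so the printed df expose the
design. A within factor with one group reduces F to the square of the
paired t, which the suite checks numerically.

t tests are two-tailed: paired (one-sample t on differences, df = n − 1)
and pooled-variance Student (df = n₁ + n₂ − 2; pooled, not Welch, since
the classical integer-df Student test is the field's convention for
these designs). Degenerate inputs are flagged, not fudged: zero variance
with equal means gives t = 0, p = 1; with unequal means an infinite-t
flag with p = 0. p-values come from the scipy t and F distributions;
only the distributions are delegated — every sum of squares and
statistic is computed here.

## Diet energetics

Energy density is `(4·protein + 4·carb + 9·fat) / 100` kcal/g (Atwater
factors) from grams per 100 g; energy shares are rounded half-up to
integers to match how vendor sheets print them. The shipped control
(18/62/10 g%) and protein-restricted (5/76/10 g%) compositions both
compute to 4.1 kcal/g at one decimal — the isocaloric design constraint.
Vendor tables round some cells by other rules (the restricted diet's
protein share prints differently than plain Atwater arithmetic gives);
only the arithmetically stable cells are asserted in tests. Cage intake
is normalised to grams/day/rat by dividing the cage total by its
occupancy, with the cage as the statistical unit.

## The simulator

Sessions are an alternating pause/cluster renewal process:

| parameter | default | meaning |
|---|---|---|
| `cluster_size_mean` | 6 licks | mean of shifted-geometric cluster sizes (support ≥ 1, memoryless run lengths; negative binomial available for overdispersion) |
| `ili_mean`, `ili_sd` | 0.15 s, 0.02 s | within-cluster ILI, Normal truncated to (0.05, 0.5] — the 6–7 Hz rhythmic band |
| `pause_median`, `pause_sigma` | 6 s, 0.6 | log-normal between-cluster pauses |
| `pause_min` | 0.6 s | pause floor, strictly above the 0.5 s threshold |
| `satiety_decay` | 0 | multiplicative pause growth per cluster |
| `appetition_onset`, `appetition_factor` | off | step increase in cluster-size mean after a post-ingestive delay (default onset 1200 s when enabled) |
| `duration` | 3600 s | session length |

Because ILIs are truncated below the threshold and pauses floored above
it, segmentation at 0.5 s recovers the generated clusters *exactly* —
ground truth is identifiable by construction. This is a deliberate
idealization: real ILI distributions have tails crossing the threshold,
so passing recovery tests demonstrates correctness of the analysis
chain, not robustness to threshold leakage (raise `ili_max` for "leaky"
robustness runs). Other simplifications: no circadian or multi-day
carry-over structure, no drinking-burst micro-rhythm variation, and the
default laws are literature-conventional shapes, not fits to any
apparatus.

Preference sessions run a single cluster process; each cluster initiates
at the casein bottle i.i.d. with probability p and draws its size from
that bottle's palatability law, so the long-run preference score has the
closed form `p·μ_c / (p·μ_c + (1−p)·μ_m)`.

The default cohort encodes the study conditions the analysis targets:
12 rats per diet group, 4 alternating single-bottle conditioning days
(solution order and flavor assignment counterbalanced across rats) then
a two-bottle test; PR rats get casein cluster sizes ×1.4 and casein
allocation p = 0.75 (expected preference 0.808), NR rats are indifferent
(p = 0.5, expected 0.5); PR rats additionally get a ×1.4 appetition step
at 1200 s on their first casein conditioning day. Cage intake mirrors
group housing — per group, 4 main cages of 3 rats plus 4 pilot cages of
2 rats (16 cages, so the intake t test has 14 df) — with NR intake
20 g/day/rat (SD 1.5) and a 1.15× PR hyperphagia factor, a moderate
hyperphagia without weight change.

Randomness is hierarchical: the experiment seed spawns a fixed-key
substream per rat and per cage, so adding animals never perturbs
existing ones and identical configurations are byte-identical on disk.

## Calibration choices

Monte-Carlo calibration of the statistics stage (type-I error under the
effect-free configuration, power at the default effect sizes) uses
900-s sessions: rejection rates are insensitive to session length and
this keeps 200-replicate runs to seconds. The single fixed-seed recovery
cohort uses full hour-long sessions. The power requirement (≥ 80% for
the diet × solution interaction at the default effect sizes over 100
replicates) is a package-defined target for its own defaults.

## Numerical and degenerate-input policy

Timestamps are written with 4 decimals (0.1 ms, below lickometer
resolution), making CSV round trips exact at that precision; duplicate
timestamps on one bottle are physically impossible and collapsed with a
warning on read. Sums of squares use mean-centered accumulation; a tiny
negative SS from cancellation is floored at 0. All-identical responses
give F = 0, p = 1 across effects. Groups with a single subject, within
factors with a single level, and zero-lick preference scores are
rejected or reported missing rather than silently propagated.

## Known limitations

- The operant-box text reader handles the common named-array export
  dialect; other vendor formats need conversion to the long-form CSV.
- The ANOVA covers one between and one within factor (the designs here);
  it is not a general mixed-model engine, and no post-hoc corrections
  beyond the planned paired/pooled t follow-ups are provided.
- Simulator defaults are idealized conventions, not parameter estimates
  of any particular apparatus or strain; conclusions about real data
  require the real recordings.
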