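# Methods

## Temporal model

Time is measured in whole days (integer day-of-year); all intervals are
closed, and an interval's length is `end − start + 1`. This matches the
resolution of field pollination censuses, where the observation unit is
the field day. A species' **phenophase** is the interval between its
first and last observed interaction; the **season** runs from the first
to the last observed visit of any pair.

The **activity rule** converts point observations into intervals: a pair
observed interacting at least once is scored as interacting during its
entire phenophase overlap. This is deliberately conservative — it hides
single days of inactivity and makes the binary link structure a pure
function of (phenophases, observed pairs). Visit counts are accepted on
input but never weight anything.

A network restricted to a window `[a, b]` contains every species whose
phenophase intersects the window and every observed pair whose joint
overlap intersects it. Consequences used as test invariants: the union
of all 1-day slices equals the static network, and a window equal to the
season reproduces it exactly.

## Core and tail species

Generalization is the linkage level L, the number of distinct partners
over the season (or over the window, for windowed summaries). Tail
species have L ≤ 2, core species L > 2. Species active in a window with
no active partner (L = 0) are classified tail and flagged *isolated*;
this happens routinely in daily slices when a specialist's partner has
not yet entered the network. Daily summaries use each slice's own
linkage levels by default — a season-wide generalist can be a daily
specialist, and that stunting of the daily tail is precisely the signal
of interest; season-wide classification can be imposed via the
`core_tail` argument instead. Reported percentages are rounded half-up
to integer percent; full precision is kept internally.

## NODF and its nulls

For every unordered pair of rows (and of columns) with strictly
different marginal fills, the paired term is `100 · overlap / fill_sparser`;
equal-fill pairs and pairs involving an empty line contribute 0. NODF is
the mean over all row pairs and column pairs, in [0, 100], and is
invariant to input ordering. The display sort orders lines by descending
fill, breaking ties by increasing mean partner fill, then stably.

Because equal-fill pairs contribute exactly 0, NODF is *not* monotone
under adding links in general: a link that creates an equal-fill pair
can zero a previously positive term. This is a property of the metric,
not an implementation artefact.

Two binary null models are provided. *Equiprobable*: every cell is 1
with probability `fill/(R·C)`. *Degree-proportional* (default): cell
(i, j) is 1 with probability `(k_i/C + k_j/R)/2`, which preserves the
expected fill exactly and each margin in expectation — the standard
choice for pollination-network NODF tests. Null replicates may contain
empty lines; they are retained and scored with the degenerate-line rule
above, since discarding them would bias the null towards nestedness.
Significance is `p = (1 + #{null ≥ observed}) / (reps + 1)`; the add-one
correction keeps p strictly positive at finite replicates.

## Mid-domain test

For one core plant, the domain spans from the earliest start to the
latest end among the phenophases of its tail visitors. The null places
each range, keeping its observed length, with its start uniform on the
feasible integer positions; placement on the discrete day lattice makes
the model exactly enumerable on small cases (the tests exploit this).
Geometric constraint alone then peaks expected richness mid-domain.

The statistic D of a richness curve is its mean daily absolute deviation
from the mean simulated curve. A signed mean difference would average to
approximately zero for every curve by construction, carrying no
information; the absolute deviation makes D a dispersion-from-null
statistic that the rank comparison requires. The empirical rank is
`1 + #{simulated D < empirical D}` (ascending; ties rank below, noted in
the result metadata) and the percentile is `rank/(runs + 1)`. A
percentile near 1 means the observed phenophases segregate more than
random placement allows; near 0, that they clump more. Both tails are
reported because either is a deviation from the geometric null. The
default is 5000 runs.

## Time delays

The delay from species i to species j is `start_j − start_i`, floored at
1 day — the clock granularity: a species entering a network in which j
is already (or still) active can interact with it immediately, so
overlapping pairs directed late-to-early have delay exactly 1. Ordered
pairs with disjoint phenophases split by direction: forward in time the
delay is the start-to-start difference; backward in time the connection
is **temporally impossible**. The classification is total: every ordered
pair of valid phenophases receives exactly one of the four classes, and
`impossible(i→j) ⟺ disjoint-forward(j→i)`.

Direct delays are tabulated over observed links in both directions (by
the activity rule these always fall in an overlap class). The indirect
universe is every remaining ordered pair within the giant component,
pooling 2-mode pairs (plant–visitor never observed interacting) and
1-mode pairs (plant–plant, visitor–visitor). Classification is by
phenophase geometry alone; connectivity is assumed through the giant
component, and the existence of a time-respecting coupler chain (every
consecutive static link non-impossible) is a separate verification
(`find_coupler_chain`, shortest chain by BFS with deterministic
neighbour order), not a filter on the percentages. Transmission delays
contributed by the couplers' own biology are ignored. Component size
ties break towards the component containing the smallest species id.

## Synthetic community generator

The generator emulates the structure the analysis assumes, so the whole
pipeline is testable without field data. Defaults describe one
high-arctic season: 70 days starting day 165; 26 core + 8 tail plants;
27 core + 51 tail flower visitors; core phenophase length ~N(31, 6²)
days, tail ~N(6, 2²), both clipped to [1, season]; core starts drawn
from an early-skewed truncated normal (mean at 10% of the season, sd
30%) so cores anchor the beginning of the season yet stagger across it;
60% of tail species start within the last 35% of the season ("late
burst"; an early-burst and a no-burst mode exist). Tail visitors carry
trophic-role labels (75% visitor, 18% parasitoid, 7% hyper-parasitoid)
and coarse taxon groups at arctic frequencies; the labels inform no
computation.

Links: every core plant × core visitor pair with overlapping phenophases
is linked with probability `0.33 · w_p · w_a` (capped at 1), where the
w are lognormal abundance weights (sd 0.8, mean 1). Each tail species
attaches to up to 2 overlapping core partners chosen with probability
proportional to `abundance · (1 + current L)`, redrawing its start (up
to 100 times) if nothing overlaps. Abundance-product linking plus
abundance-and-degree-proportional attachment is the standard generative
explanation of nestedness in mutualistic webs, and the resulting
networks are NODF-significant against the degree-proportional null in
≥ 80% of seeds, with connectance near 11% and a static pollinator tail
fraction near 0.7.

Finally, each linked species' phenophase is trimmed to the hull of its
pair overlaps, because a *network* phenophase is operationally the span
between first and last possible observations. Trimming preserves all
links and overlaps, and makes phenophase inference from dense
observations exact.

The observation layer thins each pair's overlap with per-day Poisson
visit counts (rate 0.5/day by default) and guarantees at least one
record per pair, so the observed network equals the intended one and
downstream results are deterministic given the seed. A no-guarantee flag
exists to study detection-induced phenophase shrinkage; it is off by
default. The generator does not model observer schedules, weather,
abundance dynamics, or trophic interactions beyond labels — so passing
tests demonstrate correctness of the *analysis* under the stated
generative assumptions, not robustness to field-sampling artefacts.

## Numerical and design choices

- Explicit season bounds, when supplied, win over inference; records
  outside them are dropped and logged.
- Input columns are mapped by name or position (CSV and TSV); no fixed
  header convention is assumed.
- All Monte Carlo stages take explicit seeds; the pipeline derives and
  records per-stage seeds in its provenance block, and identical configs
  yield byte-identical report bundles.
- Degenerate inputs error early with named species/rows: empty record
  lists, matrices smaller than 2×2 or all-zero, regressions with fewer
  than 3 points or zero variance in L, ranges exceeding their domain.
- Problem sizes in the test-suite calibration checks (50-seed
  calibrations at 200–500 Monte Carlo replicates, 12×12 null matrices,
  20 generator seeds at 1000 NODF replicates) were chosen to give stable
  pass/fail behaviour at interactive runtimes; the acceptance script
  uses the full defaults (1000 NODF replicates, 5000 mid-domain runs).

## Known limitations

- The binary activity rule ignores interaction intensity; weighted
  nestedness and frequency-weighted delays are out of scope.
- Phenophases are single intervals; multi-brooded species with split
  activity periods are represented by their hull.
- The degree-proportional null preserves margins only in expectation;
  fixed-margin (swap) nulls are not implemented.
- Mid-domain ranges are placed independently; the null ignores any
  interaction between tail species' phenologies.
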