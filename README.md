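# phenonet

Temporal (phenophase-resolved) analysis of bipartite plant–flower-visitor
networks.

Most pollination networks are analysed as *static* structures: every
species and link observed over a season is treated as simultaneously
present. But species are only network members during their **phenophase**
— the interval between their first and last observed interaction — and a
season is really a succession of small, rapidly turning-over networks.
`phenonet` builds both views from daily visitation records and quantifies
what the static view hides:

- **Network construction under the activity rule.** If a plant and a
  visitor were observed interacting at least once, they are scored as
  interacting throughout their phenophase overlap. The season can be cut
  into windows of any thickness down to one field day.
- **Nestedness (NODF) with null models.** NODF scores, for every pair of
  rows and columns with strictly decreasing marginal fill, the percentage
  of the sparser line's links shared with the denser line. Significance
  comes from equiprobable or degree-proportional (marginal-preserving)
  Monte Carlo nulls. Core species have linkage level L > 2, tail
  (specialist) species L ≤ 2, and the relative tail length is t/(c+t).
- **Mid-domain test of tail phenology.** For a core plant, the
  phenophases of its tail visitors define a domain; a RangeModel-style
  Monte Carlo (uniform placement of each range within the domain) gives
  the null daily richness curve. The statistic D is the mean daily
  absolute deviation from the null mean curve; the observed D is ranked
  among the simulated Ds (percentile = rank/(runs+1)).
- **Time delays and temporal impossibility.** The delay d(i→j) between
  two species is the difference between their phenophase starts, floored
  at 1 day. Ordered pairs fall into four classes: overlapping
  forward/backward, and disjoint forward (long delays) or disjoint
  backward — **temporally impossible**, because effects cannot reach a
  species that left the network before the source entered. Direct links,
  and all indirect pairs of the giant component (including plant–plant
  and visitor–visitor one-mode pairs connected through temporal
  couplers), are classified and tabulated by core/tail block.
- **A synthetic community generator** that emulates an arctic season:
  long-phenophase, abundance-heterogeneous core species anchoring the
  season, and short-phenophase tail species attaching to one or two core
  partners, with a late-season burst of tail visitors.

## Worked example

```python
import phenonet as pn

cfg = pn.GeneratorConfig(seed=1)           # a 70-day, 34-plant, 78-visitor season
species, phen, pairs = pn.generate_community(cfg)
records = pn.generate_observations(phen, pairs, cfg)

phen_obs = pn.infer_phenophases(records)   # phenophases from the records alone
start, end, length = pn.season_bounds(records)

static = pn.build_network(phen_obs, pn.observed_pairs(records))
daily = pn.summarize(pn.slice_daily(phen_obs, pn.observed_pairs(records)))

m = pn.IncidenceMatrix.from_network(static)
nest = pn.nodf_significance(m, model="degree_proportional", n_reps=1000, seed=2)

ct = pn.classify_core_tail(static)
table = pn.aggregate(
    pn.direct_delays(static, phen_obs) + pn.indirect_delays(static, phen_obs), ct
)
```

Output:

```
season: days 165-233 (69 d), 1803 records
static network: A=77 pollinators, P=34 plants, I=296 links, C=11%
static pollinator tail: 0.70
mean daily pollinator tail: 0.48 (5.6 species/day)
NODF = 24.5 (null 17.8), P = 0.001
indirect links impossible: 33% (tail->core 65%, core->tail 6%)
```

Reading it: the pooled static network has connectance C = 100·I/(A·P) =
11% and a long pollinator tail (70% of visitor species are specialists),
and is significantly nested. In the daily view the tail is stunted — on
an average day only ~5–6 tail species are present (48% of that day's
visitors). A third of all indirect connections are temporally impossible,
and overwhelmingly in the tail→core direction: late-season tail species
cannot affect core species that have already left the network. None of
this is visible in the static topology.

## Command line

```bash
phenonet simulate --seed 1 --out obs.csv --truth truth.json
phenonet build    --input obs.csv --out edges.csv --summary summary.json
phenonet slices   --input obs.csv --window 10 --out windows.csv
phenonet nodf     --obs obs.csv --null degree_proportional --reps 1000 --seed 42
phenonet middomain --input obs.csv --core-plant P03 --runs 5000 --seed 7
phenonet delays   --input obs.csv --out delays.csv --table table.json
phenonet report   --input obs.csv --out run1/ --seed 11
```

`report` writes the full bundle (summaries, nestedness, per-plant
mid-domain tests, delay tables, provenance with all seeds); identical
configs produce byte-identical bundles.

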