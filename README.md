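# herpatlas

Tools for national-scale reptile (or other terrestrial vertebrate) atlas
analyses: gridded richness mapping, climatic-space characterization,
presence-only distribution models, phylogenetic conservation metrics and a
protected-area gap analysis — with a synthetic-data generator that builds
complete study systems with known truth, so every stage can be validated
end to end without any GIS downloads.

## Who this is for

Conservation biogeographers working from a point-occurrence database, a
time-calibrated species tree and standard environmental rasters, who need
the chain

```
occurrences ─► atlas grid occupancy ─► richness maps
climate rasters ─► PCA climatic space ─► variance-quota clusters
occurrences + 4 predictors ─► ANN ensemble SDM ─► binary range
tree + ranges ─► Faith PD, PD effect size, fair-proportion ED
ranges + protected areas ─► AOO / SPD protection percentages vs targets
```

as reproducible, seeded, testable code rather than a GIS click-path.

## The core quantities

* **Faith's phylogenetic diversity (PD)** of the species set `S` in a grid
  cell is the total branch length of the union of root-to-tip paths,
  `PD(S) = Σ_{b ∈ ∪ paths(S)} ℓ(b)` (rooted: a single-species cell carries
  its full lineage depth, in millions of years).
* **PD standardized effect size**: `PDses = (PD_obs − mean PD_null) / sd
  PD_null`, with the null built from equal-richness uniform draws from the
  native species pool and a two-tailed rank p-value using the
  `(r+1)/(n+1)` convention.
* **Fair-proportion evolutionary distinctiveness (ED)** of a tip is
  `Σ_b ℓ(b)/n_tips(b)` along its root path; ED sums to the total tree
  length, and species are binned low (<48 my), medium (48–96) or high
  (>96).
* **The distribution model** is a single-hidden-layer network (4 logistic
  units, logistic output) trained by batch gradient descent on
  cross-entropy (rate 0.01, 2,000 iterations) against 5 pseudo-absences
  per presence balanced across a 500-m altitude split; 100 replicates with
  25 % held out give an AUC and a mean suitability surface, thresholded at
  the lowest presence prediction and filtered to components contiguous
  with a presence.
* **Gap analysis**: AOO = unique occupied 2×2 km cells × 4 km²; SPD = fine
  cells inside the modelled range (or the records' convex hull for
  species with <5 presence pixels); protection percentages from exact
  polygon intersection, classified against the 17 % and 12 % coverage
  targets.

## Worked example

```python
from herpatlas.synthetic import ScenarioConfig, generate_scenario
from herpatlas.gridding import build_grid, occupancy, richness_map
from herpatlas.phylodiversity import fair_proportion_ed, pd_map, \
    pd_richness_correlation, prune_tree

scenario = generate_scenario(ScenarioConfig(seed=42, records_per_species=50))
print(len(scenario.occurrences), "records,",
      len(scenario.occurrences.species), "species")

atlas = build_grid(scenario.config.extent, 10 / 60)     # 10 arc-minute cells
native = scenario.attributes.loc[scenario.attributes.native, "species"]
occ = {s: c for s, c in occupancy(scenario.occurrences, atlas).items()
       if s in set(native)}
tree = prune_tree(scenario.tree, list(occ))
pd_cells = pd_map(occ, tree, atlas)
rich = richness_map(occ, atlas)
print("max cell richness:", max(rich.values.values()))
print("max cell PD (my):", round(max(pd_cells.values.values()), 1))
print("PD–richness r:", round(pd_richness_correlation(pd_cells, rich), 3))
print(fair_proportion_ed(tree).head(3).to_string(index=False))
```

prints

```
908 records, 20 species
max cell richness: 8
max cell PD (my): 632.7
PD-richness r: 0.96
species        ed category
   sp01 91.402955   medium
   sp03 79.572576   medium
   sp04 77.351191   medium
```

908 deduplicated records for a 20-species fauna; the richest 10-arc-minute
cell holds 8 of the 18 native species and 633 my of accumulated
evolutionary history, and PD tracks richness closely (r = 0.96) — the
familiar pattern that raw species counts are a good surrogate for
evolutionary history. The leading species sit on long, weakly shared
branches of this small tree and land in the medium-ED bin.

The full pipeline (ingest → grids → climate space → SDM → PD/ED → gap →
reports) runs from one config file:

```
herpatlas synth --out world --seed 42
herpatlas run-all --config run.cfg --seed 42
# or in one step:
herpatlas run-synth --out run42 --seed 42
```

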