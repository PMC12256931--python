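# waveways

Functional-connectivity modelling for grizzly and black bears moving among
Pacific-salmon spawning reaches in a coastal island–fjord landscape, built
for movement ecologists and conservation planners who want the full analysis
— resistance surface, circuit-theory current maps, ranked least-cost
corridors, and an empirical validation — as tested, reusable, scriptable
Python rather than a chain of GIS operations.

## The model

Bears tracking the salmon resource wave must cross terrain, cutblocks, and
open water. The landscape is scored as a **resistance surface**: three
habitat layers, each on an ordinal 1 (very low) to 6 (very high) scale —

| layer | classes |
|---|---|
| terrain ruggedness (TRI) | six natural-break classes, 1–6 |
| landcover | mature forest / shrub / rock = 1, regenerating stands (10–75 y) = 3, snow & ice = 6 |
| open water | < 1 km from shore = 3, 1–3 km = 5, > 3 km = 6 |

summed equally and rescaled onto a cumulative 1–10 surface at 150 m
resolution. The raster then becomes a resistor network (8-neighbour; edge
resistance = mean of the two cell values, ×√2 on diagonals). For each pair
of **focal nodes** (midpoints of each salmon species' spawning reach per
stream, merged within 150 m), a unit current is injected and the Laplacian
system *Lv = b* solved; the potential drop gives the **effective resistance
R̂** (and conductance Ĝ = 1/R̂), while per-cell current density — summed
over all pairs into the cumulative current map — is proportional to
random-walk passage probability, exposing pinch points.

For planning, the current map is inverted into a conductance cost surface
and one least-cost path is traced per node pair; the cheapest 5% (by
accumulated cost) are buffered into 1200 m-wide candidate corridors and
their overlap with protected areas is reported.

The surface is validated against movements inferred from genetic recapture:
an individual detected at two hair-snag sites in one season transited
between them. Because transits are rare among all site pairs, the
association of transit with z(Ĝ) and z(distance) is fitted by **Firth's
penalized-likelihood logistic regression** (maximising
l(β) + ½ log det XᵀWX), which is bias-reduced and finite even under
complete separation. A conductance odds ratio above 1 validates the
surface.

A synthetic-landscape module generates every input — autocorrelated
terrain, land/water mosaics with islands, species-labelled stream reaches,
snag-site designs, half-normal detection histories, and Bernoulli transits
— so the whole pipeline runs and is tested fully offline.

## Worked example

```sh
waveways run --out demo --seed 42
```

runs all six stages on the default 9 × 9 km synthetic landscape and logs:

```
simulate: 2160 land cells, 6 streams, 9 reaches, 20 sites, 62 detections
resistance: 3600 cells, cumulative range [1.00, 10.00]
nodes: 9 midpoints -> 6 merged -> 6 snapped (15 pairs)
circuit: 3600 graph nodes, 15 focal pairs, 190 site pairs
lcp: 15 paths, top 1 kept, corridor area 1.4 km^2
validate: OR conductance 1.043, distance 0.211 (9/190 transited)
```

Reading it: the cumulative resistance surface spans its full 1–10 scale;
nine reach midpoints merge to six focal nodes, giving 6·5/2 = 15 circuit
pairs; the top 5% of the 15 least-cost paths (⌈0.75⌉ = 1) becomes a 1.4 km²
corridor. The validation fit (`demo/validation.txt`) reports, per predictor,
the coefficient, odds ratio, 95% CI, and p-value — here distance strongly
suppresses transit (OR 0.21) while conductance is uninformative at this toy
scale (OR 1.04, CI spanning 1), a reminder that the validation has little
power with 9 transits among 190 pairs. Each stage also leaves its artifacts
(`cumulative_current.asc`, `effective_conductance.csv`, `lcp_top.geojson`,
`corridors.geojson`, `manifest.json`, …) in the run directory, and any stage
can be re-run alone, e.g. `waveways lcp --out demo`.

## Layout

- `waveways.synthetic` — landscape, sampling-design, and movement simulators
- `waveways.resistance` — TRI, Jenks breaks, class schemes, cumulative surface
- `waveways.nodes` — reach midpoints, 150 m merge, grid snapping
- `waveways.circuit` — sparse Laplacian solver, R̂/Ĝ, current maps
- `waveways.corridors` — cost conversion, FETE least-cost paths, ranking, buffers
- `waveways.validation` — transit edge lists, Firth regression, prediction curves
- `waveways.pipeline` / `waveways.cli` — stage orchestration, manifests, `waveways` CLI

Rasters are read and written as ESRI ASCII grids, vectors as GeoJSON, and
tables as CSV, so every artifact is plain text and diffable. See
`docs/methods.md` for modelling assumptions and numerical choices.
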