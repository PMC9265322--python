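# econetkit

Construction and structural evaluation of regional **ecological networks**
from categorical land-cover rasters, for landscape ecologists and spatial
planners working at metropolitan scale. The package implements the full
source–corridor–node workflow used in ecological-security planning, plus a
Markov–cellular-automaton land-cover projector and a seeded
synthetic-landscape generator so every stage is testable without external
data.

## The workflow

1. **Morphological spatial pattern analysis (MSPA).** A binary
   foreground/background landscape (foreground: paddy field, woodland,
   grassland, water area, bottomland) is segmented with chamfer-distance
   morphology into *core, islet, edge, perforation, bridge, loop, branch*.
   Core components are candidate ecological sources.
2. **Connectivity-based source selection.** On the patch graph with
   edge-to-edge distances `d_ij` and a dispersal threshold, the indices

   - `LCP = Σ_components (Δ_i / S_L)²`
   - `IIC = [Σ_ij a_i a_j / (1 + nl_ij)] / S_L²`
   - `PC  = [Σ_ij a_i a_j μ*_ij] / S_L²`, `μ*` the best path product of
     `p(d) = exp(k d)` with `p = 0.5` at the threshold,

   are computed at thresholds of 100–2000 m. Patch importance
   `dΦ_x = 100·(Φ − Φ_remove,x)/Φ` ranks patches; sources are patches with
   `dPC > 1`.
3. **Resistance surface.** Four graded layers — MSPA class, land-cover
   class, elevation, slope — mapped to coefficients on a 1–100 ladder and
   overlaid as a weighted sum with AHP weights (0.5638, 0.2634, 0.1178,
   0.055 by default; consistency ratio checked).
4. **Corridors.** Exact Dijkstra cost distance over the surface; the
   least-cost path is traced for every source pair, paths under 10 km and
   duplicates are dropped, and survivors are ranked by the gravity model
   `G_ij = L_max² ln(a_i) ln(a_j) / L_ij²`, tiered at
   `G > 100` (level 1), `10 < G ≤ 100` (level 2), `1 < G ≤ 10` (level 3),
   `G ≤ 1` excluded.
5. **Nodes.** D8 flow analysis of the resistance surface (priority-flood
   fill, steepest-descent routing, accumulation) yields valley lines and —
   on the negated surface — ridge lines. Nodes are typed *strategic* (ridge
   × maximum-cost corridor), *natural* (crossings of corridors persistent
   across dates) and *artificial* (valley × roads/rivers/paddy).
6. **Network structure.** For each corridor–node pairing:
   `α = (L − V + 1)/(2V − 5)`, `β = L/V`, `γ = L/(3(V − 2))`, and
   `cost ratio = 1 − L/C` with `C` the summed corridor length.

The Markov–CA module estimates class-transition matrices from raster pairs,
projects per-class demand (`counts × Pᵏ`, integer-conserving), and allocates
it with a cellular automaton driven by suitability × neighbourhood density ×
class inertia, validated by Kappa and overall accuracy.

## Worked example

The numbered drivers under `analysis/` run the whole study on the synthetic
demo landscape (220 × 300 cells at 90 m, three dates, seed 42):

```sh
python analysis/01_generate_landscape.py
python analysis/02_project_landuse.py
python analysis/03_identify_sources.py
python analysis/04_resistance_surface.py
python analysis/05_extract_corridors.py
python analysis/06_locate_nodes.py
python analysis/07_evaluate_network.py
```

Selected output (abridged):

```
47 core patches of >= 10 cells; largest 61.51 km2
 threshold_m  NC    IIC     PC  dPC_mean  dPC_max
       100.0  47 0.1493 0.1493    2.1277  55.3789
      1000.0   3 0.3944 0.4757    4.7505  65.3877
      2000.0   1 0.4377 0.6682    4.6539  59.4877
13 sources with dPC > 1.0 at 1000 m
resistance surface: min 10.00, mean 40.46, max 77.26
15 paths survive the >= 10.0 km length filter and deduplication
tiers (bounds (1.0, 10.0, 100.0)): level 1: 12, level 2: 3; excluded: 0
70 nodes: {'strategic': 6, 'natural': 3, 'artificial': 61}
agreement with held-out t2: kappa = 0.9478, OA = 0.9565
```

Reading this: at the 100 m threshold every patch is its own component
(NC = 47); by 2000 m the landscape is fully connected and IIC/PC rise
monotonically. Thirteen core patches contribute more than 1 % of total PC
when removed and become sources; their pairwise least-cost paths over the
resistance surface yield 15 corridors, most with high gravity because the
demo sources are large and close. Node counts are dominated by artificial
nodes, as valley lines repeatedly cross the paddy/water substrate. The CA
projection reproduces the held-out third date with κ ≈ 0.95. All tables and
rasters land under `results/demo/`.

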