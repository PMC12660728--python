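# riverscape

Historical biogeography and stream-order diversity analysis for riverine
clades — built around the questions raised by Amazonian fish radiations,
where river networks act simultaneously as dispersal corridors, barriers,
and habitat templates.

The package has two analysis tracks and a synthetic-data generator that
makes both testable end to end without any external downloads:

1. **Ancestral-area estimation under DEC.**  A lineage's geographic range is
   a subset of discrete bioregions evolving along a time-calibrated
   phylogeny under the dispersal–extinction–cladogenesis (DEC) model:
   between speciations the range gains area *j* at rate
   δ · Σ_{i∈R} m_ij (δ the macroevolutionary dispersal rate, *m* the
   dispersal-multiplier matrix of the current time slice) and loses any
   occupied area at rate *e*; at speciation the range splits by vicariance
   or subset sympatry, all distinct ordered daughter pairs equally likely.
   A *landscape evolution model* (LEM) packages the bioregions with one
   multiplier matrix per time slice, so paleogeographic rearrangements
   (e.g. a connectivity switch at 10 Ma) enter the likelihood directly.
   The engine computes the pruning likelihood, maximizes it over (δ, e),
   compares LEMs by AIC = 2K − 2 lnL (K = 2), and reconstructs marginal
   ancestral-range posteriors at every internal node.

2. **Stream-order diversity partitioning.**  Occurrence records keyed by
   Strahler stream order (SO) are cleaned (duplicate coordinates collapsed,
   out-of-bounds records dropped), turned into a species × SO incidence
   matrix, and partitioned into per-order alpha diversity, pooled gamma,
   Whittaker's beta β_W = γ / ᾱ, and pairwise absolute turnover
   β_A = (S₁ − c) + (S₂ − c).  River-segment tables supply Horton-law
   summaries (shares of total length, surface area and volume per order)
   and per-km alpha densities with a stream-order regression
   (min–max-normalized via N = (x − x_min)/(x_max − x_min)).

## Worked example

Simulate a 24-species clade with known ground truth, then fit two rival
LEMs and reconstruct ancestral areas:

```python
import numpy as np
from riverscape import (SimulationConfig, simulate_bundle, read_newick,
                        load_lem, read_range_matrix, fit_lems,
                        marginal_ancestral_ranges, DECParams)
from riverscape.geography import stepping_stone_chain

config = SimulationConfig(seed=7, n_tips=24, n_records=300)
simulate_bundle(config, "demo")                      # writes tree/ranges/LEM/...
tree = read_newick("demo/tree.nwk")
lem = load_lem("demo/lem.yaml")                      # the generating chain LEM
full = stepping_stone_chain(list("ABCD"), name="full4")
full.slices[0].multipliers[:] = 1 - np.eye(4)        # rival: full connectivity
ranges = read_range_matrix("demo/ranges.csv", lem)
fits, table = fit_lems(tree, ranges, [lem, full], seed=1)
print(table.to_string(index=False))
```

```
   lem  n_species  n_regions model        lnL  K    delta            e       AIC     dAIC  favored
chain4         24          4   DEC -18.771185  2 0.026794 1.000000e-09 41.542370 0.000000     True
 full4         24          4   DEC -23.063087  2 0.009138 6.470886e-09 50.126175 8.583805    False
```

The generating stepping-stone model wins by ΔAIC ≈ 8.6; the rival has to
spread its dispersal rate over corridors the data never used.  `delta` and
`e` are events per lineage per Myr; lnL is in nats.  Marginal
ancestral-range posteriors per node come from the same fit:

```python
dists = marginal_ancestral_ranges(tree, ranges, lem,
                                  DECParams(fits[0].delta_hat, fits[0].e_hat))
```

giving, per internal node, a probability for each candidate range
(`nd1  13.4 Ma  AB  0.987` reads: at the 13.4 Ma node, range {A,B} has
posterior 0.987).

The same analyses are scriptable from the shell:

```sh
riverscape simulate --out demo --seed 7 --n-tips 24
riverscape fit --tree demo/tree.nwk --ranges demo/ranges.csv \
    --lem demo/lem.yaml --out results --seed 1
riverscape diversity --occurrences demo/occurrences.csv \
    --segments demo/segments.csv --out results
riverscape sisters --tree demo/tree.nwk --ranges demo/ranges.csv \
    --lem demo/lem.yaml --out results
```

Example seven-bioregion LEM configs (a stepping-stone adjacency and a
two-time-slice paleogeographic scenario over the Brazilian Shield, Guiana
Shield, La Plata, Negro, Orinoco, Trans-Andean and Western Amazon regions)
ship under `src/riverscape/configs/` as documented synthetic
reconstructions.

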