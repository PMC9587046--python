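# msgnet

Analysis toolkit for **mixed-species groups (MSGs) of savanna mammals along
stress gradients**. In African savannas, herbivores of different species
aggregate into mixed groups, and the *stress gradient hypothesis* predicts
that such positive associations intensify under environmental stress —
predation risk from lions, or scarce/overabundant forage. `msgnet`
implements the full analysis chain a field survey of this kind needs, plus a
synthetic-data generator with known planted structure so every stage has a
parameter-recovery test without any field data.

## What it computes

Given sighting records (species, location, date, count, habitat) or
pre-formed animal groups:

1. **Group formation & scenario classification** (`msgnet.spatial`) —
   single-linkage chaining of sightings within 50 m into groups; lion home
   range as an 85%-isopleth minimum convex polygon over predator sightings;
   NDVI tertiles (small/medium/large productivity); 2-km core/edge
   human-activity zone.
2. **MSG-occurrence regression** (`msgnet.glm`) — logistic regression of
   group type (mixed = 1 vs single-species = 0) on habitat, NDVI class,
   home-range membership and zone, reported as odds ratios with Wald 95%
   CIs; Cramér's V collinearity screen.
3. **Association networks** (`msgnet.networks`) — species graphs weighted by
   Dice's index `w_ij = 2 N_ij / (N_i + N_j)`, where `N_i`, `N_j`, `N_ij`
   count groups containing species *i*, *j*, and both. Node strength
   `s_i = Σ_j w_ij`, the disparity (Y) measure `Y_i = Σ_j (w_ij / s_i)²`,
   and a Barrat-style weighted clustering coefficient. Scenario networks
   (inside/outside the lion home range; NDVI tertiles) are compared via
   three disjoint subsampled replicates and Welch's t-test on the logs of
   focal-species-averaged measures. Graphviz DOT export for figures.
4. **Dyadic randomisation tests** (`msgnet.nullmodels`) — the null holds
   every binary group×species matrix with the observed row and column sums
   equally likely, sampled by checkerboard swaps (Monte-Carlo chain); the
   habitat-stratified variant additionally fixes per-habitat species totals,
   so an association that survives it cannot be explained by shared habitat
   preference. An exact enumeration oracle validates the chain on small
   matrices.
5. **Assortative mixing** (`msgnet.assortment`) — fractional-logit
   regression of pairwise Dice weights on similarity in lion prey
   susceptibility (Jacobs' index) and in diet (monocot proportion), with
   significance from node-label permutation.
6. **Synthetic surveys** (`msgnet.simulate`) — a one-round
   independent-joining generator over a 183 km² landscape: a seed species
   drawn by abundance × habitat preference, other species joining with
   probability `logistic(α_j + a_seed,j + scenario term)`; planted pairwise
   affinities `a_ij` and scenario odds ratios are recorded in a truth file.

## Worked example

```bash
msgnet simulate --out-dir survey --seed 4 --n-groups 900
msgnet classify --groups survey/groups.csv --lions survey/lions.csv \
    --out survey/classified.csv
msgnet glm --groups survey/classified.csv --out survey/or.csv
```

The regression table (this exact output, seed 4):

```
                  term  odds_ratio   ci_low  ci_high  p_value   n
    habitat[grassland]    1.941168 1.278748 2.946739 0.001843 900
habitat[open_bushland]    2.082833 1.424603 3.045194 0.000153 900
     habitat[riverine]    0.497140 0.183632 1.345885 0.169015 900
     ndvi_class[small]    1.981982 1.347317 2.915611 0.000513 900
     ndvi_class[large]    1.485897 1.008542 2.189190 0.045179 900
        in_lhr[inside]    1.625735 1.022524 2.584793 0.039964 900
            zone[core]    1.031018 0.737659 1.441041 0.858085 900
```

Read: mixed groups were about 1.6 times more likely inside the (estimated,
85% MCP) lion home range than outside — the planted truth is an odds ratio
of 1.69 — and more likely at both small and large NDVI than at medium
(planted 1.82 / 1.64), the U-shaped productivity effect. The zone term is
null, as planted. Reference levels: bushland habitat, medium NDVI, outside
the home range, edge zone. Downstream:

```bash
msgnet compare --groups survey/classified.csv --pair inside_lhr,outside_lhr \
    --seed 1 --out survey/compare.csv        # Welch tests on 3 network measures
msgnet dyads --groups survey/classified.csv --scenario inside_lhr \
    --out survey/dyads.csv                   # randomisation tests per species pair
msgnet assort --groups survey/classified.csv --scenario inside_lhr \
    --out survey/assort.csv                  # assortative-mixing permutation test
```

`dyads.csv` lists, per pair, the Dice index, the co-occurrence count and
upper-tail p-values under both nulls; pairs significant without but not with
habitat stratification are associations explainable by shared habitat
preference.

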