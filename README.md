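# somward

Clustering and visualization of how students cognitively structure the
concept of *aliveness*, from ranked free-list survey data, using a
self-organizing map (SOM) combined with topology-constrained Ward
agglomeration (SOM-Ward).

## The problem and the data

In the underlying survey task, each of 100 high-school students wrote
down "the first 10 living things coming to your mind", in order.  The
listing order carries signal: things named early are more prototypically
*alive* to the respondent.  Each written name is assigned to one of ten
biological groups (1 prokaryotes/protists/funguses, 2 plants,
3 invertebrates, 4 fishes, 5 amphibians, 6 reptiles, 7 birds, 8 wild
mammals, 9 domestic mammals and pets, 10 human), preserving ranks.

For student *i* and group *g*, let r<sub>g</sub> be the mean 1-based
rank at which the student listed members of *g*.  The model input is
the **aliveness score**

    x_g = 11 − r_g   if group g was listed,
    x_g = 0          otherwise,

so a group listed only first scores 10, only last scores 1, and an
unlisted group scores 0 (without the reflection, "never listed" would
sit next to "listed first" in Euclidean distance).  This yields a
100 × 10 matrix on the 0–10 scale, which ships with the package.

## The model

1. **Batch SOM.**  A hexagonal grid of ~1000 neurons, each with a
   weight vector w<sub>j</sub> ∈ ℝ¹⁰.  The best matching unit (BMU) of
   an input x is i(x) = argmin<sub>j</sub> ‖x − w<sub>j</sub>‖.  Per
   epoch, all BMUs are found with frozen weights, then every weight is
   replaced by the Gaussian-neighborhood-weighted mean of the data:
   w<sub>j</sub> = Σ<sub>i</sub> h<sub>j,i(x_i)</sub> x<sub>i</sub> /
   Σ<sub>i</sub> h<sub>j,i(x_i)</sub>, with
   h<sub>j,b</sub> = exp(−d<sub>grid</sub>(j,b)²/2σ²).  The radius σ
   decays exponentially to the **tension** parameter (0.5 here); the
   classic sequential rule
   w<sub>j</sub> ← w<sub>j</sub> + η h<sub>j,i(x)</sub>(x − w<sub>j</sub>)
   is also implemented.
2. **SOM-Ward.**  Ward agglomeration over the neuron prototypes, with
   merge cost d<sub>rs</sub> = n<sub>r</sub>n<sub>s</sub>/(n<sub>r</sub>+n<sub>s</sub>) ·
   ‖x̄<sub>r</sub> − x̄<sub>s</sub>‖² (the increase in within-cluster
   SSE) — except that clusters that are not lattice-adjacent are
   treated as infinitely distant, so only *associated* clusters merge.
   Nodes are weighted by their mapped-student counts, making the
   agglomeration observation-level.  Cutting the dendrogram at k = 3
   and assigning each student to its BMU's cluster yields the student
   segmentation.
3. **Map products.**  U-matrix (per-neuron mean weight distance to
   lattice neighbors; ridges mark cluster boundaries), per-variable
   component planes, and hit counts, exported as CSV matrices and PNG
   heatmaps.

## Worked example

```sh
somward transform src/somward/data/example_responses.tsv -o examples.csv
somward run examples.csv -o out -k 2 --neurons 64 --epochs 15
```

Or, in Python, the full canonical analysis:

```python
>>> import somward as sw
>>> ds = sw.load_packaged_dataset()          # 100 students x 10 variables
>>> res = sw.run_analysis(ds, k=3, target_neurons=1000, order_by="human")
>>> {c: round(p) for c, p in res.solution.percentages.items()}
{3: 35, 2: 33, 1: 32}
>>> res.solution.profile.round(2)[["human", "domestic_mammals", "fishes"]]
         human  domestic_mammals  fishes
cluster
1         8.32              4.21    0.41
2         4.83              6.44    2.94
3         0.76              5.66    2.23
```

Cluster 1 is the *anthropocentric* segment (human scores dominate),
cluster 2 the *primary animistic* segment (domestic/familiar animals —
birds, pets, fishes), cluster 3 the *secondary animistic* segment
(wild/unfamiliar animals and microorganisms).  The numbered scripts
under `analysis/` run the same pipeline step by step and write their
tables under `results/`:

```sh
python analysis/01_preprocess.py        # coding + rank transform checks
python analysis/02_run_somward.py       # canonical ~1000-neuron run
python analysis/03_replication.py       # 10-seed medians
python analysis/04_synthetic_recovery.py  # planted-archetype ARI
```

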