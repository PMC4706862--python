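"""Train the ~1000-neuron batch map on the 100-student dataset and cut
the SOM-Ward dendrogram at k = 3.

This is the canonical deterministic run (linear initialization, batch
mode, tension 0.5, mapped-student node weights).  Writes the trained
map, merge trace, cluster solution, profile table, U-matrix, hit counts
and component planes under results/somward/ and prints the cluster
shares and the tail of the merge-distance curve.
"""

from pathlib import Path

import somward as sw

OUT = Path(__file__).resolve().parents[1] / "results" / "somward"

ds = sw.load_packaged_dataset()
rows, cols = sw.plan_grid(ds.values, target_neurons=1000)
print(f"planned grid: {rows} x {cols} = {rows * cols} neurons")

res = sw.run_analysis(ds, k=3, target_neurons=1000, order_by="human")
sw.write_outputs(res, ds, OUT)

print(f"quantization error: {res.quantization_error:.4f}")
print("merge-distance curve tail (k, Ward distance):",
      [(k, round(d, 1)) for k, d in sw.merge_distance_curve(res.trace)[-5:]])
print("clusters (1 = highest human mean):")
prof = res.solution.profile
for c in prof.index:
    top = prof.loc[c].sort_values(ascending=False)
    print(f"  C{c}: {res.solution.percentages[c]:.0f}% of students; "
          f"top variables: {top.index[0]} {top.iloc[0]:.2f}, "
          f"{top.index[1]} {top.iloc[1]:.2f}")
print(f"outputs in {OUT}")
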