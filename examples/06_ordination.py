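"""Sample ordination: Euclidean distances, NMDS, medians to T0.

The metatranscriptome of each array is its log2 profile over the
detected-gene universe; NMDS embeds the pairwise Euclidean distances and
reports Kruskal stress-1 (values below ~0.1 indicate a faithful 2-D
picture). Median distances to the T0 controls rank how strongly each
nutrient amendment moved the community transcriptome.
"""

import phytoarray as pa

design = pa.simulate_design(seed=1)
intensities, sheet, _truth = pa.simulate_experiment(
    design, pa.default_truth_config(seed=1))
expr = pa.normalize_pipeline(intensities, design)

d = pa.euclidean_distances(expr)
result = pa.nmds(d, dim=2, restarts=20, seed=1)
print(f"NMDS over {len(d)} samples: stress-1 = {result.stress:.3f}")

medians = pa.group_distance_summary(d, sheet)
print("median Euclidean distance to T0 controls, ascending:")
print(medians.round(2).to_string())
# Conditions with implanted responses (urea, NH4, NO3, FDW) sit further
# from T0 than the T24 controls; replicates of a condition cluster
# together in the embedding.
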