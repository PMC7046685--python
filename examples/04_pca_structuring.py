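"""Population structuring by PCA on consensus ROH regions.

Codes every animal 0/1 at the most frequent consensus ROH regions
(frequency >= 12.5%, capped at 170), runs PCA on the centered incidence
matrix, retains components by the Kaiser rule, and ranks regions by their
contribution to the retained components.
"""

import rohscan

cfg = rohscan.emulate_study_profile(seed=3)
gm, _ = rohscan.simulate_panel(cfg)
segments = rohscan.detect_roh_sliding(gm)

curve = rohscan.support_curve(segments, gm.variants, gm.samples["sample_id"])
regions = rohscan.call_islands(curve, min_freq=0.125)
incidence = rohscan.build_incidence(segments, regions, gm.samples["sample_id"],
                                    min_freq=0.125, top_n=170)
print(f"incidence matrix: {incidence.shape[0]} samples x "
      f"{incidence.shape[1]} consensus regions")

pca = rohscan.run_pca(incidence)
print(f"Kaiser rule retains {pca.k_retained} of {len(pca.eigenvalues)} components; "
      f"PC1-3 explain {pca.explained_pct[:3].sum():.1f}% of variance "
      f"(PC1 alone {pca.explained_pct[0]:.1f}%)")

top10 = rohscan.top_contributing_loci(pca, 10)
print("\nten regions contributing most to the retained components:")
print(top10.round(2).to_string())

scores = pca.scores.join(gm.samples.set_index("sample_id")["group"])
print("\ngroup centroids in PC1/PC2 (distinct utility groups separate):")
print(scores.groupby("group")[["PC1", "PC2"]].mean().round(2).to_string())
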