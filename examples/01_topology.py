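"""Atlas topology: from ROI -> network assignments to network-pair sets.

Builds the default synthetic 13-network / 230-ROI atlas, enumerates all
unordered ROI-pairs and partitions them into network-pairs, then applies the
small-pair exclusion rule used before significance testing.
"""

import fcora

atlas = fcora.make_synthetic_atlas()
index = fcora.build_roi_pair_index(atlas)

print(f"{atlas.n_rois} ROIs across {atlas.n_networks} networks")
print(f"{index.n_pairs} ROI-pairs partitioned into "
      f"{index.n_network_pairs} network-pairs")

report = fcora.network_pair_report(index)
print("\nFive largest network-pairs:")
print(report.nlargest(5, "size").to_string(index=False))

kept, removed = fcora.exclude_small_network_pairs(index.network_pairs, min_size=50)
print(f"\n{len(removed)} network-pairs have fewer than 50 ROI-pairs and are "
      f"excluded from testing; {len(kept)} retained.")
print("The counts matter because the smallest attainable null tail of a "
      "size-S pair is (1-alpha)^S:")
print(f"  size 6 at alpha=0.5 -> {fcora.min_attainable_tail(6, 0.5):.4f} "
      "(can never reach the 1e-4 Bonferroni target)")
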