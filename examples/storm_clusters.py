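"""Cluster and nearest-neighbor analysis of simulated localization data.

Builds two conditions — dimers only, and a dimer/tetramer mixture — plus a
clustered pattern with a 40% clustered fraction, then runs the cluster
detector, the nearest-neighbor analysis and the two-sample KS comparison.
"""

import numpy as np

from navclust import simulate as sim
from navclust import storm

# 40% of molecules planted in clusters, one blink per molecule
cfg = sim.LocSimConfig(clustered_fraction=0.4,
                       blinks_per_molecule=sim.DistSpec(1.0, 0), seed=12)
table, truth = sim.simulate_localization_pattern(cfg)
cs = storm.detect_clusters(table, eps=20.0, min_pts=3)
print("clustered pattern: %d localizations, planted clustered fraction %.1f%%"
      % (len(table), 100 * (truth["blink_cluster"] >= 0).mean()))
print("  percent clustered (DBSCAN eps=20 nm, min_pts=3): %.1f%%"
      % cs.percent_clustered)
print("  clusters found: %d, median radius %.1f nm (planted mean %.0f nm)"
      % (len(cs.clusters), cs.clusters["radius_nm"].median(),
         cfg.cluster_radius.mean))

# dimers (NN mode ~6 nm) vs dimers+tetramers (modes ~6 and ~12 nm)
uni, _ = sim.simulate_oligomer_pattern(n_dimers=5000, n_tetramers=0, seed=21)
bi, _ = sim.simulate_oligomer_pattern(n_dimers=2500, n_tetramers=1250, seed=22)
nn_uni = storm.nearest_neighbor_distances(uni, bin_width=2.0)
nn_bi = storm.nearest_neighbor_distances(bi, bin_width=2.0)

centers = 0.5 * (nn_bi.bin_edges[:-1] + nn_bi.bin_edges[1:])
dens = nn_bi.density
peaks = sorted([(dens[i], centers[i]) for i in range(1, len(dens) - 1)
                if dens[i] >= dens[i - 1] and dens[i] > dens[i + 1]])[-2:]
print("\nmixture NN histogram modes (2 nm bins):",
      sorted(round(float(c), 1) for _, c in peaks), "nm")

d, p = storm.ks_two_sample(nn_uni.distances, nn_bi.distances)
print("two-sample KS, dimer-only vs mixture: D = %.3f, p = %.3g "
      "(n = %d, %d)" % (d, p, len(nn_uni.distances), len(nn_bi.distances)))
print("\nA vanishing p says the two nearest-neighbor distributions differ; "
      "the extra ~12 nm mode is the tetramer spacing.")
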