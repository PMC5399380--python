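"""From a raw z-stack to the spheroid's point cloud.

Shows the middle pipeline stages: Otsu threshold from the greyscale
distribution profile, binarisation, voxel-centre point cloud, and
DBSCAN isolation of the main spheroid from injected salt noise.
"""

import numpy as np

import lumenfill as lf

stack, truth = lf.generate_phantom(lf.hollow_control_spec(seed=3))
grey = lf.to_greyscale(stack)

profile = lf.build_profile(grey)
threshold = lf.compute_threshold(profile)
mask = lf.binarize(grey, threshold)
print(f"Otsu threshold: {threshold:.1f} (intensities span "
      f"{grey.voxels.min():.0f}..{grey.voxels.max():.0f})")
print(f"foreground voxels: {mask.mask.sum()} "
      f"-> {mask.mask.sum() * grey.voxel_volume_um3:.0f} um^3")

# corrupt the mask with isolated far-away voxels, as detector noise would
rng = np.random.default_rng(0)
for _ in range(50):
    z, y, x = rng.integers(0, 5), rng.integers(0, 10), rng.integers(0, 10)
    mask.mask[z, y, x] = True

cloud = lf.mask_to_points(mask, grey.pitch)
eps = lf.default_eps_um(grey.pitch)  # 2 x max pitch = 4 um
labeling = lf.cluster_points(cloud, eps_um=eps, min_points=10)
main = lf.extract_main_cluster(cloud, labeling)
n_clusters = len(set(labeling.labels) - {-1})
n_noise = int((labeling.labels == -1).sum())
print(f"DBSCAN (eps = {eps} um): {n_clusters} cluster(s), {n_noise} noise points")
print(f"main cluster keeps {len(main)} of {len(cloud)} points "
      "(injected noise voxels rejected)")
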