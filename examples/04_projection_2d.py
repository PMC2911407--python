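"""2D projection: what localization microscopy would see.

Projects each fiber onto a random plane (as in 2D high-resolution light
microscopy), then compares the 2D pair statistics with the 3D ones:
projection only shortens distances, fills in the sub-10 nm region, but
keeps the dominant peak identifiable.
"""

import numpy as np

import e2afiber as ef

cfg = ef.SimulationConfig(params=ef.default_params().regular(),
                          fiber_length_bp=80_000, n_fibers=12, rng_seed=3)
ens = ef.simulate_ensemble(cfg)
rng = np.random.default_rng(0)

d3, r3 = ef.pair_distances(ens.fibers, cutoff_nm=40.0)
proj = [ef.project_fiber(f, rng=rng) for f in ens.fibers]
d2, r2 = ef.pair_distances(ens.fibers, cutoff_nm=40.0, points_override=proj)

h3 = ef.conditional_probability(r3, 40.0)
h2 = ef.conditional_probability(r2, 40.0, dimensionality=2)
below10_3d = h3.counts[h3.centers < 10].sum()
below10_2d = h2.counts[h2.centers < 10].sum()
print(f"pairs below 10 nm   3D: {below10_3d:.0f}   2D: {below10_2d:.0f}")
print(f"pairs within 40 nm  3D: {h3.n_pairs_total}   2D: {h2.n_pairs_total}")

n_pts = sum(f.n_nucleosomes for f in ens.fibers)
h2.n_points_total = n_pts
rc, g2 = ef.pair_distribution_2d(h2)
k = np.argmax(g2 * (rc > 15))
print(f"g2D first shell at r = {rc[k]:.1f} nm (shifted below its 3D "
      "position: projection can only shorten distances)")
# 3D p(r) is exactly zero below the 11 nm contact distance; after
# projection formerly longer distances fold below 10 nm -- an artifact
# a microscopy analysis must expect.
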