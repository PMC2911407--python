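"""Nucleosome pair statistics: p(r), r_Delta table and peak structure.

Reproduces the genomic-vs-spatial distance ladder of the calibrated
zigzag: adjacent nucleosomes sit ~51 nm apart while second neighbours
(Delta=2) are closest in space (~37 nm) -- the crossed-linker geometry.
"""

import numpy as np

import e2afiber as ef

cfg = ef.SimulationConfig(params=ef.default_params().regular(),
                          fiber_length_bp=80_000, n_fibers=12, rng_seed=3)
ens = ef.simulate_ensemble(cfg)

d, r = ef.pair_distances(ens.fibers, delta_max=10)
st = ef.r_delta_stats(d, r)
print("Delta [NRL]   <r>    sigma   mode  (nm)")
for dd, m, s, mf in zip(st.delta, st.mean_nm, st.sd_nm, st.mode_nm):
    print(f"{dd:8d}   {m:7.2f} {s:6.2f} {mf:7.2f}")

# conditional probability p(r) inside a 40 nm sphere and its peaks
d40, r40 = ef.pair_distances(ens.fibers, cutoff_nm=60.0)
h = ef.conditional_probability(r40, 60.0, bin_nm=1.0)
modes = {int(a): float(m) for a, m in
         zip(st.delta, ef.r_delta_stats(d, r, mode_bin_nm=1.0).mode_nm) if a <= 3}
peaks = ef.detect_peaks(h.centers, h.p(), component_modes=modes,
                        prominence_frac=0.05, smooth_bins=3)
for label, pk in zip(peaks.labelled(), peaks.peaks):
    print(f"peak {label}: r = {pk.position_nm:.1f} nm <- Delta {pk.deltas}")
# The dominant peak is the sharp Delta=1 shell; the much broader
# Delta=3 shell has the same 51 nm mean and superposes on it, while the
# Delta=2 shell forms the left flank.
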