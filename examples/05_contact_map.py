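"""Random-collision statistics: interaction maps, central gap, loops.

Contacts are site pairs within the 35 nm interaction radius; the
genomic stretch between them is a loop.  Regular fibers are too stiff
to loop on the few-kbp scale, so their contact map has a wide empty
band around the diagonal; histone depletion fills it in -- the
mechanism that lets promoters and enhancers meet.
"""

import numpy as np

import e2afiber as ef

params = ef.default_params()
for label, p in [("regular", params.regular()), ("disturbed", params)]:
    cfg = ef.SimulationConfig(params=p, fiber_length_bp=160_000, n_fibers=20,
                              rng_seed=11)
    ens = ef.simulate_ensemble(cfg)
    cmap = ef.interaction_map(ens.fibers, bin_bp=2000)
    gap = ef.gap_width(ef.center_cut(cmap))
    loops = [r.loop_bp / 1000 for f in ens.fibers for r in ef.detect_contacts(f)]
    loops = np.asarray(loops)
    small = (loops <= 10.0).sum() if len(loops) else 0
    mn = loops.min() if len(loops) else float("nan")
    print(f"{label:9s}: central gap {gap:5.1f} kbp | {len(loops):6d} contacts, "
          f"{small} loops <= 10 kbp, shortest {mn:.1f} kbp")
# The disturbed map's central gap is much narrower and kbp-scale loops
# appear only with depletion.
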