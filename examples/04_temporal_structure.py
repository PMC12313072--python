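"""Probe which temporal scales survive reconstruction.

Evaluates reconstructions against temporally disrupted versions of the
true stimuli: moment-matched textures (no temporal sequence at all) and
segment-shuffled spectrograms at nine window sizes from 12 to 2,000 ms.
"""

import numpy as np

from neurosound import benchmark as bm
from neurosound.features import SHUFFLE_WINDOWS_MS

bench = bm.make_benchmark(seed=1, profile="generator",
                          noise_sd=bm.DEFAULT_NOISE_SD)
recs = bm.reconstruct_test_set(bench, source="decoded")

plain = np.mean([o.accuracy for o in
                 bm.recon_identification(recs, bench, stage=0)])
tex = np.mean([o.accuracy for o in
               bm.recon_identification(recs, bench, perturbation="texture",
                                       seed=9)])
print(f"pixel identification, intact true candidate:   {plain:.3f}")
print(f"pixel identification, textured true candidate: {tex:.3f}")

print("shuffle windows (category stage):")
for wms in SHUFFLE_WINDOWS_MS:
    acc = np.mean([o.accuracy for o in
                   bm.recon_identification(recs, bench, perturbation="shuffle",
                                           window_ms=wms, seed=9, stage=6)])
    print(f"  {wms:5d} ms  accuracy {acc:.3f}")

# Texturing the true candidate removes its temporal sequence and lowers
# pixel-level accuracy. Under shuffling, coarse segments tend to score at
# least as well as fine ones because they spare the short-term structure
# reconstructions actually carry — at this desk scale the trend is shallow
# and fluctuates a little from seed to seed.
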