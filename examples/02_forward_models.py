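"""Evaluate the MM and TID forward models on the acquisition protocol.

Restricted diffusion inside spheres makes the MM signal depend on the
diffusion time: at equal b, the long-Delta measurements are attenuated
more than exp(-b ADC) would predict. The TID model, by construction,
gives identical signals at both diffusion times for equal b.
"""

import numpy as np

from mmtid import (MMParams, TIDParams, mm_signal, sphere_gpd_roots,
                   tid_signal, two_diffusion_time_protocol)

proto = two_diffusion_time_protocol()
print("first GPD sphere eigenvalues:", np.round(sphere_gpd_roots(3), 5))

mm = MMParams(R=10.0, Di=1.0, De=0.6, fi=0.41)   # typical day-0 tumor voxel
tid = TIDParams(Dprime=1.5)
s_mm = mm_signal(mm, proto)
s_tid = tid_signal(tid, proto)
print("   b (s/mm^2)   Delta    S_MM     S_TID")
for m, a, b in zip(proto, s_mm, s_tid):
    print(f"  {m.b:9.1f}  {m.Delta:6.2f}  {a:7.4f}  {b:7.4f}")
# Note the MM signal at b=1000 (Delta=9.86) vs b=689 (Delta=40): the
# restricted compartment decays little with Delta while the b-driven
# extracellular part dominates — this time dependence is what the AICc
# comparison detects.
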