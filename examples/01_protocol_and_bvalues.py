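"""Build the two PGSE protocols and inspect their b-values.

The two-diffusion-time protocol (delta = 4.65 ms, Delta = 9.86 / 40.0 ms,
G = 0/113/207/293 mT/m, rise 0.245 ms) drives the MM/TID model
comparison; the single-diffusion-time protocol (same short Delta, no
b=0) drives conventional ADC mapping.
"""

from mmtid import (compute_b_value, single_diffusion_time_protocol,
                   two_diffusion_time_protocol)

two = two_diffusion_time_protocol()
print("two-diffusion-time protocol:")
for m in two:
    print(f"  G={m.G:5.0f} mT/m  Delta={m.Delta:5.2f} ms  b={m.b:7.1f} s/mm^2")

one = single_diffusion_time_protocol()
print("single-diffusion-time protocol (ADC):")
for m in one:
    print(f"  G={m.G:5.0f} mT/m  Delta={m.Delta:5.2f} ms  b={m.b:7.1f} s/mm^2")

b = compute_b_value(G=293, delta=4.65, Delta=9.86, rise=0.245)
print(f"strongest short-Delta measurement: b = {b:.1f} -> nominal {round(b / 10) * 10}")
# The b-values round to the nominal 150/500/1000 set; the ratio between
# the two diffusion times at fixed G is exactly constant (about 4.593).
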