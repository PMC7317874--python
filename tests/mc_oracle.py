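"""Random-walk Monte-Carlo oracle for restricted diffusion in a sphere.

Independent of the package's GPD implementation: walkers diffuse inside
an impermeable sphere (Gaussian steps, specular reflection at the
boundary), accumulating spin phase under the exact trapezoidal gradient
waveform; the echo attenuation is the ensemble mean of cos(phase).
"""

import numpy as np
from numba import njit

GAMMA_MS = 2.6752219e8 * 1e-12  # rad per (ms * mT/m * um)


@njit(cache=True)
def sphere_walk_attenuation(R, Di, G, delta, Delta, rise,
                            n_walkers=30000, n_steps=1200, seed=0):
    """<cos phi> for walkers in a sphere of radius R (um), D=Di (um^2/ms).

    Gradient: two trapezoidal lobes of amplitude G (mT/m), total duration
    delta (ms), ramps rise (ms), leading edges separated by Delta (ms);
    the second lobe has opposite effective polarity (spin echo).
    """
    np.random.seed(seed)
    T = Delta + delta
    dt = T / n_steps
    sig = np.sqrt(2.0 * Di * dt)
    acc = 0.0
    for _ in range(n_walkers):
        # uniform initial position inside the sphere
        while True:
            x = (np.random.random() * 2.0 - 1.0) * R
            y = (np.random.random() * 2.0 - 1.0) * R
            z = (np.random.random() * 2.0 - 1.0) * R
            if x * x + y * y + z * z <= R * R:
                break
        phase = 0.0
        for i in range(n_steps):
            t = (i + 0.5) * dt
            g = 0.0
            tl = t
            if 0.0 <= tl <= delta:
                a = min(min(tl / rise, (delta - tl) / rise), 1.0)
                if a > 0.0:
                    g += a
            tl = t - Delta
            if 0.0 <= tl <= delta:
                a = min(min(tl / rise, (delta - tl) / rise), 1.0)
                if a > 0.0:
                    g -= a
            x += np.random.normal() * sig
            y += np.random.normal() * sig
            z += np.random.normal() * sig
            r = np.sqrt(x * x + y * y + z * z)
            if r > R:
                # reflect the radial excess back inside
                f = (2.0 * R - r) / r
                x *= f
                y *= f
                z *= f
            phase += g * x * dt
        acc += np.cos(GAMMA_MS * G * phase)
    return acc / n_walkers
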