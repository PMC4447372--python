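"""Inner loops of the Brownian-dynamics photon-trace simulator.

The simulator pre-draws per-bin displacement randomness for a chunk of time
bins from a single numpy Generator (so the random stream is owned by the
caller and fully seeded) and hands it to one of two interchangeable
kernels that advance the particle positions through a periodic box and
accumulate the summed detection-profile weight per bin:

* a numba ``njit`` kernel (default when numba imports), and
* a vectorized numpy fallback.

Displacements are variance-matched uniform steps rather than Gaussian
draws: the displacement over k bins is a k-fold convolution, so by the
central limit theorem the distribution is Gaussian to high accuracy for
every lag beyond a couple of bins, and even at one bin the correlation
error is O(kurtosis * (step/width)^4) ~ 1e-5 at the default step sizes —
while uniform variates generate several times faster than Gaussian ones.

Both kernels consume the identical variate array; they differ only in
float summation order, so traces are bit-identical per backend and seed.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly on import
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

# Detection weights below exp(-Q_CUTOFF) are dropped (~1e-7 of peak).
_Q_CUTOFF = 16.0

#: scale factor turning a unit-variance requirement into a uniform width:
#: steps are (u - 1/2) * sqrt(12) * sd for u ~ U[0, 1).
UNIFORM_SCALE = math.sqrt(12.0)


def _accumulate_numpy(u, pos, width, box, inv4w2, inv4wz2, out):
    """Advance positions by uniform steps and add per-bin profile sums.

    u     : (m, n, 3) float32 uniform variates in [0, 1)
    pos   : (n, 3) float32 positions relative to the focus (box center)
    width : (3,) float64 full widths of the uniform step per axis
    box   : (3,) float64 box side lengths
    """
    steps = (u - np.float32(0.5)) * width.astype(np.float32)
    traj = np.cumsum(steps, axis=0, dtype=np.float32)
    traj += pos[None, :, :]
    for ax in range(3):  # fold into [-L/2, L/2) around the focus
        L = box[ax]
        t = traj[:, :, ax]
        t -= L * np.floor(t / L + 0.5)
    pos[:] = traj[-1]
    q = inv4w2 * (traj[:, :, 0] ** 2 + traj[:, :, 1] ** 2)
    q += inv4wz2 * traj[:, :, 2] ** 2
    w = np.exp(-q, dtype=np.float32)
    w[q > _Q_CUTOFF] = 0.0
    out += w.sum(axis=1, dtype=np.float64)


if _HAVE_NUMBA:

    @njit(cache=True, fastmath=True)
    def _accumulate_numba(u, pos, width, box, inv4w2, inv4wz2, out):  # pragma: no cover
        m, n = u.shape[0], u.shape[1]
        wx = np.float32(width[0])
        wy = np.float32(width[1])
        wz = np.float32(width[2])
        Lx, Ly, Lz = box[0], box[1], box[2]
        ix, iy, iz = 1.0 / Lx, 1.0 / Ly, 1.0 / Lz
        half = np.float32(0.5)
        for t in range(m):
            s = 0.0
            for i in range(n):
                x = pos[i, 0] + (u[t, i, 0] - half) * wx
                x -= Lx * math.floor(x * ix + 0.5)
                y = pos[i, 1] + (u[t, i, 1] - half) * wy
                y -= Ly * math.floor(y * iy + 0.5)
                z = pos[i, 2] + (u[t, i, 2] - half) * wz
                z -= Lz * math.floor(z * iz + 0.5)
                pos[i, 0] = x
                pos[i, 1] = y
                pos[i, 2] = z
                q = inv4w2 * (x * x + y * y) + inv4wz2 * z * z
                if q < _Q_CUTOFF:
                    s += math.exp(-q)
            out[t] += s

    accumulate = _accumulate_numba
else:
    accumulate = _accumulate_numpy
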