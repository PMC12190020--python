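"""Independent reference computations used by several test modules."""

import numpy as np


def closed_form_scheffe(transformed):
    """Closed-form Scheffé estimates on vertex/edge-midpoint designs:
    k_i = mean Phi at vertex i, k_ij = 4*mean Phi(edge ij) - 2*(k_i + k_j)."""
    groups = {}
    for z, phi in transformed:
        groups.setdefault(z.key(6), []).append(phi)
    m = {k: np.mean(v) for k, v in groups.items()}
    k1, k2, k3 = m[(1, 0, 0)], m[(0, 1, 0)], m[(0, 0, 1)]
    k12 = 4 * m[(0.5, 0.5, 0)] - 2 * (k1 + k2)
    k13 = 4 * m[(0.5, 0, 0.5)] - 2 * (k1 + k3)
    k23 = 4 * m[(0, 0.5, 0.5)] - 2 * (k2 + k3)
    return np.array([k1, k2, k3, k12, k13, k23])
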