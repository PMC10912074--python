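"""Independent numerical oracles used by the tests.

These deliberately avoid the closed-form convolution machinery of the
package: the compartment system is integrated as a stiff ODE with the
continuous input curves, and frame averages are taken by quadrature.
"""

import numpy as np
from scipy.integrate import simpson, solve_ivp


def ode_frame_averages(kp, inp, schedule, rtol=1e-10, atol=1e-12):
    """Frame-averaged 2TCM signal by stiff ODE integration (Radau)."""

    def rhs(t, y):
        cp = inp.parent_plasma(t)
        return [
            kp.K1 * cp - (kp.k2 + kp.k3) * y[0] + kp.k4 * y[1],
            kp.k3 * y[0] - kp.k4 * y[1],
        ]

    sol = solve_ivp(
        rhs,
        [0.0, schedule.ends[-1]],
        [0.0, 0.0],
        method="Radau",
        rtol=rtol,
        atol=atol,
        dense_output=True,
        max_step=0.25,
    )
    vals = []
    for a, b in schedule.frames:
        tt = np.linspace(a, b, 201)
        c = sol.sol(tt).sum(axis=0) + kp.vB * np.asarray(inp.whole_blood(tt))
        vals.append(simpson(c, x=tt) / (b - a))
    return np.array(vals)


def flood_fill_26(mask, start):
    """Connected component of ``start`` in a boolean 3D mask, 26-connectivity,
    by explicit breadth-first search."""
    mask = np.asarray(mask, dtype=bool)
    out = np.zeros_like(mask)
    if not mask[start]:
        return out
    stack = [start]
    out[start] = True
    shape = mask.shape
    while stack:
        x, y, z = stack.pop()
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    if dx == dy == dz == 0:
                        continue
                    u, v, w = x + dx, y + dy, z + dz
                    if (
                        0 <= u < shape[0]
                        and 0 <= v < shape[1]
                        and 0 <= w < shape[2]
                        and mask[u, v, w]
                        and not out[u, v, w]
                    ):
                        out[u, v, w] = True
                        stack.append((u, v, w))
    return out
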