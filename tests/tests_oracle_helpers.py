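"""Independent fixed-step integrator used as an oracle against the stiff
solver.  Kept free of any phgap solver machinery beyond the RHS assembly."""

import numpy as np


def rk4_final_state(scheme, params, condition, t_end, dt=1e-3):
    """Classical fourth-order Runge-Kutta at a fixed step; returns state in M."""
    from phgap.gap_kinetics import _resolve_rates, _rhs_factory

    y = np.zeros(len(scheme.species))
    for s, v in scheme.initial(condition).items():
        y[scheme.index[s]] = v * 1e6
    rhs, _ = _rhs_factory(scheme, _resolve_rates(scheme, params, condition))
    for _ in range(int(round(t_end / dt))):
        k1 = rhs(0.0, y)
        k2 = rhs(0.0, y + 0.5 * dt * k1)
        k3 = rhs(0.0, y + 0.5 * dt * k2)
        k4 = rhs(0.0, y + dt * k3)
        y = y + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    return y * 1e-6
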