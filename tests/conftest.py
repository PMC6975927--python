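import numpy as np
import pytest
from scipy.integrate import solve_ivp


@pytest.fixture(scope="session")
def ode_oracle():
    """Independent adaptive-ODE integration of the sequential chain.

    Integrates dS0/dt = -k1 S0, dSi/dt = ki S_{i-1} - k_{i+1} Si with an
    absorbing terminal state, without touching the package's closed-form
    or matrix-exponential code paths.
    """

    def integrate(rates, times):
        k = np.asarray(rates, dtype=float)
        n = len(k)

        def rhs(_t, y):
            dy = np.zeros(n + 1)
            dy[0] = -k[0] * y[0]
            for i in range(1, n):
                dy[i] = k[i - 1] * y[i - 1] - k[i] * y[i]
            dy[n] = k[n - 1] * y[n - 1]
            return dy

        y0 = np.zeros(n + 1)
        y0[0] = 1.0
        times = np.asarray(times, dtype=float)
        t_span = (0.0, max(times[-1], 1e-12))
        sol = solve_ivp(rhs, t_span, y0, t_eval=times, method="DOP853",
                        rtol=1e-12, atol=1e-14)
        assert sol.success
        return sol.y.T

    return integrate
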