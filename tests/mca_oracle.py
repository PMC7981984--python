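"""Independent control-coefficient oracle by steady-state perturbation.

Builds an explicit kinetic model from (stoichiometry, reference state,
elasticity matrix) using log-linear rate laws

    v_i(x, e_i) = e_i * v_ref_i * prod_j (x_j / x_ref_j)^(E_ij)

whose scaled elasticities equal E everywhere, perturbs one enzyme level at a
time, re-solves the steady state (in independent log-concentration
coordinates, respecting conserved moieties), and reads flux control
coefficients off as central differences of ln v.  This never touches the
package's linear-algebra control formulas, only its reduction (N_R, L).
"""

import numpy as np
from scipy.optimize import root


def log_linear_rates(v_ref, x_ref, E):
    v_ref = np.asarray(v_ref, dtype=float)
    x_ref = np.asarray(x_ref, dtype=float)
    E = np.asarray(E, dtype=float)

    def rates(x, e):
        return e * v_ref * np.exp(E @ np.log(x / x_ref))

    return rates


def solve_steady_state(N_R, L, x_ref, ind_idx, rates, e):
    """Solve N_R v(x(x_ind)) = 0 with x_full affine in x_ind via L."""
    x_ref = np.asarray(x_ref, dtype=float)
    x_ind_ref = x_ref[ind_idx]

    def x_full(x_ind):
        return x_ref + L @ (x_ind - x_ind_ref)

    def residual(u):  # u = ln(x_ind / x_ind_ref)
        return N_R @ rates(x_full(x_ind_ref * np.exp(u)), e)

    sol = root(residual, np.zeros(len(ind_idx)))
    resid = np.abs(residual(sol.x)).max()
    if resid > 1e-10:
        raise RuntimeError(f"steady-state solve failed (residual {resid:.2e})")
    return x_full(x_ind_ref * np.exp(sol.x))


def fcc_by_perturbation(N_R, L, v_ref, x_ref, ind_idx, E, h=0.001):
    """(fluxes x enzymes) FCC matrix by +/-h enzyme perturbation."""
    rates = log_linear_rates(v_ref, x_ref, E)
    n = len(v_ref)
    fcc = np.zeros((n, n))
    for k in range(n):
        results = []
        for factor in (1.0 + h, 1.0 - h):
            e = np.ones(n)
            e[k] = factor
            x = solve_steady_state(N_R, L, x_ref, ind_idx, rates, e)
            results.append(np.log(np.abs(rates(x, e))))
        fcc[:, k] = (results[0] - results[1]) / (np.log(1.0 + h) - np.log(1.0 - h))
    return fcc
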