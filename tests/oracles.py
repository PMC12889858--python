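"""Independent brute-force solvers used to validate the fast updates.

These deliberately share no code with the package's solvers: the variant
subproblem is solved by proximal gradient (FISTA) on the raw objective,
and the trace subproblem (without decorrelation) by a dense Kronecker
normal-equation solve.
"""

import numpy as np


def variant_objective(a, residuals, trace_blocks, gamma1, gamma2, lam, neighbors):
    """Raw variant-subproblem objective at slice ``a`` (N x p)."""
    obj = 0.0
    for resid, phi in zip(residuals, trace_blocks):
        obj += float(np.sum((resid - a @ phi) ** 2))
    obj += gamma1 * float(np.abs(a).sum())
    for w, other in zip(lam, neighbors):
        obj += gamma2 * w * float(np.sum((other - a) ** 2))
    return obj


def prox_gradient_variant(
    residuals,
    trace_blocks,
    gamma1,
    gamma2,
    lam,
    neighbors,
    shape,
    nonneg=False,
    tol=1e-13,
    max_iter=500_000,
):
    """Proximal gradient (FISTA with adaptive restart) on the subproblem.

    Stops when the iterate stops moving for a stretch of iterations, which
    is robust against FISTA's non-monotone objective.
    """
    gram = np.zeros((shape[1], shape[1]))
    linear = np.zeros(shape)
    for resid, phi in zip(residuals, trace_blocks):
        gram += phi @ phi.T
        linear += resid @ phi.T
    lam_total = float(np.sum(lam))
    for w, other in zip(lam, neighbors):
        linear += gamma2 * w * other
    lip = 2.0 * (np.linalg.eigvalsh(gram)[-1] + gamma2 * lam_total)
    lip = max(lip, 1e-12)
    step = 1.0 / lip
    scale = max(1.0, np.abs(linear).max(initial=0.0))

    def prox_step(z):
        x = z - step * 2.0 * (z @ gram + gamma2 * lam_total * z - linear)
        thresh = step * gamma1
        if nonneg:
            return np.maximum(0.0, x - thresh)
        return np.sign(x) * np.maximum(0.0, np.abs(x) - thresh)

    a = np.zeros(shape)
    z = a.copy()
    t = 1.0
    quiet = 0
    for _ in range(max_iter):
        a_new = prox_step(z)
        # gradient-scheme adaptive restart
        if np.sum((z - a_new) * (a_new - a)) > 0:
            t = 1.0
            z = a_new.copy()
        else:
            t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
            z = a_new + ((t - 1.0) / t_new) * (a_new - a)
            t = t_new
        change = np.abs(a_new - a).max(initial=0.0)
        a = a_new
        quiet = quiet + 1 if change <= tol * scale else 0
        if quiet >= 20:
            break
    return a


def dense_trace_solve(y, loading, gamma3):
    """Exact trace update without decorrelation via a dense Kronecker solve."""
    n, p = loading.shape
    t_len = y.shape[1]
    ata = loading.T @ loading
    diff = np.zeros((t_len - 1, t_len))
    for t in range(t_len - 1):
        diff[t, t] = -1.0
        diff[t, t + 1] = 1.0
    smooth = diff.T @ diff
    system = np.kron(np.eye(t_len), ata) + gamma3 * np.kron(smooth, np.eye(p))
    rhs = (loading.T @ y).flatten(order="F")
    sol = np.linalg.solve(system, rhs)
    return sol.reshape((p, t_len), order="F")
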