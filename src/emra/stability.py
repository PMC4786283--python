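"""Jacobians, fixed-point stability classification, steady-state location.

Stability of a fixed point is decided by the sign of the leading real part
of the Jacobian spectrum, *after* discarding structural zeros: a network
with conserved pools (e.g. ATP + ADP) always has one exactly-zero
eigenvalue per pool, which reflects conservation rather than marginal
dynamics.  Up to one eigenvalue per conserved pool with |Re| below
``EPS_STRUCT`` is excluded before taking the maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .errors import NumericalError
from .kinetics import PackedKinetics, ParameterSet
from .network import MetabolicNetwork, MoietyBasis

#: |Re| below which an eigenvalue may be treated as a conservation mode.
EPS_STRUCT = 1e-7

#: Convergence tolerance on the steady-state residual ||S v||_inf.
STEADY_STATE_TOL = 1e-9

#: Horizon of the time-integration fallback (normalized time).
FALLBACK_T_END = 1e4


@dataclass
class SteadyStateRecord:
    """A located fixed point with its flux vector and stability verdict."""

    xbar: np.ndarray
    v: np.ndarray
    lead_re: float
    stable: bool
    converged: bool


def jacobian(net: MetabolicNetwork, p: ParameterSet, x) -> np.ndarray:
    """Central finite-difference Jacobian of dx̄/dt at ``x``."""
    return packed_jacobian(PackedKinetics(net, p), np.asarray(x, dtype=float))


def packed_jacobian(pk: PackedKinetics, x: np.ndarray) -> np.ndarray:
    """J_ij = d(S v)_i / dx_j by central differences, h = 1e-6 max(x_j, 1).

    The rate laws are smooth rational functions on x >= 0, so central
    differences at this step give ~8 significant digits; an analytic
    cross-check for the unregulated forms lives in the test suite.
    """
    n = x.shape[0]
    J = np.empty((n, n))
    for j in range(n):
        h = 1e-6 * max(x[j], 1.0)
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] = max(xm[j] - h, 0.0)
        J[:, j] = (pk.rhs(0.0, xp) - pk.rhs(0.0, xm)) / (xp[j] - xm[j])
    if not np.all(np.isfinite(J)):
        bad = np.unique(np.nonzero(~np.isfinite(J))[0])
        names = [pk.net.metabolite_ids[i] for i in bad]
        raise NumericalError(f"non-finite Jacobian entries in rows: {names}")
    return J


def classify_stability(J: np.ndarray, moieties: MoietyBasis | int = 0):
    """(lead_re, stable) from the Jacobian spectrum, ignoring structural zeros.

    ``moieties`` may be a :class:`MoietyBasis` or just the count of
    conserved pools.  At most that many eigenvalues with |Re| < EPS_STRUCT
    are excluded; the fixed point is stable iff the remaining leading real
    part is below -EPS_STRUCT (zero-eigenvalue cases count as not stable).
    """
    n_struct = moieties if isinstance(moieties, int) else moieties.dim
    try:
        eigs = scipy.linalg.eigvals(J)
    except Exception as exc:  # pragma: no cover - eig failure is exotic
        raise NumericalError(f"eigenvalue computation failed: {exc}") from exc
    re = np.sort(np.real(eigs))[::-1]  # descending
    candidates = np.abs(re) < EPS_STRUCT
    to_drop = min(n_struct, int(candidates.sum()))
    if to_drop:
        keep = np.ones(re.shape[0], dtype=bool)
        # drop the near-zero entries closest to zero first
        order = np.argsort(np.abs(re))
        keep[order[:to_drop]] = False
        re = re[keep]
    lead_re = float(re[0]) if re.size else -np.inf
    return lead_re, bool(lead_re < -EPS_STRUCT)


def _structural_info(pk: PackedKinetics):
    """Active-stoichiometry rank data: (selected rows, left-null basis)."""
    S_act = pk.S[:, pk.vmax > 0]
    if S_act.size == 0:
        S_act = np.zeros((pk.S.shape[0], 1))
    rank = np.linalg.matrix_rank(S_act, tol=1e-10)
    # independent rows of S_act via column-pivoted QR of its transpose
    _q, _r, piv = scipy.linalg.qr(S_act.T, pivoting=True, mode="economic")
    rows = np.sort(piv[:rank])
    null = scipy.linalg.null_space(S_act.T, rcond=1e-10)
    return rows, null.T  # null rows m satisfy m @ S_act = 0


def n_structural_zeros(pk: PackedKinetics) -> int:
    """Number of conserved pools of the *active* network (Vmax > 0)."""
    _rows, null = _structural_info(pk)
    return null.shape[0]


def packed_find_steady_state(
    pk: PackedKinetics,
    x0: np.ndarray,
    tol: float = STEADY_STATE_TOL,
    max_iter: int = 60,
    fallback: bool = True,
) -> SteadyStateRecord:
    """Damped Newton on the moiety-projected balance S v(x̄) = 0.

    The raw system is rank-deficient whenever the active network conserves
    pools; the square system solved combines a maximal independent subset
    of metabolite balances with the conservation constraints
    m^T (x - x0) = 0.  On Newton failure the state is relaxed by stiff time
    integration to t = 1e4 and re-polished.  Never raises for
    non-convergence: the record's ``converged`` flag is the verdict.
    """
    rows, null = _structural_info(pk)
    n = x0.shape[0]

    def F(x):
        bal = pk.rhs(0.0, x)[rows]
        if null.shape[0]:
            return np.concatenate([bal, null @ (x - x0)])
        return bal

    def newton(x):
        x = np.maximum(np.asarray(x, dtype=float), 0.0)
        f = F(x)
        for _ in range(max_iter):
            if np.max(np.abs(pk.rhs(0.0, x))) < tol and np.max(np.abs(f)) < 10 * tol:
                return x, True
            # forward-difference Jacobian of F
            JF = np.empty((f.shape[0], n))
            for j in range(n):
                h = 1e-7 * max(abs(x[j]), 1e-3)
                xp = x.copy()
                xp[j] += h
                JF[:, j] = (F(xp) - f) / h
            try:
                step = np.linalg.solve(JF, -f)
            except np.linalg.LinAlgError:
                step, *_ = np.linalg.lstsq(JF, -f, rcond=None)
            if not np.all(np.isfinite(step)):
                return x, False
            lam, f_norm = 1.0, np.linalg.norm(f)
            improved = False
            for _ in range(40):
                x_new = np.maximum(x + lam * step, 0.0)
                f_new = F(x_new)
                if np.linalg.norm(f_new) < (1.0 - 1e-4 * lam) * f_norm:
                    x, f = x_new, f_new
                    improved = True
                    break
                lam *= 0.5
            if not improved:
                return x, False
        return x, np.max(np.abs(pk.rhs(0.0, x))) < tol

    x_sol, ok = newton(x0)
    if not ok and fallback:
        from scipy.integrate import solve_ivp

        sol = solve_ivp(
            pk.rhs,
            (0.0, FALLBACK_T_END),
            np.maximum(x0, 0.0),
            method="LSODA",
            rtol=1e-8,
            atol=1e-10,
        )
        if sol.success:
            x_sol, ok = newton(sol.y[:, -1])

    v = pk.rates(x_sol)
    if ok:
        J = packed_jacobian(pk, x_sol)
        lead_re, stable = classify_stability(J, null.shape[0])
    else:
        lead_re, stable = np.nan, False
    return SteadyStateRecord(
        xbar=x_sol, v=v, lead_re=lead_re, stable=stable, converged=bool(ok)
    )


def find_steady_state(
    net: MetabolicNetwork, p: ParameterSet, x0, **kwargs
) -> SteadyStateRecord:
    """Locate a steady state from ``x0``; see :func:`packed_find_steady_state`."""
    return packed_find_steady_state(
        PackedKinetics(net, p), np.asarray(x0, dtype=float), **kwargs
    )


def reference_stability(net: MetabolicNetwork, p: ParameterSet):
    """(lead_re, stable) of the reference fixed point x̄ = 1."""
    pk = PackedKinetics(net, p)
    J = packed_jacobian(pk, np.ones(net.n_metabolites))
    return classify_stability(J, n_structural_zeros(pk))
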