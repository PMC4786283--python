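"""Time-domain operation: continuous, batch and fed-batch runs.

A batch run reuses the continuous model with a minimum of changes: all
exchange Vmax values are set to zero (the reactions stay in the model for
bookkeeping) and the starting substrate is charged up front — by default
200x its reference concentration — while every other species starts at its
reference value of 1.  Product then accumulates because its consuming
exchange is off.  Fed-batch keeps the input exchange active on a
piecewise-constant rate schedule with the output exchange off.

Production bookkeeping is unified across modes: the production rate is the
net formation rate of the product species (its concentration derivative
plus any export flux), and the cumulative product is the product
accumulated in the reactor plus the amount exported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .errors import ConfigurationError, NumericalError
from .ensemble import Ensemble
from .kinetics import PackedKinetics, ParameterSet
from .network import MetabolicNetwork

DEFAULT_BATCH_MULTIPLIER = 200.0
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10

#: Productive-steady-state classifier defaults: the state derivative must
#: be flat to within ``FLUX_TOL`` and the output flux must exceed
#: ``PROD_TOL`` times the reference output flux ("non-trivial").
FLUX_TOL = 1e-6
PROD_TOL = 0.01

#: Integration horizon used when classifying unconstrained draws.
CLASSIFY_T_END = 1e4


@dataclass
class Trajectory:
    """Integrated time course with flux and production series."""

    t: np.ndarray
    xbar_t: np.ndarray  # (n_times, n_metabolites)
    v_t: np.ndarray  # (n_times, n_reactions)
    production_rate: np.ndarray
    product_amount: np.ndarray
    mode: str
    net: MetabolicNetwork = field(repr=False)
    pk: PackedKinetics = field(repr=False)

    def series(self, metabolite: str) -> np.ndarray:
        return self.xbar_t[:, self.net.metabolite_index(metabolite)]

    def final_rhs_norm(self) -> float:
        return float(np.max(np.abs(self.pk.rhs(0.0, self.xbar_t[-1]))))

    def final_output_flux(self) -> float:
        mask = np.array([k == "output_exchange" for k in self.net.kind])
        return float(self.v_t[-1][mask].sum())


def _product_row(net: MetabolicNetwork) -> np.ndarray:
    """Indicator over metabolites drained by output exchanges."""
    row = np.zeros(net.n_metabolites)
    for j, kind in enumerate(net.kind):
        if kind == "output_exchange":
            row[np.nonzero(net.S[:, j])[0][0]] = 1.0
    if not row.any():
        raise ConfigurationError("network has no output exchange")
    return row


def to_batch(
    net: MetabolicNetwork,
    p: ParameterSet,
    substrate: str,
    multiplier: float = DEFAULT_BATCH_MULTIPLIER,
):
    """Convert a continuous parameterization to batch operation.

    Returns ``(net, p_batch, x0)``: exchange Vmax set to 0, all other
    parameters untouched, and the initial state equal to the reference
    state except for the substrate charged at ``multiplier``.
    """
    if multiplier <= 0:
        raise ConfigurationError("batch multiplier must be > 0")
    i_sub = net.metabolite_index(substrate)
    if p.vmax is None:
        raise ConfigurationError("ParameterSet has no Vmax; run solve_vmax first")
    vmax = dict(p.vmax)
    for j, rxn in enumerate(net.reaction_ids):
        if net.kind[j] != "enzymatic":
            vmax[rxn] = 0.0
    x0 = np.ones(net.n_metabolites)
    x0[i_sub] = multiplier
    return net, p.with_vmax(vmax), x0


def _build_trajectory(net, pk, sol, mode) -> Trajectory:
    x_t = sol.y.T
    v_t = np.array([pk.rates(x) for x in x_t])
    prod_row = _product_row(net)
    # production = net formation of the product species + export flux
    out_mask = np.array([k == "output_exchange" for k in net.kind])
    formation = np.array([(net.S[prod_row > 0, :] @ v).sum() for v in v_t])
    export = v_t[:, out_mask].sum(axis=1)
    rate = formation + export
    amount = np.concatenate(
        [[0.0], np.cumsum(0.5 * (rate[1:] + rate[:-1]) * np.diff(sol.t))]
    )
    return Trajectory(
        t=sol.t,
        xbar_t=x_t,
        v_t=v_t,
        production_rate=rate,
        product_amount=amount,
        mode=mode,
        net=net,
        pk=pk,
    )


def integrate(
    net: MetabolicNetwork,
    p: ParameterSet,
    x0,
    t_end: float,
    mode: str = "continuous",
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    n_points: int | None = 400,
    stop_when_depleted: tuple[str, float] | None = None,
) -> Trajectory:
    """Stiff integration of dx̄/dt = S v(x̄) with flux/production series.

    ``stop_when_depleted=(metabolite, fraction)`` installs a terminal event
    that stops the run once that species falls below ``fraction`` of its
    initial value (used for batch runs, default substrate < 1%).
    ``n_points=None`` keeps the solver's natural (dense near fast
    transients) step points instead of a uniform grid.
    """
    if mode not in ("continuous", "batch"):
        raise ConfigurationError(f"unknown mode {mode!r}")
    x0 = np.asarray(x0, dtype=float)
    if np.any(x0 < 0):
        raise ValueError("initial concentrations must be nonnegative")
    pk = PackedKinetics(net, p)
    events = None
    if stop_when_depleted is not None:
        met, frac = stop_when_depleted
        i_met = net.metabolite_index(met)
        floor = frac * x0[i_met]

        def depleted(t, x):
            return x[i_met] - floor

        depleted.terminal = True
        events = depleted
    t_eval = None if n_points is None else np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(
        pk.rhs,
        (0.0, t_end),
        x0,
        method="LSODA",
        rtol=rtol,
        atol=atol,
        t_eval=t_eval,
        events=events,
    )
    if not sol.success and sol.status != 1:
        raise NumericalError(
            f"integration failed at t={sol.t[-1] if sol.t.size else 0.0:g}: "
            f"{sol.message}"
        )
    if sol.status == 1 and sol.t_events and len(sol.t_events[0]):
        # terminal event fired between t_eval points: append its state
        sol.t = np.append(sol.t, sol.t_events[0][-1])
        sol.y = np.hstack([sol.y, sol.y_events[0][-1][:, None]])
    return _build_trajectory(net, pk, sol, mode)


def batch_run(
    net: MetabolicNetwork,
    p: ParameterSet,
    substrate: str,
    multiplier: float = DEFAULT_BATCH_MULTIPLIER,
    t_end: float = 1e4,
    depletion_fraction: float = 0.01,
    **kwargs,
) -> Trajectory:
    """Convenience wrapper: to_batch + integrate until substrate depletion."""
    net_b, p_b, x0 = to_batch(net, p, substrate, multiplier)
    kwargs.setdefault("n_points", None)  # natural steps resolve the plateau
    return integrate(
        net_b,
        p_b,
        x0,
        t_end,
        mode="batch",
        stop_when_depleted=(substrate, depletion_fraction),
        **kwargs,
    )


def detect_plateau(
    traj: Trajectory, window_frac: float = 0.1, rel_tol: float = 0.02
) -> tuple[float, float] | None:
    """Locate a production-rate plateau, if any.

    A plateau is declared at the earliest time from which the production
    rate stays within ``rel_tol`` (default +/-2%) of its local mean over a
    sliding window spanning ``window_frac`` of the total run duration.
    Returns ``(t_start, plateau_rate)`` or ``None`` — bifurcated batch
    runs never flatten, so absence of a plateau is the time-domain
    signature of a lost pseudo-steady state.
    """
    t, r = traj.t, traj.production_rate
    width = window_frac * t[-1]
    for i in range(len(t)):
        t0 = t[i]
        if t0 + width > t[-1]:
            break
        mask = (t >= t0) & (t <= t0 + width)
        if mask.sum() < 3:
            continue
        window = r[mask]
        mean = window.mean()
        if mean <= 0:
            continue
        if np.max(np.abs(window - mean)) <= rel_tol * mean:
            return float(t0), float(mean)
    return None


def classify_productive(
    traj: Trajectory, flux_tol: float = FLUX_TOL, prod_tol: float = PROD_TOL
) -> bool:
    """True iff the trajectory settled at a non-trivial productive state.

    Requires a continuous-mode run; checks that the endpoint derivative is
    below ``flux_tol`` and the output flux exceeds ``prod_tol`` times the
    reference output flux.
    """
    if traj.mode != "continuous":
        raise ConfigurationError("productivity is a continuous-mode notion")
    net = traj.net
    out_mask = np.array([k == "output_exchange" for k in net.kind])
    vref_out = float(net.vref[out_mask].sum())
    return bool(
        traj.final_rhs_norm() < flux_tol
        and traj.final_output_flux() > prod_tol * vref_out
    )


def _relax_to_steady_state(pk, x0, t_end, flux_tol, rtol, atol):
    """Integrate in expanding windows, stopping early once flat or diverged."""
    checkpoints = [50.0, 200.0, 1000.0, 5000.0, t_end]
    t0, x = 0.0, np.asarray(x0, dtype=float)
    for t1 in checkpoints:
        if t1 <= t0:
            continue
        sol = solve_ivp(
            pk.rhs, (t0, t1), x, method="LSODA", rtol=rtol, atol=atol
        )
        if not sol.success:
            return sol.y[:, -1] if sol.y.size else x, False
        x, t0 = sol.y[:, -1], t1
        if np.max(np.abs(pk.rhs(0.0, x))) < flux_tol:
            return x, True
        if np.max(x) > 1e9:
            return x, False
    return x, True


def productive_member(
    net: MetabolicNetwork,
    p: ParameterSet,
    t_end: float = CLASSIFY_T_END,
    flux_tol: float = FLUX_TOL,
    prod_tol: float = PROD_TOL,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> bool:
    """Does this (usually unconstrained) member reach a productive state?

    Integrates the continuous system from the reference state with early
    exit once the state is flat; applies the :func:`classify_productive`
    criteria to the endpoint.
    """
    pk = PackedKinetics(net, p)
    x, _flat = _relax_to_steady_state(
        pk, np.ones(net.n_metabolites), t_end, flux_tol, rtol, atol
    )
    out_mask = np.array([k == "output_exchange" for k in net.kind])
    vref_out = float(net.vref[out_mask].sum())
    v = pk.rates(x)
    return bool(
        np.max(np.abs(pk.rhs(0.0, x))) < flux_tol
        and float(v[out_mask].sum()) > prod_tol * vref_out
    )


def productive_fraction(net: MetabolicNetwork, ens: Ensemble, **kwargs) -> float:
    """Fraction of ensemble members reaching a productive steady state."""
    hits = sum(productive_member(net, p, **kwargs) for p in ens.members)
    return hits / max(len(ens.members), 1)


def fed_batch(
    net: MetabolicNetwork,
    p: ParameterSet,
    feed_schedule,
    x0=None,
    t_end: float = 100.0,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    n_points: int = 200,
) -> Trajectory:
    """Fed-batch run: scheduled feed rate, output exchange off.

    ``feed_schedule`` is either a single multiplier applied from t = 0 or a
    list of ``(time, multiplier)`` breakpoints (piecewise constant, applied
    to every input exchange's reference Vmax).  Product accumulates in the
    reactor; cofactor time series are available via ``Trajectory.series``.
    """
    if np.isscalar(feed_schedule):
        feed_schedule = [(0.0, float(feed_schedule))]
    schedule = sorted((float(t), float(m)) for t, m in feed_schedule)
    if not schedule or schedule[0][0] > 0.0:
        schedule = [(0.0, 0.0)] + schedule
    if any(m < 0 for _t, m in schedule):
        raise ConfigurationError("feed multipliers must be nonnegative")
    if p.vmax is None:
        raise ConfigurationError("ParameterSet has no Vmax; run solve_vmax first")

    in_rxns = [r for r, k in zip(net.reaction_ids, net.kind) if k == "input_exchange"]
    out_rxns = [r for r, k in zip(net.reaction_ids, net.kind) if k == "output_exchange"]
    base_in = {r: p.vmax[r] for r in in_rxns}
    x = np.ones(net.n_metabolites) if x0 is None else np.asarray(x0, dtype=float)

    pieces = []
    breaks = [t for t, _m in schedule] + [t_end]
    for (t_start, mult), t_stop in zip(schedule, breaks[1:]):
        if t_stop <= t_start:
            continue
        vmax = dict(p.vmax)
        for r in out_rxns:
            vmax[r] = 0.0
        for r in in_rxns:
            vmax[r] = base_in[r] * mult
        p_piece = p.with_vmax(vmax)
        pk = PackedKinetics(net, p_piece)
        t_eval = np.linspace(t_start, t_stop, max(int(n_points * (t_stop - t_start) / t_end), 2))
        sol = solve_ivp(
            pk.rhs, (t_start, t_stop), x, method="LSODA",
            rtol=rtol, atol=atol, t_eval=t_eval,
        )
        if not sol.success:
            raise NumericalError(f"fed-batch integration failed: {sol.message}")
        pieces.append((sol, pk))
        x = sol.y[:, -1]

    net_f = net
    ts = np.concatenate([s.t for s, _pk in pieces])
    ys = np.concatenate([s.y.T for s, _pk in pieces])
    v_t = np.concatenate([[pk.rates(xx) for xx in s.y.T] for s, pk in pieces])
    prod_row = _product_row(net_f)
    out_mask = np.array([k == "output_exchange" for k in net_f.kind])
    formation = np.array([(net_f.S[prod_row > 0, :] @ v).sum() for v in v_t])
    export = v_t[:, out_mask].sum(axis=1)
    rate = formation + export
    amount = np.concatenate(
        [[0.0], np.cumsum(0.5 * (rate[1:] + rate[:-1]) * np.diff(ts))]
    )
    return Trajectory(
        t=ts,
        xbar_t=ys,
        v_t=v_t,
        production_rate=rate,
        product_amount=amount,
        mode="batch",
        net=net_f,
        pk=pieces[-1][1],
    )
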