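"""Normalized saturation rate laws and Vmax solving.

All concentrations are normalized to their reference steady-state values
(x̄ = X / X_ss), so affinity constants enter only as scaled ratios
K̄ = Km / X_ss and the reference state is x̄ = 1.  The forms used are the
common modular rate law family:

* irreversible enzymatic reaction with substrates s (multiplicity n_s)::

      v = Vmax * prod_s (x̄_s/K̄_s)^n_s
          / [ prod_s (1 + x̄_s/K̄_s)^n_s + sum_I x̄_I/K̄i_I ]

  where the sum runs over competitive inhibitors.  The two-substrate
  instance is exactly the textbook random-order bi-substrate equation for
  glucokinase, with or without the G6P inhibition term.

* reversible enzymatic reaction, substrates s / products p::

      v = Vmax * [ prod_s (x̄_s/K̄_s)^n_s - γ * prod_p (x̄_p/K̄_p)^n_p ]
          / [ prod_s (1+x̄_s/K̄_s)^n_s + prod_p (1+x̄_p/K̄_p)^n_p - 1 + inh ]

  γ is not sampled directly: each reversible reaction carries a reference
  driving-force ratio ρ ∈ (0, 1) and γ = ρ * prod_s K̄_s^-n_s / prod_p
  K̄_p^-n_p, so that at x̄ = 1 the reverse term is exactly ρ times the
  forward term and the net reference rate is positive by construction.

* ``input_exchange``: v = Vmax (constant-rate feed);
  ``output_exchange``: v = Vmax * (x̄/K̄) / (1 + x̄/K̄).

Vmax values are never sampled in the reference-constrained mode; they are
solved so each reaction carries exactly its reference flux at x̄ = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError
from .network import MetabolicNetwork

__all__ = [
    "ParameterSet",
    "PackedKinetics",
    "rate",
    "rate_vector",
    "solve_vmax",
    "ode_rhs",
]

# integer codes used by the packed evaluator
_IRREVERSIBLE, _INPUT, _OUTPUT, _REVERSIBLE = 0, 1, 2, 3

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit as _njit

    def _jit(fn):
        return _njit(cache=True)(fn)

except ImportError:  # pragma: no cover

    def _jit(fn):
        return fn


@dataclass
class ParameterSet:
    """One sampled kinetic parameterization of a network.

    ``kbar`` maps (reaction, metabolite) to the scaled affinity K̄;
    ``rho`` maps reversible reactions to their reference driving-force
    ratio; ``kibar`` maps regulator edges to scaled inhibition constants;
    ``vmax`` is filled by :func:`solve_vmax` (constrained mode) or sampled
    directly (unconstrained mode).  ``seed_info`` records RNG provenance.
    """

    kbar: dict[tuple[str, str], float]
    rho: dict[str, float] = field(default_factory=dict)
    kibar: dict[tuple[str, str], float] = field(default_factory=dict)
    vmax: dict[str, float] | None = None
    seed_info: dict = field(default_factory=dict)

    def with_vmax(self, vmax: dict[str, float]) -> "ParameterSet":
        return replace(self, vmax=dict(vmax))


def _get(mapping, key, what):
    try:
        return mapping[key]
    except (KeyError, TypeError):
        raise ConfigurationError(f"missing {what} for {key}") from None


def _rate_factors(net: MetabolicNetwork, rxn: str, p: ParameterSet, x):
    """(numerator, denominator) of the rate law for ``rxn`` at Vmax = 1."""
    j = net.reaction_index(rxn)
    kind = net.kind[j]
    xv = np.asarray(x, dtype=float)
    if np.any(xv < 0):
        raise ValueError("negative concentration passed to rate()")

    if kind == "input_exchange":
        return 1.0, 1.0

    subs = net.substrates(rxn)
    if kind == "output_exchange":
        (met, _n), = subs
        r = xv[net.metabolite_index(met)] / _get(p.kbar, (rxn, met), "kbar")
        return r, 1.0 + r

    num_f, den_s = 1.0, 1.0
    for met, n in subs:
        r = xv[net.metabolite_index(met)] / _get(p.kbar, (rxn, met), "kbar")
        num_f *= r**n
        den_s *= (1.0 + r) ** n
    inh = 0.0
    for reg in net.regulators:
        if reg.reaction == rxn:
            ki = _get(p.kibar, (rxn, reg.metabolite), "kibar")
            inh += xv[net.metabolite_index(reg.metabolite)] / ki

    if not net.reversible[j]:
        return num_f, den_s + inh

    rho = _get(p.rho, rxn, "rho")
    num_r, den_p = 1.0, 1.0
    ks_scale, kp_scale = 1.0, 1.0
    for met, n in net.products(rxn):
        k = _get(p.kbar, (rxn, met), "kbar")
        r = xv[net.metabolite_index(met)] / k
        num_r *= r**n
        den_p *= (1.0 + r) ** n
        kp_scale *= k**-n
    for met, n in subs:
        ks_scale *= _get(p.kbar, (rxn, met), "kbar") ** -n
    gamma = rho * ks_scale / kp_scale
    return num_f - gamma * num_r, den_s + den_p - 1.0 + inh


def rate(net: MetabolicNetwork, rxn: str, p: ParameterSet, x) -> float:
    """Reaction rate of ``rxn`` at normalized state ``x`` (reference form).

    This is the readable scalar implementation; hot loops use
    :class:`PackedKinetics`, which is tested for exact agreement with it.
    """
    num, den = _rate_factors(net, rxn, p, x)
    vmax = _get(p.vmax or {}, rxn, "vmax")
    return vmax * num / den


def rate_vector(net: MetabolicNetwork, p: ParameterSet, x) -> np.ndarray:
    return np.array([rate(net, r, p, x) for r in net.reaction_ids])


def solve_vmax(net: MetabolicNetwork, p: ParameterSet) -> ParameterSet:
    """Fill Vmax so every reaction carries its reference flux at x̄ = 1.

    Vmax_r = vref_r * D_r(1) / N_r(1); N_r(1) > 0 is guaranteed by the
    ρ-construction of the reversible rate law, so this never fails.
    Idempotent: Vmax does not enter N or D.
    """
    ones = np.ones(net.n_metabolites)
    vmax = {}
    for j, rxn in enumerate(net.reaction_ids):
        num, den = _rate_factors(net, rxn, p, ones)
        vmax[rxn] = float(net.vref[j]) * den / num
    return p.with_vmax(vmax)


def ode_rhs(net: MetabolicNetwork, p: ParameterSet, x) -> np.ndarray:
    """Time derivative S @ v(x̄) of the normalized concentrations."""
    return net.S @ rate_vector(net, p, x)


# ---------------------------------------------------------------------------
# packed fast path


def _pack_segments(entries):
    """CSR-style (ptr, met, exp, k) arrays from per-reaction entry lists."""
    ptr = np.zeros(len(entries) + 1, dtype=np.int64)
    met, exp, k = [], [], []
    for j, seg in enumerate(entries):
        for m, n, kk in seg:
            met.append(m)
            exp.append(float(n))
            k.append(kk)
        ptr[j + 1] = len(met)
    return (
        ptr,
        np.array(met, dtype=np.int64),
        np.array(exp, dtype=np.float64),
        np.array(k, dtype=np.float64),
    )


def _rates_kernel(
    x,
    kind,
    vmax,
    gamma,
    s_ptr,
    s_met,
    s_exp,
    s_k,
    p_ptr,
    p_met,
    p_exp,
    p_k,
    i_ptr,
    i_met,
    i_k,
    out,
):
    for j in range(kind.shape[0]):
        if kind[j] == 1:
            out[j] = vmax[j]
            continue
        num = 1.0
        den_s = 1.0
        for e in range(s_ptr[j], s_ptr[j + 1]):
            r = x[s_met[e]] / s_k[e]
            num *= r ** s_exp[e]
            den_s *= (1.0 + r) ** s_exp[e]
        if kind[j] == 2:
            out[j] = vmax[j] * num / den_s
            continue
        inh = 0.0
        for e in range(i_ptr[j], i_ptr[j + 1]):
            inh += x[i_met[e]] / i_k[e]
        if kind[j] == 0:
            out[j] = vmax[j] * num / (den_s + inh)
        else:
            rev = 1.0
            den_p = 1.0
            for e in range(p_ptr[j], p_ptr[j + 1]):
                r = x[p_met[e]] / p_k[e]
                rev *= r ** p_exp[e]
                den_p *= (1.0 + r) ** p_exp[e]
            out[j] = vmax[j] * (num - gamma[j] * rev) / (den_s + den_p - 1.0 + inh)
    return out


_rates_kernel_jit = _jit(_rates_kernel)


class PackedKinetics:
    """Array-compiled rate evaluator for one (network, parameter set) pair.

    Builds flat index/parameter arrays once so the full rate vector, the ODE
    right-hand side and finite-difference Jacobians cost microseconds inside
    sampling, continuation and integration loops.  ``vmax`` is exposed as a
    mutable array so enzyme-amount perturbations are in-place multipliers.
    """

    def __init__(self, net: MetabolicNetwork, p: ParameterSet):
        if p.vmax is None:
            raise ConfigurationError("ParameterSet has no Vmax; run solve_vmax first")
        self.net = net
        self.S = np.ascontiguousarray(net.S, dtype=np.float64)
        kind_codes = []
        subs, prods, inhs = [], [], []
        gamma = np.zeros(net.n_reactions)
        for j, rxn in enumerate(net.reaction_ids):
            kind = net.kind[j]
            s_entries, p_entries, i_entries = [], [], []
            if kind == "input_exchange":
                kind_codes.append(_INPUT)
            else:
                for met, n in net.substrates(rxn):
                    s_entries.append(
                        (net.metabolite_index(met), n, _get(p.kbar, (rxn, met), "kbar"))
                    )
                if kind == "output_exchange":
                    kind_codes.append(_OUTPUT)
                elif net.reversible[j]:
                    kind_codes.append(_REVERSIBLE)
                    ks_scale = kp_scale = 1.0
                    for met, n, k in s_entries:
                        ks_scale *= k**-n
                    for met, n in net.products(rxn):
                        k = _get(p.kbar, (rxn, met), "kbar")
                        p_entries.append((net.metabolite_index(met), n, k))
                        kp_scale *= k**-n
                    gamma[j] = _get(p.rho, rxn, "rho") * ks_scale / kp_scale
                else:
                    kind_codes.append(_IRREVERSIBLE)
                if kind == "enzymatic":
                    for reg in net.regulators:
                        if reg.reaction == rxn:
                            i_entries.append(
                                (
                                    net.metabolite_index(reg.metabolite),
                                    1,
                                    _get(p.kibar, (rxn, reg.metabolite), "kibar"),
                                )
                            )
            subs.append(s_entries)
            prods.append(p_entries)
            inhs.append(i_entries)
        self.kind_codes = np.array(kind_codes, dtype=np.int64)
        self.vmax = np.array(
            [_get(p.vmax, r, "vmax") for r in net.reaction_ids], dtype=np.float64
        )
        self.gamma = gamma
        self._s = _pack_segments(subs)
        self._p = _pack_segments(prods)
        i_ptr, i_met, _i_exp, i_k = _pack_segments(inhs)
        self._i = (i_ptr, i_met, i_k)

    def copy(self) -> "PackedKinetics":
        dup = object.__new__(PackedKinetics)
        dup.__dict__.update(self.__dict__)
        dup.vmax = self.vmax.copy()
        return dup

    def rates(self, x: np.ndarray) -> np.ndarray:
        out = np.empty(self.kind_codes.shape[0])
        xc = np.maximum(np.asarray(x, dtype=np.float64), 0.0)
        return _rates_kernel_jit(
            xc,
            self.kind_codes,
            self.vmax,
            self.gamma,
            *self._s,
            *self._p,
            *self._i,
            out,
        )

    def rhs(self, t: float, x: np.ndarray) -> np.ndarray:
        """ODE right-hand side S @ v; signature matches solve_ivp."""
        return self.S @ self.rates(x)

    def scale_vmax(self, reactions: list[str] | str, factor: float) -> None:
        """Multiply Vmax of the named reaction(s) in place."""
        if isinstance(reactions, str):
            reactions = [reactions]
        for rxn in reactions:
            self.vmax[self.net.reaction_index(rxn)] *= factor
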