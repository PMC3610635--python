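"""Mass-action rate equations and steady-state solution.

From a :class:`~itamnet.network.ReactionNetwork` we assemble the
stoichiometry matrix N (species x reactions), per-reaction mass-action
fluxes v(c) = k * prod(reactant concentrations), and the four linear
conservation laws (total chain, kinase, phosphatase and ZAP-70) read
off each species' molecular composition.  The time derivative is
dc/dt = N v(c) and each conserved moiety's row annihilates N exactly.

Steady states are located by stiff integration from the resting state
(all chains unphosphorylated and unbound, enzymes and ZAP free),
followed by a Newton polish on a square system in which four rate rows
are replaced by the conservation constraints.  Integration-then-polish
guarantees the physically reachable branch; an optional warm start
(``x0``) lets dose-response sweeps continue from the neighbouring grid
point, with the same residual and conservation contracts enforced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .constructs import ConcentrationTotals
from .network import CHAIN, KINASE, PHOSPHATASE, ZAP, ReactionNetwork, Species

__all__ = [
    "RateSystem",
    "SteadyState",
    "SteadyStateError",
    "build_rate_system",
    "solve_steady_state",
    "observable",
]

MOIETIES = ("chain", "kinase", "phosphatase", "zap")


class SteadyStateError(RuntimeError):
    """Raised when the solver cannot certify a steady state.

    Carries the last residual so a caller can report how far from
    stationarity the run ended.
    """

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


@dataclass
class RateSystem:
    """Mass-action ODE system for one reaction network."""

    net: ReactionNetwork
    stoichiometry: np.ndarray  # (n_species, n_reactions) int
    rate_constants: np.ndarray  # (n_reactions,)
    reactant_idx: list[tuple[int, ...]]  # per reaction, indices into species
    conservation: np.ndarray  # (4, n_species) int — moiety composition rows

    @property
    def n_species(self) -> int:
        return self.stoichiometry.shape[0]

    def fluxes(self, c: np.ndarray) -> np.ndarray:
        v = self.rate_constants.copy()
        for j, idx in enumerate(self.reactant_idx):
            for i in idx:
                v[j] *= c[i]
        return v

    def rhs(self, c: np.ndarray) -> np.ndarray:
        return self.stoichiometry @ self.fluxes(c)

    def jacobian(self, c: np.ndarray) -> np.ndarray:
        n_r = len(self.reactant_idx)
        dv = np.zeros((n_r, self.n_species))
        for j, idx in enumerate(self.reactant_idx):
            k = self.rate_constants[j]
            if len(idx) == 1:
                dv[j, idx[0]] += k
            else:  # molecularity 2 (possibly i == i for dimerization-style terms)
                a, b = idx
                dv[j, a] += k * c[b]
                dv[j, b] += k * c[a]
        return self.stoichiometry @ dv


def build_rate_system(net: ReactionNetwork) -> RateSystem:
    """Assemble stoichiometry, rate constants and conservation rows."""
    n_s, n_r = net.n_species, net.n_reactions
    N = np.zeros((n_s, n_r), dtype=np.int64)
    ks = np.empty(n_r)
    reactant_idx: list[tuple[int, ...]] = []
    for j, rxn in enumerate(net.reactions):
        for sp in rxn.reactants:
            N[net.index[sp], j] -= 1
        for sp in rxn.products:
            N[net.index[sp], j] += 1
        ks[j] = rxn.rate_constant
        reactant_idx.append(tuple(net.index[sp] for sp in rxn.reactants))
    C = np.array(net.composition(), dtype=np.int64).T  # (4, n_species)
    if np.any(C @ N != 0):
        raise ValueError("conservation rows do not annihilate the stoichiometry matrix")
    return RateSystem(net, N, ks, reactant_idx, C)


@dataclass
class SteadyState:
    """Steady-state concentration vector with residual diagnostics."""

    concentrations: np.ndarray  # clipped to >= 0 for reporting, uM
    residual_norm: float  # max |dc/dt|, uM/s
    conservation_residuals: np.ndarray  # per-moiety relative error
    raw: np.ndarray  # unclipped solution

    def as_dict(self, net: ReactionNetwork) -> dict[str, float]:
        return dict(zip(net.species_names(), self.concentrations))


def initial_state(sys: RateSystem, totals: ConcentrationTotals) -> np.ndarray:
    """Resting state: bare chain plus free enzymes/ZAP at their totals."""
    c0 = np.zeros(sys.n_species)
    for i, sp in enumerate(sys.net.species):
        if sp.kind == CHAIN and sp.sites == 0 and sp.zap == 0 and sp.enzyme is None:
            c0[i] = totals.chain_total
        elif sp.kind == KINASE:
            c0[i] = totals.kinase_total
        elif sp.kind == PHOSPHATASE:
            c0[i] = totals.phosphatase_total
        elif sp.kind == ZAP:
            c0[i] = totals.zap_total
    return c0


def _totals_vector(totals: ConcentrationTotals) -> np.ndarray:
    return np.array(
        [totals.chain_total, totals.kinase_total, totals.phosphatase_total, totals.zap_total]
    )


def _moiety_rows_to_replace(sys: RateSystem) -> list[int]:
    # one representative species per moiety: bare chain, free kinase/phosphatase/ZAP
    rows = []
    for kind in (CHAIN, KINASE, PHOSPHATASE, ZAP):
        for i, sp in enumerate(sys.net.species):
            if sp.kind == kind and sp.sites == 0 and sp.zap == 0 and sp.enzyme is None:
                rows.append(i)
                break
    return rows


def _conservation_rel_err(sys, c, t_vec, scale):
    return np.abs(sys.conservation @ c - t_vec) / scale


def _check(sys: RateSystem, c: np.ndarray, t_vec: np.ndarray, tol: float) -> tuple[bool, float, np.ndarray]:
    scale = max(t_vec.max(), 1e-30)
    res = float(np.max(np.abs(sys.rhs(c)))) if c.size else 0.0
    cons = _conservation_rel_err(sys, c, t_vec, scale)
    ok = (
        res <= tol * scale
        and np.all(cons <= 1e-6)
        and np.all(c >= -1e-12)
    )
    return ok, res, cons


def _newton_polish(
    sys: RateSystem, c: np.ndarray, t_vec: np.ndarray, max_iter: int = 60
) -> np.ndarray | None:
    """Damped Newton on the square system with four rate rows replaced by
    the conservation constraints; falls back to MINPACK hybr if plain
    Newton stalls."""
    rows = _moiety_rows_to_replace(sys)
    if len(rows) != 4:
        return None

    def fun(c):
        f = sys.rhs(c)
        f[rows] = sys.conservation @ c - t_vec
        return f

    def jac(c):
        J = sys.jacobian(c)
        J[rows] = sys.conservation
        return J

    x = np.asarray(c, dtype=float).copy()
    fx = fun(x)
    norm = np.linalg.norm(fx)
    for _ in range(max_iter):
        if norm < 1e-13 * max(t_vec.max(), 1.0):
            return x
        try:
            dx = np.linalg.solve(jac(x), -fx)
        except np.linalg.LinAlgError:
            break
        lam = 1.0
        for _ in range(30):
            x_new = x + lam * dx
            f_new = fun(x_new)
            n_new = np.linalg.norm(f_new)
            if n_new < norm:
                x, fx, norm = x_new, f_new, n_new
                break
            lam *= 0.5
        else:
            break
    if norm < 1e-13 * max(t_vec.max(), 1.0):
        return x
    sol = root(fun, c, jac=jac, method="hybr", tol=1e-14)
    if sol.success:
        return sol.x
    return None


def solve_steady_state(
    sys: RateSystem,
    totals: ConcentrationTotals,
    tol: float = 1e-8,
    t_max: float = 1e6,
    x0: np.ndarray | None = None,
) -> SteadyState:
    """Compute the steady state reached from the resting state.

    Convergence contract: max |dc/dt| <= ``tol`` x (largest total
    concentration), every conserved total matched to relative error
    1e-6, and concentrations nonnegative to -1e-12.  Failure to meet
    the contract by ``t_max`` seconds of integration raises
    :class:`SteadyStateError` carrying the last residual.

    If ``x0`` is given, a Newton polish is attempted from it first
    (warm start for sweeps); the same contract is enforced, and the
    solver falls back to integration from rest if the polish fails.
    """
    t_vec = _totals_vector(totals)
    scale = max(t_vec.max(), 1e-30)

    if sys.n_species == 0 or len(sys.reactant_idx) == 0:
        c = initial_state(sys, totals) if x0 is None else np.asarray(x0, dtype=float)
        ok, res, cons = _check(sys, c, t_vec, tol)
        return SteadyState(np.clip(c, 0, None), res, cons, c)

    if x0 is not None:
        cand = _newton_polish(sys, np.asarray(x0, dtype=float), t_vec)
        if cand is not None:
            ok, res, cons = _check(sys, cand, t_vec, tol)
            if ok:
                return SteadyState(np.clip(cand, 0, None), res, cons, cand)

    c = initial_state(sys, totals)
    rhs = lambda t, y: sys.rhs(y)
    jac = lambda t, y: sys.jacobian(y)
    t0, span = 0.0, 10.0
    last_res = float(np.max(np.abs(sys.rhs(c))))
    while t0 < t_max:
        t1 = min(t0 + span, t_max)
        sol = solve_ivp(
            rhs,
            (t0, t1),
            c,
            method="LSODA",
            jac=jac,
            rtol=1e-8,
            atol=1e-12 * scale,
        )
        if not sol.success:
            raise SteadyStateError(
                f"integration failed at t={t0:g}: {sol.message}", residual=last_res
            )
        c = sol.y[:, -1]
        last_res = float(np.max(np.abs(sys.rhs(c))))
        if last_res <= tol * scale:
            break
        t0, span = t1, span * 10.0
    polished = _newton_polish(sys, c, t_vec)
    if polished is not None:
        ok, res, cons = _check(sys, polished, t_vec, tol)
        if ok:
            return SteadyState(np.clip(polished, 0, None), res, cons, polished)
    ok, res, cons = _check(sys, c, t_vec, tol)
    if not ok:
        raise SteadyStateError(
            f"no steady state to tolerance {tol:g} by t_max={t_max:g} s "
            f"(residual {res:g} uM/s)",
            residual=res,
        )
    return SteadyState(np.clip(c, 0, None), res, cons, c)


def observable(state: SteadyState, net: ReactionNetwork, which: str) -> float:
    """Concentration-weighted observable of a steady state.

    ``bound_zap``: sum of [species] x (number of docked ZAP-70);
    ``total_phosphorylation``: sum of [species] x (number of phosphate
    groups), counting enzyme- and ZAP-bound chain isoforms alike.
    """
    w = np.asarray(net.observable_weights(which), dtype=float)
    return float(w @ state.concentrations)
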