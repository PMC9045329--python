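"""Membrane-enzyme proteome allocation by growth-rate maximization.

The proteome fractions of the membrane enzymes are treated as decision
variables constrained to a fixed total budget (the membrane proteome
fraction phi_M); the objective is the steady-state specific growth rate.
The outer problem is solved with the Nelder-Mead simplex method, the inner
problem is the steady-state solve.  The simplex works on n-1 free
fractions, the last one being the budget remainder; infeasible points
(negative fractions) are rejected with a penalty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .dynamics import solve_steady_state
from .mca import _objective
from .network import NetworkModel

__all__ = ["AllocationProblem", "AllocationResult",
           "optimize_membrane_enzymes", "random_feasible_phi"]


@dataclass
class AllocationProblem:
    decision_ids: list[str]  # membrane enzyme ids
    phi_total: float  # budget
    max_iter: int = 10_000
    tolerance: float = 1e-10
    initial_simplex_rel: float = 10.0  # percent-scale relative simplex size
    seed: int = 0


@dataclass
class AllocationResult:
    phi: dict[str, float]
    mu: float  # achieved objective value
    n_eval: int
    converged: bool
    history: list = field(default_factory=list)


class AllocationError(RuntimeError):
    pass


def _apply_phi(model: NetworkModel, ids, phi) -> NetworkModel:
    m = model
    for rid, p in zip(ids, phi):
        m = m.with_phi(rid, float(p))
    return m


def random_feasible_phi(n: int, phi_total: float, rng) -> np.ndarray:
    """Uniform sample from the allocation simplex (Dirichlet(1))."""
    w = rng.dirichlet(np.ones(n))
    return w * phi_total


def optimize_membrane_enzymes(model: NetworkModel,
                              prob: AllocationProblem | None = None,
                              objective: str = "mu") -> AllocationResult:
    """Maximize steady-state growth over the membrane-enzyme simplex.

    Deterministic for a given problem seed.  Raises
    :class:`AllocationError` if no feasible starting point yields a
    positive objective.
    """
    if prob is None:
        prob = AllocationProblem(
            [r.id for r in model.membrane_enzymes],
            model.cell.phi_membrane_total)
    ids = list(prob.decision_ids)
    n = len(ids)
    if n < 2:
        raise AllocationError("need at least two decision enzymes")
    x0_full = np.array([model.reaction(r).phi for r in ids])
    if abs(x0_full.sum() - prob.phi_total) > 1e-9:
        x0_full = np.full(n, prob.phi_total / n)

    warm = {"state": None}
    n_eval = {"n": 0}
    history = []

    def neg_mu(x):
        # x = first n-1 fractions; last is the budget remainder
        phi = np.append(x, prob.phi_total - x.sum())
        if (phi < 0).any():
            return 1e3 * (1.0 + float(np.abs(phi[phi < 0]).sum()))
        m = _apply_phi(model, ids, phi)
        ss = solve_steady_state(m, x0=warm["state"], polish=True)
        n_eval["n"] += 1
        if not ss.converged:
            return 1e3
        warm["state"] = ss.state
        val = _objective(ss, objective)
        history.append((phi.copy(), val))
        return -val

    x0 = x0_full[:-1]
    rng = np.random.default_rng(prob.seed)
    # relative initial simplex: vertices displaced by a percentage of the
    # starting point (sign chosen at random per vertex, seeded)
    step = prob.initial_simplex_rel / 100.0
    simplex = [x0.copy()]
    for i in range(n - 1):
        v = x0.copy()
        v[i] += step * max(x0[i], prob.phi_total / n) \
            * (1 if rng.random() < 0.5 else -1)
        simplex.append(np.clip(v, 0.0, prob.phi_total))
    res = minimize(neg_mu, x0, method="Nelder-Mead",
                   options={"maxiter": prob.max_iter,
                            "xatol": prob.tolerance,
                            "fatol": prob.tolerance,
                            "initial_simplex": np.array(simplex)})
    if not np.isfinite(res.fun) or res.fun >= 1e3:
        raise AllocationError("optimization failed: no feasible optimum")
    best = np.append(res.x, prob.phi_total - res.x.sum())
    return AllocationResult(
        phi=dict(zip(ids, best.tolist())),
        mu=-float(res.fun), n_eval=n_eval["n"],
        converged=bool(res.success), history=history)
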