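"""ODE assembly, integration, and steady-state location.

The metabolic state is the vector of free metabolite concentrations plus the
membrane potential.  Mass balance gives dC_j/dt = (J_j + sum_i c_ji v_i)/V
for every free species; charge translocation gives
d(dpsi)/dt = (F/C_m) sum_i c_C,i v_i.  Clamped species (ATP/ADP/Pi, the
external gas phase, buffered ions) have zero derivative, and one member per
conserved moiety pool is computed algebraically from the pool total, which
enforces moiety conservation exactly and removes the redundancy of the
stoichiometry.

Steady states are located the same way the study system is run in practice:
stiff integration to long time (default 1e6 s, far beyond the ~1e3 s
relaxation time of the network), with an optional Newton polish of the
algebraic system afterwards (off by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .network import ACTIVITY_ONE_SPECIES, NetworkModel

__all__ = ["MetabolicState", "SteadyStateResult", "assemble_odes",
           "integrate", "solve_steady_state"]

log = logging.getLogger(__name__)

_CONC_FLOOR = 1e-30
_RESIDUAL_CONC_SCALE = 1e-12  # mol/L; absolute floor for relative residuals


@dataclass
class MetabolicState:
    """Metabolite concentrations (mol/L) + membrane potential (V) at time t."""

    conc: dict[str, float]
    psi: float
    time: float = 0.0


@dataclass
class SteadyStateResult:
    state: MetabolicState
    velocities: dict[str, float]  # mol/s per cell (biomass: g/s)
    fluxes: dict[str, float]  # diffusive, mol/s, positive = influx
    delta_g: dict[str, float]  # J/mol, enzyme reactions
    mu: float  # gross specific growth rate, 1/s
    mu_net: float  # mu minus the maintenance-equivalent rate, 1/s
    converged: bool
    residual: float


class AssemblyError(ValueError):
    pass


class OdeSystem:
    """Compiled right-hand side of the model ODEs.

    Precomputes index arrays so the rhs is cheap to evaluate; exposes
    ``rhs(t, y)`` on the packed vector [free concentrations..., psi] as well
    as a state-level ``__call__`` returning per-species derivatives.
    """

    def __init__(self, model: NetworkModel):
        self.model = model
        cell = model.cell
        self.rt = cell.rt
        self.met_ids = list(model.metabolites)
        self.index = {m: i for i, m in enumerate(self.met_ids)}
        n_met = len(self.met_ids)

        for rxn in model.reactions:
            for sp in rxn.stoich:
                if sp not in self.index:
                    raise AssemblyError(
                        f"reaction {rxn.id}: unknown species {sp!r}")

        self.template = np.array(
            [model.metabolites[m].concentration_init for m in self.met_ids])
        fixed = np.array([model.metabolites[m].fixed for m in self.met_ids])

        # one member per pool (the last-listed) is eliminated algebraically
        self.elim: list[tuple[int, float, list[int]]] = []
        elim_set: set[int] = set()
        for pool in model.moieties.values():
            e = self.index[pool.members[-1]]
            if fixed[e] or e in elim_set:
                raise AssemblyError(
                    f"moiety {pool.id}: cannot eliminate {pool.members[-1]}")
            elim_set.add(e)
            others = [self.index[m] for m in pool.members[:-1]]
            self.elim.append((e, pool.total, others))
        # members eliminated for one pool must not feed another elimination
        for _, _, others in self.elim:
            if any(o in elim_set for o in others):
                raise AssemblyError("moiety pools share eliminated members")

        self.free_idx = np.array(
            [i for i in range(n_met)
             if not fixed[i] and i not in elim_set], dtype=int)
        self.n_free = len(self.free_idx)

        # per-metabolite compartment volume (L)
        self.volume = np.array(
            [model.compartments[model.metabolites[m].compartment].volume
             for m in self.met_ids])

        # reaction bookkeeping -------------------------------------------
        self.rxn_ids = [r.id for r in model.reactions]
        n_rxn = len(model.reactions)
        self.S = np.zeros((n_met, n_rxn))
        for j, rxn in enumerate(model.reactions):
            for sp, c in rxn.stoich.items():
                self.S[self.index[sp], j] += c

        enz = [j for j, r in enumerate(model.reactions) if r.kind == "enzyme"]
        self.enz_idx = np.array(enz, dtype=int)
        ev = [model.reactions[j] for j in enz]
        self.vmax = np.array([cell.w_prot * r.kcat * r.phi for r in ev])
        self.ln_keq = np.log([r.keq for r in ev])
        self.chi = np.array([float(r.chi) for r in ev])
        self.cc = np.array([r.charge_out for r in ev])
        # quotient stoichiometry (activity-one species excluded)
        self.Mq = np.zeros((len(ev), n_met))
        for i, r in enumerate(ev):
            for sp, c in r.stoich.items():
                if sp not in ACTIVITY_ONE_SPECIES:
                    self.Mq[i, self.index[sp]] += c
        # flat (reaction, species) saturation pairs, grouped per reaction
        # (substrates first, so the product block is all_slice minus
        # sub_slice)
        pair_met, pair_km, pair_exp = [], [], []
        self.sub_slices, self.all_slices = [], []
        self.convenience = []
        for r in ev:
            start = len(pair_met)
            subs = [(sp, c) for sp, c in r.stoich.items() if sp in r.km
                    and c < 0]
            prods = [(sp, c) for sp, c in r.stoich.items() if sp in r.km
                     and c > 0]
            for sp, c in subs + prods:
                pair_met.append(self.index[sp])
                pair_km.append(r.km[sp])
                pair_exp.append(abs(c))
            self.sub_slices.append(slice(start, start + len(subs)))
            self.all_slices.append(slice(start, len(pair_met)))
            self.convenience.append(r.rate_law == "convenience")
        self.pair_met = np.array(pair_met, dtype=int)
        self.pair_km = np.array(pair_km)
        self.pair_exp = np.array(pair_exp)

        self.cc_full = np.zeros(n_rxn)
        self.cc_full[self.enz_idx] = self.cc
        self.f_over_cm = cell.faraday / cell.capacitance

        self.maint_idx = [j for j, r in enumerate(model.reactions)
                          if r.kind == "maintenance"]
        self.bio_idx = [j for j, r in enumerate(model.reactions)
                        if r.kind == "biomass"]
        self.maint_flux = cell.maintenance_atp * cell.dry_mass
        atp_prod = [j for j, r in enumerate(model.reactions)
                    if r.kind == "enzyme" and r.stoich.get("atp", 0) > 0]
        self.atp_synthase_idx = atp_prod[0] if atp_prod else None
        # precursor-availability factors for the biomass drain: the drains
        # are otherwise zeroth-order sinks and would pull a pool negative
        # when its supply reaction saturates; K is far below operating
        # concentrations so the factor only acts near depletion
        self.drain_idx = []
        if self.bio_idx:
            bio = model.reactions[self.bio_idx[0]]
            self.drain_idx = [self.index[sp] for sp, c in bio.stoich.items()
                              if c < 0 and sp != "atp"]
        self.drain_k = 1e-6  # mol/L

        # diffusion
        self.diff_sp_idx = np.array(
            [self.index[d.species] for d in model.diffusions], dtype=int)
        self.diff_coef = np.array(
            [4.0 * np.pi * d.d_coeff * cell.radius * 1e3
             for d in model.diffusions])
        self.diff_env = np.array([d.c_env for d in model.diffusions])

        self._neg_warned = False

    # -- state packing ---------------------------------------------------
    def pack(self, state: MetabolicState) -> np.ndarray:
        y = np.empty(self.n_free + 1)
        for k, i in enumerate(self.free_idx):
            y[k] = state.conc[self.met_ids[i]]
        y[-1] = state.psi
        return y

    def unpack(self, y: np.ndarray, time: float = 0.0) -> MetabolicState:
        c = self.full_conc(y)
        return MetabolicState(
            {m: c[i] for i, m in enumerate(self.met_ids)}, float(y[-1]), time)

    def initial_vector(self) -> np.ndarray:
        y = np.empty(self.n_free + 1)
        y[:-1] = self.template[self.free_idx]
        y[-1] = 0.135  # starting membrane potential guess, V
        return y

    def full_conc(self, y: np.ndarray) -> np.ndarray:
        c = self.template.copy()
        c[self.free_idx] = y[:-1]
        for e, total, others in self.elim:
            c[e] = total - c[others].sum()
        neg = c < 0
        if neg.any():
            if not self._neg_warned and (c[neg] < -1e-9).any():
                log.warning("negative concentration excursion clipped: %s",
                            [self.met_ids[i] for i in np.where(neg)[0]])
                self._neg_warned = True
            c = np.maximum(c, 0.0)
        return c

    # -- physics ---------------------------------------------------------
    def velocities(self, c: np.ndarray, psi: float) -> np.ndarray:
        """Velocities of every reaction (enzymes, maintenance, biomass)."""
        v = np.zeros(len(self.rxn_ids))
        v[self.enz_idx] = self._enzyme_velocities(c, psi)[0]
        for j in self.maint_idx:
            v[j] = self.maint_flux
        for j in self.bio_idx:
            v[j] = self._biomass_flux(v, c)
        return v

    def _enzyme_velocities(self, c, psi):
        ln_c = np.log(np.maximum(np.nan_to_num(c), _CONC_FLOOR))
        dg = self.rt * (self.Mq @ ln_c - self.ln_keq) \
            + self.cc * self.model.cell.faraday * psi
        tf = 1.0 - np.exp(np.minimum(dg / (self.chi * self.rt), 500.0))
        term = (np.maximum(c[self.pair_met], 0.0) / self.pair_km) \
            ** self.pair_exp
        n = len(self.vmax)
        sat = np.empty(n)
        for i in range(n):
            subs = term[self.sub_slices[i]]
            if self.convenience[i]:
                prods = term[self.sub_slices[i].stop:self.all_slices[i].stop]
                sat[i] = (subs / (1.0 + subs)).prod() / (1.0 + prods.sum())
            else:
                sat[i] = subs.prod() / (1.0 + term[self.all_slices[i]].sum())
        return self.vmax * sat * tf, dg, sat, tf

    def _biomass_flux(self, v: np.ndarray, c: np.ndarray) -> float:
        """Herbert-Pirt assignment: ATP surplus over maintenance -> biomass.

        The surplus-driven flux is attenuated by the availability of the
        reduced-cofactor and acetyl-CoA precursors (hyperbolic factors with
        a 1 uM half-saturation) so the drains cannot outrun their supply.
        """
        if self.atp_synthase_idx is None or not self.maint_idx:
            return 0.0
        surplus = v[self.atp_synthase_idx] - self.maint_flux
        flux = max(0.0, surplus) / self.model.biomass.atp_per_g
        for i in self.drain_idx:
            flux *= c[i] / (c[i] + self.drain_k)
        return flux

    def delta_g(self, c: np.ndarray, psi: float) -> np.ndarray:
        ln_c = np.log(np.maximum(c, _CONC_FLOOR))
        return self.rt * (self.Mq @ ln_c - self.ln_keq) \
            + self.cc * self.model.cell.faraday * psi

    def diffusive_fluxes(self, c: np.ndarray) -> np.ndarray:
        return self.diff_coef * (self.diff_env - c[self.diff_sp_idx])

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        c = self.full_conc(y)
        v = self.velocities(c, float(y[-1]))
        dc = self.S @ v
        np.add.at(dc, self.diff_sp_idx, self.diffusive_fluxes(c))
        dc /= self.volume
        dy = np.empty_like(y)
        dy[:-1] = dc[self.free_idx]
        dy[-1] = self.f_over_cm * float(self.cc_full @ v)
        return dy

    def __call__(self, state: MetabolicState):
        """Per-species derivative map + d(psi)/dt at ``state``."""
        y = self.pack(state)
        dy = self.rhs(state.time, y)
        c = self.full_conc(y)
        v = self.velocities(c, state.psi)
        dc = self.S @ v
        np.add.at(dc, self.diff_sp_idx, self.diffusive_fluxes(c))
        dc /= self.volume
        fixed = {m.id for m in self.model.metabolites.values() if m.fixed}
        return ({m: (0.0 if m in fixed else dc[i])
                 for i, m in enumerate(self.met_ids)}, float(dy[-1]))

    # -- residual --------------------------------------------------------
    def residual(self, y: np.ndarray) -> float:
        """max relative |dC/dt| (1/s) over free species and psi."""
        dy = self.rhs(0.0, y)
        scale = np.maximum(np.abs(y[:-1]), _RESIDUAL_CONC_SCALE)
        r = np.abs(dy[:-1]) / scale
        r_psi = abs(dy[-1]) / max(abs(y[-1]), 1e-3)
        return float(max(r.max(), r_psi)) if r.size else float(r_psi)


def assemble_odes(model: NetworkModel) -> OdeSystem:
    """Compile the model into an ODE system (see :class:`OdeSystem`)."""
    return OdeSystem(model)


def integrate(model: NetworkModel, t_end: float, abs_tol: float = 1e-8,
              rel_tol: float = 1e-6, x0: MetabolicState | None = None,
              n_points: int = 50, system: OdeSystem | None = None
              ) -> list[MetabolicState]:
    """Integrate the model forward and return a trajectory of states."""
    sys_ = system or assemble_odes(model)
    y0 = sys_.pack(x0) if x0 is not None else sys_.initial_vector()
    if t_end <= 0:
        return [sys_.unpack(y0, 0.0)]
    t_eval = np.linspace(0.0, t_end, n_points + 1)
    sol = solve_ivp(sys_.rhs, (0.0, t_end), y0, method="LSODA",
                    atol=abs_tol, rtol=rel_tol, t_eval=t_eval)
    if not sol.success:
        raise RuntimeError(
            f"integration failed at t={sol.t[-1]:.3g}s: {sol.message}; "
            f"last state retained")
    return [sys_.unpack(sol.y[:, k], sol.t[k]) for k in range(sol.y.shape[1])]


def _polish(sys_: OdeSystem, y: np.ndarray, tol: float) -> np.ndarray | None:
    """Newton polish of the steady state in log-concentration space."""
    floor = 1e-16
    z0 = np.concatenate([np.log(np.maximum(y[:-1], floor)), [y[-1]]])
    scale = np.maximum(np.abs(y[:-1]), _RESIDUAL_CONC_SCALE)

    def fun(z):
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            yy = np.concatenate([np.exp(np.minimum(z[:-1], 100.0)),
                                 [z[-1]]])
            dy = sys_.rhs(0.0, yy)
        out = np.empty_like(dy)
        out[:-1] = np.nan_to_num(dy[:-1] / scale, nan=1e6)
        out[-1] = np.nan_to_num(dy[-1], nan=1e6)
        return out

    try:
        sol = root(fun, z0, method="hybr", options={"xtol": 1e-12})
    except Exception:  # pragma: no cover - defensive
        return None
    if not sol.success:
        return None
    y_new = np.concatenate([np.exp(sol.x[:-1]), [sol.x[-1]]])
    # accept only a genuine *polish*: the root must be close to the current
    # point (root-finding from afar can land on spurious/unstable roots)
    d_conc = np.abs(sol.x[:-1] - z0[:-1]).max() if len(z0) > 1 else 0.0
    if d_conc > 0.7 or abs(sol.x[-1] - z0[-1]) > 0.01:
        return None
    if sys_.residual(y_new) <= max(tol, sys_.residual(y)):
        return y_new
    return None


def solve_steady_state(model: NetworkModel, t_max: float = 1e6,
                       residual_tol: float = 1e-8, polish: bool = False,
                       x0: MetabolicState | None = None,
                       abs_tol: float = 1e-8, rel_tol: float = 1e-6,
                       system: OdeSystem | None = None) -> SteadyStateResult:
    """Integrate to long time and verify a steady state.

    Integration proceeds in expanding windows; a window ends early once the
    maximum relative |dC/dt| falls below ``residual_tol`` (1/s).  When
    ``polish`` is set, a Newton refinement of the algebraic steady-state
    system is attempted first from the current point (useful for warm starts
    and for tight finite-difference work); the polished point is only
    accepted if it improves the residual.

    Non-convergence is reported on the result (``converged=False``), not
    raised.
    """
    sys_ = system or assemble_odes(model)
    y = sys_.pack(x0) if x0 is not None else sys_.initial_vector()
    t_done = 0.0

    if polish:
        y_p = _polish(sys_, y, residual_tol)
        if y_p is not None:
            y = y_p

    windows = [1e3, 1e4, 1e5, t_max]
    while sys_.residual(y) > residual_tol and t_done < t_max:
        t_next = next((w for w in windows if w > t_done), t_max)
        t_next = min(t_next, t_max)
        sol = solve_ivp(sys_.rhs, (t_done, t_next), y, method="LSODA",
                        atol=abs_tol, rtol=rel_tol)
        y = np.maximum(sol.y[:, -1], 0.0) if sol.success else y
        if not sol.success:
            break
        t_done = t_next
        if polish:
            y_p = _polish(sys_, y, residual_tol)
            if y_p is not None:
                y = y_p
                break

    res = sys_.residual(y)
    state = sys_.unpack(y, t_done)
    c = sys_.full_conc(y)
    v = sys_.velocities(c, state.psi)
    dg = sys_.delta_g(c, state.psi)
    fluxes = sys_.diffusive_fluxes(c)
    cell = model.cell
    if sys_.atp_synthase_idx is not None:
        v_atp = v[sys_.atp_synthase_idx]
        mu = v_atp / model.biomass.atp_per_g / cell.dry_mass
        mu_net = (v_atp - sys_.maint_flux) / model.biomass.atp_per_g \
            / cell.dry_mass
    else:
        mu = mu_net = 0.0
    return SteadyStateResult(
        state=state,
        velocities={rid: float(v[j]) for j, rid in enumerate(sys_.rxn_ids)},
        fluxes={d.species: float(fluxes[k])
                for k, d in enumerate(model.diffusions)},
        delta_g={model.reactions[j].id: float(dg[i])
                 for i, j in enumerate(sys_.enz_idx)},
        mu=float(mu), mu_net=float(mu_net),
        converged=bool(res <= residual_tol), residual=float(res),
    )
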