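"""Monod-equation analysis of simulated growth curves.

The phenomenological layer on top of the mechanistic model: sweep steady
states over a methanol grid, extract the Monod parameters the way a
physiologist would (mu_max as the rate at saturating substrate, K_M as the
concentration at half mu_max, specific affinity alpha as the initial
slope), evaluate the classical rate laws

    Monod:        mu = mu_max C / (C + K_M)
    alternative:  mu = mu_max alpha C / (mu_max + alpha C)
    first order:  mu = alpha C
    Liebig:       mu = min(mu_max, alpha C)

and the Gaussian-amended alternative form

    mu = mu_max alpha C/(mu_max + alpha C)
         + mu_o exp[-pi (ln(mu_max/(alpha C)) / beta)^2],

whose correction term absorbs the growth-rate control exerted by the
non-rate-determining enzymes and moieties at intermediate substrate.
The approximate control coefficients implied by the alternative form are
eps_MCR = alpha C/(alpha C + mu_max) and eps_MTA = mu_max/(alpha C +
mu_max); they sum to one identically.

All rates are handled in 1/day (the customary reporting unit);
concentrations in mol/L.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq, curve_fit

from .constants import SECONDS_PER_DAY
from .dynamics import SteadyStateResult, solve_steady_state
from .network import NetworkModel

__all__ = ["GrowthCurve", "MonodFit", "CompositeParams", "growth_curve",
           "extract_mu_max", "extract_k_m", "extract_alpha", "monod",
           "alt_monod", "first_order", "liebig", "approx_control",
           "amended_monod", "fit_gaussian_amendment", "fit_monod",
           "composite_params", "rate_law_comparison"]


class ExtractionError(ValueError):
    pass


@dataclass
class GrowthCurve:
    methanol: np.ndarray  # mol/L
    mu: np.ndarray  # 1/day (gross specific growth rate)

    def __post_init__(self):
        self.methanol = np.asarray(self.methanol, float)
        self.mu = np.asarray(self.mu, float)
        if self.methanol.shape != self.mu.shape:
            raise ValueError("methanol and mu must have equal length")

    def interpolator(self):
        return PchipInterpolator(np.log(self.methanol), self.mu)


@dataclass
class MonodFit:
    mu_max: float  # 1/day
    k_m: float  # mol/L
    alpha: float  # 1/(M day)
    mu_o: float = 0.0  # 1/day
    beta_low: float = float("nan")  # C < mu_max/alpha
    beta_high: float = float("nan")  # C >= mu_max/alpha


@dataclass
class CompositeParams:
    k_mta_app: float  # mol/g/s
    k_mcr_app: float  # mol/g/s
    c_com_0: float  # mol/L, free coenzyme M near zero methanol
    cob_saturation: float  # T_CoB/(T_CoB + Km_CoB)
    alpha: float  # 1/(M day), mechanistic composite
    mu_max: float  # 1/day, mechanistic composite


def growth_curve(model: NetworkModel, grid) -> GrowthCurve:
    """Steady-state gross specific growth rate over a methanol grid.

    Solves are warm-started along the (ascending) grid.
    """
    grid = np.sort(np.asarray(grid, float))
    mus = []
    state = None
    for conc in grid:
        ss = solve_steady_state(model.set_methanol(float(conc)), x0=state,
                                polish=True)
        state = ss.state
        mus.append(ss.mu * SECONDS_PER_DAY)
    return GrowthCurve(grid, np.array(mus))


def extract_mu_max(curve: GrowthCurve) -> float:
    """Maximum growth rate, approximated by the rate at 1 M methanol."""
    if curve.methanol[-1] < 0.999:
        raise ExtractionError("curve must extend to 1 M methanol")
    return float(curve.interpolator()(0.0))  # log(1 M) = 0


def extract_k_m(curve: GrowthCurve, mu_max: float | None = None) -> float:
    """Half-saturation constant: methanol driving growth at mu_max/2.

    Monotone (PCHIP) interpolation in log-concentration.
    """
    mu_max = extract_mu_max(curve) if mu_max is None else mu_max
    f = curve.interpolator()
    lo, hi = np.log(curve.methanol[0]), np.log(curve.methanol[-1])
    g = lambda x: f(x) - mu_max / 2.0
    if g(lo) * g(hi) > 0:
        raise ExtractionError("curve does not bracket mu_max/2")
    return float(np.exp(brentq(g, lo, hi)))


def extract_alpha(curve: GrowthCurve, c_lin: float = 1e-5) -> float:
    """Specific affinity: zero-intercept slope over points below ``c_lin``.

    Least squares of mu against C with the intercept pinned at the origin,
    using every grid point below 10 uM by default.
    """
    mask = curve.methanol < c_lin
    if mask.sum() < 1:
        raise ExtractionError(f"no grid points below {c_lin} M")
    c, mu = curve.methanol[mask], curve.mu[mask]
    return float((mu * c).sum() / (c * c).sum())


def fit_monod(curve: GrowthCurve) -> MonodFit:
    """Full phenomenological extraction incl. the Gaussian amendment."""
    mu_max = extract_mu_max(curve)
    k_m = extract_k_m(curve, mu_max)
    alpha = extract_alpha(curve)
    mu_o, b_lo, b_hi = fit_gaussian_amendment(curve, mu_max, alpha)
    return MonodFit(mu_max, k_m, alpha, mu_o, b_lo, b_hi)


# -- rate laws --------------------------------------------------------------

def monod(C, mu_max: float, k_m: float):
    """Classical Monod equation."""
    C = np.asarray(C, float)
    return mu_max * C / (C + k_m)


def alt_monod(C, mu_max: float, alpha: float):
    """Monod recast with specific affinity (K_M approximated by
    mu_max/alpha)."""
    C = np.asarray(C, float)
    return mu_max * alpha * C / (mu_max + alpha * C)


def first_order(C, alpha: float):
    """Low-substrate first-order limit."""
    return alpha * np.asarray(C, float)


def liebig(C, mu_max: float, alpha: float, c_o: float | None = None):
    """Law-of-the-minimum form: first order below c_o, constant above."""
    C = np.asarray(C, float)
    c_o = mu_max / alpha if c_o is None else c_o
    return np.where(C >= c_o, mu_max, alpha * C)


def approx_control(C, mu_max: float, alpha: float):
    """Control-coefficient approximations implied by the alternative form.

    Returns (eps_MCR, eps_MTA); the pair sums to one identically.
    """
    C = np.asarray(C, float)
    ac = alpha * C
    return ac / (ac + mu_max), mu_max / (ac + mu_max)


def amended_monod(C, fit: MonodFit):
    """Alternative Monod plus the asymmetric Gaussian correction.

    The correction peaks at C = mu_max/alpha (argument zero), with separate
    breadths below (beta_low) and above (beta_high) the peak; it is
    continuous at the switch because the argument vanishes there.
    """
    C = np.asarray(C, float)
    base = alt_monod(C, fit.mu_max, fit.alpha)
    x = np.log(fit.mu_max / (fit.alpha * C))
    beta = np.where(C < fit.mu_max / fit.alpha, fit.beta_low, fit.beta_high)
    with np.errstate(invalid="ignore"):
        corr = fit.mu_o * np.exp(-np.pi * (x / beta) ** 2)
    return base + np.nan_to_num(corr)


def fit_gaussian_amendment(curve: GrowthCurve, mu_max: float, alpha: float
                           ) -> tuple[float, float, float]:
    """Fit (mu_o, beta_low, beta_high) to the residual above alt_monod.

    mu_o is the largest residual on the grid; each beta is fitted by least
    squares on the relative residual (residual/mu), separately for points
    below and above the peak concentration mu_max/alpha.  A curve that
    already follows the alternative Monod form yields mu_o = 0 and NaN
    breadths (degenerate fit, reported as such).
    """
    resid = curve.mu - alt_monod(curve.methanol, mu_max, alpha)
    mu_o = float(resid.max())
    if mu_o <= 1e-12 * max(abs(curve.mu).max(), 1.0):
        return 0.0, float("nan"), float("nan")
    x = np.log(mu_max / (alpha * curve.methanol))
    w = 1.0 / np.maximum(curve.mu, 1e-12 * curve.mu.max())

    def fit_side(mask):
        mask = mask & (resid > 1e-6 * mu_o)
        if mask.sum() < 2:
            return float("nan")
        def f(xx, beta):
            return mu_o * np.exp(-np.pi * (xx / beta) ** 2)
        popt, _ = curve_fit(f, x[mask], resid[mask], p0=[2.0],
                            sigma=1.0 / w[mask], maxfev=10000)
        return float(abs(popt[0]))

    beta_low = fit_side(curve.methanol < mu_max / alpha)
    beta_high = fit_side(curve.methanol >= mu_max / alpha)
    return mu_o, beta_low, beta_high


def composite_params(model: NetworkModel, ss_low: SteadyStateResult,
                     ss_high: SteadyStateResult) -> CompositeParams:
    """Mechanistic composite expressions for alpha and mu_max.

    alpha is governed by the methanol:CoM methyltransferase at vanishing
    substrate (its apparent rate constant is the catalytic constant scaled
    by the free-coenzyme-M occupancy there); mu_max by the methyl-CoM
    reductase at saturation (catalytic constant scaled by the occupancies
    of the methyl-CoM and CoB pools).  Yields convert product fluxes to
    biomass, and the per-cell fluxes are normalized by dry mass to give
    specific rates, so

        alpha  = W_prot phi_MTA Y_P/CH3OH k_MTA,app
                 / (K_m,CH3OH dry_mass)
        mu_max = W_prot phi_MCR Y_P/CH4 k_MCR,app / dry_mass

    ``ss_low`` must be a converged state well below 0.2 mM methanol
    (supplies C_CoM,0); ``ss_high`` well above 15 mM.
    """
    mta = model.reaction("MTA")
    mcr = model.reaction("MCR")
    t_com = model.moieties["CoM"].total
    t_cob = model.moieties["CoB"].total
    c_com0 = ss_low.state.conc["com"]

    k_mta_app = mta.kcat * c_com0 / (c_com0 + mta.km["com"])
    cob_sat = t_cob / (t_cob + mcr.km["cob"])
    k_mcr_app = mcr.kcat * t_com / (t_com + mcr.km["mcom"]) * cob_sat

    cell = model.cell
    bio = model.biomass
    alpha = (cell.w_prot * mta.phi * bio.y_p_ch3oh * k_mta_app
             / mta.km["ch3oh_c"] / cell.dry_mass) * SECONDS_PER_DAY
    mu_max = (cell.w_prot * mcr.phi * bio.y_p_ch4 * k_mcr_app
              / cell.dry_mass) * SECONDS_PER_DAY
    return CompositeParams(k_mta_app, k_mcr_app, c_com0, cob_sat,
                           alpha, mu_max)


def rate_law_comparison(curve: GrowthCurve, fit: MonodFit):
    """Per-grid-point relative difference (sim - law)/sim for each law.

    Returns a dict of arrays keyed by law name ("monod", "alt_monod",
    "amended"), plus the grid, suitable for a tidy table.
    """
    sim = curve.mu
    out = {"methanol": curve.methanol}
    with np.errstate(divide="ignore", invalid="ignore"):
        out["monod"] = (sim - monod(curve.methanol, fit.mu_max, fit.k_m)) \
            / sim
        out["alt_monod"] = (sim - alt_monod(curve.methanol, fit.mu_max,
                                            fit.alpha)) / sim
        out["amended"] = (sim - amended_monod(curve.methanol, fit)) / sim
    return out
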