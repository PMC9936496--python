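"""Two-state oligomeric coiled-coil unfolding thermodynamics.

The model: a folded n-mer (default heterodimer E·K) unfolds reversibly into
its constituent chains.  The free energy of unfolding follows the
Gibbs–Helmholtz expansion anchored at the reference temperature ``T0``
where ΔG = 0 and Ku = Kf = 1 (standard state 1 mol/L):

    ΔG_u(T) = ΔH°·(1 − T/T0) + ΔCp·[(T − T0) − T·ln(T/T0)]

with ΔH° the unfolding enthalpy at T0 and ΔCp a temperature-independent
heat-capacity change.  The unfolding constant Ku(T) = exp(−ΔG_u/RT) (in
mol/L) closes a mass balance that yields the folded fraction at a given
total monomer concentration Ct; melting curves are the folded fraction
interpolating between linear folded/unfolded baselines.  Multiple
concentrations are fitted globally with one shared thermodynamic triple
and per-curve baselines.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)

#: Gas constant, J·mol⁻¹·K⁻¹.
R_GAS = 8.314

#: Exponent clamp applied before exponentiation to avoid overflow.
EXP_CLAMP = 700.0

KELVIN_OFFSET = 273.15


def celsius_to_kelvin(t_celsius):
    """Convert °C to K (K = °C + 273.15)."""
    return np.asarray(t_celsius, dtype=float) + KELVIN_OFFSET


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UnfoldingParams:
    """Thermodynamic triple of the two-state unfolding model.

    Parameters
    ----------
    dH0 : float
        Unfolding enthalpy at the reference temperature, kJ·mol⁻¹.
    T0 : float
        Reference temperature where ΔG = 0 and Ku = Kf = 1, K.
    dCp : float
        Heat-capacity change of unfolding, kJ·mol⁻¹·K⁻¹.
    stoichiometry : int
        Number of chains in the folded species (2 = dimer).
    hetero : bool
        True for an equimolar hetero-oligomer (distinct strands),
        False for a homo-oligomer.
    c_std : float
        Standard-state concentration; fixed at 1 mol·L⁻¹.
    """

    dH0: float
    T0: float
    dCp: float
    stoichiometry: int = 2
    hetero: bool = True
    c_std: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite([self.dH0, self.T0, self.dCp]).all():
            raise ValueError("thermodynamic parameters must be finite")
        if self.T0 <= 0:
            raise ValueError(f"T0 must be positive (K), got {self.T0}")
        if self.stoichiometry < 2:
            raise ValueError("stoichiometry must be >= 2")
        if self.c_std != 1.0:
            raise ValueError("standard state is fixed at 1 mol/L")


@dataclass(frozen=True)
class BaselineParams:
    """Linear folded/unfolded baselines: signal = a + b·T (T in K)."""

    aF: float
    bF: float
    aU: float
    bU: float

    def __post_init__(self) -> None:
        if not np.isfinite([self.aF, self.bF, self.aU, self.bU]).all():
            raise ValueError("baseline parameters must be finite")

    def folded(self, T):
        return self.aF + self.bF * np.asarray(T, dtype=float)

    def unfolded(self, T):
        return self.aU + self.bU * np.asarray(T, dtype=float)


@dataclass(frozen=True)
class MeltCurve:
    """One concentration's thermal melting curve.

    ``temperatures`` in K (strictly increasing), ``signal`` in mdeg or mean
    residue ellipticity (``signal_unit``), ``Ct`` the total monomer
    concentration in mol/L (both strands summed for a heterodimer).
    """

    temperatures: np.ndarray
    signal: np.ndarray
    Ct: float
    label: str = ""
    signal_unit: str = "MRE"

    MIN_POINTS = 8

    def __post_init__(self) -> None:
        object.__setattr__(self, "temperatures",
                           np.asarray(self.temperatures, dtype=float))
        object.__setattr__(self, "signal",
                           np.asarray(self.signal, dtype=float))
        if self.temperatures.shape != self.signal.shape:
            raise ValueError("temperature and signal lengths differ")
        if self.temperatures.size < self.MIN_POINTS:
            raise ValueError(
                f"need >= {self.MIN_POINTS} points per curve, "
                f"got {self.temperatures.size}")
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        if not self.Ct > 0:
            raise ValueError("Ct must be positive")
        if self.signal_unit not in ("mdeg", "MRE"):
            raise ValueError("signal_unit must be 'mdeg' or 'MRE'")

    def __len__(self) -> int:
        return int(self.temperatures.size)


@dataclass
class GlobalFitResult:
    """Result of a shared-parameter fit across melting curves."""

    params: UnfoldingParams
    baselines: list[BaselineParams]
    Ku20: float
    Kf20: float
    residual_sum: float
    aic: float
    converged: bool
    n_points: int = 0
    message: str = ""
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.converged and not np.isfinite(self.aic):
            raise ValueError("AIC must be finite for a converged fit")


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------

def gibbs_free_energy(params: UnfoldingParams, T):
    """Unfolding free energy ΔG_u(T) in kJ·mol⁻¹.

    Gibbs–Helmholtz form anchored at ``params.T0`` (ΔG = 0 there); for
    ΔCp = 0 this reduces exactly to the van 't Hoff expression
    ΔH°·(1 − T/T0).  ``T`` in K, scalar or array.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be positive (K)")
    T0 = params.T0
    dG = (params.dH0 * (1.0 - T / T0)
          + params.dCp * ((T - T0) - T * np.log(T / T0)))
    return dG if dG.ndim else float(dG)


def unfolding_constant(params: UnfoldingParams, T):
    """Equilibrium constants at temperature ``T`` (K).

    Returns a dict with ``Ku`` (mol/L), ``Kf`` = 1/Ku (L/mol) and a
    ``clamped`` flag set when the exponent hit the overflow guard.
    Ku(T0) = 1 by construction.
    """
    dG = gibbs_free_energy(params, T)          # kJ/mol
    expo = -np.asarray(dG, dtype=float) * 1e3 / (R_GAS * np.asarray(T, float))
    clamped = bool(np.any(np.abs(expo) > EXP_CLAMP))
    if clamped:
        logger.warning("unfolding_constant: exponent clamped at ±%g", EXP_CLAMP)
    expo = np.clip(expo, -EXP_CLAMP, EXP_CLAMP)
    Ku = params.c_std * np.exp(expo)
    Ku = Ku if Ku.ndim else float(Ku)
    return {"Ku": Ku, "Kf": 1.0 / Ku, "clamped": clamped}


def _hetero_dimer_fraction(Ku, Ct):
    # Root of Ct·f² − (2Ct + 2Ku)·f + Ct = 0 in [0, 1]; written in a
    # cancellation-safe form (small root of the quadratic).
    Ku = np.asarray(Ku, dtype=float)
    b = 2.0 * Ct + 2.0 * Ku
    disc = np.sqrt(b * b - 4.0 * Ct * Ct)
    return (2.0 * Ct) / (b + disc)


def _mass_balance_log_ku(f, Ct, n, hetero):
    # log Ku implied by folded fraction f under the n-mer mass balance.
    # Hetero (equimolar strands, Ct = total monomer): each free strand at
    # (1−f)·Ct/n, complex at f·Ct/n  →  Ku = (1−f)^n · (Ct/n)^(n−1) / f.
    # Homo: free monomer (1−f)·Ct, complex f·Ct/n →
    # Ku = n·(1−f)^n·Ct^(n−1) / f.
    if hetero:
        return (n * np.log1p(-f) + (n - 1) * np.log(Ct / n) - np.log(f))
    return (np.log(n) + n * np.log1p(-f) + (n - 1) * np.log(Ct) - np.log(f))


def fraction_folded(Ku, Ct, stoichiometry: int = 2, hetero: bool = True):
    """Folded fraction from the n-mer mass balance.

    ``Ku`` in mol/L (scalar or array), ``Ct`` total monomer concentration in
    mol/L.  For the heterodimer the quadratic closed form is used
    (Ku = (1−f)²·Ct/(2f)); other stoichiometries are solved by root
    bracketing on the mass-balance residual to relative tolerance 1e−12.
    Monotone non-increasing in Ku, non-decreasing in Ct.
    """
    Ct_arr = np.asarray(Ct, dtype=float)
    if np.any(Ct_arr <= 0):
        raise ValueError("Ct must be positive")
    Ku_arr = np.asarray(Ku, dtype=float)
    if np.any(Ku_arr < 0) or not np.isfinite(Ku_arr).all():
        raise ValueError("Ku must be finite and non-negative")
    Ku_arr, Ct_b = np.broadcast_arrays(Ku_arr, Ct_arr)
    Ct = Ct_b

    if stoichiometry == 2 and hetero:
        f = np.where(Ku_arr == 0.0, 1.0, _hetero_dimer_fraction(Ku_arr, Ct))
        return f if f.ndim else float(f)

    n = int(stoichiometry)
    # Vectorized root bracketing in x = ln f: the implied ln Ku is
    # strictly decreasing and concave in x, so a few bisection steps
    # followed by safeguarded Newton converge quadratically; the
    # combination resolves the root far below the 1e-12 relative
    # contract.
    scalar = Ku_arr.ndim == 0
    ku = np.atleast_1d(Ku_arr).astype(float)
    Ct = np.atleast_1d(Ct).astype(float)
    zero = ku == 0.0
    target = np.where(zero, 0.0, np.log(np.where(zero, 1.0, ku)))
    lo = np.full_like(ku, np.log(1e-19))
    hi = np.full_like(ku, np.log1p(-1e-16))

    def g(x):
        return _mass_balance_log_ku(np.exp(x), Ct, n, hetero) - target

    pinned_lo = g(lo) <= 0.0  # Ku so large that f underflows the bracket
    pinned_hi = g(hi) >= 0.0  # Ku so small that f is 1 to precision
    for _ in range(8):
        mid = 0.5 * (lo + hi)
        take_hi = g(mid) >= 0.0
        lo = np.where(take_hi, mid, lo)
        hi = np.where(take_hi, hi, mid)
    x = 0.5 * (lo + hi)
    for _ in range(20):
        ex = np.exp(x)
        gx = g(x)
        dgx = -n * ex / (1.0 - ex) - 1.0
        step = gx / dgx
        x = np.clip(x - step, lo, hi)
        if np.max(np.abs(step)) < 1e-15:
            break
    f = np.exp(x)
    f = np.where(pinned_lo, 0.0, f)
    f = np.where(pinned_hi | zero, 1.0, f)
    return float(f[0]) if scalar else f


def predict_melt_curve(params: UnfoldingParams, baselines: BaselineParams,
                       Ct: float, temperatures):
    """Forward melting-curve model.

    signal(T) = f(T)·(aF + bF·T) + (1 − f(T))·(aU + bU·T), with the folded
    fraction f from the mass balance at Ku(T).  For the heterodimer the
    apparent midpoint (f = 0.5) sits where Ku(T) = Ct/4.
    """
    T = np.asarray(temperatures, dtype=float)
    Ku = unfolding_constant(params, T)["Ku"]
    f = fraction_folded(Ku, Ct, params.stoichiometry, params.hetero)
    return f * baselines.folded(T) + (1.0 - f) * baselines.unfolded(T)


# ---------------------------------------------------------------------------
# Global fitting
# ---------------------------------------------------------------------------

_FIT_BOUNDS_LO = (10.0, KELVIN_OFFSET, 0.0)       # dH0, T0, dCp
_FIT_BOUNDS_HI = (3000.0, 700.0, 50.0)


def _initial_guess(curves: list[MeltCurve], template) -> UnfoldingParams:
    # The profiled objective is a narrow ridge in (ΔH°, T0): away from
    # parameter pairs whose predicted apparent midpoint matches the data,
    # the cost explodes.  So the start walks along that ridge: take the
    # steepest-slope temperature of the first curve as the apparent
    # midpoint Tm, and for each trial ΔH° solve the T0 that puts the
    # model midpoint (Ku(Tm) equal to the mass-balance value at f = 1/2)
    # at Tm.  The cheapest of those ridge points seeds the polish.
    from scipy.optimize import brentq

    c = curves[0]
    slope = np.gradient(c.signal, c.temperatures)
    t_m = float(c.temperatures[np.argmax(np.abs(slope))])
    n, hetero = template.stoichiometry, template.hetero
    # ΔG at the apparent midpoint implied by the mass balance at f = 1/2.
    log_ku_mid = float(_mass_balance_log_ku(np.float64(0.5),
                                            np.float64(c.Ct), n, hetero))
    dG_mid = -R_GAS * t_m * log_ku_mid / 1e3   # kJ/mol

    best, best_rss = np.array([200.0, t_m + 60.0, 2.0]), np.inf
    for dH0 in (100.0, 150.0, 200.0, 250.0, 300.0, 400.0, 600.0):
        for dCp in (1.0, 2.0, 3.0):
            def h(T0):
                p = UnfoldingParams(dH0=dH0, T0=T0, dCp=dCp,
                                    stoichiometry=n, hetero=hetero)
                return gibbs_free_energy(p, t_m) - dG_mid

            lo, hi = t_m + 0.5, _FIT_BOUNDS_HI[1]
            if h(lo) * h(hi) > 0:
                continue
            T0 = brentq(h, lo, hi, xtol=1e-6)
            theta = np.array([dH0, T0, dCp])
            rss = float(np.sum(_residuals(theta, curves, template) ** 2))
            if rss < best_rss:
                best, best_rss = theta, rss
    return UnfoldingParams(dH0=float(best[0]), T0=float(best[1]),
                           dCp=float(best[2]))


def _fraction_grid(theta, curves, template):
    # Folded fraction over the concatenated (T, Ct) grid of all curves:
    # one vectorized mass-balance solve per model evaluation.
    params = replace(template, dH0=float(theta[0]), T0=float(theta[1]),
                     dCp=float(theta[2]))
    T = np.concatenate([c.temperatures for c in curves])
    Ct = np.concatenate([np.full(len(c), c.Ct) for c in curves])
    Ku = unfolding_constant(params, T)["Ku"]
    return params, T, fraction_folded(Ku, Ct, params.stoichiometry,
                                      params.hetero)


def _solve_baselines(theta, curves, template):
    # Baselines enter the model linearly (variable projection): for fixed
    # thermodynamics the optimal per-curve (aF, bF, aU, bU) is a 4-column
    # linear least-squares solve with design [f, f·T, 1−f, (1−f)·T].
    params, T, f = _fraction_grid(theta, curves, template)
    baselines, residuals = [], []
    start = 0
    for curve in curves:
        sl = slice(start, start + len(curve))
        fT, Tc = f[sl], T[sl]
        A = np.column_stack([fT, fT * Tc, 1.0 - fT, (1.0 - fT) * Tc])
        beta, *_ = np.linalg.lstsq(A, curve.signal, rcond=None)
        baselines.append(BaselineParams(aF=float(beta[0]), bF=float(beta[1]),
                                        aU=float(beta[2]), bU=float(beta[3])))
        residuals.append(curve.signal - A @ beta)
        start += len(curve)
    return params, baselines, np.concatenate(residuals)


def _residuals(theta, curves, template):
    return _solve_baselines(theta, curves, template)[2]


def fit_global(curves, stoichiometry: int = 2, hetero: bool = True,
               init: UnfoldingParams | None = None) -> GlobalFitResult:
    """Global least-squares fit of shared (ΔH°, T0, ΔCp) with per-curve
    linear baselines.

    Deterministic given data and the initial guess.  Returns the fitted
    parameters together with Ku/Kf at 20 °C, the residual sum of squares and
    the AIC (Gaussian likelihood, ``k`` = 3 shared + 4 per curve + 1 for σ).
    """
    curves = list(curves)
    if not curves:
        raise ValueError("need at least one melting curve")
    n_points = sum(len(c) for c in curves)
    n_free = 3 + 4 * len(curves)
    if n_points <= n_free:
        raise ValueError(
            f"{n_points} data points cannot constrain {n_free} parameters")

    template = UnfoldingParams(dH0=200.0, T0=380.0, dCp=2.0,
                               stoichiometry=stoichiometry, hetero=hetero)
    if init is None:
        init = _initial_guess(curves, template)
    x0 = np.asarray([init.dH0, init.T0, init.dCp], dtype=float)

    lo = np.asarray(_FIT_BOUNDS_LO)
    hi = np.asarray(_FIT_BOUNDS_HI)
    x0 = np.clip(x0, lo + 1e-9, hi - 1e-9)

    # diff_step well above the linear-solve roundoff inside the profiled
    # residual; tolerances matched to what that objective can resolve.
    sol = least_squares(_residuals, x0, args=(curves, template),
                        bounds=(lo, hi), x_scale=[100.0, 10.0, 1.0],
                        diff_step=1e-6, max_nfev=500,
                        xtol=1e-10, ftol=1e-10, gtol=1e-10)

    params, baselines, res = _solve_baselines(sol.x, curves, template)
    rss = float(np.sum(res ** 2))
    converged = bool(sol.success)
    if not converged:
        logger.warning("fit_global did not converge: %s", sol.message)
    # AIC for i.i.d. Gaussian residuals with profiled variance.
    aic = (n_points * np.log(max(rss, 1e-300) / n_points)
           + 2.0 * (n_free + 1)) if converged else np.nan

    k20 = unfolding_constant(params, celsius_to_kelvin(20.0))
    return GlobalFitResult(
        params=params, baselines=baselines,
        Ku20=float(k20["Ku"]), Kf20=float(k20["Kf"]),
        residual_sum=rss, aic=float(aic) if converged else np.nan,
        converged=converged, n_points=n_points, message=str(sol.message))


def compare_models(curves, candidate_stoichiometries,
                   hetero: bool = True) -> list[GlobalFitResult]:
    """Fit each candidate stoichiometry and rank by AIC (ascending).

    Ties (ΔAIC < 1e−9) are broken in favor of the lower stoichiometry.
    A single candidate is returned as-is.
    """
    candidates = list(candidate_stoichiometries)
    if not candidates:
        raise ValueError("need at least one candidate stoichiometry")
    results = []
    for n in candidates:
        try:
            results.append(fit_global(curves, stoichiometry=n, hetero=hetero))
        except ValueError:
            raise
    converged = [r for r in results if r.converged]
    if not converged:
        raise RuntimeError("no candidate stoichiometry converged")
    converged.sort(key=lambda r: (round(r.aic, 9), r.params.stoichiometry))
    return converged


def bootstrap_confidence(fit: GlobalFitResult, curves, n_boot: int = 200,
                         seed: int = 0, level: float = 0.95
                         ) -> dict[str, tuple[float, float]]:
    """Residual-resampling bootstrap intervals for (ΔH°, T0, ΔCp).

    Residuals of the converged fit are resampled with replacement (pooled
    across curves), added back onto the fitted model and refitted starting
    from the fitted parameters.  Intervals are the (1−level)/2 and
    (1+level)/2 percentiles.  Reproducible under a fixed seed.
    """
    if not fit.converged:
        raise ValueError("bootstrap requires a converged fit")
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    curves = list(curves)
    rng = np.random.default_rng(seed)

    fitted = [predict_melt_curve(fit.params, b, c.Ct, c.temperatures)
              for c, b in zip(curves, fit.baselines)]
    residuals = np.concatenate([c.signal - p
                                for c, p in zip(curves, fitted)])
    if np.allclose(residuals, 0.0):
        warnings.warn("all residuals zero; bootstrap intervals degenerate")

    samples = {"dH0": [], "T0": [], "dCp": []}
    sizes = [len(c) for c in curves]
    for _ in range(n_boot):
        draw = rng.choice(residuals, size=residuals.size, replace=True)
        pieces = np.split(draw, np.cumsum(sizes)[:-1])
        boot_curves = [
            MeltCurve(c.temperatures, p + e, c.Ct, c.label, c.signal_unit)
            for c, p, e in zip(curves, fitted, pieces)]
        r = fit_global(boot_curves, fit.params.stoichiometry,
                       fit.params.hetero, init=fit.params)
        samples["dH0"].append(r.params.dH0)
        samples["T0"].append(r.params.T0)
        samples["dCp"].append(r.params.dCp)

    alpha = (1.0 - level) / 2.0
    ci = {k: (float(np.percentile(v, 100 * alpha)),
              float(np.percentile(v, 100 * (1 - alpha))))
          for k, v in samples.items()}
    fit.ci = ci
    return ci
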