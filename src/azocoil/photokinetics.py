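"""Photoswitch characterization: CD normalization, isomer composition,
thermal relaxation and photocycling kinetics.

An azobenzene photoswitch interconverts between trans and cis under
illumination and relaxes thermally from cis back to trans.  This module
estimates the cis/trans composition from single-wavelength absorbance
unmixing or HPLC peak areas, fits first-order thermal relaxation, and
simulates phase-wise photokinetics

    df_cis/dt = k_tc·(1 − f_cis) − (k_ct + k_relax)·f_cis

whose photostationary state (PSS) within a phase is the fixed point
f_cis(∞) = k_tc / (k_tc + k_ct + k_relax).  Each constant-rate phase has
an exact exponential solution, so no numerical integrator is needed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

#: Prefactor of the mean-residue-ellipticity convention
#: [θ] = MRE_PREFACTOR·θ_obs(mdeg)/(c(mM)·n·l(cm)).  Exposed so an
#: alternative normalization convention can be swapped in.
MRE_PREFACTOR = 100.0

#: Convergence tolerance for run-to-PSS phases.
PSS_TOL = 1e-6


@dataclass(frozen=True)
class EllipticityMeasurement:
    """One CD reading: observed ellipticity θ_obs (mdeg), peptide
    concentration c (mM), number of peptide bonds n, path length l (cm)."""

    theta_obs: float
    c: float
    n: int
    l: float

    def __post_init__(self) -> None:
        if not self.c > 0:
            raise ValueError("concentration must be positive")
        if self.n < 1:
            raise ValueError("need at least one peptide bond")
        if not self.l > 0:
            raise ValueError("path length must be positive")


@dataclass(frozen=True)
class IsomerComposition:
    """cis/trans fractions with replicate spread.

    ``deviation`` is half the max−min spread across replicates (the same
    units as the fractions); ``sd`` the sample standard deviation.
    """

    f_cis: float
    f_trans: float
    deviation: float = 0.0
    sd: float = 0.0
    n_replicates: int = 1

    def __post_init__(self) -> None:
        if abs(self.f_cis + self.f_trans - 1.0) > 1e-12:
            raise ValueError("fractions must sum to 1")
        if not (0.0 <= self.f_cis <= 1.0):
            raise ValueError("fractions must lie in [0, 1]")


@dataclass(frozen=True)
class RelaxationFit:
    """First-order thermal relaxation y(t) = offset + amplitude·exp(−k·t).

    ``k`` in min⁻¹, ``t_half`` = ln2/k in min, ``k_ci`` an approximate 95%
    interval on k from the fit covariance.
    """

    k: float
    t_half: float
    amplitude: float
    offset: float
    k_ci: tuple[float, float] = (np.nan, np.nan)

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("rate must be non-negative")
        if not np.isclose(self.t_half * self.k, np.log(2.0), rtol=1e-9):
            raise ValueError("t_half and k are inconsistent")


@dataclass(frozen=True)
class Phase:
    """One illumination (or dark) phase of a photokinetic schedule.

    ``duration`` in min, or None to run until the PSS is reached
    (|f − f(∞)| < PSS_TOL).
    """

    label: str
    k_tc: float
    k_ct: float
    k_relax: float = 0.0
    duration: float | None = None

    def __post_init__(self) -> None:
        if min(self.k_tc, self.k_ct, self.k_relax) < 0:
            raise ValueError("rates must be non-negative")
        if self.duration is not None and not self.duration > 0:
            raise ValueError("phase duration must be positive")

    @property
    def k_total(self) -> float:
        return self.k_tc + self.k_ct + self.k_relax

    @property
    def f_pss(self) -> float:
        """Analytic photostationary cis fraction of this phase."""
        k = self.k_total
        if k == 0.0:
            raise ValueError("PSS undefined when all rates are zero")
        return self.k_tc / k


@dataclass(frozen=True)
class PhotoKineticModel:
    """Ordered illumination schedule acting on a single photoswitch pool."""

    schedule: tuple[Phase, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "schedule", tuple(self.schedule))
        if not self.schedule:
            raise ValueError("schedule must contain at least one phase")


def mean_residue_ellipticity(m: EllipticityMeasurement,
                             prefactor: float = MRE_PREFACTOR) -> float:
    """Mean residue molar ellipticity [θ] in deg·cm²·dmol⁻¹·res⁻¹.

    [θ] = prefactor·θ_obs/(c·n·l) with θ_obs in mdeg, c in mM, n the number
    of peptide bonds and l the path length in cm.
    """
    return prefactor * m.theta_obs / (m.c * m.n * m.l)


def isomer_fraction_from_absorbance(A: float, A_trans_ref: float,
                                    A_cis_ref: float) -> IsomerComposition:
    """Single-wavelength linear unmixing of the cis fraction.

    f_cis = (A_trans_ref − A)/(A_trans_ref − A_cis_ref).  Values outside
    [−0.02, 1.02] are rejected as inconsistent references; values inside
    that band but outside [0, 1] are clipped with a warning.
    """
    denom = A_trans_ref - A_cis_ref
    if denom == 0:
        raise ValueError("degenerate unmixing: reference absorbances equal")
    f_cis = (A_trans_ref - A) / denom
    if not (-0.02 <= f_cis <= 1.02):
        raise ValueError(
            f"unmixed cis fraction {f_cis:.4f} outside plausible range; "
            "check reference absorbances")
    if not (0.0 <= f_cis <= 1.0):
        warnings.warn(f"cis fraction {f_cis:.4f} clipped into [0, 1]")
        f_cis = min(max(f_cis, 0.0), 1.0)
    return IsomerComposition(f_cis=f_cis, f_trans=1.0 - f_cis)


def absorbance_from_fraction(f_cis: float, A_trans_ref: float,
                             A_cis_ref: float) -> float:
    """Inverse of :func:`isomer_fraction_from_absorbance` (round-trip)."""
    return A_trans_ref - f_cis * (A_trans_ref - A_cis_ref)


def pss_from_peak_areas(replicates) -> IsomerComposition:
    """Isomer composition from replicate HPLC (area_trans, area_cis) pairs.

    Per replicate the fractions are areas over their sum; the reported
    value is the mean across replicates, the deviation half the max−min
    spread (the convention for a small number of repeat injections),
    with the standard deviation also recorded.
    """
    replicates = list(replicates)
    if not replicates:
        raise ValueError("need at least one replicate")
    fracs = []
    for i, (a_trans, a_cis) in enumerate(replicates):
        if a_trans < 0 or a_cis < 0:
            raise ValueError(f"replicate {i}: negative peak area")
        total = a_trans + a_cis
        if total == 0:
            raise ValueError(f"replicate {i}: all-zero peak areas")
        fracs.append(a_cis / total)
    fracs = np.asarray(fracs)
    f_cis = float(np.mean(fracs))
    deviation = float((fracs.max() - fracs.min()) / 2.0)
    sd = float(np.std(fracs, ddof=1)) if len(fracs) > 1 else 0.0
    return IsomerComposition(f_cis=f_cis, f_trans=1.0 - f_cis,
                             deviation=deviation, sd=sd,
                             n_replicates=len(fracs))


def fit_relaxation(t, y) -> RelaxationFit:
    """Fit first-order decay y(t) = offset + amplitude·exp(−k·t).

    ``t`` in min (ascending, ≥ 4 points).  Raises if the series carries no
    detectable decay.  The fit is scale-equivariant in y: scaling y scales
    amplitude and offset but leaves k unchanged.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size != y.size:
        raise ValueError("t and y lengths differ")
    if t.size < 4:
        raise ValueError("need at least 4 points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("t must be strictly ascending")

    scale = float(np.max(np.abs(y)))
    span = float(y.max() - y.min())
    if scale == 0.0 or span < 1e-12 * max(scale, 1.0):
        raise ValueError("no decay detected: series is flat")

    # Initial guess: offset from the tail, rate from the half-crossing.
    offset0 = float(y[-1])
    amp0 = float(y[0] - offset0)
    half_idx = int(np.argmin(np.abs((y - offset0) - amp0 / 2.0)))
    t_half0 = float(t[half_idx]) if t[half_idx] > 0 else float(t[-1]) / 2.0
    k0 = np.log(2.0) / t_half0

    def model(tt, offset, amplitude, k):
        return offset + amplitude * np.exp(-k * tt)

    popt, pcov = curve_fit(model, t, y, p0=[offset0, amp0, k0],
                           maxfev=20000)
    offset, amplitude, k = map(float, popt)
    if k <= 0 or not np.isfinite(k):
        raise ValueError("no decay detected: fitted rate not positive")
    k_sd = float(np.sqrt(pcov[2, 2])) if np.isfinite(pcov[2, 2]) else np.nan
    if np.isfinite(k_sd) and k_sd > 0 and k / k_sd < 2.0:
        raise ValueError("no decay detected: rate indistinguishable from 0")
    return RelaxationFit(k=k, t_half=np.log(2.0) / k, amplitude=amplitude,
                         offset=offset,
                         k_ci=(k - 1.96 * k_sd, k + 1.96 * k_sd))


def _phase_solution(f0: float, phase: Phase, t):
    """Exact solution of the phase ODE from initial cis fraction f0."""
    k = phase.k_total
    t = np.asarray(t, dtype=float)
    if k == 0.0:
        return np.full_like(t, f0)
    return phase.f_pss + (f0 - phase.f_pss) * np.exp(-k * t)


def simulate_photokinetics(model: PhotoKineticModel, f_cis0: float = 0.0,
                           points_per_phase: int = 50):
    """Integrate the cis fraction through the illumination schedule.

    Each constant-rate phase is solved exactly (exponential approach to its
    PSS).  Run-to-PSS phases terminate once |f − f(∞)| < 1e−6; a
    run-to-PSS phase with all rates zero cannot terminate and raises.

    Returns ``(t, f_cis, phase_ends)``: concatenated time grid (min), the
    cis fraction on it, and a list of (label, t_end, f_end) per phase.
    """
    if not (0.0 <= f_cis0 <= 1.0):
        raise ValueError("f_cis0 must lie in [0, 1]")
    times, fractions, phase_ends = [0.0], [float(f_cis0)], []
    t_now, f_now = 0.0, float(f_cis0)
    for phase in model.schedule:
        if phase.duration is not None:
            dur = phase.duration
        else:
            k = phase.k_total
            if k == 0.0:
                raise ValueError(
                    f"phase '{phase.label}': run-to-PSS cannot terminate "
                    "with all rates zero")
            gap = abs(f_now - phase.f_pss)
            # run until strictly inside the tolerance band (half of it)
            target = PSS_TOL / 2.0
            dur = (np.log(gap / target) / k) if gap > target else target / k
        local_t = np.linspace(0.0, dur, points_per_phase + 1)[1:]
        local_f = _phase_solution(f_now, phase, local_t)
        times.extend((t_now + local_t).tolist())
        fractions.extend(np.atleast_1d(local_f).tolist())
        t_now += dur
        f_now = float(fractions[-1])
        phase_ends.append((phase.label, t_now, f_now))
    return np.asarray(times), np.asarray(fractions), phase_ends
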