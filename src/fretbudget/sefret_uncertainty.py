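"""Analytical precision bounds for the dFRET and aFRET estimators.

For Poisson-distributed channel counts the variance of an unmixed FRET
estimate phi(I_DD, I_DA, I_AA) is, to first order,

    Var(phi) = sum_c (d phi / d I_c)^2 * mu_c

evaluated at the channel means (delta method). Because the three-cube model
has exactly three free parameters behind three Poisson channels, the plug-in
estimator is the exact maximum-likelihood estimator and the delta-method
variance coincides with the Cramér-Rao lower bound from the Fisher
information matrix; :func:`fisher_crlb` provides the independent Fisher
route and the two agree to numerical precision at interior parameter points.

Results are reported as the photon-normalized precision

    sigma_tilde = sqrt(Var * N_P),    N_P = mu_DD + mu_DA + mu_AA,

which is independent of the exposure (total photon count) and decomposes as

    sigma_tilde^2 = sigma_E^2 + sigma_SBT^2 + sigma_B^2

into the intrinsic FRET-efficiency term, the spectral-bleed-through /
direct-excitation penalty and the background penalty (defined by model
ablation: sigma_E is the bound with crosstalk and background switched off,
sigma_SBT the additional quadrature term with crosstalk on, sigma_B the
remainder with background on).

The photon-budget calculator inverts the normalization: to reach a target
standard deviation sigma on the FRET estimate one needs
``N_D = sigma_tilde^2 / sigma^2`` detected photons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sefret_core import (
    Background,
    FretSystem,
    IDEAL_SYSTEM,
    NO_BACKGROUND,
    ParameterDomainError,
    SamplePopulation,
    channel_means,
    unmix,
)

__all__ = [
    "SigmaResult",
    "delta_sigma",
    "fisher_crlb",
    "sigma_decomposition",
    "expected_bias",
    "photon_budget",
    "predicted_sigma",
    "sigma_sweep",
    "SingularFisherError",
]


class SingularFisherError(ArithmeticError):
    """The Fisher matrix is numerically singular at this parameter point."""


@dataclass(frozen=True)
class SigmaResult:
    """Photon-normalized precision of a FRET estimator.

    Attributes
    ----------
    sigma_tilde
        Normalized standard deviation; the standard deviation at N_P
        detected photons is ``sigma_tilde / sqrt(N_P)``.
    n_p
        Normalization photon count (expected photons, signal + background).
    components
        ``(sigma_e, sigma_sbt, sigma_b)`` quadrature decomposition.
    estimator
        ``"dfret"`` or ``"afret"`` (or ``"tcspc"`` for lifetime bounds).
    """

    sigma_tilde: float
    n_p: float
    components: tuple[float, float, float]
    estimator: str

    @property
    def sigma_e(self) -> float:
        return self.components[0]

    @property
    def sigma_sbt(self) -> float:
        return self.components[1]

    @property
    def sigma_b(self) -> float:
        return self.components[2]


def _check_estimator(which: str) -> str:
    w = which.lower()
    if w not in ("dfret", "afret"):
        raise ParameterDomainError("estimator must be 'dfret' or 'afret'")
    return w


def _gradient(mu: np.ndarray, sys: FretSystem, which: str) -> np.ndarray:
    """Analytic partial derivatives of the estimator w.r.t. the channels."""
    i_dd, i_da, i_aa = mu
    c = i_da - sys.der * i_dd - sys.aer * i_aa
    if which == "dfret":
        den = i_dd + sys.eta * c
        if den <= 0:
            raise ParameterDomainError("dFRET undefined at the channel means")
        den2 = den * den
        return np.array(
            [
                -sys.eta * (sys.der * i_dd + c) / den2,
                sys.eta * i_dd / den2,
                -sys.eta * sys.aer * i_dd / den2,
            ]
        )
    if i_aa <= 0:
        raise ParameterDomainError("aFRET undefined: I_AA mean is zero")
    return np.array(
        [
            -sys.epsilon * sys.der / i_aa,
            sys.epsilon / i_aa,
            -sys.epsilon * (sys.aer * i_aa + c) / (i_aa * i_aa),
        ]
    )


def _n_p(mu: np.ndarray, np_channels: str) -> float:
    if np_channels == "all":
        return float(mu.sum())
    if np_channels == "donor":
        # donor-excitation acquisitions only (I_DD + I_DA)
        return float(mu[0] + mu[1])
    raise ParameterDomainError("np_channels must be 'all' or 'donor'")


def _sigma_tilde_raw(
    pop: SamplePopulation,
    sys: FretSystem,
    exposure: float,
    bg: Background,
    which: str,
    np_channels: str,
) -> tuple[float, float]:
    """(sigma_tilde, N_P) by the delta method, without decomposition."""
    mu = channel_means(pop, sys, exposure, bg).as_array()
    grad = _gradient(mu, sys, which)
    var = float(np.sum(grad**2 * mu))
    n_p = _n_p(mu, np_channels)
    return math.sqrt(var * n_p), n_p


def sigma_decomposition(
    pop: SamplePopulation,
    sys: FretSystem = IDEAL_SYSTEM,
    exposure: float = 1.0,
    bg: Background = NO_BACKGROUND,
    which: str = "dfret",
    np_channels: str = "all",
) -> tuple[float, float, float]:
    """Quadrature decomposition (sigma_e, sigma_sbt, sigma_b) by ablation.

    ``sigma_e`` is the bound with crosstalk and background removed,
    ``sigma_sbt = sqrt(sigma^2(no bg) - sigma_e^2)`` the crosstalk penalty,
    ``sigma_b = sqrt(sigma^2 - sigma^2(no bg))`` the background penalty.
    Small negative intermediate differences (roundoff) are floored at zero.
    """
    which = _check_estimator(which)
    total, _ = _sigma_tilde_raw(pop, sys, exposure, bg, which, np_channels)
    no_bg, _ = _sigma_tilde_raw(pop, sys, exposure, NO_BACKGROUND, which, np_channels)
    ideal_sys = FretSystem(der=0.0, aer=0.0, eta=sys.eta, epsilon=sys.epsilon)
    sigma_e, _ = _sigma_tilde_raw(pop, ideal_sys, exposure, NO_BACKGROUND, which, np_channels)

    def _floored_sqrt(x: float, scale: float) -> float:
        if x < 0:
            if abs(x) > 1e-12 * max(scale, 1.0):
                raise ArithmeticError("decomposition produced a negative component")
            x = 0.0
        return math.sqrt(x)

    sigma_sbt = _floored_sqrt(no_bg**2 - sigma_e**2, total**2)
    sigma_b = _floored_sqrt(total**2 - no_bg**2, total**2)
    return sigma_e, sigma_sbt, sigma_b


def delta_sigma(
    pop: SamplePopulation,
    sys: FretSystem = IDEAL_SYSTEM,
    exposure: float = 1.0,
    bg: Background = NO_BACKGROUND,
    which: str = "dfret",
    np_channels: str = "all",
) -> SigmaResult:
    """Photon-normalized precision of dFRET/aFRET by error propagation.

    Exposure invariance: the result is identical for any ``exposure > 0``
    (both the variance and 1/N_P scale as 1/exposure).
    """
    which = _check_estimator(which)
    sigma, n_p = _sigma_tilde_raw(pop, sys, exposure, bg, which, np_channels)
    comps = sigma_decomposition(pop, sys, exposure, bg, which, np_channels)
    return SigmaResult(sigma, n_p, comps, which)


def _fisher_means_and_jacobian(
    theta: np.ndarray,
    sys: FretSystem,
    b_abs: np.ndarray,
    which: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Channel means and their Jacobian under theta = (q, G, R).

    q is the estimand (f_D E for dFRET, f_A E for aFRET), G the total donor
    brightness g*n_D and R = n_A/n_D the acceptor/donor abundance ratio.
    Backgrounds are known constants.
    """
    q, big_g, r = theta
    eta, eps = sys.eta, sys.epsilon
    if which == "dfret":
        fde, d_fde = q, np.array([1.0, 0.0, 0.0])
    else:  # q = f_A E; f_D E = q * R
        fde, d_fde = q * r, np.array([r, 0.0, q])

    mu_dd = big_g * (1.0 - fde)
    d_mu_dd = -big_g * d_fde + np.array([0.0, 1.0 - fde, 0.0])
    s = big_g * fde / eta
    d_s = big_g * d_fde / eta + np.array([0.0, fde / eta, 0.0])
    mu_aa = (eps / eta) * big_g * r
    d_mu_aa = (eps / eta) * np.array([0.0, r, big_g])
    mu_da = s + sys.der * mu_dd + sys.aer * mu_aa
    d_mu_da = d_s + sys.der * d_mu_dd + sys.aer * d_mu_aa

    mu = np.array([mu_dd, mu_da, mu_aa]) + b_abs
    jac = np.vstack([d_mu_dd, d_mu_da, d_mu_aa])
    return mu, jac


def fisher_crlb(
    pop: SamplePopulation,
    sys: FretSystem = IDEAL_SYSTEM,
    exposure: float = 1.0,
    bg: Background = NO_BACKGROUND,
    which: str = "dfret",
    np_channels: str = "all",
) -> SigmaResult:
    """Cramér-Rao lower bound for dFRET/aFRET via the Fisher matrix.

    The Poisson channel model is parametrized by theta = (q, G, R) with
    q the apparent efficiency being estimated;
    ``J_ij = sum_c mu_c^-1 (d mu_c/d theta_i)(d mu_c/d theta_j)`` and
    ``Var(q_hat) = (J^-1)_11``. Backgrounds enter as known constants.
    """
    which = _check_estimator(which)
    g = float(exposure)
    if g <= 0:
        raise ParameterDomainError("exposure must be > 0")
    sig = channel_means(pop, sys, g, Background()).as_array()
    b_abs = np.array(bg.resolve(tuple(sig)))
    big_g = g * pop.n_donors
    r = pop.n_acceptors / pop.n_donors
    q = pop.f_d * pop.efficiency if which == "dfret" else pop.f_a * pop.efficiency
    theta = np.array([q, big_g, r])

    mu, jac = _fisher_means_and_jacobian(theta, sys, b_abs, which)
    if np.any(mu <= 0):
        raise ParameterDomainError(
            "Fisher bound requires strictly positive channel means; "
            f"means are {tuple(mu)}"
        )
    j_mat = (jac / mu[:, None]).T @ jac
    cond = np.linalg.cond(j_mat)
    if not np.isfinite(cond) or cond > 1e12:
        raise SingularFisherError(
            f"Fisher matrix is singular at q={q:.4g} (condition number {cond:.3g}); "
            "the parametrization is degenerate at this point"
        )
    var = float(np.linalg.inv(j_mat)[0, 0])
    n_p = _n_p(mu, np_channels)
    sigma = math.sqrt(max(var, 0.0) * n_p)
    comps = sigma_decomposition(pop, sys, g, bg, which, np_channels)
    return SigmaResult(sigma, n_p, comps, which)


def expected_bias(
    pop: SamplePopulation,
    sys: FretSystem = IDEAL_SYSTEM,
    exposure: float = 1.0,
    bg: Background = NO_BACKGROUND,
    which: str = "dfret",
) -> float:
    """Systematic error of the plug-in estimator at the channel means.

    Without background the estimators are exactly unbiased at the means;
    with background they are not (the unmixing formulas do not subtract it),
    and this returns the resulting asymptotic bias.
    """
    which = _check_estimator(which)
    est = unmix(channel_means(pop, sys, exposure, bg), sys)
    if which == "dfret":
        if not est.dfret_valid:
            raise ParameterDomainError("dFRET invalid at the channel means")
        return est.dfret - pop.f_d * pop.efficiency
    if not est.afret_valid:
        raise ParameterDomainError("aFRET invalid at the channel means")
    return est.afret - pop.f_a * pop.efficiency


def photon_budget(sigma_tilde: float, sigma_target: float, rounded: bool = True) -> float:
    """Photons needed to reach a target standard deviation.

    ``N_D = sigma_tilde^2 / sigma_target^2``, rounded half-up to an integer
    photon count unless ``rounded=False``.
    """
    if sigma_tilde <= 0 or sigma_target <= 0:
        raise ParameterDomainError("sigma_tilde and sigma_target must be > 0")
    n = (sigma_tilde / sigma_target) ** 2
    return math.floor(n + 0.5) if rounded else n


def predicted_sigma(sigma_tilde: float, n_p: float) -> float:
    """Standard deviation of the FRET estimate at ``n_p`` detected photons."""
    if sigma_tilde < 0:
        raise ParameterDomainError("sigma_tilde must be >= 0")
    if n_p < 1:
        raise ParameterDomainError("n_p must be >= 1")
    return sigma_tilde / math.sqrt(n_p)


def power_series_grid(n: int = 128, e_max: float = 0.99) -> np.ndarray:
    """Efficiency grid denser near E = 0: E_i = e_max * (i/(n-1))^2."""
    i = np.arange(n)
    return e_max * (i / (n - 1)) ** 2


def sigma_sweep(
    grid: np.ndarray | int = 128,
    f_d: float = 1.0,
    f_a: float = 1.0,
    sys: FretSystem = IDEAL_SYSTEM,
    bg: Background = NO_BACKGROUND,
    which: str = "dfret",
    np_channels: str = "all",
) -> pd.DataFrame:
    """Precision curve sigma_tilde(E) over an efficiency grid.

    ``grid`` is either an explicit array of efficiencies in [0, 0.99] or a
    point count for the default power-series grid. Returns a deterministic
    table with one row per grid point; endpoints where the estimator is
    undefined (e.g. aFRET normalization) raise, while the dFRET bound at
    exactly E = 0 in an ideal system is the genuine limit 0.
    """
    which = _check_estimator(which)
    e_grid = power_series_grid(int(grid)) if np.isscalar(grid) else np.asarray(grid, float)
    if np.any((e_grid < 0) | (e_grid > 0.99)):
        raise ParameterDomainError("efficiency grid must lie within [0, 0.99]")
    rows = []
    for e in e_grid:
        pop = SamplePopulation.from_fractions(float(e), f_d, f_a)
        res = delta_sigma(pop, sys, 1.0, bg, which, np_channels)
        rows.append(
            {
                "E": float(e),
                "sigma_tilde": res.sigma_tilde,
                "sigma_e": res.sigma_e,
                "sigma_sbt": res.sigma_sbt,
                "sigma_b": res.sigma_b,
                "estimator": which,
                "f_D": f_d,
                "f_A": f_a,
                "der": sys.der,
                "aer": sys.aer,
                "eta": sys.eta,
                "epsilon": sys.epsilon,
                "beta": bg.beta if bg.beta is not None else 0.0,
            }
        )
    return pd.DataFrame(rows)
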