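"""Forward model and estimators for three-cube sensitized-emission FRET.

The three-cube method acquires three intensity images: donor emission under
donor excitation (``i_dd``), acceptor-channel emission under donor
excitation (``i_da``) and acceptor emission under acceptor excitation
(``i_aa``). The sensitized emission in ``i_da`` is contaminated by donor
spectral bleed-through (quantified by the donor emission ratio, DER) and by
direct excitation of the acceptor (quantified by the acceptor excitation
ratio, AER). The crosstalk-corrected FRET signal is

    cFRET = I_DA - DER * I_DD - AER * I_AA

and the apparent FRET efficiencies are

    dFRET = eta * cFRET / (I_DD + eta * cFRET)      (estimates f_D * E)
    aFRET = eps * cFRET / I_AA                      (estimates f_A * E)

where ``eta`` and ``eps`` are calibration factors absorbing the ratios of
excitation intensities, quantum yields and detection efficiencies, measured
on a reference sample of known FRET efficiency. ``f_D`` and ``f_A`` are the
fractions of donor and acceptor molecules engaged in FRET.

Brightness convention of the forward model: one donor excitation that decays
radiatively contributes one expected photon to ``i_dd``; ``eta`` and ``eps``
absorb all remaining instrument factors. Under this convention the noise-free
estimators return exactly ``f_D * E`` and ``f_A * E``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SamplePopulation",
    "FretSystem",
    "Background",
    "ChannelTriplet",
    "FretEstimates",
    "channel_means",
    "unmix",
    "calibrate_der_aer",
    "calibrate_eta_epsilon",
    "ParameterDomainError",
    "CalibrationError",
]


class ParameterDomainError(ValueError):
    """A parameter lies outside its physical domain."""


class CalibrationError(ValueError):
    """A calibration input is degenerate (zero or negative denominator)."""


@dataclass(frozen=True)
class SamplePopulation:
    """Molecular composition of a pixel or bulk sample.

    Parameters
    ----------
    n_pairs
        Number of FRET-competent donor-acceptor pairs.
    n_d_free
        Number of donors not engaged in FRET.
    n_a_free
        Number of acceptors not engaged in FRET.
    efficiency
        FRET efficiency E of the interacting pairs, in [0, 1].
    """

    n_pairs: float
    n_d_free: float
    n_a_free: float
    efficiency: float

    def __post_init__(self) -> None:
        if min(self.n_pairs, self.n_d_free, self.n_a_free) < 0:
            raise ParameterDomainError("molecule counts must be >= 0")
        if self.n_pairs + self.n_d_free <= 0:
            raise ParameterDomainError("sample contains no donors")
        if self.n_pairs + self.n_a_free <= 0:
            raise ParameterDomainError("sample contains no acceptors")
        if not 0.0 <= self.efficiency <= 1.0:
            raise ParameterDomainError("FRET efficiency must lie in [0, 1]")

    @property
    def n_donors(self) -> float:
        return self.n_pairs + self.n_d_free

    @property
    def n_acceptors(self) -> float:
        return self.n_pairs + self.n_a_free

    @property
    def f_d(self) -> float:
        """Fraction of donors engaged in FRET."""
        return self.n_pairs / self.n_donors

    @property
    def f_a(self) -> float:
        """Fraction of acceptors engaged in FRET."""
        return self.n_pairs / self.n_acceptors

    @classmethod
    def from_fractions(
        cls,
        efficiency: float,
        f_d: float,
        f_a: float,
        n_pairs: float = 100.0,
    ) -> "SamplePopulation":
        """Build a population from (E, f_D, f_A) with ``n_pairs`` pairs.

        The absolute pair count only sets the overall brightness scale; the
        normalized precision sigma_tilde does not depend on it.
        """
        if not 0 < f_d <= 1 or not 0 < f_a <= 1:
            raise ParameterDomainError("f_d and f_a must lie in (0, 1]")
        n_d_free = n_pairs * (1.0 - f_d) / f_d
        n_a_free = n_pairs * (1.0 - f_a) / f_a
        return cls(n_pairs, n_d_free, n_a_free, efficiency)


@dataclass(frozen=True)
class FretSystem:
    """Instrument/fluorophore crosstalk and calibration factors.

    ``der`` is the donor spectral bleed-through ratio [I_DA/I_DD] of a
    donor-only sample, ``aer`` the acceptor direct-excitation ratio
    [I_DA/I_AA] of an acceptor-only sample; ``eta`` and ``epsilon`` are the
    dFRET/aFRET normalization factors. The ideal system is
    ``der = aer = 0, eta = epsilon = 1``.
    """

    der: float = 0.0
    aer: float = 0.0
    eta: float = 1.0
    epsilon: float = 1.0

    def __post_init__(self) -> None:
        if self.der < 0 or self.aer < 0:
            raise ParameterDomainError("der and aer must be >= 0")
        if self.eta <= 0 or self.epsilon <= 0:
            raise ParameterDomainError("eta and epsilon must be > 0")

    def to_dict(self) -> dict:
        return {
            "der": self.der,
            "aer": self.aer,
            "eta": self.eta,
            "epsilon": self.epsilon,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FretSystem":
        return cls(**{k: float(d[k]) for k in ("der", "aer", "eta", "epsilon")})


#: Confocal CFP-YFP system reported in the seFRET literature.
SYSTEM_CONFOCAL = FretSystem(der=0.42, aer=0.60, eta=0.52, epsilon=6.3)
#: Wide-field CFP-citrine system reported in the seFRET literature.
SYSTEM_WIDEFIELD = FretSystem(der=1.07, aer=0.29, eta=0.015, epsilon=42.0)
IDEAL_SYSTEM = FretSystem()


@dataclass(frozen=True)
class Background:
    """Expected background photons per channel.

    Either absolute per-channel levels (``b_dd``, ``b_da``, ``b_aa``) or a
    single relative fraction ``beta`` applied to each channel's signal mean,
    ``b_c = beta * mu_c(signal)`` (so the signal-to-background ratio is
    ``1 / beta``). The fractional form is resolved against the signal means
    by :func:`channel_means`.
    """

    b_dd: float = 0.0
    b_da: float = 0.0
    b_aa: float = 0.0
    beta: float | None = None

    def __post_init__(self) -> None:
        if min(self.b_dd, self.b_da, self.b_aa) < 0:
            raise ParameterDomainError("background levels must be >= 0")
        if self.beta is not None and not 0.0 <= self.beta < 1.0:
            raise ParameterDomainError("beta must lie in [0, 1)")

    def resolve(self, signal_means: tuple[float, float, float]) -> tuple[float, float, float]:
        """Absolute background triplet for the given signal means."""
        if self.beta is None:
            return (self.b_dd, self.b_da, self.b_aa)
        return tuple(self.beta * m for m in signal_means)  # type: ignore[return-value]

    def to_dict(self) -> dict:
        d = {"b_dd": self.b_dd, "b_da": self.b_da, "b_aa": self.b_aa}
        if self.beta is not None:
            d["beta"] = self.beta
        return d


NO_BACKGROUND = Background()


@dataclass(frozen=True)
class ChannelTriplet:
    """Expected means or observed counts in the three seFRET channels."""

    i_dd: float
    i_da: float
    i_aa: float
    role: str = "means"  # "means" | "counts"

    def __post_init__(self) -> None:
        if self.role not in ("means", "counts"):
            raise ParameterDomainError("role must be 'means' or 'counts'")
        if min(self.i_dd, self.i_da, self.i_aa) < 0:
            raise ParameterDomainError("channel intensities must be >= 0")
        if self.role == "counts":
            for v in (self.i_dd, self.i_da, self.i_aa):
                if v != int(v):
                    raise ParameterDomainError("counts must be integers")

    def as_array(self) -> np.ndarray:
        return np.array([self.i_dd, self.i_da, self.i_aa], dtype=float)

    @property
    def total(self) -> float:
        return self.i_dd + self.i_da + self.i_aa


@dataclass(frozen=True)
class FretEstimates:
    """Result of unmixing one channel triplet.

    ``cfret`` may be negative under noise (it is deliberately not clamped so
    that Monte-Carlo moments stay unbiased). ``dfret``/``afret`` whose
    denominators are non-positive are flagged invalid rather than raised, so
    per-pixel image unmixing degrades gracefully.
    """

    cfret: float
    dfret: float
    afret: float
    dfret_valid: bool = True
    afret_valid: bool = True


def channel_means(
    pop: SamplePopulation,
    sys: FretSystem = IDEAL_SYSTEM,
    exposure: float = 1.0,
    bg: Background = NO_BACKGROUND,
) -> ChannelTriplet:
    """Expected photon counts in the three seFRET channels.

    ``exposure`` (g) is the expected number of detected photons per donor
    per acquisition in donor-channel brightness units. The signal means are

        mu_DD = g * n_D * (1 - f_D E)
        s     = g * n_D * f_D E / eta          (sensitized emission)
        mu_AA = g * (eps / eta) * n_A
        mu_DA = s + DER * mu_DD + AER * mu_AA

    plus the per-channel backgrounds. The acceptor-channel amplitude
    ``g (eps/eta) n_A`` makes the noise-free aFRET estimate exactly
    ``f_A * E``.
    """
    if exposure <= 0:
        raise ParameterDomainError("exposure must be > 0")
    g = float(exposure)
    n_d, n_a = pop.n_donors, pop.n_acceptors
    fde = pop.f_d * pop.efficiency

    mu_dd = g * n_d * (1.0 - fde)
    s = g * n_d * fde / sys.eta
    mu_aa = g * (sys.epsilon / sys.eta) * n_a
    mu_da = s + sys.der * mu_dd + sys.aer * mu_aa

    b_dd, b_da, b_aa = bg.resolve((mu_dd, mu_da, mu_aa))
    return ChannelTriplet(mu_dd + b_dd, mu_da + b_da, mu_aa + b_aa)


def unmix(obs: ChannelTriplet | tuple, sys: FretSystem = IDEAL_SYSTEM) -> FretEstimates:
    """Crosstalk-corrected FRET estimates from one channel triplet."""
    if not isinstance(obs, ChannelTriplet):
        obs = ChannelTriplet(*obs)
    c, d, a, dv, av = _unmix_arrays(
        np.asarray(obs.i_dd, float),
        np.asarray(obs.i_da, float),
        np.asarray(obs.i_aa, float),
        sys,
    )
    return FretEstimates(float(c), float(d), float(a), bool(dv), bool(av))


def _unmix_arrays(i_dd, i_da, i_aa, sys: FretSystem):
    """Vectorized unmixing; invalid estimates are flagged, not clamped."""
    cfret = i_da - sys.der * i_dd - sys.aer * i_aa
    denom_d = i_dd + sys.eta * cfret
    dv = denom_d > 0
    av = i_aa > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        dfret = np.where(dv, sys.eta * cfret / np.where(dv, denom_d, 1.0), np.nan)
        afret = np.where(av, sys.epsilon * cfret / np.where(av, i_aa, 1.0), np.nan)
    # a zero sensitized signal with valid denominators is a genuine 0, keep it
    return cfret, dfret, afret, dv, av


def calibrate_der_aer(
    donor_only: ChannelTriplet | np.ndarray,
    acceptor_only: ChannelTriplet | np.ndarray,
) -> tuple[float, float]:
    """DER and AER from donor-only and acceptor-only reference acquisitions.

    Accepts a single :class:`ChannelTriplet` or an ``(n, 3)`` array of
    per-pixel counts. Image inputs are reduced by the ratio of channel sums
    (not the mean of per-pixel ratios) to avoid the ratio-of-Poisson bias at
    low counts.
    """
    d = _sum_triplet(donor_only)
    a = _sum_triplet(acceptor_only)
    if d[0] <= 0:
        raise CalibrationError("donor-only reference has no I_DD signal")
    if a[2] <= 0:
        raise CalibrationError("acceptor-only reference has no I_AA signal")
    return d[1] / d[0], a[1] / a[2]


def _sum_triplet(x) -> np.ndarray:
    if isinstance(x, ChannelTriplet):
        return x.as_array()
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 1:
        return arr
    return arr.reshape(-1, 3).sum(axis=0)


def calibrate_eta_epsilon(
    reference: ChannelTriplet,
    e_ref: float,
    der: float,
    aer: float,
) -> tuple[float, float]:
    """Calibration factors eta and epsilon from a reference of known E.

    The reference sample is assumed fully interacting (f_D = f_A = 1), so
    its true apparent efficiencies both equal ``e_ref``. Solving
    ``dfret = e_ref`` and ``afret = e_ref`` for the factors gives

        eta = e_ref * I_DD / (cFRET * (1 - e_ref))
        eps = e_ref * I_AA / cFRET
    """
    if not 0.0 < e_ref < 1.0:
        raise CalibrationError("reference efficiency must lie in (0, 1)")
    cfret = reference.i_da - der * reference.i_dd - aer * reference.i_aa
    if cfret <= 0:
        raise CalibrationError("reference cFRET must be > 0")
    eta = e_ref * reference.i_dd / (cfret * (1.0 - e_ref))
    epsilon = e_ref * reference.i_aa / cfret
    return eta, epsilon


def apparent_efficiencies(pop: SamplePopulation) -> tuple[float, float]:
    """Ground-truth apparent efficiencies (f_D E, f_A E)."""
    return pop.f_d * pop.efficiency, pop.f_a * pop.efficiency
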