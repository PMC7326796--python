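"""Composite empirical small-angle scattering model.

The measured 1D intensity is described as a sum of up to three structural
terms plus a flat background::

    I(q) = C1 * q**(-P1)                                  (low-q power law)
         + G * exp(-q^2 Rg^2 / 3) + B * qstar**(-P2)      (unified level)
         + A * exp(-(q - q0)^2 / (2 w^2))                 (Gaussian peak)
         + bkg

with ``qstar = q / erf(q Rg / sqrt(6))**3``.  All intensities are in one
shared arbitrary unit; q is in inverse Angstroms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
from scipy.special import erf

from .errors import ConfigurationError, DomainError

__all__ = [
    "ModelParams",
    "TERMS",
    "power_law_term",
    "unified_level_term",
    "gaussian_peak_term",
    "model_intensity",
    "smear_profile",
    "FWHM_TO_SIGMA",
    "sigma_q_over_q",
]

#: Names of the structural terms understood by :func:`model_intensity`.
TERMS = ("power_law", "unified", "peak")

#: Conversion from a FWHM-type fractional spread to a Gaussian sigma.
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def sigma_q_over_q(wavelength_spread: float) -> float:
    """Fractional Gaussian q-resolution implied by a FWHM wavelength spread."""
    return wavelength_spread * FWHM_TO_SIGMA


@dataclass
class ModelParams:
    """Parameters of the composite empirical model.

    Attributes
    ----------
    pl_prefactor : float
        Power-law scale C1 (intensity * A^-P1).
    pl_exponent : float
        Low-q power-law exponent P1, dimensionless, in (1, 4.5].
    level_G : float
        Guinier prefactor of the unified level (intensity).
    level_Rg : float
        Radius of gyration of the unified level, Angstrom.
    level_B : float
        High-q prefactor of the unified level (intensity * A^-P2).
    level_P2 : float
        Mid-q power-law exponent P2, dimensionless, in (0, 4].
    peak_amp : float
        Gaussian peak amplitude A (intensity).
    peak_center : float
        Peak position q0, inverse Angstrom.
    peak_width : float
        Gaussian standard deviation w, inverse Angstrom.
    background : float
        Flat background (intensity).
    """

    pl_prefactor: float = 0.0
    pl_exponent: float = 3.5
    level_G: float = 0.0
    level_Rg: float = 100.0
    level_B: float = 0.0
    level_P2: float = 2.0
    peak_amp: float = 0.0
    peak_center: float = 0.1
    peak_width: float = 0.02
    background: float = 0.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.pl_prefactor < 0 or self.level_G < 0 or self.level_B < 0 \
                or self.peak_amp < 0 or self.background < 0:
            raise DomainError("prefactors, amplitudes and background must be >= 0")
        if not (1.0 < self.pl_exponent <= 4.5):
            raise DomainError(f"pl_exponent must lie in (1, 4.5], got {self.pl_exponent}")
        if not (0.0 < self.level_P2 <= 4.0):
            raise DomainError(f"level_P2 must lie in (0, 4], got {self.level_P2}")
        if self.level_Rg <= 0:
            raise DomainError("level_Rg must be > 0")
        if self.peak_center <= 0:
            raise DomainError("peak_center must be > 0")
        if self.peak_width <= 0:
            raise DomainError("peak_width must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**d)

    def replace(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


def _check_q(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0):
        raise DomainError("q must be strictly positive")
    return q


def power_law_term(q, prefactor: float, exponent: float):
    """Evaluate ``prefactor * q**(-exponent)``.

    Strictly decreasing in q for a positive exponent.
    """
    q = _check_q(q)
    if prefactor < 0:
        raise DomainError("prefactor must be >= 0")
    return prefactor * q ** (-exponent)


def unified_level_term(q, G: float, Rg: float, B: float, P: float):
    """Evaluate one unified (Guinier + power-law) structural level.

    ``G * exp(-q^2 Rg^2 / 3) + B * qstar**(-P)`` with
    ``qstar = q / erf(q Rg / sqrt(6))**3``.  Tends to G as q -> 0 and to
    ``B * q**(-P)`` once ``q * Rg >> 1``.
    """
    q = _check_q(q)
    if Rg <= 0:
        raise DomainError("Rg must be > 0")
    if G < 0 or B < 0:
        raise DomainError("G and B must be >= 0")
    guinier = G * np.exp(-(q * Rg) ** 2 / 3.0)
    e3 = erf(q * Rg / np.sqrt(6.0)) ** 3
    with np.errstate(divide="ignore"):
        qstar = np.where(e3 > 0, q / np.where(e3 > 0, e3, 1.0), np.inf)
    tail = B * qstar ** (-P)
    return guinier + tail


def gaussian_peak_term(q, A: float, q0: float, w: float):
    """Gaussian diffraction peak ``A * exp(-(q - q0)^2 / (2 w^2))``."""
    q = np.asarray(q, dtype=float)
    if w <= 0:
        raise DomainError("peak width must be > 0")
    if q0 <= 0:
        raise DomainError("peak center must be > 0")
    if A < 0:
        raise DomainError("peak amplitude must be >= 0")
    return A * np.exp(-((q - q0) ** 2) / (2.0 * w ** 2))


def model_intensity(q, params: ModelParams, terms=TERMS, include_background: bool = True):
    """Sum of the enabled structural terms plus (optionally) the background.

    Parameters
    ----------
    q : array_like
        Scattering vector values, A^-1, strictly positive.
    params : ModelParams
    terms : sequence of str
        Subset of :data:`TERMS` to evaluate; must be non-empty.
    include_background : bool
        Add the flat background term.
    """
    terms = tuple(terms)
    if not terms:
        raise ConfigurationError("at least one structural term must be enabled")
    unknown = set(terms) - set(TERMS)
    if unknown:
        raise ConfigurationError(f"unknown model terms: {sorted(unknown)}")
    q = _check_q(q)
    out = np.zeros_like(q, dtype=float)
    if "power_law" in terms:
        out += power_law_term(q, params.pl_prefactor, params.pl_exponent)
    if "unified" in terms:
        out += unified_level_term(q, params.level_G, params.level_Rg,
                                  params.level_B, params.level_P2)
    if "peak" in terms:
        out += gaussian_peak_term(q, params.peak_amp, params.peak_center,
                                  params.peak_width)
    if include_background:
        out = out + params.background
    return out


def smear_profile(q, intensity, frac_resolution: float):
    """Smear a model curve with a Gaussian of q-proportional width.

    Each output point is a normalised Gaussian-weighted average of the input
    curve with sigma = ``frac_resolution * q``.  A fractional resolution of
    zero returns the input unchanged; a flat curve is invariant.

    Parameters
    ----------
    q : array_like
        Strictly increasing grid, A^-1.
    intensity : array_like
        Model curve on that grid.
    frac_resolution : float
        sigma_q / q, >= 0.
    """
    q = np.asarray(q, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if q.ndim != 1 or q.shape != intensity.shape:
        raise DomainError("q and intensity must be matching 1D arrays")
    if np.any(np.diff(q) <= 0):
        raise DomainError("q grid must be strictly increasing")
    if frac_resolution < 0:
        raise DomainError("fractional resolution must be >= 0")
    if frac_resolution == 0:
        return intensity.copy()
    sigma = frac_resolution * q  # per output point
    dq = np.gradient(q)
    # kernel[i, j]: weight of input point j in output point i
    diff = q[None, :] - q[:, None]
    kernel = np.exp(-0.5 * (diff / sigma[:, None]) ** 2) * dq[None, :]
    kernel /= kernel.sum(axis=1, keepdims=True)
    return kernel @ intensity
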