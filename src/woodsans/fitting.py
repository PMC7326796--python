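"""Staged weighted least-squares fitting of reduced profiles.

Protocol:

1. subtract the amorphous profile from the aligned one to enhance the
   diffraction peak (removes the mid-q contribution);
2. fit the subtracted curve with two structural levels (power law + peak)
   for the low-q exponent P1 and the peak position q0;
3. fit the amorphous (or isotropic) profile with three structural levels
   (power law + unified level) for the mid-q Rg and exponent P2;
4. report per-parameter uncertainty intervals as the range where the
   profiled chi-square stays below ``chi2_ratio`` (default 1.06) times the
   minimum chi-square.

Parameters may be fixed (e.g. P1 = 3.6 for weak-featured decayed samples);
fixed parameters are reported with an empty interval and a flag.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.optimize import brentq, least_squares

from .errors import ContractError, DataError
from .model import ModelParams, model_intensity, sigma_q_over_q, smear_profile
from .reduction import Profile1D

__all__ = [
    "FitConfig",
    "FitResult",
    "ParameterInterval",
    "subtract_amorphous",
    "fit_profile",
    "fit_two_level",
    "fit_three_level",
    "profile_uncertainty",
    "write_fit_result",
    "read_fit_result",
]

log = logging.getLogger(__name__)

DEFAULT_Q_WINDOW = (0.003, 0.27)

# parameter names owned by each structural term
_TERM_PARAMS = {
    "power_law": ("pl_prefactor", "pl_exponent"),
    "unified": ("level_G", "level_Rg", "level_B", "level_P2"),
    "peak": ("peak_amp", "peak_center", "peak_width"),
}

_BOUNDS = {
    "pl_prefactor": (0.0, np.inf),
    "pl_exponent": (1.0 + 1e-9, 4.5),
    "level_G": (0.0, np.inf),
    "level_Rg": (1e-2, 1e5),
    "level_B": (0.0, np.inf),
    "level_P2": (1e-9, 4.0),
    "peak_amp": (0.0, np.inf),
    "peak_center": (1e-4, 1.0),
    "peak_width": (1e-6, np.inf),
    "background": (0.0, np.inf),
}


@dataclass
class FitConfig:
    """Configuration of one staged fit."""

    terms: tuple = ("power_law", "unified", "peak")
    fixed: dict = field(default_factory=dict)
    q_window: tuple = DEFAULT_Q_WINDOW
    chi2_ratio: float = 1.06
    max_iterations: int = 2000
    init_overrides: dict = field(default_factory=dict)
    smear: bool = False
    wavelength_spread: float = 0.13

    def __post_init__(self):
        if self.chi2_ratio <= 1:
            raise ContractError("chi2_ratio must exceed 1")
        lo, hi = self.q_window
        if not lo < hi:
            raise ContractError("q_window must be a non-empty interval")


@dataclass(frozen=True)
class ParameterInterval:
    lo: float
    hi: float
    open_lo: bool = False
    open_hi: bool = False


@dataclass
class FitResult:
    """Best-fit parameters and chi-square statistics for one profile."""

    params: ModelParams
    terms: tuple
    fixed: dict
    chi2: float
    red_chi2: float
    n_points: int
    n_free: int
    converged: bool
    label: str
    sample_id: str
    q_window: tuple
    intervals: dict = field(default_factory=dict)
    message: str = ""

    @property
    def rg_nm(self) -> float:
        """Radius of gyration in nanometres (model stores Angstrom)."""
        return self.params.level_Rg / 10.0

    def free_names(self):
        names = [n for t in self.terms for n in _TERM_PARAMS[t]]
        names.append("background")
        return [n for n in names if n not in self.fixed]


# ---------------------------------------------------------------------------
# subtraction

def subtract_amorphous(aligned: Profile1D, amorphous: Profile1D) -> Profile1D:
    """Aligned minus amorphous intensity, enhancing the diffraction peak.

    The amorphous curve is linearly interpolated onto the aligned grid when
    the grids differ; points outside the common q-range are dropped.
    Negative intensities are retained.
    """
    lo = max(aligned.q.min(), amorphous.q.min())
    hi = min(aligned.q.max(), amorphous.q.max())
    if lo > hi:
        raise DataError("aligned and amorphous q-ranges are disjoint")
    keep = (aligned.q >= lo) & (aligned.q <= hi)
    if not np.any(keep):
        raise DataError("no aligned points inside the common q-range")
    q = aligned.q[keep]
    if amorphous.q.shape == q.shape and np.allclose(amorphous.q, q):
        ib, sb = amorphous.I, amorphous.sigma_I
    else:
        ib = np.interp(q, amorphous.q, amorphous.I)
        sb = np.interp(q, amorphous.q, amorphous.sigma_I)
    I = aligned.I[keep] - ib
    sigma = np.sqrt(aligned.sigma_I[keep] ** 2 + sb ** 2)
    sq = aligned.sigma_q[keep] if aligned.sigma_q is not None else None
    prov = dict(aligned.provenance)
    prov["subtracted_from"] = amorphous.label
    return Profile1D(q=q, I=I, sigma_I=sigma, sigma_q=sq, label="subtracted",
                     sample_id=aligned.sample_id, provenance=prov)


# ---------------------------------------------------------------------------
# initialization heuristics (deterministic)

def _loglog_slope(q, I, window):
    mask = (q >= window[0]) & (q <= window[1]) & (I > 0)
    if mask.sum() < 2:
        return None, None
    coeffs = np.polyfit(np.log(q[mask]), np.log(I[mask]), 1)
    return -coeffs[0], np.exp(coeffs[1])


def _initial_guess(q, I, terms, overrides):
    init = {"background": max(float(np.min(I)), 0.0)}
    if "power_law" in terms:
        p1, c1 = _loglog_slope(q, I, (q.min(), min(0.01, q.min() * 4)))
        if p1 is None or not (1.0 < p1 <= 4.5):
            p1 = 3.5
        lo_mask = I > 0
        if c1 is None or not np.isfinite(c1) or c1 <= 0:
            c1 = float(I[lo_mask][0] * q[lo_mask][0] ** p1) if lo_mask.any() else 1e-6
        init["pl_exponent"] = float(np.clip(p1, 1.01, 4.49))
        init["pl_prefactor"] = c1
    if "peak" in terms:
        hw_lo = max(0.1, q.min())
        peak_mask = (q >= hw_lo) & (q <= 0.3)
        if peak_mask.sum() < 3:
            peak_mask = q >= np.median(q)
        qq, ii = q[peak_mask], I[peak_mask]
        j = int(np.argmax(ii))
        q0 = float(qq[j])
        baseline = float(np.median(ii))
        init["peak_center"] = q0
        init["peak_width"] = 0.2 * q0
        init["peak_amp"] = max(float(ii[j] - baseline), 1e-3 * max(abs(ii[j]), 1e-30))
    if "unified" in terms:
        mid = (q >= 0.01) & (q <= 0.1) & (I > 0)
        rg = 50.0
        if mid.sum() >= 3:
            s = np.polyfit(q[mid] ** 2, np.log(I[mid]), 1)[0]
            if s < 0:
                rg = float(np.sqrt(-3.0 * s))
        rg = float(np.clip(rg, 5.0, 500.0))
        init["level_Rg"] = rg
        qg = 1.0 / rg
        g = float(np.interp(qg, q, I))
        init["level_G"] = max(g, 1e-6)
        p2 = 2.0
        init["level_P2"] = p2
        hi_mask = (q >= 0.1) & (I > 0)
        if hi_mask.any():
            qh, ih = q[hi_mask][-1], I[hi_mask][-1]
            init["level_B"] = max(float(ih * qh ** p2) * 0.5, 1e-9)
        else:
            init["level_B"] = 1e-4
    init.update(overrides)
    return init


# ---------------------------------------------------------------------------
# core fit

def _assemble_params(values: dict) -> ModelParams:
    base = ModelParams()
    kwargs = {f: getattr(base, f) for f in base.__dataclass_fields__}
    kwargs.update(values)
    # bypass range validation pitfalls by clipping into legal open intervals
    return ModelParams(**kwargs)


def _prepare(profile: Profile1D, config: FitConfig):
    lo, hi = config.q_window
    mask = (profile.q >= lo) & (profile.q <= hi)
    q = profile.q[mask]
    I = profile.I[mask]
    s = profile.sigma_I[mask]
    if q.size == 0:
        raise DataError("q_window selects no data points")
    if np.all(s == 0):
        log.warning("all-zero sigma column; falling back to unit weights")
        w = np.ones_like(q)
    else:
        s = np.where(s > 0, s, np.min(s[s > 0]))
        w = 1.0 / s
    return q, I, w


def _fit_core(q, I, w, config: FitConfig, init: dict):
    free = [n for t in config.terms for n in _TERM_PARAMS[t]]
    free.append("background")
    free = [n for n in free if n not in config.fixed]
    if q.size < len(free):
        raise DataError("fewer data points than free parameters")

    fixed_vals = dict(config.fixed)
    lb = np.array([_BOUNDS[n][0] for n in free])
    ub = np.array([_BOUNDS[n][1] for n in free])
    x0 = np.array([np.clip(init[n], lb[i] + 1e-15, min(ub[i], 1e30)) for i, n in enumerate(free)])

    frac = sigma_q_over_q(config.wavelength_spread) if config.smear else 0.0

    def model_of(x):
        values = dict(zip(free, x))
        values.update(fixed_vals)
        params = _assemble_params(values)
        m = model_intensity(q, params, terms=config.terms)
        if frac > 0:
            m = smear_profile(q, m, frac)
        return m, params

    def resid(x):
        m, _ = model_of(x)
        return (m - I) * w

    scale = np.where(np.abs(x0) > 0, np.abs(x0), 1.0)
    res = least_squares(resid, x0, bounds=(lb, ub), x_scale=scale,
                        max_nfev=config.max_iterations, method="trf",
                        ftol=1e-12, xtol=1e-12, gtol=1e-12)
    _, params = model_of(res.x)
    chi2 = float(np.sum(res.fun ** 2))
    dof = max(q.size - len(free), 1)
    return params, free, chi2, chi2 / dof, bool(res.success), res.status


def fit_profile(profile: Profile1D, config: FitConfig) -> FitResult:
    """Weighted least-squares fit of the configured model terms to a profile."""
    q, I, w = _prepare(profile, config)
    init = _initial_guess(q, I, config.terms, config.init_overrides)
    init.update(config.fixed)
    params, free, chi2, red, ok, status = _fit_core(q, I, w, config, init)
    msg = "" if ok else f"optimizer did not converge (status {status})"
    if not ok:
        log.warning("fit on %s/%s: %s", profile.sample_id, profile.label, msg)
    return FitResult(params=params, terms=tuple(config.terms),
                     fixed=dict(config.fixed), chi2=chi2, red_chi2=red,
                     n_points=q.size, n_free=len(free), converged=ok,
                     label=profile.label, sample_id=profile.sample_id,
                     q_window=tuple(config.q_window), message=msg)


def fit_two_level(subtracted: Profile1D, config: Optional[FitConfig] = None) -> FitResult:
    """Two-level fit (power law + peak) of a subtracted curve for P1 and q0."""
    if config is None:
        config = FitConfig(terms=("power_law", "peak"))
    elif set(config.terms) != {"power_law", "peak"}:
        config = replace(config, terms=("power_law", "peak"))
    return fit_profile(subtracted, config)


def fit_three_level(profile: Profile1D, config: Optional[FitConfig] = None,
                    include_peak: bool = False) -> FitResult:
    """Three-level fit (power law + unified level) of an amorphous/isotropic
    profile for the mid-q Rg and P2.

    ``include_peak`` adds a weak Gaussian peak term.  Fixed parameters in the
    config (e.g. ``{"pl_exponent": 3.6}`` for decayed shavings) are honored
    exactly and flagged in the result.
    """
    terms = ("power_law", "unified") + (("peak",) if include_peak else ())
    if config is None:
        config = FitConfig(terms=terms)
    else:
        config = replace(config, terms=terms)
    return fit_profile(profile, config)


# ---------------------------------------------------------------------------
# chi-square profiling

def _refit_chi2(profile, config, fix_name, fix_value, warm):
    cfg = replace(config, fixed={**config.fixed, fix_name: fix_value},
                  init_overrides={**warm})
    q, I, w = _prepare(profile, cfg)
    init = dict(warm)
    init[fix_name] = fix_value
    _, _, chi2, _, _, _ = _fit_core(q, I, w, cfg, init)
    return chi2


def profile_uncertainty(result: FitResult, data: Profile1D, name: str,
                        chi2_ratio: Optional[float] = None,
                        config: Optional[FitConfig] = None,
                        scan_factor: float = 10.0) -> ParameterInterval:
    """Chi-square-profile uncertainty interval for one free parameter.

    The named parameter is scanned away from its best-fit value, re-optimizing
    all other free parameters at each point; the interval is the range where
    ``chi2 < chi2_ratio * chi2_min``.  Endpoints are refined by root bracketing
    well below 1% of the parameter value.  If no crossing occurs within
    ``scan_factor`` times the best-fit value (or the parameter bounds) the
    corresponding side is flagged open.
    """
    if name in result.fixed:
        raise ContractError(f"parameter {name!r} is fixed; no profile interval")
    if not result.converged:
        raise ContractError("cannot profile a non-converged fit")
    if config is None:
        config = FitConfig(terms=result.terms, fixed=dict(result.fixed),
                           q_window=result.q_window)
    ratio = chi2_ratio if chi2_ratio is not None else config.chi2_ratio
    if ratio <= 1:
        raise ContractError("chi2_ratio must exceed 1")

    best = {n: getattr(result.params, n) for n in result.params.__dataclass_fields__}
    vhat = best[name]
    chi2_min = result.chi2
    target = ratio * chi2_min
    lo_bound, hi_bound = _BOUNDS[name]
    scale = abs(vhat) if vhat != 0 else 1.0

    def g(v):
        return _refit_chi2(data, config, name, v, best) - target

    def find_edge(direction):
        step = 0.01 * scale
        prev = vhat
        for _ in range(40):
            v = vhat + direction * step
            v = np.clip(v, lo_bound + 1e-15, hi_bound if np.isfinite(hi_bound) else v)
            if v == prev:  # pinned at a bound
                return float(v), True
            if (direction > 0 and v >= vhat + scan_factor * scale) or \
               (direction < 0 and v <= max(lo_bound + 1e-15, vhat - scan_factor * scale)):
                if g(v) <= 0:
                    return float(v), True
                break
            if g(v) > 0:
                xtol = min(0.01 * scale, 0.002 * abs(v - vhat) + 1e-15)
                edge = brentq(g, *sorted((prev, v)), xtol=xtol)
                return float(edge), False
            prev = v
            step *= 2.0
            if direction < 0 and vhat + direction * step <= lo_bound:
                step = vhat - lo_bound - 1e-15
                if step <= 0:
                    return float(lo_bound), True
        # ran out of scan range without crossing
        return float(np.clip(vhat + direction * scan_factor * scale,
                             lo_bound, hi_bound)), True

    hi, open_hi = find_edge(+1.0)
    lo, open_lo = find_edge(-1.0)
    lo = min(lo, vhat)
    hi = max(hi, vhat)
    return ParameterInterval(lo=lo, hi=hi, open_lo=open_lo, open_hi=open_hi)


# ---------------------------------------------------------------------------
# serialization

def write_fit_result(path, result: FitResult) -> None:
    """Flat key=value report file."""
    lines = {
        "sample_id": result.sample_id,
        "label": result.label,
        "terms": ",".join(result.terms),
        "chi2": repr(result.chi2),
        "red_chi2": repr(result.red_chi2),
        "n_points": result.n_points,
        "n_free": result.n_free,
        "converged": result.converged,
        "q_window_lo": repr(result.q_window[0]),
        "q_window_hi": repr(result.q_window[1]),
    }
    if result.message:
        lines["message"] = result.message
    with open(path, "w") as fh:
        for k, v in lines.items():
            fh.write(f"{k} = {v}\n")
        for pname, value in result.params.to_dict().items():
            fixed = pname in result.fixed
            iv = result.intervals.get(pname)
            lo = iv.lo if iv else ""
            hi = iv.hi if iv else ""
            fh.write(f"param {pname} = {float(value)!r} fixed={fixed} lo={lo} hi={hi}\n")


def read_fit_result(path) -> FitResult:
    """Read a report written by :func:`write_fit_result`."""
    meta, params, fixed, intervals = {}, {}, {}, {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("param "):
                body = line[len("param "):]
                pname, rest = body.split(" = ", 1)
                valstr, *flags = rest.split(" ")
                params[pname] = float(valstr)
                fdict = dict(f.split("=", 1) for f in flags)
                if fdict.get("fixed") == "True":
                    fixed[pname] = params[pname]
                if fdict.get("lo") and fdict.get("hi"):
                    intervals[pname] = ParameterInterval(float(fdict["lo"]),
                                                         float(fdict["hi"]))
            else:
                k, _, v = line.partition(" =")
                meta[k] = v.lstrip()
    return FitResult(
        params=ModelParams(**params),
        terms=tuple(meta["terms"].split(",")),
        fixed=fixed,
        chi2=float(meta["chi2"]),
        red_chi2=float(meta["red_chi2"]),
        n_points=int(meta["n_points"]),
        n_free=int(meta["n_free"]),
        converged=meta["converged"] == "True",
        label=meta["label"],
        sample_id=meta["sample_id"],
        q_window=(float(meta["q_window_lo"]), float(meta["q_window_hi"])),
        intervals=intervals,
        message=meta.get("message", ""),
    )
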