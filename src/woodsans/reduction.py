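"""2D detector-frame reduction to 1D scattering profiles.

A corrected frame is reduced either anisotropically into an *aligned* and an
*amorphous* sector profile, or — when no anisotropy is detected — into a
single *isotropic* profile.  Two instrument configurations (long and short
sample-to-detector distance) are merged into one curve covering the full
q-range.

Conventions
-----------
* ``counts`` arrays are indexed ``[row, col]`` = ``[y, x]``;
  ``detector_shape`` is ``(ny, nx)`` i.e. ``counts.shape``.
* ``beam_center_px`` is ``(x, y)`` in 0-based pixel units, pixel centers at
  integer coordinates.
* Azimuth is measured in degrees counterclockwise from the detector +x axis,
  in ``[0, 360)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import h5py
import numpy as np

from .errors import DataError, DomainError, FormatError
from .model import sigma_q_over_q

__all__ = [
    "InstrumentConfig",
    "DetectorFrame",
    "Sector",
    "Profile1D",
    "AnisotropyResult",
    "pixel_q",
    "pixel_coordinates",
    "correct_frame",
    "detect_anisotropy",
    "sector_reduce",
    "merge_profiles",
    "reduce_frame",
    "linear_q_bins",
    "write_frame",
    "read_frame",
    "write_profile",
    "read_profile",
]

PROFILE_LABELS = ("aligned", "amorphous", "isotropic", "subtracted")


@dataclass(frozen=True)
class InstrumentConfig:
    """Geometry and resolution of one instrument configuration."""

    wavelength_A: float
    wavelength_spread: float
    sdd_m: float
    beam_center_px: tuple
    pixel_pitch_mm: float
    detector_shape: tuple
    q_range: tuple

    def __post_init__(self):
        if self.wavelength_A <= 0:
            raise DomainError("wavelength must be > 0")
        if self.sdd_m <= 0:
            raise DomainError("sample-to-detector distance must be > 0")
        if not (0 <= self.wavelength_spread < 1):
            raise DomainError("wavelength spread must lie in [0, 1)")
        if self.pixel_pitch_mm <= 0:
            raise DomainError("pixel pitch must be > 0")
        qmin, qmax = self.q_range
        if not qmin < qmax:
            raise DomainError("q_range must satisfy q_min < q_max")
        ny, nx = self.detector_shape
        bx, by = self.beam_center_px
        if not (-nx <= bx <= 2 * nx and -ny <= by <= 2 * ny):
            raise DomainError("beam center is far outside the detector")


@dataclass
class DetectorFrame:
    """Raw counts grid plus everything needed to correct and reduce it."""

    counts: np.ndarray
    monitor_counts: float
    config: InstrumentConfig
    sample_id: str = ""
    dark: Optional[np.ndarray] = None
    sensitivity: Optional[np.ndarray] = None
    background: Optional[np.ndarray] = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if tuple(self.counts.shape) != tuple(self.config.detector_shape):
            raise FormatError("counts shape does not match config.detector_shape")
        if self.monitor_counts <= 0:
            raise DomainError("monitor_counts must be > 0")
        if np.any(self.counts < 0):
            raise DomainError("counts must be non-negative")
        for name in ("dark", "sensitivity", "background"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != self.counts.shape:
                    raise FormatError(f"{name} shape does not match counts")
                setattr(self, name, arr)
        if self.sensitivity is not None and np.any(self.sensitivity <= 0):
            raise DataError("sensitivity entries must be > 0")


@dataclass(frozen=True)
class Sector:
    """An azimuthal wedge, optionally pooled with its 180-degree mirror."""

    center_azimuth_deg: float
    half_width_deg: float
    twofold: bool = True

    def __post_init__(self):
        if not (0 <= self.center_azimuth_deg < 360):
            raise DomainError("center azimuth must lie in [0, 360)")
        if not (0 < self.half_width_deg <= 90):
            raise DomainError("half width must lie in (0, 90]")

    def contains(self, azimuth_deg: np.ndarray) -> np.ndarray:
        """Boolean mask of azimuths (degrees) inside the sector."""
        d = np.abs((np.asarray(azimuth_deg) - self.center_azimuth_deg + 180.0) % 360.0 - 180.0)
        inside = d <= self.half_width_deg
        if self.twofold:
            inside = inside | (np.abs(d - 180.0) <= self.half_width_deg)
        return inside


@dataclass
class Profile1D:
    """A reduced 1D scattering curve."""

    q: np.ndarray
    I: np.ndarray
    sigma_I: np.ndarray
    label: str
    sample_id: str = ""
    sigma_q: Optional[np.ndarray] = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        self.sigma_I = np.asarray(self.sigma_I, dtype=float)
        if not (self.q.shape == self.I.shape == self.sigma_I.shape):
            raise FormatError("q, I and sigma_I must have equal lengths")
        if self.sigma_q is not None:
            self.sigma_q = np.asarray(self.sigma_q, dtype=float)
            if self.sigma_q.shape != self.q.shape:
                raise FormatError("sigma_q length mismatch")
        if self.q.size and np.any(np.diff(self.q) <= 0):
            raise FormatError("q must be strictly increasing")
        if np.any(self.sigma_I < 0):
            raise FormatError("sigma_I must be >= 0")
        if self.label not in PROFILE_LABELS:
            raise FormatError(f"label must be one of {PROFILE_LABELS}")

    def __len__(self):
        return self.q.size


@dataclass(frozen=True)
class AnisotropyResult:
    anisotropic: bool
    score: float
    orientation_deg: Optional[float]


# ---------------------------------------------------------------------------
# geometry

def pixel_q(r, config: InstrumentConfig):
    """Scattering vector (A^-1) at radial distance ``r`` (m) from the beam.

    theta = arctan(r / L) / 2 and q = 4 pi sin(theta) / lambda.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise DomainError("radial distance must be >= 0")
    theta = 0.5 * np.arctan(r / config.sdd_m)
    return 4.0 * np.pi * np.sin(theta) / config.wavelength_A


def pixel_coordinates(config: InstrumentConfig):
    """Per-pixel (q, azimuth_deg, r_m) grids for a configuration."""
    ny, nx = config.detector_shape
    bx, by = config.beam_center_px
    x = np.arange(nx, dtype=float) - bx
    y = np.arange(ny, dtype=float) - by
    dx, dy = np.meshgrid(x, y)
    r = np.hypot(dx, dy) * config.pixel_pitch_mm * 1e-3
    phi = np.degrees(np.arctan2(dy, dx)) % 360.0
    return pixel_q(r, config), phi, r


# ---------------------------------------------------------------------------
# corrections

def correct_frame(frame: DetectorFrame):
    """Monitor-normalise a frame and apply sensitivity/dark/background corrections.

    Returns ``(intensity, sigma)`` grids.  The per-pixel model is

        I = ((counts - dark) / sensitivity) / monitor - background_term

    with ``background_term = (background / sensitivity) / monitor``.  Sigma is
    propagated from Poisson statistics of the raw counts only
    (``sigma_counts = sqrt(counts)``).
    """
    counts = frame.counts.astype(float)
    dark = frame.dark if frame.dark is not None else 0.0
    sens = frame.sensitivity if frame.sensitivity is not None else 1.0
    bkg = frame.background if frame.background is not None else 0.0
    monitor = frame.monitor_counts
    intensity = ((counts - dark) / sens) / monitor - (bkg / sens) / monitor
    sigma = np.sqrt(counts) / sens / monitor
    return intensity, sigma


# ---------------------------------------------------------------------------
# anisotropy detection

def detect_anisotropy(intensity: np.ndarray, config: InstrumentConfig,
                      q_window: tuple, threshold: float = 0.1,
                      n_phi: int = 72) -> AnisotropyResult:
    """Classify a corrected frame as isotropic or anisotropic.

    The annulus ``q_window`` is folded into ``n_phi`` azimuthal bins; the
    anisotropy score is the amplitude of the second circular harmonic of the
    binned profile divided by its mean.  When the score exceeds ``threshold``
    the harmonic phase gives the lobe orientation.
    """
    q, phi, _ = pixel_coordinates(config)
    lo, hi = q_window
    mask = (q >= lo) & (q <= hi)
    if not np.any(mask):
        raise DataError("q_window selects no pixels")
    phi_sel = phi[mask]
    i_sel = intensity[mask]
    bins = np.floor(phi_sel / (360.0 / n_phi)).astype(int)
    sums = np.bincount(bins, weights=i_sel, minlength=n_phi)
    npix = np.bincount(bins, minlength=n_phi)
    ok = npix > 0
    means = sums[ok] / npix[ok]
    centers = np.radians((np.arange(n_phi)[ok] + 0.5) * (360.0 / n_phi))
    mean_i = means.mean()
    if mean_i <= 0:
        return AnisotropyResult(False, 0.0, None)
    c2 = np.mean(means * np.cos(2 * centers))
    s2 = np.mean(means * np.sin(2 * centers))
    score = 2.0 * np.hypot(c2, s2) / mean_i
    if score > threshold:
        phi0 = (0.5 * np.degrees(np.arctan2(s2, c2))) % 180.0
        return AnisotropyResult(True, float(score), float(phi0))
    return AnisotropyResult(False, float(score), None)


# ---------------------------------------------------------------------------
# sector reduction

def linear_q_bins(config: InstrumentConfig, n_bins: int = 100) -> np.ndarray:
    """Linearly spaced q-bin centers spanning the configuration's q_range."""
    qmin, qmax = config.q_range
    edges = np.linspace(qmin, qmax, n_bins + 1)
    return 0.5 * (edges[:-1] + edges[1:])


def _bin_index(q_values: np.ndarray, q_bins: np.ndarray) -> np.ndarray:
    """Nearest-center bin assignment; -1 marks out-of-range pixels."""
    if np.any(np.diff(q_bins) <= 0):
        raise DomainError("q_bins must be strictly increasing")
    mids = 0.5 * (q_bins[1:] + q_bins[:-1])
    idx = np.searchsorted(mids, q_values)
    half0 = (q_bins[1] - q_bins[0]) / 2 if q_bins.size > 1 else np.inf
    half1 = (q_bins[-1] - q_bins[-2]) / 2 if q_bins.size > 1 else np.inf
    lo = q_bins[0] - half0
    hi = q_bins[-1] + half1
    idx[(q_values < lo) | (q_values > hi)] = -1
    return idx


def sector_reduce(intensity: np.ndarray, sigma: np.ndarray,
                  config: InstrumentConfig, sector: Optional[Sector],
                  q_bins: np.ndarray, label: str = "isotropic",
                  sample_id: str = "") -> Profile1D:
    """Azimuthal-sector average of a corrected frame onto a q grid.

    Pixels are assigned to the *nearest* q-bin center of ``q_bins`` and, when
    a sector is given, filtered by azimuth (pooling the 180-degree mirror for
    two-fold sectors).  Bin intensity is the mean of contributing pixels; the
    uncertainty is the propagated error of that mean.  Empty bins are dropped.
    ``sector=None`` averages over all azimuths.
    """
    q_bins = np.asarray(q_bins, dtype=float)
    q, phi, _ = pixel_coordinates(config)
    mask = np.ones_like(q, dtype=bool)
    if sector is not None:
        mask &= sector.contains(phi)
    idx = _bin_index(q.ravel(), q_bins)
    idx[~mask.ravel()] = -1
    valid = idx >= 0
    if not np.any(valid):
        raise DataError("sector covers no pixels in any q bin")
    idx = idx[valid]
    ival = intensity.ravel()[valid]
    svar = sigma.ravel()[valid] ** 2
    n = np.bincount(idx, minlength=q_bins.size)
    sums = np.bincount(idx, weights=ival, minlength=q_bins.size)
    vars_ = np.bincount(idx, weights=svar, minlength=q_bins.size)
    keep = n > 0
    I = sums[keep] / n[keep]
    sig = np.sqrt(vars_[keep]) / n[keep]
    qc = q_bins[keep]
    sq = sigma_q_over_q(config.wavelength_spread) * qc
    prov = {
        "reduction": "sector" if sector is not None else "isotropic",
        "n_pixels": int(n[keep].sum()),
        "sdd_m": config.sdd_m,
    }
    if sector is not None:
        prov["sector_center_deg"] = sector.center_azimuth_deg
        prov["sector_half_width_deg"] = sector.half_width_deg
    return Profile1D(q=qc, I=I, sigma_I=sig, sigma_q=sq, label=label,
                     sample_id=sample_id, provenance=prov)


def merge_profiles(long_distance: Profile1D, short_distance: Profile1D) -> Profile1D:
    """Merge long- and short-distance curves into one profile.

    The short-distance (high-q) curve is scaled by the median intensity ratio
    over the overlapping q region; duplicate q values are averaged.  The scale
    factor is recorded in the provenance.
    """
    if long_distance.label != short_distance.label:
        raise DataError("profiles to merge must share a sector label")
    lo = max(long_distance.q.min(), short_distance.q.min())
    hi = min(long_distance.q.max(), short_distance.q.max())
    if lo >= hi:
        raise DataError("q ranges of the two configurations do not overlap")
    in_overlap = (short_distance.q >= lo) & (short_distance.q <= hi)
    if not np.any(in_overlap):
        raise DataError("no short-distance points inside the overlap region")
    long_interp = np.interp(short_distance.q[in_overlap], long_distance.q, long_distance.I)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = long_interp / short_distance.I[in_overlap]
    ratios = ratios[np.isfinite(ratios)]
    if ratios.size == 0:
        raise DataError("overlap region has no usable intensity ratios")
    scale = float(np.median(ratios))

    q = np.concatenate([long_distance.q, short_distance.q])
    I = np.concatenate([long_distance.I, short_distance.I * scale])
    s = np.concatenate([long_distance.sigma_I, short_distance.sigma_I * scale])
    if long_distance.sigma_q is not None and short_distance.sigma_q is not None:
        sq = np.concatenate([long_distance.sigma_q, short_distance.sigma_q])
    else:
        sq = None
    order = np.argsort(q, kind="stable")
    q, I, s = q[order], I[order], s[order]
    if sq is not None:
        sq = sq[order]
    # average exact duplicates
    uq, inv, counts = np.unique(q, return_inverse=True, return_counts=True)
    if uq.size != q.size:
        I = np.bincount(inv, weights=I) / counts
        s = np.sqrt(np.bincount(inv, weights=s ** 2)) / counts
        if sq is not None:
            sq = np.bincount(inv, weights=sq) / counts
        q = uq
    prov = dict(long_distance.provenance)
    prov.update({"merge_scale": scale,
                 "merged_from_sdd_m": [long_distance.provenance.get("sdd_m"),
                                       short_distance.provenance.get("sdd_m")]})
    return Profile1D(q=q, I=I, sigma_I=s, sigma_q=sq, label=long_distance.label,
                     sample_id=long_distance.sample_id, provenance=prov)


# ---------------------------------------------------------------------------
# high-level frame reduction

def reduce_frame(frame: DetectorFrame, q_bins: Optional[np.ndarray] = None,
                 sector_half_width_deg: float = 25.0,
                 anisotropy_window: Optional[tuple] = None,
                 anisotropy_threshold: float = 0.1,
                 orientation_deg: Optional[float] = None) -> dict:
    """Correct and reduce one frame into labelled profiles.

    Returns ``{"aligned": ..., "amorphous": ...}`` when the frame is
    anisotropic (aligned sector centered on the detected or supplied lobe
    orientation, amorphous sector 90 degrees away) or ``{"isotropic": ...}``
    otherwise.
    """
    cfg = frame.config
    if q_bins is None:
        q_bins = linear_q_bins(cfg)
    intensity, sigma = correct_frame(frame)
    if anisotropy_window is None:
        qmin, qmax = cfg.q_range
        anisotropy_window = (qmin + 0.3 * (qmax - qmin), qmin + 0.8 * (qmax - qmin))
    if orientation_deg is None:
        res = detect_anisotropy(intensity, cfg, anisotropy_window,
                                threshold=anisotropy_threshold)
    else:
        res = AnisotropyResult(True, np.inf, orientation_deg % 180.0)
    if not res.anisotropic:
        prof = sector_reduce(intensity, sigma, cfg, None, q_bins,
                             label="isotropic", sample_id=frame.sample_id)
        return {"isotropic": prof}
    phi0 = res.orientation_deg
    aligned = Sector(phi0 % 360.0, sector_half_width_deg, twofold=True)
    amorphous = Sector((phi0 + 90.0) % 360.0, sector_half_width_deg, twofold=True)
    return {
        "aligned": sector_reduce(intensity, sigma, cfg, aligned, q_bins,
                                 label="aligned", sample_id=frame.sample_id),
        "amorphous": sector_reduce(intensity, sigma, cfg, amorphous, q_bins,
                                   label="amorphous", sample_id=frame.sample_id),
    }


# ---------------------------------------------------------------------------
# file formats

def write_frame(path, frame: DetectorFrame) -> None:
    """Write a frame to an HDF5 container (NXcanSAS-inspired flat layout)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("counts", data=frame.counts.astype(np.int64))
        for name in ("dark", "sensitivity", "background"):
            arr = getattr(frame, name)
            if arr is not None:
                f.create_dataset(name, data=arr)
        cfg = frame.config
        f.attrs["wavelength_A"] = cfg.wavelength_A
        f.attrs["wavelength_spread"] = cfg.wavelength_spread
        f.attrs["sdd_m"] = cfg.sdd_m
        f.attrs["beam_center_px"] = list(cfg.beam_center_px)
        f.attrs["pixel_pitch_mm"] = cfg.pixel_pitch_mm
        f.attrs["q_range_invA"] = list(cfg.q_range)
        f.attrs["monitor"] = frame.monitor_counts
        f.attrs["sample_id"] = frame.sample_id


def read_frame(path) -> DetectorFrame:
    """Read a frame written by :func:`write_frame`."""
    with h5py.File(path, "r") as f:
        counts = f["counts"][...]
        opt = {name: f[name][...] if name in f else None
               for name in ("dark", "sensitivity", "background")}
        cfg = InstrumentConfig(
            wavelength_A=float(f.attrs["wavelength_A"]),
            wavelength_spread=float(f.attrs["wavelength_spread"]),
            sdd_m=float(f.attrs["sdd_m"]),
            beam_center_px=tuple(f.attrs["beam_center_px"]),
            pixel_pitch_mm=float(f.attrs["pixel_pitch_mm"]),
            detector_shape=counts.shape,
            q_range=tuple(f.attrs["q_range_invA"]),
        )
        return DetectorFrame(counts=counts, monitor_counts=float(f.attrs["monitor"]),
                             config=cfg, sample_id=str(f.attrs["sample_id"]),
                             dark=opt["dark"], sensitivity=opt["sensitivity"],
                             background=opt["background"])


def write_profile(path, profile: Profile1D) -> None:
    """Write a 1D profile as '#'-headed ASCII columns (q, I, sigma_I[, sigma_q])."""
    cols = [profile.q, profile.I, profile.sigma_I]
    names = ["q_invA", "I", "sigma_I"]
    if profile.sigma_q is not None:
        cols.append(profile.sigma_q)
        names.append("sigma_q")
    with open(path, "w") as fh:
        fh.write(f"# sample_id: {profile.sample_id}\n")
        fh.write(f"# label: {profile.label}\n")
        fh.write(f"# provenance: {json.dumps(profile.provenance)}\n")
        fh.write("# columns: " + " ".join(names) + "\n")
        for row in zip(*cols):
            fh.write(" ".join(f"{v:.10e}" for v in row) + "\n")


def read_profile(path) -> Profile1D:
    """Read a profile written by :func:`write_profile`."""
    meta = {}
    data = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    key, val = body.split(":", 1)
                    meta[key.strip()] = val.strip()
            else:
                data.append([float(v) for v in line.split()])
    if not data:
        raise FormatError(f"no data rows in {path}")
    arr = np.asarray(data, dtype=float)
    prov = json.loads(meta.get("provenance", "{}"))
    sigma_q = arr[:, 3] if arr.shape[1] > 3 else None
    return Profile1D(q=arr[:, 0], I=arr[:, 1], sigma_I=arr[:, 2], sigma_q=sigma_q,
                     label=meta.get("label", "isotropic"),
                     sample_id=meta.get("sample_id", ""), provenance=prov)
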