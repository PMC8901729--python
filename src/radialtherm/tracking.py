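"""Catheter micro-coil localization and motion-curve extraction.

Each micro-coil has a near-delta spatial sensitivity, so the 1D inverse
Fourier transform of its spoke samples is a projection profile with a
single (possibly split) peak.  Two consecutive golden-angle projections
(111.25 degrees apart) determine the in-plane coil position — the
algebraic equivalent of locating the bright intersection in a
two-projection back-projection (Radon) map — at a temporal resolution of
two TR (~48 ms).  The peak intensity serves as a qualitative out-of-plane
("Z-intensity") surrogate.

The raw curves carry a small projection-angle-dependent bias which is
removed by fitting a low-order periodic function of the spoke angle; the
debiased curves are then split into a medium-frequency "filtered" variant
(Gaussian low-pass, -3 dB at 0.883 Hz), a respiratory variant (0.377 Hz)
and a cardiac variant (their difference).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .raw_io import MICROCOIL_DISTAL, MICROCOIL_PROXIMAL, RadialKspace


@dataclass
class CoilProfile:
    """Magnitude projection profile of one micro-coil spoke."""

    magnitude: np.ndarray
    positions_mm: np.ndarray
    angle_deg: float
    spoke_index: int = -1
    peak_mm: float | None = None
    peak_intensity: float | None = None
    valid: bool = True


@dataclass
class MotionTrace:
    """Per-spoke-pair displacement curves and Z-intensity surrogate."""

    times_s: np.ndarray
    x_mm: np.ndarray
    y_mm: np.ndarray
    z_intensity: np.ndarray
    variant: str = "raw"
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.times_s)
        if not (len(self.x_mm) == len(self.y_mm) == len(self.z_intensity) == n):
            raise ValueError("trace fields must have equal length")
        if self.valid is None:
            self.valid = np.ones(n, dtype=bool)

    @property
    def sample_rate_hz(self) -> float:
        return 1.0 / float(np.median(np.diff(self.times_s)))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times_s, "x_mm": self.x_mm,
                             "y_mm": self.y_mm, "z_intensity": self.z_intensity,
                             "variant": self.variant})


def coil_profile(spoke: np.ndarray, angle_deg: float, fov_mm: float,
                 matrix_size: int, spoke_index: int = -1) -> CoilProfile:
    """Centred inverse Fourier transform magnitude of one micro-coil spoke.

    With readout oversampling the profile spans twice the FoV at the native
    pixel size ``FoV/matrix``.
    """
    spoke = np.asarray(spoke)
    r = len(spoke)
    prof = np.abs(np.fft.fftshift(np.fft.ifft(np.fft.ifftshift(spoke)))) * r
    positions = (np.arange(r) - r // 2) * (fov_mm / matrix_size)
    valid = bool(np.max(prof) > 0)
    return CoilProfile(magnitude=prof, positions_mm=positions,
                       angle_deg=float(angle_deg), spoke_index=spoke_index,
                       valid=valid)


def smooth_and_locate(profile: CoilProfile,
                      sigma_px: float = 2.0) -> tuple[float, float]:
    """Gaussian-smoothed peak barycenter and intensity of a profile.

    The peak position is the intensity-weighted barycenter over the
    contiguous region above half of the smoothed maximum (robust to split
    peaks); the intensity is the smoothed maximum.  Returns
    ``(nan, 0.0)`` and flags the profile invalid for a flat input.
    """
    mag = profile.magnitude
    smoothed = gaussian_filter1d(mag, sigma_px, mode="wrap") if sigma_px > 0 \
        else mag.astype(float)
    peak = float(np.max(smoothed))
    if not profile.valid or peak <= 0 or np.ptp(smoothed) < 1e-12 * peak:
        profile.valid = False
        profile.peak_mm, profile.peak_intensity = float("nan"), 0.0
        return float("nan"), 0.0
    imax = int(np.argmax(smoothed))
    half = 0.5 * peak
    lo = imax
    while lo > 0 and smoothed[lo - 1] >= half:
        lo -= 1
    hi = imax
    while hi < len(smoothed) - 1 and smoothed[hi + 1] >= half:
        hi += 1
    w = smoothed[lo:hi + 1]
    pos = float(np.sum(profile.positions_mm[lo:hi + 1] * w) / np.sum(w))
    profile.peak_mm, profile.peak_intensity = pos, peak
    return pos, peak


def localize_pair(p1: float, p2: float, rho1_deg: float, rho2_deg: float,
                  min_sin_deg: float = 5.0) -> tuple[float, float] | None:
    """Solve ``p_j = x cos(rho_j) + y sin(rho_j)`` for the coil position.

    Exact algebraic equivalent of the argmax of the two-projection
    back-projection map.  Near-parallel projections (angle separation below
    ``min_sin_deg`` mod 180) are rejected as invalid samples.
    """
    sep = np.deg2rad((rho2_deg - rho1_deg) % 180.0)
    if min(abs(np.sin(sep)), 1.0) < np.sin(np.deg2rad(min_sin_deg)):
        return None
    r1, r2 = np.deg2rad(rho1_deg), np.deg2rad(rho2_deg)
    a = np.array([[np.cos(r1), np.sin(r1)], [np.cos(r2), np.sin(r2)]])
    x, y = np.linalg.solve(a, np.array([p1, p2]))
    return float(x), float(y)


def backprojection_map(prof1: CoilProfile, prof2: CoilProfile,
                       matrix_size: int, fov_mm: float) -> np.ndarray:
    """Diagnostic two-projection back-projection image (product of profiles)."""
    off = (np.arange(matrix_size) - matrix_size // 2) * (fov_mm / matrix_size)
    yy, xx = np.meshgrid(off, off, indexing="ij")
    out = np.ones_like(xx)
    for prof in (prof1, prof2):
        rho = np.deg2rad(prof.angle_deg)
        p = xx * np.cos(rho) + yy * np.sin(rho)
        out = out * np.interp(p, prof.positions_mm, prof.magnitude)
    return out


def gaussian_lowpass(signal: np.ndarray, cutoff_hz: float,
                     sample_rate_hz: float) -> np.ndarray:
    """Zero-phase Gaussian low-pass with -3 dB *amplitude* at ``cutoff_hz``.

    The amplitude response is ``exp(-f^2 / (2 sigma_f^2))`` with
    ``sigma_f = cutoff / sqrt(ln 2)`` so that the gain at the cutoff is
    ``1/sqrt(2)``; edges are handled by reflection.
    """
    if cutoff_hz >= sample_rate_hz / 2.0:
        raise ValueError("cutoff must be below the Nyquist frequency")
    if cutoff_hz <= 0:
        raise ValueError("cutoff must be positive")
    sigma_f = cutoff_hz / np.sqrt(np.log(2.0))
    sigma_n = sample_rate_hz / (2.0 * np.pi * sigma_f)
    return gaussian_filter1d(np.asarray(signal, dtype=float), sigma_n,
                             mode="reflect", truncate=6.0)


def debias_positions(trace: MotionTrace, angles_deg: np.ndarray,
                     order: int = 4, learning_mask=None) -> MotionTrace:
    """Remove the projection-angle-dependent localization bias.

    Fits a Fourier series of order ``order`` in the spoke angle (mod 360)
    to x and y over the learning span and subtracts the angle-dependent
    part (the constant term, i.e. the true mean position, is retained).
    With insufficient angular coverage the trace is returned unchanged
    with a warning.
    """
    angles = np.asarray(angles_deg, dtype=float) % 360.0
    if learning_mask is None:
        learning_mask = np.ones(len(angles), dtype=bool)
    fit_mask = learning_mask & trace.valid
    n_par = 2 * order + 1
    coverage = np.ptp(np.sort(angles[fit_mask])) if np.any(fit_mask) else 0.0
    if np.sum(fit_mask) < 2 * n_par or coverage < 270.0:
        warnings.warn("insufficient angular coverage for angle-bias removal; "
                      "returning trace unchanged")
        return trace
    rho = np.deg2rad(angles)
    cols = [np.ones_like(rho)]
    for k in range(1, order + 1):
        cols += [np.cos(k * rho), np.sin(k * rho)]
    a = np.stack(cols, axis=1)
    out = replace(trace)
    for attr in ("x_mm", "y_mm"):
        v = getattr(trace, attr)
        coef, *_ = np.linalg.lstsq(a[fit_mask], v[fit_mask], rcond=None)
        coef[0] = 0.0  # keep the mean position
        setattr(out, attr, v - a @ coef)
    return out


def decompose_motion(trace: MotionTrace) -> dict[str, MotionTrace]:
    """Split a debiased raw trace into filtered/respiratory/cardiac variants.

    filtered = Gaussian low-pass at 0.883 Hz; respiratory = low-pass at
    0.377 Hz; cardiac = filtered - respiratory.  In-plane curves of all
    variants are mean-centered.
    """
    fs = trace.sample_rate_hz
    out: dict[str, MotionTrace] = {}
    x0, y0 = trace.x_mm - trace.x_mm.mean(), trace.y_mm - trace.y_mm.mean()
    filt = {a: gaussian_lowpass(v, 0.883, fs) for a, v in (("x", x0), ("y", y0))}
    resp = {a: gaussian_lowpass(v, 0.377, fs) for a, v in (("x", x0), ("y", y0))}
    z_f = gaussian_lowpass(trace.z_intensity, 0.883, fs)
    z_r = gaussian_lowpass(trace.z_intensity, 0.377, fs)

    def centered(v):
        return v - v.mean()

    out["filtered"] = MotionTrace(trace.times_s, centered(filt["x"]),
                                  centered(filt["y"]), z_f, "filtered",
                                  trace.valid.copy())
    out["respiratory"] = MotionTrace(trace.times_s, centered(resp["x"]),
                                     centered(resp["y"]), z_r, "respiratory",
                                     trace.valid.copy())
    out["cardiac"] = MotionTrace(trace.times_s,
                                 centered(filt["x"] - resp["x"]),
                                 centered(filt["y"] - resp["y"]),
                                 z_f - z_r, "cardiac", trace.valid.copy())
    return out


def track(k: RadialKspace, use_coils: str = "both",
          profile_sigma_px: float = 2.0,
          max_invalid_fraction: float = 0.20,
          learning_mask=None) -> dict[str, MotionTrace]:
    """Localize the micro-coils on every consecutive spoke pair.

    Returns the debiased ``raw`` trace plus the ``filtered``,
    ``respiratory`` and ``cardiac`` variants (time resolution 2 TR).
    ``use_coils`` selects ``proximal``, ``distal`` or ``both`` (positions
    averaged).  More than ``max_invalid_fraction`` invalid pairs raises an
    error advising a slice/channel check.
    """
    roles = {MICROCOIL_PROXIMAL: None, MICROCOIL_DISTAL: None}
    for i, r in enumerate(k.channel_roles):
        if r in roles:
            roles[r] = i
    wanted = {"both": [MICROCOIL_PROXIMAL, MICROCOIL_DISTAL],
              "proximal": [MICROCOIL_PROXIMAL],
              "distal": [MICROCOIL_DISTAL]}.get(use_coils)
    if wanted is None:
        raise ValueError(f"use_coils must be both|proximal|distal, got {use_coils!r}")
    channels = []
    for r in wanted:
        if roles[r] is None:
            raise ValueError(f"required micro-coil channel {r!r} not present")
        channels.append(roles[r])

    matrix = k.params.matrix_size
    fov = k.params.fov_mm
    n_pairs = k.n_spokes // 2
    times = np.empty(n_pairs)
    x = np.full(n_pairs, np.nan)
    y = np.full(n_pairs, np.nan)
    z = np.zeros(n_pairs)
    valid = np.zeros(n_pairs, dtype=bool)
    pair_angles = np.empty(n_pairs)

    for ip in range(n_pairs):
        s1, s2 = 2 * ip, 2 * ip + 1
        times[ip] = 0.5 * (k.times_s[s1] + k.times_s[s2])
        pair_angles[ip] = k.angles_deg[s1]
        pos_acc, z_acc, ok = [], [], True
        for ch in channels:
            ps, zs = [], []
            for s in (s1, s2):
                prof = coil_profile(k.data[s, :, ch], k.angles_deg[s], fov,
                                    matrix, spoke_index=s)
                p, inten = smooth_and_locate(prof, profile_sigma_px)
                if not prof.valid:
                    ok = False
                ps.append(p)
                zs.append(inten)
            if ok:
                sol = localize_pair(ps[0], ps[1], k.angles_deg[s1],
                                    k.angles_deg[s2])
                if sol is None:
                    ok = False
                else:
                    pos_acc.append(sol)
            z_acc.extend(zs)
        z[ip] = float(np.mean(z_acc)) if z_acc else 0.0
        if ok and pos_acc:
            x[ip] = float(np.mean([p[0] for p in pos_acc]))
            y[ip] = float(np.mean([p[1] for p in pos_acc]))
            valid[ip] = True

    frac_invalid = 1.0 - valid.mean()
    if frac_invalid > max_invalid_fraction:
        raise RuntimeError(
            f"{frac_invalid:.0%} of spoke pairs failed micro-coil localization; "
            "check the slice position and the tracking channel assignment")
    # invalid pairs are linearly interpolated in time before filtering
    for v in (x, y):
        bad = ~valid
        if bad.any():
            v[bad] = np.interp(times[bad], times[valid], v[valid])

    raw = MotionTrace(times, x, y, z, "raw", valid)
    pair_mask = None
    if learning_mask is not None:
        pair_mask = np.asarray(learning_mask)[::2][:n_pairs]
    raw = debias_positions(raw, pair_angles, learning_mask=pair_mask)
    out = {"raw": raw}
    out.update(decompose_motion(raw))
    return out


def select_projections(z_trace: MotionTrace, keep_fraction: float = 0.70,
                       smooth_sigma: float = 2.0) -> np.ndarray:
    """Per-spoke gating mask keeping the quietest fraction of the Z cycle.

    Computes the smoothed ``|dZ/dt|`` and keeps the ``keep_fraction`` of
    spoke pairs with the lowest values (earliest samples win ties); the
    mask has spoke granularity (each pair flag is repeated for both of its
    spokes).
    """
    if not 0.0 < keep_fraction <= 1.0:
        raise ValueError("keep_fraction must be in (0, 1]")
    z = np.asarray(z_trace.z_intensity, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("z_intensity must be finite")
    dz = np.abs(np.gradient(z, z_trace.times_s))
    if smooth_sigma > 0:
        dz = gaussian_filter1d(dz, smooth_sigma, mode="reflect")
    # flush numerical jitter so exact ties keep their acquisition order
    scale = np.ptp(z) / float(np.median(np.diff(z_trace.times_s)))
    if scale == 0.0:
        dz = np.zeros_like(dz)
    else:
        dz[dz <= 1e-9 * scale] = 0.0
    n_keep = int(np.ceil(keep_fraction * len(z)))
    order = np.argsort(dz, kind="stable")
    pair_mask = np.zeros(len(z), dtype=bool)
    pair_mask[order[:n_keep]] = True
    return np.repeat(pair_mask, 2)
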