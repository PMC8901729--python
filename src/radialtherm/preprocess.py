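"""Channel conditioning and per-spoke rigid 2D motion correction in k-space.

Imaging channels are noise pre-whitened and PCA-compressed (90% retained
variance by default); each projection is then motion-corrected with a
phase shift linear in the readout coordinate — the exact inverse of the
Fourier-shift phase the simulator applies, so a corrected spoke equals the
spoke a static (mean-position) object would have produced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .raw_io import RadialKspace, Trajectory
from .tracking import MotionTrace


@dataclass
class ChannelModel:
    """Noise covariance, whitening transform and PCA compression matrix."""

    covariance: np.ndarray
    whitener: np.ndarray
    compressor: np.ndarray | None = None
    retained_variance: float = 1.0

    @property
    def n_components(self) -> int:
        return (self.compressor.shape[1] if self.compressor is not None
                else self.whitener.shape[0])


def estimate_noise(k: RadialKspace, edge_fraction: float = 0.05) -> ChannelModel:
    """Estimate the imaging-channel noise covariance from object-free samples.

    Uses the outer ``edge_fraction`` of readout samples of all spokes
    (beyond the object's k-space support) averaged over spokes.  With fewer
    than 1e3 noise samples an identity covariance is returned with a
    warning.
    """
    data = k.imaging_data
    if data.shape[2] == 0:
        raise ValueError("no imaging channels present")
    r = data.shape[1]
    n_edge = max(1, int(round(0.5 * edge_fraction * r)))
    x = np.concatenate([data[:, :n_edge, :], data[:, -n_edge:, :]], axis=1)
    x = x.reshape(-1, data.shape[2])
    n_ch = x.shape[1]
    if x.shape[0] < 1000:
        warnings.warn("fewer than 1000 noise samples; using identity covariance")
        cov = np.eye(n_ch, dtype=complex)
    else:
        x = x - x.mean(axis=0)
        cov = (x.conj().T @ x) / (x.shape[0] - 1)
    # noiseless data: edge covariance is negligible against the signal;
    # whitening falls back to the identity
    center = data[:, data.shape[1] // 2, :]
    signal_rms = float(np.sqrt(np.mean(np.abs(center) ** 2)))
    if np.sqrt(np.abs(np.diag(cov)).max()) < 1e-8 * max(signal_rms, 1e-300):
        return ChannelModel(covariance=cov,
                            whitener=np.eye(n_ch, dtype=complex))
    return ChannelModel(covariance=cov, whitener=_whitener_from_cov(cov))


def _whitener_from_cov(cov: np.ndarray) -> np.ndarray:
    """Inverse Cholesky factor; identity fallback for (near) zero covariance."""
    scale = float(np.max(np.abs(np.diag(cov)).real, initial=0.0))
    if scale <= 0 or not np.all(np.isfinite(cov)):
        return np.eye(cov.shape[0], dtype=complex)
    try:
        chol = np.linalg.cholesky(cov)
        return np.linalg.inv(chol)
    except np.linalg.LinAlgError:
        return np.eye(cov.shape[0], dtype=complex)


def prewhiten(k: RadialKspace, model: ChannelModel | None = None) -> RadialKspace:
    """Apply the whitening transform to the imaging channels.

    Micro-coil channels pass through untouched.  Re-estimating the model on
    the whitened output yields an identity whitener (idempotence).
    """
    if model is None:
        model = estimate_noise(k)
    img_idx = k.imaging_idx
    if len(img_idx) <= 1:
        return k
    data = k.data.copy()
    # samples in rows: y = x @ W^H makes the sample covariance identity
    data[:, :, img_idx] = k.imaging_data @ model.whitener.conj().T
    return k.replace_data(data)


def compress(k: RadialKspace, variance_threshold: float = 0.90,
             model: ChannelModel | None = None
             ) -> tuple[RadialKspace, np.ndarray]:
    """Project imaging channels onto leading principal components.

    Retains the smallest number of components whose cumulative variance
    reaches ``variance_threshold``; returns the compressed container and
    the (n_ch, n_comp) projection matrix so the same compression can be
    applied to later data.
    """
    if not 0.0 < variance_threshold <= 1.0:
        raise ValueError("variance_threshold must be in (0, 1]")
    img = k.imaging_data
    n_ch = img.shape[2]
    if n_ch <= 1:
        return k, np.eye(max(n_ch, 1), dtype=complex)
    x = img.reshape(-1, n_ch)
    c = (x.conj().T @ x) / x.shape[0]
    evals, evecs = np.linalg.eigh(c)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    cum = np.cumsum(evals) / np.sum(evals)
    n_comp = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
    if variance_threshold >= 1.0:
        n_comp = n_ch
    v = evecs[:, :n_comp]
    compressed = x @ v.conj()
    out_data = np.concatenate(
        [compressed.reshape(img.shape[0], img.shape[1], n_comp),
         k.data[:, :, k.microcoil_idx]], axis=2)
    roles = (["imaging"] * n_comp
             + [k.channel_roles[i] for i in k.microcoil_idx])
    return k.replace_data(out_data, roles), v


def prewhiten_and_compress(k: RadialKspace, model: ChannelModel | None = None,
                           variance_threshold: float = 0.90
                           ) -> tuple[RadialKspace, ChannelModel]:
    """Pre-whitening followed by PCA coil compression (micro-coils excluded)."""
    if model is None:
        model = estimate_noise(k)
    white = prewhiten(k, model)
    out, v = compress(white, variance_threshold)
    full = ChannelModel(covariance=model.covariance, whitener=model.whitener,
                        compressor=v, retained_variance=variance_threshold)
    return out, full


def apply_channel_model(k: RadialKspace, model: ChannelModel) -> RadialKspace:
    """Apply a previously fitted whitening + compression to new spokes."""
    white = prewhiten(k, model)
    img = white.imaging_data
    v = model.compressor
    if v is None or len(white.imaging_idx) <= 1:
        return white
    compressed = img.reshape(-1, img.shape[2]) @ v.conj()
    n_comp = v.shape[1]
    out_data = np.concatenate(
        [compressed.reshape(img.shape[0], img.shape[1], n_comp),
         white.data[:, :, white.microcoil_idx]], axis=2)
    roles = (["imaging"] * n_comp
             + [white.channel_roles[i] for i in white.microcoil_idx])
    return white.replace_data(out_data, roles)


def correct_spoke(spoke: np.ndarray, radii: np.ndarray, angle_deg: float,
                  dx_mm: float, dy_mm: float, fov_mm: float) -> np.ndarray:
    """Motion-correct one spoke by the k-space phase ramp.

    ``out(k_r) = in(k_r) * exp(+i 2 pi k_r (dx cos rho + dy sin rho)/FoV)``
    with ``k_r`` in cycles/FoV and displacements in millimetres relative to
    the mean position.  NaN displacements pass the spoke through unchanged.
    """
    if not (np.isfinite(dx_mm) and np.isfinite(dy_mm)):
        return np.asarray(spoke).copy()
    rho = np.deg2rad(angle_deg % 360.0)
    shift = dx_mm * np.cos(rho) + dy_mm * np.sin(rho)
    ramp = np.exp(2j * np.pi * radii * shift / fov_mm)
    spoke = np.asarray(spoke)
    return spoke * (ramp if spoke.ndim == 1 else ramp[:, None])


def displacement_per_spoke(k: RadialKspace, trace: MotionTrace,
                           mean_span_s: tuple[float, float] | None = None,
                           interpolate: bool = False
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Per-spoke (dx, dy) from a per-pair trace, mean position subtracted.

    By default both spokes of a pair receive the pair's displacement;
    ``interpolate=True`` uses linear interpolation in time instead.  The
    mean is taken over ``mean_span_s`` (e.g. the learning phase) or the
    whole trace.
    """
    t0, t1 = trace.times_s[0], trace.times_s[-1]
    dt = float(np.median(np.diff(trace.times_s)))
    if k.times_s[0] < t0 - dt or k.times_s[-1] > t1 + dt:
        raise ValueError("motion trace does not cover the acquisition span")
    if mean_span_s is None:
        mx, my = trace.x_mm.mean(), trace.y_mm.mean()
    else:
        m = (trace.times_s >= mean_span_s[0]) & (trace.times_s <= mean_span_s[1])
        if not m.any():
            raise ValueError("mean_span_s selects no trace samples")
        mx, my = trace.x_mm[m].mean(), trace.y_mm[m].mean()
    if interpolate:
        dx = np.interp(k.times_s, trace.times_s, trace.x_mm) - mx
        dy = np.interp(k.times_s, trace.times_s, trace.y_mm) - my
    else:
        idx = np.clip(np.searchsorted(trace.times_s, k.times_s) , 0,
                      len(trace.times_s) - 1)
        # snap to the pair whose midpoint is nearest
        left = np.clip(idx - 1, 0, None)
        use_left = (np.abs(k.times_s - trace.times_s[left])
                    <= np.abs(trace.times_s[idx] - k.times_s))
        idx = np.where(use_left, left, idx)
        dx = trace.x_mm[idx] - mx
        dy = trace.y_mm[idx] - my
    return dx, dy


def correct_all(k: RadialKspace, trace: MotionTrace,
                mean_span_s: tuple[float, float] | None = None,
                interpolate: bool = False) -> RadialKspace:
    """Apply the per-spoke phase-ramp correction to every imaging channel."""
    dx, dy = displacement_per_spoke(k, trace, mean_span_s, interpolate)
    traj = k.trajectory()
    radii = traj.radii
    cos, sin = traj.directions()
    shift = dx * cos + dy * sin
    ramp = np.exp(2j * np.pi * np.outer(shift, radii) / k.params.fov_mm)
    data = k.data.copy()
    img_idx = k.imaging_idx
    data[:, :, img_idx] = data[:, :, img_idx] * ramp[:, :, None]
    return k.replace_data(data)
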