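"""Direct temperature estimation from undersampled radial k-space.

The per-frame signal model combines multibaseline and referenceless
phase correction: at image voxel j,

    y_j = (sum_b x_{b,j} w_b) * exp(i ({A c}_j + theta_j)) + eps_j

where x_b are motion-binned complex baseline images, w the baseline
weights, A an orthonormal low-order polynomial basis with coefficients c
(B0 drift / residual smooth phase), and theta the temperature-induced
phase.  For undersampled frames the model is fitted *directly in k-space*:

    minimize  1/2 sum_ch || y_ch - E[(B_ch w) o e^{i(Ac+theta)}] ||^2
              + lambda ||theta||_1 + beta theta^T D^T D theta

with E the radial Fourier sampling operator of the window's spokes and D
second-order finite differences along both axes.  The regularization
weights are dimensionless: E is normalized to unit spectral norm and the
library stack to unit RMS magnitude over the object mask, so the
per-resolution defaults (lambda, beta) transfer across scenes.

The solver is a majorize-minimize scheme: with the density-compensated
operator normalized to unit spectral norm, each outer iteration forms the
Landweber surrogate image and solves an image-domain subproblem on it —
w by (nonnegative) linear least squares, c by weighted polynomial
regression with the heated neighbourhood excluded, and theta by damped
incremental-phase proximal steps with the heating-sign constraint.  An
unregularized warm-up pass first builds data consistency and estimates
the per-voxel phase-noise scale (lambda thresholds in units of that
scale, referenced to Nyquist sampling); a final pass refits theta on its
detected support without the penalties.  See docs/methods.md.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy.optimize import nnls
from scipy.signal import butter, filtfilt

from .library import BaselineLibrary, PolynomialBasis
from .nufft import RadialDFT
from .raw_io import AcquisitionParams, RadialKspace, Trajectory
from .simulate import prf_rad_per_degC

_LAMBDA_TABLE = {1.0: 0.1, 2.0: 0.2, 3.0: 0.5}


def default_regularization(resolution_mm: float) -> tuple[float, float]:
    """Per-resolution default (lambda, beta): (0.1, 0.05) at 1 mm,
    (0.2, 0.05) at 2 mm, (0.5, 0.05) at 3 mm (nearest resolution)."""
    key = min(_LAMBDA_TABLE, key=lambda r: abs(r - resolution_mm))
    return _LAMBDA_TABLE[key], 0.05


@dataclass
class FitConfig:
    """Tunable parameters of the k-space temperature fit."""

    lambda_sparsity: float = 0.5
    beta_roughness: float = 0.05
    window_spokes: int = 40
    stride_spokes: int | None = None
    max_iter: int = 40
    warmup_iters: int = 10       # lambda-continuation: l1 off while data
                                 # consistency builds up
    debias_iters: int = 8        # final pass: refit theta on its detected
                                 # support without the l1 shrinkage
    tol: float = 1e-3
    init: str = "cold"           # "cold": theta=0, uniform w, c=0 per frame
                                 # "warm": carry w and c from the previous frame
    enforce_sign: bool = True    # heating phase sign fixed by the PRF constant
    w_nonneg: bool = True
    w_update_every: int = 1
    theta_drift_mask_rad: float = 0.10
    #: sign of the heating-induced phase 2 pi gamma B0 alpha TE (negative
    #: for the conventional alpha < 0)
    heating_phase_sign: float = -1.0

    def __post_init__(self) -> None:
        if self.lambda_sparsity < 0 or self.beta_roughness < 0:
            raise ValueError("regularization weights must be >= 0")
        if self.window_spokes < 1:
            raise ValueError("window_spokes must be >= 1")
        if self.stride_spokes is not None and self.stride_spokes < 1:
            raise ValueError("stride_spokes must be >= 1")


@dataclass
class FitResult:
    w: np.ndarray
    c: np.ndarray
    theta: np.ndarray
    converged: bool
    n_iter: int
    residual_norm: float


@dataclass
class TemperatureSeries:
    """Per-frame phase and temperature maps with frame provenance."""

    times_s: np.ndarray
    theta: np.ndarray            # [n_frames, N, N] radians
    delta_t: np.ndarray          # [n_frames, N, N] degC
    window_spokes: int
    stride_spokes: int
    w: np.ndarray | None = None
    c: np.ndarray | None = None
    converged: np.ndarray | None = None
    spoke_start: np.ndarray | None = None

    @property
    def n_frames(self) -> int:
        return len(self.times_s)

    @property
    def frame_spacing_s(self) -> float:
        if self.n_frames < 2:
            return float("nan")
        return float(np.median(np.diff(self.times_s)))


@dataclass
class RoiStats:
    """Temperature uncertainty over an unheated ROI.

    Mean and SD (over ROI voxels) of the per-voxel temporal standard
    deviation of temperature, evaluated strictly after the training period
    and before heating onset.
    """

    mask: np.ndarray
    mean_degC: float
    sd_degC: float
    per_voxel_sd: np.ndarray
    n_frames: int


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def phase_to_temperature(theta: np.ndarray,
                         params: AcquisitionParams) -> np.ndarray:
    """Convert the fitted phase map to degC via the PRF constant.

    ``dT = theta / (2 pi gamma B0 alpha 1e-6 TE)``; with the conventional
    negative alpha, heating (negative phase at positive TE) maps to
    positive temperature change.
    """
    if params.prf_alpha_ppm_per_degC == 0:
        raise ValueError("PRF coefficient alpha must be non-zero")
    return np.asarray(theta) / prf_rad_per_degC(params)


def _roughness_grad(theta: np.ndarray) -> np.ndarray:
    """Gradient of ``theta^T D^T D theta`` (without the beta factor),
    D = second-order finite differences along each axis."""
    out = np.zeros_like(theta)
    for axis in range(2):
        d2 = np.diff(theta, 2, axis=axis)
        sl = [slice(None)] * 2

        def seg(a, b):
            s = list(sl)
            s[axis] = slice(a, b)
            return tuple(s)

        out[seg(0, -2)] += d2
        out[seg(1, -1)] -= 2 * d2
        out[seg(2, None)] += d2
    return 2.0 * out


def _heat_exclusion(theta: np.ndarray, theta0: float,
                    n_dilate: int = 3) -> np.ndarray:
    """Soft weight excluding the heated neighbourhood from the drift fit.

    Voxels within ``n_dilate`` pixels of the current theta support (plus a
    smooth per-voxel attenuation) do not inform the polynomial background,
    so the compact heating spot cannot leak into the drift estimate.
    """
    hot = np.abs(theta) > theta0
    if hot.any():
        for _ in range(n_dilate):
            hot = _dilate(hot)
    return np.exp(-(theta / theta0) ** 2) * (~hot)


def _dilate(mask: np.ndarray) -> np.ndarray:
    """Binary dilation by one pixel (4-neighbourhood)."""
    out = mask.copy()
    out[1:, :] |= mask[:-1, :]
    out[:-1, :] |= mask[1:, :]
    out[:, 1:] |= mask[:, :-1]
    out[:, :-1] |= mask[:, 1:]
    return out


def _solve_w(cols: np.ndarray, y: np.ndarray, nonneg: bool) -> np.ndarray:
    """Least squares for the real baseline weights of complex columns."""
    a = np.concatenate([cols.real, cols.imag], axis=0)
    b = np.concatenate([y.real, y.imag], axis=0)
    if nonneg:
        w, _ = nnls(a, b)
    else:
        w, *_ = np.linalg.lstsq(a, b, rcond=None)
    if w.sum() <= 0:
        w = np.ones(cols.shape[1]) / cols.shape[1]
    return w


# ---------------------------------------------------------------------------
# image-domain reference fit
# ---------------------------------------------------------------------------

def image_domain_fit(y_img: np.ndarray, library: BaselineLibrary,
                     basis: PolynomialBasis, max_iter: int = 25,
                     tol: float = 1e-6, w_nonneg: bool = True,
                     theta_drift_mask_rad: float = 0.10) -> FitResult:
    """Voxelwise reference fit of the multibaseline/referenceless model.

    Requires a fully sampled complex frame image (single channel).
    Alternates (i) baseline weights by linear least squares, (ii) the
    polynomial coefficients by weighted phase regression with the current
    theta support excluded, (iii) theta as the voxelwise phase residual.
    Serves as the brute-force oracle for :func:`kspace_fit` on fully
    sampled data.
    """
    y = np.asarray(y_img)
    n = library.matrix_size
    if y.shape != (n, n):
        raise ValueError("frame image shape does not match the library")
    b = library.images[..., 0] if library.images.ndim == 4 else library.images
    bflat = b.reshape(library.n_bins, -1).T      # [npix, n_bins]
    if not np.any(np.abs(bflat) > 0):
        raise ValueError("library images are all zero")
    yflat = y.ravel()
    mask = basis.mask.ravel()
    a = basis.columns

    theta = np.zeros(n * n)
    c = np.zeros(a.shape[1])
    w = np.ones(library.n_bins) / library.n_bins
    for it in range(max_iter):
        phase = np.exp(1j * (a @ c + theta))
        w = _solve_w(bflat * phase[:, None], yflat, w_nonneg)
        m = bflat @ w
        psi = np.angle(yflat * np.conj(m))
        weight = (np.abs(m) ** 2) * mask
        drift_sel = weight * _heat_exclusion(theta.reshape(n, n),
                                             theta_drift_mask_rad).ravel()
        aw = a * drift_sel[:, None]
        c_new, *_ = np.linalg.lstsq(aw.T @ a, aw.T @ psi, rcond=None)
        theta_new = (psi - a @ c_new) * mask
        dmax = np.max(np.abs(theta_new - theta))
        theta, c = theta_new, c_new
        if dmax < tol and it >= 2:
            break
    resid = float(np.linalg.norm(yflat - (bflat @ w) * np.exp(1j * (a @ c + theta))))
    return FitResult(w=w, c=c, theta=theta.reshape(n, n), converged=True,
                     n_iter=it + 1, residual_norm=resid)


# ---------------------------------------------------------------------------
# direct k-space fit
# ---------------------------------------------------------------------------

def kspace_fit(window: np.ndarray, traj: Trajectory, library: BaselineLibrary,
               basis: PolynomialBasis, config: FitConfig,
               init: FitResult | None = None,
               operator: RadialDFT | None = None,
               spectral_norm: float | None = None) -> FitResult:
    """Fit (w, c, theta) directly to one window of undersampled spokes.

    ``window`` is ``[n_spokes, n_readout]`` or ``[..., n_channels]`` of
    motion-corrected imaging-channel samples matching the library's
    channels and matrix size.
    """
    y = np.asarray(window)
    if y.ndim == 2:
        y = y[:, :, None]
    n = library.matrix_size
    npix = n * n
    b = library.images
    if b.ndim == 3:
        b = b[..., None]
    n_bins, _, _, n_ch = b.shape
    if y.shape[2] != n_ch:
        raise ValueError("window channel count does not match the library")
    if not np.any(np.abs(b) > 0):
        raise ValueError("library images are all zero")

    op = operator if operator is not None else RadialDFT(traj)
    # density-compensation preconditioning: fit || W^1/2 (y - E u) ||^2 with
    # ramp weights W = dcf/N^2, which makes E^H W E approximately the
    # identity, so Jacobi (per-voxel) steps converge quickly and the
    # k-space fixed point matches the image-domain fit
    from .recon import density_compensation

    wsqrt = np.sqrt(density_compensation(traj) / npix)
    if spectral_norm is None:
        s = _weighted_spectral_norm(op, wsqrt, n)
    else:
        s = spectral_norm

    mask2d = basis.mask
    maskf = mask2d.ravel()
    gamma = float(np.sqrt(np.mean(
        np.abs(b.reshape(n_bins, npix, n_ch)[:, maskf, :]) ** 2)))
    if gamma <= 0:
        raise ValueError("library has no signal inside the mask")
    bhat = (b / gamma).reshape(n_bins, npix, n_ch)
    yhat = y / (s * gamma)
    a = basis.columns
    lam, beta = config.lambda_sparsity, config.beta_roughness

    # theta always starts at zero (fresh support detection per frame);
    # warm starts carry over only the drift coefficients and bin weights
    theta = np.zeros(npix)
    c = np.zeros(a.shape[1])
    w = np.ones(n_bins) / n_bins
    if init is not None and config.init == "warm":
        c = init.c.copy()
        w = init.w.copy()

    heat_sign = config.heating_phase_sign

    def fwd(img_flat_ch):
        return op.forward(img_flat_ch.reshape(n, n, n_ch)) * wsqrt[:, :, None] / s

    def adj(res):
        return op.adjoint(res * wsqrt[:, :, None]).reshape(npix, n_ch) / s

    yhat = yhat * wsqrt[:, :, None]

    converged = False
    resid_norm = np.inf
    m = np.tensordot(w, bhat, axes=(0, 0))           # [npix, n_ch]
    support = None
    # phase schedule: lambda-continuation warm-up (l1 off while the
    # Landweber surrogate builds data consistency), main l1 phase selecting
    # the theta support, then a debiasing pass with theta restricted to the
    # detected support (each phase runs to tolerance or its iteration cap)
    phases = []
    if lam > 0:
        phases.append(("warmup", max(config.warmup_iters, config.max_iter),
                       0.0, beta))
        phases.append(("main", config.max_iter, lam, beta))
        if config.debias_iters > 0:
            # pure data refit on the detected support: both penalties off so
            # the l1 shrinkage and roughness flattening do not bias the peak
            phases.append(("debias", max(config.debias_iters, config.max_iter),
                           0.0, 0.0))
    else:
        phases.append(("main", config.max_iter, 0.0, beta))
    it_total = 0
    sigma_theta = None   # per-voxel phase-noise scale, set after warm-up
    for phase_name, n_iter, lam_eff, beta_eff in phases:
        if phase_name == "debias":
            # refit only the confidently heated support; the sub-threshold
            # background keeps its regularized estimate
            level = 3.0 * sigma_theta if sigma_theta is not None else 0.0
            support = np.abs(theta) > level
            if not support.any():
                break
            sup2d = support.reshape(n, n)
            for _ in range(3):
                sup2d = _dilate(sup2d)
            support = sup2d.ravel() & (maskf > 0)
            theta_frozen = theta.copy()
        for it in range(1, n_iter + 1):
            it_total += 1
            phase = np.exp(1j * (a @ c + theta))
            u = m * phase[:, None]
            # majorize-minimize: with ||E_hat|| <= 1 the data term is
            # majorized at u by 1/2 ||v - q||^2, q the Landweber surrogate
            r = fwd(u) - yhat
            resid_norm = float(np.linalg.norm(r))
            q = u - adj(r)
            theta_prev = theta
            # image-domain subproblem on q: weights, drift polynomial, theta
            if (it - 1) % config.w_update_every == 0:
                sel = maskf
                cols = (bhat[:, sel, :] * phase[sel, None]).reshape(n_bins, -1).T
                w = _solve_w(cols, q[sel].ravel(), config.w_nonneg)
                m = np.tensordot(w, bhat, axes=(0, 0))
            # incremental phase relative to the current model: immune to
            # +-pi wrapping of the accumulated heating + background phase.
            # Coherence damping keeps noise-dominated voxels from phase
            # random-walking across iterations.
            cross = np.sum(q * np.conj(m * phase[:, None]), axis=1)
            coh = np.abs(cross) / (np.sum(np.abs(q) * np.abs(m), axis=1) + 1e-30)
            weight = np.sum(np.abs(m) ** 2, axis=1) * maskf
            # low-signal voxels carry noise-dominated phase: damp their
            # increments (and cap each step at pi/2) so they cannot wander
            snr_damp = weight / (weight + 0.02 * weight.max())
            delta = np.clip(np.angle(cross), -np.pi / 2, np.pi / 2) \
                * np.minimum(coh, 1.0) * snr_damp
            psi = (a @ c + theta) + delta
            # exclude the heated neighbourhood from the drift fit; if the
            # exclusion swallows the object (small matrices, wide heating),
            # keep the previous drift estimate instead of an unstable solve
            drift_sel = weight * _heat_exclusion(
                theta.reshape(n, n), config.theta_drift_mask_rad).ravel()
            if drift_sel.sum() > 0.02 * weight.sum():
                aw = a * drift_sel[:, None]
                ata = aw.T @ a
                ata += np.eye(ata.shape[0]) * (1e-8 * np.trace(ata).real
                                               + 1e-30)
                c = np.linalg.solve(ata, aw.T @ psi)
            # theta: proximal steps on the diagonal surrogate quadratic
            target = (psi - a @ c) * maskf
            # 32 = spectral bound of D^T D (16 per axis), not just its
            # diagonal; the weight floor keeps dim voxels quasi-static
            tau = 1.0 / (weight + 2.0 * beta_eff * 32.0 + 2e-3 * weight.max())
            for _ in range(4):
                grad = weight * (theta - target) + 2.0 * beta_eff * _roughness_grad(
                    theta.reshape(n, n)).ravel() * maskf
                t_new = theta - tau * grad
                if lam_eff > 0 and sigma_theta is not None:
                    thr = tau * lam_eff * sigma_theta * weight
                    t_new = np.sign(t_new) * np.maximum(np.abs(t_new) - thr, 0.0)
                if config.enforce_sign:
                    t_new = np.minimum(t_new, 0.0) if heat_sign < 0 \
                        else np.maximum(t_new, 0.0)
                t_new = t_new * maskf
                if support is not None:
                    # refit on the support, freeze the regularized background
                    t_new = np.where(support, t_new, theta_frozen)
                # generous safety bound (~80 degC at the default constants)
                theta = np.clip(t_new, -2 * np.pi, 2 * np.pi)
            dmax = float(np.max(np.abs(theta - theta_prev)))
            if dmax < config.tol and it >= 3:
                converged = True
                break
        else:
            converged = False
        if phase_name == "warmup":
            # per-voxel phase-noise scale from the unregularized residual
            # phase of the unheated region: sigma_theta_j = kappa/|m_j|.
            # lambda then acts as a threshold in units of the local noise.
            resid_phase = target - theta
            sel = drift_sel > 0.25 * np.median(drift_sel[maskf > 0])
            kappa = 1.4826 * float(np.median(
                np.abs(resid_phase[sel]) * np.sqrt(weight[sel]))) if sel.any() \
                else 0.0
            # reference the scale to Nyquist sampling: the threshold is then
            # fixed in radians for a given resolution and noise level, so
            # stronger undersampling raises the background SD (not the
            # threshold)
            nyquist = np.pi / 2.0 * n
            kappa *= min(np.sqrt(y.shape[0] / nyquist), 1.0)
            kappa = max(kappa, 1e-6)
            sigma_theta = kappa / np.sqrt(np.maximum(weight, 1e-12 * weight.max()))
    it = it_total
    return FitResult(w=w, c=c, theta=theta.reshape(n, n), converged=converged,
                     n_iter=it, residual_norm=resid_norm)


def _weighted_spectral_norm(op: RadialDFT, wsqrt: np.ndarray, n: int,
                            n_iter: int = 10) -> float:
    """Largest singular value of the weighted operator ``W^1/2 E``."""
    rng = np.random.default_rng(0)
    x = (rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n)))
    s = 1.0
    for _ in range(n_iter):
        x = op.adjoint(op.forward(x) * wsqrt ** 2)
        s = np.linalg.norm(x)
        x = x / s
    return float(np.sqrt(s))


# ---------------------------------------------------------------------------
# series
# ---------------------------------------------------------------------------

def run_series(k_corr: RadialKspace, library: BaselineLibrary,
               basis: PolynomialBasis, config: FitConfig,
               start_spoke: int = 0,
               max_frames: int | None = None) -> TemperatureSeries:
    """Fit consecutive windows of spokes and convert to temperature maps.

    Windows of ``config.window_spokes`` spokes advance by
    ``config.stride_spokes`` (default: the window length, i.e.
    non-overlapping frames); fitting starts at ``start_spoke`` (first spoke
    after the learning span).  Stops cleanly when fewer than a full window
    remains.
    """
    stride = config.stride_spokes or config.window_spokes
    win = config.window_spokes
    n = library.matrix_size
    params = k_corr.params

    starts = list(range(start_spoke, k_corr.n_spokes - win + 1, stride))
    if max_frames is not None:
        starts = starts[:max_frames]
    if not starts:
        return TemperatureSeries(np.empty(0), np.empty((0, n, n)),
                                 np.empty((0, n, n)), win, stride)

    # golden-angle windows share their spectral norm to high accuracy;
    # estimate it once on the first window
    from .recon import density_compensation

    first_traj = k_corr.subset(np.arange(starts[0], starts[0] + win)).trajectory(n)
    wsqrt0 = np.sqrt(density_compensation(first_traj) / n ** 2)
    snorm = _weighted_spectral_norm(RadialDFT(first_traj), wsqrt0, n)

    thetas, dts, times, ws, cs, conv = [], [], [], [], [], []
    prev: FitResult | None = None
    for s0 in starts:
        idx = np.arange(s0, s0 + win)
        sub = k_corr.subset(idx)
        traj = sub.trajectory(n)
        res = kspace_fit(sub.imaging_data, traj, library, basis, config,
                         init=prev, spectral_norm=snorm)
        prev = res
        thetas.append(res.theta)
        dts.append(phase_to_temperature(res.theta, params))
        times.append(float(np.mean(sub.times_s)))
        ws.append(res.w)
        cs.append(res.c)
        conv.append(res.converged)
    return TemperatureSeries(
        times_s=np.asarray(times), theta=np.stack(thetas),
        delta_t=np.stack(dts), window_spokes=win, stride_spokes=stride,
        w=np.stack(ws), c=np.stack(cs), converged=np.asarray(conv),
        spoke_start=np.asarray(starts))


def temporal_filter(series: TemperatureSeries, cutoff_hz: float = 0.14,
                    order: int = 4) -> TemperatureSeries:
    """Zero-phase (forward-backward) Butterworth low-pass per voxel."""
    if series.n_frames < 2:
        return series
    fs = 1.0 / series.frame_spacing_s
    if cutoff_hz >= fs / 2.0:
        raise ValueError("cutoff must be below the frame Nyquist frequency")
    sos_b, sos_a = butter(order, cutoff_hz, fs=fs)
    padlen = min(3 * max(len(sos_a), len(sos_b)), series.n_frames - 1)
    dt = filtfilt(sos_b, sos_a, series.delta_t, axis=0, padlen=padlen)
    th = filtfilt(sos_b, sos_a, series.theta, axis=0, padlen=padlen)
    return dataclasses.replace(series, delta_t=dt, theta=th)


def roi_uncertainty(series: TemperatureSeries, roi: np.ndarray,
                    training_end_s: float, heating_start_s: float) -> RoiStats:
    """Temperature uncertainty: mean +/- SD over the ROI of the per-voxel
    temporal SD, over frames after training and before heating."""
    roi = np.asarray(roi, dtype=bool)
    sel = (series.times_s > training_end_s) & (series.times_s < heating_start_s)
    if np.sum(sel) < 2:
        raise ValueError("fewer than two frames between training end and "
                         "heating start")
    stack = series.delta_t[sel]
    per_voxel = np.std(stack, axis=0, ddof=1)
    vals = per_voxel[roi]
    return RoiStats(mask=roi, mean_degC=float(np.mean(vals)),
                    sd_degC=float(np.std(vals)), per_voxel_sd=per_voxel,
                    n_frames=int(np.sum(sel)))


def save_series(series: TemperatureSeries, path) -> None:
    with h5py.File(path, "a") as f:
        if "temperature" in f:
            del f["temperature"]
        g = f.create_group("temperature")
        g.create_dataset("times_s", data=series.times_s)
        g.create_dataset("theta", data=series.theta)
        g.create_dataset("delta_t", data=series.delta_t)
        g.attrs["window_spokes"] = series.window_spokes
        g.attrs["stride_spokes"] = series.stride_spokes
        if series.w is not None:
            g.create_dataset("w", data=series.w)
        if series.c is not None:
            g.create_dataset("c", data=series.c)
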