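"""Motion-state multibaseline library and polynomial background basis.

Before heating, a learning phase sorts the motion-corrected spokes into
motion-state bins (10 amplitude bins of the drive curve for the phantom
setting; 3 cardiac x 8 respiratory phases for the in-vivo-like setting)
and reconstructs one complex baseline image per bin and channel.  A
6th-order 2D polynomial basis, orthonormalized over the object mask,
absorbs B0 drift and residual smooth background phase during fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
from scipy.signal import find_peaks

from .raw_io import RadialKspace
from .recon import nufft_adjoint


@dataclass
class BaselineLibrary:
    """Motion-binned complex baseline images.

    ``images`` is ``[n_bins, N, N, n_channels]``; ``counts`` holds the
    spokes per bin; ``spoke_indices`` maps each bin back to the learning
    spokes it was reconstructed from.
    """

    images: np.ndarray
    counts: np.ndarray
    spoke_indices: list[np.ndarray]
    matrix_size: int
    fov_mm: float
    bin_description: str = ""

    @property
    def n_bins(self) -> int:
        return self.images.shape[0]

    def mean_image(self) -> np.ndarray:
        """Count-weighted mean baseline (per channel)."""
        w = self.counts / self.counts.sum()
        return np.tensordot(w, self.images, axes=(0, 0))

    def object_mask(self, rel_threshold: float = 0.10) -> np.ndarray:
        sos = np.sqrt(np.sum(np.abs(self.mean_image()) ** 2, axis=-1))
        return sos > rel_threshold * sos.max()


@dataclass
class PolynomialBasis:
    """Orthonormal low-order 2D polynomial basis over an image mask.

    ``columns`` is ``[n_pixels, n_cols]`` over the full (flattened) grid,
    zero outside the mask and orthonormal with respect to the masked inner
    product.
    """

    columns: np.ndarray
    mask: np.ndarray
    order: int

    @property
    def n_cols(self) -> int:
        return self.columns.shape[1]

    def phase_map(self, c: np.ndarray) -> np.ndarray:
        n = self.mask.shape[0]
        return (self.columns @ c).reshape(n, n)


def assign_bins_1d(curve: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Equal-count quantile bins of a per-spoke displacement curve.

    Per-bin counts differ by at most one; labels are monotone in the curve
    value.  A (near-)constant curve cannot define motion states and raises
    with a hint to reduce ``n_bins``.
    """
    curve = np.asarray(curve, dtype=float)
    n = len(curve)
    if n_bins > n:
        raise ValueError(f"n_bins={n_bins} exceeds the {n} available spokes")
    if not np.all(np.isfinite(curve)):
        raise ValueError("curve must be finite over the learning span")
    scale = max(np.ptp(curve), 0.0)
    if n_bins > 1 and scale <= 1e-9 * max(1.0, np.max(np.abs(curve))):
        raise ValueError("displacement curve is constant: all spokes fall in "
                         "one motion state; reduce n_bins to 1")
    ranks = np.empty(n, dtype=int)
    ranks[np.argsort(curve, kind="stable")] = np.arange(n)
    return (ranks * n_bins) // n


def assign_bins_2d(resp_curve: np.ndarray, cardiac_signal: np.ndarray,
                   times_s: np.ndarray, n_resp: int = 8, n_card: int = 3
                   ) -> np.ndarray:
    """Joint respiratory-amplitude x cardiac-phase bin labels.

    Respiratory label: quantile bin of the respiratory displacement
    (``n_resp`` levels).  Cardiac label: phase within the cardiac cycle
    (cycle boundaries from the peaks of the cardiac signal) split into
    ``n_card`` tertiles.  Joint label = ``resp * n_card + card``.
    """
    resp_curve = np.asarray(resp_curve, dtype=float)
    cardiac = np.asarray(cardiac_signal, dtype=float)
    times = np.asarray(times_s, dtype=float)
    if not (len(resp_curve) == len(cardiac) == len(times)):
        raise ValueError("curves must be defined per spoke")
    resp_label = assign_bins_1d(resp_curve, n_resp)

    std = np.std(cardiac)
    if std <= 1e-12:
        raise ValueError("cardiac signal has no detectable peaks; "
                         "fall back to 1D amplitude binning")
    # dominant period from the spectrum bounds the peak spacing
    dt = float(np.median(np.diff(times)))
    spec = np.abs(np.fft.rfft(cardiac - cardiac.mean()))
    freqs = np.fft.rfftfreq(len(cardiac), dt)
    f0 = freqs[np.argmax(spec[1:]) + 1]
    if f0 <= 0:
        raise ValueError("cardiac signal has no detectable periodicity; "
                         "fall back to 1D amplitude binning")
    distance = max(1, int(0.6 / f0 / dt))
    peaks, _ = find_peaks(cardiac, distance=distance, prominence=0.5 * std)
    if len(peaks) < 2:
        raise ValueError("fewer than two cardiac peaks detected; "
                         "fall back to 1D amplitude binning")
    peak_t = times[peaks]
    period = float(np.median(np.diff(peak_t)))
    # phase in [0,1): linear between peaks, extrapolated with the median period
    phase = np.empty(len(times))
    idx = np.searchsorted(peak_t, times, side="right") - 1
    before = idx < 0
    after = idx >= len(peak_t) - 1
    mid = ~(before | after)
    phase[mid] = ((times[mid] - peak_t[idx[mid]])
                  / (peak_t[idx[mid] + 1] - peak_t[idx[mid]]))
    phase[before] = ((times[before] - (peak_t[0] - period)) / period)
    phase[after] = (times[after] - peak_t[idx[after]]) / period
    phase = np.mod(phase, 1.0)
    card_label = np.minimum((phase * n_card).astype(int), n_card - 1)
    return resp_label * n_card + card_label


def build_library(k_learning: RadialKspace, labels: np.ndarray,
                  matrix_size: int, min_spokes: int = 20,
                  merge_small: bool = False,
                  bin_description: str = "") -> BaselineLibrary:
    """Per-bin adjoint reconstruction of the motion-corrected learning spokes."""
    labels = np.asarray(labels)
    if len(labels) != k_learning.n_spokes:
        raise ValueError("labels must cover the learning spokes")
    if matrix_size != k_learning.params.matrix_size:
        raise ValueError(
            f"matrix_size {matrix_size} does not match the data's "
            f"{k_learning.params.matrix_size}; apply truncate_readout first")
    bin_ids = np.unique(labels)
    counts = np.array([np.sum(labels == b) for b in bin_ids])
    if merge_small:
        while np.any(counts < min_spokes) and len(bin_ids) > 1:
            i = int(np.argmin(counts))
            j = i - 1 if i > 0 else i + 1
            labels = labels.copy()
            labels[labels == bin_ids[i]] = bin_ids[j]
            bin_ids = np.unique(labels)
            counts = np.array([np.sum(labels == b) for b in bin_ids])
    small = counts < min_spokes
    if np.any(small):
        raise ValueError(
            f"bins {list(bin_ids[small])} have fewer than {min_spokes} spokes "
            "(counts " + str(list(counts[small])) + "); enable merging or "
            "reduce the bin count")
    images, idx_lists = [], []
    for b in bin_ids:
        idx = np.flatnonzero(labels == b)
        sub = k_learning.subset(idx)
        traj = sub.trajectory(matrix_size)
        images.append(nufft_adjoint(sub.imaging_data, traj))
        idx_lists.append(idx)
    return BaselineLibrary(images=np.stack(images), counts=counts,
                           spoke_indices=idx_lists, matrix_size=matrix_size,
                           fov_mm=k_learning.params.fov_mm,
                           bin_description=bin_description)


def polynomial_basis(matrix_size: int, order: int = 6,
                     mask: np.ndarray | None = None) -> PolynomialBasis:
    """2D monomials up to total ``order`` on [-1,1]^2, orthonormal over the mask.

    Order 6 gives ``(6+1)(6+2)/2 = 28`` columns before any rank trimming.
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    n = matrix_size
    if mask is None:
        mask = np.ones((n, n), dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask must be non-empty")
    off = (np.arange(n) - n // 2) / (n / 2)
    yy, xx = np.meshgrid(off, off, indexing="ij")
    cols = []
    for total in range(order + 1):
        for p in range(total + 1):
            q = total - p
            cols.append((xx ** p * yy ** q).ravel())
    a = np.stack(cols, axis=1)
    am = a[mask.ravel()]
    q_mat, r_mat = np.linalg.qr(am)
    # trim numerically dependent columns (tiny masks)
    keep = np.abs(np.diag(r_mat)) > 1e-10 * np.abs(r_mat[0, 0])
    q_mat = q_mat[:, keep]
    full = np.zeros((n * n, q_mat.shape[1]))
    full[mask.ravel()] = q_mat
    return PolynomialBasis(columns=full, mask=mask, order=order)


def save_library(lib: BaselineLibrary, path) -> None:
    with h5py.File(path, "a") as f:
        if "library" in f:
            del f["library"]
        g = f.create_group("library")
        g.create_dataset("images", data=lib.images)
        g.create_dataset("counts", data=lib.counts)
        g.attrs["matrix_size"] = lib.matrix_size
        g.attrs["fov_mm"] = lib.fov_mm
        g.attrs["bins"] = lib.bin_description
        for i, idx in enumerate(lib.spoke_indices):
            g.create_dataset(f"spokes_{i}", data=idx)


def load_library(path) -> BaselineLibrary:
    with h5py.File(path, "r") as f:
        g = f["library"]
        n_bins = g["images"].shape[0]
        return BaselineLibrary(
            images=g["images"][()],
            counts=g["counts"][()],
            spoke_indices=[g[f"spokes_{i}"][()] for i in range(n_bins)],
            matrix_size=int(g.attrs["matrix_size"]),
            fov_mm=float(g.attrs["fov_mm"]),
            bin_description=str(g.attrs["bins"]),
        )
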