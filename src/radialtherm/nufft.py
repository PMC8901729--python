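"""Exact non-uniform discrete Fourier transform along radial spokes.

At the matrix sizes this package targets (<= 128-ish), the radial
non-uniform Fourier transform is evaluated exactly by direct summation
instead of approximate gridding: each spoke's equally spaced readout
locations allow a phasor-recurrence evaluation (one complex exponential per
pixel, then repeated multiplication), which keeps the cost at one
vector-vector product per readout sample.  The exact operator doubles as
its own oracle: the Fourier shift theorem and the adjoint identity hold to
machine precision, which the motion-correction and fitting stages rely on.

For iterative fitting the operator can be materialized as a dense
complex64 matrix (size permitting), turning each application into a single
BLAS matmul.

Coordinate conventions: image pixels sit at integer offsets
``(ix - N//2, iy - N//2)``; positions in FoV units are ``offset / N``;
k-locations are in cycles per FoV; the forward transform uses
``exp(-i 2 pi k . r)``.
"""

from __future__ import annotations

import numpy as np

from .raw_io import Trajectory


class RadialDFT:
    """Exact forward/adjoint radial Fourier sampling operator.

    Parameters
    ----------
    traj:
        Radial trajectory (defines spoke angles, readout radii in
        cycles/FoV and the image matrix size).
    max_dense_bytes:
        Materialize the dense complex64 operator when it fits within this
        budget; otherwise applications loop over spokes.
    """

    def __init__(self, traj: Trajectory, max_dense_bytes: float = 1.2e9):
        self.traj = traj
        self.n = int(traj.matrix_size)
        self.npix = self.n * self.n
        off = np.arange(self.n) - self.n // 2
        yy, xx = np.meshgrid(off, off, indexing="ij")
        self._xhat = (xx / self.n).ravel()
        self._yhat = (yy / self.n).ravel()
        cos, sin = traj.directions()
        self._cos = cos
        self._sin = sin
        self.n_samples = traj.n_spokes * traj.n_readout
        self._dense: np.ndarray | None = None
        if self.n_samples * self.npix * 8 <= max_dense_bytes:
            self._dense = self._build_dense()

    # -- dense path --------------------------------------------------------
    def _spoke_rows_at(self, cos: float, sin: float,
                       dtype=np.complex128) -> np.ndarray:
        """Dense forward rows for one spoke direction ([R, npix])."""
        radii = self.traj.radii
        t = cos * self._xhat + sin * self._yhat
        base = np.exp(-2j * np.pi * self.traj.dk * t).astype(dtype, copy=False)
        cur = np.exp(-2j * np.pi * radii[0] * t).astype(dtype, copy=False)
        rows = np.empty((len(radii), self.npix), dtype=dtype)
        for m in range(len(radii)):
            rows[m] = cur
            if m + 1 < len(radii):
                cur = cur * base
        return rows

    def _spoke_rows(self, i: int) -> np.ndarray:
        return self._spoke_rows_at(self._cos[i], self._sin[i])

    def _build_dense(self) -> np.ndarray:
        r = self.traj.n_readout
        e = np.empty((self.n_samples, self.npix), dtype=np.complex64)
        for i in range(self.traj.n_spokes):
            e[i * r:(i + 1) * r] = self._spoke_rows(i)
        return e

    @property
    def is_dense(self) -> bool:
        return self._dense is not None

    # -- applications ------------------------------------------------------
    def forward(self, img: np.ndarray) -> np.ndarray:
        """Sample the image's spectrum at the trajectory locations.

        ``img`` is ``(N, N)`` or ``(N, N, n_ch)``; returns
        ``(n_spokes, R)`` or ``(n_spokes, R, n_ch)``.
        """
        img = np.asarray(img)
        multi = img.ndim == 3
        flat = img.reshape(self.npix, -1)
        ns, r = self.traj.n_spokes, self.traj.n_readout
        if self._dense is not None:
            y = self._dense @ flat.astype(np.complex64)
        else:
            y = np.empty((self.n_samples, flat.shape[1]), dtype=np.complex128)
            for i in range(ns):
                y[i * r:(i + 1) * r] = self._spoke_rows(i) @ flat
        y = y.reshape(ns, r, -1)
        return y if multi else y[:, :, 0]

    def adjoint(self, y: np.ndarray) -> np.ndarray:
        """Plain conjugate-transpose of :meth:`forward` (no density weights)."""
        y = np.asarray(y)
        multi = y.ndim == 3
        ns, r = self.traj.n_spokes, self.traj.n_readout
        flat = y.reshape(self.n_samples, -1)
        if self._dense is not None:
            # (conj(y)^T E)^H avoids materializing E^H
            img = (flat.astype(np.complex64).conj().T @ self._dense).conj().T
        else:
            img = np.zeros((self.npix, flat.shape[1]), dtype=np.complex128)
            for i in range(ns):
                img += self._spoke_rows(i).conj().T @ flat[i * r:(i + 1) * r]
        img = img.reshape(self.n, self.n, -1)
        return img if multi else img[:, :, 0]

    def spectral_norm(self, n_iter: int = 12) -> float:
        """Largest singular value via deterministic power iteration."""
        rng = np.random.default_rng(0)
        x = rng.standard_normal(self.npix) + 1j * rng.standard_normal(self.npix)
        x = x.reshape(self.n, self.n)
        s = 1.0
        for _ in range(n_iter):
            x = self.adjoint(self.forward(x))
            s = np.linalg.norm(x)
            x = x / s
        return float(np.sqrt(s))
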