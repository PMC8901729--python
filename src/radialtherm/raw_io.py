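"""Raw radial data containers, golden-angle trajectory generation and HDF5 I/O.

Conventions used throughout the package (documented once, used everywhere):

* Spoke angles ``rho_R`` are measured from the X (readout image) axis,
  counter-clockwise, and spokes traverse the full k-space diameter.
  Accumulated golden-angle values are stored; they are reduced mod 360
  only when sampling.
* Radial k-space coordinates ``k_r`` are expressed in cycles per field of
  view, so a rigid in-plane shift by ``(dx, dy)`` millimetres multiplies a
  spoke by ``exp(-i 2 pi k_r (dx cos rho + dy sin rho) / FoV_mm)`` and the
  motion-correction operator applies the conjugate ramp.
* Timestamps are seconds as float64, one spoke per TR.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import h5py
import numpy as np

#: Golden-angle increment 180 / phi with phi the golden ratio (degrees).
GOLDEN_ANGLE_DEG = 180.0 / ((1.0 + math.sqrt(5.0)) / 2.0)

IMAGING = "imaging"
MICROCOIL_PROXIMAL = "microcoil_proximal"
MICROCOIL_DISTAL = "microcoil_distal"
_VALID_ROLES = {IMAGING, MICROCOIL_PROXIMAL, MICROCOIL_DISTAL}


@dataclass
class AcquisitionParams:
    """Acquisition metadata of a radial golden-angle GRE scan.

    Defaults follow a 1.5 T continuous radial protocol: 220 mm FoV, 512
    readout points with 2x oversampling, 3 mm slice, TE 20 ms, TR 24.14 ms,
    250 Hz/px readout bandwidth.  The PRF thermometry coefficient
    ``prf_alpha_ppm_per_degC`` is the conventional -0.01 ppm/degC for
    aqueous tissue.
    """

    fov_mm: float = 220.0
    n_readout: int = 512
    oversampling: int = 2
    slice_thickness_mm: float = 3.0
    te_s: float = 0.020
    tr_s: float = 0.02414
    flip_deg: float = 15.0
    readout_bandwidth_hz_per_px: float = 250.0
    b0_tesla: float = 1.5
    gamma_hz_per_tesla: float = 42.577e6
    prf_alpha_ppm_per_degC: float = -0.01

    def __post_init__(self) -> None:
        for name in ("fov_mm", "n_readout", "oversampling", "slice_thickness_mm",
                     "te_s", "tr_s", "readout_bandwidth_hz_per_px", "b0_tesla",
                     "gamma_hz_per_tesla"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.te_s >= self.tr_s:
            raise ValueError("te_s must be smaller than tr_s")
        if self.n_readout % 2 != 0:
            raise ValueError("n_readout must be even")

    @property
    def matrix_size(self) -> int:
        """Native reconstruction matrix (readout points / oversampling)."""
        return self.n_readout // self.oversampling

    @property
    def native_resolution_mm(self) -> float:
        return self.fov_mm / self.matrix_size

    def replace(self, **kwargs) -> "AcquisitionParams":
        return dataclasses.replace(self, **kwargs)


def golden_angle_sequence(n_spokes: int) -> np.ndarray:
    """Accumulated golden-angle values ``m * 180/phi`` in degrees.

    Values grow past 360 degrees; callers reduce mod 360 when sampling.
    """
    if n_spokes < 1:
        raise ValueError("n_spokes must be >= 1")
    return np.arange(n_spokes, dtype=np.float64) * GOLDEN_ANGLE_DEG


@dataclass
class Trajectory:
    """Radial sampling locations for a set of spokes.

    ``radii`` is the common, centred readout coordinate vector in cycles
    per FoV (``k_r = (m - R//2) * dk`` with ``dk = matrix_size/n_readout``);
    per-spoke unit directions follow from ``angles_deg``.
    """

    angles_deg: np.ndarray
    radii: np.ndarray
    matrix_size: int
    fov_mm: float

    @property
    def n_spokes(self) -> int:
        return len(self.angles_deg)

    @property
    def n_readout(self) -> int:
        return len(self.radii)

    @property
    def dk(self) -> float:
        return float(self.radii[1] - self.radii[0])

    def directions(self) -> tuple[np.ndarray, np.ndarray]:
        rho = np.deg2rad(np.asarray(self.angles_deg) % 360.0)
        return np.cos(rho), np.sin(rho)

    def kxky(self) -> tuple[np.ndarray, np.ndarray]:
        """Full (n_spokes, n_readout) k-space coordinates in cycles/FoV."""
        c, s = self.directions()
        return np.outer(c, self.radii), np.outer(s, self.radii)

    def subset(self, spoke_idx) -> "Trajectory":
        return Trajectory(np.asarray(self.angles_deg)[spoke_idx], self.radii,
                          self.matrix_size, self.fov_mm)


def build_trajectory(angles_deg, params: AcquisitionParams,
                     matrix_size: int | None = None) -> Trajectory:
    """Centred symmetric radial trajectory for the given spoke angles.

    Sample spacing is ``matrix_size / n_readout`` cycles per FoV, which
    accounts for the readout oversampling (edge ``|k_r|`` approaches
    ``matrix_size/2``).
    """
    angles = np.asarray(angles_deg, dtype=np.float64)
    m = params.matrix_size if matrix_size is None else int(matrix_size)
    r = params.n_readout
    dk = m / r
    radii = (np.arange(r) - r // 2) * dk
    return Trajectory(angles, radii, m, params.fov_mm)


@dataclass
class RadialKspace:
    """Complex radial spoke samples with golden-angle metadata.

    ``data`` is ``[n_spokes, n_readout, n_channels]``; ``channel_roles``
    flags each channel as imaging or as one of the two catheter micro-coils
    (tracking channels, excluded from image reconstruction).
    """

    data: np.ndarray
    angles_deg: np.ndarray
    times_s: np.ndarray
    channel_roles: list[str]
    params: AcquisitionParams

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.angles_deg = np.asarray(self.angles_deg, dtype=np.float64)
        self.times_s = np.asarray(self.times_s, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("data must be [n_spokes, n_readout, n_channels]")
        if self.data.shape[1] != self.params.n_readout:
            raise ValueError("n_readout of data does not match params.n_readout")
        if len(self.channel_roles) != self.data.shape[2]:
            raise ValueError("channel_roles length must match channel count")
        bad = [r for r in self.channel_roles if r not in _VALID_ROLES]
        if bad:
            raise ValueError(f"unknown channel roles: {bad}")
        if len(self.angles_deg) != self.data.shape[0]:
            raise ValueError("angles_deg length must match spoke count")
        if len(self.times_s) != self.data.shape[0]:
            raise ValueError("times_s length must match spoke count")
        if len(self.angles_deg) > 1:
            inc = np.diff(self.angles_deg)
            if np.any(np.abs(inc - GOLDEN_ANGLE_DEG) > 1e-6):
                raise ValueError("angles must increase by the golden-angle "
                                 "increment between consecutive spokes")

    @property
    def n_spokes(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]

    @property
    def imaging_idx(self) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.channel_roles)
                         if r == IMAGING], dtype=int)

    @property
    def microcoil_idx(self) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.channel_roles)
                         if r != IMAGING], dtype=int)

    @property
    def imaging_data(self) -> np.ndarray:
        return self.data[:, :, self.imaging_idx]

    def trajectory(self, matrix_size: int | None = None) -> Trajectory:
        return build_trajectory(self.angles_deg, self.params, matrix_size)

    def subset(self, spoke_idx) -> "RadialKspace":
        """Arbitrary spoke subset; bypasses the golden-increment check."""
        out = RadialKspace.__new__(RadialKspace)
        out.data = self.data[spoke_idx]
        out.angles_deg = self.angles_deg[spoke_idx]
        out.times_s = self.times_s[spoke_idx]
        out.channel_roles = list(self.channel_roles)
        out.params = self.params
        return out

    def replace_data(self, data: np.ndarray,
                     channel_roles: list[str] | None = None) -> "RadialKspace":
        out = RadialKspace.__new__(RadialKspace)
        out.data = data
        out.angles_deg = self.angles_deg
        out.times_s = self.times_s
        out.channel_roles = (list(self.channel_roles) if channel_roles is None
                             else list(channel_roles))
        out.params = self.params
        return out


_PARAM_FIELDS = [f.name for f in dataclasses.fields(AcquisitionParams)]


def write_raw(k: RadialKspace, path) -> None:
    """Write the package's HDF5 container (lossless round trip)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("kspace", data=k.data)
        f.create_dataset("angles", data=k.angles_deg)
        f.create_dataset("times", data=k.times_s)
        f.create_dataset("roles", data=np.array(k.channel_roles, dtype="S"))
        g = f.create_group("params")
        for name in _PARAM_FIELDS:
            g.attrs[name] = getattr(k.params, name)
        f.attrs["trajectory"] = "radial_golden_angle"
        f.attrs["format"] = "radialtherm-raw-v1"


def read_raw(path) -> RadialKspace:
    """Read a raw radial container.

    Accepts the package's own HDF5 layout.  Files without radial-trajectory
    metadata or with missing channel-role / parameter fields are rejected
    with an explicit error naming the problem.
    """
    with h5py.File(path, "r") as f:
        if "kspace" not in f:
            raise ValueError(
                f"{path}: not a radialtherm raw container (no /kspace dataset); "
                "convert external data to the documented layout first")
        traj = f.attrs.get("trajectory", "")
        if traj and traj != "radial_golden_angle":
            raise ValueError(f"{path}: non-radial trajectory {traj!r} rejected")
        if "roles" not in f:
            nch = f["kspace"].shape[2]
            raise ValueError(
                f"{path}: missing channel-role metadata for channels "
                f"{list(range(nch))}")
        g = f["params"]
        kwargs = {}
        for name in _PARAM_FIELDS:
            if name not in g.attrs:
                raise ValueError(f"{path}: missing acquisition field {name!r}")
            val = g.attrs[name]
            kwargs[name] = (int(val) if name in ("n_readout", "oversampling")
                            else float(val))
        roles = [r.decode() if isinstance(r, bytes) else str(r)
                 for r in f["roles"][()]]
        return RadialKspace(
            data=f["kspace"][()],
            angles_deg=f["angles"][()],
            times_s=f["times"][()],
            channel_roles=roles,
            params=AcquisitionParams(**kwargs),
        )
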