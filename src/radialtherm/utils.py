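"""Acquisition arithmetic helpers (frame timing, bandwidth, pixel sizes)."""

from __future__ import annotations


def frame_duration_s(n_spokes: int, tr_s: float = 0.02414) -> float:
    """Temporal resolution of an ``n_spokes``-projection frame."""
    return n_spokes * tr_s


def tracking_resolution_s(tr_s: float = 0.02414) -> float:
    """Micro-coil tracking update interval: two consecutive projections."""
    return 2.0 * tr_s


def run_duration_s(n_spokes: int, tr_s: float = 0.02414) -> float:
    """Total acquisition length of a continuous run."""
    return n_spokes * tr_s


def reconstructed_pixel_mm(fov_mm: float, matrix: int) -> float:
    """In-plane pixel size of the reconstructed image."""
    return fov_mm / matrix


def epi_phase_encode_bandwidth_hz_per_px(inter_echo_s: float,
                                         n_phase_encode: int) -> float:
    """Phase-encode bandwidth of an EPI readout: 1/(inter-echo delay x PE matrix).

    Retained as a calculator for comparing against the EPI alternative
    (e.g. 0.77 ms and 128 phase-encode steps give ~10 Hz/px).
    """
    if inter_echo_s <= 0 or n_phase_encode <= 0:
        raise ValueError("inputs must be positive")
    return 1.0 / (inter_echo_s * n_phase_encode)
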