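"""Scalar-detector analyses.

Isocenter-shift composition and coordinate-frame conversion, couch
attenuation, gating dose deviation and beam-off latency, and the reference
dose equation (TG-51-style with a magnetic-field correction factor).

Coordinate frames
-----------------
For a head-first-supine patient the three subsystems map the anatomical
directions (Left, Superior, Anterior) as

=========  =========  ==========  ===========
direction  linac_iec  mri_dicom   laser_dicom
=========  =========  ==========  ===========
Left       +X         +X          +X
Superior   +Y         -Z          -Z
Anterior   +Z         +Y          +Y
=========  =========  ==========  ===========

so converting a vector between the Linac (IEC 61217) and MRI (DICOM)
frames is (x, y, z)_RT <-> (x, z, -y)_MRI; the laser frame shares the MRI
axis convention.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .containers import MotionTrace

__all__ = [
    "FRAMES",
    "IsocenterShiftSet",
    "CouchAttenuationEntry",
    "GatingCharges",
    "ReferenceDoseInputs",
    "compose_isocenter_shifts",
    "convert_frame",
    "couch_attenuation_eq4",
    "couch_attenuation_eq5",
    "attenuation_factor_measured",
    "attenuation_factor_tps",
    "attenuation_deviation",
    "gating_deviation",
    "beam_off_latency",
    "reference_dose",
]

# rows of M map a frame vector to anatomical (L, S, A) components
_TO_ANATOMICAL = {
    "linac_iec": np.eye(3),
    "mri_dicom": np.array([[1.0, 0.0, 0.0], [0.0, 0.0, -1.0], [0.0, 1.0, 0.0]]),
}
_TO_ANATOMICAL["laser_dicom"] = _TO_ANATOMICAL["mri_dicom"]

FRAMES = tuple(_TO_ANATOMICAL)


def convert_frame(v: Sequence[float], frame_from: str, frame_to: str) -> np.ndarray:
    """Convert a 3-vector between the Linac, MRI and laser frames.

    Left/Superior/Anterior semantics are preserved; the transforms are
    orthonormal so round trips are exact.
    """
    for f in (frame_from, frame_to):
        if f not in _TO_ANATOMICAL:
            raise ValueError(f"unknown frame {f!r}; supported: {FRAMES}")
    v = np.asarray(v, dtype=float)
    if v.shape != (3,):
        raise ValueError("expected a 3-vector")
    anat = _TO_ANATOMICAL[frame_from] @ v
    return _TO_ANATOMICAL[frame_to].T @ anat


@dataclass
class IsocenterShiftSet:
    """MRI/radiation/laser isocenter shifts in a declared frame.

    Componentwise, ``mr_to_rt = mr_to_laser + laser_to_rt`` with
    ``laser_to_rt = -rt_to_laser``.
    """

    mr_to_laser_mm: np.ndarray
    rt_to_laser_mm: np.ndarray
    mr_to_rt_mm: np.ndarray
    frame: str = "laser_dicom"

    def __post_init__(self) -> None:
        self.mr_to_laser_mm = np.asarray(self.mr_to_laser_mm, dtype=float)
        self.rt_to_laser_mm = np.asarray(self.rt_to_laser_mm, dtype=float)
        self.mr_to_rt_mm = np.asarray(self.mr_to_rt_mm, dtype=float)
        expected = self.mr_to_laser_mm - self.rt_to_laser_mm
        if not np.allclose(self.mr_to_rt_mm, expected, atol=1e-12):
            raise ValueError("mr_to_rt must equal mr_to_laser - rt_to_laser")
        if self.frame not in FRAMES:
            raise ValueError(f"unknown frame {self.frame!r}")


def compose_isocenter_shifts(
    mr_to_laser_mm: Sequence[float],
    rt_to_laser_mm: Sequence[float],
    frame: str = "laser_dicom",
    frame_mr: str | None = None,
    frame_rt: str | None = None,
) -> IsocenterShiftSet:
    """Compose the MRI-to-radiation shift from the two laser-relative shifts.

    The laser-to-radiation terms enter with inverted sign, so
    ``mr_to_rt = mr_to_laser - rt_to_laser`` componentwise.  Both inputs
    must be expressed in the same frame.
    """
    frame_mr = frame if frame_mr is None else frame_mr
    frame_rt = frame if frame_rt is None else frame_rt
    if frame_mr != frame_rt:
        raise ValueError(f"mixed frames: {frame_mr!r} vs {frame_rt!r}")
    mr = np.asarray(mr_to_laser_mm, dtype=float)
    rt = np.asarray(rt_to_laser_mm, dtype=float)
    if mr.shape != (3,) or rt.shape != (3,):
        raise ValueError("shifts must be 3-vectors")
    return IsocenterShiftSet(mr, rt, mr - rt, frame=frame_mr)


# ----------------------------------------------------------------------
# couch attenuation
# ----------------------------------------------------------------------
@dataclass
class CouchAttenuationEntry:
    gantry_deg: float
    measured_factor: float
    tps_factor: float
    deviation_pct: float

    def __post_init__(self) -> None:
        if self.measured_factor <= 0 or self.tps_factor <= 0:
            raise ValueError("attenuation factors must be positive")
        expected = attenuation_deviation(self.measured_factor, self.tps_factor)
        if abs(self.deviation_pct - expected) > 1e-9:
            raise ValueError("deviation inconsistent with the factor columns")


def couch_attenuation_eq4(r_theta: float, r0: float) -> float:
    """Measured relative attenuation, percent form: 100*(1 - R_theta/R_0)."""
    if r0 <= 0:
        raise ValueError("reference reading must be positive")
    return 100.0 * (1.0 - r_theta / r0)


def couch_attenuation_eq5(mu: float, reference_mu: float) -> float:
    """TPS relative attenuation, percent form: 100*(1 - MU/Reference)."""
    if reference_mu <= 0:
        raise ValueError("reference MU must be positive")
    return 100.0 * (1.0 - mu / reference_mu)


def attenuation_factor_measured(r_theta: float, r0: float) -> float:
    """Reference-normalised measured attenuation factor R_0 / R_theta.

    This is the factor form that the tabulated relative-attenuation values
    (~1.0-1.2) use: readings drop through the couch, so the factor rises
    above 1 at attenuated gantry angles.
    """
    if r_theta <= 0 or r0 <= 0:
        raise ValueError("readings must be positive")
    return r0 / r_theta


def attenuation_factor_tps(mu: float, reference_mu: float) -> float:
    """Calculated attenuation factor MU / Reference_MU (per 1 Gy at iso)."""
    if mu <= 0 or reference_mu <= 0:
        raise ValueError("monitor units must be positive")
    return mu / reference_mu


def attenuation_deviation(measured_factor: float, tps_factor: float) -> float:
    """Percent deviation of measured vs TPS attenuation factors, 1 dp."""
    if tps_factor <= 0:
        raise ValueError("TPS factor must be positive")
    return round(100.0 * (measured_factor - tps_factor) / tps_factor, 1)


# ----------------------------------------------------------------------
# gating
# ----------------------------------------------------------------------
@dataclass
class GatingCharges:
    """Electrometer charges for non-gated and gated deliveries (nC)."""

    d_ng: float
    d_g: float

    def __post_init__(self) -> None:
        if self.d_ng == 0:
            raise ValueError("non-gated charge must be nonzero")


def gating_deviation(charges: GatingCharges) -> float:
    """Signed percent deviation 100*(D_ng - D_g)/D_ng between deliveries.

    Reports conventionally quote the magnitude rounded to 2 dp.
    """
    return 100.0 * (charges.d_ng - charges.d_g) / charges.d_ng


def beam_off_latency(
    trace: MotionTrace,
    boundary_mm: float | None = None,
    max_latency_s: float = 1.0,
) -> float:
    """Mean beam-off latency from a motion trace with beam states.

    For each event where the target exits the gating boundary, the exit
    time is found by linear interpolation of |position| across the boundary
    and the beam-off time is the midpoint of the last beam-on and first
    beam-off frames; the latency is the mean difference.  At least three
    such events are required.
    """
    if boundary_mm is None:
        boundary_mm = trace.meta.get("gating_boundary_mm")
        if boundary_mm is None:
            raise ValueError("boundary_mm not given and absent from trace metadata")
    t = trace.time_s
    a = np.abs(trace.position_mm)
    inside = a <= boundary_mm
    beam = trace.beam_on.astype(int)
    latencies = []
    exits = np.nonzero(inside[:-1] & ~inside[1:])[0]
    offs = np.nonzero((beam[:-1] == 1) & (beam[1:] == 0))[0]
    for i in exits:
        # interpolated boundary-crossing time within [t_i, t_{i+1}]
        da, db = a[i] - boundary_mm, a[i + 1] - boundary_mm
        t_cross = t[i] + (t[i + 1] - t[i]) * da / (da - db) if db != da else t[i]
        later = offs[offs >= i]
        if later.size == 0:
            continue
        j = later[0]
        t_off = 0.5 * (t[j] + t[j + 1])
        # guard against pairing an exit with the NEXT event's beam-off
        # transition when the gate window fell between two frames; the
        # midpoint estimate may legitimately precede the crossing by up to
        # one frame at zero latency
        dt = t[i + 1] - t[i]
        if -dt <= t_off - t_cross <= max_latency_s:
            latencies.append(t_off - t_cross)
    if len(latencies) < 3:
        raise ValueError(f"only {len(latencies)} boundary-exit events found; need >= 3")
    return float(np.mean(latencies))


# ----------------------------------------------------------------------
# reference dose
# ----------------------------------------------------------------------
@dataclass
class ReferenceDoseInputs:
    """Inputs to the reference-dose equation D = M * N_Dw * k_Q * k_B.

    ``k_b`` defaults to the 0.35 T perpendicular-orientation magnetic-field
    correction 0.9957.  ``k_q`` may be omitted when a (%dd(10)x, k_Q)
    anchor table and ``pdd10x_pct`` are provided for linear interpolation.
    """

    corrected_reading: float
    nd_w: float
    k_q: float | None = None
    k_b: float = 0.9957
    pdd10x_pct: float | None = None

    def __post_init__(self) -> None:
        if self.nd_w <= 0:
            raise ValueError("nd_w must be positive")
        for name, val in (("k_q", self.k_q), ("k_b", self.k_b)):
            if val is not None and not (0.9 < val < 1.1):
                raise ValueError(f"{name} must lie in (0.9, 1.1)")


def reference_dose(
    inputs: ReferenceDoseInputs,
    kq_table: Sequence[tuple[float, float]] | None = None,
) -> float:
    """Reference dose per MU: corrected reading x N_D,w x k_Q x k_B.

    When ``inputs.k_q`` is None, k_Q is linearly interpolated at
    ``inputs.pdd10x_pct`` from the user-supplied ``kq_table`` of
    (%dd(10)x, k_Q) anchors; values outside the table range are rejected.
    """
    kq = inputs.k_q
    if kq is None:
        if kq_table is None or inputs.pdd10x_pct is None:
            raise ValueError("k_q absent: provide a kq_table and pdd10x_pct")
        tab = np.asarray(sorted(kq_table), dtype=float)
        lo, hi = tab[0, 0], tab[-1, 0]
        if not (lo <= inputs.pdd10x_pct <= hi):
            raise ValueError(
                f"%dd(10)x = {inputs.pdd10x_pct} outside the table range [{lo}, {hi}]"
            )
        kq = float(np.interp(inputs.pdd10x_pct, tab[:, 0], tab[:, 1]))
        if not (0.9 < kq < 1.1):
            raise ValueError("interpolated k_q outside the plausible range (0.9, 1.1)")
    return inputs.corrected_reading * inputs.nd_w * kq * inputs.k_b
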