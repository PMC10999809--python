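"""Structural metrics from force-displacement records.

Extracts the standard quasi-static compression metrics from a test record:
stiffness as the maximum slope of a moving linear regression over one third
of the monotonic segment, yield by the 0.2 % apparent-strain offset
criterion, ultimate load as the absolute force maximum, energy to the
ultimate point by trapezoidal integration, and the apparent (area/height
normalized) counterparts. Records are low-pass filtered with a zero-phase
Butterworth filter (2.5 Hz cut-off) before extraction.

Units: force kN, displacement mm, time s, stiffness kN/mm, energy J
(1 kN*mm = 1 J), apparent stresses MPa.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "LoadCurve",
    "StructuralResult",
    "filter_curve",
    "synchronize",
    "monotonic_segment",
    "compute_stiffness",
    "compute_yield",
    "compute_ultimate_and_energy",
    "apparent_properties",
    "analyze_curve",
]


@dataclass
class LoadCurve:
    """Force-displacement-time record of a compression test."""

    time: np.ndarray  # s, strictly increasing
    displacement: np.ndarray  # mm
    force: np.ndarray  # kN
    metadata: dict = field(default_factory=dict)  # height_mm, area_mm2, ...

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.displacement = np.asarray(self.displacement, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if not (len(self.time) == len(self.displacement) == len(self.force)):
            raise ValueError("time/displacement/force must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        for a in (self.time, self.displacement, self.force):
            if not np.all(np.isfinite(a)):
                raise ValueError("curve values must be finite")

    def __len__(self) -> int:
        return len(self.time)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"time_s": self.time, "displacement_mm": self.displacement, "force_kN": self.force}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, **metadata) -> "LoadCurve":
        df = pd.read_csv(path)
        return cls(df["time_s"].values, df["displacement_mm"].values, df["force_kN"].values, metadata)


@dataclass
class StructuralResult:
    """Structural and apparent mechanical properties of one sample."""

    stiffness: float  # kN/mm
    yield_force: float | None  # kN, None if the offset line never intersects
    yield_displacement: float | None  # mm
    ultimate_force: float  # kN
    ultimate_displacement: float  # mm
    energy_to_ultimate: float  # J
    apparent_modulus: float | None = None  # MPa
    apparent_yield: float | None = None  # MPa
    apparent_strength: float | None = None  # MPa
    apparent_ultimate_strain: float | None = None
    energy_density_to_ultimate: float | None = None  # MPa (mJ/mm^3)
    stiffness_window: tuple[int, int] | None = None
    flags: list = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), default=lambda o: None, indent=2))


def resample_uniform(curve: LoadCurve, dt: float | None = None) -> LoadCurve:
    """Resample to a uniform time step by linear interpolation."""
    steps = np.diff(curve.time)
    if dt is None:
        dt = float(np.median(steps))
    if np.allclose(steps, dt, rtol=1e-9, atol=1e-12):
        return curve
    t = np.arange(curve.time[0], curve.time[-1] + dt / 2, dt)
    return LoadCurve(
        t,
        np.interp(t, curve.time, curve.displacement),
        np.interp(t, curve.time, curve.force),
        dict(curve.metadata),
    )


def filter_curve(curve: LoadCurve, cutoff: float = 2.5, order: int = 2) -> LoadCurve:
    """Zero-phase Butterworth low-pass on force and displacement channels.

    The record is resampled to a uniform time step first; a second-order
    filter applied forward-backward gives zero phase and a squared magnitude
    response (|H|^2 = 1/2 at the cut-off).
    """
    curve = resample_uniform(curve)
    dt = curve.time[1] - curve.time[0]
    fs = 1.0 / dt
    if cutoff >= fs / 2:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist {fs / 2:.3g} Hz")
    b, a = signal.butter(order, cutoff / (fs / 2))
    return LoadCurve(
        curve.time,
        signal.filtfilt(b, a, curve.displacement),
        signal.filtfilt(b, a, curve.force),
        dict(curve.metadata),
    )


def synchronize(channels: dict[str, tuple[np.ndarray, np.ndarray]]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Align channels in time on their first preconditioning peak.

    ``channels`` maps a name to ``(time, values)``. Each channel is shifted
    so the first prominent peak of every channel occurs at the same time as
    in the first channel. Raises if a channel has no detectable peak.
    """
    names = list(channels)
    peak_times = {}
    for name in names:
        t, v = channels[name]
        v = np.asarray(v, dtype=float)
        prom = 0.1 * (v.max() - v.min())
        peaks, _ = signal.find_peaks(v, prominence=prom)
        if len(peaks) == 0:
            raise ValueError(f"channel {name!r}: no detectable preconditioning peak")
        peak_times[name] = np.asarray(t, dtype=float)[peaks[0]]
    t_ref = peak_times[names[0]]
    out = {}
    for name in names:
        t, v = channels[name]
        out[name] = (np.asarray(t, dtype=float) - (peak_times[name] - t_ref), np.asarray(v, dtype=float))
    return out


def monotonic_segment(curve: LoadCurve, force_eps: float | None = None,
                      start: int | None = None) -> tuple[int, int]:
    """Locate the monotonic loading ramp: (start, index of ultimate).

    Start is the last upcrossing of (near-)zero force before the global
    force maximum, i.e. the end of the last preconditioning cycle; the
    ultimate index is the FIRST sample attaining the maximum force.
    ``start`` overrides detection.
    """
    f = curve.force
    i_ult = int(np.argmax(f))
    if start is None:
        if force_eps is None:
            force_eps = max(1e-9, 0.01 * f[: i_ult + 1].max())
        low = f[: i_ult + 1] <= force_eps
        ups = np.nonzero(low[:-1] & ~low[1:])[0]
        start = int(ups[-1]) if len(ups) else 0
    return int(start), i_ult


def compute_stiffness(curve: LoadCurve, segment: tuple[int, int] | None = None) -> tuple[float, tuple[int, int]]:
    """Maximum slope of a moving OLS regression over 1/3 of the ramp.

    The window length is ceil(N/3) samples of the monotonic segment; the
    earliest window wins slope ties. Returns (stiffness kN/mm, window).
    """
    i0, i1 = segment if segment is not None else monotonic_segment(curve)
    d = curve.displacement[i0 : i1 + 1]
    f = curve.force[i0 : i1 + 1]
    n = len(d)
    if n < 6:
        raise ValueError("monotonic segment has fewer than 6 points")
    w = int(np.ceil(n / 3))
    w = max(w, 2)
    # rolling OLS slope via cumulative sums
    c1 = np.concatenate([[0.0], np.cumsum(d)])
    c2 = np.concatenate([[0.0], np.cumsum(d * d)])
    cf = np.concatenate([[0.0], np.cumsum(f)])
    cdf = np.concatenate([[0.0], np.cumsum(d * f)])
    starts = np.arange(0, n - w + 1)
    sx = c1[starts + w] - c1[starts]
    sxx = c2[starts + w] - c2[starts]
    sy = cf[starts + w] - cf[starts]
    sxy = cdf[starts + w] - cdf[starts]
    denom = w * sxx - sx * sx
    with np.errstate(divide="ignore", invalid="ignore"):
        slopes = np.where(denom > 0, (w * sxy - sx * sy) / denom, -np.inf)
    j = int(np.argmax(slopes))
    return float(slopes[j]), (i0 + j, i0 + j + w - 1)


def compute_yield(
    curve: LoadCurve,
    stiffness: float,
    height_mm: float,
    segment: tuple[int, int] | None = None,
    offset_strain: float = 0.002,
    d_origin: float | None = None,
) -> tuple[float | None, float | None]:
    """Yield by the 0.2 % apparent-strain offset criterion.

    The offset line F = K * (d - offset_strain * height) is intersected with
    the measured ramp; the first intersection gives (yield force kN, yield
    displacement mm). Displacements are taken from ``d_origin`` (default:
    the zero-force point extrapolated at the elastic slope from the segment
    start). Returns (None, None) if no intersection occurs before the
    ultimate point (flagged undefined).
    """
    i0, i1 = segment if segment is not None else monotonic_segment(curve)
    d = curve.displacement[i0 : i1 + 1]
    f = curve.force[i0 : i1 + 1]
    if d_origin is None:
        d_origin = zero_force_origin(curve, stiffness, (i0, i1))
    d = d - d_origin  # ramp-local displacement
    d0 = offset_strain * height_mm
    g = f - stiffness * (d - d0)  # curve minus offset line; starts positive
    cross = np.nonzero((g[:-1] > 0) & (g[1:] <= 0))[0]
    if len(cross) == 0:
        return None, None
    i = int(cross[0])
    # linear interpolation of the zero of g between samples i, i+1
    w = g[i] / (g[i] - g[i + 1])
    d_y = d[i] + w * (d[i + 1] - d[i])
    f_y = stiffness * (d_y - d0)
    return float(f_y), float(d_y)


def zero_force_origin(curve: LoadCurve, stiffness: float, segment: tuple[int, int]) -> float:
    """Zero-force displacement origin: elastic back-extrapolation from the ramp start."""
    i0, _ = segment
    return float(curve.displacement[i0] - curve.force[i0] / stiffness)


def compute_ultimate_and_energy(
    curve: LoadCurve, segment: tuple[int, int] | None = None, d_origin: float | None = None
) -> tuple[float, float, float]:
    """Ultimate force (kN), its displacement (mm, ramp-local), and energy (J).

    The ultimate point is the first sample attaining the absolute force
    maximum; energy is the trapezoidal area under force-displacement from
    the monotonic start to the ultimate point (kN*mm = J).
    """
    i0, i1 = segment if segment is not None else monotonic_segment(curve)
    origin = curve.displacement[i0] if d_origin is None else d_origin
    d = curve.displacement[i0 : i1 + 1] - origin
    f = curve.force[i0 : i1 + 1]
    if len(d) == 0:
        raise ValueError("empty monotonic segment")
    energy = float(np.trapezoid(f, d))
    return float(f[-1]), float(d[-1]), energy


def apparent_properties(result: StructuralResult, area_mm2: float, height_mm: float,
                        curve: LoadCurve | None = None,
                        segment: tuple[int, int] | None = None) -> StructuralResult:
    """Fill the apparent (size-normalized) fields of a StructuralResult.

    apparent modulus = stiffness * height / area (MPa), apparent yield and
    strength = force / area (MPa), apparent ultimate strain = displacement /
    height, energy density = area under the apparent stress-strain curve up
    to the apparent strength (MPa). The energy density uses the measured
    curve when given, else the stored energy / (area * height).
    """
    if area_mm2 <= 0 or height_mm <= 0:
        raise ValueError("area and height must be positive")
    kN_to_N = 1000.0
    result.apparent_modulus = result.stiffness * kN_to_N * height_mm / area_mm2
    if result.yield_force is not None:
        result.apparent_yield = result.yield_force * kN_to_N / area_mm2
    result.apparent_strength = result.ultimate_force * kN_to_N / area_mm2
    result.apparent_ultimate_strain = result.ultimate_displacement / height_mm
    if curve is not None:
        i0, i1 = segment if segment is not None else monotonic_segment(curve)
        strain = (curve.displacement[i0 : i1 + 1] - curve.displacement[i0]) / height_mm
        stress = curve.force[i0 : i1 + 1] * kN_to_N / area_mm2
        result.energy_density_to_ultimate = float(np.trapezoid(stress, strain))
    else:
        result.energy_density_to_ultimate = (
            result.energy_to_ultimate * 1000.0 / (area_mm2 * height_mm)
        )
    return result


def analyze_curve(
    curve: LoadCurve,
    height_mm: float | None = None,
    area_mm2: float | None = None,
    prefilter: bool = True,
    cutoff: float = 2.5,
    segment_start: int | None = None,
) -> StructuralResult:
    """Full extraction pipeline on one record.

    Optionally low-pass filters the record (experimental data; FE curves are
    noise-free and skip it), locates the monotonic ramp, and computes the
    structural and apparent metrics.
    """
    height_mm = height_mm if height_mm is not None else curve.metadata.get("height_mm")
    area_mm2 = area_mm2 if area_mm2 is not None else curve.metadata.get("area_mm2")
    if height_mm is None:
        raise ValueError("sample height required (argument or curve metadata)")
    work = filter_curve(curve, cutoff=cutoff) if prefilter else curve
    seg = monotonic_segment(work, start=segment_start)
    stiffness, window = compute_stiffness(work, seg)
    d_zero = zero_force_origin(work, stiffness, seg)
    f_y, d_y = compute_yield(work, stiffness, height_mm, seg, d_origin=d_zero)
    f_u, d_u, energy = compute_ultimate_and_energy(work, seg, d_origin=d_zero)
    res = StructuralResult(
        stiffness=stiffness,
        yield_force=f_y,
        yield_displacement=d_y,
        ultimate_force=f_u,
        ultimate_displacement=d_u,
        energy_to_ultimate=energy,
        stiffness_window=window,
        flags=[] if f_y is not None else ["yield_undefined"],
    )
    if area_mm2 is not None:
        apparent_properties(res, area_mm2, height_mm, work, seg)
    return res
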