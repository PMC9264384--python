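"""Arrival-time distribution (ATD) data model and chromatogram CSV I/O.

A mobilogram is the intensity of one ion versus its transit time through the
ion-mobility cell, exported from instrument software as a two-column
chromatogram (arrival time in ms, intensity in counts).  Traces are
normalized to percent relative intensity (RI) before comparison:

    RI(t) = 100 * I(t) / I_max

which makes the comparison insensitive to fragmentation efficiency and
sample concentration.  ``align`` puts two normalized traces on one shared
time grid (linear interpolation over the overlap only, no extrapolation) so
they can be subtracted point by point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np


@dataclass
class Mobilogram:
    """Raw ATD trace for one ion: arrival times (ms) vs intensity (counts)."""

    times: np.ndarray
    intensities: np.ndarray
    ion_label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape:
            raise ValueError("times and intensities must have equal length")
        if self.times.size < 3:
            raise ValueError("trace too short: need at least 3 points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("arrival times must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValueError("negative intensity; pass clip_negative to clip at read time")
        if self.intensities.max() <= 0:
            raise ValueError("cannot normalize empty signal: max intensity is 0")

    @property
    def i_max(self) -> float:
        return float(self.intensities.max())


@dataclass
class NormalizedMobilogram:
    """ATD trace as relative intensity, RI in [0, 100] percent.

    Traces produced by :func:`normalize` peak at exactly 100; a trace that
    has been cropped/interpolated by :func:`align` may peak slightly lower.
    """

    times: np.ndarray
    ri: np.ndarray
    ion_label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.ri = np.asarray(self.ri, dtype=float)
        if self.times.shape != self.ri.shape:
            raise ValueError("times and ri must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("arrival times must be strictly increasing")
        if self.ri.min() < 0 or self.ri.max() > 100 + 1e-9:
            raise ValueError("relative intensity must lie in [0, 100] %")


class AlignedPair(NamedTuple):
    a: NormalizedMobilogram
    b: NormalizedMobilogram
    overlap_fraction_a: float
    overlap_fraction_b: float
    warnings: tuple[str, ...]


def read_chromatogram(path, *, clip_negative: bool = False, sep: str = ",",
                      decimal: str = ".", ion_label: str = "",
                      meta: dict | None = None) -> Mobilogram:
    """Parse an exported chromatogram CSV into a :class:`Mobilogram`.

    Expects two numeric columns (time in ms, intensity), comma-separated,
    with an optional single header line.  Rows are sorted by time; duplicate
    time points are rejected.  Errors name the offending line.
    """
    rows: list[tuple[float, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = [p.strip() for p in line.split(sep)]
            if decimal != ".":
                parts = [p.replace(decimal, ".") for p in parts]
            if len(parts) < 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns")
            try:
                t, i = float(parts[0]), float(parts[1])
            except ValueError:
                if lineno == 1 and not rows:
                    continue  # tolerate a single header line
                raise ValueError(
                    f"{path}: line {lineno}: non-numeric row {line!r}"
                ) from None
            rows.append((t, i))
    if len(rows) < 3:
        raise ValueError(f"{path}: trace too short ({len(rows)} points, need >= 3)")
    rows.sort(key=lambda r: r[0])
    times = np.array([r[0] for r in rows])
    intens = np.array([r[1] for r in rows])
    if np.any(np.diff(times) == 0):
        dup = times[np.where(np.diff(times) == 0)[0][0]]
        raise ValueError(f"{path}: duplicate time point {dup}")
    if np.any(intens < 0):
        if clip_negative:
            intens = np.clip(intens, 0.0, None)
        else:
            raise ValueError(
                f"{path}: negative intensity found; pass clip_negative=True to clip"
            )
    return Mobilogram(times, intens, ion_label=ion_label, meta=dict(meta or {}))


def write_chromatogram(m: Mobilogram, path, *, header: bool = True) -> None:
    """Write a trace back to chromatogram CSV, 6 significant digits."""
    with open(path, "w") as fh:
        if header:
            fh.write("time_ms,intensity\n")
        for t, i in zip(m.times, m.intensities):
            fh.write(f"{t:.6g},{i:.6g}\n")


def normalize(m: Mobilogram | NormalizedMobilogram) -> NormalizedMobilogram:
    """Scale a trace to percent relative intensity: RI(t) = 100·I(t)/I_max.

    Idempotent after the first application.  Raises on an all-zero trace.
    """
    if isinstance(m, NormalizedMobilogram):
        y = m.ri
    else:
        y = m.intensities
    peak = y.max()
    if peak <= 0:
        raise ValueError("cannot normalize empty signal: max intensity is 0")
    # divide before scaling so the maximum maps to exactly 100.0
    return NormalizedMobilogram(m.times.copy(), 100.0 * (y / peak),
                                ion_label=m.ion_label, meta=dict(m.meta))


def align(a: NormalizedMobilogram, b: NormalizedMobilogram) -> AlignedPair:
    """Put two normalized traces on the grid of ``a`` over their time overlap.

    ``b`` is linearly interpolated onto ``a``'s grid points inside the
    overlap; nothing is extrapolated.  If the grids are already identical
    both traces are returned unchanged.  An overlap below 80% of either
    trace's time range is flagged in the returned warnings and metadata.
    """
    if np.array_equal(a.times, b.times):
        return AlignedPair(a, b, 1.0, 1.0, ())
    lo = max(a.times[0], b.times[0])
    hi = min(a.times[-1], b.times[-1])
    if lo >= hi:
        raise ValueError(
            f"disjoint time ranges: [{a.times[0]}, {a.times[-1]}] vs "
            f"[{b.times[0]}, {b.times[-1]}] ms"
        )
    mask = (a.times >= lo) & (a.times <= hi)
    grid = a.times[mask]
    if grid.size < 2:
        raise ValueError("overlap contains fewer than 2 grid points")
    span_a = a.times[-1] - a.times[0]
    span_b = b.times[-1] - b.times[0]
    frac_a = (hi - lo) / span_a if span_a > 0 else 1.0
    frac_b = (hi - lo) / span_b if span_b > 0 else 1.0
    warns = tuple(
        f"overlap is {frac * 100:.1f}% of trace {name!r} time range"
        for frac, name in ((frac_a, a.ion_label or "a"), (frac_b, b.ion_label or "b"))
        if frac < 0.8
    )
    b_interp = np.interp(grid, b.times, b.ri)
    meta_a = dict(a.meta, overlap_fraction=frac_a, align_warnings=warns)
    meta_b = dict(b.meta, overlap_fraction=frac_b, align_warnings=warns)
    out_a = NormalizedMobilogram(grid, a.ri[mask], ion_label=a.ion_label, meta=meta_a)
    out_b = NormalizedMobilogram(grid, b_interp, ion_label=b.ion_label, meta=meta_b)
    return AlignedPair(out_a, out_b, frac_a, frac_b, warns)
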