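"""The NSI (normalized subtraction integration) statistic.

Two arrival-time distributions are compared by normalizing each to percent
relative intensity, subtracting them point by point to give the signed
difference D(t), taking the absolute value, and integrating |D| over time
with the trapezoid rule:

    NSI = ∫ |RI_ref(t) − RI_iso(t)| dt      (units: %·ms)

Identical traces give NSI = 0; the score is symmetric in its arguments and
invariant to positive rescaling of either raw trace.  Along a fragment
ladder, per-fragment NSI values are smoothed with a three-point running
average (fragments n−1, n, n+1) before threshold-based site calling, which
damps fragment-to-fragment fluctuation from ion statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.integrate import trapezoid

from .mobilogram import Mobilogram, NormalizedMobilogram, align, normalize, read_chromatogram
from .peptide import FragmentIon


@dataclass
class DifferenceCurve:
    """Signed pointwise difference of two relative-intensity traces."""

    times: np.ndarray
    d: np.ndarray  # RI_ref − RI_iso, in %
    abs_d: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        if self.times.shape != self.d.shape:
            raise ValueError("times and d must have equal length")
        self.abs_d = np.abs(self.d)
        if self.abs_d.max(initial=0.0) > 200.0 + 1e-9:
            raise ValueError("|D| exceeds 200%: inputs are not normalized traces")


class NSIResult(NamedTuple):
    nsi: float
    curve: DifferenceCurve
    overlap_fraction: float
    warnings: tuple[str, ...]


@dataclass
class NSIEntry:
    fragment: FragmentIon
    nsi: float
    charge_used: int
    isotopes_summed: bool = False

    def __post_init__(self) -> None:
        if self.nsi < 0:
            raise ValueError("NSI must be non-negative")


@dataclass
class NSISeries:
    """Per-fragment NSI values along one b or y ladder.

    ``running_avg`` maps observed fragment index n to the mean NSI over the
    observed members of {n−1, n, n+1}; it is only defined at observed
    indices (the window shrinks at ladder ends and across gaps rather than
    padding with zeros).  ``missing`` lists requested indices with no usable
    ATD pair.
    """

    entries: list[NSIEntry] = field(default_factory=list)
    running_avg: dict[int, float] = field(default_factory=dict)
    missing: list[int] = field(default_factory=list)

    @property
    def series(self) -> str:
        kinds = {e.fragment.series for e in self.entries}
        if len(kinds) != 1:
            raise ValueError(f"series is mixed or empty: {sorted(kinds)}")
        return kinds.pop()

    def observed(self) -> dict[int, float]:
        """Observed fragment index → raw NSI, sorted by index."""
        return {e.fragment.n: e.nsi for e in sorted(self.entries, key=lambda e: e.fragment.n)}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "series": e.fragment.series,
                "n": e.fragment.n,
                "terminal_residue": e.fragment.terminal_residue,
                "charge": e.charge_used,
                "nsi": e.nsi,
                "running_avg": self.running_avg.get(e.fragment.n, np.nan),
            }
            for e in sorted(self.entries, key=lambda e: e.fragment.n)
        ]
        return pd.DataFrame(rows, columns=["series", "n", "terminal_residue",
                                           "charge", "nsi", "running_avg"])


def difference_curve(ref: NormalizedMobilogram, iso: NormalizedMobilogram) -> DifferenceCurve:
    """D(t) = RI_ref(t) − RI_iso(t) on a shared grid (align() first if needed)."""
    if not np.array_equal(ref.times, iso.times):
        raise ValueError("traces are on different time grids; apply align() first")
    return DifferenceCurve(ref.times.copy(), ref.ri - iso.ri)


def integrate_nsi(curve: DifferenceCurve) -> float:
    """Trapezoid-rule integral of |D| over time, in %·ms."""
    if curve.times.size < 2:
        raise ValueError("need at least 2 time points to integrate")
    return float(trapezoid(curve.abs_d, curve.times))


def nsi_pair(ref_raw: Mobilogram, iso_raw: Mobilogram) -> NSIResult:
    """Full NSI of two raw traces: normalize → align → subtract → integrate.

    The two traces must describe the same ion: a charge recorded in both
    traces' metadata must agree (comparing e.g. y15 at z=1 with y15 at z=2
    is an error, not a warning, because the two ions have different
    mobilities).  A mismatch in the ``isotopes_summed`` metadata flag is
    reported as a warning only.
    """
    warns: list[str] = []
    z_ref, z_iso = ref_raw.meta.get("charge"), iso_raw.meta.get("charge")
    if z_ref is not None and z_iso is not None and int(z_ref) != int(z_iso):
        raise ValueError(
            f"charge mismatch: reference is z={z_ref}, isomer is z={z_iso}; "
            "NSI pairs must use the same ion"
        )
    if ref_raw.ion_label and iso_raw.ion_label and ref_raw.ion_label != iso_raw.ion_label:
        raise ValueError(
            f"ion label mismatch: {ref_raw.ion_label!r} vs {iso_raw.ion_label!r}"
        )
    s_ref = ref_raw.meta.get("isotopes_summed")
    s_iso = iso_raw.meta.get("isotopes_summed")
    if s_ref is not None and s_iso is not None and bool(s_ref) != bool(s_iso):
        msg = "isotopes_summed flags differ between reference and isomer traces"
        warnings.warn(msg, stacklevel=2)
        warns.append(msg)
    aligned = align(normalize(ref_raw), normalize(iso_raw))
    warns.extend(aligned.warnings)
    curve = difference_curve(aligned.a, aligned.b)
    return NSIResult(integrate_nsi(curve), curve,
                     min(aligned.overlap_fraction_a, aligned.overlap_fraction_b),
                     tuple(warns))


def running_average(series: NSISeries) -> NSISeries:
    """Fill ``running_avg``: at each observed n, mean NSI over observed
    members of {n−1, n, n+1}.  The window shrinks at the ladder ends and
    across gaps; missing neighbours are never treated as zero."""
    obs = series.observed()
    if not obs:
        raise ValueError("no observed fragments")
    ra = {
        n: float(np.mean([obs[m] for m in (n - 1, n, n + 1) if m in obs]))
        for n in obs
    }
    return NSISeries(entries=list(series.entries), running_avg=ra,
                     missing=list(series.missing))


def series_from_manifest(manifest: pd.DataFrame, peptide_length: int,
                         *, base_dir=None, clip_negative: bool = False,
                         on_missing: str = "record") -> dict[tuple[str, str], NSISeries]:
    """Compute NSI series from a manifest of exported chromatogram files.

    ``manifest`` needs columns sample, series, n, charge, role (ref|iso),
    path; rows pair on (sample, series, n, charge).  Returns one
    :class:`NSISeries` (running average filled) per (sample, series),
    recording unpaired or unreadable fragments in ``missing``.
    """
    from pathlib import Path

    required = {"sample", "series", "n", "charge", "role", "path"}
    missing_cols = required - set(manifest.columns)
    if missing_cols:
        raise ValueError(f"manifest missing column(s): {sorted(missing_cols)}")
    out: dict[tuple[str, str], NSISeries] = {}
    for (sample, ser), grp in manifest.groupby(["sample", "series"], sort=True):
        result = NSISeries()
        for n, sub in grp.groupby("n", sort=True):
            roles = dict(zip(sub["role"], sub["path"]))
            zs = sub["charge"].unique()
            if len(zs) != 1:
                raise ValueError(
                    f"{sample} {ser}{n}: mixed charges {sorted(zs)} within one pair"
                )
            if "ref" not in roles or "iso" not in roles:
                result.missing.append(int(n))
                continue
            try:
                traces = {
                    role: read_chromatogram(
                        Path(base_dir) / p if base_dir else p,
                        clip_negative=clip_negative,
                        meta={"charge": int(zs[0])},
                    )
                    for role, p in roles.items()
                }
                res = nsi_pair(traces["ref"], traces["iso"])
            except (OSError, ValueError):
                if on_missing == "raise":
                    raise
                result.missing.append(int(n))
                continue
            frag = FragmentIon(series=str(ser), n=int(n), z=int(zs[0]),
                               peptide_length=peptide_length)
            result.entries.append(NSIEntry(frag, res.nsi, charge_used=int(zs[0])))
        if result.entries:
            out[(str(sample), str(ser))] = running_average(result)
        else:
            out[(str(sample), str(ser))] = result
    return out
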