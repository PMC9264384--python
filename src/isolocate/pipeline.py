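"""In-memory glue: simulated experiment → NSI series → site call."""

from __future__ import annotations

from .localization import SiteCall, call_site, select_threshold
from .nsi import NSIEntry, NSISeries, nsi_pair, running_average
from .simulate import SimulationResult


def nsi_series(result: SimulationResult, series: str = "y") -> NSISeries:
    """Per-fragment NSI (running average filled) for one ladder of a
    simulated experiment, without touching disk."""
    out = NSISeries()
    for pair in result.pairs:
        if pair.fragment.series != series:
            continue
        res = nsi_pair(pair.ref, pair.iso)
        out.entries.append(NSIEntry(pair.fragment, res.nsi,
                                    charge_used=pair.fragment.z))
    if not out.entries:
        raise ValueError(f"simulation contains no {series!r} fragments")
    return running_average(out)


def localize(result: SimulationResult, series: str = "y",
             threshold_mode: str = "auto",
             threshold_value: float | None = None) -> SiteCall:
    """Run the full NSI → running average → threshold → site-call chain."""
    ser = nsi_series(result, series=series)
    thr = select_threshold(ser, threshold_mode, threshold_value)
    if thr is None:
        return SiteCall(None, None, None, threshold_mode,
                        flags=["no transition detected"])
    return call_site(ser, thr, result.experiment.peptide, method=threshold_mode)
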