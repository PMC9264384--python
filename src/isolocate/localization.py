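"""Site calling from an NSI running-average series.

Along a y (or b) fragment ladder, fragments that contain the isomerized
residue show elevated NSI against the reference standard, while shorter
fragments match it; the series therefore steps up at one fragment index.
The first fragment whose running-average NSI reaches a threshold maps back
to the residue at its inner terminus: site = L − n* + 1 for y ions, n* for
b ions.

The threshold is either user-fixed (matching the by-inspection practice of
choosing one threshold per experiment) or derived automatically from the
series: the largest single increase between consecutive running-average
values marks the candidate transition, and the threshold is the midpoint
between the mean level before the jump and the mean level after it.  The
candidate is only accepted when the two levels are robustly separated —
median(post) − median(pre) must exceed ``SEPARATION_SIGMA`` robust standard
deviations (1.4826 × pooled within-side MAD).  A single large jump is not
enough: per-fragment NSI noise is heavy-tailed (one low-count fragment can
produce an outlier), so significance is judged on the sustained level
change that a genuine conformational transition produces, not on one
difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nsi import NSISeries
from .peptide import Peptide

#: Robust z-scores of level separation required to accept an auto transition.
SEPARATION_SIGMA = 5.0
_MAD_TO_SIGMA = 1.4826  # MAD → σ for a normal distribution


@dataclass
class SiteCall:
    """Result of localizing the isomerized residue from one NSI series.

    ``site_range`` is set when fragments are missing around the transition:
    the true site is then only bounded between the residues implied by the
    last observed below-threshold and first observed above-threshold
    fragments.
    """

    called_site: int | None
    transition_fragment: tuple[str, int] | None  # (series, n*)
    threshold: float | None
    method: str  # "fixed" | "auto"
    site_range: tuple[int, int] | None = None
    confidence: str = "normal"  # "high" | "normal" | "flagged"
    flags: list[str] = field(default_factory=list)


def _sorted_running_avg(series: NSISeries) -> tuple[np.ndarray, np.ndarray]:
    if not series.running_avg:
        raise ValueError("running_avg is empty: apply running_average() first")
    ns = np.array(sorted(series.running_avg), dtype=int)
    vals = np.array([series.running_avg[n] for n in ns], dtype=float)
    return ns, vals


def select_threshold(series: NSISeries, mode: str = "auto",
                     value: float | None = None) -> float | None:
    """Choose the NSI threshold separating "matching" from "different".

    ``mode="fixed"`` returns ``value`` unchanged.  ``mode="auto"`` locates
    the largest increase between consecutive observed running-average values
    and returns the midpoint of the pre-jump and post-jump mean levels, or
    None (no transition detected) when the two levels are not separated by
    at least :data:`SEPARATION_SIGMA` robust standard deviations.
    """
    if mode == "fixed":
        if value is None or value <= 0:
            raise ValueError("fixed mode requires a positive threshold value")
        return float(value)
    if mode != "auto":
        raise ValueError(f"unknown threshold mode {mode!r}")
    _, vals = _sorted_running_avg(series)
    if vals.size < 4:
        raise ValueError(f"auto threshold needs >= 4 observed fragments, got {vals.size}")
    diffs = np.diff(vals)
    j = int(np.argmax(diffs))
    jump = float(diffs[j])
    pre, post = vals[: j + 1], vals[j + 1:]
    separation = float(np.median(post) - np.median(pre))
    deviations = np.concatenate(
        [np.abs(pre - np.median(pre)), np.abs(post - np.median(post))]
    )
    scale = _MAD_TO_SIGMA * float(np.median(deviations))
    if jump <= 0 or separation < SEPARATION_SIGMA * scale:
        return None
    return float((pre.mean() + post.mean()) / 2.0)


def call_site(series: NSISeries, threshold: float, peptide: Peptide,
              method: str = "fixed") -> SiteCall:
    """Map the first above-threshold fragment to the isomerized residue.

    n* is the smallest observed fragment index with running-average NSI ≥
    threshold; the call is site = n* for b ions and L − n* + 1 for y ions.
    If every fragment is below threshold the call is None (consistent with a
    non-isomerized sample).  Gaps spanning the transition widen the call to
    a residue interval; later re-crossings below threshold flag the series
    as non-monotone but do not move the call.
    """
    ns, vals = _sorted_running_avg(series)
    ser = series.series
    L = peptide.length
    call = SiteCall(called_site=None, transition_fragment=None,
                    threshold=float(threshold), method=method)
    above = vals >= threshold
    if not above.any():
        return call
    k = int(np.argmax(above))
    n_star = int(ns[k])
    call.transition_fragment = (ser, n_star)

    def to_site(n: int) -> int:
        return n if ser == "b" else L - n + 1

    call.called_site = to_site(n_star)
    if k > 0 and ns[k] - ns[k - 1] > 1:
        # fragments between the last "matching" and first "different" one
        # were not observed: the site is only bounded to an interval
        lo_n, hi_n = int(ns[k - 1]) + 1, n_star
        bounds = sorted((to_site(lo_n), to_site(hi_n)))
        call.site_range = (bounds[0], bounds[1])
        call.flags.append("gap near transition")
    if not above[k:].all():
        call.flags.append("non-monotone series")
    if vals.size < 4:
        call.flags.append("sparse series")
    if peptide.sequence is not None and peptide.sequence[call.called_site - 1] not in "DN":
        call.flags.append(
            f"called residue {peptide.sequence[call.called_site - 1]} is not D/N"
        )
    if call.flags:
        call.confidence = "flagged"
    return call


def reconcile_series(y_call: SiteCall, b_call: SiteCall | None = None) -> SiteCall:
    """Combine y- and b-series calls; the y call wins.

    y ions span almost the whole sequence while observed b ladders are
    short, so the y call carries the site; an agreeing b call upgrades
    confidence and a disagreeing one flags the call without changing it.
    """
    out = SiteCall(called_site=y_call.called_site,
                   transition_fragment=y_call.transition_fragment,
                   threshold=y_call.threshold, method=y_call.method,
                   site_range=y_call.site_range,
                   confidence=y_call.confidence, flags=list(y_call.flags))
    if b_call is None or b_call.called_site is None:
        return out
    if b_call.called_site == y_call.called_site:
        if out.confidence == "normal":
            out.confidence = "high"
        out.flags.append("b-series agreement")
    else:
        out.flags.append(
            f"series disagreement: y->{y_call.called_site}, b->{b_call.called_site}"
        )
        out.confidence = "flagged"
    return out
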