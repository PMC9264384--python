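# Methods

## Problem and approach

Isoaspartate (isoAsp) formation inserts an extra methylene into the peptide
backbone without changing the mass, so an isomerized peptide is invisible to
m/z measurement alone.  Ion mobility separates the conformers: the arrival
time distribution (ATD) of an ion through the mobility cell reflects its
collision cross section, and fragments that contain the isomerized residue
adopt measurably different conformations from the corresponding fragments
of a non-isomerized reference standard.  `isolocate` quantifies the
difference between two ATDs and localizes the modified residue from where
along the CID b/y fragment ladder the difference switches on.

## The NSI statistic

For one ion, the exported chromatogram gives intensity `I(t)` on an
arrival-time grid in milliseconds.  Each trace is first normalized to
percent relative intensity,

    RI(t) = 100 · I(t) / I_max ,

which removes fragmentation-efficiency and concentration effects while
preserving peak position and shape.  The two normalized traces are
subtracted point by point, `D(t) = RI_ref(t) − RI_iso(t)`, and the absolute
difference is integrated by the trapezoid rule
(`scipy.integrate.trapezoid`):

    NSI = ∫ |D(t)| dt        [%·ms]

Identical ATDs give NSI = 0; two fully separated unimodal peaks give
approximately twice the area of one normalized peak.  NSI is symmetric in
its two arguments, invariant to positive rescaling of either raw trace, and
bounded by `200 · (t_end − t_start)`.

Subtraction is computed reference-minus-isomer; the sign never affects NSI
but the signed curve is kept for diagnostics.  Integration runs over the
full aligned time overlap of the two traces — no trimming window is
applied, because any windowing choice would change NSI magnitudes.

## Alignment and normalization details

Exported traces are compared on a common grid.  Identical grids pass
through untouched; otherwise the second trace is linearly interpolated onto
the reference trace's grid restricted to the time overlap, with no
extrapolation.  An overlap below 80% of either trace's range is flagged.
A trace produced by `normalize()` peaks at exactly 100%; after cropping or
interpolation the sampled maximum of the aligned trace may fall slightly
below 100, and it is deliberately not re-normalized — re-normalizing after
alignment would silently inflate the difference curve.

Raw ATDs are never smoothed before NSI: smoothing would change NSI
magnitudes in a bandwidth-dependent way.

Negative intensities in an exported file are rejected by default (ion
counts cannot be negative, so they indicate an export problem); an explicit
`clip_negative` option clips them to zero instead.

Pairing rules: an NSI value is only formed between traces of the same ion —
a charge-state mismatch recorded in the trace metadata is an error, not a
warning, because different charge states of the same fragment have
different mobilities.  A mismatch in whether isotope peaks were summed
during extraction is tolerated with a warning.  NSI values from different
acquisitions (replicates) are never merged into one series.

## Running average and site calling

Per-fragment NSI values fluctuate with ion statistics, so the series over
fragment index n is smoothed with a three-point running average: the value
plotted at n is the mean NSI of fragments n−1, n, n+1.  At the ladder ends
and across unobserved fragments the window shrinks to the observed members;
missing neighbours are never counted as zeros, which would fabricate
similarity.

A fragment ladder of an isomerized peptide shows a step: fragments too
short to contain the isomerized residue match the reference (low NSI), and
every fragment from the first site-containing one onward differs (high
NSI).  The first fragment whose running-average NSI reaches a threshold
maps to the residue at its inner terminus:

    site = L − n* + 1   (y series)        site = n*   (b series)

for an L-mer with transition fragment n*.  y ions drive the call because
observed y ladders span nearly the whole sequence; an available b-series
call is reconciled in (agreement raises confidence, disagreement flags the
call without changing it).

Thresholds come in two modes:

* **fixed** — the user supplies one threshold per experiment, matching the
  practice of inspecting the series and choosing a per-replicate value.
  Thresholds are not transferable between acquisitions because baseline NSI
  (the null level between genuinely equivalent ATDs) varies with ion
  statistics and arrival-time drift from run to run.
* **auto** — the largest increase between consecutive running-average
  values marks the candidate transition; the threshold returned is the
  midpoint between the mean level before the jump and the mean level after
  it.  For an ideal step of height H this midpoint always lands strictly
  between the smeared shoulder value (H/3, one index before the true
  transition) and the first full transition value (2H/3), so the mapped
  site is exact.

**Transition significance.**  The auto mode must also decide when *no*
transition exists (a non-isomerized sample).  Per-fragment null NSI values
are heavy-tailed — a single low-count fragment can throw a large outlier —
so the size of the largest single jump relative to a MAD-based scale of the
values is an unreliable test; in simulation it flags a transition in over
half of all null ladders.  Instead the candidate transition is accepted
only when the levels on its two sides are robustly separated:

    median(post) − median(pre) ≥ 5 · (1.4826 · pooled within-side MAD)

A genuine conformational transition under the modeled effect sizes
separates the levels by 10–30 robust standard deviations, so the
conservative 5σ requirement costs no detection power there (0 missed sites
in 100 simulated ladders) while holding the null call rate to ~2%.  The
trade-off is reduced sensitivity to very small sustained shifts (below
roughly 5 robust σ of the series noise); such samples are reported as "no
transition detected" rather than guessed.

Auto mode needs at least 4 observed fragments.  If fragments are missing
around the transition the call widens to a residue interval bounded by the
last observed below-threshold and first observed above-threshold fragments;
a series that re-crosses the threshold after the transition is flagged
non-monotone and the first crossing is reported.

## Fragment chemistry

`fragment_mz` computes monoisotopic m/z by straight summation of standard
residue masses (pyteomics' table), plus water for y ions, plus z protons
(proton 1.007276 Da, water 18.010565 Da), plus the mass deltas of
modifications falling inside the fragment span.  isoAsp is a zero-mass
modification flag, so isomer and reference ladders are isobaric by
construction.  A lipid anchor or any other fixed modification is a generic
(position, mass) pair; no structure is modeled.  a/c/x/z ions, internal
fragments, neutral losses and isotope patterns are out of scope.

## Synthetic data generator

No instrument data ships with the package; the simulator produces the
ref/iso chromatogram pairs the pipeline consumes, with known ground truth.

* **Peak model** — each fragment's reference ATD is a Gaussian on a uniform
  millisecond grid.  Defaults: grid 35–60 ms at 0.1 ms spacing, peak sigma
  1.0 ms, centers drifting upward 0.35 ms per residue from 40 ms (longer
  fragments arrive later).  These are order-of-magnitude choices consistent
  with printed single-pass arrival times (tens of ms, sub-ms features);
  they are not calibrated to any instrument.
* **Perturbation** — fragments containing the planted site get an
  arrival-time shift (default 1.0 ms, the order of the shift reported for a
  short site-containing y fragment), optionally a shape change (a second
  Gaussian component, or a width change — shape changes are often more
  visible than shifts of the ATD maximum), optionally attenuated as
  exp(−attenuation·k) with k the number of residues beyond the shortest
  site-containing fragment, reflecting that a local backbone change matters
  relatively more in a short fragment.  Attenuation defaults to 0.
* **Noise** — per-bin independent Poisson counts with mean equal to the
  expected bin count (shot-noise model of TOF ion arrivals), default 5000
  expected counts per trace.  An optional global arrival-time jitter knob
  emulates drift between acquisitions.

What the simulator does **not** emulate: traveling-wave transport physics,
multi-pass resolution growth, conformer interconversion, chemical
backgrounds, co-eluting interferences, detector saturation, or correlated
baseline structure.  Passing the simulated-recovery tests therefore shows
the statistic and caller are correct for step-shaped conformational
differences under counting noise — not that any particular instrument or
sample will produce such clean ladders.

## Problem sizes used in tests and the acceptance script

Simulated studies use 30-residue peptides (y1–y29 ladders, 29 ref/iso
pairs, 251-point traces), sites 9/15/21, and 100-seed batches for the
recovery and false-call rates.  The acceptance script runs one full
pipeline per site and reports the called residue position.

## Numerical choices

* Trapezoid integration on the native export grid; verified against a
  fine-grid Riemann oracle to 0.1% on smooth traces.
* Normalization divides before scaling (`100·(I/I_max)`) so the maximum
  maps to exactly 100.0 in floating point.
* Linear interpolation only, no extrapolation; interpolation at shared grid
  nodes reproduces the node values.
* MAD→σ factor 1.4826 (normal consistency).
* Ties in the largest-jump search resolve to the earliest jump.

## Known limitations

* One isomerization site per peptide is assumed; mixtures and multi-site
  deconvolution are out of scope.
* Auto thresholding needs the ladder to include fragments on both sides of
  the transition; a site too close to a terminus for the observed series
  cannot produce a step and is reported as no transition.
* CCS calibration, vendor raw formats, and retention-time logic are out of
  scope; the tool starts from exported time/intensity chromatograms.
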