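"""Synthetic mobilogram generator for end-to-end pipeline testing.

Real input to the pipeline is vendor-exported chromatograms of fragment-ion
arrival-time distributions; none are bundled here, so this module builds a
full ref/iso fragment-ladder experiment from first principles.  Each
fragment's reference ATD is a Gaussian peak on a millisecond grid whose
center drifts slowly upward with fragment length (longer fragments arrive
later).  The isomer trace is drawn from the same distribution unless the
fragment contains the planted isomerization site, in which case a
conformational perturbation is applied: an arrival-time shift, and/or a
shape change (a second, offset Gaussian component or a width change), both
optionally attenuated exponentially with the number of residues beyond the
site — short fragments feel a local backbone change relatively more than
long ones.  Per-bin counting (shot) noise with variance equal to the
expected count emulates TOF ion statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .mobilogram import Mobilogram, write_chromatogram
from .peptide import FragmentIon, Peptide, fragment_contains_site


@dataclass(frozen=True)
class GridSpec:
    """Uniform arrival-time grid: [t_start, t_end] ms in steps of dt."""

    t_start: float = 35.0
    t_end: float = 60.0
    dt: float = 0.1

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start or self.dt <= 0:
            raise ValueError("grid requires t_end > t_start and dt > 0")

    def times(self) -> np.ndarray:
        n = int(round((self.t_end - self.t_start) / self.dt)) + 1
        return self.t_start + self.dt * np.arange(n)


@dataclass(frozen=True)
class ShiftModel:
    """Conformational perturbation applied to site-containing fragments.

    dt_shift
        Arrival-time displacement in ms (default 1.0, on the order of the
        shifts seen for short site-containing fragments).
    shape_mode
        "none", "bimodal" (second component of given weight at
        ``bimodal_offset`` ms) or "width" (sigma multiplied by
        ``width_factor``); shape changes are often more pronounced than
        shifts of the ATD maximum.
    attenuation
        Exponential decay rate of the perturbation per residue beyond the
        site: a fragment with k residues more than the shortest
        site-containing fragment feels exp(−attenuation·k) of the effect.
    """

    dt_shift: float = 1.0
    shape_mode: str = "none"
    bimodal_weight: float = 0.3
    bimodal_offset: float = 1.5
    width_factor: float = 1.5
    attenuation: float = 0.0

    def __post_init__(self) -> None:
        if self.dt_shift < 0:
            raise ValueError("dt_shift must be >= 0")
        if self.shape_mode not in ("none", "bimodal", "width"):
            raise ValueError(f"unknown shape_mode {self.shape_mode!r}")
        if not 0.0 <= self.bimodal_weight <= 1.0:
            raise ValueError("bimodal_weight must lie in [0, 1]")
        if self.attenuation < 0:
            raise ValueError("attenuation must be >= 0")


@dataclass
class SyntheticExperiment:
    """Specification of one simulated ref/iso fragment-ladder acquisition."""

    peptide: Peptide
    grid: GridSpec = field(default_factory=GridSpec)
    shift: ShiftModel = field(default_factory=ShiftModel)
    sigma: float = 1.0  # base peak width, ms
    counts: float = 5000.0  # expected total ion count per trace
    seed: int = 0
    series: tuple[str, ...] = ("y",)
    center_start: float = 40.0  # arrival time of n=1 fragments, ms
    center_drift: float = 0.35  # ms per residue of fragment length
    charge: int = 1
    acquisition_jitter: float = 0.0  # global ms jitter between acquisitions

    def __post_init__(self) -> None:
        if self.peptide.iso_site is None:
            raise ValueError("experiment peptide needs a planted iso_site")
        if self.counts <= 0 or self.sigma <= 0:
            raise ValueError("counts and sigma must be positive")
        last = self.center_start + self.center_drift * (self.peptide.length - 1)
        hi_needed = last + self.shift.dt_shift + 5 * self.sigma
        lo_needed = self.center_start - 5 * self.sigma
        if self.grid.t_start > lo_needed or self.grid.t_end < hi_needed:
            raise ValueError(
                f"grid [{self.grid.t_start}, {self.grid.t_end}] ms does not cover "
                f"all peak centers ± 5σ (need [{lo_needed:.1f}, {hi_needed:.1f}])"
            )


@dataclass
class FragmentPair:
    fragment: FragmentIon
    ref: Mobilogram
    iso: Mobilogram
    perturbed: bool


@dataclass
class SimulationResult:
    experiment: SyntheticExperiment
    pairs: list[FragmentPair]

    def ground_truth(self) -> dict:
        exp = self.experiment
        return {
            "iso_site": exp.peptide.iso_site,
            "length": exp.peptide.length,
            "dt_shift_ms": exp.shift.dt_shift,
            "shape_mode": exp.shift.shape_mode,
            "attenuation": exp.shift.attenuation,
            "seed": exp.seed,
            "perturbed": sorted(
                (p.fragment.series, p.fragment.n) for p in self.pairs if p.perturbed
            ),
        }


def _gaussian(t: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))


def simulate_atd(center: float, sigma: float, grid: GridSpec, counts: float,
                 rng: np.random.Generator | None = None, *,
                 second_center: float | None = None,
                 second_weight: float = 0.0,
                 ion_label: str = "", meta: dict | None = None) -> Mobilogram:
    """One synthetic ATD: (possibly bimodal) Gaussian + per-bin shot noise.

    Expected per-bin intensity is the Gaussian density times ``counts·dt``;
    with ``rng`` given, each bin is drawn independently from a Poisson with
    that mean (variance equals the expected count), otherwise the noise-free
    expectation is returned.  A grid coarser than the peak width
    (dt > sigma) cannot resolve the peak and triggers a warning.
    """
    if sigma <= 0 or counts <= 0:
        raise ValueError("sigma and counts must be positive")
    if grid.dt > sigma:
        warnings.warn(
            f"grid spacing {grid.dt} ms exceeds peak sigma {sigma} ms: peak under-resolved",
            stacklevel=2,
        )
    t = grid.times()
    dens = (1.0 - second_weight) * _gaussian(t, center, sigma)
    if second_weight > 0.0:
        if second_center is None:
            raise ValueError("second_weight > 0 requires second_center")
        dens = dens + second_weight * _gaussian(t, second_center, sigma)
    expected = counts * grid.dt * dens
    intens = expected if rng is None else rng.poisson(expected).astype(float)
    if intens.max() <= 0:  # pathological all-zero Poisson draw
        intens = intens + 1e-12
        intens[np.argmin(np.abs(t - center))] = 1.0
    return Mobilogram(t, intens, ion_label=ion_label, meta=dict(meta or {}))


def simulate_experiment(exp: SyntheticExperiment,
                        out_dir: str | Path | None = None) -> SimulationResult:
    """Generate ref/iso ATD pairs for every fragment of the requested series.

    The reference trace always follows the base peak parameters; the isomer
    trace is identical in distribution unless the fragment contains the
    planted site, in which case the shift model — attenuated by the number
    of residues beyond the site — perturbs its center and/or shape.  With
    ``out_dir`` set, chromatogram CSVs, a pairing manifest and a
    ground-truth YAML are written there.
    """
    pep = exp.peptide
    rng = np.random.default_rng(exp.seed)
    jitter = exp.acquisition_jitter * rng.standard_normal() if exp.acquisition_jitter else 0.0
    pairs: list[FragmentPair] = []
    for ser in exp.series:
        n_min_containing = pep.iso_site if ser == "b" else pep.length - pep.iso_site + 1
        for n in range(1, pep.length):
            frag = FragmentIon(series=ser, n=n, z=exp.charge, peptide_length=pep.length)
            center = exp.center_start + exp.center_drift * n
            ref = simulate_atd(center, exp.sigma, exp.grid, exp.counts, rng,
                               ion_label=frag.label,
                               meta={"charge": exp.charge, "sample": "ref"})
            perturbed = fragment_contains_site(pep.length, pep.iso_site, ser, n)
            if perturbed:
                extra = n - n_min_containing
                f = float(np.exp(-exp.shift.attenuation * extra))
                c_iso = center + exp.shift.dt_shift * f + jitter
                sig_iso = exp.sigma
                w2, c2 = 0.0, None
                if exp.shift.shape_mode == "bimodal":
                    w2 = exp.shift.bimodal_weight * f
                    c2 = c_iso + exp.shift.bimodal_offset
                elif exp.shift.shape_mode == "width":
                    sig_iso = exp.sigma * (1.0 + (exp.shift.width_factor - 1.0) * f)
                iso = simulate_atd(c_iso, sig_iso, exp.grid, exp.counts, rng,
                                   second_center=c2, second_weight=w2,
                                   ion_label=frag.label,
                                   meta={"charge": exp.charge, "sample": "iso"})
            else:
                iso = simulate_atd(center + jitter, exp.sigma, exp.grid, exp.counts,
                                   rng, ion_label=frag.label,
                                   meta={"charge": exp.charge, "sample": "iso"})
            pairs.append(FragmentPair(frag, ref, iso, perturbed))
    result = SimulationResult(exp, pairs)
    if out_dir is not None:
        _write_experiment(result, Path(out_dir))
    return result


def _write_experiment(result: SimulationResult, out_dir: Path) -> None:
    import csv

    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / "manifest.csv"
    with open(manifest_path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["sample", "series", "n", "charge", "role", "path"])
        for p in result.pairs:
            for role, trace in (("ref", p.ref), ("iso", p.iso)):
                fname = f"{role}_{p.fragment.series}{p.fragment.n}_z{p.fragment.z}.csv"
                write_chromatogram(trace, out_dir / fname)
                wr.writerow(["sim", p.fragment.series, p.fragment.n,
                             p.fragment.z, role, fname])
    with open(out_dir / "ground_truth.yaml", "w") as fh:
        yaml.safe_dump(result.ground_truth(), fh, sort_keys=False)
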