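"""Peptide and fragment-ion chemistry for b/y ladders.

A collision-induced-dissociation (CID) fragment ladder covers the peptide
backbone: ``b_n`` contains the first *n* residues (N-terminal), ``y_n`` the
last *n* (C-terminal).  Because isoaspartate (isoAsp) is isobaric with Asp,
an isomerized peptide and its reference standard produce identical fragment
m/z ladders; what differs is the ion-mobility arrival-time distribution of
fragments that *contain* the isomerized residue.  This module provides the
purely combinatorial side of that picture: which fragments contain a given
residue, the expected match/differ pattern along the ladder, and monoisotopic
m/z computation with arbitrary fixed modifications.

Residue numbering is 1-based throughout (Asp9 means the ninth residue).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml
from pyteomics import mass as _pt_mass

PROTON_MASS = 1.007276  # Da
WATER_MASS = 18.010565  # Da

#: Monoisotopic residue masses (Da), standard 20 amino acids.
RESIDUE_MASSES: dict[str, float] = dict(_pt_mass.std_aa_mass)


class DomainError(ValueError):
    """An input outside the valid peptide/fragment domain."""


@dataclass(frozen=True)
class Modification:
    """A fixed-mass modification at one residue.

    ``mass_delta`` may be zero: isoAsp is modeled as a zero-mass flag so the
    isomer and reference ladders are isobaric by construction.
    """

    position: int  # 1-based residue index
    mass_delta: float  # Da
    label: str = ""


@dataclass(frozen=True)
class Peptide:
    """A peptide described by length, optional sequence and modifications.

    Parameters
    ----------
    length
        Residue count (>= 2).
    sequence
        Optional one-letter residue string; required for m/z computation.
    modifications
        Fixed-mass modifications, e.g. a lipid anchor at a known Lys.
    iso_site
        Ground-truth 1-based position of the isomerized residue, when known.
    """

    length: int
    sequence: str | None = None
    modifications: tuple[Modification, ...] = ()
    iso_site: int | None = None

    def __post_init__(self) -> None:
        if self.length < 2:
            raise DomainError(f"peptide length must be >= 2, got {self.length}")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise DomainError(
                f"sequence length {len(self.sequence)} != declared length {self.length}"
            )
        object.__setattr__(self, "modifications", tuple(self.modifications))
        for m in self.modifications:
            if not 1 <= m.position <= self.length:
                raise DomainError(f"modification position {m.position} outside [1, {self.length}]")
        if self.iso_site is not None:
            if not 1 <= self.iso_site <= self.length:
                raise DomainError(f"iso_site {self.iso_site} outside [1, {self.length}]")
            if self.sequence is not None and self.sequence[self.iso_site - 1] not in "DN":
                warnings.warn(
                    f"iso_site {self.iso_site} is {self.sequence[self.iso_site - 1]}, "
                    "not D or N; isoAsp normally arises from Asp or Asn",
                    stacklevel=2,
                )

    @classmethod
    def from_yaml(cls, path) -> "Peptide":
        """Read a peptide description from a key-value config file.

        Keys: ``length``, optional ``sequence``, optional ``iso_site``,
        optional ``modifications`` as a list of ``position:mass:label``
        strings or ``{position, mass_delta, label}`` mappings.
        """
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        mods = []
        for item in cfg.get("modifications", []) or []:
            if isinstance(item, str):
                pos, delta, *label = item.split(":")
                mods.append(Modification(int(pos), float(delta), label[0] if label else ""))
            else:
                mods.append(
                    Modification(int(item["position"]), float(item["mass_delta"]),
                                 str(item.get("label", "")))
                )
        seq = cfg.get("sequence")
        length = int(cfg["length"]) if "length" in cfg else len(seq)
        return cls(length=length, sequence=seq, modifications=tuple(mods),
                   iso_site=cfg.get("iso_site"))


@dataclass(frozen=True)
class FragmentIon:
    """One b or y fragment ion.

    ``terminal_residue`` is the 1-based position of the fragment's inner
    terminus in the parent peptide: for ``y_n`` of an L-mer it is
    ``L - n + 1`` (the residue the fragment "ends in" when read N→C), for
    ``b_n`` it is ``n``.
    """

    series: str  # "b" or "y"
    n: int
    z: int
    peptide_length: int
    mz: float | None = None
    terminal_residue: int = field(init=False)

    def __post_init__(self) -> None:
        if self.series not in ("b", "y"):
            raise DomainError(f"series must be 'b' or 'y', got {self.series!r}")
        if not 1 <= self.n <= self.peptide_length - 1:
            raise DomainError(
                f"fragment index {self.n} outside [1, {self.peptide_length - 1}]"
            )
        if self.z < 1:
            raise DomainError(f"charge must be >= 1, got {self.z}")
        if self.mz is not None and self.mz <= 0:
            raise DomainError("m/z must be positive")
        term = self.n if self.series == "b" else self.peptide_length - self.n + 1
        object.__setattr__(self, "terminal_residue", term)

    @property
    def label(self) -> str:
        return f"{self.series}{self.n}+{self.z}"


def fragment_span(peptide_length: int, series: str, n: int) -> tuple[int, int]:
    """Inclusive 1-based residue span covered by fragment ``series``/``n``."""
    if series == "b":
        return 1, n
    if series == "y":
        return peptide_length - n + 1, peptide_length
    raise DomainError(f"series must be 'b' or 'y', got {series!r}")


def fragment_mz(peptide: Peptide, series: str, n: int, z: int) -> float:
    """Monoisotopic m/z (Th) of fragment ``series``-``n`` at charge ``z``.

    ``y_n`` = (sum of last-n residue masses + water + z·proton + in-span
    modification deltas) / z; ``b_n`` the same without water.
    """
    if peptide.sequence is None:
        raise DomainError("sequence required to compute fragment m/z")
    if not 1 <= n <= peptide.length - 1:
        raise DomainError(f"fragment index {n} outside [1, {peptide.length - 1}]")
    if z < 1:
        raise DomainError(f"charge must be >= 1, got {z}")
    lo, hi = fragment_span(peptide.length, series, n)
    try:
        residue_sum = sum(RESIDUE_MASSES[aa] for aa in peptide.sequence[lo - 1:hi])
    except KeyError as exc:
        raise DomainError(f"unknown residue {exc.args[0]!r}") from None
    mod_sum = sum(m.mass_delta for m in peptide.modifications if lo <= m.position <= hi)
    neutral = residue_sum + mod_sum + (WATER_MASS if series == "y" else 0.0)
    return (neutral + z * PROTON_MASS) / z


def fragment_contains_site(peptide_length: int, site: int, series: str, n: int) -> bool:
    """True iff fragment ``series``-``n`` covers residue ``site``."""
    if not 1 <= site <= peptide_length:
        raise DomainError(f"site {site} outside [1, {peptide_length}]")
    if not 1 <= n <= peptide_length - 1:
        raise DomainError(f"fragment index {n} outside [1, {peptide_length - 1}]")
    lo, hi = fragment_span(peptide_length, series, n)
    return lo <= site <= hi


def expected_pattern(peptide_length: int, site: int, series: str) -> np.ndarray:
    """Theoretical match/differ pattern along the fragment ladder.

    Element ``n-1`` (for n = 1..L-1) is True when fragment n contains the
    isomerized residue and its arrival-time distribution is therefore
    expected to differ from the reference standard's.  The pattern is a
    step: once a fragment contains the site, every longer fragment does.
    """
    return np.array(
        [fragment_contains_site(peptide_length, site, series, n)
         for n in range(1, peptide_length)],
        dtype=bool,
    )
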