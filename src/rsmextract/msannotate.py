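"""Monoisotopic mass arithmetic and neutral-loss annotation for
negative-mode ESI-MS peak tables.

The calculated m/z of a deprotonated ion [M-H]- is the sum of
monoisotopic atomic masses of the neutral formula minus the mass of a
hydrogen atom (1.007825 u).  Subtracting the H atom rather than the
bare proton (1.007276 u) ignores the electron gained by the anion; the
two conventions differ by 0.00055 u and the atom convention is the one
used by common peak-table software, so it is the default here (the
proton convention is available via ``convention="proton"``).

Fragment interpretation is pure mass arithmetic: a neutral loss is the
difference between a precursor (or larger fragment) m/z and a fragment
m/z, matched against a library of diagnostic losses (glycoside residues,
galloyl, water, CO, CO2, ketene, SO3, ...).  No structural identity is
ever asserted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "MONOISOTOPIC_MASS",
    "HYDROGEN_ATOM_MASS",
    "PROTON_MASS",
    "ElementalFormula",
    "monoisotopic_deprotonated_mz",
    "ppm_error",
    "LossLibrary",
    "DEFAULT_LOSSES",
    "FragmentMatch",
    "AnnotatedPeak",
    "annotate_losses",
    "annotate_peak",
]

# IUPAC 2021 monoisotopic atomic masses (u)
MONOISOTOPIC_MASS = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
}

HYDROGEN_ATOM_MASS = 1.00782503207
ELECTRON_MASS = 0.00054857991
PROTON_MASS = HYDROGEN_ATOM_MASS - ELECTRON_MASS

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalFormula:
    """An element -> count map with Hill-order canonical text form."""

    counts: tuple  # sorted (element, count) pairs

    def __post_init__(self) -> None:
        for el, c in self.counts:
            if el not in MONOISOTOPIC_MASS:
                raise ValueError(f"unknown element symbol {el!r}")
            if not (isinstance(c, int) and c > 0):
                raise ValueError(f"element counts must be positive integers, got {el}{c}")

    @classmethod
    def parse(cls, text: str) -> "ElementalFormula":
        counts: dict = {}
        pos = 0
        for m in _FORMULA_RE.finditer(text.strip()):
            if not m.group(0):
                continue
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {text!r} at position {pos}")
            pos = m.end()
            el = m.group(1)
            n = int(m.group(2)) if m.group(2) else 1
            counts[el] = counts.get(el, 0) + n
        if pos != len(text.strip()) or not counts:
            raise ValueError(f"cannot parse formula {text!r}")
        return cls(counts=cls._hill_sort(counts))

    @staticmethod
    def _hill_sort(counts: dict) -> tuple:
        # Hill order: C first, H second, then alphabetical
        def key(el):
            return {"C": (0, ""), "H": (1, "")}.get(el, (2, el))

        return tuple(sorted(counts.items(), key=lambda kv: key(kv[0])))

    def __str__(self) -> str:
        return "".join(f"{el}{c if c > 1 else ''}" for el, c in self.counts)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        counts = dict(self.counts)
        for el, c in other.counts:
            counts[el] = counts.get(el, 0) + c
        return ElementalFormula(counts=self._hill_sort(counts))

    @property
    def monoisotopic_mass(self) -> float:
        """Neutral monoisotopic mass (u)."""
        return sum(MONOISOTOPIC_MASS[el] * c for el, c in self.counts)


def monoisotopic_deprotonated_mz(formula: ElementalFormula | str, convention: str = "hydrogen_atom") -> float:
    """Calculated m/z of the [M-H]- ion for a neutral formula."""
    if isinstance(formula, str):
        formula = ElementalFormula.parse(formula)
    if convention == "hydrogen_atom":
        delta = HYDROGEN_ATOM_MASS
    elif convention == "proton":
        delta = PROTON_MASS
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return formula.monoisotopic_mass - delta


def ppm_error(observed: float, calculated: float) -> float:
    """Signed mass error in parts per million."""
    if calculated <= 0:
        raise ValueError("calculated m/z must be > 0")
    return 1e6 * (observed - calculated) / calculated


@dataclass(frozen=True)
class LossLibrary:
    """Named neutral losses with exact masses (u)."""

    losses: tuple  # (name, mass) pairs

    def __post_init__(self) -> None:
        names = [n for n, _ in self.losses]
        if len(set(names)) != len(names):
            raise ValueError("loss names must be unique")
        if any(m <= 0 for _, m in self.losses):
            raise ValueError("loss masses must be positive")

    def items(self):
        return self.losses

    def match(self, delta: float, tol_da: float) -> list:
        """Names of library losses within ``tol_da`` of ``delta``."""
        return [n for n, m in self.losses if abs(delta - m) <= tol_da]


DEFAULT_LOSSES = LossLibrary(
    losses=(
        ("hexose residue", 162.0528),
        ("deoxyhexose residue", 146.0579),
        ("pentose residue", 132.0423),
        ("galloyl", 152.0110),
        ("water", 18.0106),
        ("CO", 27.9949),
        ("ketene (C2H2O)", 42.0106),
        ("CO2", 43.9898),
        ("2CO", 55.9898),
        ("methyl radical (CH3)", 15.0235),
        ("C-glycoside cut (C2H4O2)", 60.0211),
        ("C-glycoside cut (C3H6O3)", 90.0317),
        ("C-glycoside cut (C4H8O4)", 120.0423),
        ("SO3", 79.9568),
        ("glucuronyl residue", 176.0321),
        ("rutinosyl residue", 308.1107),
    )
)


@dataclass(frozen=True)
class FragmentMatch:
    """Neutral-loss interpretation of one mass difference."""

    parent_mz: float
    fragment_mz: float
    delta: float
    matched: tuple  # names of matched losses; empty if unexplained


@dataclass(frozen=True)
class AnnotatedPeak:
    """One peak-table row: formula, masses, error, fragment annotations."""

    formula: ElementalFormula
    observed_mz: float
    calculated_mz: float
    ppm: float
    precursor_losses: tuple = ()
    pairwise_losses: tuple = ()
    name: str = ""


def annotate_losses(
    precursor_mz: float,
    fragment_mzs: Sequence[float],
    lib: LossLibrary = DEFAULT_LOSSES,
    tol_da: float = 0.05,
):
    """Match precursor->fragment and fragment->fragment mass differences.

    Returns ``(precursor_matches, pairwise_matches)``; every difference
    appears in the output, matched names empty when no library loss lies
    within ``tol_da``.  Fragment pairs are taken larger -> smaller.
    """
    if tol_da <= 0:
        raise ValueError("tol_da must be > 0")
    frags = sorted(float(f) for f in fragment_mzs)
    precursor_matches = []
    for f in frags:
        delta = precursor_mz - f
        precursor_matches.append(
            FragmentMatch(parent_mz=precursor_mz, fragment_mz=f, delta=delta, matched=tuple(lib.match(delta, tol_da)))
        )
    pairwise = []
    for i in range(len(frags)):
        for j in range(i + 1, len(frags)):
            delta = frags[j] - frags[i]
            pairwise.append(
                FragmentMatch(parent_mz=frags[j], fragment_mz=frags[i], delta=delta, matched=tuple(lib.match(delta, tol_da)))
            )
    return tuple(precursor_matches), tuple(pairwise)


def annotate_peak(
    formula: ElementalFormula | str,
    observed_mz: float,
    fragment_mzs: Sequence[float] = (),
    lib: LossLibrary = DEFAULT_LOSSES,
    tol_da: float = 0.05,
    name: str = "",
    convention: str = "hydrogen_atom",
) -> AnnotatedPeak:
    """Full annotation of one peak: calculated [M-H]- m/z, ppm error and
    neutral-loss matches of its fragment list against the library."""
    if isinstance(formula, str):
        formula = ElementalFormula.parse(formula)
    calc = monoisotopic_deprotonated_mz(formula, convention=convention)
    prec, pair = annotate_losses(observed_mz, fragment_mzs, lib=lib, tol_da=tol_da)
    return AnnotatedPeak(
        formula=formula,
        observed_mz=float(observed_mz),
        calculated_mz=calc,
        ppm=ppm_error(observed_mz, calc),
        precursor_losses=prec,
        pairwise_losses=pair,
        name=name,
    )
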