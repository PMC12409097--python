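"""Elemental formulas, natural isotope patterns, and exact masses.

Isotope patterns are represented as plain 1-D numpy arrays of fractional
abundances indexed by *nominal mass offset* (0, +1, +2, ...) relative to the
lightest isotopologue.  Mass defects between isotopes of different elements
(e.g. the -3.8 mDa offset of a 29Si species relative to a 13C species at the
same nominal offset) are deliberately not resolved here: the nominal-mass
binning matches how natural-isotope-abundance correction of GC-MS
isotopologue envelopes is done in practice, while high-resolution mass
defects only matter for the extraction windows handled in
:mod:`aspenrich.gcms_io`.

The isotope masses and abundances are pinned to one published IUPAC/CIAAW
table shipped as a versioned package data file (``data/isotopes.csv``) so
results are reproducible regardless of upstream table revisions.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "ElementFormula",
    "parse_formula",
    "natural_pattern",
    "convolve",
    "monoisotopic_mass",
    "isotope_table",
    "NATURAL_13C",
    "C13_C12_MASS_DIFF",
]

#: Natural 13C atom fraction (IUPAC representative value).
NATURAL_13C = 0.0107

#: Mass difference between 13C and 12C in Da; spacing of 13C isotopologues.
C13_C12_MASS_DIFF = 1.00336

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def _load_isotope_table() -> dict[str, list[tuple[int, float, float]]]:
    """Load the pinned isotope table: element -> [(offset, mass, abundance)]."""
    table: dict[str, list[tuple[int, float, float]]] = {}
    ref = resources.files("aspenrich").joinpath("data/isotopes.csv")
    with ref.open("r", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            table.setdefault(row["element"], []).append(
                (int(row["offset"]), float(row["mass"]), float(row["abundance"]))
            )
    for isotopes in table.values():
        isotopes.sort()
    return table


_TABLE: dict[str, list[tuple[int, float, float]]] | None = None


def isotope_table() -> dict[str, list[tuple[int, float, float]]]:
    """The pinned isotope table, loaded lazily from package data."""
    global _TABLE
    if _TABLE is None:
        _TABLE = _load_isotope_table()
    return _TABLE


@dataclass(frozen=True)
class ElementFormula:
    """An elemental composition over the supported elements (C,H,N,O,Si,S,P).

    Counts are non-negative integers and at least one atom must be present.
    """

    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        table = isotope_table()
        cleaned = {}
        for element, count in self.counts.items():
            if element not in table:
                raise ValueError(f"unsupported element: {element!r}")
            if count < 0:
                raise ValueError(f"negative count for {element}: {count}")
            if count:
                cleaned[element] = int(count)
        if not cleaned:
            raise ValueError("formula must contain at least one atom")
        object.__setattr__(self, "counts", cleaned)

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def without(self, element: str, n: int) -> "ElementFormula":
        """Composition with ``n`` atoms of ``element`` removed."""
        if self[element] < n:
            raise ValueError(
                f"cannot remove {n} {element} from formula with {self[element]}"
            )
        counts = dict(self.counts)
        counts[element] = counts[element] - n
        if counts[element] == 0:
            del counts[element]
        return ElementFormula(counts)

    def to_string(self) -> str:
        """Canonical Hill-notation string (C, H, then alphabetical)."""
        order = []
        if "C" in self.counts:
            order.append("C")
            if "H" in self.counts:
                order.append("H")
            order.extend(sorted(e for e in self.counts if e not in ("C", "H")))
        else:
            order = sorted(self.counts)
        return "".join(
            f"{e}{self.counts[e]}" if self.counts[e] > 1 else e for e in order
        )

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


def parse_formula(text: str) -> ElementFormula:
    """Parse a Hill-notation formula string such as ``"C13H31NO4Si3"``."""
    if not text or not text.strip():
        raise ValueError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(text):
        if match.start() != pos:
            raise ValueError(f"malformed formula string: {text!r}")
        element, digits = match.groups()
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = match.end()
    if pos != len(text):
        raise ValueError(f"malformed formula string: {text!r}")
    return ElementFormula(counts)


def _single_atom_pattern(element: str) -> np.ndarray:
    isotopes = isotope_table()[element]
    pattern = np.zeros(isotopes[-1][0] + 1)
    for offset, _mass, abundance in isotopes:
        pattern[offset] = abundance
    return pattern


def convolve(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Discrete convolution of two isotope patterns, renormalized to sum 1."""
    out = np.convolve(np.asarray(a, float), np.asarray(b, float))
    return out / out.sum()


def _prune(pattern: np.ndarray, prune: float) -> np.ndarray:
    # drop trailing entries below the prune threshold, then renormalize
    keep = len(pattern)
    while keep > 1 and pattern[keep - 1] < prune:
        keep -= 1
    pattern = pattern[:keep]
    return pattern / pattern.sum()


def natural_pattern(formula: ElementFormula | dict[str, int] | str,
                    prune: float = 1e-9) -> np.ndarray:
    """Natural isotopologue pattern of a formula by elementwise convolution.

    Parameters
    ----------
    formula
        An :class:`ElementFormula`, a ``{element: count}`` mapping, or a
        Hill-notation string.
    prune
        Trailing pattern entries below this fraction are removed and the
        pattern renormalized; must lie in [0, 1e-6].
    """
    if not 0 <= prune <= 1e-6:
        raise ValueError("prune must be in [0, 1e-6]")
    if isinstance(formula, str):
        formula = parse_formula(formula)
    elif isinstance(formula, dict):
        formula = ElementFormula(formula)
    pattern = np.ones(1)
    for element, count in formula.counts.items():
        atom = _single_atom_pattern(element)
        # exponentiation by squaring keeps this cheap for large H counts
        power = np.ones(1)
        base = atom
        n = count
        while n:
            if n & 1:
                power = np.convolve(power, base)
            n >>= 1
            if n:
                base = np.convolve(base, base)
        pattern = np.convolve(pattern, power)
    return _prune(pattern / pattern.sum(), prune)


def binomial_13c_pattern(n_carbons: int, p: float = NATURAL_13C) -> np.ndarray:
    """Isotopologue pattern of ``n_carbons`` carbons each 13C with probability p."""
    pattern = np.ones(1)
    atom = np.array([1.0 - p, p])
    for _ in range(n_carbons):
        pattern = np.convolve(pattern, atom)
    return pattern


def monoisotopic_mass(formula: ElementFormula | dict[str, int] | str) -> float:
    """Sum of lightest-isotope masses, in Da."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    elif isinstance(formula, dict):
        formula = ElementFormula(formula)
    table = isotope_table()
    return sum(table[el][0][1] * n for el, n in formula.counts.items())
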