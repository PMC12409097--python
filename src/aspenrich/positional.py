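"""Per-carbon-position 13C enrichment from fragment enrichments.

Fragment E13C values are carbon-number-weighted averages over the backbone
positions a fragment covers, so positional enrichments follow from linear
combinations of fragment enrichments.  With fragments covering {1,2,3,4},
{2,3,4}, {2,3} and {3,4}:

    e1 = 4*E1234 - 3*E234
    e2 = 3*E234  - 2*E34
    e3 = 2*E23 + 2*E34 - 3*E234
    e4 = 3*E234  - 2*E23

These identities imply mean(e1..e4) = E1234 exactly.  Standard deviations
are propagated under an independence assumption between fragments (they
share the ion source, so correlations are possible but unknown; see the
methods note), e.g. sd(e1) = sqrt(16*sd(E1234)^2 + 9*sd(E234)^2).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .fragments import FragmentSpec

__all__ = [
    "FragmentEnrichment",
    "PositionalEnrichment",
    "positional_e13c",
    "propagate_sd",
    "cross_check",
]

_REQUIRED_COVERAGES = {
    "E1234": frozenset({1, 2, 3, 4}),
    "E234": frozenset({2, 3, 4}),
    "E23": frozenset({2, 3}),
    "E34": frozenset({3, 4}),
}

#: Enrichment values outside [0 - tol, 1 + tol] are flagged (not clipped).
_E13C_TOLERANCE = 0.02


@dataclass
class FragmentEnrichment:
    """E13C of one fragment with its backbone coverage."""

    coverage: frozenset[int]
    e13c: float
    sd: float | None = None
    fragment: FragmentSpec | None = None
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.coverage = frozenset(self.coverage)
        if not (-_E13C_TOLERANCE <= self.e13c <= 1 + _E13C_TOLERANCE):
            self.flags.add("e13c_out_of_range")
        if self.sd is not None and self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass
class PositionalEnrichment:
    """Per-position enrichments e1..e4 with propagated SDs and provenance."""

    e: np.ndarray
    sd: np.ndarray | None = None
    provenance: dict[int, tuple[str, ...]] = field(default_factory=dict)
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.e = np.asarray(self.e, dtype=float)
        # noise can push positions slightly outside [0,1]; values are kept
        # as-is (so accuracy statistics stay unbiased) but flagged
        finite = self.e[np.isfinite(self.e)]
        if finite.size and (finite.min() < -0.05 or finite.max() > 1.05):
            self.flags.add("position_out_of_range")


def _check_coverage(name: str, frag: FragmentEnrichment) -> None:
    if frag.coverage != _REQUIRED_COVERAGES[name]:
        raise ValueError(
            f"{name} requires coverage {sorted(_REQUIRED_COVERAGES[name])}, "
            f"got {sorted(frag.coverage)}"
        )


def positional_e13c(
    E1234: FragmentEnrichment,
    E234: FragmentEnrichment,
    E23: FragmentEnrichment | None = None,
    E34: FragmentEnrichment | None = None,
) -> PositionalEnrichment:
    """Combine fragment enrichments into per-position enrichments.

    ``E23`` and ``E34`` may be omitted (e.g. nominal-mass EI data provides
    only whole-backbone and {2,3,4} fragments); positions that depend on a
    missing fragment are reported as NaN (undetermined) rather than imputed.
    """
    _check_coverage("E1234", E1234)
    _check_coverage("E234", E234)
    if E23 is not None:
        _check_coverage("E23", E23)
    if E34 is not None:
        _check_coverage("E34", E34)

    nan = float("nan")
    e1 = 4 * E1234.e13c - 3 * E234.e13c
    e2 = 3 * E234.e13c - 2 * E34.e13c if E34 is not None else nan
    e3 = (
        2 * E23.e13c + 2 * E34.e13c - 3 * E234.e13c
        if E23 is not None and E34 is not None
        else nan
    )
    e4 = 3 * E234.e13c - 2 * E23.e13c if E23 is not None else nan

    def _label(frag: FragmentEnrichment | None) -> str:
        if frag is None:
            return "missing"
        if frag.fragment is not None:
            return f"{frag.fragment.analyte} m/z {frag.fragment.ion_label}"
        return f"coverage {sorted(frag.coverage)}"

    provenance = {
        1: (_label(E1234), _label(E234)),
        2: (_label(E234), _label(E34)),
        3: (_label(E23), _label(E34), _label(E234)),
        4: (_label(E234), _label(E23)),
    }
    flags: set[str] = set()
    for frag in (E1234, E234, E23, E34):
        if frag is not None:
            flags |= frag.flags
    if E23 is None or E34 is None:
        flags.add("undetermined_positions")
    result = PositionalEnrichment(
        e=np.array([e1, e2, e3, e4]), provenance=provenance, flags=flags
    )
    result.sd = propagate_sd(E1234, E234, E23, E34)
    return result


def propagate_sd(
    E1234: FragmentEnrichment,
    E234: FragmentEnrichment,
    E23: FragmentEnrichment | None = None,
    E34: FragmentEnrichment | None = None,
) -> np.ndarray | None:
    """Propagate fragment SDs to positional SDs (independence assumption)."""
    inputs = [E1234, E234, E23, E34]
    present = [f for f in inputs if f is not None]
    if any(f.sd is None for f in present):
        return None

    def sd(frag: FragmentEnrichment | None) -> float:
        return frag.sd if frag is not None else float("nan")

    s1234, s234, s23, s34 = (sd(f) for f in inputs)
    return np.array(
        [
            math.sqrt(16 * s1234**2 + 9 * s234**2),
            math.sqrt(9 * s234**2 + 4 * s34**2),
            math.sqrt(4 * s23**2 + 4 * s34**2 + 9 * s234**2),
            math.sqrt(9 * s234**2 + 4 * s23**2),
        ]
    )


def cross_check(
    alternatives: list[PositionalEnrichment], tol: float = 0.02
) -> dict:
    """Compare alternative positional calculations as an internal sanity check.

    Returns a report with per-position maximum pairwise absolute difference,
    the list of pairwise comparisons, and positions whose disagreement
    exceeds ``tol``.
    """
    if len(alternatives) < 2:
        raise ValueError("need at least 2 alternative calculations")
    pairs = list(itertools.combinations(range(len(alternatives)), 2))
    comparisons = []
    max_delta = np.zeros(4)
    for i, j in pairs:
        delta = np.abs(alternatives[i].e - alternatives[j].e)
        comparisons.append({"pair": (i, j), "abs_delta": delta})
        max_delta = np.fmax(max_delta, delta)
    flagged = [p + 1 for p in range(4) if max_delta[p] > tol]
    return {
        "max_abs_delta": max_delta,
        "comparisons": comparisons,
        "flagged_positions": flagged,
        "tol": tol,
    }
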