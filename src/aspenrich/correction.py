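"""Natural-isotope-abundance (NIA) correction of mass isotopologue
distributions and fractional 13C enrichment (E13C).

The measured isotopologue envelope of a fragment ion mixes the tracer signal
with naturally occurring heavy isotopes of every atom in the ion (13C of
derivative carbons, 29/30Si of the silyl groups, 2H, 15N, 17/18O).  The
correction expresses the measured envelope as a linear combination of
theoretical envelopes, one per tracer-13C count j = 0..n, where column j is
the natural pattern of the formula minus the n backbone carbons, shifted by
j, convolved with a binomial natural-13C pattern over the remaining n-j
backbone carbons.  Solving the resulting non-negative least-squares problem
yields tracer isotopologue fractions x0..xn and

    E13C = sum_j j * x_j / n

the average tracer 13C fraction over the covered backbone carbons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.optimize

from .fragments import FragmentSpec
from .isotopes import (
    NATURAL_13C,
    ElementFormula,
    binomial_13c_pattern,
    natural_pattern,
)

__all__ = [
    "CorrectionMatrix",
    "CorrectedMID",
    "StandardCertificate",
    "build_matrix",
    "correct",
    "e13c_of",
    "expected_e13c",
    "tracer_excess",
]


@dataclass(frozen=True)
class CorrectionMatrix:
    """NIA correction matrix for one fragment.

    ``matrix`` has one row per measured mass offset (0..m) and one column per
    tracer-13C count (0..n_tracer).  Columns sum to <= 1; mass truncated to
    the measured length.
    """

    fragment: FragmentSpec
    matrix: np.ndarray

    @property
    def n_measured(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_tracer(self) -> int:
        return self.matrix.shape[1] - 1


@dataclass
class CorrectedMID:
    """Tracer isotopologue fractions after NIA correction."""

    fractions: np.ndarray
    e13c: float
    residual_norm: float
    flags: set[str] = field(default_factory=set)
    fragment: FragmentSpec | None = None
    sample_id: str = ""


@dataclass(frozen=True)
class StandardCertificate:
    """Certificate of a 13C-labelled aspartic acid reference substance.

    ``purity`` is the certified 13C atom fraction at the labelled
    position(s); ``label_positions`` is empty for the natural standard.
    """

    label_positions: frozenset[int]
    purity: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.purity <= 1:
            raise ValueError("purity must be in (0, 1]")


def rest_pattern(formula: ElementFormula, n_tracer: int):
    """Natural pattern of a formula with its tracer carbons removed
    (a delta at offset 0 when nothing remains, e.g. a bare carbon cluster)."""
    counts = dict(formula.counts)
    if counts.get("C", 0) < n_tracer:
        raise ValueError("fewer carbons in formula than tracer positions")
    counts["C"] -= n_tracer
    if counts["C"] == 0:
        del counts["C"]
    if not counts:
        return np.ones(1)
    return natural_pattern(ElementFormula(counts))


def build_matrix(frag: FragmentSpec, n_measured: int) -> CorrectionMatrix:
    """Build the NIA correction matrix for a fragment.

    ``n_measured`` is the number of measured mass offsets and must be at
    least ``n_tracer + 1``.
    """
    if frag.ion_formula is None:
        raise ValueError(f"fragment {frag.key} has no ion formula")
    n = frag.n_tracer
    if n_measured < n + 1:
        raise ValueError("n_measured must be >= n_tracer + 1")
    rest = rest_pattern(frag.ion_formula, n)
    matrix = np.zeros((n_measured, n + 1))
    for j in range(n + 1):
        unlabeled = binomial_13c_pattern(n - j)
        column = np.convolve(rest, unlabeled)
        column = np.concatenate([np.zeros(j), column])[:n_measured]
        matrix[: len(column), j] = column
    return CorrectionMatrix(fragment=frag, matrix=matrix)


def correct(
    raw,
    M: CorrectionMatrix,
    method: str = "nnls",
    poor_fit_threshold: float = 0.05,
) -> CorrectedMID:
    """NIA-correct a raw MID measurement to tracer isotopologue fractions.

    ``raw`` is a :class:`~aspenrich.gcms_io.MIDMeasurement` or a plain
    abundance vector.  ``method='nnls'`` (default) solves the non-negative
    least-squares problem; ``method='lstsq'`` is an unconstrained solve kept
    as a cross-check, with negative fractions clipped and flagged.
    """
    fragment = getattr(raw, "fragment", None)
    sample_id = getattr(raw, "sample_id", "")
    abundances = np.asarray(getattr(raw, "abundances", raw), dtype=float)
    if abundances.sum() <= 0:
        raise ValueError("all-zero raw abundance vector")

    matrix = M.matrix
    raw_flags = getattr(raw, "flags", None)  # ndarray.flags is not ours
    flags: set[str] = set(raw_flags) if isinstance(raw_flags, set) else set()
    if len(abundances) < matrix.shape[0]:
        # drop trailing matrix rows and renormalize columns
        matrix = matrix[: len(abundances)]
        matrix = matrix / matrix.sum(axis=0, keepdims=True)
        flags.add("matrix_truncated")
    measured = abundances[: matrix.shape[0]]
    measured = measured / measured.sum()

    if method == "nnls":
        x, _ = scipy.optimize.nnls(matrix, measured)
    elif method == "lstsq":
        x, *_ = np.linalg.lstsq(matrix, measured, rcond=None)
        if np.any(x < -1e-12):
            flags.add("negative_clipped")
        x = np.clip(x, 0, None)
    else:
        raise ValueError(f"unknown method {method!r}")

    residual = np.linalg.norm(matrix @ x - measured) / np.linalg.norm(measured)
    if x.sum() <= 0:
        raise ValueError("degenerate correction: zero solution")
    fractions = x / x.sum()
    if residual > poor_fit_threshold:
        flags.add("poor_fit")
    return CorrectedMID(
        fractions=fractions,
        e13c=e13c_of(fractions, M.n_tracer),
        residual_norm=float(residual),
        flags=flags,
        fragment=fragment,
        sample_id=sample_id,
    )


def corrected_to_frame(corrected: list[CorrectedMID]):
    """Tabulate corrected MIDs (one row per measurement) for CSV export."""
    import pandas as pd

    rows = []
    for c in corrected:
        frag = c.fragment
        rows.append(
            {
                "sample_id": c.sample_id,
                "fragment": f"{frag.analyte} m/z {frag.ion_label}" if frag else "",
                "fractions": ";".join(f"{x:.6g}" for x in c.fractions),
                "e13c_percent": 100.0 * c.e13c,
                "residual": c.residual_norm,
                "flags": ";".join(sorted(c.flags)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["sample_id", "fragment", "fractions", "e13c_percent",
                 "residual", "flags"],
    )


def e13c_of(fractions, n: int) -> float:
    """Fractional 13C enrichment of tracer isotopologue fractions.

    ``sum_j j * x_j / n`` for fractions x over j = 0..len-1.
    """
    if n == 0:
        raise ValueError("n must be positive")
    fractions = np.asarray(fractions, dtype=float)
    return float(np.dot(np.arange(len(fractions)), fractions) / n)


def tracer_excess(atom_fraction: float, natural: float = NATURAL_13C) -> float:
    """Tracer 13C fraction corresponding to a total 13C atom fraction.

    NIA correction attributes the natural 13C share of a position to the
    unlabelled pool, so a standard certified at total atom fraction ``p``
    comes back with tracer enrichment ``(p - a) / (1 - a)``.
    """
    return (atom_fraction - natural) / (1.0 - natural)


def expected_e13c(
    cert: StandardCertificate,
    position: int | str,
    fraction_in_mixture: float = 1.0,
) -> float:
    """Expected post-correction enrichment of a standard in a mixture.

    ``position`` is a backbone carbon 1..4 or ``"whole"`` for the
    whole-molecule average.  Expected enrichment at a labelled position is
    ``fraction_in_mixture * purity``; 0 elsewhere.
    """
    if position == "whole":
        return float(
            np.mean([expected_e13c(cert, p, fraction_in_mixture) for p in range(1, 5)])
        )
    if position not in (1, 2, 3, 4):
        raise ValueError("position must be 1..4 or 'whole'")
    if position in cert.label_positions:
        return fraction_in_mixture * cert.purity
    return 0.0
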