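"""Molar aspartate quantification and molar positional 13C.

The quantifier is the *sum of all isotopologue abundances* of the chosen
analyte, so the labelling state does not bias concentration.  Responses are
ratios to the 13C6-sorbitol internal standard (25 ng per injection),
calibrated by an ordinary least-squares line against a dilution series of
non-labelled reference compound, then normalized to OD750 and sample
volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from .positional import PositionalEnrichment

__all__ = [
    "SampleMeta",
    "CalibrationModel",
    "QuantResult",
    "fit_calibration",
    "quantify",
    "positional_molar",
    "ASPARTATE_MW",
]

#: Molecular weight of aspartic acid, g/mol.
ASPARTATE_MW = 133.103


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    od750: float
    volume_ml: float
    time_min: float = 0.0
    injection_ng: float | None = None
    split_ratio: float = 1.0
    is_abundance: float = 0.0  # 13C6-sorbitol internal standard counts

    def __post_init__(self) -> None:
        if self.od750 <= 0 or self.volume_ml <= 0:
            raise ValueError("od750 and volume_ml must be positive")
        if self.split_ratio < 1:
            raise ValueError("split_ratio must be >= 1")


@dataclass(frozen=True)
class CalibrationModel:
    """OLS line of response (sum MID / IS abundance) vs amount (ng)."""

    slope: float
    intercept: float
    r_squared: float
    levels_ng: tuple[float, ...] = ()

    @property
    def response_range(self) -> tuple[float, float]:
        responses = [self.slope * ng + self.intercept for ng in self.levels_ng]
        return (min(responses), max(responses)) if responses else (0.0, np.inf)


@dataclass
class QuantResult:
    pmol_per_od_ml: float
    amount_ng: float
    flags: set[str] = field(default_factory=set)


def fit_calibration(levels: list[tuple[float, float]]) -> CalibrationModel:
    """Fit the calibration line over (amount ng, response) pairs.

    Requires at least 3 distinct amounts and a positive slope.
    """
    amounts = np.array([ng for ng, _ in levels], dtype=float)
    responses = np.array([r for _, r in levels], dtype=float)
    if len(np.unique(amounts)) < 3:
        raise ValueError("need at least 3 distinct calibration levels")
    fit = scipy.stats.linregress(amounts, responses)
    if fit.slope <= 0:
        raise ValueError(f"non-positive calibration slope: {fit.slope}")
    return CalibrationModel(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        levels_ng=tuple(sorted(set(amounts))),
    )


def quantify(
    sum_mid: float,
    meta: SampleMeta,
    cal: CalibrationModel,
    mw: float = ASPARTATE_MW,
    aliquot_factor: float = 1.0,
) -> QuantResult:
    """Convert a summed isotopologue abundance to pmol per OD750 per mL.

    The response ``sum_mid / is_abundance`` is inverted through the
    calibration line to ng injected, multiplied by the split ratio and an
    aliquot factor covering extraction/derivatization partitioning, then
    converted via ``mw`` to pmol and normalized by OD750 x volume.
    """
    if meta.is_abundance <= 0:
        raise ValueError("internal standard abundance must be positive")
    flags: set[str] = set()
    response = sum_mid / meta.is_abundance
    low, high = cal.response_range
    if response < low:
        flags.add("below_calibration_range")
    elif response > high:
        flags.add("above_calibration_range")
    amount_ng = (response - cal.intercept) / cal.slope * meta.split_ratio
    amount_ng *= aliquot_factor
    if amount_ng < 0:
        amount_ng = 0.0
        flags.add("below_calibration_range")
    pmol = amount_ng / mw * 1e3  # ng / (g/mol) -> pmol
    return QuantResult(
        pmol_per_od_ml=pmol / (meta.od750 * meta.volume_ml),
        amount_ng=amount_ng,
        flags=flags,
    )


def positional_molar(
    enrichment: PositionalEnrichment | np.ndarray,
    conc_pmol_per_od_ml: float,
) -> np.ndarray:
    """Molar 13C per backbone position: m_i = e_i x aspartate concentration."""
    if conc_pmol_per_od_ml < 0:
        raise ValueError("concentration must be non-negative")
    e = (
        enrichment.e
        if isinstance(enrichment, PositionalEnrichment)
        else np.asarray(enrichment, float)
    )
    return e * conc_pmol_per_od_ml
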