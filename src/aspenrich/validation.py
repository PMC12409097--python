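"""Standard-mixture designs, accuracy/precision statistics, detection-limit
scan, and saturation flagging.

Method validation rests on gravimetric mixtures of certified 13C-labelled
aspartic acid standards with natural aspartic acid.  Expected positional
enrichments follow from composition arithmetic (mole fraction x certificate
purity); accuracy is the mean deviation of measured from expected
enrichment and precision the SD of that deviation, both in percentage
points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .correction import StandardCertificate

__all__ = [
    "CERTIFICATES",
    "MixtureDesign",
    "DeviationStats",
    "table_s1_designs",
    "expected_positional",
    "deviation_stats",
    "detection_scan",
    "flag_saturation",
]

#: Certified reference substances: 13C atom fraction at the labelled
#: positions per the manufacturer's analytical certificates.
CERTIFICATES: dict[str, StandardCertificate] = {
    "natural": StandardCertificate(frozenset(), purity=1.0),
    "U-13C": StandardCertificate(frozenset({1, 2, 3, 4}), purity=0.990),
    "1-13C": StandardCertificate(frozenset({1}), purity=0.996),
    "2-13C": StandardCertificate(frozenset({2}), purity=0.997),
    "3-13C": StandardCertificate(frozenset({3}), purity=0.996),
    "4-13C": StandardCertificate(frozenset({4}), purity=0.993),
}


@dataclass(frozen=True)
class MixtureDesign:
    """A standard mixture: components with mole fractions summing to 1."""

    name: str
    components: tuple[tuple[StandardCertificate, float], ...]
    total_ng_injected: float = 25.0

    def __post_init__(self) -> None:
        total = sum(f for _, f in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mole fractions sum to {total}, expected 1")


@dataclass
class DeviationStats:
    """Accuracy (mean deviation) and precision (SD of deviation), in
    percentage points."""

    group: str
    mean_dev: float
    sd_dev: float
    n: int


def table_s1_designs() -> list[MixtureDesign]:
    """Reconstructed 36-mixture validation panel.

    The certified composition list itself is not publicly deposited; this
    reconstruction follows the stated design: the six pure standards, each
    labelled standard mixed with natural aspartic acid at molar ratios
    5:95, 10:90, 50:50, 90:10 and 95:5, and the equal 1:1:1:1 positional mix
    isotopically diluted by natural aspartic acid to 100, 50, 20, 10 and 4 %
    of total — 6 + 25 + 5 = 36 mixtures.
    """
    natural = CERTIFICATES["natural"]
    designs: list[MixtureDesign] = []
    for name, cert in CERTIFICATES.items():
        designs.append(MixtureDesign(f"pure {name}", ((cert, 1.0),)))
    ratios = (0.05, 0.10, 0.50, 0.90, 0.95)
    for name, cert in CERTIFICATES.items():
        if name == "natural":
            continue
        for labeled_fraction in ratios:
            designs.append(
                MixtureDesign(
                    f"{name} {labeled_fraction:.0%} in natural",
                    ((cert, labeled_fraction), (natural, 1.0 - labeled_fraction)),
                )
            )
    positional = [CERTIFICATES[k] for k in ("1-13C", "2-13C", "3-13C", "4-13C")]
    for dilution in (1.0, 0.5, 0.2, 0.1, 0.04):
        components = [(cert, dilution / 4.0) for cert in positional]
        if dilution < 1.0:
            components.append((natural, 1.0 - dilution))
        designs.append(
            MixtureDesign(
                f"equal positional mix at {dilution:.0%}", tuple(components)
            )
        )
    assert len(designs) == 36
    return designs


def expected_positional(design: MixtureDesign) -> np.ndarray:
    """Expected per-position enrichment (fractions): e_i = sum_c f_c * purity_c
    over components labelled at position i."""
    expected = np.zeros(4)
    for cert, mole_fraction in design.components:
        for position in cert.label_positions:
            expected[position - 1] += mole_fraction * cert.purity
    return expected


def deviation_stats(
    measured: list[np.ndarray] | np.ndarray,
    expected: np.ndarray | float,
    group: str = "",
) -> DeviationStats:
    """Accuracy/precision of measured enrichments against an expectation.

    Deviations (measured - expected) are converted to percentage points and
    pooled; the SD uses ddof=1 and needs at least 2 measurements.
    """
    measured = np.asarray(measured, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if measured.ndim > 1 and measured.shape[-1] != np.atleast_1d(expected).shape[-1]:
        raise ValueError("measured and expected dimensions do not match")
    deviations = (measured - expected).ravel() * 100.0
    deviations = deviations[np.isfinite(deviations)]
    if deviations.size < 2:
        raise ValueError("need at least 2 measurements for deviation stats")
    return DeviationStats(
        group=group,
        mean_dev=float(deviations.mean()),
        sd_dev=float(deviations.std(ddof=1)),
        n=int(deviations.size),
    )


def detection_scan(
    deviations_by_level: dict[float, dict[str, list[float]]],
    threshold_pp: float = 1.0,
) -> dict[str, float | None]:
    """Minimal acceptable injection amount per fragment.

    ``deviations_by_level`` maps injection amount (ng) to per-fragment lists
    of enrichment deviations in percentage points.  A level passes when the
    mean |deviation| is within ``threshold_pp``; the reported minimum is the
    lowest level from which all higher levels also pass (``None`` when no
    level qualifies).
    """
    if len(deviations_by_level) < 3:
        raise ValueError("need at least 3 injection levels")
    levels = sorted(deviations_by_level)
    fragments = sorted(
        {frag for devs in deviations_by_level.values() for frag in devs}
    )
    result: dict[str, float | None] = {}
    for frag in fragments:
        minimum: float | None = None
        for level in reversed(levels):
            devs = deviations_by_level[level].get(frag)
            if devs is None or np.mean(np.abs(devs)) > threshold_pp:
                break
            minimum = level
        result[frag] = minimum
    return result


def flag_saturation(abundance: float, threshold: float = 1e7) -> bool:
    """True when a fragment's summed abundance exceeds the detector
    saturation threshold (such measurements are excluded from positional
    calculation unless acquired with an adjusted split ratio)."""
    if abundance < 0:
        raise ValueError("abundance must be non-negative")
    return abundance > threshold
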