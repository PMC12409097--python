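"""Fragment-ion registry for silylated aspartic acid derivatives.

Positional enrichment analysis needs fragment ions whose covered
backbone-carbon positions are known: the whole backbone {1,2,3,4}, the
{2,3,4} fragment formed by loss of the 1-C carboxy group, and smaller
two-carbon fragments.  The registry is shipped as data (CSV), not code, so
certified m/z values and formulas can be dropped in without a release.

Entries whose certified m/z/formula are not publicly available ship as
``requires-user-input`` placeholders; :func:`default_registry` resolves them
by default from a companion file of *synthetic stand-in* formulas
(``data/synthetic_fragments.csv``) that are chemically plausible but not
certified, so that simulation-driven workflows run end to end.  Stand-ins
carry ``status='synthetic-standin'``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .isotopes import ElementFormula, monoisotopic_mass, parse_formula

__all__ = ["FragmentSpec", "load_registry", "default_registry", "lookup"]

#: Maximum allowed |exact_mz - monoisotopic mass| for APCI registry entries.
MASS_TOLERANCE_DA = 0.01


@dataclass(frozen=True)
class FragmentSpec:
    """A registered fragment ion of a derivatized analyte.

    ``ion_formula`` is the composition of the charged species as detected
    (e.g. the [M+H]+ formula includes the proton).  ``backbone_positions``
    are the aspartate backbone carbons (1..4) retained in the fragment.
    """

    analyte: str
    ion_label: int
    exact_mz: float | None
    ion_formula: ElementFormula | None
    backbone_positions: frozenset[int]
    ionization: str = "APCI"
    status: str = "verified"
    notes: str = ""

    def __post_init__(self) -> None:
        if not self.backbone_positions:
            raise ValueError("backbone_positions must be non-empty")
        if not self.backbone_positions <= {1, 2, 3, 4}:
            raise ValueError("backbone_positions must be a subset of {1,2,3,4}")
        if self.ion_formula is not None:
            if self.n_tracer > self.ion_formula["C"]:
                raise ValueError(
                    "more tracer carbons than carbons in the ion formula"
                )
            if (
                self.ionization == "APCI"
                and self.exact_mz is not None
                and abs(self.exact_mz - monoisotopic_mass(self.ion_formula))
                > MASS_TOLERANCE_DA
            ):
                raise ValueError(
                    f"exact_mz {self.exact_mz} inconsistent with formula "
                    f"{self.ion_formula} for {self.analyte} m/z {self.ion_label}"
                )

    @property
    def n_tracer(self) -> int:
        """Number of aspartate backbone carbons covered by the fragment."""
        return len(self.backbone_positions)

    @property
    def is_placeholder(self) -> bool:
        return self.ion_formula is None

    @property
    def key(self) -> tuple[str, int]:
        return (self.analyte, self.ion_label)


def _row_to_spec(row: pd.Series) -> FragmentSpec:
    formula = None
    if isinstance(row["ion_formula"], str) and row["ion_formula"].strip():
        formula = parse_formula(row["ion_formula"])
    mz = None if pd.isna(row["exact_mz"]) else float(row["exact_mz"])
    positions = frozenset(int(p) for p in str(row["backbone_positions"]).split(";"))
    return FragmentSpec(
        analyte=row["analyte"],
        ion_label=int(row["ion_label"]),
        exact_mz=mz,
        ion_formula=formula,
        backbone_positions=positions,
        ionization=row["ionization"],
        status=row.get("status", "verified"),
        notes=row.get("notes", "") if isinstance(row.get("notes"), str) else "",
    )


def load_registry(path: str | Path) -> list[FragmentSpec]:
    """Load a fragment registry from a CSV file.

    Expected header: analyte, ion_label, exact_mz, ion_formula,
    backbone_positions (``;``-separated), ionization, status, notes.
    """
    frame = pd.read_csv(path)
    return [_row_to_spec(row) for _, row in frame.iterrows()]


def _packaged(name: str) -> list[FragmentSpec]:
    with resources.as_file(resources.files("aspenrich") / "data" / name) as p:
        return load_registry(p)


def default_registry(include_synthetic: bool = True) -> list[FragmentSpec]:
    """The shipped fragment registry for aspartic acid 3TMS / 2TMS.

    With ``include_synthetic=True`` (default), placeholder entries whose
    certified formulas must normally be supplied by the user are resolved
    from the packaged synthetic stand-in file so the full positional
    pipeline can run on simulated data.
    """
    entries = {spec.key: spec for spec in _packaged("fragment_registry.csv")}
    if include_synthetic:
        for spec in _packaged("synthetic_fragments.csv"):
            if entries.get(spec.key) is None or entries[spec.key].is_placeholder:
                entries[spec.key] = spec
    return list(entries.values())


def lookup(registry: list[FragmentSpec], analyte: str, ion_label: int) -> FragmentSpec:
    """Find a fragment by analyte name and nominal ion label."""
    for spec in registry:
        if spec.analyte == analyte and spec.ion_label == int(ion_label):
            return spec
    raise KeyError(f"no registry entry for {analyte!r} m/z {ion_label}")
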