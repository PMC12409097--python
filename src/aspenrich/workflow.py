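"""End-to-end analysis workflows.

Two pipelines mirror the two halves of the method:

* standards validation — a simulated (or measured) mixture panel of
  certified standards is NIA-corrected, combined into positional
  enrichments, and summarized as accuracy/precision statistics per fragment
  and per carbon position;
* labelling analysis — a dynamic 13CO2 pulse experiment is processed
  through correction, positional algebra, molar quantification and
  sigmoidal fitting into per-position assimilation rates under light and
  dark conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .correction import CorrectionMatrix, build_matrix, correct
from .fragments import FragmentSpec, default_registry, lookup
from .kinetics import SigmoidalFit, TimeCourse, fit_sigmoid, rate_table
from .positional import FragmentEnrichment, PositionalEnrichment, positional_e13c
from .quantify import SampleMeta, fit_calibration, positional_molar, quantify
from .validation import (
    MixtureDesign,
    deviation_stats,
    expected_positional,
    flag_saturation,
    table_s1_designs,
)

__all__ = [
    "RunConfig",
    "StandardsReport",
    "LabelingReport",
    "run_standards_validation",
    "run_labeling_analysis",
    "analyze_labeling_dataset",
]

#: Fragments feeding the four-coverage positional algebra (whole backbone is
#: taken from the [M]+ ion, whose MID is free of the [M+H]+/[M]+ overlap).
POSITIONAL_FRAGMENTS = {"E1234": 349, "E234": 232, "E23": 216, "E34": 203}


@dataclass
class RunConfig:
    """Configuration for the command-line workflows."""

    mode: str = "standards"  # standards | labeling
    seed: int = 0
    out_dir: str | None = None
    cv_multiplicative: float = 0.01
    baseline_sd: float = 0.0
    saturation_threshold: float = 1e7
    injection_ng: float = 25.0
    replicates: int = 4
    conditions: tuple[str, ...] = ("light", "dark")
    accuracy_bound_pp: float = 1.0
    precision_bound_pp: float = 2.5
    fragment_bound_pp: float = 1.1
    threshold_ratio: float = 0.75
    threshold_aic: float = -10.0
    registry_path: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "conditions" in raw:
            raw["conditions"] = tuple(raw["conditions"])
        return cls(**raw)


def _noise_from_config(cfg: RunConfig):
    from .simulate import NoiseModel

    return NoiseModel(
        cv_multiplicative=cfg.cv_multiplicative,
        baseline_sd=cfg.baseline_sd,
        saturation_threshold=cfg.saturation_threshold,
    )


def _registry_from_config(cfg: RunConfig) -> list[FragmentSpec]:
    if cfg.registry_path:
        from .fragments import load_registry

        return load_registry(cfg.registry_path)
    return default_registry()


@dataclass
class StandardsReport:
    fragment_stats: pd.DataFrame
    position_stats: pd.DataFrame
    excluded: list[str]
    accuracy_bound_pp: float = 1.0
    precision_bound_pp: float = 2.5
    fragment_bound_pp: float = 1.1

    @property
    def positions_pass(self) -> bool:
        return bool(
            (self.position_stats["mean_dev"].abs() < self.accuracy_bound_pp).all()
            and (self.position_stats["sd_dev"] < self.precision_bound_pp).all()
        )

    def summary(self) -> str:
        lines = ["standards validation report", ""]
        lines.append("per-position accuracy/precision (percentage points):")
        for _, row in self.position_stats.iterrows():
            lines.append(
                f"  {int(row['position'])}-C  mean dev {row['mean_dev']:+.3f}  "
                f"SD {row['sd_dev']:.3f}  (n={int(row['n'])})"
            )
        lines.append(
            f"positional bounds (|mean| < {self.accuracy_bound_pp}, "
            f"SD < {self.precision_bound_pp}): "
            + ("PASS" if self.positions_pass else "FAIL")
        )
        lines.append("")
        lines.append("per-fragment accuracy/precision (percentage points):")
        for _, row in self.fragment_stats.iterrows():
            lines.append(
                f"  {row['analyte']} m/z {row['ion_label']}  "
                f"mean dev {row['mean_dev']:+.3f}  SD {row['sd_dev']:.3f}  "
                f"(n={row['n']})"
            )
        if self.excluded:
            lines.append("")
            lines.append("excluded measurements:")
            lines.extend(f"  {entry}" for entry in self.excluded)
        return "\n".join(lines)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.fragment_stats.to_csv(out / "fragment_stats.csv", index=False)
        self.position_stats.to_csv(out / "position_stats.csv", index=False)
        (out / "summary.txt").write_text(self.summary() + "\n", encoding="utf-8")


def _expected_fragment_e13c(design: MixtureDesign, frag: FragmentSpec) -> float:
    expected = expected_positional(design)
    return float(
        np.mean([expected[p - 1] for p in sorted(frag.backbone_positions)])
    )


def run_standards_validation(
    seed: int = 0,
    noise=None,
    designs: list[MixtureDesign] | None = None,
    registry: list[FragmentSpec] | None = None,
    injection_ng: float = 25.0,
    replicates: int = 4,
    accuracy_bound_pp: float = 1.0,
    precision_bound_pp: float = 2.5,
    fragment_bound_pp: float = 1.1,
    response_factors: dict[int, float] | None = None,
    split_ratios: dict[int, float] | None = None,
    out_dir: str | Path | None = None,
) -> StandardsReport:
    """Simulate and validate the standard-mixture panel.

    Defaults reproduce the validation design: 36 mixtures x 4 technical
    replicates at 25 ng injected, every registered fragment measured, the
    near-saturating fragments at split ratio 1:5.
    """
    from .simulate import NoiseModel, simulate_mixture_panel

    noise = noise or NoiseModel()
    designs = designs or table_s1_designs()
    registry = registry or [
        f for f in default_registry() if f.ion_formula is not None
    ]
    panel = simulate_mixture_panel(
        designs, [injection_ng], replicates, noise, registry=registry,
        response_factors=response_factors, split_ratios=split_ratios, seed=seed,
    )

    matrices: dict[tuple[str, int], CorrectionMatrix] = {}
    excluded: list[str] = []
    frag_devs: dict[tuple[str, int], list[float]] = {}
    per_sample: dict[tuple[str, int], dict[int, float]] = {}
    for pm in panel:
        frag = pm.mid.fragment
        if flag_saturation(pm.mid.total_abundance, noise.saturation_threshold):
            excluded.append(
                f"{pm.mid.sample_id} m/z {frag.ion_label}: saturated "
                f"({pm.mid.total_abundance:.3g} counts)"
            )
            continue
        if frag.key not in matrices:
            matrices[frag.key] = build_matrix(frag, len(pm.mid.abundances))
        corrected = correct(pm.mid, matrices[frag.key])
        dev = corrected.e13c - _expected_fragment_e13c(pm.design, frag)
        frag_devs.setdefault(frag.key, []).append(dev)
        per_sample.setdefault((pm.design.name, pm.replicate), {})[
            frag.ion_label
        ] = corrected.e13c

    fragment_rows = []
    for (analyte, ion_label), devs in sorted(frag_devs.items()):
        stats = deviation_stats(np.array(devs), 0.0, group=f"{analyte} {ion_label}")
        fragment_rows.append(
            {
                "analyte": analyte,
                "ion_label": ion_label,
                "mean_dev": stats.mean_dev,
                "sd_dev": stats.sd_dev,
                "n": stats.n,
            }
        )

    coverage_of = {
        name: lookup(registry, "aspartic acid 3TMS", label).backbone_positions
        for name, label in POSITIONAL_FRAGMENTS.items()
    }
    expected_by_design = {d.name: expected_positional(d) for d in designs}
    position_devs: dict[int, list[float]] = {p: [] for p in range(1, 5)}
    for (design_name, _rep), e13cs in sorted(per_sample.items()):
        if not all(label in e13cs for label in POSITIONAL_FRAGMENTS.values()):
            continue
        enrichments = {
            name: FragmentEnrichment(coverage_of[name], e13cs[label])
            for name, label in POSITIONAL_FRAGMENTS.items()
        }
        pos = positional_e13c(
            enrichments["E1234"], enrichments["E234"],
            enrichments["E23"], enrichments["E34"],
        )
        expected = expected_by_design[design_name]
        for p in range(4):
            position_devs[p + 1].append(pos.e[p] - expected[p])

    # positions lacking full fragment coverage (e.g. everything saturated)
    # appear as explicit NaN gaps rather than being silently dropped
    position_rows = []
    for p, devs in position_devs.items():
        if len(devs) >= 2:
            stats = deviation_stats(np.array(devs), 0.0, group=f"{p}-C")
            row = {"position": p, "mean_dev": stats.mean_dev,
                   "sd_dev": stats.sd_dev, "n": stats.n}
        else:
            row = {"position": p, "mean_dev": np.nan, "sd_dev": np.nan,
                   "n": len(devs)}
        position_rows.append(row)

    report = StandardsReport(
        fragment_stats=pd.DataFrame(fragment_rows),
        position_stats=pd.DataFrame(position_rows),
        excluded=excluded,
        accuracy_bound_pp=accuracy_bound_pp,
        precision_bound_pp=precision_bound_pp,
        fragment_bound_pp=fragment_bound_pp,
    )
    if out_dir is not None:
        report.write(out_dir)
    return report


@dataclass
class LabelingReport:
    timecourse: pd.DataFrame
    rates: pd.DataFrame
    fits: dict[tuple[str, str], list[SigmoidalFit]] = field(default_factory=dict)

    def summary(self) -> str:
        lines = ["labelling analysis report", "", "assimilation rates:"]
        for _, row in self.rates.iterrows():
            if row["detected"]:
                lines.append(
                    f"  {row['position']} ({row['condition']}): "
                    f"max rate {row['max_slope']:.3f} pmol OD750^-1 mL^-1 min^-1, "
                    f"half-max at {row['half_max_time']:.1f} min "
                    f"({row['n_sigmoidal']}/{row['n_replicates']} replicates)"
                )
            else:
                lines.append(f"  {row['position']} ({row['condition']}): ND")
        return "\n".join(lines)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.timecourse.to_csv(out / "timecourse.csv", index=False)
        self.rates.to_csv(out / "rates.csv", index=False)
        (out / "summary.txt").write_text(self.summary() + "\n", encoding="utf-8")


def analyze_labeling_dataset(
    dataset,
    threshold_ratio: float = 0.75,
    threshold_aic: float = -10.0,
    saturation_threshold: float = 1e7,
) -> LabelingReport:
    """Process one pulse-labelling dataset through the full chain.

    Corrects every fragment MID, combines the four-coverage set into
    positional enrichments, quantifies the aspartate pool against the
    calibration series, converts to molar positional 13C, and fits
    per-replicate sigmoids for each position.
    """
    if not dataset.samples:
        raise ValueError("empty sample set")
    times_by_rep: dict[int, set[float]] = {}
    for s in dataset.samples:
        times_by_rep.setdefault(s.replicate, set()).add(s.time_min)
    for rep, times in times_by_rep.items():
        if 0.0 not in times:
            raise ValueError(f"replicate {rep} is missing the t=0 sample")

    cal = fit_calibration(dataset.calibration_levels)
    condition = dataset.scenario.condition
    aliquot_factor = 1.0 / dataset.scenario.injection_fraction

    matrices: dict[tuple[str, int], CorrectionMatrix] = {}
    rows = []
    for s in dataset.samples:
        e13cs: dict[int, float] = {}
        for mid in s.mids:
            if flag_saturation(mid.total_abundance, saturation_threshold):
                continue
            key = mid.fragment.key
            if key not in matrices:
                matrices[key] = build_matrix(mid.fragment, len(mid.abundances))
            e13cs[mid.fragment.ion_label] = correct(mid, matrices[key]).e13c
        if not all(l in e13cs for l in POSITIONAL_FRAGMENTS.values()):
            raise ValueError(
                f"sample {s.sample_id}: missing fragment coverage for the "
                "positional equations"
            )
        frag_by_label = {m.fragment.ion_label: m.fragment for m in s.mids}
        enr = {
            name: FragmentEnrichment(
                frag_by_label[label].backbone_positions, e13cs[label]
            )
            for name, label in POSITIONAL_FRAGMENTS.items()
        }
        pos = positional_e13c(enr["E1234"], enr["E234"], enr["E23"], enr["E34"])
        meta = SampleMeta(
            sample_id=s.sample_id, od750=s.od750, volume_ml=s.volume_ml,
            time_min=s.time_min, is_abundance=s.internal_standard_abundance,
        )
        pool = quantify(
            s.quant_sum_abundance, meta, cal, aliquot_factor=aliquot_factor
        ).pmol_per_od_ml
        molar = positional_molar(pos, pool)
        rows.append(
            {
                "condition": condition, "replicate": s.replicate,
                "time_min": s.time_min, "pool_pmol_per_od_ml": pool,
                **{f"e{p}_percent": pos.e[p - 1] * 100 for p in range(1, 5)},
                **{f"m{p}_pmol_per_od_ml": molar[p - 1] for p in range(1, 5)},
            }
        )
    frame = pd.DataFrame(rows).sort_values(
        ["replicate", "time_min"], ignore_index=True
    )

    # detection floor: 1 % of the strongest molar signal in the dataset
    molar_cols = [f"m{p}_pmol_per_od_ml" for p in range(1, 5)]
    signal_floor = 0.01 * float(np.nanmax(frame[molar_cols].to_numpy()))
    fits: dict[tuple[str, str], list[SigmoidalFit]] = {}
    for p in range(1, 5):
        key = (f"{p}-C", condition)
        fits[key] = []
        for rep, group in frame.groupby("replicate"):
            tc = TimeCourse(
                group["time_min"].to_numpy(),
                group[f"m{p}_pmol_per_od_ml"].to_numpy(),
                replicate_id=f"rep{rep}",
            )
            fits[key].append(
                fit_sigmoid(
                    tc,
                    threshold_ratio=threshold_ratio,
                    threshold_aic=threshold_aic,
                    signal_floor=signal_floor,
                )
            )
    return LabelingReport(timecourse=frame, rates=rate_table(fits), fits=fits)


def run_labeling_analysis(
    seed: int = 0,
    noise=None,
    conditions: tuple[str, ...] = ("light", "dark"),
    out_dir: str | Path | None = None,
    threshold_ratio: float = 0.75,
    threshold_aic: float = -10.0,
) -> LabelingReport:
    """Simulate and analyze day/night pulse-labelling experiments."""
    from .simulate import NoiseModel, dark_scenario, light_scenario, simulate_timecourse

    noise = noise or NoiseModel()
    scenario_of = {"light": light_scenario, "dark": dark_scenario}
    frames, rates, fits = [], [], {}
    for index, condition in enumerate(conditions):
        dataset = simulate_timecourse(
            scenario_of[condition](), noise, seed=seed * len(conditions) + index
        )
        report = analyze_labeling_dataset(
            dataset, threshold_ratio=threshold_ratio, threshold_aic=threshold_aic,
            saturation_threshold=noise.saturation_threshold,
        )
        frames.append(report.timecourse)
        rates.append(report.rates)
        fits.update(report.fits)
    combined = LabelingReport(
        timecourse=pd.concat(frames, ignore_index=True),
        rates=pd.concat(rates, ignore_index=True),
        fits=fits,
    )
    if out_dir is not None:
        combined.write(out_dir)
    return combined
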