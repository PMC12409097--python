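"""Reading GC-MS data and extracting raw mass isotopologue distributions.

Two acquisition paths are supported, mirroring common instrument setups:

* high-resolution APCI chromatograms in mzML (centroided): isotopologue
  traces are extracted in +-0.005 Da windows around the fragment's exact m/z
  plus multiples of the 13C-12C mass difference, and abundances are the
  trapezoidal areas under the peak apex +-10 scans;
* nominal-mass EI data as pre-integrated peak tables (CSV), where
  abundances are peak apex heights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fragments import FragmentSpec
from .isotopes import C13_C12_MASS_DIFF

__all__ = [
    "ScanSeries",
    "Traces",
    "MIDMeasurement",
    "load_mzml",
    "extract_traces",
    "mid_apci",
    "mid_ei",
]

#: Default number of mass offsets measured beyond the tracer isotopologues,
#: capturing the Si-driven tail of the natural envelope.
DEFAULT_EXTRA_MASSES = 3


@dataclass
class ScanSeries:
    """Ordered centroided scans: (retention time in s, m/z array, intensity array)."""

    scans: list[tuple[float, np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        rts = [s[0] for s in self.scans]
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise ValueError("retention times must be strictly increasing")
        for _, mz, inten in self.scans:
            if len(mz) != len(inten):
                raise ValueError("m/z and intensity arrays differ in length")

    @property
    def retention_times(self) -> np.ndarray:
        return np.array([s[0] for s in self.scans])

    def __len__(self) -> int:
        return len(self.scans)


@dataclass
class Traces:
    """Per-isotopologue extracted-ion traces of one fragment."""

    fragment: FragmentSpec
    retention_times: np.ndarray
    intensities: np.ndarray  # shape (n_isotopologues, n_scans)


@dataclass
class MIDMeasurement:
    """Raw isotopologue abundance vector for one fragment in one injection."""

    fragment: FragmentSpec
    sample_id: str
    abundances: np.ndarray
    quant_mode: str = "apex_area"  # apex_area | apex_height
    apex_rt: float | None = None
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.abundances = np.asarray(self.abundances, dtype=float)
        if np.any(self.abundances < 0):
            raise ValueError("abundances must be non-negative")
        if len(self.abundances) < self.n_tracer + 1:
            raise ValueError(
                "abundance vector shorter than n_tracer + 1 isotopologues"
            )

    @property
    def n_tracer(self) -> int:
        return self.fragment.n_tracer

    @property
    def total_abundance(self) -> float:
        return float(self.abundances.sum())


_ACC_PROFILE = "MS:1000128"
_ACC_SCAN_START = "MS:1000016"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INTENSITY_ARRAY = "MS:1000515"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"


def _decode_binary(element, ns: str) -> np.ndarray:
    import base64
    import zlib

    accessions = {
        cv.get("accession") for cv in element.iter(f"{ns}cvParam")
    }
    binary = element.find(f"{ns}binary")
    raw = base64.b64decode(binary.text or "")
    if _ACC_ZLIB in accessions:
        raw = zlib.decompress(raw)
    dtype = "<f4" if _ACC_F32 in accessions else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def load_mzml(
    path: str | Path, rt_range: tuple[float, float] | None = None
) -> ScanSeries:
    """Load centroided scans from an mzML file.

    A self-contained reader for centroided MS1 mzML (uncompressed or
    zlib-compressed 32/64-bit float arrays); retention times are reported
    in seconds.  Profile-mode spectra are rejected: traces are extracted
    from centroided peaks only.
    """
    import xml.etree.ElementTree as ET

    path = Path(path)
    if not path.exists():
        raise ValueError(f"no such file: {path}")
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise ValueError(f"unreadable mzML file {path}: {exc}") from exc
    root = tree.getroot()
    ns = root.tag[: root.tag.index("}") + 1] if root.tag.startswith("{") else ""

    scans: list[tuple[float, np.ndarray, np.ndarray]] = []
    for spectrum in root.iter(f"{ns}spectrum"):
        params = {cv.get("accession") for cv in spectrum.findall(f"{ns}cvParam")}
        if _ACC_PROFILE in params:
            raise ValueError(
                "profile-mode data not supported; centroid the file first"
            )
        rt = None
        for scan in spectrum.iter(f"{ns}scan"):
            for cv in scan.findall(f"{ns}cvParam"):
                if cv.get("accession") == _ACC_SCAN_START:
                    rt = float(cv.get("value"))
                    if cv.get("unitName") == "minute":
                        rt *= 60.0
        if rt is None:
            raise ValueError("spectrum without scan start time")
        if rt_range is not None and not rt_range[0] <= rt <= rt_range[1]:
            continue
        mz_array = intensity_array = None
        for array in spectrum.iter(f"{ns}binaryDataArray"):
            accessions = {cv.get("accession") for cv in array.findall(f"{ns}cvParam")}
            if _ACC_MZ_ARRAY in accessions:
                mz_array = _decode_binary(array, ns)
            elif _ACC_INTENSITY_ARRAY in accessions:
                intensity_array = _decode_binary(array, ns)
        if mz_array is None or intensity_array is None:
            raise ValueError("spectrum missing m/z or intensity array")
        scans.append((rt, mz_array, intensity_array))
    if not scans:
        raise ValueError(f"no scans loaded from {path}")
    scans.sort(key=lambda s: s[0])
    return ScanSeries(scans)


def extract_traces(
    series: ScanSeries,
    frag: FragmentSpec,
    rt_window: tuple[float, float],
    tol: float = 0.005,
    spacing: float = C13_C12_MASS_DIFF,
    n_isotopologues: int | None = None,
) -> Traces:
    """Extract per-isotopologue intensity traces for one fragment.

    For isotopologue i the trace sums intensities of centroids within
    ``+-tol`` of ``exact_mz + i * spacing`` in each scan inside
    ``rt_window``.  Window centers follow the 13C isotopologue series; 29Si
    species fall close enough to be collected and are removed downstream by
    NIA correction.
    """
    if frag.exact_mz is None:
        raise ValueError(f"fragment {frag.key} has no exact m/z")
    rts = series.retention_times
    if rt_window[0] < rts[0] or rt_window[1] > rts[-1]:
        raise ValueError("rt_window outside the scan range")
    if n_isotopologues is None:
        n_isotopologues = frag.n_tracer + 1 + DEFAULT_EXTRA_MASSES

    in_window = [
        s for s in series.scans if rt_window[0] <= s[0] <= rt_window[1]
    ]
    centers = frag.exact_mz + spacing * np.arange(n_isotopologues)
    traces = np.zeros((n_isotopologues, len(in_window)))
    window_rts = np.empty(len(in_window))
    for k, (rt, mz, inten) in enumerate(in_window):
        window_rts[k] = rt
        for i, center in enumerate(centers):
            mask = np.abs(mz - center) <= tol
            if mask.any():
                traces[i, k] = inten[mask].sum()
    return Traces(fragment=frag, retention_times=window_rts, intensities=traces)


def mid_apci(
    traces: Traces,
    sample_id: str = "",
    apex_halfwidth: int = 10,
    noise_floor: float = 0.0,
) -> MIDMeasurement | None:
    """Integrate traces over the apex +-``apex_halfwidth`` scans.

    The apex is located on the *sum* of the isotopologue traces, which stays
    well-defined when M0 vanishes in highly enriched samples.  Returns
    ``None`` (missing measurement) when no apex rises above ``noise_floor``.
    """
    summed = traces.intensities.sum(axis=0)
    if summed.max(initial=0.0) <= noise_floor:
        return None
    apex = int(np.argmax(summed))
    lo = max(0, apex - apex_halfwidth)
    hi = min(len(summed) - 1, apex + apex_halfwidth)
    rts = traces.retention_times[lo : hi + 1]
    abundances = np.array(
        [np.trapezoid(tr[lo : hi + 1], rts) for tr in traces.intensities]
    )
    return MIDMeasurement(
        fragment=traces.fragment,
        sample_id=sample_id,
        abundances=np.clip(abundances, 0, None),
        quant_mode="apex_area",
        apex_rt=float(traces.retention_times[apex]),
    )


def mid_ei(
    peak_table: pd.DataFrame,
    frag: FragmentSpec,
    sample_id: str,
) -> MIDMeasurement:
    """Build a MID from a pre-integrated EI peak table.

    The table needs columns ``sample_id``, ``ion_label``, ``isotopologue``
    (0-based mass offset) and ``abundance`` (apex height).  Rows must be
    unique per (sample, fragment, isotopologue) and cover offsets
    0..L-1 with L >= n_tracer + 1.
    """
    rows = peak_table[
        (peak_table["sample_id"] == sample_id)
        & (peak_table["ion_label"].astype(int) == frag.ion_label)
    ]
    if rows.empty:
        raise ValueError(f"no rows for {sample_id!r} m/z {frag.ion_label}")
    if rows["isotopologue"].duplicated().any():
        raise ValueError(
            f"duplicate isotopologue rows for {sample_id!r} m/z {frag.ion_label}"
        )
    indices = sorted(int(i) for i in rows["isotopologue"])
    if indices != list(range(len(indices))):
        raise ValueError("isotopologue indices must be contiguous from 0")
    if len(indices) < frag.n_tracer + 1:
        raise ValueError(
            f"need at least {frag.n_tracer + 1} isotopologues, got {len(indices)}"
        )
    ordered = rows.sort_values("isotopologue")["abundance"].to_numpy(float)
    return MIDMeasurement(
        fragment=frag,
        sample_id=sample_id,
        abundances=ordered,
        quant_mode="apex_height",
    )
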