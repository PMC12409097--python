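"""Write a synthetic chromatogram to mzML and re-extract the MID.

Simulates a partially labelled aspartic acid 3TMS fragment, writes it as a
centroided mzML file with Gaussian chromatographic peaks, reads the file
back, extracts per-isotopologue traces in +-0.005 Da windows spaced by the
13C-12C mass difference, and integrates the apex +-10 scans.  The
recovered isotopologue fractions match the simulated ones to better than
0.1 %.
"""

import tempfile
from pathlib import Path

import numpy as np

from aspenrich import default_registry, extract_traces, load_mzml, lookup, mid_apci
from aspenrich.simulate import simulate_mid, write_mzml

fragment = lookup(default_registry(), "aspartic acid 3TMS", 232)
mid = simulate_mid(fragment, {2: 0.3, 3: 0.1, 4: 0.6}, scale=2e5)

path = Path(tempfile.mkdtemp()) / "aspartate.mzml"
write_mzml([mid], path)
series = load_mzml(path)
recovered = mid_apci(extract_traces(series, fragment, (302.0, 328.0)), "demo")

simulated = mid.abundances / mid.abundances.sum()
measured = recovered.abundances / recovered.abundances.sum()
print(f"wrote {len(series)} scans to {path.name}; apex at {recovered.apex_rt} s")
print("simulated fractions:", np.array2string(simulated, precision=5))
print("recovered fractions:", np.array2string(measured, precision=5))
print(f"max relative error: {np.max(np.abs(measured / simulated - 1)):.2e}")
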