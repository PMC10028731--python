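"""Median-normalize IP/control coverage, call dual-threshold peaks and
screen their shape.

A base qualifies when normalized IP coverage > 4 while every control stays
< 3; qualifying runs become peaks, and each peak's coverage profile is
correlated against an ideal triangle (1.0 = perfectly triangular).
"""

import numpy as np

import sigmascan as sg
from sigmascan.coverage import PeakCallerParams

genome, truth, ip, control = sg.simulate_regulon(sg.SyntheticRegulonConfig(seed=0))
ip_n = sg.normalize_coverage(ip)
control_n = sg.normalize_coverage(control)

peaks = sg.call_peaks(ip_n, [control_n], PeakCallerParams())
kept = [p for p in peaks if p.passed_shape]
print(f"putative peaks: {len(peaks)}; passing the triangularity screen: {len(kept)}")

centers = np.array(truth.peak_centers)
print("peak  summit  max_cov  triangularity  dist_to_planted_site")
for i, p in enumerate(kept):
    d = int(np.abs(centers - p.summit).min())
    print(f"{i:4d}  {p.summit:6d}  {p.max_coverage:7.1f}  {p.triangularity:13.3f}  {d:3d} bp")
# Every summit lands within a few bp of a planted site center; the short
# threshold-edge slivers the raw run extraction produces are rejected by
# the shape screen (negative triangularity).

windows = sg.extract_site_windows(genome, kept, 60)
print(f"\nextracted {len(windows)} summit-centered 60-bp windows for motif discovery")
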