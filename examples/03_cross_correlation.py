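"""Dynamic cross-correlation map with planted anticorrelation between the
TCR constant domains.

An ensemble is generated in which the Calpha and Cbeta regions move in
antiphase; the block summary of the correlation map reads that back.
"""

from tcrdyn import make_toy_complex
from tcrdyn.correlation import cross_correlation_matrix, region_block_summary
from tcrdyn.synthetic import sample_correlated_regions

top, ref = make_toy_complex(
    {"groove": 20, "Valpha": 8, "Vbeta": 8, "Calpha": 8, "Cbeta": 7},
    "SLLMWITQC",
    seed=1,
)
ens = sample_correlated_regions(
    top, ref, {("Calpha", "Cbeta"): -0.9}, sigma=0.1, jitter=1e-4,
    n_frames=5000, seed=7,
)
cm = cross_correlation_matrix(ens, fit=False)
regions = {name: top.region_map[name] for name in ("Calpha", "Cbeta", "groove")}
summary = region_block_summary(cm, regions)
print(summary.to_string(index=False, float_format=lambda x: f"{x:.3f}"))
# the Calpha-Cbeta block mean sits near the planted -0.9 and most of its
# entries fall in the anticorrelated band [-1, -0.25]; blocks involving
# the groove stay neutral (mean ~ 0)
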