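"""Recover injected per-section misalignments by boundary correlation.

The fixture renders a smoothly varying elliptical brain whose sections are
shifted by known integer offsets.  Alignment traces each tissue silhouette,
blurs it with a Gaussian, and exhaustively searches integer translations
maximizing correlation with the previous aligned section.
"""

from mctrace.alignment import adjacent_vs_lag
from mctrace.pipeline import run_synthetic
from mctrace.synthetic import preset

spec = preset("alignment_shifts")
result = run_synthetic(spec, align=True, validate_thicknesses=[0, 1, 2, 4])

print("section  injected   recovered")
for t, inj in zip(result.transforms, result.truth.shifts):
    print(f"  {t.rc_index:>3}    {str(inj):>9}  {str(t.shift):>9}")

print()
for thick, (adj, far) in zip([0, 1, 2, 4],
                             adjacent_vs_lag(result.alignment_report, lag=5)):
    print(f"edge thickness {thick}: adjacent corr {adj:.3f} vs lag-5 {far:.3f}")
print()
print("Recovered shifts are the exact negatives of the injected ones, and")
print("adjacent sections correlate far more strongly than distant ones —")
print("the signature of a tight serial reconstruction.")
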