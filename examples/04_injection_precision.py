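"""Injection-site precision: fraction of bulb cells inside the granule layer.

Generates the single-experiment injection fixture (a granule-cell-layer ring
nested in an elliptical olfactory bulb, with 84% of labeled cells placed in
the layer), runs the full pipeline, and reports the recovered precision.
"""

from mctrace import injection_site_report
from mctrace.pipeline import run_synthetic
from mctrace.synthetic import preset

result = run_synthetic(preset("fig4_example"), align=False)
rep = injection_site_report(result.reconstruction, "MOB", "GCL")

x, y, z = rep.center_of_mass
print(f"cells inside GCL:   {rep.n_inside}")
print(f"cells outside GCL:  {rep.n_outside} (elsewhere in the bulb)")
print(f"fraction inside:    {100 * rep.fraction_inside:.1f}%")
print(f"injection center of mass: ({x:.0f}, {y:.0f}, {z:.0f}) um")
print()
print("The generator placed 84% of labeled somata inside the layer; the")
print("recovered percentage matches to within a couple of points, the")
print("residual being density-dependent merging of touching somata.")
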