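"""Synthesize one parametric aorta+valve case and export its surface.

Builds a moderately stenotic case (AVA 0.8 cm^2), prints the centerline and
lumen bookkeeping, and writes an STL surface you can open in any mesh viewer.
"""

import numpy as np

from hemoline import GeometryParams, build_case, export_surface

params = GeometryParams(ava=0.8, seed=1)
case = build_case(params, label="demo")

cl = case.centerline
print(f"centerline: {cl.n_points} points at {cl.spacing:g} mm spacing "
      f"({cl.arc_length[-1]:.0f} mm total)")
for region in ("LVOT", "valve", "ascending", "arch", "descending"):
    idx = cl.region_indices(region)
    print(f"  {region:10s} {len(idx):3d} points, "
          f"area {case.areas[idx].min():6.1f}-{case.areas[idx].max():6.1f} mm^2")

valve_area = case.areas[case.valve_indices()].min()
print(f"valve orifice area {valve_area:.1f} mm^2 (target AVA {params.ava} cm^2 "
      f"= {params.ava * 100:.0f} mm^2)")

mesh = export_surface(case, "demo_case.stl")
print(f"wrote demo_case.stl: {len(mesh.vertices)} vertices, "
      f"surface area {mesh.area / 100:.1f} cm^2")
# The valve region shows the smallest areas: that constriction is what
# produces the transvalvular pressure gradient in the next example.
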