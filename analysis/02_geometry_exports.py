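#!/usr/bin/env python
"""Export graft surfaces and cross-section outlines for the key designs.

Builds watertight STL surfaces of the plain (conventional) tube and of the
reference spiral-ridged graft, plus trailing-edge cross-section outlines as
CSV polygons, and reports the monitoring-plane stations in the host artery.

Writes results/geometry/.
"""

import math
from pathlib import Path

import numpy as np

from spiralgraft.geometry import (
    GraftSpec,
    RidgeDesign,
    build_graft_surface,
    cross_section_at,
    place_monitoring_planes,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "geometry"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    graft = GraftSpec()
    reference = RidgeDesign()  # single circular ridge, TEO 180, H_ref

    for name, design in (("conventional", None), ("reference_spiral", reference)):
        mesh = build_graft_surface(graft, design, n_theta=128, n_z=160)
        mesh.export(OUT / f"{name}.stl")
        print(f"{name:<18} watertight={mesh.is_watertight} "
              f"euler={mesh.euler_number} area={mesh.area:.1f} mm^2")

    cs = cross_section_at(graft.graft_length, graft, reference)
    for i, outline in enumerate(cs.ridge_outlines):
        np.savetxt(OUT / f"reference_ridge_outline_{i}.csv", outline,
                   delimiter=",", header="x_mm,y_mm", comments="")
    print(f"\nTrailing-edge cross-section: net flow area "
          f"{cs.net_flow_area:.3f} mm^2 "
          f"(plain lumen {math.pi * 9:.3f} mm^2, blockage "
          f"{100 * (1 - cs.net_flow_area / (math.pi * 9)):.1f}%)")

    print("\nMonitoring planes (distal of the anastomosis toe):")
    for p in place_monitoring_planes(graft):
        print(f"  {p.label}: {p.axial_offset_from_toe:.0f} mm")
    print(f"\nWrote {OUT}")


if __name__ == "__main__":
    main()
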