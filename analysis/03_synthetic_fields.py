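#!/usr/bin/env python
"""Generate the synthetic field fixtures that stand in for CFD exports.

Produces one example of each generator with its analytically known ground
truth — a Poiseuille plane, a solid-body swirl plane, a retrograde-patch
plane snapped to the reference configuration's recorded plane-2 recirculation
(12.07%), a square-wave WSS series, and the triphasic femoral inlet waveform
(0.9 s cycle, peak at 0.25 s, reversal at 0.41 s) — and writes them in both
the CSV dialect and legacy VTK ASCII.

Writes results/fields/.
"""

from pathlib import Path

import numpy as np

from spiralgraft.fields import (
    synth_poiseuille,
    synth_retrograde_patch,
    synth_swirl,
    synth_waveform,
    synth_wss_series,
    write_field,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "fields"
SEED = 2026


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)

    pois = synth_poiseuille(3.0, 0.317, label="plane3")
    swirl = synth_swirl(3.0, omega=2.505e-3, label="plane3")  # mean V_yz = 5.01e-3
    centre = tuple(rng.uniform(-0.3, 0.3, size=2))
    patch = synth_retrograde_patch(3.0, 0.317, 0.1207, -0.05,
                                   patch_center=centre, label="plane2")
    for name, f in (("poiseuille", pois), ("swirl", swirl), ("patch", patch)):
        write_field(OUT / f"{name}.csv", f)
        write_field(OUT / f"{name}.vtk", f)
        print(f"{name:<12} truth: {f.meta}")

    series = synth_wss_series(n_axial=20, n_theta=32, n_t=17,
                              pattern="colinear_square_wave",
                              reversed_fraction=0.25,
                              base_vector=(2.295, 0.0))
    write_field(OUT / "wss_square.json", series)
    print(f"wss_square   truth: OSI = 0.25, TAWSS = 2.295 Pa")

    wf = synth_waveform()
    np.savetxt(OUT / "inlet_waveform.csv",
               np.column_stack([wf.times, wf.velocity]), delimiter=",",
               header="time_s,mean_velocity_m_per_s", comments="")
    print(f"waveform     peak {wf(wf.peak_time):.3f} m/s @ {wf.peak_time} s, "
          f"reversal {wf(wf.reversal_time):.3f} m/s @ {wf.reversal_time} s, "
          f"cycle mean 0.317 m/s")
    print(f"\nWrote {OUT}")


if __name__ == "__main__":
    main()
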