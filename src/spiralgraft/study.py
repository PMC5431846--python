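"""Design-study orchestration: the 13-configuration table and comparisons.

The parametric study varies four ridge design parameters around a reference
configuration (single circular ridge, r = 1.5 mm, trailing edge at the heel
180°, pitch H_ref = 86.54 mm):

* cross-sectional shape (elliptical height L1/D = 0.3, circular 0.25,
  elliptical width 0.2) at fixed lens area;
* trailing-edge orientation (0°, 90°, 180°, 270°);
* number of ridges (1, 2, 3) at fixed *total* lens area 3.157 mm²;
* helical pitch (H_ref and ±20%).

The CFD result columns for each configuration (pressure drop, plane-3 mean
secondary velocity, spatial-mean WSS, recirculation percentages at planes
1–2) ship as a packaged CSV of recorded values — they are outputs of flow
solves on ~3-million-element meshes and are consumed here, not recomputed.
Every value carries a provenance flag (``recorded`` vs ``recomputed``) and
the geometric entries are re-derived from the constraint solvers at build
time.

:func:`run_pipeline` exercises the whole chain end to end on synthetic
fields whose ground truths are calibrated to the recorded values, so the
reporting path is testable without a CFD solver.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import fields as flds
from . import geometry as geom
from . import metrics as mtr

__all__ = [
    "DesignTable",
    "ComparisonReport",
    "load_table1",
    "build_design_table",
    "normalize_to_reference",
    "percent_change",
    "recirculation_difference",
    "headline_statements",
    "run_pipeline",
]

_DATA = Path(__file__).parent / "data" / "table1.csv"

#: Result columns whose recorded values come from the study's CFD solves.
METRIC_COLUMNS = (
    "pressure_drop_Pa",
    "vyz_plane3_mm_per_s",
    "wss_mean_Pa",
    "recirculation_plane1_pct",
    "recirculation_plane2_pct",
)


@dataclass
class DesignTable:
    """One record per configuration: design parameters + metric values.

    ``data`` holds the design parameters, solved geometry (``radius_mm`` for
    circular ridges, ``L2_mm`` for elliptical, ``pitch_mm``) and the metric
    columns; ``provenance`` maps each metric column to ``recorded`` or
    ``recomputed``. Exactly one row is flagged reference.
    """

    data: pd.DataFrame
    provenance: dict = field(default_factory=dict)
    lumen_diameter: float = 6.0

    def __post_init__(self) -> None:
        n_ref = int(self.data["is_reference"].sum())
        if n_ref != 1:
            raise ValueError(f"exactly one reference row required, found {n_ref}")

    @property
    def reference(self) -> pd.Series:
        return self.data[self.data["is_reference"] == 1].iloc[0]

    def row(self, config: str) -> pd.Series:
        sel = self.data[self.data["config"] == config]
        if sel.empty:
            raise KeyError(f"no configuration named {config!r}")
        return sel.iloc[0]


@dataclass
class ComparisonReport:
    """Per-configuration metrics normalized by the reference configuration."""

    normalized: pd.DataFrame  # config x metric, reference row == 1.0
    reference_config: str


def load_table1() -> pd.DataFrame:
    """The packaged per-configuration design/result table (recorded values)."""
    return pd.read_csv(_DATA)


def build_design_table(config: dict | None = None) -> DesignTable:
    """Build the design table, re-deriving all geometric entries via solvers.

    For every configuration the per-ridge dimensions are solved from the
    constant-total-area constraint: circular designs get ``radius_mm`` from
    the lens-area root-find (count-aware), elliptical designs get ``L2_mm``
    from the ellipse–disc clipping solver at the tabulated L1. The pitch in mm
    follows from H/D. Metric columns are attached with provenance
    ``recorded``.
    """
    cfg = config or {}
    diameter = float(cfg.get("lumen_diameter", 6.0))
    total_area = float(cfg.get("ridge_total_area", geom.RIDGE_TOTAL_AREA))
    lumen_radius = 0.5 * diameter
    df = load_table1()

    radii, l2s = [], []
    for _, r in df.iterrows():
        try:
            if r["shape"] == "circular":
                radius = geom.solve_circular_radius(
                    total_area, int(r["count"]), lumen_radius
                )
                radii.append(radius)
                l2s.append(radius)
            else:
                L1 = float(r["L1_over_D"]) * diameter
                L2 = geom.solve_ellipse_tangential_axis(
                    L1, total_area, int(r["count"]), lumen_radius
                )
                radii.append(float(r["L1_over_D"]) * diameter)
                l2s.append(L2)
        except ValueError as exc:
            raise ValueError(
                f"geometry solve failed for configuration {r['config']!r}: {exc}"
            ) from exc
    df = df.assign(
        radius_mm=radii,  # radial semi-axis L1 in mm (solved for circular)
        L2_mm=l2s,
        pitch_mm=df["H_over_D"] * diameter,
    )
    provenance = {col: "recorded" for col in METRIC_COLUMNS}
    return DesignTable(df, provenance, diameter)


def normalize_to_reference(
    table: DesignTable,
    metrics: tuple[str, ...] = METRIC_COLUMNS,
) -> ComparisonReport:
    """Divide every metric column by the reference configuration's value."""
    ref = table.reference
    out = table.data[["config"]].copy()
    for m in metrics:
        ref_val = float(ref[m])
        if ref_val == 0.0:
            raise ZeroDivisionError(f"reference value for {m!r} is zero")
        out[m] = table.data[m] / ref_val
    return ComparisonReport(out.set_index("config"), str(ref["config"]))


def percent_change(
    table: DesignTable, config_a: str, config_b: str, metric: str
) -> float:
    """100 * (value_a - value_b) / value_b for one metric column."""
    a, b = table.row(config_a), table.row(config_b)
    if metric not in table.data.columns:
        raise KeyError(f"no metric column {metric!r}")
    return float(100.0 * (a[metric] - b[metric]) / b[metric])


def recirculation_difference(
    table: DesignTable, config_a: str, config_b: str, plane: int
) -> float:
    """Recirculation reduction value_a - value_b in percentage points.

    ``plane`` is 1 or 2 (monitoring planes 1 mm and 5 mm distal of the toe);
    a positive result means configuration b reduces the retrograde area
    relative to configuration a.
    """
    col = f"recirculation_plane{plane}_pct"
    if col not in table.data.columns:
        raise KeyError(f"no recirculation column for plane {plane}")
    a, b = table.row(config_a), table.row(config_b)
    return float(a[col] - b[col])


def headline_statements(table: DesignTable) -> dict[str, float]:
    """The study's key percentage/ratio comparisons, from the table values.

    All derived with :func:`percent_change` / :func:`recirculation_difference`
    / :func:`normalize_to_reference` against the reference configuration.
    """
    ref = table.reference["config"]
    vyz_norm = normalize_to_reference(table).normalized["vyz_plane3_mm_per_s"]
    return {
        # spatial-mean WSS increases from rotating the trailing edge
        "wss_increase_teo90_pct": percent_change(table, "teo_90", ref, "wss_mean_Pa"),
        "wss_increase_teo270_pct": percent_change(table, "teo_270", ref, "wss_mean_Pa"),
        # secondary-velocity gains at plane 3
        "vyz_increase_double_pct": percent_change(
            table, "double", ref, "vyz_plane3_mm_per_s"
        ),
        "vyz_increase_elliptical_height_pct": percent_change(
            table, "elliptical_height", ref, "vyz_plane3_mm_per_s"
        ),
        "vyz_ratio_teo270": float(vyz_norm["teo_270"]),
        # retrograde-area reductions at monitoring plane 2
        "recirc_reduction_teo270_plane2_pts": recirculation_difference(
            table, ref, "teo_270", 2
        ),
        "recirc_reduction_triple_plane2_pts": recirculation_difference(
            table, ref, "triple", 2
        ),
    }


# ---------------------------------------------------------------------------
# End-to-end pipeline


def _synthesize_config_fields(
    row: pd.Series,
    rng: np.random.Generator,
    *,
    lumen_radius: float,
    n_r: int,
    n_theta: int,
) -> dict:
    """Synthetic monitoring-plane fields calibrated to a config's recorded values.

    Plane 3 gets a solid-body swirl whose exact mean secondary velocity is the
    recorded V_yz; planes 1 and 2 get retrograde patches snapped to the
    recorded recirculation fractions. The vortex-centre jitter is seeded so a
    rerun with the same master seed is byte-identical.
    """
    vyz = float(row["vyz_plane3_mm_per_s"]) * 1e-3  # table is in 1e-3 m/s
    omega = 1.5 * vyz / lumen_radius  # mean of solid-body swirl = (2/3) w R
    planes = {
        "plane3": flds.synth_swirl(
            lumen_radius, omega, kind="solid_body", n_r=n_r, n_theta=n_theta,
            label="plane3",
        )
    }
    for plane, col in (("plane1", "recirculation_plane1_pct"),
                       ("plane2", "recirculation_plane2_pct")):
        frac = float(row[col]) / 100.0
        # seeded jitter of the patch centre: area snapping keeps the recorded
        # fraction, but the patch location varies between configurations
        centre = tuple(rng.uniform(-0.1, 0.1, size=2) * lumen_radius)
        planes[plane] = flds.synth_retrograde_patch(
            lumen_radius, forward_speed=0.317, patch_fraction=frac,
            patch_speed=-0.05, n_r=n_r, n_theta=n_theta,
            patch_center=centre, label=plane,
        )
    return planes


def run_pipeline(config: dict | None = None) -> dict:
    """End-to-end study: geometry -> synthetic fields -> metrics -> report.

    ``config`` keys (all optional): ``output_dir`` (writes CSVs when given),
    ``seed`` (master seed, forked per configuration), ``n_r``/``n_theta``
    (plane grids), ``wss_grid`` ((n_axial, n_theta, n_t) for the transient
    surface series). Returns a bundle with the design table (recomputed
    provenance on the synthetic-field metrics), the comparison report, the
    headline statements and an unfolded TAWSS map. Deterministic for a given
    config: the summary CSV is byte-identical across reruns.
    """
    cfg = dict(config or {})
    seed = int(cfg.get("seed", 0))
    n_r = int(cfg.get("n_r", 32))
    n_theta = int(cfg.get("n_theta", 64))
    out_dir = cfg.get("output_dir")
    log: list[str] = []

    def stage(name: str):
        log.append(name)

    try:
        stage("design")
        table = build_design_table(cfg)
    except ValueError as exc:
        raise RuntimeError(f"[stage design] {exc}") from exc

    lumen_radius = 0.5 * table.lumen_diameter
    master = np.random.SeedSequence(seed)
    children = master.spawn(len(table.data))

    stage("synth+metrics")
    recomputed = {"config": [], "vyz_plane3_mm_per_s": [],
                  "recirculation_plane1_pct": [], "recirculation_plane2_pct": []}
    for (idx, row), child in zip(table.data.iterrows(), children):
        try:
            planes = _synthesize_config_fields(
                row, np.random.default_rng(child),
                lumen_radius=lumen_radius, n_r=n_r, n_theta=n_theta,
            )
            _, vyz_mean = mtr.secondary_velocity(planes["plane3"])
            recomputed["config"].append(row["config"])
            recomputed["vyz_plane3_mm_per_s"].append(vyz_mean * 1e3)
            for plane in (1, 2):
                recomputed[f"recirculation_plane{plane}_pct"].append(
                    mtr.retrograde_area_fraction(planes[f"plane{plane}"])
                )
        except ValueError as exc:
            raise RuntimeError(
                f"[stage synth+metrics] configuration {row['config']!r}: {exc}"
            ) from exc

    recomputed_df = pd.DataFrame(recomputed).set_index("config")

    stage("transient-indices")
    n_ax, n_th_s, n_t = cfg.get("wss_grid", (40, 32, 91))
    series = flds.synth_wss_series(
        n_axial=n_ax, n_theta=n_th_s, n_t=n_t,
        base_vector=(float(table.reference["wss_mean_Pa"]), 0.0),
        pattern="colinear_square_wave",
        reversed_fraction=round(0.2 * (n_t - 1)) / (n_t - 1),
    )
    tawss_map = mtr.unfold_surface(series, mtr.tawss(series),
                                   name="TAWSS", units="Pa")
    osi_map = mtr.unfold_surface(series, mtr.osi(series), name="OSI", units="-")

    stage("report")
    report = normalize_to_reference(table)
    statements = headline_statements(table)

    bundle = {
        "table": table,
        "recomputed": recomputed_df,
        "report": report,
        "statements": statements,
        "tawss_map": tawss_map,
        "osi_map": osi_map,
        "log": log,
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.data.to_csv(out / "design_table.csv", index=False)
        recomputed_df.to_csv(out / "recomputed_metrics.csv")
        report.normalized.to_csv(out / "comparison_normalized.csv")
        (out / "headline_statements.json").write_text(
            json.dumps(statements, indent=1, sort_keys=True) + "\n"
        )
        _write_map_csv(out / "tawss_map.csv", tawss_map)
    return bundle


def _write_map_csv(path: Path, m: mtr.IndexSurfaceMap) -> None:
    """Unfolded map as a CSV matrix plus a JSON sidecar with the axes."""
    np.savetxt(path, m.values, delimiter=",")
    sidecar = {
        "name": m.name, "units": m.units, "cut_angle_deg": m.cut_angle,
        "radius_mm": m.radius,
        "axial_mm": [float(v) for v in m.x],
        "arc_length_mm": [float(v) for v in m.y],
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(sidecar, indent=1) + "\n")
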