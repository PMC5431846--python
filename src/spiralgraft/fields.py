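"""Discrete flow/WSS field containers, file I/O and synthetic generators.

The study's haemodynamic indices are computed from two kinds of discrete
fields that a CFD solver would normally export:

* :class:`PlanarVelocityField` — velocity samples on a circular cross-section
  (monitoring plane) of the host artery: axial component ``u`` plus in-plane
  components ``v``, ``w`` along the in-plane Y and Z axes, on a polar
  cell-centred grid with exact annular-sector cell areas.
* :class:`WallShearSeries` — a time series of wall-shear-stress vectors on a
  cylindrical host-artery surface grid, spanning one flow cycle (period
  T = 0.9 s by default) on uniform time samples.

Because no solver output ships with the package, this module also provides
generators that emulate the relevant flow features with analytically known
index values: Poiseuille profiles, solid-body / Lamb–Oseen swirl, retrograde
patches of prescribed area fraction, square-wave/rotating WSS histories, and a
parameterized triphasic femoral inlet waveform (peak at 0.25 s, reversal at
0.41 s of a 0.9 s cycle). The metrics module recovering each generator's
ground truth is the backbone of the test suite.

Files are written either as a documented CSV dialect or as legacy VTK ASCII
structured grids (``velocity`` / ``wss`` vector arrays); a JSON manifest binds
the per-time-step VTK files of a series together.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import root
from scipy.special import i0e

__all__ = [
    "ParseError",
    "SchemaError",
    "WaveformInfeasibleError",
    "PlanarVelocityField",
    "WallShearSeries",
    "Waveform",
    "read_field",
    "write_field",
    "synth_poiseuille",
    "synth_swirl",
    "synth_retrograde_patch",
    "synth_wss_series",
    "synth_waveform",
]


class ParseError(ValueError):
    """Malformed field file; carries the 1-based line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"{message}" + (f" (line {line})" if line else ""))


class SchemaError(ValueError):
    """Structurally valid file that lacks a required array or metadata key."""


class WaveformInfeasibleError(ValueError):
    """Waveform constraints cannot be met by the pulse parameterization."""


# ---------------------------------------------------------------------------
# Containers


@dataclass
class PlanarVelocityField:
    """Velocity samples on a disc cross-section, polar cell-centred grid.

    ``r`` (n_r) and ``theta`` (n_theta) are cell-centre coordinates; ``u``,
    ``v``, ``w`` and ``cell_area`` have shape (n_r, n_theta). Cell areas are
    the exact annular-sector areas, so they tile the disc exactly and
    area-weighted means of radially symmetric fields are exact.
    """

    radius: float  # disc radius R_a [mm]
    r: np.ndarray  # cell-centre radii [mm], shape (n_r,)
    theta: np.ndarray  # cell-centre angles [rad], shape (n_theta,)
    u: np.ndarray  # axial velocity [m/s], (n_r, n_theta)
    v: np.ndarray  # in-plane Y velocity [m/s]
    w: np.ndarray  # in-plane Z velocity [m/s]
    cell_area: np.ndarray  # [mm^2], (n_r, n_theta)
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shape = (len(self.r), len(self.theta))
        for name in ("u", "v", "w", "cell_area"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
        disc_area = math.pi * self.radius**2
        if abs(self.cell_area.sum() - disc_area) > 1e-3 * disc_area:
            raise ValueError(
                f"cell areas sum to {self.cell_area.sum():.6g} mm^2, "
                f"disc area is {disc_area:.6g} mm^2 (0.1% closure violated)"
            )

    @property
    def total_area(self) -> float:
        return float(self.cell_area.sum())


@dataclass
class WallShearSeries:
    """WSS vector time series on a cylindrical host-artery surface grid.

    The cylinder axis is the Cartesian x axis (flow direction); surface nodes
    sit at (axial, R cos(theta), R sin(theta)). ``tau`` has shape
    (n_t, n_axial, n_theta, 3) holding the Cartesian components
    (tau_x, tau_y, tau_z) in Pa, tangent to the surface. Time samples are
    uniform and span one period [0, T].
    """

    radius: float  # host artery radius [mm]
    axial: np.ndarray  # axial node coordinates [mm], (n_axial,)
    theta: np.ndarray  # circumferential node angles [rad], (n_theta,)
    times: np.ndarray  # [s], (n_t,), uniform, times[-1]-times[0] == period
    tau: np.ndarray  # [Pa], (n_t, n_axial, n_theta, 3)
    period: float = 0.9  # flow cycle T [s]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        nt, nz, nth = len(self.times), len(self.axial), len(self.theta)
        if self.tau.shape != (nt, nz, nth, 3):
            raise ValueError(
                f"tau has shape {self.tau.shape}, expected {(nt, nz, nth, 3)}"
            )
        if nt < 3:
            raise ValueError("need at least 3 time samples")
        dt = np.diff(self.times)
        if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
            raise ValueError("time samples must be uniform")
        if not math.isclose(self.times[-1] - self.times[0], self.period,
                            rel_tol=1e-9):
            raise ValueError("time samples must span exactly one period")
        # tangency: WSS must have no radial (surface-normal) component
        normal = np.stack(
            [np.zeros_like(self.theta), np.cos(self.theta), np.sin(self.theta)], axis=-1
        )  # (n_theta, 3)
        radial = np.einsum("tzqc,qc->tzq", self.tau, normal)
        mag = np.linalg.norm(self.tau, axis=-1)
        bad = np.abs(radial) > 1e-6 * np.maximum(mag, 1e-300)
        if np.any(bad & (mag > 0)):
            raise ValueError("WSS vectors must be tangent to the cylinder surface")

    @property
    def n_t(self) -> int:
        return len(self.times)

    def snapshot(self, time_index: int) -> np.ndarray:
        """(n_axial, n_theta, 3) WSS vectors at one time sample."""
        return self.tau[time_index]


@dataclass
class Waveform:
    """Periodic inlet mean-velocity waveform (triphasic femoral shape).

    Built by :func:`synth_waveform`; ``times``/``velocity`` are samples over
    one period including both endpoints (first == last), and ``__call__``
    evaluates the underlying smooth periodic function at arbitrary times.
    """

    period: float
    times: np.ndarray
    velocity: np.ndarray
    peak_time: float
    reversal_time: float
    _coeffs: tuple = field(default=(), repr=False)

    def __call__(self, t) -> np.ndarray:
        c0, a1, a2, s1, s2, k1, k2 = self._coeffs
        t = np.asarray(t, dtype=float)
        w = 2.0 * math.pi / self.period
        g1 = np.exp(k1 * (np.cos(w * (t - s1)) - 1.0))
        g2 = np.exp(k2 * (np.cos(w * (t - s2)) - 1.0))
        return c0 + a1 * g1 + a2 * g2


# ---------------------------------------------------------------------------
# Polar grid helpers


def _polar_grid(radius: float, n_r: int, n_theta: int):
    """Cell-centre radii/angles and exact annular-sector areas for a disc."""
    r_edges = np.linspace(0.0, radius, n_r + 1)
    r = 0.5 * (r_edges[:-1] + r_edges[1:])
    theta = (np.arange(n_theta) + 0.5) * (2.0 * math.pi / n_theta)
    d_theta = 2.0 * math.pi / n_theta
    ring_area = 0.5 * (r_edges[1:] ** 2 - r_edges[:-1] ** 2) * d_theta
    area = np.repeat(ring_area[:, None], n_theta, axis=1)
    return r, theta, area


# ---------------------------------------------------------------------------
# Synthetic generators


def synth_poiseuille(
    radius: float,
    mean_velocity: float,
    *,
    n_r: int = 64,
    n_theta: int = 128,
    label: str = "",
) -> PlanarVelocityField:
    """Axisymmetric parabolic profile u(r) = 2 V (1 - r^2/R^2), no swirl."""
    if radius <= 0.0:
        raise ValueError("radius must be positive")
    r, theta, area = _polar_grid(radius, n_r, n_theta)
    u = 2.0 * mean_velocity * (1.0 - (r / radius) ** 2)
    u = np.repeat(u[:, None], n_theta, axis=1)
    zeros = np.zeros_like(u)
    return PlanarVelocityField(
        radius, r, theta, u, zeros.copy(), zeros.copy(), area, label,
        meta={"generator": "poiseuille", "mean_velocity": mean_velocity},
    )


def synth_swirl(
    radius: float,
    omega: float,
    *,
    kind: str = "solid_body",
    core_radius: float = 1.0,
    center_offset: float = 0.0,
    n_r: int = 64,
    n_theta: int = 128,
    label: str = "",
) -> PlanarVelocityField:
    """In-plane vortex on zero axial flow (the swirl patterns of a spiral graft).

    ``solid_body``: in-plane speed omega*rho about a centre offset by
    ``center_offset`` along +Y (rho = distance from that centre). For zero
    offset the area-weighted mean in-plane speed is (2/3)*omega*R exactly.

    ``lamb_oseen``: u_theta(rho) = Gamma/(2 pi rho) * (1 - exp(-rho^2/rc^2))
    with core angular velocity omega at the centre, i.e.
    Gamma = 2 pi rc^2 * omega. The circulation around the rim is
    Gamma * (1 - exp(-R^2/rc^2)).

    Note units: coordinates are mm, so with omega in rad/s the speeds carry
    the mm-based scale consistently; the metrics only ever compare like with
    like, so the generator keeps grid units.
    """
    if kind not in ("solid_body", "lamb_oseen"):
        raise ValueError(f"unknown swirl kind {kind!r}")
    if kind == "lamb_oseen" and core_radius <= 0.0:
        raise ValueError("core_radius must be positive for lamb_oseen")
    if abs(center_offset) >= radius:
        raise ValueError("vortex centre must lie inside the disc")
    r, theta, area = _polar_grid(radius, n_r, n_theta)
    rr, tt = np.meshgrid(r, theta, indexing="ij")
    y = rr * np.cos(tt) - center_offset
    z = rr * np.sin(tt)
    rho = np.hypot(y, z)
    with np.errstate(divide="ignore", invalid="ignore"):
        if kind == "solid_body":
            speed = omega * rho
        else:
            gamma = 2.0 * math.pi * core_radius**2 * omega
            speed = np.where(
                rho > 0.0,
                gamma / (2.0 * math.pi * np.maximum(rho, 1e-300))
                * (1.0 - np.exp(-(rho**2) / core_radius**2)),
                0.0,
            )
    # azimuthal unit vector about the (offset) centre: (-z, y)/rho
    with np.errstate(invalid="ignore"):
        ey = np.where(rho > 0, -z / np.maximum(rho, 1e-300), 0.0)
        ez = np.where(rho > 0, y / np.maximum(rho, 1e-300), 0.0)
    v = speed * ey
    w = speed * ez
    u = np.zeros_like(v)
    gt_mean = (2.0 / 3.0) * omega * radius if (
        kind == "solid_body" and center_offset == 0.0
    ) else None
    return PlanarVelocityField(
        radius, r, theta, u, v, w, area, label,
        meta={"generator": f"swirl_{kind}", "omega": omega,
              "core_radius": core_radius, "center_offset": center_offset,
              "mean_secondary_truth": gt_mean},
    )


def synth_retrograde_patch(
    radius: float,
    forward_speed: float,
    patch_fraction: float,
    patch_speed: float,
    *,
    n_r: int = 64,
    n_theta: int = 128,
    patch_center: tuple[float, float] = (0.0, 0.0),
    label: str = "",
) -> PlanarVelocityField:
    """Uniform forward axial flow with a retrograde circular patch.

    The patch is the set of grid cells nearest ``patch_center`` whose summed
    area snaps (by cell count) as close as possible to
    ``patch_fraction`` x disc area; inside it the axial velocity is
    ``patch_speed`` (negative for retrograde flow). The achieved fraction is
    recorded in ``meta['achieved_patch_fraction']``.
    """
    if not (0.0 <= patch_fraction < 1.0):
        raise ValueError("patch_fraction must lie in [0, 1)")
    if math.hypot(*patch_center) >= radius:
        raise ValueError("patch centre must lie inside the disc")
    r, theta, area = _polar_grid(radius, n_r, n_theta)
    rr, tt = np.meshgrid(r, theta, indexing="ij")
    y = rr * np.cos(tt) - patch_center[0]
    z = rr * np.sin(tt) - patch_center[1]
    dist = np.hypot(y, z).ravel()
    order = np.argsort(dist)
    target = patch_fraction * area.sum()
    cum = np.cumsum(area.ravel()[order])
    # cell-count snapping: stop at the prefix whose area is closest to target
    k = int(np.argmin(np.abs(cum - target))) + 1 if patch_fraction > 0.0 else 0
    mask = np.zeros(dist.shape, dtype=bool)
    if k:
        mask[order[:k]] = True
    mask = mask.reshape(area.shape)
    u = np.where(mask, patch_speed, forward_speed)
    zeros = np.zeros_like(u, dtype=float)
    achieved = float(area[mask].sum() / area.sum()) if k else 0.0
    return PlanarVelocityField(
        radius, r, theta, u.astype(float), zeros.copy(), zeros.copy(), area, label,
        meta={"generator": "retrograde_patch",
              "achieved_patch_fraction": achieved},
    )


def synth_wss_series(
    *,
    n_axial: int = 200,
    n_theta: int = 128,
    n_t: int = 91,
    period: float = 0.9,
    radius: float = 3.0,
    length: float = 120.0,
    base_vector: tuple[float, float] = (1.0, 0.0),
    pattern: str = "steady",
    reversed_fraction: float = 0.0,
    amplitude: float | None = None,
) -> WallShearSeries:
    """Synthetic WSS history on a cylinder with analytically known indices.

    ``base_vector`` = (axial, circumferential) components in the local tangent
    frame at each node, which keeps every vector tangent to the surface.

    Patterns:

    * ``steady`` — constant vector: OSI = 0, TAWSS = |base|, RRT = 1/|base|.
    * ``colinear_square_wave`` — +A along the base direction for a fraction
      (1 - p) of the cycle and -A for fraction p (p = ``reversed_fraction``).
      The sign switches fall half a sample off the switch nodes, so BOTH
      trapezoid integrals (of the vector and of its magnitude) are exact and
      OSI = (1 - |1 - 2p|)/2 holds to machine precision. Requires
      p*(n_t - 1) to be an integer.
    * ``rotating`` — constant magnitude A rotating once per cycle in the
      tangent plane: TAWSS = A, OSI = 0.5, RRT divergent.
    """
    if pattern not in ("steady", "colinear_square_wave", "rotating"):
        raise ValueError(f"unknown pattern {pattern!r}")
    if not (0.0 <= reversed_fraction <= 1.0):
        raise ValueError("reversed_fraction must lie in [0, 1]")
    axial = np.linspace(0.0, length, n_axial)
    theta = np.arange(n_theta) * (2.0 * math.pi / n_theta)
    times = np.linspace(0.0, period, n_t)
    # local tangent frame: axial x-hat and circumferential theta-hat
    ax_hat = np.zeros((n_theta, 3))
    ax_hat[:, 0] = 1.0
    th_hat = np.stack(
        [np.zeros_like(theta), -np.sin(theta), np.cos(theta)], axis=-1
    )
    b_ax, b_circ = base_vector
    base = b_ax * ax_hat + b_circ * th_hat  # (n_theta, 3)
    base_mag = math.hypot(b_ax, b_circ)
    A = base_mag if amplitude is None else float(amplitude)

    if pattern == "steady":
        tau = np.broadcast_to(base, (n_t, n_axial, n_theta, 3)).copy()
    elif pattern == "rotating":
        phase = 2.0 * math.pi * times / period
        tau = (
            A * np.cos(phase)[:, None, None, None] * ax_hat[None, None, :, :]
            + A * np.sin(phase)[:, None, None, None] * th_hat[None, None, :, :]
        )
        tau = np.broadcast_to(tau, (n_t, n_axial, n_theta, 3)).copy()
    else:
        n_int = n_t - 1
        m_float = reversed_fraction * n_int
        m = round(m_float)
        if abs(m_float - m) > 1e-9:
            raise ValueError(
                f"reversed_fraction*{n_int} must be an integer so the square "
                f"wave lands on sample boundaries, got {m_float}"
            )
        if base_mag == 0.0:
            raise ValueError("square wave needs a nonzero base direction")
        unit = base / base_mag
        sign = np.ones(n_t)
        if m >= n_int:  # fully reversed
            sign[:] = -1.0
        elif m > 0:
            start = max(1, (n_int - m) // 2)
            sign[start : start + m] = -1.0
        tau = A * sign[:, None, None, None] * np.broadcast_to(
            unit, (n_axial, n_theta, 3)
        )[None]
        tau = tau.copy()
    return WallShearSeries(
        radius, axial, theta, times, tau, period,
        meta={"generator": f"wss_{pattern}", "amplitude": A,
              "reversed_fraction": reversed_fraction,
              "base_vector": tuple(base_vector)},
    )


def synth_waveform(
    period: float = 0.9,
    peak_time: float = 0.25,
    reversal_time: float = 0.41,
    peak_velocity: float = 0.8,
    reversal_velocity: float = -0.2,
    mean_velocity: float = 0.317,
    *,
    kappa_peak: float = 40.0,
    kappa_reversal: float = 150.0,
    n_samples: int = 91,
) -> Waveform:
    """Parameterized triphasic femoral inlet waveform.

    A baseline plus two periodic (von Mises-shaped) pulses — a positive
    systolic pulse and a negative early-diastolic dip. The five imposed
    constraints (value and zero slope at the peak and at the reversal, and the
    cycle-averaged mean) are solved for the baseline, the two amplitudes and
    the two pulse centres, so the global maximum falls exactly at
    ``peak_time`` and the (negative) global minimum at ``reversal_time``.
    """
    if not (0.0 < peak_time < reversal_time < period):
        raise WaveformInfeasibleError("require 0 < peak_time < reversal_time < T")
    if not (reversal_velocity < 0.0 < peak_velocity):
        raise WaveformInfeasibleError("require reversal_velocity < 0 < peak_velocity")
    w = 2.0 * math.pi / period
    k1, k2 = kappa_peak, kappa_reversal

    def model(x, t):
        c0, a1, a2, s1, s2 = x
        g1 = np.exp(k1 * (np.cos(w * (t - s1)) - 1.0))
        g2 = np.exp(k2 * (np.cos(w * (t - s2)) - 1.0))
        return c0 + a1 * g1 + a2 * g2

    def dmodel(x, t):
        c0, a1, a2, s1, s2 = x
        g1 = np.exp(k1 * (np.cos(w * (t - s1)) - 1.0))
        g2 = np.exp(k2 * (np.cos(w * (t - s2)) - 1.0))
        return (-a1 * k1 * w * np.sin(w * (t - s1)) * g1
                - a2 * k2 * w * np.sin(w * (t - s2)) * g2)

    def residuals(x):
        c0, a1, a2, s1, s2 = x
        # exact cycle mean of each pulse: exp(-k) I0(k) = i0e(k)
        mean = c0 + a1 * i0e(k1) + a2 * i0e(k2)
        return [
            model(x, peak_time) - peak_velocity,
            model(x, reversal_time) - reversal_velocity,
            dmodel(x, peak_time),
            dmodel(x, reversal_time),
            mean - mean_velocity,
        ]

    x0 = np.array([mean_velocity, peak_velocity - mean_velocity,
                   reversal_velocity - mean_velocity, peak_time, reversal_time])
    sol = root(residuals, x0, method="hybr", tol=1e-13)
    if not sol.success or np.max(np.abs(residuals(sol.x))) > 1e-9:
        raise WaveformInfeasibleError(
            f"could not satisfy waveform constraints: {sol.message}"
        )
    coeffs = (*sol.x, k1, k2)
    times = np.linspace(0.0, period, n_samples)
    wf = Waveform(period, times, np.empty(n_samples), peak_time, reversal_time,
                  _coeffs=coeffs)
    wf.velocity = wf(times)

    # verify the imposed extrema are global and unique on a dense grid
    t_dense = np.linspace(0.0, period, 8192, endpoint=False)
    f_dense = wf(t_dense)
    if abs(t_dense[np.argmax(f_dense)] - peak_time) > 2e-3 * period:
        raise WaveformInfeasibleError("global maximum is not at peak_time")
    if abs(t_dense[np.argmin(f_dense)] - reversal_time) > 2e-3 * period:
        raise WaveformInfeasibleError("global minimum is not at reversal_time")
    if f_dense.min() >= 0.0:
        raise WaveformInfeasibleError("waveform never reverses")
    return wf


# ---------------------------------------------------------------------------
# File I/O

_PLANAR_CSV_TAG = "# spiralgraft planar_velocity v1"
_WSS_CSV_TAG = "# spiralgraft wall_shear_series v1"


def write_field(path, obj) -> None:
    """Write a field container to ``path``.

    Format is chosen by suffix: ``.csv`` (documented CSV dialect), ``.vtk``
    (legacy VTK ASCII structured grid; planar fields only) or ``.json``
    (manifest + one legacy VTK file per time step; series only).
    """
    path = Path(path)
    if isinstance(obj, PlanarVelocityField):
        if path.suffix == ".csv":
            _write_planar_csv(path, obj)
        elif path.suffix == ".vtk":
            _write_planar_vtk(path, obj)
        else:
            raise ValueError(f"unsupported suffix {path.suffix!r} for planar field")
    elif isinstance(obj, WallShearSeries):
        if path.suffix == ".csv":
            _write_series_csv(path, obj)
        elif path.suffix == ".json":
            _write_series_vtk(path, obj)
        else:
            raise ValueError(f"unsupported suffix {path.suffix!r} for WSS series")
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")


def read_field(path):
    """Read a field container written by :func:`write_field`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".csv":
        with open(path) as fh:
            first = fh.readline().rstrip("\n")
        if first == _PLANAR_CSV_TAG:
            return _read_planar_csv(path)
        if first == _WSS_CSV_TAG:
            return _read_series_csv(path)
        raise ParseError(f"unrecognized CSV header {first!r} in {path}", line=1)
    if path.suffix == ".vtk":
        return _read_planar_vtk(path)
    if path.suffix == ".json":
        return _read_series_vtk(path)
    raise ValueError(f"unsupported suffix {path.suffix!r}")


def _meta_header(pairs: dict) -> list[str]:
    return [f"# {k}={v}" for k, v in pairs.items()]


def _parse_meta(lines: list[str], path) -> dict:
    meta = {}
    for i, ln in enumerate(lines, start=2):
        if not ln.startswith("# ") or "=" not in ln:
            raise ParseError(f"bad metadata line {ln!r} in {path}", line=i)
        k, v = ln[2:].split("=", 1)
        meta[k.strip()] = v.strip()
    return meta


def _write_planar_csv(path: Path, f: PlanarVelocityField) -> None:
    n_r, n_th = len(f.r), len(f.theta)
    lines = [_PLANAR_CSV_TAG]
    lines += _meta_header(
        {"radius_mm": repr(f.radius), "label": f.label, "n_r": n_r, "n_theta": n_th}
    )
    lines.append("r_index,theta_index,r_mm,theta_rad,area_mm2,u,v,w")
    for i in range(n_r):
        for j in range(n_th):
            lines.append(
                f"{i},{j},{float(f.r[i])!r},{float(f.theta[j])!r},"
                f"{float(f.cell_area[i, j])!r},{float(f.u[i, j])!r},"
                f"{float(f.v[i, j])!r},{float(f.w[i, j])!r}"
            )
    path.write_text("\n".join(lines) + "\n")


def _read_planar_csv(path: Path) -> PlanarVelocityField:
    lines = path.read_text().splitlines()
    meta = _parse_meta(lines[1:5], path)
    for key in ("radius_mm", "n_r", "n_theta"):
        if key not in meta:
            raise SchemaError(f"missing metadata key {key!r} in {path}")
    n_r, n_th = int(meta["n_r"]), int(meta["n_theta"])
    header_line = 6
    if len(lines) < header_line or not lines[header_line - 1].startswith("r_index"):
        raise ParseError(f"missing column header in {path}", line=header_line)
    expected = n_r * n_th
    rows = lines[header_line:]
    if len(rows) < expected:
        raise ParseError(
            f"truncated file: expected {expected} data rows, found {len(rows)}",
            line=len(lines),
        )
    r = np.empty(n_r)
    theta = np.empty(n_th)
    u, v, w, area = (np.empty((n_r, n_th)) for _ in range(4))
    for k, ln in enumerate(rows[:expected]):
        parts = ln.split(",")
        if len(parts) != 8:
            raise ParseError(
                f"expected 8 comma-separated values, got {len(parts)}",
                line=header_line + 1 + k,
            )
        try:
            i, j = int(parts[0]), int(parts[1])
            r[i] = float(parts[2])
            theta[j] = float(parts[3])
            area[i, j] = float(parts[4])
            u[i, j], v[i, j], w[i, j] = map(float, parts[5:8])
        except (ValueError, IndexError) as exc:
            raise ParseError(str(exc), line=header_line + 1 + k) from exc
    return PlanarVelocityField(
        float(meta["radius_mm"]), r, theta, u, v, w, area, meta.get("label", "")
    )


def _write_series_csv(path: Path, s: WallShearSeries) -> None:
    lines = [_WSS_CSV_TAG]
    lines += _meta_header(
        {"radius_mm": repr(s.radius), "period_s": repr(s.period),
         "n_axial": len(s.axial), "n_theta": len(s.theta), "n_t": s.n_t}
    )
    lines.append("t_index,z_index,theta_index,time_s,axial_mm,theta_rad,taux,tauy,tauz")
    for t in range(s.n_t):
        for i in range(len(s.axial)):
            for j in range(len(s.theta)):
                tx, ty, tz = s.tau[t, i, j]
                lines.append(
                    f"{t},{i},{j},{float(s.times[t])!r},{float(s.axial[i])!r},"
                    f"{float(s.theta[j])!r},{float(tx)!r},{float(ty)!r},{float(tz)!r}"
                )
    path.write_text("\n".join(lines) + "\n")


def _read_series_csv(path: Path) -> WallShearSeries:
    lines = path.read_text().splitlines()
    meta = _parse_meta(lines[1:6], path)
    for key in ("radius_mm", "period_s", "n_axial", "n_theta", "n_t"):
        if key not in meta:
            raise SchemaError(f"missing metadata key {key!r} in {path}")
    n_z, n_th, n_t = int(meta["n_axial"]), int(meta["n_theta"]), int(meta["n_t"])
    header_line = 7
    expected = n_t * n_z * n_th
    rows = lines[header_line:]
    if len(rows) < expected:
        raise ParseError(
            f"truncated file: expected {expected} data rows, found {len(rows)}",
            line=len(lines),
        )
    axial, theta, times = np.empty(n_z), np.empty(n_th), np.empty(n_t)
    tau = np.empty((n_t, n_z, n_th, 3))
    for k, ln in enumerate(rows[:expected]):
        parts = ln.split(",")
        if len(parts) != 9:
            raise ParseError(
                f"expected 9 comma-separated values, got {len(parts)}",
                line=header_line + 1 + k,
            )
        try:
            t, i, j = int(parts[0]), int(parts[1]), int(parts[2])
            times[t], axial[i], theta[j] = map(float, parts[3:6])
            tau[t, i, j] = [float(p) for p in parts[6:9]]
        except (ValueError, IndexError) as exc:
            raise ParseError(str(exc), line=header_line + 1 + k) from exc
    return WallShearSeries(
        float(meta["radius_mm"]), axial, theta, times, tau, float(meta["period_s"])
    )


# -- legacy VTK ASCII structured grid ---------------------------------------


def _write_vtk_structured(path: Path, title: str, points: np.ndarray,
                          dims: tuple[int, int, int],
                          vectors: dict[str, np.ndarray],
                          scalars: dict[str, np.ndarray]) -> None:
    n = points.shape[0]
    out = ["# vtk DataFile Version 3.0", title, "ASCII", "DATASET STRUCTURED_GRID",
           f"DIMENSIONS {dims[0]} {dims[1]} {dims[2]}", f"POINTS {n} double"]
    out += [" ".join(repr(float(c)) for c in p) for p in points]
    out.append(f"POINT_DATA {n}")
    for name, arr in vectors.items():
        out.append(f"VECTORS {name} double")
        out += [" ".join(repr(float(c)) for c in v) for v in arr]
    for name, arr in scalars.items():
        out += [f"SCALARS {name} double 1", "LOOKUP_TABLE default"]
        out += [repr(float(x)) for x in arr]
    path.write_text("\n".join(out) + "\n")


class _VtkReader:
    """Line-oriented reader for the legacy VTK ASCII subset we write."""

    def __init__(self, path: Path):
        self.path = path
        self.lines = path.read_text().splitlines()
        self.pos = 0

    def next_line(self) -> str:
        if self.pos >= len(self.lines):
            raise ParseError(f"unexpected end of file in {self.path}",
                             line=len(self.lines))
        ln = self.lines[self.pos]
        self.pos += 1
        return ln

    def expect(self, prefix: str) -> str:
        ln = self.next_line()
        if not ln.startswith(prefix):
            raise ParseError(
                f"expected {prefix!r}, got {ln!r} in {self.path}", line=self.pos
            )
        return ln

    def read_floats(self, count: int, width: int) -> np.ndarray:
        vals = np.empty((count, width))
        for i in range(count):
            parts = self.next_line().split()
            if len(parts) != width:
                raise ParseError(
                    f"expected {width} numbers, got {len(parts)}", line=self.pos
                )
            try:
                vals[i] = [float(p) for p in parts]
            except ValueError as exc:
                raise ParseError(str(exc), line=self.pos) from exc
        return vals


def _parse_vtk_structured(path: Path):
    rd = _VtkReader(path)
    rd.expect("# vtk DataFile")
    title = rd.next_line()
    rd.expect("ASCII")
    rd.expect("DATASET STRUCTURED_GRID")
    dims = rd.expect("DIMENSIONS").split()[1:]
    dims = tuple(int(d) for d in dims)
    n = int(rd.expect("POINTS").split()[1])
    points = rd.read_floats(n, 3)
    rd.expect("POINT_DATA")
    vectors: dict[str, np.ndarray] = {}
    scalars: dict[str, np.ndarray] = {}
    while rd.pos < len(rd.lines):
        ln = rd.next_line()
        if not ln.strip():
            continue
        if ln.startswith("VECTORS"):
            name = ln.split()[1]
            vectors[name] = rd.read_floats(n, 3)
        elif ln.startswith("SCALARS"):
            name = ln.split()[1]
            rd.expect("LOOKUP_TABLE")
            scalars[name] = rd.read_floats(n, 1)[:, 0]
        else:
            raise ParseError(f"unexpected section {ln!r} in {path}", line=rd.pos)
    return title, dims, points, vectors, scalars


def _title_meta(title: str) -> dict:
    meta = {}
    for tok in title.split():
        if "=" in tok:
            k, v = tok.split("=", 1)
            meta[k] = v
    return meta


def _write_planar_vtk(path: Path, f: PlanarVelocityField) -> None:
    n_r, n_th = len(f.r), len(f.theta)
    rr, tt = np.meshgrid(f.r, f.theta, indexing="ij")
    # plane lives at x=0; in-plane axes are Cartesian y (theta=0) and z
    points = np.column_stack(
        [np.zeros(n_r * n_th), (rr * np.cos(tt)).ravel(), (rr * np.sin(tt)).ravel()]
    )
    title = (f"spiralgraft planar_velocity radius_mm={f.radius!r} "
             f"label={f.label or '-'} n_r={n_r} n_theta={n_th}")
    _write_vtk_structured(
        path, title, points, (n_th, n_r, 1),
        vectors={"velocity": np.column_stack(
            [f.u.ravel(), f.v.ravel(), f.w.ravel()])},
        scalars={"cell_area": f.cell_area.ravel(),
                 "r_mm": rr.ravel(), "theta_rad": tt.ravel()},
    )


def _read_planar_vtk(path: Path) -> PlanarVelocityField:
    title, dims, points, vectors, scalars = _parse_vtk_structured(path)
    meta = _title_meta(title)
    if "planar_velocity" not in title:
        raise SchemaError(f"{path} is not a planar velocity field")
    if "velocity" not in vectors:
        raise SchemaError(f"missing 'velocity' vector array in {path}")
    for key in ("cell_area", "r_mm", "theta_rad"):
        if key not in scalars:
            raise SchemaError(f"missing '{key}' scalar array in {path}")
    n_r, n_th = int(meta["n_r"]), int(meta["n_theta"])
    shape = (n_r, n_th)
    vel = vectors["velocity"]
    label = meta.get("label", "")
    return PlanarVelocityField(
        float(meta["radius_mm"]),
        scalars["r_mm"].reshape(shape)[:, 0].copy(),
        scalars["theta_rad"].reshape(shape)[0].copy(),
        vel[:, 0].reshape(shape), vel[:, 1].reshape(shape),
        vel[:, 2].reshape(shape),
        scalars["cell_area"].reshape(shape),
        "" if label == "-" else label,
    )


def _write_series_vtk(manifest_path: Path, s: WallShearSeries) -> None:
    stem = manifest_path.stem
    n_z, n_th = len(s.axial), len(s.theta)
    zz, tt = np.meshgrid(s.axial, s.theta, indexing="ij")
    points = np.column_stack(
        [zz.ravel(), (s.radius * np.cos(tt)).ravel(), (s.radius * np.sin(tt)).ravel()]
    )
    files = []
    for t in range(s.n_t):
        fname = f"{stem}_t{t:04d}.vtk"
        title = (f"spiralgraft wss_step radius_mm={s.radius!r} "
                 f"n_axial={n_z} n_theta={n_th} time_s={float(s.times[t])!r}")
        _write_vtk_structured(
            manifest_path.parent / fname, title, points, (n_th, n_z, 1),
            vectors={"wss": s.tau[t].reshape(-1, 3)},
            scalars={"axial_mm": zz.ravel(), "theta_rad": tt.ravel()},
        )
        files.append(fname)
    manifest = {
        "format": "spiralgraft wall_shear_series v1",
        "period_s": s.period,
        "radius_mm": s.radius,
        "times_s": [float(t) for t in s.times],
        "files": files,
    }
    manifest_path.write_text(json.dumps(manifest, indent=1) + "\n")


def _read_series_vtk(manifest_path: Path) -> WallShearSeries:
    try:
        manifest = json.loads(manifest_path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"malformed manifest {manifest_path}: {exc}",
                         line=exc.lineno) from exc
    if manifest.get("format") != "spiralgraft wall_shear_series v1":
        raise SchemaError(f"{manifest_path} is not a WSS series manifest")
    times = np.asarray(manifest["times_s"], dtype=float)
    tau = None
    axial = theta = None
    for t, fname in enumerate(manifest["files"]):
        title, dims, points, vectors, scalars = _parse_vtk_structured(
            manifest_path.parent / fname
        )
        meta = _title_meta(title)
        if "wss" not in vectors:
            raise SchemaError(f"missing 'wss' vector array in {fname}")
        n_z, n_th = int(meta["n_axial"]), int(meta["n_theta"])
        if tau is None:
            tau = np.empty((len(times), n_z, n_th, 3))
            axial = scalars["axial_mm"].reshape(n_z, n_th)[:, 0].copy()
            theta = scalars["theta_rad"].reshape(n_z, n_th)[0].copy()
        tau[t] = vectors["wss"].reshape(n_z, n_th, 3)
    return WallShearSeries(
        float(manifest["radius_mm"]), axial, theta, times, tau,
        float(manifest["period_s"]),
    )
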