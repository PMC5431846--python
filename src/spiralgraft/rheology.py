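"""Blood rheology: Carreau-Yasuda shear-thinning viscosity and flow characterization.

Blood is shear-thinning: its apparent viscosity falls from a low-shear plateau
``mu_zero`` (rouleaux formation dominates) to a high-shear plateau ``mu_inf``
(fully dispersed cells). The Carreau-Yasuda model interpolates between the two
plateaus::

    mu(gamma_dot) = mu_inf + (mu_zero - mu_inf) / [1 + (lambda*gamma_dot)**a]**((1-n)/a)

with time constant ``lambda`` setting the shear rate where thinning begins,
Yasuda exponent ``a`` controlling the sharpness of the transition, and power-law
index ``n < 1`` giving the slope of the thinning region.

The scalar shear rate fed into the model is the second invariant of the rate of
deformation tensor D = (grad u + grad u^T)/2,

    gamma_dot = sqrt(2 * tr(D @ D)),

which is frame-invariant and reduces to |du/dy| for simple shear.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CarreauYasudaParams",
    "FluidProperties",
    "viscosity",
    "shear_rate_invariant",
    "reynolds_number",
]


@dataclass(frozen=True)
class CarreauYasudaParams:
    """Carreau-Yasuda constants for blood (SI units).

    Defaults are standard literature values for whole blood at 37 C:
    mu_zero = 22 mPa·s, mu_inf = 2.2 mPa·s, lambda = 0.11 s, a = 0.644,
    n = 0.392.
    """

    mu_zero: float = 22e-3  # low-shear plateau viscosity [Pa s]
    mu_inf: float = 2.2e-3  # high-shear plateau viscosity [Pa s]
    lambda_time: float = 0.11  # time constant [s]
    yasuda_a: float = 0.644  # transition sharpness exponent [-]
    power_n: float = 0.392  # power-law index [-]

    def __post_init__(self) -> None:
        if not (self.mu_zero > self.mu_inf > 0.0):
            raise ValueError(
                f"require mu_zero > mu_inf > 0, got mu_zero={self.mu_zero}, "
                f"mu_inf={self.mu_inf}"
            )
        if self.lambda_time <= 0.0:
            raise ValueError(f"lambda_time must be positive, got {self.lambda_time}")
        if self.yasuda_a <= 0.0:
            raise ValueError(f"yasuda_a must be positive, got {self.yasuda_a}")
        if not (0.0 < self.power_n < 1.0):
            raise ValueError(
                f"power_n must lie in (0, 1) for shear thinning, got {self.power_n}"
            )


@dataclass(frozen=True)
class FluidProperties:
    """Bulk fluid constants used for characterization numbers.

    ``nominal_viscosity`` is a constant reference viscosity used only to form
    dimensionless numbers (Reynolds); the flow itself is shear-thinning. The
    default 3.5 mPa·s is the common high-shear reference for blood and
    reproduces Re ~ 570 for the 0.317 m/s, 6 mm inlet condition.
    """

    density: float = 1050.0  # [kg m^-3]
    nominal_viscosity: float = 3.5e-3  # [Pa s]

    def __post_init__(self) -> None:
        if self.density <= 0.0:
            raise ValueError(f"density must be positive, got {self.density}")
        if self.nominal_viscosity <= 0.0:
            raise ValueError(
                f"nominal_viscosity must be positive, got {self.nominal_viscosity}"
            )


def viscosity(gamma_dot, params: CarreauYasudaParams = CarreauYasudaParams()):
    """Carreau-Yasuda dynamic viscosity at shear rate ``gamma_dot`` [s^-1].

    Accepts scalars or arrays; gamma_dot = 0 is evaluated exactly (the model is
    finite there, mu(0) = mu_zero). Negative shear rates are a domain error:
    the invariant feeding this function is non-negative by construction.
    """
    g = np.asarray(gamma_dot, dtype=float)
    if np.any(g < 0.0):
        raise ValueError("shear rate must be non-negative")
    lam_g = params.lambda_time * g
    exponent = (1.0 - params.power_n) / params.yasuda_a
    mu = params.mu_inf + (params.mu_zero - params.mu_inf) / (
        1.0 + lam_g**params.yasuda_a
    ) ** exponent
    return mu if np.ndim(gamma_dot) else float(mu)


def shear_rate_invariant(velocity_gradient) -> float:
    """Scalar shear rate sqrt(2 tr(D^2)) from a 3x3 velocity gradient [s^-1].

    D is the symmetric part of the gradient, so any rigid rotation
    (antisymmetric gradient) yields exactly zero, and the result is invariant
    under rotation of the coordinate frame.
    """
    grad = np.asarray(velocity_gradient, dtype=float)
    if grad.shape != (3, 3):
        raise ValueError(f"velocity gradient must be 3x3, got shape {grad.shape}")
    if not np.all(np.isfinite(grad)):
        raise ValueError("velocity gradient entries must be finite")
    d = 0.5 * (grad + grad.T)
    return float(np.sqrt(2.0 * np.trace(d @ d)))


def reynolds_number(
    mean_velocity: float,
    diameter: float,
    props: FluidProperties = FluidProperties(),
) -> float:
    """Reynolds number rho*V*D/mu using the nominal (constant) viscosity."""
    if mean_velocity <= 0.0 or diameter <= 0.0:
        raise ValueError("mean_velocity and diameter must be positive")
    return props.density * mean_velocity * diameter / props.nominal_viscosity
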