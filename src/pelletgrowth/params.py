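"""Model parameters, unit scales, grids and pellet state.

The model describes a spherical micromass pellet made of two volume
fractions, cells ``n`` and proteoglycan matrix ``p`` with ``n + p = 1``,
fed by a generic nutrient ``B`` that diffuses in from the stirred medium.
Cells consume nutrient and convert it into matrix with saturating
(Michaelis-Menten) kinetics; the volume created by matrix production
drives a radial velocity field that expands the pellet.

After nondimensionalisation the model depends on two dimensionless
parameters only:

* ``kappa`` -- the Michaelis constant relative to the medium nutrient
  concentration; it sets how sharply consumption and production shut
  down as the nutrient is depleted.
* ``sigma0`` -- the initial pellet radius relative to the nutrient
  diffusion length scale; it controls whether the pellet interior is
  nutrient-starved from the start.

A third group, ``xi``, compares the matrix production rate with the
nutrient consumption rate.  This implementation works in the
quasi-steady limit ``xi = 0`` (nutrient transport equilibrates
instantaneously on the production time scale), which is the regime the
model analysis is based on; the constructor rejects any other value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

__all__ = [
    "ModelParameters",
    "DimensionalScales",
    "RadialGrid",
    "PelletState",
    "kinetics_f",
    "days_to_model_time",
    "model_time_to_days",
    "validate_state",
    "default_config",
    "load_config",
]

#: Relative tolerance for the sigma0 == S0/L cross-consistency check.
_SIGMA0_RTOL = 1e-12


def kinetics_f(B, kappa: float):
    """Shared nutrient dependence of consumption and production.

    Both the nutrient consumption rate and the matrix production rate
    are proportional to ``f(B) * n`` with ``f(B) = B/(kappa + B)`` for
    positive nutrient and zero otherwise (matrix cannot degrade back
    into nutrient).  Negative nutrient values, which can only arise as
    round-off, are clamped to zero.

    Parameters
    ----------
    B : float or ndarray
        Dimensionless nutrient concentration.
    kappa : float
        Dimensionless Michaelis constant, must be positive.

    Returns
    -------
    float or ndarray
        Rate factor in ``[0, 1)``, monotone nondecreasing in ``B``.
    """
    if kappa <= 0:
        raise ValueError(f"kappa must be positive, got {kappa}")
    Bp = np.maximum(B, 0.0)
    out = Bp / (kappa + Bp)
    if np.isscalar(B):
        return float(out)
    return out


@dataclass(frozen=True)
class ModelParameters:
    """Dimensionless model inputs.

    Attributes
    ----------
    kappa : float
        Michaelis constant over the medium nutrient concentration.
    sigma0 : float
        Initial pellet radius over the nutrient diffusion length.
    xi : float
        Production-to-consumption rate ratio; fixed at 0 (quasi-steady
        nutrient limit).  Any other value is rejected.
    """

    kappa: float
    sigma0: float
    xi: float = 0.0

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError(f"kappa must be positive, got {self.kappa}")
        if self.sigma0 <= 0:
            raise ValueError(f"sigma0 must be positive, got {self.sigma0}")
        if self.xi != 0.0:
            raise ValueError(
                "only the quasi-steady nutrient limit xi = 0 is supported, "
                f"got xi = {self.xi}"
            )


@dataclass(frozen=True)
class DimensionalScales:
    """Mapping between dimensionless model quantities and lab units.

    ``L_um`` is the nutrient diffusion length scale and ``S0_um`` the
    initial pellet radius, both in micrometres; their ratio must equal
    the ``sigma0`` of the paired :class:`ModelParameters`.  ``beta_per_day``
    is the proteoglycan production rate constant interpreted per day,
    which defines the dimensionless time unit ``1/beta`` (see
    ``docs/methods.md`` for why the per-day interpretation is used and
    how to override it).  ``B0`` is the medium nutrient concentration in
    its own normalised units and is 1 by construction.
    """

    L_um: float = 14.0
    beta_per_day: float = 0.23
    S0_um: float = 84.0
    B0: float = 1.0

    def __post_init__(self) -> None:
        for name in ("L_um", "beta_per_day", "S0_um", "B0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")

    @property
    def sigma0(self) -> float:
        """Dimensionless initial radius implied by the lab scales."""
        return self.S0_um / self.L_um

    def consistent_with(self, params: ModelParameters) -> bool:
        """Whether S0/L matches ``params.sigma0`` to 1e-12 relative."""
        return abs(self.sigma0 - params.sigma0) <= _SIGMA0_RTOL * abs(params.sigma0)


def days_to_model_time(days, scales: DimensionalScales):
    """Convert laboratory days to dimensionless model time ``beta * days``.

    With the quasi-steady nutrient, matrix production is the only rate
    left in the model, so dimensionless time is measured in units of the
    inverse production rate constant ``1/beta``.
    """
    arr = np.asarray(days, dtype=float)
    if np.any(arr < 0):
        raise ValueError("days must be nonnegative")
    out = scales.beta_per_day * arr
    return float(out) if np.isscalar(days) else out


def model_time_to_days(t, scales: DimensionalScales):
    """Inverse of :func:`days_to_model_time`."""
    arr = np.asarray(t, dtype=float)
    out = arr / scales.beta_per_day
    return float(out) if np.isscalar(t) else out


@dataclass(frozen=True)
class RadialGrid:
    """Uniform grid on the mapped radial coordinate ``y = r/S(t)``.

    The moving pellet boundary is fixed to ``y = 1`` by the front-fixing
    map, so one static grid serves the whole simulation.
    """

    N: int
    y: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.N < 3:
            raise ValueError(f"grid needs at least 3 nodes, got N={self.N}")
        object.__setattr__(self, "y", np.linspace(0.0, 1.0, self.N))

    @property
    def dy(self) -> float:
        return 1.0 / (self.N - 1)


@dataclass
class PelletState:
    """Radial profiles on the mapped grid at one instant.

    Attributes
    ----------
    t : float
        Dimensionless time.
    S : float
        Dimensionless pellet radius.
    n, p, B, v : ndarray
        Cell fraction, matrix fraction, nutrient and radial velocity at
        the grid nodes.  ``p`` is closed algebraically as ``1 - n``.
    p_debug : ndarray or None
        Independently integrated matrix fraction, populated only when
        the transport solver runs with ``track_independent_p``; used to
        test the algebraic closure, never in production runs.
    """

    t: float
    S: float
    n: np.ndarray
    p: np.ndarray
    B: np.ndarray
    v: np.ndarray
    p_debug: np.ndarray | None = None

    def copy(self) -> "PelletState":
        return PelletState(
            t=self.t,
            S=self.S,
            n=self.n.copy(),
            p=self.p.copy(),
            B=self.B.copy(),
            v=self.v.copy(),
            p_debug=None if self.p_debug is None else self.p_debug.copy(),
        )


def validate_state(
    state: PelletState,
    sigma0: float | None = None,
    closure_tol: float = 1e-10,
    bounds_tol: float = 1e-9,
) -> list[str]:
    """Check every :class:`PelletState` invariant; return violations.

    Pure: the state is not modified.  An empty list means the state is
    valid.  ``bounds_tol`` absorbs round-off on the [0, 1] bounds of the
    volume fractions and the nutrient; the volume-fraction closure is
    checked at ``closure_tol``.

    Raises
    ------
    ValueError
        If the profile arrays do not share one length (a structural
        defect rather than a physical invariant violation).
    """
    lengths = {len(state.n), len(state.p), len(state.B), len(state.v)}
    if len(lengths) != 1:
        raise ValueError(f"profile arrays have mismatched lengths: {sorted(lengths)}")

    violations: list[str] = []
    if np.any(state.n < -bounds_tol) or np.any(state.n > 1 + bounds_tol):
        violations.append("cell fraction n outside [0, 1]")
    if np.any(state.p < -bounds_tol) or np.any(state.p > 1 + bounds_tol):
        violations.append("matrix fraction p outside [0, 1]")
    closure = np.max(np.abs(state.n + state.p - 1.0))
    if closure > closure_tol:
        violations.append(
            f"volume-fraction closure |n + p - 1| = {closure:.2e} exceeds {closure_tol:.0e}"
        )
    if np.any(state.B < -bounds_tol) or np.any(state.B > 1 + bounds_tol):
        violations.append("nutrient B outside [0, 1]")
    if abs(state.v[0]) > bounds_tol:
        violations.append("centre symmetry condition v = 0 at r = 0 violated")
    if sigma0 is not None and state.S < sigma0 * (1 - 1e-12):
        violations.append(f"pellet radius S = {state.S} below initial sigma0 = {sigma0}")
    return violations


# ---------------------------------------------------------------------------
# Configuration

_CONFIG_KEYS = ("kappa", "sigma0", "beta_per_day", "L_um", "S0_um")


def default_config() -> dict[str, float]:
    """Default parameter configuration: the fitted values for the
    day-21/28 ATDC-5 pellet data."""
    return {"kappa": 0.3, "sigma0": 6.0, "beta_per_day": 0.23, "L_um": 14.0, "S0_um": 84.0}


def load_config(path: str | Path | None = None, overrides: dict[str, Any] | None = None):
    """Build ``(ModelParameters, DimensionalScales)`` from a YAML/JSON file.

    Missing keys fall back to :func:`default_config`.  If both
    ``sigma0`` and the pair ``(S0_um, L_um)`` are given they must agree
    to 1e-12 relative.
    """
    cfg = default_config()
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else _load_any(text)
        if loaded is None:
            loaded = {}
        unknown = set(loaded) - set(_CONFIG_KEYS)
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        explicit = dict(loaded)
        cfg.update(loaded)
    else:
        explicit = {}
    if overrides:
        explicit.update({k: v for k, v in overrides.items() if v is not None})
        cfg.update(explicit)

    if "sigma0" in explicit and not ("S0_um" in explicit or "L_um" in explicit):
        # sigma0 given alone: rescale S0 to keep the unit mapping coherent
        cfg["S0_um"] = cfg["sigma0"] * cfg["L_um"]
    scales = DimensionalScales(
        L_um=cfg["L_um"], beta_per_day=cfg["beta_per_day"], S0_um=cfg["S0_um"]
    )
    if abs(scales.sigma0 - cfg["sigma0"]) > _SIGMA0_RTOL * abs(cfg["sigma0"]):
        raise ValueError(
            f"inconsistent configuration: S0_um/L_um = {scales.sigma0} "
            f"but sigma0 = {cfg['sigma0']}"
        )
    params = ModelParameters(kappa=cfg["kappa"], sigma0=cfg["sigma0"])
    return params, scales


def _load_any(text: str):
    try:
        return json.loads(text)
    except json.JSONDecodeError:
        return yaml.safe_load(text)
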