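"""Deterministic size-at-age growth functions.

Two classical three-parameter curves for indeterminate growers such as
salmonids, in the parametrizations most commonly used for longitudinal
size-at-age data:

* von Bertalanffy (vBGF), ``L(t) = L_inf * (1 - exp(-k (t - t0)))`` —
  asymptotic length ``L_inf`` (mm), growth-rate coefficient ``k`` (1/yr)
  and ``t0``, the hypothetical age at which length would be zero. An
  equivalent form anchored at the length at age zero, ``L0``, is
  ``L(t) = L_inf * (1 - exp(-k t)) + L0 * exp(-k t)``.

* Gompertz (GGF), ``L(t) = A * exp(-exp(-k_G (t - T_i)))`` — asymptote
  ``A`` (mm), growth coefficient ``k_G`` (1/yr) and inflection age ``T_i``
  (yr). At ``t = T_i`` the curve has attained exactly ``exp(-1)`` (about
  37%) of its final size.

All functions are pure, accept scalar or array ages, and never clamp:
the vBGF is negative for ``t < t0`` by construction, which keeps the
surface smooth for the optimizers built on top of it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "VbgfParams",
    "GompertzParams",
    "vbgf_length",
    "vbgf_length_from_L0",
    "vbgf_t0_from_L0",
    "gompertz_length",
    "inflection_fraction",
]


@dataclass(frozen=True)
class VbgfParams:
    """von Bertalanffy parameters.

    L_inf : asymptotic length (mm), > 0
    k     : growth-rate coefficient (1/yr), > 0
    t0    : hypothetical age at zero length (yr), any sign
    L0    : optional length at age 0 (mm), 0 <= L0 < L_inf, for the
            age-zero-anchored form
    """

    L_inf: float
    k: float
    t0: float = 0.0
    L0: float | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.L_inf) and self.L_inf > 0):
            raise ValueError(f"L_inf must be finite and > 0, got {self.L_inf}")
        if not (np.isfinite(self.k) and self.k > 0):
            raise ValueError(f"k must be finite and > 0, got {self.k}")
        if not np.isfinite(self.t0):
            raise ValueError(f"t0 must be finite, got {self.t0}")
        if self.L0 is not None:
            if not np.isfinite(self.L0) or self.L0 < 0 or self.L0 >= self.L_inf:
                raise ValueError(
                    f"L0 must satisfy 0 <= L0 < L_inf, got L0={self.L0}, L_inf={self.L_inf}"
                )


@dataclass(frozen=True)
class GompertzParams:
    """Gompertz parameters.

    A   : asymptotic length (mm), > 0
    k_G : growth coefficient (1/yr), > 0
    T_i : age at the inflection point (yr), any sign
    """

    A: float
    k_G: float
    T_i: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.A) and self.A > 0):
            raise ValueError(f"A must be finite and > 0, got {self.A}")
        if not (np.isfinite(self.k_G) and self.k_G > 0):
            raise ValueError(f"k_G must be finite and > 0, got {self.k_G}")
        if not np.isfinite(self.T_i):
            raise ValueError(f"T_i must be finite, got {self.T_i}")


def _check_age(t):
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("ages must be finite")
    return t


def vbgf_length(t, p: VbgfParams):
    """von Bertalanffy length-at-age, t0 parametrization.

    Returns ``L_inf * (1 - exp(-k (t - t0)))``; negative below ``t0``.
    """
    t = _check_age(t)
    out = p.L_inf * (1.0 - np.exp(-p.k * (t - p.t0)))
    return out if out.ndim else float(out)


def vbgf_length_from_L0(t, p: VbgfParams):
    """von Bertalanffy length-at-age anchored at length L0 at age 0.

    Returns ``L_inf * (1 - exp(-k t)) + L0 * exp(-k t)``; ``L(0) == L0``.
    """
    if p.L0 is None:
        raise ValueError("VbgfParams.L0 is required for the age-zero-anchored form")
    t = _check_age(t)
    decay = np.exp(-p.k * t)
    out = p.L_inf * (1.0 - decay) + p.L0 * decay
    return out if out.ndim else float(out)


def vbgf_t0_from_L0(L0: float, L_inf: float, k: float) -> float:
    """Map the age-zero length L0 to the equivalent t0.

    The two vBGF forms describe the same curve when
    ``t0 = log(1 - L0 / L_inf) / k``; L0 = 0 gives t0 = 0.
    """
    if not (0 <= L0 < L_inf):
        raise ValueError(f"t0 undefined: need 0 <= L0 < L_inf, got L0={L0}, L_inf={L_inf}")
    if k <= 0:
        raise ValueError(f"k must be > 0, got {k}")
    return math.log(1.0 - L0 / L_inf) / k


def gompertz_length(t, p: GompertzParams):
    """Gompertz length-at-age, ``A * exp(-exp(-k_G (t - T_i)))``.

    Strictly positive, strictly increasing, bounded above by ``A``.
    """
    t = _check_age(t)
    out = p.A * np.exp(-np.exp(-p.k_G * (t - p.T_i)))
    return out if out.ndim else float(out)


def inflection_fraction() -> float:
    """Fraction of the Gompertz asymptote attained at the inflection age.

    Exactly ``exp(-1)`` (~0.3679, i.e. ~37% of final growth), independent
    of the parameter values.
    """
    return math.exp(-1.0)
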