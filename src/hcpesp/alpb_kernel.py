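"""Screened per-charge potential in the ALPB model.

The analytic linearized Poisson-Boltzmann (ALPB) model gives a closed-form
approximation to the potential outside a low-dielectric solute immersed in
a high-dielectric solvent.  The potential at an outside observation point
due to a single point charge ``q`` inside the solute is

    phi = (q / eps_in) * 1/(1 + alpha*beta) * [ (1+alpha)/d - alpha*(1-beta)/r ]

with ``beta = eps_in/eps_out``, ``d`` the charge-to-point distance, ``r``
the structure-center-to-point distance, and ``alpha`` the universal ALPB
constant (~0.580127).  In the limit ``eps_in = eps_out`` (beta = 1) the
screening term vanishes and the expression collapses exactly to Coulomb's
law ``q/(eps*d)``, which anchors the analytic tests.

Charges are in elementary charge units e and distances in Å, so the natural
output unit is e/Å scaled by 1/permittivity; multiplying by
:data:`KCAL_MOL_PER_E_ANGSTROM` converts to kcal/(mol·e).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np

#: Conversion from e/(Å·relative permittivity) to kcal/(mol·e).
KCAL_MOL_PER_E_ANGSTROM = 332.0636

#: Universal ALPB constant alpha.
DEFAULT_ALPHA = 0.580127


@dataclasses.dataclass
class ALPBParams:
    """Dielectric and unit parameters of the ALPB potential.

    Parameters
    ----------
    eps_in : float
        Relative permittivity of the solute interior (> 0). Default 1.
    eps_out : float
        Relative permittivity of the solvent (> 0). Default 80 (water).
    alpha : float
        Dimensionless ALPB constant (>= 0). Default 0.580127.
    unit_factor : float
        Output-unit multiplier (> 0). Default 1 (natural units);
        332.0636 yields kcal/(mol·e).
    """

    eps_in: float = 1.0
    eps_out: float = 80.0
    alpha: float = DEFAULT_ALPHA
    unit_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.eps_in <= 0 or self.eps_out <= 0:
            raise ValueError("permittivities must be positive")
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if self.unit_factor <= 0:
            raise ValueError("unit_factor must be positive")

    @property
    def beta(self) -> float:
        """Dielectric ratio eps_in/eps_out."""
        return self.eps_in / self.eps_out

    def coefficients(self) -> tuple[float, float, float]:
        """(prefactor, d-coefficient, r-coefficient) of the kernel.

        phi = prefactor * q * (c_d/d - c_r/r) with
        prefactor = unit_factor / (eps_in*(1+alpha*beta)),
        c_d = 1+alpha, c_r = alpha*(1-beta).
        """
        beta = self.beta
        pref = self.unit_factor / (self.eps_in * (1.0 + self.alpha * beta))
        return pref, 1.0 + self.alpha, self.alpha * (1.0 - beta)


@dataclasses.dataclass
class KernelQuery:
    """Geometry of one kernel evaluation: charge-to-vertex distance ``d``
    and structure-center-to-vertex distance ``r``, both Å and positive."""

    d: float
    r: float

    def __post_init__(self) -> None:
        if not (self.d > 0):
            raise ValueError(f"charge-to-vertex distance d must be positive, got {self.d}")
        if not (self.r > 0):
            raise ValueError(f"center-to-vertex distance r must be positive, got {self.r}")


def alpb_potential(q: float, query: KernelQuery, params: ALPBParams) -> float:
    """Potential at one point due to one charge (output units)."""
    pref, c_d, c_r = params.coefficients()
    return pref * q * (c_d / query.d - c_r / query.r)


def alpb_potential_array(
    q: np.ndarray,
    d: np.ndarray,
    r: np.ndarray | float,
    params: ALPBParams,
    dtype=np.float64,
) -> np.ndarray:
    """Elementwise kernel over arrays of charges and distances.

    ``dtype`` selects the arithmetic precision; with ``np.float32`` every
    operand is cast down first, emulating a single-precision pipeline.
    The caller is responsible for d > 0 and r > 0.
    """
    pref, c_d, c_r = params.coefficients()
    q = np.asarray(q, dtype=dtype)
    d = np.asarray(d, dtype=dtype)
    r = np.asarray(r, dtype=dtype)
    pref = dtype(pref)
    c_d = dtype(c_d)
    c_r = dtype(c_r)
    return pref * q * (c_d / d - c_r / r)


def alpb_potential_batch(
    qs: Sequence[float], queries: Sequence[KernelQuery], params: ALPBParams
) -> float:
    """Sum of scalar kernel evaluations over paired charges and queries."""
    if len(qs) != len(queries):
        raise ValueError(f"length mismatch: {len(qs)} charges vs {len(queries)} queries")
    d = np.array([kq.d for kq in queries], dtype=float)
    r = np.array([kq.r for kq in queries], dtype=float)
    if np.any(d <= 0) or np.any(r <= 0):
        raise ValueError("all distances must be positive")
    return float(alpb_potential_array(np.asarray(qs, dtype=float), d, r, params).sum())
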