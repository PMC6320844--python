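"""Partition coefficients from membrane-coated-fiber (MCF) extraction.

The MCF assay exposes a polymer-coated fiber to a solute-spiked
formulation; the partition coefficient K_MCF/mix is the ratio of the
equilibrium solute concentration inside the membrane coating to the
equilibrium concentration remaining in the formulation.  With

* ``n0``  amount of solute extracted into the membrane (ug),
* ``C0``  starting solute concentration in the formulation (ug/mL),
* ``Vd``  volume of formulation in the vial (mL),
* ``Vm``  volume of the membrane coating (mL),

the equilibrium concentrations are ``C_pe = n0/Vm`` (membrane) and
``C_me = C0 - n0/Vd`` (formulation), giving

    K = C_pe / C_me = n0 * Vd / (Vm * (C0*Vd - n0)).

If extraction removes a fixed proportion ``p`` of the solute regardless
of ``C0`` (``n0 = p*C0``), K collapses to ``p*Vd / (Vm*(Vd - p))`` and is
independent of the starting concentration.  That closed form is the
"partition theory" tested statistically in :mod:`mcflfer.theory`; the
algebraic identity between the two routes is property-tested.

Units are fixed (ug, mL, ug/mL); the formula is unit-consistent only
under one convention, so no unit inference is attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import PartitionDomainError

__all__ = [
    "MCFMeasurement",
    "PartitionResult",
    "partition_coefficient",
    "theoretical_partition",
    "partition_arrays",
]


@dataclass(frozen=True)
class MCFMeasurement:
    """Raw extraction quantities for one replicate measurement.

    Invariants: ``Vm > 0``, ``Vd > 0``, ``C0 > 0`` and
    ``0 <= n0 < C0*Vd`` (the extracted amount cannot reach the total
    amount of solute in the vial, or the equilibrium formulation
    concentration would be <= 0).
    """

    n0: float  # ug extracted into the membrane
    C0: float  # ug/mL starting concentration
    Vd: float  # mL formulation volume
    Vm: float  # mL membrane volume

    def __post_init__(self) -> None:
        if self.Vm <= 0 or self.Vd <= 0:
            raise PartitionDomainError(
                f"volumes must be positive: Vd={self.Vd}, Vm={self.Vm}"
            )
        if self.C0 <= 0:
            raise PartitionDomainError(f"C0 must be positive: C0={self.C0}")
        if not 0 <= self.n0 < self.C0 * self.Vd:
            raise PartitionDomainError(
                f"n0={self.n0} outside [0, C0*Vd={self.C0 * self.Vd}): "
                "equilibrium formulation concentration would be <= 0"
            )

    @property
    def c_pe(self) -> float:
        """Equilibrium concentration in the membrane, n0/Vm (ug/mL)."""
        return self.n0 / self.Vm

    @property
    def c_me(self) -> float:
        """Equilibrium concentration in the formulation, C0 - n0/Vd (ug/mL)."""
        return self.C0 - self.n0 / self.Vd


@dataclass(frozen=True)
class PartitionResult:
    """A partition coefficient and its base-10 logarithm.

    ``log_k`` is ``None`` when ``k == 0`` (no extraction): such rows
    carry no usable response and are excluded from model fitting.
    """

    k: float
    log_k: float | None

    @property
    def defined(self) -> bool:
        return self.log_k is not None


def partition_coefficient(m: MCFMeasurement) -> PartitionResult:
    """K_MCF/mix from raw extraction quantities.

    K = n0*Vd / (Vm*(C0*Vd - n0)).  Returns k = 0 with an absent log_k
    when nothing was extracted.
    """
    k = m.n0 * m.Vd / (m.Vm * (m.C0 * m.Vd - m.n0))
    return PartitionResult(k=k, log_k=math.log10(k) if k > 0 else None)


def theoretical_partition(p: float, Vd: float, Vm: float) -> float:
    """Partition coefficient implied by proportional extraction.

    If n0 = p*C0 with proportionality constant ``p`` (0 <= p <= 1) not
    depending on C0, then K = p*Vd / (Vm*(Vd - p)) for every C0.
    """
    if Vm <= 0 or Vd <= 0:
        raise PartitionDomainError(f"volumes must be positive: Vd={Vd}, Vm={Vm}")
    if p < 0 or Vd - p <= 0:
        raise PartitionDomainError(f"need 0 <= p < Vd, got p={p}, Vd={Vd}")
    return p * Vd / (Vm * (Vd - p))


def partition_arrays(n0, C0, Vd, Vm):
    """Vectorised partition coefficients for observation tables.

    Returns ``(k, log_k)`` arrays; ``log_k`` is NaN where ``k == 0``.
    Raises :class:`PartitionDomainError` if any row violates the
    measurement invariants.
    """
    n0 = np.asarray(n0, dtype=float)
    C0 = np.asarray(C0, dtype=float)
    Vd = np.asarray(Vd, dtype=float)
    Vm = np.asarray(Vm, dtype=float)
    if np.any(Vm <= 0) or np.any(Vd <= 0) or np.any(C0 <= 0):
        raise PartitionDomainError("volumes and C0 must be positive in every row")
    if np.any(n0 < 0) or np.any(n0 >= C0 * Vd):
        raise PartitionDomainError("n0 must satisfy 0 <= n0 < C0*Vd in every row")
    k = n0 * Vd / (Vm * (C0 * Vd - n0))
    with np.errstate(divide="ignore"):
        log_k = np.where(k > 0, np.log10(np.where(k > 0, k, 1.0)), np.nan)
    return k, log_k
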