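"""Centesimal-dilution arithmetic: theoretical molarity along a potency
chain, expected molecule counts via Avogadro's number, and solvent
(ethanol) fraction tracking.

A centesimal step dilutes 1:100, so ``n`` steps scale the mother-tincture
molarity by 100**-n (total dilution factor 10**(2n)). The in-assay step of
adding 1 ml drug solution to a 10-ml culture plate is conventionally
modelled as an extra factor of 10. Expected molecule counts below 1 are
reported as real-valued Poisson means, flagged sub-molecular, never
truncated.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: 2019 SI exact value, mol^-1
AVOGADRO = 6.02214076e23


@dataclass
class DilutionSpec:
    """A potency chain: base molarity, centesimal steps, extra linear factors."""

    base_molarity: float
    centesimal_steps: int = 0
    extra_factors: tuple[float, ...] = ()
    solvent_ethanol_fraction: float = 30.0  # % v/v used at each step

    def __post_init__(self) -> None:
        if self.base_molarity <= 0:
            raise ValueError("base_molarity must be positive")
        if self.centesimal_steps < 0:
            raise ValueError("centesimal_steps must be >= 0")
        if any(f < 1 for f in self.extra_factors):
            raise ValueError("extra dilution factors must be >= 1")

    @property
    def total_factor_log10(self) -> float:
        """log10 of the total dilution factor, 2n + sum(log10 extras)."""
        return 2.0 * self.centesimal_steps + float(
            np.sum([np.log10(f) for f in self.extra_factors])
        )


def centesimal_molarity(spec: DilutionSpec) -> float:
    """Theoretical solute molarity after the whole chain."""
    return spec.base_molarity / 10.0 ** spec.total_factor_log10


@dataclass
class MoleculeCount:
    molarity: float
    volume_l: float
    count: float
    per_cell: float | None = None
    sub_molecular: bool = field(init=False)

    def __post_init__(self) -> None:
        self.sub_molecular = self.count < 1.0


def molecule_count(
    molarity: float, volume_l: float, cells: int | None = None
) -> MoleculeCount:
    """Expected number of solute molecules in a volume (and per cell).

    The count is a Poisson mean: ``molarity * volume * N_A``; values below 1
    are flagged ``sub_molecular``.
    """
    if volume_l <= 0:
        raise ValueError("volume must be positive")
    count = molarity * volume_l * AVOGADRO
    per_cell = count / cells if cells else None
    return MoleculeCount(molarity=molarity, volume_l=volume_l, count=count, per_cell=per_cell)


def ethanol_fraction(c_in: float, v_in: float, v_total: float) -> float:
    """Ethanol % v/v after diluting ``v_in`` of a ``c_in``-% solution to ``v_total``."""
    if not 0 <= c_in <= 100:
        raise ValueError("ethanol fraction must be in [0, 100] %")
    if v_in <= 0 or v_total <= 0 or v_in > v_total:
        raise ValueError("need 0 < v_in <= v_total")
    return c_in * v_in / v_total


def chain_ethanol(c_start: float, steps: Sequence[tuple[float, float]]) -> float:
    """Apply successive (v_in, v_total) dilution steps to an ethanol fraction."""
    c = c_start
    for v_in, v_total in steps:
        c = ethanol_fraction(c, v_in, v_total)
    return c
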