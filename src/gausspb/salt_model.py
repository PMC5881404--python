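"""Born desolvation penalty for mobile ions and their Boltzmann
distributions in the surface-free dielectric.

Without a molecular surface there is no ion-exclusion region: mobile
ions are instead suppressed energetically.  An ion of valence z and Born
radius r0 moving from bulk solvent (eps_out) into a region of local
dielectric eps(r) pays the Born transfer energy

    dG_penalty(r) = (N_A z^2 e^2 / (8 pi eps0 r0)) * (1/eps(r) - 1/eps_out),

positive wherever eps(r) < eps_out, zero in bulk.  The local ion
concentration then follows a Boltzmann law in the total energy,

    c(r) = c_bulk * exp( (-z * phi(r) * kT - dG_penalty(r)) / RT ),

with phi in kT/e, so ions vanish from the low-dielectric solute interior
but can populate partially hydrated cavities.

Sign convention: the penalty is implemented as positive in low-dielectric
regions so that ``exp(-dG/RT)`` suppresses ions inside the solute — the
physically meaningful direction for a desolvation penalty.  The opposite
overall sign can be selected via ``convention="attractive"`` for audit
purposes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import CODATA, JOULES_PER_KCAL, kT_kcal
from .grids import ScalarField

__all__ = ["IonSpecies", "born_penalty", "penalty_field", "ion_concentration_field", "neutral_salt"]


@dataclass(frozen=True)
class IonSpecies:
    """A mobile ion species: valence z, bulk concentration (mol/L), Born radius (Å)."""

    valence: int
    bulk_concentration: float
    born_radius: float = 2.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.born_radius <= 0:
            raise ValueError(f"born_radius must be > 0, got {self.born_radius}")
        if self.bulk_concentration < 0:
            raise ValueError("bulk_concentration must be >= 0")


def neutral_salt(concentration: float, born_radius: float = 2.0) -> list[IonSpecies]:
    """A charge-balanced 1:1 electrolyte at the given molarity."""
    return [
        IonSpecies(valence=1, bulk_concentration=concentration, born_radius=born_radius, label="cation"),
        IonSpecies(valence=-1, bulk_concentration=concentration, born_radius=born_radius, label="anion"),
    ]


def check_charge_balance(ions: list[IonSpecies]) -> None:
    net = sum(i.valence * i.bulk_concentration for i in ions)
    if abs(net) > 1e-12:
        raise ValueError(f"ion species are not charge-balanced in bulk (net {net} M·e)")


def born_penalty(
    eps_local: float | np.ndarray,
    ion: IonSpecies,
    eps_out: float,
    convention: str = "penalty",
) -> float | np.ndarray:
    """Born transfer energy (kcal/mol) for an ion at local dielectric ``eps_local``.

    Evaluated from CODATA constants in SI units and converted:
    ``N_A z^2 e^2 / (8 pi eps0 r0) * (1/eps_local - 1/eps_out)``.
    Positive when ``eps_local < eps_out`` (unfavourable), exactly zero at
    ``eps_local = eps_out``.
    """
    eps_local = np.asarray(eps_local, dtype=float)
    if np.any(eps_local <= 0):
        raise ValueError("eps_local must be > 0")
    if convention not in ("penalty", "attractive"):
        raise ValueError(f"unknown sign convention {convention!r}")
    r0_m = ion.born_radius * 1e-10
    prefactor_J = (
        CODATA.avogadro
        * ion.valence**2
        * CODATA.elementary_charge**2
        / (8.0 * np.pi * CODATA.vacuum_permittivity * r0_m)
    )
    dg = (prefactor_J / JOULES_PER_KCAL) * (1.0 / eps_local - 1.0 / eps_out)
    if convention == "attractive":
        dg = -dg
    return float(dg) if dg.ndim == 0 else dg


def penalty_field(
    eps_field: ScalarField,
    ion: IonSpecies,
    eps_out: float | None = None,
    convention: str = "penalty",
) -> ScalarField:
    """Nodewise Born penalty map (kcal/mol) for one ion species.

    ``eps_out`` defaults to the bulk value recorded on the dielectric map
    (falling back to its maximum); the penalty is exactly zero wherever
    the map equals it.
    """
    if eps_field.role != "dielectric":
        raise ValueError(f"expected a dielectric field, got role {eps_field.role!r}")
    if eps_out is None:
        eps_out = float(eps_field.metadata.get("eps_out", eps_field.values.max()))
    dg = born_penalty(eps_field.values, ion, eps_out, convention=convention)
    return ScalarField(grid=eps_field.grid, values=dg, role="penalty", units="kcal/mol")


def ion_concentration_field(
    potential: ScalarField,
    penalty: ScalarField,
    ion: IonSpecies,
    temperature: float = 298.15,
) -> ScalarField:
    """Boltzmann concentration map ``c(r) = c_bulk exp(-z phi - dG_pen/RT)`` (mol/L).

    ``potential`` must be in kT/e (so ``z * phi`` is already in thermal
    units); the penalty map is in kcal/mol and is divided by RT.
    """
    if potential.role != "potential":
        raise ValueError(f"expected a potential field, got role {potential.role!r}")
    if penalty.role != "penalty":
        raise ValueError(f"expected a penalty field, got role {penalty.role!r}")
    potential.require_same_grid(penalty)
    rt = kT_kcal(temperature)
    exponent = -ion.valence * potential.values - penalty.values / rt
    c = ion.bulk_concentration * np.exp(np.minimum(exponent, 700.0))
    return ScalarField(grid=potential.grid, values=c, role="concentration", units="mol/L")
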