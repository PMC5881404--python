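"""Finite-difference Poisson and Poisson-Boltzmann solver with a
spatially varying dielectric.

The PDE solved (Gaussian-units convention, potentials internally in
kT/e) is

    div[ eps(r) grad phi(r) ] = -4 pi ( rho_solute(r)
          + sum_i z_i e c_i^bulk exp( (-z_i e phi(r) - dG_penalty_i(r)) / RT ) )

discretized on a uniform grid with a flux-conservative 7-point stencil.
The dielectric enters at the six cell-face midpoints by direct evaluation
of the Gaussian model (see :class:`~gausspb.gaussian_dielectric.DielectricMaps`),
no averaging of node values.  Fixed solute charges are spread to the
eight surrounding nodes with trilinear weights.  The linear system is
solved by checkerboard (red-black) successive over-relaxation; the
nonlinear Boltzmann term is lagged one sweep and damped.

Polar solvation energies use the standard two-solve reaction-field
scheme: the same grid and charges are solved once with the solvated
dielectric map and once with a uniform ``eps_in`` reference, and

    dG_polar = 1/2 sum_i q_i [ phi_solv(r_i) - phi_ref(r_i) ]

cancels the grid self-energy between the two solves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import KCOUL, MOLAR_TO_PER_A3, kT_kcal
from .gaussian_dielectric import DielectricMaps, GaussianParams, dielectric_maps
from .grids import GridSpec, ScalarField
from .salt_model import IonSpecies, check_charge_balance, penalty_field
from .structure_io import Structure

__all__ = [
    "SolverConfig",
    "ConvergenceError",
    "charge_spread",
    "solve_poisson",
    "solve_pbe",
    "reaction_field_energy",
    "binding_polar_energy",
    "discrete_residual",
]

FOUR_PI = 4.0 * np.pi


class ConvergenceError(RuntimeError):
    """Solver failed to converge; carries the final residual."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


@dataclass(frozen=True)
class SolverConfig:
    """Finite-difference solver configuration.

    tolerance is the maximum allowed potential change per SOR sweep in
    kT/e; boundary is either 'zero' (grounded box) or 'debye_huckel'
    (sum of screened monopole potentials of all solute charges).
    """

    params: GaussianParams = field(default_factory=GaussianParams)
    temperature: float = 298.15
    tolerance: float = 1e-6
    max_iterations: int = 20000
    mode: str = "linear"
    boundary: str = "debye_huckel"
    relaxation: float = 1.9
    nonlinear_damping: float = 0.6
    spacing: float = 0.5
    margin_fraction: float = 0.4
    min_margin: float = 10.0

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if not (0 < self.relaxation < 2):
            raise ValueError("relaxation must be in (0, 2)")
        if self.mode not in ("linear", "nonlinear"):
            raise ValueError(f"mode must be linear or nonlinear, got {self.mode!r}")
        if self.boundary not in ("zero", "debye_huckel"):
            raise ValueError(f"boundary must be zero or debye_huckel, got {self.boundary!r}")

    def grid_for(self, structure: Structure) -> GridSpec:
        lo, hi = structure.bounds()
        return GridSpec.from_bounds(
            lo, hi, self.spacing, self.margin_fraction, self.min_margin
        )


def charge_spread(structure: Structure, grid: GridSpec) -> ScalarField:
    """Distribute atomic charges to the 8 surrounding nodes (trilinear).

    Node values are charges in e (not densities); their sum equals the
    structure's total charge.  A charged atom outside the grid raises.
    """
    structure.require_nonempty("charge_spread")
    q = np.zeros(grid.shape, dtype=float)
    pos = structure.positions
    charges = structure.charges
    inside = grid.contains(pos)
    bad = np.nonzero((~inside) & (charges != 0))[0]
    if bad.size:
        names = [structure.atoms[i].name for i in bad[:5]]
        raise ValueError(f"charged atom(s) outside the grid box: {names}")
    frac = grid.to_index(pos)
    base = np.floor(frac).astype(int)
    base = np.minimum(base, np.asarray(grid.shape) - 2)  # atoms exactly on the top face
    t = frac - base
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (
                    (t[:, 0] if dx else 1 - t[:, 0])
                    * (t[:, 1] if dy else 1 - t[:, 1])
                    * (t[:, 2] if dz else 1 - t[:, 2])
                )
                np.add.at(q, (base[:, 0] + dx, base[:, 1] + dy, base[:, 2] + dz), w * charges)
    return ScalarField(grid=grid, values=q, role="charge", units="e")


def _as_maps(eps, grid: GridSpec) -> DielectricMaps:
    if isinstance(eps, DielectricMaps):
        return eps
    return DielectricMaps.uniform(float(eps), grid)


def _ionic_strength_per_A3(ions: list[IonSpecies]) -> float:
    """sum_i z_i^2 c_i in ions/Å³."""
    return sum(i.valence**2 * i.bulk_concentration * MOLAR_TO_PER_A3 for i in ions)


def debye_kappa(ions: list[IonSpecies], eps_out: float, temperature: float) -> float:
    """Inverse Debye length (1/Å) of the bulk electrolyte."""
    if not ions:
        return 0.0
    c = KCOUL / kT_kcal(temperature)
    return float(np.sqrt(FOUR_PI * c * _ionic_strength_per_A3(ions) / eps_out))


def _boundary_values(
    grid: GridSpec,
    charge_field: ScalarField,
    eps_bulk: float,
    kappa: float,
    temperature: float,
) -> np.ndarray:
    """Dirichlet boundary: screened monopole sum of all grid charges, kT/e."""
    c = KCOUL / kT_kcal(temperature)
    phi = np.zeros(grid.shape, dtype=float)
    idx = np.nonzero(charge_field.values)
    if idx[0].size == 0:
        return phi
    qpos = np.stack(idx, axis=-1) * grid.spacing + np.asarray(grid.origin)
    qval = charge_field.values[idx]
    nx, ny, nz = grid.shape
    faces = []
    for axis, side in ((0, 0), (0, nx - 1), (1, 0), (1, ny - 1), (2, 0), (2, nz - 1)):
        sel = [np.arange(n) for n in grid.shape]
        sel[axis] = np.array([side])
        I, J, K = np.meshgrid(*sel, indexing="ij")
        faces.append((I.ravel(), J.ravel(), K.ravel()))
    for I, J, K in faces:
        pts = np.stack([I, J, K], axis=-1) * grid.spacing + np.asarray(grid.origin)
        d = np.linalg.norm(pts[:, None, :] - qpos[None, :, :], axis=-1)
        d = np.maximum(d, 0.5 * grid.spacing)
        phi[I, J, K] = (c / eps_bulk) * np.sum(qval[None, :] * np.exp(-kappa * d) / d, axis=1)
    return phi


def _interior_faces(maps: DielectricMaps):
    ex, ey, ez = maps.face_x, maps.face_y, maps.face_z
    return (
        ex[:-1, 1:-1, 1:-1], ex[1:, 1:-1, 1:-1],
        ey[1:-1, :-1, 1:-1], ey[1:-1, 1:, 1:-1],
        ez[1:-1, 1:-1, :-1], ez[1:-1, 1:-1, 1:],
    )


def _checkerboard(shape: tuple[int, int, int]) -> np.ndarray:
    idx = np.add.outer(np.add.outer(np.arange(shape[0]), np.arange(shape[1])), np.arange(shape[2]))
    return (idx % 2) == 0


def _neighbor_sum(phi, exm, exp_, eym, eyp, ezm, ezp):
    return (
        exm * phi[:-2, 1:-1, 1:-1] + exp_ * phi[2:, 1:-1, 1:-1]
        + eym * phi[1:-1, :-2, 1:-1] + eyp * phi[1:-1, 2:, 1:-1]
        + ezm * phi[1:-1, 1:-1, :-2] + ezp * phi[1:-1, 1:-1, 2:]
    )


def _sor(
    maps: DielectricMaps,
    charge_field: ScalarField,
    config: SolverConfig,
    lin_screen: np.ndarray | None = None,
    lin_source: np.ndarray | None = None,
    nonlinear: dict | None = None,
    bc_kappa: float = 0.0,
    phi0: np.ndarray | None = None,
) -> tuple[np.ndarray, int, float]:
    """Red-black SOR on the flux-conservative stencil.

    ``lin_screen``/``lin_source`` are the diagonal screening and constant
    ionic source of the linearized Boltzmann term on interior nodes;
    ``nonlinear`` carries per-species data for the full Boltzmann source.
    Returns (phi, iterations, final max |dphi|).
    """
    grid = maps.grid
    h = grid.spacing
    kt = kT_kcal(config.temperature)
    c = KCOUL / kt

    exm, exp_, eym, eyp, ezm, ezp = _interior_faces(maps)
    diag = exm + exp_ + eym + eyp + ezm + ezp
    if lin_screen is not None:
        diag = diag + lin_screen
    inv_diag = 1.0 / diag

    src = (FOUR_PI * c / h) * charge_field.values[1:-1, 1:-1, 1:-1]
    if lin_source is not None:
        src = src + lin_source

    if phi0 is None:
        phi = np.zeros(grid.shape, dtype=float)
    else:
        phi = phi0.copy()
    if config.boundary == "debye_huckel":
        bvals = _boundary_values(grid, charge_field, maps.bulk_eps, bc_kappa, config.temperature)
    else:
        bvals = np.zeros(grid.shape)
    for axis in range(3):
        for side in (0, -1):
            sl = [slice(None)] * 3
            sl[axis] = side
            phi[tuple(sl)] = bvals[tuple(sl)]

    red = _checkerboard(tuple(s - 2 for s in grid.shape))
    black = ~red
    omega = config.relaxation

    ion_src = None
    if nonlinear is not None:
        ion_src = np.zeros_like(src)

    interior = (slice(1, -1),) * 3
    grow_count = 0
    last_change = np.inf
    for sweep in range(1, config.max_iterations + 1):
        if nonlinear is not None:
            phi_int = np.clip(phi[interior], -50.0, 50.0)
            target = np.zeros_like(src)
            for z, cb, lam in nonlinear["species"]:
                target += FOUR_PI * c * h * h * z * cb * lam * np.exp(-z * phi_int)
            ion_src = (
                config.nonlinear_damping * target
                + (1.0 - config.nonlinear_damping) * ion_src
            )
        max_change = 0.0
        view = phi[interior]
        for color in (red, black):
            num = _neighbor_sum(phi, exm, exp_, eym, eyp, ezm, ezp) + src
            if ion_src is not None:
                num += ion_src
            step = omega * (num * inv_diag - view)
            masked = step[color]
            if masked.size:
                max_change = max(max_change, float(np.abs(masked).max()))
                view[color] += masked
        if max_change <= config.tolerance:
            return phi, sweep, max_change
        grow_count = grow_count + 1 if max_change > last_change else 0
        last_change = max_change
        if grow_count >= 50 or not np.isfinite(max_change):
            raise ConvergenceError(
                f"solver diverging (residual {max_change:.3g} after {sweep} sweeps); "
                "try a smaller relaxation factor",
                residual=max_change,
            )
    raise ConvergenceError(
        f"no convergence within {config.max_iterations} sweeps "
        f"(final max |dphi| = {last_change:.3g} kT/e)",
        residual=last_change,
    )


def solve_poisson(
    eps, charge_field: ScalarField, config: SolverConfig | None = None
) -> ScalarField:
    """Solve the salt-free Poisson equation; returns the potential in kT/e.

    ``eps`` is a :class:`DielectricMaps` (face-midpoint dielectrics) or a
    scalar for a uniform medium.
    """
    config = config or SolverConfig()
    maps = _as_maps(eps, charge_field.grid)
    _check_eps_positive(maps)
    phi, iters, resid = _sor(maps, charge_field, config)
    return ScalarField(
        grid=charge_field.grid, values=phi, role="potential", units="kT/e",
        metadata={"iterations": iters, "final_residual": resid, "mode": "poisson"},
    )


def _check_eps_positive(maps: DielectricMaps) -> None:
    if min(maps.face_x.min(), maps.face_y.min(), maps.face_z.min()) <= 0:
        raise ValueError("dielectric must be positive at all face midpoints")


def solve_pbe(
    eps,
    charge_field: ScalarField,
    ions: list[IonSpecies],
    penalty_fields: dict[str, ScalarField] | list[ScalarField] | None = None,
    config: SolverConfig | None = None,
) -> ScalarField:
    """Solve the Poisson-Boltzmann equation with Born-penalty-weighted ions.

    Each species' local accessibility is ``lambda_i(r) = exp(-dG_i(r)/RT)``
    from its penalty map; mode='linear' solves the Debye-Hückel
    linearization with position-dependent screening, mode='nonlinear'
    iterates the full Boltzmann source (lagged, damped).  With no ions
    (or all zero concentrations) this reduces exactly to Poisson.
    """
    config = config or SolverConfig()
    maps = _as_maps(eps, charge_field.grid)
    _check_eps_positive(maps)
    ions = [i for i in (ions or []) if i.bulk_concentration > 0]
    if not ions:
        return solve_poisson(maps, charge_field, config)
    check_charge_balance(ions)

    if penalty_fields is None:
        penalties = [penalty_field(maps.node, ion, eps_out=maps.bulk_eps) for ion in ions]
    elif isinstance(penalty_fields, dict):
        penalties = [penalty_fields[ion.label] for ion in ions]
    else:
        penalties = list(penalty_fields)
    if len(penalties) != len(ions):
        raise ValueError("need one penalty field per ion species")
    for p in penalties:
        if p.grid.shape != charge_field.grid.shape or not np.allclose(
            p.grid.origin, charge_field.grid.origin
        ):
            raise ValueError("penalty field grid does not match the charge grid")

    kt = kT_kcal(config.temperature)
    c = KCOUL / kt
    h = charge_field.grid.spacing
    interior = (slice(1, -1),) * 3

    species = []
    for ion, pen in zip(ions, penalties):
        lam = np.exp(-np.minimum(pen.values[interior] / kt, 700.0))
        species.append((ion.valence, ion.bulk_concentration * MOLAR_TO_PER_A3, lam))

    kappa = debye_kappa(ions, maps.bulk_eps, config.temperature)
    if config.mode == "linear":
        screen = np.zeros(tuple(s - 2 for s in charge_field.grid.shape))
        const = np.zeros_like(screen)
        for z, cb, lam in species:
            screen += FOUR_PI * c * h * h * z * z * cb * lam
            const += FOUR_PI * c * h * h * z * cb * lam
        phi, iters, resid = _sor(
            maps, charge_field, config,
            lin_screen=screen, lin_source=const, bc_kappa=kappa,
        )
    else:
        nl = {"species": species}
        phi, iters, resid = _sor(maps, charge_field, config, nonlinear=nl, bc_kappa=kappa)
    return ScalarField(
        grid=charge_field.grid, values=phi, role="potential", units="kT/e",
        metadata={
            "iterations": iters, "final_residual": resid,
            "mode": f"pbe-{config.mode}", "kappa": kappa,
        },
    )


def discrete_residual(
    maps: DielectricMaps, phi: ScalarField, charge_field: ScalarField, config: SolverConfig
) -> np.ndarray:
    """Flux-balance residual at interior nodes (Poisson operator).

    At convergence, the summed face fluxes around each node balance the
    node's charge source: residual -> 0.
    """
    kt = kT_kcal(config.temperature)
    c = KCOUL / kt
    h = phi.grid.spacing
    exm, exp_, eym, eyp, ezm, ezp = _interior_faces(maps)
    diag = exm + exp_ + eym + eyp + ezm + ezp
    interior = (slice(1, -1),) * 3
    flux = _neighbor_sum(phi.values, exm, exp_, eym, eyp, ezm, ezp) - diag * phi.values[interior]
    return flux + (FOUR_PI * c / h) * charge_field.values[interior]


def reaction_field_energy(
    structure: Structure,
    config: SolverConfig,
    eps_solvated: DielectricMaps,
    ions: list[IonSpecies] | None = None,
) -> float:
    """Polar solvation (reaction-field) energy in kcal/mol.

    Two solves on the same grid and charges: the solvated dielectric map,
    and a uniform ``eps_in`` reference with no salt.  The energy is half
    the charge-weighted potential difference at the atom centres
    (trilinear interpolation); the grid self-energy cancels.
    """
    structure.require_nonempty("reaction_field_energy")
    grid = eps_solvated.grid
    charge = charge_spread(structure, grid)
    phi_solv = solve_pbe(eps_solvated, charge, ions or [], config=config)
    eps_in = float(eps_solvated.node.metadata.get("eps_in", eps_solvated.params.eps_in))
    phi_ref = solve_poisson(DielectricMaps.uniform(eps_in, grid), charge, config)
    kt = kT_kcal(config.temperature)
    dphi = phi_solv.interpolate(structure.positions) - phi_ref.interpolate(structure.positions)
    return float(0.5 * np.sum(structure.charges * dphi) * kt)


def binding_polar_energy(
    complex_structure: Structure,
    monomer_a: Structure,
    monomer_b: Structure,
    config: SolverConfig,
    ions: list[IonSpecies] | None = None,
    sharp: bool = False,
    probe_radius: float = 0.0,
) -> float:
    """Polar solvation component of binding: ``dG(AB) - dG(A) - dG(B)``.

    All three reaction-field energies are computed on one common grid
    sized for the complex, so the difference is free of regridding
    artifacts.  The complex atom set must equal the union of the
    monomers' (validated by count and atom labels).
    """
    if len(monomer_a) == 0 or len(monomer_b) == 0:
        return 0.0
    _validate_partition(complex_structure, monomer_a, monomer_b)
    lo = np.minimum.reduce([s.bounds()[0] for s in (complex_structure, monomer_a, monomer_b)])
    hi = np.maximum.reduce([s.bounds()[1] for s in (complex_structure, monomer_a, monomer_b)])
    grid = GridSpec.from_bounds(lo, hi, config.spacing, config.margin_fraction, config.min_margin)

    if sharp:
        from .gaussian_dielectric import traditional_dielectric_maps

        builder = lambda s: traditional_dielectric_maps(s, grid, config.params, probe_radius)
    else:
        builder = lambda s: dielectric_maps(s, grid, config.params)

    energies = [
        reaction_field_energy(s, config, builder(s), ions=ions)
        for s in (complex_structure, monomer_a, monomer_b)
    ]
    return energies[0] - energies[1] - energies[2]


def _validate_partition(complex_structure: Structure, a: Structure, b: Structure) -> None:
    if len(complex_structure) != len(a) + len(b):
        raise ValueError(
            f"complex has {len(complex_structure)} atoms but monomers have "
            f"{len(a)} + {len(b)}"
        )
    key = lambda atom: (atom.chain, atom.residue, atom.residue_number, atom.name)
    if sorted(map(key, complex_structure.atoms)) != sorted(
        map(key, list(a.atoms) + list(b.atoms))
    ):
        raise ValueError("complex atom labels do not match the union of the monomers")
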