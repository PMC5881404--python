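"""Deterministic toy-system generators.

Every module is testable without downloads: a single ion for Born-model
oracles, a diatomic pair for interface scans, two compact random blobs
standing in for binding partners, and an atom slab standing in for a
lipid membrane.  Random placements use numpy's PCG64 generator with an
explicit seed; the same spec and seed always reproduce the same
structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure_io import Atom, Structure

__all__ = ["FixtureSpec", "make_fixture", "single_ion", "diatomic", "pair_of_blobs", "slab"]


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative description of a toy system.

    kind: one of single_ion, diatomic, pair_of_blobs, slab.  The
    geometry dict carries kind-specific parameters (radii Å, charges e,
    counts, thickness Å); seed drives any random placement.
    """

    kind: str
    geometry: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in {"single_ion", "diatomic", "pair_of_blobs", "slab"}:
            raise ValueError(f"unknown fixture kind {self.kind!r}")


def single_ion(radius: float = 2.0, charge: float = 1.0, center=(0.0, 0.0, 0.0)) -> Structure:
    """One spherical ion (default +1e, R = 2 Å) — the Born-model toy."""
    atom = Atom(name="ION", position=tuple(center), radius=radius, charge=charge, residue="ION")
    return Structure(atoms=[atom], label="single_ion")


def diatomic(
    distance: float = 4.0,
    radius: float = 2.0,
    charges: tuple[float, float] = (0.0, 0.0),
) -> tuple[Structure, Structure]:
    """Two single-atom partners a given center-center distance apart on x."""
    if distance < 0 or radius <= 0:
        raise ValueError("distance must be >= 0 and radius > 0")
    a = Structure(
        atoms=[Atom(name="A", position=(0.0, 0.0, 0.0), radius=radius, charge=charges[0], residue="TOY")],
        label="partnerA",
    )
    b = Structure(
        atoms=[Atom(name="B", position=(distance, 0.0, 0.0), radius=radius, charge=charges[1], residue="TOY")],
        label="partnerB",
    )
    return a, b


def pair_of_blobs(
    n_atoms: int = 40,
    blob_radius: float = 8.0,
    atom_radius: float = 1.8,
    gap: float = 2.0,
    charge_scale: float = 0.0,
    seed: int = 0,
) -> tuple[Structure, Structure]:
    """Two compact random atom clusters mimicking binding partners.

    Atoms are placed uniformly inside two spheres of ``blob_radius``
    whose surfaces are ``gap`` Å apart along x.  ``charge_scale`` draws
    per-atom charges uniformly from ±charge_scale, then removes the mean
    so each blob is net-neutral.
    """
    if n_atoms < 1 or blob_radius <= 0 or atom_radius <= 0:
        raise ValueError("nonphysical blob parameters")
    rng = np.random.default_rng(seed)
    centers = [
        np.array([0.0, 0.0, 0.0]),
        np.array([2 * blob_radius + gap, 0.0, 0.0]),
    ]
    blobs = []
    for which, center in enumerate(centers):
        # uniform-in-sphere via rejection from the bounding cube
        pts = []
        while len(pts) < n_atoms:
            cand = rng.uniform(-blob_radius, blob_radius, size=(4 * n_atoms, 3))
            keep = cand[np.sum(cand**2, axis=1) <= blob_radius**2]
            pts.extend(keep.tolist())
        pts = np.array(pts[:n_atoms]) + center
        if charge_scale > 0:
            q = rng.uniform(-charge_scale, charge_scale, size=n_atoms)
            q -= q.mean()
        else:
            q = np.zeros(n_atoms)
        atoms = [
            Atom(
                name=f"C{i + 1}", position=tuple(p), radius=atom_radius,
                charge=float(qi), residue="BLB", chain="AB"[which], residue_number=i + 1,
            )
            for i, (p, qi) in enumerate(zip(pts, q))
        ]
        blobs.append(Structure(atoms=atoms, label=f"blob{'AB'[which]}"))
    return blobs[0], blobs[1]


def slab(
    thickness: float = 38.0,
    lateral: float = 30.0,
    lattice: float = 2.5,
    atom_radius: float = 1.8,
) -> Structure:
    """Atoms filling a z-slab spanning the box laterally — a membrane
    stand-in with the typical 38 Å thickness of a POPC bilayer."""
    if thickness <= 0 or lateral <= 0 or lattice <= 0 or atom_radius <= 0:
        raise ValueError("nonphysical slab parameters")
    xs = np.arange(-lateral / 2, lateral / 2 + 1e-9, lattice)
    zs = np.arange(-thickness / 2, thickness / 2 + 1e-9, lattice)
    zs = zs[np.abs(zs) <= thickness / 2 + 1e-9]
    atoms = []
    n = 0
    for z in zs:
        for x in xs:
            for y in xs:
                n += 1
                atoms.append(
                    Atom(
                        name=f"C{n}", position=(float(x), float(y), float(z)),
                        radius=atom_radius, charge=0.0, residue="MEM", residue_number=n,
                    )
                )
    return Structure(atoms=atoms, label="slab")


def make_fixture(spec: FixtureSpec):
    """Build the structure(s) described by a :class:`FixtureSpec`."""
    g = dict(spec.geometry)
    if spec.kind == "single_ion":
        return single_ion(**g)
    if spec.kind == "diatomic":
        return diatomic(**g)
    if spec.kind == "pair_of_blobs":
        return pair_of_blobs(seed=spec.seed, **g)
    return slab(**g)
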