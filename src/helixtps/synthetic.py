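"""Synthetic nucleic-acid crystal models and calculated structure factors.

This module generates the idealized crystals used to study translational
pseudosymmetry (TPS) caused by helical repeats:

* a three-turn A-form RNA duplex stacked along ``c`` in an R32:H-like cell
  (a = b = 42.89, c = 266.94 Angstrom), whose ~29.7 Angstrom helical turn
  produces a 9-fold pseudo-repeat along ``c``;
* a one-turn "hairpin-like" control duplex in a tetragonal cell with no TPS;
* a random-atom control obeying Wilson statistics.

Imperfection of the pseudosymmetry is tunable along the two classical axes:
"displacive" (coordinate jitter between the pseudo-related copies) and
"replacive" (compositional differences between them).

Structure factors are computed by direct summation over symmetry-expanded
atoms with a simplified constant-scattering-weight model (electrons per
element; resolution falloff carried entirely by the isotropic B factor).
After normalization to E values, the TPS/Wilson diagnostics downstream are
insensitive to this simplification.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gemmi
import numpy as np

# --------------------------------------------------------------------------
# constants and scattering model
# --------------------------------------------------------------------------

#: electrons per element for the constant-weight scattering model
ELECTRON_COUNTS = {"P": 15.0, "O": 8.0, "N": 7.0, "C": 6.0}

#: electrons carried by the three base-ring pseudo-atoms (total per base,
#: excluding the explicitly placed glycosidic nitrogen)
BASE_RING_ELECTRONS = {"A": 58.0, "G": 66.0, "C": 46.0, "U": 47.0}

#: space groups the generator knows how to populate
SUPPORTED_SPACE_GROUPS = ("P1", "R32:H", "P43")

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

#: default duplex sequence: 16 purines (10 A + 6 G) followed by 16 U, so the
#: two dyad-related strands pair as 10 A-U Watson-Crick plus 6 G-U wobble pairs
DEFAULT_DUPLEX_SEQUENCE = "AAGAGAAGAGAAGAGA" + "U" * 16

# Reduced per-residue template in helix-local cylindrical coordinates:
# (name, element, radius Angstrom, phase degrees, z offset Angstrom).
# One phosphate-to-phosphate repeat of an idealized A-form backbone plus the
# glycosidic nitrogen and three ring pseudo-atoms marching toward the axis.
_RESIDUE_TEMPLATE = [
    ("P", "P", 9.0, 0.0, 0.00),
    ("O5'", "O", 8.6, 6.0, -0.60),
    ("C5'", "C", 8.5, 12.0, -1.20),
    ("C4'", "C", 8.3, 18.0, -1.10),
    ("C3'", "C", 8.9, 24.0, -0.50),
    ("O3'", "O", 9.0, 28.0, -0.10),
    ("C1'", "C", 7.3, 22.0, -1.50),
    ("N", "N", 5.9, 25.0, -1.60),
]
_RING_TEMPLATE = [
    ("R1", 4.4, 27.0, -1.65),
    ("R2", 3.0, 30.0, -1.70),
    ("R3", 1.6, 33.0, -1.75),
]

DEFAULT_B_ISO = 10.0  # Angstrom^2, matches the low-B atomic-resolution regime


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class UnitCell:
    """Crystallographic unit cell (lengths in Angstrom, angles in degrees)."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"cell length {name} must be positive")
        for name in ("alpha", "beta", "gamma"):
            v = getattr(self, name)
            if not 0.0 < v < 180.0:
                raise ValueError(f"cell angle {name} must lie in (0, 180)")
        if self.gemmi().volume <= 0:
            raise ValueError("cell metric is not positive definite")

    def gemmi(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(self.a, self.b, self.c, self.alpha, self.beta, self.gamma)

    @property
    def volume(self) -> float:
        return self.gemmi().volume

    @property
    def orth_matrix(self) -> np.ndarray:
        """Fractional -> cartesian matrix, ``a`` along x (right-handed)."""
        return np.array(self.gemmi().orth.mat.tolist(), dtype=float)

    @property
    def frac_matrix(self) -> np.ndarray:
        return np.array(self.gemmi().frac.mat.tolist(), dtype=float)

    def orthogonalize(self, frac: np.ndarray) -> np.ndarray:
        return np.asarray(frac, dtype=float) @ self.orth_matrix.T

    def fractionalize(self, cart: np.ndarray) -> np.ndarray:
        return np.asarray(cart, dtype=float) @ self.frac_matrix.T

    def reciprocal_metric(self) -> np.ndarray:
        g = self.orth_matrix.T @ self.orth_matrix
        return np.linalg.inv(g)

    def d_spacings(self, hkl: np.ndarray) -> np.ndarray:
        """d in Angstrom for an (N, 3) integer index array (triclinic metric)."""
        hkl = np.atleast_2d(np.asarray(hkl, dtype=float))
        s2 = np.einsum("ni,ij,nj->n", hkl, self.reciprocal_metric(), hkl)
        with np.errstate(divide="ignore"):
            return 1.0 / np.sqrt(s2)


class SpaceGroupOps:
    """Closed operator set of a supported space group (incl. centering)."""

    def __init__(self, identifier: str):
        if identifier not in SUPPORTED_SPACE_GROUPS:
            raise ValueError(
                f"space group {identifier!r} is not supported; "
                f"supported groups: {', '.join(SUPPORTED_SPACE_GROUPS)}"
            )
        self.identifier = identifier
        self._sg = gemmi.SpaceGroup(identifier)
        self._gops = self._sg.operations()
        den = gemmi.Op.DEN
        ops = list(self._gops)
        self.rotations = np.array([op.rot for op in ops], dtype=np.int64) // den
        self.translations = np.array([op.tran for op in ops], dtype=float) / den

    @property
    def n_ops(self) -> int:
        return len(self.rotations)

    def gemmi_ops(self) -> gemmi.GroupOps:
        return self._gops

    def gemmi_sg(self) -> gemmi.SpaceGroup:
        return self._sg

    # ---- reflection classification, vectorized over an (N, 3) index array

    def _images(self, hkl: np.ndarray) -> np.ndarray:
        """Reciprocal-space images h' = h R for every operator: (n_ops, N, 3)."""
        return np.einsum("nj,oji->oni", hkl, self.rotations)

    def systematically_absent(self, hkl: np.ndarray) -> np.ndarray:
        hkl = np.atleast_2d(np.asarray(hkl, dtype=np.int64))
        images = self._images(hkl)
        same = np.all(images == hkl[None, :, :], axis=2)
        phase = np.einsum("nj,oj->on", hkl, self.translations)
        noninteger = np.abs(phase - np.round(phase)) > 1e-9
        return np.any(same & noninteger, axis=0)

    def centric(self, hkl: np.ndarray) -> np.ndarray:
        hkl = np.atleast_2d(np.asarray(hkl, dtype=np.int64))
        images = self._images(hkl)
        return np.any(np.all(images == -hkl[None, :, :], axis=2), axis=0)

    def epsilon(self, hkl: np.ndarray) -> np.ndarray:
        hkl = np.atleast_2d(np.asarray(hkl, dtype=np.int64))
        images = self._images(hkl)
        return np.sum(np.all(images == hkl[None, :, :], axis=2), axis=0)

    def canonical(self, hkl: np.ndarray) -> np.ndarray:
        """Lexicographically-largest symmetry+Friedel image of each index."""
        hkl = np.atleast_2d(np.asarray(hkl, dtype=np.int64))
        images = self._images(hkl)
        images = np.concatenate([images, -images], axis=0)  # Friedel
        span = int(np.abs(images).max()) + 1
        keys = (images[..., 0] * (2 * span) + images[..., 1]) * (2 * span) + images[..., 2]
        best = np.argmax(keys, axis=0)
        return images[best, np.arange(hkl.shape[0]), :]


@dataclass
class Atom:
    """One scatterer: element, fractional position, occupancy, isotropic B.

    ``weight`` overrides the element electron count (used by the base-ring
    pseudo-atoms whose weight depends on the base identity).
    """

    element: str
    position: np.ndarray
    occupancy: float = 1.0
    b_iso: float = DEFAULT_B_ISO
    name: str = ""
    strand: int = 0
    residue: int = 0
    bp_index: int = 0
    turn: int = -1
    base: str = ""
    weight: float | None = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.weight is None and self.element not in ELECTRON_COUNTS:
            raise ValueError(f"no scattering weight defined for element {self.element!r}")
        if not 0.0 < self.occupancy <= 1.0:
            raise ValueError("occupancy must be in (0, 1]")
        if self.b_iso < 0:
            raise ValueError("b_iso must be non-negative")

    @property
    def scattering_weight(self) -> float:
        return self.weight if self.weight is not None else ELECTRON_COUNTS[self.element]


@dataclass
class CrystalModel:
    """Unit cell + symmetry + asymmetric-unit atom list.

    ``cartesian`` marks a free-standing fragment whose positions are cartesian
    Angstrom (before :func:`place_in_cell`); crystal models store fractional
    coordinates reduced to [0, 1).
    """

    cell: UnitCell | None
    symmetry: SpaceGroupOps | None
    atoms: list[Atom]
    cartesian: bool = False

    def positions(self) -> np.ndarray:
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.position for a in self.atoms])

    def weights(self) -> np.ndarray:
        return np.array([a.scattering_weight * a.occupancy for a in self.atoms])

    def b_factors(self) -> np.ndarray:
        return np.array([a.b_iso for a in self.atoms])

    def turns(self) -> np.ndarray:
        return np.array([a.turn for a in self.atoms])

    def copy(self) -> "CrystalModel":
        return CrystalModel(
            cell=self.cell,
            symmetry=self.symmetry,
            atoms=[dataclasses.replace(a, position=a.position.copy()) for a in self.atoms],
            cartesian=self.cartesian,
        )

    def subset(self, mask: np.ndarray) -> "CrystalModel":
        atoms = [a for a, keep in zip(self.atoms, mask) if keep]
        return CrystalModel(self.cell, self.symmetry, atoms, self.cartesian)


@dataclass(frozen=True)
class HelixSpec:
    """Geometry of an idealized A-form duplex.

    ``rise`` defaults to one ninth of c/3 of the reference cell spread over
    11 base pairs (c = 266.94, turn length 29.66 Angstrom), matching the
    9-fold pseudo-repeat geometry; the true fiber rise is a free parameter.
    """

    n_bp: int = 32
    rise: float = 266.94 / 9.0 / 11.0
    twist: float = 360.0 / 11.0
    sequence: str | None = None
    b_iso: float = DEFAULT_B_ISO

    def __post_init__(self) -> None:
        if self.n_bp < 1:
            raise ValueError("n_bp must be >= 1")
        if self.rise <= 0:
            raise ValueError("rise must be positive")
        if not 0.0 < self.twist < 360.0:
            raise ValueError("twist must lie in (0, 360)")

    @property
    def bp_per_turn(self) -> int:
        return int(round(360.0 / self.twist))

    def resolved_sequence(self) -> str:
        seq = self.sequence
        if seq is None:
            seq = (DEFAULT_DUPLEX_SEQUENCE * (1 + self.n_bp // 32))[: self.n_bp]
        if len(seq) != self.n_bp:
            raise ValueError(f"sequence length {len(seq)} != n_bp {self.n_bp}")
        for i, ch in enumerate(seq):
            if ch not in _COMPLEMENT:
                raise ValueError(f"unknown base {ch!r} at sequence position {i}")
        return seq


# --------------------------------------------------------------------------
# model builders
# --------------------------------------------------------------------------


def _residue_atoms(base: str, b_iso: float) -> list[tuple[str, str, float, float, float, float | None]]:
    ring_w = BASE_RING_ELECTRONS[base] / 3.0
    out = [(name, el, r, phi, z, None) for name, el, r, phi, z in _RESIDUE_TEMPLATE]
    out += [(name, "C", r, phi, z) + (ring_w,) for name, r, phi, z in _RING_TEMPLATE]
    return out


def build_aform_duplex(spec: HelixSpec) -> CrystalModel:
    """Build an idealized A-form duplex as a cartesian fragment.

    The helix axis runs along z; base pair ``j`` sits at height ``j * rise``
    rotated by ``j * twist``; the duplex is centered so its pseudo-dyad lies
    on the cartesian x axis at z = 0.  Strand 2 is the exact dyad image of
    strand 1 (the duplex is built from two copies of the same strand, as in a
    head-to-head self-paired construct), so a crystallographic two-fold along
    x can later regenerate it from the one-strand asymmetric unit.

    Atoms carry strand, residue, spatial base-pair index and turn annotations
    (turn = floor(bp_index / bp_per_turn)).
    """
    seq = spec.resolved_sequence()
    n = spec.n_bp
    bp_per_turn = spec.bp_per_turn
    z_center = (n - 1) * spec.rise / 2.0
    atoms: list[Atom] = []
    for j in range(n):
        base = seq[j]
        theta0 = math.radians(j * spec.twist)
        z0 = j * spec.rise - z_center
        for name, el, r, phi, dz, w in _residue_atoms(base, spec.b_iso):
            th = theta0 + math.radians(phi)
            pos = np.array([r * math.cos(th), r * math.sin(th), z0 + dz])
            atoms.append(
                Atom(el, pos, 1.0, spec.b_iso, name=name, strand=0, residue=j,
                     bp_index=j, turn=j // bp_per_turn, base=base, weight=w)
            )
    # strand 2: dyad about the x axis; residue j lands at base-pair n-1-j
    strand1 = list(atoms)
    for a in strand1:
        pos = a.position * np.array([1.0, -1.0, -1.0])
        bp = n - 1 - a.residue
        atoms.append(
            dataclasses.replace(a, position=pos, strand=1,
                                bp_index=bp, turn=bp // bp_per_turn)
        )
    return CrystalModel(cell=None, symmetry=None, atoms=atoms, cartesian=True)


def place_in_cell(
    fragment: CrystalModel,
    cell: UnitCell,
    symmetry: SpaceGroupOps | str,
    origin_offset: Sequence[float] = (0.0, 0.0, 0.0),
    asu_strand: int | None = None,
) -> CrystalModel:
    """Fractionalize a cartesian fragment into a unit cell.

    ``origin_offset`` is added in fractional coordinates after
    fractionalization; when ``asu_strand`` is given only that strand is kept
    as the asymmetric unit (used when a crystallographic dyad regenerates the
    mate).  Positions are reduced to [0, 1).
    """
    if not fragment.cartesian:
        raise ValueError("fragment must carry cartesian coordinates")
    if isinstance(symmetry, str):
        symmetry = SpaceGroupOps(symmetry)
    offset = np.asarray(origin_offset, dtype=float)
    atoms = []
    for a in fragment.atoms:
        if asu_strand is not None and a.strand != asu_strand:
            continue
        frac = cell.fractionalize(a.position) + offset
        atoms.append(dataclasses.replace(a, position=frac % 1.0))
    model = CrystalModel(cell=cell, symmetry=symmetry, atoms=atoms, cartesian=False)
    # sanity: fragment must fit inside the cell after fractionalization
    span = np.ptp(fragment.positions(), axis=0) if fragment.atoms else np.zeros(3)
    lengths = np.array([cell.a, cell.b, cell.c])
    if np.any(span > lengths):
        raise ValueError("fragment does not fit in the unit cell")
    return model


def perturb_turns(
    model: CrystalModel,
    displacive_sigma: float,
    replacive_fraction: float,
    seed: int,
) -> CrystalModel:
    """Degrade the helical pseudosymmetry of an annotated model.

    Displacive imperfection: each turn receives an independent rigid
    translation jitter and each atom an independent isotropic Gaussian
    displacement, both with total expected displacement ``displacive_sigma``
    (component std sigma/sqrt(3)).  Replacive imperfection: the given
    fraction of base pairs is re-typed to a different base (ring pseudo-atom
    weights change; backbone positions are kept).  Deterministic for a fixed
    seed.
    """
    if displacive_sigma < 0:
        raise ValueError("displacive_sigma must be >= 0")
    if not 0.0 <= replacive_fraction <= 1.0:
        raise ValueError("replacive_fraction must lie in [0, 1]")
    turns = model.turns()
    if model.atoms and (turns < 0).any():
        raise ValueError("model lacks turn annotations; run the duplex builder first")
    out = model.copy()
    if displacive_sigma == 0.0 and replacive_fraction == 0.0:
        return out
    rng = np.random.default_rng(seed)
    comp_sigma = displacive_sigma / math.sqrt(3.0)

    frac_mode = not model.cartesian and model.cell is not None
    if displacive_sigma > 0:
        # per (strand, turn) rigid jitter: the pseudo-related copies drift apart
        keys = sorted({(a.strand, a.turn) for a in out.atoms})
        rigid = {k: rng.normal(0.0, comp_sigma, 3) for k in keys}
        for a in out.atoms:
            delta = rigid[(a.strand, a.turn)] + rng.normal(0.0, comp_sigma, 3)
            if frac_mode:
                frac = a.position + out.cell.fractionalize(delta)
                a.position = frac % 1.0
            else:
                a.position = a.position + delta
    if replacive_fraction > 0:
        bps = sorted({a.bp_index for a in out.atoms})
        n_flip = int(round(replacive_fraction * len(bps)))
        flip = set(rng.choice(bps, size=n_flip, replace=False).tolist())
        new_base: dict[int, str] = {}
        for bp in flip:
            olds = {a.base for a in out.atoms if a.bp_index == bp}
            old = next(iter(olds))
            choices = [b for b in "ACGU" if b != old]
            new_base[bp] = choices[rng.integers(len(choices))]
        for a in out.atoms:
            if a.bp_index in flip:
                nb = new_base[a.bp_index]
                a.base = nb
                if a.name.startswith("R"):
                    a.weight = BASE_RING_ELECTRONS[nb] / 3.0
    return out


def random_atom_structure(
    n_atoms: int,
    cell: UnitCell,
    seed: int,
    b_iso: float = 0.0,
    element: str = "C",
) -> CrystalModel:
    """Equal-weight atoms uniform in a P1 cell — the Wilson-statistics control."""
    if n_atoms < 2:
        raise ValueError("n_atoms must be >= 2")
    rng = np.random.default_rng(seed)
    pos = rng.random((n_atoms, 3))
    atoms = [Atom(element, p, 1.0, b_iso, name=element) for p in pos]
    return CrystalModel(cell=cell, symmetry=SpaceGroupOps("P1"), atoms=atoms)


# --------------------------------------------------------------------------
# structure factors
# --------------------------------------------------------------------------


def unique_reflections(cell: UnitCell, symmetry: SpaceGroupOps, d_min: float) -> np.ndarray:
    """Unique non-absent Miller indices to d_min under Friedel + point group."""
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    gstar = cell.reciprocal_metric()
    rec_len = np.sqrt(np.diag(gstar))
    limits = np.floor(1.0 / (d_min * rec_len)).astype(int) + 1
    axes = [np.arange(-m, m + 1, dtype=np.int64) for m in limits]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    s2 = np.einsum("ni,ij,nj->n", grid.astype(float), gstar, grid.astype(float))
    keep = (s2 <= 1.0 / d_min**2 + 1e-12) & (s2 > 0)
    grid = grid[keep]
    # canonical representative under symmetry + Friedel, chunked for memory
    reps = []
    for start in range(0, grid.shape[0], 200_000):
        reps.append(symmetry.canonical(grid[start:start + 200_000]))
    reps = np.concatenate(reps, axis=0)
    uniq = np.unique(reps, axis=0)
    absent = symmetry.systematically_absent(uniq)
    uniq = uniq[~absent]
    # sort by resolution then index, stable across runs
    d = cell.d_spacings(uniq)
    order = np.lexsort((uniq[:, 2], uniq[:, 1], uniq[:, 0], -d))
    return uniq[order]


def _expand_atoms(model: CrystalModel) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Symmetry-expand the asymmetric unit: positions, weights, B factors."""
    pos = model.positions()
    w = model.weights()
    b = model.b_factors()
    sym = model.symmetry
    all_pos = np.concatenate(
        [(pos @ rot.T + tran) % 1.0 for rot, tran in zip(sym.rotations, sym.translations)]
    )
    n = sym.n_ops
    return all_pos, np.tile(w, n), np.tile(b, n)


def calc_structure_factors(
    model: CrystalModel,
    d_min: float,
    sigma_fraction: float = 0.02,
    n_sigma_shells: int = 10,
) -> "ReflectionSet":
    """Direct-summation structure factors of a crystal model to d_min.

    F(h) = sum_j w_j * occ_j * exp(-B_j s^2 / 4) * exp(2 pi i h.x_j) over
    symmetry-expanded atoms; returns the unique reflection set with
    amplitudes, phases and a synthetic sigma model
    sigma(F) = sigma_fraction * F + shell-median floor.
    """
    from .reflections import ReflectionSet  # local import to avoid a cycle

    if not model.atoms:
        raise ValueError("cannot compute structure factors of an empty model")
    if model.cartesian or model.cell is None or model.symmetry is None:
        raise ValueError("model must be placed in a cell with symmetry first")
    hkl = unique_reflections(model.cell, model.symmetry, d_min)
    pos, w, b = _expand_atoms(model)
    gstar = model.cell.reciprocal_metric()
    s2 = np.einsum("ni,ij,nj->n", hkl.astype(float), gstar, hkl.astype(float))
    F = np.empty(hkl.shape[0], dtype=complex)
    chunk = max(1, 4_000_000 // max(1, pos.shape[0]))
    for start in range(0, hkl.shape[0], chunk):
        sl = slice(start, start + chunk)
        dot = hkl[sl].astype(float) @ pos.T
        phases = np.exp(2j * np.pi * dot)
        damp = np.exp(-np.outer(s2[sl] / 4.0, b)) * w[None, :]
        F[sl] = (phases * damp).sum(axis=1)
    amp = np.abs(F)
    phase = np.degrees(np.angle(F))
    # sigma model: fractional term plus a per-shell median floor
    d = model.cell.d_spacings(hkl)
    order = np.argsort(-d)
    shells = np.array_split(order, max(1, n_sigma_shells))
    floor = np.empty_like(amp)
    for sh in shells:
        floor[sh] = sigma_fraction * np.median(amp[sh])
    sigma = sigma_fraction * amp + floor
    return ReflectionSet(
        cell=model.cell, symmetry=model.symmetry, hkl=hkl,
        F=amp, sigma=sigma, phase=phase,
    )


# --------------------------------------------------------------------------
# reference presets
# --------------------------------------------------------------------------

DSRNA_CELL = UnitCell(42.89, 42.89, 266.94, 90.0, 90.0, 120.0)
HAIRPIN_CELL = UnitCell(36.0, 36.0, 60.0, 90.0, 90.0, 90.0)


def simulate_reference_pair(
    preset: str,
    displacive_sigma: float = 0.0,
    replacive_fraction: float = 0.0,
    seed: int = 0,
    d_min: float = 1.05,
) -> tuple[CrystalModel, "ReflectionSet"]:
    """Build a preset crystal and its calculated structure factors.

    ``"dsRNA-like"``: 32-bp three-turn duplex along c in the R32:H reference
    cell (one strand in the asymmetric unit; R centering plus the three-turn
    molecule give the 9-fold c pseudo-repeat).  ``"hairpin-like"``: one-turn
    11-bp duplex in a tetragonal P43 cell, axis along the a x b diagonal, no
    TPS.  Imperfection parameters feed :func:`perturb_turns`.
    """
    if preset in ("dsRNA-like", "dsrna"):
        spec = HelixSpec(n_bp=32)
        frag = build_aform_duplex(spec)
        model = place_in_cell(
            frag, DSRNA_CELL, "R32:H", origin_offset=(0.25, 0.0, 0.0), asu_strand=0
        )
    elif preset in ("hairpin-like", "hairpin"):
        spec = HelixSpec(n_bp=11)
        frag = build_aform_duplex(spec)
        # tilt the helix axis onto the a x b diagonal, as in the control
        axis = np.array([1.0, 1.0, 0.0]) / math.sqrt(2.0)
        rot = _rotation_from_z(axis)
        for a in frag.atoms:
            a.position = rot @ a.position
        # general-position placement: special xy positions such as (1/2, 1/2)
        # would let the 4_3 screw generate an artificial c/2 pseudo-repeat
        model = place_in_cell(frag, HAIRPIN_CELL, "P43", origin_offset=(0.30, 0.55, 0.25))
    else:
        raise ValueError(f"unknown preset {preset!r}; use 'dsRNA-like' or 'hairpin-like'")
    model = perturb_turns(model, displacive_sigma, replacive_fraction, seed)
    refl = calc_structure_factors(model, d_min=d_min)
    return model, refl


def _rotation_from_z(axis: np.ndarray) -> np.ndarray:
    """Rotation matrix taking the z axis onto ``axis`` (unit vector)."""
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, axis)
    c = float(np.dot(z, axis))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


# --------------------------------------------------------------------------
# coordinate I/O
# --------------------------------------------------------------------------


def to_gemmi_structure(model: CrystalModel, name: str = "synthetic") -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = name
    st.cell = model.cell.gemmi()
    st.spacegroup_hm = model.symmetry.gemmi_sg().xhm()
    mdl = gemmi.Model("1")
    strands = sorted({a.strand for a in model.atoms})
    for s in strands:
        chain = gemmi.Chain(chr(ord("A") + s))
        residues: dict[int, gemmi.Residue] = {}
        for a in model.atoms:
            if a.strand != s:
                continue
            res = residues.get(a.residue)
            if res is None:
                res = gemmi.Residue()
                res.name = a.base or "UNK"
                res.seqid = gemmi.SeqId(a.residue + 1, " ")
                residues[a.residue] = res
            at = gemmi.Atom()
            at.name = a.name or a.element
            at.element = gemmi.Element(a.element if a.element in ELECTRON_COUNTS else "C")
            cart = model.cell.orthogonalize(a.position)
            at.pos = gemmi.Position(*cart)
            at.occ = a.occupancy
            at.b_iso = a.b_iso
            res.add_atom(at)
        for idx in sorted(residues):
            chain.add_residue(residues[idx])
        mdl.add_chain(chain)
    st.add_model(mdl)
    st.setup_entities()
    return st


def write_model(model: CrystalModel, path: str) -> None:
    """Write PDB (``.pdb``) or mmCIF (anything else) coordinates."""
    st = to_gemmi_structure(model)
    if str(path).endswith(".pdb"):
        st.write_pdb(str(path))
    else:
        st.make_mmcif_document().write_file(str(path))


def read_model(path: str) -> CrystalModel:
    """Read a PDB/mmCIF coordinate file back into a CrystalModel.

    Turn annotations are not recoverable from a plain coordinate file; use
    :func:`helixtps.helix.partition_turns` to regenerate them.
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    gc = st.cell
    cell = UnitCell(gc.a, gc.b, gc.c, gc.alpha, gc.beta, gc.gamma)
    label = st.spacegroup_hm or "P1"
    sym = None
    for cand in SUPPORTED_SPACE_GROUPS:
        if gemmi.SpaceGroup(cand).xhm() == gemmi.SpaceGroup(label).xhm():
            sym = SpaceGroupOps(cand)
            break
    if sym is None:
        raise ValueError(
            f"space group {label!r} is not supported; "
            f"supported groups: {', '.join(SUPPORTED_SPACE_GROUPS)}"
        )
    atoms = []
    for si, chain in enumerate(st[0]):
        for res in chain:
            for at in res:
                el = at.element.name
                if el not in ELECTRON_COUNTS:
                    el, w = "C", None
                frac = cell.fractionalize(np.array([at.pos.x, at.pos.y, at.pos.z]))
                atoms.append(
                    Atom(el, frac % 1.0, min(max(at.occ, 1e-6), 1.0), max(at.b_iso, 0.0),
                         name=at.name, strand=si, residue=res.seqid.num - 1,
                         bp_index=res.seqid.num - 1, base=res.name if res.name in "ACGU" else "")
                )
    return CrystalModel(cell=cell, symmetry=sym, atoms=atoms)
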