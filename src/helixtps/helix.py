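"""Model-level TPS quantification: turn partitions and translation-only r.m.s.d.

The pseudo-translation relating helical turns is measured directly on the
coordinates: residues of two turns are paired by offset, the mapping is a
pure translation (difference of paired-atom centroids — no rotation, because
the diagnostic asks how well a translation alone superposes the turns), and
the r.m.s.d. after translation measures the imperfection of the TPS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import CrystalModel, UnitCell

#: atom-name subsets for superposition; "backbone" excludes the sugar ring
ATOM_SUBSETS: dict[str, tuple[str, ...] | None] = {
    "backbone": ("P", "OP1", "OP2", "O5'", "C5'", "C4'", "C3'", "O3'"),
    "P": ("P",),
    "all": None,
}


@dataclass
class TurnPartition:
    turns: list[range]     # base-pair index ranges, one per turn
    bp_per_turn: int

    def turn_of(self, bp_index: int) -> int:
        return bp_index // self.bp_per_turn


@dataclass
class SuperpositionResult:
    translation: np.ndarray  # cartesian Angstrom
    rmsd: float
    n_atoms: int
    atom_subset: str


def partition_turns(model: CrystalModel, bp_per_turn: int = 11) -> TurnPartition:
    """Partition annotated base pairs into consecutive turns.

    The final turn may be short (e.g. a 32-bp duplex at 11 bp/turn partitions
    as 11/11/10).  Turn annotations on the model atoms are updated in place.
    """
    if bp_per_turn < 1:
        raise ValueError("bp_per_turn must be >= 1")
    bps = sorted({a.bp_index for a in model.atoms})
    if not bps:
        raise ValueError("model has no base-pair annotations")
    n_bp = max(bps) + 1
    turns = [range(start, min(start + bp_per_turn, n_bp))
             for start in range(0, n_bp, bp_per_turn)]
    for a in model.atoms:
        a.turn = a.bp_index // bp_per_turn
    return TurnPartition(turns=turns, bp_per_turn=bp_per_turn)


def _cartesian_positions(model: CrystalModel) -> np.ndarray:
    pos = model.positions()
    if model.cartesian or model.cell is None:
        return pos
    # unwrap each fractional axis about its circular mean, so a connected
    # molecule wrapped across the cell boundary is reassembled before
    # orthogonalizing (valid while the molecule spans < half the cell)
    ang = 2.0 * np.pi * pos
    center = np.arctan2(np.sin(ang).mean(axis=0), np.cos(ang).mean(axis=0)) / (2.0 * np.pi)
    unwrapped = center + ((pos - center + 0.5) % 1.0 - 0.5)
    return model.cell.orthogonalize(unwrapped)


def translation_rmsd(model: CrystalModel, partition: TurnPartition,
                     turn_a: int, turn_b: int,
                     atom_subset: str = "backbone") -> SuperpositionResult:
    """Translation-only superposition of two turns.

    Residue j of ``turn_a`` is paired with residue j of ``turn_b`` (by offset
    within the turn, per strand); unpaired residues of a short turn are
    dropped.  The translation is the difference of paired centroids and the
    r.m.s.d. is evaluated after applying it (no rotation).
    """
    if atom_subset not in ATOM_SUBSETS:
        raise ValueError(f"atom_subset must be one of {sorted(ATOM_SUBSETS)}")
    names = ATOM_SUBSETS[atom_subset]
    if not (0 <= turn_a < len(partition.turns) and 0 <= turn_b < len(partition.turns)):
        raise ValueError("turn index out of range")
    range_a, range_b = partition.turns[turn_a], partition.turns[turn_b]
    cart = _cartesian_positions(model)
    # index atoms by (strand, offset-within-turn, atom name)
    def collect(rng: range) -> dict[tuple, int]:
        table = {}
        for i, a in enumerate(model.atoms):
            if a.bp_index in rng and (names is None or a.name in names):
                table[(a.strand, a.bp_index - rng.start, a.name)] = i
        return table

    ta, tb = collect(range_a), collect(range_b)
    keys = sorted(set(ta) & set(tb))
    if not keys:
        raise ValueError("no paired atoms between the requested turns")
    xa = cart[[ta[k] for k in keys]]
    xb = cart[[tb[k] for k in keys]]
    t = xb.mean(axis=0) - xa.mean(axis=0)
    diff = xb - (xa + t)
    rmsd = float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))
    return SuperpositionResult(translation=t, rmsd=rmsd, n_atoms=len(keys),
                               atom_subset=atom_subset)


def predicted_period(cell: UnitCell, turn_length: float,
                     duplexes_per_cell_along_c: int = 3) -> int:
    """Expected l-index period of the TPS-enhanced classes.

    Repeats per cell = duplexes stacked along c times turns per duplex; for
    the reference cell (c = 266.94 A, turn ~29.66 A, three R-centered
    duplexes of three turns) this is 9, matching the enhanced l = 9n classes.
    """
    if turn_length <= 0 or duplexes_per_cell_along_c < 1:
        raise ValueError("turn_length and duplex count must be positive")
    span = cell.c / duplexes_per_cell_along_c
    turns_per_duplex = max(1, int(round(span / turn_length)))
    return duplexes_per_cell_along_c * turns_per_duplex
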