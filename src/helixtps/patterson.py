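"""Patterson synthesis, peak search and TPS-vector diagnostics.

A translation t repeating part of the cell contents produces an off-origin
Patterson peak at +/- t; for a helix of several turns stacked along c the
peak sits one turn length up the w axis (and a weaker one at two turn
lengths, carried by half as many interatomic vectors).  The delete-turn
check recomputes calculated Pattersons with one helical turn removed: losing
the middle turn removes the one-turn peak, losing an end turn removes the
two-turn peak, validating the TPS interpretation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.fft

from .reflections import ReflectionSet, normalize
from .synthetic import CrystalModel, UnitCell, calc_structure_factors

ORIGIN_EXCLUSION_DEFAULT = 5.0  # Angstrom; past the ~3.4 A base-stacking peaks


# --------------------------------------------------------------------------
# map container
# --------------------------------------------------------------------------


@dataclass
class MapGrid:
    """Real-space map sampled on a fractional grid (FFT-friendly dims)."""

    cell: UnitCell
    values: np.ndarray  # (nu, nv, nw)

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def origin_value(self) -> float:
        return float(self.values[0, 0, 0])

    def sigma(self, origin_exclusion: float = ORIGIN_EXCLUSION_DEFAULT) -> float:
        """Map standard deviation excluding a sphere around the origin."""
        dist = self._origin_distances()
        mask = dist >= origin_exclusion
        if not mask.any():
            mask = np.ones_like(dist, dtype=bool)
        return float(self.values[mask].std())

    def _origin_distances(self) -> np.ndarray:
        nu, nv, nw = self.dims
        fu = np.fft.fftfreq(nu)[:, None, None]
        fv = np.fft.fftfreq(nv)[None, :, None]
        fw = np.fft.fftfreq(nw)[None, None, :]
        frac = np.stack(np.broadcast_arrays(fu, fv, fw), axis=-1)
        cart = frac @ self.cell.orth_matrix.T
        return np.linalg.norm(cart, axis=-1)

    def frac_to_cart_distance(self, frac: np.ndarray) -> float:
        """Minimal-image cartesian distance of a fractional point from origin."""
        f = (np.asarray(frac, dtype=float) + 0.5) % 1.0 - 0.5
        return float(np.linalg.norm(self.cell.orthogonalize(f)))


def origin_equivalents(symmetry) -> np.ndarray:
    """Fractional vectors carrying origin-height Patterson peaks: the pure
    (centering) translations of the space group."""
    rots = symmetry.rotations
    ident = np.all(rots == np.eye(3, dtype=rots.dtype), axis=(1, 2))
    return symmetry.translations[ident] % 1.0


@dataclass
class Peak:
    position: np.ndarray   # fractional, in [0, 1)
    height: float
    height_pct: float      # % of origin peak
    distance: float        # Angstrom from origin (minimal image)
    sigma_level: float


@dataclass
class TPSReport:
    detected: bool
    vector: np.ndarray | None
    peak: Peak | None
    threshold_pct: float


@dataclass
class AxisProfile:
    axis: str
    frac: np.ndarray
    distance: np.ndarray   # Angstrom along the cell edge
    values: np.ndarray
    peaks: list[Peak]


@dataclass
class TurnDeletionReport:
    turn_deleted: int | None
    turn_length: float
    one_turn_peak_present: bool
    two_turn_peak_present: bool
    profile: AxisProfile


# --------------------------------------------------------------------------
# synthesis
# --------------------------------------------------------------------------


def _fft_dims(cell: UnitCell, grid_spacing: float, max_h: np.ndarray) -> tuple[int, ...]:
    dims = []
    for length, mh in zip((cell.a, cell.b, cell.c), max_h):
        n = max(int(np.ceil(length / grid_spacing)), 2 * int(mh) + 2)
        dims.append(scipy.fft.next_fast_len(n, real=False))
    return tuple(dims)


def patterson_synthesis(rset: ReflectionSet, grid_spacing: float | None = None,
                        coefficients: str = "F2") -> MapGrid:
    """Fourier synthesis of the Patterson function.

    Coefficients |F|^2 (default) or E^2 (sharpened), Friedel mates completed,
    the unique set expanded to P1 by the point-group rotations, F000 omitted.
    P(u) = (1/V) sum_h C_h exp(2 pi i h.u); the origin is the global maximum
    by construction.  Default grid spacing is d_min / 3.
    """
    if len(rset) == 0:
        raise ValueError("empty reflection set")
    d_min = rset.resolution_range[1]
    if grid_spacing is None:
        grid_spacing = d_min / 3.0
    if grid_spacing > d_min / 2.0 + 1e-9:
        raise ValueError(f"grid spacing {grid_spacing} too coarse for d_min {d_min:.3f} "
                         "(need <= d_min/2)")
    if coefficients == "F2":
        coeff = rset.F**2
    elif coefficients == "E2":
        coeff = normalize(rset).Z
    else:
        raise ValueError("coefficients must be 'F2' or 'E2'")
    # expand to P1 under the rotation parts (+ Friedel)
    rots = rset.symmetry.rotations
    images = np.einsum("nj,oji->oni", rset.hkl, rots).reshape(-1, 3)
    values = np.tile(coeff, rots.shape[0])
    images = np.concatenate([images, -images])
    values = np.concatenate([values, values])
    max_h = np.abs(images).max(axis=0)
    dims = _fft_dims(rset.cell, grid_spacing, max_h)
    grid = np.zeros(dims, dtype=complex)
    idx = tuple((images[:, i] % dims[i]) for i in range(3))
    grid[idx] = values  # symmetry mates carry identical coefficients
    n_total = np.prod(dims)
    p = np.fft.ifftn(grid).real * (n_total / rset.cell.volume)
    return MapGrid(cell=rset.cell, values=p)


# --------------------------------------------------------------------------
# peak search
# --------------------------------------------------------------------------


def _quadratic_refine_1d(fm: float, f0: float, fp: float) -> tuple[float, float]:
    """Vertex offset in [-0.5, 0.5] and value gain of the parabola through
    (-1, fm), (0, f0), (1, fp)."""
    denom = fm - 2.0 * f0 + fp
    if denom >= 0:  # not a maximum; keep the grid point
        return 0.0, 0.0
    delta = 0.5 * (fm - fp) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    gain = -0.25 * (fm - fp) * delta
    return delta, gain


def peak_search(mapgrid: MapGrid, sigma_min: float = 3.0,
                origin_exclusion: float = ORIGIN_EXCLUSION_DEFAULT,
                min_separation: float = 2.0,
                origin_equivalents: np.ndarray | None = None) -> list[Peak]:
    """Local maxima above ``sigma_min`` map sigmas, outside the origin sphere.

    ``origin_equivalents`` lists fractional vectors to exclude alongside the
    origin (the pure centering translations, whose Patterson peaks have full
    origin height and carry no TPS information).  Positions are refined by
    separable quadratic interpolation over the 3^3 neighbourhood; nearby
    candidates are greedily thinned to ``min_separation`` Angstrom; results
    are sorted by height (ties broken by lexicographically lowest fractional
    position).
    """
    from scipy.ndimage import maximum_filter

    v = mapgrid.values
    if not np.all(np.isfinite(v)):
        raise ValueError("map contains non-finite values")
    dims = v.shape
    sig = mapgrid.sigma(origin_exclusion=min(origin_exclusion, ORIGIN_EXCLUSION_DEFAULT))
    local_max = v == maximum_filter(v, size=3, mode="wrap")
    cand = np.argwhere(local_max & (v >= sigma_min * sig))
    origin = mapgrid.origin_value
    excl_centers = np.zeros((1, 3)) if origin_equivalents is None else np.vstack(
        [np.zeros(3), np.atleast_2d(origin_equivalents)])
    cart = mapgrid.cell.orth_matrix

    def _near_excluded(frac: np.ndarray) -> bool:
        df = (frac[None, :] - excl_centers + 0.5) % 1.0 - 0.5
        return bool(np.any(np.linalg.norm(df @ cart.T, axis=1) < origin_exclusion))

    peaks: list[tuple[tuple, Peak]] = []
    for iu, iv, iw in cand:
        frac = np.array([iu / dims[0], iv / dims[1], iw / dims[2]])
        if _near_excluded(frac):
            continue
        height = float(v[iu, iv, iw])
        refined = frac.copy()
        for ax, idx0 in enumerate((iu, iv, iw)):
            sel: list = [iu, iv, iw]
            vals = []
            for off in (-1, 0, 1):
                sel[ax] = (idx0 + off) % dims[ax]
                vals.append(float(v[tuple(sel)]))
            delta, gain = _quadratic_refine_1d(*vals)
            refined[ax] = (frac[ax] + delta / dims[ax]) % 1.0
            height += gain
        peak = Peak(
            position=refined,
            height=height,
            height_pct=100.0 * height / origin if origin > 0 else np.nan,
            distance=mapgrid.frac_to_cart_distance(refined),
            sigma_level=height / sig if sig > 0 else np.inf,
        )
        peaks.append(((-peak.height, *np.round(refined, 9)), peak))
    peaks.sort(key=lambda t: t[0])
    kept: list[Peak] = []
    cart = mapgrid.cell.orth_matrix
    for _, p in peaks:
        ok = True
        for q in kept:
            df = (p.position - q.position + 0.5) % 1.0 - 0.5
            if np.linalg.norm(cart @ df) < min_separation:
                ok = False
                break
        if ok:
            kept.append(p)
    return kept


def axis_profile(mapgrid: MapGrid, axis: str = "w",
                 sigma_min: float = 3.0, origin_exclusion: float = 4.0) -> AxisProfile:
    """Density along one cell edge with a 1-D peak list (distances in A)."""
    try:
        ax = {"u": 0, "v": 1, "w": 2}[axis]
    except KeyError:
        raise ValueError("axis must be 'u', 'v' or 'w'") from None
    v = mapgrid.values
    sel: list = [0, 0, 0]
    sel[ax] = slice(None)
    line = np.asarray(v[tuple(sel)], dtype=float)
    n = len(line)
    frac = np.arange(n) / n
    edge = (mapgrid.cell.a, mapgrid.cell.b, mapgrid.cell.c)[ax]
    dist = frac * edge
    sig = mapgrid.sigma()
    origin = mapgrid.origin_value
    peaks = []
    for i in range(n):
        fm, f0, fp = line[(i - 1) % n], line[i], line[(i + 1) % n]
        if f0 < max(fm, fp) or (f0 == fm and f0 == fp):
            continue
        delta, gain = _quadratic_refine_1d(fm, f0, fp)
        f_ref = (i + delta) / n % 1.0
        if f_ref > 0.5:
            continue  # centrosymmetric mate of a peak already reported
        height = float(f0 + gain)
        pos = np.zeros(3)
        pos[ax] = f_ref
        d = min(f_ref, 1 - f_ref) * edge
        if d < 1e-6:
            continue  # origin itself
        peaks.append(Peak(position=pos, height=height,
                          height_pct=100.0 * height / origin if origin > 0 else np.nan,
                          distance=d,
                          sigma_level=height / sig if sig > 0 else np.inf))
    peaks = [p for p in peaks if p.sigma_level >= sigma_min
             and p.distance >= origin_exclusion]
    peaks.sort(key=lambda p: -p.height)
    return AxisProfile(axis=axis, frac=frac, distance=dist, values=line, peaks=peaks)


def tps_check(peaks: list[Peak], threshold_pct: float = 20.0) -> TPSReport:
    """Declare TPS when the strongest off-origin peak reaches threshold_pct
    of the origin height."""
    if not peaks:
        return TPSReport(detected=False, vector=None, peak=None,
                         threshold_pct=threshold_pct)
    best = max(peaks, key=lambda p: p.height_pct)
    detected = best.height_pct >= threshold_pct
    return TPSReport(detected=detected,
                     vector=best.position if detected else None,
                     peak=best, threshold_pct=threshold_pct)


# --------------------------------------------------------------------------
# delete-turn validation
# --------------------------------------------------------------------------


def _estimate_turn_length(model: CrystalModel) -> float:
    """Adjacent-turn centroid separation along c, in Angstrom."""
    turns = model.turns()
    uniq = np.unique(turns[turns >= 0])
    if len(uniq) < 2:
        raise ValueError("model needs >= 2 annotated turns")
    pos = model.positions()
    if not model.cartesian:
        # unwrap around the duplex: use minimal-image z relative to first atom
        z0 = pos[0, 2]
        zf = (pos[:, 2] - z0 + 0.5) % 1.0 - 0.5
        z = zf * model.cell.c
    else:
        z = pos[:, 2]
    cz = [z[turns == t].mean() for t in uniq]
    return float(np.mean(np.abs(np.diff(sorted(cz)))))


def _profile_peak_present(profile: AxisProfile, target: float, tol: float,
                          sigma_min: float = 5.0) -> bool:
    return any(abs(p.distance - target) <= tol and p.sigma_level >= sigma_min
               for p in profile.peaks)


def delete_turn_check(model: CrystalModel, turn_to_delete: int | None,
                      d_min: float = 2.8, grid_spacing: float | None = None,
                      turn_length: float | None = None) -> TurnDeletionReport:
    """Calculated-Patterson check of the TPS interpretation.

    Removes one annotated turn (0-based index; ``None`` keeps the full model),
    synthesizes the calculated Patterson, and reports whether the one-turn and
    two-turn w-axis peaks survive (>= 5 sigma within two grid steps of the
    expected distance).
    """
    turns = model.turns()
    uniq = np.unique(turns[turns >= 0])
    if len(uniq) < 3:
        raise ValueError("delete-turn check needs >= 3 annotated turns")
    if turn_to_delete is not None and turn_to_delete not in uniq:
        raise ValueError(f"turn {turn_to_delete} not present; turns are {uniq.tolist()}")
    if turn_length is None:
        turn_length = _estimate_turn_length(model)
    work = model if turn_to_delete is None else model.subset(turns != turn_to_delete)
    refl = calc_structure_factors(work, d_min=d_min)
    pmap = patterson_synthesis(refl, grid_spacing=grid_spacing)
    prof = axis_profile(pmap, "w", sigma_min=0.0, origin_exclusion=4.0)
    step = model.cell.c / pmap.dims[2]
    tol = max(2.0 * step, 2.0)
    one = _profile_peak_present(prof, turn_length, tol)
    two = _profile_peak_present(prof, 2.0 * turn_length, tol)
    return TurnDeletionReport(turn_deleted=turn_to_delete, turn_length=turn_length,
                              one_turn_peak_present=one, two_turn_peak_present=two,
                              profile=prof)


# --------------------------------------------------------------------------
# map output
# --------------------------------------------------------------------------


def write_peaks_tsv(peaks: list[Peak], path: str) -> None:
    """Peak list as TSV with fractional and Angstrom columns."""
    with open(path, "w") as fh:
        fh.write("u\tv\tw\theight\theight_pct\tdistance_A\tsigma\n")
        for p in peaks:
            fh.write(f"{p.position[0]:.6f}\t{p.position[1]:.6f}\t"
                     f"{p.position[2]:.6f}\t{p.height:.6g}\t"
                     f"{p.height_pct:.3f}\t{p.distance:.4f}\t"
                     f"{p.sigma_level:.3f}\n")


def write_map_tsv(mapgrid: MapGrid, path: str) -> None:
    """Flat TSV (u, v, w, value) of the map grid."""
    nu, nv, nw = mapgrid.dims
    with open(path, "w") as fh:
        fh.write("u\tv\tw\tvalue\n")
        for iu in range(nu):
            for iv in range(nv):
                for iw in range(nw):
                    fh.write(f"{iu / nu:.6f}\t{iv / nv:.6f}\t{iw / nw:.6f}\t"
                             f"{mapgrid.values[iu, iv, iw]:.6g}\n")


def write_map_ccp4(mapgrid: MapGrid, path: str) -> None:
    """Binary CCP4/MRC map via gemmi (P1 sampling of the synthesized grid)."""
    import gemmi

    grid = gemmi.FloatGrid(*mapgrid.dims)
    grid.set_unit_cell(mapgrid.cell.gemmi())
    grid.spacegroup = gemmi.SpaceGroup("P1")
    arr = np.array(grid, copy=False)
    arr[...] = mapgrid.values.astype(np.float32)
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    ccp4.write_ccp4_map(str(path))
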