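"""Reflection containers, normalization and intensity-distribution diagnostics.

Translational pseudosymmetry (TPS) leaves three reciprocal-space fingerprints
that this module measures:

* the cumulative distribution of normalized intensities Z = E^2 departs from
  the Wilson acentric law 1 - exp(-z) toward the hyper-dispersed mixture law
  of m perfect translational copies;
* structure factors averaged by their l Miller index alternate with the
  period of the pseudo-repeat along c (e.g. enhanced at l = 9n, depressed at
  l = 9n +/- 4, 5 for a 9-fold repeat);
* the strongest reflections carry an outsized share of the total scattering
  power (cumulative power curve), so their loss is costlier.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import gemmi
import numpy as np
import pandas as pd

from .synthetic import SpaceGroupOps, UnitCell, SUPPORTED_SPACE_GROUPS

# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------


@dataclass
class ReflectionSet:
    """Unique indexed amplitudes with sigmas (and, if calculated, phases)."""

    cell: UnitCell
    symmetry: SpaceGroupOps
    hkl: np.ndarray            # (N, 3) int
    F: np.ndarray              # amplitudes, arbitrary scale
    sigma: np.ndarray
    phase: np.ndarray | None = None   # degrees, for calculated sets

    def __post_init__(self) -> None:
        self.hkl = np.asarray(self.hkl, dtype=np.int64).reshape(-1, 3)
        self.F = np.asarray(self.F, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.phase is not None:
            self.phase = np.asarray(self.phase, dtype=float)
        if len(self.F) != len(self.hkl) or len(self.sigma) != len(self.hkl):
            raise ValueError("hkl, F, sigma must have matching lengths")
        if np.any(self.sigma < 0):
            raise ValueError("sigmas must be non-negative")

    def __len__(self) -> int:
        return len(self.F)

    @property
    def d(self) -> np.ndarray:
        return self.cell.d_spacings(self.hkl)

    @property
    def resolution_range(self) -> tuple[float, float]:
        d = self.d
        return float(d.max()), float(d.min())

    def epsilon(self) -> np.ndarray:
        return self.symmetry.epsilon(self.hkl)

    def centric(self) -> np.ndarray:
        return self.symmetry.centric(self.hkl)

    def select(self, mask: np.ndarray) -> "ReflectionSet":
        return ReflectionSet(
            self.cell, self.symmetry, self.hkl[mask], self.F[mask],
            self.sigma[mask], None if self.phase is None else self.phase[mask],
        )

    # ---- writers --------------------------------------------------------

    def write_hkl(self, path: str | Path) -> None:
        """Whitespace text: h k l F sigF."""
        with open(path, "w") as fh:
            for (h, k, l), f, s in zip(self.hkl, self.F, self.sigma):
                fh.write(f"{h:5d} {k:5d} {l:5d} {f:14.6f} {s:12.6f}\n")

    def write_sf_mmcif(self, path: str | Path, block_name: str = "synthetic") -> None:
        """Structure-factor mmCIF with a _refln loop (F_meas_au convention)."""
        doc = gemmi.cif.Document()
        block = doc.add_new_block(block_name)
        c = self.cell
        for tag, val in [
            ("_cell.length_a", c.a), ("_cell.length_b", c.b), ("_cell.length_c", c.c),
            ("_cell.angle_alpha", c.alpha), ("_cell.angle_beta", c.beta),
            ("_cell.angle_gamma", c.gamma),
        ]:
            block.set_pair(tag, f"{val:.4f}")
        block.set_pair("_symmetry.space_group_name_H-M",
                       gemmi.cif.quote(self.symmetry.gemmi_sg().xhm()))
        loop = block.init_loop("_refln.", ["index_h", "index_k", "index_l",
                                           "F_meas_au", "F_meas_sigma_au"])
        for (h, k, l), f, s in zip(self.hkl, self.F, self.sigma):
            loop.add_row([str(h), str(k), str(l), f"{f:.6f}", f"{s:.6f}"])
        doc.write_file(str(path))

    def write_mtz(self, path: str | Path) -> None:
        mtz = gemmi.Mtz(with_base=True)
        mtz.spacegroup = self.symmetry.gemmi_sg()
        mtz.set_cell_for_all(self.cell.gemmi())
        mtz.add_dataset("synthetic")
        mtz.add_column("F", "F")
        mtz.add_column("SIGF", "Q")
        data = np.column_stack([self.hkl.astype(float), self.F, self.sigma])
        mtz.set_data(data)
        mtz.write_to_file(str(path))


@dataclass
class NormalizedReflection:
    """One reflection after E normalization (record view of NormalizedSet)."""

    hkl: tuple[int, int, int]
    d: float
    epsilon: int
    centric: bool
    E: float
    Z: float


@dataclass
class NormalizedSet:
    """Array-backed collection of normalized reflections (Z = E^2)."""

    base: ReflectionSet
    E: np.ndarray
    epsilon: np.ndarray
    centric: np.ndarray
    shell_index: np.ndarray

    @property
    def Z(self) -> np.ndarray:
        return self.E**2

    def __len__(self) -> int:
        return len(self.E)

    def __iter__(self) -> Iterator[NormalizedReflection]:
        d = self.base.d
        for i in range(len(self.E)):
            yield NormalizedReflection(
                tuple(int(x) for x in self.base.hkl[i]), float(d[i]),
                int(self.epsilon[i]), bool(self.centric[i]),
                float(self.E[i]), float(self.E[i] ** 2),
            )

    def acentric(self) -> "NormalizedSet":
        m = ~self.centric
        return NormalizedSet(self.base.select(m), self.E[m], self.epsilon[m],
                             self.centric[m], self.shell_index[m])


@dataclass
class WilsonFit:
    scale: float
    B: float
    shell_table: pd.DataFrame  # columns: s2_mean, mean_I, n

    def predicted_log_mean_I(self, s2: np.ndarray) -> np.ndarray:
        return np.log(self.scale) - 0.5 * self.B * np.asarray(s2)


@dataclass
class LProfile:
    l_values: np.ndarray
    mean_F_over_sigma: np.ndarray  # NaN marks empty l classes
    counts: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"l": self.l_values, "mean_F_over_sigma": self.mean_F_over_sigma,
                             "count": self.counts})


@dataclass
class PowerCurve:
    sorted_fractions: np.ndarray  # cumulative sum(F^2) fractions, descending-F order
    n: int

    def fraction_of_top(self, k: int) -> float:
        if k <= 0:
            return 0.0
        return float(self.sorted_fractions[min(k, self.n) - 1])


@dataclass
class ZcdfResult:
    z_sorted: np.ndarray
    ecdf: np.ndarray
    d_wilson: float
    d_tps: float
    tps_m: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"z": self.z_sorted, "ecdf": self.ecdf})


# --------------------------------------------------------------------------
# reading and merging
# --------------------------------------------------------------------------


def merge_equivalents(rset: ReflectionSet) -> tuple[ReflectionSet, int]:
    """Merge symmetry/Friedel equivalents; returns merged set and the number
    of observations absorbed into existing unique reflections."""
    canon = rset.symmetry.canonical(rset.hkl)
    uniq, inverse, counts = np.unique(canon, axis=0, return_inverse=True,
                                      return_counts=True)
    with np.errstate(divide="ignore"):
        w = np.where(rset.sigma > 0, 1.0 / rset.sigma**2, 1.0)
    F = np.bincount(inverse, w * rset.F) / np.bincount(inverse, w)
    sig = np.sqrt(np.bincount(inverse, w * rset.sigma**2) / np.bincount(inverse, w))
    sig /= np.sqrt(counts)
    merged = ReflectionSet(rset.cell, rset.symmetry, uniq, F, sig)
    return merged, int(len(rset) - len(uniq))


def read_reflections(
    path: str | Path,
    format: str,
    cell: UnitCell | None = None,
    spacegroup: str | None = None,
) -> ReflectionSet:
    """Read reflection data and merge to a unique set.

    Formats: ``"sf-mmcif"`` (_refln loop; cell and symmetry from the file),
    ``"hkl-text"`` (whitespace ``h k l F sigF``; cell/spacegroup must be
    supplied) and ``"mtz"``.  When only intensities are present they are
    converted to amplitudes by sqrt, with negative intensities clamped to
    zero (the clamp count is stored as ``.n_clamped`` on the result).
    """
    path = Path(path)
    n_clamped = 0
    if format == "hkl-text":
        if cell is None or spacegroup is None:
            raise ValueError("hkl-text input needs an explicit cell and space group")
        arr = np.loadtxt(path, ndmin=2)
        if arr.shape[1] < 4:
            raise ValueError("hkl-text needs at least 4 columns: h k l F [sigF]")
        hkl_f = arr[:, :3]
        if np.any(np.abs(hkl_f - np.round(hkl_f)) > 1e-6):
            raise ValueError("non-integer Miller indices in hkl-text input")
        F = arr[:, 3]
        sig = arr[:, 4] if arr.shape[1] > 4 else np.zeros_like(F)
        rset = ReflectionSet(cell, SpaceGroupOps(spacegroup),
                             np.round(hkl_f).astype(np.int64), F, sig)
    elif format == "sf-mmcif":
        doc = gemmi.cif.read(str(path))
        block = doc.sole_block()
        def _num(tag: str) -> float:
            v = block.find_value(tag)
            if v is None:
                raise ValueError(f"missing {tag} in {path}")
            return float(v)
        file_cell = UnitCell(_num("_cell.length_a"), _num("_cell.length_b"),
                             _num("_cell.length_c"), _num("_cell.angle_alpha"),
                             _num("_cell.angle_beta"), _num("_cell.angle_gamma"))
        sg_name = block.find_value("_symmetry.space_group_name_H-M")
        if sg_name is not None:
            sg_name = gemmi.cif.as_string(sg_name)
        label = spacegroup or _match_supported(sg_name)
        cols = ["index_h", "index_k", "index_l"]
        table = block.find("_refln.", cols + ["F_meas_au", "F_meas_sigma_au"])
        if len(table) > 0:
            rows = np.array([[float(table[i][j]) for j in range(5)]
                             for i in range(len(table))])
            F, sig = rows[:, 3], rows[:, 4]
        else:
            table = block.find("_refln.", cols + ["intensity_meas", "intensity_sigma"])
            if len(table) == 0:
                raise ValueError(f"no amplitude or intensity loop found in {path}")
            rows = np.array([[float(table[i][j]) for j in range(5)]
                             for i in range(len(table))])
            I, sigI = rows[:, 3], rows[:, 4]
            n_clamped = int((I < 0).sum())
            I = np.clip(I, 0.0, None)
            F = np.sqrt(I)
            with np.errstate(divide="ignore", invalid="ignore"):
                sig = np.where(F > 0, sigI / (2 * F), np.sqrt(np.clip(sigI, 0, None)))
        rset = ReflectionSet(cell or file_cell, SpaceGroupOps(label),
                             rows[:, :3].astype(np.int64), F, sig)
    elif format == "mtz":
        mtz = gemmi.read_mtz_file(str(path))
        arr = np.array(mtz, copy=True)
        labels = [c.label for c in mtz.columns]
        def col(*names: str) -> np.ndarray | None:
            for n in names:
                if n in labels:
                    return arr[:, labels.index(n)]
            return None
        hkl_f = np.column_stack([col("H"), col("K"), col("L")])
        F = col("F", "FP", "F_meas_au")
        sig = col("SIGF", "SIGFP", "F_meas_sigma_au")
        if F is None:
            raise ValueError("no amplitude column found in MTZ file")
        if sig is None:
            sig = np.zeros_like(F)
        gc = mtz.cell
        mcell = cell or UnitCell(gc.a, gc.b, gc.c, gc.alpha, gc.beta, gc.gamma)
        label = spacegroup or _match_supported(mtz.spacegroup.xhm())
        good = np.isfinite(F)
        rset = ReflectionSet(mcell, SpaceGroupOps(label),
                             hkl_f[good].astype(np.int64), F[good], sig[good])
    else:
        raise ValueError(f"unknown format {format!r}; use sf-mmcif, hkl-text or mtz")
    merged, _ = merge_equivalents(rset)
    merged.n_clamped = n_clamped  # type: ignore[attr-defined]
    return merged


def _match_supported(sg_name: str | None) -> str:
    if sg_name is None:
        raise ValueError("space group missing from file; pass spacegroup=")
    target = gemmi.SpaceGroup(sg_name).xhm()
    for cand in SUPPORTED_SPACE_GROUPS:
        if gemmi.SpaceGroup(cand).xhm() == target:
            return cand
    raise ValueError(
        f"space group {sg_name!r} is not supported; "
        f"supported groups: {', '.join(SUPPORTED_SPACE_GROUPS)}"
    )


# --------------------------------------------------------------------------
# Wilson fit and normalization
# --------------------------------------------------------------------------


def _equal_count_shells(s2: np.ndarray, n_shells: int, min_per_shell: int = 50
                        ) -> np.ndarray:
    """Shell index per reflection: equal-count shells in s^2 order."""
    n = len(s2)
    n_shells = max(1, min(n_shells, n // min_per_shell if n >= min_per_shell else 1))
    order = np.argsort(s2, kind="stable")
    idx = np.empty(n, dtype=int)
    idx[order] = (np.arange(n) * n_shells) // n
    return idx


def wilson_fit(rset: ReflectionSet, shells: int = 20,
               d_max: float | None = None, d_min: float | None = None) -> WilsonFit:
    """Straight-line Wilson fit: ln<I> vs <s^2> over equal-count shells.

    With the constant-weight scattering model, <I> = scale * exp(-B s^2 / 2),
    so B = -2 * slope.  An optional resolution window [d_max, d_min] limits
    the fit range.
    """
    d = rset.d
    mask = np.ones(len(rset), dtype=bool)
    if d_max is not None:
        mask &= d <= d_max
    if d_min is not None:
        mask &= d >= d_min
    sub = rset.select(mask)
    if len(sub) < 3 * 50:
        raise ValueError("too few reflections for a Wilson fit (need >= 3 shells of 50)")
    s2 = 1.0 / sub.d**2
    I = sub.F**2
    idx = _equal_count_shells(s2, shells)
    n_sh = idx.max() + 1
    if n_sh < 3:
        raise ValueError("too few shells for a Wilson fit")
    s2_mean = np.bincount(idx, s2) / np.bincount(idx)
    I_mean = np.bincount(idx, I) / np.bincount(idx)
    counts = np.bincount(idx)
    slope, intercept = np.polyfit(s2_mean, np.log(I_mean), 1, w=np.sqrt(counts))
    table = pd.DataFrame({"s2_mean": s2_mean, "mean_I": I_mean, "n": counts})
    return WilsonFit(scale=float(np.exp(intercept)), B=float(-2.0 * slope),
                     shell_table=table)


def normalize(rset: ReflectionSet, shells: int = 20) -> NormalizedSet:
    """Convert amplitudes to normalized structure factors E (Z = E^2).

    Z = I / (epsilon * <I/epsilon>_shell) with the shell mean curve linearly
    interpolated in s^2 between equal-count shell centres, then pinned so
    that every shell's mean Z is exactly 1 (the normalization invariant).
    """
    if len(rset) == 0:
        raise ValueError("cannot normalize an empty reflection set")
    eps = rset.epsilon().astype(float)
    cen = rset.centric()
    s2 = 1.0 / rset.d**2
    I = rset.F**2
    idx = _equal_count_shells(s2, shells)
    n_sh = idx.max() + 1
    I_over_eps = I / eps
    mean_sh = np.bincount(idx, I_over_eps) / np.bincount(idx)
    if np.any(mean_sh <= 0):
        raise ValueError("a resolution shell has zero mean intensity")
    centers = np.bincount(idx, s2) / np.bincount(idx)
    curve = np.interp(s2, centers, mean_sh)
    Z = I_over_eps / curve
    # pin the per-shell mean to 1 exactly
    corr = np.bincount(idx, Z) / np.bincount(idx)
    Z = Z / corr[idx]
    return NormalizedSet(base=rset, E=np.sqrt(Z), epsilon=eps.astype(int),
                         centric=cen, shell_index=idx)


# --------------------------------------------------------------------------
# theoretical and empirical Z distributions
# --------------------------------------------------------------------------


def cdf_wilson_acentric(z):
    """Wilson acentric law P(Z <= z) = 1 - exp(-z)."""
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise ValueError("z must be non-negative")
    return 1.0 - np.exp(-z)


def cdf_perfect_tps(z, m: int):
    """Mixture law for m perfect translational copies.

    A fraction (m-1)/m of acentric reflections is extinct (Z = 0) and the
    remaining 1/m is exponential with mean m, keeping the overall mean Z at 1:
    cdf(z) = (m-1)/m + (1/m) (1 - exp(-z/m)).
    """
    if int(m) != m or m < 1:
        raise ValueError("m must be an integer >= 1")
    m = int(m)
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise ValueError("z must be non-negative")
    return (m - 1) / m + (1.0 - np.exp(-z / m)) / m


def empirical_zcdf(normalized: NormalizedSet, acentric_only: bool = True,
                   tps_m: int = 3, ztol: float = 1e-6) -> ZcdfResult:
    """Empirical cdf of Z with Kolmogorov distances to both theoretical laws.

    Z values below ``ztol`` are treated as exact zeros so that numerically
    extinct reflections land on the point mass of the perfect-TPS law.
    """
    nset = normalized.acentric() if acentric_only else normalized
    if len(nset) == 0:
        raise ValueError("no reflections left after centric filtering")
    z = np.sort(nset.Z)
    z = np.where(z < ztol, 0.0, z)
    n = len(z)
    ecdf_hi = np.arange(1, n + 1) / n
    ecdf_lo = np.arange(0, n) / n

    def ks(theory: np.ndarray, theory_left: np.ndarray) -> float:
        # theory_left is the law's left limit, which differs from the cdf
        # at a point mass (the extinct fraction of the perfect-TPS law)
        return float(max(np.max(ecdf_hi - theory),
                         np.max(theory_left - ecdf_lo)))

    wil = cdf_wilson_acentric(z)
    d_w = ks(wil, wil)  # continuous law: left limit equals the cdf
    tps = cdf_perfect_tps(z, tps_m)
    tps_left = np.where(z > 0, tps, 0.0)
    d_t = ks(tps, tps_left)
    return ZcdfResult(z_sorted=z, ecdf=ecdf_hi, d_wilson=d_w, d_tps=d_t, tps_m=tps_m)


# --------------------------------------------------------------------------
# l-index profiles and periodicity
# --------------------------------------------------------------------------


def l_profile(rset: ReflectionSet) -> LProfile:
    """Mean F/sigma per l Miller index over all h, k."""
    if np.any(rset.sigma[rset.F > 0] <= 0):
        raise ValueError("sigmas must be positive to form F/sigma profiles")
    ls = rset.hkl[:, 2]
    lo, hi = int(ls.min()), int(ls.max())
    l_values = np.arange(lo, hi + 1)
    ratio = np.where(rset.sigma > 0, rset.F / np.where(rset.sigma > 0, rset.sigma, 1.0), 0.0)
    counts = np.bincount(ls - lo, minlength=len(l_values))
    sums = np.bincount(ls - lo, ratio, minlength=len(l_values))
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return LProfile(l_values=l_values, mean_F_over_sigma=means, counts=counts)


def detect_period(profile: LProfile, threshold: float = 3.0,
                  min_period: int = 2) -> tuple[int | None, float]:
    """Dominant period of an l profile from its discrete autocorrelation.

    The mean-centred (empty classes zero-filled), variance-normalized profile
    is autocorrelated; the candidate period is the smallest lag within 90% of
    the autocorrelation maximum.  The score is the autocorrelation at that
    lag in units of its white-noise (Bartlett) standard error 1/sqrt(n - k),
    the noise floor of a sample autocorrelation; below ``threshold`` the
    result is (None, score).
    """
    x = profile.mean_F_over_sigma.astype(float).copy()
    populated = np.isfinite(x)
    if populated.sum() < 3:
        raise ValueError("need at least 3 populated l classes")
    mu = np.nanmean(x)
    x = np.where(populated, x - mu, 0.0)
    sd = np.sqrt(np.mean(x**2))
    if sd == 0:
        return None, 0.0
    x = x / sd
    n = len(x)
    max_lag = n // 2
    if max_lag < min_period:
        raise ValueError("profile too short for period detection")
    lags = np.arange(min_period, max_lag + 1)
    ac = np.array([np.dot(x[:-k], x[k:]) / (n - k) for k in lags])
    peak = ac.max()
    if peak <= 0:
        return None, 0.0
    candidates = lags[ac >= 0.9 * peak]
    period = int(candidates.min())
    score = float(ac[lags == period][0] * np.sqrt(n - period))
    if score < threshold:
        return None, score
    return period, score


# --------------------------------------------------------------------------
# scattering power
# --------------------------------------------------------------------------


def cumulative_power(rset: ReflectionSet) -> PowerCurve:
    """Cumulative fraction of total scattering power (sum F^2, F000 absent),
    accumulated in descending-amplitude order."""
    if len(rset) == 0:
        raise ValueError("empty reflection set")
    F2 = np.sort(rset.F**2)[::-1]
    total = F2.sum()
    if total == 0:
        raise ValueError("all amplitudes are zero")
    return PowerCurve(sorted_fractions=np.cumsum(F2) / total, n=len(F2))


def delete_top_n(rset: ReflectionSet, n: int,
                 manifest_path: str | Path | None = None
                 ) -> tuple[ReflectionSet, pd.DataFrame]:
    """Remove the n largest-amplitude reflections; returns (kept, manifest)."""
    if not 0 <= n <= len(rset):
        raise ValueError(f"n must lie in [0, {len(rset)}]")
    order = np.argsort(-rset.F, kind="stable")
    removed_idx = order[:n]
    mask = np.ones(len(rset), dtype=bool)
    mask[removed_idx] = False
    manifest = pd.DataFrame({
        "h": rset.hkl[removed_idx, 0], "k": rset.hkl[removed_idx, 1],
        "l": rset.hkl[removed_idx, 2], "F": rset.F[removed_idx],
        "d": rset.d[removed_idx],
    })
    if manifest_path is not None:
        manifest.to_csv(manifest_path, sep="\t", index=False)
    return rset.select(mask), manifest
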