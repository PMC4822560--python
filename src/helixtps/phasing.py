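"""Statistics of stochastic ab initio phasing experiments.

Each phasing experiment tests up to ``cap`` random phase sets; every trial
is an independent Bernoulli success/failure, so the number of failed trials
before the first success follows a geometric distribution, right-censored at
the trial cap.  This module provides the capped-trial simulator, the
censored-geometric maximum-likelihood fit, geometric probability plots, a
tie-aware k-sample Anderson-Darling comparison of trial-count samples, and
the phase-set figures of merit (fFOM2 components, weighted mean phase error,
map correlation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_TRIAL_CAP = 600  # phase sets per phasing experiment

# --------------------------------------------------------------------------
# trial-count containers
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TrialOutcome:
    """Failures before first success in one phasing experiment."""

    n_failures: int
    censored: bool
    cap: int = DEFAULT_TRIAL_CAP

    def __post_init__(self) -> None:
        if self.censored and self.n_failures != self.cap:
            raise ValueError("a censored outcome must record n_failures == cap")
        if not self.censored and not 0 <= self.n_failures < self.cap:
            raise ValueError("uncensored n_failures must lie in [0, cap)")


@dataclass
class ExperimentSet:
    outcomes: list[TrialOutcome]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.outcomes:
            raise ValueError("an ExperimentSet must be non-empty")

    def __len__(self) -> int:
        return len(self.outcomes)

    @property
    def failures(self) -> np.ndarray:
        return np.array([o.n_failures for o in self.outcomes])

    @property
    def censored(self) -> np.ndarray:
        return np.array([o.censored for o in self.outcomes])

    def uncensored_failures(self) -> np.ndarray:
        return self.failures[~self.censored]

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame({
            "experiment_id": np.arange(len(self)),
            "n_failures": self.failures,
            "censored": self.censored.astype(int),
            "cap": [o.cap for o in self.outcomes],
        })
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, label: str = "") -> "ExperimentSet":
        df = pd.read_csv(path, sep="\t")
        outcomes = [TrialOutcome(int(r.n_failures), bool(r.censored), int(r.cap))
                    for r in df.itertuples()]
        return cls(outcomes=outcomes, label=label or Path(path).stem)


@dataclass
class GeometricFit:
    p: float
    se: float
    loglik: float
    n_success: int
    n_censored: int


@dataclass
class ProbPlot:
    theoretical_quantiles: np.ndarray
    observed_quantiles: np.ndarray
    r: float
    degenerate: bool = False


@dataclass
class ADResult:
    a2kn: float
    variance: float
    standardized: float
    p: float
    method: str = "interpolation"


# --------------------------------------------------------------------------
# simulation and fitting
# --------------------------------------------------------------------------


def simulate_experiments(p: float, n_experiments: int, cap: int = DEFAULT_TRIAL_CAP,
                         seed: int = 0, label: str = "") -> ExperimentSet:
    """Capped Bernoulli-trial experiments: failures before first success,
    censored at ``cap`` trials."""
    if not 0.0 < p <= 1.0:
        raise ValueError("p must lie in (0, 1]")
    if cap < 1 or n_experiments < 1:
        raise ValueError("cap and n_experiments must be >= 1")
    rng = np.random.default_rng(seed)
    fails = rng.geometric(p, size=n_experiments) - 1
    outcomes = [
        TrialOutcome(int(min(f, cap)), bool(f >= cap), cap) for f in fails
    ]
    return ExperimentSet(outcomes=outcomes, label=label)


def fit_geometric_censored(experiments: ExperimentSet) -> GeometricFit:
    """Maximum-likelihood geometric success probability with right-censoring.

    For S successes with failure counts x_i and C experiments censored at
    their caps, p_hat = S / (sum(x_i + 1) + sum(caps)); the standard error
    comes from the observed Fisher information.
    """
    cens = experiments.censored
    x = experiments.failures
    caps = np.array([o.cap for o in experiments.outcomes])
    S = int((~cens).sum())
    if S == 0:
        raise ValueError("all experiments are censored; p is not identifiable")
    total_failures = int(x[~cens].sum() + caps[cens].sum())
    p_hat = S / (S + total_failures)
    with np.errstate(divide="ignore"):
        loglik = S * np.log(p_hat) + (total_failures * np.log1p(-p_hat)
                                      if total_failures else 0.0)
    info = S / p_hat**2
    if p_hat < 1.0:
        info += total_failures / (1.0 - p_hat) ** 2
    se = 1.0 / np.sqrt(info)
    return GeometricFit(p=float(p_hat), se=float(se), loglik=float(loglik),
                        n_success=S, n_censored=int(cens.sum()))


def geometric_loglik(p: float, experiments: ExperimentSet) -> float:
    """Censored-geometric log-likelihood (for grid-search cross-checks)."""
    if not 0.0 < p <= 1.0:
        return -np.inf
    cens = experiments.censored
    x = experiments.failures
    caps = np.array([o.cap for o in experiments.outcomes])
    nf = int(x[~cens].sum() + caps[cens].sum())
    ll = (~cens).sum() * np.log(p)
    if nf:
        if p == 1.0:
            return -np.inf
        ll += nf * np.log1p(-p)
    return float(ll)


def geometric_prob_plot(experiments: ExperimentSet, fit: GeometricFit) -> ProbPlot:
    """Ordered uncensored counts vs geometric quantiles at (i - 0.5)/n."""
    obs = np.sort(experiments.uncensored_failures())
    n = len(obs)
    if n < 3:
        if n == 2:
            theo = stats.geom.ppf((np.arange(1, 3) - 0.5) / 2, fit.p) - 1
            return ProbPlot(theo, obs.astype(float), r=1.0 if obs[0] != obs[1] else 0.0,
                            degenerate=True)
        raise ValueError("need at least 3 uncensored outcomes")
    q = (np.arange(1, n + 1) - 0.5) / n
    theo = stats.geom.ppf(q, fit.p) - 1  # failures-before-success support
    if obs.std() == 0 or theo.std() == 0:
        return ProbPlot(theo, obs.astype(float), r=0.0, degenerate=True)
    r = float(np.corrcoef(theo, obs)[0, 1])
    return ProbPlot(theo, obs.astype(float), r=r)


# --------------------------------------------------------------------------
# k-sample Anderson-Darling test (tie-aware / midrank form)
# --------------------------------------------------------------------------

_AD_SIG = np.array([0.25, 0.10, 0.05, 0.025, 0.01, 0.005, 0.001])
_AD_B0 = np.array([0.675, 1.281, 1.645, 1.960, 2.326, 2.573, 3.085])
_AD_B1 = np.array([-0.245, 0.250, 0.678, 1.149, 1.822, 2.364, 3.615])
_AD_B2 = np.array([-0.105, -0.305, -0.362, -0.391, -0.396, -0.345, 0.154])


def _ad_statistic_midrank(samples: list[np.ndarray], pooled_sorted: np.ndarray
                          ) -> float:
    """Tie-adjusted k-sample Anderson-Darling statistic (midrank form)."""
    N = len(pooled_sorted)
    zstar = np.unique(pooled_sorted)
    left = np.searchsorted(pooled_sorted, zstar, side="left")
    right = np.searchsorted(pooled_sorted, zstar, side="right")
    lj = (right - left).astype(float)
    Bj = left + lj / 2.0
    denom = Bj * (N - Bj) - N * lj / 4.0
    inner_ok = denom > 0
    a2 = 0.0
    for s in samples:
        s = np.sort(s)
        sl = np.searchsorted(s, zstar, side="left")
        sr = np.searchsorted(s, zstar, side="right")
        Mij = sl + (sr - sl) / 2.0
        ni = len(s)
        num = (N * Mij - ni * Bj) ** 2
        term = np.zeros_like(lj)
        term[inner_ok] = (lj[inner_ok] / N) * num[inner_ok] / denom[inner_ok]
        a2 += term.sum() / ni
    return float((N - 1.0) / N * a2)


def _ad_null_variance(k: int, n_sizes: list[int]) -> float:
    N = sum(n_sizes)
    H = sum(1.0 / n for n in n_sizes)
    h = sum(1.0 / i for i in range(1, N))
    g = sum(1.0 / ((N - i) * j)
            for i in range(1, N - 1) for j in range(i + 1, N))
    a = (4.0 * g - 6.0) * (k - 1) + (10.0 - 6.0 * g) * H
    b = (2.0 * g - 4.0) * k**2 + 8.0 * h * k + (2.0 * g - 14.0 * h - 4.0) * H \
        - 8.0 * h + 4.0 * g - 6.0
    c = (6.0 * h + 2.0 * g - 2.0) * k**2 + (4.0 * h - 4.0 * g + 6.0) * k \
        + (2.0 * h - 6.0) * H + 4.0 * h
    d = (2.0 * h + 6.0) * k**2 - 4.0 * h * k
    return (a * N**3 + b * N**2 + c * N + d) / ((N - 1.0) * (N - 2.0) * (N - 3.0))


def _ad_interpolated_p(standardized: float, k: int) -> float:
    """Asymptotic p by quadratic interpolation of published critical values,
    with monotone log-linear extrapolation beyond the tabulated range."""
    m = k - 1
    critical = _AD_B0 + _AD_B1 / np.sqrt(m) + _AD_B2 / m
    logsig = np.log(_AD_SIG)
    t = standardized
    if t <= critical[0]:
        slope = (logsig[1] - logsig[0]) / (critical[1] - critical[0])
        logp = logsig[0] + slope * (t - critical[0])
    elif t >= critical[-1]:
        slope = (logsig[-1] - logsig[-2]) / (critical[-1] - critical[-2])
        logp = logsig[-1] + slope * (t - critical[-1])
    else:
        coeffs = np.polyfit(critical, logsig, 2)
        logp = float(np.polyval(coeffs, t))
    return float(np.clip(np.exp(logp), 1e-300, 1.0))


def ad_ksample(samples: list, permutations: int | None = None,
               seed: int = 0) -> ADResult:
    """k-sample Anderson-Darling test for identical parent populations.

    Uses the tie-aware (midrank) statistic with its exact null variance and
    an interpolated asymptotic p-value; ``permutations`` switches to a seeded
    permutation p-value (also the default whenever any sample has fewer than
    5 observations).  The statistic is rank-based, hence invariant under any
    common strictly monotone transform of all samples.
    """
    arrays = [np.asarray(s, dtype=float).ravel() for s in samples]
    k = len(arrays)
    if k < 2:
        raise ValueError("need at least two samples")
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each sample needs at least 2 observations")
    pooled = np.sort(np.concatenate(arrays))
    if np.ptp(pooled) == 0:
        warnings.warn("all observations identical across samples; p = 1")
        return ADResult(a2kn=0.0, variance=0.0, standardized=-np.inf, p=1.0,
                        method="degenerate")
    a2 = _ad_statistic_midrank(arrays, pooled)
    var = _ad_null_variance(k, [len(a) for a in arrays])
    standardized = (a2 - (k - 1.0)) / np.sqrt(var)
    if permutations is None and min(len(a) for a in arrays) < 5:
        permutations = 9999
    if permutations:
        rng = np.random.default_rng(seed)
        sizes = np.cumsum([len(a) for a in arrays])[:-1]
        count = 0
        flat = pooled.copy()
        for _ in range(permutations):
            rng.shuffle(flat)
            parts = np.split(flat, sizes)
            stat = _ad_statistic_midrank([np.sort(p) for p in parts], np.sort(flat))
            if stat >= a2:
                count += 1
        p = (count + 1.0) / (permutations + 1.0)
        return ADResult(a2kn=a2, variance=var, standardized=standardized, p=p,
                        method="permutation")
    p = _ad_interpolated_p(standardized, k)
    return ADResult(a2kn=a2, variance=var, standardized=standardized, p=p)


# --------------------------------------------------------------------------
# phase-set figures of merit
# --------------------------------------------------------------------------


@dataclass
class FomReport:
    cc_all: float
    cc_large: float
    cc_weak: float
    cc_wE: float
    rat: float
    mean_Ecalc2_weak: float
    ffom2: float
    success: bool
    threshold: float


@dataclass
class PhaseComparison:
    wmpe: float
    map_cc: float
    shell_table: pd.DataFrame | None = None


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if x.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def compute_ffom2(E_obs: np.ndarray, E_calc: np.ndarray,
                  weights: np.ndarray | None = None,
                  threshold: float = 3.0) -> FomReport:
    """Global figure of merit of a trial phase set.

    Components follow the standard construction: CC between observed and
    calculated E over all reflections, over the 70% largest observed E
    ("large") and the 30% smallest ("weak"); CC_w,E between the large
    observed E and their statistical weights (the calculated E serve as the
    weight proxy when none are supplied); RAT = <E^2_calc>_weak /
    <E^2_calc>_all, which drops well below 1 when the map correctly leaves
    the weak reflections weak.  The combined score
    ffom2 = CC_all + CC_large + CC_w,E + 1/RAT (RAT floored at 0.1)
    scores a random map near 1 and a correct map near 5 against the success
    threshold of 3.0.
    """
    E_obs = np.asarray(E_obs, dtype=float)
    E_calc = np.asarray(E_calc, dtype=float)
    if E_obs.shape != E_calc.shape:
        raise ValueError("E_obs and E_calc must have matching shapes")
    n = len(E_obs)
    order = np.argsort(E_obs, kind="stable")
    n_weak = int(round(0.30 * n))
    weak = order[:n_weak]
    large = order[n_weak:]
    if min(len(weak), len(large)) < 10:
        raise ValueError("fewer than 10 reflections in a partition")
    w = E_calc if weights is None else np.asarray(weights, dtype=float)
    cc_all = _pearson(E_obs, E_calc)
    cc_large = _pearson(E_obs[large], E_calc[large])
    cc_weak = _pearson(E_obs[weak], E_calc[weak])
    cc_wE = _pearson(E_obs[large], w[large])
    mean_weak = float(np.mean(E_calc[weak] ** 2))
    mean_all = float(np.mean(E_calc**2))
    rat = mean_weak / mean_all if mean_all > 0 else 1.0
    ffom2 = cc_all + cc_large + cc_wE + 1.0 / max(rat, 0.1)
    return FomReport(cc_all=cc_all, cc_large=cc_large, cc_weak=cc_weak,
                     cc_wE=cc_wE, rat=rat, mean_Ecalc2_weak=mean_weak,
                     ffom2=float(ffom2), success=bool(ffom2 > threshold),
                     threshold=threshold)


def phase_error(phases_a: np.ndarray, phases_b: np.ndarray,
                weights: np.ndarray | None = None,
                d: np.ndarray | None = None, shells: int = 10) -> PhaseComparison:
    """Weighted mean absolute circular phase difference and map correlation.

    wMPE = sum(w |dphi|) / sum(w) in degrees, dphi wrapped to [-180, 180];
    the map correlation is evaluated in reciprocal space via Parseval with
    the weights doubling as Fourier amplitudes:
    mapCC = sum(w^2 cos dphi) / sum(w^2).  Origin/enantiomorph ambiguity is
    not searched — callers must pre-align the phase sets.
    """
    pa = np.asarray(phases_a, dtype=float)
    pb = np.asarray(phases_b, dtype=float)
    if pa.shape != pb.shape:
        raise ValueError("phase arrays must have matching shapes")
    w = np.ones_like(pa) if weights is None else np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        raise ValueError("total weight must be positive")
    dphi = (pa - pb + 180.0) % 360.0 - 180.0
    wmpe = float(np.sum(w * np.abs(dphi)) / np.sum(w))
    map_cc = float(np.sum(w**2 * np.cos(np.radians(dphi))) / np.sum(w**2))
    table = None
    if d is not None:
        d = np.asarray(d, dtype=float)
        order = np.argsort(-d)
        groups = np.array_split(order, shells)
        rows = []
        for g in groups:
            if len(g) == 0:
                continue
            rows.append({
                "d_max": d[g].max(), "d_min": d[g].min(), "n": len(g),
                "wmpe": float(np.sum(w[g] * np.abs(dphi[g])) / np.sum(w[g])),
                "map_cc": float(np.sum(w[g] ** 2 * np.cos(np.radians(dphi[g])))
                                / np.sum(w[g] ** 2)),
            })
        table = pd.DataFrame(rows)
    return PhaseComparison(wmpe=wmpe, map_cc=map_cc, shell_table=table)
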