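"""The linked dual-Poisson blink-count mixture ("fluorescence redundancy").

A quantum dot blinks into dark states stochastically, so the number of full
dark intervals per fixed-duration kymograph is Poisson. Two dots on one
complex almost never blink simultaneously: the joint dark probability is the
product of the individual ones, so a dimer's blink *rate* (per second) is the
square of the monomer's. With observation duration ``dur`` (s) and a monomer
expectation of ``bl`` blinks per kymograph,

    p_mon(n)   = bl^n e^-bl / n!
    bl_dim     = (bl / dur)^2 * dur          (hard constraint, never fitted)
    p_blink(n) = alpha * p_mon(n) + (1 - alpha) * p_dim(n)

A single shared ``bl`` and one mixture amplitude ``alpha`` per dataset are
fit simultaneously to two percentage histograms of blinks per kymograph by
least squares; ``100 * (1 - alpha)`` is the percent of molecules that are
dimers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

__all__ = [
    "BlinkHistogram",
    "DualPoissonFit",
    "poisson_pmf",
    "dimer_expected",
    "mixture_pmf",
    "fit_dual_poisson",
    "fit_single_poisson_grid",
    "fit_mixture_mle",
    "read_blink_counts_csv",
    "histogram_from_counts",
]


@dataclass
class BlinkHistogram:
    """Percentage-occurrence histogram of blinks per kymograph at one fixed
    observation duration."""

    duration_s: float
    percent_at_n: dict[int, float]
    n_kymographs: int

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        if not self.percent_at_n:
            raise ValueError("histogram must not be empty")
        for n in self.percent_at_n:
            if n < 0 or int(n) != n:
                raise ValueError("blink counts must be non-negative integers")
        total = sum(self.percent_at_n.values())
        if abs(total - 100.0) > 1e-6:
            raise ValueError(f"percentages must sum to 100 (got {total})")

    def percents_on_support(self, max_n: int) -> np.ndarray:
        """Dense percentage vector on n = 0..max_n (zero-padded)."""
        out = np.zeros(max_n + 1)
        for n, p in self.percent_at_n.items():
            out[int(n)] = p
        return out

    @property
    def max_n(self) -> int:
        return max(int(n) for n in self.percent_at_n)

    def approx_counts(self) -> np.ndarray:
        """Reconstruct per-kymograph counts (for bootstrap resampling)."""
        counts = []
        for n, p in sorted(self.percent_at_n.items()):
            counts.extend([int(n)] * int(round(p * self.n_kymographs / 100.0)))
        return np.array(counts, dtype=int)


@dataclass
class DualPoissonFit:
    """Result of the simultaneous two-dataset mixture fit.

    ``bl_dim`` is always recomputed from ``bl_mon`` through the squared-rate
    link; ``dimer_percent_per_dataset`` is ``100 * (1 - alpha)`` per dataset.
    """

    bl_mon: float
    bl_dim: float
    duration_s: float
    alpha_per_dataset: tuple[float, ...]
    dimer_percent_per_dataset: tuple[float, ...]
    r_squared: float
    se_per_dataset: tuple[float, ...] | None = None
    converged: bool = True
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "bl_mon": self.bl_mon,
            "bl_dim": self.bl_dim,
            "duration_s": self.duration_s,
            "alpha_per_dataset": list(self.alpha_per_dataset),
            "dimer_percent_per_dataset": list(self.dimer_percent_per_dataset),
            "dimer_percent_se_per_dataset": (
                list(self.se_per_dataset) if self.se_per_dataset else None
            ),
            "r_squared": self.r_squared,
            "converged": self.converged,
            "diagnostics": self.diagnostics,
        }


def poisson_pmf(n, expected: float):
    """P(N = n) for N ~ Poisson(expected), evaluated in log space.

    ``poisson_pmf(0, 0) = 1`` by the empty-product convention.
    """
    n_arr = np.asarray(n)
    if np.any(n_arr < 0) or not np.all(np.equal(np.mod(n_arr, 1), 0)):
        raise ValueError("n must be a non-negative integer")
    if expected < 0:
        raise ValueError("expected must be >= 0")
    out = stats.poisson.pmf(n_arr, expected)
    return float(out) if np.isscalar(n) else out


def dimer_expected(bl_mon: float, duration_s: float) -> float:
    """Expected dimer blinks per kymograph from the monomer expectation.

    Simultaneous darkness of two independent emitters requires both to be
    dark: the per-second dimer blink rate is the square of the monomer's, so
    ``bl_dim = (bl_mon / duration_s)^2 * duration_s``.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    if bl_mon < 0:
        raise ValueError("bl_mon must be >= 0")
    return (bl_mon / duration_s) ** 2 * duration_s


def mixture_pmf(n, bl_mon: float, alpha: float, duration_s: float):
    """The two-component blink mixture: alpha p_mon + (1 - alpha) p_dim."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    bl_dim = dimer_expected(bl_mon, duration_s)
    return alpha * poisson_pmf(n, bl_mon) + (1.0 - alpha) * poisson_pmf(n, bl_dim)


def _fast_pmf(support: np.ndarray, lam: float) -> np.ndarray:
    """Poisson pmf on an integer support, log-space, no scipy call overhead."""
    if lam <= 0.0:
        out = np.zeros_like(support)
        out[support == 0] = 1.0
        return out
    from scipy.special import gammaln

    return np.exp(support * np.log(lam) - lam - gammaln(support + 1.0))


def _residuals(params: np.ndarray, support: np.ndarray, obs: list[np.ndarray], duration: float):
    bl = params[0]
    p_mon = _fast_pmf(support, bl)
    p_dim = _fast_pmf(support, (bl / duration) ** 2 * duration)
    res = []
    for k, o in enumerate(obs):
        a = params[1 + k]
        res.append(100.0 * (a * p_mon + (1.0 - a) * p_dim) - o)
    return np.concatenate(res)


def _jacobian(params: np.ndarray, support: np.ndarray, obs: list[np.ndarray], duration: float):
    bl = params[0]
    lam_dim = (bl / duration) ** 2 * duration
    p_mon = _fast_pmf(support, bl)
    p_dim = _fast_pmf(support, lam_dim)
    # d pmf(n; lam)/d lam = pmf(n-1; lam) - pmf(n; lam)
    d_mon = np.concatenate(([0.0], p_mon[:-1])) - p_mon
    d_dim = (np.concatenate(([0.0], p_dim[:-1])) - p_dim) * (2.0 * bl / duration)
    m = support.size
    jac = np.zeros((m * len(obs), 1 + len(obs)))
    for k in range(len(obs)):
        a = params[1 + k]
        rows = slice(k * m, (k + 1) * m)
        jac[rows, 0] = 100.0 * (a * d_mon + (1.0 - a) * d_dim)
        jac[rows, 1 + k] = 100.0 * (p_mon - p_dim)
    return jac


def _solve(support, obs, duration, x0):
    n_ds = len(obs)
    lo = [1e-9] + [0.0] * n_ds
    hi = [np.inf] + [1.0] * n_ds
    return least_squares(
        _residuals,
        np.clip(x0, lo, hi),
        jac=_jacobian,
        bounds=(lo, hi),
        args=(support, obs, duration),
        method="trf",
    )


def fit_dual_poisson(
    hist_a: BlinkHistogram,
    hist_b: BlinkHistogram,
    n_bootstrap: int = 1000,
    seed: int = 0,
    counts_a: np.ndarray | None = None,
    counts_b: np.ndarray | None = None,
) -> DualPoissonFit:
    """Simultaneously fit the linked mixture to two blink histograms.

    Free parameters are the shared monomer expectation ``bl_mon`` and one
    amplitude per dataset; the dimer expectation is recomputed from
    ``bl_mon`` at every optimizer step, never fitted. The objective is the
    summed squared difference between observed and model percentages on the
    dense support n = 0..max observed (zero-padded), jointly over both
    datasets. 10 multi-starts (bl_mon log-spaced over [0.5, 30], amplitudes
    cycling 0.1..0.9) guard against local minima; ties go to the smallest
    ``bl_mon``. Bootstrap SEs of the dimer percents resample kymographs with
    replacement and re-solve warm-started from the point estimate.

    ``counts_a``/``counts_b`` optionally provide the raw per-kymograph counts
    for the bootstrap; otherwise they are reconstructed from the histogram.
    Set ``n_bootstrap=0`` to skip uncertainty estimation.
    """
    if abs(hist_a.duration_s - hist_b.duration_s) > 1e-9:
        raise ValueError("both histograms must share one duration")
    duration = hist_a.duration_s
    max_n = max(hist_a.max_n, hist_b.max_n)
    support = np.arange(max_n + 1, dtype=float)
    obs = [hist_a.percents_on_support(max_n), hist_b.percents_on_support(max_n)]

    bl_starts = np.geomspace(0.5, 30.0, 10)
    alpha_starts = np.linspace(0.1, 0.9, 10)
    solutions = []
    n_fail = 0
    for bl0, a0 in zip(bl_starts, alpha_starts):
        try:
            res = _solve(support, obs, duration, np.array([bl0, a0, a0]))
        except Exception:
            n_fail += 1
            continue
        solutions.append(res)
    best = None
    if solutions:
        min_cost = min(r.cost for r in solutions)
        # equivalent optima (e.g. a pure-Poisson dataset fits equally as the
        # monomer or the dimer branch): break the tie to the smallest bl_mon
        tol = max(1e-9, 1e-9 * min_cost)
        ties = [r for r in solutions if r.cost <= min_cost + tol]
        best = min(ties, key=lambda r: r.x[0])
    if best is None:
        return DualPoissonFit(
            bl_mon=np.nan,
            bl_dim=np.nan,
            duration_s=duration,
            alpha_per_dataset=(np.nan, np.nan),
            dimer_percent_per_dataset=(np.nan, np.nan),
            r_squared=np.nan,
            converged=False,
            diagnostics={"n_failed_starts": n_fail, "message": "all starts failed"},
        )

    bl = float(best.x[0])
    alphas = tuple(float(a) for a in best.x[1:])
    sse = float(2.0 * best.cost)
    all_obs = np.concatenate(obs)
    sst = float(np.sum((all_obs - all_obs.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else np.nan

    ses = None
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        raw = [
            np.asarray(counts_a) if counts_a is not None else hist_a.approx_counts(),
            np.asarray(counts_b) if counts_b is not None else hist_b.approx_counts(),
        ]
        boot = np.full((n_bootstrap, 2), np.nan)
        for i in range(n_bootstrap):
            rs_obs = []
            rs_max = 0
            samples = [rng.choice(c, size=c.size, replace=True) for c in raw]
            rs_max = max(int(s.max()) for s in samples)
            sup = np.arange(max(rs_max, 1) + 1, dtype=float)
            for s in samples:
                pct = np.bincount(s, minlength=sup.size) * (100.0 / s.size)
                rs_obs.append(pct.astype(float))
            try:
                res = _solve(sup, rs_obs, duration, np.array([bl, *alphas]))
                boot[i] = 100.0 * (1.0 - res.x[1:])
            except Exception:
                continue
        ok = np.isfinite(boot).all(axis=1)
        ses = tuple(float(v) for v in boot[ok].std(axis=0, ddof=1))

    return DualPoissonFit(
        bl_mon=bl,
        bl_dim=dimer_expected(bl, duration),
        duration_s=duration,
        alpha_per_dataset=alphas,
        dimer_percent_per_dataset=tuple(100.0 * (1.0 - a) for a in alphas),
        r_squared=r2,
        se_per_dataset=ses,
        converged=bool(best.success),
        diagnostics={
            "sse": sse,
            "n_failed_starts": n_fail,
            "n_bootstrap": n_bootstrap,
            "seed": seed,
            "optimizer_status": int(best.status),
        },
    )


def fit_single_poisson_grid(
    hist: BlinkHistogram, bl_grid: np.ndarray | None = None
) -> tuple[float, float]:
    """Brute-force one-parameter Poisson percentage fit (cross-check oracle).

    Scans ``bl`` over a grid (default 0.01..30 step 0.001) and returns the
    (bl, sse) minimizing the summed squared percentage difference.
    """
    if bl_grid is None:
        bl_grid = np.arange(0.01, 30.0, 0.001)
    support = np.arange(hist.max_n + 1)
    obs = hist.percents_on_support(hist.max_n)
    pmf = stats.poisson.pmf(support[None, :], bl_grid[:, None]) * 100.0
    sse = ((pmf - obs[None, :]) ** 2).sum(axis=1)
    i = int(np.argmin(sse))
    return float(bl_grid[i]), float(sse[i])


def fit_mixture_mle(
    counts: np.ndarray, duration_s: float, alpha0: float = 0.5, bl0: float = 10.0
) -> tuple[float, float]:
    """Maximum-likelihood fit of (bl_mon, alpha) on raw counts — a
    cross-check utility only; the least-squares percentage fit is the primary
    estimator."""
    from scipy.optimize import minimize

    counts = np.asarray(counts, dtype=int)

    def nll(x):
        bl, a = x
        p = mixture_pmf(counts, bl, a, duration_s)
        return -np.sum(np.log(np.clip(p, 1e-300, None)))

    res = minimize(
        nll, x0=[bl0, alpha0], bounds=[(1e-6, None), (0.0, 1.0)], method="L-BFGS-B"
    )
    return float(res.x[0]), float(res.x[1])


def read_blink_counts_csv(path: str | Path) -> np.ndarray:
    """Read a per-kymograph blink-count CSV (kymograph_id,blink_count)."""
    df = pd.read_csv(path)
    return df["blink_count"].to_numpy(dtype=int)


def histogram_from_counts(counts: np.ndarray, duration_s: float) -> BlinkHistogram:
    counts = np.asarray(counts, dtype=int)
    if counts.size == 0:
        raise ValueError("no counts")
    values, freq = np.unique(counts, return_counts=True)
    percent = {int(v): 100.0 * f / counts.size for v, f in zip(values, freq)}
    return BlinkHistogram(
        duration_s=duration_s, percent_at_n=percent, n_kymographs=counts.size
    )


def write_fit_report(fit: DualPoissonFit, path: str | Path) -> None:
    Path(path).write_text(json.dumps(fit.to_dict(), indent=1, sort_keys=True))


def fitted_vs_observed(
    fit: DualPoissonFit, hists: list[BlinkHistogram], labels: list[str] | None = None
) -> pd.DataFrame:
    """Observed vs fitted percentages per dataset (for plotting/export)."""
    max_n = max(h.max_n for h in hists)
    support = np.arange(max_n + 1)
    rows = []
    labels = labels or [f"dataset_{i}" for i in range(len(hists))]
    for h, a, lab in zip(hists, fit.alpha_per_dataset, labels):
        obs = h.percents_on_support(max_n)
        model = 100.0 * mixture_pmf(support, fit.bl_mon, a, fit.duration_s)
        for n in support:
            rows.append(
                {
                    "dataset": lab,
                    "n_blinks": int(n),
                    "observed_percent": obs[n],
                    "fitted_percent": model[n],
                }
            )
    return pd.DataFrame(rows)
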