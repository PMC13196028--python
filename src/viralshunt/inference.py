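"""Staged weighted least-squares parametrization of the lysis-recycling model.

The model is fitted to replicate OD600 growth curves in three sequential
stages, each constraining the parameters that the corresponding subset of the
data actually informs:

1. **Glucose kinetics** — ``mu_g_max`` and ``K_S_g`` from the 100WT
   (WT-only) culture, which never lyses.
2. **Lysis dynamics** — the lysis rate ``delta`` and the integer number of
   lysis compartments ``k`` from the early time points of the 100TS
   (TS-only) culture, with stage-1 parameters frozen.  ``k`` is found by
   exhaustive search over an integer grid with a nested 1-D bounded
   optimization of ``delta``; ties break toward smaller ``k``.
3. **Lysate dynamics** — ``mu_l_max``, ``K_S_l``, and the recycling
   efficiency ``epsilon`` from the mixed cultures, with stages 1-2 frozen,
   so that only populations that actually experience recycling inform the
   lysate parameters.

Residuals are log-scale and weighted by the replicate standard deviation
(floored to stabilize near-noiseless points):

    r = [ln(OD_mean) - ln(OD_model)] / max(SD, sd_floor)

Model curves are evaluated by the ODE solver at the observation times
themselves, so the "interpolate the model to the data grid" step is exact.
Uncertainty comes from a nonparametric bootstrap: replicate columns are
resampled with replacement per mix, the whole three-stage fit is re-run, and
95% CIs are the 2.5th-97.5th percentiles of the bootstrap distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize_scalar

from .dynamics import (
    DEFAULT_GLUCOSE_OD,
    InitialState,
    ModelParams,
    SolverConfig,
    Trajectory,
    simulate,
)

__all__ = [
    "DataError",
    "UsageError",
    "ConfigError",
    "GrowthCurveDataset",
    "FitConfig",
    "FitResult",
    "ThreeStageFit",
    "BootstrapResult",
    "weighted_log_residuals",
    "fit_stage1",
    "fit_stage2",
    "fit_stage3",
    "run_three_stage_fit",
    "bootstrap_cis",
    "fit_diagnostics",
    "normalized_delta_biomass",
]


class DataError(ValueError):
    """Input data do not support the requested operation."""


class UsageError(ValueError):
    """Operation called on the wrong kind of dataset."""


class ConfigError(ValueError):
    """Invalid fit configuration."""


@dataclass(frozen=True)
class GrowthCurveDataset:
    """Replicate OD600 time series for one inoculum mix.

    ``replicates`` has shape ``(n_times, n_replicates)``; ``od_mean`` and
    ``od_sd`` (sample SD, ddof=1; zero for a single replicate) are derived.
    """

    mix_label: str
    wt_fraction: float
    ts_fraction: float
    initial_od: float
    times: np.ndarray
    replicates: np.ndarray

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        reps = np.asarray(self.replicates, dtype=float)
        if reps.ndim != 2 or reps.shape[0] != times.size:
            raise DataError("replicates must be a (n_times, n_replicates) matrix")
        if np.any(np.diff(times) <= 0):
            raise DataError("times must be strictly increasing")
        if np.any(reps <= 0):
            raise DataError("OD observations must be positive")
        if not np.isclose(self.wt_fraction + self.ts_fraction, 1.0):
            raise DataError("wt_fraction + ts_fraction must equal 1")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "replicates", reps)

    @property
    def n_replicates(self) -> int:
        return self.replicates.shape[1]

    @property
    def od_mean(self) -> np.ndarray:
        return self.replicates.mean(axis=1)

    @property
    def od_sd(self) -> np.ndarray:
        if self.n_replicates < 2:
            return np.zeros(self.times.size)
        return self.replicates.std(axis=1, ddof=1)

    def resample_replicates(self, rng: np.random.Generator) -> "GrowthCurveDataset":
        """Bootstrap draw: resample replicate columns with replacement."""
        idx = rng.integers(0, self.n_replicates, size=self.n_replicates)
        return replace(self, replicates=self.replicates[:, idx])


_DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "mu_g_max": (1e-4, 5.0),
    "K_S_g": (1e-6, 1.0),
    "mu_l_max": (1e-4, 5.0),
    # lysate concentrations stay well below half-saturation in this system
    # (uptake is near-linear in C_l); bounding K_S_l away from zero excludes
    # the degenerate saturated-uptake mode the data cannot distinguish
    "K_S_l": (1e-2, 1.0),
    "delta": (1e-3, 10.0),
    "epsilon": (0.0, 1.0),
}


@dataclass(frozen=True)
class FitConfig:
    """Bounds, initial guesses, and numerical settings for the staged fit.

    Bounds default to broad, positivity-respecting boxes; rate-like and
    affinity-like parameters are optimized on a log10 scale (trust-region
    reflective least squares), ``epsilon`` on its natural [0, 1] scale.
    """

    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_BOUNDS)
    )
    sd_floor: float = 1e-3
    n_early_points: int = 4
    k_grid: tuple[int, ...] = tuple(range(1, 51))
    c_g0: float | None = None  # None: saturation OD minus inoculum OD of 100WT
    ts_lysate_growth: bool = False
    # initial guesses; None means derive from the data
    mu_g_max0: float | None = None
    K_S_g0: float = 0.01
    delta0: float | None = None
    k0: int = 6
    mu_l_max0: float = 0.5
    K_S_l0: float = 0.1
    epsilon0: float = 0.3
    ftol: float = 1e-10
    xtol: float = 1e-10
    solver: SolverConfig = field(default_factory=SolverConfig)

    def bound(self, name: str) -> tuple[float, float]:
        return self.bounds.get(name, _DEFAULT_BOUNDS[name])


@dataclass(frozen=True)
class FitResult:
    """Outcome of one fitting stage.

    ``estimates`` holds the stage's free parameters; ``fixed`` carries values
    frozen from earlier stages (and the inferred initial glucose pool).
    AIC/BIC use the known-variance Gaussian form on the standardized
    residuals of the weighted fit: ``AIC = RSS + 2p``, ``BIC = RSS + p ln n``.
    """

    stage: int
    estimates: dict[str, float]
    bounds: dict[str, tuple[float, float]]
    rss: float
    n_obs: int
    n_params: int
    residuals: np.ndarray = field(repr=False)
    fixed: dict[str, float] = field(default_factory=dict)
    ci95: dict[str, tuple[float, float]] | None = None

    @property
    def aic(self) -> float:
        return self.rss + 2.0 * self.n_params

    @property
    def bic(self) -> float:
        return self.rss + self.n_params * np.log(self.n_obs)


class ThreeStageFit(NamedTuple):
    stage1: FitResult
    stage2: FitResult
    stage3: FitResult

    def model_params(self, ts_lysate_growth: bool = False) -> ModelParams:
        """Consolidate the stage estimates into a ModelParams."""
        return ModelParams(
            mu_g_max=self.stage1.estimates["mu_g_max"],
            K_S_g=self.stage1.estimates["K_S_g"],
            mu_l_max=self.stage3.estimates["mu_l_max"],
            K_S_l=self.stage3.estimates["K_S_l"],
            delta=self.stage2.estimates["delta"],
            k=int(self.stage2.estimates["k"]),
            epsilon=self.stage3.estimates["epsilon"],
            ts_lysate_growth=ts_lysate_growth,
        )

    @property
    def c_g0(self) -> float:
        return self.stage1.fixed["c_g0"]

    def table(self) -> pd.DataFrame:
        """Consolidated parameter table across stages."""
        rows = []
        for res in self:
            for name, value in res.estimates.items():
                lo, hi = res.bounds.get(name, (np.nan, np.nan))
                ci = res.ci95.get(name) if res.ci95 else (np.nan, np.nan)
                rows.append(
                    {
                        "stage": res.stage,
                        "parameter": name,
                        "estimate": value,
                        "bound_lo": lo,
                        "bound_hi": hi,
                        "ci95_lo": ci[0],
                        "ci95_hi": ci[1],
                        "rss": res.rss,
                        "aic": res.aic,
                        "bic": res.bic,
                    }
                )
        return pd.DataFrame(rows)


def weighted_log_residuals(
    dataset: GrowthCurveDataset, traj: Trajectory, sd_floor: float = 1e-3
) -> np.ndarray:
    """Log-scale residuals weighted by the (floored) replicate SD.

    The model od is interpolated linearly in time to the observation grid
    (exact when the trajectory was evaluated at those times).
    """
    if traj.times[0] > dataset.times[0] or traj.times[-1] < dataset.times[-1]:
        raise DataError("trajectory does not span the observation times")
    od_model = np.interp(dataset.times, traj.times, traj.od)
    od_mean = dataset.od_mean
    if np.any(od_mean <= 0) or np.any(od_model <= 0):
        raise DataError("nonpositive OD encountered in residual computation")
    w = np.maximum(dataset.od_sd, sd_floor)
    return (np.log(od_mean) - np.log(od_model)) / w


def _residuals_for(
    dataset: GrowthCurveDataset,
    params: ModelParams,
    c_g0: float,
    cfg: FitConfig,
    times: np.ndarray | None = None,
) -> np.ndarray:
    """Forward-simulate one mix at its observation times and form residuals."""
    times = dataset.times if times is None else times
    init = InitialState(
        B_WT0=dataset.wt_fraction * dataset.initial_od,
        TS0=dataset.ts_fraction * dataset.initial_od,
        C_g0=c_g0,
    )
    t_eval = times if times[0] == 0.0 else np.concatenate(([0.0], times))
    traj = simulate(params, init, t_end=times[-1], solver_cfg=cfg.solver, t_eval=t_eval)
    od_model = traj.od if times[0] == 0.0 else traj.od[1:]
    # extreme candidate parameters can drive a fully lysed culture's od to
    # the solver's negative-excursion scale; floor it so the log residual
    # stays defined (and enormous, steering the optimizer away)
    od_model = np.maximum(od_model, 1e-12)
    od_mean = dataset.od_mean[: times.size]
    w = np.maximum(dataset.od_sd[: times.size], cfg.sd_floor)
    return (np.log(od_mean) - np.log(od_model)) / w


def _log_slope_guess(times: np.ndarray, od: np.ndarray) -> float:
    """Early-window log-slope of the mean OD, for initial growth-rate guesses."""
    n = min(3, times.size)
    if n < 2:
        return 0.5
    return float((np.log(od[n - 1]) - np.log(od[0])) / (times[n - 1] - times[0]))


def _clip_to(value: float, lo: float, hi: float) -> float:
    return float(min(max(value, lo), hi))


def fit_stage1(dataset_100wt: GrowthCurveDataset, cfg: FitConfig | None = None) -> FitResult:
    """Stage 1: glucose kinetics (``mu_g_max``, ``K_S_g``) from WT-only data.

    The initial glucose pool is taken as the saturation OD minus the
    inoculum OD unless ``cfg.c_g0`` overrides it.
    """
    cfg = cfg or FitConfig()
    if dataset_100wt.ts_fraction > 0:
        raise UsageError("stage 1 requires a WT-only (TS-free) dataset")
    c_g0 = cfg.c_g0
    if c_g0 is None:
        c_g0 = float(dataset_100wt.od_mean.max() - dataset_100wt.initial_od)
        if c_g0 <= 0:
            raise DataError("cannot infer initial glucose: no OD increase in data")

    b_mu = cfg.bound("mu_g_max")
    b_ks = cfg.bound("K_S_g")
    mu0 = cfg.mu_g_max0
    if mu0 is None:
        mu0 = _log_slope_guess(dataset_100wt.times, dataset_100wt.od_mean)
    x0 = np.log10([_clip_to(mu0, *b_mu), _clip_to(cfg.K_S_g0, *b_ks)])

    def resid(x: np.ndarray) -> np.ndarray:
        mu_g, ks_g = 10.0 ** x
        params = ModelParams(
            mu_g_max=mu_g, K_S_g=ks_g, mu_l_max=0.0, K_S_l=1.0, delta=0.0, k=1,
            epsilon=0.0, ts_lysate_growth=cfg.ts_lysate_growth,
        )
        return _residuals_for(dataset_100wt, params, c_g0, cfg)

    sol = least_squares(
        resid,
        x0,
        bounds=(np.log10([b_mu[0], b_ks[0]]), np.log10([b_mu[1], b_ks[1]])),
        method="trf",
        ftol=cfg.ftol,
        xtol=cfg.xtol,
    )
    mu_g, ks_g = 10.0 ** sol.x
    r = resid(sol.x)
    return FitResult(
        stage=1,
        estimates={"mu_g_max": float(mu_g), "K_S_g": float(ks_g)},
        bounds={"mu_g_max": b_mu, "K_S_g": b_ks},
        rss=float(r @ r),
        n_obs=r.size,
        n_params=2,
        residuals=r,
        fixed={"c_g0": c_g0},
    )


def fit_stage2(
    dataset_100ts: GrowthCurveDataset,
    stage1: FitResult,
    n_early_points: int | None = None,
    cfg: FitConfig | None = None,
) -> FitResult:
    """Stage 2: lysis rate ``delta`` and compartment number ``k`` from the
    early window of TS-only data (default: the first four time points).

    ``k`` is scanned exhaustively over ``cfg.k_grid`` with a nested bounded
    1-D optimization of ``log10(delta)``; ties break toward smaller ``k``.
    """
    cfg = cfg or FitConfig()
    if dataset_100ts.wt_fraction > 0:
        raise UsageError("stage 2 requires a TS-only dataset")
    n_early = cfg.n_early_points if n_early_points is None else n_early_points
    if dataset_100ts.times.size < n_early:
        raise DataError(
            f"stage 2 needs at least {n_early} time points, "
            f"got {dataset_100ts.times.size}"
        )
    t_early = dataset_100ts.times[:n_early]
    mu_g = stage1.estimates["mu_g_max"]
    ks_g = stage1.estimates["K_S_g"]
    c_g0 = stage1.fixed["c_g0"]
    b_d = cfg.bound("delta")
    lo, hi = np.log10(b_d)

    def rss_for(k: int, log_delta: float) -> float:
        # TS-only biomass is independent of the lysate parameters in the
        # default model variant, so mu_l is simply switched off here.
        params = ModelParams(
            mu_g_max=mu_g, K_S_g=ks_g, mu_l_max=0.0, K_S_l=1.0,
            delta=10.0 ** log_delta, k=k, epsilon=0.0,
            ts_lysate_growth=cfg.ts_lysate_growth,
        )
        r = _residuals_for(dataset_100ts, params, c_g0, cfg, times=t_early)
        return float(r @ r)

    best: tuple[float, int, float] | None = None
    for k in cfg.k_grid:
        opt = minimize_scalar(
            lambda x, k=k: rss_for(k, x),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-10, "maxiter": 500},
        )
        if best is None or opt.fun < best[0]:
            best = (float(opt.fun), int(k), float(opt.x))
    rss, k_hat, log_d_hat = best
    delta_hat = 10.0 ** log_d_hat
    params = ModelParams(
        mu_g_max=mu_g, K_S_g=ks_g, mu_l_max=0.0, K_S_l=1.0, delta=delta_hat,
        k=k_hat, epsilon=0.0, ts_lysate_growth=cfg.ts_lysate_growth,
    )
    r = _residuals_for(dataset_100ts, params, c_g0, cfg, times=t_early)
    return FitResult(
        stage=2,
        estimates={"delta": float(delta_hat), "k": float(k_hat)},
        bounds={"delta": b_d, "k": (cfg.k_grid[0], cfg.k_grid[-1])},
        rss=float(r @ r),
        n_obs=r.size,
        n_params=2,
        residuals=r,
        fixed={"mu_g_max": mu_g, "K_S_g": ks_g, "c_g0": c_g0},
    )


def fit_stage3(
    datasets_mixed: Sequence[GrowthCurveDataset],
    stage1: FitResult,
    stage2: FitResult,
    cfg: FitConfig | None = None,
) -> FitResult:
    """Stage 3: lysate parameters (``mu_l_max``, ``K_S_l``, ``epsilon``)
    from the mixed WT-TS cultures, pooling residuals across mixes."""
    cfg = cfg or FitConfig()
    datasets_mixed = list(datasets_mixed)
    if not datasets_mixed:
        raise UsageError("stage 3 requires at least one mixed dataset")
    for ds in datasets_mixed:
        if ds.wt_fraction == 0 or ds.ts_fraction == 0:
            raise UsageError(
                f"stage 3 accepts only mixed populations; got monoculture "
                f"'{ds.mix_label}'"
            )
    mu_g = stage1.estimates["mu_g_max"]
    ks_g = stage1.estimates["K_S_g"]
    c_g0 = stage1.fixed["c_g0"]
    delta = stage2.estimates["delta"]
    k = int(stage2.estimates["k"])
    b_ml = cfg.bound("mu_l_max")
    b_kl = cfg.bound("K_S_l")
    b_e = cfg.bound("epsilon")

    def resid(x: np.ndarray) -> np.ndarray:
        mu_l, ks_l = 10.0 ** x[:2]
        eps = x[2]
        params = ModelParams(
            mu_g_max=mu_g, K_S_g=ks_g, mu_l_max=mu_l, K_S_l=ks_l,
            delta=delta, k=k, epsilon=eps, ts_lysate_growth=cfg.ts_lysate_growth,
        )
        return np.concatenate(
            [_residuals_for(ds, params, c_g0, cfg) for ds in datasets_mixed]
        )

    x0 = np.array(
        [
            np.log10(_clip_to(cfg.mu_l_max0, *b_ml)),
            np.log10(_clip_to(cfg.K_S_l0, *b_kl)),
            _clip_to(cfg.epsilon0, *b_e),
        ]
    )
    sol = least_squares(
        resid,
        x0,
        bounds=(
            [np.log10(b_ml[0]), np.log10(b_kl[0]), b_e[0]],
            [np.log10(b_ml[1]), np.log10(b_kl[1]), b_e[1]],
        ),
        method="trf",
        ftol=cfg.ftol,
        xtol=cfg.xtol,
    )
    mu_l, ks_l = 10.0 ** sol.x[:2]
    eps = float(sol.x[2])
    r = resid(sol.x)
    return FitResult(
        stage=3,
        estimates={"mu_l_max": float(mu_l), "K_S_l": float(ks_l), "epsilon": eps},
        bounds={"mu_l_max": b_ml, "K_S_l": b_kl, "epsilon": b_e},
        rss=float(r @ r),
        n_obs=r.size,
        n_params=3,
        residuals=r,
        fixed={
            "mu_g_max": mu_g, "K_S_g": ks_g, "c_g0": c_g0,
            "delta": delta, "k": float(k),
        },
    )


def _partition(datasets: Iterable[GrowthCurveDataset]):
    """Split datasets into (100WT, 100TS, mixed) by inoculum composition."""
    wt_only, ts_only, mixed = [], [], []
    for ds in datasets:
        if ds.ts_fraction == 0:
            wt_only.append(ds)
        elif ds.wt_fraction == 0:
            ts_only.append(ds)
        else:
            mixed.append(ds)
    # the reference WT-only culture is the one at the full inoculum OD
    ref_wt = max(wt_only, key=lambda d: d.initial_od) if wt_only else None
    ts = ts_only[0] if ts_only else None
    return ref_wt, ts, mixed


def run_three_stage_fit(
    datasets: Iterable[GrowthCurveDataset] | Mapping[str, GrowthCurveDataset],
    cfg: FitConfig | None = None,
) -> ThreeStageFit:
    """Run the three fitting stages in order, threading frozen parameters.

    ``datasets`` must include a WT-only culture, a TS-only culture, and at
    least one mixed culture; a ``DataError`` names whatever is missing.
    """
    cfg = cfg or FitConfig()
    if isinstance(datasets, Mapping):
        datasets = list(datasets.values())
    ref_wt, ts, mixed = _partition(datasets)
    missing = []
    if ref_wt is None:
        missing.append("a WT-only (100WT) dataset for stage 1")
    if ts is None:
        missing.append("a TS-only (100TS) dataset for stage 2")
    if not mixed:
        missing.append("a mixed WT-TS dataset for stage 3")
    if missing:
        raise DataError("three-stage fit is missing " + " and ".join(missing))
    s1 = fit_stage1(ref_wt, cfg)
    s2 = fit_stage2(ts, s1, cfg=cfg)
    s3 = fit_stage3(mixed, s1, s2, cfg)
    return ThreeStageFit(s1, s2, s3)


@dataclass(frozen=True)
class BootstrapResult:
    """Point fit plus bootstrap draws and percentile CIs."""

    point: ThreeStageFit
    draws: pd.DataFrame
    ci95: dict[str, tuple[float, float]]
    n_boot: int
    seed: int | None

    def ci(self, level: float) -> dict[str, tuple[float, float]]:
        """Percentile CI at another nominal level from the stored draws."""
        alpha = (100.0 - level) / 2.0
        return {
            name: (
                float(np.percentile(self.draws[name], alpha)),
                float(np.percentile(self.draws[name], 100.0 - alpha)),
            )
            for name in self.draws.columns
        }

    def fits_with_ci(self) -> ThreeStageFit:
        """The point-estimate FitResults with per-stage ci95 attached."""
        by_stage = {
            1: ("mu_g_max", "K_S_g"),
            2: ("delta", "k"),
            3: ("mu_l_max", "K_S_l", "epsilon"),
        }
        out = []
        for res in self.point:
            ci = {name: self.ci95[name] for name in by_stage[res.stage]}
            out.append(replace(res, ci95=ci))
        return ThreeStageFit(*out)


def bootstrap_cis(
    datasets: Iterable[GrowthCurveDataset] | Mapping[str, GrowthCurveDataset],
    cfg: FitConfig | None = None,
    n_boot: int = 1000,
    seed: int | None = 0,
    fix_k: bool = False,
    ci_level: float = 95.0,
) -> BootstrapResult:
    """Nonparametric bootstrap over replicate columns, per mix.

    Each draw resamples every dataset's replicate columns with replacement
    (independently across mixes), recomputes means/SDs, and re-runs the
    three-stage fit warm-started from the point estimates.  With ``fix_k``
    the integer compartment number is held at its point estimate during the
    refits (a common treatment of a discrete structural parameter that makes
    large bootstrap runs cheap); the default re-scans the full k grid.
    """
    if n_boot < 1:
        raise ConfigError("n_boot must be >= 1")
    cfg = cfg or FitConfig()
    if isinstance(datasets, Mapping):
        datasets = list(datasets.values())
    datasets = list(datasets)
    point = run_three_stage_fit(datasets, cfg)

    k_hat = int(point.stage2.estimates["k"])
    warm = replace(
        cfg,
        mu_g_max0=point.stage1.estimates["mu_g_max"],
        K_S_g0=point.stage1.estimates["K_S_g"],
        mu_l_max0=point.stage3.estimates["mu_l_max"],
        K_S_l0=point.stage3.estimates["K_S_l"],
        epsilon0=point.stage3.estimates["epsilon"],
        c_g0=None,
        k_grid=(k_hat,) if fix_k else cfg.k_grid,
    )
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_boot):
        resampled = [ds.resample_replicates(rng) for ds in datasets]
        fit = run_three_stage_fit(resampled, warm)
        rows.append(
            {
                "mu_g_max": fit.stage1.estimates["mu_g_max"],
                "K_S_g": fit.stage1.estimates["K_S_g"],
                "delta": fit.stage2.estimates["delta"],
                "k": fit.stage2.estimates["k"],
                "mu_l_max": fit.stage3.estimates["mu_l_max"],
                "K_S_l": fit.stage3.estimates["K_S_l"],
                "epsilon": fit.stage3.estimates["epsilon"],
            }
        )
    draws = pd.DataFrame(rows)
    alpha = (100.0 - ci_level) / 2.0
    ci = {
        name: (
            float(np.percentile(draws[name], alpha)),
            float(np.percentile(draws[name], 100.0 - alpha)),
        )
        for name in draws.columns
    }
    return BootstrapResult(point=point, draws=draws, ci95=ci, n_boot=n_boot, seed=seed)


def fit_diagnostics(result: FitResult) -> tuple[float, float, float]:
    """(RSS, AIC, BIC) from the stage's standardized residuals.

    Known-variance Gaussian form with constants dropped: ``AIC = RSS + 2p``
    and ``BIC = RSS + p ln n`` where p counts the stage's free parameters.
    """
    rss = float(result.residuals @ result.residuals)
    p = result.n_params
    n = result.n_obs
    return rss, rss + 2.0 * p, rss + p * np.log(n)


def normalized_delta_biomass(series: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Biomass difference normalized to the 100WT control:
    ``(od - od_ref) / od_ref`` pointwise on a shared time grid."""
    series = np.asarray(series, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if series.shape != reference.shape:
        raise ValueError("series and reference must share a time grid")
    if np.any(reference == 0):
        raise ValueError("reference biomass must be nonzero")
    return (series - reference) / reference
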