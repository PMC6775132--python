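"""Hill-kinetics screen of metabolite-TF pairs.

For each pair, the sign of the linear correlation picks the model form:
activation y = y_max * x^h / (x^h + K_H^h) or inhibition
y = y_max * K_H^h / (x^h + K_H^h), with activation constant K_H (µM)
and Hill coefficient h capped at 10. Because inferred TF activities are
z-scored (and so can be negative) the Hill output is mapped through an
affine layer: given (K_H, h) the transform u(x) is computed and the
scale/offset (y_max, baseline) solved by ordinary least squares, leaving
a two-parameter nonlinear problem solved from 50 random starts. Each
pair is additionally fit with the TF activity shifted back by one time
point (expression responds after the metabolite moves); the better R^2
wins. R^2 is 1 - SS_res/SS_tot of measured activity against transformed
metabolite levels; Pearson's squared correlation is reported alongside.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .model_io import MetaboliteTable
from .nca import ActivityEnsemble

logger = logging.getLogger(__name__)

__all__ = [
    "HillModel",
    "HillFitResult",
    "HillFitSettings",
    "AlignedSeries",
    "align_series",
    "select_mode",
    "hill_transform",
    "fit_hill_pair",
    "screen_all_pairs",
    "results_table",
]

MIN_POINTS = 6
_H_FLOOR = 1e-3


@dataclass
class HillFitSettings:
    n_starts: int = 50
    h_max: float = 10.0
    lag_candidates: tuple[int, ...] = (0, -1)
    r2_threshold: float = 0.75
    align_window: float = 1.0  # hours; max grid mismatch when pairing
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if not set(self.lag_candidates) <= {0, -1}:
            raise ValueError("lags limited to 0 (none) and -1 (one point)")


@dataclass
class HillModel:
    mode: str  # "activation" | "inhibition"
    K_H: float  # µM
    h: float
    y_max: float
    baseline: float

    def __post_init__(self) -> None:
        if self.mode not in ("activation", "inhibition"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not self.K_H > 0:
            raise ValueError("K_H must be positive")
        if not 0 < self.h <= 10 + 1e-9:
            raise ValueError("Hill coefficient must lie in (0, 10]")

    def predict(self, x: np.ndarray) -> np.ndarray:
        u = hill_transform(x, self.K_H, self.h, self.mode)
        return self.y_max * u + self.baseline


@dataclass
class HillFitResult:
    metabolite_id: str
    regulator_id: str
    model: HillModel | None
    lag_applied: int  # 0 or -1
    r_squared: float
    r_squared_pearson: float = np.nan
    n_multistarts: int = 0
    best_start_seed: int | None = None
    n_points: int = 0
    flags: list[str] = field(default_factory=list)

    @property
    def failed(self) -> bool:
        return self.model is None

    def passes(self, threshold: float = 0.75) -> bool:
        return (not self.failed) and self.r_squared > threshold


@dataclass
class AlignedSeries:
    """Metabolite and activity profiles paired on the transcriptome grid."""

    metabolites: pd.DataFrame  # metabolites x matched time points (µM means)
    activities: pd.DataFrame  # regulators x matched time points (z-score)
    time_points: np.ndarray
    n_dropped: int = 0
    skipped_reason: str | None = None


def align_series(
    metabolites: MetaboliteTable,
    activities: ActivityEnsemble,
    window: float = 1.0,
) -> AlignedSeries:
    """Pair the two time grids.

    For each transcriptome time point, take the replicate-mean metabolite
    value at the nearest metabolome time point within ``window`` hours;
    transcriptome points without a match are dropped and counted. Series
    shorter than six points after matching are unusable for fitting.
    """
    met_profiles = metabolites.mean_profiles()
    met_times = np.asarray(met_profiles.columns, float)
    act_times = np.asarray(activities.time_points, float)

    matched_cols, met_cols = [], []
    for i, t in enumerate(act_times):
        j = int(np.argmin(np.abs(met_times - t)))
        if abs(met_times[j] - t) <= window:
            matched_cols.append(i)
            met_cols.append(j)
    n_dropped = len(act_times) - len(matched_cols)

    if len(matched_cols) < MIN_POINTS:
        return AlignedSeries(
            metabolites=pd.DataFrame(index=met_profiles.index),
            activities=pd.DataFrame(index=activities.mean.index),
            time_points=np.empty(0),
            n_dropped=n_dropped,
            skipped_reason=(
                f"only {len(matched_cols)} common time points within "
                f"{window} h (need {MIN_POINTS})"
            ),
        )

    times = act_times[matched_cols]
    met = met_profiles.iloc[:, met_cols]
    met.columns = times
    act = activities.mean.iloc[:, matched_cols]
    act.columns = times
    return AlignedSeries(met, act, times, n_dropped=n_dropped)


def select_mode(x: np.ndarray, y: np.ndarray) -> tuple[str, list[str]]:
    """Pick the Hill form from the sign of the linear correlation."""
    flags: list[str] = []
    if np.std(x) == 0 or np.std(y) == 0:
        return "activation", ["degenerate_constant_series"]
    r = stats.pearsonr(x, y).statistic
    if abs(r) < 1e-12:
        flags.append("zero_correlation_tiebreak")
        return "activation", flags
    return ("activation" if r > 0 else "inhibition"), flags


def hill_transform(
    x: np.ndarray, K_H: float, h: float, mode: str
) -> np.ndarray:
    """u(x) = x^h/(x^h + K_H^h) (activation) or K_H^h/(x^h + K_H^h).

    Computed via t = (x/K_H)^h to stay finite for large h.
    """
    x = np.asarray(x, float)
    with np.errstate(over="ignore"):
        t = np.power(np.maximum(x, 0.0) / K_H, h)
    act = np.where(np.isinf(t), 1.0, t / (1.0 + t))
    return act if mode == "activation" else 1.0 - act


def _affine_fit(u: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """OLS of y on u: returns (y_max, baseline, ss_res)."""
    design = np.column_stack([u, np.ones_like(u)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return float(coef[0]), float(coef[1]), float(resid @ resid)


def _objective(params: np.ndarray, x: np.ndarray, y: np.ndarray, mode: str
               ) -> float:
    log_k, h = params
    u = hill_transform(x, float(np.exp(log_k)), h, mode)
    if np.ptp(u) == 0:  # saturated transform: affine fit on a constant
        return float(np.sum((y - y.mean()) ** 2))
    return _affine_fit(u, y)[2]


def _fit_one_lag(
    x: np.ndarray,
    y: np.ndarray,
    mode: str,
    settings: HillFitSettings,
    rng: np.random.Generator,
) -> tuple[HillModel | None, float, int | None]:
    """Multistart nested fit for one (x, y) pairing; returns best model,
    its SS_res, and the index of the winning start."""
    positive = x[x > 0]
    if positive.size == 0:
        return None, np.inf, None
    k_lo, k_hi = positive.min() / 10.0, 10.0 * x.max()
    bounds = [
        (np.log(k_lo / 10.0), np.log(k_hi * 10.0)),
        (_H_FLOOR, settings.h_max),
    ]

    best: tuple[float, float, float] | None = None  # ss, logk, h
    best_start = None
    for start in range(settings.n_starts):
        log_k0 = rng.uniform(np.log(k_lo), np.log(k_hi))
        h0 = rng.uniform(_H_FLOOR, settings.h_max)
        try:
            res = optimize.minimize(
                _objective,
                np.array([log_k0, h0]),
                args=(x, y, mode),
                method="L-BFGS-B",
                bounds=bounds,
            )
        except Exception:  # optimizer blow-up counts as a failed start
            continue
        if not np.isfinite(res.fun):
            continue
        if best is None or res.fun < best[0]:
            best = (float(res.fun), float(res.x[0]), float(res.x[1]))
            best_start = start
    if best is None:
        return None, np.inf, None

    ss, log_k, h = best
    k = float(np.exp(log_k))
    u = hill_transform(x, k, h, mode)
    if np.ptp(u) == 0:
        y_max, baseline = 0.0, float(y.mean())
    else:
        y_max, baseline, ss = _affine_fit(u, y)
    model = HillModel(mode=mode, K_H=k, h=min(h, settings.h_max),
                      y_max=y_max, baseline=baseline)
    return model, ss, best_start


def _lagged(x: np.ndarray, y: np.ndarray, lag: int
            ) -> tuple[np.ndarray, np.ndarray]:
    """lag -1 pairs the TF activity at t_{i+1} with the metabolite at t_i."""
    if lag == 0:
        return x, y
    return x[:-1], y[1:]


def fit_hill_pair(
    x: np.ndarray,
    y: np.ndarray,
    metabolite_id: str = "",
    regulator_id: str = "",
    settings: HillFitSettings | None = None,
    seed: int | None = None,
) -> HillFitResult:
    """Best Hill fit of a metabolite series x (µM) to a TF activity y.

    Runs the 50-start nested fit at each candidate lag; the highest R^2
    (1 - SS_res/SS_tot) wins. When every start fails the result carries
    r_squared = -inf and a failure flag.
    """
    settings = settings or HillFitSettings()
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if np.any(x < 0):
        raise ValueError("metabolite concentrations must be >= 0")
    if x.size < MIN_POINTS:
        raise ValueError(f"need at least {MIN_POINTS} points, got {x.size}")

    mode, flags = select_mode(x, y)
    if "degenerate_constant_series" in flags:
        return HillFitResult(
            metabolite_id, regulator_id, None, 0, -np.inf,
            n_multistarts=settings.n_starts, n_points=int(x.size), flags=flags,
        )

    seed = settings.seed if seed is None else seed
    best_result: HillFitResult | None = None
    for lag in settings.lag_candidates:
        xl, yl = _lagged(x, y, lag)
        if xl.size < MIN_POINTS:
            continue
        # independent but deterministic stream per lag
        rng = np.random.default_rng((seed, lag & 1))
        model, ss, start = _fit_one_lag(xl, yl, mode, settings, rng)
        if model is None:
            continue
        ss_tot = float(np.sum((yl - yl.mean()) ** 2))
        r2 = 1.0 - ss / ss_tot if ss_tot > 0 else -np.inf
        pred = model.predict(xl)
        pearson = (
            float(stats.pearsonr(yl, pred).statistic ** 2)
            if np.std(pred) > 0
            else np.nan
        )
        result = HillFitResult(
            metabolite_id, regulator_id, model, lag, float(r2),
            r_squared_pearson=pearson, n_multistarts=settings.n_starts,
            best_start_seed=start, n_points=int(xl.size), flags=list(flags),
        )
        if best_result is None or result.r_squared > best_result.r_squared:
            best_result = result
    if best_result is None:
        return HillFitResult(
            metabolite_id, regulator_id, None, 0, -np.inf,
            n_multistarts=settings.n_starts, n_points=int(x.size),
            flags=flags + ["all_starts_failed"],
        )
    return best_result


def _pair_seed(master_seed: int, metabolite_id: str, regulator_id: str) -> int:
    """Stable per-pair seed independent of input ordering."""
    digest = hashlib.sha256(
        f"{master_seed}:{metabolite_id}:{regulator_id}".encode()
    ).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def screen_all_pairs(
    metabolites: MetaboliteTable,
    activities: ActivityEnsemble,
    settings: HillFitSettings | None = None,
    regulator_ids: list[str] | None = None,
) -> list[HillFitResult]:
    """Fit every (metabolite, regulator) pair and rank by R^2.

    Deterministic under the master seed and invariant to the order of
    rows in either input (per-pair seeds are keyed by the pair's ids).
    Pairs whose aligned series is too short are skipped with a reason.
    """
    settings = settings or HillFitSettings()
    aligned = align_series(metabolites, activities, settings.align_window)
    if aligned.skipped_reason is not None:
        raise ValueError(f"grids cannot be aligned: {aligned.skipped_reason}")
    regs = (
        list(aligned.activities.index)
        if regulator_ids is None
        else list(regulator_ids)
    )
    mets = list(aligned.metabolites.index)
    if not regs or not mets:
        raise ValueError("empty metabolite or regulator list")

    results = []
    for met in mets:
        x = aligned.metabolites.loc[met].to_numpy()
        for reg in regs:
            y = aligned.activities.loc[reg].to_numpy()
            results.append(
                fit_hill_pair(
                    x, y, met, reg, settings,
                    seed=_pair_seed(settings.seed, met, reg),
                )
            )
    results.sort(
        key=lambda r: (-r.r_squared if np.isfinite(r.r_squared) else np.inf,
                       r.metabolite_id, r.regulator_id)
    )
    return results


def results_table(
    results: list[HillFitResult], threshold: float = 0.75
) -> pd.DataFrame:
    """Flat results table with a pass flag at the R^2 threshold."""
    rows = []
    for r in results:
        rows.append({
            "metabolite": r.metabolite_id,
            "TF": r.regulator_id,
            "mode": r.model.mode if r.model else "",
            "K_H": r.model.K_H if r.model else np.nan,
            "h": r.model.h if r.model else np.nan,
            "lag": r.lag_applied,
            "R2": r.r_squared,
            "R2_pearson": r.r_squared_pearson,
            "passed_threshold": r.passes(threshold),
        })
    return pd.DataFrame(
        rows,
        columns=["metabolite", "TF", "mode", "K_H", "h", "lag", "R2",
                 "R2_pearson", "passed_threshold"],
    )
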