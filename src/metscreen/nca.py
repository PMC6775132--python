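"""Transcription-factor activity inference by network component analysis.

Expression E (genes x time, log10 TPM) is factorized as E ~ A.P where A
carries the fixed zero pattern of the known regulatory network and P is
the latent regulator activity. The objective min ||E - A.P||^2 is solved
by alternating least squares: the zero pattern of A is preserved exactly,
each half-step is an exact least-squares solve, so the residual trace is
monotone non-increasing. Because (A, P) is only identified up to
per-regulator scale and sign, an ensemble of randomized restarts is
z-score normalized and sign-aligned before mean activities and
percentile confidence bands are computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_io import ConnectivityMatrix, ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "NcaSettings",
    "NcaRestart",
    "ActivityEnsemble",
    "run_nca_single",
    "run_nca_ensemble",
    "align_and_summarize",
    "variance_explained",
    "check_identifiability",
]


@dataclass
class NcaSettings:
    """Knobs for the alternating-least-squares search.

    n_restarts
        Randomized initializations; 100 gives stable means and 95% bands.
    convergence_relative_tolerance
        Stop when the summed squared residual changes by no more than
        this fraction between outer iterations (default 1%).
    max_iterations
        Safety cap on outer iterations.
    condition_limit / ridge
        Per-gene subproblems with condition number above the limit are
        solved with a small ridge penalty to stay defined on pathological
        topologies.
    """

    n_restarts: int = 100
    convergence_relative_tolerance: float = 0.01
    max_iterations: int = 500
    condition_limit: float = 1e8
    ridge: float = 1e-6
    #: Restarts whose final residual exceeds this factor of the best
    #: restart's residual are treated as trapped in a poor local optimum
    #: and excluded from the ensemble summary.
    restart_residual_factor: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.convergence_relative_tolerance < 1:
            raise ValueError("convergence tolerance must be in (0, 1)")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")


@dataclass
class NcaRestart:
    """Result of one randomized ALS run."""

    A: np.ndarray  # genes x regulators, zero pattern of the network
    P: np.ndarray  # regulators x time
    residual_trace: np.ndarray
    converged: bool

    @property
    def residual(self) -> float:
        return float(self.residual_trace[-1])


@dataclass
class ActivityEnsemble:
    """Regulator activities summarized over aligned NCA restarts.

    ``mean`` / ``ci_low`` / ``ci_high`` are regulators x time on the
    z-score scale; ``relative_ci_width`` is the mean 95% band width
    divided by each regulator's activity range (the "confidence interval
    > 100%" quantity of the TF quality filter).
    """

    regulator_ids: list[str]
    time_points: np.ndarray
    restarts: list[np.ndarray]  # aligned, z-scored regulator x time
    mean: pd.DataFrame
    ci_low: pd.DataFrame
    ci_high: pd.DataFrame
    relative_ci_width: pd.Series
    residuals: list[float] = field(default_factory=list)
    converged_flags: list[bool] = field(default_factory=list)

    @property
    def n_restarts(self) -> int:
        return len(self.restarts)

    def profile(self, regulator_id: str) -> np.ndarray:
        return self.mean.loc[regulator_id].to_numpy()

    @classmethod
    def from_truth(
        cls, profiles: pd.DataFrame, time_points: np.ndarray
    ) -> "ActivityEnsemble":
        """Wrap known activity profiles as a degenerate one-member ensemble."""
        zero = profiles * 0.0
        return cls(
            regulator_ids=list(profiles.index),
            time_points=np.asarray(time_points, float),
            restarts=[profiles.to_numpy().copy()],
            mean=profiles.copy(),
            ci_low=profiles.copy(),
            ci_high=profiles.copy(),
            relative_ci_width=zero.iloc[:, 0].rename("relative_ci_width"),
            residuals=[0.0],
            converged_flags=[True],
        )


def _zscore_rows(matrix: np.ndarray) -> np.ndarray:
    mean = matrix.mean(axis=1, keepdims=True)
    std = matrix.std(axis=1, keepdims=True)
    out = np.where(std > 0, (matrix - mean) / np.where(std == 0, 1.0, std), 0.0)
    return out


def _solve_gene_row(p_sub: np.ndarray, e_row: np.ndarray, settings: NcaSettings
                    ) -> np.ndarray:
    """Least-squares weights of one gene on its regulators' activities."""
    design = p_sub.T  # time x k
    if np.linalg.cond(design) > settings.condition_limit:
        k = design.shape[1]
        gram = design.T @ design + settings.ridge * np.eye(k)
        return np.linalg.solve(gram, design.T @ e_row)
    sol, *_ = np.linalg.lstsq(design, e_row, rcond=None)
    return sol


def run_nca_single(
    expression: ExpressionMatrix | pd.DataFrame,
    connectivity: ConnectivityMatrix,
    settings: NcaSettings | None = None,
    restart_seed: int = 0,
) -> NcaRestart:
    """One alternating-least-squares run from a random initialization.

    Alternates (i) P <- argmin ||E - A.P|| given A (global least
    squares) and (ii) per-gene re-estimation of the nonzero entries of A
    given P. Stops when the relative change of the summed squared
    residual is at or below the tolerance.
    """
    settings = settings or NcaSettings()
    e = _expression_means(expression, connectivity)
    pattern = connectivity.pattern().T  # genes x regulators
    n_genes, n_regs = pattern.shape
    if n_genes <= n_regs:
        raise ValueError(
            f"NCA needs more genes ({n_genes}) than regulators ({n_regs})"
        )

    rng = np.random.default_rng(restart_seed)
    a = np.where(pattern, rng.uniform(-1.0, 1.0, size=pattern.shape), 0.0)

    gene_regs = [np.flatnonzero(pattern[i]) for i in range(n_genes)]
    trace = []
    converged = False
    p = np.zeros((n_regs, e.shape[1]))
    for _ in range(settings.max_iterations):
        p, *_ = np.linalg.lstsq(a, e, rcond=None)
        for i, idx in enumerate(gene_regs):
            a[i, idx] = _solve_gene_row(p[idx], e[i], settings)
        residual = float(np.sum((e - a @ p) ** 2))
        if trace:
            prev = trace[-1]
            rel = abs(prev - residual) / prev if prev > 0 else 0.0
            trace.append(residual)
            if rel <= settings.convergence_relative_tolerance:
                converged = True
                break
        else:
            trace.append(residual)
    # final P consistent with the last A update
    p, *_ = np.linalg.lstsq(a, e, rcond=None)
    return NcaRestart(a, p, np.asarray(trace), converged)


def _expression_means(
    expression: ExpressionMatrix | pd.DataFrame,
    connectivity: ConnectivityMatrix,
) -> np.ndarray:
    """Replicate-mean expression restricted and ordered to network genes."""
    profiles = (
        expression.mean_profiles()
        if isinstance(expression, ExpressionMatrix)
        else expression
    )
    missing = [g for g in connectivity.gene_ids if g not in profiles.index]
    if missing:
        raise ValueError(
            f"genes in the network but not the expression data: {missing[:5]}"
        )
    return profiles.loc[connectivity.gene_ids].to_numpy()


def run_nca_ensemble(
    expression: ExpressionMatrix | pd.DataFrame,
    connectivity: ConnectivityMatrix,
    settings: NcaSettings | None = None,
) -> ActivityEnsemble:
    """Randomized-restart ensemble: run, align, summarize, orient.

    After alignment each regulator's profile is oriented against the
    sign annotations of the interaction tables (where present): the
    factorization only identifies activities up to sign, and anchoring
    the recovered weights to the annotated activation/repression signs
    makes activation-vs-inhibition calls downstream meaningful.
    """
    settings = settings or NcaSettings()
    seeds = np.random.SeedSequence(settings.seed).generate_state(
        settings.n_restarts
    )
    restarts = [
        run_nca_single(expression, connectivity, settings, int(s) % (2**31))
        for s in seeds
    ]
    time_points = (
        expression.time_points
        if isinstance(expression, ExpressionMatrix)
        else np.asarray(expression.columns, float)
    )
    return align_and_summarize(
        restarts,
        connectivity.regulator_ids,
        time_points,
        settings,
        sign_matrix=np.sign(connectivity.weights.to_numpy()).T,
    )


def align_and_summarize(
    restarts: list[NcaRestart],
    regulator_ids: list[str],
    time_points: np.ndarray,
    settings: NcaSettings | None = None,
    sign_matrix: np.ndarray | None = None,
) -> ActivityEnsemble:
    """Remove the per-regulator scale/sign ambiguity, then summarize.

    Each converged restart's activity rows are z-scored over time and
    sign-aligned (by correlation) to the lowest-residual restart.
    Restarts trapped in clearly worse local optima (final residual above
    ``restart_residual_factor`` times the best) are dropped before
    summarizing. The mean and the 2.5/97.5 percentile band are computed
    pointwise; the band is widened to contain the mean where percentile
    rounding on small ensembles would exclude it.
    """
    settings = settings or NcaSettings()
    kept = [r for r in restarts if r.converged]
    if not kept:
        raise ValueError("no converged NCA restart; cannot summarize")
    best = min(r.residual for r in kept)
    cutoff = settings.restart_residual_factor * best + 1e-12
    pruned = [r for r in kept if r.residual <= cutoff]
    if len(pruned) < len(kept):
        logger.info(
            "pruned %d of %d converged restarts (residual > %.3g)",
            len(kept) - len(pruned), len(kept), cutoff,
        )
    kept = pruned
    aligned = []
    flips = []
    reference = _zscore_rows(min(kept, key=lambda r: r.residual).P)
    for restart in kept:
        z = _zscore_rows(restart.P)
        flip = np.ones(z.shape[0])
        for j in range(z.shape[0]):
            if np.dot(z[j], reference[j]) < 0:
                z[j] = -z[j]
                flip[j] = -1.0
        aligned.append(z)
        flips.append(flip)

    if sign_matrix is not None:
        # Orient each regulator against the annotated activation /
        # repression signs: the factorization only fixes activities up
        # to sign, and the restart-aligned orientation is arbitrary. A
        # magnitude-weighted vote over every kept restart's recovered
        # weights (strong edges carry more reliable signs) decides; an
        # unannotated regulator (all-zero sign column) keeps the
        # restart-reference orientation.
        votes = np.zeros(len(regulator_ids))
        for restart, flip in zip(kept, flips):
            votes += flip * np.einsum("gj,gj->j", restart.A, sign_matrix)
        for j in np.flatnonzero(votes < 0):
            for z in aligned:
                z[j] = -z[j]

    stack = np.stack(aligned)  # restarts x regulators x time
    mean = stack.mean(axis=0)
    lo = np.minimum(np.percentile(stack, 2.5, axis=0), mean)
    hi = np.maximum(np.percentile(stack, 97.5, axis=0), mean)

    activity_range = mean.max(axis=1) - mean.min(axis=1)
    width = (hi - lo).mean(axis=1)
    rel_width = np.where(
        activity_range > 0,
        width / np.where(activity_range == 0, 1.0, activity_range),
        np.where(width > 0, np.inf, 0.0),
    )

    time_points = np.asarray(time_points, float)
    as_df = lambda m: pd.DataFrame(m, index=regulator_ids, columns=time_points)
    return ActivityEnsemble(
        regulator_ids=list(regulator_ids),
        time_points=time_points,
        restarts=aligned,
        mean=as_df(mean),
        ci_low=as_df(lo),
        ci_high=as_df(hi),
        relative_ci_width=pd.Series(
            rel_width, index=regulator_ids, name="relative_ci_width"
        ),
        residuals=[r.residual for r in kept],
        converged_flags=[r.converged for r in restarts],
    )


def variance_explained(
    expression: ExpressionMatrix | pd.DataFrame,
    connectivity: ConnectivityMatrix,
    restart: NcaRestart,
) -> float:
    """Fraction of per-gene-centered expression variance captured by A.P.

    1 - ||E - AP||^2 / ||E - rowmean(E)||^2, clamped to [0, 1].
    """
    e = _expression_means(expression, connectivity)
    ss_res = float(np.sum((e - restart.A @ restart.P) ** 2))
    centered = e - e.mean(axis=1, keepdims=True)
    ss_tot = float(np.sum(centered**2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else 0.0
    return float(np.clip(1.0 - ss_res / ss_tot, 0.0, 1.0))


def check_identifiability(connectivity: ConnectivityMatrix) -> dict:
    """Advisory identifiability report for a network topology.

    Flags regulators with identical target sets (their activities are
    interchangeable) and regulators whose entire target set is covered
    by the union of the others (their contribution is not separable).
    The global basal regulator is exempt: it overlaps everything by
    construction. Never blocks a run.
    """
    pattern = connectivity.pattern()
    if pattern.size == 0 or not pattern.any():
        raise ValueError("empty connectivity matrix")
    regs = connectivity.tf_ids

    target_sets = {r: frozenset(connectivity.targets_of(r)) for r in regs}
    groups: dict[frozenset, list[str]] = {}
    for r, t in target_sets.items():
        groups.setdefault(t, []).append(r)
    duplicated = [sorted(g) for g in groups.values() if len(g) > 1]

    covered = []
    for r in regs:
        others = set().union(
            *(target_sets[o] for o in regs if o != r), frozenset()
        )
        if target_sets[r] and target_sets[r] <= others:
            covered.append(r)

    ok = not duplicated and not covered
    return {
        "identifiable": ok,
        "duplicated_target_sets": duplicated,
        "fully_covered_regulators": covered,
    }
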