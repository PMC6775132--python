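"""End-to-end screen: TF filtering, known-network recovery, prediction.

The screen excludes TFs whose activity trivially tracks the growth
phases (on-off-on), TFs whose 95% confidence band exceeds their activity
range, and two-component regulators (driven by external signals rather
than internal metabolites). Surviving TFs are paired with every measured
metabolite, each pair is scored by the Hill fit, and candidates must
clear both the R^2 threshold and the metabolic-network proximity
criterion. Small utilities cover z-score hierarchical clustering of
omics trajectories and the adenylate energy charge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .hill_fit import HillFitResult, HillFitSettings, screen_all_pairs
from .metnet_distance import (
    CriterionVerdict,
    MetabolicModel,
    build_adjacency,
    distance_criterion,
)
from .model_io import (
    ConnectivityMatrix,
    ExpressionMatrix,
    LiteratureNetwork,
    MetaboliteTable,
)
from .nca import ActivityEnsemble, NcaSettings, run_nca_ensemble

logger = logging.getLogger(__name__)

__all__ = [
    "TfFilterSettings",
    "TfFilterReport",
    "CandidateInteraction",
    "filter_tfs",
    "recover_known_network",
    "predict_interactions",
    "per_tf_effector_stats",
    "cluster_dynamics",
    "energy_charge",
    "run_screen",
    "ScreenResult",
]


@dataclass
class TfFilterSettings:
    on_off_on_correlation: float = 0.9  # |corr| with growth-phase indicator
    max_relative_ci_width: float = 1.0  # "confidence interval > 100%"
    r2_threshold: float = 0.75


@dataclass
class TfFilterReport:
    regulator_id: str
    excluded: bool
    reasons: list[str] = field(default_factory=list)

    VALID_REASONS = ("on_off_on", "wide_confidence", "two_component")

    def __post_init__(self) -> None:
        if self.excluded != bool(self.reasons):
            raise ValueError("excluded must match non-empty reasons")
        bad = set(self.reasons) - set(self.VALID_REASONS)
        if bad:
            raise ValueError(f"unknown filter reasons: {bad}")


@dataclass
class CandidateInteraction:
    metabolite_id: str
    regulator_id: str
    mode: str
    K_H: float
    h: float
    r_squared: float
    lag_applied: int
    satisfied_by: str
    witness_gene: str | None
    known_in_literature: bool = False


def filter_tfs(
    ensemble: ActivityEnsemble,
    two_component_list: list[str] | set[str] = (),
    phase_boundaries_hours: tuple[float, float] | None = None,
    settings: TfFilterSettings | None = None,
    regulator_ids: list[str] | None = None,
) -> list[TfFilterReport]:
    """Flag TFs to exclude from the metabolite screen.

    (i) on-off-on: |Pearson correlation| between the mean activity and
    the binary growth-phase indicator (1 in either growth phase, 0 in
    starvation) above the threshold; a profile that merely tracks the
    phases correlates with every growth-coupled metabolite and carries
    no specific signal. (ii) wide confidence: mean 95% band width above
    100% of the regulator's activity range. (iii) membership in the
    two-component regulator list.
    """
    settings = settings or TfFilterSettings()
    if phase_boundaries_hours is None:
        raise ValueError("phase boundaries are required for the on-off-on filter")
    h1, h2 = phase_boundaries_hours
    times = np.asarray(ensemble.time_points, float)
    indicator = ((times < h1) | (times >= h2)).astype(float)
    two_component = set(two_component_list)

    reports = []
    for reg in regulator_ids or ensemble.regulator_ids:
        reasons = []
        profile = ensemble.mean.loc[reg].to_numpy()
        if np.std(profile) > 0 and np.std(indicator) > 0:
            corr = abs(stats.pearsonr(profile, indicator).statistic)
            if corr >= settings.on_off_on_correlation:
                reasons.append("on_off_on")
        width = float(ensemble.relative_ci_width.loc[reg])
        if width > settings.max_relative_ci_width:
            reasons.append("wide_confidence")
        if reg in two_component:
            reasons.append("two_component")
        reports.append(TfFilterReport(reg, bool(reasons), reasons))
    return reports


def retained_tfs(reports: list[TfFilterReport]) -> list[str]:
    return [r.regulator_id for r in reports if not r.excluded]


def recover_known_network(
    literature: LiteratureNetwork,
    fits: list[HillFitResult],
    r2_threshold: float = 0.75,
) -> pd.DataFrame:
    """Check the screen against a curated metabolite-TF network.

    One row per literature edge: ``covered`` when the pair was actually
    fitted (metabolite measured and TF profile retained), ``recovered``
    when the fit clears the R^2 threshold, ``mode_match`` when the
    fitted activation/inhibition agrees with the annotation (edges of
    unknown mode never count as mismatch). Uncovered edges are reported,
    not failed.
    """
    fit_index = {(f.metabolite_id, f.regulator_id): f for f in fits}
    rows = []
    for edge in literature.edges.itertuples():
        fit = fit_index.get((edge.metabolite_id, edge.regulator_id))
        covered = fit is not None
        recovered = bool(fit and fit.passes(r2_threshold))
        if recovered and edge.mode in ("activation", "inhibition"):
            mode_match = fit.model.mode == edge.mode
        else:
            mode_match = None
        rows.append({
            "metabolite_id": edge.metabolite_id,
            "regulator_id": edge.regulator_id,
            "annotated_mode": edge.mode,
            "covered": covered,
            "recovered": recovered,
            "fitted_mode": fit.model.mode if recovered else "",
            "mode_match": mode_match,
            "R2": fit.r_squared if covered else np.nan,
        })
    return pd.DataFrame(rows)


def recovery_summary(report: pd.DataFrame) -> dict:
    """Per-TF roll-up: of the covered TFs, how many have at least one
    known effector above threshold."""
    covered = report[report["covered"]]
    by_tf = covered.groupby("regulator_id")["recovered"].any()
    matches = report["mode_match"].dropna().astype(bool)
    return {
        "tfs_covered": int(by_tf.size),
        "tfs_recovered": int(by_tf.sum()),
        "edges_recovered": int(covered["recovered"].sum()),
        "mode_matches": int(matches.sum()),
        "mode_mismatches": int((~matches).sum()),
    }


def predict_interactions(
    fits: list[HillFitResult],
    verdicts: dict[tuple[str, str], CriterionVerdict],
    filter_reports: list[TfFilterReport],
    literature: LiteratureNetwork | None = None,
    r2_threshold: float = 0.75,
) -> list[CandidateInteraction]:
    """Candidate interactions: R^2 above threshold, proximity criterion
    passed, TF retained by the quality filters."""
    keep = set(retained_tfs(filter_reports))
    known = (
        {(e.metabolite_id, e.regulator_id) for e in literature.edges.itertuples()}
        if literature is not None
        else set()
    )
    candidates = []
    for fit in fits:
        if fit.regulator_id not in keep or not fit.passes(r2_threshold):
            continue
        verdict = verdicts.get((fit.metabolite_id, fit.regulator_id))
        if verdict is None or not verdict.passes:
            continue
        candidates.append(
            CandidateInteraction(
                metabolite_id=fit.metabolite_id,
                regulator_id=fit.regulator_id,
                mode=fit.model.mode,
                K_H=fit.model.K_H,
                h=fit.model.h,
                r_squared=fit.r_squared,
                lag_applied=fit.lag_applied,
                satisfied_by=verdict.satisfied_by,
                witness_gene=verdict.witness_gene,
                known_in_literature=(fit.metabolite_id, fit.regulator_id)
                in known,
            )
        )
    candidates.sort(key=lambda c: (-c.r_squared, c.metabolite_id, c.regulator_id))
    return candidates


def per_tf_effector_counts(
    candidates: list[CandidateInteraction],
) -> pd.Series:
    counts = pd.Series(
        [c.regulator_id for c in candidates], dtype=object
    ).value_counts()
    counts.name = "n_effectors"
    return counts


def per_tf_effector_stats(
    fits: list[HillFitResult],
    verdicts: dict[tuple[str, str], CriterionVerdict],
    r2_threshold: float = 0.75,
    tf_subset: set[str] | None = None,
) -> dict:
    """Mean number of effector metabolites per TF before and after the
    proximity criterion, over TFs with at least one passing metabolite.

    ``tf_subset`` restricts the denominator (e.g. to the TFs whose
    known effectors were recovered); by default every TF with a passing
    metabolite counts. Returns n/a (None) averages when no pair passes
    the R^2 threshold.
    """
    before: dict[str, int] = {}
    after: dict[str, int] = {}
    for fit in fits:
        if not fit.passes(r2_threshold):
            continue
        if tf_subset is not None and fit.regulator_id not in tf_subset:
            continue
        before[fit.regulator_id] = before.get(fit.regulator_id, 0) + 1
        verdict = verdicts.get((fit.metabolite_id, fit.regulator_id))
        if verdict is not None and verdict.passes:
            after[fit.regulator_id] = after.get(fit.regulator_id, 0) + 1
    if not before:
        return {"mean_before": None, "mean_after": None, "n_tfs": 0}
    tfs = sorted(before)
    return {
        "mean_before": float(np.mean([before[t] for t in tfs])),
        "mean_after": float(np.mean([after.get(t, 0) for t in tfs])),
        "n_tfs": len(tfs),
    }


# ---------------------------------------------------------------------------
# light utilities


def cluster_dynamics(
    matrix: pd.DataFrame,
    k: int = 4,
    method: str = "average",
    metric: str = "euclidean",
) -> tuple[pd.Series, pd.DataFrame]:
    """Group trajectories by agglomerative clustering of z-scored rows.

    Returns integer labels (1..k) per row and the per-cluster mean
    z-score profile. Constant rows get a flat z-score of 0. The
    partition depends only on the set of rows, not their order.
    """
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    std = values.std(axis=1, keepdims=True)
    z = np.where(std > 0, (values - mean) / np.where(std == 0, 1.0, std), 0.0)

    order = np.argsort(matrix.index.to_numpy())  # order-independent linkage
    linkage = hierarchy.linkage(z[order], method=method, metric=metric)
    labels_sorted = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    labels = np.empty(len(order), dtype=int)
    labels[order] = labels_sorted

    label_series = pd.Series(labels, index=matrix.index, name="cluster")
    zframe = pd.DataFrame(z, index=matrix.index, columns=matrix.columns)
    profiles = zframe.groupby(label_series).mean()
    return label_series, profiles


def energy_charge(atp, adp, amp):
    """Adenylate energy charge (ATP + ADP/2) / (ATP + ADP + AMP)."""
    atp, adp, amp = (np.asarray(v, float) for v in (atp, adp, amp))
    total = atp + adp + amp
    if np.any(total <= 0):
        raise ValueError("adenylate pool must be positive")
    return (atp + 0.5 * adp) / total


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class ScreenResult:
    ensemble: ActivityEnsemble
    filter_reports: list[TfFilterReport]
    fits: list[HillFitResult]
    verdicts: dict[tuple[str, str], CriterionVerdict]
    candidates: list[CandidateInteraction]
    recovery: pd.DataFrame | None
    summary: dict


def run_screen(
    expression: ExpressionMatrix,
    connectivity: ConnectivityMatrix,
    metabolites: MetaboliteTable,
    model: MetabolicModel,
    phase_boundaries_hours: tuple[float, float],
    two_component_list: list[str] = (),
    literature: LiteratureNetwork | None = None,
    nca_settings: NcaSettings | None = None,
    hill_settings: HillFitSettings | None = None,
    filter_settings: TfFilterSettings | None = None,
    metabolite_annotation: dict[str, set[str]] | None = None,
    ensemble: ActivityEnsemble | None = None,
) -> ScreenResult:
    """Full screen from inputs to candidate interactions.

    Runs the activity inference (unless a precomputed ensemble is
    supplied), applies the TF quality filters, fits Hill kinetics to
    every retained TF x metabolite pair, evaluates the proximity
    criterion on the metabolic model and intersects the three gates.
    The basal regulator never enters the screen.
    """
    filter_settings = filter_settings or TfFilterSettings()
    hill_settings = hill_settings or HillFitSettings(
        r2_threshold=filter_settings.r2_threshold
    )
    if ensemble is None:
        ensemble = run_nca_ensemble(expression, connectivity, nca_settings)

    reports = filter_tfs(
        ensemble,
        two_component_list,
        phase_boundaries_hours,
        filter_settings,
        regulator_ids=connectivity.tf_ids,
    )
    keep = retained_tfs(reports)
    logger.info("retained %d of %d TFs", len(keep), len(connectivity.tf_ids))

    fits = screen_all_pairs(metabolites, ensemble, hill_settings, keep)

    f_prime, _ = build_adjacency(model)
    verdicts = {
        (f.metabolite_id, f.regulator_id): distance_criterion(
            f.metabolite_id,
            f.regulator_id,
            model,
            connectivity.targets_of(f.regulator_id),
            f_prime=f_prime,
            metabolite_annotation=metabolite_annotation,
        )
        for f in fits
    }
    candidates = predict_interactions(
        fits, verdicts, reports, literature, filter_settings.r2_threshold
    )
    recovery = (
        recover_known_network(literature, fits, filter_settings.r2_threshold)
        if literature is not None
        else None
    )

    threshold = filter_settings.r2_threshold
    n_pass_r2 = sum(f.passes(threshold) for f in fits)
    stats_ = per_tf_effector_stats(fits, verdicts, threshold)
    counts = per_tf_effector_counts(candidates)
    summary = {
        "tfs_total": len(connectivity.tf_ids),
        "tfs_retained": len(keep),
        "pairs_tested": len(fits),
        "pairs_passing_r2": int(n_pass_r2),
        "pairs_passing_criterion": len(candidates),
        "mean_effectors_before_criterion": stats_["mean_before"],
        "mean_effectors_after_criterion": stats_["mean_after"],
        "tfs_with_1_or_2_effectors": int((counts <= 2).sum()),
    }
    if recovery is not None:
        summary.update(recovery_summary(recovery))
    return ScreenResult(
        ensemble, reports, fits, verdicts, candidates, recovery, summary
    )
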