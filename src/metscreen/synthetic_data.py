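"""Ground-truthed synthetic inputs for the screen.

Emulates the structure of a growth / carbon-starvation / regrowth
time-course experiment: a sparse signed regulatory network with a global
basal regulator, smooth phase-wise TF activity profiles (including an
on-off-on profile that tracks the growth phases), log-scale expression
E = A.P plus Gaussian noise in duplicate samples, metabolite
trajectories obtained by inverting the Hill transform so that planted
metabolite-TF couplings are exactly recoverable, and a small
stoichiometric toy model wired so that planted pairs satisfy the
network-distance criterion. Every stage of the analysis has a recovery
test against the planted truth.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .metnet_distance import MetabolicModel
from .model_io import (
    GLOBAL_REGULATOR_ID,
    ConnectivityMatrix,
    ExpressionMatrix,
    LiteratureNetwork,
    MetaboliteTable,
    write_expression,
    write_interaction_table,
    write_metabolic_model,
    write_metabolites,
)
from .nca import ActivityEnsemble

logger = logging.getLogger(__name__)

__all__ = [
    "PlantedInteraction",
    "SyntheticScenario",
    "generate_regulatory_network",
    "generate_tf_activities",
    "generate_expression",
    "generate_metabolites",
    "generate_toy_metabolic_model",
    "simulate_bundle",
]

#: Planted activities are mapped affinely into this interval before the
#: Hill inversion; the saturating branches are asymptotic, so hitting 0
#: or 1 would need infinite concentrations.
RESCALE_INTERVAL = (0.05, 0.95)


@dataclass(frozen=True)
class PlantedInteraction:
    """A ground-truth metabolite-TF coupling through Hill kinetics."""

    metabolite_id: str
    regulator_id: str
    mode: str  # "activation" | "inhibition"
    K_H: float  # µM
    h: float
    lag: int = 0  # 0 or 1 time point (expression follows the metabolite)

    def __post_init__(self) -> None:
        if self.mode not in ("activation", "inhibition"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not self.K_H > 0:
            raise ValueError("K_H must be > 0")
        if not 0 < self.h <= 10:
            raise ValueError("Hill coefficient must lie in (0, 10]")
        if self.lag not in (0, 1):
            raise ValueError("lag must be 0 or 1 time point")


def _default_planted(n: int = 10) -> list[PlantedInteraction]:
    """Ten couplings spanning both modes, a K_H decade range, varied
    cooperativity and a few one-point lags."""
    k_values = np.round(np.logspace(1, 3, n), 1)  # 10 .. 1000 µM
    h_values = [1.0, 2.0, 4.0]
    out = []
    for i in range(n):
        out.append(
            PlantedInteraction(
                metabolite_id=f"met{i:02d}",
                regulator_id=f"tf{i + 1:02d}",
                mode="activation" if i % 2 == 0 else "inhibition",
                K_H=float(k_values[i]),
                h=h_values[i % 3],
                lag=1 if i % 4 == 3 else 0,
            )
        )
    return out


@dataclass
class SyntheticScenario:
    """Study design of one synthetic experiment.

    Defaults mirror the structure of the bioreactor switch experiment
    the analysis is built for -- 29 transcriptome and 35 metabolome time
    points over 20 h spanning growth, carbon starvation and regrowth,
    duplicate samples, ~16% transcript noise (0.065 on the log10 scale)
    and ~18% lognormal metabolite noise -- at a network size small
    enough for randomized-restart inference to run at the desk.
    """

    n_genes: int = 150
    n_regulators: int = 12
    n_metabolites: int = 20
    n_timepoints: int = 29
    n_metabolome_timepoints: int = 35
    total_hours: float = 20.0
    phase_boundaries: tuple[int, int] = (8, 25)  # growth->starv, starv->regrowth
    noise_sd: float = 0.065  # additive, log10 expression scale
    metabolite_noise_cv: float = 0.18  # lognormal coefficient of variation
    replicate_count: int = 2
    planted_interactions: list[PlantedInteraction] | None = None
    two_component_regulators: tuple[str, ...] = ("tf11",)
    seed: int = 0

    def __post_init__(self) -> None:
        b1, b2 = self.phase_boundaries
        if not 0 < b1 < b2 < self.n_timepoints:
            raise ValueError(
                "phase boundaries must be strictly increasing indices "
                "inside the time grid"
            )
        if self.n_regulators >= self.n_genes:
            raise ValueError("NCA requires more genes than regulators")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.replicate_count < 1:
            raise ValueError("replicate_count must be >= 1")
        if self.planted_interactions is None:
            self.planted_interactions = [
                p for p in _default_planted()
                if int(p.regulator_id[2:]) <= self.n_regulators - 2
                and int(p.metabolite_id[3:]) < self.n_metabolites
            ]
        for p in self.planted_interactions:
            reg_idx = int(p.regulator_id[2:])
            met_idx = int(p.metabolite_id[3:])
            if reg_idx >= self.n_regulators or met_idx >= self.n_metabolites:
                raise ValueError(
                    f"planted interaction {p} references an id outside the "
                    "scenario"
                )

    # -- naming and grids ---------------------------------------------------

    @property
    def regulator_ids(self) -> list[str]:
        return [f"tf{i:02d}" for i in range(self.n_regulators)]

    @property
    def gene_ids(self) -> list[str]:
        return [f"g{i:03d}" for i in range(self.n_genes)]

    @property
    def metabolite_ids(self) -> list[str]:
        return [f"met{i:02d}" for i in range(self.n_metabolites)]

    @property
    def transcriptome_times(self) -> np.ndarray:
        return np.round(
            np.linspace(0.0, self.total_hours, self.n_timepoints), 4
        )

    @property
    def metabolome_times(self) -> np.ndarray:
        return np.round(
            np.linspace(0.0, self.total_hours, self.n_metabolome_timepoints), 4
        )

    @property
    def phase_boundary_hours(self) -> tuple[float, float]:
        t = self.transcriptome_times
        b1, b2 = self.phase_boundaries
        return float(t[b1]), float(t[b2])

    def grid_alignment(self) -> pd.DataFrame:
        """Nearest metabolome time point for each transcriptome point."""
        mt = self.metabolome_times
        rows = [
            (t, float(mt[np.argmin(np.abs(mt - t))]))
            for t in self.transcriptome_times
        ]
        return pd.DataFrame(rows, columns=["transcriptome_h", "metabolome_h"])

    def phase_of(self, hours: np.ndarray) -> np.ndarray:
        """0 growth, 1 starvation, 2 regrowth."""
        h1, h2 = self.phase_boundary_hours
        hours = np.asarray(hours, float)
        return np.where(hours < h1, 0, np.where(hours < h2, 1, 2))


# ---------------------------------------------------------------------------
# regulatory network


def generate_regulatory_network(scenario: SyntheticScenario) -> ConnectivityMatrix:
    """Sparse signed topology with guaranteed NCA identifiability.

    Each TF owns one exclusive gene that no other TF (besides the basal
    regulator) targets, which makes target sets pairwise distinct and
    never fully covered by the other TFs; remaining genes draw one
    primary TF plus occasional extras. The basal regulator is connected
    to every gene. Weights are uniform in magnitude [0.3, 1] with random
    sign.
    """
    rng = np.random.default_rng((scenario.seed, 0))
    n_tf, n_genes = scenario.n_regulators, scenario.n_genes
    if n_tf > n_genes:
        raise ValueError(
            f"cannot build {n_tf} distinct target sets from {n_genes} genes"
        )
    genes, tfs = scenario.gene_ids, scenario.regulator_ids
    weights = pd.DataFrame(
        0.0, index=tfs + [GLOBAL_REGULATOR_ID], columns=genes
    )

    def draw_weight() -> float:
        return float(rng.uniform(0.3, 1.0) * rng.choice([-1.0, 1.0]))

    for j, tf in enumerate(tfs):  # exclusive gene per TF
        weights.at[tf, genes[j]] = draw_weight()
    for i in range(n_tf, n_genes):
        if n_tf:
            primary = int(rng.integers(n_tf))
            weights.at[tfs[primary], genes[i]] = draw_weight()
            for j in range(n_tf):  # sparse extra edges
                if j != primary and rng.random() < 0.15:
                    weights.at[tfs[j], genes[i]] = draw_weight()
    weights.loc[GLOBAL_REGULATOR_ID] = 1.0
    return ConnectivityMatrix(weights)


# ---------------------------------------------------------------------------
# activities


def _relaxation_profile(
    times: np.ndarray,
    boundaries_h: tuple[float, float],
    levels: np.ndarray,
    taus: np.ndarray,
    start_level: float,
    delays: np.ndarray | None = None,
) -> np.ndarray:
    """Piecewise exponential relaxation toward a per-phase target level.

    Within each phase x(t) holds its previous value for an optional
    per-phase response delay, then relaxes toward the phase level with
    time constant tau. Delays stagger when regulators react to a phase
    switch, which is what makes a population of profiles mutually
    distinguishable: with only three phases, zero-delay profiles would
    be near-linear combinations of each other. The grid step is added
    to the post-delay elapsed time so the first relaxing point has
    already moved off the previous level.
    """
    dt = float(times[1] - times[0]) if len(times) > 1 else 1.0
    if delays is None:
        delays = np.zeros(3)
    edges = [times[0], *boundaries_h, times[-1] + dt]
    out = np.empty_like(times, dtype=float)
    current = start_level
    for phase in range(3):
        mask = (times >= edges[phase]) & (times < edges[phase + 1])
        if not mask.any():
            continue
        t_phase = times[mask]
        elapsed = t_phase - edges[phase] - delays[phase] + dt
        decay = np.where(
            elapsed > 0, np.exp(-np.maximum(elapsed, 0.0) / taus[phase]), 1.0
        )
        out[mask] = levels[phase] + (current - levels[phase]) * decay
        current = float(out[mask][-1])
    return out


def generate_tf_activities(
    scenario: SyntheticScenario,
    constant_regulators: tuple[str, ...] = (),
) -> ActivityEnsemble:
    """Smooth planted activity profiles on the transcriptome grid.

    The first TF follows on-off-on dynamics (high in both growth phases,
    low during starvation, fast transitions) to exercise the TF phase
    filter; the remaining TFs relax toward random per-phase levels; the
    basal regulator is constant. Returned as a degenerate single-member
    ensemble that downstream stages accept anywhere an inferred ensemble
    would go.
    """
    rng = np.random.default_rng((scenario.seed, 1))
    times = scenario.transcriptome_times
    bounds = scenario.phase_boundary_hours
    profiles = {}
    for j, tf in enumerate(scenario.regulator_ids):
        if tf in constant_regulators:
            profiles[tf] = np.full_like(times, 1.0)
        elif j == 0:  # on-off-on: tracks the growth phases
            profiles[tf] = _relaxation_profile(
                times, bounds,
                levels=np.array([1.0, 0.0, 1.0]),
                taus=np.array([0.3, 0.3, 0.3]),
                start_level=1.0,
            )
        else:
            # The starvation switch is a strong perturbation meant to
            # excite every regulator: require a minimum dynamic range
            # (level span >= 0.5) so no profile degenerates toward the
            # constant case, and distinct growth-phase levels
            # (|L0 - L2| >= 0.35) so no profile mimics the on-off-on
            # pattern reserved for the first TF.
            levels = rng.uniform(0.0, 1.0, size=3)
            while np.ptp(levels) < 0.5 or abs(levels[0] - levels[2]) < 0.35:
                levels = rng.uniform(0.0, 1.0, size=3)
            phase_len = np.diff([times[0], *bounds, times[-1]])
            profiles[tf] = _relaxation_profile(
                times, bounds,
                levels=levels,
                taus=rng.uniform(0.5, 3.0, size=3),
                start_level=float(levels[0]),
                delays=rng.uniform(0.0, 0.45, size=3) * phase_len,
            )
    profiles[GLOBAL_REGULATOR_ID] = np.full_like(times, 1.0)
    frame = pd.DataFrame(profiles, index=times).T
    return ActivityEnsemble.from_truth(frame, times)


# ---------------------------------------------------------------------------
# expression


def generate_expression(
    truth_activities: ActivityEnsemble,
    connectivity: ConnectivityMatrix,
    scenario: SyntheticScenario,
) -> ExpressionMatrix:
    """E = A.P + eps on the log10 scale, in replicate columns.

    Replicate columns at the same time point share the noiseless mean
    A.P and differ only in the i.i.d. normal(0, noise_sd^2) noise.
    """
    p = truth_activities.mean
    missing = [r for r in connectivity.regulator_ids if r not in p.index]
    if missing:
        raise ValueError(f"activities missing regulators: {missing}")
    p = p.loc[connectivity.regulator_ids]
    if p.shape[1] != scenario.n_timepoints:
        raise ValueError(
            f"activity grid has {p.shape[1]} points, scenario declares "
            f"{scenario.n_timepoints}"
        )
    mean = connectivity.weights.to_numpy().T @ p.to_numpy()  # genes x time

    rng = np.random.default_rng((scenario.seed, 2))
    times = scenario.transcriptome_times
    columns, data = [], []
    for k, t in enumerate(times):
        for rep in range(1, scenario.replicate_count + 1):
            columns.append(f"t{t:g}_r{rep}")
            noise = rng.normal(0.0, scenario.noise_sd, size=scenario.n_genes)
            data.append(mean[:, k] + noise)
    values = pd.DataFrame(
        np.column_stack(data), index=connectivity.gene_ids, columns=columns
    )
    sample_times = np.repeat(times, scenario.replicate_count)
    reps = list(range(1, scenario.replicate_count + 1)) * len(times)
    return ExpressionMatrix(values, sample_times, reps)


# ---------------------------------------------------------------------------
# metabolites


def _rescale_unit(profile: np.ndarray) -> np.ndarray | None:
    lo, hi = RESCALE_INTERVAL
    span = profile.max() - profile.min()
    if span == 0:
        return None
    return lo + (hi - lo) * (profile - profile.min()) / span


def invert_hill(r: np.ndarray, K_H: float, h: float, mode: str) -> np.ndarray:
    """Concentration x at which the Hill transform equals r in (0, 1)."""
    r = np.asarray(r, float)
    ratio = r / (1.0 - r) if mode == "activation" else (1.0 - r) / r
    return K_H * ratio ** (1.0 / h)


def generate_metabolites(
    truth_activities: ActivityEnsemble,
    scenario: SyntheticScenario,
) -> tuple[MetaboliteTable, dict]:
    """Metabolite trajectories coupled to planted TF activities.

    For each planted interaction the regulator's activity profile is
    rescaled into (0.05, 0.95) and pushed through the inverse Hill
    transform, so that refitting the forward model recovers (mode, K_H,
    h) exactly in the noiseless limit. A planted lag of one point makes
    the activity trail the metabolite by one transcriptome sample.
    Non-planted metabolites follow smooth random trajectories over a
    1-1000 µM range. Multiplicative lognormal noise emulates measurement
    error; replicates share the noiseless trajectory.
    """
    rng = np.random.default_rng((scenario.seed, 3))
    tt = scenario.transcriptome_times
    mt = scenario.metabolome_times
    bounds = scenario.phase_boundary_hours

    planted_by_met = {p.metabolite_id: p for p in scenario.planted_interactions}
    truth_records = []
    noiseless = {}
    for met in scenario.metabolite_ids:
        planted = planted_by_met.get(met)
        if planted is not None:
            profile = truth_activities.mean.loc[planted.regulator_id].to_numpy()
            if planted.lag == 1:
                # activity at t_{i+1} responds to the metabolite at t_i
                profile = np.append(profile[1:], profile[-1])
            r = _rescale_unit(profile)
            if r is None:
                warnings.warn(
                    f"activity of {planted.regulator_id} is constant; "
                    f"cannot invert the Hill transform for {met}",
                    stacklevel=2,
                )
                planted = None
            else:
                x_tt = invert_hill(r, planted.K_H, planted.h, planted.mode)
                noiseless[met] = np.interp(mt, tt, x_tt)
                truth_records.append(asdict(planted))
        if planted is None:  # decoy: smooth random trajectory
            log_levels = rng.uniform(0.0, 3.0, size=3)
            taus = rng.uniform(0.5, 2.0, size=3)
            start = float(rng.uniform(0.0, 3.0))
            log_x = _relaxation_profile(mt, bounds, log_levels, taus, start)
            noiseless[met] = 10.0 ** log_x

    sigma = float(np.sqrt(np.log(1.0 + scenario.metabolite_noise_cv**2)))
    columns, data = [], []
    for k, t in enumerate(mt):
        for rep in range(1, scenario.replicate_count + 1):
            columns.append(f"t{t:g}_r{rep}")
            noise = (
                np.exp(rng.normal(0.0, sigma, size=scenario.n_metabolites))
                if sigma > 0
                else np.ones(scenario.n_metabolites)
            )
            data.append(
                np.array([noiseless[m][k] for m in scenario.metabolite_ids])
                * noise
            )
    values = pd.DataFrame(
        np.column_stack(data), index=scenario.metabolite_ids, columns=columns
    )
    sample_times = np.repeat(mt, scenario.replicate_count)
    reps = list(range(1, scenario.replicate_count + 1)) * len(mt)
    table = MetaboliteTable(values, sample_times, reps)

    ground_truth = {
        "planted": truth_records,
        "transcriptome_times": tt.tolist(),
        "metabolome_times": mt.tolist(),
        "phase_boundary_hours": list(bounds),
        "activity_profiles": {
            reg: truth_activities.mean.loc[reg].tolist()
            for reg in truth_activities.regulator_ids
        },
    }
    return table, ground_truth


# ---------------------------------------------------------------------------
# toy metabolic model


def generate_toy_metabolic_model(
    scenario: SyntheticScenario,
    connectivity: ConnectivityMatrix | None = None,
) -> MetabolicModel:
    """Small stoichiometric model consistent with the planted truth.

    Each planted metabolite is a substrate of a reaction encoded by a
    target gene of its planted TF (its own exclusive gene when the
    regulatory network is supplied), in a subsystem of its own, so the
    planted pair satisfies the substrate/product criterion and no other.
    Decoy metabolites feed transport reactions encoded by genes of the
    on-off-on TF, which the screen excludes, so chance correlators fail
    the criterion. Cofactors participate everywhere and two non-cytosolic
    species exercise the pruning step.
    """
    planted = list(scenario.planted_interactions)
    tf_gene: dict[str, str] = {}
    if connectivity is not None:
        for p in planted:
            targets = sorted(connectivity.targets_of(p.regulator_id))
            if not targets:
                raise ValueError(f"{p.regulator_id} has no target genes")
            tf_gene[p.regulator_id] = targets[0]
        # decoy reactions use only the on-off-on TF's exclusive gene
        # (gene index 0): no screened TF targets it, so chance
        # correlators among decoys cannot satisfy the criterion
        onoff = scenario.regulator_ids[0]
        exclusive = [
            g for g in sorted(connectivity.targets_of(onoff))
            if all(
                g not in connectivity.targets_of(tf)
                for tf in connectivity.tf_ids
                if tf != onoff
            )
        ]
        onoff_targets = exclusive or sorted(connectivity.targets_of(onoff))
    else:
        for i, p in enumerate(planted):
            tf_gene[p.regulator_id] = f"g{int(p.regulator_id[2:]):03d}"
        onoff_targets = ["g000"]

    mets: dict[str, str] = {}  # id -> compartment
    reactions: list[dict] = []

    def add_met(mid: str, compartment: str = "c") -> str:
        mets.setdefault(mid, compartment)
        return mid

    cofactors = [add_met("cof_atp"), add_met("cof_nad")]
    add_met("ext_glc", "e")
    add_met("per_glc", "p")

    hub = add_met("internal_hub")
    for i, p in enumerate(planted):
        product = add_met(f"internal_{i:02d}")
        reactions.append({
            "id": f"rxn_planted_{i:02d}",
            "subsystem": f"pathway_{i:02d}",
            "genes": [tf_gene[p.regulator_id]],
            "stoichiometry": {
                add_met(p.metabolite_id): -1.0,
                product: 1.0,
                "cof_atp": -1.0,
            },
        })
        reactions.append({
            "id": f"rxn_link_{i:02d}",
            "subsystem": f"pathway_{i:02d}",
            "genes": [tf_gene[p.regulator_id]],
            "stoichiometry": {product: -1.0, hub: 1.0, "cof_nad": -1.0},
        })
    decoys = [m for m in scenario.metabolite_ids
              if m not in {p.metabolite_id for p in planted}]
    for i, met in enumerate(decoys):
        gene = onoff_targets[i % len(onoff_targets)]
        reactions.append({
            "id": f"rxn_decoy_{i:02d}",
            "subsystem": "transport",
            "genes": [gene],
            "stoichiometry": {add_met(met): -1.0, hub: 1.0},
        })
    # uptake chain through the non-cytosolic species, geneless on purpose
    reactions.append({
        "id": "rxn_uptake",
        "subsystem": "transport",
        "genes": [],
        "stoichiometry": {"ext_glc": -1.0, "per_glc": 1.0},
    })

    met_ids = list(mets)
    rxn_ids = [r["id"] for r in reactions]
    gene_ids = sorted({g for r in reactions for g in r["genes"]})
    n = pd.DataFrame(0.0, index=met_ids, columns=rxn_ids)
    g = pd.DataFrame(False, index=rxn_ids, columns=gene_ids)
    subsystems, geneless = {}, []
    for r in reactions:
        for mid, coef in r["stoichiometry"].items():
            n.at[mid, r["id"]] = coef
        subsystems[r["id"]] = r["subsystem"]
        if r["genes"]:
            g.loc[r["id"], r["genes"]] = True
        else:
            geneless.append(r["id"])
    return MetabolicModel(
        stoichiometry=n,
        reaction_genes=g,
        subsystems=subsystems,
        compartments=dict(mets),
        cofactors=cofactors,
        geneless_reactions=geneless,
    )


# ---------------------------------------------------------------------------
# bundle


def simulate_bundle(scenario: SyntheticScenario, out_dir) -> dict:
    """Generate one full scenario and write every input the CLI consumes.

    Emits expression.tsv (TPM scale), metabolites.tsv (µM), network.tsv
    (regulator-gene triplets), model.json, literature.tsv (the planted
    truth as a curated network), two_component.tsv, truth.json and
    alignment.tsv (transcriptome-to-metabolome grid map). Returns the
    in-memory objects.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    connectivity = generate_regulatory_network(scenario)
    activities = generate_tf_activities(scenario)
    expression = generate_expression(activities, connectivity, scenario)
    metabolites, truth = generate_metabolites(activities, scenario)
    model = generate_toy_metabolic_model(scenario, connectivity)

    write_expression(expression, out / "expression.tsv")
    write_metabolites(metabolites, out / "metabolites.tsv")
    write_interaction_table(connectivity, out / "network.tsv")
    write_metabolic_model(model, out / "model.json")
    literature = LiteratureNetwork(
        pd.DataFrame(
            [
                (p.metabolite_id, p.regulator_id, p.mode)
                for p in scenario.planted_interactions
            ],
            columns=["metabolite_id", "regulator_id", "mode"],
        )
    )
    literature.edges.to_csv(out / "literature.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"regulator": list(scenario.two_component_regulators)}
    ).to_csv(out / "two_component.tsv", sep="\t", index=False)
    scenario.grid_alignment().to_csv(out / "alignment.tsv", sep="\t", index=False)
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)

    return {
        "connectivity": connectivity,
        "activities": activities,
        "expression": expression,
        "metabolites": metabolites,
        "model": model,
        "literature": literature,
        "truth": truth,
    }
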