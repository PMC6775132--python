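"""Metabolite-gene distances on a genome-scale metabolic model.

A metabolic model is reduced to an undirected bipartite graph with
metabolite and gene nodes: cofactors and non-cytosolic metabolites are
pruned from the stoichiometric matrix N, the metabolite-gene adjacency
F = |N|.G is computed from the reaction-gene matrix G, and an edge is
drawn wherever the boolean F' is true. Shortest-path lengths on this
graph measure how close a metabolite is to the enzymes a transcription
factor controls, and the two-part proximity criterion (substrate/product
of a target-gene enzyme, or shared metabolic subsystem) prunes
metabolite-TF candidate interactions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_COFACTORS",
    "MetabolicModel",
    "DistanceMatrix",
    "CriterionVerdict",
    "build_adjacency",
    "all_pairs_distance",
    "tf_min_distance",
    "distance_criterion",
]

#: Ubiquitous currency metabolites pruned before building the bipartite
#: graph. Users supply their own list for non-default id namespaces.
DEFAULT_COFACTORS: tuple[str, ...] = (
    "atp", "adp", "amp",
    "nad", "nadh", "nadp", "nadph",
    "coa", "accoa",
    "h", "h2o", "pi", "ppi", "co2", "o2", "nh4",
    "gtp", "gdp", "gmp", "utp", "udp", "ump", "ctp", "cdp", "cmp",
    "fad", "fadh2", "q8", "q8h2",
)

CYTOSOL_COMPARTMENTS = ("c", "cytosol", "cytoplasm")


@dataclass
class MetabolicModel:
    """Stoichiometric model with gene associations and annotations.

    Attributes
    ----------
    stoichiometry : DataFrame, metabolites x reactions
        Signed stoichiometric matrix N.
    reaction_genes : DataFrame, reactions x genes (bool)
        G(r, g) true when gene g appears in reaction r's gene rule
        (any gene in the boolean rule counts; reachability, not
        enzyme logic).
    subsystems : dict reaction id -> subsystem label
        Reactions without annotation map to "unknown subsystem".
    compartments : dict metabolite id -> compartment tag
        "c" cytosolic, "p" periplasmic, "e" extracellular.
    cofactors : list of metabolite ids
    geneless_reactions : list of reaction ids retained without genes
    """

    stoichiometry: pd.DataFrame
    reaction_genes: pd.DataFrame
    subsystems: dict[str, str] = field(default_factory=dict)
    compartments: dict[str, str] = field(default_factory=dict)
    cofactors: list[str] = field(default_factory=list)
    geneless_reactions: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n_rxn_n = self.stoichiometry.shape[1]
        n_rxn_g = self.reaction_genes.shape[0]
        if n_rxn_n != n_rxn_g or list(self.stoichiometry.columns) != list(
            self.reaction_genes.index
        ):
            raise ValueError(
                "stoichiometry columns and reaction_genes rows must list the "
                f"same reactions (got {n_rxn_n} vs {n_rxn_g})"
            )
        unknown = set(self.cofactors) - set(self.metabolite_ids)
        if unknown:
            raise ValueError(f"cofactors not in the model: {sorted(unknown)}")

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.stoichiometry.index)

    @property
    def reaction_ids(self) -> list[str]:
        return list(self.stoichiometry.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.reaction_genes.columns)

    def subsystem_of(self, reaction_id: str) -> str:
        return self.subsystems.get(reaction_id, "unknown subsystem")


@dataclass
class DistanceMatrix:
    """Pairwise shortest-path lengths between metabolites and genes.

    All finite entries are odd positive integers: the graph is bipartite
    and every metabolite-gene path alternates node types. Unreachable
    pairs are ``inf``.
    """

    values: pd.DataFrame  # metabolites x genes, float with inf

    def distance(self, metabolite_id: str, gene_id: str) -> float:
        return float(self.values.at[metabolite_id, gene_id])

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path) -> None:
        out = self.values.replace(np.inf, "Inf")
        out.to_csv(path, sep="\t", index_label="metabolite")

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col="metabolite")
        df.index.name = None
        return cls(df.replace("Inf", np.inf).astype(float))


@dataclass
class CriterionVerdict:
    """Outcome of the two-part metabolite-TF proximity criterion."""

    metabolite_id: str
    regulator_id: str
    passes: bool
    satisfied_by: str  # "substrate_product" | "subsystem" | "none"
    witness_gene: str | None = None
    computable: bool = True

    def __post_init__(self) -> None:
        if self.passes != (self.satisfied_by != "none"):
            raise ValueError("passes must match satisfied_by != 'none'")


def _met_node(metabolite_id: str) -> tuple[str, str]:
    return ("met", metabolite_id)


def _gene_node(gene_id: str) -> tuple[str, str]:
    return ("gene", gene_id)


def prune_model_matrices(
    model: MetabolicModel,
    cofactors: list[str] | None = None,
) -> pd.DataFrame:
    """Return N restricted to cytosolic, non-cofactor metabolites."""
    drop = set(model.cofactors if cofactors is None else cofactors)
    keep = []
    for met in model.metabolite_ids:
        if met in drop:
            continue
        comp = model.compartments.get(met, "c").lower()
        if comp not in CYTOSOL_COMPARTMENTS:
            continue
        keep.append(met)
    return model.stoichiometry.loc[keep]


def build_adjacency(
    model: MetabolicModel,
    cofactors: list[str] | None = None,
) -> tuple[pd.DataFrame, nx.Graph]:
    """Build the boolean metabolite-gene adjacency F' and its graph.

    Cofactors and periplasmic/extracellular metabolites are removed from
    the stoichiometric matrix first; then F = |N| . G and F' = bool(F).
    The returned graph is undirected and bipartite with nodes
    ``("met", id)`` and ``("gene", id)``; an edge means the metabolite is
    a substrate or product of a reaction encoded by the gene. Geneless
    reactions contribute no edges.

    Raises
    ------
    ValueError
        If no edge survives pruning (empty graph).
    """
    n_pruned = prune_model_matrices(model, cofactors)
    g_matrix = model.reaction_genes.astype(float)
    f = n_pruned.abs().to_numpy() @ g_matrix.to_numpy()
    f_prime = pd.DataFrame(
        f > 0, index=n_pruned.index, columns=g_matrix.columns
    )

    graph = nx.Graph()
    mets, genes = np.nonzero(f_prime.to_numpy())
    for i, j in zip(mets, genes):
        graph.add_edge(
            _met_node(f_prime.index[i]), _gene_node(f_prime.columns[j])
        )
    if graph.number_of_edges() == 0:
        raise ValueError(
            "empty metabolite-gene graph after pruning cofactors and "
            "non-cytosolic metabolites"
        )
    return f_prime, graph


def all_pairs_distance(
    graph: nx.Graph,
    f_prime: pd.DataFrame | None = None,
) -> DistanceMatrix:
    """Breadth-first shortest paths from every metabolite to every gene.

    Unreachable pairs are ``inf``. When ``f_prime`` is given its index
    and columns fix the output layout (metabolites or genes absent from
    the graph get all-inf rows/columns); otherwise the layout is the
    sorted node sets of the graph.
    """
    if f_prime is not None:
        met_ids = list(f_prime.index)
        gene_ids = list(f_prime.columns)
    else:
        met_ids = sorted(n[1] for n in graph.nodes if n[0] == "met")
        gene_ids = sorted(n[1] for n in graph.nodes if n[0] == "gene")

    values = np.full((len(met_ids), len(gene_ids)), np.inf)
    gene_pos = {g: j for j, g in enumerate(gene_ids)}
    for i, met in enumerate(met_ids):
        node = _met_node(met)
        if node not in graph:
            continue
        lengths = nx.single_source_shortest_path_length(graph, node)
        for target, dist in lengths.items():
            if target[0] == "gene" and target[1] in gene_pos:
                values[i, gene_pos[target[1]]] = dist
    return DistanceMatrix(pd.DataFrame(values, index=met_ids, columns=gene_ids))


def tf_min_distance(
    metabolite_id: str,
    tf_targets: set[str] | list[str],
    distances: DistanceMatrix,
) -> float | None:
    """Smallest distance from a metabolite to any target gene of a TF.

    Returns ``None`` (not computable, distinct from ``inf``) when the
    metabolite is absent from the distance matrix or none of the target
    genes is in the model.
    """
    if metabolite_id not in distances.values.index:
        return None
    present = [g for g in tf_targets if g in distances.values.columns]
    if not present:
        return None
    return float(distances.values.loc[metabolite_id, present].min())


def _tf_subsystems(
    model: MetabolicModel, tf_targets: set[str]
) -> dict[str, tuple[str, str]]:
    """Subsystems controlled by a TF: union over reactions encoded by
    its target genes. Maps subsystem -> (witness gene, reaction)."""
    out: dict[str, tuple[str, str]] = {}
    g = model.reaction_genes
    target_cols = [c for c in g.columns if c in tf_targets]
    if not target_cols:
        return out
    sub = g[target_cols]
    for rxn in g.index[sub.any(axis=1)]:
        witness = sub.columns[sub.loc[rxn]][0]
        out.setdefault(model.subsystem_of(rxn), (witness, rxn))
    return out


def metabolite_subsystems(
    model: MetabolicModel,
    metabolite_id: str,
    annotation: dict[str, set[str]] | None = None,
) -> set[str]:
    """Subsystems of a metabolite.

    Taken from the user annotation table when present; otherwise
    defaults to the subsystems of the reactions the metabolite
    participates in.
    """
    if annotation and metabolite_id in annotation:
        return set(annotation[metabolite_id])
    if metabolite_id not in model.stoichiometry.index:
        return set()
    row = model.stoichiometry.loc[metabolite_id]
    return {model.subsystem_of(r) for r in row.index[row != 0]}


def distance_criterion(
    metabolite_id: str,
    regulator_id: str,
    model: MetabolicModel,
    tf_targets: set[str] | list[str],
    f_prime: pd.DataFrame | None = None,
    metabolite_annotation: dict[str, set[str]] | None = None,
) -> CriterionVerdict:
    """Two-part proximity criterion for a metabolite-TF pair.

    Passes when (1) the metabolite is a substrate or product of an
    enzyme encoded by a target gene of the TF (adjacency in F'), or
    (2) the metabolite shares a metabolic subsystem with such an enzyme.
    Criterion 2 is distance-free. A metabolite absent from the model
    with no subsystem annotation yields a not-computable verdict.
    """
    targets = set(tf_targets)
    if f_prime is None:
        f_prime, _ = build_adjacency(model)

    # criterion 1: direct substrate/product adjacency
    if metabolite_id in f_prime.index:
        row = f_prime.loc[metabolite_id]
        hits = [g for g in row.index[row] if g in targets]
        if hits:
            return CriterionVerdict(
                metabolite_id, regulator_id, True, "substrate_product",
                witness_gene=hits[0],
            )

    # criterion 2: shared metabolic subsystem
    met_subs = metabolite_subsystems(model, metabolite_id, metabolite_annotation)
    tf_subs = _tf_subsystems(model, targets)
    shared = sorted((met_subs & set(tf_subs)) - {"unknown subsystem"})
    if shared:
        witness, _ = tf_subs[shared[0]]
        return CriterionVerdict(
            metabolite_id, regulator_id, True, "subsystem", witness_gene=witness
        )

    computable = bool(met_subs) or metabolite_id in model.stoichiometry.index
    return CriterionVerdict(
        metabolite_id, regulator_id, False, "none", computable=computable
    )
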