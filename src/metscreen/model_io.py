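"""Readers and writers for the external formats of the screen.

Time-course tables are plain TSV with the first column holding ids and
the remaining column headers encoding sampling time and replicate as
``t<hours>_r<replicate>`` (e.g. ``t3.5_r2``). Expression is stored
internally on the log10 scale in TPM units; metabolite concentrations
are linear µM. Regulatory networks are (regulator, gene, sign) triplet
tables; metabolic models are SBML (read through cobrapy) or this
package's JSON schema.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .metnet_distance import MetabolicModel

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "ConnectivityMatrix",
    "MetaboliteTable",
    "LiteratureNetwork",
    "load_expression",
    "write_expression",
    "load_metabolites",
    "write_metabolites",
    "load_interaction_table",
    "write_interaction_table",
    "assemble_connectivity",
    "load_literature_network",
    "load_metabolic_model",
    "write_metabolic_model",
    "GLOBAL_REGULATOR_ID",
]

#: Name of the synthetic basal regulator connected to every gene; it
#: absorbs RNA-polymerase baseline expression in the factorization.
GLOBAL_REGULATOR_ID = "global_basal"

_SAMPLE_RE = re.compile(r"^t(?P<time>-?\d+(?:\.\d+)?)_r(?P<rep>\d+)$")


def _parse_sample_columns(columns) -> tuple[np.ndarray, list[int]]:
    times, reps = [], []
    for col in columns:
        m = _SAMPLE_RE.match(str(col))
        if m is None:
            raise ValueError(
                f"cannot parse sample header {col!r}; expected 't<hours>_r<rep>'"
            )
        times.append(float(m.group("time")))
        reps.append(int(m.group("rep")))
    t = np.asarray(times, dtype=float)
    if np.any(np.diff(t) < 0):
        raise ValueError("sample columns must be sorted by ascending time")
    return t, reps


@dataclass
class _TimeCourse:
    """Shared structure of expression and metabolite tables."""

    values: pd.DataFrame  # ids x sample columns
    sample_times: np.ndarray  # hours, one per column
    replicate_labels: list[int]

    def __post_init__(self) -> None:
        ids = self.values.index
        if ids.has_duplicates:
            dup = ids[ids.duplicated()].unique().tolist()
            raise ValueError(f"duplicate ids: {dup}")

    @property
    def ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def time_points(self) -> np.ndarray:
        """Unique sampling times, ascending (hours)."""
        return np.unique(self.sample_times)

    def mean_profiles(self) -> pd.DataFrame:
        """Replicate-mean trajectory per id (ids x unique time points)."""
        grouped = self.values.T.groupby(self.sample_times).mean().T
        return grouped.reindex(columns=self.time_points)


@dataclass
class ExpressionMatrix(_TimeCourse):
    """log10-transformed gene expression (TPM), genes x samples."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValueError("expression matrix contains non-finite values")

    @property
    def gene_ids(self) -> list[str]:
        return self.ids


@dataclass
class MetaboliteTable(_TimeCourse):
    """Metabolite concentrations (µM), metabolites x samples."""

    def __post_init__(self) -> None:
        super().__post_init__()
        vals = self.values.to_numpy()
        if np.any(vals[np.isfinite(vals)] < 0):
            raise ValueError("metabolite concentrations must be >= 0")

    @property
    def metabolite_ids(self) -> list[str]:
        return self.ids


@dataclass
class ConnectivityMatrix:
    """Signed regulator-gene topology (regulators x genes).

    The zero pattern is the fixed network structure; nonzero entries are
    free initial weights for the factorization. One row is the global
    basal regulator, connected to every gene.
    """

    weights: pd.DataFrame  # regulators x genes
    global_regulator: str = GLOBAL_REGULATOR_ID

    def __post_init__(self) -> None:
        if self.global_regulator in self.weights.index:
            row = self.weights.loc[self.global_regulator]
            if (row == 0).any():
                raise ValueError("global regulator row must connect all genes")
        dead = self.weights.columns[(self.weights != 0).sum(axis=0) == 0]
        if len(dead):
            raise ValueError(
                f"genes with no regulator: {list(dead[:5])}"
                + ("..." if len(dead) > 5 else "")
            )

    @property
    def regulator_ids(self) -> list[str]:
        return list(self.weights.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.weights.columns)

    @property
    def tf_ids(self) -> list[str]:
        """Regulators excluding the global basal row."""
        return [r for r in self.weights.index if r != self.global_regulator]

    def pattern(self) -> np.ndarray:
        """Boolean regulators x genes nonzero pattern."""
        return (self.weights.to_numpy() != 0)

    def targets_of(self, regulator_id: str) -> set[str]:
        row = self.weights.loc[regulator_id]
        return set(row.index[row != 0])


@dataclass
class LiteratureNetwork:
    """Curated metabolite-TF interactions with annotated mode."""

    edges: pd.DataFrame  # columns: metabolite_id, regulator_id, mode
    unresolved: list[tuple[str, str]] = field(default_factory=list)

    MODES = ("activation", "inhibition", "unknown")

    def __post_init__(self) -> None:
        required = {"metabolite_id", "regulator_id", "mode"}
        missing = required - set(self.edges.columns)
        if missing:
            raise ValueError(f"literature network missing columns: {missing}")
        bad = set(self.edges["mode"]) - set(self.MODES)
        if bad:
            raise ValueError(f"unknown interaction modes: {bad}")

    def resolve(
        self, metabolite_ids: list[str], regulator_ids: list[str]
    ) -> "LiteratureNetwork":
        """Report edges whose ids are absent from the loaded tables.

        Unresolvable edges are recorded, never silently dropped.
        """
        mets, regs = set(metabolite_ids), set(regulator_ids)
        unresolved = [
            (row.metabolite_id, row.regulator_id)
            for row in self.edges.itertuples()
            if row.metabolite_id not in mets or row.regulator_id not in regs
        ]
        for met, reg in unresolved:
            logger.warning("literature edge (%s, %s) not resolvable", met, reg)
        return LiteratureNetwork(self.edges.copy(), unresolved=unresolved)


# ---------------------------------------------------------------------------
# expression / metabolite tables


def load_expression(
    path,
    pseudocount: float = 0.01,
    pseudocount_policy: str = "clip",
) -> ExpressionMatrix:
    """Read a TPM table and log10-transform it.

    Zero TPMs are handled per policy: ``"clip"`` (default) floors values
    at the pseudocount before the log, so nonzero TPMs well above the
    floor are untouched; ``"add"`` adds the pseudocount everywhere.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    times, reps = _parse_sample_columns(df.columns)
    if not df.map(lambda v: isinstance(v, (int, float))).all().all():
        bad = df.columns[~df.apply(pd.api.types.is_numeric_dtype)]
        raise ValueError(f"non-numeric expression values in columns {list(bad)}")
    tpm = df.astype(float)
    if (tpm.to_numpy() < 0).any():
        raise ValueError("negative TPM values")
    if pseudocount_policy == "clip":
        logged = np.log10(tpm.clip(lower=pseudocount))
    elif pseudocount_policy == "add":
        logged = np.log10(tpm + pseudocount)
    else:
        raise ValueError(f"unknown pseudocount policy {pseudocount_policy!r}")
    return ExpressionMatrix(logged, times, reps)


def write_expression(expr: ExpressionMatrix, path) -> None:
    """Write an expression matrix back to linear TPM scale."""
    tpm = 10.0 ** expr.values
    tpm.to_csv(path, sep="\t", index_label="gene")


def load_metabolites(path) -> MetaboliteTable:
    df = pd.read_csv(path, sep="\t", index_col=0).astype(float)
    times, reps = _parse_sample_columns(df.columns)
    return MetaboliteTable(df, times, reps)


def write_metabolites(table: MetaboliteTable, path) -> None:
    table.values.to_csv(path, sep="\t", index_label="metabolite")


# ---------------------------------------------------------------------------
# regulatory network


def load_interaction_table(path) -> pd.DataFrame:
    """Read (regulator, gene[, sign]) triplets; sign defaults to +1."""
    df = pd.read_csv(path, sep="\t", dtype={"regulator": str, "gene": str})
    if not {"regulator", "gene"} <= set(df.columns):
        raise ValueError("interaction table needs 'regulator' and 'gene' columns")
    if "sign" not in df.columns:
        df["sign"] = 1.0
    df["sign"] = df["sign"].astype(float).replace(0.0, 1.0)
    return df[["regulator", "gene", "sign"]]


def write_interaction_table(connectivity: ConnectivityMatrix, path) -> None:
    rows = []
    w = connectivity.weights
    for reg in connectivity.tf_ids:
        row = w.loc[reg]
        for gene in row.index[row != 0]:
            rows.append((reg, gene, float(np.sign(row[gene]) or 1.0)))
    pd.DataFrame(rows, columns=["regulator", "gene", "sign"]).to_csv(
        path, sep="\t", index=False
    )


def assemble_connectivity(
    interaction_tables: list[pd.DataFrame],
    gene_universe: list[str],
    add_global_regulator: bool = True,
) -> ConnectivityMatrix:
    """Union regulator-gene tables into one signed topology.

    Genes are restricted to ``gene_universe`` (typically the genes with
    expression data); regulators left with zero targets are dropped with
    a log entry; a global basal regulator connected to all retained
    genes is appended. The result is independent of table order: edges
    are deduplicated and rows/columns sorted.
    """
    if not interaction_tables:
        raise ValueError("no interaction tables supplied")
    edges = pd.concat(interaction_tables, ignore_index=True)
    if edges.empty:
        raise ValueError("interaction tables are empty")
    # union semantics: last sign wins only if tables disagree; keep first
    edges = edges.sort_values(["regulator", "gene"]).drop_duplicates(
        subset=["regulator", "gene"], keep="first"
    )

    universe = set(gene_universe)
    outside = edges.loc[~edges["gene"].isin(universe), "gene"].unique()
    for gene in outside:
        logger.info("gene %s absent from expression data; excluded", gene)
    edges = edges[edges["gene"].isin(universe)]
    if edges.empty:
        raise ValueError("no network gene overlaps the expression data")

    genes = sorted(edges["gene"].unique())
    regulators = sorted(edges["regulator"].unique())
    weights = pd.DataFrame(0.0, index=regulators, columns=genes)
    for row in edges.itertuples():
        weights.at[row.regulator, row.gene] = row.sign

    empty = [r for r in regulators if (weights.loc[r] == 0).all()]
    for reg in empty:
        logger.info("regulator %s has no targets after restriction; dropped", reg)
    weights = weights.drop(index=empty)

    if add_global_regulator:
        weights.loc[GLOBAL_REGULATOR_ID] = 1.0
    return ConnectivityMatrix(weights)


def load_literature_network(path) -> LiteratureNetwork:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "mode" not in df.columns:
        df["mode"] = "unknown"
    df["mode"] = df["mode"].fillna("unknown")
    return LiteratureNetwork(df[["metabolite_id", "regulator_id", "mode"]])


# ---------------------------------------------------------------------------
# metabolic model


def load_metabolic_model(path) -> MetabolicModel:
    """Load a metabolic model from SBML (via cobrapy) or package JSON."""
    path = Path(path)
    if path.suffix.lower() in {".xml", ".sbml"}:
        return _model_from_cobra(path)
    with open(path) as fh:
        doc = json.load(fh)
    return _model_from_dict(doc)


def write_metabolic_model(model: MetabolicModel, path) -> None:
    doc = {
        "metabolites": [
            {"id": m, "compartment": model.compartments.get(m, "c")}
            for m in model.metabolite_ids
        ],
        "reactions": [
            {
                "id": r,
                "subsystem": model.subsystems.get(r, ""),
                "genes": sorted(
                    model.reaction_genes.columns[model.reaction_genes.loc[r]]
                ),
                "stoichiometry": {
                    m: float(model.stoichiometry.at[m, r])
                    for m in model.metabolite_ids
                    if model.stoichiometry.at[m, r] != 0
                },
            }
            for r in model.reaction_ids
        ],
        "cofactors": list(model.cofactors),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)


def _model_from_dict(doc: dict) -> MetabolicModel:
    met_ids = [m["id"] for m in doc["metabolites"]]
    compartments = {m["id"]: m.get("compartment", "c") for m in doc["metabolites"]}
    rxn_ids = [r["id"] for r in doc["reactions"]]
    gene_ids = sorted({g for r in doc["reactions"] for g in r.get("genes", [])})

    n = pd.DataFrame(0.0, index=met_ids, columns=rxn_ids)
    g = pd.DataFrame(False, index=rxn_ids, columns=gene_ids)
    subsystems: dict[str, str] = {}
    geneless = []
    for rxn in doc["reactions"]:
        rid = rxn["id"]
        for met, coef in rxn["stoichiometry"].items():
            n.at[met, rid] = float(coef)
        if rxn.get("subsystem"):
            subsystems[rid] = rxn["subsystem"]
        genes = rxn.get("genes", [])
        if genes:
            g.loc[rid, genes] = True
        else:
            geneless.append(rid)
            logger.info("reaction %s has no gene association", rid)
    return MetabolicModel(
        stoichiometry=n,
        reaction_genes=g,
        subsystems=subsystems,
        compartments=compartments,
        cofactors=list(doc.get("cofactors", [])),
        geneless_reactions=geneless,
    )


def _model_from_cobra(path: Path) -> MetabolicModel:
    # lazy import: cobra is only needed on the SBML path and is slow to load
    import cobra.io

    cm = cobra.io.read_sbml_model(str(path))
    doc = {
        "metabolites": [
            {"id": m.id, "compartment": m.compartment or "c"}
            for m in cm.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "subsystem": r.subsystem or "",
                # flatten the boolean gene rule: any gene in the rule maps
                # to the reaction (reachability, not enzyme logic)
                "genes": sorted(g.id for g in r.genes),
                "stoichiometry": {
                    m.id: float(coef) for m, coef in r.metabolites.items()
                },
            }
            for r in cm.reactions
        ],
        "cofactors": [],
    }
    return _model_from_dict(doc)
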