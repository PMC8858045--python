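"""Domain containers and file formats.

Expression matrices travel as TSV (genes x samples) with per-sample
condition/batch labels either in a sidecar TSV or encoded in the header as
``sample|condition[|batch]``. Gene sets use GMT, interaction networks an
edge-list TSV compatible with STRING exports, and drug-target maps a flat
three-column TSV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

CASE = "case"
CONTROL = "control"

__all__ = [
    "ExpressionMatrix",
    "GeneSetCollection",
    "DrugTarget",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_gene_sets_gmt",
    "write_gene_sets_gmt",
    "read_edge_list",
    "write_edge_list",
    "read_drug_targets_tsv",
    "write_drug_targets_tsv",
    "standardize_per_batch",
]


@dataclass
class ExpressionMatrix:
    """Gene-by-sample log-intensity matrix with condition/batch labels.

    ``values`` has shape ``(len(gene_ids), len(sample_ids))``. ``condition``
    holds ``"case"``/``"control"`` per sample; ``batch`` defaults to a single
    batch. ``n_dropped_rows`` counts gene rows removed at load time for
    containing missing values.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    condition: list[str]
    batch: list[str] = field(default_factory=list)
    n_dropped_rows: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(self.condition) != len(self.sample_ids):
            raise ValueError("condition labels must match sample count")
        bad = set(self.condition) - {CASE, CONTROL}
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")
        if not self.batch:
            self.batch = ["batch0"] * len(self.sample_ids)
        if len(self.batch) != len(self.sample_ids):
            raise ValueError("batch labels must match sample count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def case_mask(self) -> np.ndarray:
        return np.array([c == CASE for c in self.condition])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_genes(self, genes) -> "ExpressionMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        keep = [g for g in genes if g in idx]
        rows = [idx[g] for g in keep]
        return ExpressionMatrix(
            gene_ids=keep,
            sample_ids=list(self.sample_ids),
            values=self.values[rows],
            condition=list(self.condition),
            batch=list(self.batch),
        )


@dataclass
class GeneSetCollection:
    """Named gene sets plus an optional explicit background universe."""

    sets: dict[str, set]
    universe: set | None = None

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")


@dataclass(frozen=True)
class DrugTarget:
    drug_id: str
    drug_name: str
    targets: frozenset

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValueError(f"drug {self.drug_id} has no targets")


# ---------------------------------------------------------------------------
# Expression TSV


def _parse_header_labels(columns):
    """Decode 'sample|condition[|batch]' column headers, if present."""
    if not all("|" in c for c in columns):
        return None
    sample_ids, condition, batch = [], [], []
    for col in columns:
        parts = col.split("|")
        if len(parts) not in (2, 3):
            return None
        sample_ids.append(parts[0])
        condition.append(parts[1])
        batch.append(parts[2] if len(parts) == 3 else "batch0")
    return sample_ids, condition, batch


def read_expression_tsv(path, labels_path=None) -> ExpressionMatrix:
    """Load a genes-x-samples TSV.

    Condition/batch come from the sidecar TSV ``labels_path`` (columns
    sample_id, condition, optional batch) or from header-encoded columns.
    Duplicate gene ids are collapsed by per-cell median, mirroring
    probe-to-gene collapse in microarray preprocessing. Rows containing
    missing values are dropped (counted in ``n_dropped_rows``); a non-numeric
    cell is a hard error naming its row and column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    raw_columns = list(df.columns)
    if len(set(raw_columns)) != len(raw_columns):
        raise ValueError(f"duplicate sample id in header of {path}")

    numeric = df.apply(pd.to_numeric, errors="coerce")
    # a cell that failed conversion but was not blank/NA in the source is malformed
    stripped = df.apply(lambda col: col.astype(str).str.strip())
    bad = numeric.isna() & df.notna() & (stripped != "")
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric value {df.iat[r, c]!r} at gene {df.index[r]!r}, "
            f"sample {raw_columns[c]!r} in {path}"
        )

    n_before = numeric.shape[0]
    numeric = numeric.dropna(axis=0, how="any")
    n_dropped = n_before - numeric.shape[0]
    if numeric.index.has_duplicates:
        numeric = numeric.groupby(level=0, sort=False).median()

    header = _parse_header_labels(raw_columns)
    if labels_path is not None:
        lab = pd.read_csv(labels_path, sep="\t", dtype=str)
        lab = lab.set_index("sample_id")
        missing = [s for s in raw_columns if s not in lab.index]
        if missing:
            raise ValueError(f"samples missing from labels file: {missing}")
        condition = [lab.loc[s, "condition"] for s in raw_columns]
        batch = (
            [lab.loc[s, "batch"] for s in raw_columns]
            if "batch" in lab.columns
            else []
        )
        sample_ids = raw_columns
    elif header is not None:
        sample_ids, condition, batch = header
        numeric.columns = sample_ids
    else:
        raise ValueError(
            f"{path}: no labels sidecar given and header is not "
            "'sample|condition[|batch]'-encoded"
        )
    return ExpressionMatrix(
        gene_ids=[str(g) for g in numeric.index],
        sample_ids=list(sample_ids),
        values=numeric.to_numpy(float),
        condition=list(condition),
        batch=list(batch),
        n_dropped_rows=n_dropped,
    )


def write_expression_tsv(expr: ExpressionMatrix, path, labels_path=None) -> None:
    """Write an expression TSV; labels go to a sidecar or into the header."""
    if labels_path is not None:
        expr.to_frame().to_csv(path, sep="\t")
        pd.DataFrame(
            {
                "sample_id": expr.sample_ids,
                "condition": expr.condition,
                "batch": expr.batch,
            }
        ).to_csv(labels_path, sep="\t", index=False)
    else:
        cols = [
            f"{s}|{c}|{b}"
            for s, c, b in zip(expr.sample_ids, expr.condition, expr.batch)
        ]
        df = pd.DataFrame(expr.values, index=expr.gene_ids, columns=cols)
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gene_sets_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: name <tab> description <tab> member..."""
    sets: dict[str, set] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has <3 fields")
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = {m for m in fields[2:] if m}
            if not members:
                warnings.warn(f"{path}:{lineno}: empty set {name!r} dropped")
                continue
            sets[name] = members
    return GeneSetCollection(sets=sets)


def write_gene_sets_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, "na", *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# Edge lists


def read_edge_list(path, min_score: float | None = None) -> nx.Graph:
    """Read a 2- or 3-column (node, node[, score]) TSV into a simple graph.

    Self-loops are dropped and reciprocal/duplicate edges collapsed. With a
    3-column file, ``min_score`` keeps only rows with score >= min_score
    (default: no filtering).
    """
    g = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: fewer than 2 columns")
            u, v = fields[0], fields[1]
            if len(fields) >= 3 and min_score is not None:
                if float(fields[2]) < min_score:
                    continue
            if u == v:
                continue
            g.add_edge(u, v)
    if g.number_of_nodes() == 0:
        warnings.warn(f"{path}: empty network")
    return g


def write_edge_list(graph: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in graph.edges()):
            fh.write(f"{u}\t{v}\n")


# ---------------------------------------------------------------------------
# Drug-target tables


def read_drug_targets_tsv(path) -> list[DrugTarget]:
    """Read (drug_id, drug_name, target) rows into one entry per drug."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"drug_id", "drug_name", "target"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: columns must include {sorted(required)}")
    drugs = []
    for drug_id, grp in df.groupby("drug_id", sort=True):
        names = grp["drug_name"].unique()
        drugs.append(
            DrugTarget(
                drug_id=str(drug_id),
                drug_name=str(names[0]),
                targets=frozenset(grp["target"]),
            )
        )
    return drugs


def write_drug_targets_tsv(drugs, path) -> None:
    rows = [
        {"drug_id": d.drug_id, "drug_name": d.drug_name, "target": t}
        for d in drugs
        for t in sorted(d.targets)
    ]
    pd.DataFrame(rows, columns=["drug_id", "drug_name", "target"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Batch standardization


def standardize_per_batch(expr: ExpressionMatrix):
    """Z-score each gene within each batch (mean 0, sd 1 per batch).

    A deliberately simple alternative to empirical-Bayes batch moderation:
    it removes per-batch location/scale differences gene by gene. Genes
    constant within a batch are set to 0 there and returned in ``flags``.

    Returns ``(ExpressionMatrix, flags)`` where flags maps gene id to the
    batches in which it was constant.
    """
    values = expr.values.copy()
    batches = np.array(expr.batch)
    flags: dict[str, list[str]] = {}
    for b in dict.fromkeys(expr.batch):
        cols = np.where(batches == b)[0]
        if cols.size < 2:
            raise ValueError(f"batch {b!r} has fewer than 2 samples")
        block = values[:, cols]
        mu = block.mean(axis=1, keepdims=True)
        sd = block.std(axis=1, ddof=1, keepdims=True)
        const = sd[:, 0] == 0
        sd[const] = 1.0
        block = (block - mu) / sd
        block[const] = 0.0
        values[:, cols] = block
        for i in np.where(const)[0]:
            flags.setdefault(expr.gene_ids[i], []).append(b)
    out = ExpressionMatrix(
        gene_ids=list(expr.gene_ids),
        sample_ids=list(expr.sample_ids),
        values=values,
        condition=list(expr.condition),
        batch=list(expr.batch),
    )
    return out, flags
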