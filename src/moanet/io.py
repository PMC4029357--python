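"""Domain types and file I/O.

Core containers for the pipeline: expression matrices (log2 absolute or
log2 fold-change scale), sample metadata, per-drug signature gene sets,
the mode-of-action (MoA) network, and prediction reports.

All tabular interchange is plain TSV (tab separator, no quoting, UTF-8,
"." decimal); gene sets are written in the Broad GMT format and the
network in GraphML.  Readers and writers are exact inverses on valid
inputs (reals round-trip to 12 significant digits).  Loading never
silently reorders or drops rows or columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SampleRecord",
    "SignatureEntry",
    "DrugSignature",
    "MoaNetwork",
    "PredictionResult",
    "QueryProfile",
    "read_expression",
    "write_expression",
    "read_metadata",
    "write_metadata",
    "read_query",
    "write_signatures_gmt",
    "write_signatures_tsv",
    "read_signatures_tsv",
    "write_network_graphml",
    "read_network_graphml",
    "write_predictions_tsv",
]

ROLES = ("treated", "vehicle")
SCALE_TAGS = ("absolute_log2", "log2_fold_change")

#: format used for every real value written to disk; 12 significant
#: digits is the round-trip contract of the TSV dialect.
FLOAT_FMT = "%.12g"


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """A genes x samples matrix of log2-scale values.

    Parameters
    ----------
    gene_ids, sample_ids
        Unique, order-preserving row / column identifiers.
    values
        Real matrix of shape ``(len(gene_ids), len(sample_ids))``; all
        entries must be finite.
    scale_tag
        ``"absolute_log2"`` for normalized intensities or
        ``"log2_fold_change"`` for treated-minus-baseline profiles.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    scale_tag: str = "absolute_log2"

    def __post_init__(self) -> None:
        self.gene_ids = [str(g).strip() for g in self.gene_ids]
        self.sample_ids = [str(s).strip() for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.scale_tag not in SCALE_TAGS:
            raise ValueError(f"unknown scale_tag {self.scale_tag!r}")
        _check_unique(self.gene_ids, "gene_id")
        _check_unique(self.sample_ids, "sample_id")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def column(self, sample_id: str) -> np.ndarray:
        return self.values[:, self.sample_ids.index(sample_id)]

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return ExpressionMatrix(
            list(self.gene_ids), list(sample_ids),
            self.values[:, idx].copy(), self.scale_tag,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids,
                            columns=self.sample_ids)


def _check_unique(ids: list[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what} {x!r}")
        seen.add(x)


def read_expression(path, scale_tag: str = "absolute_log2") -> ExpressionMatrix:
    """Read a tab-delimited matrix (first column gene id, header = samples).

    Raises
    ------
    ValueError
        On duplicate gene/sample ids (naming the id) or a non-numeric
        cell (naming row and column).
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    gene_ids = [str(g).strip() for g in df.index]
    sample_ids = [str(s).strip() for s in df.columns]
    _check_unique(gene_ids, "gene_id")
    _check_unique(sample_ids, "sample_id")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = np.nonzero(converted.isna().to_numpy() & df[col].notna().to_numpy())[0]
        if bad.size:
            raise ValueError(
                f"non-numeric value {df[col].iloc[bad[0]]!r} at gene "
                f"{gene_ids[bad[0]]!r}, sample {sample_ids[j]!r}"
            )
        missing = np.nonzero(converted.isna().to_numpy())[0]
        if missing.size:
            raise ValueError(
                f"missing value at gene {gene_ids[missing[0]]!r}, "
                f"sample {sample_ids[j]!r}"
            )
        values[:, j] = converted.to_numpy()
    return ExpressionMatrix(gene_ids, sample_ids, values, scale_tag)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", float_format=FLOAT_FMT,
                             index_label="gene_id")


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

@dataclass
class SampleRecord:
    """One array sample: treated (drug_name required) or vehicle control."""

    sample_id: str
    drug_name: str
    cell_line: str
    dose: str = ""
    batch: str = ""
    role: str = "treated"

    def __post_init__(self) -> None:
        self.sample_id = str(self.sample_id).strip()
        self.drug_name = str(self.drug_name).strip()
        if self.role not in ROLES:
            raise ValueError(
                f"sample {self.sample_id!r}: role {self.role!r} not in {ROLES}"
            )
        if self.role == "treated" and not self.drug_name:
            raise ValueError(
                f"treated sample {self.sample_id!r} has empty drug_name"
            )


METADATA_COLUMNS = ["sample_id", "drug_name", "cell_line", "dose", "batch", "role"]


def read_metadata(path) -> list[SampleRecord]:
    """Read the sample metadata TSV; every record is validated."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata is missing required columns {missing}")
    return [
        SampleRecord(row.sample_id, row.drug_name, row.cell_line,
                     row.dose, row.batch, row.role)
        for row in df.itertuples(index=False)
    ]


def write_metadata(records: list[SampleRecord], path) -> None:
    pd.DataFrame(
        [[r.sample_id, r.drug_name, r.cell_line, r.dose, r.batch, r.role]
         for r in records],
        columns=METADATA_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# drug signatures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SignatureEntry:
    """One signature gene: direction (+1 up / -1 down), p-value, mean z."""

    gene_id: str
    direction: int
    p_value: float
    mean_z: float

    def __post_init__(self) -> None:
        if self.direction not in (1, -1):
            raise ValueError(f"direction must be +1/-1, got {self.direction}")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")
        if self.mean_z != 0 and self.direction != (1 if self.mean_z > 0 else -1):
            raise ValueError(
                f"gene {self.gene_id!r}: direction {self.direction} "
                f"inconsistent with mean_z {self.mean_z}"
            )


@dataclass
class DrugSignature:
    """The consistently differentially expressed gene set of one drug."""

    drug_name: str
    entries: list[SignatureEntry]
    n_samples_used: int

    def __post_init__(self) -> None:
        if self.n_samples_used < 2:
            raise ValueError("a signature requires >= 2 samples")
        _check_unique([e.gene_id for e in self.entries], "signature gene")

    @property
    def gene_ids(self) -> list[str]:
        return [e.gene_id for e in self.entries]

    def directions(self) -> dict[str, int]:
        return {e.gene_id: e.direction for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)


def write_signatures_gmt(signatures: list[DrugSignature], path) -> None:
    """Write signatures as GMT gene sets, one line per drug per direction.

    Set names are ``<drug>_up`` / ``<drug>_down``; the description field
    carries ``n_samples_used``.  Directions with no genes emit no line.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for sig in signatures:
            for suffix, want in (("up", 1), ("down", -1)):
                genes = [e.gene_id for e in sig.entries if e.direction == want]
                if genes:
                    fh.write("\t".join(
                        [f"{sig.drug_name}_{suffix}", str(sig.n_samples_used)]
                        + genes) + "\n")


SIGNATURE_COLUMNS = ["drug_name", "gene_id", "direction", "p_value",
                     "mean_z", "n_samples_used"]


def write_signatures_tsv(signatures: list[DrugSignature], path) -> None:
    rows = [
        [s.drug_name, e.gene_id, e.direction, e.p_value, e.mean_z,
         s.n_samples_used]
        for s in signatures for e in s.entries
    ]
    pd.DataFrame(rows, columns=SIGNATURE_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_signatures_tsv(path) -> list[DrugSignature]:
    df = pd.read_csv(path, sep="\t", dtype={"drug_name": str, "gene_id": str})
    out: list[DrugSignature] = []
    if df.empty:
        return out
    for drug, grp in df.groupby("drug_name", sort=False):
        entries = [
            SignatureEntry(str(r.gene_id), int(r.direction),
                           float(r.p_value), float(r.mean_z))
            for r in grp.itertuples(index=False)
        ]
        out.append(DrugSignature(str(drug), entries,
                                 int(grp["n_samples_used"].iloc[0])))
    return out


# ---------------------------------------------------------------------------
# MoA network
# ---------------------------------------------------------------------------

@dataclass
class MoaNetwork:
    """Drugs partitioned into modes of action, with centers and links.

    ``intra_edges`` connect same-MoA drug pairs whose distance is below
    the clustering threshold; ``inter_moa_edges`` link distinct MoAs
    whose closest member pair falls below the threshold (the network's
    secondary, "black edge" level).
    """

    drugs: list[str]
    moa_of: dict[str, str]
    centers: dict[str, str]
    intra_edges: list[tuple[str, str, float]]
    inter_moa_edges: list[tuple[str, str, float]]
    threshold: float
    moa_members: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.moa_members:
            members: dict[str, list[str]] = {}
            for d in self.drugs:
                members.setdefault(self.moa_of[d], []).append(d)
            self.moa_members = members
        for d in self.drugs:
            if d not in self.moa_of:
                raise ValueError(f"drug {d!r} has no MoA assignment")
        for moa, center in self.centers.items():
            if center not in self.moa_members.get(moa, []):
                raise ValueError(
                    f"center {center!r} is not a member of MoA {moa!r}")
        for a, b, dist in self.intra_edges:
            if self.moa_of[a] != self.moa_of[b]:
                raise ValueError(f"intra edge {a!r}-{b!r} crosses MoAs")
            if not dist < self.threshold:
                raise ValueError(
                    f"intra edge {a!r}-{b!r} at distance {dist} >= threshold")
        for m1, m2, _ in self.inter_moa_edges:
            if m1 == m2:
                raise ValueError(f"inter-MoA self edge on {m1!r}")

    @property
    def moa_ids(self) -> list[str]:
        return list(self.moa_members)


def write_network_graphml(network: MoaNetwork, path) -> None:
    """Write the network as GraphML.

    Node attributes: ``moa_id``, ``is_center``.  Edge attributes:
    ``kind`` in {intra, inter_moa}, ``distance``.  Inter-MoA edges are
    materialized between the two MoA centers.  The threshold is stored
    as a graph attribute.
    """
    g = nx.Graph(threshold=float(network.threshold))
    centers = set(network.centers.values())
    for d in network.drugs:
        g.add_node(d, moa_id=network.moa_of[d], is_center=d in centers)
    for a, b, dist in network.intra_edges:
        g.add_edge(a, b, kind="intra", distance=float(dist))
    for m1, m2, dist in network.inter_moa_edges:
        g.add_edge(network.centers[m1], network.centers[m2],
                   kind="inter_moa", distance=float(dist))
    nx.write_graphml(g, path)


def read_network_graphml(path) -> MoaNetwork:
    g = nx.read_graphml(path)
    drugs = list(g.nodes)
    moa_of = {d: g.nodes[d]["moa_id"] for d in drugs}
    centers: dict[str, str] = {
        moa_of[d]: d for d in drugs if g.nodes[d].get("is_center")
    }
    intra, inter = [], []
    for a, b, attrs in g.edges(data=True):
        if attrs["kind"] == "intra":
            intra.append((a, b, float(attrs["distance"])))
        else:
            m1, m2 = sorted((moa_of[a], moa_of[b]))
            inter.append((m1, m2, float(attrs["distance"])))
    return MoaNetwork(drugs, moa_of, centers, intra, inter,
                      float(g.graph["threshold"]))


# ---------------------------------------------------------------------------
# query profiles and prediction reports
# ---------------------------------------------------------------------------

@dataclass
class QueryProfile:
    """A single log2 fold-change profile used to query the network."""

    gene_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g).strip() for g in self.gene_ids]
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.gene_ids, "gene_id")
        if self.values.shape != (len(self.gene_ids),):
            raise ValueError("query values do not match gene_ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("query contains non-finite values")

    def as_mapping(self) -> dict[str, float]:
        return dict(zip(self.gene_ids, self.values))


def read_query(path) -> QueryProfile:
    """Read a two-column (gene_id, value) TSV query profile."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    return QueryProfile(
        [str(g) for g in df.iloc[:, 0]],
        df.iloc[:, 1].astype(float).to_numpy(),
    )


PREDICTION_HEADER = "Rank\tDrug\tMeanExpression\tMoA"


@dataclass
class PredictionResult:
    """Two-level ranking of MoAs and drugs against a query profile.

    ``rows`` are ``(rank, drug_name, score, moa_id)`` with dense ranks
    1..N, grouped in contiguous MoA blocks following ``moa_order``;
    ``score`` is the per-drug mean expression of matched signature genes
    in the query (NaN when no signature gene overlaps the query).
    """

    mode: str
    rows: list[tuple[int, str, float, str]]
    moa_order: list[tuple[str, float]]

    def __post_init__(self) -> None:
        if self.mode not in ("similar", "reverse"):
            raise ValueError(f"mode must be similar/reverse, got {self.mode!r}")
        ranks = [r for r, *_ in self.rows]
        if ranks != list(range(1, len(self.rows) + 1)):
            raise ValueError("ranks must be dense 1..N")

    def top(self, n: int = 20) -> list[tuple[int, str, float, str]]:
        return self.rows[:n]


def write_predictions_tsv(result: PredictionResult, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(PREDICTION_HEADER + "\n")
        for rank, drug, score, moa in result.rows:
            txt = "NA" if math.isnan(score) else FLOAT_FMT % score
            fh.write(f"{rank}\t{drug}\t{txt}\t{moa}\n")
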