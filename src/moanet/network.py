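"""Signature-based drug distance, MoA clustering, and network assembly.

Each QC-passed drug is summarized as a consensus log2 fold-change
profile (per-gene median over its kept samples).  The similarity of
two drugs a and b evaluates each drug's signature in the *other*
drug's profile:

    S_ab = 1/2 * [ (1/n) sum_{i in sig(a)} dir_i * b_i / var(b)
                 + (1/m) sum_{j in sig(b)} dir_j * a_j / var(a) ]

where n, m are the signature sizes and var(.) is the variance of the
consensus profile across genes.  Distances are reported as
``D = D_max - S`` with ``D_max`` the maximum off-diagonal similarity,
so the most similar pair has distance 0.

Whether two drugs share a mode of action is decided against the
empirical background of all pairwise distances: the clustering
threshold is the lower-tail ``p_level`` quantile (default 0.01) of the
pooled distances.  Average-linkage hierarchical clustering cut at that
threshold yields the MoAs (singletons allowed); each MoA's center is
its highest-betweenness member, and two MoAs are linked when their
closest member pair falls below the threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import norm

from .io import DrugSignature, ExpressionMatrix, MoaNetwork, SampleRecord
from .qc import QcReport

__all__ = [
    "DrugProfile",
    "DistanceMatrix",
    "BackgroundDistribution",
    "build_profiles",
    "pairwise_similarity",
    "distance_matrix",
    "background_threshold",
    "cluster_moas",
    "build_network",
]

DEFAULT_P_LEVEL = 0.01
DEFAULT_LINKAGE = "average"


@dataclass
class DrugProfile:
    """Consensus fold-change profile and signature of one drug."""

    drug_name: str
    gene_ids: list[str]
    consensus_values: np.ndarray
    signature: DrugSignature

    def __post_init__(self) -> None:
        self.consensus_values = np.asarray(self.consensus_values, float)
        if self.consensus_values.shape != (len(self.gene_ids),):
            raise ValueError("consensus length does not match gene_ids")
        self.variance = float(self.consensus_values.var(ddof=1))
        if not self.variance > 0:
            raise ValueError(f"drug {self.drug_name!r} has zero variance")
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    def value(self, gene_id: str) -> float | None:
        i = self._index.get(gene_id)
        return None if i is None else float(self.consensus_values[i])


def build_profiles(
    fold_changes: ExpressionMatrix,
    metadata: list[SampleRecord],
    signatures: dict[str, DrugSignature],
    qc_reports: dict[str, QcReport] | None = None,
) -> list[DrugProfile]:
    """Per-gene median over QC-passed samples for every signatured drug."""
    by_id = {r.sample_id: r for r in metadata}
    drug_samples: dict[str, list[str]] = {}
    for sid in fold_changes.sample_ids:
        rec = by_id.get(sid)
        if rec is not None and rec.role == "treated":
            drug_samples.setdefault(rec.drug_name, []).append(sid)
    profiles = []
    for drug, sig in signatures.items():
        sids = drug_samples.get(drug, [])
        if qc_reports and drug in qc_reports:
            report = qc_reports[drug]
            if report.drug_removed:
                continue
            sids = [s for s in sids if s in report.kept_sample_ids]
        if not sids:
            continue
        cols = [fold_changes.sample_ids.index(s) for s in sids]
        consensus = np.median(fold_changes.values[:, cols], axis=1)
        profiles.append(DrugProfile(drug, list(fold_changes.gene_ids),
                                    consensus, sig))
    return profiles


def _directed_term(sig: DrugSignature, other: DrugProfile,
                   signed: bool) -> tuple[float, int]:
    total, matched = 0.0, 0
    for entry in sig.entries:
        v = other.value(entry.gene_id)
        if v is None:
            continue
        matched += 1
        total += (entry.direction * v) if signed else v
    return total, matched


def pairwise_similarity(
    profile_a: DrugProfile,
    profile_b: DrugProfile,
    signed: bool = True,
) -> float:
    """Symmetric signature cross-expression similarity S_ab.

    With ``signed=True`` (default) each signature gene contributes its
    direction-adjusted expression in the other profile, so a shared
    *down*-regulation signature scores as similar.  ``signed=False``
    restores the literal unsigned reading.  Signature genes absent
    from the other profile are skipped (with a warning); an error is
    raised if nothing matches.
    """
    ta, na = _directed_term(profile_a.signature, profile_b, signed)
    tb, nb = _directed_term(profile_b.signature, profile_a, signed)
    if na == 0 and nb == 0:
        raise ValueError(
            f"no signature gene of {profile_a.drug_name!r} or "
            f"{profile_b.drug_name!r} matches the other profile")
    if na < len(profile_a.signature) or nb < len(profile_b.signature):
        warnings.warn(
            f"similarity {profile_a.drug_name!r}~{profile_b.drug_name!r}: "
            f"skipped unmatched signature genes")
    term_a = (ta / na) / profile_b.variance if na else 0.0
    term_b = (tb / nb) / profile_a.variance if nb else 0.0
    return 0.5 * (term_a + term_b)


@dataclass
class DistanceMatrix:
    """Drug x drug similarities S and distances D = D_max - S."""

    drugs: list[str]
    S: np.ndarray
    D: np.ndarray
    D_max: float

    def off_diagonal(self) -> np.ndarray:
        iu = np.triu_indices(len(self.drugs), k=1)
        return self.D[iu]

    def condensed(self) -> np.ndarray:
        return squareform(self.D, checks=False)


def distance_matrix(profiles: list[DrugProfile],
                    signed: bool = True) -> DistanceMatrix:
    """All-pairs similarity and the D_max - S distance transform.

    ``D_max`` is the maximum off-diagonal similarity, so the most
    similar pair has distance exactly 0 and all distances are
    non-negative.  Diagonals of D are 0 by convention.
    """
    n = len(profiles)
    if n < 2:
        raise ValueError("distance matrix needs >= 2 drug profiles")
    S = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            S[a, b] = S[b, a] = pairwise_similarity(
                profiles[a], profiles[b], signed)
    iu = np.triu_indices(n, k=1)
    d_max = float(S[iu].max())
    D = d_max - S
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix([p.drug_name for p in profiles], S, D, d_max)


@dataclass
class BackgroundDistribution:
    """Pooled pairwise distances and the p_level clustering threshold."""

    distances: np.ndarray
    threshold: float
    p_level: float

    def __post_init__(self) -> None:
        self.distances = np.sort(np.asarray(self.distances, float))


def background_threshold(
    dm: DistanceMatrix,
    p_level: float = DEFAULT_P_LEVEL,
    estimator: str = "pooled",
) -> BackgroundDistribution:
    """Threshold at the lower ``p_level`` tail of the background distances.

    Two drugs closer than this threshold are closer than expected under
    the background (population) distance distribution — the
    distribution of distances between drugs that do *not* share a mode
    of action — and are merged into one MoA.

    ``estimator="pooled"`` takes the empirical ``p_level`` quantile
    (linear interpolation between order statistics) of all off-diagonal
    distances.  This is unbiased when same-MoA pairs are a negligible
    fraction (below ``p_level``) of all pairs, as in a large corpus
    with many small MoAs.  ``estimator="robust"`` instead fits the
    background bulk by median and MAD and takes the normal ``p_level``
    lower quantile, which tolerates a substantial fraction of
    genuinely-similar pairs contaminating the lower tail of the pool
    (as happens in small datasets with pronounced planted structure).
    """
    pooled = dm.off_diagonal()
    if pooled.size < 10:
        raise ValueError("background needs >= 10 off-diagonal distances")
    if np.ptp(pooled) == 0:
        warnings.warn("degenerate background: all pairwise distances equal")
        return BackgroundDistribution(pooled, float(pooled[0]), p_level)
    if estimator == "pooled":
        thr = float(np.quantile(pooled, p_level))  # linear interpolation
    elif estimator == "robust":
        med = float(np.median(pooled))
        sigma = 1.4826 * float(np.median(np.abs(pooled - med)))
        thr = med + sigma * float(norm.ppf(p_level))
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return BackgroundDistribution(pooled, thr, p_level)


def cluster_moas(
    dm: DistanceMatrix,
    threshold: float,
    linkage_method: str = DEFAULT_LINKAGE,
) -> dict[str, str]:
    """Agglomerative clustering cut at the background threshold.

    Returns drug -> MoA id; MoA ids are ``MoA1, MoA2, ...`` numbered by
    first appearance in drug order.  Singleton MoAs are expected — some
    compounds simply share no treatment effect with others.
    """
    Z = linkage(dm.condensed(), method=linkage_method)
    labels = fcluster(Z, t=threshold, criterion="distance")
    relabel: dict[int, str] = {}
    moa_of: dict[str, str] = {}
    for drug, lab in zip(dm.drugs, labels):
        if lab not in relabel:
            relabel[lab] = f"MoA{len(relabel) + 1}"
        moa_of[drug] = relabel[lab]
    return moa_of


def build_network(
    partition: dict[str, str],
    dm: DistanceMatrix,
    threshold: float,
) -> MoaNetwork:
    """Assemble the MoA network from a partition and the distances.

    Intra-MoA edges join same-MoA pairs with distance below threshold;
    each MoA's center is the member with the largest betweenness
    centrality on its intra-edge subgraph (ties -> lexicographically
    smallest drug); MoAs whose closest member pair is below threshold
    are linked at the secondary level.
    """
    drugs = list(dm.drugs)
    idx = {d: i for i, d in enumerate(drugs)}
    members: dict[str, list[str]] = {}
    for d in drugs:
        members.setdefault(partition[d], []).append(d)

    intra: list[tuple[str, str, float]] = []
    centers: dict[str, str] = {}
    for moa, mem in members.items():
        g = nx.Graph()
        g.add_nodes_from(mem)
        for a in range(len(mem)):
            for b in range(a + 1, len(mem)):
                d = float(dm.D[idx[mem[a]], idx[mem[b]]])
                if d < threshold:
                    intra.append((mem[a], mem[b], d))
                    g.add_edge(mem[a], mem[b])
        bc = nx.betweenness_centrality(g, normalized=False)
        centers[moa] = min(mem, key=lambda d: (-bc[d], d))

    moa_ids = list(members)
    inter: list[tuple[str, str, float]] = []
    for i in range(len(moa_ids)):
        for j in range(i + 1, len(moa_ids)):
            pair_d = min(
                float(dm.D[idx[a], idx[b]])
                for a in members[moa_ids[i]] for b in members[moa_ids[j]]
            )
            if pair_d < threshold:
                inter.append((moa_ids[i], moa_ids[j], pair_d))

    return MoaNetwork(drugs, dict(partition), centers, intra, inter,
                      float(threshold), {m: list(v) for m, v in members.items()})
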