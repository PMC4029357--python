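"""Rank MoAs and drugs against a query fold-change profile.

A query — the profile of a sample treated by a new compound, or of a
tumor — is scored against every drug signature in the network: the
drug's score ("mean expression") is the direction-adjusted mean of its
signature genes' values in the query.  MoAs are scored by aggregating
their member drugs and the report is a two-level ranking: MoAs first,
then drugs within each MoA, in contiguous blocks.

*Similar* mode ranks descending at both levels (largest positive
match first) and identifies compounds with the same treatment effect;
*reverse* mode ranks ascending (most negative first) and nominates
compounds expected to oppose the query — the setting used to screen
therapeutics against a tumor profile.  For every query,
``reverse(q) == similar(-q)`` exactly.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from .io import DrugSignature, MoaNetwork, PredictionResult, QueryProfile

__all__ = ["drug_query_score", "rank_predictions"]

MIN_QUERY_COVERAGE = 0.5


def drug_query_score(query: QueryProfile | dict[str, float],
                     signature: DrugSignature) -> float:
    """Direction-adjusted mean of the signature genes found in the query.

    Returns NaN when no signature gene is present in the query (the
    drug is then excluded from ranking rather than silently dropped).
    """
    mapping = query.as_mapping() if isinstance(query, QueryProfile) else query
    total, matched = 0.0, 0
    for entry in signature.entries:
        v = mapping.get(entry.gene_id)
        if v is None:
            continue
        matched += 1
        total += entry.direction * v
    if matched == 0:
        return float("nan")
    return total / matched


def rank_predictions(
    query: QueryProfile,
    network: MoaNetwork,
    signatures: dict[str, DrugSignature],
    mode: str = "similar",
    moa_aggregation: str = "mean",
) -> PredictionResult:
    """Two-level MoA/drug ranking of the network against a query.

    MoA score aggregates member drug scores (``mean`` by default,
    ``max`` available).  Similar mode sorts both levels descending,
    reverse mode ascending; ties break by MoA id / drug name ascending,
    so the ranking is deterministic.  Drugs whose signatures share no
    gene with the query score NaN and are appended after all ranked
    drugs, with a warning.
    """
    if mode not in ("similar", "reverse"):
        raise ValueError(f"mode must be similar/reverse, got {mode!r}")
    if moa_aggregation not in ("mean", "max"):
        raise ValueError(f"unknown moa_aggregation {moa_aggregation!r}")
    if not network.drugs:
        raise ValueError("empty network")

    mapping = query.as_mapping()
    net_genes = {e.gene_id for d in network.drugs
                 if d in signatures for e in signatures[d].entries}
    if not net_genes:
        raise ValueError("network drugs have no signature genes")
    coverage = sum(g in mapping for g in net_genes) / len(net_genes)
    if coverage < MIN_QUERY_COVERAGE:
        raise ValueError(
            f"query covers only {coverage:.1%} of network signature genes "
            f"(< {MIN_QUERY_COVERAGE:.0%})")

    scores: dict[str, float] = {}
    unscored: list[str] = []
    for drug in network.drugs:
        sig = signatures.get(drug)
        s = drug_query_score(mapping, sig) if sig is not None else float("nan")
        if math.isnan(s):
            unscored.append(drug)
        else:
            scores[drug] = s
    if unscored:
        warnings.warn(
            f"{len(unscored)} drug(s) had no signature gene in the query "
            f"and are reported unranked at the bottom: {sorted(unscored)}")

    sign = -1.0 if mode == "similar" else 1.0  # descending vs ascending
    moa_scores: dict[str, float] = {}
    for moa, members in network.moa_members.items():
        vals = [scores[d] for d in members if d in scores]
        if vals:
            moa_scores[moa] = (float(np.mean(vals)) if moa_aggregation == "mean"
                               else float(np.max(vals)))

    moa_order = sorted(moa_scores, key=lambda m: (sign * moa_scores[m], m))
    rows: list[tuple[int, str, float, str]] = []
    rank = 1
    for moa in moa_order:
        ranked = sorted(
            (d for d in network.moa_members[moa] if d in scores),
            key=lambda d: (sign * scores[d], d))
        for d in ranked:
            rows.append((rank, d, scores[d], moa))
            rank += 1
    for d in sorted(unscored):
        rows.append((rank, d, float("nan"), network.moa_of[d]))
        rank += 1
    return PredictionResult(mode, rows,
                            [(m, moa_scores[m]) for m in moa_order])
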