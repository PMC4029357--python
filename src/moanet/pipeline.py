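"""End-to-end orchestration: fold changes -> signatures -> QC -> network."""

from __future__ import annotations

from dataclasses import dataclass

from .io import DrugSignature, ExpressionMatrix, MoaNetwork, SampleRecord
from .network import (
    DEFAULT_LINKAGE,
    DEFAULT_P_LEVEL,
    BackgroundDistribution,
    DistanceMatrix,
    background_threshold,
    build_network,
    build_profiles,
    cluster_moas,
    distance_matrix,
)
from .qc import DEFAULT_MIN_AGREEMENT, QcReport, qc_dataset
from .signature import (
    DEFAULT_ALPHA,
    NullDistribution,
    build_null,
    signatures_for_dataset,
)

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    """Everything the construction phase produces, in pipeline order."""

    null: NullDistribution
    signatures: dict[str, DrugSignature]
    signature_flags: dict[str, str]
    qc_reports: dict[str, QcReport]
    distances: DistanceMatrix
    background: BackgroundDistribution
    partition: dict[str, str]
    network: MoaNetwork


def run_pipeline(
    fold_changes: ExpressionMatrix,
    metadata: list[SampleRecord],
    alpha: float = DEFAULT_ALPHA,
    n_null_draws: int = 200_000,
    seed: int | None = None,
    min_agreement: float = DEFAULT_MIN_AGREEMENT,
    p_level: float = DEFAULT_P_LEVEL,
    background_estimator: str = "robust",
    linkage_method: str = DEFAULT_LINKAGE,
    pairing: str = "cross_drug",
) -> PipelineResult:
    """Build the MoA network from a fold-change matrix and metadata.

    Stages: empirical null from cross-drug pairs; replicate QC (drugs
    with more than 3 samples); signature selection on QC-passed samples
    (single-sample and no-signature drugs removed); consensus profiles;
    the D_max - S distance matrix; the background threshold at
    ``p_level`` (robust background fit by default, so planted or real
    MoA structure does not contaminate the calibration); average-linkage
    clustering cut at the threshold; and network assembly with
    betweenness centers.
    """
    null = build_null(fold_changes, metadata, n_null_draws, seed, pairing)
    qc_reports = qc_dataset(fold_changes, metadata, null, alpha, min_agreement)

    kept_samples = [
        sid
        for report in qc_reports.values()
        for sid in report.kept_sample_ids
    ]
    kept_matrix = fold_changes.subset_samples(
        [s for s in fold_changes.sample_ids if s in set(kept_samples)])
    signatures, flags = signatures_for_dataset(
        kept_matrix, metadata, null, alpha)

    profiles = build_profiles(kept_matrix, metadata, signatures, qc_reports)
    dm = distance_matrix(profiles)
    background = background_threshold(dm, p_level, background_estimator)
    partition = cluster_moas(dm, background.threshold, linkage_method)
    network = build_network(partition, dm, background.threshold)
    return PipelineResult(null, signatures, flags, qc_reports, dm,
                          background, partition, network)
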