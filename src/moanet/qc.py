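"""Replicate quality control: drop samples inconsistent with their drug.

Perturbation corpora contain outlier samples whose expression patterns
differ substantially from the other replicates of the same drug;
keeping them only adds noise to signature selection and the MoA
network.  QC is applied to drugs with more than 3 samples (smaller
drugs pass through unchanged).

Pairwise *agreement* between two replicates is the number of genes
their pair signature selects at level alpha, normalized by the count
expected by chance (``n_genes * alpha``): a value around 1 means no
more consistency than random pairing, while true replicates sharing a
signature score far above 1.  Samples are removed iteratively — worst
mean agreement first — until every remaining pair clears the
``min_agreement`` floor; a drug whose final pair still fails is
removed entirely.

The exact removal schedule is this package's reconstruction of the
procedure sketched in the original workflow; it is deliberately simple
and parameterized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ExpressionMatrix, SampleRecord
from .signature import (
    DEFAULT_ALPHA,
    NullDistribution,
    ZScaledSample,
    _pair_selection_mask,
    z_scale_matrix,
)

__all__ = ["QcReport", "sample_agreement", "filter_drug_samples", "qc_dataset"]

DEFAULT_MIN_AGREEMENT = 5.0
QC_MIN_SAMPLES = 4  # QC applies only to drugs with more than 3 samples


@dataclass
class QcReport:
    """Outcome of QC for one drug."""

    drug_name: str
    kept_sample_ids: list[str]
    removed_sample_ids: list[str]
    agreement_matrix: np.ndarray
    rule_trace: list[str] = field(default_factory=list)

    @property
    def drug_removed(self) -> bool:
        return len(self.kept_sample_ids) < 2


def sample_agreement(
    sample_a: ZScaledSample,
    sample_b: ZScaledSample,
    null: NullDistribution,
    alpha: float = DEFAULT_ALPHA,
) -> float:
    """Pair-signature gene count over the chance expectation n*alpha."""
    mask, _ = _pair_selection_mask(sample_a, sample_b, null, alpha)
    n_genes = sample_a.z_values.size
    return float(mask.sum()) / (n_genes * alpha)


def filter_drug_samples(
    drug_name: str,
    samples: list[ZScaledSample],
    null: NullDistribution,
    alpha: float = DEFAULT_ALPHA,
    min_agreement: float = DEFAULT_MIN_AGREEMENT,
) -> QcReport:
    """Iteratively remove the least-consistent replicates of one drug.

    Drugs with fewer than 4 samples pass through untouched.  While any
    remaining pair scores below ``min_agreement``, the sample with the
    lowest mean agreement to the others is removed (ties broken by
    removing the lexicographically larger sample id); iteration stops
    when all pairs pass or only two samples remain.  If the final pair
    still fails, the whole drug is flagged removed.  Deterministic.
    """
    ids = [s.sample_id for s in samples]
    n = len(samples)
    if n < QC_MIN_SAMPLES:
        return QcReport(drug_name, list(ids), [], np.zeros((n, n)),
                        [f"pass-through: {n} samples (< {QC_MIN_SAMPLES})"])

    agree = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            agree[a, b] = agree[b, a] = sample_agreement(
                samples[a], samples[b], null, alpha)

    active = list(range(n))
    trace: list[str] = []
    while len(active) > 2:
        sub = agree[np.ix_(active, active)]
        off = sub[~np.eye(len(active), dtype=bool)]
        if off.min() >= min_agreement:
            break
        means = sub.sum(axis=1) / (len(active) - 1)
        # lowest mean agreement; tie -> lexicographically larger sample id
        worst = min(range(len(active)),
                    key=lambda k: (means[k], _desc_key(ids[active[k]])))
        removed_id = ids[active[worst]]
        trace.append(
            f"removed {removed_id}: mean agreement {means[worst]:.3f}, "
            f"min pair {off.min():.3f} < {min_agreement}")
        del active[worst]

    kept = [ids[k] for k in active]
    removed = [i for i in ids if i not in kept]
    if len(active) == 2 and agree[active[0], active[1]] < min_agreement:
        trace.append(
            f"final pair agreement {agree[active[0], active[1]]:.3f} "
            f"< {min_agreement}: drug removed")
        removed = list(ids)
        kept = []
    if not trace:
        trace.append("all pairs consistent; no removals")
    return QcReport(drug_name, kept, removed, agree, trace)


class _desc_key(str):
    """Inverts lexicographic order so min() picks the *larger* id on ties."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)


def qc_dataset(
    fold_changes: ExpressionMatrix,
    metadata: list[SampleRecord],
    null: NullDistribution,
    alpha: float = DEFAULT_ALPHA,
    min_agreement: float = DEFAULT_MIN_AGREEMENT,
) -> dict[str, QcReport]:
    """Run replicate QC for every drug in the dataset."""
    by_id = {r.sample_id: r for r in metadata}
    drug_samples: dict[str, list[str]] = {}
    for sid in fold_changes.sample_ids:
        rec = by_id.get(sid)
        if rec is not None and rec.role == "treated":
            drug_samples.setdefault(rec.drug_name, []).append(sid)
    z = z_scale_matrix(fold_changes)
    return {
        drug: filter_drug_samples(
            drug, [z[s] for s in sids], null, alpha, min_agreement)
        for drug, sids in drug_samples.items()
    }
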