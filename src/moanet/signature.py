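"""Signature gene-set selection via the replicate-consistency statistic R.

Most drugs in connectivity-map style corpora have only two treatment
samples, so conventional differential tests (t-test, moderated t) are
not applicable.  Instead, each gene in a pair of replicate fold-change
profiles is scored with

    R = z_x * z_y - |z_x - z_y|

where ``z = x / sigma_x`` is the gene's fold change scaled by the
standard deviation of its whole sample vector.  R is symmetric and is
large exactly when both replicates are strongly and concordantly
regulated; discordant genes are penalized by the absolute difference.

Significance is assessed against an empirical null built by randomly
pairing samples of *different* drugs (pairs that are not consistently
differentially expressed) and drawing one random gene per pair.  Genes
with upper-tail p-value below ``alpha`` (default 0.001, i.e. p < 0.1%)
and agreeing signs form the pair signature; a drug's signature is the
intersection of all its pairwise signatures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import DrugSignature, ExpressionMatrix, SampleRecord, SignatureEntry

__all__ = [
    "ZScaledSample",
    "NullDistribution",
    "consistency_statistic",
    "z_scale",
    "z_scale_matrix",
    "build_null",
    "select_pair_signature",
    "select_drug_signature",
    "signatures_for_dataset",
]

DEFAULT_ALPHA = 0.001
MIN_NULL_DRAWS = 100_000


@dataclass
class ZScaledSample:
    """A fold-change profile scaled by its own standard deviation."""

    sample_id: str
    z_values: np.ndarray

    def __post_init__(self) -> None:
        self.z_values = np.asarray(self.z_values, float)


def z_scale(sample_id: str, values: np.ndarray) -> ZScaledSample:
    """Scale a fold-change vector by its across-gene standard deviation."""
    values = np.asarray(values, float)
    sigma = values.std(ddof=1)
    if not sigma > 0:
        raise ValueError(f"sample {sample_id!r} has zero variance")
    return ZScaledSample(sample_id, values / sigma)


def z_scale_matrix(matrix: ExpressionMatrix) -> dict[str, ZScaledSample]:
    return {
        sid: z_scale(sid, matrix.values[:, j])
        for j, sid in enumerate(matrix.sample_ids)
    }


def consistency_statistic(z_x, z_y):
    """R = z_x*z_y - |z_x - z_y|; symmetric, elementwise on arrays."""
    z_x = np.asarray(z_x, float)
    z_y = np.asarray(z_y, float)
    return z_x * z_y - np.abs(z_x - z_y)


# ---------------------------------------------------------------------------
# empirical null
# ---------------------------------------------------------------------------

@dataclass
class NullDistribution:
    """Sorted empirical null of R from random cross-drug sample pairs."""

    r_values: np.ndarray
    n_draws: int
    seed: int | None
    pairing: str = "cross_drug"

    def __post_init__(self) -> None:
        self.r_values = np.sort(np.asarray(self.r_values, float))
        if self.n_draws < MIN_NULL_DRAWS:
            raise ValueError(
                f"null needs >= {MIN_NULL_DRAWS} draws, got {self.n_draws}")

    def p_value(self, r):
        """Upper-tail p with +1/(n+1) continuity; vectorized."""
        r = np.asarray(r, float)
        n = self.r_values.size
        n_ge = n - np.searchsorted(self.r_values, r, side="left")
        return (n_ge + 1.0) / (n + 1.0)

    def quantile(self, q: float) -> float:
        return float(np.quantile(self.r_values, q))


def build_null(
    fold_changes: ExpressionMatrix,
    metadata: list[SampleRecord],
    n_draws: int = 200_000,
    seed: int | None = None,
    pairing: str = "cross_drug",
) -> NullDistribution:
    """Pool R over random sample pairs and one random gene per pair.

    With the default ``cross_drug`` pairing, the two samples of every
    draw come from different drugs, so the pooled R represents genes
    that are not consistently differentially expressed.  The
    ``within_drug`` option resamples pairs inside each drug instead.
    Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    by_id = {r.sample_id: r for r in metadata}
    sample_drug = []
    for j, sid in enumerate(fold_changes.sample_ids):
        rec = by_id.get(sid)
        if rec is not None and rec.role == "treated":
            sample_drug.append((j, rec.drug_name))
    drugs = sorted({d for _, d in sample_drug})
    if len(drugs) < 2:
        raise ValueError("null construction needs samples from >= 2 drugs")

    z = np.column_stack([
        z_scale(sid, fold_changes.values[:, j]).z_values
        for j, sid in ((j, fold_changes.sample_ids[j]) for j, _ in sample_drug)
    ])
    drug_idx = np.array([drugs.index(d) for _, d in sample_drug])
    n_samples = z.shape[1]

    i = rng.integers(0, n_samples, size=n_draws)
    j = rng.integers(0, n_samples, size=n_draws)
    if pairing == "cross_drug":
        bad = drug_idx[i] == drug_idx[j]
        while bad.any():
            j[bad] = rng.integers(0, n_samples, size=int(bad.sum()))
            bad = drug_idx[i] == drug_idx[j]
    elif pairing == "within_drug":
        bad = (drug_idx[i] != drug_idx[j]) | (i == j)
        while bad.any():
            j[bad] = rng.integers(0, n_samples, size=int(bad.sum()))
            bad = (drug_idx[i] != drug_idx[j]) | (i == j)
    else:
        raise ValueError(f"unknown pairing {pairing!r}")
    genes = rng.integers(0, z.shape[0], size=n_draws)
    r = consistency_statistic(z[genes, i], z[genes, j])
    return NullDistribution(r, n_draws, seed, pairing)


# ---------------------------------------------------------------------------
# signature selection
# ---------------------------------------------------------------------------

def select_pair_signature(
    sample_a: ZScaledSample,
    sample_b: ZScaledSample,
    null: NullDistribution,
    alpha: float = DEFAULT_ALPHA,
    gene_ids: list[str] | None = None,
) -> list[tuple[str, int, float]]:
    """Genes with p < alpha and agreeing signs in a pair of replicates.

    Returns ``(gene_id, direction, p)`` tuples; direction is the sign
    of ``z_a + z_b``.  Genes whose z values disagree in sign are never
    selected.
    """
    mask, p = _pair_selection_mask(sample_a, sample_b, null, alpha)
    if gene_ids is None:
        gene_ids = [str(i) for i in range(sample_a.z_values.size)]
    zsum = sample_a.z_values + sample_b.z_values
    return [
        (gene_ids[i], 1 if zsum[i] > 0 else -1, float(p[i]))
        for i in np.nonzero(mask)[0]
    ]


def _pair_selection_mask(
    sample_a: ZScaledSample,
    sample_b: ZScaledSample,
    null: NullDistribution,
    alpha: float,
) -> tuple[np.ndarray, np.ndarray]:
    za, zb = sample_a.z_values, sample_b.z_values
    if za.shape != zb.shape:
        raise ValueError("paired samples have different gene counts")
    r = consistency_statistic(za, zb)
    p = null.p_value(r)
    mask = (p < alpha) & (np.sign(za) == np.sign(zb)) & (za != 0)
    return mask, p


def select_drug_signature(
    samples: list[ZScaledSample],
    null: NullDistribution,
    alpha: float = DEFAULT_ALPHA,
    gene_ids: list[str] | None = None,
    drug_name: str = "",
) -> tuple[DrugSignature | None, str]:
    """Intersect pairwise signatures over all replicate pairs of a drug.

    Returns ``(signature, flag)``; the flag is ``"ok"``,
    ``"single_sample"`` (drug has < 2 samples, no signature possible)
    or ``"no_signature"`` (the pairwise intersection is empty).  The
    direction of a signature gene is the sign of its mean z across all
    samples and its p-value is the maximum pairwise p.
    """
    if len(samples) < 2:
        return None, "single_sample"
    n_genes = samples[0].z_values.size
    if gene_ids is None:
        gene_ids = [str(i) for i in range(n_genes)]
    keep = np.ones(n_genes, bool)
    worst_p = np.zeros(n_genes)
    for a in range(len(samples)):
        for b in range(a + 1, len(samples)):
            mask, p = _pair_selection_mask(samples[a], samples[b], null, alpha)
            keep &= mask
            worst_p = np.maximum(worst_p, p)
            if not keep.any():
                return None, "no_signature"
    mean_z = np.mean([s.z_values for s in samples], axis=0)
    entries = [
        SignatureEntry(gene_ids[i], 1 if mean_z[i] > 0 else -1,
                       float(worst_p[i]), float(mean_z[i]))
        for i in np.nonzero(keep)[0]
    ]
    sig = DrugSignature(drug_name, entries, len(samples))
    return sig, "ok"


def signatures_for_dataset(
    fold_changes: ExpressionMatrix,
    metadata: list[SampleRecord],
    null: NullDistribution,
    alpha: float = DEFAULT_ALPHA,
) -> tuple[dict[str, DrugSignature], dict[str, str]]:
    """Select a signature for every drug in a fold-change matrix.

    Returns the signatures of drugs flagged ``ok`` plus a per-drug flag
    table reporting ``single_sample`` and ``no_signature`` drugs
    separately (both categories are removed downstream).
    """
    by_id = {r.sample_id: r for r in metadata}
    drug_samples: dict[str, list[str]] = {}
    for sid in fold_changes.sample_ids:
        rec = by_id.get(sid)
        if rec is not None and rec.role == "treated":
            drug_samples.setdefault(rec.drug_name, []).append(sid)
    z = z_scale_matrix(fold_changes)
    signatures: dict[str, DrugSignature] = {}
    flags: dict[str, str] = {}
    for drug, sids in drug_samples.items():
        sig, flag = select_drug_signature(
            [z[s] for s in sids], null, alpha,
            gene_ids=fold_changes.gene_ids, drug_name=drug)
        flags[drug] = flag
        if sig is not None and len(sig):
            signatures[drug] = sig
    return signatures, flags
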