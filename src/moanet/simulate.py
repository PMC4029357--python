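"""Synthetic perturbation datasets with planted MoA structure.

Generates gene-level log2 fold-change matrices that emulate a
connectivity-map style corpus: several modes of action, each with its
own signature gene set and up/down directions; several drugs per MoA;
replicate samples per drug; i.i.d. Gaussian noise; and a configurable
fraction of outlier samples that are pure noise.  A matching ground
truth records the planted MoA membership, signature genes, and outlier
samples, so every pipeline stage can be tested without any external
download.

The defaults reflect the study conditions the pipeline is designed
for: 10,000 genes, 6 MoAs x 5 drugs x 3 replicates, 100 signature
genes per MoA at effect size 5 noise SDs, and a 10% outlier rate.

A probe-level mode (``generate_probe_dataset``) adds per-probe offsets
and vehicle control columns on the absolute log2 scale to exercise the
normalization chain; the fold-change mode is the primary fixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ExpressionMatrix, QueryProfile, SampleRecord

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_dataset",
    "generate_probe_dataset",
    "generate_query",
    "replace_with_outlier",
]


@dataclass
class SimulationConfig:
    """Planted-structure dataset parameters.

    ``effect_size`` is expressed in units of the noise standard
    deviation; ``overlap_fraction`` makes consecutive MoAs share that
    fraction of their signature genes.
    """

    n_genes: int = 10_000
    n_moas: int = 6
    drugs_per_moa: int = 5
    samples_per_drug: int = 3
    signature_size: int = 100
    effect_size: float = 5.0
    noise_sd: float = 1.0
    outlier_rate: float = 0.0
    overlap_fraction: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_moas", "drugs_per_moa",
                     "samples_per_drug", "signature_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.outlier_rate <= 1.0:
            raise ValueError("outlier_rate must be in [0, 1]")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        fresh = self.signature_size - int(round(
            self.overlap_fraction * self.signature_size))
        if self.signature_size + (self.n_moas - 1) * fresh > self.n_genes:
            raise ValueError("signature genes exceed n_genes")


@dataclass
class GroundTruth:
    """Planted structure: MoA membership, signatures, outliers."""

    moa_of_drug: dict[str, str]
    signature_genes_of_moa: dict[str, dict[str, int]]
    outlier_sample_ids: list[str] = field(default_factory=list)

    def drugs_of_moa(self, moa_id: str) -> list[str]:
        return [d for d, m in self.moa_of_drug.items() if m == moa_id]


def generate_dataset(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, list[SampleRecord], GroundTruth]:
    """Simulate a fold-change matrix with planted MoAs.

    Signature genes of a drug's MoA take value
    ``direction * effect_size * noise_sd`` plus noise; all other genes
    are pure ``N(0, noise_sd^2)`` noise.  With probability
    ``outlier_rate`` a sample is replaced by pure noise and recorded in
    the ground truth.  Byte-identical under the same seed.
    """
    rng = np.random.default_rng(config.seed)
    gene_ids = [f"g{i:05d}" for i in range(config.n_genes)]

    fresh = config.signature_size - int(round(
        config.overlap_fraction * config.signature_size))
    sig_of_moa: dict[str, dict[str, int]] = {}
    cursor = 0
    prev: list[int] = []
    for m in range(config.n_moas):
        moa = f"moa{m}"
        if m == 0:
            idx = list(range(cursor, cursor + config.signature_size))
            cursor += config.signature_size
        else:
            shared = prev[:config.signature_size - fresh]
            idx = shared + list(range(cursor, cursor + fresh))
            cursor += fresh
        dirs = rng.choice([-1, 1], size=len(idx))
        sig_of_moa[moa] = {gene_ids[i]: int(d) for i, d in zip(idx, dirs)}
        prev = idx

    moa_of_drug: dict[str, str] = {}
    records: list[SampleRecord] = []
    columns: list[np.ndarray] = []
    sample_ids: list[str] = []
    outliers: list[str] = []
    for m in range(config.n_moas):
        moa = f"moa{m}"
        pattern = np.zeros(config.n_genes)
        for g, d in sig_of_moa[moa].items():
            pattern[int(g[1:])] = d * config.effect_size * config.noise_sd
        for d in range(config.drugs_per_moa):
            drug = f"drug_m{m}_{d}"
            moa_of_drug[drug] = moa
            for s in range(config.samples_per_drug):
                sid = f"{drug}_s{s}"
                noise = rng.normal(0.0, config.noise_sd, config.n_genes)
                is_outlier = rng.random() < config.outlier_rate
                col = noise if is_outlier else pattern + noise
                if is_outlier:
                    outliers.append(sid)
                sample_ids.append(sid)
                columns.append(col)
                records.append(SampleRecord(sid, drug, "synthetic",
                                            "", "b0", "treated"))

    matrix = ExpressionMatrix(gene_ids, sample_ids,
                              np.column_stack(columns), "log2_fold_change")
    return matrix, records, GroundTruth(moa_of_drug, sig_of_moa, outliers)


def replace_with_outlier(
    matrix: ExpressionMatrix,
    truth: GroundTruth,
    sample_id: str,
    noise_sd: float = 1.0,
    seed: int | None = None,
) -> None:
    """Overwrite one sample with pure noise and record it as an outlier.

    Lets tests plant an exact number of outliers at chosen positions
    instead of relying on the stochastic ``outlier_rate``.
    """
    rng = np.random.default_rng(seed)
    j = matrix.sample_ids.index(sample_id)
    matrix.values[:, j] = rng.normal(0.0, noise_sd, matrix.n_genes)
    if sample_id not in truth.outlier_sample_ids:
        truth.outlier_sample_ids.append(sample_id)


def generate_query(
    truth: GroundTruth,
    moa_id: str,
    polarity: str = "similar",
    noise_sd: float = 0.0,
    seed: int | None = None,
    n_genes: int | None = None,
    gene_ids: list[str] | None = None,
    effect_size: float = 5.0,
) -> QueryProfile:
    """A query profile matching (or opposing) a planted MoA pattern.

    ``similar`` polarity reproduces the MoA's signature pattern,
    ``reverse`` negates it; Gaussian noise of SD ``noise_sd`` is added
    everywhere.  At ``noise_sd=0`` the similar query equals the MoA
    consensus pattern exactly and the reverse query its negation.
    """
    if moa_id not in truth.signature_genes_of_moa:
        raise ValueError(f"unknown MoA {moa_id!r}")
    if polarity not in ("similar", "reverse"):
        raise ValueError(f"polarity must be similar/reverse, got {polarity!r}")
    if gene_ids is None:
        if n_genes is None:
            n_genes = 1 + max(
                int(g[1:]) for sig in truth.signature_genes_of_moa.values()
                for g in sig)
        gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    index = {g: i for i, g in enumerate(gene_ids)}
    values = np.zeros(len(gene_ids))
    flip = 1.0 if polarity == "similar" else -1.0
    for g, d in truth.signature_genes_of_moa[moa_id].items():
        values[index[g]] = flip * d * effect_size
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, values.size)
    return QueryProfile(gene_ids, values)


def generate_probe_dataset(
    config: SimulationConfig,
    probes_per_gene: int = 4,
    n_vehicles: int = 3,
    baseline_mean: float = 7.0,
    technical_sd: float = 0.2,
    probe_sd: float = 0.1,
) -> tuple[ExpressionMatrix, list[SampleRecord], dict[str, str], GroundTruth]:
    """Probe-level absolute-scale variant for exercising normalization.

    Each gene expands to ``probes_per_gene`` probes with fixed probe
    offsets; vehicle control columns carry the per-gene baseline alone.
    Treated columns carry baseline + the drug's planted MoA pattern
    plus gene-level technical noise of SD ``technical_sd`` and
    per-probe measurement noise of SD ``probe_sd``.  Unchanged genes
    therefore sit at technical-noise distance from the baseline, as on
    a real array — the regime rank-invariant normalization assumes
    (the large per-gene ``noise_sd`` of the fold-change fixture would
    make every treated distribution systematically wider than its
    baseline, which the normalization would then wrongly compress).
    Returns the probe matrix, metadata (treated + vehicles), the
    probe->gene map, and the ground truth.
    """
    fc, records, truth = generate_dataset(config)
    rng = np.random.default_rng(
        None if config.seed is None else config.seed + 1)
    gene_base = rng.normal(baseline_mean, 1.0, fc.n_genes)
    probe_ids, probe_to_gene = [], {}
    offsets = []
    for g in fc.gene_ids:
        for k in range(probes_per_gene):
            pid = f"{g}_p{k}"
            probe_ids.append(pid)
            probe_to_gene[pid] = g
            offsets.append(rng.normal(0.0, 0.5))
    offsets = np.array(offsets)
    gene_idx = np.repeat(np.arange(fc.n_genes), probes_per_gene)

    gene_index = {g: i for i, g in enumerate(fc.gene_ids)}
    patterns = {}
    for moa, sig in truth.signature_genes_of_moa.items():
        pattern = np.zeros(fc.n_genes)
        for g, d in sig.items():
            pattern[gene_index[g]] = d * config.effect_size * config.noise_sd
        patterns[moa] = pattern

    outliers = set(truth.outlier_sample_ids)
    cols, sids = [], []
    for rec in records:
        pattern = (np.zeros(fc.n_genes) if rec.sample_id in outliers
                   else patterns[truth.moa_of_drug[rec.drug_name]])
        signal = gene_base + pattern + rng.normal(0.0, technical_sd,
                                                  fc.n_genes)
        cols.append(signal[gene_idx] + offsets
                    + rng.normal(0.0, probe_sd, len(probe_ids)))
        sids.append(rec.sample_id)
    vehicle_records = []
    for v in range(n_vehicles):
        sid = f"vehicle_{v}"
        signal = gene_base + rng.normal(0.0, technical_sd, fc.n_genes)
        cols.append(signal[gene_idx] + offsets
                    + rng.normal(0.0, probe_sd, len(probe_ids)))
        sids.append(sid)
        vehicle_records.append(SampleRecord(sid, "", "synthetic",
                                            "", "b0", "vehicle"))
    matrix = ExpressionMatrix(probe_ids, sids, np.column_stack(cols),
                              "absolute_log2")
    return matrix, records + vehicle_records, probe_to_gene, truth
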