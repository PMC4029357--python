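"""Preprocessing chain: normalized intensities -> log2 fold-change profiles.

The chain mirrors the standard perturbation-array workflow for
background-adjusted probe or gene level data:

1. quantile normalization of the untreated (vehicle) samples;
2. rank-invariant normalization of each treated sample against the
   median of its vehicle group, to correct nonlinear abnormality;
3. optional median-polish summarization of probe-level blocks into one
   value per probe set per sample;
4. fold-change assembly: treated minus the per-gene median of the
   matching vehicle group (same batch and cell line), on the log2 scale.

Background correction of raw scanner data is out of scope; inputs are
assumed background-adjusted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, SampleRecord

__all__ = [
    "VehicleBaseline",
    "quantile_normalize",
    "rank_invariant_normalize",
    "median_polish",
    "median_polish_summarize",
    "assemble_fold_change",
    "normalize_pipeline",
]


@dataclass
class VehicleBaseline:
    """Per-gene median of the untreated vehicle samples (log2 scale)."""

    gene_ids: list[str]
    baseline_values: np.ndarray

    def __post_init__(self) -> None:
        self.baseline_values = np.asarray(self.baseline_values, float)
        if self.baseline_values.shape != (len(self.gene_ids),):
            raise ValueError("baseline length does not match gene_ids")


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------

def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every column onto the mean order-statistic distribution.

    After normalization each column's sorted value vector equals the
    cross-column mean of order statistics; within-column rank order is
    preserved and ties receive the mean of their reference positions.
    Idempotent to floating precision.
    """
    x = matrix.values
    if x.shape[1] < 2:
        warnings.warn("quantile_normalize: single column, returned unchanged")
        return matrix
    order = np.argsort(x, axis=0, kind="stable")
    reference = np.mean(np.take_along_axis(x, order, axis=0), axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        mapped = np.empty_like(col)
        mapped[order[:, j]] = reference
        # tied values all receive the mean of their reference positions
        if np.unique(col).size < col.size:
            mapped = pd.Series(mapped).groupby(col).transform("mean").to_numpy()
        out[:, j] = mapped
    return ExpressionMatrix(list(matrix.gene_ids), list(matrix.sample_ids),
                            out, matrix.scale_tag)


# ---------------------------------------------------------------------------
# rank-invariant normalization
# ---------------------------------------------------------------------------

def _running_median(y: np.ndarray, window: int) -> np.ndarray:
    """Centered running median; the window shrinks near the edges."""
    half = window // 2
    n = y.size
    out = np.empty(n)
    for i in range(n):
        k = min(half, i, n - 1 - i)
        out[i] = np.median(y[i - k:i + k + 1])
    return out


def rank_invariant_normalize(
    sample: np.ndarray,
    baseline: VehicleBaseline,
    rank_tolerance: float = 0.05,
    tail_fraction: float = 0.05,
    min_invariant: int = 50,
) -> np.ndarray:
    """Map a sample onto a baseline via its rank-invariant genes.

    Genes whose rank differs between sample and baseline by at most
    ``rank_tolerance * n_genes`` — excluding the extreme
    ``tail_fraction`` of ranks at each end — anchor a monotone
    piecewise-linear sample->baseline mapping (running-median smoothed,
    linearly extrapolated beyond the anchored range), which is then
    applied to all genes.  When the sample already equals the baseline
    the mapping is the exact identity.

    Falls back to a median-shift normalization, with a warning, when
    fewer than ``min_invariant`` rank-invariant genes are found.
    """
    sample = np.asarray(sample, float)
    base = baseline.baseline_values
    if sample.shape != base.shape:
        raise ValueError("sample and baseline gene sets differ")
    n = sample.size
    rs = np.argsort(np.argsort(sample, kind="stable"), kind="stable")
    rb = np.argsort(np.argsort(base, kind="stable"), kind="stable")
    lo, hi = tail_fraction * (n - 1), (1.0 - tail_fraction) * (n - 1)
    mean_rank = 0.5 * (rs + rb)
    invariant = (
        (np.abs(rs - rb) <= rank_tolerance * n)
        & (mean_rank >= lo) & (mean_rank <= hi)
    )
    if invariant.sum() < min_invariant:
        warnings.warn(
            f"rank-invariant set has {int(invariant.sum())} genes "
            f"(< {min_invariant}); falling back to median-shift"
        )
        return sample - np.median(sample) + np.median(base)

    xs = sample[invariant]
    ys = base[invariant]
    order = np.argsort(xs, kind="stable")
    xs, ys = xs[order], ys[order]
    window = max(5, (xs.size // 20) | 1)
    ys = _running_median(ys, window)
    ys = np.maximum.accumulate(ys)  # enforce monotone mapping
    # collapse duplicate abscissae for interpolation
    xs_u, first = np.unique(xs, return_index=True)
    ys_u = np.array([ys[first[i]:(first[i + 1] if i + 1 < first.size else ys.size)].mean()
                     for i in range(first.size)])
    out = np.interp(sample, xs_u, ys_u)
    # Linear extrapolation beyond the anchored range.  Slopes come from a
    # least-squares fit over the outer decile of anchor points: a
    # two-point end-segment slope is far too noisy and would attenuate
    # (or inflate) genuinely extreme genes, which are exactly the ones
    # living outside the rank-invariant range.
    if xs_u.size >= 2:
        k = max(2, xs_u.size // 10)
        left = sample < xs_u[0]
        right = sample > xs_u[-1]
        sl = _slope(xs_u[:k], ys_u[:k])
        sr = _slope(xs_u[-k:], ys_u[-k:])
        out[left] = ys_u[0] + sl * (sample[left] - xs_u[0])
        out[right] = ys_u[-1] + sr * (sample[right] - xs_u[-1])
    return out


def _slope(x: np.ndarray, y: np.ndarray) -> float:
    dx = x - x.mean()
    denom = float(dx @ dx)
    if denom == 0.0:
        return 1.0
    return float(dx @ (y - y.mean())) / denom


# ---------------------------------------------------------------------------
# median polish summarization
# ---------------------------------------------------------------------------

def median_polish(
    block: np.ndarray, max_iter: int = 10, tol: float = 1e-6
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Two-way Tukey median polish of a probes x samples block.

    Returns ``(overall, row_effects, col_effects, residuals)`` with
    ``block ≈ overall + row + col + residuals``.  Iterates alternate
    row/column median sweeps until the total absolute adjustment falls
    below ``tol`` or ``max_iter`` sweeps have run.
    """
    resid = np.asarray(block, float).copy()
    nrow, ncol = resid.shape
    overall = 0.0
    row = np.zeros(nrow)
    col = np.zeros(ncol)
    for _ in range(max_iter):
        rmed = np.median(resid, axis=1)
        row += rmed
        resid -= rmed[:, None]
        cdelta = np.median(col)
        overall += cdelta
        col -= cdelta
        cmed = np.median(resid, axis=0)
        col += cmed
        resid -= cmed[None, :]
        rdelta = np.median(row)
        overall += rdelta
        row -= rdelta
        if np.abs(rmed).sum() + np.abs(cmed).sum() < tol:
            break
    return overall, row, col, resid


def median_polish_summarize(
    probe_matrix: ExpressionMatrix, probe_to_gene: dict[str, str]
) -> ExpressionMatrix:
    """Summarize probe-level rows into one value per gene per sample.

    Each gene's probes form a two-way table (probes x samples); the
    per-sample summary is ``overall + column effect`` from its median
    polish.  A single-probe gene's summaries equal that probe's values.
    Summaries are invariant to probe-row permutation.
    """
    genes: dict[str, list[int]] = {}
    for i, probe in enumerate(probe_matrix.gene_ids):
        try:
            gene = probe_to_gene[probe]
        except KeyError:
            raise ValueError(f"probe {probe!r} missing from probe map") from None
        genes.setdefault(gene, []).append(i)
    gene_ids = list(genes)
    out = np.empty((len(gene_ids), probe_matrix.n_samples))
    for g, gene in enumerate(gene_ids):
        rows = genes[gene]
        block = probe_matrix.values[rows, :]
        if len(rows) == 1:
            out[g] = block[0]
            continue
        # sort probe rows for a permutation-invariant polish
        block = block[np.lexsort(block.T[::-1])]
        overall, _, col, _ = median_polish(block)
        out[g] = overall + col
    return ExpressionMatrix(gene_ids, list(probe_matrix.sample_ids), out,
                            probe_matrix.scale_tag)


# ---------------------------------------------------------------------------
# fold-change assembly
# ---------------------------------------------------------------------------

def vehicle_group_key(record: SampleRecord) -> tuple[str, str]:
    """Vehicle grouping key: same batch and cell line share a baseline."""
    return (record.batch, record.cell_line)


def assemble_fold_change(
    treated: ExpressionMatrix,
    vehicles: ExpressionMatrix,
    metadata: list[SampleRecord],
) -> tuple[ExpressionMatrix, list[str]]:
    """Per treated sample: log2 fold change over its vehicle-group median.

    Returns the fold-change matrix and the list of treated sample ids
    that were excluded because no matching vehicle group existed (each
    exclusion also raises a warning).
    """
    if treated.gene_ids != vehicles.gene_ids:
        raise ValueError("treated and vehicle matrices have different genes")
    by_id = {r.sample_id: r for r in metadata}
    vehicle_groups: dict[tuple[str, str], list[int]] = {}
    for j, sid in enumerate(vehicles.sample_ids):
        rec = by_id.get(sid)
        if rec is not None and rec.role == "vehicle":
            vehicle_groups.setdefault(vehicle_group_key(rec), []).append(j)

    kept_ids: list[str] = []
    columns: list[np.ndarray] = []
    dropped: list[str] = []
    for j, sid in enumerate(treated.sample_ids):
        rec = by_id.get(sid)
        if rec is None or rec.role != "treated":
            raise ValueError(f"sample {sid!r} has no treated metadata record")
        group = vehicle_groups.get(vehicle_group_key(rec))
        if not group:
            warnings.warn(f"treated sample {sid!r} has no matching vehicles; excluded")
            dropped.append(sid)
            continue
        baseline = np.median(vehicles.values[:, group], axis=1)
        kept_ids.append(sid)
        columns.append(treated.values[:, j] - baseline)
    if not kept_ids:
        raise ValueError("no treated sample had a matching vehicle group")
    fc = ExpressionMatrix(list(treated.gene_ids), kept_ids,
                          np.column_stack(columns), "log2_fold_change")
    return fc, dropped


def normalize_pipeline(
    treated: ExpressionMatrix,
    vehicles: ExpressionMatrix,
    metadata: list[SampleRecord],
    probe_to_gene: dict[str, str] | None = None,
    rank_tolerance: float = 0.05,
) -> tuple[ExpressionMatrix, list[str]]:
    """Run the full preprocessing chain and return fold changes.

    Vehicles are quantile normalized; each treated sample is
    rank-invariant normalized against its vehicle-group median; with a
    probe map both matrices are median-polish summarized; finally fold
    changes are assembled against the vehicle-group medians.
    """
    vehicles = quantile_normalize(vehicles)
    by_id = {r.sample_id: r for r in metadata}
    vehicle_groups: dict[tuple[str, str], list[int]] = {}
    for j, sid in enumerate(vehicles.sample_ids):
        rec = by_id.get(sid)
        if rec is not None and rec.role == "vehicle":
            vehicle_groups.setdefault(vehicle_group_key(rec), []).append(j)

    normed = treated.values.copy()
    for j, sid in enumerate(treated.sample_ids):
        rec = by_id.get(sid)
        if rec is None:
            continue
        group = vehicle_groups.get(vehicle_group_key(rec))
        if not group:
            continue
        baseline = VehicleBaseline(
            list(vehicles.gene_ids),
            np.median(vehicles.values[:, group], axis=1),
        )
        normed[:, j] = rank_invariant_normalize(
            treated.values[:, j], baseline, rank_tolerance)
    treated = ExpressionMatrix(list(treated.gene_ids),
                               list(treated.sample_ids), normed,
                               treated.scale_tag)
    if probe_to_gene is not None:
        treated = median_polish_summarize(treated, probe_to_gene)
        vehicles = median_polish_summarize(vehicles, probe_to_gene)
    return assemble_fold_change(treated, vehicles, metadata)
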