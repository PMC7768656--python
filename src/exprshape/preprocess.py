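"""Preprocessing chain for expression cohorts.

Order for RNA-seq counts: quantile-normalize the raw values across samples,
log2-transform with a pseudo-count, then drop genes whose log2 values fall
below 1 in more than a quarter of samples.  Microarray log-intensities skip
normalization/filtering and only need probe-to-gene averaging.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .data import ExpressionMatrix, Scale

logger = logging.getLogger(__name__)

__all__ = [
    "log2_transform",
    "filter_low_expression",
    "quantile_normalize",
    "collapse_probes",
    "read_probe_map",
]


def log2_transform(m: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """log2(x + offset) on a RAW-scale matrix; result is LOG2 scale."""
    if m.scale is not Scale.RAW:
        raise ValueError("log2_transform expects a RAW-scale matrix")
    shifted = m.values + offset
    if np.any(shifted <= 0):
        g = int(np.argmax((shifted <= 0).any(axis=1)))
        raise ValueError(
            f"gene {m.gene_ids[g]!r} has value + offset <= 0; log2 undefined"
        )
    return ExpressionMatrix(
        list(m.gene_ids), list(m.sample_ids), np.log2(shifted), Scale.LOG2
    )


def filter_low_expression(
    m: ExpressionMatrix, threshold: float = 1.0, max_fraction: float = 0.25
) -> ExpressionMatrix:
    """Drop genes with values below `threshold` in more than `max_fraction` of samples.

    The comparison is strict on the fraction: a gene with exactly 25% of
    samples below 1 is retained.
    """
    if m.scale is not Scale.LOG2:
        raise ValueError("filter_low_expression expects a LOG2-scale matrix")
    frac_low = (m.values < threshold).mean(axis=1)
    keep = frac_low <= max_fraction
    n_removed = int((~keep).sum())
    logger.info("filter_low_expression: removed %d of %d genes", n_removed, m.n_genes)
    if not keep.any():
        raise ValueError(
            "filter_low_expression removed every gene; review the threshold"
        )
    return ExpressionMatrix(
        [g for g, k in zip(m.gene_ids, keep) if k],
        list(m.sample_ids),
        m.values[keep],
        m.scale,
    )


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Rank-based quantile normalization across samples.

    The k-th smallest value in every sample is replaced by the mean of the
    k-th smallest values across all samples; ties within a sample receive
    the mean of the reference values they span.  Idempotent and
    rank-preserving within each sample.
    """
    if m.n_samples < 2:
        logger.warning("quantile_normalize: single sample, returned unchanged")
        return m
    v = m.values
    n_genes, n_samples = v.shape
    reference = np.sort(v, axis=0).mean(axis=1)
    out = np.empty_like(v)
    for j in range(n_samples):
        col = v[:, j]
        order = np.argsort(col, kind="stable")
        mapped = np.empty(n_genes)
        mapped[order] = reference
        # ties span several reference slots: average within each tie group
        sorted_col = col[order]
        boundaries = np.flatnonzero(np.diff(sorted_col) != 0) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [n_genes]))
        if len(starts) < n_genes:  # at least one tie group
            sums = np.add.reduceat(reference, starts)
            means = sums / (ends - starts)
            expanded = np.repeat(means, ends - starts)
            mapped[order] = expanded
        out[:, j] = mapped
    return ExpressionMatrix(list(m.gene_ids), list(m.sample_ids), out, m.scale)


def read_probe_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV ``probe_id  gene_symbol`` -> dict."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("probe map needs two columns: probe_id, gene_symbol")
    probes = df.iloc[:, 0].astype(str)
    genes = df.iloc[:, 1].astype(str)
    if probes.duplicated().any():
        dup = probes[probes.duplicated()].iloc[0]
        raise ValueError(f"duplicate probe id {dup!r} in probe map")
    if (genes.str.len() == 0).any():
        raise ValueError("empty gene symbol in probe map")
    return dict(zip(probes, genes))


def collapse_probes(m: ExpressionMatrix, probe_map: dict[str, str]) -> ExpressionMatrix:
    """Average all probe rows mapping to the same gene symbol.

    Probes absent from the map are dropped (count logged).  Output genes are
    ordered by first appearance of their symbol among the retained probes.
    """
    if not probe_map:
        raise ValueError("empty probe map")
    mapped_rows: dict[str, list[int]] = {}
    n_unmapped = 0
    for i, probe in enumerate(m.gene_ids):
        sym = probe_map.get(probe)
        if sym is None:
            n_unmapped += 1
            continue
        mapped_rows.setdefault(sym, []).append(i)
    if n_unmapped:
        logger.info("collapse_probes: dropped %d unmapped probe(s)", n_unmapped)
    if not mapped_rows:
        raise ValueError("no probes mapped to any gene symbol")
    symbols = list(mapped_rows)
    values = np.vstack([m.values[rows].mean(axis=0) for rows in mapped_rows.values()])
    return ExpressionMatrix(symbols, list(m.sample_ids), values, m.scale)
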