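"""Two-group differential expression: per-gene statistics, BH adjustment,
significance filtering into a bioset.

The per-gene test is the two-group one-way ANOVA, computed as the
pooled-variance t-test (identical p-value); a Welch variant is available
behind a flag.  Fold-changes come out in the signed linear convention of
:mod:`sigscreen.core_io`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_io import (
    Bioset,
    BiosetMetadata,
    BiosetRecord,
    ExpressionMatrix,
    SigscreenError,
    log2_to_signed,
)


@dataclass(frozen=True)
class DegConfig:
    """Settings for DEG calling.

    var_floor guards against zero pooled variance (identical replicate
    values) producing p = 0 on degenerate synthetic inputs.
    """

    fdr_threshold: float = 0.01
    min_samples_per_group: int = 3
    var_floor: float = 1e-8
    welch: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr_threshold < 1.0:
            raise SigscreenError("fdr_threshold must be in (0, 1)")
        if self.min_samples_per_group < 2:
            raise SigscreenError("min_samples_per_group must be >= 2")


def gene_stats(
    matrix: ExpressionMatrix,
    group_a: str,
    group_b: str,
    cfg: DegConfig = DegConfig(),
) -> pd.DataFrame:
    """Per-gene two-group statistics for ``group_a`` vs ``group_b``.

    Returns a frame indexed by gene with columns ``mean_a``, ``mean_b``,
    ``fold_change`` (signed linear, ``2**(mean_a - mean_b)`` mapped so a
    ratio below 1 is reported as its negative reciprocal) and ``raw_p``.
    """
    ia = matrix.group_columns(group_a)
    ib = matrix.group_columns(group_b)
    for label, idx in ((group_a, ia), (group_b, ib)):
        if idx.size == 0:
            raise SigscreenError(f"group {label!r} not present in matrix")
        if idx.size < cfg.min_samples_per_group:
            raise SigscreenError(
                f"group {label!r} has {idx.size} samples, "
                f"need >= {cfg.min_samples_per_group}"
            )
    a = matrix.values[:, ia]
    b = matrix.values[:, ib]
    na, nb = a.shape[1], b.shape[1]
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)

    diff = mean_a - mean_b
    if cfg.welch:
        se2 = np.maximum(var_a / na + var_b / nb, cfg.var_floor)
        t = diff / np.sqrt(se2)
        df = se2**2 / (
            (var_a / na) ** 2 / (na - 1) + (var_b / nb) ** 2 / (nb - 1) + 1e-300
        )
    else:
        pooled = ((na - 1) * var_a + (nb - 1) * var_b) / (na + nb - 2)
        pooled = np.maximum(pooled, cfg.var_floor)
        t = diff / np.sqrt(pooled * (1.0 / na + 1.0 / nb))
        df = float(na + nb - 2)
    raw_p = 2.0 * sps.t.sf(np.abs(t), df)
    raw_p = np.minimum(raw_p, 1.0)

    return pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "fold_change": log2_to_signed(diff),
            "raw_p": raw_p,
        },
        index=pd.Index(matrix.genes, name="gene"),
    )


def adjust_bh(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved.

    adj(i) = min over j with p(j) >= p(i) of p(j) * m / rank(j), capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise SigscreenError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise SigscreenError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def call_degs(
    stats: pd.DataFrame,
    cfg: DegConfig = DegConfig(),
    metadata: BiosetMetadata = BiosetMetadata(),
) -> Bioset:
    """Filter a :func:`gene_stats` table into a bioset at ``fdr_threshold``.

    The threshold is inclusive (adjusted p equal to the threshold passes).
    ``universe_size`` is the number of genes tested.
    """
    if stats.empty:
        raise SigscreenError("empty stats table")
    adj = adjust_bh(stats["raw_p"].to_numpy())
    keep = adj <= cfg.fdr_threshold
    records = [
        BiosetRecord(gene=g, fold_change=fc, adj_p=p)
        for g, fc, p in zip(
            stats.index[keep], stats["fold_change"].to_numpy()[keep], adj[keep]
        )
    ]
    return Bioset(records=records, metadata=metadata, universe_size=len(stats))


def stats_with_adjusted(stats: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of a gene_stats frame with an ``adj_p`` column added."""
    out = stats.copy()
    out["adj_p"] = adjust_bh(stats["raw_p"].to_numpy())
    return out
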