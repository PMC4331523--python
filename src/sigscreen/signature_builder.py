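"""Derive a receptor-dependent signature from paired wild-type/null
experiments across multiple chemicals.

Per chemical, a gene is receptor-dependent when it (a) changes significantly
in treated wild-type vs wild-type control, (b) does NOT change significantly
in the same direction in treated null vs null control, and (c) differs
significantly between treated wild-type and treated null animals.  Across
chemicals, genes are retained when their direction is consistent everywhere
they appear, they are supported by enough chemicals, their average wild-type
fold-change clears a magnitude floor, and they are not claimed in the same
direction by any exclusion signature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix, GeneId, GeneSignature, SigscreenError
from .deg import DegConfig, gene_stats, stats_with_adjusted

logger = logging.getLogger(__name__)


@dataclass
class ChemicalExperiment:
    """Full (unfiltered) stats tables for one chemical's three contrasts.

    Each table is indexed by gene and carries ``fold_change`` (signed linear)
    and ``adj_p`` columns; the three tables must share the same gene universe.
    """

    name: str
    wt_treated_vs_ctrl: pd.DataFrame
    null_treated_vs_ctrl: pd.DataFrame
    wt_treated_vs_null_treated: pd.DataFrame

    def __post_init__(self) -> None:
        base = set(self.wt_treated_vs_ctrl.index)
        for label, table in (
            ("null_treated_vs_ctrl", self.null_treated_vs_ctrl),
            ("wt_treated_vs_null_treated", self.wt_treated_vs_null_treated),
        ):
            if set(table.index) != base:
                raise SigscreenError(
                    f"experiment {self.name!r}: {label} gene universe differs "
                    "from wt_treated_vs_ctrl"
                )


@dataclass
class BuilderConfig:
    fdr_threshold: float = 0.01
    min_abs_avg_fc: float = 1.5
    min_chemical_support: int = 2
    exclusion_signatures: list[GeneSignature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr_threshold < 1.0:
            raise SigscreenError("fdr_threshold must be in (0, 1)")
        if self.min_chemical_support < 1:
            raise SigscreenError("min_chemical_support must be >= 1")


def dependent_genes_for_chemical(
    exp: ChemicalExperiment, cfg: BuilderConfig = BuilderConfig()
) -> pd.DataFrame:
    """Genes whose treatment response requires the receptor, for one chemical.

    Returns a frame indexed by gene with columns ``direction`` (+1/-1) and
    ``wt_fold_change``.  A significant *opposite*-direction change in the
    null contrast does not disqualify a gene; a same-direction one does.
    """
    wt = exp.wt_treated_vs_ctrl
    null = exp.null_treated_vs_ctrl.loc[wt.index]
    wtn = exp.wt_treated_vs_null_treated.loc[wt.index]

    wt_sig = wt["adj_p"].to_numpy() <= cfg.fdr_threshold
    wt_dir = np.sign(wt["fold_change"].to_numpy())
    null_sig_same = (null["adj_p"].to_numpy() <= cfg.fdr_threshold) & (
        np.sign(null["fold_change"].to_numpy()) == wt_dir
    )
    wtn_sig = wtn["adj_p"].to_numpy() <= cfg.fdr_threshold

    keep = wt_sig & ~null_sig_same & wtn_sig
    return pd.DataFrame(
        {
            "direction": wt_dir[keep].astype(int),
            "wt_fold_change": wt["fold_change"].to_numpy()[keep],
        },
        index=wt.index[keep],
    )


def combine_signature(
    per_chemical: Sequence[pd.DataFrame],
    cfg: BuilderConfig = BuilderConfig(),
    probe_to_gene: Mapping[GeneId, GeneId] | None = None,
    name: str = "signature",
) -> GeneSignature:
    """Merge per-chemical dependent-gene tables into one directional signature.

    Selection: consistent direction across all supporting chemicals; support
    in at least ``min_chemical_support`` chemicals; |mean wild-type
    fold-change over supporting chemicals| >= ``min_abs_avg_fc``; with a
    probe→gene mapping, probes of one gene must agree in direction (the gene
    is dropped and logged otherwise); genes altered in the same direction in
    any exclusion signature are removed.
    """
    if len(per_chemical) < 2:
        raise SigscreenError("need at least two chemicals to combine")
    if not 1 <= cfg.min_chemical_support <= len(per_chemical):
        raise SigscreenError(
            "min_chemical_support must be between 1 and the number of chemicals"
        )

    directions: dict[GeneId, list[int]] = {}
    fcs: dict[GeneId, list[float]] = {}
    for table in per_chemical:
        for gene, row in table.iterrows():
            directions.setdefault(gene, []).append(int(row["direction"]))
            fcs.setdefault(gene, []).append(float(row["wt_fold_change"]))

    kept: dict[GeneId, float] = {}
    for gene, dirs in directions.items():
        if len(set(dirs)) != 1:
            continue  # direction conflict across chemicals
        if len(dirs) < cfg.min_chemical_support:
            continue
        # sorted summation keeps the mean invariant to chemical ordering
        avg_fc = float(np.mean(sorted(fcs[gene])))
        if abs(avg_fc) < cfg.min_abs_avg_fc:
            continue
        kept[gene] = avg_fc

    if probe_to_gene is not None:
        collapsed: dict[GeneId, list[float]] = {}
        conflicted: set[GeneId] = set()
        for probe, avg_fc in kept.items():
            gene = probe_to_gene.get(probe, probe)
            collapsed.setdefault(gene, []).append(avg_fc)
        for gene, values in collapsed.items():
            if len({v > 0 for v in values}) > 1:
                conflicted.add(gene)
        for gene in conflicted:
            logger.warning(
                "dropping gene %r: probes disagree in direction", gene
            )
        kept = {
            gene: float(np.mean(sorted(values)))
            for gene, values in collapsed.items()
            if gene not in conflicted
        }

    for excl in cfg.exclusion_signatures:
        up, down = excl.up_genes, excl.down_genes
        kept = {
            gene: fc
            for gene, fc in kept.items()
            if not (fc > 0 and gene in up) and not (fc < 0 and gene in down)
        }

    up = sorted(((g, fc) for g, fc in kept.items() if fc > 0))
    down = sorted(((g, fc) for g, fc in kept.items() if fc < 0))
    return GeneSignature(up=up, down=down, name=name)


def build_signature(
    experiments: Sequence[ChemicalExperiment],
    cfg: BuilderConfig = BuilderConfig(),
    probe_to_gene: Mapping[GeneId, GeneId] | None = None,
    name: str = "signature",
) -> GeneSignature:
    """Convenience: per-chemical selection followed by combination."""
    tables = [dependent_genes_for_chemical(exp, cfg) for exp in experiments]
    return combine_signature(tables, cfg, probe_to_gene=probe_to_gene, name=name)


#: group labels expected in a four-group knockout-design matrix
KO_GROUPS = ("wt_ctrl", "wt_treated", "null_ctrl", "null_treated")


def experiment_from_matrix(
    name: str,
    matrix: ExpressionMatrix,
    deg_cfg: DegConfig = DegConfig(),
) -> ChemicalExperiment:
    """Compute the three contrasts of a four-group wild-type/null matrix.

    The matrix must carry the groups ``wt_ctrl``, ``wt_treated``,
    ``null_ctrl`` and ``null_treated``.
    """

    def contrast(a: str, b: str) -> pd.DataFrame:
        return stats_with_adjusted(gene_stats(matrix, a, b, deg_cfg))

    return ChemicalExperiment(
        name=name,
        wt_treated_vs_ctrl=contrast("wt_treated", "wt_ctrl"),
        null_treated_vs_ctrl=contrast("null_treated", "null_ctrl"),
        wt_treated_vs_null_treated=contrast("wt_treated", "null_treated"),
    )
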