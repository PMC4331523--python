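"""Compendium screening: apply a signature to every bioset, call
activation/suppression at a p-value threshold, derive the BH-based cutoff,
and tabulate the results."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import Bioset, GeneId, GeneSignature, SigscreenError
from .deg import adjust_bh
from .running_fisher import RunningFisherConfig, compare

logger = logging.getLogger(__name__)

CALL_ACTIVATED = "activated"
CALL_SUPPRESSED = "suppressed"
CALL_NEUTRAL = "neutral"

#: columns of the screening output table
TABLE_COLUMNS = [
    "study_id",
    "contrast_name",
    "factor_class",
    "factor_name",
    "sex",
    "genotype",
    "direction",
    "p_value",
    "signed_score",
    "call",
    "error",
]


@dataclass(frozen=True)
class ScreenConfig:
    """Fixed operational p cutoff (the BH-derived one is computed alongside)."""

    p_threshold: float = 1e-4
    bh_alpha: float = 0.001
    target_gene: GeneId = "Ppara"
    target_fc_threshold: float = 1.2

    def __post_init__(self) -> None:
        if not 0.0 < self.p_threshold < 1.0:
            raise SigscreenError("p_threshold must be in (0, 1)")


def classify(direction: int, p_value: float, p_threshold: float) -> str:
    if p_value <= p_threshold and direction > 0:
        return CALL_ACTIVATED
    if p_value <= p_threshold and direction < 0:
        return CALL_SUPPRESSED
    return CALL_NEUTRAL


def screen(
    signature: GeneSignature,
    biosets: Sequence[Bioset],
    cfg: ScreenConfig = ScreenConfig(),
    rf_cfg: RunningFisherConfig = RunningFisherConfig(),
) -> pd.DataFrame:
    """One row per bioset: metadata, signed score, p, direction and call.

    A bioset whose comparison fails is recorded as a flagged neutral row so
    the screen always completes.
    """
    if not biosets:
        raise SigscreenError("empty bioset list")
    rows = []
    for bs in biosets:
        md = bs.metadata
        base = {
            "study_id": md.study_id,
            "contrast_name": md.contrast_name,
            "factor_class": md.factor_class.value,
            "factor_name": md.factor_name,
            "sex": md.sex.value,
            "genotype": md.genotype.value,
        }
        try:
            res = compare(signature, bs, cfg=rf_cfg)
            base.update(
                direction=res.direction,
                p_value=res.p_value,
                signed_score=res.signed_score,
                call=classify(res.direction, res.p_value, cfg.p_threshold),
                error="",
            )
        except Exception as exc:  # degrade gracefully, never abort the screen
            logger.warning("comparison failed for %r: %s", md.contrast_name, exc)
            base.update(
                direction=0, p_value=1.0, signed_score=0.0,
                call=CALL_NEUTRAL, error=str(exc),
            )
        rows.append(base)
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def derive_cutoff(pvalues, alpha: float = 0.001) -> float:
    """Largest raw p declared significant by BH step-up at ``alpha``; 0 if none."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise SigscreenError("empty p-value list")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise SigscreenError("p-values must lie in [0, 1]")
    significant = adjust_bh(p) <= alpha
    if not significant.any():
        return 0.0
    return float(p[significant].max())


def summarize_by_category(table: pd.DataFrame) -> pd.DataFrame:
    """Counts of activated/suppressed calls per factor class."""
    from .core_io import FactorClass

    out = pd.DataFrame(
        0,
        index=pd.Index([fc.value for fc in FactorClass], name="factor_class"),
        columns=[CALL_ACTIVATED, CALL_SUPPRESSED],
    )
    for call in (CALL_ACTIVATED, CALL_SUPPRESSED):
        counts = table.loc[table["call"] == call, "factor_class"].value_counts()
        out.loc[counts.index, call] = counts
    return out


_BINS = ("up", "down", "no_change")
_CALLS = (CALL_ACTIVATED, CALL_SUPPRESSED, CALL_NEUTRAL)


def target_gene_concordance(
    table: pd.DataFrame,
    target_fc: Mapping[str, float],
    cfg: ScreenConfig = ScreenConfig(),
) -> pd.DataFrame:
    """3x3 table: target-gene trichotomy (|fc| >= threshold) x screen call.

    ``target_fc`` maps contrast_name to the signed linear fold-change of the
    target gene; contrasts absent from the mapping fall in the no-change bin.
    Every table row is counted exactly once.
    """
    out = pd.DataFrame(
        0, index=pd.Index(_BINS, name="target"), columns=list(_CALLS)
    )
    t = cfg.target_fc_threshold
    for _, row in table.iterrows():
        fc = target_fc.get(row["contrast_name"])
        if fc is None or abs(fc) < t:
            bin_ = "no_change"
        elif fc > 0:
            bin_ = "up"
        else:
            bin_ = "down"
        out.loc[bin_, row["call"]] += 1
    return out


def write_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False,
                       dtype={"error": str})
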