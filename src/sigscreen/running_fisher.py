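"""Fold-change rank-based directional similarity between a signature and a
bioset.

A bioset is split into up- and down-regulated halves, each rank-ordered by
descending |fold-change|.  For each of the four (signature half, bioset
half) pairs, the list is scanned at every rank where a signature member
occurs (plus the endpoint), a one-sided Fisher exact (upper-tail
hypergeometric) overlap p-value is computed at each cut, and the minimum is
Bonferroni-corrected by the number of scan points.  Concordant-pair evidence
(sig-up·bio-up, sig-down·bio-down) is weighed against discordant-pair
evidence on the -log10 scale; the winning direction's pair p-values are
combined by Fisher's method into a single p, reported alongside a signed
-log10 score (negative when the bioset opposes the signature).

The scan grid, per-cut correction and combination rule are the declared
reference semantics of this artifact, kept behind :class:`RunningFisherConfig`
so alternates can be swapped in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from .core_io import Bioset, GeneId, GeneSignature, SigscreenError


@dataclass(frozen=True)
class RankedHalf:
    """One direction of a bioset, ordered by descending |fold-change|.

    Ties in magnitude are broken lexicographically by gene id so the
    ranking is deterministic and platform-independent.
    """

    genes: tuple[GeneId, ...]
    direction: str  # "up" | "down"

    @classmethod
    def from_records(cls, records, direction: str) -> "RankedHalf":
        if direction not in ("up", "down"):
            raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
        want_positive = direction == "up"
        picked = [
            (abs(r.fold_change), r.gene)
            for r in records
            if r.fold_change != 0 and (r.fold_change > 0) == want_positive
        ]
        picked.sort(key=lambda t: (-t[0], t[1]))
        return cls(genes=tuple(g for _, g in picked), direction=direction)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class RunningFisherConfig:
    """Tunable semantics of the scan; defaults are the reference behaviour."""

    scan_at_member_ranks: bool = True
    include_endpoint: bool = True
    scan_correction: str = "bonferroni"  # only choice implemented

    def __post_init__(self) -> None:
        if self.scan_correction != "bonferroni":
            raise SigscreenError(
                f"unknown scan correction {self.scan_correction!r}"
            )


@dataclass(frozen=True)
class RunningFisherResult:
    direction: int  # +1 activated-like, -1 suppressed-like, 0 tie/empty
    p_value: float
    signed_score: float
    pair_pvalues: dict[str, float]
    overlap: tuple[GeneId, ...]

    def to_dict(self) -> dict:
        return {
            "direction": self.direction,
            "p_value": self.p_value,
            "signed_score": self.signed_score,
            "pair_pvalues": dict(self.pair_pvalues),
            "overlap": list(self.overlap),
        }


def fisher_overlap_p(k: int, subset_in_top: int, subset_size: int, universe: int) -> float:
    """Upper-tail hypergeometric P[X >= subset_in_top], X ~ Hypergeom(universe,
    subset_size, k) — the one-sided Fisher exact enrichment p at cut depth k."""
    if not (0 <= subset_in_top <= min(k, subset_size)):
        raise SigscreenError(
            f"impossible counts: {subset_in_top} of subset {subset_size} in top {k}"
        )
    if subset_size > universe or k > universe:
        raise SigscreenError("subset or cut larger than universe")
    if subset_in_top == 0:
        return 1.0
    return float(sps.hypergeom.sf(subset_in_top - 1, universe, subset_size, k))


def running_min_p(
    signature_half: Iterable[GeneId],
    ranked: RankedHalf,
    universe: int,
    cfg: RunningFisherConfig = RunningFisherConfig(),
) -> float:
    """Best overlap p along the ranked list, corrected for the scan count.

    Scan points are the ranks at which a signature member occurs plus the
    list endpoint; the minimum cut p-value is multiplied by the number of
    scan points (capped at 1).  Empty inputs give p = 1.
    """
    members = set(signature_half)
    if universe < len(ranked):
        raise SigscreenError("universe smaller than ranked list")
    if not members or len(ranked) == 0:
        return 1.0
    m = len(members)
    scan_points: list[tuple[int, int]] = []  # (k, overlap at k)
    hits = 0
    for rank, gene in enumerate(ranked.genes, start=1):
        if gene in members:
            hits += 1
            if cfg.scan_at_member_ranks:
                scan_points.append((rank, hits))
    if cfg.include_endpoint and (
        not scan_points or scan_points[-1][0] != len(ranked)
    ):
        scan_points.append((len(ranked), hits))
    if not scan_points:
        return 1.0
    best = min(fisher_overlap_p(k, x, m, universe) for k, x in scan_points)
    return min(1.0, best * len(scan_points))


_PAIRS = (
    ("up_up", "up", "up", +1),
    ("down_down", "down", "down", +1),
    ("up_down", "up", "down", -1),
    ("down_up", "down", "up", -1),
)


def _fisher_combine(pvalues: Sequence[float]) -> float:
    """Fisher's method: chi-square on -2*sum(ln p), df = 2*len(pvalues)."""
    if not pvalues:
        return 1.0
    stat = -2.0 * sum(math.log(max(p, 1e-300)) for p in pvalues)
    return float(sps.chi2.sf(stat, 2 * len(pvalues)))


def compare(
    signature: GeneSignature,
    bioset: Bioset,
    universe: int | None = None,
    cfg: RunningFisherConfig = RunningFisherConfig(),
) -> RunningFisherResult:
    """Directional similarity of ``bioset`` to ``signature``.

    ``universe`` defaults to the bioset's platform size
    (``bioset.universe_size``); pass an explicit count to impose a shared
    (e.g. intersected-platform) gene space.  Result ordering is independent
    of the input ordering of bioset records — ranking is recomputed here.
    """
    n = bioset.universe_size if universe is None else int(universe)
    if n <= 0:
        raise SigscreenError("universe must be positive")

    ranked = {
        "up": RankedHalf.from_records(bioset.records, "up"),
        "down": RankedHalf.from_records(bioset.records, "down"),
    }
    sig_half = {"up": signature.up_genes, "down": signature.down_genes}

    if len(bioset) == 0:
        return RunningFisherResult(0, 1.0, 0.0, {}, ())

    pair_p: dict[str, float] = {}
    pair_sign: dict[str, int] = {}
    for key, s, b, sign in _PAIRS:
        if not sig_half[s] or len(ranked[b]) == 0:
            continue  # pair not evaluable; contributes no evidence
        pair_p[key] = running_min_p(sig_half[s], ranked[b], n, cfg)
        pair_sign[key] = sign

    evidence_c = sum(-math.log10(p) for k, p in pair_p.items() if pair_sign[k] > 0)
    evidence_d = sum(-math.log10(p) for k, p in pair_p.items() if pair_sign[k] < 0)

    if evidence_c > evidence_d:
        direction = 1
    elif evidence_d > evidence_c:
        direction = -1
    else:
        direction = 0
    winning_sign = 1 if direction >= 0 else -1
    winning = [p for k, p in pair_p.items() if pair_sign[k] == winning_sign]
    p_value = _fisher_combine(winning)

    bioset_genes = set(bioset.genes())
    overlap = tuple(
        sorted((sig_half["up"] | sig_half["down"]) & bioset_genes)
    )
    score = 0.0 if direction == 0 else direction * -math.log10(max(p_value, 1e-300))
    return RunningFisherResult(
        direction=direction,
        p_value=p_value,
        signed_score=score,
        pair_pvalues=pair_p,
        overlap=overlap,
    )
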