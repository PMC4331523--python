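"""Synthetic data with known ground truth for the whole pipeline.

Two generators:

* :func:`simulate_ko_experiments` — paired wild-type/null two-group
  experiments for several chemicals, with a planted receptor-dependent
  program (responds in wild-type only) and planted receptor-independent
  responders (respond in both genotypes, so the builder must exclude them);
* :func:`simulate_compendium` — annotated activator / suppressor / null
  biosets that echo a tunable, direction-concordant (or discordant)
  fraction of the program at top-biased ranks.

Everything is a pure function of its config and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core_io import (
    Bioset,
    BiosetMetadata,
    BiosetRecord,
    ExpressionMatrix,
    FactorClass,
    GeneId,
    Genotype,
    Sex,
    SigscreenError,
)

#: planted program up:down imbalance, mirroring a strongly induction-heavy
#: receptor program (~13:1)
UP_DOWN_RATIO = (137, 10)

#: group labels of a simulated knockout-design chemical experiment
GROUPS = ("wt_ctrl", "wt_treated", "null_ctrl", "null_treated")


def gene_name(i: int) -> GeneId:
    return f"G{i:05d}"


@dataclass(frozen=True)
class SimConfig:
    """Knockout-experiment simulation settings.

    Effect sizes are |log2 fold-change| drawn uniformly from
    ``effect_log2fc`` (default floor 0.8, i.e. linear fold-change >= ~1.74).
    """

    n_genes: int = 20000
    n_program: int = 131
    n_independent: int = 30
    effect_log2fc: tuple[float, float] = (0.8, 2.5)
    noise_sd: float = 0.15
    n_per_group: int = 6
    n_chemicals: int = 3
    chemical_presence_prob: float = 0.85
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_program + self.n_independent > self.n_genes:
            raise SigscreenError("planted genes exceed universe size")
        if not 0.0 <= self.chemical_presence_prob <= 1.0:
            raise SigscreenError("chemical_presence_prob must be in [0, 1]")
        if self.noise_sd < 0 or self.n_per_group < 2 or self.n_chemicals < 1:
            raise SigscreenError("invalid simulation config")

    @property
    def n_program_up(self) -> int:
        return round(self.n_program * UP_DOWN_RATIO[0] / sum(UP_DOWN_RATIO))

    @property
    def n_program_down(self) -> int:
        return self.n_program - self.n_program_up


@dataclass(frozen=True)
class CompendiumSimConfig:
    n_activators: int = 60
    n_suppressors: int = 30
    n_nulls: int = 200
    overlap_fraction: float = 0.6
    bioset_size: int = 300
    mag_log2_range: tuple[float, float] = (0.3, 2.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise SigscreenError("overlap_fraction must be in [0, 1]")
        if self.bioset_size < 1:
            raise SigscreenError("bioset_size must be positive")


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted program membership plus the simulated universe size."""

    program_up: frozenset[GeneId]
    program_down: frozenset[GeneId]
    independent: frozenset[GeneId]
    n_genes: int

    def __post_init__(self) -> None:
        if (
            self.program_up & self.program_down
            or (self.program_up | self.program_down) & self.independent
        ):
            raise SigscreenError("planted gene sets must be disjoint")

    @property
    def program(self) -> frozenset[GeneId]:
        return self.program_up | self.program_down

    def to_dict(self) -> dict:
        return {
            "program_up": sorted(self.program_up),
            "program_down": sorted(self.program_down),
            "independent": sorted(self.independent),
            "n_genes": self.n_genes,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticTruth":
        return cls(
            program_up=frozenset(d["program_up"]),
            program_down=frozenset(d["program_down"]),
            independent=frozenset(d["independent"]),
            n_genes=int(d["n_genes"]),
        )


def simulate_ko_experiments(
    cfg: SimConfig = SimConfig(),
) -> tuple[list[tuple[str, ExpressionMatrix]], SyntheticTruth]:
    """Per-chemical four-group matrices plus the planted truth.

    Program genes receive their effect only in wild-type treated samples;
    independent responders receive it in the treated samples of both
    genotypes; all other genes are baseline plus noise.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = [gene_name(i) for i in range(cfg.n_genes)]

    planted = rng.choice(cfg.n_genes, cfg.n_program + cfg.n_independent, replace=False)
    prog_idx = planted[: cfg.n_program]
    indep_idx = planted[cfg.n_program:]
    up_idx = prog_idx[: cfg.n_program_up]
    down_idx = prog_idx[cfg.n_program_up:]

    lo, hi = cfg.effect_log2fc
    effect = np.zeros(cfg.n_genes)
    effect[up_idx] = rng.uniform(lo, hi, up_idx.size)
    effect[down_idx] = -rng.uniform(lo, hi, down_idx.size)
    indep_sign = rng.choice([-1.0, 1.0], indep_idx.size)
    effect[indep_idx] = indep_sign * rng.uniform(lo, hi, indep_idx.size)

    truth = SyntheticTruth(
        program_up=frozenset(genes[i] for i in up_idx),
        program_down=frozenset(genes[i] for i in down_idx),
        independent=frozenset(genes[i] for i in indep_idx),
        n_genes=cfg.n_genes,
    )

    experiments: list[tuple[str, ExpressionMatrix]] = []
    for c in range(cfg.n_chemicals):
        name = f"chem{c + 1}"
        present = np.zeros(cfg.n_genes, dtype=bool)
        present[prog_idx] = rng.random(prog_idx.size) < cfg.chemical_presence_prob
        present[indep_idx] = True

        baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, cfg.n_genes)
        n = cfg.n_per_group
        samples, groups = [], {}
        for g in GROUPS:
            for i in range(n):
                s = f"{name}_{g}_{i + 1}"
                samples.append(s)
                groups[s] = g
        values = baseline[:, None] + rng.normal(
            0.0, cfg.noise_sd, (cfg.n_genes, len(samples))
        )
        wt_treated = slice(n, 2 * n)
        null_treated = slice(3 * n, 4 * n)
        prog_effect = np.where(present[prog_idx], effect[prog_idx], 0.0)
        values[prog_idx, wt_treated] += prog_effect[:, None]
        values[indep_idx, wt_treated] += effect[indep_idx, None]
        values[indep_idx, null_treated] += effect[indep_idx, None]

        experiments.append(
            (name, ExpressionMatrix(genes=list(genes), samples=samples,
                                    values=values, groups=groups))
        )
    return experiments, truth


def _metadata_for(i: int, label: str) -> BiosetMetadata:
    classes = list(FactorClass)
    return BiosetMetadata(
        study_id=f"SYN{i:04d}",
        contrast_name=f"bioset_{i:04d}",
        factor_class=classes[i % len(classes)],
        factor_name=f"{label}_{i:04d}",
        sex=Sex.unknown,
        genotype=Genotype.wild_type,
    )


def simulate_compendium(
    cfg: CompendiumSimConfig,
    truth: SyntheticTruth,
) -> tuple[list[Bioset], list[str]]:
    """Annotated biosets with class labels ``activator``/``suppressor``/``null``.

    Activators echo ``floor(overlap_fraction * |program|)`` randomly chosen
    program genes with concordant signs and magnitudes drawn from the upper
    quartile of the bioset's magnitude distribution; suppressors do the same
    with flipped signs; nulls are uniform draws with random signs.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = [gene_name(i) for i in range(truth.n_genes)]
    program = sorted(truth.program_up) + sorted(truth.program_down)
    program_sign = {g: 1.0 for g in truth.program_up}
    program_sign.update({g: -1.0 for g in truth.program_down})
    non_program = [g for g in genes if g not in truth.program]

    n_echo = math.floor(cfg.overlap_fraction * len(program))
    if n_echo > cfg.bioset_size:
        raise SigscreenError(
            f"echoed program ({n_echo}) exceeds bioset_size ({cfg.bioset_size})"
        )

    lo, hi = cfg.mag_log2_range

    def magnitudes(n: int) -> np.ndarray:
        return np.exp2(rng.uniform(lo, hi, n))

    def build(i: int, label: str) -> Bioset:
        pool = np.sort(magnitudes(cfg.bioset_size))[::-1]
        if label in ("activator", "suppressor"):
            echo = list(rng.choice(program, n_echo, replace=False))
            flip = -1.0 if label == "suppressor" else 1.0
            top_q = pool[: max(1, cfg.bioset_size // 4)]
            echo_mags = rng.choice(top_q, n_echo)
            records = [
                BiosetRecord(
                    gene=g,
                    fold_change=float(flip * program_sign[g] * mag),
                    adj_p=float(rng.uniform(1e-6, 0.01)),
                )
                for g, mag in zip(echo, echo_mags)
            ]
            fillers = list(rng.choice(non_program, cfg.bioset_size - n_echo,
                                      replace=False))
            filler_mags = rng.choice(pool, len(fillers))
        else:
            records = []
            fillers = list(rng.choice(genes, cfg.bioset_size, replace=False))
            filler_mags = rng.choice(pool, len(fillers))
        signs = rng.choice([-1.0, 1.0], len(fillers))
        records += [
            BiosetRecord(
                gene=g,
                fold_change=float(s * mag),
                adj_p=float(rng.uniform(1e-6, 0.01)),
            )
            for g, s, mag in zip(fillers, signs, filler_mags)
        ]
        return Bioset(
            records=records,
            metadata=_metadata_for(i, label),
            universe_size=truth.n_genes,
        )

    biosets, labels = [], []
    plan = (
        ["activator"] * cfg.n_activators
        + ["suppressor"] * cfg.n_suppressors
        + ["null"] * cfg.n_nulls
    )
    for i, label in enumerate(plan):
        biosets.append(build(i, label))
        labels.append(label)
    return biosets, labels
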