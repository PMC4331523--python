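"""Domain types and file I/O for biosets, signatures and expression matrices.

The on-disk formats are deliberately plain text:

* biosets — 3-column TSV (``gene``/``fold_change``/``adj_p``) or 2-column
  RNK (gene, signed fold-change), with ``# key=value`` header directives;
* signatures — GMT (two sets, ``<name>_UP`` and ``<name>_DOWN``) plus an
  optional 2-column fold-change table;
* matrices — GCT 1.2 or plain TSV, with a separate sample→group table.

Fold-changes are stored signed on the linear scale: ``-1.5`` means a
1.5-fold decrease, and ``|fold_change| >= 1`` by convention.  Log2 values
are converted at this boundary, nowhere else.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Genes are identified by plain, whitespace-stripped, case-preserved strings.
GeneId = str

#: Fallback platform size when neither a header directive nor a companion
#: matrix provides one (order of the shared 430A/430_2 probe count).
DEFAULT_UNIVERSE_SIZE = 22690

_FLOAT_FMT = "%.17g"  # exact float round-trip


class SigscreenError(ValueError):
    """Base class for validation and parse failures."""


class ParseError(SigscreenError):
    pass


class FactorClass(str, Enum):
    chemical = "chemical"
    gene = "gene"
    diet = "diet"
    hormone_cytokine = "hormone_cytokine"
    life_stage = "life_stage"
    stress = "stress"
    strain = "strain"
    infection = "infection"
    other = "other"


class Sex(str, Enum):
    male = "male"
    female = "female"
    mixed = "mixed"
    unknown = "unknown"


class Genotype(str, Enum):
    wild_type = "wild_type"
    knockout_knockdown = "knockout_knockdown"
    transgenic = "transgenic"
    unknown = "unknown"


def normalize_gene(raw: str) -> GeneId:
    """Strip whitespace; reject empty identifiers."""
    g = raw.strip()
    if not g:
        raise ParseError("empty gene identifier")
    return g


@dataclass(frozen=True)
class BiosetMetadata:
    study_id: str = ""
    contrast_name: str = ""
    factor_class: FactorClass = FactorClass.other
    factor_name: str = ""
    sex: Sex = Sex.unknown
    genotype: Genotype = Genotype.unknown


@dataclass(frozen=True)
class BiosetRecord:
    """One gene in a contrast: signed linear fold-change + adjusted p.

    ``adj_p`` is NaN for records read from RNK files, which carry no
    significance column.
    """

    gene: GeneId
    fold_change: float
    adj_p: float = math.nan

    def __post_init__(self) -> None:
        if self.fold_change == 0 or not math.isfinite(self.fold_change):
            raise SigscreenError(
                f"fold_change must be finite and non-zero for {self.gene!r}"
            )
        if not math.isnan(self.adj_p) and not (0.0 <= self.adj_p <= 1.0):
            raise SigscreenError(
                f"adj_p must be in [0, 1] for {self.gene!r}, got {self.adj_p}"
            )


@dataclass
class Bioset:
    """A statistically filtered gene list from one two-condition contrast."""

    records: list[BiosetRecord]
    metadata: BiosetMetadata = field(default_factory=BiosetMetadata)
    universe_size: int = DEFAULT_UNIVERSE_SIZE

    def __post_init__(self) -> None:
        seen: set[GeneId] = set()
        for r in self.records:
            if r.gene in seen:
                raise SigscreenError(f"duplicate gene in bioset: {r.gene!r}")
            seen.add(r.gene)
        if self.universe_size < len(self.records):
            raise SigscreenError(
                f"universe_size {self.universe_size} smaller than record "
                f"count {len(self.records)}"
            )

    def genes(self) -> list[GeneId]:
        return [r.gene for r in self.records]

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class GeneSignature:
    """Directional gene list: up/down members with average fold-changes."""

    up: list[tuple[GeneId, float]]
    down: list[tuple[GeneId, float]]
    name: str = "signature"

    def __post_init__(self) -> None:
        up_genes = [g for g, _ in self.up]
        down_genes = [g for g, _ in self.down]
        if len(set(up_genes)) != len(up_genes) or len(set(down_genes)) != len(
            down_genes
        ):
            raise SigscreenError("duplicate gene within a signature half")
        overlap = set(up_genes) & set(down_genes)
        if overlap:
            raise SigscreenError(
                f"gene(s) in both UP and DOWN sets: {sorted(overlap)}"
            )
        for g, fc in self.up:
            if fc <= 0:
                raise SigscreenError(f"up gene {g!r} has non-positive fc {fc}")
        for g, fc in self.down:
            if fc >= 0:
                raise SigscreenError(f"down gene {g!r} has non-negative fc {fc}")

    @property
    def up_genes(self) -> set[GeneId]:
        return {g for g, _ in self.up}

    @property
    def down_genes(self) -> set[GeneId]:
        return {g for g, _ in self.down}

    def __len__(self) -> int:
        return len(self.up) + len(self.down)


@dataclass
class ExpressionMatrix:
    """genes x samples log2 expression values with a sample→group mapping."""

    genes: list[GeneId]
    samples: list[str]
    values: np.ndarray
    groups: dict[str, str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise SigscreenError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(set(self.samples)) != len(self.samples):
            raise SigscreenError("duplicate sample labels")
        missing = [s for s in self.samples if s not in self.groups]
        if missing:
            raise SigscreenError(f"samples without a group: {missing}")
        if len(self.genes) and not np.isfinite(self.values).any(axis=1).all():
            bad = [
                self.genes[i]
                for i in np.where(~np.isfinite(self.values).any(axis=1))[0]
            ]
            raise SigscreenError(f"rows with no finite value: {bad[:5]}")

    def group_columns(self, group: str) -> np.ndarray:
        idx = [i for i, s in enumerate(self.samples) if self.groups[s] == group]
        return np.asarray(idx, dtype=int)


# ---------------------------------------------------------------------------
# fold-change scale helpers


def log2_to_signed(log2fc: float | np.ndarray) -> float | np.ndarray:
    """Map log2 ratios to the signed linear convention (|value| >= 1).

    ``0.0 -> +1.0``; ``1.0 -> +2.0``; ``-1.0 -> -2.0``.
    """
    arr = np.asarray(log2fc, dtype=float)
    out = np.where(arr >= 0, np.exp2(arr), -np.exp2(-arr))
    return float(out) if np.isscalar(log2fc) or arr.ndim == 0 else out


def signed_to_log2(fc: float | np.ndarray) -> float | np.ndarray:
    arr = np.asarray(fc, dtype=float)
    out = np.where(arr >= 0, np.log2(np.abs(arr)), -np.log2(np.abs(arr)))
    return float(out) if np.isscalar(fc) or arr.ndim == 0 else out


# ---------------------------------------------------------------------------
# bioset I/O

_META_KEYS = ("study_id", "contrast_name", "factor_class", "factor_name",
              "sex", "genotype")


def _parse_directives(lines: Iterable[str]) -> dict[str, str]:
    out: dict[str, str] = {}
    for line in lines:
        body = line.lstrip("#").strip()
        if "=" in body:
            key, _, value = body.partition("=")
            out[key.strip()] = value.strip()
    return out


def read_bioset(
    path: str | Path,
    dialect: str = "tsv3col",
    default_universe: int | None = None,
) -> Bioset:
    """Read a bioset from a 3-column TSV or a 2-column RNK file.

    The TSV dialect requires the header ``gene<TAB>fold_change<TAB>adj_p``;
    the RNK dialect has no header and no adjusted p column.  ``#`` lines are
    comments; ``# universe=N`` and ``# study_id=...``-style directives are
    honoured in both dialects.
    """
    if dialect not in ("tsv3col", "rnk"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    directives: dict[str, str] = {}
    records: list[BiosetRecord] = []
    seen: set[GeneId] = set()
    header_seen = False
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                directives.update(_parse_directives([line]))
                continue
            parts = line.split("\t")
            if dialect == "tsv3col" and not header_seen:
                expected = ["gene", "fold_change", "adj_p"]
                if [p.strip() for p in parts[:3]] != expected:
                    raise ParseError(
                        f"{path}:{lineno}: expected header {expected}, "
                        f"got {parts[:3]}"
                    )
                header_seen = True
                continue
            want = 3 if dialect == "tsv3col" else 2
            if len(parts) < want:
                raise ParseError(
                    f"{path}:{lineno}: expected {want} columns, got {len(parts)}"
                )
            gene = normalize_gene(parts[0])
            if gene in seen:
                raise ParseError(f"{path}:{lineno}: duplicate gene {gene!r}")
            seen.add(gene)
            try:
                fc = float(parts[1])
                adj_p = float(parts[2]) if dialect == "tsv3col" else math.nan
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: unparseable number: {exc}")
            try:
                records.append(BiosetRecord(gene=gene, fold_change=fc, adj_p=adj_p))
            except SigscreenError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}")
    universe = int(directives.get(
        "universe",
        default_universe if default_universe is not None else DEFAULT_UNIVERSE_SIZE,
    ))
    meta_kwargs: dict[str, object] = {}
    for key in _META_KEYS:
        if key in directives:
            value = directives[key]
            if key == "factor_class":
                meta_kwargs[key] = FactorClass(value)
            elif key == "sex":
                meta_kwargs[key] = Sex(value)
            elif key == "genotype":
                meta_kwargs[key] = Genotype(value)
            else:
                meta_kwargs[key] = value
    return Bioset(
        records=records,
        metadata=BiosetMetadata(**meta_kwargs),
        universe_size=universe,
    )


def write_bioset(bioset: Bioset, path: str | Path, dialect: str = "tsv3col") -> None:
    if dialect not in ("tsv3col", "rnk"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    md = bioset.metadata
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# universe={bioset.universe_size}\n")
        for key in _META_KEYS:
            value = getattr(md, key)
            value = value.value if isinstance(value, Enum) else value
            if value:
                fh.write(f"# {key}={value}\n")
        if dialect == "tsv3col":
            fh.write("gene\tfold_change\tadj_p\n")
            for r in bioset.records:
                fh.write(
                    f"{r.gene}\t{_FLOAT_FMT % r.fold_change}\t"
                    f"{_FLOAT_FMT % r.adj_p}\n"
                )
        else:
            for r in bioset.records:
                fh.write(f"{r.gene}\t{_FLOAT_FMT % r.fold_change}\n")


# ---------------------------------------------------------------------------
# signature I/O


def read_signature(
    gmt_path: str | Path, fc_path: str | Path | None = None
) -> GeneSignature:
    """Read a directional signature from GMT (+ optional fold-change table).

    The GMT file must contain exactly two sets, ``<name>_UP`` and
    ``<name>_DOWN`` (either may be empty).  Without a fold-change table the
    magnitudes default to +1.5 / -1.5 with a logged warning.
    """
    gmt_path = Path(gmt_path)
    sets: dict[str, list[GeneId]] = {}
    with gmt_path.open(encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"{gmt_path}: malformed GMT line {line!r}")
            sets[parts[0].strip()] = [normalize_gene(g) for g in parts[2:] if g.strip()]
    ups = [n for n in sets if n.endswith("_UP")]
    downs = [n for n in sets if n.endswith("_DOWN")]
    if len(sets) != 2 or len(ups) != 1 or len(downs) != 1:
        raise ParseError(
            f"{gmt_path}: expected exactly two sets <name>_UP and <name>_DOWN, "
            f"got {sorted(sets)}"
        )
    name_up, name_down = ups[0][: -len("_UP")], downs[0][: -len("_DOWN")]
    if name_up != name_down:
        raise ParseError(
            f"{gmt_path}: set name prefixes differ: {name_up!r} vs {name_down!r}"
        )
    up_genes, down_genes = sets[ups[0]], sets[downs[0]]
    both = set(up_genes) & set(down_genes)
    if both:
        raise ParseError(f"{gmt_path}: gene(s) in both sets: {sorted(both)}")

    if fc_path is not None:
        fc_map: dict[GeneId, float] = {}
        with Path(fc_path).open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if parts[0].strip() == "gene":
                    continue
                try:
                    fc_map[normalize_gene(parts[0])] = float(parts[1])
                except (IndexError, ValueError) as exc:
                    raise ParseError(f"{fc_path}:{lineno}: {exc}")
        up, down = [], []
        for g in up_genes:
            fc = fc_map.get(g, 1.5)
            if fc <= 0:
                raise ParseError(
                    f"fold-change table gives {g!r} fc {fc} but it is in the UP set"
                )
            up.append((g, fc))
        for g in down_genes:
            fc = fc_map.get(g, -1.5)
            if fc >= 0:
                raise ParseError(
                    f"fold-change table gives {g!r} fc {fc} but it is in the DOWN set"
                )
            down.append((g, fc))
    else:
        logger.warning(
            "no fold-change table for %s; defaulting magnitudes to ±1.5", gmt_path
        )
        up = [(g, 1.5) for g in up_genes]
        down = [(g, -1.5) for g in down_genes]
    return GeneSignature(up=up, down=down, name=name_up)


def write_signature(
    signature: GeneSignature,
    gmt_path: str | Path,
    fc_path: str | Path | None = None,
) -> None:
    gmt_path = Path(gmt_path)
    with gmt_path.open("w", encoding="utf-8") as fh:
        up = "\t".join(g for g, _ in signature.up)
        down = "\t".join(g for g, _ in signature.down)
        fh.write(f"{signature.name}_UP\tup-regulated members\t{up}".rstrip("\t") + "\n")
        fh.write(
            f"{signature.name}_DOWN\tdown-regulated members\t{down}".rstrip("\t") + "\n"
        )
    if fc_path is not None:
        with Path(fc_path).open("w", encoding="utf-8") as fh:
            fh.write("gene\tavg_fold_change\n")
            for g, fc in list(signature.up) + list(signature.down):
                fh.write(f"{g}\t{_FLOAT_FMT % fc}\n")


# ---------------------------------------------------------------------------
# matrix I/O


def read_gct(path: str | Path, groups: Mapping[str, str] | None = None) -> ExpressionMatrix:
    """Read a GCT 1.2 matrix; the sample→group mapping is supplied separately."""
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise ParseError(f"{path}: expected GCT version line '#1.2', got {version!r}")
        dims = fh.readline().split()
        n_rows, n_cols = int(dims[0]), int(dims[1])
        df = pd.read_csv(fh, sep="\t", index_col=0, float_precision="round_trip")
    df = df.drop(columns=["Description"], errors="ignore")
    if df.shape != (n_rows, n_cols):
        raise ParseError(
            f"{path}: declared {n_rows}x{n_cols}, found {df.shape[0]}x{df.shape[1]}"
        )
    samples = [str(c) for c in df.columns]
    grp = dict(groups) if groups is not None else {s: "all" for s in samples}
    return ExpressionMatrix(
        genes=[normalize_gene(str(g)) for g in df.index],
        samples=samples,
        values=df.to_numpy(dtype=float),
        groups=grp,
    )


def write_gct(matrix: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("#1.2\n")
        fh.write(f"{len(matrix.genes)}\t{len(matrix.samples)}\n")
        fh.write("NAME\tDescription\t" + "\t".join(matrix.samples) + "\n")
        for i, g in enumerate(matrix.genes):
            row = "\t".join(_FLOAT_FMT % v for v in matrix.values[i])
            fh.write(f"{g}\tna\t{row}\n")


def read_matrix_tsv(
    path: str | Path, groups: Mapping[str, str] | None = None
) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#",
                     float_precision="round_trip")
    samples = [str(c) for c in df.columns]
    grp = dict(groups) if groups is not None else {s: "all" for s in samples}
    return ExpressionMatrix(
        genes=[normalize_gene(str(g)) for g in df.index],
        samples=samples,
        values=df.to_numpy(dtype=float),
        groups=grp,
    )


def write_matrix_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = pd.DataFrame(matrix.values, index=matrix.genes, columns=matrix.samples)
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_groups(path: str | Path) -> dict[str, str]:
    """Read a 2-column sample→group TSV (header ``sample<TAB>group``)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if list(df.columns[:2]) != ["sample", "group"]:
        raise ParseError(f"{path}: expected header sample<TAB>group")
    return dict(zip(df["sample"], df["group"]))


def write_groups(groups: Mapping[str, str], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("sample\tgroup\n")
        for sample, group in groups.items():
            fh.write(f"{sample}\t{group}\n")


# ---------------------------------------------------------------------------
# full statistics tables (all genes of a contrast, unfiltered)


def read_stats_table(path: str | Path) -> pd.DataFrame:
    """Read a full per-gene stats table (gene, fold_change, adj_p) as a frame.

    Unlike a bioset this is unfiltered: it covers every gene of the contrast
    and is the unit of input to the signature builder.
    """
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    required = {"gene", "fold_change", "adj_p"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    df["gene"] = df["gene"].map(normalize_gene)
    if df["gene"].duplicated().any():
        dup = df.loc[df["gene"].duplicated(), "gene"].iloc[0]
        raise ParseError(f"{path}: duplicate gene {dup!r}")
    return df.set_index("gene")


def write_stats_table(stats: pd.DataFrame, path: str | Path) -> None:
    out = stats.reset_index()
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")
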