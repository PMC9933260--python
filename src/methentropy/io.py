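"""Readers, writers and validated containers for every external format.

Coordinate conventions
----------------------
* CpG sites are 1-based single positions, strand-collapsed (a CpG is never
  duplicated per strand).  This is the Bismark-coverage convention.
* BED inputs are 0-based half-open; the conversion to 1-based point queries
  happens inside :meth:`RegionSet.contains`, nowhere else.
* The percent column of Bismark coverage files is never trusted; methylated /
  unmethylated counts are authoritative and percent is recomputed.

Missing data
------------
Absence of a (site, sample) cell in :class:`CpGCountMatrix` is represented as
NaN and is distinct from observed ``(0, 0)`` counts; presence-fraction filters
downstream rely on that distinction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ParseError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "CpGCountMatrix",
    "EpireadRecord",
    "RegionSet",
    "SampleSheet",
    "TurnoverTable",
    "ExpressionTable",
    "read_cpg_counts",
    "write_bismark_cov",
    "read_epireads",
    "write_epireads",
    "read_bed_regions",
    "write_bed_regions",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_turnover_table",
    "write_turnover_table",
    "read_expression_table",
    "write_expression_table",
    "read_promoter_map",
]

CELL_TYPES = ("stem", "nonstem", "whole")


# ---------------------------------------------------------------------------
# CpG count matrix
# ---------------------------------------------------------------------------

@dataclass
class CpGCountMatrix:
    """Per-CpG methylated/total read counts across samples.

    ``meth`` and ``total`` are float DataFrames with a ``(chromosome,
    position)`` MultiIndex and one column per sample.  NaN marks an absent
    cell; any non-NaN cell satisfies ``0 <= meth <= total``.
    """

    meth: pd.DataFrame
    total: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.meth.index.equals(self.total.index) or not list(
            self.meth.columns
        ) == list(self.total.columns):
            raise ValidationError("meth and total frames must be aligned")
        if self.meth.columns.duplicated().any():
            raise ValidationError("sample ids must be unique")
        if self.meth.index.duplicated().any():
            raise ValidationError("(chromosome, position) sites must be unique")
        # canonical site order: chromosome, then position ascending
        if not self.meth.index.is_monotonic_increasing:
            order = self.meth.index.sortlevel([0, 1])[1]
            object.__setattr__(self, "meth", self.meth.iloc[order])
            object.__setattr__(self, "total", self.total.iloc[order])
        present = self.total.notna()
        if not present.equals(self.meth.notna()):
            raise ValidationError("meth/total presence masks differ")
        m = self.meth.to_numpy(float)
        t = self.total.to_numpy(float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(m, initial=0.0) < 0 or np.nanmin(t, initial=0.0) < 0:
                raise ValidationError("counts must be non-negative")
            if np.any(m[present.to_numpy()] > t[present.to_numpy()]):
                raise ValidationError("methylated count exceeds total count")

    # -- construction -------------------------------------------------------
    @classmethod
    def from_long(cls, rows: pd.DataFrame) -> "CpGCountMatrix":
        """Build from a long frame with columns
        ``sample_id, chromosome, position, meth, total``."""
        dup = rows.duplicated(["sample_id", "chromosome", "position"])
        if dup.any():
            r = rows[dup].iloc[0]
            raise ValidationError(
                f"duplicate site {r.chromosome}:{r.position} for sample {r.sample_id}"
            )
        meth = rows.pivot(index=["chromosome", "position"], columns="sample_id", values="meth")
        total = rows.pivot(index=["chromosome", "position"], columns="sample_id", values="total")
        meth.columns.name = None
        total.columns.name = None
        return cls(meth.astype(float), total.astype(float))

    # -- accessors -----------------------------------------------------------
    @property
    def samples(self) -> list[str]:
        return list(self.meth.columns)

    @property
    def sites(self) -> list[tuple[str, int]]:
        return [(str(c), int(p)) for c, p in self.meth.index]

    @property
    def n_sites(self) -> int:
        return len(self.meth.index)

    def present(self) -> pd.DataFrame:
        return self.total.notna()

    def percent(self) -> pd.DataFrame:
        """Percent methylation (0-100); NaN where absent or total == 0."""
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * self.meth / self.total
        return pct.where(self.total > 0)

    def select_sites(self, keep: np.ndarray | pd.Index) -> "CpGCountMatrix":
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            return CpGCountMatrix(self.meth.loc[keep], self.total.loc[keep])
        return CpGCountMatrix(self.meth.loc[keep], self.total.loc[keep])

    def merge(self, other: "CpGCountMatrix") -> "CpGCountMatrix":
        """Outer join on (chromosome, position); sample sets must be disjoint."""
        overlap = set(self.samples) & set(other.samples)
        if overlap:
            raise ValidationError(f"samples present in both matrices: {sorted(overlap)}")
        meth = self.meth.join(other.meth, how="outer")
        total = self.total.join(other.total, how="outer")
        return CpGCountMatrix(meth, total)


def _parse_count_line(
    fields: Sequence[str], path: str, lineno: int, dialect: str
) -> tuple[str, int, int, int]:
    try:
        if dialect == "bismark_cov":
            if len(fields) != 6:
                raise ValueError(f"expected 6 columns, found {len(fields)}")
            chrom, start, _end, _pct, n_meth, n_unmeth = fields
            pos = int(start)
            m, u = int(n_meth), int(n_unmeth)
        else:  # tsv: chrom, position, count_methylated, count_unmethylated
            if len(fields) != 4:
                raise ValueError(f"expected 4 columns, found {len(fields)}")
            chrom = fields[0]
            pos, m, u = int(fields[1]), int(fields[2]), int(fields[3])
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: malformed line ({exc})") from None
    if m < 0 or u < 0:
        raise ValidationError(f"{path}:{lineno}: negative count")
    if pos < 1:
        raise ValidationError(f"{path}:{lineno}: position must be 1-based positive")
    return chrom, pos, m, m + u


def read_cpg_counts(
    paths: str | Path | Sequence[str | Path],
    dialect: str = "bismark_cov",
    sample_ids: Sequence[str] | None = None,
) -> CpGCountMatrix:
    """Read one or more per-sample CpG count files into a single matrix.

    ``bismark_cov`` files carry 6 whitespace-separated columns (chrom, start,
    end, percent, count_methylated, count_unmethylated; 1-based inclusive);
    the percent column is ignored and recomputed from counts.  ``tsv`` files
    carry 4 columns (chrom, position, count_methylated, count_unmethylated).
    Multiple files merge by (chromosome, position) outer join; cells missing
    from a file are marked absent.  Sample ids default to file stems.
    """
    if dialect not in ("bismark_cov", "tsv"):
        raise ValidationError(f"unknown dialect {dialect!r}")
    if isinstance(paths, (str, Path)):
        paths = [paths]
    paths = [Path(p) for p in paths]
    if sample_ids is None:
        sample_ids = [p.name.split(".")[0] for p in paths]
    if len(sample_ids) != len(paths):
        raise ValidationError("sample_ids must match paths in length")

    frames = []
    for sample, path in zip(sample_ids, paths):
        records: list[tuple[str, int, int, int]] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                records.append(
                    _parse_count_line(line.split(), str(path), lineno, dialect)
                )
        df = pd.DataFrame(records, columns=["chromosome", "position", "meth", "total"])
        df["sample_id"] = sample
        frames.append(df)
    rows = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["chromosome", "position", "meth", "total", "sample_id"]
    )
    return CpGCountMatrix.from_long(rows)


def write_bismark_cov(matrix: CpGCountMatrix, sample_id: str, path: str | Path) -> None:
    """Write one sample's present cells in Bismark-coverage dialect."""
    if sample_id not in matrix.samples:
        raise ValidationError(f"unknown sample {sample_id!r}")
    meth = matrix.meth[sample_id]
    total = matrix.total[sample_id]
    with open(path, "w") as fh:
        for (chrom, pos), m in meth.items():
            t = total.loc[(chrom, pos)]
            if np.isnan(t):
                continue
            m, t = int(m), int(t)
            pct = 100.0 * m / t if t > 0 else 0.0
            fh.write(f"{chrom}\t{pos}\t{pos}\t{pct:.6g}\t{m}\t{t - m}\n")


# ---------------------------------------------------------------------------
# Epireads
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EpireadRecord:
    """Methylation calls of one sequenced allele at named CpG positions.

    ``states`` is a string over ``{M, U}`` aligned with ``cpg_positions``
    (1-based, strictly increasing).
    """

    chromosome: str
    read_id: str
    cpg_positions: tuple[int, ...]
    states: str

    def __post_init__(self) -> None:
        if len(self.states) != len(self.cpg_positions):
            raise ValidationError(
                f"read {self.read_id}: {len(self.cpg_positions)} positions "
                f"but {len(self.states)} states"
            )
        if any(b <= a for a, b in zip(self.cpg_positions, self.cpg_positions[1:])):
            raise ValidationError(f"read {self.read_id}: positions not strictly increasing")
        bad = set(self.states) - {"M", "U"}
        if bad:
            raise ValidationError(f"read {self.read_id}: invalid state characters {sorted(bad)}")

    @property
    def n_methylated(self) -> int:
        return self.states.count("M")

    def state_at(self, position: int) -> str | None:
        try:
            return self.states[self.cpg_positions.index(position)]
        except ValueError:
            return None


def read_epireads(path: str | Path) -> list[EpireadRecord]:
    """Read an epiread TSV: chromosome, read_id, comma-joined positions, states."""
    records: list[EpireadRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns, found {len(fields)}")
            chrom, read_id, pos_s, states = fields
            try:
                positions = tuple(int(p) for p in pos_s.split(","))
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer CpG position") from None
            try:
                records.append(EpireadRecord(chrom, read_id, positions, states))
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from None
    return records


def write_epireads(records: Iterable[EpireadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#chromosome\tread_id\tcpg_positions\tstates\n")
        for r in records:
            fh.write(
                f"{r.chromosome}\t{r.read_id}\t"
                f"{','.join(str(p) for p in r.cpg_positions)}\t{r.states}\n"
            )


# ---------------------------------------------------------------------------
# Genomic regions (BED)
# ---------------------------------------------------------------------------

@dataclass
class RegionSet:
    """Named set of genomic intervals, 0-based half-open, normalized.

    Normalization sorts intervals and merges overlapping or book-ended ones,
    so the stored representation is canonical and idempotent under repeated
    normalization.
    """

    name: str
    intervals: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def from_intervals(
        cls, name: str, intervals: Iterable[tuple[str, int, int]]
    ) -> "RegionSet":
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            if start >= end:
                raise ValidationError(f"empty or inverted interval {chrom}:{start}-{end}")
            if start < 0:
                raise ValidationError(f"negative start {chrom}:{start}-{end}")
            by_chrom.setdefault(str(chrom), []).append((int(start), int(end)))
        merged: dict[str, np.ndarray] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            out: list[list[int]] = []
            for s, e in ivs:
                if out and s <= out[-1][1]:
                    out[-1][1] = max(out[-1][1], e)
                else:
                    out.append([s, e])
            merged[chrom] = np.asarray(out, dtype=np.int64)
        return cls(name=name, intervals=merged)

    def to_intervals(self) -> list[tuple[str, int, int]]:
        out = []
        for chrom in sorted(self.intervals):
            for s, e in self.intervals[chrom]:
                out.append((chrom, int(s), int(e)))
        return out

    @property
    def n_intervals(self) -> int:
        return sum(len(v) for v in self.intervals.values())

    def contains(self, chromosome: str, positions: Sequence[int] | np.ndarray) -> np.ndarray:
        """Membership of 1-based point positions (converted internally to 0-based)."""
        pos0 = np.asarray(positions, dtype=np.int64) - 1
        ivs = self.intervals.get(chromosome)
        if ivs is None or len(ivs) == 0:
            return np.zeros(pos0.shape, dtype=bool)
        idx = np.searchsorted(ivs[:, 0], pos0, side="right") - 1
        ok = idx >= 0
        ok[ok] &= pos0[ok] < ivs[idx[ok], 1]
        return ok

    def overlaps(self, chromosome: str, start: int, end: int) -> bool:
        """Whether the 0-based half-open query interval overlaps any region."""
        ivs = self.intervals.get(chromosome)
        if ivs is None or len(ivs) == 0:
            return False
        idx = np.searchsorted(ivs[:, 0], end, side="left")
        return bool(idx > 0 and ivs[idx - 1, 1] > start)


def read_bed_regions(path: str | Path, name: str) -> RegionSet:
    """Read a BED3+ file (0-based half-open) into a normalized RegionSet."""
    intervals: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
            if start >= end:
                raise ValidationError(f"{path}:{lineno}: start >= end")
            intervals.append((fields[0], start, end))
    return RegionSet.from_intervals(name, intervals)


def write_bed_regions(regions: RegionSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, s, e in regions.to_intervals():
            fh.write(f"{chrom}\t{s}\t{e}\n")


# ---------------------------------------------------------------------------
# Tabular metadata
# ---------------------------------------------------------------------------

def _read_table(path: str | Path) -> pd.DataFrame:
    """CSV/TSV with a header row; delimiter sniffed."""
    try:
        return pd.read_csv(path, sep=None, engine="python", comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: could not parse table ({exc})") from None


def _check_columns(df: pd.DataFrame, required: Sequence[str], path: str | Path) -> pd.DataFrame:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        logger.warning("%s: ignoring unknown columns %s", path, extra)
    return df[list(required)].copy()


@dataclass
class SampleSheet:
    """Sample metadata: tissue, age (months), cell type and pool size."""

    df: pd.DataFrame  # sample_id, tissue, age_months, cell_type, pool_size

    def __post_init__(self) -> None:
        df = self.df
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValidationError(f"duplicate sample_id values: {dups}")
        if (df["age_months"] <= 0).any():
            raise ValidationError("age_months must be positive")
        if (df["pool_size"] < 1).any():
            raise ValidationError("pool_size must be >= 1")
        bad = set(df["cell_type"]) - set(CELL_TYPES)
        if bad:
            raise ValidationError(f"unknown cell_type values: {sorted(bad)}")
        self.df = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df["sample_id"])

    def row(self, sample_id: str) -> pd.Series:
        hit = self.df[self.df["sample_id"] == sample_id]
        if hit.empty:
            raise ValidationError(f"unknown sample {sample_id!r}")
        return hit.iloc[0]

    def age_of(self, sample_id: str) -> float:
        return float(self.row(sample_id)["age_months"])

    def tissue_of(self, sample_id: str) -> str:
        return str(self.row(sample_id)["tissue"])

    def samples_where(
        self,
        tissue: str | None = None,
        age_months: float | None = None,
        cell_type: str | None = None,
    ) -> list[str]:
        df = self.df
        if tissue is not None:
            df = df[df["tissue"] == tissue]
        if age_months is not None:
            df = df[np.isclose(df["age_months"], age_months)]
        if cell_type is not None:
            df = df[df["cell_type"] == cell_type]
        return list(df["sample_id"])


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = _check_columns(
        _read_table(path),
        ["sample_id", "tissue", "age_months", "cell_type", "pool_size"],
        path,
    )
    try:
        df["age_months"] = df["age_months"].astype(float)
        df["pool_size"] = df["pool_size"].astype(int)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric age_months or pool_size ({exc})") from None
    df["sample_id"] = df["sample_id"].astype(str)
    df["tissue"] = df["tissue"].astype(str)
    df["cell_type"] = df["cell_type"].astype(str)
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.df.to_csv(path, index=False)


@dataclass
class TurnoverTable:
    """Organ -> average fraction of cells replaced per day."""

    df: pd.DataFrame  # organ, per_day_turnover

    def __post_init__(self) -> None:
        if self.df["organ"].duplicated().any():
            raise ValidationError("duplicate organ rows in turnover table")
        if (self.df["per_day_turnover"] < 0).any():
            raise ValidationError("per_day_turnover must be >= 0")
        self.df = self.df.reset_index(drop=True)

    def thirty_day(self) -> pd.Series:
        """30-day turnover rate: 30 times the average per-day turnover rate."""
        return pd.Series(
            (30.0 * self.df["per_day_turnover"]).to_numpy(),
            index=self.df["organ"].to_numpy(),
            name="turnover_30day",
        )


def read_turnover_table(path: str | Path) -> TurnoverTable:
    df = _check_columns(_read_table(path), ["organ", "per_day_turnover"], path)
    try:
        df["per_day_turnover"] = df["per_day_turnover"].astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric turnover ({exc})") from None
    df["organ"] = df["organ"].astype(str)
    return TurnoverTable(df)


def write_turnover_table(table: TurnoverTable, path: str | Path) -> None:
    table.df.to_csv(path, index=False)


@dataclass
class ExpressionTable:
    """Per-gene, per-sample log2 expression (reads per kilobase per million)."""

    df: pd.DataFrame  # gene_id, sample_id, log2_expression

    def __post_init__(self) -> None:
        if self.df.duplicated(["gene_id", "sample_id"]).any():
            raise ValidationError("duplicate (gene_id, sample_id) rows")
        self.df = self.df.reset_index(drop=True)

    def mean_by_gene(self, samples: Sequence[str] | None = None) -> pd.Series:
        df = self.df
        if samples is not None:
            df = df[df["sample_id"].isin(list(samples))]
        return df.groupby("gene_id")["log2_expression"].mean()


def read_expression_table(path: str | Path) -> ExpressionTable:
    df = _check_columns(_read_table(path), ["gene_id", "sample_id", "log2_expression"], path)
    try:
        df["log2_expression"] = df["log2_expression"].astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric expression ({exc})") from None
    df["gene_id"] = df["gene_id"].astype(str)
    df["sample_id"] = df["sample_id"].astype(str)
    return ExpressionTable(df)


def write_expression_table(table: ExpressionTable, path: str | Path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


def read_promoter_map(path: str | Path) -> pd.DataFrame:
    """Read a BED4 file mapping promoter intervals to gene ids.

    Returns a frame with columns gene_id, chromosome, start, end (0-based
    half-open).  A gene may only map to one promoter interval.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected BED4 (chrom start end gene)")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
            if start >= end:
                raise ValidationError(f"{path}:{lineno}: start >= end")
            rows.append((fields[3], fields[0], start, end))
    df = pd.DataFrame(rows, columns=["gene_id", "chromosome", "start", "end"])
    if df["gene_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate gene_id in promoter map")
    return df
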