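"""Readers, writers and genome tiling for per-cytosine methylation count tables.

Internal coordinates are 1-based closed intervals throughout; BED output is
converted to 0-based half-open on disk.  Strands are never merged: each
(chrom, pos, strand) triple is an independent site.  Sites with zero read
coverage are kept but their methylation level is MISSING (NaN), not 0.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CytosineSite",
    "MethylomeSample",
    "MethylMatrix",
    "GenomicRegion",
    "read_counts_table",
    "write_counts_table",
    "read_chrom_sizes",
    "build_matrix",
    "tile_genome",
    "write_intervals",
]

VALID_STRANDS = frozenset({"+", "-", "*"})
VALID_CONTEXTS = frozenset({"CG", "CHG", "CHH", "unknown"})

SITE_COLUMNS = ["chrom", "pos", "strand", "context", "n_meth", "n_total"]
KEY_COLUMNS = ["chrom", "pos", "strand"]


class CountTableError(ValueError):
    """Raised for malformed count tables (carries a line number when known)."""


def _normalize_context(ctx: str) -> str:
    ctx = str(ctx).upper()
    return ctx if ctx in ("CG", "CHG", "CHH") else "unknown"


def _normalize_strand(s: str) -> str:
    # Unicode minus occasionally shows up in hand-edited tables.
    s = str(s).replace("−", "-")
    if s not in VALID_STRANDS:
        raise CountTableError(f"invalid strand {s!r}")
    return s


@dataclass(frozen=True)
class CytosineSite:
    """A single cytosine: coordinates, sequence context and read counts."""

    chrom: str
    pos: int
    strand: str
    context: str
    n_meth: int
    n_total: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.n_meth < 0 or self.n_total < 0:
            raise ValueError("read counts must be non-negative")
        if self.n_meth > self.n_total:
            raise ValueError(
                f"n_meth ({self.n_meth}) exceeds n_total ({self.n_total})"
            )
        object.__setattr__(self, "strand", _normalize_strand(self.strand))
        object.__setattr__(self, "context", _normalize_context(self.context))

    @property
    def level(self) -> float:
        """Methylation level n_meth/n_total; NaN when coverage is zero."""
        if self.n_total == 0:
            return float("nan")
        return self.n_meth / self.n_total


def _validate_site_frame(df: pd.DataFrame, *, source: str = "<memory>") -> pd.DataFrame:
    if (df["pos"] < 1).any():
        bad = df.index[df["pos"] < 1][0]
        raise CountTableError(f"{source}: pos < 1 at row {bad}")
    if (df["n_meth"] > df["n_total"]).any():
        bad = df.index[df["n_meth"] > df["n_total"]][0]
        raise CountTableError(
            f"{source}: n_meth > n_total at line {bad + 2}"
        )
    if (df["n_meth"] < 0).any() or (df["n_total"] < 0).any():
        raise CountTableError(f"{source}: negative read count")
    dup = df.duplicated(subset=KEY_COLUMNS)
    if dup.any():
        key = df.loc[dup.idxmax(), KEY_COLUMNS].tolist()
        raise CountTableError(f"{source}: duplicate site key {tuple(key)}")
    df = df.sort_values(["chrom", "pos", "strand"], kind="mergesort")
    return df.reset_index(drop=True)


@dataclass
class MethylomeSample:
    """One methylome: a sorted, deduplicated table of cytosine sites.

    ``sites`` has columns chrom, pos, strand, context, n_meth, n_total and is
    sorted by (chrom, pos, strand) with unique keys.
    """

    sample_id: str
    sites: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=SITE_COLUMNS)
    )

    def __post_init__(self) -> None:
        df = self.sites.copy()
        if len(df) == 0:
            df = pd.DataFrame(columns=SITE_COLUMNS)
            df = df.astype(
                {"pos": "int64", "n_meth": "int64", "n_total": "int64"}
            )
        else:
            df = df[SITE_COLUMNS].astype(
                {
                    "chrom": "str",
                    "pos": "int64",
                    "strand": "str",
                    "context": "str",
                    "n_meth": "int64",
                    "n_total": "int64",
                }
            )
            df["strand"] = df["strand"].map(_normalize_strand)
            df["context"] = df["context"].map(_normalize_context)
            df = _validate_site_frame(df, source=self.sample_id)
        self.sites = df

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def levels(self) -> np.ndarray:
        """Per-site methylation level; NaN where coverage is zero (MISSING)."""
        total = self.sites["n_total"].to_numpy(dtype=float)
        meth = self.sites["n_meth"].to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            lv = np.where(total > 0, meth / np.where(total > 0, total, 1), np.nan)
        return lv

    def iter_sites(self) -> Iterable[CytosineSite]:
        for row in self.sites.itertuples(index=False):
            yield CytosineSite(
                row.chrom, int(row.pos), row.strand, row.context,
                int(row.n_meth), int(row.n_total),
            )


def _read_generic(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    expected = set(SITE_COLUMNS)
    if not expected.issubset(df.columns):
        missing = expected - set(df.columns)
        raise CountTableError(f"{path}: missing columns {sorted(missing)}")
    return df[SITE_COLUMNS]


def _read_cx_report(path: str) -> pd.DataFrame:
    names = ["chrom", "pos", "strand", "count_meth", "count_unmeth",
             "context", "tricontext"]
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=names,
                     dtype=str)
    meth = pd.to_numeric(df["count_meth"], errors="coerce")
    unmeth = pd.to_numeric(df["count_unmeth"], errors="coerce")
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["pos"],
            "strand": df["strand"],
            "context": df["context"],
            "n_meth": meth,
            "n_total": meth + unmeth,
        }
    )
    return out


def _read_methratio(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"chrom", "pos", "strand", "context", "C_count", "CT_count"}
    if not required.issubset(df.columns):
        missing = required - set(df.columns)
        raise CountTableError(f"{path}: missing columns {sorted(missing)}")
    return pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["pos"],
            "strand": df["strand"],
            "context": df["context"],
            "n_meth": df["C_count"],
            "n_total": df["CT_count"],
        }
    )


_DIALECTS = {
    "generic": _read_generic,
    "cx_report": _read_cx_report,
    "methratio": _read_methratio,
}


def read_counts_table(
    path: str | os.PathLike, dialect: str = "generic", sample_id: str | None = None
) -> MethylomeSample:
    """Read a per-cytosine count table into a :class:`MethylomeSample`.

    Parameters
    ----------
    path
        Tab-separated file.  Accepted dialects:

        ``generic``
            header ``chrom pos strand context n_meth n_total``
        ``cx_report``
            7 headerless columns chrom/pos/strand/count_meth/count_unmeth/
            context/tricontext; ``n_total = count_meth + count_unmeth``
        ``methratio``
            header with at least chrom, pos, strand, context, C_count,
            CT_count; counts taken from C_count/CT_count
    dialect
        One of the keys above.
    sample_id
        Defaults to the file's base name without extension.

    Raises
    ------
    CountTableError
        On malformed lines (reported with their line number), ``n_meth >
        n_total``, or duplicate (chrom, pos, strand) keys.
    """
    path = os.fspath(path)
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    df = _DIALECTS[dialect](path)
    if sample_id is None:
        sample_id = os.path.splitext(os.path.basename(path))[0]
    if len(df) == 0:
        return MethylomeSample(sample_id)

    for col in ("pos", "n_meth", "n_total"):
        num = pd.to_numeric(df[col], errors="coerce")
        bad = num.isna()
        if bad.any():
            # +2: one for the header line, one for 0-based indexing.  The
            # cx_report dialect has no header, hence +1 there.
            offset = 1 if dialect == "cx_report" else 2
            lineno = int(bad.idxmax()) + offset
            raise CountTableError(
                f"{path}: malformed value in column {col!r} at line {lineno}"
            )
        df[col] = num.astype("int64")
    try:
        return MethylomeSample(sample_id, df)
    except CountTableError as exc:
        raise CountTableError(f"{path}: {exc}") from None


def write_counts_table(sample: MethylomeSample, path: str | os.PathLike) -> None:
    """Write a sample back out in the generic dialect (lossless round trip)."""
    sample.sites.to_csv(path, sep="\t", index=False)


def read_chrom_sizes(path: str | os.PathLike) -> dict[str, int]:
    """Read a two-column ``chrom<TAB>length`` table."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "length"], dtype={"chrom": str})
    sizes = dict(zip(df["chrom"], df["length"].astype(int)))
    for chrom, size in sizes.items():
        if size < 1:
            raise ValueError(f"chromosome {chrom} has non-positive size {size}")
    return sizes


# ---------------------------------------------------------------------------
# Multi-sample matrix
# ---------------------------------------------------------------------------

@dataclass
class MethylMatrix:
    """Union-of-sites methylation level matrix across samples.

    ``sites`` holds one row per (chrom, pos, strand) key in sorted order with
    a pooled ``context`` column.  ``levels`` and ``coverages`` are
    ``(n_sites, n_samples)`` arrays; MISSING observations (a sample lacking
    the site, or zero coverage) are NaN in ``levels`` and 0 in ``coverages``.
    """

    sites: pd.DataFrame
    levels: np.ndarray
    coverages: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=float)
        self.coverages = np.asarray(self.coverages, dtype=float)
        n = len(self.sites)
        k = len(self.sample_ids)
        if self.levels.shape != (n, k) or self.coverages.shape != (n, k):
            raise ValueError("levels/coverages shape mismatch with sites/samples")
        finite = self.levels[np.isfinite(self.levels)]
        if finite.size and ((finite < 0).any() or (finite > 1).any()):
            raise ValueError("methylation levels must lie in [0, 1]")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def subset_context(self, context: str) -> "MethylMatrix":
        mask = (self.sites["context"] == context).to_numpy()
        return MethylMatrix(
            self.sites.loc[mask].reset_index(drop=True),
            self.levels[mask],
            self.coverages[mask],
            list(self.sample_ids),
        )


def build_matrix(samples: Sequence[MethylomeSample]) -> MethylMatrix:
    """Assemble a :class:`MethylMatrix` over the union of all samples' sites.

    Where a sample lacks a site, or covers it with zero reads, its level is
    MISSING (NaN).  Downstream entropy treats MISSING as zero bits; divergence
    computations skip such sites.
    """
    if len(samples) == 0:
        raise ValueError("build_matrix requires at least one sample")
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_id in sample list")

    frames = []
    for s in samples:
        df = s.sites[KEY_COLUMNS + ["context"]].copy()
        df["level"] = s.levels
        df["coverage"] = s.sites["n_total"].to_numpy(dtype=float)
        df["sample"] = s.sample_id
        frames.append(df)
    tall = pd.concat(frames, ignore_index=True)

    keys = (
        tall[KEY_COLUMNS + ["context"]]
        .drop_duplicates(subset=KEY_COLUMNS)
        .sort_values(["chrom", "pos", "strand"], kind="mergesort")
        .reset_index(drop=True)
    )
    index = pd.MultiIndex.from_frame(keys[KEY_COLUMNS])
    n = len(keys)
    levels = np.full((n, len(ids)), np.nan)
    coverages = np.zeros((n, len(ids)))
    for j, s in enumerate(samples):
        sub = tall[tall["sample"] == s.sample_id]
        loc = index.get_indexer(pd.MultiIndex.from_frame(sub[KEY_COLUMNS]))
        levels[loc, j] = sub["level"].to_numpy()
        coverages[loc, j] = sub["coverage"].to_numpy()
    return MethylMatrix(keys, levels, coverages, ids)


# ---------------------------------------------------------------------------
# Genome tiling and interval output
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicRegion:
    """1-based closed genomic interval."""

    chrom: str
    start: int
    end: int
    partial: bool = False

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"invalid region {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def tile_genome(chrom_sizes: Mapping[str, int], l: int) -> list[GenomicRegion]:
    """Split each chromosome into contiguous non-overlapping tiles of length *l*.

    The final tile is retained even when shorter than *l* and is flagged
    ``partial`` so downstream distribution fits can exclude it.
    """
    if l < 1:
        raise ValueError(f"tile length must be >= 1, got {l}")
    tiles: list[GenomicRegion] = []
    for chrom, size in chrom_sizes.items():
        if size < 1:
            raise ValueError(f"chromosome {chrom} has non-positive size")
        start = 1
        while start <= size:
            end = min(start + l - 1, size)
            tiles.append(GenomicRegion(chrom, start, end, partial=(end - start + 1 < l)))
            start = end + 1
    return tiles


def regions_to_frame(regions: Sequence[GenomicRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
            "partial": [r.partial for r in regions],
        }
    )


def write_intervals(
    features: pd.DataFrame,
    path: str | os.PathLike,
    name_column: str | None = None,
    score_column: str | None = None,
) -> None:
    """Write features as BED6, converting 1-based closed to 0-based half-open.

    ``features`` needs ``chrom``, ``start``, ``end`` columns (internal
    convention); ``strand`` defaults to ``.``; ``name``/``score`` columns are
    configurable.  An empty feature table produces a file with only the
    header comment.
    """
    with io.open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
        if len(features) == 0:
            return
        for col in ("chrom", "start", "end"):
            if col not in features.columns:
                raise ValueError(f"features lack required column {col!r}")
        names = (
            features[name_column].astype(str)
            if name_column
            else pd.Series(["."] * len(features), index=features.index)
        )
        scores = (
            features[score_column]
            if score_column
            else pd.Series(["0"] * len(features), index=features.index)
        )
        strands = (
            features["strand"].astype(str)
            if "strand" in features.columns
            else pd.Series(["."] * len(features), index=features.index)
        )
        for (_, row), name, score, strand in zip(
            features.iterrows(), names, scores, strands
        ):
            fh.write(
                f"{row['chrom']}\t{int(row['start']) - 1}\t{int(row['end'])}"
                f"\t{name}\t{score}\t{strand if strand in VALID_STRANDS else '.'}\n"
            )
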