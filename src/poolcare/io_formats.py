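"""Readers and writers for the formats the pipeline touches.

The central exchange format is the Popoolation2 "sync" table: one row per
genomic site, with per-population read counts as colon-separated sextuples
in the fixed order A:T:C:G:N:del.  Gene structure comes from GFF3, masks
from BED, the reference from FASTA, and gene category / GO-term mappings
from two-column TSV files.

All coordinates are 0-based half-open internally; sync and GFF3 coordinates
(1-based) are converted exactly once, at the parse/write boundary.  BED is
already 0-based half-open and passes through unchanged.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import gffutils
import numpy as np
import pandas as pd

#: sync column order (Popoolation2 convention).  N and del are parsed and
#: round-tripped but never counted as alleles.
SYNC_ALLELES = ("A", "T", "C", "G", "N", "del")
#: indices of the four true nucleotide classes within a sync sextuple
ACGT_IDX = (0, 1, 2, 3)
#: maps base -> sync column
BASE_TO_COL = {"A": 0, "T": 1, "C": 2, "G": 3, "N": 4}

GENE_CATEGORIES = ("TF", "expression_related", "lncRNA", "other")


class SyncParseError(ValueError):
    """Raised for malformed sync input; carries the offending line number."""


@dataclass
class AlleleCounts:
    """One sync record: per-population allele counts at a single site.

    ``pos`` is 0-based internally (the sync file prints ``pos + 1``).
    ``counts`` has shape (n_pops, 6) in A:T:C:G:N:del order.
    """

    chrom: str
    pos: int
    ref: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.pos < 0:
            raise SyncParseError(f"position must be >= 1 (1-based), got {self.pos + 1}")
        if self.counts.ndim != 2 or self.counts.shape[1] != 6:
            raise SyncParseError("counts must have shape (n_pops, 6)")
        if (self.counts < 0).any():
            raise SyncParseError("negative allele count")

    @property
    def n_pops(self) -> int:
        return self.counts.shape[0]


def parse_sync_line(line: str, n_pops: int, line_number: int | None = None) -> AlleleCounts:
    """Parse one sync line into an :class:`AlleleCounts` record.

    Parameters
    ----------
    line
        Tab- or whitespace-separated sync record ``chrom pos ref c1 .. cN``.
    n_pops
        Expected number of population count columns.
    line_number
        Optional 1-based line number used in error messages.

    Raises
    ------
    SyncParseError
        On wrong field arity, non-integer counts, or pos < 1.
    """
    where = f" at line {line_number}" if line_number is not None else ""
    fields = line.split()
    if len(fields) != 3 + n_pops:
        raise SyncParseError(
            f"expected {n_pops} populations (= {3 + n_pops} fields), "
            f"got {len(fields) - 3 if len(fields) >= 3 else 0}{where}"
        )
    chrom, pos_s, ref = fields[0], fields[1], fields[2]
    try:
        pos1 = int(pos_s)
    except ValueError as exc:
        raise SyncParseError(f"non-integer position {pos_s!r}{where}") from exc
    if pos1 < 1:
        raise SyncParseError(f"position must be >= 1, got {pos1}{where}")
    counts = np.empty((n_pops, 6), dtype=np.int64)
    for i, tok in enumerate(fields[3:]):
        parts = tok.split(":")
        if len(parts) != 6:
            raise SyncParseError(f"count field {tok!r} is not a sextuple{where}")
        try:
            counts[i] = [int(p) for p in parts]
        except ValueError as exc:
            raise SyncParseError(f"non-integer count in {tok!r}{where}") from exc
    if (counts < 0).any():
        raise SyncParseError(f"negative count{where}")
    return AlleleCounts(chrom=chrom, pos=pos1 - 1, ref=ref, counts=counts)


def format_sync_record(rec: AlleleCounts) -> str:
    """Inverse of :func:`parse_sync_line` (tab-separated, 1-based position)."""
    cols = ["%d:%d:%d:%d:%d:%d" % tuple(row) for row in rec.counts]
    return "\t".join([rec.chrom, str(rec.pos + 1), rec.ref] + cols)


@dataclass
class SyncTable:
    """Column-oriented in-memory sync dataset.

    Rows are sorted by (chrom, pos); ``counts`` has shape
    (n_sites, n_pops, 6).  Population order is fixed by ``pops`` and must
    come from the sample sheet, never be inferred.
    """

    chrom: np.ndarray
    pos: np.ndarray  # 0-based
    ref: np.ndarray
    counts: np.ndarray
    pops: list[str]

    def __post_init__(self) -> None:
        n = len(self.pos)
        if not (len(self.chrom) == len(self.ref) == self.counts.shape[0] == n):
            raise ValueError("column lengths disagree")
        if self.counts.ndim != 3 or self.counts.shape[2] != 6:
            raise ValueError("counts must have shape (n_sites, n_pops, 6)")
        if self.counts.shape[1] != len(self.pops):
            raise ValueError("population count mismatch")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_pops(self) -> int:
        return len(self.pops)

    def records(self) -> Iterator[AlleleCounts]:
        for i in range(self.n_sites):
            yield AlleleCounts(
                chrom=str(self.chrom[i]),
                pos=int(self.pos[i]),
                ref=str(self.ref[i]),
                counts=self.counts[i],
            )


def read_sync(path: str | Path | io.TextIOBase, pops: Sequence[str]) -> SyncTable:
    """Read a whole sync file into a :class:`SyncTable`.

    Uses a vectorised pandas path (the files can run to hundreds of
    thousands of rows); malformed rows surface as :class:`SyncParseError`.
    """
    pops = list(pops)
    n_pops = len(pops)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "pos", "ref"] + pops,
            dtype={"chrom": str, "ref": str},
            comment=None,
        )
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise SyncParseError(f"cannot read sync file: {exc}") from exc
    if df.shape[1] != 3 + n_pops:
        raise SyncParseError(f"expected {3 + n_pops} columns, got {df.shape[1]}")
    if not np.issubdtype(df["pos"].dtype, np.integer):
        raise SyncParseError("non-integer position column")
    if (df["pos"] < 1).any():
        bad = int(np.argmax(df["pos"].to_numpy() < 1)) + 1
        raise SyncParseError(f"position < 1 at line {bad}")
    counts = np.empty((len(df), n_pops, 6), dtype=np.int64)
    for i, p in enumerate(pops):
        col = df[p].astype(str).str.split(":", expand=True)
        if col.shape[1] != 6:
            raise SyncParseError(f"count field for population {p} is not a sextuple")
        try:
            counts[:, i, :] = col.to_numpy(dtype=np.int64)
        except ValueError as exc:
            raise SyncParseError(f"non-integer count in population {p}") from exc
    if (counts < 0).any():
        raise SyncParseError("negative allele count")
    return SyncTable(
        chrom=df["chrom"].to_numpy(dtype=object),
        pos=df["pos"].to_numpy(dtype=np.int64) - 1,
        ref=df["ref"].to_numpy(dtype=object),
        counts=counts,
        pops=pops,
    )


def write_sync(table: SyncTable, path: str | Path) -> None:
    """Write a sync file; byte-identical round trip with :func:`read_sync`."""
    cols: list[list[str]] = [
        [str(c) for c in table.chrom],
        [str(p) for p in (table.pos + 1).tolist()],
        [str(r) for r in table.ref],
    ]
    for i in range(table.n_pops):
        rows = table.counts[:, i, :].tolist()
        cols.append(["%d:%d:%d:%d:%d:%d" % tuple(r) for r in rows])
    with open(path, "w") as fh:
        fh.write("\n".join("\t".join(fields) for fields in zip(*cols)))
        fh.write("\n")


# ---------------------------------------------------------------------------
# region masks (BED)
# ---------------------------------------------------------------------------


@dataclass
class RegionMask:
    """Per-chromosome sets of merged, sorted half-open 0-based intervals."""

    intervals: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def from_intervals(cls, raw: Iterable[tuple[str, int, int]]) -> "RegionMask":
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in raw:
            if end <= start:
                continue
            by_chrom.setdefault(chrom, []).append((int(start), int(end)))
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
        return cls(intervals=merged)

    def contains(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Vectorised membership test for 0-based positions."""
        ivs = self.intervals.get(chrom)
        pos = np.asarray(pos)
        if ivs is None or len(ivs) == 0:
            return np.zeros(pos.shape, dtype=bool)
        idx = np.searchsorted(ivs[:, 0], pos, side="right") - 1
        ok = idx >= 0
        hit = np.zeros(pos.shape, dtype=bool)
        hit[ok] = pos[ok] < ivs[idx[ok], 1]
        return hit

    def total_length(self) -> int:
        return int(sum((iv[:, 1] - iv[:, 0]).sum() for iv in self.intervals.values()))


def read_bed_mask(path: str | Path) -> RegionMask:
    """Read a BED3 file (0-based half-open) into a merged :class:`RegionMask`."""
    rows: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"BED line {ln}: fewer than 3 columns")
            rows.append((parts[0], int(parts[1]), int(parts[2])))
    return RegionMask.from_intervals(rows)


def apply_mask(table: SyncTable, mask: RegionMask) -> SyncTable:
    """Drop sync rows whose site lies inside the mask; order preserved.

    Input must be sorted by (chrom, pos); raises ``ValueError`` otherwise.
    """
    order_ok = True
    ch = table.chrom
    for i in range(1, table.n_sites):
        if ch[i] == ch[i - 1] and table.pos[i] <= table.pos[i - 1]:
            order_ok = False
            break
    if not order_ok:
        raise ValueError("sync records must be sorted by (chrom, pos)")
    keep = np.ones(table.n_sites, dtype=bool)
    for chrom in pd.unique(ch):
        sel = ch == chrom
        keep[sel] = ~mask.contains(str(chrom), table.pos[sel])
    return SyncTable(
        chrom=table.chrom[keep],
        pos=table.pos[keep],
        ref=table.ref[keep],
        counts=table.counts[keep],
        pops=table.pops,
    )


# ---------------------------------------------------------------------------
# gene models (GFF3 + category table)
# ---------------------------------------------------------------------------


@dataclass
class GeneModel:
    """A gene with strand, ordered CDS intervals and a category label.

    ``start``/``end`` and the CDS intervals are 0-based half-open.  CDS
    intervals are stored in transcription order (descending genomic
    coordinate on the − strand).  Genes whose total CDS length is not a
    multiple of three are flagged (``valid_cds=False``) and excluded from
    codon-aware statistics; genes with no CDS (e.g. lncRNA) have an empty
    list and ``valid_cds=False``.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    cds: list[tuple[int, int]]
    category: str = "other"
    valid_cds: bool = True

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)


def read_category_table(path: str | Path) -> dict[str, str]:
    """Read the two-column gene_id -> category TSV.

    Unknown category labels are an error; genes absent from the table
    default to ``other`` downstream.
    """
    out: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"category table line {ln}: need 2 columns")
            gene, cat = parts[0], parts[1]
            if cat not in GENE_CATEGORIES:
                raise ValueError(
                    f"category table line {ln}: unknown category {cat!r} "
                    f"(expected one of {GENE_CATEGORIES})"
                )
            out[gene] = cat
    return out


def read_term_map(path: str | Path) -> dict[str, set[str]]:
    """Read a gene -> term TSV (one pair per line) into gene -> {terms}."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                continue
            out.setdefault(parts[0], set()).add(parts[1])
    return out


def read_gene_models(
    gff3: str | Path,
    category_table: str | Path | dict[str, str] | None = None,
) -> list[GeneModel]:
    """Load gene models from GFF3 plus an optional category mapping.

    CDS features are attached to their gene via the Parent chain; CDS
    intervals falling outside the gene span trigger a warning and flag the
    gene invalid.  Output order follows (chrom, start).
    """
    if category_table is None:
        categories: dict[str, str] = {}
    elif isinstance(category_table, dict):
        categories = category_table
    else:
        categories = read_category_table(category_table)

    db = gffutils.create_db(
        str(gff3),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        g_start, g_end = g.start - 1, g.end  # to 0-based half-open
        cds_raw: list[tuple[int, int]] = []
        ok = True
        for c in db.children(g, featuretype="CDS"):
            s, e = c.start - 1, c.end
            if s < g_start or e > g_end:
                warnings.warn(
                    f"gene {g.id}: CDS [{s},{e}) outside gene span; gene flagged"
                )
                ok = False
            cds_raw.append((s, e))
        cds_raw.sort()
        # non-overlap check in genomic order
        for a, b in zip(cds_raw, cds_raw[1:]):
            if b[0] < a[1]:
                warnings.warn(f"gene {g.id}: overlapping CDS intervals; gene flagged")
                ok = False
        strand = g.strand if g.strand in ("+", "-") else "+"
        cds = list(reversed(cds_raw)) if strand == "-" else cds_raw
        total = sum(e - s for s, e in cds)
        if total == 0 or total % 3 != 0:
            ok = False
        genes.append(
            GeneModel(
                gene_id=g.id,
                chrom=g.seqid,
                strand=strand,
                start=g_start,
                end=g_end,
                cds=cds,
                category=categories.get(g.id, "other"),
                valid_cds=ok,
            )
        )
    genes.sort(key=lambda gm: (gm.chrom, gm.start, gm.gene_id))
    return genes


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------


@dataclass
class SampleSheet:
    """Population metadata in sync column order: name, block, regime, pool size."""

    names: list[str]
    blocks: list[int]
    regimes: list[str]
    pool_sizes: list[int]

    def __post_init__(self) -> None:
        n = len(self.names)
        if not (len(self.blocks) == len(self.regimes) == len(self.pool_sizes) == n):
            raise ValueError("sample sheet columns disagree in length")
        for r in self.regimes:
            if r not in ("FC", "NC"):
                raise ValueError(f"regime must be FC or NC, got {r!r}")

    def pairs_by_block(self) -> dict[int, tuple[int, int]]:
        """Map block -> (index of FC population, index of NC population)."""
        out: dict[int, tuple[int, int]] = {}
        for b in sorted(set(self.blocks)):
            idx = [i for i, bb in enumerate(self.blocks) if bb == b]
            fc = [i for i in idx if self.regimes[i] == "FC"]
            nc = [i for i in idx if self.regimes[i] == "NC"]
            if len(fc) != 1 or len(nc) != 1:
                raise ValueError(f"block {b} must contain exactly one FC and one NC population")
            out[b] = (fc[0], nc[0])
        return out


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", comment="#")
    need = {"name", "block", "regime", "pool_size"}
    if not need.issubset(df.columns):
        raise ValueError(f"sample sheet must have columns {sorted(need)}")
    return SampleSheet(
        names=[str(x) for x in df["name"]],
        blocks=[int(x) for x in df["block"]],
        regimes=[str(x) for x in df["regime"]],
        pool_sizes=[int(x) for x in df["pool_size"]],
    )


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tblock\tregime\tpool_size\n")
        for i, name in enumerate(sheet.names):
            fh.write(f"{name}\t{sheet.blocks[i]}\t{sheet.regimes[i]}\t{sheet.pool_sizes[i]}\n")
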