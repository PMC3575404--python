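"""Domain types and file I/O for gene neighborhood scoring.

All genomic coordinates are stored 0-based, half-open (BED convention).
GFF3 input, which is 1-based inclusive, is converted on read.  Chromosome
names are compared verbatim; no "chr" prefix normalization is applied, so
location files and synteny-block files must agree on naming.
"""

from __future__ import annotations

import dataclasses
from bisect import bisect_right
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclasses.dataclass(frozen=True)
class GeneRecord:
    """One non-overlapping transcript/gene on the reference genome."""

    gene_id: str
    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    strand: str  # "+" or "-"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"{self.gene_id}: start ({self.start}) must be < end ({self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclasses.dataclass
class ExpressionMatrix:
    """Genes x samples quantitative expression with optional detection calls.

    ``values`` rows align with ``gene_ids``; columns with ``sample_ids``.
    ``detection``, when present, holds "P"/"A"/"M" flags of the same shape
    (microarray present/absent/marginal calls).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    detection: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains missing values")
        if self.n_samples < 2:
            raise ValueError("at least 2 samples are required")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids in expression matrix")
        if self.detection is not None:
            self.detection = np.asarray(self.detection, dtype=object)
            if self.detection.shape != self.values.shape:
                raise ValueError("detection matrix shape differs from values")
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row_index(self, gene_id: str) -> int:
        try:
            return self._index[gene_id]
        except KeyError:
            raise KeyError(f"gene {gene_id!r} not in expression matrix") from None

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.row_index(gene_id)]


@dataclasses.dataclass(frozen=True)
class SyntenyParams:
    """Chaining parameters for building syntenic blocks from marker anchors.

    min_blk: minimum reference span (bp) of a surviving block.
    max_gap: maximum gap (bp) between consecutive anchors joined into one chain,
        applied on both the reference and the target genome.
    num_mark: minimum number of anchors per block.
    """

    min_blk: int = 100_000
    max_gap: int = 1_000_000
    num_mark: int = 2

    def __post_init__(self) -> None:
        if self.min_blk <= 0 or self.max_gap <= 0 or self.num_mark < 1:
            raise ValueError("synteny parameters must be strictly positive, num_mark >= 1")


@dataclasses.dataclass(frozen=True)
class SyntenyBlock:
    ref_chrom: str
    ref_start: int
    ref_end: int
    tgt_chrom: str
    tgt_start: int
    tgt_end: int
    orientation: str  # "+" or "-"

    def __post_init__(self) -> None:
        if self.ref_start >= self.ref_end:
            raise ValueError(
                f"block {self.ref_chrom}:{self.ref_start}-{self.ref_end}: "
                "ref_start must be < ref_end"
            )
        if self.orientation not in ("+", "-"):
            raise ValueError(f"orientation must be '+' or '-', got {self.orientation!r}")


class SyntenyBlockSet:
    """Non-overlapping reference-genome intervals conserved in one species.

    Blocks are indexed per reference chromosome by sorted start coordinate,
    so containment queries are O(log n) bisections.
    """

    def __init__(self, species: str, blocks: Iterable[SyntenyBlock]):
        self.species = species
        self.blocks = sorted(blocks, key=lambda b: (b.ref_chrom, b.ref_start))
        self._starts: dict[str, list[int]] = {}
        self._by_chrom: dict[str, list[SyntenyBlock]] = {}
        for b in self.blocks:
            self._by_chrom.setdefault(b.ref_chrom, []).append(b)
        for chrom, blist in self._by_chrom.items():
            prev_end = -1
            for b in blist:
                if b.ref_start < prev_end:
                    raise ValueError(
                        f"species {species}: overlapping reference blocks on {chrom} "
                        f"at {b.ref_start}"
                    )
                prev_end = b.ref_end
            self._starts[chrom] = [b.ref_start for b in blist]

    def __len__(self) -> int:
        return len(self.blocks)

    def containing_block(self, chrom: str, start: int, end: int) -> Optional[SyntenyBlock]:
        """Return the block whose reference interval contains [start, end), if any."""
        if start >= end:
            raise ValueError("span start must be < end")
        starts = self._starts.get(chrom)
        if not starts:
            return None
        i = bisect_right(starts, start) - 1
        if i < 0:
            return None
        b = self._by_chrom[chrom][i]
        return b if end <= b.ref_end else None


@dataclasses.dataclass
class Neighborhood:
    """A candidate window of consecutive genes with its scores.

    ``size_key`` stratifies the permutation null: the gene count in
    gene_count mode, the requested bp size in bp mode.  Scores are None
    until the corresponding pipeline stage fills them in.
    """

    chrom: str
    member_gene_ids: tuple[str, ...]
    span_start: int
    span_end: int
    size_mode: str  # "gene_count" or "bp"
    size_key: int
    start_index: int  # index of the first member within its chromosome's gene list
    anc: Optional[float] = None
    p_value: Optional[float] = None
    ss: Optional[float] = None
    tns: Optional[float] = None
    extra_size_keys: tuple[int, ...] = ()  # bp mode: other requested sizes also satisfied

    def __post_init__(self) -> None:
        if len(self.member_gene_ids) < 2:
            raise ValueError("a neighborhood needs at least 2 member genes")
        if self.size_mode not in ("gene_count", "bp"):
            raise ValueError(f"unknown size_mode {self.size_mode!r}")

    @property
    def size_genes(self) -> int:
        return len(self.member_gene_ids)


# ---------------------------------------------------------------------------
# Readers / writers


def _error(path: str, lineno: int, msg: str) -> ParseError:
    return ParseError(f"{path}:{lineno}: {msg}")


def read_gene_locations(path: str, format: str = "bed") -> list[GeneRecord]:
    """Read gene/transcript locations from BED6 or GFF3.

    Returns records sorted by (chrom, start).  Duplicate gene ids are
    rejected: the downstream pipeline requires unique identifiers.
    """
    if format not in ("bed", "gff3"):
        raise ValueError(f"format must be 'bed' or 'gff3', got {format!r}")
    records: list[GeneRecord] = []
    seen: set[str] = set()
    n_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            n_lines += 1
            fields = line.split("\t")
            try:
                if format == "bed":
                    if len(fields) < 6:
                        raise ValueError(f"expected >= 6 BED fields, got {len(fields)}")
                    chrom, start, end, name, _score, strand = fields[:6]
                    rec = GeneRecord(name, chrom, int(start), int(end), strand)
                else:
                    if len(fields) != 9:
                        raise ValueError(f"expected 9 GFF3 fields, got {len(fields)}")
                    chrom, _src, _type, start, end, _score, strand, _phase, attrs = fields
                    gene_id = _gff3_id(attrs)
                    # GFF3 is 1-based inclusive; internal is 0-based half-open.
                    rec = GeneRecord(gene_id, chrom, int(start) - 1, int(end), strand)
            except (ValueError, KeyError) as exc:
                raise _error(path, lineno, str(exc)) from exc
            if rec.gene_id in seen:
                raise _error(path, lineno, f"duplicate gene_id {rec.gene_id!r}")
            seen.add(rec.gene_id)
            records.append(rec)
    if n_lines == 0:
        raise ParseError(f"{path}: no gene records found")
    records.sort(key=lambda r: (r.chrom, r.start, r.end, r.gene_id))
    return records


def _gff3_id(attrs: str) -> str:
    pairs = dict(
        kv.split("=", 1) for kv in attrs.split(";") if kv and "=" in kv
    )
    for key in ("ID", "gene_id", "Name"):
        if key in pairs:
            return pairs[key]
    raise ValueError(f"no ID/gene_id/Name attribute in {attrs!r}")


def write_gene_locations(records: Sequence[GeneRecord], path: str) -> None:
    """Write records as BED6 (score column fixed at 0)."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.gene_id}\t0\t{r.strand}\n")


def read_expression_table(
    path: str, detection_path: Optional[str] = None
) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene ids, header sample ids).

    Missing or non-numeric values are errors: the pipeline assumes a
    complete matrix and performs no imputation.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: need at least 2 sample columns, got {df.shape[1]}")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric expression value ({exc})") from exc
    detection = None
    gene_ids = [str(g) for g in df.index]
    sample_ids = [str(s) for s in df.columns]
    if detection_path is not None:
        det = pd.read_csv(
            detection_path, sep="\t", index_col=0, dtype=str, keep_default_na=False
        )
        if list(det.columns) != sample_ids:
            raise ParseError(
                f"{detection_path}: sample header does not match expression table"
            )
        missing = set(det.index) - set(gene_ids)
        if missing:
            raise ParseError(
                f"{detection_path}: genes absent from expression table: {sorted(missing)[:5]}"
            )
        det = det.reindex(gene_ids)
        if det.isna().any().any():
            absent = [g for g in gene_ids if g not in set(df.index.intersection(det.index))]
            raise ParseError(
                f"{detection_path}: missing detection rows for some genes: {absent[:5]}"
            )
        bad = set(det.to_numpy().ravel()) - {"P", "A", "M"}
        if bad:
            raise ParseError(f"{detection_path}: invalid detection flags {sorted(bad)}")
        detection = det.to_numpy(dtype=object)
    return ExpressionMatrix(gene_ids, sample_ids, values, detection)


_BLOCK_COLUMNS = [
    "ref_chrom",
    "ref_start",
    "ref_end",
    "tgt_chrom",
    "tgt_start",
    "tgt_end",
    "orientation",
]


def read_synteny_blocks(path: str, species: Optional[str] = None) -> SyntenyBlockSet:
    """Read a per-species synteny block TSV (seven columns, optional header).

    An empty file is a valid empty set: that species then conserves no
    neighborhood and contributes 0 to every synteny-score numerator.
    """
    if species is None:
        species = path
    blocks: list[SyntenyBlock] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "ref_chrom":  # header row
                continue
            if len(fields) != 7:
                raise _error(path, lineno, f"expected 7 fields, got {len(fields)}")
            try:
                blocks.append(
                    SyntenyBlock(
                        fields[0],
                        int(fields[1]),
                        int(fields[2]),
                        fields[3],
                        int(fields[4]),
                        int(fields[5]),
                        fields[6],
                    )
                )
            except ValueError as exc:
                raise _error(path, lineno, str(exc)) from exc
    return SyntenyBlockSet(species, blocks)


def write_synteny_blocks(block_set: SyntenyBlockSet, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_BLOCK_COLUMNS) + "\n")
        for b in block_set.blocks:
            fh.write(
                f"{b.ref_chrom}\t{b.ref_start}\t{b.ref_end}\t"
                f"{b.tgt_chrom}\t{b.tgt_start}\t{b.tgt_end}\t{b.orientation}\n"
            )
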