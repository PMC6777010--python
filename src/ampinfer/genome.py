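"""Gene-coordinate catalog and rank-order primitives.

The amplicon-inference algorithm reasons about gene *order* along a
chromosome, not about base pairs: "between", "nearest" and "span" are all
defined over the rank of a gene within its chromosome.  This module loads a
gene coordinate table, assigns each gene a rank, and exposes the rank-space
lookups everything downstream is built on.

Conventions
-----------
* Coordinates are stored 0-based half-open (BED convention) internally.
  All three accepted dialects (``tsv4``, ``tsv5``, ``bed4``) already use
  that convention; a future 1-based dialect would be converted on load.
* Within a chromosome, genes are ordered by ``(start, end, symbol)`` and
  ranked 0..n-1.  Overlapping or nested genes are therefore handled
  deterministically without any interval arithmetic.
* One record per symbol.  A source listing several intervals for the same
  symbol (multiple transcripts) is rejected; collapsing transcripts to a
  single representative interval is a data-preparation step.
* Symbol matching is case-insensitive (clinical reports are inconsistent,
  e.g. ``C15ORF65`` vs ``C15orf65``); output always carries the coordinate
  file's casing.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence, TextIO, Union

from .errors import CoordinateLoadError

__all__ = [
    "GeneRecord",
    "GenomeIndex",
    "DIALECTS",
    "load_gene_coordinates",
    "resolve_symbols",
    "genes_in_rank_span",
]

#: Accepted coordinate-file dialects (all 0-based half-open):
#:   tsv4: symbol <TAB> chrom <TAB> start <TAB> end
#:   tsv5: tsv4 plus a cytoband column (e.g. "11q13.3")
#:   bed4: chrom <TAB> start <TAB> end <TAB> symbol  (BED standard)
DIALECTS = ("tsv4", "tsv5", "bed4")

Source = Union[str, Path, TextIO]


@dataclass(frozen=True)
class GeneRecord:
    """One gene: symbol, location, optional cytogenetic band, and rank.

    ``rank`` is the gene's 0-based ordinal within its chromosome; it is
    assigned by :class:`GenomeIndex` and is ``-1`` on unindexed records.
    """

    symbol: str
    chrom: str
    start: int
    end: int
    cytoband: str | None = None
    rank: int = -1

    def __post_init__(self) -> None:
        if not self.symbol or any(c.isspace() for c in self.symbol):
            raise ValueError(f"invalid gene symbol: {self.symbol!r}")
        if self.start >= self.end:
            raise ValueError(
                f"{self.symbol}: start must be < end ({self.start} >= {self.end})"
            )


def _natural_chrom_key(chrom: str) -> tuple[int, int, str]:
    """Sort chromosomes 1..22, X, Y, others — numerically where possible."""
    name = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if name.isdigit():
        return (0, int(name), "")
    special = {"X": 23, "Y": 24, "M": 25, "MT": 25}
    if name.upper() in special:
        return (0, special[name.upper()], "")
    return (1, 0, name)


class GenomeIndex:
    """Per-chromosome rank-ordered gene catalog with symbol lookup.

    Construction sorts genes within each chromosome by (start, end, symbol),
    assigns ranks, and indexes symbols case-insensitively.  Duplicate
    symbols (after case folding) are rejected.
    """

    def __init__(self, records: Iterable[GeneRecord]):
        per_chrom: dict[str, list[GeneRecord]] = {}
        for rec in records:
            per_chrom.setdefault(rec.chrom, []).append(rec)

        self._chroms: dict[str, tuple[GeneRecord, ...]] = {}
        self._by_symbol: dict[str, GeneRecord] = {}
        for chrom in sorted(per_chrom, key=_natural_chrom_key):
            ordered = sorted(per_chrom[chrom], key=lambda g: (g.start, g.end, g.symbol))
            ranked = tuple(replace(g, rank=i) for i, g in enumerate(ordered))
            self._chroms[chrom] = ranked
            for g in ranked:
                key = g.symbol.casefold()
                if key in self._by_symbol:
                    raise ValueError(f"duplicate gene symbol: {g.symbol}")
                self._by_symbol[key] = g

    # -- basic container behaviour ------------------------------------

    @property
    def chromosomes(self) -> tuple[str, ...]:
        return tuple(self._chroms)

    def genes_on(self, chrom: str) -> tuple[GeneRecord, ...]:
        if chrom not in self._chroms:
            raise KeyError(f"unknown chromosome: {chrom}")
        return self._chroms[chrom]

    def n_genes(self, chrom: str) -> int:
        return len(self.genes_on(chrom))

    def __len__(self) -> int:
        return len(self._by_symbol)

    def __iter__(self) -> Iterator[GeneRecord]:
        for chrom in self._chroms:
            yield from self._chroms[chrom]

    def __contains__(self, symbol: str) -> bool:
        return symbol.casefold() in self._by_symbol

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenomeIndex):
            return NotImplemented
        return tuple(self) == tuple(other)

    # -- lookups -------------------------------------------------------

    def lookup(self, symbol: str) -> GeneRecord:
        """Case-insensitive symbol lookup; raises ``KeyError`` if absent."""
        try:
            return self._by_symbol[symbol.casefold()]
        except KeyError:
            raise KeyError(f"unknown gene symbol: {symbol}") from None

    def get(self, symbol: str) -> GeneRecord | None:
        return self._by_symbol.get(symbol.casefold())

    def gene_at(self, chrom: str, rank: int) -> GeneRecord:
        genes = self.genes_on(chrom)
        if not 0 <= rank < len(genes):
            raise IndexError(f"rank {rank} out of range for {chrom} ({len(genes)} genes)")
        return genes[rank]

    # -- serialization -------------------------------------------------

    def to_tsv(self, dialect: str = "tsv4") -> str:
        """Serialize in one of the accepted dialects (round-trips on load)."""
        _check_dialect(dialect)
        lines = []
        for g in self:
            if dialect == "tsv4":
                lines.append(f"{g.symbol}\t{g.chrom}\t{g.start}\t{g.end}")
            elif dialect == "tsv5":
                lines.append(
                    f"{g.symbol}\t{g.chrom}\t{g.start}\t{g.end}\t{g.cytoband or ''}"
                )
            else:  # bed4
                lines.append(f"{g.chrom}\t{g.start}\t{g.end}\t{g.symbol}")
        return "\n".join(lines) + "\n"


def _check_dialect(dialect: str) -> None:
    if dialect not in DIALECTS:
        raise CoordinateLoadError(
            f"unknown dialect {dialect!r}; expected one of {', '.join(DIALECTS)}"
        )


def _open_source(source: Source) -> tuple[TextIO, bool]:
    if isinstance(source, (str, Path)):
        return open(source, encoding="utf-8"), True
    return source, False


def load_gene_coordinates(source: Source, dialect: str = "tsv4") -> GenomeIndex:
    """Load a gene coordinate table into a :class:`GenomeIndex`.

    ``source`` is a path or an open text stream.  Blank lines and lines
    starting with ``#`` are ignored.  Malformed rows (wrong column count,
    non-integer coordinates, start >= end) and duplicate symbols reject the
    whole load with a :class:`~ampinfer.errors.CoordinateLoadError` naming
    the offending line or symbol.
    """
    _check_dialect(dialect)
    ncols = {"tsv4": 4, "tsv5": 5, "bed4": 4}[dialect]
    stream, should_close = _open_source(source)
    records: list[GeneRecord] = []
    try:
        for lineno, raw in enumerate(stream, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != ncols:
                raise CoordinateLoadError(
                    f"line {lineno}: expected {ncols} tab-separated fields "
                    f"for dialect {dialect}, got {len(fields)}"
                )
            if dialect == "bed4":
                chrom, start_s, end_s, symbol = fields
                cytoband = None
            else:
                symbol, chrom, start_s, end_s = fields[:4]
                cytoband = fields[4].strip() or None if dialect == "tsv5" else None
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise CoordinateLoadError(
                    f"line {lineno}: non-integer coordinates "
                    f"({start_s!r}, {end_s!r})"
                ) from None
            try:
                records.append(
                    GeneRecord(symbol.strip(), chrom.strip(), start, end, cytoband)
                )
            except ValueError as exc:
                raise CoordinateLoadError(f"line {lineno}: {exc}") from None
    finally:
        if should_close:
            stream.close()
    try:
        return GenomeIndex(records)
    except ValueError as exc:  # duplicate symbol
        raise CoordinateLoadError(str(exc)) from None


def load_gene_coordinates_text(text: str, dialect: str = "tsv4") -> GenomeIndex:
    """Convenience wrapper: load from an in-memory string."""
    return load_gene_coordinates(io.StringIO(text), dialect=dialect)


def resolve_symbols(
    index: GenomeIndex, symbols: Sequence[str]
) -> tuple[tuple[GeneRecord, ...], tuple[str, ...]]:
    """Partition tokens into (known records, unknown tokens).

    Matching is case-insensitive; returned records carry the index casing.
    The partition is exhaustive and order-preserving — no token is lost or
    duplicated, and severity is the caller's decision.
    """
    known: list[GeneRecord] = []
    unknown: list[str] = []
    for sym in symbols:
        rec = index.get(sym)
        if rec is None:
            unknown.append(sym)
        else:
            known.append(rec)
    return tuple(known), tuple(unknown)


def genes_in_rank_span(
    index: GenomeIndex, chrom: str, lo: int, hi: int
) -> tuple[GeneRecord, ...]:
    """All genes with rank in ``[lo, hi]`` inclusive, in rank order."""
    genes = index.genes_on(chrom)
    if not (0 <= lo <= hi < len(genes)):
        raise IndexError(
            f"rank span [{lo}, {hi}] invalid for {chrom} ({len(genes)} genes)"
        )
    return genes[lo : hi + 1]


def assign_cytobands(index: GenomeIndex, source: Source) -> GenomeIndex:
    """Return a new index with cytobands assigned from a UCSC-style file.

    Expected format: ``chrom <TAB> start <TAB> end <TAB> band`` (extra
    columns such as Giemsa stain are ignored).  A gene is assigned the band
    containing its start position; the stored label is the band prefixed
    with the chromosome name without any ``chr`` prefix, e.g. ``11q13.3``.
    """
    stream, should_close = _open_source(source)
    bands: dict[str, list[tuple[int, int, str]]] = {}
    try:
        for lineno, raw in enumerate(stream, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise CoordinateLoadError(
                    f"cytoband line {lineno}: expected >=4 fields, got {len(fields)}"
                )
            chrom, start_s, end_s, band = fields[:4]
            try:
                bands.setdefault(chrom, []).append((int(start_s), int(end_s), band))
            except ValueError:
                raise CoordinateLoadError(
                    f"cytoband line {lineno}: non-integer coordinates"
                ) from None
    finally:
        if should_close:
            stream.close()
    for intervals in bands.values():
        intervals.sort()

    def band_of(g: GeneRecord) -> str | None:
        for start, end, name in bands.get(g.chrom, ()):
            if start <= g.start < end:
                stripped = g.chrom[3:] if g.chrom.lower().startswith("chr") else g.chrom
                return f"{stripped}{name}"
        return None

    return GenomeIndex(
        replace(g, cytoband=band_of(g) or g.cytoband, rank=-1) for g in index
    )
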