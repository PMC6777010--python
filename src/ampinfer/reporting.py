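"""Census annotation, region labels, and report rendering.

An :class:`AmpliconReport` decorates an inferred amplicon with the pieces a
molecular tumor board wants at a glance: a cytoband-range region label, the
number of potentially co-amplified genes, and the cancer gene census
members falling inside the inferred extent (reported genes included when
they are census members).  The *extent* pooled for annotation is core plus
boundary genes: the report deliberately does not distinguish likely
co-amplified core genes from possibly co-amplified boundary genes, since
both warrant the same follow-up.

Renderers produce a human-readable table, TSV, JSON (lossless; see
:func:`reports_from_json`), or BED with one core and one possibly-amplified
interval per amplicon.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, TextIO, Union

from .errors import CensusError, RenderError
from .genome import GeneRecord
from .inference import AmpliconCall

__all__ = [
    "CensusSet",
    "AmpliconReport",
    "DEFAULT_LINK_TEMPLATE",
    "FORMATS",
    "load_census",
    "annotate",
    "region_label",
    "render",
    "reports_from_json",
]

#: COSMIC per-gene page; link construction only, never fetched.
DEFAULT_LINK_TEMPLATE = "https://cancer.sanger.ac.uk/cosmic/gene/analysis?ln={symbol}"

FORMATS = ("text", "tsv", "json", "bed")

Source = Union[str, Path, TextIO]


@dataclass(frozen=True)
class CensusSet:
    """Genes recurrently somatically altered in cancer (COSMIC-census style).

    ``tiers`` optionally maps a symbol to its census tier label.
    Membership tests are case-insensitive.
    """

    symbols: tuple[str, ...]
    tiers: dict[str, str]

    def __post_init__(self) -> None:
        if not self.symbols:
            raise CensusError("census set has no genes")

    def __contains__(self, symbol: str) -> bool:
        return symbol.casefold() in {s.casefold() for s in self.symbols}

    def __len__(self) -> int:
        return len(self.symbols)


def load_census(source: Source) -> CensusSet:
    """Load a census list: one ``symbol`` or ``symbol<TAB>tier`` per line.

    Blank lines and ``#`` comments are ignored; duplicate symbols collapse
    case-insensitively.  An empty result raises
    :class:`~ampinfer.errors.CensusError`.
    """
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as fh:
            lines = fh.readlines()
    else:
        lines = source.readlines()
    symbols: list[str] = []
    tiers: dict[str, str] = {}
    seen: set[str] = set()
    for raw in lines:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        sym = fields[0].strip()
        if not sym or sym.casefold() in seen:
            continue
        seen.add(sym.casefold())
        symbols.append(sym)
        if len(fields) > 1 and fields[1].strip():
            tiers[sym] = fields[1].strip()
    if not symbols:
        raise CensusError("census file contains no genes")
    return CensusSet(symbols=tuple(symbols), tiers=tiers)


@dataclass(frozen=True)
class AmpliconReport:
    """One amplicon plus its annotation, ready for rendering."""

    call: AmpliconCall
    region_label: str
    coamplified_count: int
    census_genes: tuple[str, ...]
    links: dict[str, str]


def region_label(call: AmpliconCall) -> str:
    """Region label for the full inferred extent (core plus boundary genes).

    With cytobands loaded the label is ``Chr{first band}–{last band}``,
    collapsing to a single band when they agree (e.g. ``Chr4q12``); without
    cytobands it falls back to ``chrom:start-end`` over the extent's
    outermost coordinates.
    """
    extent = call.extent_genes
    first, last = extent[0], extent[-1]
    if first.cytoband and last.cytoband:
        if first.cytoband == last.cytoband:
            return f"Chr{first.cytoband}"
        return f"Chr{first.cytoband}–{last.cytoband}"
    return f"{call.chrom}:{call.extent_start}-{call.extent_end}"


def annotate(
    call: AmpliconCall,
    census: CensusSet | None,
    link_template: str = DEFAULT_LINK_TEMPLATE,
) -> AmpliconReport:
    """Build the report for one completed call.

    ``census_genes`` are the census members among core plus boundary genes,
    in rank order — including reported genes that are census members.
    ``coamplified_count`` is the number of extent genes that are not
    themselves reported: the genes riding along with the reported ones.
    """
    extent = call.extent_genes
    census_genes = tuple(
        g.symbol for g in extent if census is not None and g.symbol in census
    )
    reported = {g.symbol for g in call.reported_genes}
    count = len(extent) - len(reported)
    linked = [g.symbol for g in call.reported_genes] + [
        s for s in census_genes if s not in reported
    ]
    links = {s: link_template.format(symbol=s) for s in linked}
    return AmpliconReport(
        call=call,
        region_label=region_label(call),
        coamplified_count=count,
        census_genes=census_genes,
        links=links,
    )


# ---------------------------------------------------------------------------
# rendering


def _gene_to_dict(g: GeneRecord) -> dict:
    return {
        "symbol": g.symbol,
        "chrom": g.chrom,
        "start": g.start,
        "end": g.end,
        "cytoband": g.cytoband,
        "rank": g.rank,
    }


def _gene_from_dict(d: dict) -> GeneRecord:
    return GeneRecord(
        symbol=d["symbol"],
        chrom=d["chrom"],
        start=d["start"],
        end=d["end"],
        cytoband=d.get("cytoband"),
        rank=d.get("rank", -1),
    )


def _report_to_dict(r: AmpliconReport) -> dict:
    c = r.call
    return {
        "id": c.id,
        "chrom": c.chrom,
        "reported_genes": [_gene_to_dict(g) for g in c.reported_genes],
        "core_genes": [_gene_to_dict(g) for g in c.core_genes],
        "left_boundary_gene": (
            _gene_to_dict(c.left_boundary_gene) if c.left_boundary_gene else None
        ),
        "right_boundary_gene": (
            _gene_to_dict(c.right_boundary_gene) if c.right_boundary_gene else None
        ),
        "boundary_genes_left": [_gene_to_dict(g) for g in c.boundary_genes_left],
        "boundary_genes_right": [_gene_to_dict(g) for g in c.boundary_genes_right],
        "adjacent_to": list(c.adjacent_to),
        "left_unbounded": c.left_unbounded,
        "right_unbounded": c.right_unbounded,
        "region_label": r.region_label,
        "coamplified_count": r.coamplified_count,
        "census_genes": list(r.census_genes),
        "links": dict(r.links),
    }


def _report_from_dict(d: dict) -> AmpliconReport:
    call = AmpliconCall(
        id=d["id"],
        chrom=d["chrom"],
        reported_genes=tuple(_gene_from_dict(g) for g in d["reported_genes"]),
        core_genes=tuple(_gene_from_dict(g) for g in d["core_genes"]),
        left_boundary_gene=(
            _gene_from_dict(d["left_boundary_gene"])
            if d["left_boundary_gene"]
            else None
        ),
        right_boundary_gene=(
            _gene_from_dict(d["right_boundary_gene"])
            if d["right_boundary_gene"]
            else None
        ),
        boundary_genes_left=tuple(
            _gene_from_dict(g) for g in d["boundary_genes_left"]
        ),
        boundary_genes_right=tuple(
            _gene_from_dict(g) for g in d["boundary_genes_right"]
        ),
        adjacent_to=tuple(d["adjacent_to"]),
        extended=True,
    )
    return AmpliconReport(
        call=call,
        region_label=d["region_label"],
        coamplified_count=d["coamplified_count"],
        census_genes=tuple(d["census_genes"]),
        links=dict(d["links"]),
    )


def _gene_location(g: GeneRecord) -> str:
    return f"Chr{g.cytoband}" if g.cytoband else g.chrom


def _render_text(
    reports: Sequence[AmpliconReport],
    verbose: bool,
    assayed_genes: Sequence[str] | None,
) -> str:
    if not reports:
        return "No amplicons inferred.\n"
    header = [
        "Amplicon",
        "Reported genes (location)",
        "Co-amplified (region)",
        "Census genes",
        "Closely co-located",
    ]
    rows = []
    for r in reports:
        c = r.call
        bounds = ""
        if c.left_unbounded or c.right_unbounded:
            sides = [s for s, u in (("left", c.left_unbounded), ("right", c.right_unbounded)) if u]
            bounds = f" [unbounded {'/'.join(sides)}]"
        rows.append(
            [
                c.id,
                ", ".join(f"{g.symbol} ({_gene_location(g)})" for g in c.reported_genes),
                f"{r.coamplified_count} ({r.region_label}){bounds}",
                ", ".join(r.census_genes) or "-",
                ", ".join(c.adjacent_to) or "-",
            ]
        )
    widths = [max(len(h), *(len(row[i]) for row in rows)) for i, h in enumerate(header)]
    lines = [
        "  ".join(h.ljust(w) for h, w in zip(header, widths)).rstrip(),
        "  ".join("-" * w for w in widths),
    ]
    for row in rows:
        lines.append("  ".join(v.ljust(w) for v, w in zip(row, widths)).rstrip())
    out = "\n".join(lines) + "\n"
    if verbose:
        blocks = []
        if assayed_genes is not None:
            blocks.append(
                f"Assayed genes ({len(assayed_genes)}): " + ", ".join(assayed_genes)
            )
        for r in reports:
            c = r.call
            blocks.append(
                f"{c.id}: all genes in inferred amplicon: "
                + ", ".join(g.symbol for g in c.extent_genes)
            )
            bg = [g.symbol for g in (c.left_boundary_gene, c.right_boundary_gene) if g]
            blocks.append(
                f"{c.id}: boundary non-amplified genes: " + (", ".join(bg) or "none")
            )
        out += "\n" + "\n".join(blocks) + "\n"
    return out


TSV_HEADER = (
    "amplicon_id",
    "chrom",
    "reported_genes",
    "region",
    "coamplified_count",
    "census_genes",
    "closely_colocated_with",
    "core_start",
    "core_end",
    "extent_start",
    "extent_end",
    "left_boundary_gene",
    "right_boundary_gene",
)


def _render_tsv(reports: Sequence[AmpliconReport]) -> str:
    lines = ["\t".join(TSV_HEADER)]
    for r in reports:
        c = r.call
        lines.append(
            "\t".join(
                [
                    c.id,
                    c.chrom,
                    ",".join(g.symbol for g in c.reported_genes),
                    r.region_label,
                    str(r.coamplified_count),
                    ",".join(r.census_genes),
                    ",".join(c.adjacent_to),
                    str(c.core_start),
                    str(c.core_end),
                    str(c.extent_start),
                    str(c.extent_end),
                    c.left_boundary_gene.symbol if c.left_boundary_gene else "",
                    c.right_boundary_gene.symbol if c.right_boundary_gene else "",
                ]
            )
        )
    return "\n".join(lines) + "\n"


def _render_json(
    reports: Sequence[AmpliconReport],
    verbose: bool,
    assayed_genes: Sequence[str] | None,
) -> str:
    doc: dict = {"amplicons": [_report_to_dict(r) for r in reports]}
    if verbose and assayed_genes is not None:
        doc["assayed_genes"] = list(assayed_genes)
    return json.dumps(doc, indent=2, sort_keys=True) + "\n"


def _render_bed(reports: Sequence[AmpliconReport]) -> str:
    """Two intervals per amplicon: the core and the possibly-amplified extent."""
    lines = []
    for r in reports:
        c = r.call
        lines.append(f"{c.chrom}\t{c.core_start}\t{c.core_end}\t{c.id}_core")
        lines.append(f"{c.chrom}\t{c.extent_start}\t{c.extent_end}\t{c.id}_possible")
    return "\n".join(lines) + ("\n" if lines else "")


def render(
    reports: Sequence[AmpliconReport],
    fmt: str = "text",
    verbose: bool = False,
    assayed_genes: Sequence[str] | None = None,
) -> str:
    """Render annotated amplicons in one of :data:`FORMATS`.

    ``verbose`` adds the assayed gene list, the full gene content of each
    inferred amplicon, and the boundary non-amplified genes (text/JSON).
    Zero amplicons yield a well-formed empty document in every format.
    """
    if fmt == "text":
        return _render_text(reports, verbose, assayed_genes)
    if fmt == "tsv":
        return _render_tsv(reports)
    if fmt == "json":
        return _render_json(reports, verbose, assayed_genes)
    if fmt == "bed":
        return _render_bed(reports)
    raise RenderError(f"unknown format {fmt!r}; expected one of {', '.join(FORMATS)}")


def reports_from_json(document: str) -> tuple[list[AmpliconReport], list[str] | None]:
    """Parse a JSON render back into reports (lossless round-trip)."""
    doc = json.loads(document)
    reports = [_report_from_dict(d) for d in doc["amplicons"]]
    return reports, doc.get("assayed_genes")


def build_reports(
    calls: Iterable[AmpliconCall],
    census: CensusSet | None = None,
    link_template: str = DEFAULT_LINK_TEMPLATE,
) -> list[AmpliconReport]:
    """Annotate every call; convenience composition used by the CLI."""
    return [annotate(c, census, link_template) for c in calls]
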