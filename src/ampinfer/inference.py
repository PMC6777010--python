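"""Amplicon inference from gene-level amplification calls.

The algorithm takes three inputs — the genome's gene order, the assay
panel, and the set of genes a clinical report calls amplified — and
reconstructs the contiguous amplified regions (amplicons) they imply:

1. **Classify** every gene in the genome as reported-amplified (in the
   query), assayed-not-amplified (on the panel but not in the query), or
   not assayed.
2. **Build** amplicons: scanning each chromosome in rank order, two
   consecutive reported genes belong to the same amplicon iff no
   assayed-not-amplified gene lies strictly between them.  All genes
   between the outermost reported genes of an amplicon (its *core*) are
   considered amplified, assayed or not.
3. **Extend** boundaries: the nearest assayed-not-amplified gene on each
   side delimits the amplicon; every gene between the core and that
   boundary gene — exclusive on both sides — is *possibly* amplified.
   With no assayed non-amplified gene beyond the core on one side, the
   possibly-amplified region runs to the chromosome end and that side is
   reported as unbounded.
4. **Flag** closely co-located amplicons: when two amplicons on the same
   chromosome are separated by at most ``max_gap`` assayed-not-amplified
   genes (default 1, the shared-boundary-gene situation), the separating
   gene may have been erroneously not called amplified, so both calls are
   mutually flagged.

Everything is deterministic set logic in rank space: identical inputs give
identical calls.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

from .errors import UnknownGeneError
from .genome import GeneRecord, GenomeIndex, resolve_symbols
from .panels import AmplifiedQuery, Panel

__all__ = [
    "GeneStatus",
    "AmpliconCall",
    "classify_genes",
    "build_amplicons",
    "extend_boundaries",
    "flag_adjacent",
    "infer",
]

logger = logging.getLogger("ampinfer")


class GeneStatus(enum.Enum):
    """Observation status of one gene for a given (panel, query)."""

    REPORTED_AMPLIFIED = "reported_amplified"
    ASSAYED_NOT_AMPLIFIED = "assayed_not_amplified"
    NOT_ASSAYED = "not_assayed"


StatusMap = Mapping[str, GeneStatus]


@dataclass(frozen=True)
class AmpliconCall:
    """One inferred amplicon.

    ``core_genes`` spans the outermost reported genes inclusive (all
    considered amplified); ``boundary_genes_left``/``right`` are the
    possibly-amplified genes between the core and the nearest
    assayed-not-amplified gene on each side (that *boundary gene* itself
    excluded).  ``adjacent_to`` lists the ids of closely co-located
    amplicons on the same chromosome.
    """

    id: str
    chrom: str
    reported_genes: tuple[GeneRecord, ...]
    core_genes: tuple[GeneRecord, ...]
    left_boundary_gene: GeneRecord | None = None
    right_boundary_gene: GeneRecord | None = None
    boundary_genes_left: tuple[GeneRecord, ...] = ()
    boundary_genes_right: tuple[GeneRecord, ...] = ()
    adjacent_to: tuple[str, ...] = ()
    extended: bool = field(default=False)

    @property
    def core_lo(self) -> int:
        return self.core_genes[0].rank

    @property
    def core_hi(self) -> int:
        return self.core_genes[-1].rank

    @property
    def boundary_genes(self) -> tuple[GeneRecord, ...]:
        return self.boundary_genes_left + self.boundary_genes_right

    @property
    def extent_genes(self) -> tuple[GeneRecord, ...]:
        """Core plus boundary genes, in rank order (the full inferred extent)."""
        return self.boundary_genes_left + self.core_genes + self.boundary_genes_right

    @property
    def core_start(self) -> int:
        return min(g.start for g in self.core_genes)

    @property
    def core_end(self) -> int:
        return max(g.end for g in self.core_genes)

    @property
    def extent_start(self) -> int:
        return min(g.start for g in self.extent_genes)

    @property
    def extent_end(self) -> int:
        return max(g.end for g in self.extent_genes)

    @property
    def left_unbounded(self) -> bool:
        """True when no assayed non-amplified gene exists left of the core."""
        return self.extended and self.left_boundary_gene is None

    @property
    def right_unbounded(self) -> bool:
        return self.extended and self.right_boundary_gene is None


def classify_genes(
    index: GenomeIndex,
    panel: Panel,
    query: AmplifiedQuery,
    *,
    skip_unknown: bool = False,
) -> dict[str, GeneStatus]:
    """Assign every gene in the index exactly one :class:`GeneStatus`.

    Query genes are reported-amplified; remaining panel genes are
    assayed-not-amplified; everything else is not assayed.  Query symbols
    absent from the index raise :class:`~ampinfer.errors.UnknownGeneError`
    unless ``skip_unknown``, which demotes them to a warning.  Query genes
    off the panel are accepted (the report evidently assayed them) with a
    warning; panel genes absent from the index are dropped with a warning —
    they can neither bound nor join amplicons.
    """
    known, unknown = resolve_symbols(index, query.symbols)
    if unknown:
        if not skip_unknown:
            raise UnknownGeneError(unknown)
        logger.warning(
            "skipping %d unknown query gene(s): %s", len(unknown), ", ".join(unknown)
        )

    off_panel = [g.symbol for g in known if g.symbol not in panel]
    if off_panel:
        logger.warning(
            "%d query gene(s) not on panel %r, treating as assayed and "
            "amplified: %s",
            len(off_panel),
            panel.name,
            ", ".join(off_panel),
        )

    panel_known, panel_unknown = resolve_symbols(index, panel.symbols)
    if panel_unknown:
        logger.warning(
            "dropped %d panel gene(s) absent from the genome index",
            len(panel_unknown),
        )

    statuses: dict[str, GeneStatus] = {g.symbol: GeneStatus.NOT_ASSAYED for g in index}
    for g in panel_known:
        statuses[g.symbol] = GeneStatus.ASSAYED_NOT_AMPLIFIED
    for g in known:
        statuses[g.symbol] = GeneStatus.REPORTED_AMPLIFIED
    return statuses


def build_amplicons(index: GenomeIndex, statuses: StatusMap) -> list[AmpliconCall]:
    """Consolidate reported amplified genes into amplicons, per chromosome.

    Two consecutive reported genes (in rank order) join the same amplicon
    iff no assayed-not-amplified gene lies strictly between them; not-assayed
    genes never separate.  Returns calls sorted by (chromosome, core start
    rank) with sequential ids; boundary fields are left for
    :func:`extend_boundaries`.
    """
    calls: list[AmpliconCall] = []
    for chrom in index.chromosomes:
        genes = index.genes_on(chrom)
        reported = [g for g in genes if statuses[g.symbol] is GeneStatus.REPORTED_AMPLIFIED]
        if not reported:
            continue
        groups: list[list[GeneRecord]] = [[reported[0]]]
        for prev, nxt in zip(reported, reported[1:]):
            separated = any(
                statuses[g.symbol] is GeneStatus.ASSAYED_NOT_AMPLIFIED
                for g in genes[prev.rank + 1 : nxt.rank]
            )
            if separated:
                groups.append([nxt])
            else:
                groups[-1].append(nxt)
        for group in groups:
            core = genes[group[0].rank : group[-1].rank + 1]
            calls.append(
                AmpliconCall(
                    id="",  # assigned below, after global ordering
                    chrom=chrom,
                    reported_genes=tuple(group),
                    core_genes=tuple(core),
                )
            )
    return [replace(c, id=f"amp{i}") for i, c in enumerate(calls, start=1)]


def extend_boundaries(
    call: AmpliconCall, index: GenomeIndex, statuses: StatusMap
) -> AmpliconCall:
    """Complete a call with its boundary genes and possibly-amplified sets.

    The left boundary gene is the highest-rank assayed-not-amplified gene
    below the core (symmetric on the right); the possibly-amplified genes
    on each side lie strictly between boundary gene and core.  A side with
    no boundary gene extends to the chromosome end and is marked unbounded.
    """
    genes = index.genes_on(call.chrom)

    left_bg = None
    for g in reversed(genes[: call.core_lo]):
        if statuses[g.symbol] is GeneStatus.ASSAYED_NOT_AMPLIFIED:
            left_bg = g
            break
    right_bg = None
    for g in genes[call.core_hi + 1 :]:
        if statuses[g.symbol] is GeneStatus.ASSAYED_NOT_AMPLIFIED:
            right_bg = g
            break

    left_lo = left_bg.rank + 1 if left_bg is not None else 0
    right_hi = right_bg.rank if right_bg is not None else len(genes)
    return replace(
        call,
        left_boundary_gene=left_bg,
        right_boundary_gene=right_bg,
        boundary_genes_left=tuple(genes[left_lo : call.core_lo]),
        boundary_genes_right=tuple(genes[call.core_hi + 1 : right_hi]),
        extended=True,
    )


def flag_adjacent(
    calls: Iterable[AmpliconCall],
    index: GenomeIndex,
    statuses: StatusMap,
    max_gap: int = 1,
) -> list[AmpliconCall]:
    """Mutually flag same-chromosome amplicons in very close proximity.

    For each consecutive same-chromosome pair, the assayed-not-amplified
    genes strictly between the two cores are counted; when that count is at
    most ``max_gap`` the separating gene(s) may be erroneously un-called and
    both amplicons list each other in ``adjacent_to``.  ``max_gap`` must be
    >= 1: separated amplicons always have at least one separator, so 0
    would contradict the merge rule.
    """
    if max_gap < 1:
        raise ValueError(f"max_gap must be >= 1, got {max_gap}")
    calls = list(calls)
    adjacency: dict[str, list[str]] = {c.id: [] for c in calls}
    for a, b in zip(calls, calls[1:]):
        if a.chrom != b.chrom:
            continue
        between = index.genes_on(a.chrom)[a.core_hi + 1 : b.core_lo]
        n_separators = sum(
            1
            for g in between
            if statuses[g.symbol] is GeneStatus.ASSAYED_NOT_AMPLIFIED
        )
        if n_separators <= max_gap:
            adjacency[a.id].append(b.id)
            adjacency[b.id].append(a.id)
    return [replace(c, adjacent_to=tuple(adjacency[c.id])) for c in calls]


def infer(
    index: GenomeIndex,
    panel: Panel,
    query: AmplifiedQuery,
    *,
    max_gap: int = 1,
    skip_unknown: bool = False,
) -> list[AmpliconCall]:
    """Run the full pipeline: classify, build, extend, flag.

    Deterministic for fixed inputs; returns completed calls sorted by
    (chromosome, core start).
    """
    statuses = classify_genes(index, panel, query, skip_unknown=skip_unknown)
    calls = build_amplicons(index, statuses)
    calls = [extend_boundaries(c, index, statuses) for c in calls]
    calls = flag_adjacent(calls, index, statuses, max_gap=max_gap)
    logger.info(
        "inferred %d amplicon(s), %d flagged as closely co-located",
        len(calls),
        sum(1 for c in calls if c.adjacent_to),
    )
    return calls
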