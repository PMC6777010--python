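"""Synthetic genomes, panels and amplification profiles.

Real validation data for this problem would be matched pairs of sparse
panel reports and dense copy-number profiles, which are not bundled here.
Instead this module generates toy genomes with known ("true") amplicons,
derives the gene list a panel assay would report for them, and measures how
well inference recovers the truth.  It also builds the canonical 30-gene
walkthrough scenario used throughout the documentation and tests.

The simulator emulates a noiseless assay: every assayed gene inside a true
amplicon is reported amplified, every assayed gene outside is not.  It does
not model erroneous vendor calls — the algorithm is deterministic set
logic, and its behaviour under miscalls is flagged downstream (adjacency
flags), not simulated here.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .errors import SimulationError
from .genome import GeneRecord, GenomeIndex
from .inference import AmpliconCall, infer
from .panels import AmplifiedQuery, Panel, parse_amplified_list
from .reporting import CensusSet

__all__ = [
    "Figure1Fixture",
    "TruthProfile",
    "BoundaryErrorSummary",
    "figure1_fixture",
    "make_toy_genome",
    "simulate_profile",
    "boundary_error",
    "density_sweep",
]


# ---------------------------------------------------------------------------
# the 30-gene walkthrough scenario


@dataclass(frozen=True)
class Figure1Fixture:
    """The canonical toy scenario: one chromosome, 30 numbered genes.

    Genes g1..g30 sit on chromosome ``chrT``, gene gK spanning
    ``[K*1000, K*1000+500)``.  The assay evaluates {g4, g8, g13, g20, g27};
    the report calls {g8, g13, g20} amplified.  Inference must produce a
    single amplicon: core g8..g20, boundary genes g4 and g27, possibly
    amplified g5..g7 and g21..g26.

    The region holds 7 cancer-relevant (census) genes, five of them assayed.
    Which five are assayed is a fixture choice: here the census comprises
    all five panel genes plus two unassayed genes inside the inferred
    extent (g10 in the core, g23 in the boundary region).
    """

    index: GenomeIndex
    panel: Panel
    census: CensusSet
    query: AmplifiedQuery
    expected_call: AmpliconCall


def figure1_fixture() -> Figure1Fixture:
    index = GenomeIndex(
        GeneRecord(f"g{k}", "chrT", k * 1000, k * 1000 + 500)
        for k in range(1, 31)
    )
    panel = Panel(name="toy5", symbols=("g4", "g8", "g13", "g20", "g27"))
    census = CensusSet(
        symbols=("g4", "g8", "g10", "g13", "g20", "g23", "g27"), tiers={}
    )
    query = parse_amplified_list("g8,g13,g20")

    def g(k: int) -> GeneRecord:
        return index.lookup(f"g{k}")

    expected = AmpliconCall(
        id="amp1",
        chrom="chrT",
        reported_genes=(g(8), g(13), g(20)),
        core_genes=tuple(g(k) for k in range(8, 21)),
        left_boundary_gene=g(4),
        right_boundary_gene=g(27),
        boundary_genes_left=tuple(g(k) for k in range(5, 8)),
        boundary_genes_right=tuple(g(k) for k in range(21, 27)),
        adjacent_to=(),
        extended=True,
    )
    return Figure1Fixture(index, panel, census, query, expected)


# ---------------------------------------------------------------------------
# random toy genomes and truth profiles


def make_toy_genome(n_genes: int, n_chroms: int, seed: int) -> GenomeIndex:
    """A reproducible toy genome with non-overlapping, uniquely named genes.

    Genes g1..gN are distributed round-robin over chromosomes chr1..chrM;
    within a chromosome, intervals are laid left to right with random
    lengths and gaps drawn from ``random.Random(seed)``.
    """
    if not n_genes >= n_chroms >= 1:
        raise SimulationError(
            f"need n_genes >= n_chroms >= 1, got {n_genes}, {n_chroms}"
        )
    rng = random.Random(seed)
    cursors = {f"chr{c + 1}": 0 for c in range(n_chroms)}
    records = []
    for i in range(n_genes):
        chrom = f"chr{i % n_chroms + 1}"
        start = cursors[chrom] + rng.randrange(100, 5000)
        end = start + rng.randrange(200, 20000)
        cursors[chrom] = end
        records.append(GeneRecord(f"g{i + 1}", chrom, start, end))
    return GenomeIndex(records)


@dataclass(frozen=True)
class TruthProfile:
    """A simulated ground truth: genome, panel, true amplicons, report.

    ``true_amplicons`` maps chromosome to disjoint inclusive rank intervals.
    A gene is truly amplified iff its rank falls inside one of them (rank
    containment, the same convention inference reasons in).  ``reported``
    is exactly the assayed genes that are truly amplified — the query the
    vendor's report would print.
    """

    genome: GenomeIndex
    panel: Panel
    true_amplicons: dict[str, tuple[tuple[int, int], ...]]
    reported: tuple[str, ...]

    @property
    def query(self) -> AmplifiedQuery:
        return AmplifiedQuery(symbols=self.reported, raw_text=", ".join(self.reported))


def _place_disjoint_intervals(
    n_genes: int, k: int, rng: random.Random
) -> list[tuple[int, int]]:
    """Place k disjoint rank intervals on [0, n_genes), >=1 gene between them."""
    max_len = max(1, n_genes // (3 * k))
    lengths = [rng.randint(1, max_len) for _ in range(k)]
    required = sum(lengths) + (k - 1)
    if required > n_genes:
        raise SimulationError(
            f"cannot place {k} amplicons on a {n_genes}-gene chromosome"
        )
    slack = n_genes - required
    cuts = sorted(rng.randint(0, slack) for _ in range(k))
    gaps = [cuts[0]] + [cuts[i] - cuts[i - 1] for i in range(1, k)]
    intervals = []
    pos = 0
    for gap, length in zip(gaps, lengths):
        lo = pos + gap
        intervals.append((lo, lo + length - 1))
        pos = lo + length + 1  # +1 enforces a >=1 gene gap to the next
    return intervals


def simulate_profile(
    genome: GenomeIndex, panel_density: float, n_amplicons: int, seed: int
) -> TruthProfile:
    """Sample a panel and disjoint true amplicons; derive the reported genes.

    The panel contains a uniform sample (without replacement) of
    ``panel_density`` of all genes; amplicons are assigned to chromosomes
    with probability proportional to gene count and placed uniformly with
    at least one gene between consecutive amplicons.  Reproducible per
    seed.
    """
    if not 0 < panel_density <= 1:
        raise SimulationError(f"panel density must be in (0, 1], got {panel_density}")
    if n_amplicons < 0:
        raise SimulationError(f"n_amplicons must be >= 0, got {n_amplicons}")
    rng = random.Random(seed)

    all_genes = list(genome)
    n_panel = max(1, round(panel_density * len(all_genes)))
    panel_genes = sorted(
        rng.sample(all_genes, n_panel), key=lambda g: (g.chrom, g.rank)
    )
    panel = Panel(name="simulated", symbols=tuple(g.symbol for g in panel_genes))

    per_chrom: dict[str, int] = {}
    chroms = list(genome.chromosomes)
    weights = [genome.n_genes(c) for c in chroms]
    for _ in range(n_amplicons):
        per_chrom_choice = rng.choices(chroms, weights=weights)[0]
        per_chrom[per_chrom_choice] = per_chrom.get(per_chrom_choice, 0) + 1

    true_amplicons: dict[str, tuple[tuple[int, int], ...]] = {}
    for chrom, k in sorted(per_chrom.items()):
        true_amplicons[chrom] = tuple(
            _place_disjoint_intervals(genome.n_genes(chrom), k, rng)
        )

    assayed = {g.symbol for g in panel_genes}
    reported = []
    for chrom in genome.chromosomes:
        intervals = true_amplicons.get(chrom, ())
        for g in genome.genes_on(chrom):
            if g.symbol in assayed and any(lo <= g.rank <= hi for lo, hi in intervals):
                reported.append(g.symbol)
    return TruthProfile(
        genome=genome,
        panel=panel,
        true_amplicons=true_amplicons,
        reported=tuple(reported),
    )


# ---------------------------------------------------------------------------
# recovery metrics


@dataclass(frozen=True)
class BoundaryErrorSummary:
    """Per-side overshoot (in genes) of inferred extents beyond the truth.

    Overshoot on a side is how many gene ranks the possibly-amplified
    extent extends past the true amplicon; it is >= 0 whenever inference is
    sound.  ``n`` counts matched amplicons; an empty summary has n == 0 and
    ``None`` statistics.
    """

    n: int
    mean_left: float | None
    max_left: int | None
    mean_right: float | None
    max_right: int | None

    @property
    def mean_per_side(self) -> float | None:
        if self.n == 0:
            return None
        return (self.mean_left + self.mean_right) / 2

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean_left": self.mean_left,
            "max_left": self.max_left,
            "mean_right": self.mean_right,
            "max_right": self.max_right,
            "mean_per_side": self.mean_per_side,
        }


def boundary_error(
    truth: TruthProfile, calls: list[AmpliconCall]
) -> BoundaryErrorSummary:
    """Match calls to true amplicons and summarize boundary overshoot.

    Each call's reported genes must fall inside exactly one true amplicon,
    and each true amplicon containing at least one assayed gene must own
    exactly one call; any other configuration signals an inference bug and
    raises :class:`~ampinfer.errors.SimulationError`.  True amplicons
    containing no assayed gene are invisible to the assay and are excluded
    from the summary.
    """
    matched: dict[tuple[str, int, int], AmpliconCall] = {}
    for call in calls:
        containing = [
            (call.chrom, lo, hi)
            for lo, hi in truth.true_amplicons.get(call.chrom, ())
            if all(lo <= g.rank <= hi for g in call.reported_genes)
        ]
        if len(containing) != 1:
            raise SimulationError(
                f"call {call.id} matches {len(containing)} true amplicons; "
                "expected exactly 1"
            )
        key = containing[0]
        if key in matched:
            raise SimulationError(f"true amplicon {key} matched by multiple calls")
        matched[key] = call

    assayed = set(truth.panel.symbols)
    for chrom, intervals in truth.true_amplicons.items():
        genes = truth.genome.genes_on(chrom)
        for lo, hi in intervals:
            has_assayed = any(g.symbol in assayed for g in genes[lo : hi + 1])
            if has_assayed and (chrom, lo, hi) not in matched:
                raise SimulationError(
                    f"true amplicon {chrom}:[{lo},{hi}] contains assayed genes "
                    "but no call matched it"
                )

    lefts: list[int] = []
    rights: list[int] = []
    for (chrom, lo, hi), call in matched.items():
        extent = call.extent_genes
        left = lo - extent[0].rank
        right = extent[-1].rank - hi
        if left < 0 or right < 0:
            raise SimulationError(
                f"call {call.id} extent undershoots truth {chrom}:[{lo},{hi}]"
            )
        lefts.append(left)
        rights.append(right)

    if not lefts:
        return BoundaryErrorSummary(0, None, None, None, None)
    return BoundaryErrorSummary(
        n=len(lefts),
        mean_left=sum(lefts) / len(lefts),
        max_left=max(lefts),
        mean_right=sum(rights) / len(rights),
        max_right=max(rights),
    )


def truth_is_visible(truth: TruthProfile) -> bool:
    """True when the assay can resolve every true amplicon separately.

    Requires at least one assayed gene inside every true amplicon (so each
    is detected) and at least one assayed gene in every gap between
    consecutive true amplicons on a chromosome (so neighbours are not
    merged).  This is the precondition of the recovery guarantee: under it,
    inferred calls are in bijection with true amplicons.
    """
    assayed = {s.casefold() for s in truth.panel.symbols}
    for chrom, intervals in truth.true_amplicons.items():
        genes = truth.genome.genes_on(chrom)
        ordered = sorted(intervals)
        for lo, hi in ordered:
            if not any(g.symbol.casefold() in assayed for g in genes[lo : hi + 1]):
                return False
        for (_, ahi), (blo, _) in zip(ordered, ordered[1:]):
            if not any(g.symbol.casefold() in assayed for g in genes[ahi + 1 : blo]):
                return False
    return True


def density_sweep(
    densities: tuple[float, ...] = (0.1, 0.2, 0.5, 1.0),
    n_seeds: int = 100,
    n_genes: int = 500,
    n_chroms: int = 5,
    n_amplicons: int = 3,
    base_seed: int = 0,
) -> list[dict]:
    """Mean boundary overshoot as a function of panel density.

    For each density, ``n_seeds`` independent toy genomes and truth
    profiles are simulated, inference is run on the implied report, and the
    per-side overshoot is averaged over every matched amplicon.  Only
    *visible* profiles (see :func:`truth_is_visible`) are scored: when a
    truth amplicon or an inter-truth gap holds no assayed gene, the
    call/truth correspondence is ill-defined and the seed is skipped.
    Denser panels place an assayed non-amplified gene closer to each true
    edge, so overshoot should fall as density rises.
    """
    rows = []
    for density in densities:
        total = 0.0
        count = 0
        for s in range(n_seeds):
            seed = base_seed + s
            genome = make_toy_genome(n_genes, n_chroms, seed)
            truth = simulate_profile(genome, density, n_amplicons, seed + 10_000)
            if not truth.reported or not truth_is_visible(truth):
                continue
            calls = infer(genome, truth.panel, truth.query)
            summary = boundary_error(truth, calls)
            if summary.n:
                total += summary.mean_per_side * summary.n
                count += summary.n
        rows.append(
            {
                "density": density,
                "n_seeds": n_seeds,
                "n_amplicons_matched": count,
                "mean_overshoot_per_side": (total / count) if count else None,
            }
        )
    return rows
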