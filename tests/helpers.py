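"""Independent brute-force oracles and random-instance generators.

The oracles deliberately use a different strategy from the implementation:
amplicon grouping is decided by union-find over *every pair* of reported
genes (the implementation scans consecutive pairs), and separator counts
are direct enumerations.  They stay quadratic and dumb on purpose.
"""

from __future__ import annotations

import random

from ampinfer import (
    AmplifiedQuery,
    GeneStatus,
    GenomeIndex,
    Panel,
    make_toy_genome,
)


def oracle_group_reported(
    index: GenomeIndex, statuses
) -> list[tuple[str, tuple[str, ...]]]:
    """Group reported genes into amplicons by exhaustive pairwise union-find.

    Two reported genes are in the same amplicon iff no assayed-not-amplified
    gene lies strictly between them in rank.  Returns, per chromosome in
    index order, (chrom, symbols of one group) sorted by leftmost rank.
    """
    groups: list[tuple[str, tuple[str, ...]]] = []
    for chrom in index.chromosomes:
        genes = index.genes_on(chrom)
        reported = [g for g in genes if statuses[g.symbol] is GeneStatus.REPORTED_AMPLIFIED]
        if not reported:
            continue
        parent = list(range(len(reported)))

        def find(i: int) -> int:
            while parent[i] != i:
                i = parent[i]
            return i

        for i in range(len(reported)):
            for j in range(i + 1, len(reported)):
                lo, hi = reported[i].rank, reported[j].rank
                blocked = any(
                    statuses[g.symbol] is GeneStatus.ASSAYED_NOT_AMPLIFIED
                    for g in genes[lo + 1 : hi]
                )
                if not blocked:
                    parent[find(j)] = find(i)
        comps: dict[int, list] = {}
        for i, g in enumerate(reported):
            comps.setdefault(find(i), []).append(g)
        for comp in sorted(comps.values(), key=lambda c: c[0].rank):
            groups.append((chrom, tuple(g.symbol for g in comp)))
    return groups


def oracle_separator_count(index: GenomeIndex, statuses, chrom, hi_rank, lo_rank) -> int:
    """Assayed non-amplified genes with rank strictly in (hi_rank, lo_rank)."""
    return sum(
        1
        for g in index.genes_on(chrom)
        if hi_rank < g.rank < lo_rank
        and statuses[g.symbol] is GeneStatus.ASSAYED_NOT_AMPLIFIED
    )


def random_instance(seed: int):
    """A random toy genome with a random panel and random amplified subset.

    Unlike simulate_profile this draws arbitrary (not truth-consistent)
    amplification calls, exercising the grouping logic on adversarial
    status patterns.
    """
    rng = random.Random(seed)
    n_genes = rng.randint(20, 500)
    n_chroms = rng.randint(1, 5)
    index = make_toy_genome(n_genes, n_chroms, seed)
    genes = list(index)
    n_panel = rng.randint(1, max(1, n_genes // 2))
    panel_genes = rng.sample(genes, n_panel)
    panel = Panel(
        name=f"random{seed}",
        symbols=tuple(g.symbol for g in sorted(panel_genes, key=lambda g: g.symbol)),
    )
    p_amp = rng.uniform(0.05, 0.6)
    amplified = [g.symbol for g in panel_genes if rng.random() < p_amp]
    if not amplified:
        amplified = [rng.choice(panel_genes).symbol]
    query = AmplifiedQuery(symbols=tuple(amplified), raw_text=",".join(amplified))
    return index, panel, query
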