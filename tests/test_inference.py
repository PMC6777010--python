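"""The core algorithm: classification, consolidation, boundaries, flags."""

import pytest
from helpers import oracle_group_reported, oracle_separator_count, random_instance

from ampinfer import (
    AmplifiedQuery,
    GeneStatus,
    Panel,
    UnknownGeneError,
    build_amplicons,
    classify_genes,
    extend_boundaries,
    flag_adjacent,
    infer,
    make_toy_genome,
    parse_amplified_list,
    render,
    build_reports,
)


def _statuses(index, panel, query):
    return classify_genes(index, panel, query)


# -- classification -----------------------------------------------------


def test_classify_walkthrough_statuses(fig1):
    statuses = _statuses(fig1.index, fig1.panel, fig1.query)
    by_status = {}
    for sym, st in statuses.items():
        by_status.setdefault(st, set()).add(sym)
    assert by_status[GeneStatus.REPORTED_AMPLIFIED] == {"g8", "g13", "g20"}
    assert by_status[GeneStatus.ASSAYED_NOT_AMPLIFIED] == {"g4", "g27"}
    assert len(by_status[GeneStatus.NOT_ASSAYED]) == 25
    assert len(statuses) == 30  # statuses partition the index


def test_off_panel_query_gene_counts_as_assayed_amplified(fig1):
    # a gene absent from the panel but present in the genome was evidently
    # assayed by whatever produced the report
    query = parse_amplified_list("g8,g10")
    statuses = _statuses(fig1.index, fig1.panel, query)
    assert statuses["g10"] is GeneStatus.REPORTED_AMPLIFIED


def test_everything_amplified_leaves_no_negatives(fig1):
    query = AmplifiedQuery(fig1.panel.symbols, ",".join(fig1.panel.symbols))
    statuses = _statuses(fig1.index, fig1.panel, query)
    assert all(
        st is not GeneStatus.ASSAYED_NOT_AMPLIFIED for st in statuses.values()
    )


def test_unknown_query_gene_is_hard_error_unless_skipped(fig1):
    query = parse_amplified_list("g8,NOTAGENE")
    with pytest.raises(UnknownGeneError, match="NOTAGENE"):
        classify_genes(fig1.index, fig1.panel, query)
    statuses = classify_genes(fig1.index, fig1.panel, query, skip_unknown=True)
    assert statuses["g8"] is GeneStatus.REPORTED_AMPLIFIED


# -- consolidation ------------------------------------------------------


def test_walkthrough_consolidates_to_one_amplicon(fig1):
    statuses = _statuses(fig1.index, fig1.panel, fig1.query)
    calls = build_amplicons(fig1.index, statuses)
    assert len(calls) == 1
    assert [g.symbol for g in calls[0].reported_genes] == ["g8", "g13", "g20"]
    assert calls[0].core_genes[0].symbol == "g8"
    assert calls[0].core_genes[-1].symbol == "g20"


def test_chromosomes_never_merge():
    index = make_toy_genome(20, 2, 1)
    sym = lambda i: f"g{i}"  # noqa: E731
    panel = Panel("p", tuple(sym(i) for i in (1, 2, 5, 6)))
    query = parse_amplified_list(f"{sym(1)},{sym(2)}")  # g1 on chr1, g2 on chr2
    calls = build_amplicons(index, _statuses(index, panel, query))
    assert len(calls) == 2
    assert {c.chrom for c in calls} == {"chr1", "chr2"}


@pytest.mark.parametrize("seed", range(100))
def test_consolidation_matches_pairwise_oracle(seed):
    """Scan-based grouping equals exhaustive pairwise union-find."""
    index, panel, query = random_instance(seed)
    statuses = _statuses(index, panel, query)
    calls = build_amplicons(index, statuses)
    got = [(c.chrom, tuple(g.symbol for g in c.reported_genes)) for c in calls]
    assert got == oracle_group_reported(index, statuses)


def test_each_reported_gene_in_exactly_one_call(fig1):
    for seed in range(20):
        index, panel, query = random_instance(seed)
        statuses = _statuses(index, panel, query)
        calls = build_amplicons(index, statuses)
        reported = [
            g.symbol for g in index if statuses[g.symbol] is GeneStatus.REPORTED_AMPLIFIED
        ]
        claimed = [g.symbol for c in calls for g in c.reported_genes]
        assert sorted(claimed) == sorted(reported)
        # cores on one chromosome are disjoint and separated by >=1 negative
        by_chrom = {}
        for c in calls:
            by_chrom.setdefault(c.chrom, []).append(c)
        for chrom, chrom_calls in by_chrom.items():
            for a, b in zip(chrom_calls, chrom_calls[1:]):
                assert a.core_hi < b.core_lo
                assert (
                    oracle_separator_count(index, statuses, chrom, a.core_hi, b.core_lo)
                    >= 1
                )


# -- boundary extension -------------------------------------------------


def test_walkthrough_boundaries(fig1):
    statuses = _statuses(fig1.index, fig1.panel, fig1.query)
    (call,) = build_amplicons(fig1.index, statuses)
    call = extend_boundaries(call, fig1.index, statuses)
    assert call.left_boundary_gene.symbol == "g4"
    assert call.right_boundary_gene.symbol == "g27"
    assert [g.symbol for g in call.boundary_genes_left] == ["g5", "g6", "g7"]
    assert [g.symbol for g in call.boundary_genes_right] == [
        f"g{k}" for k in range(21, 27)
    ]
    assert not (set(call.core_genes) & set(call.boundary_genes))


def test_chromosome_end_side_is_unbounded():
    index = make_toy_genome(10, 1, 3)
    panel = Panel("p", ("g1", "g5"))
    query = parse_amplified_list("g1")
    (call,) = infer(index, panel, query)
    assert call.left_boundary_gene is None and call.left_unbounded
    assert call.boundary_genes_left == ()  # g1 is the first gene
    assert call.right_boundary_gene.symbol == "g5"


def test_possibly_amplified_region_extends_to_chromosome_end():
    index = make_toy_genome(10, 1, 3)
    panel = Panel("p", ("g5", "g8"))
    query = parse_amplified_list("g8")
    (call,) = infer(index, panel, query)
    assert call.right_unbounded
    assert [g.symbol for g in call.boundary_genes_right] == ["g9", "g10"]


def test_immediately_adjacent_boundary_gene_gives_empty_side(fig1):
    # g4 assayed and adjacent to reported g5: nothing lies strictly between
    panel = Panel("p", ("g4", "g27"))
    query = parse_amplified_list("g5")
    (call,) = infer(fig1.index, panel, query)
    assert call.left_boundary_gene.symbol == "g4"
    assert call.boundary_genes_left == ()


# -- adjacency flagging -------------------------------------------------


def test_shared_boundary_gene_flags_both_calls():
    index = make_toy_genome(30, 1, 5)
    panel = Panel("p", ("g5", "g10", "g15"))  # g10 separates g5 and g15
    query = parse_amplified_list("g5,g15")
    calls = infer(index, panel, query)
    assert len(calls) == 2
    assert calls[0].adjacent_to == (calls[1].id,)
    assert calls[1].adjacent_to == (calls[0].id,)


def test_different_chromosomes_never_flagged():
    index = make_toy_genome(20, 2, 5)
    panel = Panel("p", ("g1", "g2", "g3", "g4"))
    query = parse_amplified_list("g1,g2")
    calls = infer(index, panel, query)
    assert all(c.adjacent_to == () for c in calls)


def test_max_gap_zero_rejected(fig1):
    statuses = _statuses(fig1.index, fig1.panel, fig1.query)
    calls = build_amplicons(fig1.index, statuses)
    with pytest.raises(ValueError, match="max_gap"):
        flag_adjacent(calls, fig1.index, statuses, max_gap=0)


@pytest.mark.parametrize("max_gap", [1, 2, 3])
def test_flagging_matches_separator_enumeration(max_gap):
    for seed in range(30):
        index, panel, query = random_instance(seed)
        statuses = _statuses(index, panel, query)
        calls = infer(index, panel, query, max_gap=max_gap)
        by_chrom = {}
        for c in calls:
            by_chrom.setdefault(c.chrom, []).append(c)
        for chrom, chrom_calls in by_chrom.items():
            for a, b in zip(chrom_calls, chrom_calls[1:]):
                n_sep = oracle_separator_count(
                    index, statuses, chrom, a.core_hi, b.core_lo
                )
                flagged = b.id in a.adjacent_to
                assert flagged == (n_sep <= max_gap)
                assert (a.id in b.adjacent_to) == flagged  # symmetric


# -- end-to-end properties ----------------------------------------------


def test_walkthrough_end_to_end(fig1):
    calls = infer(fig1.index, fig1.panel, fig1.query)
    assert calls == [fig1.expected_call]


def test_panel_monotonicity():
    """Adding an assayed non-amplified gene never widens any extent."""
    for seed in range(30):
        index, panel, query = random_instance(seed)
        before = {
            g.symbol: c
            for c in infer(index, panel, query)
            for g in c.reported_genes
        }
        amplified = {s.casefold() for s in query.symbols}
        candidates = [
            g.symbol
            for g in index
            if g.symbol not in panel and g.symbol.casefold() not in amplified
        ]
        if not candidates:
            continue
        import random as _random

        extra = _random.Random(seed).choice(candidates)
        bigger = Panel(panel.name, panel.symbols + (extra,))
        after = {
            g.symbol: c
            for c in infer(index, bigger, query)
            for g in c.reported_genes
        }
        for sym, call_after in after.items():
            ranks_after = {g.rank for g in call_after.extent_genes}
            ranks_before = {g.rank for g in before[sym].extent_genes}
            assert ranks_after <= ranks_before


def test_inference_is_deterministic(fig1, census):
    runs = []
    for _ in range(2):
        calls = infer(fig1.index, fig1.panel, fig1.query)
        runs.append(render(build_reports(calls, census), "json", verbose=True,
                           assayed_genes=sorted(fig1.panel.symbols)))
    assert runs[0] == runs[1]
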