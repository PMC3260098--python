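"""Primer enumeration, scoring, pair selection and genome-wide batch design."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from knockkit import thermo
from knockkit.primer_design import (
    DATABASE_PRESET,
    PILOT_PRESET,
    DesignConstraints,
    NO_PAIR_WINDOW_TOO_SHORT,
    design_genome,
    enumerate_candidates,
    get_preset,
    pick_pair,
    score,
)
from knockkit.reports import primer_table

from _oracles import brute_force_pick, naive_enumerate, revcomp


def _random_window(n, seed, gc=0.52):
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def test_pure_at_window_has_no_candidates():
    assert enumerate_candidates("AT" * 25, "forward", DATABASE_PRESET) == []


def test_soft_masked_window_has_no_candidates():
    win = _random_window(60, seed=0).lower()
    assert enumerate_candidates(win, "forward", DATABASE_PRESET) == []
    assert enumerate_candidates(win, "reverse", DATABASE_PRESET) == []


def test_candidates_only_overlap_the_embedded_primable_region():
    """A window that is homopolymer except for one well-behaved 20-mer can
    only yield candidates overlapping that 20-mer."""
    insert = "GGTTCCCTACACTGCTGTAC"  # 55% GC, Tm ~54, clamp-safe both ways
    win = "A" * 200 + insert + "A" * 200
    for orientation in ("forward", "reverse"):
        cands = enumerate_candidates(win, orientation, DATABASE_PRESET)
        naive = naive_enumerate(win, orientation, DATABASE_PRESET)
        assert {(c.window_offset, len(c)) for c in cands} == {
            (i, L) for i, L, _, _ in naive
        }
        assert cands
        for c in cands:
            assert c.window_offset < 220 and c.substring_end > 200


@pytest.mark.parametrize("orientation", ["forward", "reverse"])
def test_enumeration_matches_brute_force(orientation):
    win = _random_window(400, seed=7)
    cands = enumerate_candidates(win, orientation, DATABASE_PRESET)
    naive = naive_enumerate(win, orientation, DATABASE_PRESET)
    assert {(c.window_offset, len(c)) for c in cands} == {
        (i, L) for i, L, _, _ in naive
    }
    by_pos = {(i, L): (tm, pen) for i, L, tm, pen in naive}
    for c in cands:
        tm, pen = by_pos[(c.window_offset, len(c))]
        assert c.tm == pytest.approx(tm, abs=1e-6)
        assert c.penalty == pytest.approx(pen, abs=1e-6)


def test_every_emitted_candidate_respects_hard_constraints():
    c = DATABASE_PRESET
    win = _random_window(800, seed=13)
    for orientation in ("forward", "reverse"):
        for cand in enumerate_candidates(win, orientation, c):
            assert c.primer_len_min <= len(cand) <= c.primer_len_max
            assert c.gc_min <= thermo.gc_content(cand.core_seq) <= c.gc_max
            assert c.tm_min <= thermo.melting_temperature(cand.core_seq) <= c.tm_max
            assert thermo.gc_clamp_run(cand.core_seq) <= c.gc_clamp_max_run
            assert thermo.self_complementarity(cand.core_seq) <= c.self_comp_max
            sub = win[cand.window_offset : cand.substring_end]
            expected = sub if orientation == "forward" else revcomp(sub)
            assert cand.core_seq == expected


@settings(max_examples=15, derandomize=True, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_candidate_constraints_hold_on_random_windows(seed):
    c = DATABASE_PRESET
    win = _random_window(150, seed=seed)
    for cand in enumerate_candidates(win, "forward", c):
        assert c.gc_min <= cand.gc <= c.gc_max
        assert c.tm_min <= cand.tm <= c.tm_max
        assert cand.clamp_run <= c.gc_clamp_max_run


def test_score_zero_iff_both_optima_met():
    win = _random_window(600, seed=21)
    cands = enumerate_candidates(win, "forward", DATABASE_PRESET)
    for cand in cands:
        expected = abs(cand.tm - 56.0) + abs(len(cand) - 20)
        assert score(cand, DATABASE_PRESET) == pytest.approx(expected)
        assert (cand.penalty == 0) == (cand.tm == 56.0 and len(cand) == 20)


def test_larger_tm_deviation_scores_strictly_worse():
    win = _random_window(600, seed=22)
    cands = [c for c in enumerate_candidates(win, "forward", DATABASE_PRESET)
             if len(c) == 20]
    cands.sort(key=lambda c: abs(c.tm - 56.0))
    assert len(cands) > 2
    assert cands[0].penalty < cands[-1].penalty


def test_pick_pair_equals_exhaustive_search_optimum():
    c = DATABASE_PRESET
    win = _random_window(1500, seed=31)
    pair, reason = pick_pair(win, c)
    assert reason is None
    expected, key = brute_force_pick(win, c)
    got = (
        pair.forward.window_offset,
        len(pair.forward),
        pair.reverse.window_offset,
        len(pair.reverse),
    )
    assert got == expected
    assert pair.penalty == pytest.approx(key[0], abs=1e-6)
    assert c.product_min <= pair.product_length <= c.product_max


def test_pick_pair_on_short_window_reports_failure_not_exception():
    win = _random_window(900, seed=41)
    pair, reason = pick_pair(win, DATABASE_PRESET)
    assert pair is None and reason == NO_PAIR_WINDOW_TOO_SHORT


def test_pick_pair_with_sparse_candidates_finds_the_constructed_pair():
    """Two primable islands ~1100 bp apart in a dead window: the chosen pair
    must bridge them and match the brute-force optimum."""
    fwd_site = "GGTTCCCTACACTGCTGTAC"
    rev_site_template = "TTCCCGATACCGGGTTAAAG"
    win = (
        "A" * 100 + fwd_site + "A" * (1100 - len(fwd_site)) + rev_site_template
        + "A" * 80
    )
    pair, reason = pick_pair(win, DATABASE_PRESET)
    assert reason is None
    expected, _ = brute_force_pick(win, DATABASE_PRESET)
    got = (
        pair.forward.window_offset,
        len(pair.forward),
        pair.reverse.window_offset,
        len(pair.reverse),
    )
    assert got == expected
    assert pair.forward.window_offset < 120
    assert pair.reverse.substring_end > 1100


def test_preset_lookup():
    assert get_preset("database") is DATABASE_PRESET
    assert get_preset("pilot") is PILOT_PRESET
    with pytest.raises(ValueError):
        get_preset("nope")
    assert PILOT_PRESET.primer_len_max == 20
    assert PILOT_PRESET.gc_min == pytest.approx(0.40)


def test_constraint_validation():
    with pytest.raises(ValueError):
        DesignConstraints(primer_len_min=21, primer_len_opt=20)
    with pytest.raises(ValueError):
        DesignConstraints(product_max=2000, flank_window=1500)


def test_design_gene_statuses(small_world, full_design, giant_design):
    assert full_design.status == "full"
    assert set(full_design.tailed_primers) == {"5F", "5R", "3F", "3R"}
    partials = [d for d in small_world["designs"] if d.status == "partial"]
    assert len(partials) == 2  # the two contig-edge genes
    for d in partials:
        assert d.flanks.truncated in ("5'", "3'", "both")
    assert giant_design.flanks.deleted_span == 2_200


def test_design_genome_summary_partitions_gene_set(small_world):
    s = small_world["summary"]
    assert s["n_full"] + s["n_partial"] + s["n_failed"] == s["n_genes"] == 20


def test_design_genome_empty_annotation(small_world):
    designs, summary = design_genome(small_world["genome"], [])
    assert designs == []
    assert summary == {"n_genes": 0, "n_full": 0, "n_partial": 0, "n_failed": 0}


def test_design_genome_deterministic(small_world):
    designs2, summary2 = design_genome(
        small_world["genome"],
        small_world["genes"],
        marker_system=small_world["marker"],
        screen=True,
    )
    assert summary2 == small_world["summary"]
    t1 = primer_table(small_world["designs"]).to_csv(sep="\t", index=False)
    t2 = primer_table(designs2).to_csv(sep="\t", index=False)
    assert t1 == t2
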