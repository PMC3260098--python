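"""Tail topology, gap-repair assembly, in-silico PCR and integration."""

import numpy as np
import pytest

from knockkit.assembly import (
    MultiMappingFlankError,
    assemble_cassette,
    attach_linkers,
    in_silico_pcr,
    simulate_gap_repair,
    simulate_integration,
    tailed_amplicon,
)
from knockkit.genome_io import GeneModel, Genome
from knockkit.markers import builtin_marker

from _oracles import revcomp


def _rand(n, seed, alphabet="ACGT"):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list(alphabet), size=n))


class TestAttachLinkers:
    def test_tails_follow_assembly_topology(self, full_design, small_world):
        mk = small_world["marker"]
        tp = full_design.tailed_primers
        assert all(len(t.tail) == 29 for t in tp.values())
        assert tp["5F"].tail == mk.vector_left_end[-29:]
        assert tp["5R"].tail == revcomp(mk.marker_seq[:29])
        assert tp["3F"].tail == mk.marker_seq[-29:]
        assert tp["3R"].tail == revcomp(mk.vector_right_end[:29])
        for t in tp.values():
            assert t.full_seq == t.tail + t.core

    def test_zero_linker_length_degenerates_to_core(self, full_design, small_world):
        tp = attach_linkers(
            full_design.pair_5prime,
            full_design.pair_3prime,
            small_world["marker"],
            linker_length=0,
        )
        for t in tp.values():
            assert t.full_seq == t.core

    def test_marker_shorter_than_linker_rejected(self, full_design, small_world):
        import dataclasses

        mk = small_world["marker"]
        with pytest.raises(ValueError):
            attach_linkers(
                full_design.pair_5prime, full_design.pair_3prime, mk,
                linker_length=len(mk.marker_seq) + 1,
            )


class TestGapRepair:
    def _fragments(self, seed=3):
        """Three fragments with designed exact 29-nt terminal overlaps."""
        a = _rand(300, seed)
        b = _rand(400, seed + 1)
        c = _rand(350, seed + 2)
        f1 = a
        f2 = a[-29:] + b
        f3 = b[-29:] + c
        return [f1, f2, f3]

    def test_linear_assembly_conserves_length(self):
        frags = self._fragments()
        res = simulate_gap_repair(frags)
        assert res.ok
        assert all(j.exact and j.overlap >= 29 for j in res.junction_report)
        assert len(res.cassette_seq) == sum(map(len, frags)) - 2 * 29

    def test_single_mismatch_at_overlap_center_fails_that_junction(self):
        frags = self._fragments()
        mut = list(frags[1])
        mut[14] = "A" if mut[14] != "A" else "C"  # center of the first overlap
        frags[1] = "".join(mut)
        res = simulate_gap_repair(frags)
        assert not res.ok
        assert res.failed_junction == (0, 1)

    def test_circular_assembly_with_vector(self):
        frags = self._fragments()
        vec = frags[-1][-29:] + _rand(500, 9) + frags[0][:29]
        res = simulate_gap_repair(frags, vector=vec)
        assert res.ok
        total = sum(map(len, frags)) + len(vec)
        assert len(res.plasmid_seq) == total - 4 * 29
        # cassette wraps the origin but is a substring of the circular plasmid
        assert res.cassette_seq in res.plasmid_seq + res.plasmid_seq

    def test_design_topology_assembles_in_order(self, full_design, small_world):
        res = assemble_cassette(full_design, small_world["marker"])
        mk = small_world["marker"]
        assert res.ok
        cassette = res.cassette_seq
        # order: 5' flank amplicon, marker, 3' flank amplicon
        assert cassette.startswith(full_design.tailed_primers["5F"].full_seq)
        assert mk.marker_seq in cassette
        assert cassette.endswith(revcomp(full_design.tailed_primers["3R"].full_seq))
        i5 = cassette.find(mk.marker_seq)
        amp5_len = full_design.pair_5prime.product_length + 2 * 29
        assert i5 == amp5_len - 29


class TestInSilicoPcr:
    def test_unique_exact_sites_give_one_product(self):
        t = _rand(3000, 17)
        fwd = t[500:520]
        rev = revcomp(t[1980:2000])
        (p,) = in_silico_pcr(t, fwd, rev)
        assert p.length == 1500
        assert p.seq == t[500:2000]

    def test_absent_reverse_primer_gives_no_product(self):
        t = _rand(3000, 18)
        fwd = t[100:120]
        rev = _rand(20, 99)
        assert in_silico_pcr(t, fwd, rev) == []

    def test_tails_dangle_and_appear_in_product(self):
        t = _rand(2000, 19)
        tail_f, tail_r = _rand(29, 20), _rand(29, 21)
        fwd = tail_f + t[300:320]
        rev = tail_r + revcomp(t[1300:1320])
        (p,) = in_silico_pcr(t, fwd, rev, max_dangle_5prime=29)
        assert p.length == 1020 + 58
        assert p.seq == tail_f + t[300:1320] + revcomp(tail_r)
        # without the declared dangle allowance the tail counts as mismatches
        assert in_silico_pcr(t, fwd, rev) == []

    def test_distal_mismatches_tolerated_up_to_limit(self):
        t = _rand(2000, 23)
        site = t[400:420]
        rev = revcomp(t[1400:1420])
        for n_mut, expect in ((2, 1), (3, 0)):
            fwd = list(site)
            for k in range(n_mut):  # mutate 5'-distal bases, keep 15-nt seed
                fwd[k] = "A" if fwd[k] != "A" else "C"
            prods = in_silico_pcr(t, "".join(fwd), rev)
            assert len(prods) == expect

    def test_seed_mismatch_abolishes_binding(self):
        t = _rand(2000, 29)
        fwd = list(t[400:420])
        fwd[-1] = "A" if fwd[-1] != "A" else "C"  # 3'-terminal mismatch
        rev = revcomp(t[1400:1420])
        assert in_silico_pcr(t, "".join(fwd), rev) == []

    def test_cassette_pcr_recovers_assembled_cassette(self, full_design, small_world):
        res = assemble_cassette(full_design, small_world["marker"])
        tp = full_design.tailed_primers
        prods = in_silico_pcr(
            res.plasmid_seq, tp["5F"].full_seq, tp["3R"].full_seq,
            max_product=8000, circular=True,
        )
        assert len(prods) == 1
        assert prods[0].seq == res.cassette_seq
        expected_len = (
            full_design.pair_5prime.product_length
            + full_design.pair_3prime.product_length
            + len(small_world["marker"].marker_seq)
            + 2 * 29
        )
        assert prods[0].length == expected_len


class TestIntegration:
    def test_length_conservation_and_substring_checks(self, full_design, small_world):
        genome, mk = small_world["genome"], small_world["marker"]
        mutant = simulate_integration(genome, full_design, mk)
        g = full_design.gene
        assert mutant.contig_length(g.contig) == (
            genome.contig_length(g.contig)
            - full_design.flanks.deleted_span
            + len(mk.marker_seq)
        )
        wt_orf = genome.fetch(g.contig, g.start, g.end)
        assert wt_orf in genome.fetch(g.contig, 0, genome.contig_length(g.contig))
        mut_contig = mutant.fetch(g.contig, 0, mutant.contig_length(g.contig))
        assert wt_orf not in mut_contig
        insert = mk.marker_seq if g.strand == "+" else revcomp(mk.marker_seq)
        assert insert in mut_contig
        # untouched contigs identical
        for name in genome.contig_names:
            if name != g.contig:
                n = genome.contig_length(name)
                assert genome.fetch(name, 0, n) == mutant.fetch(name, 0, n)

    def test_giant_orf_loses_exactly_first_2200_bp(self, giant_design, small_world):
        genome, mk = small_world["genome"], small_world["marker"]
        g = giant_design.gene
        mutant = simulate_integration(genome, giant_design, mk)
        fl = giant_design.flanks
        assert fl.deletion_end - fl.deletion_start == 2_200
        deleted_oriented = genome.fetch_oriented(
            g.contig, fl.deletion_start, fl.deletion_end, g.strand
        )
        orf = genome.fetch_oriented(g.contig, g.start, g.end, g.strand)
        assert deleted_oriented == orf[:2_200]
        mut_contig = mutant.fetch(g.contig, 0, mutant.contig_length(g.contig))
        deleted_genomic = genome.fetch(g.contig, fl.deletion_start, fl.deletion_end)
        assert deleted_genomic not in mut_contig
        # the rest of the giant ORF is retained, in place
        if g.strand == "+":
            retained = genome.fetch(g.contig, fl.deletion_end, g.end)
        else:
            retained = genome.fetch(g.contig, g.start, fl.deletion_start)
        assert retained in mut_contig

    def test_multi_mapping_flank_refused(self, full_design, small_world):
        genome = small_world["genome"]
        g = full_design.gene
        win = full_design.flanks.five_prime
        dup = Genome(
            dict(genome.items())
            | {"extra": genome.fetch(win.contig, win.gstart, win.gend)}
        )
        with pytest.raises(MultiMappingFlankError):
            simulate_integration(dup, full_design, small_world["marker"])


def test_round_trip_on_every_full_design(small_world):
    """design -> tails -> gap repair -> cassette PCR -> integration -> the
    junction screen is positive on the mutant and silent on wild type."""
    genome, mk = small_world["genome"], small_world["marker"]
    full = [d for d in small_world["designs"] if d.status == "full"]
    assert full
    for d in full:
        res = assemble_cassette(d, mk)
        assert res.ok, d.gene_id
        tp = d.tailed_primers
        prods = in_silico_pcr(
            res.plasmid_seq, tp["5F"].full_seq, tp["3R"].full_seq,
            max_product=8000, circular=True,
        )
        assert len(prods) == 1 and prods[0].seq == res.cassette_seq, d.gene_id
        mutant = simulate_integration(genome, d, mk)
        assay = d.screen
        assert assay is not None, d.gene_id
        hits = []
        for name in mutant.contig_names:
            n = mutant.contig_length(name)
            hits += in_silico_pcr(
                mutant.fetch(name, 0, n), assay.outside_primer, assay.marker_primer,
                max_product=3000,
            )
        assert [h.length for h in hits] == [assay.expected_mutant_product], d.gene_id
        for name in genome.contig_names:
            n = genome.contig_length(name)
            assert not in_silico_pcr(
                genome.fetch(name, 0, n), assay.outside_primer, assay.marker_primer,
                max_product=3000,
            ), d.gene_id
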