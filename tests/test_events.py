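import numpy as np
import pytest
import scipy.stats

import isousage as iu
from isousage.events import _subtract, _region_intervals


def tx(tid, exons, strand="+", cds=None, gene="G"):
    return iu.TranscriptModel(tid, gene, "chrT", strand, tuple(exons), cds)


def mirror(t, M=1_000_000):
    exons = tuple(sorted((M - e, M - s) for s, e in t.exons))
    cds = (M - t.cds[1], M - t.cds[0]) if t.cds else None
    strand = "-" if t.strand == "+" else "+"
    return iu.TranscriptModel(t.transcript_id, t.gene_id, t.chrom, strand, exons, cds)


def exonic_bases(t):
    return {b for s, e in t.exons for b in range(s, e)}


class TestCanonicalEvents:
    def test_exon_skipping(self):
        a = tx("A", [(0, 100), (200, 300), (400, 500)])
        b = tx("B", [(0, 100), (400, 500)])
        events = iu.call_splice_events(a, b)
        assert len(events) == 1
        ev = events[0]
        assert ev.type == "exon_skipping"
        assert ev.interval == (200, 300)
        assert ev.inclusion_isoform == "A"

    def test_intron_retention(self):
        a = tx("A", [(0, 100), (200, 300)])
        b = tx("B", [(0, 300)])
        events = iu.call_splice_events(a, b)
        assert [e.type for e in events] == ["intron_retention"]
        assert events[0].interval == (100, 200)
        assert events[0].inclusion_isoform == "B"

    def test_alt_donor_on_plus_strand(self):
        # introns (100,200) vs (120,200): shared end (acceptor), moving start (donor)
        a = tx("A", [(0, 100), (200, 300)])
        b = tx("B", [(0, 120), (200, 300)])
        events = iu.call_splice_events(a, b)
        assert [e.type for e in events] == ["alt_donor"]
        assert events[0].interval == (100, 120)
        assert events[0].inclusion_isoform == "B"  # shorter intron, more exon

    def test_same_structure_minus_strand_is_alt_acceptor(self):
        a = tx("A", [(0, 100), (200, 300)], strand="-")
        b = tx("B", [(0, 120), (200, 300)], strand="-")
        events = iu.call_splice_events(a, b)
        assert [e.type for e in events] == ["alt_acceptor"]

    def test_alt_first_and_last_exons(self):
        base = tx("A", [(1000, 1100), (1200, 1300), (1400, 1500)])
        alt_first = tx("B", [(500, 600), (1200, 1300), (1400, 1500)])
        events = iu.call_splice_events(base, alt_first)
        assert [e.type for e in events] == ["alt_first_exon"]
        alt_last = tx("C", [(1000, 1100), (1200, 1300), (1800, 1900)])
        events = iu.call_splice_events(base, alt_last)
        assert [e.type for e in events] == ["alt_last_exon"]
        # on '-' the genomic-left terminal exon is the transcription last one
        events = iu.call_splice_events(
            mirror(base), mirror(alt_first)
        )
        assert [e.type for e in events] == ["alt_first_exon"]

    def test_identical_transcripts_no_events(self):
        a = tx("A", [(0, 100), (200, 300)])
        b = tx("B", [(0, 100), (200, 300)])
        assert iu.call_splice_events(a, b) == []

    def test_different_strand_rejected(self):
        with pytest.raises(ValueError):
            iu.call_splice_events(
                tx("A", [(0, 100)]), tx("B", [(0, 100)], strand="-")
            )


@pytest.fixture(scope="module")
def random_pairs():
    cfg = iu.SimulationConfig(
        n_genes=250, isoform_count_distribution={2: 1.0}, seed=21
    )
    genes = iu.group_by_gene(iu.simulate_gene_models(cfg))
    return [tuple(txs) for txs in genes.values()]


class TestStrandCovariance:

    def test_strand_flip_swaps_donor_acceptor_and_terminals(self, random_pairs):
        """Flipping only the strand annotation reverses transcription
        direction: donor<->acceptor and first<->last exon events swap,
        skipping and retention are preserved."""
        swap = {
            "alt_donor": "alt_acceptor",
            "alt_acceptor": "alt_donor",
            "alt_first_exon": "alt_last_exon",
            "alt_last_exon": "alt_first_exon",
        }
        checked = 0
        for a, b in random_pairs:
            flip = "-" if a.strand == "+" else "+"
            fa = iu.TranscriptModel(
                a.transcript_id, a.gene_id, a.chrom, flip, a.exons, a.cds
            )
            fb = iu.TranscriptModel(
                b.transcript_id, b.gene_id, b.chrom, flip, b.exons, b.cds
            )
            orig = [e.type for e in iu.call_splice_events(a, b)]
            flipped = [e.type for e in iu.call_splice_events(fa, fb)]
            assert flipped == [swap.get(t, t) for t in orig]
            checked += len(orig)
        assert checked >= 200

    def test_mirror_and_flip_preserves_event_types(self, random_pairs):
        """Mirroring coordinates AND flipping strand preserves transcription
        direction, so every event type is preserved with mirrored intervals."""
        for a, b in random_pairs:
            orig = iu.call_splice_events(a, b)
            mirrored = iu.call_splice_events(mirror(a), mirror(b))
            assert sorted(e.type for e in orig) == sorted(
                e.type for e in mirrored
            )
            M = 1_000_000
            orig_ivs = sorted(e.interval for e in orig)
            mirr_ivs = sorted((M - e.interval[1], M - e.interval[0]) for e in mirrored)
            assert orig_ivs == mirr_ivs

    def test_symmetry_in_argument_order(self, random_pairs):
        for a, b in random_pairs[:100]:
            ab = iu.call_splice_events(a, b)
            ba = iu.call_splice_events(b, a)
            assert sorted((e.type, e.interval, e.inclusion_isoform) for e in ab) == (
                sorted((e.type, e.interval, e.inclusion_isoform) for e in ba)
            )
            assert iu.compare_pair(a, b) == iu.compare_pair(b, a)

    def test_symmetric_difference_covered_by_events(self, random_pairs):
        """Every differing exonic base lies inside a called event interval or
        a terminal exon-length difference; skip/retention intervals lie
        entirely inside the symmetric difference."""
        for a, b in random_pairs:
            diff = exonic_bases(a) ^ exonic_bases(b)
            events = iu.call_splice_events(a, b)
            covered = set()
            for e in events:
                covered |= set(range(*e.interval))
            # terminal length differences (shared terminal exons of unequal extent)
            span = (
                min(a.span[0], b.span[0]),
                max(a.span[1], b.span[1]),
            )
            inner = (
                max(a.span[0], b.span[0]),
                min(a.span[1], b.span[1]),
            )
            terminal = set(range(span[0], inner[0])) | set(
                range(inner[1], span[1])
            )
            assert diff <= covered | terminal
            for e in events:
                if e.type in ("exon_skipping", "intron_retention"):
                    assert set(range(*e.interval)) <= diff


class TestComparePair:
    def test_identical_transcripts_all_false(self):
        a = tx("A", [(0, 100), (200, 300)], cds=(50, 250))
        b = tx("B", [(0, 100), (200, 300)], cds=(50, 250))
        sd = iu.compare_pair(a, b)
        assert not (sd.differs_5utr or sd.differs_exons or sd.differs_3utr)
        assert sd.primary_category is None

    def test_extended_last_exon_is_pure_3utr(self):
        a = tx("A", [(0, 100), (200, 400)], cds=(50, 300))
        b = tx("B", [(0, 100), (200, 500)], cds=(50, 300))
        sd = iu.compare_pair(a, b)
        assert sd.differs_3utr and not sd.coding_change
        assert not sd.differs_exons and not sd.differs_5utr
        assert sd.primary_category == "alt_3utr"

    def test_skipped_exon_inside_cds(self):
        a = tx("A", [(0, 100), (200, 300), (400, 500)], cds=(50, 450))
        b = tx("B", [(0, 100), (400, 500)], cds=(50, 450))
        sd = iu.compare_pair(a, b)
        assert sd.differs_exons and sd.coding_change
        assert sd.primary_category == "alt_splicing"

    def test_alt_first_exon_in_utr_is_alt_promoter(self):
        a = tx("A", [(1000, 1100), (1200, 1300), (1400, 1500)], cds=(1250, 1450))
        b = tx("B", [(500, 600), (1200, 1300), (1400, 1500)], cds=(1250, 1450))
        sd = iu.compare_pair(a, b)
        assert sd.differs_5utr and not sd.coding_change
        assert sd.primary_category == "alt_promoter"

    def test_no_cds_flag(self):
        a = tx("A", [(0, 100), (200, 300)])
        b = tx("B", [(0, 300)])
        sd = iu.compare_pair(a, b)
        assert sd.no_cds and sd.primary_category == "alt_splicing"

    def test_flags_match_base_labeling_brute_force(self):
        """Region flags agree with literal per-base labeling over all exonic
        positions of both isoforms."""
        cfg = iu.SimulationConfig(
            n_genes=60, isoform_count_distribution={2: 1.0}, seed=22
        )
        genes = iu.group_by_gene(iu.simulate_gene_models(cfg))
        checked = 0
        for a, b in (tuple(t) for t in genes.values()):
            if a.cds is None or b.cds is None:
                continue
            sd = iu.compare_pair(a, b)
            expect_5 = expect_3 = expect_cds = False
            for x, y in ((a, b), (b, a)):
                regions = _region_intervals(x)
                labels = {}
                for name, ivs in regions.items():
                    for s, e in ivs:
                        for pos in range(s, e):
                            labels[pos] = name
                diff = exonic_bases(x) - exonic_bases(y)
                kinds = {labels[p] for p in diff}
                expect_5 |= "5utr" in kinds
                expect_3 |= "3utr" in kinds
                expect_cds |= "cds" in kinds
            assert sd.differs_5utr == expect_5
            assert sd.differs_3utr == expect_3
            assert sd.coding_change == expect_cds
            checked += 1
        assert checked >= 20


class TestSummaries:
    def test_all_skipping_pairs(self):
        a = tx("A", [(0, 100), (200, 300), (400, 500)])
        b = tx("B", [(0, 100), (400, 500)])
        pr = iu.IsoformPairResult("G", "A", "B", beta=1.0, F=9.0, p=0.001, q=0.01)
        pr.structural_diff = iu.compare_pair(a, b)
        events = {("A", "B"): iu.call_splice_events(a, b)}
        summary = iu.summarize_pairs([pr], events)
        assert summary.event_type_fractions["exon_skipping"] == 1.0
        assert sum(summary.category_fractions.values()) == pytest.approx(1.0)
        assert summary.inclusion_counts["exon_skipping"]["TN"] == 0
        assert summary.inclusion_counts["exon_skipping"]["ERpos"] == 1

    def test_category_fractions_partition(self, power_sim):
        cfg, models, matrix, annotations, truth, results = power_sim
        genes = {t.transcript_id: t for t in models}
        sig = [r for r in results if r.q is not None and r.q < 0.05][:200]
        events = {}
        for r in sig:
            r.structural_diff = iu.compare_pair(genes[r.iso_a], genes[r.iso_b])
            events[(r.iso_a, r.iso_b)] = iu.call_splice_events(
                genes[r.iso_a], genes[r.iso_b]
            )
        summary = iu.summarize_pairs(sig, events)
        assert summary.n_pairs == len(sig)
        assert sum(summary.category_fractions.values()) == pytest.approx(1.0)
        assert sum(summary.event_type_fractions.values()) <= 1.0 + 1e-9

    def test_symmetric_planting_balances_inclusion_counts(self, power_sim):
        """With switch directions drawn 50/50, inclusion counts must not
        differ between subtypes beyond binomial sampling error."""
        cfg, models, matrix, annotations, truth, results = power_sim
        genes = {t.transcript_id: t for t in models}
        sig = [r for r in results if r.q is not None and r.q < 0.05]
        events = {}
        for r in sig:
            r.structural_diff = iu.compare_pair(genes[r.iso_a], genes[r.iso_b])
            events[(r.iso_a, r.iso_b)] = iu.call_splice_events(
                genes[r.iso_a], genes[r.iso_b]
            )
        summary = iu.summarize_pairs(sig, events)
        counts = summary.inclusion_counts
        n_tn = counts["exon_skipping"]["TN"] + counts["intron_retention"]["TN"]
        n_er = counts["exon_skipping"]["ERpos"] + counts["intron_retention"]["ERpos"]
        total = n_tn + n_er
        assert total >= 20
        p = scipy.stats.binomtest(n_tn, total, 0.5).pvalue
        assert p > 0.05

    def test_events_to_bed(self):
        a = tx("A", [(0, 100), (200, 300), (400, 500)])
        b = tx("B", [(0, 100), (400, 500)])
        from isousage.events import events_to_bed

        events = iu.call_splice_events(a, b)
        track = events_to_bed([(events[0], "G")])
        assert track.intervals[0] == ("chrT", 200, 300, "exon_skipping:G")


class TestIntervalAlgebra:
    def test_subtract(self):
        assert _subtract([(0, 10)], [(3, 5)]) == [(0, 3), (5, 10)]
        assert _subtract([(0, 10)], [(0, 10)]) == []
        assert _subtract([(0, 5), (8, 12)], [(4, 9)]) == [(0, 4), (9, 12)]
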