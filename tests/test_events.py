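"""Unit tests for GTF reading, event detection, and catalog I/O."""

import pytest

from splicestrata.events import (
    EVENT_TYPES,
    AnnotationError,
    GtfParseError,
    SpliceEvent,
    TranscriptModel,
    detect_events,
    read_event_catalog,
    read_gtf,
    write_event_catalog,
)
from splicestrata.simulate import CohortSpec, generate_annotation

from conftest import gtf_line, make_tx


class TestTranscriptModel:
    def test_exons_sorted_on_construction(self):
        tx = make_tx("g", "t", [(301, 400), (101, 200)])
        assert tx.exons == ((101, 200), (301, 400))

    def test_rejects_inverted_interval(self):
        with pytest.raises(AnnotationError, match="start > end"):
            make_tx("g", "t", [(200, 100)])

    def test_rejects_overlapping_exons(self):
        with pytest.raises(AnnotationError, match="overlapping"):
            make_tx("g", "t", [(1, 100), (50, 200)])

    def test_tx_exons_minus_strand_reverses_order(self):
        tx = make_tx("g", "t", [(1, 100), (201, 300)], strand="-")
        assert tx.tx_exons == ((-300, -201), (-100, -1))


class TestReadGtf:
    def test_basic_two_exon_transcript(self, gtf_file):
        path = gtf_file(
            [
                gtf_line("chr1", 101, 200, "+", "g1", "t1"),
                gtf_line("chr1", 301, 400, "+", "g1", "t1"),
            ]
        )
        models = read_gtf(path)
        assert len(models) == 1
        assert models[0].exons == ((101, 200), (301, 400))
        assert models[0].gene_id == "g1"
        assert models[0].strand == "+"

    def test_out_of_order_exons_sorted(self, gtf_file):
        shuffled = gtf_file(
            [
                gtf_line("chr1", 301, 400, "+", "g1", "t1"),
                gtf_line("chr1", 101, 200, "+", "g1", "t1"),
            ]
        )
        models = read_gtf(shuffled)
        assert models[0].exons == ((101, 200), (301, 400))

    def test_missing_transcript_id_is_parse_error(self, gtf_file):
        bad = "\t".join(
            ("chr1", "src", "exon", "1", "100", ".", "+", ".", 'gene_id "g1";')
        )
        path = gtf_file([bad])
        with pytest.raises(GtfParseError, match=":1:"):
            read_gtf(path)

    def test_wrong_field_count_names_line(self, gtf_file):
        path = gtf_file(
            [gtf_line("chr1", 1, 100, "+", "g1", "t1"), "chr1\tbroken"]
        )
        with pytest.raises(GtfParseError, match=":2:"):
            read_gtf(path)

    def test_inconsistent_strand_is_validation_error(self, gtf_file):
        path = gtf_file(
            [
                gtf_line("chr1", 1, 100, "+", "g1", "t1"),
                gtf_line("chr1", 201, 300, "-", "g1", "t1"),
            ]
        )
        with pytest.raises(AnnotationError, match="t1"):
            read_gtf(path)

    def test_non_exon_features_ignored(self, gtf_file):
        path = gtf_file(
            [
                gtf_line("chr1", 1, 500, "+", "g1", "t1", feature="transcript"),
                gtf_line("chr1", 1, 100, "+", "g1", "t1"),
            ]
        )
        assert len(read_gtf(path)[0].exons) == 1


class TestDetectEvents:
    def test_se_definition_case(self, se_gene):
        events = detect_events(se_gene)
        assert len(events) == 1
        ev = events[0]
        assert ev.event_type == "SE"
        assert ev.inclusion_transcripts == {"t1"}
        assert ev.total_transcripts == {"t1", "t2"}

    def test_single_isoform_gene_yields_nothing(self):
        txs = [make_tx("g", "t1", [(1, 100), (201, 300)])]
        assert detect_events(txs) == []

    def test_all_seven_types_on_engineered_annotation(self):
        txs, _ = generate_annotation(CohortSpec(events_per_type=1, n_genes=10))
        events = detect_events(txs)
        assert len(events) == 7
        assert sorted(e.event_type for e in events) == sorted(EVENT_TYPES)

    def test_minus_strand_a5_not_misread_as_a3(self):
        # Same genomic coordinates as a plus-strand A3 gene, but on the
        # minus strand the alternative acceptor side becomes the donor
        # side, so the event is an A5. Oracle: re-running detection on the
        # coordinate-flipped plus-strand annotation gives the A3 label.
        exons = {
            "t1": [(1, 100), (301, 400)],
            "t2": [(1, 100), (251, 400)],
        }
        minus = [make_tx("g", t, e, strand="-") for t, e in exons.items()]
        events = detect_events(minus)
        assert len(events) == 1
        assert events[0].event_type == "A5"
        as_plus = [make_tx("g", t, e, strand="+") for t, e in exons.items()]
        assert detect_events(as_plus)[0].event_type == "A3"

    def test_strand_flip_swaps_a5_a3_af_al(self):
        # Re-labelling every transcript's strand (same coordinates) reverses
        # transcription order: A5<->A3 and AF<->AL swap while SE/MX/RI
        # counts are preserved.
        txs, _ = generate_annotation(CohortSpec(events_per_type=2, n_genes=20))
        flipped = [
            make_tx(
                t.gene_id, t.transcript_id, t.exons,
                strand="-" if t.strand == "+" else "+",
                chrom=t.chrom,
            )
            for t in txs
        ]
        orig = {t: 0 for t in EVENT_TYPES}
        flip = {t: 0 for t in EVENT_TYPES}
        for ev in detect_events(txs):
            orig[ev.event_type] += 1
        for ev in detect_events(flipped):
            flip[ev.event_type] += 1
        swap = {"A5": "A3", "A3": "A5", "AF": "AL", "AL": "AF"}
        for etype in EVENT_TYPES:
            assert flip[swap.get(etype, etype)] == orig[etype]

    def test_mirror_and_flip_preserves_event_types(self):
        # Mirroring coordinates AND flipping strand leaves the
        # transcription-order structure intact: every event keeps its type.
        txs, _ = generate_annotation(CohortSpec(events_per_type=1, n_genes=10))
        span = max(e for t in txs for _, e in t.exons) + 1
        mirrored = [
            make_tx(
                t.gene_id, t.transcript_id,
                [(span - e, span - s) for s, e in t.exons],
                strand="-" if t.strand == "+" else "+",
                chrom=t.chrom,
            )
            for t in txs
        ]
        orig = sorted((e.gene_id, e.event_type) for e in detect_events(txs))
        mirr = sorted((e.gene_id, e.event_type) for e in detect_events(mirrored))
        assert orig == mirr

    def test_deterministic_sorted_output(self):
        txs, _ = generate_annotation(CohortSpec(events_per_type=3, n_genes=30))
        e1 = detect_events(txs)
        e2 = detect_events(list(reversed(txs)))
        assert [x.event_id for x in e1] == [x.event_id for x in e2]
        keys = [(e.gene_id, e.event_type, e.defining_coords) for e in e1]
        assert keys == sorted(keys)

    def test_mixed_strand_gene_rejected(self):
        txs = [
            make_tx("g", "t1", [(1, 100), (201, 300)]),
            make_tx("g", "t2", [(1, 100)], strand="-"),
        ]
        with pytest.raises(AnnotationError, match="strand"):
            detect_events(txs)

    def test_compatible_third_transcript_pooled(self, se_gene):
        # a third isoform sharing the skip junction joins the exclusion set
        extra = make_tx("g1", "t3", [(51, 100), (401, 450)])
        events = detect_events(se_gene + [extra])
        se = [e for e in events if e.event_type == "SE"][0]
        assert se.inclusion_transcripts == {"t1"}
        assert "t3" in se.total_transcripts


class TestSpliceEventInvariants:
    def test_inclusion_must_be_proper_subset(self):
        with pytest.raises(ValueError, match="proper subset"):
            SpliceEvent(
                event_id="x", gene_id="g", event_type="SE",
                inclusion_transcripts=frozenset({"a"}),
                total_transcripts=frozenset({"a"}),
                defining_coords=(1,),
            )

    def test_unknown_type_rejected(self):
        with pytest.raises(ValueError, match="unknown event type"):
            SpliceEvent(
                event_id="x", gene_id="g", event_type="XX",
                inclusion_transcripts=frozenset({"a"}),
                total_transcripts=frozenset({"a", "b"}),
                defining_coords=(1,),
            )


class TestCatalogIO:
    def test_round_trip_identity(self, tmp_path):
        txs, truth = generate_annotation(CohortSpec(events_per_type=2, n_genes=20))
        path = tmp_path / "catalog.tsv"
        write_event_catalog(truth, path)
        back = read_event_catalog(path)
        assert [(e.event_id, e.event_type, e.inclusion_transcripts,
                 e.total_transcripts) for e in back] == [
            (e.event_id, e.event_type, e.inclusion_transcripts,
             e.total_transcripts) for e in truth
        ]

    def test_empty_catalog_is_header_only(self, tmp_path):
        path = tmp_path / "empty.tsv"
        write_event_catalog([], path)
        assert path.read_text().count("\n") == 1
        assert read_event_catalog(path) == []

    def test_unknown_type_token_is_parse_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "event_id\tgene_id\tevent_type\tinclusion_transcripts\t"
            "total_transcripts\n"
            "g;XX:chr1:1:+\tg\tXX\ta\ta,b\n"
        )
        with pytest.raises(ValueError, match="XX"):
            read_event_catalog(path)
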