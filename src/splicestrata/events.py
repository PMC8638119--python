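"""Local alternative-splicing event detection from transcript annotations.

Transcript exon structures are compared pairwise within each gene to find
the seven local event patterns: skipped exon (SE), mutually exclusive exons
(MX), alternative 5'/3' splice site (A5/A3), retained intron (RI), and
alternative first/last exon (AF/AL).

All detection happens in *transcription-order* coordinates: minus-strand
transcripts are handled by negating genomic positions, so a single set of
plus-strand rules applies to both strands and strand symmetry (A5<->A3,
AF<->AL under coordinate mirroring) holds by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

EVENT_TYPES = ("SE", "MX", "A5", "A3", "RI", "AF", "AL")


class GtfParseError(ValueError):
    """Raised for malformed GTF content; carries the offending line number."""


class AnnotationError(ValueError):
    """Raised for annotations violating transcript-model invariants."""


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript as an ordered set of exon intervals on one strand.

    Coordinates are 1-based inclusive (GTF convention). Exons are sorted by
    start and must be pairwise non-overlapping.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(
                f"transcript {self.transcript_id}: strand must be '+' or '-', "
                f"got {self.strand!r}"
            )
        if not self.exons:
            raise AnnotationError(f"transcript {self.transcript_id}: no exons")
        exons = tuple(sorted(self.exons))
        for start, end in exons:
            if start > end:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: exon ({start}, {end}) "
                    "has start > end"
                )
        for (_, e1), (s2, _) in zip(exons, exons[1:]):
            if s2 <= e1:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: overlapping exons"
                )
        object.__setattr__(self, "exons", exons)

    @property
    def tx_exons(self) -> tuple[tuple[int, int], ...]:
        """Exons in transcription order in signed coordinates.

        On '+' identical to genomic coordinates; on '-' every position x is
        mapped to -x so that transcription still runs left-to-right and exon
        tuples keep (lower, higher) orientation.
        """
        if self.strand == "+":
            return self.exons
        return tuple((-e, -s) for s, e in reversed(self.exons))


@dataclass(frozen=True)
class SpliceEvent:
    """One local splicing event: two alternative forms within a gene."""

    event_id: str
    gene_id: str
    event_type: str
    inclusion_transcripts: frozenset[str]
    total_transcripts: frozenset[str]
    defining_coords: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")
        inc = frozenset(self.inclusion_transcripts)
        tot = frozenset(self.total_transcripts)
        if not inc or not (inc < tot):
            raise ValueError(
                f"event {self.event_id}: inclusion transcripts must be a "
                "non-empty proper subset of total transcripts"
            )
        object.__setattr__(self, "inclusion_transcripts", inc)
        object.__setattr__(self, "total_transcripts", tot)

    @property
    def exclusion_transcripts(self) -> frozenset[str]:
        return self.total_transcripts - self.inclusion_transcripts


def _parse_attributes(attr_field: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in attr_field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Read exon features from a GTF file into transcript models.

    Only ``exon`` features are consulted; gene_id and transcript_id
    attributes are required on each. Raises :class:`GtfParseError` with the
    line number for malformed lines and :class:`AnnotationError` for
    transcripts mixing chromosomes or strands.
    """
    path = Path(path)
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tid -> (gene, chrom, strand)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{path}:{lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr = fields
            if feature != "exon":
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise GtfParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            attrs = _parse_attributes(attr)
            if "transcript_id" not in attrs or "gene_id" not in attrs:
                raise GtfParseError(
                    f"{path}:{lineno}: exon lacks gene_id/transcript_id"
                )
            tid = attrs["transcript_id"]
            record = (attrs["gene_id"], chrom, strand)
            if tid in meta and meta[tid] != record:
                raise AnnotationError(
                    f"transcript {tid}: inconsistent gene/chrom/strand "
                    f"across exon records"
                )
            meta.setdefault(tid, record)
            exons.setdefault(tid, []).append((start, end))
    models = [
        TranscriptModel(
            gene_id=meta[tid][0],
            transcript_id=tid,
            chrom=meta[tid][1],
            strand=meta[tid][2],
            exons=tuple(exs),
        )
        for tid, exs in exons.items()
    ]
    models.sort(key=lambda t: (t.gene_id, t.transcript_id))
    return models


# ---------------------------------------------------------------------------
# Event detection.
#
# Within each gene, transcripts are converted to transcription-order signed
# coordinates (tx space). In tx space every junction is a (donor, acceptor)
# pair with donor = end of the upstream exon and acceptor = start of the
# downstream exon, regardless of strand. Candidate events are generated from
# all transcript pairs, deduplicated by coordinate signature, and finally
# every transcript of the gene compatible with either form is pooled into
# the form sets.
# ---------------------------------------------------------------------------


@dataclass
class _Candidate:
    """An event pattern in tx space, before transcript pooling."""

    event_type: str
    # tx-space coordinates identifying the event, type-specific layout.
    key: tuple[int, ...]
    chrom: str
    strand: str
    gene_id: str
    # Predicates deciding form membership are stored as the tx-space data
    # needed by the per-type matchers below.
    inc_data: tuple = ()
    exc_data: tuple = ()


def _junctions(tx_exons: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    return [
        (tx_exons[i][1], tx_exons[i + 1][0]) for i in range(len(tx_exons) - 1)
    ]


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def _pair_candidates(
    ta: TranscriptModel, tb: TranscriptModel
) -> Iterable[_Candidate]:
    """Yield all local event patterns supported by transcript pair (ta, tb)."""
    xa, xb = ta.tx_exons, tb.tx_exons
    ja, jb = _junctions(xa), _junctions(xb)
    sja, sjb = set(ja), set(jb)
    common = dict(
        chrom=ta.chrom, strand=ta.strand, gene_id=ta.gene_id
    )

    # SE: A has junctions (d1,a1),(d2,a2) over a middle exon, B skips with
    # junction (d1,a2).
    for (a_exons, a_j, b_j) in ((xa, ja, sjb), (xb, jb, sja)):
        for i in range(len(a_j) - 1):
            d1, m_start = a_j[i]
            m_end, a2 = a_j[i + 1]
            if (d1, a2) in b_j:
                yield _Candidate(
                    "SE",
                    key=(d1, m_start, m_end, a2),
                    inc_data=((d1, m_start), (m_end, a2)),
                    exc_data=((d1, a2),),
                    **common,
                )

    # MX: A path d->M1->a, B path d->M2->a with disjoint middle exons.
    for i in range(len(ja) - 1):
        d, m1s = ja[i]
        m1e, acc = ja[i + 1]
        for k in range(len(jb) - 1):
            d2, m2s = jb[k]
            m2e, acc2 = jb[k + 1]
            if d != d2 or acc != acc2:
                continue
            if (m1s, m1e) == (m2s, m2e):
                continue
            if _overlap((m1s, m1e), (m2s, m2e)):
                continue
            # each middle exon must be exclusive to its transcript pair side
            first, second = sorted([(m1s, m1e), (m2s, m2e)])
            yield _Candidate(
                "MX",
                key=(d, *first, *second, acc),
                inc_data=((d, first[0]), (first[1], acc)),
                exc_data=((d, second[0]), (second[1], acc)),
                **common,
            )

    # A5 / A3 / AF / AL: junctions sharing one site, differing at the other.
    for ia, (da, aa) in enumerate(ja):
        for ib, (db, ab) in enumerate(jb):
            if aa == ab and da != db:
                # shared acceptor, alternative donors: exon ends differ.
                up_a, up_b = xa[ia], xb[ib]
                if _overlap(up_a, up_b):
                    # A5: inclusion = longer upstream exon (larger donor).
                    d_long, d_short = max(da, db), min(da, db)
                    yield _Candidate(
                        "A5",
                        key=(d_short, d_long, aa),
                        inc_data=((d_long, aa),),
                        exc_data=((d_short, aa),),
                        **common,
                    )
                elif ia == 0 and ib == 0:
                    # AF: distinct non-overlapping first exons to a common
                    # acceptor; inclusion = 5'-most first exon.
                    f1, f2 = sorted([up_a, up_b])
                    yield _Candidate(
                        "AF",
                        key=(*f1, *f2, aa),
                        inc_data=(f1, (f1[1], aa)),
                        exc_data=(f2, (f2[1], aa)),
                        **common,
                    )
            if da == db and aa != ab:
                down_a, down_b = xa[ia + 1], xb[ib + 1]
                if _overlap(down_a, down_b):
                    # A3: inclusion = longer downstream exon (smaller acceptor).
                    a_long, a_short = min(aa, ab), max(aa, ab)
                    yield _Candidate(
                        "A3",
                        key=(da, a_long, a_short),
                        inc_data=((da, a_long),),
                        exc_data=((da, a_short),),
                        **common,
                    )
                elif ia == len(ja) - 1 and ib == len(jb) - 1:
                    # AL: distinct non-overlapping last exons from a common
                    # donor; inclusion = 3'-most last exon (mirror of AF).
                    l1, l2 = sorted([down_a, down_b])
                    yield _Candidate(
                        "AL",
                        key=(da, *l1, *l2),
                        inc_data=((da, l2[0]), l2),
                        exc_data=((da, l1[0]), l1),
                        **common,
                    )

    # RI: one transcript has a single exon exactly spanning two consecutive
    # exons (and the intervening intron) of the other.
    for (spliced, retained) in ((xa, xb), (xb, xa)):
        sj = _junctions(spliced)
        retained_exons = set(retained)
        for i, (d, a) in enumerate(sj):
            s1, e1 = spliced[i]
            s2, e2 = spliced[i + 1]
            if (s1, e2) in retained_exons:
                yield _Candidate(
                    "RI",
                    key=(s1, e1, s2, e2),
                    inc_data=((s1, e2),),
                    exc_data=((e1, s2), s1, e2),
                    **common,
                )


def _matches_form(
    tx: TranscriptModel, event_type: str, data: tuple
) -> bool:
    """Does transcript tx contain the tx-space features defining one form?"""
    exons = tx.tx_exons
    juncs = set(_junctions(exons))
    exon_set = set(exons)
    if event_type in ("SE", "MX", "A5", "A3"):
        return all(j in juncs for j in data)
    if event_type == "AF":
        first_exon, junc = data
        return exons[0] == first_exon and junc in juncs
    if event_type == "AL":
        junc, last_exon = data
        return exons[-1] == last_exon and junc in juncs
    if event_type == "RI":
        if len(data) == 1:  # inclusion: the retained exon itself
            return data[0] in exon_set
        junc, s1, e2 = data
        if junc not in juncs:
            return False
        # flanking exon boundaries must match the event exactly
        i = _junctions(exons).index(junc)
        return exons[i][0] == s1 and exons[i + 1][1] == e2
    raise ValueError(event_type)


def _genomic_coords(key: tuple[int, ...], strand: str) -> tuple[int, ...]:
    """Map tx-space signature coordinates back to sorted genomic positions."""
    if strand == "+":
        return tuple(sorted(key))
    return tuple(sorted(-c for c in key))


def make_event_id(
    gene_id: str, event_type: str, chrom: str, coords: Sequence[int], strand: str
) -> str:
    sig = "-".join(str(c) for c in coords)
    return f"{gene_id};{event_type}:{chrom}:{sig}:{strand}"


def detect_events(transcripts: Iterable[TranscriptModel]) -> list[SpliceEvent]:
    """Detect and classify all pairwise-supported local splicing events.

    Events are deduplicated by coordinate signature; every transcript of the
    gene compatible with either form is pooled into that form's set. Output
    is sorted by (gene_id, event_type, defining_coords) and deterministic.
    """
    by_gene: dict[str, list[TranscriptModel]] = {}
    for tx in transcripts:
        by_gene.setdefault(tx.gene_id, []).append(tx)

    events: list[SpliceEvent] = []
    for gene_id in sorted(by_gene):
        txs = sorted(by_gene[gene_id], key=lambda t: t.transcript_id)
        if len(txs) < 2:
            continue
        chroms = {t.chrom for t in txs}
        strands = {t.strand for t in txs}
        if len(chroms) > 1 or len(strands) > 1:
            raise AnnotationError(
                f"gene {gene_id}: transcripts span multiple chromosomes or "
                "strands"
            )
        seen: dict[tuple[str, tuple[int, ...]], _Candidate] = {}
        for i in range(len(txs)):
            for j in range(i + 1, len(txs)):
                for cand in _pair_candidates(txs[i], txs[j]):
                    seen.setdefault((cand.event_type, cand.key), cand)
        for (etype, _key), cand in seen.items():
            inc = frozenset(
                t.transcript_id
                for t in txs
                if _matches_form(t, etype, cand.inc_data)
            )
            exc = frozenset(
                t.transcript_id
                for t in txs
                if _matches_form(t, etype, cand.exc_data)
            )
            exc -= inc  # a transcript cannot support both forms
            if not inc or not exc:
                continue
            coords = _genomic_coords(cand.key, cand.strand)
            events.append(
                SpliceEvent(
                    event_id=make_event_id(
                        gene_id, etype, cand.chrom, coords, cand.strand
                    ),
                    gene_id=gene_id,
                    event_type=etype,
                    inclusion_transcripts=inc,
                    total_transcripts=inc | exc,
                    defining_coords=coords,
                )
            )
    events.sort(key=lambda e: (e.gene_id, e.event_type, e.defining_coords))
    return events


# ---------------------------------------------------------------------------
# Catalog I/O: ioe-style TSV with comma-joined transcript sets.
# ---------------------------------------------------------------------------

_CATALOG_COLUMNS = (
    "event_id",
    "gene_id",
    "event_type",
    "inclusion_transcripts",
    "total_transcripts",
)


def write_event_catalog(events: Iterable[SpliceEvent], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(_CATALOG_COLUMNS) + "\n")
        for ev in events:
            fh.write(
                "\t".join(
                    (
                        ev.event_id,
                        ev.gene_id,
                        ev.event_type,
                        ",".join(sorted(ev.inclusion_transcripts)),
                        ",".join(sorted(ev.total_transcripts)),
                    )
                )
                + "\n"
            )


def _coords_from_event_id(event_id: str) -> tuple[int, ...]:
    try:
        _, rest = event_id.split(";", 1)
        parts = rest.split(":")
        return tuple(int(c) for c in parts[2].split("-"))
    except (ValueError, IndexError):
        return ()


def read_event_catalog(path: str | Path) -> list[SpliceEvent]:
    path = Path(path)
    events: list[SpliceEvent] = []
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _CATALOG_COLUMNS:
            raise ValueError(f"{path}: unexpected catalog header {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(_CATALOG_COLUMNS):
                raise ValueError(f"{path}:{lineno}: wrong field count")
            event_id, gene_id, etype, inc_s, tot_s = fields
            if etype not in EVENT_TYPES:
                raise ValueError(
                    f"{path}:{lineno}: unknown event_type {etype!r}"
                )
            events.append(
                SpliceEvent(
                    event_id=event_id,
                    gene_id=gene_id,
                    event_type=etype,
                    inclusion_transcripts=frozenset(inc_s.split(",")),
                    total_transcripts=frozenset(tot_s.split(",")),
                    defining_coords=_coords_from_event_id(event_id),
                )
            )
    return events
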