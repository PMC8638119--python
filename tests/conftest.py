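import numpy as np
import pandas as pd
import pytest

from splicestrata.events import TranscriptModel, detect_events
from splicestrata.simulate import CohortSpec, generate_annotation, generate_cohort


def make_tx(gene, tid, exons, strand="+", chrom="chr1"):
    return TranscriptModel(
        gene_id=gene, transcript_id=tid, chrom=chrom, strand=strand,
        exons=tuple(exons),
    )


@pytest.fixture
def se_gene():
    """Three-exon isoform plus the exon-skipping isoform."""
    return [
        make_tx("g1", "t1", [(1, 100), (201, 300), (401, 500)]),
        make_tx("g1", "t2", [(1, 100), (401, 500)]),
    ]


@pytest.fixture
def default_spec():
    return CohortSpec(seed=11)


@pytest.fixture
def small_cohort():
    """One planted event per type, 40 samples: fast full-pipeline substrate."""
    spec = CohortSpec(
        n_samples=40, n_genes=30, events_per_type=1, seed=5,
        shifted_fraction=1.0,
    )
    txs, truth = generate_annotation(spec)
    cohort = generate_cohort(spec, txs, truth)
    return spec, txs, truth, cohort


@pytest.fixture
def gtf_file(tmp_path):
    def _write(lines):
        path = tmp_path / "test.gtf"
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write


def gtf_line(chrom, start, end, strand, gene, tx, feature="exon"):
    attrs = f'gene_id "{gene}"; transcript_id "{tx}";'
    return "\t".join(
        (chrom, "src", feature, str(start), str(end), ".", strand, ".", attrs)
    )
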