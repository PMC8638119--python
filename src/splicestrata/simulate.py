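"""Synthetic cohorts with planted, driver-correlated splicing structure.

The generator builds (a) a GTF annotation of minimal multi-isoform genes,
each instantiating exactly one of the seven local splicing patterns, with a
ground-truth event catalog; and (b) a cohort of transcript TPMs and
gene-level abundances in which a driver gene follows a three-component
equal-variance Gaussian mixture (log2 CPM scale) and a chosen fraction of
events shifts Psi in the high-driver stratum, with type-level direction
given by a composition-bias map. The truth object is sufficient to score
every downstream call.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .events import EVENT_TYPES, SpliceEvent, TranscriptModel, make_event_id

DRIVER_GENE_ID = "DRIVER"

_CHROM = "chrSim"
_GENE_SPAN = 1000
_GENE_SPACING = 10_000

DEFAULT_COMPOSITION_BIAS: dict[str, float] = {
    "SE": +1.0, "A3": +1.0, "A5": +1.0,
    "MX": -1.0, "AF": -1.0, "AL": -1.0,
    "RI": 0.0,
}


@dataclass(frozen=True)
class CohortSpec:
    n_samples: int = 94
    n_genes: int = 80
    events_per_type: int | Mapping[str, int] = 4
    driver_means: tuple[float, float, float] = (2.0, 5.0, 8.0)
    driver_sd: float = 0.5
    driver_weights: tuple[float, float, float] = (0.3, 0.4, 0.3)
    shifted_fraction: float = 0.5
    delta_psi_effect: float = 0.3
    composition_bias: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMPOSITION_BIAS)
    )
    psi_noise_sd: float = 0.05
    libsize_range: tuple[float, float] = (1e6, 3e6)
    seed: int = 0

    def events_by_type(self) -> dict[str, int]:
        if isinstance(self.events_per_type, Mapping):
            counts = {t: int(self.events_per_type.get(t, 0)) for t in EVENT_TYPES}
        else:
            counts = {t: int(self.events_per_type) for t in EVENT_TYPES}
        if any(v < 0 for v in counts.values()):
            raise ValueError("events_per_type must be >= 0")
        return counts

    def validate(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if not np.all(np.diff(self.driver_means) > 0):
            raise ValueError("driver_means must be strictly increasing")
        if self.driver_sd <= 0:
            raise ValueError("driver_sd must be positive")
        if abs(sum(self.driver_weights) - 1.0) > 1e-9:
            raise ValueError("driver_weights must sum to 1")
        if not 0 <= self.shifted_fraction <= 1:
            raise ValueError("shifted_fraction must be in [0, 1]")
        if not 0 <= self.delta_psi_effect < 0.7:
            raise ValueError(
                "delta_psi_effect infeasible: target Psi must stay in (0, 1)"
            )
        n_event_genes = sum(self.events_by_type().values())
        if self.n_genes < n_event_genes + 1:
            raise ValueError(
                f"n_genes must cover {n_event_genes} event genes plus the driver"
            )
        lo, hi = self.libsize_range
        if not 0 < lo <= hi:
            raise ValueError("invalid libsize_range")


@dataclass(frozen=True)
class CohortTruth:
    strata: pd.Series              # sample_id -> low/intermediate/high
    driver_values: pd.Series       # sample_id -> log2-scale driver value
    baseline_psi: pd.Series        # event_id -> baseline Psi
    target_psi: pd.DataFrame       # events x {low, intermediate, high}
    shifted_events: dict[str, int]  # event_id -> +1 / -1 shift direction
    catalog: tuple[SpliceEvent, ...]


@dataclass(frozen=True)
class SimulatedCohort:
    tpm: pd.DataFrame              # transcripts x samples
    gene_abundance: pd.DataFrame   # genes x samples (expected counts)
    truth: CohortTruth
    spec: CohortSpec


# ---------------------------------------------------------------------------
# Gene templates, written in transcription-order local coordinates so the
# same template yields the same event type on either strand. Each entry:
# (isoform exon lists, inclusion isoform index, event signature coords).
# ---------------------------------------------------------------------------

_TEMPLATES: dict[str, tuple[tuple[tuple[tuple[int, int], ...], ...], int, tuple[int, ...]]] = {
    "SE": ((((1, 100), (201, 300), (401, 500)), ((1, 100), (401, 500))),
           0, (100, 201, 300, 401)),
    "MX": ((((1, 100), (201, 300), (501, 600)), ((1, 100), (351, 450), (501, 600))),
           0, (100, 201, 300, 351, 450, 501)),
    "A5": ((((1, 100), (301, 400)), ((1, 150), (301, 400))),
           1, (100, 150, 301)),
    "A3": ((((1, 100), (301, 400)), ((1, 100), (251, 400))),
           1, (100, 251, 301)),
    "RI": ((((1, 100), (201, 300)), ((1, 300),)),
           1, (1, 100, 201, 300)),
    "AF": ((((1, 100), (401, 500)), ((201, 300), (401, 500))),
           0, (1, 100, 201, 300, 401)),
    "AL": ((((1, 100), (201, 300)), ((1, 100), (401, 500))),
           1, (100, 201, 300, 401, 500)),
}


def generate_annotation(
    spec: CohortSpec,
) -> tuple[list[TranscriptModel], list[SpliceEvent]]:
    """Build the synthetic transcript models and the ground-truth catalog.

    Genes are laid out on non-overlapping intervals of one chromosome,
    alternating between the two strands.
    """
    spec.validate()
    counts = spec.events_by_type()
    if all(v == 0 for v in counts.values()):
        raise ValueError("at least one event is required")
    transcripts: list[TranscriptModel] = []
    truth: list[SpliceEvent] = []
    gene_index = 0
    for etype in EVENT_TYPES:
        isoforms, inc_idx, sig_local = _TEMPLATES[etype]
        for k in range(counts[etype]):
            gene_id = f"G{etype}{k:03d}"
            strand = "+" if gene_index % 2 == 0 else "-"
            offset = gene_index * _GENE_SPACING
            tids = []
            for t_i, exons in enumerate(isoforms):
                if strand == "+":
                    g_exons = tuple((offset + s, offset + e) for s, e in exons)
                else:
                    g_exons = tuple(
                        (offset + _GENE_SPAN - e, offset + _GENE_SPAN - s)
                        for s, e in exons
                    )
                tid = f"{gene_id}.t{t_i + 1}"
                tids.append(tid)
                transcripts.append(
                    TranscriptModel(
                        gene_id=gene_id,
                        transcript_id=tid,
                        chrom=_CHROM,
                        strand=strand,
                        exons=g_exons,
                    )
                )
            if strand == "+":
                coords = tuple(sorted(offset + c for c in sig_local))
            else:
                coords = tuple(sorted(offset + _GENE_SPAN - c for c in sig_local))
            truth.append(
                SpliceEvent(
                    event_id=make_event_id(gene_id, etype, _CHROM, coords, strand),
                    gene_id=gene_id,
                    event_type=etype,
                    inclusion_transcripts=frozenset({tids[inc_idx]}),
                    total_transcripts=frozenset(tids),
                    defining_coords=coords,
                )
            )
            gene_index += 1
    truth.sort(key=lambda e: (e.gene_id, e.event_type, e.defining_coords))
    return transcripts, truth


def annotation_to_gtf(transcripts: list[TranscriptModel]) -> str:
    """Serialize transcript models as GTF exon records."""
    lines = []
    for tx in transcripts:
        for start, end in tx.exons:
            attrs = f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}";'
            lines.append(
                "\t".join(
                    (
                        tx.chrom, "splicestrata_sim", "exon",
                        str(start), str(end), ".", tx.strand, ".", attrs,
                    )
                )
            )
    return "\n".join(lines) + "\n"


def _pick_shifted_events(
    spec: CohortSpec, truth: list[SpliceEvent], rng: np.random.Generator
) -> dict[str, int]:
    """Choose which events shift in the high stratum and in which direction.

    Types with a nonzero composition bias contribute
    round(shifted_fraction * n_type) events each, shifting with the bias
    sign; unbiased types never shift.
    """
    shifted: dict[str, int] = {}
    by_type: dict[str, list[str]] = {t: [] for t in EVENT_TYPES}
    for ev in truth:
        by_type[ev.event_type].append(ev.event_id)
    for etype in EVENT_TYPES:
        bias = float(spec.composition_bias.get(etype, 0.0))
        ids = by_type[etype]
        if bias == 0.0 or not ids:
            continue
        n_shift = int(round(spec.shifted_fraction * len(ids)))
        chosen = rng.choice(len(ids), size=n_shift, replace=False)
        for j in sorted(chosen):
            shifted[ids[j]] = 1 if bias > 0 else -1
    return shifted


def generate_cohort(
    spec: CohortSpec,
    transcripts: list[TranscriptModel] | None = None,
    truth_catalog: list[SpliceEvent] | None = None,
) -> SimulatedCohort:
    """Simulate transcript TPMs and gene abundances for a cohort.

    Driver expression (log2 CPM scale) is drawn from the three-component
    equal-variance mixture; realized Psi is logit-normal around the
    stratum-specific target; transcript TPMs distribute each event gene's
    expression across its two isoforms according to realized Psi.
    """
    spec.validate()
    if transcripts is None or truth_catalog is None:
        transcripts, truth_catalog = generate_annotation(spec)
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    samples = [f"S{i + 1:03d}" for i in range(n)]

    # --- driver mixture and strata -------------------------------------
    comp = rng.choice(3, size=n, p=np.asarray(spec.driver_weights, dtype=float))
    driver = np.asarray(spec.driver_means)[comp] + rng.normal(
        0.0, spec.driver_sd, size=n
    )
    stratum_names = np.array(["low", "intermediate", "high"])
    strata = pd.Series(stratum_names[comp], index=samples, name="stratum")
    driver_values = pd.Series(driver, index=samples, name="driver_log2")

    # --- planted Psi structure ------------------------------------------
    event_ids = [ev.event_id for ev in truth_catalog]
    shifted = _pick_shifted_events(spec, truth_catalog, rng)
    delta = spec.delta_psi_effect
    baseline = pd.Series(
        rng.uniform(0.2, 0.8, size=len(event_ids)), index=event_ids
    )
    # keep shifted targets inside (0, 1): re-draw baselines in a feasible band
    for eid, sign in shifted.items():
        if sign > 0:
            baseline[eid] = rng.uniform(0.15, min(0.85, 0.95 - delta))
        else:
            baseline[eid] = rng.uniform(max(0.15, 0.05 + delta), 0.85)
    target_high = baseline.copy()
    for eid, sign in shifted.items():
        target_high[eid] = np.clip(baseline[eid] + sign * delta, 0.02, 0.98)
    target_psi = pd.DataFrame(
        {"low": baseline, "intermediate": baseline, "high": target_high}
    )

    # --- realized Psi and transcript TPMs -------------------------------
    targets = target_psi[strata.to_numpy()].to_numpy()  # events x samples
    noise = rng.normal(0.0, spec.psi_noise_sd, size=targets.shape)
    realized = expit(logit(targets) + noise)

    gene_level = {}  # per event gene: CPM-scale expression level
    for ev in truth_catalog:
        gene_level[ev.gene_id] = rng.uniform(20.0, 60.0)

    tx_rows: dict[str, np.ndarray] = {}
    for i, ev in enumerate(truth_catalog):
        level = gene_level[ev.gene_id]
        (inc_tid,) = tuple(ev.inclusion_transcripts)
        (exc_tid,) = tuple(ev.exclusion_transcripts)
        tx_rows[inc_tid] = level * realized[i]
        tx_rows[exc_tid] = level * (1.0 - realized[i])
    tpm = pd.DataFrame.from_dict(tx_rows, orient="index", columns=samples)
    tpm = tpm.sort_index()

    # --- gene-level abundances ------------------------------------------
    n_event_genes = len(gene_level)
    n_filler = spec.n_genes - n_event_genes - 1
    filler_ids = [f"FILLER{i:04d}" for i in range(n_filler)]
    filler_base = rng.uniform(5e3, 2.5e4, size=n_filler)
    filler_noise = rng.lognormal(0.0, 0.05, size=(n_filler, n))
    filler_cpm = filler_base[:, None] * filler_noise

    driver_cpm = 2.0**driver - 1.0
    event_cpm = np.tile(
        np.array([gene_level[g] for g in sorted(gene_level)])[:, None], (1, n)
    )
    # rescale filler so each sample's CPM column sums to one million
    remaining = 1e6 - driver_cpm - event_cpm.sum(axis=0)
    filler_cpm = filler_cpm * (remaining / filler_cpm.sum(axis=0))[None, :]

    libsize = rng.uniform(*spec.libsize_range, size=n)
    cpm = np.vstack([driver_cpm[None, :], event_cpm, filler_cpm])
    counts = cpm * libsize[None, :] / 1e6
    gene_ids = [DRIVER_GENE_ID] + sorted(gene_level) + filler_ids
    gene_abundance = pd.DataFrame(counts, index=gene_ids, columns=samples)

    truth = CohortTruth(
        strata=strata,
        driver_values=driver_values,
        baseline_psi=baseline,
        target_psi=target_psi,
        shifted_events=shifted,
        catalog=tuple(truth_catalog),
    )
    return SimulatedCohort(
        tpm=tpm, gene_abundance=gene_abundance, truth=truth, spec=spec
    )


# ---------------------------------------------------------------------------
# Serialization of a full cohort to plain-text files.
# ---------------------------------------------------------------------------


def write_cohort(cohort: SimulatedCohort, outdir: str | Path) -> dict[str, Path]:
    """Write GTF, TPM and gene tables, truth tables, and a manifest."""
    from .events import write_event_catalog
    from .psi import write_matrix_tsv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    transcripts, _ = generate_annotation(cohort.spec)
    paths = {
        "annotation": outdir / "annotation.gtf",
        "tpm": outdir / "transcript_tpm.tsv",
        "gene_abundance": outdir / "gene_abundance.tsv",
        "truth_catalog": outdir / "truth_catalog.tsv",
        "truth_strata": outdir / "truth_strata.tsv",
        "truth_psi": outdir / "truth_psi.tsv",
        "manifest": outdir / "manifest.json",
    }
    paths["annotation"].write_text(annotation_to_gtf(transcripts))
    write_matrix_tsv(cohort.tpm, paths["tpm"])
    write_matrix_tsv(cohort.gene_abundance, paths["gene_abundance"])
    write_event_catalog(cohort.truth.catalog, paths["truth_catalog"])
    truth_strata = pd.DataFrame(
        {
            "sample_id": cohort.truth.strata.index,
            "stratum": cohort.truth.strata.to_numpy(),
            "driver_log2": cohort.truth.driver_values.to_numpy(),
        }
    )
    truth_strata.to_csv(paths["truth_strata"], sep="\t", index=False)
    truth_psi = cohort.truth.target_psi.copy()
    truth_psi["shift_direction"] = [
        cohort.truth.shifted_events.get(eid, 0) for eid in truth_psi.index
    ]
    truth_psi.to_csv(paths["truth_psi"], sep="\t", index_label="event_id")
    spec_dict = asdict(cohort.spec)
    spec_dict["composition_bias"] = dict(spec_dict["composition_bias"])
    if isinstance(spec_dict["events_per_type"], Mapping):
        spec_dict["events_per_type"] = dict(spec_dict["events_per_type"])
    paths["manifest"].write_text(json.dumps(spec_dict, indent=2, sort_keys=True))
    return paths
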