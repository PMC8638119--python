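"""Percent-spliced-in (Psi) quantification from transcript TPM abundances.

Psi of an event in a sample is the TPM mass of its inclusion transcripts
divided by the TPM mass of all transcripts participating in the event.
Events whose total TPM falls below an expression floor are reported as
missing (NaN) rather than imputed.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .events import SpliceEvent

DEFAULT_MIN_TOTAL_TPM = 1.0
DEFAULT_MAX_MISSING_FRAC = 0.2


def validate_abundance(tpm: pd.DataFrame) -> None:
    """Check a transcripts x samples TPM matrix: nonnegative, finite, unique ids."""
    if tpm.index.has_duplicates or tpm.columns.has_duplicates:
        raise ValueError("duplicate transcript or sample ids in abundance matrix")
    values = tpm.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("abundance matrix contains non-finite values")
    if (values < 0).any():
        raise ValueError("abundance matrix contains negative values")


def compute_psi(
    catalog: Sequence[SpliceEvent],
    abundance: pd.DataFrame,
    min_total_tpm: float = DEFAULT_MIN_TOTAL_TPM,
) -> pd.DataFrame:
    """Compute the events x samples Psi matrix.

    Parameters
    ----------
    catalog
        Splice events whose transcripts must all be rows of ``abundance``.
    abundance
        Transcripts x samples TPM matrix.
    min_total_tpm
        Entries whose total-form TPM sum is below this floor become NaN.

    Returns
    -------
    DataFrame indexed by event_id with values in [0, 1] or NaN.
    """
    validate_abundance(abundance)
    if min_total_tpm < 0:
        raise ValueError("min_total_tpm must be >= 0")
    known = set(abundance.index)
    rows = []
    for ev in catalog:
        missing_tx = ev.total_transcripts - known
        if missing_tx:
            raise KeyError(
                f"event {ev.event_id} references transcripts absent from the "
                f"abundance matrix: {sorted(missing_tx)}"
            )
        inc = abundance.loc[sorted(ev.inclusion_transcripts)].sum(axis=0)
        tot = abundance.loc[sorted(ev.total_transcripts)].sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            psi = inc / tot
        psi[tot < min_total_tpm] = np.nan
        rows.append(psi.rename(ev.event_id))
    if not rows:
        return pd.DataFrame(columns=abundance.columns)
    return pd.DataFrame(rows)


def filter_psi(
    psi: pd.DataFrame, max_missing_frac: float = DEFAULT_MAX_MISSING_FRAC
) -> pd.DataFrame:
    """Drop events missing in more than ``max_missing_frac`` of samples."""
    if not 0 <= max_missing_frac <= 1:
        raise ValueError("max_missing_frac must be in [0, 1]")
    if psi.shape[1] == 0:
        return psi
    frac_missing = psi.isna().mean(axis=1)
    return psi.loc[frac_missing <= max_missing_frac]


# ---------------------------------------------------------------------------
# TSV serialization. Matrices are rows-as-features, columns-as-samples,
# missing values written as "NA".
# ---------------------------------------------------------------------------


def write_matrix_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", na_rep="NA", index_label="id")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], comment="#")
    df.index.name = None
    return df


def event_ids(catalog: Iterable[SpliceEvent]) -> list[str]:
    return [ev.event_id for ev in catalog]
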