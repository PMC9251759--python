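"""Target-decoy global FDR over PSMs and threshold filtering.

The global FDR at a row of the score-ranked PSM list is estimated from the
cumulative decoy count, FDR(n) = D(n) / T(n); q-values are the running
minimum of the raw FDR taken from the bottom of the list upward. PSMs are
filtered (typically at 1% FDR) before any site-level analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

from .records import PsmRecord

Ordering = Literal["probability", "score"]


@dataclass
class FdrRow:
    psm: PsmRecord
    rank: int
    cum_targets: int
    cum_decoys: int
    raw_fdr: float
    q_value: float


def _ordering_key(psm: PsmRecord, ordering: Ordering) -> float:
    value = psm.psm_probability if ordering == "probability" else psm.psm_score
    if value is None:
        raise ValueError(
            f"PSM {psm.spectrum_id!r} lacks the {ordering} ordering key"
        )
    return value


def compute_psm_fdr(
    psms: Sequence[PsmRecord],
    ordering: Ordering = "probability",
    plus_one: bool = False,
) -> list[FdrRow]:
    """Rank PSMs by descending score/probability and attach FDR and q-values.

    Ties are broken conservatively: at an equal ordering key, decoy PSMs
    sort above targets (so they are counted before the targets they compete
    with); otherwise input order is preserved. ``plus_one`` switches the
    estimator from D/T to (D+1)/T.
    """
    if not psms:
        return []
    if all(p.is_decoy_protein for p in psms):
        raise ValueError("all PSMs are decoys; no targets to estimate FDR over")
    ranked = sorted(
        range(len(psms)),
        key=lambda i: (-_ordering_key(psms[i], ordering), not psms[i].is_decoy_protein, i),
    )
    rows: list[FdrRow] = []
    targets = decoys = 0
    for rank, i in enumerate(ranked, start=1):
        psm = psms[i]
        if psm.is_decoy_protein:
            decoys += 1
        else:
            targets += 1
        numerator = decoys + (1 if plus_one else 0)
        raw = min(1.0, numerator / targets) if targets else 1.0
        rows.append(FdrRow(psm, rank, targets, decoys, raw, q_value=raw))
    running = 1.0
    for row in reversed(rows):
        running = min(running, row.raw_fdr)
        row.q_value = running
    return rows


def filter_psm_fdr(rows: Sequence[FdrRow], alpha: float = 0.01) -> list[PsmRecord]:
    """Return target (non-decoy, non-contaminant) PSMs with q-value <= alpha."""
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    return [
        row.psm
        for row in rows
        if row.q_value <= alpha
        and not row.psm.is_decoy_protein
        and not row.psm.is_contaminant
    ]
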