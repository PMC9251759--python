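"""Global false localization rate (FLR) estimators over a ranked site list.

Three estimators are provided, each yielding a raw running FLR per row of a
ranked site table (and, after monotonization, q-values):

* **model FLR** — the running mean of the local FLR (one minus the combined
  probability): ``FLR_model(n) = sum_{i<=n} (1 - p_i) / n``. Trusts the
  calibration of the probabilities the localization software reports.

* **decoy FLR** — counts phosphosites reported on a decoy amino acid (a
  residue that cannot biologically carry the modification, so every such
  site is a known false localization) and scales them to the target
  residues: ``FLR_decoy(n) = 2 * (T_c / X_c) * pX_c(n) / n``, where ``T_c``
  and ``X_c`` are the total target (STY) and decoy residue counts over the
  peptides of the retained PSM set, and ``pX_c(n)`` is the cumulative count
  of decoy-residue sites at or above row n. Under random mislocalization a
  wrong site lands on targets versus the decoy in proportion ``T_c : X_c``;
  the factor 2 makes the estimate cover the wrong hits on both classes and
  errs conservative for a rare decoy residue.

* **answer-key FLR** — for synthetic libraries with known true positions:
  the running fraction of sites not matching the key,
  ``FLR_key(n) = F_c(n) / n``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .records import AnswerKey, DecoyConfig, PsmRecord
from .sites import RankedSiteTable


@dataclass(frozen=True)
class FlrCounters:
    """Residue totals behind the decoy estimator's target/decoy ratio."""

    target_count: int  # T_c: target residues over retained PSM peptides
    decoy_count: int  # X_c: decoy residues over the same peptides

    @property
    def ratio(self) -> float:
        return self.target_count / self.decoy_count


def count_residues(
    psms: Sequence[PsmRecord],
    config: DecoyConfig,
    unique_peptides: bool = False,
) -> FlrCounters:
    """Count target and decoy residues over the peptides of a PSM set.

    Counting is per PSM with multiplicity: the same peptide observed in k
    PSMs contributes k times (``unique_peptides=True`` switches to counting
    each distinct peptide once). The PSM set should be the post-FDR set
    contributing at least one scored site to the ranked table —
    :meth:`RankedSiteTable.contributing_psms` yields exactly that set.
    """
    if config.decoy_residue is None:
        raise ValueError("decoy residue not configured")
    peptides = [p.peptide for p in psms]
    if unique_peptides:
        peptides = list(dict.fromkeys(peptides))
    targets = sum(c in config.target_residues for pep in peptides for c in pep)
    decoys = sum(c == config.decoy_residue for pep in peptides for c in pep)
    if targets == 0:
        raise ValueError("no target residues in the retained PSM set")
    if decoys == 0:
        raise ValueError(
            f"decoy residue {config.decoy_residue!r} absent from the retained PSM set"
        )
    return FlrCounters(target_count=targets, decoy_count=decoys)


def model_flr(table: RankedSiteTable) -> np.ndarray:
    """Running mean of the local FLR (1 - combined probability) per row."""
    probs = [s.combined_probability for s in table]
    if any(p is None for p in probs):
        raise ValueError("model FLR requires combined probabilities on every row")
    local = 1.0 - np.asarray(probs, dtype=float)
    n = np.arange(1, len(local) + 1, dtype=float)
    return np.cumsum(local) / n


def decoy_flr(table: RankedSiteTable, counters: FlrCounters) -> np.ndarray:
    """Normalized decoy-site count over rows: 2 * (T_c/X_c) * pX_c(n) / n, capped at 1."""
    if len(table) == 0:
        return np.empty(0)
    decoy_cum = np.cumsum(table.is_decoy_site())
    n = np.arange(1, len(table) + 1, dtype=float)
    raw = 2.0 * counters.ratio * decoy_cum / n
    return np.minimum(raw, 1.0)


def answer_key_flr(table: RankedSiteTable, key: AnswerKey) -> np.ndarray:
    """Running fraction of sites whose position does not match the answer key."""
    missing = sorted({s.peptide for s in table if s.peptide not in key})
    if missing:
        raise KeyError(
            f"{len(missing)} peptides absent from the answer key "
            f"(first few: {missing[:5]}); apply answer_key_filter first"
        )
    false = np.array(
        [s.site_position not in key.true_positions(s.peptide) for s in table],
        dtype=float,
    )
    n = np.arange(1, len(false) + 1, dtype=float)
    return np.cumsum(false) / n


@dataclass(frozen=True)
class Removal:
    psm: PsmRecord
    reason: str


def answer_key_filter(
    psms: Sequence[PsmRecord], key: AnswerKey
) -> tuple[list[PsmRecord], list[Removal]]:
    """Keep only PSMs directly comparable to the answer key.

    Removed (with a logged reason): peptides that are proper substrings of
    a key peptide ("partial peptide"), peptides absent from the key, PSMs
    whose reported modification count differs from the expected count, and
    PSMs carrying other variable modifications.
    """
    kept: list[PsmRecord] = []
    removed: list[Removal] = []
    for psm in psms:
        if psm.peptide not in key:
            reason = "partial peptide" if key.is_partial(psm.peptide) else "peptide not in key"
            removed.append(Removal(psm, reason))
        elif len(psm.mod_positions) != key.expected_mod_count(psm.peptide):
            removed.append(
                Removal(
                    psm,
                    f"count mismatch: {len(psm.mod_positions)} reported vs "
                    f"{key.expected_mod_count(psm.peptide)} expected",
                )
            )
        elif psm.other_modifications:
            removed.append(Removal(psm, "additional modifications"))
        else:
            kept.append(psm)
    return kept, removed


def to_q_values(raw: np.ndarray) -> np.ndarray:
    """Monotonize a raw running FLR into q-values.

    q(n) = min over m >= n of raw(m): the smallest global FLR at which row
    n would still be accepted. Non-decreasing down the list.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size and (np.min(raw) < 0 or np.max(raw) > 1):
        raise ValueError("raw FLR values must lie in [0, 1]")
    return np.minimum.accumulate(raw[::-1])[::-1]


@dataclass
class ThresholdResult:
    """Rows accepted at a global FLR threshold and the target-site yield."""

    n_rows: int
    target_site_count: int
    decoy_site_count: int
    rows: RankedSiteTable

    @property
    def attained(self) -> bool:
        """False when no row met the threshold (e.g. the decoy estimate
        saturated at 1 before reaching it) — report "n/a" in that case."""
        return self.n_rows > 0


def threshold_at(
    table: RankedSiteTable, q_values: np.ndarray, alpha: float
) -> ThresholdResult:
    """All rows down to the last row with q-value <= alpha."""
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    q_values = np.asarray(q_values, dtype=float)
    if len(q_values) != len(table):
        raise ValueError("q-value vector does not match the table")
    passing = np.nonzero(q_values <= alpha)[0]
    cut = int(passing[-1]) + 1 if passing.size else 0
    subset = table.sites[:cut]
    decoys = sum(s.is_decoy_site for s in subset)
    return ThresholdResult(
        n_rows=cut,
        target_site_count=cut - decoys,
        decoy_site_count=decoys,
        rows=RankedSiteTable(sites=list(subset), mode=table.mode),
    )
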