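"""Expansion of FDR-filtered PSMs into per-phosphosite rows and ranking.

Each PSM contributes one row per scored modified position. Rows carry a
combined probability — PSM probability times site localization probability,
justified when the two are (near-)independent — and are ranked descending
by either the combined probability or the localization probability alone
(the latter for small search databases where PSM probabilities are
unreliable).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Literal, Sequence

import numpy as np
import pandas as pd

from .records import DecoyConfig, PsmRecord, SiteRecord

RankMode = Literal["combined", "ptm_only"]


def expand_to_sites(psms: Sequence[PsmRecord], config: DecoyConfig) -> list[SiteRecord]:
    """One :class:`SiteRecord` per (PSM, modified position).

    ``combined_probability`` is the product of the PSM and localization
    probabilities (``None`` when the PSM probability is absent);
    ``is_decoy_site`` flags sites on the configured decoy residue.
    """
    sites: list[SiteRecord] = []
    for psm in psms:
        if len(psm.ptm_probabilities) != len(psm.mod_positions):
            raise ValueError(
                f"PSM {psm.spectrum_id!r}: {len(psm.ptm_probabilities)} localization "
                f"probabilities for {len(psm.mod_positions)} modified positions"
            )
        for position, ptm_prob in zip(psm.mod_positions, psm.ptm_probabilities):
            if not 1 <= position <= len(psm.peptide):
                raise ValueError(
                    f"PSM {psm.spectrum_id!r}: position {position} outside peptide"
                )
            residue = psm.peptide[position - 1]
            combined = (
                None
                if psm.psm_probability is None
                else psm.psm_probability * ptm_prob
            )
            sites.append(
                SiteRecord(
                    psm=psm,
                    site_position=position,
                    residue=residue,
                    ptm_probability=ptm_prob,
                    combined_probability=combined,
                    is_decoy_site=residue == config.decoy_residue,
                )
            )
    return sites


@dataclass
class RankedSiteTable:
    """Site records in ranked order plus per-row bookkeeping.

    ``psm_counts`` and ``prob_bins`` are populated only on collapsed tables
    (supporting-PSM count and two-decimal probability bin per row).
    """

    sites: list[SiteRecord]
    mode: RankMode = "combined"
    psm_counts: list[int] | None = None
    prob_bins: list[float] | None = None

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self) -> Iterator[SiteRecord]:
        return iter(self.sites)

    def order_keys(self) -> np.ndarray:
        """The ranking key of every row, in table order."""
        return np.array([_rank_key(s, self.mode) for s in self.sites], dtype=float)

    def is_decoy_site(self) -> np.ndarray:
        return np.array([s.is_decoy_site for s in self.sites], dtype=bool)

    def contributing_psms(self) -> list[PsmRecord]:
        """Unique underlying PSMs, in first-appearance order.

        A PSM with several scored sites appears once; distinct PSMs of the
        same peptide each appear (multiplicity is intended: residue counts
        for the decoy estimator are per-PSM).
        """
        seen: dict[int, PsmRecord] = {}
        for s in self.sites:
            seen.setdefault(id(s.psm), s.psm)
        return list(seen.values())

    def to_frame(self, estimates: dict[str, np.ndarray] | None = None) -> pd.DataFrame:
        rows = []
        for s in self.sites:
            rows.append(
                {
                    "spectrum_id": s.psm.spectrum_id,
                    "peptide": s.peptide,
                    "site_position": s.site_position,
                    "residue": s.residue,
                    "psm_probability": s.psm.psm_probability,
                    "ptm_probability": s.ptm_probability,
                    "combined_probability": s.combined_probability,
                    "is_decoy_site": s.is_decoy_site,
                }
            )
        df = pd.DataFrame(rows)
        if self.psm_counts is not None:
            df["psm_count"] = self.psm_counts
        if self.prob_bins is not None:
            df["probability_bin"] = self.prob_bins
        for name, values in (estimates or {}).items():
            df[name] = np.asarray(values)
        return df


def _rank_key(site: SiteRecord, mode: RankMode) -> float:
    if mode == "ptm_only":
        return site.ptm_probability
    if site.combined_probability is None:
        raise ValueError(
            f"PSM {site.psm.spectrum_id!r} lacks psm_probability; "
            "rank with mode='ptm_only' or calibrate scores first"
        )
    return site.combined_probability


def rank_sites(sites: Sequence[SiteRecord], mode: RankMode = "combined") -> RankedSiteTable:
    """Order sites descending by the selected probability.

    Tie-break at an equal key is conservative for every downstream
    estimator: decoy-residue sites sort above target sites, then input
    order is preserved.
    """
    if mode not in ("combined", "ptm_only"):
        raise ValueError(f"unknown rank mode {mode!r}")
    order = sorted(
        range(len(sites)),
        key=lambda i: (-_rank_key(sites[i], mode), not sites[i].is_decoy_site, i),
    )
    return RankedSiteTable(sites=[sites[i] for i in order], mode=mode)
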