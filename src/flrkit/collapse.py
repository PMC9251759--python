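"""Collapsing multiple PSM observations of a site to one ranked row.

Several PSMs frequently support the same phosphosite. Ranking the collapsed
rows purely by maximum probability ignores the evidence in spectral counts,
and high-scoring false sites are often single-PSM; the rule used here
balances the two: take the maximum probability per site, bin it to two
decimal places (floor), rank by bin descending, and within a bin rank by
supporting-PSM count descending.
"""

from __future__ import annotations

import math
from typing import Hashable, Literal

from .records import SiteRecord
from .sites import RankedSiteTable

CollapseKey = Literal["peptidoform", "protein_site"]


def _group_key(site: SiteRecord, by: CollapseKey) -> Hashable:
    if by == "peptidoform":
        return (site.peptide, site.site_position)
    psm = site.psm
    if psm.protein_positions is None or not psm.protein_accessions:
        raise ValueError(
            f"PSM {psm.spectrum_id!r} lacks protein coordinates required for "
            "protein_site collapsing"
        )
    idx = psm.mod_positions.index(site.site_position)
    return (psm.protein_accessions[0], psm.protein_positions[idx])


def _rank_probability(site: SiteRecord, mode: str) -> float:
    if mode == "ptm_only":
        return site.ptm_probability
    if site.combined_probability is None:
        raise ValueError(f"PSM {site.psm.spectrum_id!r} lacks a combined probability")
    return site.combined_probability


def collapse(table: RankedSiteTable, by: CollapseKey = "protein_site") -> RankedSiteTable:
    """Collapse a ranked site table to one row per site.

    The returned table keeps, per group, the source row attaining the
    maximum probability (decoy flags and probabilities survive collapse),
    annotated with the supporting-PSM count and the two-decimal probability
    bin. Ordering: bin descending, then PSM count descending, then unbinned
    maximum probability, then first appearance in the input.
    """
    if by not in ("peptidoform", "protein_site"):
        raise ValueError(f"unknown collapse key {by!r}")
    groups: dict[Hashable, dict] = {}
    for site in table:
        key = _group_key(site, by)
        prob = _rank_probability(site, table.mode)
        group = groups.get(key)
        if group is None:
            groups[key] = {
                "best": site,
                "prob": prob,
                "spectra": {site.psm.spectrum_id},
                "first": len(groups),
            }
        else:
            group["spectra"].add(site.psm.spectrum_id)
            if prob > group["prob"]:
                group["best"], group["prob"] = site, prob

    def prob_bin(p: float) -> float:
        return math.floor(p * 100.0) / 100.0

    ordered = sorted(
        groups.values(),
        key=lambda g: (-prob_bin(g["prob"]), -len(g["spectra"]), -g["prob"], g["first"]),
    )
    return RankedSiteTable(
        sites=[g["best"] for g in ordered],
        mode=table.mode,
        psm_counts=[len(g["spectra"]) for g in ordered],
        prob_bins=[prob_bin(g["prob"]) for g in ordered],
    )
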