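"""Decoy-suitability diagnostics.

A good decoy amino acid should sit, relative to confidently localized
phosphosites, at distances distributed like the genuine target residues
(S/T/Y): incorrect localizations preferentially land on nearby residues, so
a decoy clustered unusually close to (or far from) true sites mis-states
the random mislocalization rate. Two diagnostics are provided:

* nearest-residue offset histograms — the signed distance from each
  confident site to the nearest residue of a candidate set;
* proximal probability profiles — the mean combined probability of
  confident sites grouped by the amino acid at the -1 or +1 neighbor
  position, which exposes motif effects (e.g. a decoy residue frequently
  preceding true sites attracts mislocalized probability mass).
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .records import SiteRecord

DEFAULT_PROXIMAL_MIN_PROBABILITY = 0.68  # confident-site cutoff for neighbor profiles


def _protein_context(
    site: SiteRecord, proteins: Mapping[str, str] | None
) -> tuple[str, int]:
    """Resolve (sequence, 1-based site position) in protein context.

    Falls back to the peptide itself (with a warning) when no protein
    sequence can be resolved.
    """
    psm = site.psm
    if proteins:
        for acc in psm.protein_accessions:
            seq = proteins.get(acc)
            if seq is None:
                continue
            if psm.protein_positions is not None and site.site_position in psm.mod_positions:
                pos = psm.protein_positions[psm.mod_positions.index(site.site_position)]
            else:
                start = seq.find(psm.peptide)
                if start < 0:
                    raise ValueError(
                        f"PSM {psm.spectrum_id!r}: peptide not found in protein {acc}"
                    )
                pos = start + site.site_position
            if not 1 <= pos <= len(seq) or seq[pos - 1] != site.residue:
                raise ValueError(
                    f"PSM {psm.spectrum_id!r}: site position {pos} does not match "
                    f"residue {site.residue!r} in protein {acc}"
                )
            return seq, pos
    warnings.warn(
        "no protein context resolved; falling back to peptide sequence",
        stacklevel=3,
    )
    return psm.peptide, site.site_position


def nearest_residue_offsets(
    sites: Sequence[SiteRecord],
    candidates: Iterable[str],
    proteins: Mapping[str, str] | None = None,
    window: int = 10,
) -> list[int | None]:
    """Signed offset to the nearest candidate residue per site.

    Negative offsets point toward the N-terminus; the site's own position
    is excluded; equidistant ties resolve to the negative offset; ``None``
    when no candidate lies within ±window. Sites should be pre-filtered to
    an assumed-correct subset (e.g. ≤5% model-FLR q-value).
    """
    candidate_set = frozenset(candidates)
    offsets: list[int | None] = []
    for site in sites:
        seq, pos = _protein_context(site, proteins)
        found: int | None = None
        for d in range(1, window + 1):
            left, right = pos - d, pos + d
            if left >= 1 and seq[left - 1] in candidate_set:
                found = -d
                break
            if right <= len(seq) and seq[right - 1] in candidate_set:
                found = d
                break
        offsets.append(found)
    return offsets


def offset_histogram(offsets: Iterable[int | None]) -> dict[int, float]:
    """Normalized frequency per signed offset (``None`` entries dropped)."""
    counts: dict[int, int] = {}
    for off in offsets:
        if off is not None:
            counts[off] = counts.get(off, 0) + 1
    if not counts:
        raise ValueError("no offsets to histogram")
    total = sum(counts.values())
    return {off: counts[off] / total for off in sorted(counts)}


def compare_offset_histograms(
    sites: Sequence[SiteRecord],
    decoy_residue: str,
    target_residues: Iterable[str] = "STY",
    proteins: Mapping[str, str] | None = None,
    window: int = 10,
) -> pd.DataFrame:
    """Decoy-residue and target-residue offset histograms over the same sites."""
    rows = []
    for label, cand in (("decoy", {decoy_residue}), ("target", set(target_residues))):
        hist = offset_histogram(
            nearest_residue_offsets(sites, cand, proteins=proteins, window=window)
        )
        rows.extend(
            {"candidate_set": label, "offset": off, "frequency": freq}
            for off, freq in hist.items()
        )
    return pd.DataFrame(rows, columns=["candidate_set", "offset", "frequency"])


def proximal_probability_profile(
    sites: Sequence[SiteRecord],
    offset: int,
    min_probability: float = DEFAULT_PROXIMAL_MIN_PROBABILITY,
) -> pd.DataFrame:
    """Mean combined probability of confident sites per neighbor amino acid.

    ``offset`` must be -1 or +1 (the residue immediately N- or C-terminal
    of the site, in peptide context); sites below ``min_probability`` and
    peptide-terminal sites lacking the neighbor are skipped. Returns one
    row per neighbor letter with the mean probability and the site count.
    """
    if offset not in (-1, 1):
        raise ValueError("offset must be -1 or +1")
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for site in sites:
        prob = site.combined_probability
        if prob is None or prob < min_probability:
            continue
        neighbor_pos = site.site_position + offset
        if not 1 <= neighbor_pos <= len(site.peptide):
            continue
        letter = site.peptide[neighbor_pos - 1]
        sums[letter] = sums.get(letter, 0.0) + prob
        counts[letter] = counts.get(letter, 0) + 1
    rows = [
        {"residue": aa, "mean_probability": sums[aa] / counts[aa], "n_sites": counts[aa]}
        for aa in sorted(sums)
    ]
    return pd.DataFrame(rows, columns=["residue", "mean_probability", "n_sites"])
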