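"""Reading and writing the plain-text interchange formats.

The ingestion boundary of the toolkit is a tab-separated interchange table
(one row per PSM), not any search-engine native format. Missing values are
written as ``"."``. A header row is mandatory and files are UTF-8.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .records import AnswerKey, AnswerKeyEntry, PsmRecord, SiteRecord

PSM_COLUMNS = [
    "spectrum_id",
    "peptide",
    "charge",
    "mod_positions",
    "psm_probability",
    "psm_score",
    "ptm_probabilities",
    "protein",
    "is_decoy",
    "is_contaminant",
]

SITE_COLUMNS = [
    "spectrum_id",
    "peptide",
    "charge",
    "site_position",
    "residue",
    "psm_probability",
    "ptm_probability",
    "combined_probability",
    "is_decoy_site",
    "protein",
    "protein_position",
]

MISSING = "."


def _fmt(value) -> str:
    if value is None:
        return MISSING
    if isinstance(value, float):
        if math.isnan(value):
            return MISSING
        return format(value, ".10g")
    return str(value)


def _join(values: Iterable) -> str:
    out = ";".join(_fmt(v) for v in values)
    return out if out else MISSING


def write_psm_table(psms: Sequence[PsmRecord], path: str | Path) -> None:
    rows = []
    for p in psms:
        rows.append(
            {
                "spectrum_id": p.spectrum_id,
                "peptide": p.peptide,
                "charge": p.charge,
                "mod_positions": _join(p.mod_positions),
                "psm_probability": _fmt(p.psm_probability),
                "psm_score": _fmt(p.psm_score),
                "ptm_probabilities": _join(p.ptm_probabilities),
                "protein": _join(p.protein_accessions),
                "is_decoy": int(p.is_decoy_protein),
                "is_contaminant": int(p.is_contaminant),
            }
        )
    pd.DataFrame(rows, columns=PSM_COLUMNS).to_csv(path, sep="\t", index=False)


def _parse_float(text: str) -> float | None:
    return None if text == MISSING else float(text)


def _parse_int_list(text: str) -> list[int]:
    return [] if text == MISSING else [int(x) for x in text.split(";")]


def _parse_float_list(text: str) -> list[float]:
    return [] if text == MISSING else [float(x) for x in text.split(";")]


class TableFormatError(ValueError):
    """Raised when an interchange table cannot be parsed, with row location."""


def read_psm_table(path: str | Path) -> list[PsmRecord]:
    """Parse an interchange PSM table.

    Rejects tables mixing native and missing PSM probabilities: estimator
    inputs must be homogeneous, so either every row carries a probability or
    none does (and every row then needs a raw score for calibration).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = [c for c in PSM_COLUMNS if c not in df.columns]
    if missing_cols:
        raise TableFormatError(f"{path}: missing columns {missing_cols}")
    records: list[PsmRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            records.append(
                PsmRecord(
                    spectrum_id=row.spectrum_id,
                    peptide=row.peptide,
                    charge=int(row.charge),
                    mod_positions=_parse_int_list(row.mod_positions),
                    ptm_probabilities=_parse_float_list(row.ptm_probabilities),
                    psm_probability=_parse_float(row.psm_probability),
                    psm_score=_parse_float(row.psm_score),
                    protein_accessions=[] if row.protein == MISSING else row.protein.split(";"),
                    is_decoy_protein=bool(int(row.is_decoy)),
                    is_contaminant=bool(int(row.is_contaminant)),
                )
            )
        except (ValueError, TypeError) as exc:
            raise TableFormatError(f"{path}: row {i + 2}: {exc}") from exc
    with_prob = sum(r.psm_probability is not None for r in records)
    if 0 < with_prob < len(records):
        raise TableFormatError(
            f"{path}: {len(records) - with_prob} rows lack psm_probability while others "
            "carry one; calibrated and native probabilities must not be mixed"
        )
    return records


def write_answer_key(key: AnswerKey, path: str | Path) -> None:
    rows = [
        {
            "peptide": pep,
            "true_positions": _join(sorted(entry.true_positions)),
            "expected_mod_count": entry.expected_mod_count,
        }
        for pep, entry in key.entries.items()
    ]
    pd.DataFrame(rows, columns=["peptide", "true_positions", "expected_mod_count"]).to_csv(
        path, sep="\t", index=False
    )


def read_answer_key(path: str | Path) -> AnswerKey:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    entries = {}
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            entries[row.peptide] = AnswerKeyEntry(
                frozenset(_parse_int_list(row.true_positions)),
                int(row.expected_mod_count),
            )
        except (ValueError, TypeError) as exc:
            raise TableFormatError(f"{path}: row {i + 2}: {exc}") from exc
    return AnswerKey(entries)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a protein FASTA into ``{accession: sequence}`` (description dropped)."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_site_table(sites: Sequence[SiteRecord], path: str | Path) -> None:
    """Write one row per scored site (ranked or unranked)."""
    rows = []
    for s in sites:
        p = s.psm
        protein_position = None
        if p.protein_positions is not None and s.site_position in p.mod_positions:
            protein_position = p.protein_positions[p.mod_positions.index(s.site_position)]
        rows.append(
            {
                "spectrum_id": p.spectrum_id,
                "peptide": p.peptide,
                "charge": p.charge,
                "site_position": s.site_position,
                "residue": s.residue,
                "psm_probability": _fmt(p.psm_probability),
                "ptm_probability": _fmt(s.ptm_probability),
                "combined_probability": _fmt(s.combined_probability),
                "is_decoy_site": int(s.is_decoy_site),
                "protein": _join(p.protein_accessions),
                "protein_position": _fmt(protein_position),
            }
        )
    pd.DataFrame(rows, columns=SITE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_site_table(path: str | Path) -> list[SiteRecord]:
    """Read a site table, rebuilding one shared PsmRecord per spectrum.

    Rows of the same ``spectrum_id`` reference a single PSM object, so
    residue counting over "the PSM set with a scored phosphosite" counts
    each spectrum once regardless of its number of sites.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = [c for c in SITE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise TableFormatError(f"{path}: missing columns {missing_cols}")
    psms: dict[str, PsmRecord] = {}
    sites: list[SiteRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            psm = psms.get(row.spectrum_id)
            if psm is None:
                psm = PsmRecord(
                    spectrum_id=row.spectrum_id,
                    peptide=row.peptide,
                    charge=int(row.charge),
                    mod_positions=[],
                    ptm_probabilities=[],
                    psm_probability=_parse_float(row.psm_probability),
                    protein_accessions=[] if row.protein == MISSING else row.protein.split(";"),
                    protein_positions=[],
                )
                psms[row.spectrum_id] = psm
            position = int(row.site_position)
            ptm_prob = float(row.ptm_probability)
            psm.mod_positions.append(position)
            psm.ptm_probabilities.append(ptm_prob)
            prot_pos = _parse_float(row.protein_position)
            psm.protein_positions.append(None if prot_pos is None else int(prot_pos))
            sites.append(
                SiteRecord(
                    psm=psm,
                    site_position=position,
                    residue=row.residue,
                    ptm_probability=ptm_prob,
                    combined_probability=_parse_float(row.combined_probability),
                    is_decoy_site=bool(int(row.is_decoy_site)),
                )
            )
        except (ValueError, TypeError) as exc:
            raise TableFormatError(f"{path}: row {i + 2}: {exc}") from exc
    for psm in psms.values():
        if any(p is None for p in psm.protein_positions):
            psm.protein_positions = None
    return sites
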