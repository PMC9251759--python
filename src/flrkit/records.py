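"""Core domain types for PTM site localization analysis.

All sequence coordinates are 1-based: the N-terminal residue of a peptide
(or protein) is position 1. Probabilities are stored as probability-correct;
the local false localization rate (PEP) of a record is ``1 - probability``
and is derived at use sites, never stored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Residues the field has proposed as phospho-decoys: no (or negligible)
#: biological phosphorylation, reasonably frequent in most proteomes.
DECOY_CANDIDATE_RESIDUES = frozenset("AGLDEP")


@dataclass(frozen=True)
class DecoyConfig:
    """Which residues genuinely carry the modification, and which residue
    serves as the decoy.

    For canonical phosphorylation the target residues are S, T and Y; the
    decoy residue is one that cannot biologically carry a phosphate
    (e.g. alanine), searched as modifiable so that every localization onto
    it is a known false localization.
    """

    target_residues: frozenset[str] = frozenset("STY")
    decoy_residue: str | None = "A"

    def __post_init__(self) -> None:
        if self.decoy_residue is not None:
            if len(self.decoy_residue) != 1:
                raise ValueError("decoy_residue must be a single residue letter")
            if self.decoy_residue in self.target_residues:
                raise ValueError(
                    f"decoy residue {self.decoy_residue!r} is a target residue"
                )

    @property
    def candidate_residues(self) -> frozenset[str]:
        """All residues a reported site may fall on (targets plus decoy)."""
        if self.decoy_residue is None:
            return self.target_residues
        return self.target_residues | {self.decoy_residue}


@dataclass
class PsmRecord:
    """One peptide-spectrum match carrying the modification of interest.

    ``mod_positions`` are 1-based positions within ``peptide``;
    ``ptm_probabilities`` is parallel to it. ``psm_probability`` is the
    probability the PSM is correct and may be ``None`` only when a raw
    ``psm_score`` is available for later calibration.
    """

    spectrum_id: str
    peptide: str
    charge: int
    mod_positions: list[int]
    ptm_probabilities: list[float]
    psm_probability: float | None = None
    psm_score: float | None = None
    protein_accessions: list[str] = field(default_factory=list)
    protein_positions: list[int] | None = None
    is_decoy_protein: bool = False
    is_contaminant: bool = False
    #: other variable modifications observed on the peptide (names only);
    #: consulted by answer-key filtering, never serialized to the interchange TSV.
    other_modifications: tuple[str, ...] = ()


@dataclass
class SiteRecord:
    """One scored phosphosite on one PSM."""

    psm: PsmRecord
    site_position: int
    residue: str
    ptm_probability: float
    combined_probability: float | None
    is_decoy_site: bool

    @property
    def peptide(self) -> str:
        return self.psm.peptide


@dataclass(frozen=True)
class AnswerKeyEntry:
    true_positions: frozenset[int]
    expected_mod_count: int


class AnswerKey:
    """Ground-truth map from peptide sequence to its true modified positions.

    Used for synthetic peptide libraries where the manufactured
    phosphosite(s) of every peptide are known.
    """

    def __init__(self, entries: Mapping[str, AnswerKeyEntry]):
        self.entries = dict(entries)

    @classmethod
    def from_positions(
        cls, mapping: Mapping[str, Iterable[int]], expected_counts: Mapping[str, int] | None = None
    ) -> "AnswerKey":
        entries = {}
        for peptide, positions in mapping.items():
            pos = frozenset(int(p) for p in positions)
            count = expected_counts[peptide] if expected_counts else len(pos)
            for p in pos:
                if not 1 <= p <= len(peptide):
                    raise ValueError(
                        f"answer key position {p} outside peptide {peptide!r}"
                    )
            entries[peptide] = AnswerKeyEntry(pos, count)
        return cls(entries)

    def __contains__(self, peptide: str) -> bool:
        return peptide in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def true_positions(self, peptide: str) -> frozenset[int]:
        return self.entries[peptide].true_positions

    def expected_mod_count(self, peptide: str) -> int:
        return self.entries[peptide].expected_mod_count

    def is_partial(self, peptide: str) -> bool:
        """True when ``peptide`` is a proper substring of some key peptide."""
        if peptide in self.entries:
            return False
        return any(peptide in full for full in self.entries)


@dataclass(frozen=True)
class ValidationIssue:
    row: int
    field: str
    message: str


def validate_table(records: Sequence[PsmRecord]) -> list[ValidationIssue]:
    """Check every PSM record against the schema invariants.

    Returns one :class:`ValidationIssue` per violation (a record may yield
    several); never mutates or drops records. An empty list means the table
    is valid.
    """
    issues: list[ValidationIssue] = []

    def add(row: int, field_name: str, message: str) -> None:
        issues.append(ValidationIssue(row, field_name, message))

    for i, rec in enumerate(records):
        if not rec.peptide or any(c not in AMINO_ACIDS for c in rec.peptide):
            add(i, "peptide", f"peptide {rec.peptide!r} is not an uppercase 20-letter amino acid string")
        if rec.charge < 1:
            add(i, "charge", f"charge {rec.charge} is not a positive integer")
        for p in rec.mod_positions:
            if not 1 <= p <= len(rec.peptide):
                add(i, "mod_positions", f"position {p} out of range for peptide of length {len(rec.peptide)}")
        if any(b <= a for a, b in zip(rec.mod_positions, rec.mod_positions[1:])):
            add(i, "mod_positions", f"positions {rec.mod_positions} not strictly increasing")
        if len(rec.ptm_probabilities) != len(rec.mod_positions):
            add(
                i,
                "ptm_probabilities",
                f"{len(rec.ptm_probabilities)} localization probabilities for "
                f"{len(rec.mod_positions)} modified positions",
            )
        for q in rec.ptm_probabilities:
            if not 0.0 <= q <= 1.0:
                add(i, "ptm_probabilities", f"probability {q} outside [0,1]")
        if rec.psm_probability is not None and not 0.0 <= rec.psm_probability <= 1.0:
            add(i, "psm_probability", f"probability {rec.psm_probability} outside [0,1]")
        if rec.psm_probability is None and rec.psm_score is None:
            add(i, "psm_probability", "missing psm_probability without a raw psm_score to calibrate")
        if rec.protein_positions is not None and len(rec.protein_positions) != len(rec.mod_positions):
            add(i, "protein_positions", "protein coordinates not parallel to mod_positions")
    return issues
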