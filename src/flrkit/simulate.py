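"""Simulator of site-level search-engine output with known ground truth.

The simulator emulates the statistical structure the FLR estimators
assume, at the probability level (no spectra): a protein database is drawn
with configurable residue frequencies, digested tryptically, and a library
of phosphopeptides — each with one fixed true modified position on a
target residue — is sampled into PSMs. Per PSM a correctness probability
is drawn; with that probability the true site is reported, otherwise the
site is mislocalized onto another candidate residue (targets + decoy) of
the peptide. Reported probabilities are either perfectly calibrated
(equal to the generative correctness probability) or systematically
shifted.

Mislocalization models
----------------------
``uniform``
    The wrong site lands on the decoy class with probability
    ``x / (t + x)`` — the peptide's candidate-residue class frequencies,
    the true site's own residue included in ``t`` — then uniformly within
    the class, excluding the true position. This is the generative model
    under which random wrong hits split between targets and decoy exactly
    in proportion to the residue counts ``T_c : X_c``, the assumption the
    decoy estimator normalizes by. (A naive uniform draw over candidate
    positions minus the true one under-weights the target class by one
    residue per peptide and would bias the decoy estimator upward by
    roughly c/(c-1) for c candidates per peptide.)
``nearest``
    The wrong site goes to the candidate residue nearest to the true site
    (ties toward the N-terminus), emulating localizers that slide the
    modification to an adjacent plausible acceptor.

A ``motif_bias`` term additionally snaps a wrong site onto the decoy
residue immediately N-terminal of the true site (when present) with the
given probability — reproducing the motif effect that makes residues
frequently preceding true sites poor decoys.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .records import AMINO_ACIDS, AnswerKey, DecoyConfig, PsmRecord
from .sites import RankedSiteTable


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulation run. ``seed`` is mandatory."""

    seed: int
    n_proteins: int = 200
    protein_length_mean: int = 300
    #: residue -> frequency; defaults to uniform 1/20 over the 20 amino acids
    residue_frequencies: Mapping[str, float] | None = None
    n_psms: int = 5000
    decoy: DecoyConfig = field(default_factory=DecoyConfig)
    #: Beta(a, b) for the per-site localization correctness probability
    ptm_beta: tuple[float, float] = (8.0, 1.0)
    #: Beta(a, b) for the PSM correctness probability
    psm_beta: tuple[float, float] = (18.0, 1.0)
    mislocalization: Literal["uniform", "nearest"] = "uniform"
    calibration: Literal["calibrated", "miscalibrated"] = "calibrated"
    #: logit shift applied to the *reported* site probability when miscalibrated
    miscalibration_shift: float = 0.0
    #: probability a wrong site snaps onto a decoy residue at -1 of the true site
    motif_bias: float = 0.0
    #: eligible library peptides carry at least this many target residues
    min_target_sites: int = 2
    max_missed_cleavages: int = 2
    peptide_length_range: tuple[int, int] = (7, 30)
    #: fraction of additional decoy-protein PSMs emitted (for FDR demos)
    decoy_psm_fraction: float = 0.0

    def frequencies(self) -> tuple[list[str], np.ndarray]:
        freqs = self.residue_frequencies or {aa: 1.0 for aa in AMINO_ACIDS}
        letters = sorted(freqs)
        weights = np.array([freqs[aa] for aa in letters], dtype=float)
        if np.any(weights < 0) or weights.sum() <= 0:
            raise ValueError("residue frequencies must be non-negative and sum > 0")
        if self.decoy.decoy_residue is not None and freqs.get(self.decoy.decoy_residue, 0.0) <= 0:
            raise ValueError(
                f"decoy residue {self.decoy.decoy_residue!r} has zero frequency"
            )
        return letters, weights / weights.sum()


@dataclass(frozen=True)
class SiteTruth:
    """Ground truth for one emitted site row."""

    spectrum_id: str
    is_correct: bool
    true_position: int
    reported_position: int
    residue: str


@dataclass
class SimResult:
    psms: list[PsmRecord]
    answer_key: AnswerKey
    truth: list[SiteTruth]
    proteins: dict[str, str]
    config: SimConfig

    def truth_by_spectrum(self) -> dict[str, SiteTruth]:
        return {t.spectrum_id: t for t in self.truth}


def _digest(sequence: str, max_missed: int, length_range: tuple[int, int]):
    """Tryptic peptides (cut after K/R, not before P) with start offsets."""
    cuts = [0]
    for i, aa in enumerate(sequence[:-1]):
        if aa in "KR" and sequence[i + 1] != "P":
            cuts.append(i + 1)
    cuts.append(len(sequence))
    fragments = [(cuts[j], cuts[j + 1]) for j in range(len(cuts) - 1)]
    lo, hi = length_range
    for j in range(len(fragments)):
        for missed in range(max_missed + 1):
            if j + missed >= len(fragments):
                break
            start, end = fragments[j][0], fragments[j + missed][1]
            if lo <= end - start <= hi:
                yield start, sequence[start:end]


def _mislocalize(
    peptide: str,
    true_pos: int,
    config: SimConfig,
    rng: np.random.Generator,
) -> int:
    """Choose the reported position for a row that failed localization."""
    decoy_aa = config.decoy.decoy_residue
    targets = [i + 1 for i, aa in enumerate(peptide) if aa in config.decoy.target_residues]
    decoys = (
        [i + 1 for i, aa in enumerate(peptide) if aa == decoy_aa] if decoy_aa else []
    )
    if (
        config.motif_bias > 0.0
        and decoy_aa is not None
        and true_pos >= 2
        and peptide[true_pos - 2] == decoy_aa
        and rng.random() < config.motif_bias
    ):
        return true_pos - 1
    if config.mislocalization == "nearest":
        others = [p for p in targets + decoys if p != true_pos]
        if not others:
            return true_pos
        return min(others, key=lambda p: (abs(p - true_pos), p - true_pos))
    # uniform (class-frequency-proportional); see module docstring
    t, x = len(targets), len(decoys)
    wrong_targets = [p for p in targets if p != true_pos]
    if x and rng.random() < x / (t + x):
        return int(rng.choice(decoys))
    if not wrong_targets:
        return int(rng.choice(decoys)) if decoys else true_pos
    return int(rng.choice(wrong_targets))


def _logit_shift(p: float, shift: float) -> float:
    p = min(max(p, 1e-9), 1.0 - 1e-9)
    z = np.log(p / (1.0 - p)) + shift
    return float(1.0 / (1.0 + np.exp(-z)))


def simulate(config: SimConfig) -> SimResult:
    """Run one simulation; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    letters, probs = config.frequencies()

    proteins: dict[str, str] = {}
    for i in range(config.n_proteins):
        length = int(
            rng.integers(config.protein_length_mean // 2, config.protein_length_mean * 3 // 2 + 1)
        )
        proteins[f"SIMPROT{i:05d}"] = "".join(rng.choice(letters, size=length, p=probs))

    # phosphopeptide library: one true site per unique peptide sequence
    library: dict[str, tuple[str, int, int]] = {}  # peptide -> (acc, start0, true_pos)
    for acc, seq in proteins.items():
        for start0, peptide in _digest(
            seq, config.max_missed_cleavages, config.peptide_length_range
        ):
            if peptide in library:
                continue
            targets = [
                i + 1 for i, aa in enumerate(peptide) if aa in config.decoy.target_residues
            ]
            if len(targets) < config.min_target_sites:
                continue
            library[peptide] = (acc, start0, int(rng.choice(targets)))
    if not library:
        raise ValueError("no eligible peptides generated; enlarge the protein database")
    peptides = list(library)

    psms: list[PsmRecord] = []
    truth: list[SiteTruth] = []
    choices = rng.integers(0, len(peptides), size=config.n_psms)
    for i, j in enumerate(choices):
        # one rng per row: row outcomes are reproducible in isolation, and
        # paired runs differing only in one model term share all other rows
        row_rng = np.random.default_rng([config.seed, i])
        peptide = peptides[j]
        acc, start0, true_pos = library[peptide]
        p_psm = float(row_rng.beta(*config.psm_beta))
        p_ptm = float(row_rng.beta(*config.ptm_beta))
        correct = row_rng.random() < p_psm * p_ptm
        pos = true_pos if correct else _mislocalize(peptide, true_pos, config, row_rng)
        reported_ptm = (
            p_ptm
            if config.calibration == "calibrated"
            else _logit_shift(p_ptm, config.miscalibration_shift)
        )
        spectrum_id = f"sim{i:06d}"
        psms.append(
            PsmRecord(
                spectrum_id=spectrum_id,
                peptide=peptide,
                charge=int(row_rng.integers(2, 4)),
                mod_positions=[pos],
                ptm_probabilities=[reported_ptm],
                psm_probability=p_psm,
                protein_accessions=[acc],
                protein_positions=[start0 + pos],
            )
        )
        truth.append(
            SiteTruth(
                spectrum_id=spectrum_id,
                is_correct=pos == true_pos,
                true_position=true_pos,
                reported_position=pos,
                residue=peptide[pos - 1],
            )
        )

    n_decoy_psms = round(config.decoy_psm_fraction * config.n_psms)
    for i in range(n_decoy_psms):
        peptide = peptides[int(rng.integers(0, len(peptides)))]
        shuffled = "".join(rng.permutation(list(peptide)))
        candidates = [
            k + 1
            for k, aa in enumerate(shuffled)
            if aa in config.decoy.candidate_residues
        ]
        if not candidates:
            continue
        psms.append(
            PsmRecord(
                spectrum_id=f"simdecoy{i:06d}",
                peptide=shuffled,
                charge=int(rng.integers(2, 4)),
                mod_positions=[int(rng.choice(candidates))],
                ptm_probabilities=[float(rng.beta(2.0, 2.0))],
                psm_probability=float(rng.beta(1.0, 3.0)),
                protein_accessions=["DECOY_SIM"],
                is_decoy_protein=True,
            )
        )

    answer_key = AnswerKey.from_positions(
        {pep: {library[pep][2]} for pep in peptides}
    )
    return SimResult(psms=psms, answer_key=answer_key, truth=truth, proteins=proteins, config=config)


def true_flr(table: RankedSiteTable, truth: Sequence[SiteTruth] | Mapping[str, SiteTruth]) -> np.ndarray:
    """Running true FLR over a ranked table: cumulative wrong-site fraction.

    The simulated truth plays the role of an answer key; this equals the
    answer-key estimator evaluated against the generative truth.
    """
    by_spectrum = (
        truth if isinstance(truth, Mapping) else {t.spectrum_id: t for t in truth}
    )
    wrong = []
    for site in table:
        t = by_spectrum.get(site.psm.spectrum_id)
        if t is None:
            raise KeyError(f"no truth row for spectrum {site.psm.spectrum_id!r}")
        wrong.append(site.site_position != t.true_position)
    wrong_arr = np.asarray(wrong, dtype=float)
    n = np.arange(1, len(wrong_arr) + 1, dtype=float)
    return np.cumsum(wrong_arr) / n


def write_truth(truth: Sequence[SiteTruth], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "spectrum_id": t.spectrum_id,
                "is_correct": int(t.is_correct),
                "true_position": t.true_position,
                "reported_position": t.reported_position,
                "residue": t.residue,
            }
            for t in truth
        ]
    ).to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> list[SiteTruth]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [
        SiteTruth(
            spectrum_id=row.spectrum_id,
            is_correct=bool(int(row.is_correct)),
            true_position=int(row.true_position),
            reported_position=int(row.reported_position),
            residue=row.residue,
        )
        for row in df.itertuples(index=False)
    ]


def decoy_frequency_table(
    decoy_residue: str = "A",
    decoy_frequency: float = 0.19,
    target_total: float = 0.15,
) -> dict[str, float]:
    """Residue frequency table with a chosen decoy-residue frequency.

    The S/T/Y targets share ``target_total`` equally, the decoy residue
    gets ``decoy_frequency``, and the remaining residues split the rest
    uniformly. Note the pooled residue counts over the *eligible* peptide
    library do not mirror the raw frequencies: eligible peptides carry at
    least two target residues, which over-represents targets.
    """
    if decoy_residue in "STY":
        raise ValueError("decoy residue cannot be a target residue")
    freqs = {aa: 0.0 for aa in AMINO_ACIDS}
    for aa in "STY":
        freqs[aa] = target_total / 3.0
    freqs[decoy_residue] = decoy_frequency
    others = [aa for aa in AMINO_ACIDS if aa not in set("STY" + decoy_residue)]
    for aa in others:
        freqs[aa] = (1.0 - target_total - decoy_frequency) / len(others)
    return freqs


def parity_frequencies(decoy_residue: str = "A") -> dict[str, float]:
    """Frequency table under which pooled counts come out near parity.

    Parity means the target residue count T_c about equals the decoy
    residue count X_c over the retained PSM set. Because eligibility
    conditions peptides on carrying two or more targets, parity of pooled
    counts requires a decoy frequency (0.19) above the combined raw S+T+Y
    frequency (0.15); the value was calibrated once against the default
    digestion settings.
    """
    return decoy_frequency_table(decoy_residue, decoy_frequency=0.19)
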