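from __future__ import annotations

import numpy as np
import pytest

import flrkit as fk


def make_psm(
    peptide: str,
    positions: list[int],
    ptm_probs: list[float],
    psm_prob: float | None = 0.9,
    spectrum_id: str = "s1",
    **kwargs,
) -> fk.PsmRecord:
    return fk.PsmRecord(
        spectrum_id=spectrum_id,
        peptide=peptide,
        charge=2,
        mod_positions=positions,
        ptm_probabilities=ptm_probs,
        psm_probability=psm_prob,
        **kwargs,
    )


def make_table(
    probs: list[float],
    decoy_flags: list[bool],
    peptides: list[str] | None = None,
    positions: list[int] | None = None,
) -> fk.RankedSiteTable:
    """A ranked table straight from parallel probability/decoy-flag lists.

    Rows are taken as already ranked (probabilities need not be sorted);
    each row gets its own single-site PSM.
    """
    sites = []
    for i, (p, d) in enumerate(zip(probs, decoy_flags)):
        peptide = peptides[i] if peptides else ("AS" if d else "SA")
        pos = positions[i] if positions else (1 if d else 1)
        psm = make_psm(
            peptide, [pos], [p], psm_prob=1.0, spectrum_id=f"row{i}"
        )
        sites.append(
            fk.SiteRecord(
                psm=psm,
                site_position=pos,
                residue=peptide[pos - 1],
                ptm_probability=p,
                combined_probability=p,
                is_decoy_site=d,
            )
        )
    return fk.RankedSiteTable(sites=sites, mode="combined")


@pytest.fixture(scope="session")
def sim_calibrated():
    """Default calibrated simulation at the standard study size."""
    config = fk.SimConfig(seed=20240, n_psms=20000, n_proteins=300)
    return fk.simulate(config)


@pytest.fixture(scope="session")
def ranked_calibrated(sim_calibrated):
    sites = fk.expand_to_sites(sim_calibrated.psms, sim_calibrated.config.decoy)
    return fk.rank_sites(sites)


def threshold_row(true_curve: np.ndarray, alpha: float) -> int:
    """Last row whose monotonized true FLR is at or below alpha."""
    q = fk.to_q_values(true_curve)
    idx = np.nonzero(q <= alpha)[0]
    if idx.size == 0:
        raise AssertionError(f"true FLR never reaches {alpha}")
    return int(idx[-1])
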