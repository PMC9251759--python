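"""Score calibration by target/decoy histogram binning.

For search engines reporting only raw scores, a probability-correct is
estimated per equal-width score bin from the target and decoy counts in the
bin: PEP_b = min(1, D_b / T_b), probability = 1 - PEP_b. Zero-target bins
inherit the nearest populated bin, and the bin probabilities are made
monotone non-decreasing in score by isotonic pooling of adjacent bins
(a probability should never drop as the score improves).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.isotonic import IsotonicRegression


@dataclass
class HistogramCalibrator:
    """A fitted step-function mapping score -> probability correct."""

    bin_edges: np.ndarray  # length B + 1
    probabilities: np.ndarray  # length B, monotone non-decreasing

    def __call__(self, scores) -> np.ndarray:
        scores = np.asarray(scores, dtype=float)
        idx = np.clip(
            np.searchsorted(self.bin_edges[1:-1], scores, side="right"),
            0,
            len(self.probabilities) - 1,
        )
        return self.probabilities[idx]


def histogram_calibrate(scores, is_decoy, bins: int = 100) -> HistogramCalibrator:
    """Fit a target/decoy histogram calibrator.

    ``scores`` and ``is_decoy`` are parallel; bins are equal-width over the
    observed score range.
    """
    scores = np.asarray(scores, dtype=float)
    is_decoy = np.asarray(is_decoy, dtype=bool)
    if scores.size != is_decoy.size:
        raise ValueError("scores and is_decoy must be parallel")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if bins < 1:
        raise ValueError("bins must be a positive integer")
    if not is_decoy.any():
        raise ValueError("cannot calibrate without decoys")
    if is_decoy.all():
        raise ValueError("cannot calibrate without targets")

    lo, hi = float(scores.min()), float(scores.max())
    if hi == lo:  # degenerate: a single score value
        hi = lo + 1.0
    edges = np.linspace(lo, hi, bins + 1)
    targets, _ = np.histogram(scores[~is_decoy], bins=edges)
    decoys, _ = np.histogram(scores[is_decoy], bins=edges)

    pep = np.ones(bins)
    populated = targets > 0
    pep[populated] = np.minimum(1.0, decoys[populated] / targets[populated])
    # zero-target bins inherit the nearest populated bin (lower index on ties)
    if not populated.all():
        pop_idx = np.nonzero(populated)[0]
        for b in np.nonzero(~populated)[0]:
            pep[b] = pep[pop_idx[np.argmin(np.abs(pop_idx - b))]]

    prob = 1.0 - pep
    centers = 0.5 * (edges[:-1] + edges[1:])
    weights = np.maximum(targets + decoys, 0.5)  # inherited bins get nominal weight
    iso = IsotonicRegression(y_min=0.0, y_max=1.0, increasing=True)
    prob = iso.fit_transform(centers, prob, sample_weight=weights)
    return HistogramCalibrator(bin_edges=edges, probabilities=prob)
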