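"""Participant-by-participant signed similarity network.

Nodes are participants; the weight between two participants is the Pearson
correlation of their (residualized) tract profiles across all tracts, so the
network is signed: positive edges link participants with similar white-matter
profiles, negative edges link dissimilar ones.  The diagonal is zero by
convention and self-loops never enter modularity sums.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .prep import ResidualizedProfiles, tract_columns


@dataclass
class SimilarityNetwork:
    """Symmetric signed matrix of participant-participant Pearson r."""

    ids: list[str]
    weights: np.ndarray  # (n, n), symmetric, zero diagonal, |w| <= 1

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1] or w.shape[0] != len(self.ids):
            raise ValueError("weights must be square and match ids")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("weights must be symmetric")
        if np.any(np.abs(w) > 1 + 1e-12):
            raise ValueError("|weights| must be <= 1")
        np.fill_diagonal(w, 0.0)
        self.weights = w

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.ids, columns=self.ids)


def build_network(profiles: ResidualizedProfiles | pd.DataFrame) -> SimilarityNetwork:
    """Pearson-correlate every pair of participants across tract values."""
    if isinstance(profiles, ResidualizedProfiles):
        table = profiles.data
    else:
        table = profiles
    tracts = tract_columns(table)
    if len(table) < 3 or len(tracts) < 3:
        raise ValueError("need at least 3 participants and 3 tracts")
    values = table[tracts].to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=0)
    degenerate = sd <= 1e-12 * np.maximum(1.0, np.abs(values).max(axis=1))
    if np.any(degenerate):
        bad = table["participant_id"].to_numpy()[degenerate]
        raise ValueError(f"zero across-tract variance for participant(s): {list(bad)}")
    w = np.corrcoef(values)
    np.fill_diagonal(w, 0.0)
    w = np.clip((w + w.T) / 2.0, -1.0, 1.0)
    return SimilarityNetwork(ids=list(table["participant_id"]), weights=w)
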