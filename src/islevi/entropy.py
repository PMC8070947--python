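"""Entropy-difference ranking of indicators against the assessment result.

For the discretized result E and each discretized indicator I the association
is scored by the entropy difference

    V(I) = |S(E, I) - S(E)| = S(I | E),

the conditional Shannon entropy (base 2) of the indicator given the result,
estimated from empirical cell frequencies over the study area. A smaller V
means the indicator carries more information about the result; indicators
with V below a threshold (default 1 bit) are flagged as *key indicators*.

Under empirical independence V equals the indicator's own marginal entropy
S(I) (up to log2 m_i for an m_i-state layer); V is 0 when the indicator
determines — and is determined by — the result states.

A mutual-information variant, V_MI(I) = S(E) + S(I) - S(E, I) (larger =
stronger association), is available behind ``method='mutual_information'``
for sensitivity checks; the conditional-entropy reading is the default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bayes import joint_counts
from .grid import CategoricalRaster, RegionMask

DEFAULT_KEY_THRESHOLD = 1.0  # bits


def shannon_entropy(p: np.ndarray) -> float:
    """Base-2 Shannon entropy of a probability vector, with 0 log 0 = 0."""
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError("probabilities must be nonnegative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"probabilities sum to {p.sum():.12f}, not 1")
    nz = p > 0
    return float(-(p[nz] * np.log2(p[nz])).sum())


def _joint_probs(e: CategoricalRaster, i: CategoricalRaster, domain: RegionMask) -> np.ndarray:
    t = joint_counts(e, i, domain, "E", "I")
    return t.counts / t.total


def joint_entropy(e: CategoricalRaster, i: CategoricalRaster, domain: RegionMask) -> float:
    """S(E, I): entropy of the empirical joint state distribution over the mask."""
    return shannon_entropy(_joint_probs(e, i, domain).ravel())


def entropy_difference(
    e: CategoricalRaster,
    i: CategoricalRaster,
    domain: RegionMask,
    method: str = "conditional",
) -> float:
    """V(I) for one indicator layer against the result layer.

    ``method='conditional'`` (default) returns |S(E,I) - S(E)| = S(I|E);
    ``method='mutual_information'`` returns S(E) + S(I) - S(E,I).
    """
    pj = _joint_probs(e, i, domain)
    s_joint = shannon_entropy(pj.ravel())
    s_e = shannon_entropy(pj.sum(axis=1))
    if method == "conditional":
        return abs(s_joint - s_e)
    if method == "mutual_information":
        s_i = shannon_entropy(pj.sum(axis=0))
        return s_e + s_i - s_joint
    raise ValueError(f"unknown method {method!r}")


@dataclass
class EntropyReport:
    """Per-indicator entropy differences and key-indicator flags."""

    result_entropy: float
    table: pd.DataFrame  # columns: indicator, joint_entropy, entropy_difference, key_flag
    threshold: float
    method: str = "conditional"

    @property
    def key_indicators(self) -> list[str]:
        return list(self.table.loc[self.table["key_flag"], "indicator"])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def rank_key_indicators(
    result: CategoricalRaster,
    indicators: dict[str, CategoricalRaster],
    domain: RegionMask,
    threshold: float = DEFAULT_KEY_THRESHOLD,
    method: str = "conditional",
) -> EntropyReport:
    """Score every indicator against the result and flag the key ones.

    Indicators are sorted by strength of association (ascending V for the
    conditional reading, descending for mutual information); ``key_flag`` is
    true where the conditional V falls below the threshold (or MI above it).
    """
    if not indicators:
        raise ValueError("need at least one indicator layer")
    sel = result.valid & domain.member
    counts = np.bincount(result.levels[sel], minlength=result.n_states + 1)[1:]
    result_entropy = shannon_entropy(counts / counts.sum())
    rows = []
    for name, layer in indicators.items():
        pj = _joint_probs(result, layer, domain)
        s_joint = shannon_entropy(pj.ravel())
        s_e = shannon_entropy(pj.sum(axis=1))
        if method == "conditional":
            v = abs(s_joint - s_e)
            flag = v < threshold
        else:
            v = s_e + shannon_entropy(pj.sum(axis=0)) - s_joint
            flag = v > threshold
        rows.append(
            {
                "indicator": name,
                "joint_entropy": s_joint,
                "entropy_difference": v,
                "key_flag": flag,
            }
        )
    table = pd.DataFrame(rows).sort_values(
        "entropy_difference", ascending=(method == "conditional"), kind="mergesort"
    )
    table = table.reset_index(drop=True)
    return EntropyReport(float(result_entropy), table, threshold, method)
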