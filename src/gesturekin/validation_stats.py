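"""Coder-agreement statistics for paired feature tables.

Automatic extraction is validated against human coding (or two human
coders against each other) with Spearman's rho per feature, Bonferroni
correction over the feature family, and unweighted Cohen's kappa for the
features quantified on set scales (vertical amplitude, binned peak
velocity).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import cohen_kappa_score

from .exceptions import GestureKinError

__all__ = [
    "PairedRatings",
    "spearman_rho",
    "cohens_kappa",
    "compare_tables",
    "DEFAULT_COMPARE_FEATURES",
    "DEFAULT_SCALES",
]

#: Features compared between coders by default.
DEFAULT_COMPARE_FEATURES: Tuple[str, ...] = (
    "vertical_amplitude",
    "peak_velocity_bin",
    "submovements_total",
    "hold_count",
)

#: Set scales for the two features that admit a kappa.
DEFAULT_SCALES: Dict[str, Tuple[int, ...]] = {
    "vertical_amplitude": tuple(range(1, 5)),
    "peak_velocity_bin": tuple(range(1, 8)),
}


@dataclass(frozen=True)
class PairedRatings:
    """Two coders' values for one feature over the same items."""

    feature: str
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        b = np.asarray(self.b, dtype=float)
        if a.shape != b.shape or a.ndim != 1:
            raise ValueError("a and b must be equal-length one-dimensional sequences")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)

    @property
    def n(self) -> int:
        return self.a.size


def spearman_rho(
    p: PairedRatings,
    method: str = "t",
    n_permutations: int = 10_000,
    seed: Optional[int] = None,
) -> Tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    Ranks use midranks for ties.  ``method='t'`` (default) takes the
    p-value from the t-distribution approximation, appropriate at the
    sample sizes typical of coder-validation sets; ``method='permutation'``
    uses a seeded permutation test for small n.
    """
    if p.n < 3:
        raise ValueError(f"need at least 3 paired items, got {p.n}")
    if np.all(p.a == p.a[0]) or np.all(p.b == p.b[0]):
        raise GestureKinError(
            f"{p.feature}: a rater's values have zero variance; rho is undefined"
        )
    if method == "t":
        res = stats.spearmanr(p.a, p.b)
        return float(res.statistic), float(res.pvalue)
    if method == "permutation":
        rng = np.random.default_rng(seed)
        obs = float(stats.spearmanr(p.a, p.b).statistic)
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(p.b)
            if abs(stats.spearmanr(p.a, perm).statistic) >= abs(obs) - 1e-12:
                count += 1
        return obs, (count + 1) / (n_permutations + 1)
    raise ValueError("method must be 't' or 'permutation'")


def cohens_kappa(p: PairedRatings, scale: Sequence[int]) -> float:
    """Unweighted Cohen's kappa on a declared category scale.

    kappa = (p_o - p_e) / (1 - p_e) with expected agreement from the
    product of the raters' marginal distributions.
    """
    scale = list(scale)
    for name, arr in (("a", p.a), ("b", p.b)):
        outside = sorted(set(arr.tolist()) - set(float(s) for s in scale))
        if outside:
            raise GestureKinError(
                f"{p.feature}: rater {name} has values outside the declared scale: {outside}"
            )
    return float(cohen_kappa_score(p.a, p.b, labels=[float(s) for s in scale]))


def compare_tables(
    auto: pd.DataFrame,
    manual: pd.DataFrame,
    features: Sequence[str] = DEFAULT_COMPARE_FEATURES,
    alpha: float = 0.05,
    scales: Optional[Dict[str, Sequence[int]]] = None,
) -> pd.DataFrame:
    """Per-feature agreement between two feature tables joined on act label.

    Returns one row per feature with Spearman's rho, the raw two-sided p,
    the Bonferroni-corrected p (min(1, p * n_features)), a significance
    flag at ``alpha`` on the corrected p, and unweighted kappa for
    features with a declared set scale.
    """
    if scales is None:
        scales = DEFAULT_SCALES
    a = auto.set_index(auto["act_label"].astype(str))
    b = manual.set_index(manual["act_label"].astype(str))
    only_a = sorted(set(a.index) - set(b.index))
    only_b = sorted(set(b.index) - set(a.index))
    if only_a or only_b:
        raise GestureKinError(
            f"act labels do not match: only in first table {only_a}; only in second {only_b}"
        )
    b = b.loc[a.index]

    m = len(features)
    rows = []
    for feat in features:
        if feat not in a.columns or feat not in b.columns:
            raise GestureKinError(f"feature {feat!r} missing from one of the tables")
        pr = PairedRatings(feature=feat, a=a[feat].to_numpy(float), b=b[feat].to_numpy(float))
        rho, p_raw = spearman_rho(pr)
        p_corr = min(1.0, p_raw * m)
        kappa = cohens_kappa(pr, scales[feat]) if feat in scales else np.nan
        rows.append(
            {
                "feature": feat,
                "n": pr.n,
                "rho": rho,
                "p_raw": p_raw,
                "p_bonferroni": p_corr,
                "significant": p_corr < alpha,
                "kappa": kappa,
            }
        )
    return pd.DataFrame(rows)
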