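"""Degron-versus-background comparison battery.

Annotated degron peptides are compared with length-matched background
peptides feature by feature (conservation, disorder, accessibility, PTM
counts, ...) with two-tailed Mann–Whitney tests. For small samples
(combined n up to a configurable cutoff, default 12) the null distribution
of U is enumerated exactly over every group assignment, which stays correct
under ties; larger samples use the tie-corrected normal approximation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

EXACT_CUTOFF = 12


def _u_statistic(ranks_x: np.ndarray, n_x: int) -> float:
    return float(ranks_x.sum() - n_x * (n_x + 1) / 2)


def mann_whitney_two_tailed(
    x: Sequence[float],
    y: Sequence[float],
    exact_cutoff: int = EXACT_CUTOFF,
) -> tuple[float, float]:
    """Two-tailed Mann–Whitney U test; returns (U of x, p).

    Exact branch (n_x + n_y <= ``exact_cutoff``): the pooled sample is
    midranked once, every C(n, n_x) assignment of ranks to the x group is
    enumerated, and the two-tailed p is the fraction of assignments whose U
    deviates from the null mean n_x·n_y/2 at least as much as the observed U.
    Otherwise: tie-corrected normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n_x, n_y = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u_obs = _u_statistic(ranks[:n_x], n_x)

    if n_x + n_y <= exact_cutoff:
        centre = n_x * n_y / 2
        dev = abs(u_obs - centre)
        total = comb(n_x + n_y, n_x)
        hits = 0
        for idx in combinations(range(n_x + n_y), n_x):
            u = _u_statistic(ranks[list(idx)], n_x)
            if abs(u - centre) >= dev - 1e-12:
                hits += 1
        return u_obs, hits / total

    _, p = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return u_obs, float(min(p, 1.0))


@dataclass(frozen=True)
class ComparisonResult:
    feature_name: str
    n_degron: int
    n_background: int
    median_degron: float
    median_background: float
    u_statistic: float
    p_two_tailed: float


def compare_feature_sets(
    degron_features: pd.DataFrame,
    background_features: pd.DataFrame,
    features: Sequence[str],
    exact_cutoff: int = EXACT_CUTOFF,
    bh_column: bool = False,
) -> pd.DataFrame:
    """One two-tailed Mann–Whitney comparison per feature.

    Direction is reported through the two medians. Raw p-values are the
    primary output; ``bh_column=True`` appends a Benjamini–Hochberg adjusted
    column as a clearly additive extra (it never alters the raw p's).
    """
    if degron_features.empty or background_features.empty:
        raise ValueError("both feature sets must be non-empty")
    results = []
    for feat in features:
        for df, label in ((degron_features, "degron"), (background_features, "background")):
            if feat not in df.columns:
                raise KeyError(f"feature {feat!r} missing from {label} set")
        x = degron_features[feat].to_numpy(dtype=float)
        y = background_features[feat].to_numpy(dtype=float)
        u, p = mann_whitney_two_tailed(x, y, exact_cutoff=exact_cutoff)
        results.append(
            ComparisonResult(
                feature_name=feat,
                n_degron=len(x),
                n_background=len(y),
                median_degron=float(np.median(x)),
                median_background=float(np.median(y)),
                u_statistic=u,
                p_two_tailed=p,
            )
        )
    out = pd.DataFrame([r.__dict__ for r in results])
    if bh_column:
        out["q_bh"] = _benjamini_hochberg(out["p_two_tailed"].to_numpy())
    return out


def plot_feature_comparisons(
    degron_features: pd.DataFrame,
    background_features: pd.DataFrame,
    features: Sequence[str],
    path,
) -> None:
    """Optional box-plot export of the degron/background contrasts.

    Requires matplotlib (the ``plot`` extra); the statistics above never do.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(features), figsize=(3 * len(features), 3.2))
    if len(features) == 1:
        axes = [axes]
    for ax, feat in zip(axes, features):
        ax.boxplot(
            [degron_features[feat], background_features[feat]],
            tick_labels=["degron", "background"],
        )
        ax.set_title(feat, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj
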