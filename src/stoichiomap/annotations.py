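"""Centrality vs gene-attribute statistics.

Conservation centrality is compared with external per-gene attributes
(essentiality flags, ortholog counts, coding status) through binned
fraction curves over centrality rank classes and one-sided Brunner-Munzel
rank tests between the top and bottom score quartiles. The Brunner-Munzel
test targets the stochastic-superiority probability P(X>Y) + 0.5 P(X=Y)
and, unlike Wilcoxon-Mann-Whitney, stays valid under unequal variances.
"""

from __future__ import annotations

import warnings
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["brunner_munzel", "binned_fraction_curve", "quartile_comparison"]


class BrunnerMunzelResult(NamedTuple):
    statistic: float
    pvalue: float
    estimate: float  # P(X > Y) + 0.5 P(X = Y)
    df: float


def _midranks(a: np.ndarray) -> np.ndarray:
    return stats.rankdata(a, method="average")


def brunner_munzel(x, y, alternative: str = "greater") -> BrunnerMunzelResult:
    """Brunner-Munzel rank test with the t-approximation.

    Midranks handle ties; the degrees of freedom use the Satterthwaite-type
    approximation of the original formulation. ``alternative='greater'``
    tests whether x tends to be larger than y (estimate > 1/2),
    ``'less'`` the reverse, ``'two-sided'`` either.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise ValueError("both samples need at least 2 observations")
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")

    pooled = _midranks(np.concatenate([x, y]))
    Rx, Ry = pooled[:nx], pooled[nx:]
    Rxx, Ryy = _midranks(x), _midranks(y)
    Rx_mean, Ry_mean = Rx.mean(), Ry.mean()

    # estimate of P(X > Y) + 0.5 P(X = Y)
    estimate = (Rx_mean - (nx + 1) / 2.0) / ny

    Sx2 = np.sum((Rx - Rxx - Rx_mean + (nx + 1) / 2.0) ** 2) / (nx - 1)
    Sy2 = np.sum((Ry - Ryy - Ry_mean + (ny + 1) / 2.0) ** 2) / (ny - 1)
    pooled_var = nx * Sx2 + ny * Sy2
    if pooled_var == 0:
        if estimate in (0.0, 1.0):
            # complete separation: the t-approximation degenerates; report
            # the strongest possible evidence in the observed direction
            warnings.warn(
                "completely separated samples: Brunner-Munzel p-value is 0 or 1"
            )
            W = np.inf if estimate == 0.0 else -np.inf
            p_x_larger = 0.0 if estimate == 1.0 else 1.0
            if alternative == "greater":
                p = p_x_larger
            elif alternative == "less":
                p = 1.0 - p_x_larger
            else:
                p = 0.0
            return BrunnerMunzelResult(float(W), p, float(estimate), float("nan"))
        raise ValueError(
            "zero rank variance (all-identical pooled ranks): "
            "the Brunner-Munzel statistic is undefined"
        )
    # statistic is positive when y tends to exceed x
    W = nx * ny * (Ry_mean - Rx_mean) / ((nx + ny) * np.sqrt(pooled_var))
    df = pooled_var**2 / (
        (nx * Sx2) ** 2 / (nx - 1) + (ny * Sy2) ** 2 / (ny - 1)
    )

    if alternative == "greater":  # H1: x stochastically larger -> W very negative
        p = float(stats.t.cdf(W, df))
    elif alternative == "less":
        p = float(stats.t.sf(W, df))
    else:
        p = float(2.0 * min(stats.t.cdf(W, df), stats.t.sf(W, df)))
    return BrunnerMunzelResult(float(W), p, float(estimate), float(df))


def binned_fraction_curve(
    scores, flags, n_bins: int = 10
) -> pd.DataFrame:
    """Fraction of flagged genes within each score-rank class.

    Genes are ranked by score (descending, ties broken by input order) and
    split into ``n_bins`` near-equal rank classes; the remainder is spread
    over the top classes so bin sizes differ by at most one. Rows are
    ordered from the highest-score class down.
    """
    scores = np.asarray(scores, dtype=float)
    flags = np.asarray(flags, dtype=bool)
    if scores.size != flags.size:
        raise ValueError("scores and flags must have equal length")
    if n_bins < 2 or n_bins > scores.size:
        raise ValueError("need 2 <= n_bins <= number of genes")
    order = np.argsort(-scores, kind="stable")
    base, rem = divmod(scores.size, n_bins)
    sizes = np.full(n_bins, base)
    sizes[:rem] += 1
    rows, start = [], 0
    for b in range(n_bins):
        members = order[start : start + sizes[b]]
        start += sizes[b]
        rows.append(
            {
                "bin": b + 1,
                "n_genes": int(sizes[b]),
                "n_flagged": int(flags[members].sum()),
                "fraction": float(flags[members].mean()),
            }
        )
    return pd.DataFrame(rows)


def quartile_comparison(
    scores, attribute, direction: str = "greater"
) -> dict[str, BrunnerMunzelResult]:
    """Reciprocal top-25% vs bottom-25% Brunner-Munzel tests.

    ``attribute_by_score``: attribute values of the top score quartile
    against the bottom score quartile. ``score_by_attribute``: score values
    of the top attribute quartile against the bottom attribute quartile.
    ``direction='greater'`` tests that the top-quartile values tend larger.
    """
    scores = np.asarray(scores, dtype=float)
    attribute = np.asarray(attribute, dtype=float)
    n = scores.size
    if attribute.size != n:
        raise ValueError("scores and attribute must have equal length")
    if n < 8:
        raise ValueError("need at least 8 genes for quartile comparison")
    q = n // 4

    def split(values_by, tested):
        order = np.argsort(-values_by, kind="stable")
        return tested[order[:q]], tested[order[-q:]]

    top_attr, bottom_attr = split(scores, attribute)
    top_score, bottom_score = split(attribute, scores)
    return {
        "attribute_by_score": brunner_munzel(top_attr, bottom_attr, direction),
        "score_by_attribute": brunner_munzel(top_score, bottom_score, direction),
    }
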