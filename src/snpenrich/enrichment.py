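"""Stratified Q-Q curves and hypergeometric over-representation tests.

Enrichment of an annotation is read two ways:

* *Stratified Q-Q*: observed -log10 p quantiles of the SNPs inside the
  annotation plotted against uniform-null theoretical quantiles; upward
  deflection from the identity line means an excess of small p-values.
* *Over-representation*: a one-sided hypergeometric (Fisher) test of whether
  genome-wide-significant SNPs (-log10 p > 7.3, i.e. p < ~5e-8) are
  over-represented among annotation members, Bonferroni-adjusted over the
  number of annotations tested.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .gwas import AnnotationMask, SnpPanel

__all__ = [
    "QQCurve",
    "FisherResult",
    "qq_curve",
    "stratified_qq",
    "qq_table",
    "plot_qq",
    "fisher_enrichment",
    "bonferroni",
    "fisher_table",
    "GENOME_WIDE_NEGLOG10",
]

#: Genome-wide significance: -log10 p strictly greater than this.
GENOME_WIDE_NEGLOG10 = 7.3

PlottingPosition = Literal["weibull", "naive", "hazen"]


@dataclass
class QQCurve:
    """Paired expected/observed -log10 p quantiles for one SNP stratum.

    Point j pairs the j-th smallest expected quantile with the j-th smallest
    observed -log10 p; both vectors are nondecreasing.
    """

    stratum_name: str
    expected: np.ndarray
    observed: np.ndarray
    n: int

    def max_deviation(self, central: float = 1.0) -> float:
        """Max |observed - expected| over the central fraction of ranks."""
        if not (0 < central <= 1):
            raise ValueError("central must be in (0, 1]")
        drop = int(round(self.n * (1 - central) / 2))
        hi = self.n - drop if drop else self.n
        sl = slice(drop, hi)
        return float(np.max(np.abs(self.observed[sl] - self.expected[sl])))


@dataclass
class FisherResult:
    """One 2x2 over-representation test.

    k significant members, n_in members, K significant overall, N total.
    """

    annotation_name: str
    k: int
    n_in: int
    K: int
    N: int
    odds_ratio: float
    p_hyper: float
    p_bonferroni: float | None = None
    degenerate: bool = False
    background: str = "whole_panel"


def _plotting_positions(n: int, convention: PlottingPosition) -> np.ndarray:
    i = np.arange(1, n + 1)
    if convention == "weibull":
        q = i / (n + 1)
    elif convention == "naive":
        q = i / n
    elif convention == "hazen":
        q = (i - 0.5) / n
    else:
        raise ValueError(f"unknown plotting position {convention!r}")
    return q


def qq_curve(
    pvalues: np.ndarray,
    stratum_name: str = "",
    plotting_position: PlottingPosition = "weibull",
) -> QQCurve:
    """Q-Q curve of -log10 p against uniform-null theoretical quantiles.

    The expected quantile of rank i (of n, ascending p) is -log10 of the
    plotting position; the Weibull position i/(n+1) is the default because it
    keeps the extreme rank finite. Observed values are the sorted -log10 p.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty stratum")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    n = p.size
    # rank i counted from the smallest expected quantile: positions of the
    # LARGEST p first, so reverse to pair smallest-with-smallest.
    q = _plotting_positions(n, plotting_position)
    expected = np.sort(-np.log10(q))
    observed = np.sort(-np.log10(np.sort(p)[::-1]))
    return QQCurve(stratum_name=stratum_name, expected=expected, observed=observed, n=n)


def stratified_qq(
    panel: SnpPanel,
    masks: Sequence[AnnotationMask] | None = None,
    plotting_position: PlottingPosition = "weibull",
    baseline_name: str = "all_snps",
) -> list[QQCurve]:
    """One Q-Q curve per annotation stratum plus an all-SNPs baseline.

    Empty strata are skipped with a warning rather than raising, so a run
    over many compendia degrades gracefully.
    """
    import logging

    if masks is None:
        masks = list(panel.masks.values())
    curves = [qq_curve(panel.pvalues, baseline_name, plotting_position)]
    for m in masks:
        if m.n_members == 0:
            logging.getLogger(__name__).warning(
                "stratum %r is empty; skipped", m.compendium_name
            )
            continue
        curves.append(
            qq_curve(panel.pvalues[m.member], m.compendium_name, plotting_position)
        )
    return curves


def qq_table(curves: Sequence[QQCurve]) -> pd.DataFrame:
    """Long-format TSV-ready table: stratum, rank, expected, observed."""
    frames = [
        pd.DataFrame(
            {
                "stratum": c.stratum_name,
                "rank": np.arange(1, c.n + 1),
                "expected_neglog10": c.expected,
                "observed_neglog10": c.observed,
            }
        )
        for c in curves
    ]
    return pd.concat(frames, ignore_index=True)


def plot_qq(curves: Sequence[QQCurve], path, max_points: int = 100_000):
    """Render curves to one figure; down-sample dense low ranks above
    ``max_points`` but always keep the largest 1000 -log10 p points."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    top = 0.0
    for c in curves:
        exp, obs = c.expected, c.observed
        if c.n > max_points:
            keep_tail = 1000
            head = np.linspace(0, c.n - keep_tail - 1, max_points - keep_tail).astype(int)
            idx = np.unique(np.concatenate([head, np.arange(c.n - keep_tail, c.n)]))
            exp, obs = exp[idx], obs[idx]
        ax.plot(exp, obs, lw=1, label=f"{c.stratum_name} (n={c.n})")
        top = max(top, exp.max(), obs.max())
    ax.plot([0, top], [0, top], "k--", lw=0.8, label="null")
    ax.set_xlabel("expected -log10 p")
    ax.set_ylabel("observed -log10 p")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def _odds_ratio(k: int, n_in: int, K: int, N: int) -> float:
    """Sample odds ratio with Haldane-Anscombe 0.5 correction on zero cells."""
    a, b = k, n_in - k
    c, d = K - k, (N - n_in) - (K - k)
    if min(a, b, c, d) < 0:
        raise ValueError("inconsistent 2x2 table")
    if 0 in (a, b, c, d):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def fisher_enrichment(
    panel: SnpPanel,
    mask: AnnotationMask,
    neglog10_threshold: float = GENOME_WIDE_NEGLOG10,
    background: AnnotationMask | np.ndarray | None = None,
    alternative: Literal["greater", "two-sided"] = "greater",
) -> FisherResult:
    """Hypergeometric over-representation of genome-wide-significant SNPs
    inside one annotation.

    A SNP is significant iff -log10(p) strictly exceeds ``neglog10_threshold``.
    With the default whole-panel background the 2x2 universe is the panel;
    passing a control mask (e.g. from :func:`snpenrich.matching.match_controls`)
    restricts the universe to annotation members plus controls, so enrichment
    is judged against MAF/LD-matched SNPs instead of the whole array.

    The upper-tail p-value is P[X >= k] for X ~ Hypergeom(N, K, n_in).
    """
    sig = -np.log10(panel.pvalues) > neglog10_threshold
    member = mask.member
    if background is None:
        universe = np.ones(len(panel), dtype=bool)
        bg_name = "whole_panel"
    else:
        ctrl = background.member if isinstance(background, AnnotationMask) else np.asarray(background, bool)
        universe = member | ctrl
        bg_name = "control_set"
    N = int(universe.sum())
    K = int((sig & universe).sum())
    n_in = int((member & universe).sum())
    k = int((sig & member & universe).sum())
    if n_in == 0 or N == 0:
        return FisherResult(mask.compendium_name, k, n_in, K, N,
                            odds_ratio=float("nan"), p_hyper=1.0,
                            degenerate=True, background=bg_name)
    # upper tail including k: sf(k-1)
    p_upper = float(hypergeom.sf(k - 1, N, K, n_in))
    if alternative == "greater":
        p = p_upper
    else:
        from scipy.stats import fisher_exact

        table = [[k, n_in - k], [K - k, (N - n_in) - (K - k)]]
        p = float(fisher_exact(table, alternative="two-sided")[1])
    p = min(1.0, max(p, 0.0))
    degenerate = n_in == N or K in (0, N)
    if k == n_in == K == N:
        odds = float("inf")
    else:
        odds = _odds_ratio(k, n_in, K, N)
    return FisherResult(mask.compendium_name, k, n_in, K, N,
                        odds_ratio=odds, p_hyper=p if p > 0 else np.nextafter(0, 1),
                        degenerate=degenerate, background=bg_name)


def bonferroni(results: Sequence[FisherResult]) -> list[FisherResult]:
    """Bonferroni-adjust over the number of annotations tested; order kept."""
    m = len(results)
    if m < 1:
        raise ValueError("need at least one result")
    return [replace(r, p_bonferroni=min(1.0, r.p_hyper * m)) for r in results]


def fisher_table(results: Sequence[FisherResult]) -> pd.DataFrame:
    """TSV-ready table of the 2x2 counts and test outcomes."""
    return pd.DataFrame(
        [
            {
                "annotation": r.annotation_name,
                "background": r.background,
                "N": r.N,
                "K": r.K,
                "n_in": r.n_in,
                "k": r.k,
                "odds_ratio": r.odds_ratio,
                "p_hyper": r.p_hyper,
                "p_bonferroni": r.p_bonferroni,
                "degenerate": r.degenerate,
            }
            for r in results
        ]
    )
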