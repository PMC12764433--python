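"""Cohort statistics: gene-set burdens, rank tests, 2x2 tables, growth fits.

These are the group-level analyses run over per-sample neoantigen burdens
and transplantation phenotypes: two-sided Mann-Whitney U comparisons of
gene-set strong-neoantigen counts between host genotypes, odds ratios and
one-tailed chi-square on regressor/progressor tables, Fisher's exact test
on region-gain tables, and the exponential (Malthusian) growth-rate
classification of transplanted tumor lines.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .neoantigen import PeptideCandidate


@dataclass
class GroupComparison:
    group_labels: tuple[str, str]
    n: tuple[int, int]
    u_statistic: float
    p_value: float
    method: str  # "exact" or "normal_approx"


@dataclass
class ContingencyResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    ci_low: float
    ci_high: float
    chi2: float
    p_one_tailed: float
    p_two_tailed: float
    p_fisher: float
    haldane_corrected: bool = False


@dataclass
class GrowthFit:
    times: np.ndarray
    volumes: np.ndarray
    rate_r: float
    classification: str  # progressor / regressor / unknown


# ---------------------------------------------------------------------------


def geneset_burden(
    candidates: list[PeptideCandidate], gene_set=None
) -> int:
    """Strong-neoantigen burden restricted to a gene set.

    Counts distinct source variants having at least one strong peptide in
    a gene belonging to the set (all genes when ``gene_set`` is None).
    """
    hits = set()
    for c in candidates:
        if c.is_strong and (gene_set is None or c.gene_id in gene_set):
            hits.add(c.source_variant)
    return len(hits)


def mann_whitney(
    group_a, group_b, alternative: str = "two-sided"
) -> GroupComparison:
    """Mann-Whitney U test between two groups of per-sample statistics.

    Exact p by enumeration of rank arrangements when n1+n2 <= 20 and the
    pooled values are tie-free; otherwise the normal approximation with
    tie and continuity corrections.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        # degenerate: identical groups carry no rank information
        return GroupComparison(
            group_labels=("a", "b"),
            n=(int(a.size), int(b.size)),
            u_statistic=a.size * b.size / 2.0,
            p_value=1.0,
            method="exact",
        )
    tie_free = np.unique(pooled).size == pooled.size
    if a.size + b.size <= 20 and tie_free:
        method = "exact"
        res = sps.mannwhitneyu(a, b, alternative=alternative, method="exact")
    else:
        method = "normal_approx"
        res = sps.mannwhitneyu(
            a, b, alternative=alternative, method="asymptotic", use_continuity=True
        )
    return GroupComparison(
        group_labels=("a", "b"),
        n=(int(a.size), int(b.size)),
        u_statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method=method,
    )


def contingency_2x2(
    a: int, b: int, c: int, d: int, direction: str = "greater"
) -> ContingencyResult:
    """Odds ratio, chi-square and Fisher statistics for a 2x2 table.

    Table layout is ``[[a, b], [c, d]]`` with the odds ratio (a*d)/(b*c).
    The one-tailed chi-square p is half the two-tailed Pearson p (no
    continuity correction) when the observed odds ratio lies in the
    pre-stated ``direction`` ("greater": OR > 1), else its complement.
    A zero cell triggers the Haldane-Anscombe +0.5 correction for the OR
    and its Woolf CI, flagged in the result.
    """
    cells = (a, b, c, d)
    if any(x < 0 for x in cells):
        raise ValueError("contingency cells must be non-negative")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    haldane = 0 in cells
    aa, bb, cc, dd = ((x + 0.5 for x in cells) if haldane else cells)
    odds = (aa * dd) / (bb * cc)
    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    ci_low = math.exp(math.log(odds) - 1.959963984540054 * se)
    ci_high = math.exp(math.log(odds) + 1.959963984540054 * se)

    table = np.array([[a, b], [c, d]], dtype=float)
    if table.sum() == 0 or (table.sum(0) == 0).any() or (table.sum(1) == 0).any():
        chi2, p_two = float("nan"), float("nan")
    else:
        chi2, p_two, _, _ = sps.chi2_contingency(table, correction=False)
        chi2, p_two = float(chi2), float(p_two)
    observed_greater = odds > 1
    in_direction = observed_greater == (direction == "greater")
    p_one = p_two / 2 if in_direction else 1 - p_two / 2
    _, p_fisher = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return ContingencyResult(
        table=((a, b), (c, d)),
        odds_ratio=float(odds),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        chi2=chi2,
        p_one_tailed=float(p_one),
        p_two_tailed=p_two,
        p_fisher=float(p_fisher),
        haldane_corrected=haldane,
    )


def percent(k: int, n: int) -> int:
    """Integer percentage, rounded half-up (report formatting parity)."""
    if n == 0:
        return 0
    return int(math.floor(100.0 * k / n + 0.5))


def tumor_volume(l_mm: float, w_mm: float) -> float:
    """Caliper tumor volume 0.5 x l x w^2 in mm^3 (l = longest diameter)."""
    if l_mm <= 0 or w_mm <= 0:
        raise ValueError("diameters must be positive")
    if w_mm > l_mm:
        warnings.warn("width exceeds length; swapping diameters")
        l_mm, w_mm = w_mm, l_mm
    return 0.5 * l_mm * w_mm**2


def fit_malthusian(times, volumes) -> GrowthFit:
    """Exponential (Malthusian) growth fit: slope of ln(volume) vs time.

    Only positive volumes enter the fit; fewer than three leaves the
    classification ``unknown``.  A non-positive rate classifies the line
    as a regressor.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(volumes, dtype=float)
    mask = v > 0
    if mask.sum() < 3:
        return GrowthFit(times=t, volumes=v, rate_r=float("nan"), classification="unknown")
    slope = float(np.polyfit(t[mask], np.log(v[mask]), 1)[0])
    if abs(slope) < 1e-12:  # constant volumes up to float noise
        slope = 0.0
    cls = "regressor" if slope <= 0 else "progressor"
    return GrowthFit(times=t, volumes=v, rate_r=slope, classification=cls)


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p)
    adj = np.empty(n)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (n - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj
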