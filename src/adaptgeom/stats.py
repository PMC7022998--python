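"""Nonparametric association between GAPI and performance.

Spearman rank correlation (exact permutation p at small n, t-approximation
otherwise), Blomqvist's β (the medial correlation coefficient, with an exact
binomial p), step-down Holm adjustment for the multiple-comparison families,
and Welch's unequal-variance t-test for the group comparison. Both
correlation statistics depend on the data only through ranks/median sides,
so they are invariant under strictly increasing transformations of either
variable — the property that makes them appropriate for a ratio-scale index
like GAPI against monotone performance outcomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .load_metrics import assign_quartiles

EXACT_PERMUTATION_MAX_N = 9


@dataclass(frozen=True)
class CorrelationResult:
    statistic: float
    p_raw: float
    n: int
    method: str
    p_adjusted: float | None = None


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------


def _spearman_stat(rx: np.ndarray, ry: np.ndarray) -> float:
    # Pearson correlation of the (possibly tied, average) ranks
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(np.sum(rx**2) * np.sum(ry**2)))
    if denom == 0.0:
        return math.nan
    return float(np.sum(rx * ry) / denom)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation with average ranks for ties.

    The two-sided p-value is exact (full enumeration of the n! orderings of
    the y-ranks) for n <= 9, and the usual t-approximation with n - 2
    degrees of freedom above that. A constant input has no defined rank
    correlation and yields a nan statistic.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y) or n < 4:
        raise ValueError("need paired samples with n >= 4")
    rx = sps.rankdata(x, method="average")
    ry = sps.rankdata(y, method="average")
    rho = _spearman_stat(rx, ry)
    if math.isnan(rho):
        return CorrelationResult(math.nan, math.nan, n, "spearman")
    if n <= EXACT_PERMUTATION_MAX_N:
        # vectorised full enumeration of the n! orderings of the y-ranks
        perms = np.array(list(permutations(ry)))
        rxc = rx - rx.mean()
        pc = perms - perms.mean(axis=1, keepdims=True)
        denom = np.sqrt(np.sum(rxc**2) * np.sum(pc**2, axis=1))
        rhos = (pc @ rxc) / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        t = rho * math.sqrt((n - 2) / max(1.0 - rho**2, 1e-15))
        p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return CorrelationResult(rho, min(p, 1.0), n, "spearman")


# ---------------------------------------------------------------------------
# Blomqvist beta
# ---------------------------------------------------------------------------


def blomqvist_beta(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Blomqvist's medial correlation coefficient with an exact binomial p.

    With sample medians (x~, y~), points strictly off both medians fall into
    four quadrants (numbered counter-clockwise from upper-right); β is
    (concordant - discordant) / total. Points on a median are excluded —
    Blomqvist's original treatment, which any odd-n sample forces at least
    once. Under independence the concordant count is Binomial(m, 1/2); the
    p-value is the exact two-sided binomial test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y) or n < 4:
        raise ValueError("need paired samples with n >= 4")
    xm = float(np.median(x))
    ym = float(np.median(y))
    off = (x != xm) & (y != ym)
    if not off.any():
        return CorrelationResult(math.nan, math.nan, n, "blomqvist")
    dx = x[off] > xm
    dy = y[off] > ym
    concordant = int(np.count_nonzero(dx == dy))  # quadrants 1 and 3
    m = int(off.sum())
    beta = (2 * concordant - m) / m
    p = float(sps.binomtest(concordant, m, 0.5, alternative="two-sided").pvalue)
    return CorrelationResult(beta, p, n, "blomqvist")


# ---------------------------------------------------------------------------
# Multiple testing and group comparison
# ---------------------------------------------------------------------------


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Step-down Holm-adjusted p-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def welch_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test: (t, Welch-Satterthwaite df, 2-sided p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    if se2 == 0.0:
        return 0.0, float(na + nb - 2), 1.0
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = float(2.0 * sps.t.sf(abs(t), df=df))
    return float(t), float(df), p


# ---------------------------------------------------------------------------
# GAPI vs performance grid
# ---------------------------------------------------------------------------


def correlate_gapi(
    gapi_by_combo: dict[int, Sequence[float]],
    best_pbt: Sequence[float],
    *,
    round_decimals: int | None = 2,
) -> pd.DataFrame:
    """Correlation grid of per-combination GAPI against performance.

    For every combination, Spearman and Blomqvist β are computed against the
    athletes' best %PBT and against its quartile band. Holm correction is
    applied within each (test, outcome) family across the combinations
    (m = number of combinations). Returns a tidy frame with columns
    combination, test, outcome, statistic, p_raw, p_holm, n; statistics and
    p-values rounded to ``round_decimals`` unless ``None``.
    """
    best_pbt = np.asarray(best_pbt, dtype=float)
    n = len(best_pbt)
    if n < 4:
        raise ValueError("need at least 4 athletes")
    for combo, g in gapi_by_combo.items():
        if len(g) != n:
            raise ValueError(f"combination {combo}: GAPI vector length != {n}")
    quart = assign_quartiles(best_pbt).astype(float)
    outcomes = {"quartile": quart, "best_pbt": best_pbt}
    tests = {"spearman": spearman_rho, "blomqvist": blomqvist_beta}

    rows = []
    for test_name, fn in tests.items():
        for out_name, out_vec in outcomes.items():
            family = []
            for combo in sorted(gapi_by_combo):
                res = fn(gapi_by_combo[combo], out_vec)
                family.append((combo, res))
            adj = holm_adjust([r.p_raw for _, r in family])
            for (combo, res), p_holm in zip(family, adj):
                rows.append(
                    {
                        "combination": combo,
                        "test": test_name,
                        "outcome": out_name,
                        "statistic": res.statistic,
                        "p_raw": res.p_raw,
                        "p_holm": float(p_holm),
                        "n": res.n,
                    }
                )
    df = pd.DataFrame(rows)
    if round_decimals is not None:
        for col in ("statistic", "p_raw", "p_holm"):
            df[col] = df[col].round(round_decimals)
    return df


def format_correlation_table(df: pd.DataFrame) -> str:
    """Human-readable grid: one block per combination, tests as rows."""
    lines = []
    header = f"{'':10s}{'test':12s}{'outcome':10s}{'stat':>8s}{'p':>8s}{'p_holm':>8s}"
    lines.append(header)
    for combo in sorted(df["combination"].unique()):
        sub = df[df["combination"] == combo]
        lines.append(f"GAPI_{combo}")
        for _, r in sub.iterrows():
            lines.append(
                f"{'':10s}{r['test']:12s}{r['outcome']:10s}"
                f"{r['statistic']:8.2f}{r['p_raw']:8.2f}{r['p_holm']:8.2f}"
            )
    return "\n".join(lines)
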