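"""Correlation between per-male DMC burden and sperm-quality metrics.

"DMC number" per male is reconstructed as the number of cohort-level DMCs at
which the male is informative (possesses the paired site) and shows a
nonzero methylation change; alternatives (all informative DMCs, or only
direction-concordant ones) are available via ``mode``. Rank (Spearman)
correlation is used, with a permutation p-value: exhaustive over all n!
pairings when n <= 8, seeded Monte Carlo otherwise.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .differential import DMCResult

QUALITY_METRICS = ("membrane", "mito", "motility", "fert_norm")


@dataclass
class CorrelationResult:
    cryoprotectant: str
    metric: str
    n_males: int
    rho: float
    p_value: float
    flag: str = ""       # "degenerate" when a vector is constant


def per_male_dmc_count(dmcs: Iterable[DMCResult], male: int,
                       mode: str = "nonzero") -> int:
    """Number of called DMCs attributable to one male.

    mode "nonzero": male informative and its delta != 0 (default);
    mode "informative": male merely possesses the paired site;
    mode "concordant": male's delta sign matches the DMC's majority class.
    """
    n = 0
    for r in dmcs:
        if male not in r.deltas:
            continue
        d = r.deltas[male]
        if mode == "informative":
            n += 1
        elif mode == "nonzero":
            n += d != 0
        elif mode == "concordant":
            if r.trend_class == "hyper":
                n += d > 0
            elif r.trend_class == "hypo":
                n += d < 0
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return n


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x)  # midranks for ties
    ry = stats.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def _rho_against_permutations(rx: np.ndarray, ry_perms: np.ndarray) -> np.ndarray:
    """Pearson correlation of centered rank vector rx with each row of ry_perms."""
    cx = rx - rx.mean()
    cy = ry_perms - ry_perms.mean(axis=1, keepdims=True)
    num = cy @ cx
    den = np.sqrt((cx @ cx) * (cy * cy).sum(axis=1))
    return num / den


def correlate(dmc_counts: Mapping[int, int], quality: Mapping[int, float],
              cryoprotectant: str = "", metric: str = "",
              n_perm: int = 20_000, seed: int = 0,
              exact_max_n: int = 8) -> CorrelationResult:
    """Spearman correlation of per-male DMC counts against one quality metric.

    Two-sided permutation p on |rho|: exhaustive enumeration of all n!
    pairings when n <= exact_max_n, otherwise seeded Monte Carlo with the
    observed pairing counted among the draws. Constant input is flagged
    degenerate (rho undefined).
    """
    males = sorted(set(dmc_counts) & set(quality))
    if len(males) < 3:
        raise ValueError("need >= 3 paired males")
    x = np.array([dmc_counts[m] for m in males], dtype=float)
    y = np.array([quality[m] for m in males], dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationResult(cryoprotectant, metric, len(males),
                                 float("nan"), float("nan"), flag="degenerate")
    rho = _spearman_rho(x, y)
    n = len(males)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if n <= exact_max_n:
        perms = np.array(list(itertools.permutations(range(n))))
        rhos = _rho_against_permutations(rx, ry[perms])
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(n) for _ in range(n_perm)])
        rhos = _rho_against_permutations(rx, ry[perms])
        count = 1 + int(np.sum(np.abs(rhos) >= abs(rho) - 1e-12))  # observed included
        p = count / (n_perm + 1)
    return CorrelationResult(cryoprotectant, metric, n, rho, float(p))


def correlate_all(dmcs_by_cp: Mapping[str, Sequence[DMCResult]],
                  quality_table: pd.DataFrame, mode: str = "nonzero",
                  seed: int = 0) -> pd.DataFrame:
    """Every cryoprotectant x quality-metric correlation, as a tidy frame.

    Degenerate pairs (e.g. glycerol fertilization when all values are zero)
    are kept with a "degenerate" flag and NaN statistics rather than dropped.
    """
    rows: List[CorrelationResult] = []
    for cp, dmcs in sorted(dmcs_by_cp.items()):
        sub = quality_table[quality_table["condition"] == cp]
        males = sorted(sub["male_id"].unique())
        counts = {m: per_male_dmc_count(dmcs, m, mode=mode) for m in males}
        for metric in QUALITY_METRICS:
            qual = dict(zip(sub["male_id"], sub[metric]))
            try:
                res = correlate(counts, qual, cryoprotectant=cp, metric=metric,
                                seed=seed)
            except ValueError:
                continue
            rows.append(res)
    return pd.DataFrame([r.__dict__ for r in rows])
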