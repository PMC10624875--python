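"""Paired differential-methylation calling between fresh and cryopreserved sperm.

The design is paired within male: for each male, only cytosines read (depth
>= 1) in both the fresh and the treated sample of that male enter the
comparison, and no information is borrowed from neighboring cytosines. Sites
present in at least ``min_males`` males (default 6 of 12) are tested.

The test is a self-contained paired Wald test on the variance-stabilizing
arcsine-square-root scale. Per male m with fresh counts (k_f, n_f) and
treated counts (k_t, n_t):

    p_hat = (k + 0.5) / (n + 1)                (shrunk toward 1/2)
    y     = arcsin(sqrt(p_hat))
    d_m   = y_treated - y_fresh
    v_m   = 1/(4 (n_t + 1)) + 1/(4 (n_f + 1))  (delta-method variance)

    D = sum(d_m / v_m) / sum(1 / v_m)          (inverse-variance pooling)
    z = D / sqrt(1 / sum(1 / v_m)),   p = 2 Phi(-|z|)

The pseudocounts keep the transform and its variance finite at ratio 0/1
even at depth 1, which the N>=1 inclusion rule requires. Called DMCs
(p < alpha, default 0.001, no multiplicity correction by default) are
classified hyper-/hypomethylated when more than half of the males possessing
the site move in the same direction, else unclassified.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .types import SampleMethylome, SiteKey

#: per-male count quadruple: (n_meth_fresh, n_unmeth_fresh, n_meth_treated, n_unmeth_treated)
CountPair = Tuple[int, int, int, int]


@dataclass
class PairedSiteTable:
    """All paired cytosines for one cryoprotectant across males."""

    cryoprotectant: str
    sites: Dict[SiteKey, Dict[int, CountPair]] = field(default_factory=dict)

    def n_males_with_site(self, site: SiteKey) -> int:
        return len(self.sites.get(site, {}))

    def __len__(self) -> int:
        return len(self.sites)


@dataclass
class DMCResult:
    site: SiteKey
    statistic: float
    p_value: float
    deltas: Dict[int, float]     # male -> treated ratio - fresh ratio
    trend_class: str             # hyper | hypo | unclassified
    n_males: int


def extract_paired(fresh: SampleMethylome, treated: SampleMethylome
                   ) -> Dict[SiteKey, CountPair]:
    """Sites read (depth >= 1) in both samples of one male, with both count pairs."""
    if fresh.male_id != treated.male_id:
        raise ValueError(f"male mismatch: {fresh.male_id} vs {treated.male_id}")
    out: Dict[SiteKey, CountPair] = {}
    small, big = (fresh.records, treated.records) \
        if len(fresh.records) <= len(treated.records) else (treated.records, fresh.records)
    for key in small:
        if key in big:
            f, t = fresh.records[key], treated.records[key]
            out[key] = (f.n_meth, f.n_unmeth, t.n_meth, t.n_unmeth)
    return out


def build_paired_table(fresh_by_male: Mapping[int, SampleMethylome],
                       treated_by_male: Mapping[int, SampleMethylome],
                       cryoprotectant: str) -> PairedSiteTable:
    """Assemble the cross-male paired-site table for one cryoprotectant."""
    table = PairedSiteTable(cryoprotectant=cryoprotectant)
    for male, fresh in fresh_by_male.items():
        if male not in treated_by_male:
            continue
        for key, quad in extract_paired(fresh, treated_by_male[male]).items():
            table.sites.setdefault(key, {})[male] = quad
    return table


def sharing_distribution(table: PairedSiteTable, n_males: int,
                         min_males: int = 6) -> pd.DataFrame:
    """Distribution of distinct paired sites by the number of males sharing them.

    Returns one row per sharing level 1..n_males with counts and percents of
    total distinct paired positions, plus the cumulative percent at
    >= min_males in ``df.attrs['cum_pct_min_males']``.
    """
    counts = np.zeros(n_males + 1, dtype=int)
    for males in table.sites.values():
        counts[len(males)] += 1
    total = counts.sum()
    df = pd.DataFrame({"n_males": np.arange(1, n_males + 1),
                       "n_sites": counts[1:],
                       "percent": 100.0 * counts[1:] / total if total else 0.0})
    df.attrs["cum_pct_min_males"] = float(df.loc[df.n_males >= min_males, "percent"].sum())
    return df


def select_shared_sites(table: PairedSiteTable, min_males: int = 6,
                        n_males: int = 12) -> Set[SiteKey]:
    """Paired sites present in at least ``min_males`` males (inclusive bound)."""
    if min_males > n_males:
        raise ValueError("min_males exceeds the number of males")
    return {site for site, males in table.sites.items() if len(males) >= min_males}


# ---------------------------------------------------------------------------
# the paired test
# ---------------------------------------------------------------------------

def _arcsine(k: np.ndarray, n: np.ndarray) -> np.ndarray:
    return np.arcsin(np.sqrt((k + 0.5) / (n + 1.0)))


def paired_dm_test(pairs: Mapping[int, CountPair]) -> Tuple[float, float]:
    """Paired arcsine Wald test over one site's per-male count quadruples.

    Returns (z, two-sided p). With every male showing identical fresh and
    treated counts the statistic is exactly 0 and p = 1.
    """
    quads = np.array(list(pairs.values()), dtype=float)
    kf, nf = quads[:, 0], quads[:, 0] + quads[:, 1]
    kt, nt = quads[:, 2], quads[:, 2] + quads[:, 3]
    d = _arcsine(kt, nt) - _arcsine(kf, nf)
    v = 1.0 / (4.0 * (nt + 1.0)) + 1.0 / (4.0 * (nf + 1.0))
    w = 1.0 / v
    big_d = float(np.sum(d * w) / np.sum(w))
    z = big_d / math.sqrt(1.0 / float(np.sum(w)))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def classify_dmc(deltas: Mapping[int, float]) -> str:
    """Majority-trend class over the males possessing the paired site.

    The denominator is the number of informative males (those with the site),
    not the full cohort; a male with delta exactly 0 counts toward neither
    direction. A class is assigned only when its count strictly exceeds half
    the denominator.
    """
    values = list(deltas.values())
    n = len(values)
    n_hyper = sum(1 for d in values if d > 0)
    n_hypo = sum(1 for d in values if d < 0)
    if n_hyper > n / 2:
        return "hyper"
    if n_hypo > n / 2:
        return "hypo"
    return "unclassified"


def run_paired_tests(table: PairedSiteTable, min_males: int = 6,
                     n_males: int = 12) -> List[DMCResult]:
    """Run the paired test on every site shared by >= min_males males.

    Vectorized over (site, male) rows; per-site deltas use the raw ratios
    (k/n), the test uses the shrunk arcsine scale.
    """
    selected = sorted(select_shared_sites(table, min_males, n_males))
    site_ids, males, quads = [], [], []
    for i, site in enumerate(selected):
        for male, quad in sorted(table.sites[site].items()):
            site_ids.append(i)
            males.append(male)
            quads.append(quad)
    if not selected:
        return []
    site_ids = np.array(site_ids)
    q = np.array(quads, dtype=float)
    kf, nf = q[:, 0], q[:, 0] + q[:, 1]
    kt, nt = q[:, 2], q[:, 2] + q[:, 3]
    d = _arcsine(kt, nt) - _arcsine(kf, nf)
    v = 1.0 / (4.0 * (nt + 1.0)) + 1.0 / (4.0 * (nf + 1.0))
    w = 1.0 / v
    n_sites = len(selected)
    sum_w = np.bincount(site_ids, weights=w, minlength=n_sites)
    sum_dw = np.bincount(site_ids, weights=d * w, minlength=n_sites)
    z = (sum_dw / sum_w) / np.sqrt(1.0 / sum_w)
    p = 2.0 * stats.norm.sf(np.abs(z))
    delta = kt / nt - kf / nf
    results: List[DMCResult] = []
    row = 0
    for i, site in enumerate(selected):
        n_here = len(table.sites[site])
        deltas = {males[row + j]: float(delta[row + j]) for j in range(n_here)}
        row += n_here
        results.append(DMCResult(site=site, statistic=float(z[i]),
                                 p_value=float(p[i]), deltas=deltas,
                                 trend_class=classify_dmc(deltas),
                                 n_males=n_here))
    return results


def call_dmcs(results: Iterable[DMCResult], alpha: float = 0.001,
              fdr: bool = False) -> List[DMCResult]:
    """Select DMCs at p < alpha (strict); optional Benjamini-Hochberg mode."""
    results = list(results)
    if not results:
        return []
    if fdr:
        p = np.array([r.p_value for r in results])
        q = stats.false_discovery_control(p, method="bh")
        return [r for r, qi in zip(results, q) if qi < alpha]
    return [r for r in results if r.p_value < alpha]


def results_to_frame(results: Iterable[DMCResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        chrom, pos, strand = r.site
        rows.append({"chrom": chrom, "pos": pos, "strand": strand,
                     "n_males": r.n_males, "statistic": r.statistic,
                     "p_value": r.p_value, "trend_class": r.trend_class,
                     "deltas": ";".join(f"{m}:{d:+.4g}"
                                        for m, d in sorted(r.deltas.items()))})
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "n_males",
                                       "statistic", "p_value", "trend_class", "deltas"])


def overlap_counts(dmc_sets: Mapping[str, Set[SiteKey]]) -> Dict[Tuple[str, ...], int]:
    """Exclusive Venn partition of three DMC site sets.

    Keys are sorted tuples of set names; e.g. ("DMSO",) is DMSO-only,
    ("DMSO", "MeOH", "glycerol") the triple intersection.
    """
    names = sorted(dmc_sets)
    if len(names) != 3:
        raise ValueError("expected exactly three sets")
    partition: Dict[Tuple[str, ...], int] = {}
    universe = set().union(*dmc_sets.values())
    for site in universe:
        members = tuple(sorted(n for n in names if site in dmc_sets[n]))
        partition[members] = partition.get(members, 0) + 1
    # make every region explicit, including empty ones
    from itertools import combinations
    for k in range(1, 4):
        for combo in combinations(names, k):
            partition.setdefault(tuple(sorted(combo)), 0)
    return partition
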