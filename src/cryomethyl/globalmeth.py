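"""Global methylation summaries: per-sample means, ratio histogram, PCA,
and nonparametric condition comparisons.

The analysis unit everywhere is the per-cytosine methylation ratio
(methylated reads / total reads at one strand-resolved cytosine); global
means are unweighted means of these ratios, not read-weighted pools.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .types import SampleMethylome

N_BINS = 20


def global_mean_methylation(sample: SampleMethylome, min_depth: int = 10) -> float:
    """Global methylation percent: 100 x mean ratio over depth>=min_depth cytosines."""
    ratios = [r.ratio for r in sample if r.depth >= min_depth]
    if not ratios:
        raise ValueError("no record passes the depth filter")
    return 100.0 * float(np.mean(ratios))


@dataclass
class RatioHistogram:
    """20 methylation-ratio classes of width 0.05 over [0, 1].

    Bins are left-closed ([0.00, 0.05), ...); the last class [0.95, 1.00] is
    closed on both sides so fully methylated cytosines land in it.
    """

    counts: np.ndarray          # length 20
    min_depth: int

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    @property
    def percents(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            return np.zeros(N_BINS)
        return 100.0 * self.counts / total

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, N_BINS + 1)

    def top_bin_percent(self) -> float:
        """Percent of qualifying cytosines with ratio in [0.95, 1.00]."""
        return float(self.percents[-1])

    def bottom_bin_percent(self) -> float:
        return float(self.percents[0])

    def to_frame(self) -> pd.DataFrame:
        e = self.edges
        return pd.DataFrame({"bin_low": e[:-1], "bin_high": e[1:],
                             "count": self.counts, "percent": self.percents})


def bin_ratios(samples, min_depth: int = 10) -> RatioHistogram:
    """Histogram of methylation ratios over all qualifying cytosine records.

    ``samples`` is one SampleMethylome or an iterable of them (records are
    pooled; the same genomic site in two samples counts twice, as in a
    per-condition frequency plot).
    """
    if isinstance(samples, SampleMethylome):
        samples = [samples]
    ratios = np.array([rec.ratio for s in samples for rec in s
                       if rec.depth >= min_depth])
    counts = np.zeros(N_BINS, dtype=int)
    if ratios.size:
        idx = np.minimum((ratios * N_BINS).astype(int), N_BINS - 1)
        np.add.at(counts, idx, 1)
    return RatioHistogram(counts=counts, min_depth=min_depth)


def pca_samples(samples: Sequence[SampleMethylome], min_depth: int = 1,
                ) -> Tuple[pd.DataFrame, np.ndarray]:
    """Ordination of samples by the ratios of their shared cytosines.

    Builds the complete-case matrix (sites with depth >= min_depth in every
    sample), centers per site, and takes the first two principal components
    by SVD. Component signs are fixed by convention: the loading with the
    largest magnitude on each component is made positive. Returns a frame
    (male_id, condition, pc1, pc2) and the explained-variance fractions.
    """
    if len(samples) < 3:
        raise ValueError("need at least 3 samples")
    shared = None
    for s in samples:
        keys = {k for k, r in s.records.items() if r.depth >= min_depth}
        shared = keys if shared is None else shared & keys
    if shared is None or len(shared) < 2:
        raise ValueError("fewer than 2 sites shared by all samples")
    order = sorted(shared)
    mat = np.array([[s.records[k].ratio for k in order] for s in samples])
    mat = mat - mat.mean(axis=0, keepdims=True)
    u, sv, vt = np.linalg.svd(mat, full_matrices=False)
    coords = u * sv  # sample scores
    for j in range(min(2, coords.shape[1])):
        i = np.argmax(np.abs(vt[j]))
        if vt[j, i] < 0:
            coords[:, j] *= -1.0
    var = sv ** 2
    explained = var / var.sum() if var.sum() > 0 else var
    ncomp = min(2, coords.shape[1])
    frame = pd.DataFrame({
        "male_id": [s.male_id for s in samples],
        "condition": [s.condition for s in samples],
        "pc1": coords[:, 0],
        "pc2": coords[:, 1] if ncomp > 1 else 0.0,
    })
    return frame, explained[:ncomp]


def rank_compare_conditions(values_by_condition: Dict[str, Sequence[float]],
                            alpha: float = 0.05) -> Dict:
    """Kruskal-Wallis omnibus test with Mann-Whitney pairwise follow-up.

    The pairwise rank-sum tests are only run (and reported) as a follow-up;
    degenerate all-equal input yields p = 1.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_condition.items()}
    if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
        raise ValueError("need >=2 groups with n>=2 each")
    flat = np.concatenate(list(groups.values()))
    if np.all(flat == flat[0]):
        omnibus_p = 1.0
    else:
        _, omnibus_p = stats.kruskal(*groups.values())
    pairwise = {}
    names = sorted(groups)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if np.all(groups[a] == groups[a][0]) and np.all(groups[b] == groups[b][0]) \
                    and groups[a][0] == groups[b][0]:
                p = 1.0
            else:
                _, p = stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided")
            pairwise[(a, b)] = float(p)
    return {"omnibus_p": float(omnibus_p),
            "significant": bool(omnibus_p < alpha),
            "pairwise_p": pairwise}
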