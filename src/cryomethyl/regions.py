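"""Region-level aggregation of DMCs and gene-feature annotation.

Two complementary region definitions are implemented:

* **DMRs** — the stringent sliding-window rule: a window of at least 50
  bases holding >= 5 tested CpGs of which >= 75% are DMCs (p < 0.001).
  Windows are anchored at every CpG; overlapping qualifying windows merge.
* **Potentially sensitive regions** — the empirical rule: >= 2 DMCs whose
  consecutive spacing is <= 100 bp (the read length), chained transitively
  (single linkage).

Regions are annotated against every gene feature they overlap — promoter
(5 kb upstream of the TSS), first exon, other exons, first intron, other
introns, 1 kb downstream of the TES — with no precedence: a region may carry
several labels, and is intergenic only when it overlaps none.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .types import GeneModel, SiteKey

FEATURE_NAMES = ("promoter5kb", "exon1", "exons", "intron1", "introns",
                 "downstream1kb", "intergenic")


@dataclass
class DMRCall:
    chrom: str
    start: int          # 1-based closed span of the merged qualifying windows
    end: int
    n_cpg: int          # tested CpGs inside the span
    n_dmc: int          # of which DMCs
    dmc_fraction: float


@dataclass
class SensitiveRegion:
    chrom: str
    start: int          # first member DMC
    end: int            # last member DMC
    dmc_count: Dict[str, int] = field(default_factory=dict)  # per cryoprotectant
    features: List[str] = field(default_factory=list)
    gene_ids: List[str] = field(default_factory=list)

    @property
    def n_dmc_total(self) -> int:
        return sum(self.dmc_count.values())

    def sensitive_to(self, min_dmc: int = 2) -> List[str]:
        """Cryoprotectants for which the region holds >= min_dmc DMCs."""
        return sorted(cp for cp, n in self.dmc_count.items() if n >= min_dmc)


# ---------------------------------------------------------------------------
# DMR sliding-window rule
# ---------------------------------------------------------------------------

def detect_dmrs(p_values: Mapping[SiteKey, float], window: int = 50,
                min_cpg: int = 5, min_frac: float = 0.75,
                alpha: float = 0.001) -> List[DMRCall]:
    """Sliding-window DMR detection over tested CpGs and their p-values.

    A window [p, p + window - 1] anchored at each tested CpG qualifies when it
    holds >= min_cpg CpGs of which a fraction >= min_frac are DMCs
    (p < alpha). Overlapping qualifying windows merge into one DMR spanning
    their union; member statistics are recomputed over the merged span.
    Both strand cytosines of a CpG count individually (they are distinct
    tested sites).
    """
    by_chrom: Dict[str, List[Tuple[int, float]]] = {}
    for (chrom, pos, _strand), p in p_values.items():
        by_chrom.setdefault(chrom, []).append((pos, p))
    dmrs: List[DMRCall] = []
    for chrom, items in sorted(by_chrom.items()):
        items.sort()
        pos = np.array([p for p, _ in items])
        is_dmc = np.array([pv < alpha for _, pv in items])
        qualifying: List[Tuple[int, int]] = []
        for i, anchor in enumerate(pos):
            j = np.searchsorted(pos, anchor + window, side="left")
            n = j - i
            if n >= min_cpg and is_dmc[i:j].sum() >= min_frac * n:
                qualifying.append((int(anchor), int(anchor) + window - 1))
        # merge overlapping/adjacent qualifying windows
        merged: List[List[int]] = []
        for s, e in qualifying:
            if merged and s <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        for s, e in merged:
            inside = (pos >= s) & (pos <= e)
            n_cpg = int(inside.sum())
            n_dmc = int(is_dmc[inside].sum())
            dmrs.append(DMRCall(chrom=chrom, start=s, end=e, n_cpg=n_cpg,
                                n_dmc=n_dmc, dmc_fraction=n_dmc / n_cpg))
    return dmrs


# ---------------------------------------------------------------------------
# sensitive-region clustering
# ---------------------------------------------------------------------------

def _chain_positions(positions: Sequence[int], max_gap: int) -> List[List[int]]:
    """Single-linkage chaining: consecutive positions <= max_gap apart join."""
    clusters: List[List[int]] = []
    for p in sorted(positions):
        if clusters and p - clusters[-1][-1] <= max_gap:
            clusters[-1].append(p)
        else:
            clusters.append([p])
    return clusters


def detect_sensitive_regions(dmcs_by_cp: Mapping[str, Iterable[SiteKey]],
                             max_gap: int = 100) -> List[SensitiveRegion]:
    """Cluster DMCs (pooled over cryoprotectants) into sensitive regions.

    Consecutive DMC positions <= max_gap apart chain transitively; clusters
    with >= 2 DMCs become regions. Per-cryoprotectant DMC counts are kept so
    a region can be tagged sensitive to each agent separately (>= 2 of that
    comparison's DMCs via :meth:`SensitiveRegion.sensitive_to`).
    """
    position_cp: Dict[Tuple[str, int], Dict[str, int]] = {}
    for cp, sites in dmcs_by_cp.items():
        for chrom, pos, _strand in sites:
            position_cp.setdefault((chrom, pos), {}).setdefault(cp, 0)
            position_cp[(chrom, pos)][cp] += 1
    by_chrom: Dict[str, List[int]] = {}
    for chrom, pos in position_cp:
        by_chrom.setdefault(chrom, []).append(pos)
    regions: List[SensitiveRegion] = []
    for chrom in sorted(by_chrom):
        for cluster in _chain_positions(by_chrom[chrom], max_gap):
            n_dmc = sum(sum(position_cp[(chrom, p)].values()) for p in cluster)
            if n_dmc < 2:
                continue
            counts: Dict[str, int] = {}
            for p in cluster:
                for cp, n in position_cp[(chrom, p)].items():
                    counts[cp] = counts.get(cp, 0) + n
            regions.append(SensitiveRegion(chrom=chrom, start=cluster[0],
                                           end=cluster[-1], dmc_count=counts))
    return regions


# ---------------------------------------------------------------------------
# gene-feature annotation
# ---------------------------------------------------------------------------

def feature_intervals(gene: GeneModel, promoter_len: int = 5000,
                      downstream_len: int = 1000,
                      chrom_length: Optional[int] = None
                      ) -> List[Tuple[str, int, int]]:
    """Strand-aware feature intervals of one gene, 1-based closed.

    Promoter is upstream of the TSS, downstream past the TES, both clipped at
    chromosome bounds. Exon/intron order follows transcription, so "exon1" is
    the 5'-most exon on either strand.
    """
    out: List[Tuple[str, int, int]] = []

    def clip(s: int, e: int) -> Optional[Tuple[int, int]]:
        s = max(1, s)
        if chrom_length is not None:
            e = min(e, chrom_length)
        return (s, e) if s <= e else None

    if gene.strand == "+":
        prom = clip(gene.tss - promoter_len, gene.tss - 1)
        down = clip(gene.tes + 1, gene.tes + downstream_len)
    else:
        prom = clip(gene.tss + 1, gene.tss + promoter_len)
        down = clip(gene.tes - downstream_len, gene.tes - 1)
    if prom:
        out.append(("promoter5kb", *prom))
    if down:
        out.append(("downstream1kb", *down))
    for i, (s, e) in enumerate(gene.exons):
        lo, hi = min(s, e), max(s, e)
        out.append(("exon1" if i == 0 else "exons", lo, hi))
    for i, (s, e) in enumerate(gene.introns()):
        lo, hi = min(s, e), max(s, e)
        if lo <= hi:
            out.append(("intron1" if i == 0 else "introns", lo, hi))
    return out


def annotate_region(region: SensitiveRegion, genes: Sequence[GeneModel],
                    promoter_len: int = 5000, downstream_len: int = 1000,
                    chrom_lengths: Optional[Mapping[str, int]] = None
                    ) -> SensitiveRegion:
    """Label a region with every gene feature it overlaps (no precedence).

    Mutates and returns the region: ``features`` holds the sorted label set
    ("intergenic" when nothing overlaps), ``gene_ids`` the contributing genes.
    """
    labels: Set[str] = set()
    gene_ids: Set[str] = set()
    for gene in genes:
        if gene.chrom != region.chrom:
            continue
        clen = chrom_lengths.get(gene.chrom) if chrom_lengths else None
        for name, s, e in feature_intervals(gene, promoter_len, downstream_len, clen):
            if s <= region.end and region.start <= e:
                labels.add(name)
                gene_ids.add(gene.gene_id)
    region.features = sorted(labels) if labels else ["intergenic"]
    region.gene_ids = sorted(gene_ids)
    return region


def regions_to_frame(regions: Iterable[SensitiveRegion],
                     cryoprotectants: Sequence[str] = ("DMSO", "MeOH", "glycerol")
                     ) -> pd.DataFrame:
    rows = []
    for r in regions:
        row = {"chrom": r.chrom, "start": r.start, "end": r.end}
        for cp in cryoprotectants:
            row[f"n_dmc_{cp}"] = r.dmc_count.get(cp, 0)
        row["sensitive_to"] = ";".join(r.sensitive_to())
        row["features"] = ";".join(r.features)
        row["gene_ids"] = ";".join(r.gene_ids)
        rows.append(row)
    cols = ["chrom", "start", "end"] + [f"n_dmc_{cp}" for cp in cryoprotectants] \
        + ["sensitive_to", "features", "gene_ids"]
    return pd.DataFrame(rows, columns=cols)
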