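"""Genome-representation summaries of sequenced CpG cytosines.

RRBS only captures the fragment space around MspI sites, so a central QC
question is how well the identified cytosines represent the genome: the
per-sample and pooled (per-condition union) fraction of all strand-resolved
genomic CpG cytosines, the per-sample median sequencing depth, and the
largest gap between consecutive sequenced cytosines on each chromosome
(homogeneity of coverage).

The genomic denominator counts BOTH cytosines of every CG dinucleotide —
the redundancy between strands is intentionally kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .io import read_fasta
from .types import SampleMethylome, union_site_keys


def count_genomic_cpg_cytosines(fasta) -> int:
    """Total strand-resolved CpG cytosines in a reference: 2 x CG dinucleotides.

    ``fasta`` may be a path or a {name: sequence} dict. Case-insensitive;
    ambiguity codes never form a CpG; dinucleotides do not span contigs.
    """
    seqs = fasta if isinstance(fasta, dict) else read_fasta(fasta)
    if not seqs or all(len(s) == 0 for s in seqs.values()):
        raise ValueError("empty FASTA")
    n_cg = 0
    for seq in seqs.values():
        s = seq.upper()
        n_cg += s.count("CG")
    return 2 * n_cg


def representation_percent(n_identified: int, n_genomic: int) -> float:
    """Percent of genomic CpG cytosines identified in a sample: 100 * n/N."""
    if n_genomic <= 0:
        raise ValueError("n_genomic must be positive")
    if n_identified > n_genomic:
        raise ValueError("identified cytosines exceed the genomic total")
    return round(100.0 * n_identified / n_genomic, 1)


def union_representation(samples: Sequence[SampleMethylome], n_genomic: int,
                         allow_mixed: bool = False) -> Tuple[int, float]:
    """Union of distinct site keys over samples, with its representation percent.

    Meant for the per-condition pooling of all males; by default refuses
    accidental mixing of conditions.
    """
    if not samples:
        raise ValueError("no samples")
    conditions = {s.condition for s in samples}
    if len(conditions) > 1 and not allow_mixed:
        raise ValueError(f"samples span conditions {sorted(conditions)}")
    n = len(union_site_keys(samples))
    return n, representation_percent(n, n_genomic)


def max_consecutive_gap(sample_or_keys) -> Dict[str, Tuple[int, bool]]:
    """Largest gap (bases) between consecutive sequenced cytosines, per chromosome.

    Strand is ignored for ordering: both strands of a CpG are adjacent
    positions. Returns {chrom: (max_gap, flagged)} where ``flagged`` marks
    chromosomes with fewer than 2 sites (gap reported as 0).
    """
    if isinstance(sample_or_keys, SampleMethylome):
        keys = sample_or_keys.records.keys()
    else:
        keys = sample_or_keys
    by_chrom: Dict[str, List[int]] = {}
    for chrom, pos, _strand in keys:
        by_chrom.setdefault(chrom, []).append(pos)
    out: Dict[str, Tuple[int, bool]] = {}
    for chrom, positions in by_chrom.items():
        pos = np.unique(positions)
        if len(pos) < 2:
            out[chrom] = (0, True)
        else:
            out[chrom] = (int(np.diff(pos).max()), False)
    return out


def median_depth(sample: SampleMethylome) -> float:
    """Median sequencing depth over the sample's records (even count: midpair mean)."""
    depths = sample.depths()
    if not depths:
        raise ValueError("empty sample")
    return float(np.median(depths))


@dataclass
class RepresentationSummary:
    """Table-shaped summary: one row per sample plus per-condition unions."""

    n_genomic_cytosines: int
    per_sample: pd.DataFrame = field(default_factory=pd.DataFrame)
    per_condition: pd.DataFrame = field(default_factory=pd.DataFrame)
    max_gaps: Dict[str, Tuple[int, bool]] = field(default_factory=dict)


def summarize_representation(samples: Iterable[SampleMethylome],
                             fasta) -> RepresentationSummary:
    """Build the full representation summary over a set of samples.

    The per-condition block reports both the mean of per-sample percentages
    and the percentage of the mean identified count — on real data these can
    differ, so both are shown.
    """
    samples = list(samples)
    n_genomic = count_genomic_cpg_cytosines(fasta)
    rows = []
    for s in samples:
        rows.append({"male_id": s.male_id, "condition": s.condition,
                     "n_identified": len(s),
                     "pct_representation": representation_percent(len(s), n_genomic),
                     "median_depth": median_depth(s) if len(s) else float("nan")})
    per_sample = pd.DataFrame(rows)
    cond_rows = []
    for cond in per_sample["condition"].unique():
        group = [s for s in samples if s.condition == cond]
        union_n, union_pct = union_representation(group, n_genomic)
        sub = per_sample[per_sample["condition"] == cond]
        cond_rows.append({
            "condition": cond,
            "mean_n_identified": sub["n_identified"].mean(),
            "mean_of_pct": round(sub["pct_representation"].mean(), 1),
            "pct_of_mean": representation_percent(int(sub["n_identified"].mean()),
                                                  n_genomic),
            "median_depth": sub["median_depth"].median(),
            "union_n": union_n,
            "union_pct": union_pct,
        })
    per_condition = pd.DataFrame(cond_rows)
    gaps = max_consecutive_gap(union_site_keys(samples))
    return RepresentationSummary(n_genomic_cytosines=n_genomic,
                                 per_sample=per_sample,
                                 per_condition=per_condition,
                                 max_gaps=gaps)
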