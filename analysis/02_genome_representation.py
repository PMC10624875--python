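#!/usr/bin/env python
"""How well do the sequenced cytosines represent the toy genome?

Reports per-sample and per-condition-union representation percentages of all
strand-resolved genomic CpG cytosines, per-sample median depths, and the
largest gap between consecutive sequenced cytosines (coverage homogeneity).
"""

from pathlib import Path

from cryomethyl.pipeline import load_samples_dir
from cryomethyl.representation import summarize_representation

FIX = Path("scratch/fixtures")
OUT = Path("results")


def main() -> None:
    OUT.mkdir(exist_ok=True)
    samples = load_samples_dir(FIX)
    summary = summarize_representation(samples.values(), FIX / "genome.fa")
    summary.per_sample.to_csv(OUT / "representation_samples.tsv", sep="\t", index=False)
    summary.per_condition.to_csv(OUT / "representation_conditions.tsv", sep="\t",
                                 index=False)
    print(f"genomic CpG cytosines (both strands): {summary.n_genomic_cytosines:,}")
    print(summary.per_condition.to_string(index=False))
    worst = max(g for g, _ in summary.max_gaps.values())
    print(f"max gap between consecutive sequenced cytosines (union): {worst:,} b")
    print("note: per-sample representation is roughly half the per-condition union,"
          " mirroring the partial, correlated site capture of RRBS libraries")


if __name__ == "__main__":
    main()
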