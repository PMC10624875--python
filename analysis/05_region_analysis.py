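#!/usr/bin/env python
"""Regions: strict DMR windows, sensitive-region clusters, feature annotation.

Applies the stringent DMR rule (>=50 b window, >=5 CpGs, >=75% DMCs at
p < 0.001) and the empirical sensitive-region rule (>=2 DMCs within 100 bp,
chained), then annotates each region against the toy gene models (promoter
5 kb, exon 1, exons, intron 1, introns, downstream 1 kb, intergenic).
"""

from pathlib import Path

import pandas as pd

from cryomethyl import differential as dd
from cryomethyl import regions as reg
from cryomethyl.io import read_fasta, read_gff3_genes, write_bed
from cryomethyl.pipeline import load_samples_dir
from cryomethyl.types import CRYOPROTECTANTS

FIX = Path("scratch/fixtures")
OUT = Path("results")


def main() -> None:
    OUT.mkdir(exist_ok=True)
    samples = load_samples_dir(FIX)
    genes = read_gff3_genes(FIX / "genes.gff3")
    chrom_lengths = {c: len(s) for c, s in read_fasta(FIX / "genome.fa").items()}
    fresh = {m: s for (m, c), s in samples.items() if c == "fresh"}

    dmcs_by_cp, dmr_rows = {}, []
    for cp in CRYOPROTECTANTS:
        treated = {m: s for (m, c), s in samples.items() if c == cp}
        results = dd.run_paired_tests(dd.build_paired_table(fresh, treated, cp))
        dmcs_by_cp[cp] = [r.site for r in dd.call_dmcs(results)]
        for d in reg.detect_dmrs({r.site: r.p_value for r in results}):
            dmr_rows.append({"cryoprotectant": cp, **d.__dict__})
        print(f"{cp:9s} DMCs {len(dmcs_by_cp[cp]):4d}  strict DMRs "
              f"{sum(1 for r in dmr_rows if r['cryoprotectant'] == cp)}")
    pd.DataFrame(dmr_rows, columns=["cryoprotectant", "chrom", "start", "end",
                                    "n_cpg", "n_dmc", "dmc_fraction"]) \
        .to_csv(OUT / "dmrs.tsv", sep="\t", index=False)

    regions = reg.detect_sensitive_regions(dmcs_by_cp, max_gap=100)
    for r in regions:
        reg.annotate_region(r, genes, chrom_lengths=chrom_lengths)
    frame = reg.regions_to_frame(regions, CRYOPROTECTANTS)
    frame.to_csv(OUT / "sensitive_regions.tsv", sep="\t", index=False)
    write_bed([(r.chrom, r.start, r.end) for r in regions],
              OUT / "sensitive_regions.bed", header="potentially sensitive regions")

    print(f"potentially sensitive regions (>=2 DMCs within 100 bp): {len(regions)}")
    for cp in CRYOPROTECTANTS:
        n = sum(1 for r in regions if cp in r.sensitive_to())
        print(f"  sensitive to {cp:9s}: {n}")
    genic = frame[frame.features != "intergenic"]
    print(f"  overlapping gene features: {len(genic)} "
          f"(intergenic: {len(frame) - len(genic)})")


if __name__ == "__main__":
    main()
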