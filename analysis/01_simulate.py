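#!/usr/bin/env python
"""Generate the synthetic paired cryopreservation study used by all later steps.

Writes a full fixture set (toy genome FASTA, GFF3 gene models, 48 cytosine
report files = 12 males x {fresh, DMSO, MeOH, glycerol}, sperm-quality table,
and the ground-truth tables) under scratch/fixtures/.
"""

from pathlib import Path

from cryomethyl.simulate import SimulationConfig, digest_mspi, write_fixture_set

OUT = Path("scratch/fixtures")

CONFIG = SimulationConfig(
    seed=42,
    n_chrom=2,
    chrom_length=500_000,   # 1 Mb toy genome: enough CpGs for every stage
    n_dmc_true=300,         # injected DMCs per cryoprotectant (the study's scale)
)


def main() -> None:
    write_fixture_set(CONFIG, OUT)
    # quick narration of what the fixture contains
    from cryomethyl.io import read_fasta
    seqs = read_fasta(OUT / "genome.fa")
    _, retained = digest_mspi(seqs, CONFIG.frag_min, CONFIG.frag_max)
    n_truth = sum(1 for _ in open(OUT / "truth_sites.tsv")) - 1
    n_samples = len(list(OUT.glob("*.CX_report.txt")))
    print(f"toy genome: {len(seqs)} chromosomes, "
          f"{sum(len(s) for s in seqs.values()):,} b")
    print(f"retained MspI fragments ({CONFIG.frag_min}-{CONFIG.frag_max} b): "
          f"{len(retained):,}")
    print(f"observable strand-resolved CpG cytosines: {n_truth:,}")
    print(f"sample files written: {n_samples} (12 males x 4 conditions)")
    print(f"injected DMCs: {CONFIG.n_dmc_true} per cryoprotectant, "
          f"effect {CONFIG.dmc_effect}, concordance {CONFIG.dmc_concordance}")


if __name__ == "__main__":
    main()
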