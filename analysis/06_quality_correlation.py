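#!/usr/bin/env python
"""Do males with more DMCs show worse sperm quality after thawing?

Correlates the per-male DMC burden with membrane integrity, mitochondrial
activity, motility and normalized fertilization within each cryoprotectant
(Spearman, permutation p). The generator draws quality and methylation
changes independently, so no true correlation exists; any p < 0.05 here is a
false positive at the nominal rate.
"""

from pathlib import Path

from cryomethyl import differential as dd
from cryomethyl.io import read_quality_table
from cryomethyl.pipeline import load_samples_dir
from cryomethyl.quality import correlate_all
from cryomethyl.types import CRYOPROTECTANTS

FIX = Path("scratch/fixtures")
OUT = Path("results")


def main() -> None:
    OUT.mkdir(exist_ok=True)
    samples = load_samples_dir(FIX)
    quality = read_quality_table(FIX / "quality.csv")
    fresh = {m: s for (m, c), s in samples.items() if c == "fresh"}
    dmcs_by_cp = {}
    for cp in CRYOPROTECTANTS:
        treated = {m: s for (m, c), s in samples.items() if c == cp}
        results = dd.run_paired_tests(dd.build_paired_table(fresh, treated, cp))
        dmcs_by_cp[cp] = dd.call_dmcs(results)
    corr = correlate_all(dmcs_by_cp, quality, seed=42)
    corr.to_csv(OUT / "correlations.tsv", sep="\t", index=False)
    print(corr.to_string(index=False,
                         float_format=lambda v: f"{v:.3f}"))
    hits = corr[(corr.p_value < 0.05) & (corr.flag == "")]
    degen = corr[corr.flag == "degenerate"]
    print(f"\nnominally significant (p < 0.05): {len(hits)} of "
          f"{(corr.flag == '').sum()} testable pairs")
    print(f"degenerate pairs skipped (constant input, e.g. glycerol "
          f"fertilization all zero): {len(degen)}")


if __name__ == "__main__":
    main()
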