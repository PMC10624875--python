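#!/usr/bin/env python
"""Paired differential methylation: sharing, DMC calling, trend classes, Venn.

For each cryoprotectant: pair cytosines within male (depth >= 1 in fresh and
treated), keep sites shared by >= 6 of 12 males, run the paired arcsine Wald
test, call DMCs at p < 0.001, classify hyper/hypo/unclassified by the
majority rule, and cross-tabulate DMC overlap between cryoprotectants.
Scores recovery against the generator's injected truth.
"""

import json
from pathlib import Path

import pandas as pd

from cryomethyl import differential as dd
from cryomethyl.pipeline import load_samples_dir
from cryomethyl.types import CRYOPROTECTANTS

FIX = Path("scratch/fixtures")
OUT = Path("results")


def load_truth():
    df = pd.read_csv(FIX / "truth_dmcs.tsv", sep="\t")
    truth = {}
    for r in df.itertuples():
        truth.setdefault(r.cryoprotectant, {})[(r.chrom, int(r.pos), r.strand)] \
            = r.direction
    return truth


def main() -> None:
    OUT.mkdir(exist_ok=True)
    samples = load_samples_dir(FIX)
    fresh = {m: s for (m, c), s in samples.items() if c == "fresh"}
    truth = load_truth()
    dmc_sets = {}
    for cp in CRYOPROTECTANTS:
        treated = {m: s for (m, c), s in samples.items() if c == cp}
        table = dd.build_paired_table(fresh, treated, cp)
        sharing = dd.sharing_distribution(table, n_males=12)
        sharing.to_csv(OUT / f"sharing_{cp}.tsv", sep="\t", index=False)
        results = dd.run_paired_tests(table)
        dmcs = dd.call_dmcs(results)
        dd.results_to_frame(dmcs).to_csv(OUT / f"dmc_{cp}.tsv", sep="\t", index=False)
        dmc_sets[cp] = {r.site for r in dmcs}
        classes = {c: sum(r.trend_class == c for r in dmcs)
                   for c in ("hyper", "hypo", "unclassified")}
        inj = truth.get(cp, {})
        rec = [r for r in dmcs if r.site in inj]
        dirmatch = sum(1 for r in rec if r.trend_class == inj[r.site])
        print(f"{cp:9s} paired {len(table):6,}  shared>=6 {len(results):6,}  "
              f"cum%>=6 {sharing.attrs['cum_pct_min_males']:5.1f}  "
              f"DMCs {len(dmcs):4d}  classes {classes}")
        print(f"          truth recovery {len(rec)}/{len(inj)} "
              f"({100 * len(rec) / max(1, len(inj)):.0f}%), "
              f"direction match {dirmatch}/{len(rec)}")
    venn = dd.overlap_counts(dmc_sets)
    with open(OUT / "venn.json", "w") as fh:
        json.dump({"+".join(k): v for k, v in sorted(venn.items())}, fh, indent=1)
    print("DMC overlap (exclusive regions):",
          {"+".join(k): v for k, v in sorted(venn.items())})


if __name__ == "__main__":
    main()
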