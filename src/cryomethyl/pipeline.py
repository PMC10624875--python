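"""End-to-end orchestration: simulate -> represent -> global -> DMC -> regions
-> correlations, from one config, with a run manifest for reproducibility.

All stage parameters default to the study's printed values: depth filter 10,
site sharing >= 6 males, DMC threshold p < 0.001, DMR rule 50 b / 5 CpG /
75%, sensitive-region gap 100 bp, promoter 5 kb, downstream 1 kb.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd

from . import __version__
from . import differential, globalmeth, io as mio, quality, regions as reg
from . import representation as repre
from .simulate import SimulationConfig, simulate_study, write_fixture_set
from .types import CRYOPROTECTANTS, SampleMethylome

log = logging.getLogger(__name__)

_SAMPLE_RE = re.compile(r"male(\d+)_([A-Za-z]+)\.CX_report\.txt$")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


class _stage:
    """Context manager converting any stage exception into a StageError."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        log.info("stage %s", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None and not isinstance(exc, StageError):
            raise StageError(self.name, exc) from exc
        return False


@dataclass
class PipelineConfig:
    outdir: str = "results"
    samples_dir: Optional[str] = None      # pre-existing fixture dir, or None
    genome: Optional[str] = None
    gff: Optional[str] = None
    quality_table: Optional[str] = None
    simulate: Optional[SimulationConfig] = None  # generate inputs when set
    seed: int = 0
    min_depth: int = 10
    min_males: int = 6
    alpha: float = 0.001
    dmr_window: int = 50
    dmr_min_cpg: int = 5
    dmr_min_frac: float = 0.75
    max_gap: int = 100
    promoter_len: int = 5000
    downstream_len: int = 1000


def load_samples_dir(path) -> Dict[Tuple[int, str], SampleMethylome]:
    """Load every maleNN_<condition>.CX_report.txt under a fixture directory."""
    samples: Dict[Tuple[int, str], SampleMethylome] = {}
    for f in sorted(Path(path).iterdir()):
        m = _SAMPLE_RE.search(f.name)
        if not m:
            continue
        male, cond = int(m.group(1)), m.group(2)
        samples[(male, cond)] = mio.load_sample(f, male, cond, dialect="cx")
    if not samples:
        raise FileNotFoundError(f"no CX-report samples found under {path}")
    return samples


def run_all(config: PipelineConfig) -> Dict:
    """Execute the full pipeline; returns the manifest dict (also written)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: Dict = {"version": __version__, "python": platform.python_version(),
                      "seed": config.seed,
                      "parameters": {k: v for k, v in dataclasses.asdict(config).items()
                                     if not isinstance(v, dict)},
                      "stages": {}}

    # --- stage: inputs (simulate or load) -----------------------------------
    with _stage("simulate"):
        if config.simulate is not None:
            fixdir = out / "fixtures"
            write_fixture_set(config.simulate, fixdir)
            config = dataclasses.replace(
                config, samples_dir=str(fixdir), genome=str(fixdir / "genome.fa"),
                gff=str(fixdir / "genes.gff3"), quality_table=str(fixdir / "quality.csv"))
            manifest["stages"]["simulate"] = {"outdir": str(fixdir)}
    if config.samples_dir is None:
        raise ValueError("either samples_dir or a simulate config is required")
    samples = load_samples_dir(config.samples_dir)
    n_males = len({m for m, _ in samples})
    conditions = sorted({c for _, c in samples})
    manifest["stages"]["load"] = {"n_samples": len(samples), "n_males": n_males,
                                  "conditions": conditions}

    # --- stage: genome representation ---------------------------------------
    if config.genome:
        summary = repre.summarize_representation(samples.values(), config.genome)
        summary.per_sample.to_csv(out / "representation_samples.tsv", sep="\t", index=False)
        summary.per_condition.to_csv(out / "representation_conditions.tsv", sep="\t",
                                     index=False)
        manifest["stages"]["represent"] = {
            "n_genomic_cytosines": summary.n_genomic_cytosines,
            "rows": len(summary.per_sample),
            "max_gap": max((g for g, _ in summary.max_gaps.values()), default=0)}

    # --- stage: global methylation ------------------------------------------
    rows = []
    for (male, cond), s in sorted(samples.items()):
        rows.append({"male_id": male, "condition": cond,
                     "global_mean_pct": globalmeth.global_mean_methylation(
                         s, min_depth=config.min_depth)})
    gdf = pd.DataFrame(rows)
    gdf.to_csv(out / "global_means.tsv", sep="\t", index=False)
    hist_frames = []
    for cond in conditions:
        h = globalmeth.bin_ratios([s for (m, c), s in samples.items() if c == cond],
                                  min_depth=config.min_depth)
        f = h.to_frame()
        f.insert(0, "condition", cond)
        hist_frames.append(f)
    pd.concat(hist_frames).to_csv(out / "ratio_histogram.tsv", sep="\t", index=False)
    by_cond = {c: gdf.loc[gdf.condition == c, "global_mean_pct"].tolist()
               for c in conditions}
    omnibus = globalmeth.rank_compare_conditions(by_cond)
    try:
        coords, explained = globalmeth.pca_samples(sorted(samples.values(),
                                                          key=lambda s: (s.condition, s.male_id)))
        coords.to_csv(out / "pca_coordinates.tsv", sep="\t", index=False)
    except ValueError as exc:
        explained = []
        log.warning("PCA skipped: %s", exc)
    manifest["stages"]["global"] = {"rows": len(gdf),
                                    "kruskal_p": omnibus["omnibus_p"],
                                    "pca_explained": [float(e) for e in explained]}

    # --- stage: paired differential (one table per cryoprotectant) ----------
    cps = [c for c in CRYOPROTECTANTS if c in conditions]
    fresh = {m: s for (m, c), s in samples.items() if c == "fresh"}
    dmcs_by_cp: Dict[str, List[differential.DMCResult]] = {}
    results_by_cp: Dict[str, List[differential.DMCResult]] = {}
    for cp in cps:
        treated = {m: s for (m, c), s in samples.items() if c == cp}
        table = differential.build_paired_table(fresh, treated, cp)
        sharing = differential.sharing_distribution(table, n_males=n_males,
                                                    min_males=config.min_males)
        sharing.to_csv(out / f"sharing_{cp}.tsv", sep="\t", index=False)
        results = differential.run_paired_tests(table, min_males=config.min_males,
                                              n_males=n_males)
        results_by_cp[cp] = results
        dmcs = differential.call_dmcs(results, alpha=config.alpha)
        dmcs_by_cp[cp] = dmcs
        differential.results_to_frame(dmcs).to_csv(out / f"dmc_{cp}.tsv", sep="\t",
                                                   index=False)
        manifest["stages"][f"dmc_{cp}"] = {
            "paired_sites": len(table), "tested": len(results), "dmcs": len(dmcs),
            "classes": {cls: sum(r.trend_class == cls for r in dmcs)
                        for cls in ("hyper", "hypo", "unclassified")}}
    if len(cps) == 3:
        venn = differential.overlap_counts(
            {cp: {r.site for r in dmcs_by_cp[cp]} for cp in cps})
        with open(out / "venn.json", "w") as fh:
            json.dump({"+".join(k): v for k, v in sorted(venn.items())}, fh, indent=1)
        manifest["stages"]["venn"] = {"+".join(k): v for k, v in sorted(venn.items())}

    # --- stage: regions ------------------------------------------------------
    if config.gff:
        with _stage("regions"):
            if not Path(config.gff).exists():
                raise FileNotFoundError(f"gene models not found: {config.gff}")
            genes = mio.read_gff3_genes(config.gff)
            dmrs = []
            for cp in cps:
                pvals = {r.site: r.p_value for r in results_by_cp[cp]}
                for d in reg.detect_dmrs(pvals, window=config.dmr_window,
                                         min_cpg=config.dmr_min_cpg,
                                         min_frac=config.dmr_min_frac,
                                         alpha=config.alpha):
                    dmrs.append({"cryoprotectant": cp, **d.__dict__})
            pd.DataFrame(dmrs, columns=["cryoprotectant", "chrom", "start", "end",
                                        "n_cpg", "n_dmc", "dmc_fraction"]) \
                .to_csv(out / "dmrs.tsv", sep="\t", index=False)
            sens = reg.detect_sensitive_regions(
                {cp: [r.site for r in dmcs_by_cp[cp]] for cp in cps},
                max_gap=config.max_gap)
            for r_ in sens:
                reg.annotate_region(r_, genes, promoter_len=config.promoter_len,
                                    downstream_len=config.downstream_len)
            reg.regions_to_frame(sens, cps).to_csv(out / "sensitive_regions.tsv",
                                                   sep="\t", index=False)
            mio.write_bed([(r_.chrom, r_.start, r_.end) for r_ in sens],
                          out / "sensitive_regions.bed",
                          header="potentially sensitive regions")
            manifest["stages"]["regions"] = {"dmrs": len(dmrs), "sensitive": len(sens)}

    # --- stage: quality correlation ------------------------------------------
    if config.quality_table:
        qt = mio.read_quality_table(config.quality_table)
        corr = quality.correlate_all({cp: dmcs_by_cp[cp] for cp in cps}, qt,
                                     seed=config.seed)
        corr.to_csv(out / "correlations.tsv", sep="\t", index=False)
        manifest["stages"]["correlate"] = {"rows": len(corr)}

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest
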