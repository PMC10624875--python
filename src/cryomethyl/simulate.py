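"""Synthetic RRBS study generator with known ground truth.

The generator emulates the statistical structure of a paired sperm
cryopreservation study: 12 males, each measured fresh and after freezing with
three cryoprotectants (DMSO, methanol, glycerol), on a toy genome digested
in silico with MspI (C^CGG) and size-selected to 40-220 b fragments.

The sperm methylome it mimics is strongly bimodal: by default 86% of CpG
sites are fully methylated, 12% fully unmethylated and the rest intermediate,
giving an analytic mean of 87% — close to the ~86% global methylation typical
of salmonid sperm. Bisulfite conversion of unmethylated cytosines is
incomplete (99.6% by default), so a truly unmethylated site reads methylated
with probability 0.004. Treatment effects ("injected DMCs") shift the true
ratio of chosen observable sites by a fixed amount in a majority subset of
males, and are recorded in a :class:`TruthTable` so recovery can be scored.

Genome construction plants CCGG motifs as a Poisson process on a background
sequence scrubbed of spontaneous CCGGs, so the motif count itself is Poisson
with known rate — background CpGs (~1/16 per dinucleotide in uniform random
sequence) provide the assayable sites between cut sites.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as mio
from .types import CONDITIONS, CRYOPROTECTANTS, CytosineRecord, SampleMethylome, SiteKey

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, independent RNG substream fanned out from one master seed.

    Stage re-runs draw from their own stream, so regenerating one stage never
    perturbs the others.
    """
    key = zlib.crc32(name.encode())
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study; defaults are the emulated design."""

    seed: int = 0
    n_males: int = 12
    conditions: Tuple[str, ...] = CONDITIONS
    n_chrom: int = 4
    chrom_length: int = 250_000
    mspi_density: float = 4.0          # expected CCGG motifs per kb
    frag_min: int = 40                 # size-selection window, bases
    frag_max: int = 220
    p_methylated_site: float = 0.86    # mixture weight of fully methylated sites
    p_unmethylated_site: float = 0.12  # fully unmethylated
    intermediate_low: float = 0.05     # intermediate ratios ~ U(low, high)
    intermediate_high: float = 0.95
    depth_mean: float = 30.0           # negative-binomial mean depth
    depth_dispersion: float = 4.0      # NB size; variance = m + m^2/size
    depth_sample_spread: float = 0.35  # per-sample mean factor ~ U(1-s, 1+s)
    conversion_rate: float = 0.996     # unmethylated C read converted (as T)
    over_conversion_rate: float = 0.0  # methylated C wrongly converted
    site_dropout: float = 0.55         # mean per-sample fraction of observable sites missed
    frac_well_sequenced: float = 0.48  # fraction of CpGs on "well-sequenced" fragments
    well_mean: float = 0.88            # their mean per-sample keep probability
    well_conc: float = 15.0            # Beta concentration of the well component
    poor_conc: float = 2.0             # Beta concentration of the poor component
    dmc_min_propensity: float = 0.7    # injected DMCs restricted to likely-tested sites
    n_dmc_true: int = 300              # injected DMCs per cryoprotectant
    dmc_effect: float = 0.5            # absolute true-ratio shift
    dmc_concordance: float = 0.75      # fraction of males sharing the direction
    n_genes: int = 30                  # toy gene models for annotation

    def __post_init__(self) -> None:
        if self.p_methylated_site + self.p_unmethylated_site > 1:
            raise ValueError("mixture weights exceed 1")
        if not (self.frag_min < self.frag_max):
            raise ValueError("frag_min must be < frag_max")
        if not (0.9 < self.conversion_rate <= 1.0):
            raise ValueError("conversion_rate outside (0.9, 1]")
        if self.chrom_length < self.frag_max:
            raise ValueError("chromosome shorter than frag_max")

    @property
    def poor_mean(self) -> float:
        """Mean keep probability of the poorly-sequenced component.

        Derived so that the overall mean per-sample keep probability equals
        1 - site_dropout given the well-sequenced component.
        """
        keep = 1.0 - self.site_dropout
        w = self.frac_well_sequenced
        m = (keep - w * self.well_mean) / (1.0 - w)
        if not (0.0 < m < 1.0):
            raise ValueError("inconsistent dropout mixture parameters")
        return m

    @property
    def analytic_mean(self) -> float:
        """Expected true methylation ratio under the mixture (fraction)."""
        p_int = 1.0 - self.p_methylated_site - self.p_unmethylated_site
        mid = 0.5 * (self.intermediate_low + self.intermediate_high)
        return self.p_methylated_site + p_int * mid

    @property
    def cryoprotectants(self) -> Tuple[str, ...]:
        return tuple(c for c in self.conditions if c != "fresh")


def solve_p_methylated(target_mean: float, p_unmethylated: float = 0.12,
                       intermediate_mean: float = 0.5) -> float:
    """Mixture weight of fully-methylated sites giving a target analytic mean.

    Solves  target = p_m + (1 - p_m - p_u) * intermediate_mean  for p_m.
    """
    p_m = (target_mean - (1.0 - p_unmethylated) * intermediate_mean) / (1.0 - intermediate_mean)
    if not (0.0 <= p_m <= 1.0 - p_unmethylated):
        raise ValueError(f"target mean {target_mean} unreachable with p_unmeth {p_unmethylated}")
    return p_m


# ---------------------------------------------------------------------------
# toy genome
# ---------------------------------------------------------------------------

def _scrub_motif(seq: np.ndarray, motif: bytes = b"CCGG") -> np.ndarray:
    """Destroy every occurrence of ``motif`` by flipping its first base to A.

    Flipping to A can never create a new CCGG (the motif has no A), so one or
    two passes always terminate.
    """
    m = np.frombuffer(motif, dtype=np.uint8)
    k = len(m)
    while True:
        if len(seq) < k:
            return seq
        hits = np.ones(len(seq) - k + 1, dtype=bool)
        for i in range(k):
            hits &= seq[i : len(seq) - k + 1 + i] == m[i]
        idx = np.flatnonzero(hits)
        if idx.size == 0:
            return seq
        seq[idx] = ord("A")


def build_toy_genome(config: SimulationConfig,
                     rng: Optional[np.random.Generator] = None
                     ) -> Tuple[Dict[str, str], List[SiteKey]]:
    """Random toy genome with planted MspI sites, plus its CpG cytosine list.

    Returns ``(sequences, cytosines)`` where cytosines are strand-resolved:
    each CG dinucleotide at positions (p, p+1) yields ("+", p) and ("-", p+1).
    CCGG motifs are planted as a Poisson process at ``mspi_density`` per kb on
    a background purged of spontaneous CCGGs.
    """
    rng = rng if rng is not None else substream(config.seed, "genome")
    sequences: Dict[str, str] = {}
    cytosines: List[SiteKey] = []
    for c in range(config.n_chrom):
        chrom = f"chr{c + 1}"
        L = config.chrom_length
        seq = _BASES[rng.integers(0, 4, size=L)].copy()
        seq = _scrub_motif(seq)
        n_motifs = rng.poisson(config.mspi_density * L / 1000.0)
        # non-overlapping plant positions, >=4 bases apart
        pos = np.sort(rng.choice(L - 4, size=min(n_motifs, (L - 4) // 8), replace=False))
        keep = np.ones(len(pos), dtype=bool)
        last = -10
        for i, p in enumerate(pos):
            if p - last < 4:
                keep[i] = False
            else:
                last = p
        for p in pos[keep]:
            seq[p : p + 4] = np.frombuffer(b"CCGG", dtype=np.uint8)
        s = seq.tobytes().decode("ascii")
        sequences[chrom] = s
        arr = np.frombuffer(s.encode(), dtype=np.uint8)
        cg = np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))
        for p0 in cg:  # p0 is 0-based index of the C
            cytosines.append((chrom, int(p0) + 1, "+"))
            cytosines.append((chrom, int(p0) + 2, "-"))
    return sequences, cytosines


def digest_mspi(sequences: Dict[str, str], frag_min: int, frag_max: int
                ) -> Tuple[List[Tuple[str, int, int]], List[Tuple[str, int, int]]]:
    """In-silico MspI digestion with size selection.

    Cuts at every CCGG between the first C and CGG (C^CGG). Returns
    ``(all_fragments, retained_fragments)`` as 1-based closed intervals;
    retained fragments have length within [frag_min, frag_max].
    """
    all_frags: List[Tuple[str, int, int]] = []
    retained: List[Tuple[str, int, int]] = []
    for chrom, seq in sequences.items():
        cuts = [0]
        start = seq.find("CCGG")
        while start != -1:
            cuts.append(start + 1)  # 0-based index after the leading C
            start = seq.find("CCGG", start + 1)
        cuts.append(len(seq))
        for a, b in zip(cuts, cuts[1:]):
            frag = (chrom, a + 1, b)  # 1-based closed
            all_frags.append(frag)
            if frag_min <= (b - a) <= frag_max:
                retained.append(frag)
    return all_frags, retained


def observable_sites(cytosines: Sequence[SiteKey],
                     retained: Sequence[Tuple[str, int, int]]) -> np.ndarray:
    """Boolean mask over cytosines: True where the site lies on a retained fragment."""
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for chrom, s, e in retained:
        by_chrom.setdefault(chrom, []).append((s, e))
    starts = {c: np.array([s for s, _ in sorted(v)]) for c, v in by_chrom.items()}
    ends = {c: np.array([e for _, e in sorted(v)]) for c, v in by_chrom.items()}
    mask = np.zeros(len(cytosines), dtype=bool)
    for i, (chrom, pos, _strand) in enumerate(cytosines):
        if chrom not in starts:
            continue
        j = np.searchsorted(starts[chrom], pos, side="right") - 1
        if j >= 0 and pos <= ends[chrom][j]:
            mask[i] = True
    return mask


# ---------------------------------------------------------------------------
# sequencing propensity
# ---------------------------------------------------------------------------

def _dinucleotide_index(sites: Sequence[SiteKey]) -> Tuple[List[Tuple[str, int]], np.ndarray]:
    """Map strand-resolved cytosines to their CpG dinucleotide (the + position)."""
    keys = [(c, p if s == "+" else p - 1) for c, p, s in sites]
    dinucs = sorted(set(keys))
    lookup = {d: i for i, d in enumerate(dinucs)}
    return dinucs, np.array([lookup[k] for k in keys])


def site_propensities(config: SimulationConfig, sites: Sequence[SiteKey],
                      rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Per-site probability of being captured in any one sample.

    Emulates the strong cross-sample correlation of RRBS site presence (some
    fragments are systematically more sequenced than others): each CpG
    dinucleotide draws a keep probability from a two-component Beta mixture
    — a "well-sequenced" component (default mean 0.88) and a poor one whose
    mean makes the overall average equal 1 - site_dropout. Both strand
    cytosines of a CpG share the value. Under the defaults ~88% of the
    distinct paired cytosines end up shared by >= 6 of 12 males, with the
    mode at 8-10 males.
    """
    rng = rng if rng is not None else substream(config.seed, "propensity")
    dinucs, idx = _dinucleotide_index(sites)
    n = len(dinucs)
    hi = rng.random(n) < config.frac_well_sequenced
    q = np.empty(n)
    a_hi = config.well_mean * config.well_conc
    b_hi = (1.0 - config.well_mean) * config.well_conc
    a_lo = config.poor_mean * config.poor_conc
    b_lo = (1.0 - config.poor_mean) * config.poor_conc
    q[hi] = rng.beta(a_hi, b_hi, size=int(hi.sum()))
    q[~hi] = rng.beta(a_lo, b_lo, size=int((~hi).sum()))
    return q[idx]


# ---------------------------------------------------------------------------
# truth
# ---------------------------------------------------------------------------

@dataclass
class InjectedDMC:
    site: SiteKey
    cryoprotectant: str
    direction: str          # "hyper" | "hypo"
    effect: float           # absolute shift applied (after clipping)
    males: Tuple[int, ...]  # 1-based ids of concordant males


@dataclass
class TruthTable:
    """Ground truth of the simulated study: baselines plus injected effects."""

    sites: List[SiteKey]                    # observable strand-resolved cytosines
    baseline: np.ndarray                    # true ratio per site (shared across males)
    injected: List[InjectedDMC] = field(default_factory=list)
    site_index: Dict[SiteKey, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.site_index:
            self.site_index = {s: i for i, s in enumerate(self.sites)}

    def true_ratio(self, site: SiteKey, condition: str, male_id: int) -> float:
        r = float(self.baseline[self.site_index[site]])
        for d in self.injected:
            if d.site == site and d.cryoprotectant == condition and male_id in d.males:
                r = r + d.effect if d.direction == "hyper" else r - d.effect
        return float(np.clip(r, 0.0, 1.0))

    def injected_for(self, cryoprotectant: str) -> List[InjectedDMC]:
        return [d for d in self.injected if d.cryoprotectant == cryoprotectant]


def assign_truth(config: SimulationConfig, cytosines: Sequence[SiteKey],
                 observable: Optional[np.ndarray] = None,
                 propensity: Optional[np.ndarray] = None,
                 rng: Optional[np.random.Generator] = None) -> TruthTable:
    """Draw baseline ratios and inject treatment effects on observable sites.

    Baselines come from the three-component mixture (fully methylated / fully
    unmethylated / intermediate-uniform) and are shared by both strands of a
    CpG, across males and conditions. Per cryoprotectant, ``n_dmc_true``
    observable sites receive a ±``dmc_effect`` shift in a random
    ceil(concordance x n_males) subset of males. The direction is random for
    intermediate baselines but forced away from the boundary at saturated
    ones (a hyper shift at ratio 1 would clip to nothing and the recorded
    truth would be untestable). Injection is restricted to sites with
    sequencing propensity >= ``dmc_min_propensity`` so that every recorded
    truth is discoverable by the >= 6-male analysis.
    """
    rng = rng if rng is not None else substream(config.seed, "truth")
    sites = list(cytosines) if observable is None else [
        s for s, keep in zip(cytosines, observable) if keep]
    # one baseline per CpG dinucleotide (strands of a CpG are symmetric)
    dinucs, dinuc_idx = _dinucleotide_index(sites)
    p_int = 1.0 - config.p_methylated_site - config.p_unmethylated_site
    comp = rng.choice(3, size=len(dinucs),
                      p=[config.p_methylated_site, config.p_unmethylated_site, p_int])
    inter = rng.uniform(config.intermediate_low, config.intermediate_high, size=len(dinucs))
    base_by_dinuc = np.where(comp == 0, 1.0, np.where(comp == 1, 0.0, inter))
    baseline = base_by_dinuc[dinuc_idx]

    truth = TruthTable(sites=sites, baseline=baseline)
    if propensity is None:
        propensity = site_propensities(config, sites)
    injectable = np.flatnonzero(propensity >= config.dmc_min_propensity)
    if config.n_dmc_true > len(injectable):
        raise ValueError("n_dmc_true exceeds the number of injectable observable sites")
    n_conc = int(np.ceil(config.dmc_concordance * config.n_males))
    for cp in config.cryoprotectants:
        chosen = rng.choice(injectable, size=config.n_dmc_true, replace=False)
        for idx in chosen:
            b = baseline[idx]
            if b >= 1.0 - 1e-9:
                direction = "hypo"
            elif b <= 1e-9:
                direction = "hyper"
            else:
                direction = "hyper" if rng.random() < 0.5 else "hypo"
            shift = config.dmc_effect if direction == "hyper" else -config.dmc_effect
            effect = abs(float(np.clip(b + shift, 0.0, 1.0)) - b)
            males = tuple(sorted(rng.choice(np.arange(1, config.n_males + 1),
                                            size=n_conc, replace=False).tolist()))
            truth.injected.append(InjectedDMC(site=sites[idx], cryoprotectant=cp,
                                              direction=direction, effect=effect,
                                              males=males))
    return truth


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def simulate_counts(truth: TruthTable, config: SimulationConfig,
                    propensity: Optional[np.ndarray] = None,
                    rng: Optional[np.random.Generator] = None
                    ) -> Dict[Tuple[int, str], SampleMethylome]:
    """Draw per-sample read counts for every male x condition.

    Per site and sample: depth ~ NegBin(per-sample mean, dispersion);
    methylated calls ~ Binomial(depth, r') with
    r' = r + (1 - r)(1 - conversion) - r * over_conversion — an unmethylated
    cytosine that escapes bisulfite conversion reads as methylated. Site
    presence is thinned per sample by the shared sequencing propensities
    (mean keep 1 - site_dropout), emulating partial genome representation
    with cross-sample correlation; depth-0 sites are never emitted.
    """
    rng = rng if rng is not None else substream(config.seed, "counts")
    if propensity is None:
        propensity = site_propensities(config, truth.sites)
    n_sites = len(truth.sites)
    base = truth.baseline
    # per-site true ratio matrices are built lazily per (condition, male)
    effects: Dict[Tuple[str, int], Dict[int, float]] = {}
    for d in truth.injected:
        idx = truth.site_index[d.site]
        shift = d.effect if d.direction == "hyper" else -d.effect
        for m in d.males:
            effects.setdefault((d.cryoprotectant, m), {})[idx] = shift

    size = config.depth_dispersion
    samples: Dict[Tuple[int, str], SampleMethylome] = {}
    sample_factor = {
        m: rng.uniform(1.0 - config.depth_sample_spread, 1.0 + config.depth_sample_spread)
        for m in range(1, config.n_males + 1)}
    for male in range(1, config.n_males + 1):
        for cond in config.conditions:
            mean = config.depth_mean * sample_factor[male]
            p_nb = size / (size + mean)
            keep = rng.random(n_sites) < propensity
            depth = rng.negative_binomial(size, p_nb, size=n_sites)
            depth[~keep] = 0
            r = base.copy()
            for idx, shift in effects.get((cond, male), {}).items():
                r[idx] = np.clip(r[idx] + shift, 0.0, 1.0)
            r_obs = r + (1.0 - r) * (1.0 - config.conversion_rate) \
                - r * config.over_conversion_rate
            n_meth = rng.binomial(depth, r_obs)
            sample = SampleMethylome(male_id=male, condition=cond)
            nz = np.flatnonzero(depth > 0)
            for i in nz:
                chrom, pos, strand = truth.sites[i]
                sample.records[(chrom, pos, strand)] = CytosineRecord(
                    chrom, pos, strand, int(n_meth[i]), int(depth[i] - n_meth[i]))
            samples[(male, cond)] = sample
    return samples


# ---------------------------------------------------------------------------
# toy gene models and quality table
# ---------------------------------------------------------------------------

def simulate_genes(config: SimulationConfig,
                   rng: Optional[np.random.Generator] = None) -> List[dict]:
    """Random toy gene models (for annotation tests), as GFF3-ready dicts."""
    rng = rng if rng is not None else substream(config.seed, "genes")
    genes = []
    for g in range(config.n_genes):
        chrom = f"chr{int(rng.integers(1, config.n_chrom + 1))}"
        span = int(rng.integers(2_000, 20_000))
        start = int(rng.integers(1, max(2, config.chrom_length - span)))
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(1, 9))
        # split the span into alternating exons/introns
        cuts = np.sort(rng.choice(np.arange(1, span - 1), size=2 * n_exons - 2,
                                  replace=False)) if n_exons > 1 else np.array([], dtype=int)
        bounds = np.concatenate([[0], cuts, [span - 1]])
        exons = [(start + int(bounds[2 * i]), start + int(bounds[2 * i + 1]))
                 for i in range(n_exons)]
        genes.append({"gene_id": f"gene{g + 1:03d}", "chrom": chrom, "strand": strand,
                      "start": start, "end": start + span - 1, "exons": exons})
    return genes


def write_gff3(genes: List[dict], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g["chrom"], g["start"])):
            gid, chrom, strand = g["gene_id"], g["chrom"], g["strand"]
            fh.write(f"{chrom}\tsim\tgene\t{g['start']}\t{g['end']}\t.\t{strand}\t.\t"
                     f"ID={gid}\n")
            tid = f"{gid}.t1"
            fh.write(f"{chrom}\tsim\tmRNA\t{g['start']}\t{g['end']}\t.\t{strand}\t.\t"
                     f"ID={tid};Parent={gid}\n")
            for i, (s, e) in enumerate(g["exons"], start=1):
                fh.write(f"{chrom}\tsim\texon\t{s}\t{e}\t.\t{strand}\t.\t"
                         f"ID={tid}.e{i};Parent={tid}\n")


#: per-condition means of the quality metrics; orderings follow the emulated
#: study (DMSO >= glycerol >= MeOH for membrane/mito; DMSO > MeOH > glycerol=0
#: for motility and normalized fertilization; glycerol fertilization is zero).
_QUALITY_MEANS = {
    #            membrane mito motility fert_norm
    "fresh":    (98.0, 95.0, 99.9, 100.0),
    "DMSO":     (85.0, 65.0, 30.0, 60.0),
    "MeOH":     (55.0, 25.0, 5.0, 20.0),
    "glycerol": (80.0, 60.0, 0.0, 0.0),
}
_QUALITY_SDS = {
    "fresh":    (1.0, 2.0, 0.2, 10.0),
    "DMSO":     (5.0, 8.0, 8.0, 12.0),
    "MeOH":     (18.0, 8.0, 3.0, 8.0),
    "glycerol": (6.0, 8.0, 0.0, 0.0),
}


def simulate_quality(config: SimulationConfig,
                     rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Per-male sperm-quality table mimicking the cellular-response hierarchy."""
    rng = rng if rng is not None else substream(config.seed, "quality")
    rows = []
    for male in range(1, config.n_males + 1):
        for cond in config.conditions:
            mu, sd = _QUALITY_MEANS[cond], _QUALITY_SDS[cond]
            vals = [float(np.clip(rng.normal(m, s), 0.0, None)) if s > 0 else m
                    for m, s in zip(mu, sd)]
            # percentages capped at 100 except normalized fertilization
            vals[0] = min(vals[0], 100.0)
            vals[1] = min(vals[1], 100.0)
            vals[2] = min(vals[2], 100.0)
            rows.append({"male_id": male, "condition": cond,
                         "membrane": round(vals[0], 2), "mito": round(vals[1], 2),
                         "motility": round(vals[2], 2), "fert_norm": round(vals[3], 2)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# study bundle and fixture writing
# ---------------------------------------------------------------------------

@dataclass
class ToyStudy:
    config: SimulationConfig
    sequences: Dict[str, str]
    cytosines: List[SiteKey]
    fragments: List[Tuple[str, int, int]]
    truth: TruthTable
    samples: Dict[Tuple[int, str], SampleMethylome]
    genes: List[dict]
    quality: pd.DataFrame


def simulate_study(config: SimulationConfig) -> ToyStudy:
    """Run the whole generator in memory: genome -> digestion -> truth -> counts."""
    sequences, cytosines = build_toy_genome(config)
    _, retained = digest_mspi(sequences, config.frag_min, config.frag_max)
    mask = observable_sites(cytosines, retained)
    kept = [s for s, keep in zip(cytosines, mask) if keep]
    propensity = site_propensities(config, kept)
    truth = assign_truth(config, cytosines, observable=mask, propensity=propensity)
    samples = simulate_counts(truth, config, propensity=propensity)
    genes = simulate_genes(config)
    quality = simulate_quality(config)
    return ToyStudy(config=config, sequences=sequences, cytosines=cytosines,
                    fragments=retained, truth=truth, samples=samples,
                    genes=genes, quality=quality)


def write_fixture_set(config: SimulationConfig, outdir) -> Path:
    """Materialize a full fixture set on disk; byte-identical for equal seeds."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    study = simulate_study(config)
    mio.write_fasta(study.sequences, out / "genome.fa")
    write_gff3(study.genes, out / "genes.gff3")
    mio.write_quality_table(study.quality, out / "quality.csv")
    for (male, cond), sample in sorted(study.samples.items()):
        stem = f"male{male:02d}_{cond}"
        mio.write_cx_report(sample.records.values(), out / f"{stem}.CX_report.txt")
        mio.write_bismark_coverage(sample.records.values(), out / f"{stem}.cov")
    with open(out / "truth_sites.tsv", "w") as fh:
        fh.write("chrom\tpos\tstrand\tbaseline\n")
        for s, b in zip(study.truth.sites, study.truth.baseline):
            fh.write(f"{s[0]}\t{s[1]}\t{s[2]}\t{b:.6g}\n")
    with open(out / "truth_dmcs.tsv", "w") as fh:
        fh.write("cryoprotectant\tchrom\tpos\tstrand\tdirection\teffect\tmales\n")
        for d in study.truth.injected:
            males = ",".join(str(m) for m in d.males)
            fh.write(f"{d.cryoprotectant}\t{d.site[0]}\t{d.site[1]}\t{d.site[2]}\t"
                     f"{d.direction}\t{d.effect:.6g}\t{males}\n")
    with open(out / "config.json", "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=1, sort_keys=True)
        fh.write("\n")
    return out
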