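"""Synthetic two-condition, two-genotype ChIP-seq data with ground truth.

The generator emulates the study design end to end on a toy genome: two
nutrient conditions (+N rich, -N starved) x two genotypes (WT, hda1d)
x five ChIP factors (Rpb3, Hda1, H3, H4ac, H3ac), with

* Rpb3 coding-region signal proportional to per-condition gene activity,
* Hda1 coupled to Rpb3 through the exponential law
  hda1 = exp(alpha + beta * rpb3) x multiplicative log-normal noise,
* planted Pol II-independent Hda1 binding at the URS (-600..-100) of
  RP-like genes in -N and at tRNA loci in both conditions,
* a Rap1 consensus instance planted in each RP-like URS,
* per-sample spike-in read counts (spike chromatin ~10%) from which the
  true between-sample scale factors are recoverable, and
* NB-distributed per-gene fragment counts with planted 4-fold
  repressed/induced classes for the differential test.

Every draw descends from one global seed through independent per-purpose
substreams, so outputs are deterministic and adding a sample does not
perturb the others.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import (
    Bin,
    GeneModel,
    GenomeAnnotation,
    Interval,
    TilingConvention,
    tile_genome,
    tss_relative_window,
)
from .coverage import CoverageTrack, SpikeInCounts
from .positional import reverse_complement

PLANTED_MOTIF = "ACACCCATACATTT"  # one concrete instance of ACACCCAYACAYYY

GENE_CLASSES = ("constitutive", "repressed", "induced", "rp_like", "tRNA")
CONDITIONS = ("plusN", "minusN")
FACTORS = ("Rpb3", "Hda1", "H3", "H4ac", "H3ac")


@dataclass
class SimConfig:
    seed: int = 0
    n_chromosomes: int = 3
    chrom_length: int = 300_000
    n_constitutive: int = 80
    n_repressed: int = 15
    n_induced: int = 15
    n_rp_like: int = 15
    n_trna: int = 15
    gene_length: int = 1600
    trna_length: int = 80
    min_spacing: int = 1500
    spike_fraction: float = 0.10
    hda1_alpha: float = 0.5
    hda1_beta: float = 0.002
    independent_site_excess: float = 8.0
    noise_sigma: float = 0.25
    nb_dispersion: float = 0.05
    mean_count: float = 200.0
    fold_change: float = 4.0
    background_rpb3: float = 5.0
    read_depth: int = 1_000_000
    depth_sigma: float = 0.3
    bin_size: int = 200
    end_trim: int = 200
    urs_window: tuple[int, int] = (-600, -100)
    # hda1-delta acetylation effects (log2 fold over WT)
    h4ac_urs_effect: float = 0.8
    h3ac_urs_effect: float = 0.3
    h4ac_cds_effect: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.spike_fraction < 1:
            raise ValueError("spike_fraction must lie in (0, 1)")
        for name in (
            "n_chromosomes",
            "chrom_length",
            "n_constitutive",
            "n_repressed",
            "n_induced",
            "n_rp_like",
            "n_trna",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class GroundTruth:
    gene_classes: dict[str, str]
    activities: pd.DataFrame  # gene x condition Rpb3 activity
    planted_intervals: list[tuple[Interval, str, str]]  # (iv, kind, condition)
    motif_offsets: dict[str, int]  # rp_like gene -> TSS-relative offset
    scale_factors: dict[str, float] = field(default_factory=dict)  # true d_s
    planted_bin_mask: dict[str, np.ndarray] = field(default_factory=dict)
    touched_bin_mask: dict[str, np.ndarray] = field(default_factory=dict)

    def differential_class(self, gene_id: str) -> str:
        c = self.gene_classes[gene_id]
        return {
            "repressed": "repressed",
            "induced": "induced",
            "rp_like": "repressed",  # RP-like genes shut off under starvation
        }.get(c, "unchanged")


def _substream(seed: int, purpose: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, purpose]))


def build_toy_annotation(
    config: SimConfig,
) -> tuple[GenomeAnnotation, GroundTruth, dict[str, str]]:
    """Place non-overlapping genes on a toy genome and plant Rap1 motifs.

    Genes are laid out left to right with >= ``min_spacing`` between
    neighbors (leaving the 1 kb upstream windows free of other genes);
    RP-like genes get one planted Rap1 consensus instance at a uniform
    random offset inside their -600..-100 URS. Background sequence is
    i.i.d. uniform ACGT. Deterministic given ``config.seed``.
    """
    rng = _substream(config.seed, 0)
    chroms = {f"chr{i + 1}": config.chrom_length for i in range(config.n_chromosomes)}
    class_counts = {
        "constitutive": config.n_constitutive,
        "repressed": config.n_repressed,
        "induced": config.n_induced,
        "rp_like": config.n_rp_like,
        "tRNA": config.n_trna,
    }
    prefixes = {
        "constitutive": "CON",
        "repressed": "REP",
        "induced": "IND",
        "rp_like": "RPL",
        "tRNA": "TRN",
    }
    roster: list[str] = []
    for cls, n in class_counts.items():
        roster.extend([cls] * n)
    roster = [roster[i] for i in rng.permutation(len(roster))]

    genes: list[GeneModel] = []
    counters = dict.fromkeys(class_counts, 0)
    chrom_names = list(chroms)
    cursors = {c: 2500 for c in chrom_names}  # margin past the trimmed end
    ci = 0
    for cls in roster:
        length = config.trna_length if cls == "tRNA" else config.gene_length
        placed = False
        for _ in range(len(chrom_names)):
            chrom = chrom_names[ci % len(chrom_names)]
            ci += 1
            gap = config.min_spacing + int(rng.integers(0, 1000))
            start = cursors[chrom] + gap
            # snap genes to the bin grid: mRNA TSSs become bin-aligned and
            # tRNA genes fall inside a single bin
            start = -(-start // config.bin_size) * config.bin_size
            end = start + length
            if end + 2500 > chroms[chrom]:
                continue
            counters[cls] += 1
            gid = f"{prefixes[cls]}{counters[cls]:04d}"
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneModel(
                    gene_id=gid,
                    interval=Interval(chrom, start, end),
                    strand=strand,
                    biotype="tRNA" if cls == "tRNA" else "mRNA",
                    cds=Interval(chrom, start, end),
                    is_rp=(cls == "rp_like"),
                )
            )
            cursors[chrom] = end
            placed = True
            break
        if not placed:
            raise ValueError(
                "could not place all genes without overlap; increase "
                "chrom_length or reduce gene counts"
            )
    annotation = GenomeAnnotation(chrom_lengths=chroms, genes=genes)

    # activities per condition
    act_rng = _substream(config.seed, 1)
    bg = config.background_rpb3
    acts = {}
    gene_classes = {}
    for g in genes:
        cls = {"CON": "constitutive", "REP": "repressed", "IND": "induced",
               "RPL": "rp_like", "TRN": "tRNA"}[g.gene_id[:3]]
        gene_classes[g.gene_id] = cls
        if cls == "constitutive":
            a = act_rng.uniform(200, 800)
            acts[g.gene_id] = (a, a)
        elif cls == "repressed":
            a = act_rng.uniform(400, 800)
            acts[g.gene_id] = (a, a / config.fold_change)
        elif cls == "induced":
            a = act_rng.uniform(100, 200)
            acts[g.gene_id] = (a, a * config.fold_change)
        elif cls == "rp_like":
            a = act_rng.uniform(600, 900)
            acts[g.gene_id] = (a, bg)
        else:  # tRNA: Pol III, no Rpb3 signal
            acts[g.gene_id] = (0.0, 0.0)
    activities = pd.DataFrame(acts, index=["plusN", "minusN"]).T

    # planted Pol II-independent intervals
    planted: list[tuple[Interval, str, str]] = []
    bs = config.bin_size
    for g in genes:
        cls = gene_classes[g.gene_id]
        if cls == "rp_like":
            win = tss_relative_window(
                g, annotation, config.urs_window[0], config.urs_window[1]
            )
            if win.empty:
                continue
            # snap inward to whole bins so the planted footprint is exactly
            # a run of genome bins inside the URS window
            lo = -(-win.start // bs) * bs
            hi = (win.end // bs) * bs
            if hi > lo:
                planted.append((Interval(win.chrom, lo, hi), "urs", "minusN"))
        elif cls == "tRNA":
            planted.append((g.interval, "tRNA", "both"))

    # sequence with planted motifs
    seq_rng = _substream(config.seed, 2)
    sequences = {
        c: "".join(
            np.array(list("ACGT"))[seq_rng.integers(0, 4, size=l)]
        )
        for c, l in chroms.items()
    }
    motif_rng = _substream(config.seed, 3)
    motif_offsets = {}
    m = len(PLANTED_MOTIF)
    for g in genes:
        if gene_classes[g.gene_id] != "rp_like":
            continue
        lo, hi = config.urs_window
        offset = int(motif_rng.integers(lo, hi - m + 1))
        if g.strand == "+":
            pos = g.tss + offset
            ins = PLANTED_MOTIF
        else:
            pos = g.tss - (offset + m)
            ins = reverse_complement(PLANTED_MOTIF)
        s = sequences[g.interval.chrom]
        sequences[g.interval.chrom] = s[:pos] + ins + s[pos + m :]
        motif_offsets[g.gene_id] = offset

    truth = GroundTruth(
        gene_classes=gene_classes,
        activities=activities,
        planted_intervals=planted,
        motif_offsets=motif_offsets,
    )
    return annotation, truth, sequences


@dataclass
class SimResult:
    annotation: GenomeAnnotation
    truth: GroundTruth
    sequences: dict[str, str]
    bins: list[Bin]
    tracks: dict[tuple[str, str, str], CoverageTrack]  # (factor, cond, genotype)
    spike_counts: dict[str, SpikeInCounts]
    counts: pd.DataFrame  # gene x sample (Rpb3 CDS fragment counts)
    design: pd.DataFrame
    config: SimConfig

    def track(self, factor: str, condition: str, genotype: str = "WT") -> CoverageTrack:
        return self.tracks[(factor, condition, genotype)]

    @staticmethod
    def sample_id(factor: str, condition: str, genotype: str = "WT") -> str:
        return f"{factor}_{condition}_{genotype}"


def _gene_bin_weights(
    genes: list[GeneModel], bins: list[Bin]
) -> dict[str, list[tuple[int, float]]]:
    """Per gene: (bin index, overlap fraction of the bin) pairs."""
    by_chrom: dict[str, list[Bin]] = {}
    for b in bins:
        by_chrom.setdefault(b.interval.chrom, []).append(b)
    out: dict[str, list[tuple[int, float]]] = {}
    for g in genes:
        pairs = []
        for b in by_chrom.get(g.interval.chrom, ()):
            ov = b.interval.overlap_len(g.interval)
            if ov > 0:
                pairs.append((b.index, ov / b.interval.length))
        out[g.gene_id] = pairs
    return out


def _interval_bin_fractions(iv: Interval, bins_by_chrom, width: int):
    for b in bins_by_chrom.get(iv.chrom, ()):
        ov = b.interval.overlap_len(iv)
        if ov > 0:
            yield b.index, ov / width


def simulate_chipseq(
    annotation: GenomeAnnotation,
    truth: GroundTruth,
    config: SimConfig,
) -> SimResult:
    """Draw tracks, spike-in read counts, and per-gene NB fragment counts."""
    bins = tile_genome(
        annotation,
        config.bin_size,
        config.end_trim,
        TilingConvention(trim_both=False, include_mito=False),
    )
    n_bins = len(bins)
    width = config.bin_size
    bins_by_chrom: dict[str, list[Bin]] = {}
    for b in bins:
        bins_by_chrom.setdefault(b.interval.chrom, []).append(b)
    gene_weights = _gene_bin_weights(annotation.genes, bins)

    # --- true Rpb3 bin means per condition ---------------------------------
    rpb3_true = {c: np.full(n_bins, config.background_rpb3) for c in CONDITIONS}
    for g in annotation.genes:
        for cond_i, cond in enumerate(CONDITIONS):
            act = truth.activities.loc[g.gene_id, cond]
            for idx, frac in gene_weights[g.gene_id]:
                rpb3_true[cond][idx] += act * frac

    # planted-site bin masks (per condition) and per-bin excess fraction
    excess_frac = {c: np.zeros(n_bins) for c in CONDITIONS}
    for iv, kind, scope in truth.planted_intervals:
        conds = CONDITIONS if scope == "both" else (scope,)
        for cond in conds:
            for idx, frac in _interval_bin_fractions(iv, bins_by_chrom, width):
                excess_frac[cond][idx] = max(excess_frac[cond][idx], frac)
    truth.planted_bin_mask = {c: excess_frac[c] >= 0.5 for c in CONDITIONS}
    truth.touched_bin_mask = {c: excess_frac[c] > 0 for c in CONDITIONS}

    # --- per-sample nuisance depth factors and spike counts ----------------
    depth_rng = _substream(config.seed, 10)
    spike_rng = _substream(config.seed, 11)
    tracks: dict[tuple[str, str, str], CoverageTrack] = {}
    spike_counts: dict[str, SpikeInCounts] = {}
    sample_keys: list[tuple[str, str, str]] = []
    for factor in FACTORS:
        genotypes = ("WT",) if factor in ("Rpb3", "Hda1") else ("WT", "hda1d")
        for genotype in genotypes:
            for cond in CONDITIONS:
                sample_keys.append((factor, cond, genotype))

    for key in sample_keys:
        sid = SimResult.sample_id(*key)
        d = float(np.exp(depth_rng.normal(0, config.depth_sigma)))
        truth.scale_factors[sid] = d
        base_spike = config.read_depth * config.spike_fraction
        base_target = config.read_depth * (1 - config.spike_fraction)
        spike = int(spike_rng.poisson(base_spike * d))
        target = int(spike_rng.poisson(base_target * d))
        ambiguous = int(spike_rng.poisson(0.005 * config.read_depth * d))
        spike_counts[sid] = SpikeInCounts(sid, target, spike, ambiguous)

    # --- tracks -------------------------------------------------------------
    noise_rng = _substream(config.seed, 12)
    alpha, beta = config.hda1_alpha, config.hda1_beta
    # where is transcription active (for acetylation effects)
    active_cds = {
        c: np.zeros(n_bins, dtype=bool) for c in CONDITIONS
    }
    for g in annotation.genes:
        for cond in CONDITIONS:
            if truth.activities.loc[g.gene_id, cond] > 100:
                for idx, frac in gene_weights[g.gene_id]:
                    if frac >= 0.5:
                        active_cds[cond][idx] = True

    def lognoise(sigma: float) -> np.ndarray:
        return np.exp(noise_rng.normal(0, sigma, size=n_bins))

    for key in sample_keys:
        factor, cond, genotype = key
        sid = SimResult.sample_id(*key)
        d = truth.scale_factors[sid]
        if factor == "Rpb3":
            mean = rpb3_true[cond] * lognoise(0.4 * config.noise_sigma)
        elif factor == "Hda1":
            mean = np.exp(alpha + beta * rpb3_true[cond]) * lognoise(config.noise_sigma)
            f = excess_frac[cond]
            mean *= 1 + (config.independent_site_excess - 1) * f
        elif factor == "H3":
            mean = np.ones(n_bins)
            mean[active_cds[cond]] *= 0.8  # mild nucleosome depletion
            mean = mean * lognoise(0.1)
        else:  # H4ac / H3ac
            mean = np.ones(n_bins)
            if factor == "H4ac":
                mean[active_cds[cond]] *= 1.5
            if genotype == "hda1d":
                if factor == "H4ac" and cond == "plusN":
                    mean[active_cds[cond]] *= 2**config.h4ac_cds_effect
                if cond == "minusN":
                    urs = truth.planted_bin_mask["minusN"]
                    eff = (
                        config.h4ac_urs_effect
                        if factor == "H4ac"
                        else config.h3ac_urs_effect
                    )
                    mean[urs] *= 2**eff
            mean = mean * lognoise(0.15)
        cond_label = "+N" if cond == "plusN" else "-N"
        tracks[key] = CoverageTrack(
            factor=factor,
            condition=cond_label,
            genotype=genotype,
            values=mean * d,
            scale=1.0,
            spike_normalized=False,
        )

    # --- per-gene NB fragment counts (Rpb3 over CDS), 2 reps x 2 conds ------
    count_rng = _substream(config.seed, 13)
    mrna = [g for g in annotation.genes if g.biotype != "tRNA"]
    mean_act = float(truth.activities.loc[[g.gene_id for g in mrna]].values.mean())
    per_act = config.mean_count / mean_act
    cols = {}
    design_rows = []
    r = 1.0 / config.nb_dispersion
    for cond in CONDITIONS:
        for rep in (1, 2):
            sample = f"Rpb3_{cond}_rep{rep}"
            d = float(np.exp(count_rng.normal(0, config.depth_sigma)))
            truth.scale_factors[sample] = d
            base_spike = config.read_depth * config.spike_fraction
            base_target = config.read_depth * (1 - config.spike_fraction)
            spike_counts[sample] = SpikeInCounts(
                sample,
                int(count_rng.poisson(base_target * d)),
                int(count_rng.poisson(base_spike * d)),
                int(count_rng.poisson(0.005 * config.read_depth * d)),
            )
            mus = np.array(
                [
                    max(truth.activities.loc[g.gene_id, cond] * per_act, 0.1)
                    for g in mrna
                ]
            ) * d
            p = r / (r + mus)
            cols[sample] = count_rng.negative_binomial(r, p)
            design_rows.append(
                {"sample": sample, "condition": cond, "replicate": rep}
            )
    counts = pd.DataFrame(cols, index=[g.gene_id for g in mrna])
    design = pd.DataFrame(design_rows)

    return SimResult(
        annotation=annotation,
        truth=truth,
        sequences={},
        bins=bins,
        tracks=tracks,
        spike_counts=spike_counts,
        counts=counts,
        design=design,
        config=config,
    )


def simulate_dataset(config: SimConfig) -> SimResult:
    """Convenience wrapper: build annotation + simulate in one call."""
    annotation, truth, sequences = build_toy_annotation(config)
    result = simulate_chipseq(annotation, truth, config)
    result.sequences = sequences
    return result


# ---------------------------------------------------------------------------
# fixture writing


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_fixtures(result: SimResult, directory) -> dict[str, str]:
    """Write the simulated data in the formats the pipeline consumes.

    Emits FASTA, GFF3, RP gene list, per-track bedGraph, spike-in count
    TSV, counts + design TSVs, ground-truth tables, and a manifest with
    sha256 checksums. Returns the manifest mapping.
    """
    from . import io as pio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ann = result.annotation

    pio.write_fasta(result.sequences, directory / "genome.fa")
    pio.write_gff3(ann, directory / "annotation.gff3")
    (directory / "rp_genes.txt").write_text(
        "".join(f"{g.gene_id}\n" for g in ann.rp_genes)
    )
    for (factor, cond, genotype), track in result.tracks.items():
        df = pd.DataFrame(
            {
                "chrom": [b.interval.chrom for b in result.bins],
                "start": [b.interval.start for b in result.bins],
                "end": [b.interval.end for b in result.bins],
                "value": track.values,
            }
        )
        pio.write_bedgraph(df, directory / f"{factor}_{cond}_{genotype}.bedgraph")
    spikes = pd.DataFrame(
        [
            {
                "sample": s.sample_id,
                "target_reads": s.target_reads,
                "spike_reads": s.spike_reads,
                "ambiguous_reads": s.ambiguous_reads,
            }
            for s in result.spike_counts.values()
        ]
    )
    spikes.to_csv(directory / "spike_counts.tsv", sep="\t", index=False)
    result.counts.rename_axis("gene_id").to_csv(directory / "counts.tsv", sep="\t")
    result.design.to_csv(directory / "design.tsv", sep="\t", index=False)

    truth_genes = pd.DataFrame(
        {
            "gene_id": list(result.truth.gene_classes),
            "klass": list(result.truth.gene_classes.values()),
        }
    )
    truth_genes = truth_genes.merge(
        result.truth.activities.rename_axis("gene_id").reset_index(), on="gene_id"
    )
    truth_genes.to_csv(directory / "truth_genes.tsv", sep="\t", index=False)
    planted = pd.DataFrame(
        [
            {
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "name": f"{kind}:{scope}",
                "score": 0,
                "strand": ".",
            }
            for iv, kind, scope in result.truth.planted_intervals
        ]
    )
    pio.write_bed6(planted, directory / "truth_planted.bed")

    manifest = {}
    for path in sorted(directory.iterdir()):
        if path.name == "manifest.json":
            continue
        manifest[path.name] = _sha256(path)
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
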