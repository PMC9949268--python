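"""Synthetic reference panels, paired GWA studies, and enriched annotations.

The generator emulates the three-study evaluation design: one reference
panel with block-structured LD, a sparse set of causal variants clustered
into true loci, and three GWA studies of increasing sample size (A < B < C)
sharing those causal variants — A contributes input features, B labels,
and significance in C serves as ground truth. Binary annotation tracks
cover causal variants at an enriched rate, pathogenicity score tracks are
shifted at causal variants, and an eQTL table includes causal variants
with sub-threshold p-values at an elevated rate.

Summary statistics use the standard multivariate-normal model for GWAS
z-scores: per LD block, z ~ N(√n · R a, R), with R the block's panel
correlation matrix and a the standardized causal effects; p = 2Φ(−|z|)
and OR = exp(z/√n). Individual-level genotypes exist only in the panel.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from deepgwas.annotations import IntervalAnnotation, ScoreTrack
from deepgwas.popgen import GenotypePanel

logger = logging.getLogger(__name__)

P_FLOOR = 1e-320  # keep simulated p-values inside (0, 1]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic benchmark.

    Defaults define the desk-scale analogue of the three-study design:
    20,000 variants in 40 LD blocks, 24 causal variants in 12 true loci,
    and studies of 20k/60k/120k samples. effect_sd = 0.04 is calibrated so
    the smallest study already detects roughly half the true loci while
    the larger two detect most but not all — the regime the method is
    built for, where the feature study is itself a well-powered GWAS and
    the label/truth studies add power at the margin (as with the real
    study triples whose detected-locus counts step 108 → 145 → 287).
    """

    n_variants: int = 20_000
    n_blocks: int = 40
    block_correlation: float = 0.6
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_individuals_panel: int = 200
    causal_fraction: float = 24 / 20_000
    n_causal_loci: int = 12
    effect_sd: float = 0.04
    n_small: int = 20_000
    n_large: int = 60_000
    n_validation: int = 120_000
    annotation_base_rate: float = 0.05  # q: membership rate at non-causal variants
    annotation_enrichment: float = 5.0  # e: relative rate at causal variants
    n_epigenome_tracks: int = 15
    score_shift: float = 1.0  # score-track elevation at causal variants
    spacing_bp: int = 5_000
    track_halfwidth_bp: int = 400
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.causal_fraction < 1:
            raise ValueError("causal_fraction must be in (0, 1)")
        if not 0 <= self.block_correlation < 1:
            raise ValueError("block_correlation must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")
        if self.annotation_enrichment < 1:
            raise ValueError("annotation_enrichment must be >= 1")
        if self.annotation_enrichment * self.annotation_base_rate > 1:
            raise ValueError("enriched membership rate e*q exceeds 1")
        if min(self.n_variants, self.n_blocks, self.n_individuals_panel,
               self.n_small, self.n_large, self.n_validation) <= 0:
            raise ValueError("all counts must be positive")


@dataclass
class GroundTruth:
    causal_keys: list[str]
    causal_mask: np.ndarray  # boolean over panel variants
    effects: np.ndarray  # standardized per-variant effects, 0 off the causal set
    loci: list[tuple[str, int, int]]  # (chrom, start, end) true locus spans


@dataclass
class AnnotationBundle:
    """Everything the feature assembler needs besides stats and the panel."""

    indicator_tracks: dict[str, IntervalAnnotation]
    epigenome_tracks: list[IntervalAnnotation]
    score_tracks: dict[str, ScoreTrack]
    eqtl_table: pd.DataFrame


@dataclass
class Benchmark:
    config: SimulationConfig
    panel: GenotypePanel
    truth: GroundTruth
    study_a: pd.DataFrame  # features (smallest)
    study_b: pd.DataFrame  # labels / application target
    study_c: pd.DataFrame  # ground truth (largest)
    annotations: AnnotationBundle


def _block_layout(config: SimulationConfig) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Block sizes, per-block chromosome, per-variant block index."""
    base = config.n_variants // config.n_blocks
    sizes = np.full(config.n_blocks, base, dtype=int)
    sizes[: config.n_variants - base * config.n_blocks] += 1
    blocks_per_chrom = 2
    chroms = [str(1 + b // blocks_per_chrom) for b in range(config.n_blocks)]
    block_of = np.repeat(np.arange(config.n_blocks), sizes)
    return sizes, chroms, block_of


def simulate_panel(config: SimulationConfig, seed: int | None = None) -> GenotypePanel:
    """Block-structured reference panel.

    Within a block, two latent Gaussian haplotypes per individual share an
    exchangeable correlation rho and are thresholded at each variant's
    MAF quantile (Hardy–Weinberg genotypes); blocks are independent.
    Variants are spaced ~5 kb; two blocks per chromosome, 10 Mb apart.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    sizes, chroms, _ = _block_layout(config)
    rho = config.block_correlation
    n_ind = config.n_individuals_panel
    rows = []
    geno_blocks = []
    counter = 0
    for b, (size, chrom) in enumerate(zip(sizes, chroms)):
        mafs = rng.uniform(*config.maf_range, size=size)
        thresholds = norm.ppf(mafs)
        hap_sum = np.zeros((n_ind, size))
        for _hap in range(2):
            shared = rng.standard_normal((n_ind, 1))
            noise = rng.standard_normal((n_ind, size))
            latent = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * noise
            hap_sum += latent < thresholds[None, :]
        offset = 1_000_000 + (b % 2) * 10_000_000
        pos = offset + config.spacing_bp * np.arange(size)
        for j in range(size):
            rows.append(
                {
                    "chrom": chrom,
                    "pos": int(pos[j]),
                    "variant_id": f"var{counter + j}",
                    "ref": "A",
                    "alt": "G",
                }
            )
        counter += size
        geno_blocks.append(hap_sum)
    variants = pd.DataFrame(rows)
    variants["key"] = (
        variants["chrom"] + ":" + variants["pos"].astype(str) + ":A:G"
    )
    return GenotypePanel(variants=variants, genotypes=np.hstack(geno_blocks))


def simulate_effects(
    config: SimulationConfig,
    panel: GenotypePanel,
    seed: int | None = None,
    causal_weight: np.ndarray | None = None,
) -> GroundTruth:
    """Sparse causal variants clustered into true loci, effects ~ N(0, sd²).

    ``causal_weight`` (optional, per-variant) biases causal placement —
    used to give a second trait the same causal-annotation structure as
    the first.
    """
    rng = np.random.default_rng((config.seed + 1) if seed is None else seed)
    n = panel.n_variants
    n_causal = max(1, round(config.causal_fraction * n))
    _, _, block_of = _block_layout(config)
    n_loci = min(config.n_causal_loci, config.n_blocks, n_causal)
    causal_blocks = np.sort(rng.choice(config.n_blocks, size=n_loci, replace=False))

    weight = np.ones(n) if causal_weight is None else np.asarray(causal_weight, float)
    chosen: list[int] = []
    # one causal variant per chosen block first, then the remainder anywhere
    for b in causal_blocks:
        idx = np.flatnonzero(block_of == b)
        w = weight[idx] / weight[idx].sum()
        chosen.append(int(rng.choice(idx, p=w)))
    pool = np.flatnonzero(np.isin(block_of, causal_blocks))
    pool = pool[~np.isin(pool, chosen)]
    extra = n_causal - len(chosen)
    if extra > 0 and len(pool):
        w = weight[pool] / weight[pool].sum()
        chosen.extend(rng.choice(pool, size=min(extra, len(pool)), replace=False,
                                 p=w).tolist())
    chosen_arr = np.sort(np.asarray(chosen))

    mask = np.zeros(n, dtype=bool)
    mask[chosen_arr] = True
    effects = np.zeros(n)
    effects[chosen_arr] = rng.normal(0.0, config.effect_sd, size=len(chosen_arr))
    v = panel.variants
    loci = []
    for b in causal_blocks:
        in_block = chosen_arr[np.isin(chosen_arr, np.flatnonzero(block_of == b))]
        pos = v["pos"].to_numpy()[in_block]
        loci.append((str(v["chrom"].iloc[in_block[0]]), int(pos.min()), int(pos.max())))
    return GroundTruth(
        causal_keys=v["key"].to_numpy()[chosen_arr].tolist(),
        causal_mask=mask,
        effects=effects,
        loci=loci,
    )


def _block_spectra(panel: GenotypePanel, config: SimulationConfig):
    """Eigendecompositions of per-block panel correlation matrices.

    Estimated correlations from a finite panel need not be positive
    semi-definite after the NaN/monomorphic repair; eigenvalues are
    clipped at 1e-6 (logged) so the MVN draw is always well defined.
    """
    _, _, block_of = _block_layout(config)
    spectra = []
    for b in range(config.n_blocks):
        idx = np.flatnonzero(block_of == b)
        G = panel.genotypes[:, idx]
        with np.errstate(invalid="ignore", divide="ignore"):
            R = np.corrcoef(G, rowvar=False)
        R = np.where(np.isfinite(R), R, 0.0)
        np.fill_diagonal(R, 1.0)
        lam, V = np.linalg.eigh(R)
        if lam.min() < 1e-6:
            logger.debug("block %d: clipped %d eigenvalues below 1e-6",
                         b, int((lam < 1e-6).sum()))
        lam = np.clip(lam, 1e-6, None)
        spectra.append((idx, R, lam, V))
    return spectra


def simulate_study(
    panel: GenotypePanel,
    truth: GroundTruth,
    n_samples: int,
    seed: int,
    config: SimulationConfig,
    spectra=None,
) -> pd.DataFrame:
    """Summary statistics for one GWA study of ``n_samples`` individuals."""
    rng = np.random.default_rng(seed)
    spectra = spectra or _block_spectra(panel, config)
    n = panel.n_variants
    z = np.zeros(n)
    sqrt_n = np.sqrt(n_samples)
    for idx, R, lam, V in spectra:
        mean = sqrt_n * (R @ truth.effects[idx])
        eps = rng.standard_normal(len(idx))
        z[idx] = mean + V @ (np.sqrt(lam) * eps)
    p = np.clip(2.0 * norm.sf(np.abs(z)), P_FLOOR, 1.0)
    v = panel.variants
    return pd.DataFrame(
        {
            "variant_id": v["variant_id"].to_numpy(),
            "chrom": v["chrom"].to_numpy(),
            "pos": v["pos"].to_numpy(),
            "allele_effect": v["alt"].to_numpy(),
            "allele_other": v["ref"].to_numpy(),
            "odds_ratio": np.exp(z / sqrt_n),
            "p_value": p,
            "se": np.full(n, 1.0 / sqrt_n),
            "key": v["key"].to_numpy(),
        }
    )


def _membership_to_track(
    name: str, panel: GenotypePanel, member_mask: np.ndarray, halfwidth: int
) -> IntervalAnnotation:
    v = panel.variants
    pos = v["pos"].to_numpy()[member_mask]
    chrom = v["chrom"].to_numpy()[member_mask]
    triples = [
        (c, max(0, int(p) - 1 - halfwidth), int(p) + halfwidth) for c, p in zip(chrom, pos)
    ]
    if not triples:  # keep the track non-degenerate
        triples = [("1", 0, 1)]
    return IntervalAnnotation.from_intervals(name, triples)


def simulate_annotations(
    truth: GroundTruth,
    config: SimulationConfig,
    panel: GenotypePanel,
    seed: int | None = None,
) -> AnnotationBundle:
    """Binary tracks, score tracks, and an eQTL table enriched at causal variants.

    Each binary track covers causal variants at rate e·q and non-causal at
    rate q; covered variants become short intervals (half-width < variant
    spacing, so membership is exact). Epigenome tracks share 11 core
    patterns (some duplicated with noise) so Jaccard clustering has real
    structure to find. Deterministic given the seed.
    """
    from deepgwas.schema import DEFAULT_INTERVAL_FEATURES, DEFAULT_SCORE_FEATURES

    rng = np.random.default_rng((config.seed + 2) if seed is None else seed)
    n = panel.n_variants
    causal = truth.causal_mask
    q = config.annotation_base_rate
    eq = config.annotation_enrichment * q
    hw = config.track_halfwidth_bp

    def draw_membership() -> np.ndarray:
        rate = np.where(causal, eq, q)
        return rng.random(n) < rate

    indicator = {
        name: _membership_to_track(name, panel, draw_membership(), hw)
        for name in DEFAULT_INTERVAL_FEATURES
    }

    n_groups = 11
    cores = [draw_membership() for _ in range(n_groups)]
    epigenome = []
    for t in range(config.n_epigenome_tracks):
        core = cores[t % n_groups]
        keep = rng.random(n) >= 0.15
        extra = rng.random(n) < 0.15 * q
        member = (core & keep) | extra
        epigenome.append(
            _membership_to_track(f"epi_{t:02d}", panel, member, hw)
        )

    scores = {}
    for name in DEFAULT_SCORE_FEATURES:
        vals = rng.standard_normal(n) + config.score_shift * causal
        scores[name] = ScoreTrack(
            name, pd.Series(vals, index=panel.variants["variant_id"].to_numpy())
        )

    v = panel.variants
    sub_rate = np.where(causal, 0.6, q)
    is_eqtl = rng.random(n) < sub_rate
    idx = np.flatnonzero(is_eqtl)
    _, _, block_of = _block_layout(config)
    eqtl = pd.DataFrame(
        {
            "variant_id": v["variant_id"].to_numpy()[idx],
            "key": v["key"].to_numpy()[idx],
            "gene": [f"gene{block_of[i]}" for i in idx],
            "p": 10.0 ** (-rng.uniform(6.3, 12.0, size=len(idx))),
        }
    )
    # non-eQTL rows with p above the filter threshold, so filtering matters
    idx2 = np.flatnonzero(~is_eqtl & (rng.random(n) < q))
    chaff = pd.DataFrame(
        {
            "variant_id": v["variant_id"].to_numpy()[idx2],
            "key": v["key"].to_numpy()[idx2],
            "gene": [f"gene{block_of[i]}" for i in idx2],
            "p": 10.0 ** (-rng.uniform(0.0, 5.9, size=len(idx2))),
        }
    )
    eqtl_table = pd.concat([eqtl, chaff], ignore_index=True)
    return AnnotationBundle(indicator, epigenome, scores, eqtl_table)


def annotation_hit_count(bundle: AnnotationBundle, panel: GenotypePanel) -> np.ndarray:
    """Per-variant count of binary-track memberships (indicator + epigenome)."""
    from deepgwas.annotations import overlap_indicator

    counts = np.zeros(panel.n_variants)
    for track in list(bundle.indicator_tracks.values()) + bundle.epigenome_tracks:
        counts += overlap_indicator(panel.variants, track)
    return counts


def make_benchmark(config: SimulationConfig) -> Benchmark:
    """One panel/truth with three studies (A < B < C in sample size)."""
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(6)]
    panel = simulate_panel(config, seed=seeds[0])
    truth = simulate_effects(config, panel, seed=seeds[1])
    spectra = _block_spectra(panel, config)
    study_a = simulate_study(panel, truth, config.n_small, seeds[2], config, spectra)
    study_b = simulate_study(panel, truth, config.n_large, seeds[3], config, spectra)
    study_c = simulate_study(panel, truth, config.n_validation, seeds[4], config, spectra)
    annotations = simulate_annotations(truth, config, panel, seed=seeds[5])
    return Benchmark(config, panel, truth, study_a, study_b, study_c, annotations)


def make_transfer_benchmark(
    config: SimulationConfig, trait2_seed_offset: int = 1000
) -> tuple[Benchmark, GroundTruth, pd.DataFrame, pd.DataFrame]:
    """A trained-trait benchmark plus a second trait sharing its annotation structure.

    The second trait's causal variants are drawn with probability
    proportional to 1 + (e−1)·(annotation hit count), so the annotations
    enriched at trait-1 causal variants are informative for trait 2 as
    well. Returns (trait-1 benchmark, trait-2 truth, trait-2 feature study,
    trait-2 validation study).
    """
    bench = make_benchmark(config)
    weight = 1.0 + (config.annotation_enrichment - 1.0) * annotation_hit_count(
        bench.annotations, bench.panel
    )
    truth2 = simulate_effects(
        config, bench.panel, seed=config.seed + trait2_seed_offset, causal_weight=weight
    )
    spectra = _block_spectra(bench.panel, config)
    study2 = simulate_study(
        bench.panel, truth2, config.n_large, config.seed + trait2_seed_offset + 1,
        config, spectra
    )
    study2_val = simulate_study(
        bench.panel, truth2, config.n_validation, config.seed + trait2_seed_offset + 2,
        config, spectra
    )
    return bench, truth2, study2, study2_val


# ---------------------------------------------------------------------------
# disk round-trip: the CLI's `deepgwas simulate` output
# ---------------------------------------------------------------------------

def write_vcf(panel: GenotypePanel, path: str | os.PathLike) -> None:
    """Write the panel as plain VCFv4.2 with GT genotypes."""
    v = panel.variants
    samples = [f"S{i}" for i in range(panel.n_individuals)]
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(v["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        G = panel.genotypes
        for j in range(panel.n_variants):
            calls = "\t".join(
                "./." if np.isnan(G[i, j]) else gt_map[int(round(G[i, j]))]
                for i in range(panel.n_individuals)
            )
            fh.write(
                f"{v['chrom'].iloc[j]}\t{v['pos'].iloc[j]}\t{v['variant_id'].iloc[j]}"
                f"\t{v['ref'].iloc[j]}\t{v['alt'].iloc[j]}\t.\tPASS\t.\tGT\t{calls}\n"
            )


def write_study(stats: pd.DataFrame, path: str | os.PathLike) -> None:
    out = pd.DataFrame(
        {
            "CHR": stats["chrom"],
            "BP": stats["pos"],
            "SNP": stats["variant_id"],
            "A1": stats["allele_effect"],
            "A2": stats["allele_other"],
            "OR": stats["odds_ratio"],
            "SE": stats["se"],
            "P": stats["p_value"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def write_benchmark(bench: Benchmark, outdir: str | os.PathLike) -> dict[str, str]:
    """Write the whole benchmark as files readable by the data_io module."""
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    paths = {"panel": os.path.join(outdir, "panel.vcf")}
    write_vcf(bench.panel, paths["panel"])
    for name, study in (("study_a", bench.study_a), ("study_b", bench.study_b),
                        ("study_c", bench.study_c)):
        paths[name] = os.path.join(outdir, f"{name}.tsv")
        write_study(study, paths[name])
    ann_dir = os.path.join(outdir, "annotations")
    os.makedirs(ann_dir, exist_ok=True)
    for name, track in bench.annotations.indicator_tracks.items():
        p = os.path.join(ann_dir, f"{name}.bed")
        track.to_bed(p)
        paths[f"track:{name}"] = p
    for track in bench.annotations.epigenome_tracks:
        p = os.path.join(ann_dir, f"{track.name}.bed")
        track.to_bed(p)
        paths[f"track:{track.name}"] = p
    for name, track in bench.annotations.score_tracks.items():
        p = os.path.join(ann_dir, f"{name}.tsv")
        pd.DataFrame({"variant_id": track.values.index, "score": track.values.to_numpy()}
                     ).to_csv(p, sep="\t", index=False)
        paths[f"score:{name}"] = p
    paths["eqtl"] = os.path.join(outdir, "eqtl.tsv")
    bench.annotations.eqtl_table.to_csv(paths["eqtl"], sep="\t", index=False)
    paths["truth"] = os.path.join(outdir, "truth.tsv")
    v = bench.panel.variants
    pd.DataFrame(
        {
            "key": v["key"],
            "variant_id": v["variant_id"],
            "causal": bench.truth.causal_mask.astype(int),
            "effect": bench.truth.effects,
        }
    ).to_csv(paths["truth"], sep="\t", index=False)
    paths["truth_loci"] = os.path.join(outdir, "truth_loci.tsv")
    pd.DataFrame(bench.truth.loci, columns=["chrom", "start", "end"]).to_csv(
        paths["truth_loci"], sep="\t", index=False
    )
    return paths


def null_config(config: SimulationConfig | None = None) -> SimulationConfig:
    """The same conditions with all causal effects switched off."""
    return replace(config or SimulationConfig(), effect_sd=0.0)
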