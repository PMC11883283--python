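"""Synthetic data with planted ground truth for every pipeline stage.

The study's raw data (sequencing reads, droplet files, micrographs) are
not redistributable, so each analysis stage has a generator that emulates
its input with known truth: NB-distributed RNA-seq counts over a two
genotype x two condition design with planted regeneration responses and
genotype-differential responders; binomially partitioned droplet assays;
Poisson/binomial section cell counts; spot-based two-compartment
fluorescence images; and interval sets constructed to hit target promoter
category fractions.

All generators are pure functions of (config, seed): one global seed fans
out to named independent substreams, so adding a generator never perturbs
the draws of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .chromatin import GeneModelTable, IntervalSet
from .counts_de import CountExperiment, SampleInfo, GENOTYPES, CONDITIONS
from .ddpcr import DropletWell
from .imaging import ChannelImage, SectionCellCounts

__all__ = [
    "SimulationConfig",
    "simulate_count_experiment",
    "simulate_droplet_experiment",
    "simulate_section_counts",
    "simulate_image_pair",
    "simulate_interval_sets",
]

# fixed substream ids: appending new streams must not renumber old ones
_STREAMS = {"counts": 0, "droplets": 1, "sections": 2, "images": 3, "intervals": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[stream],))
    return np.random.default_rng(ss)


@dataclass
class SimulationConfig:
    """Parameters of all generators; defaults mirror the study design.

    RNA-seq: ~20,000 genes at genome scale (tests and examples use 2,000),
    3 replicate hearts per genotype x condition cell, NB dispersion 0.1,
    ~10% of genes regeneration-responsive, ~15% of those responding
    differently between genotypes with a residual shift of ``delta`` log2
    units. ddPCR: the four-condition design with a 4.3-fold wild-type
    regeneration induction and a 2.4-fold mutant one. Proliferation:
    group indices 9.11% (WT) and 11.71% (MUT) with 24 vs 19 hearts.
    """

    seed: int = 0
    # RNA-seq counts
    n_genes: int = 20_000
    n_replicates: int = 3
    baseline_log_mean: float = float(np.log(100.0))  # lognormal of mean counts
    baseline_log_sd: float = 1.0
    libsize_log_sd: float = 0.15
    dispersion: float = 0.1
    frac_responsive: float = 0.10
    frac_differential: float = 0.15  # fraction of responsive genes
    lfc_exp_scale: float = 0.75  # |lfc| = 1 + Exp(scale) for shared responders
    delta: float = 2.0  # planted residual shift (log2)
    # droplet assays
    droplets_accepted: int = 20_000
    base_lambda: float = 0.05
    wt_induction: float = 4.3
    mut_induction: float = 2.4
    reference_lambda: float = 0.5
    reference_dilution: float = 10.0
    wells_per_condition: int = 4
    # section cell counts
    hearts_wt: int = 24
    hearts_mut: int = 19
    sections_per_heart: int = 3
    mean_mef2_per_section: float = 250.0
    prolif_index_wt: float = 0.0911
    prolif_index_mut: float = 0.1171
    # images
    image_shape: tuple[int, int] = (256, 256)
    image_background: float = 5.0
    cell_intensity_b: float = 500.0
    intensity_ratio: float = 7.36
    cells_per_compartment: int = 40
    cell_radius: int = 6
    image_noise_sd: float = 2.0
    # interval sets
    n_interval_genes: int = 305
    frac_h33: float = 187 / 305
    frac_k27_only: float = 23 / 305
    promoter_halfwidth: int = 1000
    n_background_intervals: int = 50
    interval_mean_length: int = 600

    def __post_init__(self) -> None:
        for name in ("frac_responsive", "frac_differential", "frac_h33", "frac_k27_only"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "image_shape" in raw:
            raw["image_shape"] = tuple(raw["image_shape"])
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


def _nb_draws(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """NB(mean, var = mean + phi mean^2) via the gamma-Poisson mixture."""
    if phi == 0.0:
        return rng.poisson(mean)
    shape = 1.0 / phi
    return rng.poisson(rng.gamma(shape, mean * phi))


def simulate_count_experiment(cfg: SimulationConfig) -> tuple[CountExperiment, pd.DataFrame]:
    """Simulate the two-genotype regeneration RNA-seq experiment.

    Counts are NB(libsize_j * q_g * 2^effect, phi) where the effect is the
    condition log2FC (shared between genotypes for ordinary responders)
    plus, for planted differential responders, a genotype-specific shift
    of +-delta applied to the mutant response. Increased responders are
    up-regulated genes induced delta log2 units more in the mutant;
    decreased responders are down-regulated genes repressed delta more.

    Returns
    -------
    (experiment, truth): truth is indexed by gene with columns responsive,
    true_class (increased_in_mutant / decreased_in_mutant / none),
    lfc_wt_true, lfc_mut_true.
    """
    rng = _rng(cfg.seed, "counts")
    n = cfg.n_genes
    q = np.exp(rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, size=n))

    n_resp = int(round(cfg.frac_responsive * n))
    n_diff = int(round(cfg.frac_differential * n_resp))
    perm = rng.permutation(n)
    diff_idx = perm[:n_diff]
    resp_idx = perm[n_diff:n_resp]

    lfc_wt = np.zeros(n)
    lfc_mut = np.zeros(n)
    true_class = np.array(["none"] * n, dtype=object)

    # shared (genotype-equal) regeneration responders
    mag = 1.0 + rng.exponential(cfg.lfc_exp_scale, size=len(resp_idx))
    sign = rng.choice([-1.0, 1.0], size=len(resp_idx))
    lfc_wt[resp_idx] = sign * mag
    lfc_mut[resp_idx] = lfc_wt[resp_idx]

    # differential responders: half increased / half decreased in the
    # mutant, each planted on both up- and down-regulated genes so the
    # +-delta shifts are balanced at every point of the WT axis (an
    # imbalanced design would tilt the downstream regression line). WT
    # magnitudes are chosen so both genotypes' responses stay clearly
    # detectable (|lfc| >= 1.5) after the shift.
    half = len(diff_idx) // 2
    inc, dec = diff_idx[:half], diff_idx[half:]
    for idx, shift, label in (
        (inc, cfg.delta, "increased_in_mutant"),
        (dec, -cfg.delta, "decreased_in_mutant"),
    ):
        up = rng.random(len(idx)) < 0.5
        mag_near = rng.uniform(1.5, 3.0, size=len(idx))
        mag_far = rng.uniform(1.5 + abs(shift), 3.0 + abs(shift), size=len(idx))
        # the genotype shift must point away from zero on the side it
        # lands on, so the "far" magnitude is used when shift and sign
        # oppose each other
        toward_zero_up = shift < 0
        wt = np.where(up, np.where(toward_zero_up, mag_far, mag_near),
                      -np.where(toward_zero_up, mag_near, mag_far))
        lfc_wt[idx] = wt
        lfc_mut[idx] = wt + shift
        true_class[idx] = label

    samples = []
    columns = []
    for genotype in GENOTYPES:
        for condition in CONDITIONS:
            for rep in range(1, cfg.n_replicates + 1):
                lib = np.exp(rng.normal(0.0, cfg.libsize_log_sd))
                effect = np.zeros(n)
                if condition == "regenerating":
                    effect = lfc_wt if genotype == "WT" else lfc_mut
                mean = lib * q * 2.0**effect
                columns.append(_nb_draws(rng, mean, cfg.dispersion))
                samples.append(
                    SampleInfo(f"{genotype}_{condition}_{rep}", genotype, condition, rep)
                )
    counts = np.column_stack(columns)
    genes = [f"gene{i:05d}" for i in range(n)]
    responsive = np.zeros(n, dtype=bool)
    responsive[resp_idx] = True
    responsive[diff_idx] = True
    truth = pd.DataFrame(
        {
            "responsive": responsive,
            "true_class": true_class,
            "lfc_wt_true": lfc_wt,
            "lfc_mut_true": lfc_mut,
        },
        index=pd.Index(genes, name="gene"),
    )
    return CountExperiment(counts, genes, samples), truth


def simulate_droplet_experiment(cfg: SimulationConfig) -> tuple[list[DropletWell], pd.DataFrame]:
    """Simulate the four-condition ddPCR experiment with a reference gene.

    Per-droplet template counts are Poisson(lambda), so positives are
    Binomial(accepted, 1 - exp(-lambda)). The target's lambda follows the
    study design (wild-type regeneration induces ``wt_induction``-fold,
    mutant ``mut_induction``-fold over the shared uninjured baseline); the
    reference gene is constant across conditions and read at a 1:10
    dilution. A no-RT control well with lambda ~ 0 is included per
    condition.
    """
    rng = _rng(cfg.seed, "droplets")
    lam_by_condition = {
        "WT_uninjured": cfg.base_lambda,
        "WT_regenerating": cfg.base_lambda * cfg.wt_induction,
        "MUT_uninjured": cfg.base_lambda,
        "MUT_regenerating": cfg.base_lambda * cfg.mut_induction,
    }
    wells: list[DropletWell] = []
    truth_rows = []
    wid = 0
    for condition, lam in lam_by_condition.items():
        for target, tlam, dilution in (
            ("target", lam, 1.0),
            ("reference", cfg.reference_lambda, cfg.reference_dilution),
        ):
            for _ in range(cfg.wells_per_condition):
                accepted = int(rng.integers(14_000, cfg.droplets_accepted + 1))
                pos = int(rng.binomial(accepted, 1.0 - np.exp(-tlam)))
                wid += 1
                wells.append(
                    DropletWell(
                        well_id=f"W{wid:03d}",
                        target=target,
                        accepted_droplets=accepted,
                        positive_droplets=pos,
                        dilution_factor=dilution,
                        sample=condition,
                    )
                )
                truth_rows.append(
                    {"well_id": f"W{wid:03d}", "sample": condition, "target": target,
                     "true_lambda": tlam}
                )
        # no-RT control for the target assay
        accepted = int(rng.integers(14_000, cfg.droplets_accepted + 1))
        pos = int(rng.binomial(accepted, 1.0 - np.exp(-1e-4)))
        wid += 1
        wells.append(
            DropletWell(
                well_id=f"W{wid:03d}",
                target="target",
                accepted_droplets=accepted,
                positive_droplets=pos,
                sample=condition,
                is_no_rt_control=True,
            )
        )
        truth_rows.append(
            {"well_id": f"W{wid:03d}", "sample": condition, "target": "target",
             "true_lambda": 1e-4}
        )
    return wells, pd.DataFrame(truth_rows).set_index("well_id")


def simulate_section_counts(cfg: SimulationConfig) -> tuple[list[SectionCellCounts], pd.DataFrame]:
    """Simulate Mef2/EdU section counts for the two genotype groups.

    Per section, Mef2+ nuclei ~ Poisson(mean_mef2_per_section) and
    double-positives ~ Binomial(mef2, pi_group) with the group
    proliferation indices as pi. Truth records the per-heart pi.
    """
    rng = _rng(cfg.seed, "sections")
    sections: list[SectionCellCounts] = []
    truth_rows = []
    for group, n_hearts, pi in (
        ("WT", cfg.hearts_wt, cfg.prolif_index_wt),
        ("MUT", cfg.hearts_mut, cfg.prolif_index_mut),
    ):
        for h in range(1, n_hearts + 1):
            heart_id = f"{group}_heart{h:02d}"
            for s in range(1, cfg.sections_per_heart + 1):
                mef2 = int(rng.poisson(cfg.mean_mef2_per_section))
                double = int(rng.binomial(mef2, pi)) if mef2 > 0 else 0
                sections.append(
                    SectionCellCounts(f"{heart_id}_s{s}", heart_id, max(mef2, 0), double)
                )
            truth_rows.append({"heart_id": heart_id, "group": group, "true_index": pi})
    return sections, pd.DataFrame(truth_rows).set_index("heart_id")


def _disk_footprint(shape, centers, radius) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    mask = np.zeros(shape, dtype=bool)
    for cy, cx in centers:
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
    return mask


def simulate_image_pair(cfg: SimulationConfig) -> dict:
    """Simulate a two-compartment reporter image with a planted ratio.

    The frame is split into an upper compartment (epicardium-like, A) and
    a lower one (muscle-like, B). Labeled cells are soft-edged disks of
    near-uniform reporter intensity; the same cell layout is placed in
    both compartments, with compartment-A cells scaled by the planted
    ``intensity_ratio``, on a low flat background with Gaussian noise.
    Each compartment carries a marker channel lighting up exactly the
    cell footprints (the colocalization channel), so thresholding the
    marker and measuring mean reporter fluorescence inside it — the
    measurement protocol — recovers the planted ratio.

    Returns a dict with ChannelImages ``gfp``, ``marker_a``, ``marker_b``,
    boolean compartment masks, and ``truth`` (the planted ratio).
    """
    from scipy.ndimage import gaussian_filter

    rng = _rng(cfg.seed, "images")
    h, w = cfg.image_shape
    half = h // 2
    mask_a = np.zeros((h, w), dtype=bool)
    mask_a[:half, :] = True
    mask_b = ~mask_a

    margin = 2 * cfg.cell_radius
    n = cfg.cells_per_compartment
    cy = rng.uniform(margin, half - margin, size=n)
    cx = rng.uniform(margin, w - margin, size=n)
    cells_a = _disk_footprint((h, w), zip(cy, cx), cfg.cell_radius)
    cells_b = _disk_footprint((h, w), zip(cy + half, cx), cfg.cell_radius)

    gfp = np.full((h, w), cfg.image_background, dtype=float)
    gfp[cells_a] += cfg.cell_intensity_b * cfg.intensity_ratio
    gfp[cells_b] += cfg.cell_intensity_b
    gfp = gaussian_filter(gfp, sigma=1.0)  # soften cell edges
    gfp += rng.normal(0.0, cfg.image_noise_sd, size=gfp.shape)
    gfp = np.clip(gfp, 0.0, None)

    marker_a = np.where(cells_a, 1000.0, 0.0)
    marker_b = np.where(cells_b, 1000.0, 0.0)
    return {
        "gfp": ChannelImage(gfp, role="GFP"),
        "marker_a": ChannelImage(marker_a, role="red_reporter"),
        "marker_b": ChannelImage(marker_b, role="MHC"),
        "mask_a": mask_a,
        "mask_b": mask_b,
        "truth": {"intensity_ratio": cfg.intensity_ratio},
    }


def simulate_interval_sets(cfg: SimulationConfig) -> tuple[GeneModelTable, IntervalSet, IntervalSet, pd.DataFrame]:
    """Construct gene models and mark interval sets with exact category fractions.

    Genes are laid out on two chromosomes with alternating strand,
    100 kb apart. The first round(frac_h33 * n) genes receive an H3.3-CM
    interval inside their promoter (a random subset of those also gets
    H3K27ac, as active CM promoters carry both), the next
    round(frac_k27_only * n) get only an H3K27ac interval, and the rest
    get neither. Background intervals are placed midway between promoters
    so they overlap nothing. Fractions are met exactly by construction.

    Returns (gene_models, h33_set, k27ac_set, truth).
    """
    rng = _rng(cfg.seed, "intervals")
    n = cfg.n_interval_genes
    n_h33 = int(round(cfg.frac_h33 * n))
    n_k27 = int(round(cfg.frac_k27_only * n))
    if n_h33 + n_k27 > n:
        raise ValueError("category fractions exceed 1")

    rows = []
    h33_records = []
    k27_records = []
    truth_rows = []
    order = rng.permutation(n)
    categories = np.array(["neither"] * n, dtype=object)
    categories[order[:n_h33]] = "H3.3_CM"
    categories[order[n_h33 : n_h33 + n_k27]] = "K27ac_only"

    spacing = 100_000
    for i in range(n):
        gene = f"g{i:04d}"
        chrom = "chr1" if i % 2 == 0 else "chr2"
        tss = 50_000 + (i // 2) * spacing
        strand = "+" if i % 4 < 2 else "-"
        rows.append({"gene": gene, "chrom": chrom, "tss": tss, "strand": strand})
        length = max(100, int(rng.normal(cfg.interval_mean_length, cfg.interval_mean_length / 4)))
        offset = int(rng.integers(-cfg.promoter_halfwidth + 1, cfg.promoter_halfwidth))
        start = max(0, tss + offset - length // 2)
        if categories[i] == "H3.3_CM":
            h33_records.append((chrom, start, start + length, f"h33_{gene}"))
            if rng.random() < 0.5:  # active CM promoters often carry both marks
                k27_records.append((chrom, start, start + length, f"k27_{gene}"))
        elif categories[i] == "K27ac_only":
            k27_records.append((chrom, start, start + length, f"k27_{gene}"))
        truth_rows.append({"gene": gene, "category": categories[i]})

    # background intervals far from every promoter window
    for j in range(cfg.n_background_intervals):
        chrom = "chr1" if j % 2 == 0 else "chr2"
        pos = 50_000 + int(rng.integers(0, max(1, n // 2))) * spacing + spacing // 2
        rec = (chrom, pos, pos + cfg.interval_mean_length, f"bg_{j}")
        (h33_records if j % 2 == 0 else k27_records).append(rec)

    genes = GeneModelTable(pd.DataFrame(rows).set_index("gene"))
    truth = pd.DataFrame(truth_rows).set_index("gene")
    return (
        genes,
        IntervalSet(h33_records, label="H3.3-CM"),
        IntervalSet(k27_records, label="H3K27ac"),
        truth,
    )
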