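"""Synthetic data with planted ground truth for every pipeline stage.

The generators emulate the data types the analysis consumes: droplet
scRNA-seq counts with cell-type archetypes and contiguous CNV blocks in
malignant cells, EAC/GAC reference single-cell sets with site labels,
paired tumor/NAT bulk expression with planted differential genes, a bulk
cohort with group-dependent exponential survival, paired LC-MS-like
metabolite intensities with pathway structure, cell-type reaction-flux /
stoichiometry matrix pairs, and Visium-like spot mixtures.

All randomness derives from one global seed fanned out to fixed
per-generator streams, so the same config is bit-reproducible and adding
one generator never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd

from ._utils import SEED_OFFSETS, child_rng

ORIGINS = ("AEG", "EAC", "GAC")

#: canonical protein-coding mitochondrial genes, used as the mito QC panel
MITO_GENES = (
    "MT-ND1", "MT-ND2", "MT-CO1", "MT-CO2", "MT-ATP8", "MT-ATP6", "MT-CO3",
    "MT-ND3", "MT-ND4L", "MT-ND4", "MT-ND5", "MT-ND6", "MT-CYB",
)

_CELLTYPE_NAMES = (
    "Epithelial", "Tcell", "Bcell", "Myeloid", "Fibroblast", "Endothelial",
)

#: reference sampling-site labels; only the keep-lists enter centroid building
REF_SITES = {
    "EAC": {"keep": ("esophagus_adeno",), "exclude": ("esophagus_squamous",)},
    "GAC": {"keep": ("body", "antrum", "distal"), "exclude": ("cardia",)},
}


class ConfigError(ValueError):
    """Raised when a SimConfig is internally inconsistent."""


@dataclass
class CnvBlock:
    chrom: str
    start_gene_idx: int  # index within the chromosome, 0-based
    length: int
    log2_effect: float


def _default_blocks() -> list[CnvBlock]:
    # 400 of 2000 autosomal genes (20%) at |log2| >= 0.6
    return [
        CnvBlock("chr2", 50, 150, 1.0),
        CnvBlock("chr5", 20, 120, -1.0),
        CnvBlock("chr8", 100, 100, 0.8),
        CnvBlock("chr10", 0, 30, -0.7),
    ]


@dataclass
class SimConfig:
    """Study conditions for every synthetic generator.

    The defaults are the conditions the pipeline is validated under:
    2,500 cells of which 20% are malignant, a 2,000-gene panel on ten
    chromosomes plus the 13 mitochondrial genes, CNV blocks covering 20%
    of the autosomal panel at |log2| >= 0.6, 200-gene origin programs at
    log2 effect 1, 20 paired bulk samples with 300 up / 300 down genes
    planted at log2 shift 2, a 248-sample survival cohort, 13 metabolome
    pairs, and 200 spatial spots.
    """

    n_cells: int = 2500
    n_genes: int = 2000
    n_celltypes: int = 4
    frac_malignant: float = 0.2
    origin_mix: tuple[float, float, float] = (0.2, 0.4, 0.4)
    cnv_blocks: list[CnvBlock] = field(default_factory=_default_blocks)
    program_size: int = 200
    program_effect: float = 1.0  # log2 fold on origin-program genes
    malignancy_program_size: int = 150  # genes up in all malignant cells
    malignancy_effect: float = 2.0
    normal_program_size: int = 300  # differentiation genes lost in tumors
    normal_program_effect: float = 1.5  # log2 upweight in normal epithelium
    nb_dispersion: float = 0.5
    mito_frac_range: tuple[float, float] = (0.01, 0.12)
    markers_per_type: int = 100
    marker_effect: float = 2.5  # log2 fold on cell-type marker genes
    clusters_per_origin: int = 2
    n_ref_cells: int = 300
    n_bulk_pairs: int = 20
    n_planted_de: int = 300
    planted_shift: float = 2.0  # log2, shared by bulk and metabolome planting
    cohort_size: int = 248
    hazard_by_group: dict[str, float] = field(
        default_factory=lambda: {"AEG": 0.045, "EAC": 0.015, "GAC": 0.015}
    )
    censor_horizon: float = 60.0  # months
    n_metab: int = 200
    n_metab_pairs: int = 13
    n_planted_metab: tuple[int, int] = (25, 25)
    n_pathways: int = 20
    n_reactions: int = 40
    n_flux_metabolites: int = 25
    n_spots: int = 200
    dirichlet_alpha: float | Sequence[float] = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 200:
            raise ConfigError("n_genes must be >= 200")
        if not 0.0 <= self.frac_malignant <= 1.0:
            raise ConfigError("frac_malignant must lie in [0, 1]")
        if not 0.0 <= self.mito_frac_range[0] <= self.mito_frac_range[1] <= 1.0:
            raise ConfigError("mito_frac_range must be an interval inside [0, 1]")
        if len(self.origin_mix) != 3:
            raise ConfigError("origin_mix needs three fractions (AEG, EAC, GAC)")
        if any(f < 0 or f > 1 for f in self.origin_mix):
            raise ConfigError("origin_mix fractions must lie in [0, 1]")
        if abs(sum(self.origin_mix) - 1.0) > 1e-12:
            raise ConfigError("origin_mix must sum to 1")
        if not 2 <= self.n_celltypes <= len(_CELLTYPE_NAMES):
            raise ConfigError(
                f"n_celltypes must be in [2, {len(_CELLTYPE_NAMES)}]"
            )
        self.cnv_blocks = [
            b if isinstance(b, CnvBlock) else CnvBlock(*b) for b in self.cnv_blocks
        ]
        per_chrom = _genes_per_chrom(self.n_genes)
        for b in self.cnv_blocks:
            size = per_chrom.get(b.chrom)
            if size is None:
                raise ConfigError(f"CNV block chromosome {b.chrom!r} not in genome")
            if b.start_gene_idx < 0 or b.start_gene_idx + b.length > size:
                raise ConfigError(
                    f"CNV block {b.chrom}:{b.start_gene_idx}+{b.length} exceeds "
                    f"the {size} genes on that chromosome"
                )

    @property
    def celltypes(self) -> tuple[str, ...]:
        return _CELLTYPE_NAMES[: self.n_celltypes]


@dataclass
class SyntheticTruth:
    """Planted ground truth sufficient to score every downstream stage."""

    cell_type: pd.Series | None = None
    is_malignant: pd.Series | None = None
    origin: pd.Series | None = None
    cluster: pd.Series | None = None
    cnv_profile: pd.DataFrame | None = None
    de_genes: pd.Series | None = None
    group: pd.Series | None = None
    metabolite_direction: pd.Series | None = None
    spot_proportions: pd.DataFrame | None = None


def _genes_per_chrom(n_genes: int, n_chroms: int = 10) -> dict[str, int]:
    base, extra = divmod(n_genes, n_chroms)
    return {
        f"chr{i + 1}": base + (1 if i < extra else 0) for i in range(n_chroms)
    }


@dataclass
class Archetypes:
    """Deterministic gene panel, annotation and expression archetypes.

    Shared by every generator so that, e.g., the cohort samples mix the
    same origin programs the scRNA cells carry.
    """

    genes: pd.Index
    annotation: pd.DataFrame  # gene_id index, chrom, start
    base_mean: np.ndarray  # per-gene NB mean for the background program
    type_means: pd.DataFrame  # cell types x genes
    program_genes: dict[str, pd.Index]  # origin -> gene ids
    malignancy_genes: pd.Index  # shared malignancy program (up in tumors)
    normal_program_genes: pd.Index  # epithelial differentiation, lost in tumors
    marker_genes: dict[str, pd.Index]  # cell type -> gene ids
    mito_genes: pd.Index
    cnv_log2: np.ndarray  # per-gene planted log2 copy ratio in malignant cells

    @property
    def autosomal(self) -> pd.Index:
        return self.genes.difference(self.mito_genes, sort=False)


def build_archetypes(config: SimConfig) -> Archetypes:
    return _build_archetypes_cached(_freeze(config))


def _freeze(config: SimConfig):
    return (
        config.n_genes,
        config.n_celltypes,
        tuple((b.chrom, b.start_gene_idx, b.length, b.log2_effect) for b in config.cnv_blocks),
        config.program_size,
        config.program_effect,
        config.malignancy_program_size,
        config.malignancy_effect,
        config.normal_program_size,
        config.normal_program_effect,
        config.markers_per_type,
        config.marker_effect,
        config.seed,
    )


@lru_cache(maxsize=8)
def _build_archetypes_cached(key) -> Archetypes:
    (n_genes, n_celltypes, blocks, program_size, program_effect,
     malignancy_program_size, malignancy_effect, normal_program_size,
     normal_program_effect, markers_per_type, marker_effect, seed) = key
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(SEED_OFFSETS["archetypes"],)))

    per_chrom = _genes_per_chrom(n_genes)
    chroms, starts, names = [], [], []
    gi = 0
    for chrom, size in per_chrom.items():
        for j in range(size):
            chroms.append(chrom)
            starts.append(j * 100_000)
            names.append(f"G{gi:04d}")
            gi += 1
    for j, m in enumerate(MITO_GENES):
        chroms.append("MT")
        starts.append(j * 1_000)
        names.append(m)
    genes = pd.Index(names, name="gene_id")
    annotation = pd.DataFrame({"chrom": chroms, "start": starts}, index=genes)

    n_total = len(genes)
    base_mean = rng.lognormal(mean=0.5, sigma=1.0, size=n_total)
    # mitochondrial means are rescaled per cell to hit the target fraction
    mito_mask = annotation["chrom"].to_numpy() == "MT"

    # planted CNV log2 ratio per gene (applies to malignant cells only)
    cnv_log2 = np.zeros(n_total)
    chrom_arr = annotation["chrom"].to_numpy()
    for chrom, start, length, eff in blocks:
        idx = np.flatnonzero(chrom_arr == chrom)[start : start + length]
        cnv_log2[idx] = eff

    # disjoint origin programs and cell-type markers, drawn from autosomal
    # genes outside the CNV blocks so planted effects do not confound
    free = np.flatnonzero(~mito_mask & (cnv_log2 == 0.0))
    rng.shuffle(free)
    need = (
        3 * program_size
        + malignancy_program_size
        + normal_program_size
        + n_celltypes * markers_per_type
    )
    if need > free.size:
        raise ConfigError(
            f"gene panel too small: need {need} program/marker genes, "
            f"have {free.size} outside CNV blocks"
        )
    cursor = 0
    program_genes: dict[str, pd.Index] = {}
    for origin in ORIGINS:
        program_genes[origin] = genes[np.sort(free[cursor : cursor + program_size])]
        cursor += program_size
    malignancy_genes = genes[np.sort(free[cursor : cursor + malignancy_program_size])]
    cursor += malignancy_program_size
    normal_program_genes = genes[np.sort(free[cursor : cursor + normal_program_size])]
    cursor += normal_program_size

    celltypes = _CELLTYPE_NAMES[:n_celltypes]
    marker_genes: dict[str, pd.Index] = {}
    type_means = pd.DataFrame(
        np.tile(base_mean, (n_celltypes, 1)), index=list(celltypes), columns=genes
    )
    for ct in celltypes:
        mk = np.sort(free[cursor : cursor + markers_per_type])
        cursor += markers_per_type
        marker_genes[ct] = genes[mk]
        type_means.loc[ct, genes[mk]] *= 2.0 ** marker_effect
    # differentiation program: expressed by normal epithelium, lost in tumors
    type_means.loc["Epithelial", normal_program_genes] *= 2.0 ** normal_program_effect

    return Archetypes(
        genes=genes,
        annotation=annotation,
        base_mean=base_mean,
        type_means=type_means,
        program_genes={k: v for k, v in program_genes.items()},
        malignancy_genes=malignancy_genes,
        normal_program_genes=normal_program_genes,
        marker_genes=marker_genes,
        mito_genes=genes[mito_mask],
        cnv_log2=cnv_log2,
    )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with Var = mean + dispersion * mean^2."""
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def _malignant_mean(arch: Archetypes, origin: str, config: SimConfig) -> np.ndarray:
    mean = arch.type_means.loc["Epithelial"].to_numpy().copy()
    mean *= 2.0 ** arch.cnv_log2
    cols = arch.genes.get_indexer(arch.program_genes[origin])
    mean[cols] *= 2.0 ** config.program_effect
    mal = arch.genes.get_indexer(arch.malignancy_genes)
    mean[mal] *= 2.0 ** config.malignancy_effect
    # differentiation loss: these genes drop below the unscaled background
    lost = arch.genes.get_indexer(arch.normal_program_genes)
    mean[lost] *= 2.0 ** -(config.normal_program_effect + 0.5)
    return mean


def _apply_mito_target(
    mean: np.ndarray, mito_cols: np.ndarray, target: float
) -> np.ndarray:
    """Rescale mito means so the expected mito fraction equals target."""
    mean = mean.copy()
    s_mito = mean[mito_cols].sum()
    s_rest = mean.sum() - s_mito
    if target <= 0 or s_mito == 0:
        mean[mito_cols] = 0.0
        return mean
    mean[mito_cols] *= (target / (1.0 - target)) * s_rest / s_mito
    return mean


def generate_scrna(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Simulate the in-house scRNA-seq sample.

    Returns (counts cells x genes, gene annotation, truth). Malignant
    cells are epithelial cells carrying the planted CNV blocks plus one
    of the three origin expression programs.
    """
    arch = build_archetypes(config)
    rng = child_rng(config.seed, "scrna")
    n = config.n_cells
    celltypes = list(config.celltypes)

    n_mal = int(round(n * config.frac_malignant))
    n_norm = n - n_mal
    # normal cells spread over the cell types, epithelial-rich
    weights = np.full(len(celltypes), 1.0)
    weights[0] = 2.0
    weights /= weights.sum()
    norm_types = rng.choice(celltypes, size=n_norm, p=weights)
    origins = rng.choice(ORIGINS, size=n_mal, p=np.asarray(config.origin_mix))

    barcodes = pd.Index([f"CELL{i:05d}" for i in range(n)], name="cell")
    mal_idx = np.sort(rng.choice(n, size=n_mal, replace=False))
    is_mal = np.zeros(n, dtype=bool)
    is_mal[mal_idx] = True

    cell_type = np.empty(n, dtype=object)
    cell_type[is_mal] = "Epithelial"
    cell_type[~is_mal] = norm_types
    origin = np.full(n, None, dtype=object)
    origin[mal_idx] = origins

    cluster = np.empty(n, dtype=object)
    cluster[~is_mal] = [f"C_{t}" for t in norm_types]
    sub = rng.integers(config.clusters_per_origin, size=n_mal)
    cluster[mal_idx] = [f"C_Mal_{o}_{s}" for o, s in zip(origins, sub)]

    mito_cols = arch.genes.get_indexer(arch.mito_genes)
    mito_target = rng.uniform(*config.mito_frac_range, size=n)
    depth = rng.lognormal(0.0, 0.3, size=n)

    mal_means = {o: _malignant_mean(arch, o, config) for o in ORIGINS}
    cnv_profile = np.zeros((n, len(arch.genes)))
    cnv_profile[is_mal] = arch.cnv_log2

    mean = np.empty((n, len(arch.genes)))
    for i in range(n):
        if is_mal[i]:
            mean[i] = mal_means[origin[i]]
        else:
            mean[i] = arch.type_means.loc[cell_type[i]].to_numpy()
    # rescale mito genes per cell to hit the target mito fraction, then depth
    mito_mask = np.zeros(len(arch.genes), dtype=bool)
    mito_mask[mito_cols] = True
    s_mito = mean[:, mito_mask].sum(axis=1)
    s_rest = mean.sum(axis=1) - s_mito
    factor = (mito_target / (1.0 - mito_target)) * s_rest / np.maximum(s_mito, 1e-12)
    mean[:, mito_mask] *= factor[:, None]
    mean *= depth[:, None]
    counts = _nb_draw(rng, mean, config.nb_dispersion)

    counts_df = pd.DataFrame(counts, index=barcodes, columns=arch.genes)
    truth = SyntheticTruth(
        cell_type=pd.Series(cell_type, index=barcodes, name="cell_type"),
        is_malignant=pd.Series(is_mal, index=barcodes, name="is_malignant"),
        origin=pd.Series(origin, index=barcodes, name="origin"),
        cluster=pd.Series(cluster, index=barcodes, name="cluster"),
        cnv_profile=pd.DataFrame(cnv_profile, index=barcodes, columns=arch.genes),
    )
    return counts_df, arch.annotation.copy(), truth


def generate_reference_sets(
    config: SimConfig,
) -> dict[str, tuple[pd.DataFrame, pd.DataFrame]]:
    """EAC and GAC reference single-cell sets with site/malignancy labels.

    Each class contains malignant cells from its origin archetype plus
    cells from excluded sites and non-malignant cells, so downstream
    site/malignancy filters are exercised.
    """
    arch = build_archetypes(config)
    rng = child_rng(config.seed, "reference")
    mito_cols = arch.genes.get_indexer(arch.mito_genes)
    out: dict[str, tuple[pd.DataFrame, pd.DataFrame]] = {}
    for cls in ("EAC", "GAC"):
        sites = REF_SITES[cls]
        n = config.n_ref_cells
        n_excl = int(round(0.2 * n))
        n_nonmal = int(round(0.1 * n))
        n_mal = n - n_excl - n_nonmal

        mean_mal = _malignant_mean(arch, cls, config)
        mean_norm = arch.type_means.loc["Epithelial"].to_numpy()

        rows, site_lab, mal_lab = [], [], []
        for kind, count in (("mal", n_mal), ("excl", n_excl), ("nonmal", n_nonmal)):
            for _ in range(count):
                target = rng.uniform(*config.mito_frac_range)
                depth = rng.lognormal(0.0, 0.3)
                base = mean_mal if kind != "nonmal" else mean_norm
                mean = _apply_mito_target(base, mito_cols, target) * depth
                rows.append(_nb_draw(rng, mean, config.nb_dispersion))
                if kind == "excl":
                    site_lab.append(rng.choice(sites["exclude"]))
                else:
                    site_lab.append(rng.choice(sites["keep"]))
                mal_lab.append(kind != "nonmal")
        barcodes = pd.Index([f"{cls}_{i:04d}" for i in range(n)], name="cell")
        counts = pd.DataFrame(np.array(rows), index=barcodes, columns=arch.genes)
        meta = pd.DataFrame(
            {"site": site_lab, "is_malignant": mal_lab}, index=barcodes
        )
        out[cls] = (counts, meta)
    return out


def generate_paired_bulk(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Paired tumor / NAT bulk expression with planted differential genes.

    The planted up-set contains the full AEG origin program, so the bulk-
    derived signature matches the program malignant AEG-origin cells carry.
    Matrices are linear-scale (TPM-like), samples x genes.
    """
    arch = build_archetypes(config)
    rng = child_rng(config.seed, "bulk")
    genes = arch.autosomal
    n_g = len(genes)
    n_pairs = config.n_bulk_pairs

    # bulk tumors mix malignant cells of all origins: their up-genes are the
    # shared malignancy program plus EGJ-specific (AEG-program) genes
    # bulk tumors mix malignant cells of all origins, so their up-genes are
    # the shared malignancy program plus EGJ-specific (AEG-program) genes;
    # down-genes are the differentiation program lost in tumors
    direction = pd.Series(0, index=genes, dtype=int, name="direction")
    up = list(arch.malignancy_genes) + list(arch.program_genes["AEG"])
    down = list(arch.normal_program_genes)
    pool = genes.difference(pd.Index(up + down), sort=False).to_numpy()
    rng.shuffle(pool)
    extra_up = max(0, config.n_planted_de - len(up))
    up = up + list(pool[:extra_up])
    extra_dn = max(0, config.n_planted_de - len(down))
    down = down + list(pool[extra_up : extra_up + extra_dn])
    direction.loc[up[: config.n_planted_de]] = 1
    direction.loc[down[: config.n_planted_de]] = -1

    baseline = rng.normal(5.0, 1.5, size=n_g)
    pair_eff = rng.normal(0.0, 0.5, size=n_pairs)
    shift = direction.to_numpy() * config.planted_shift
    noise_sd = 0.5

    t_log = (
        baseline[None, :]
        + pair_eff[:, None]
        + shift[None, :]
        + rng.normal(0.0, noise_sd, size=(n_pairs, n_g))
    )
    n_log = (
        baseline[None, :]
        + pair_eff[:, None]
        + rng.normal(0.0, noise_sd, size=(n_pairs, n_g))
    )
    samples_t = pd.Index([f"P{i:02d}_T" for i in range(n_pairs)], name="sample")
    samples_n = pd.Index([f"P{i:02d}_N" for i in range(n_pairs)], name="sample")
    tumor = pd.DataFrame(2.0 ** t_log, index=samples_t, columns=genes)
    nat = pd.DataFrame(2.0 ** n_log, index=samples_n, columns=genes)
    return tumor, nat, direction


def generate_cohort(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Bulk cohort: TPM-like expression, survival table and true groups.

    Samples are pseudo-bulks of one origin archetype; survival is
    exponential with the group hazard and uniform independent censoring.
    """
    arch = build_archetypes(config)
    rng = child_rng(config.seed, "cohort")
    n = config.cohort_size
    groups = rng.choice(ORIGINS, size=n, p=np.asarray(config.origin_mix))
    samples = pd.Index([f"TCGA{i:04d}" for i in range(n)], name="sample")
    genes = arch.autosomal
    gcols = arch.genes.get_indexer(genes)

    expr = np.empty((n, len(genes)))
    for i, g in enumerate(groups):
        mean = _malignant_mean(arch, g, config)[gcols]
        prof = mean * rng.lognormal(0.0, 0.3 * np.log(2.0), size=len(genes))
        expr[i] = prof / prof.sum() * 1e6  # TPM-like
    expr_df = pd.DataFrame(expr, index=samples, columns=genes)

    hazards = np.array([config.hazard_by_group[g] for g in groups])
    event_t = rng.exponential(1.0 / hazards)
    censor_t = rng.uniform(0.0, config.censor_horizon, size=n)
    time = np.minimum(event_t, censor_t)
    event = (event_t <= censor_t).astype(int)
    surv = pd.DataFrame({"time": time, "event": event}, index=samples)
    return expr_df, surv, pd.Series(groups, index=samples, name="group")


# small flavor set: metabolites the tumor/NAT comparison is known to move
_METAB_UP = ("spermine", "lithocholic_acid", "adenine", "glutamine", "proline")
_METAB_DOWN = (
    "gamma_linolenic_acid", "retinoic_acid_9cis", "dodecanoic_acid", "glutamate",
)


def generate_metabolome(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, list[str]], pd.Series]:
    """Paired tumor/normal metabolite intensities plus pathway membership.

    Returns (tumor, normal) intensity tables (metabolites x patients), a
    pathway map, and the planted signed directions. Intensities are
    log-normal; planted metabolites are shifted by ±planted_shift log2
    units in the tumor member of each pair.
    """
    rng = child_rng(config.seed, "metabolome")
    n_up, n_down = config.n_planted_metab
    names = list(_METAB_UP[:n_up]) + [
        f"metab_up_{i:02d}" for i in range(max(0, n_up - len(_METAB_UP)))
    ]
    names += list(_METAB_DOWN[:n_down]) + [
        f"metab_dn_{i:02d}" for i in range(max(0, n_down - len(_METAB_DOWN)))
    ]
    n_null = config.n_metab - len(names)
    if n_null < 0:
        raise ConfigError("n_metab smaller than the planted sets")
    names += [f"metab_{i:03d}" for i in range(n_null)]
    metabs = pd.Index(names, name="metabolite")
    direction = pd.Series(0, index=metabs, dtype=int, name="direction")
    direction.iloc[:n_up] = 1
    direction.iloc[n_up : n_up + n_down] = -1

    n_pairs = config.n_metab_pairs
    patients = pd.Index([f"PT{i:02d}" for i in range(n_pairs)], name="patient")
    base = rng.normal(20.0, 2.0, size=len(metabs))
    pat_eff = rng.normal(0.0, 1.0, size=n_pairs)
    noise_sd = 0.8
    shift = direction.to_numpy(dtype=float) * config.planted_shift
    t_log = base[:, None] + pat_eff[None, :] + shift[:, None] + rng.normal(
        0.0, noise_sd, size=(len(metabs), n_pairs)
    )
    n_log = base[:, None] + pat_eff[None, :] + rng.normal(
        0.0, noise_sd, size=(len(metabs), n_pairs)
    )
    tumor = pd.DataFrame(2.0 ** t_log, index=metabs, columns=patients)
    normal = pd.DataFrame(2.0 ** n_log, index=metabs, columns=patients)

    # pathway 1 is enriched for planted-up members, pathway 2 for planted-down
    pathways: dict[str, list[str]] = {}
    up_names, dn_names = names[:n_up], names[n_up : n_up + n_down]
    null_names = np.array(names[n_up + n_down :])
    pathways["arginine_proline_metabolism"] = (
        list(rng.choice(up_names, size=min(8, n_up), replace=False))
        + list(rng.choice(null_names, size=2, replace=False))
    )
    pathways["fatty_acid_biosynthesis"] = (
        list(rng.choice(dn_names, size=min(6, n_down), replace=False))
        + list(rng.choice(null_names, size=2, replace=False))
    )
    for i in range(max(0, config.n_pathways - 2)):
        size = int(rng.integers(5, 12))
        pathways[f"pathway_{i + 3:02d}"] = list(
            rng.choice(names, size=size, replace=False)
        )
    return tumor, normal, pathways, direction


def generate_flux_inputs(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Reaction-flux matrix R, signed stoichiometric matrix S, product R·S.

    R rows are cell types (malignant origin subtypes plus normal types);
    S columns carry compartment suffixes ([c], [e], [m], [l], [g]).
    """
    rng = child_rng(config.seed, "flux")
    celltypes = [f"Malignant_{o}" for o in ORIGINS] + list(
        _CELLTYPE_NAMES[: config.n_celltypes]
    )
    reactions = [f"RXN{i:03d}" for i in range(config.n_reactions)]
    compartments = ("[c]", "[e]", "[m]", "[l]", "[g]")
    bases = (
        "glucose", "glutamate", "glutamine", "arginine", "proline", "spermine",
        "ornithine", "putrescine", "lactate", "pyruvate",
    )
    metabs = []
    i = 0
    while len(metabs) < config.n_flux_metabolites:
        base = bases[i % len(bases)] if i < len(bases) * len(compartments) else f"m{i:03d}"
        metabs.append(f"{base}{compartments[i % len(compartments)]}")
        i += 1

    R = rng.lognormal(0.0, 1.0, size=(len(celltypes), len(reactions)))
    R *= rng.random(R.shape) < 0.7
    S = rng.integers(-2, 3, size=(len(reactions), len(metabs))).astype(float)
    S *= rng.random(S.shape) < 0.3
    R_df = pd.DataFrame(R, index=pd.Index(celltypes, name="cell_type"), columns=reactions)
    S_df = pd.DataFrame(S, index=pd.Index(reactions, name="reaction"), columns=metabs)
    product = R_df @ S_df
    return R_df, S_df, product


def generate_spots(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Visium-like spot counts mixed from cell-type archetypes.

    Spot proportions are Dirichlet over the normal cell types plus the
    three malignant origin subtypes; spot mean expression is the
    proportion-weighted archetype mean scaled to spot depth.
    """
    arch = build_archetypes(config)
    rng = child_rng(config.seed, "spots")
    types = [f"Malignant_{o}" for o in ORIGINS] + list(config.celltypes)
    centroids = np.vstack(
        [_malignant_mean(arch, o, config) for o in ORIGINS]
        + [arch.type_means.loc[t].to_numpy() for t in config.celltypes]
    )
    centroids = centroids / centroids.sum(axis=1, keepdims=True)

    alpha = np.asarray(config.dirichlet_alpha, dtype=float)
    if alpha.ndim == 0:
        alpha = np.full(len(types), float(alpha))
    if alpha.shape != (len(types),):
        raise ConfigError(
            f"dirichlet_alpha must be scalar or length {len(types)}"
        )
    props = rng.dirichlet(alpha, size=config.n_spots)
    depth = rng.lognormal(np.log(5000.0), 0.3, size=config.n_spots)
    mean = props @ centroids * depth[:, None]
    counts = _nb_draw(rng, mean, config.nb_dispersion)

    spots = pd.Index([f"SPOT{i:04d}" for i in range(config.n_spots)], name="spot")
    counts_df = pd.DataFrame(counts, index=spots, columns=arch.genes)
    props_df = pd.DataFrame(props, index=spots, columns=types)
    return counts_df, props_df
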