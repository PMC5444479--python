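"""Synthetic RIL populations and metabolome phenotypes with known truth.

The generator emulates the study design downstream stages are built for:
an F10 recombinant inbred population from a biparental cross (single-seed
descent), genotyped at 138 markers evenly spread over five chromosomes
(mean gap 3.4 cM, ~1 Mbp per 3.4 cM), phenotyped for 311 metabolite
traits organized in correlated blocks, with planted additive QTLs,
epistatic pairs, hotspot architectures, batch/day effects and outliers.

Meiosis is simulated on the marker skeleton: a gamete picks one parental
haplotype at the first marker of each chromosome and switches between
haplotypes with the inter-marker recombination probability given by the
inverse map function.  No interference beyond the map function is
modelled; the analysis only ever sees marker and pseudo-marker positions.

Traits are generated on a log-intensity-like scale:

    y = block latent + sum a_j x_j + sum e_kl x_k x_l + batch offset + noise

with x the {-1, +1} parental coding (HET -> 0).  ``to_raw_intensities``
exponentiates and applies seed-weight / internal-standard / measurement-day
factors so the normalization stage has realistic multiplicative structure
to remove.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import (
    AA,
    BB,
    HET,
    MISSING,
    GeneticMap,
    GenotypeMatrix,
    PhenotypeTable,
    SeedMqtlError,
    rng_for,
)

logger = logging.getLogger("seedmqtl")

__all__ = [
    "RilDesign",
    "SimTruth",
    "PlantedQtl",
    "PlantedEpistasis",
    "map_function",
    "inverse_map_function",
    "default_map_template",
    "simulate_ril_population",
    "simulate_metabolome",
    "to_raw_intensities",
    "study_architecture",
    "simulate_annotation_fixture",
]


# ---------------------------------------------------------------------------
# Map functions
# ---------------------------------------------------------------------------

def map_function(r, which: str = "kosambi"):
    """Genetic distance d (cM) from recombination fraction r."""
    r = np.asarray(r, float)
    if which == "kosambi":
        d_morgan = 0.25 * np.log((1 + 2 * r) / (1 - 2 * r))
    elif which == "haldane":
        d_morgan = -0.5 * np.log(1 - 2 * r)
    else:
        raise SeedMqtlError(f"unknown map function {which!r}")
    return d_morgan * 100.0


def inverse_map_function(d_cm, which: str = "kosambi"):
    """Recombination fraction r for a map distance d in cM.

    Kosambi: r = tanh(2d)/2; Haldane: r = (1 - exp(-2d))/2, with d in
    Morgans.  r lies in [0, 0.5).
    """
    d = np.asarray(d_cm, float)
    if np.any(d < 0):
        raise SeedMqtlError("map distance must be non-negative")
    d_morgan = d / 100.0
    if which == "kosambi":
        r = 0.5 * np.tanh(2 * d_morgan)
    elif which == "haldane":
        r = 0.5 * (1 - np.exp(-2 * d_morgan))
    else:
        raise SeedMqtlError(f"unknown map function {which!r}")
    return r if r.shape else float(r)


def ril_recombination_fraction(r):
    """Observed recombinant fraction between loci in selfed RILs.

    Repeated selfing lets recombinants accumulate over generations; at
    fixation the observed fraction is R = 2r/(1+2r).
    """
    r = np.asarray(r, float)
    out = 2 * r / (1 + 2 * r)
    return out if out.shape else float(out)


# ---------------------------------------------------------------------------
# Designs and truth bookkeeping
# ---------------------------------------------------------------------------

def default_map_template() -> GeneticMap:
    """Five chromosomes, 138 markers at exactly 3.4 cM spacing.

    Physical anchors place ~1 Mbp per 3.4 cM, mirroring the genome-wide
    average density of the mapping population this generator emulates.
    """
    counts = [28, 27, 27, 28, 28]
    rows = []
    for c, n in enumerate(counts, start=1):
        for i in range(n):
            cm = 3.4 * i
            rows.append(
                {
                    "marker": f"m{c}_{i + 1:02d}",
                    "chrom": str(c),
                    "pos_cm": cm,
                    "pos_bp": float(1 + round(cm * 1e6 / 3.4)),
                }
            )
    df = pd.DataFrame(rows).set_index("marker")
    return GeneticMap(df)


@dataclass
class RilDesign:
    """Parameters of the simulated RIL population.

    ``n_selfings`` counts selfing rounds applied to the fully
    heterozygous F1; 9 rounds take an F1 to F10, the study generation.
    """

    n_individuals: int = 393
    n_selfings: int = 9
    gmap: GeneticMap = field(default_factory=default_map_template)
    genotyping_error: float = 0.001
    missing_rate: float = 0.02
    map_function: str = "kosambi"

    def __post_init__(self) -> None:
        if self.n_individuals <= 0:
            raise SeedMqtlError("n_individuals must be positive")
        for rate in (self.genotyping_error, self.missing_rate):
            if not 0 <= rate <= 1:
                raise SeedMqtlError("rates must lie in [0,1]")


@dataclass
class PlantedQtl:
    chrom: str
    pos_cm: float
    effect: float
    expected_r2: float  # percent


@dataclass
class PlantedEpistasis:
    locus1: tuple[str, float]
    locus2: tuple[str, float]
    effect: float
    pattern: str = "masking"  # or "synergistic"


@dataclass
class SimTruth:
    """Ground truth of the simulated metabolome.

    planted_qtls / epistatic_pairs are keyed by trait name.  trait_blocks
    maps each trait to a (block id, latent weight); traits sharing a
    block id get correlated through a shared latent factor.  batch
    offsets are additive on the log-intensity scale (hence
    multiplicative on raw intensities).
    """

    traits: list[str]
    planted_qtls: dict[str, list[PlantedQtl]] = field(default_factory=dict)
    epistatic_pairs: dict[str, list[PlantedEpistasis]] = field(default_factory=dict)
    trait_blocks: dict[str, tuple[int, float]] = field(default_factory=dict)
    batch_effects: dict[tuple[str, str], float] = field(default_factory=dict)
    outlier_positions: list[tuple[str, str]] = field(default_factory=list)
    noise_sd: dict[str, float] = field(default_factory=dict)

    def validate_against(self, gmap: GeneticMap) -> None:
        chroms = set(gmap.chromosomes)
        for trait, qtls in self.planted_qtls.items():
            for q in qtls:
                if q.chrom not in chroms:
                    raise SeedMqtlError(
                        f"trait {trait!r}: planted chromosome {q.chrom!r} not on map"
                    )
                pos = gmap.positions(q.chrom)
                if not pos[0] <= q.pos_cm <= pos[-1]:
                    raise SeedMqtlError(
                        f"trait {trait!r}: planted position {q.pos_cm} outside "
                        f"chromosome {q.chrom} span"
                    )
                if not 0 < q.expected_r2 < 100:
                    raise SeedMqtlError("expected R2 must lie in (0,100)")


# ---------------------------------------------------------------------------
# Meiosis
# ---------------------------------------------------------------------------

def _interval_recomb(gmap: GeneticMap, which: str) -> np.ndarray:
    """Recombination fraction per adjacent marker pair, 0.5 across chromosomes."""
    r = []
    chroms = gmap.table["chrom"].to_numpy()
    pos = gmap.table["pos_cm"].to_numpy(float)
    for i in range(len(pos) - 1):
        if chroms[i] != chroms[i + 1]:
            r.append(0.5)
        else:
            r.append(inverse_map_function(pos[i + 1] - pos[i], which))
    return np.asarray(r)


def _gametes(haplos: np.ndarray, r: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One gamete per individual from (n, 2, M) haplotypes."""
    n, _, m = haplos.shape
    which = np.empty((n, m), dtype=np.int8)
    which[:, 0] = rng.integers(0, 2, n)
    cross = rng.random((n, m - 1)) < r
    which[:, 1:] = np.logical_xor.accumulate(cross, axis=1)
    which[:, 1:] ^= which[:, [0]]
    return np.take_along_axis(haplos, which[:, None, :], axis=1)[:, 0, :]


def simulate_ril_population(
    design: RilDesign, seed: int
) -> tuple[GeneticMap, GenotypeMatrix]:
    """Simulate a RIL population by single-seed descent.

    The F1 is fully heterozygous; each selfing generation draws two
    gametes per line and keeps a single offspring.  Genotyping error
    flips a call to a uniformly chosen different parental homozygote;
    missing calls are masked completely at random.
    """
    gmap = design.gmap
    rng = rng_for(seed, "ril-population")
    n, m = design.n_individuals, gmap.n_markers
    r = _interval_recomb(gmap, design.map_function)

    haplos = np.zeros((n, 2, m), dtype=np.int8)
    haplos[:, 1, :] = 1  # F1: one haplotype from each parent
    for _ in range(design.n_selfings):
        g1 = _gametes(haplos, r, rng)
        g2 = _gametes(haplos, r, rng)
        haplos = np.stack([g1, g2], axis=1)

    calls = np.where(
        haplos[:, 0, :] == haplos[:, 1, :],
        np.where(haplos[:, 0, :] == 0, AA, BB),
        HET,
    ).astype(np.int8)

    if design.genotyping_error > 0:
        err = rng.random((n, m)) < design.genotyping_error
        flip_to = rng.integers(0, 2, (n, m)).astype(np.int8)  # AA or BB
        new = np.where(calls == AA, BB, np.where(calls == BB, AA, flip_to))
        calls = np.where(err, new, calls).astype(np.int8)
    if design.missing_rate > 0:
        calls = np.where(
            rng.random((n, m)) < design.missing_rate, MISSING, calls
        ).astype(np.int8)

    ids = [f"RIL{i + 1:04d}" for i in range(n)]
    df = pd.DataFrame(calls, index=pd.Index(ids, name="id"), columns=gmap.marker_names)
    return gmap, GenotypeMatrix(df)


# ---------------------------------------------------------------------------
# Phenotype forward model
# ---------------------------------------------------------------------------

def _snap_to_marker(gmap: GeneticMap, chrom: str, pos_cm: float) -> str:
    sub = gmap.markers(chrom)
    pos = sub["pos_cm"].to_numpy(float)
    return str(sub.index[int(np.argmin(np.abs(pos - pos_cm)))])


def _dosage(calls: np.ndarray) -> np.ndarray:
    """{-1, 0, +1} coding: AA -> -1, HET/missing -> 0, BB -> +1."""
    x = np.zeros(calls.shape, float)
    x[calls == AA] = -1.0
    x[calls == BB] = 1.0
    return x


def simulate_metabolome(
    geno: GenotypeMatrix,
    gmap: GeneticMap,
    truth: SimTruth,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> PhenotypeTable:
    """Generate trait values from planted architecture (log-intensity scale).

    Planted positions are snapped to the nearest marker for effect
    computation.  Outlier positions get an 8-noise-SD offset added so the
    outlier filter has unambiguous targets.  Metadata (batch, day, seed
    weight, internal standard, seed count) is attached; batches and days
    are assigned cyclically.
    """
    truth.validate_against(gmap)
    rng = rng_for(seed, "metabolome")
    inds = geno.individuals
    n = len(inds)

    n_blocks = (
        max((b for b, _ in truth.trait_blocks.values()), default=-1) + 1
        if truth.trait_blocks
        else 0
    )
    latents = rng.standard_normal((n, max(n_blocks, 1)))

    batches = np.array([f"B{i % 4 + 1}" for i in range(n)])
    days = np.array([f"D{i % 6 + 1}" for i in range(n)])

    values = np.empty((n, len(truth.traits)))
    for t, trait in enumerate(truth.traits):
        sd = truth.noise_sd.get(trait, noise_sd)
        y = rng.standard_normal(n) * sd
        block = truth.trait_blocks.get(trait)
        if block is not None:
            bid, weight = block
            y += weight * latents[:, bid]
        for q in truth.planted_qtls.get(trait, []):
            marker = _snap_to_marker(gmap, q.chrom, q.pos_cm)
            y += q.effect * _dosage(geno.calls[marker].to_numpy())
        for ep in truth.epistatic_pairs.get(trait, []):
            m1 = _snap_to_marker(gmap, *ep.locus1)
            m2 = _snap_to_marker(gmap, *ep.locus2)
            x1 = _dosage(geno.calls[m1].to_numpy())
            x2 = _dosage(geno.calls[m2].to_numpy())
            if ep.pattern == "masking":
                # allele 2 acts only inside the x1 = -1 (AA) class
                y += ep.effect * (x1 == -1) * x2
            else:
                y += ep.effect * x1 * x2
        for (batch, bt), offset in truth.batch_effects.items():
            if bt == trait:
                y += offset * (batches == batch)
        values[:, t] = y

    df = pd.DataFrame(values, index=pd.Index(inds, name="id"), columns=truth.traits)
    for ind, trait in truth.outlier_positions:
        if ind not in df.index:
            logger.warning("outlier position (%s, %s) outside population; skipped",
                           ind, trait)
            continue
        sd = truth.noise_sd.get(trait, noise_sd)
        df.loc[ind, trait] += 8.0 * max(sd, 1.0)

    meta = pd.DataFrame(
        {
            "batch": batches,
            "day": days,
            "seed_weight": rng.uniform(15.0, 25.0, n),  # mg per 60-seed pool
            "is_intensity": rng.uniform(0.8e5, 1.2e5, n),
            "seed_count": np.full(n, 60),
        },
        index=df.index,
    )
    return PhenotypeTable(df, meta)


def to_raw_intensities(
    pheno: PhenotypeTable, day_factors: dict[str, float] | None = None
) -> PhenotypeTable:
    """Convert log-scale traits to raw detector intensities.

    Raw = exp(y) * seed_weight * IS_intensity * day_factor, i.e. exactly
    the multiplicative structure the normalization stage divides out.
    """
    if pheno.metadata is None:
        raise SeedMqtlError("metadata required to construct raw intensities")
    meta = pheno.metadata
    factor = meta["seed_weight"].to_numpy() * meta["is_intensity"].to_numpy()
    if day_factors:
        factor = factor * meta["day"].map(day_factors).to_numpy(float)
    raw = np.exp(pheno.values.to_numpy()) * factor[:, None]
    return PhenotypeTable(
        pd.DataFrame(raw, index=pheno.values.index, columns=pheno.values.columns),
        meta.copy(),
    )


def calibrated_effect(expected_r2_percent: float, total_var: float = 1.0) -> float:
    """Additive effect giving the target per-QTL R2 at unit dosage variance.

    With x in {-1,+1} at allele frequency 1/2, Var(a*x) = a^2, so
    a = sqrt(R2 * total variance)."""
    return float(np.sqrt(expected_r2_percent / 100.0 * total_var))


def study_architecture(
    gmap: GeneticMap,
    n_traits: int = 311,
    seed: int = 0,
    master_fraction: float = 0.4,
    n_blocks: int = 25,
    n_epistatic: int = 4,
    outlier_rate: float = 0.001,
    n_individuals: int = 393,
) -> SimTruth:
    """A study-scale trait architecture with hotspot and master locus.

    Builds correlated trait blocks, scatters additive QTLs with explained
    variances spanning ~0.5-78%, plants a master locus (one mid-genome
    marker driving ``master_fraction`` of all traits), a handful of
    masking epistatic pairs, batch offsets and rare outliers.  Total
    variance per trait is normalized to ~1 so expected R2 values are
    meaningful.
    """
    rng = rng_for(seed, "architecture")
    traits = [f"met{i + 1:03d}" for i in range(n_traits)]
    truth = SimTruth(traits=traits)

    chroms = gmap.chromosomes
    master_chrom = chroms[3] if len(chroms) > 3 else chroms[-1]
    master_pos = float(np.median(gmap.positions(master_chrom)))
    n_master = int(round(master_fraction * n_traits))
    master_traits = set(rng.choice(n_traits, size=n_master, replace=False).tolist())

    block_ids = rng.integers(0, n_blocks, n_traits)
    for t, trait in enumerate(traits):
        r2_budget = 0.0
        qtls = []
        if t in master_traits:
            r2 = float(rng.uniform(10, 35))
            qtls.append(
                PlantedQtl(master_chrom, master_pos, calibrated_effect(r2), r2)
            )
            r2_budget += r2
        for _ in range(rng.integers(0, 3)):
            r2 = float(min(rng.lognormal(1.2, 1.0), 78.0 - r2_budget))
            if r2 < 0.5:
                continue
            chrom = str(rng.choice(chroms))
            pos = gmap.positions(chrom)
            qtls.append(
                PlantedQtl(
                    chrom,
                    float(rng.uniform(pos[0], pos[-1])),
                    calibrated_effect(r2) * (1 if rng.random() < 0.5 else -1),
                    r2,
                )
            )
            r2_budget += r2
        if qtls:
            truth.planted_qtls[trait] = qtls
        block_var = float(rng.uniform(0.05, 0.25))
        truth.trait_blocks[trait] = (int(block_ids[t]), np.sqrt(block_var))
        resid = max(1.0 - r2_budget / 100.0 - block_var, 0.05)
        truth.noise_sd[trait] = float(np.sqrt(resid))

    for trait in rng.choice(traits, size=min(n_epistatic, n_traits), replace=False):
        c1, c2 = rng.choice(chroms, size=2, replace=False)
        p1 = gmap.positions(str(c1))
        p2 = gmap.positions(str(c2))
        truth.epistatic_pairs.setdefault(str(trait), []).append(
            PlantedEpistasis(
                (str(c1), float(rng.uniform(p1[0], p1[-1]))),
                (str(c2), float(rng.uniform(p2[0], p2[-1]))),
                effect=0.4,
                pattern="masking",
            )
        )

    for batch in ("B2", "B4"):
        for trait in rng.choice(traits, size=n_traits // 5, replace=False):
            truth.batch_effects[(batch, str(trait))] = float(rng.normal(0, 0.3))

    n_out = rng.binomial(n_individuals * n_traits, outlier_rate)
    for _ in range(n_out):
        truth.outlier_positions.append(
            (f"RIL{rng.integers(1, n_individuals + 1):04d}", str(rng.choice(traits)))
        )
    return truth


# ---------------------------------------------------------------------------
# Annotation / pathway fixture
# ---------------------------------------------------------------------------

def simulate_annotation_fixture(
    gmap: GeneticMap,
    truth: SimTruth,
    seed: int = 0,
    gene_spacing_bp: int = 20000,
    tf_fraction: float = 0.08,
):
    """Emit a PathwayDB-style fixture wired to the planted architecture.

    Genes are tiled along each chromosome every ``gene_spacing_bp``; for
    every planted QTL a designated causal gene is placed at the QTL's
    physical position and wired into a reaction that produces the trait
    metabolite, and the metabolite/gene are grouped into a pathway with
    its block siblings.  A random subset of genes is flagged as
    transcription factors.
    """
    from .core_io import PathwayDB

    if not gmap.has_bp_anchors():
        raise SeedMqtlError("annotation fixture requires bp anchors on the map")
    rng = rng_for(seed, "annotation")

    rows = []
    gid = 0
    for chrom in gmap.chromosomes:
        sub = gmap.markers(chrom)
        lo = int(sub["pos_bp"].iloc[0])
        hi = int(sub["pos_bp"].iloc[-1])
        for start in range(lo, hi, gene_spacing_bp):
            gid += 1
            rows.append(
                {
                    "gene_id": f"G{chrom}_{gid:05d}",
                    "chrom": chrom,
                    "start": start,
                    "end": start + int(gene_spacing_bp * 0.4),
                    "strand": "+" if rng.random() < 0.5 else "-",
                    "description": "tiled gene",
                }
            )
    genes = pd.DataFrame(rows).set_index("gene_id")

    reactions = {}
    pathway_members: dict[int, tuple[set, set]] = {}
    rid = 0
    for trait, qtls in truth.planted_qtls.items():
        block = truth.trait_blocks.get(trait, (0, 0.0))[0]
        mets, genes_in_pw = pathway_members.setdefault(block, (set(), set()))
        mets.add(trait)
        for q in qtls:
            bp = gmap.bp_at(q.chrom, q.pos_cm)
            sub = genes[genes["chrom"] == q.chrom]
            mid = (sub["start"] + sub["end"]) / 2.0
            causal = sub.index[int(np.argmin(np.abs(mid.to_numpy() - bp)))]
            rid += 1
            reactions[f"RXN{rid:04d}"] = {
                "genes": (causal,),
                "substrates": (f"{trait}_precursor",),
                "products": (trait,),
            }
            genes_in_pw.add(causal)

    pathways = {
        f"PWY{b:03d}": {
            "metabolites": tuple(sorted(m)),
            "genes": tuple(sorted(g)),
        }
        for b, (m, g) in sorted(pathway_members.items())
    }

    families = ["bZIP", "MYB", "WRKY", "bHLH", "ABI3VP1", "C2H2"]
    n_tf = int(round(tf_fraction * len(genes)))
    tf_genes = rng.choice(genes.index.to_numpy(), size=n_tf, replace=False)
    tf = pd.DataFrame(
        {"family": [families[i % len(families)] for i in range(n_tf)]},
        index=pd.Index(sorted(tf_genes), name="gene_id"),
    )

    rx_df = pd.DataFrame.from_dict(reactions, orient="index")
    rx_df.index.name = "reaction_id"
    if rx_df.empty:
        rx_df = pd.DataFrame(columns=["genes", "substrates", "products"])
        rx_df.index.name = "reaction_id"
    pw_df = pd.DataFrame.from_dict(pathways, orient="index")
    pw_df.index.name = "pathway_id"
    if pw_df.empty:
        pw_df = pd.DataFrame(columns=["metabolites", "genes"])
        pw_df.index.name = "pathway_id"
    return PathwayDB(genes, rx_df, pw_df, tf)
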