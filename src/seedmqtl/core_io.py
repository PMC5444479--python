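"""Domain types, configuration and file I/O for the seed mQTL pipeline.

The pipeline operates on four kinds of objects: a genetic map (marker
positions in cM, optionally anchored to physical bp coordinates), a
genotype matrix of RIL calls over the two parental homozygote classes,
a phenotype table of metabolite intensities with per-sample metadata,
and a pathway database used for candidate-gene queries.  Everything is
backed by pandas so that downstream numerics can drop to numpy arrays.

Genotype orientation is fixed throughout the package: ``AA`` is the
Col-0-type homozygote, ``BB`` the C24-type homozygote, and additive
effects are reported as (BB - AA)/2 contrasts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("seedmqtl")

# Integer genotype codes used in GenotypeMatrix.calls
AA: int = 0
BB: int = 1
HET: int = 2
MISSING: int = -1

CODE_TO_STR = {AA: "AA", BB: "BB", HET: "HET", MISSING: "NA"}
STR_TO_CODE = {v: k for k, v in CODE_TO_STR.items()}
# single-letter dialect used by the combined mapping CSV
CODE_TO_LETTER = {AA: "A", BB: "B", HET: "H", MISSING: "-"}
LETTER_TO_CODE = {v: k for k, v in CODE_TO_LETTER.items()}

METADATA_COLUMNS = ["batch", "day", "seed_weight", "is_intensity", "seed_count"]


class SeedMqtlError(ValueError):
    """Raised on invalid inputs (bad map order, unknown genotype codes, ...)."""


def rng_for(seed: int, stage: str) -> np.random.Generator:
    """Deterministic child RNG for a named pipeline stage.

    Every randomized procedure in the package draws from a generator
    obtained here, so that a single top-level seed reproduces the whole
    analysis while stages remain independent of each other's draw order.
    """
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(stage.encode())])


# ---------------------------------------------------------------------------
# Genetic map
# ---------------------------------------------------------------------------

@dataclass
class GeneticMap:
    """Marker positions in cM per chromosome, with optional bp anchors.

    ``table`` has one row per marker (index = marker name) and columns
    ``chrom``, ``pos_cm`` and optionally ``pos_bp`` (1-based physical
    position).  Within each chromosome cM positions strictly increase,
    and bp anchors, where present, increase with cM.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            dups = t.index[t.index.duplicated()].tolist()
            raise SeedMqtlError(f"duplicate marker names: {dups}")
        if "pos_bp" not in t.columns:
            t = t.assign(pos_bp=np.nan)
            self.table = t
        for chrom, sub in t.groupby("chrom", sort=False):
            pos = sub["pos_cm"].to_numpy(float)
            if np.any(pos < 0):
                raise SeedMqtlError(f"negative cM position on chromosome {chrom}")
            bad = np.flatnonzero(np.diff(pos) <= 0)
            if bad.size:
                i = bad[0]
                raise SeedMqtlError(
                    f"map positions not strictly increasing on chromosome {chrom}: "
                    f"marker {sub.index[i + 1]!r} at {pos[i + 1]} cM follows "
                    f"{sub.index[i]!r} at {pos[i]} cM"
                )
            bp = sub["pos_bp"].to_numpy(float)
            if np.isfinite(bp).all() and np.any(np.diff(bp) <= 0):
                raise SeedMqtlError(
                    f"bp anchors not increasing with cM on chromosome {chrom}"
                )

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.table["chrom"]))

    @property
    def marker_names(self) -> list[str]:
        return list(self.table.index)

    @property
    def n_markers(self) -> int:
        return len(self.table)

    def markers(self, chrom: str) -> pd.DataFrame:
        return self.table[self.table["chrom"] == chrom]

    def positions(self, chrom: str) -> np.ndarray:
        return self.markers(chrom)["pos_cm"].to_numpy(float)

    def has_bp_anchors(self) -> bool:
        return bool(np.isfinite(self.table["pos_bp"].to_numpy(float)).all())

    def bp_at(self, chrom: str, pos_cm: float) -> float:
        """Interpolate a physical position for a cM coordinate.

        Piecewise-linear between bp-anchored markers; clamped at the
        chromosome ends.
        """
        sub = self.markers(chrom)
        cm = sub["pos_cm"].to_numpy(float)
        bp = sub["pos_bp"].to_numpy(float)
        if not np.isfinite(bp).all():
            missing = sub.index[~np.isfinite(bp)][0]
            raise SeedMqtlError(f"marker {missing!r} has no bp anchor")
        return float(np.interp(pos_cm, cm, bp))

    def __eq__(self, other: object) -> bool:  # round-trip identity in tests
        if not isinstance(other, GeneticMap):
            return NotImplemented
        try:
            pd.testing.assert_frame_equal(
                self.table, other.table, check_dtype=False, atol=1e-9
            )
            return True
        except AssertionError:
            return False


@dataclass
class MapSummary:
    n_markers: int
    mean_gap_cm: float
    per_chromosome: pd.DataFrame  # columns: n_markers, span_cm, mean_gap_cm


def map_summary(gmap: GeneticMap) -> MapSummary:
    """Marker count, per-chromosome span and pooled mean inter-marker gap.

    The pooled mean gap is the sum of adjacent gaps over all chromosomes
    divided by the total number of gaps; chromosomes with fewer than two
    markers contribute no gaps.
    """
    rows = []
    total_gap = 0.0
    n_gaps = 0
    for chrom in gmap.chromosomes:
        pos = gmap.positions(chrom)
        gaps = np.diff(pos)
        if gaps.size == 0:
            logger.warning("chromosome %s has <2 markers; no gaps", chrom)
        rows.append(
            {
                "chrom": chrom,
                "n_markers": len(pos),
                "span_cm": float(pos[-1] - pos[0]) if len(pos) else 0.0,
                "mean_gap_cm": float(gaps.mean()) if gaps.size else np.nan,
            }
        )
        total_gap += float(gaps.sum())
        n_gaps += gaps.size
    per_chrom = pd.DataFrame(rows).set_index("chrom")
    mean_gap = total_gap / n_gaps if n_gaps else float("nan")
    return MapSummary(gmap.n_markers, mean_gap, per_chrom)


# ---------------------------------------------------------------------------
# Genotypes and phenotypes
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """RIL x marker calls, stored as int8 codes (AA/BB/HET/MISSING).

    ``calls`` is individuals (rows) by markers (columns); column order
    must match the accompanying :class:`GeneticMap`.
    """

    calls: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.calls.to_numpy()
        valid = np.isin(arr, (AA, BB, HET, MISSING))
        if not valid.all():
            bad = sorted(set(np.asarray(arr)[~valid].tolist()))
            raise SeedMqtlError(f"unknown genotype codes: {bad}")
        self.calls = self.calls.astype(np.int8)

    @property
    def individuals(self) -> list[str]:
        return list(self.calls.index)

    @property
    def n_individuals(self) -> int:
        return len(self.calls)

    def missing_fraction(self) -> pd.Series:
        """Per-marker fraction of MISSING calls."""
        return (self.calls == MISSING).mean(axis=0)

    def aligned_to(self, gmap: GeneticMap) -> "GenotypeMatrix":
        missing = set(gmap.marker_names) - set(self.calls.columns)
        if missing:
            raise SeedMqtlError(f"genotype matrix lacks markers: {sorted(missing)}")
        return GenotypeMatrix(self.calls[gmap.marker_names])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return self.calls.equals(other.calls)


@dataclass
class PhenotypeTable:
    """Trait values per individual plus per-sample measurement metadata.

    ``values``: individuals x traits, float with NaN for missing.
    ``metadata``: individuals x (batch, day, seed_weight, is_intensity,
    seed_count); may be None for tables that never enter normalization
    (e.g. PC scores exported for mapping).
    """

    values: pd.DataFrame
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if self.metadata is not None:
            miss = set(self.values.index) - set(self.metadata.index)
            if miss:
                raise SeedMqtlError(f"metadata missing for individuals: {sorted(miss)}")
            self.metadata = self.metadata.loc[self.values.index]

    @property
    def individuals(self) -> list[str]:
        return list(self.values.index)

    @property
    def traits(self) -> list[str]:
        return list(self.values.columns)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PhenotypeTable):
            return NotImplemented
        try:
            pd.testing.assert_frame_equal(self.values, other.values, atol=1e-9)
            if (self.metadata is None) != (other.metadata is None):
                return False
            if self.metadata is not None:
                pd.testing.assert_frame_equal(
                    self.metadata, other.metadata, check_dtype=False, atol=1e-9
                )
            return True
        except AssertionError:
            return False


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class ScanConfig:
    """Settings of the QTL analysis.

    Defaults follow the study design this pipeline implements: a 1 cM
    pseudo-marker grid, genotyping error probability 1e-4 under the
    Kosambi map function, genome-wide thresholds from 10 000 permutations
    at alpha 0.05, composite interval mapping with five forward-selected
    covariates and a 20 cM exclusion window, penalties from 3000 two-QTL
    scan permutations, 1.5-LOD support intervals, an 85% presence filter,
    outlier removal at median +/- 4 SD, and the hotspot null at the 95%
    quantile of 10 000 permutations.
    """

    step_cm: float = 1.0
    genotyping_error: float = 0.0001
    map_function: str = "kosambi"
    n_perm_main: int = 10000
    alpha: float = 0.05
    cim_covariates: int = 5
    cim_window_cm: float = 20.0
    lod_drop: float = 1.5
    n_perm_scantwo: int = 3000
    scantwo_step_cm: float = 2.5
    penalties: tuple[float, float, float] | None = None  # (main, heavy, light)
    presence_threshold: float = 0.85
    outlier_sd_mult: float = 4.0
    hotspot_quantile: float = 0.95
    n_perm_hotspot: int = 10000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise SeedMqtlError(f"alpha must be in (0,1), got {self.alpha}")
        if self.step_cm <= 0:
            raise SeedMqtlError("step_cm must be positive")
        if self.map_function not in ("kosambi", "haldane"):
            raise SeedMqtlError(f"unknown map function {self.map_function!r}")
        if self.penalties is not None:
            self.penalties = tuple(float(p) for p in self.penalties)  # type: ignore
            if any(p < 0 for p in self.penalties):
                raise SeedMqtlError("penalties must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScanConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        if data["penalties"] is not None:
            data["penalties"] = list(data["penalties"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Scan results
# ---------------------------------------------------------------------------

@dataclass
class LodCurve:
    """LOD scores on a (chromosome, cM) pseudo-marker grid.

    ``table`` columns: chrom, pos_cm, lod.  ``covariates`` records the
    marker covariates of a composite-interval-mapping curve.
    """

    table: pd.DataFrame
    covariates: list[str] | None = None

    @property
    def max_lod(self) -> float:
        return float(self.table["lod"].max())

    def chrom(self, chrom: str) -> pd.DataFrame:
        return self.table[self.table["chrom"] == chrom]

    def apex(self, chrom: str) -> tuple[float, float]:
        """(pos_cM, lod) of the chromosome maximum; ties broken leftmost."""
        sub = self.chrom(chrom)
        i = int(np.argmax(sub["lod"].to_numpy()))
        return float(sub["pos_cm"].iloc[i]), float(sub["lod"].iloc[i])


@dataclass
class SupportInterval:
    chrom: str
    apex_cm: float
    lo_cm: float
    hi_cm: float
    lo_marker: str
    hi_marker: str
    lo_bp: float | None = None
    hi_bp: float | None = None

    def __post_init__(self) -> None:
        if not self.lo_cm <= self.apex_cm <= self.hi_cm:
            raise SeedMqtlError(
                f"support interval violates lo <= apex <= hi: "
                f"{self.lo_cm}, {self.apex_cm}, {self.hi_cm}"
            )


@dataclass
class QtlEffect:
    chrom: str
    pos_cm: float
    effect: float = float("nan")  # additive (BB - AA)/2 contrast, trait units
    r2: float = float("nan")      # percent variance explained (type-III drop)
    lod: float = float("nan")


@dataclass
class QtlModel:
    """A multiple-QTL model for one trait.

    ``interactions`` holds (i, j, lod) index pairs into ``qtls``;
    ``combined_r2`` is the percent variance explained by the simultaneous
    fit; ``support`` holds one 1.5-LOD support interval per QTL.
    """

    trait: str
    qtls: list[QtlEffect] = field(default_factory=list)
    interactions: list[tuple[int, int, float]] = field(default_factory=list)
    combined_r2: float = 0.0
    lod: float = 0.0
    support: list[SupportInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        for i, j, _ in self.interactions:
            if i == j or not (0 <= i < len(self.qtls) and 0 <= j < len(self.qtls)):
                raise SeedMqtlError(f"invalid interaction pair ({i}, {j})")

    @property
    def n_qtls(self) -> int:
        return len(self.qtls)

    def to_dict(self) -> dict:
        return {
            "trait": self.trait,
            "lod": self.lod,
            "combined_r2": self.combined_r2,
            "qtls": [dataclasses.asdict(q) for q in self.qtls],
            "interactions": [list(t) for t in self.interactions],
            "support": [dataclasses.asdict(s) for s in self.support],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "QtlModel":
        return cls(
            trait=d["trait"],
            qtls=[QtlEffect(**q) for q in d["qtls"]],
            interactions=[tuple(t) for t in d["interactions"]],
            combined_r2=d["combined_r2"],
            lod=d["lod"],
            support=[SupportInterval(**s) for s in d["support"]],
        )


def write_models_json(models: Sequence[QtlModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump([m.to_dict() for m in models], fh, indent=1)


def read_models_json(path: str | Path) -> list[QtlModel]:
    with open(path) as fh:
        return [QtlModel.from_dict(d) for d in json.load(fh)]


# ---------------------------------------------------------------------------
# Pathway database
# ---------------------------------------------------------------------------

@dataclass
class PathwayDB:
    """Gene annotation plus reaction/pathway/TF relations.

    genes: index gene_id; columns chrom, start, end, strand, description
    (1-based inclusive coordinates).
    reactions: index reaction_id; columns genes, substrates, products
    (each a tuple of ids).
    pathways: index pathway_id; columns metabolites, genes (tuples).
    tf_list: index gene_id; column family.
    """

    genes: pd.DataFrame
    reactions: pd.DataFrame
    pathways: pd.DataFrame
    tf_list: pd.DataFrame

    def __post_init__(self) -> None:
        g = self.genes
        if (g["start"] > g["end"]).any():
            bad = g.index[g["start"] > g["end"]].tolist()
            raise SeedMqtlError(f"genes with start > end: {bad}")
        known = set(g.index)
        for rid, row in self.reactions.iterrows():
            unknown = set(row["genes"]) - known
            if unknown:
                raise SeedMqtlError(
                    f"reaction {rid} references unknown genes: {sorted(unknown)}"
                )
        for pid, row in self.pathways.iterrows():
            unknown = set(row["genes"]) - known
            if unknown:
                raise SeedMqtlError(
                    f"pathway {pid} references unknown genes: {sorted(unknown)}"
                )

    @property
    def metabolites(self) -> set[str]:
        mets: set[str] = set()
        for row in self.reactions.itertuples():
            mets.update(row.substrates)
            mets.update(row.products)
        for row in self.pathways.itertuples():
            mets.update(row.metabolites)
        return mets


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_map_tsv(path: str | Path) -> GeneticMap:
    """Read a genetic map TSV: chrom, marker, pos_cm[, pos_bp]."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "marker": str})
    df = df.set_index("marker")
    if "pos_bp" not in df.columns:
        df["pos_bp"] = np.nan
    return GeneticMap(df[["chrom", "pos_cm", "pos_bp"]])


def write_map_tsv(gmap: GeneticMap, path: str | Path) -> None:
    out = gmap.table.reset_index().rename(columns={"index": "marker"})
    cols = ["chrom", "marker", "pos_cm", "pos_bp"]
    out = out[[c for c in cols if c in out.columns]]
    if out["pos_bp"].isna().all():
        out = out.drop(columns=["pos_bp"])
    out.to_csv(path, sep="\t", index=False)


def read_genotypes_csv(path: str | Path) -> GenotypeMatrix:
    """Genotype CSV: rows = individuals (first column id), values AA/BB/HET/NA."""
    df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    unknown = set(np.unique(df.to_numpy())) - set(STR_TO_CODE)
    if unknown:
        raise SeedMqtlError(f"unknown genotype codes: {sorted(unknown)}")
    coded = df.apply(lambda col: col.map(STR_TO_CODE)).astype(np.int8)
    return GenotypeMatrix(coded)


def write_genotypes_csv(geno: GenotypeMatrix, path: str | Path) -> None:
    as_str = geno.calls.apply(lambda col: col.map(CODE_TO_STR))
    as_str.to_csv(path, index_label="id")


def read_phenotypes_csv(
    path: str | Path, meta_path: str | Path | None = None
) -> PhenotypeTable:
    values = pd.read_csv(path, index_col=0)
    values.index = values.index.astype(str)
    meta = None
    if meta_path is not None:
        meta = pd.read_csv(meta_path, index_col=0)
        meta.index = meta.index.astype(str)
    return PhenotypeTable(values, meta)


def write_phenotypes_csv(
    pheno: PhenotypeTable, path: str | Path, meta_path: str | Path | None = None
) -> None:
    pheno.values.to_csv(path, index_label="id")
    if meta_path is not None and pheno.metadata is not None:
        pheno.metadata.to_csv(meta_path, index_label="id")


def read_rqtl_csv(path: str | Path) -> tuple[GeneticMap, GenotypeMatrix, PhenotypeTable]:
    """Read the combined map+genotype+phenotype CSV dialect.

    Layout: header row of column names (id, trait columns, then marker
    columns), a second row giving the chromosome of each marker column
    (blank under id/traits), a third row giving cM positions, then one
    row per individual.  Genotypes use single letters A/B/H/- .
    """
    raw = pd.read_csv(path, header=None, dtype=str, keep_default_na=False)
    names = raw.iloc[0].tolist()
    chrom_row = raw.iloc[1].tolist()
    pos_row = raw.iloc[2].tolist()
    is_marker = [c != "" for c in chrom_row]
    is_marker[0] = False  # id column
    marker_cols = [i for i, m in enumerate(is_marker) if m]
    trait_cols = [i for i in range(1, len(names)) if not is_marker[i]]

    map_df = pd.DataFrame(
        {
            "chrom": [chrom_row[i] for i in marker_cols],
            "pos_cm": [float(pos_row[i]) for i in marker_cols],
            "pos_bp": np.nan,
        },
        index=pd.Index([names[i] for i in marker_cols], name="marker"),
    )
    gmap = GeneticMap(map_df)

    body = raw.iloc[3:]
    ids = body.iloc[:, 0].tolist()
    geno_raw = body.iloc[:, marker_cols]
    unknown = set(np.unique(geno_raw.to_numpy())) - set(LETTER_TO_CODE)
    if unknown:
        raise SeedMqtlError(f"unknown genotype codes: {sorted(unknown)}")
    calls = geno_raw.apply(lambda col: col.map(LETTER_TO_CODE)).astype(np.int8)
    calls.index = pd.Index(ids, name="id")
    calls.columns = [names[i] for i in marker_cols]
    geno = GenotypeMatrix(calls)

    vals = body.iloc[:, trait_cols].apply(
        lambda col: pd.to_numeric(col.mask(col == ""), errors="raise")
    ).astype(float)
    vals.index = pd.Index(ids, name="id")
    vals.columns = [names[i] for i in trait_cols]
    pheno = PhenotypeTable(vals)
    return gmap, geno, pheno


def write_rqtl_csv(
    gmap: GeneticMap,
    geno: GenotypeMatrix,
    pheno: PhenotypeTable,
    path: str | Path,
) -> None:
    """Companion writer for :func:`read_rqtl_csv` (lossless round trip)."""
    markers = gmap.marker_names
    traits = pheno.traits
    header = ["id"] + traits + markers
    chrom_row = [""] * (1 + len(traits)) + [
        str(gmap.table.loc[m, "chrom"]) for m in markers
    ]
    pos_row = [""] * (1 + len(traits)) + [
        repr(float(gmap.table.loc[m, "pos_cm"])) for m in markers
    ]
    lines = [",".join(header), ",".join(chrom_row), ",".join(pos_row)]
    calls = geno.calls[markers]
    vals = pheno.values.loc[geno.individuals, traits] if traits else None
    for ind in geno.individuals:
        row = [str(ind)]
        if vals is not None:
            row += [
                "" if pd.isna(v) else repr(float(v)) for v in vals.loc[ind].tolist()
            ]
        row += [CODE_TO_LETTER[int(c)] for c in calls.loc[ind].tolist()]
        lines.append(",".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


# --- GFF3 and pathway tables ------------------------------------------------

def read_genes_gff3(path: str | Path) -> pd.DataFrame:
    """Parse gene features from a GFF3 file into the PathwayDB gene schema."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9 or parts[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            rows.append(
                {
                    "gene_id": attrs.get("ID", ""),
                    "chrom": parts[0],
                    "start": int(parts[3]),
                    "end": int(parts[4]),
                    "strand": parts[6],
                    "description": attrs.get("description", ""),
                }
            )
    return pd.DataFrame(rows).set_index("gene_id")


def write_genes_gff3(genes: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gid, row in genes.iterrows():
            attrs = f"ID={gid}"
            if row.get("description"):
                attrs += f";description={row['description']}"
            fh.write(
                f"{row['chrom']}\t.\tgene\t{int(row['start'])}\t{int(row['end'])}"
                f"\t.\t{row['strand']}\t.\t{attrs}\n"
            )


def _split(cell: str) -> tuple[str, ...]:
    return tuple(s for s in str(cell).split(";") if s) if pd.notna(cell) else ()


def read_pathway_tables(
    reactions_path: str | Path,
    pathways_path: str | Path,
    tf_path: str | Path,
    genes: pd.DataFrame,
) -> PathwayDB:
    """Assemble a PathwayDB from TSV relation tables plus a gene table.

    reactions TSV: reaction_id, genes, substrates, products (';'-separated)
    pathways  TSV: pathway_id, metabolites, genes
    tf        TSV: gene_id, family
    """
    rx = pd.read_csv(reactions_path, sep="\t", dtype=str).set_index("reaction_id")
    for col in ("genes", "substrates", "products"):
        rx[col] = rx[col].map(_split)
    pw = pd.read_csv(pathways_path, sep="\t", dtype=str).set_index("pathway_id")
    for col in ("metabolites", "genes"):
        pw[col] = pw[col].map(_split)
    tf = pd.read_csv(tf_path, sep="\t", dtype=str).set_index("gene_id")
    return PathwayDB(genes, rx, pw, tf)


def write_pathway_tables(
    db: PathwayDB,
    reactions_path: str | Path,
    pathways_path: str | Path,
    tf_path: str | Path,
) -> None:
    rx = db.reactions.copy()
    for col in ("genes", "substrates", "products"):
        rx[col] = rx[col].map(";".join)
    rx.to_csv(reactions_path, sep="\t", index_label="reaction_id")
    pw = db.pathways.copy()
    for col in ("metabolites", "genes"):
        pw[col] = pw[col].map(";".join)
    pw.to_csv(pathways_path, sep="\t", index_label="pathway_id")
    db.tf_list.to_csv(tf_path, sep="\t", index_label="gene_id")
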