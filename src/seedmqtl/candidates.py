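"""Candidate-gene queries over QTL support intervals.

Support intervals are translated into physical windows via the bp
anchors of their flanking markers; genes overlapping a window are
classified as *direct* candidates (encoding an enzyme of a reaction
that consumes or produces the query metabolite), *indirect* candidates
(member of a pathway containing the metabolite, without a direct
reaction link), or neither.  Regulatory shortlists intersect window
genes with the transcription-factor annotation.

Currency metabolites (water, ATP-like cofactors) would make every
window a direct hit; they are excluded from direct matching by a
configurable stop-list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .core_io import GeneticMap, PathwayDB, SeedMqtlError, SupportInterval

logger = logging.getLogger("seedmqtl")

DEFAULT_STOPLIST = frozenset(
    {"WATER", "ATP", "ADP", "NAD", "NADH", "NADP", "NADPH", "PROTON", "CO2", "Pi"}
)


@dataclass(frozen=True)
class PhysicalWindow:
    chrom: str
    lo_bp: int
    hi_bp: int  # 1-based inclusive


def interval_to_window(si: SupportInterval, gmap: GeneticMap) -> PhysicalWindow:
    """Physical window spanned by the flanking markers of an interval."""
    for marker in (si.lo_marker, si.hi_marker):
        bp = gmap.table.loc[marker, "pos_bp"]
        if pd.isna(bp):
            raise SeedMqtlError(f"marker {marker!r} has no bp anchor")
    lo = int(gmap.table.loc[si.lo_marker, "pos_bp"])
    hi = int(gmap.table.loc[si.hi_marker, "pos_bp"])
    return PhysicalWindow(si.chrom, min(lo, hi), max(lo, hi))


def genes_in_window(window: PhysicalWindow, db: PathwayDB) -> pd.DataFrame:
    """Genes whose [start, end] overlaps the window (any overlap counts).

    Sorted by start coordinate.
    """
    g = db.genes
    hit = (
        (g["chrom"] == window.chrom)
        & (g["start"] <= window.hi_bp)
        & (g["end"] >= window.lo_bp)
    )
    return g[hit].sort_values("start")


def classify_candidates(
    genes: pd.DataFrame,
    metabolite: str,
    db: PathwayDB,
    stoplist: frozenset[str] = DEFAULT_STOPLIST,
) -> pd.Series:
    """Label each gene as direct / indirect / none for a metabolite.

    direct: the gene is linked to a reaction with the metabolite as a
    substrate or product; indirect: not direct, but the gene belongs to
    a pathway containing the metabolite (union over all containing
    pathways); none otherwise.  Direct takes precedence.  An unknown
    metabolite yields an empty result with a warning.
    """
    if metabolite not in db.metabolites:
        logger.warning("metabolite %r unknown to the pathway database", metabolite)
        return pd.Series(dtype=object)
    if metabolite in stoplist:
        logger.info("metabolite %r on the currency stop-list; no direct matches",
                    metabolite)

    direct_genes: set[str] = set()
    if metabolite not in stoplist:
        for row in db.reactions.itertuples():
            if metabolite in row.substrates or metabolite in row.products:
                direct_genes.update(row.genes)
    pathway_genes: set[str] = set()
    for row in db.pathways.itertuples():
        if metabolite in row.metabolites:
            pathway_genes.update(row.genes)

    labels = {}
    for gid in genes.index:
        if gid in direct_genes:
            labels[gid] = "direct"
        elif gid in pathway_genes:
            labels[gid] = "indirect"
        else:
            labels[gid] = "none"
    return pd.Series(labels, name="label")


def regulatory_shortlist(
    genes: pd.DataFrame,
    db: PathwayDB,
    seed_expressed: set[str] | None = None,
) -> pd.DataFrame:
    """TF-annotated subset of window genes, ordered for follow-up.

    Ordering: seed-expression flag first, then family name, then
    position.  Columns: family, seed_expressed, chrom, start, end.
    """
    tfs = genes.index.intersection(db.tf_list.index)
    out = genes.loc[tfs, ["chrom", "start", "end"]].copy()
    out["family"] = db.tf_list.loc[tfs, "family"]
    out["seed_expressed"] = [
        gid in seed_expressed if seed_expressed else False for gid in tfs
    ]
    return out.sort_values(
        ["seed_expressed", "family", "start"], ascending=[False, True, True]
    )


def candidate_table(
    models,
    gmap: GeneticMap,
    db: PathwayDB,
    stoplist: frozenset[str] = DEFAULT_STOPLIST,
) -> pd.DataFrame:
    """Per (trait, QTL, gene) candidate labels over a set of QTL models.

    The query metabolite of each model is its trait name; traits unknown
    to the database yield no rows.
    """
    rows = []
    for model in models:
        for k, si in enumerate(model.support):
            window = interval_to_window(si, gmap)
            genes = genes_in_window(window, db)
            labels = classify_candidates(genes, model.trait, db, stoplist)
            for gid, label in labels.items():
                if label == "none":
                    continue
                rows.append(
                    {
                        "trait": model.trait,
                        "qtl": f"{si.chrom}@{model.qtls[k].pos_cm:g}",
                        "gene": gid,
                        "label": label,
                    }
                )
    return pd.DataFrame(rows, columns=["trait", "qtl", "gene", "label"])


def coverage_statistics(
    models, gmap: GeneticMap, db: PathwayDB
) -> dict[str, float]:
    """Fraction of traits with >=1 candidate, direct-only vs direct+indirect."""
    n_direct = 0
    n_any = 0
    n_traits = 0
    for model in models:
        if not model.support:
            continue
        n_traits += 1
        labels: list[str] = []
        for si in model.support:
            window = interval_to_window(si, gmap)
            genes = genes_in_window(window, db)
            labels.extend(classify_candidates(genes, model.trait, db).tolist())
        if "direct" in labels:
            n_direct += 1
        if "direct" in labels or "indirect" in labels:
            n_any += 1
    if n_traits == 0:
        return {"direct_only": float("nan"), "direct_or_indirect": float("nan")}
    return {
        "direct_only": n_direct / n_traits,
        "direct_or_indirect": n_any / n_traits,
    }
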