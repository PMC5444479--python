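"""Correlation, PCA, Mantel, ANOVA and epistasis group summaries.

These analyses surround the mapping core: pairwise Pearson correlation
with Benjamini-Hochberg FDR control, principal component analysis on
centered and Pareto-scaled data (PC scores are exported as traits and
mapped like metabolites), a Mantel test comparing the marker similarity
structure of reciprocal-cross subsets, a two-way ANOVA probing maternal
effects, and the four-group allele summary used to visualize masking
epistasis.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio.stats.distance import DistanceMatrix, mantel as _skbio_mantel
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .core_io import AA, BB, GenotypeMatrix, PhenotypeTable, SeedMqtlError

logger = logging.getLogger("seedmqtl")


# ---------------------------------------------------------------------------
# Correlation / FDR
# ---------------------------------------------------------------------------

def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    q_(i) = min over j >= i of p_(j) * m / j after sorting ascending.
    """
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0, 1)
    return q


def pearson_fdr(
    table: PhenotypeTable, min_pairs: int = 3
) -> pd.DataFrame:
    """All pairwise Pearson correlations with BH-adjusted q-values.

    Pairwise-complete observations; pairs with fewer than ``min_pairs``
    complete observations or a zero-variance member are skipped with a
    log entry.  Columns: trait_a, trait_b, n, r, p, q.
    """
    values = table.values
    traits = list(values.columns)
    rows = []
    for a, b in itertools.combinations(traits, 2):
        pair = values[[a, b]].dropna()
        if len(pair) < min_pairs:
            logger.info("pair (%s, %s): only %d complete pairs; skipped", a, b, len(pair))
            continue
        x = pair[a].to_numpy()
        y = pair[b].to_numpy()
        if np.std(x) == 0 or np.std(y) == 0:
            logger.info("pair (%s, %s): zero variance; skipped", a, b)
            continue
        r, p = stats.pearsonr(x, y)
        rows.append({"trait_a": a, "trait_b": b, "n": len(pair),
                     "r": float(r), "p": float(p)})
    out = pd.DataFrame(rows, columns=["trait_a", "trait_b", "n", "r", "p"])
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
    else:
        out["q"] = []
    return out


def correlation_sign_split(corr: pd.DataFrame, q_cut: float = 0.05) -> dict:
    """Fraction of positive vs negative correlations, all pairs and FDR-significant."""
    def split(df: pd.DataFrame) -> tuple[float, float]:
        if not len(df):
            return float("nan"), float("nan")
        pos = float((df["r"] > 0).mean())
        return pos, 1.0 - pos
    sig = corr[corr["q"] < q_cut]
    all_pos, all_neg = split(corr)
    sig_pos, sig_neg = split(sig)
    return {
        "all_pairs": {"positive": all_pos, "negative": all_neg},
        "significant_pairs": {"positive": sig_pos, "negative": sig_neg},
    }


# ---------------------------------------------------------------------------
# PCA on Pareto-scaled data
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    scores: pd.DataFrame        # individuals x PCs
    loadings: pd.DataFrame      # traits x PCs
    variance_fraction: np.ndarray

    def scores_as_traits(self) -> PhenotypeTable:
        """PC scores packaged as mapping traits."""
        return PhenotypeTable(self.scores.copy())


def pca_pareto(
    table: PhenotypeTable,
    n_components: int = 4,
    max_missing_fraction: float = 0.2,
) -> PcaResult:
    """PCA on centered, Pareto-scaled data.

    Each trait is centered and divided by the square root of its sample
    standard deviation, damping the dominance of high-variance traits
    without fully whitening.  Missing values (at most
    ``max_missing_fraction`` per trait) are imputed by the trait mean
    before the SVD; variance fractions are eigenvalue shares.
    """
    values = table.values
    miss = values.isna().mean(axis=0)
    too_missing = miss[miss > max_missing_fraction]
    if len(too_missing):
        raise SeedMqtlError(
            f"traits exceed missing-value budget: {list(too_missing.index)}"
        )
    n_imputed = int(values.isna().to_numpy().sum())
    if n_imputed:
        logger.info("imputing %d missing values by trait means", n_imputed)
    X = values.fillna(values.mean(axis=0))
    centered = X - X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    scale = np.sqrt(sd.replace(0.0, 1.0))
    Z = (centered / scale).to_numpy(float)

    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    rank = int(np.sum(S > S[0] * 1e-12)) if len(S) else 0
    if n_components > rank:
        logger.warning("requested %d components, rank is %d", n_components, rank)
        n_components = rank
    eig = S**2
    frac = eig / eig.sum()
    cols = [f"PC{i + 1}" for i in range(n_components)]
    scores = pd.DataFrame(
        U[:, :n_components] * S[:n_components], index=values.index, columns=cols
    )
    loadings = pd.DataFrame(Vt[:n_components].T, index=values.columns, columns=cols)
    return PcaResult(scores, loadings, frac[:n_components])


# ---------------------------------------------------------------------------
# Mantel test on marker similarity
# ---------------------------------------------------------------------------

def simple_matching_similarity(geno: GenotypeMatrix) -> np.ndarray:
    """Individual x individual fraction of identical marker calls.

    Pairs of calls where either is missing are ignored in the fraction.
    """
    calls = geno.calls.to_numpy()
    n = calls.shape[0]
    valid = calls >= 0
    sim = np.empty((n, n))
    for i in range(n):
        both = valid[i] & valid
        match = (calls[i] == calls) & both
        denom = both.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            sim[i] = np.where(denom > 0, match.sum(axis=1) / denom, 0.0)
    np.fill_diagonal(sim, 1.0)
    return sim


def mantel_test(
    genoA: GenotypeMatrix,
    genoB: GenotypeMatrix,
    n_perm: int = 10000,
    seed: int = 0,
) -> tuple[float, float]:
    """Mantel test between simple-matching similarity structures.

    Both matrices must cover the same marker set and equally many
    individuals; the statistic is the Pearson correlation of the
    off-diagonal similarity entries and the p-value comes from
    row/column permutations, reported as (b + 1)/(n_perm + 1).
    """
    if list(genoA.calls.columns) != list(genoB.calls.columns):
        raise SeedMqtlError("genotype matrices must share the marker set")
    if genoA.n_individuals != genoB.n_individuals:
        raise SeedMqtlError("subsets must have equally many individuals for Mantel")
    simA = simple_matching_similarity(genoA)
    simB = simple_matching_similarity(genoB)
    # distances preserve the off-diagonal correlation up to sign symmetry
    dA = DistanceMatrix(1.0 - simA)
    dB = DistanceMatrix(1.0 - simB)
    np.random.seed(seed & 0x7FFFFFFF)  # skbio draws from the global RNG
    r, p, _ = _skbio_mantel(dA, dB, method="pearson", permutations=n_perm)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# Two-way ANOVA for maternal effects
# ---------------------------------------------------------------------------

def anova_reciprocal(
    trait: pd.Series, marker_genotype: pd.Series, subset_label: pd.Series
) -> dict[str, float]:
    """Two-way fixed-effects ANOVA (type-II SS): marker, subset, interaction.

    Returns p-values keyed 'marker', 'subset', 'interaction'.  If some
    marker x subset cell is empty the model falls back to main effects
    only (interaction p reported as NaN).
    """
    df = pd.DataFrame(
        {"y": trait, "marker": marker_genotype.astype(str),
         "subset": subset_label.astype(str)}
    ).dropna()
    for col in ("marker", "subset"):
        if df[col].nunique() < 2:
            raise SeedMqtlError(f"factor {col!r} needs at least 2 levels")
    cells = df.groupby(["marker", "subset"]).size()
    full_cells = df["marker"].nunique() * df["subset"].nunique()
    if len(cells) < full_cells:
        logger.warning("empty marker x subset cells; interaction dropped")
        fit = ols("y ~ C(marker) + C(subset)", data=df).fit()
        tab = anova_lm(fit, typ=2)
        return {
            "marker": float(tab.loc["C(marker)", "PR(>F)"]),
            "subset": float(tab.loc["C(subset)", "PR(>F)"]),
            "interaction": float("nan"),
        }
    fit = ols("y ~ C(marker) * C(subset)", data=df).fit()
    tab = anova_lm(fit, typ=2)
    return {
        "marker": float(tab.loc["C(marker)", "PR(>F)"]),
        "subset": float(tab.loc["C(subset)", "PR(>F)"]),
        "interaction": float(tab.loc["C(marker):C(subset)", "PR(>F)"]),
    }


# ---------------------------------------------------------------------------
# Epistasis allele-group summary
# ---------------------------------------------------------------------------

GROUP_ORDER = ["AA/AA", "BB/AA", "AA/BB", "BB/BB"]


@dataclass
class EpistasisGroups:
    """Four-group summary at two interacting loci with Tukey letters."""

    summary: pd.DataFrame          # index group; n, mean, median
    anova_p: float
    tukey: pd.DataFrame            # pairwise comparisons with p-adj
    letters: dict[str, str]        # compact letter display


def _compact_letters(groups: list[str], distinct: set[tuple[str, str]]) -> dict[str, str]:
    """Compact letter display by the insert-and-absorb algorithm."""
    letter_sets: list[set[str]] = [set(groups)]
    for a, b in distinct:
        for s in list(letter_sets):
            if a in s and b in s:
                letter_sets.remove(s)
                sa, sb = s - {b}, s - {a}
                for cand in (sa, sb):
                    if not any(cand <= other for other in letter_sets):
                        letter_sets.append(cand)
    letter_sets.sort(key=lambda s: sorted(groups.index(g) for g in s))
    out = {g: "" for g in groups}
    for i, s in enumerate(letter_sets):
        for g in s:
            out[g] += chr(ord("A") + i)
    return {g: "".join(sorted(v)) for g, v in out.items()}


def epistasis_groups(
    trait: pd.Series,
    geno_locus1: pd.Series,
    geno_locus2: pd.Series,
    alpha: float = 0.05,
    min_per_group: int = 4,
) -> EpistasisGroups:
    """Four-way allele-class summary with ANOVA and Tukey HSD letters.

    Individuals are split by their parental-homozygote state at the two
    interacting loci (heterozygous or missing calls are dropped); trait
    values are median-divided for the summary, as in the conventional
    normalized-abundance display.  Groups sharing a letter are not
    significantly different at ``alpha`` under Tukey's honest
    significant difference.
    """
    code = {AA: "AA", BB: "BB"}
    df = pd.DataFrame({"y": trait, "g1": geno_locus1, "g2": geno_locus2}).dropna()
    df = df[df["g1"].isin(code) & df["g2"].isin(code)]
    df["group"] = df["g1"].map(code) + "/" + df["g2"].map(code)
    med = float(df["y"].median())
    if med > 0:  # median-divided display only meaningful for positive abundances
        df["y"] = df["y"] / med

    sizes = df.groupby("group").size()
    groups = [g for g in GROUP_ORDER if sizes.get(g, 0) >= min_per_group]
    omitted = [g for g in GROUP_ORDER if 0 < sizes.get(g, 0) < min_per_group]
    if omitted:
        logger.warning("groups omitted for small size: %s", omitted)
    if len(groups) < 2:
        raise SeedMqtlError("need at least two allele groups with enough members")
    df = df[df["group"].isin(groups)]

    summary = df.groupby("group")["y"].agg(["size", "mean", "median"])
    summary.columns = ["n", "mean", "median"]
    summary = summary.reindex(groups)

    fit = ols("y ~ C(group)", data=df).fit()
    anova_p = float(anova_lm(fit, typ=2).loc["C(group)", "PR(>F)"])

    tk = pairwise_tukeyhsd(df["y"].to_numpy(), df["group"].to_numpy(), alpha=alpha)
    tukey = pd.DataFrame(
        tk.summary().data[1:], columns=[str(c) for c in tk.summary().data[0]]
    )
    distinct = {
        (str(r["group1"]), str(r["group2"]))
        for _, r in tukey.iterrows()
        if bool(r["reject"])
    }
    letters = _compact_letters(groups, distinct)
    return EpistasisGroups(summary, anova_p, tukey, letters)
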