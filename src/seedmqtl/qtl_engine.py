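"""Genome scans and multiple-QTL model selection.

The engine follows the standard RIL mapping workflow: conditional
genotype probabilities from a two-state hidden Markov model on a 1 cM
pseudo-marker grid, single-QTL interval mapping by Haley-Knott
regression, composite interval mapping with forward-selected marker
covariates and an exclusion window, genome-wide significance by
permutation, 1.5-LOD support intervals expanded to flanking markers,
two-QTL scans on a coarser grid, penalty derivation from two-QTL scan
permutations, and forward/backward penalized-LOD model selection with a
final simultaneous fit.

Residual heterozygotes (an F10 population carries ~0.2%) are treated as
missing observations in the HMM so the two-state RIL transition matrix
stays exact; their expected dosage contribution is handled by the
Haley-Knott regression on conditional expectations.

LOD convention: LOD = (n/2) * log10(RSS0 / RSS1) with RSS0 the residual
sum of squares of the comparison (null or covariate-only) model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import (
    AA,
    BB,
    GeneticMap,
    GenotypeMatrix,
    LodCurve,
    QtlEffect,
    QtlModel,
    ScanConfig,
    SeedMqtlError,
    SupportInterval,
    rng_for,
)
from .simulate import inverse_map_function, ril_recombination_fraction

logger = logging.getLogger("seedmqtl")

MIN_INFORMATIVE = 10
MAX_QTLS = 10
MAX_INTERACTIONS = 5
MIN_QTL_SEPARATION_CM = 10.0


# ---------------------------------------------------------------------------
# Genotype probabilities
# ---------------------------------------------------------------------------

@dataclass
class Genoprob:
    """Conditional genotype probabilities on a pseudo-marker grid.

    ``grid`` has columns chrom, pos_cm, is_marker, marker (name or "").
    ``probs`` maps chromosome -> array (n_individuals, n_grid, 2) over
    the two parental homozygote states (AA, BB).
    """

    gmap: GeneticMap
    grid: pd.DataFrame
    probs: dict[str, np.ndarray]
    individuals: list[str]
    _dosage: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def dosage(self) -> np.ndarray:
        """Expected additive dosage P(BB) - P(AA), shape (n, n_grid)."""
        if self._dosage is None:
            parts = [self.probs[c][:, :, 1] - self.probs[c][:, :, 0]
                     for c in self.gmap.chromosomes]
            self._dosage = np.concatenate(parts, axis=1)
        return self._dosage

    def marker_columns(self) -> np.ndarray:
        return np.flatnonzero(self.grid["is_marker"].to_numpy())

    def column_at(self, chrom: str, pos_cm: float) -> int:
        """Global grid column nearest to (chrom, pos_cm)."""
        sel = self.grid["chrom"].to_numpy() == chrom
        if not sel.any():
            raise SeedMqtlError(f"chromosome {chrom!r} not on grid")
        pos = self.grid["pos_cm"].to_numpy(float)
        idx = np.flatnonzero(sel)
        return int(idx[np.argmin(np.abs(pos[idx] - pos_cm))])


def _chrom_grid(positions: np.ndarray, step_cm: float) -> np.ndarray:
    lo, hi = positions[0], positions[-1]
    stepped = np.arange(lo, hi, step_cm) if step_cm > 0 else positions
    grid = np.union1d(np.round(positions, 9), np.round(stepped, 9))
    grid = np.union1d(grid, [np.round(hi, 9)])
    return grid


def calc_genoprob(
    geno: GenotypeMatrix,
    gmap: GeneticMap,
    cfg: ScanConfig | None = None,
    step_cm: float | None = None,
) -> Genoprob:
    """Forward-backward genotype probabilities for a selfed RIL population.

    Two hidden states (the parental homozygotes); transition probability
    between adjacent grid positions uses the RIL-adjusted recombination
    fraction R = 2r/(1+2r) with r from the configured inverse map
    function; emission is the correct call with probability 1-eps and
    the wrong call with probability eps.  HET and missing calls carry no
    information.  ``step_cm`` overrides the config grid step (used for
    the coarse two-QTL grid).
    """
    cfg = cfg or ScanConfig()
    step = cfg.step_cm if step_cm is None else step_cm
    eps = cfg.genotyping_error
    missing_chroms = set(geno.calls.columns) and set(gmap.marker_names) - set(
        geno.calls.columns
    )
    if missing_chroms:
        raise SeedMqtlError(f"genotype matrix lacks markers: {sorted(missing_chroms)}")
    calls_all = geno.aligned_to(gmap).calls
    n = len(calls_all)

    grid_frames = []
    probs: dict[str, np.ndarray] = {}
    for chrom in gmap.chromosomes:
        sub = gmap.markers(chrom)
        mpos = np.round(sub["pos_cm"].to_numpy(float), 9)
        grid = _chrom_grid(mpos, step)
        g = len(grid)
        marker_at = {p: name for p, name in zip(mpos, sub.index)}
        is_marker = np.isin(grid, mpos)

        # emissions: (n, g, 2); uniform where unobserved
        emis = np.ones((n, g, 2))
        for j, p in enumerate(grid):
            if is_marker[j]:
                obs = calls_all[marker_at[p]].to_numpy()
                emis[obs == AA, j, :] = (1 - eps, eps)
                emis[obs == BB, j, :] = (eps, 1 - eps)

        r = inverse_map_function(np.diff(grid), cfg.map_function)
        big_r = ril_recombination_fraction(np.asarray(r))

        alpha = np.empty((n, g, 2))
        alpha[:, 0, :] = 0.5 * emis[:, 0, :]
        alpha[:, 0, :] /= alpha[:, 0, :].sum(axis=1, keepdims=True)
        for j in range(1, g):
            stay = 1 - big_r[j - 1]
            sw = big_r[j - 1]
            prev = alpha[:, j - 1, :]
            trans = np.stack(
                [prev[:, 0] * stay + prev[:, 1] * sw,
                 prev[:, 0] * sw + prev[:, 1] * stay],
                axis=1,
            )
            a = trans * emis[:, j, :]
            alpha[:, j, :] = a / a.sum(axis=1, keepdims=True)

        beta = np.ones((n, g, 2))
        for j in range(g - 2, -1, -1):
            stay = 1 - big_r[j]
            sw = big_r[j]
            nxt = beta[:, j + 1, :] * emis[:, j + 1, :]
            b = np.stack(
                [nxt[:, 0] * stay + nxt[:, 1] * sw,
                 nxt[:, 0] * sw + nxt[:, 1] * stay],
                axis=1,
            )
            beta[:, j, :] = b / b.sum(axis=1, keepdims=True)

        post = alpha * beta
        post /= post.sum(axis=2, keepdims=True)
        probs[chrom] = post
        grid_frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos_cm": grid,
                    "is_marker": is_marker,
                    "marker": [marker_at.get(p, "") for p in grid],
                }
            )
        )

    grid_df = pd.concat(grid_frames, ignore_index=True)
    return Genoprob(gmap, grid_df, probs, list(calls_all.index))


# ---------------------------------------------------------------------------
# Haley-Knott scans
# ---------------------------------------------------------------------------

def _align_trait(gp: Genoprob, y) -> tuple[np.ndarray, np.ndarray]:
    """Return (y values, row mask of informative individuals)."""
    if isinstance(y, pd.Series):
        y = y.reindex(gp.individuals).to_numpy(float)
    else:
        y = np.asarray(y, float)
        if y.shape[0] != gp.n_individuals:
            raise SeedMqtlError("trait length does not match individuals")
    keep = np.isfinite(y)
    return y, keep


def _corr_lod(Xc: np.ndarray, yc: np.ndarray, rss0: float, n: int) -> np.ndarray:
    """LOD per column of centered X against centered y (simple regression)."""
    sx = np.einsum("ij,ij->j", Xc, Xc)
    sxy = yc @ Xc
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(sx > 1e-300, sxy**2 / (sx * rss0), 0.0)
    r2 = np.clip(r2, 0.0, 1.0 - 1e-15)
    return -(n / 2.0) * np.log10(1.0 - r2)


def scan_hk(gp: Genoprob, y, cfg: ScanConfig | None = None) -> LodCurve:
    """Single-QTL genome scan by Haley-Knott regression.

    At each grid point the trait is regressed on the expected genotype
    dosage; LOD = (n/2) log10(RSS0/RSS1) against the mean-only null.
    Individuals with a missing trait value are dropped.
    """
    y, keep = _align_trait(gp, y)
    n = int(keep.sum())
    if n < MIN_INFORMATIVE:
        raise SeedMqtlError(f"only {n} informative individuals (need {MIN_INFORMATIVE})")
    yk = y[keep]
    yc = yk - yk.mean()
    rss0 = float(yc @ yc)
    X = gp.dosage[keep]
    if rss0 <= 0:
        logger.warning("zero-variance trait; returning flat LOD curve")
        lod = np.zeros(X.shape[1])
    else:
        Xc = X - X.mean(axis=0)
        lod = _corr_lod(Xc, yc, rss0, n)
    table = gp.grid[["chrom", "pos_cm"]].copy()
    table["lod"] = lod
    return LodCurve(table)


def _residualize(M: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Residuals of each column of M on [1, C] (least squares)."""
    n = M.shape[0]
    D = np.column_stack([np.ones(n), C]) if C.size else np.ones((n, 1))
    beta, *_ = np.linalg.lstsq(D, M, rcond=None)
    return M - D @ beta


def scan_with_covariates(
    gp: Genoprob, y, covariates: np.ndarray, exclude_cols: np.ndarray | None = None
) -> np.ndarray:
    """LOD per grid column for adding one dosage column to a covariate model.

    ``covariates``: (n_keep, k) matrix already restricted to informative
    rows.  Uses the one-regressor-at-a-time identity: residualize both
    the trait and the candidate columns on the covariates, then the LOD
    of the augmented model follows from the residual correlation.
    """
    y, keep = _align_trait(gp, y)
    yk = y[keep]
    n = int(keep.sum())
    ry = _residualize(yk[:, None], covariates)[:, 0]
    rss_cov = float(ry @ ry)
    X = gp.dosage[keep]
    RX = _residualize(X, covariates)
    lod = _corr_lod(RX, ry, rss_cov, n) if rss_cov > 0 else np.zeros(X.shape[1])
    if exclude_cols is not None:
        lod[exclude_cols] = 0.0
    return lod


def forward_select_covariates(gp: Genoprob, y, k: int) -> list[int]:
    """Greedy forward selection of k marker columns (global grid indices)."""
    y, keep = _align_trait(gp, y)
    yk = y[keep]
    X = gp.dosage[keep]
    candidates = gp.marker_columns()
    chosen: list[int] = []
    C = np.empty((len(yk), 0))
    for _ in range(k):
        ry = _residualize(yk[:, None], C)[:, 0]
        rss = float(ry @ ry)
        if rss <= 0:
            break
        RX = _residualize(X[:, candidates], C)
        lod = _corr_lod(RX, ry, rss, len(yk))
        lod[np.isin(candidates, chosen)] = -1
        best = int(candidates[np.argmax(lod)])
        chosen.append(best)
        C = np.column_stack([C, X[:, best]])
    return chosen


def scan_cim(
    gp: Genoprob, y, cfg: ScanConfig | None = None, return_details: bool = False
):
    """Composite interval mapping.

    Forward selection picks ``cfg.cim_covariates`` marker covariates;
    at each scan position covariates within half the window (same
    chromosome) are excluded from the local model, and the LOD is
    computed against the covariate-adjusted null.
    """
    cfg = cfg or ScanConfig()
    yv, keep = _align_trait(gp, y)
    n = int(keep.sum())
    if n < MIN_INFORMATIVE:
        raise SeedMqtlError(f"only {n} informative individuals (need {MIN_INFORMATIVE})")
    chosen = forward_select_covariates(gp, y, cfg.cim_covariates)
    X = gp.dosage[keep]
    yk = yv[keep]
    grid = gp.grid
    half_w = cfg.cim_window_cm / 2.0

    cov_chrom = grid["chrom"].to_numpy()[chosen]
    cov_pos = grid["pos_cm"].to_numpy(float)[chosen]
    g_chrom = grid["chrom"].to_numpy()
    g_pos = grid["pos_cm"].to_numpy(float)

    # active-covariate mask per grid point; group identical masks
    masks = np.ones((len(grid), len(chosen)), bool)
    for ci in range(len(chosen)):
        near = (g_chrom == cov_chrom[ci]) & (np.abs(g_pos - cov_pos[ci]) < half_w)
        masks[near, ci] = False

    lod = np.zeros(len(grid))
    details: dict[int, list[str]] = {}
    uniq, inverse = np.unique(masks, axis=0, return_inverse=True)
    for u, mask in enumerate(uniq):
        cols = np.flatnonzero(inverse == u)
        C = X[:, [chosen[i] for i in np.flatnonzero(mask)]]
        ry = _residualize(yk[:, None], C)[:, 0]
        rss = float(ry @ ry)
        if rss <= 0:
            continue
        RX = _residualize(X[:, cols], C)
        lod[cols] = _corr_lod(RX, ry, rss, n)
        for c in cols:
            details[int(c)] = [
                grid["marker"].iloc[chosen[i]] or f"{cov_chrom[i]}@{cov_pos[i]}"
                for i in np.flatnonzero(mask)
            ]

    table = grid[["chrom", "pos_cm"]].copy()
    table["lod"] = lod
    curve = LodCurve(table, covariates=[grid["marker"].iloc[c] or str(c) for c in chosen])
    if return_details:
        return curve, details
    return curve


# ---------------------------------------------------------------------------
# Permutation thresholds
# ---------------------------------------------------------------------------

def permutation_maxima(
    gp: Genoprob, y, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Genome-wide maximum LOD of each of n_perm trait permutations."""
    y, keep = _align_trait(gp, y)
    yk = y[keep]
    n = len(yk)
    X = gp.dosage[keep]
    Xc = X - X.mean(axis=0)
    sx = np.einsum("ij,ij->j", Xc, Xc)
    good = sx > 1e-300

    perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
    Y = yk[perm_idx]
    Yc = Y - Y.mean(axis=1, keepdims=True)
    rss0 = np.einsum("ij,ij->i", Yc, Yc)
    S = Yc @ Xc[:, good]  # (n_perm, G)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = S**2 / (sx[good][None, :] * rss0[:, None])
    r2 = np.clip(r2, 0.0, 1.0 - 1e-15)
    maxima = -(n / 2.0) * np.log10(1.0 - r2.max(axis=1))
    return maxima


def permutation_threshold(
    gp: Genoprob,
    y,
    cfg: ScanConfig | None = None,
    n_perm: int | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Genome-wide LOD threshold from trait permutations.

    Trait values are permuted against intact genotypes; the threshold is
    the (1 - alpha) type-7 quantile of the per-permutation genome-wide
    maximum LOD.
    """
    cfg = cfg or ScanConfig()
    n_perm = n_perm or cfg.n_perm_main
    if n_perm < 100:
        raise SeedMqtlError("need at least 100 permutations")
    rng = rng or rng_for(cfg.rng_seed, "perm-threshold")
    maxima = permutation_maxima(gp, y, n_perm, rng)
    return float(np.quantile(maxima, 1.0 - cfg.alpha))


# ---------------------------------------------------------------------------
# Support intervals and peaks
# ---------------------------------------------------------------------------

def lod_support_interval(
    curve: LodCurve, gmap: GeneticMap, chrom: str, drop: float = 1.5
) -> SupportInterval:
    """Support interval from the LOD-drop rule, widened to flanking markers.

    The raw interval is the contiguous grid region around the apex with
    LOD >= apex - drop; its ends are then expanded outwards to the
    nearest true markers (chromosome ends cap the expansion).  Apex ties
    break leftmost.
    """
    sub = curve.chrom(chrom)
    if sub.empty:
        raise SeedMqtlError(f"no grid points on chromosome {chrom!r}")
    lod = sub["lod"].to_numpy(float)
    pos = sub["pos_cm"].to_numpy(float)
    apex_i = int(np.argmax(lod))
    if np.allclose(lod, lod[0]):
        logger.warning("flat LOD curve on chromosome %s; whole-chromosome interval", chrom)
    cutoff = lod[apex_i] - drop
    lo_i = apex_i
    while lo_i > 0 and lod[lo_i - 1] >= cutoff:
        lo_i -= 1
    hi_i = apex_i
    while hi_i < len(lod) - 1 and lod[hi_i + 1] >= cutoff:
        hi_i += 1

    markers = gmap.markers(chrom)
    mpos = markers["pos_cm"].to_numpy(float)
    below = np.flatnonzero(mpos <= pos[lo_i] + 1e-9)
    above = np.flatnonzero(mpos >= pos[hi_i] - 1e-9)
    lo_m = int(below[-1]) if below.size else 0
    hi_m = int(above[0]) if above.size else len(mpos) - 1
    lo_bp = hi_bp = None
    if gmap.has_bp_anchors():
        lo_bp = float(markers["pos_bp"].iloc[lo_m])
        hi_bp = float(markers["pos_bp"].iloc[hi_m])
    return SupportInterval(
        chrom=chrom,
        apex_cm=float(pos[apex_i]),
        lo_cm=float(min(mpos[lo_m], pos[lo_i])),
        hi_cm=float(max(mpos[hi_m], pos[hi_i])),
        lo_marker=str(markers.index[lo_m]),
        hi_marker=str(markers.index[hi_m]),
        lo_bp=lo_bp,
        hi_bp=hi_bp,
    )


def significant_peaks(
    curve: LodCurve, threshold: float
) -> list[tuple[str, float, float]]:
    """Per-chromosome apex positions with LOD above the threshold."""
    peaks = []
    for chrom in curve.table["chrom"].unique():
        pos, lod = curve.apex(chrom)
        if lod > threshold:
            peaks.append((str(chrom), pos, lod))
    return peaks


# ---------------------------------------------------------------------------
# Two-QTL scan
# ---------------------------------------------------------------------------

@dataclass
class ScanTwoResult:
    """Pairwise two-QTL scan surfaces on a coarse grid.

    Arrays are indexed by pair (i, j) with i < j over ``grid`` rows:
    lod_full (two QTL + interaction vs null), lod_add (two additive QTL
    vs null), lod_int = lod_full - lod_add, and lod_fv1 = lod_full minus
    the better single-QTL LOD of the two positions.
    """

    grid: pd.DataFrame
    pairs: np.ndarray  # (P, 2) grid row indices
    lod_full: np.ndarray
    lod_add: np.ndarray
    lod_int: np.ndarray
    lod_fv1: np.ndarray
    lod_one: np.ndarray  # single-QTL LOD per grid column

    def max_interaction(self) -> tuple[float, tuple[int, int]]:
        i = int(np.argmax(self.lod_int))
        return float(self.lod_int[i]), tuple(self.pairs[i])


def _pair_design_stats(X: np.ndarray):
    """Precompute the pure-genotype Gram pieces of all pairwise designs."""
    n = X.shape[0]
    s1 = X.sum(axis=0)
    S2 = X.T @ X
    X2 = X * X
    T = X2.T @ X  # T[i, j] = sum x_i^2 x_j
    Q = X2.T @ X2
    return n, s1, S2, T, Q


def _pair_pinvs(X: np.ndarray, pairs: np.ndarray):
    """Batched pseudo-inverses of the full (4-col) and additive (3-col) designs."""
    n, s1, S2, T, Q = _pair_design_stats(X)
    i, j = pairs[:, 0], pairs[:, 1]
    P = len(pairs)
    A = np.empty((P, 4, 4))
    A[:, 0, 0] = n
    A[:, 0, 1] = A[:, 1, 0] = s1[i]
    A[:, 0, 2] = A[:, 2, 0] = s1[j]
    A[:, 0, 3] = A[:, 3, 0] = S2[i, j]
    A[:, 1, 1] = S2[i, i]
    A[:, 1, 2] = A[:, 2, 1] = S2[i, j]
    A[:, 1, 3] = A[:, 3, 1] = T[i, j]
    A[:, 2, 2] = S2[j, j]
    A[:, 2, 3] = A[:, 3, 2] = T[j, i]
    A[:, 3, 3] = Q[i, j]
    pinv4 = np.linalg.pinv(A, hermitian=True)
    pinv3 = np.linalg.pinv(A[:, :3, :3], hermitian=True)
    return pinv4, pinv3


def _pair_rhs(X: np.ndarray, y: np.ndarray, pairs: np.ndarray) -> np.ndarray:
    sy = y.sum()
    v1 = y @ X
    M = X.T @ (X * y[:, None])
    i, j = pairs[:, 0], pairs[:, 1]
    v = np.empty((len(pairs), 4))
    v[:, 0] = sy
    v[:, 1] = v1[i]
    v[:, 2] = v1[j]
    v[:, 3] = M[i, j]
    return v


def _single_lods(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    yc = y - y.mean()
    rss0 = float(yc @ yc)
    Xc = X - X.mean(axis=0)
    return _corr_lod(Xc, yc, rss0, len(y)) if rss0 > 0 else np.zeros(X.shape[1])


def scan_two(gp: Genoprob, y, cfg: ScanConfig | None = None) -> ScanTwoResult:
    """Two-dimensional QTL scan over all position pairs.

    ``gp`` should be computed on a coarse grid (default 2.5 cM step) to
    bound the pair count.  For each pair the full model (two QTL plus
    their product) and the additive model are fitted by least squares;
    LOD_int = LOD_full - LOD_add is non-negative up to numerical
    tolerance because the models nest.
    """
    cfg = cfg or ScanConfig()
    yv, keep = _align_trait(gp, y)
    n = int(keep.sum())
    if n < MIN_INFORMATIVE:
        raise SeedMqtlError(f"only {n} informative individuals (need {MIN_INFORMATIVE})")
    yk = yv[keep]
    X = gp.dosage[keep]
    G = X.shape[1]
    pairs = np.column_stack(np.triu_indices(G, k=1))
    pinv4, pinv3 = _pair_pinvs(X, pairs)

    yty = float(yk @ yk)
    rss0 = yty - yk.sum() ** 2 / n
    v = _pair_rhs(X, yk, pairs)
    rss_full = yty - np.einsum("pi,pij,pj->p", v, pinv4, v)
    rss_add = yty - np.einsum("pi,pij,pj->p", v[:, :3], pinv3, v[:, :3])
    rss_full = np.clip(rss_full, 1e-12, None)
    rss_add = np.clip(rss_add, 1e-12, None)

    lod_full = (n / 2.0) * np.log10(rss0 / rss_full)
    lod_add = (n / 2.0) * np.log10(rss0 / rss_add)
    lod_int = np.clip(lod_full - lod_add, 0.0, None)
    lod_one = _single_lods(X, yk)
    lod_fv1 = lod_full - np.maximum(lod_one[pairs[:, 0]], lod_one[pairs[:, 1]])
    return ScanTwoResult(
        gp.grid[["chrom", "pos_cm"]].copy(), pairs,
        lod_full, lod_add, lod_int, lod_fv1, lod_one,
    )


@dataclass
class ScanTwoPermutations:
    """Per-permutation genome maxima of the two-QTL scan statistics."""

    max_one: np.ndarray
    max_int: np.ndarray
    max_fv1: np.ndarray


def scantwo_permutations(
    gp: Genoprob,
    y,
    cfg: ScanConfig | None = None,
    n_perm: int | None = None,
    rng: np.random.Generator | None = None,
) -> ScanTwoPermutations:
    """Permutation maxima of the two-QTL scan statistics.

    The pure-genotype parts of every pairwise design are computed once;
    each permutation only recomputes the trait-dependent right-hand
    sides, so 3000 permutations stay tractable.
    """
    cfg = cfg or ScanConfig()
    n_perm = n_perm or cfg.n_perm_scantwo
    if n_perm < 100:
        raise SeedMqtlError("need at least 100 permutations")
    rng = rng or rng_for(cfg.rng_seed, "scantwo-perm")
    yv, keep = _align_trait(gp, y)
    yk = yv[keep]
    n = len(yk)
    X = gp.dosage[keep]
    G = X.shape[1]
    pairs = np.column_stack(np.triu_indices(G, k=1))
    pinv4, pinv3 = _pair_pinvs(X, pairs)
    Xc = X - X.mean(axis=0)
    sx = np.einsum("ij,ij->j", Xc, Xc)

    max_one = np.empty(n_perm)
    max_int = np.empty(n_perm)
    max_fv1 = np.empty(n_perm)
    for p in range(n_perm):
        yp = yk[rng.permutation(n)]
        yty = float(yp @ yp)
        rss0 = yty - yp.sum() ** 2 / n
        v = _pair_rhs(X, yp, pairs)
        rss_full = np.clip(yty - np.einsum("pi,pij,pj->p", v, pinv4, v), 1e-12, None)
        rss_add = np.clip(
            yty - np.einsum("pi,pij,pj->p", v[:, :3], pinv3, v[:, :3]), 1e-12, None
        )
        lod_full = (n / 2.0) * np.log10(rss0 / rss_full)
        lod_add = (n / 2.0) * np.log10(rss0 / rss_add)
        ypc = yp - yp.mean()
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = np.where(sx > 1e-300, (ypc @ Xc) ** 2 / (sx * rss0), 0.0)
        lod_one = -(n / 2.0) * np.log10(1.0 - np.clip(r2, 0, 1 - 1e-15))
        max_one[p] = lod_one.max()
        max_int[p] = np.clip(lod_full - lod_add, 0, None).max()
        max_fv1[p] = (
            lod_full - np.maximum(lod_one[pairs[:, 0]], lod_one[pairs[:, 1]])
        ).max()
    return ScanTwoPermutations(max_one, max_int, max_fv1)


def derive_penalties(
    perms: ScanTwoPermutations, alpha: float = 0.05
) -> tuple[float, float, float]:
    """(main, heavy, light) penalties from two-QTL scan permutation maxima.

    main  = (1-alpha) quantile of the single-scan maxima;
    heavy = (1-alpha) quantile of the interaction-LOD maxima;
    light = (1-alpha) quantile of the full-vs-one maxima minus the main
    penalty, capped at heavy (heavy >= light >= 0 by construction).
    """
    q = 1.0 - alpha
    main = float(np.quantile(perms.max_one, q))
    heavy = float(np.quantile(perms.max_int, q))
    light = float(np.quantile(perms.max_fv1, q)) - main
    light = float(np.clip(light, 0.0, heavy))
    return main, heavy, light


# ---------------------------------------------------------------------------
# Multiple-QTL models
# ---------------------------------------------------------------------------

def _design_matrix(
    X: np.ndarray, cols: list[int], interactions: list[tuple[int, int]]
) -> np.ndarray:
    n = X.shape[0]
    parts = [np.ones((n, 1))]
    if cols:
        parts.append(X[:, cols])
    for a, b in interactions:
        parts.append((X[:, cols[a]] * X[:, cols[b]])[:, None])
    return np.column_stack(parts)


def _model_rss(D: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ beta
    return float(resid @ resid)


def _model_lod(
    X: np.ndarray, y: np.ndarray, cols: list[int], inter: list[tuple[int, int]],
    rss0: float,
) -> float:
    if not cols:
        return 0.0
    rss = _model_rss(_design_matrix(X, cols, inter), y)
    return (len(y) / 2.0) * np.log10(rss0 / max(rss, 1e-12))


def _interaction_penalty(
    inter: list[tuple[int, int]], heavy: float, light: float
) -> float:
    """Penalty over interactions: within each connected component of the
    QTL-interaction graph, one interaction is charged the light penalty
    and the rest the heavy penalty."""
    if not inter:
        return 0.0
    parent: dict[int, int] = {}

    def find(a: int) -> int:
        parent.setdefault(a, a)
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    comp_count: dict[int, int] = {}
    for a, b in inter:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    for a, b in inter:
        comp_count[find(a)] = comp_count.get(find(a), 0) + 1
    return sum(light + (c - 1) * heavy for c in comp_count.values())


def penalized_lod(
    lod: float, n_qtls: int, inter: list[tuple[int, int]],
    penalties: tuple[float, float, float],
) -> float:
    main, heavy, light = penalties
    return lod - main * n_qtls - _interaction_penalty(inter, heavy, light)


def _paired_add_scan(
    X: np.ndarray, yk: np.ndarray, D: np.ndarray, partner: np.ndarray,
) -> tuple[np.ndarray, float]:
    """RSS after adding [x_c, partner * x_c] to the model D, per column c.

    Lets the search discover loci whose effect is expressed only in one
    genotype class of an existing QTL (masking epistasis), which have no
    marginal effect and are invisible to single-column addition.
    """
    beta, *_ = np.linalg.lstsq(D, yk, rcond=None)
    ry = yk - D @ beta
    rss_cur = float(ry @ ry)
    U = _residualize(X, D[:, 1:])
    V = _residualize(X * partner[:, None], D[:, 1:])
    a = np.einsum("ij,ij->j", U, U)
    b = np.einsum("ij,ij->j", U, V)
    c = np.einsum("ij,ij->j", V, V)
    u = ry @ U
    v = ry @ V
    det = a * c - b * b
    with np.errstate(divide="ignore", invalid="ignore"):
        red2 = (c * u**2 - 2 * b * u * v + a * v**2) / det
        red1 = np.where(a > 1e-300, u**2 / a, 0.0)
    reduction = np.where(det > 1e-10 * np.maximum(a * c, 1e-300), red2, red1)
    reduction = np.clip(reduction, 0.0, rss_cur)
    return rss_cur - reduction, rss_cur


def stepwise_mqm(
    gp: Genoprob,
    y,
    cfg: ScanConfig,
    initial_qtls: list[tuple[str, float]] | None = None,
) -> QtlModel:
    """Forward/backward penalized-LOD multiple-QTL model search.

    Starting from the initial QTLs (typically the significant single-scan
    peaks), the forward phase repeatedly adds the additive QTL, the
    pairwise interaction between model QTLs, or the (new QTL + its
    interaction with an existing QTL) pair that maximizes the penalized
    LOD, up to a model cap; the backward phase then deletes elements one
    at a time down to the empty model.  The best model visited wins; its
    positions are refined by one-dimensional re-scans and the final
    model is refitted to report effects and variance contributions.
    """
    if cfg.penalties is None:
        raise SeedMqtlError("cfg.penalties must be set (see derive_penalties)")
    penalties = cfg.penalties
    yv, keep = _align_trait(gp, y)
    yk = yv[keep]
    n = len(yk)
    if n < MIN_INFORMATIVE:
        raise SeedMqtlError(f"only {n} informative individuals (need {MIN_INFORMATIVE})")
    X = gp.dosage[keep]
    yc = yk - yk.mean()
    rss0 = float(yc @ yc)
    grid = gp.grid
    g_chrom = grid["chrom"].to_numpy()
    g_pos = grid["pos_cm"].to_numpy(float)
    trait_name = y.name if isinstance(y, pd.Series) and y.name else "trait"

    def plod(cols: list[int], inter: list[tuple[int, int]]) -> float:
        return penalized_lod(
            _model_lod(X, yk, cols, inter, rss0), len(cols), inter, penalties
        )

    cols: list[int] = []
    inter: list[tuple[int, int]] = []
    if initial_qtls:
        for chrom, pos in initial_qtls:
            cols.append(gp.column_at(chrom, pos))

    def forbidden(cols_now: list[int]) -> np.ndarray:
        bad = np.zeros(len(grid), bool)
        for c in cols_now:
            bad |= (g_chrom == g_chrom[c]) & (
                np.abs(g_pos - g_pos[c]) < MIN_QTL_SEPARATION_CM
            )
        return bad

    best = (plod(cols, inter), list(cols), list(inter))
    if rss0 <= 0:
        return fit_qtl_model(gp, y, QtlModel(trait=trait_name))

    # forward phase
    while len(cols) < MAX_QTLS:
        candidates: list[tuple[float, list[int], list[tuple[int, int]]]] = []
        D = _design_matrix(X, cols, inter)
        ry = yk - D @ np.linalg.lstsq(D, yk, rcond=None)[0]
        rss_cov = float(ry @ ry)
        if rss_cov > 1e-12:
            RX = _residualize(X, D[:, 1:])
            lod_gain = _corr_lod(RX, ry - ry.mean(), float(ry @ ry), n)
            lod_gain[forbidden(cols)] = -np.inf
            c_new = int(np.argmax(lod_gain))
            if np.isfinite(lod_gain[c_new]):
                new_cols = cols + [c_new]
                candidates.append((plod(new_cols, inter), new_cols, list(inter)))
        if len(inter) < MAX_INTERACTIONS:
            for a in range(len(cols)):
                for b in range(a + 1, len(cols)):
                    if (a, b) in inter:
                        continue
                    new_inter = inter + [(a, b)]
                    candidates.append((plod(cols, new_inter), list(cols), new_inter))
            # new QTL added jointly with an interaction to an existing QTL
            for k in range(len(cols)):
                rss_new, _ = _paired_add_scan(X, yk, D, X[:, cols[k]])
                lod_new = (n / 2.0) * np.log10(rss0 / np.clip(rss_new, 1e-12, None))
                lod_new[forbidden(cols)] = -np.inf
                c_new = int(np.argmax(lod_new))
                if np.isfinite(lod_new[c_new]):
                    new_cols = cols + [c_new]
                    new_inter = inter + [(k, len(cols))]
                    candidates.append(
                        (
                            penalized_lod(
                                float(lod_new[c_new]), len(new_cols), new_inter,
                                penalties,
                            ),
                            new_cols,
                            new_inter,
                        )
                    )
        if not candidates:
            break
        cand = max(candidates, key=lambda t: t[0])
        cols, inter = cand[1], cand[2]
        if cand[0] > best[0]:
            best = cand
        if cand[0] < best[0] - 2 * sum(penalties):
            break  # far below the best; stop extending

    # backward phase
    while cols or inter:
        candidates = []
        for k in range(len(inter)):
            new_inter = inter[:k] + inter[k + 1:]
            candidates.append((plod(cols, new_inter), list(cols), new_inter))
        for k in range(len(cols)):
            new_cols = cols[:k] + cols[k + 1:]
            new_inter = [
                (a - (a > k), b - (b > k))
                for a, b in inter
                if a != k and b != k
            ]
            candidates.append((plod(new_cols, new_inter), new_cols, new_inter))
        if not candidates:
            break
        cand = max(candidates, key=lambda t: t[0])
        cols, inter = cand[1], cand[2]
        if cand[0] > best[0]:
            best = cand

    _, cols, inter = best
    if not cols or best[0] <= 0:
        return fit_qtl_model(gp, y, QtlModel(trait=trait_name))

    # position refinement: 1-D re-scan of each QTL holding the rest fixed
    for _ in range(2):
        moved = False
        for k in range(len(cols)):
            others = cols[:k] + cols[k + 1:]
            on_chrom = np.flatnonzero(g_chrom == g_chrom[cols[k]])
            bad = forbidden(others)
            scores = []
            for c in on_chrom:
                if bad[c]:
                    scores.append(-np.inf)
                    continue
                trial = list(cols)
                trial[k] = int(c)
                scores.append(_model_lod(X, yk, trial, inter, rss0))
            c_best = int(on_chrom[np.argmax(scores)])
            if c_best != cols[k] and np.isfinite(max(scores)):
                cols[k] = c_best
                moved = True
        if not moved:
            break

    model = QtlModel(
        trait=trait_name,
        qtls=[QtlEffect(str(g_chrom[c]), float(g_pos[c])) for c in cols],
        interactions=[(a, b, float("nan")) for a, b in inter],
    )
    return fit_qtl_model(gp, y, model, lod_drop=1.5)


def fit_qtl_model(
    gp: Genoprob, y, model: QtlModel, lod_drop: float = 1.5
) -> QtlModel:
    """Simultaneous fit of a multiple-QTL model: effects, R2, LOD drops.

    combined_R2 = 100 (1 - RSS_full/RSS0); per-QTL R2 is the type-III
    drop 100 (RSS_without - RSS_full)/TSS, and per-QTL LOD the drop-one
    LOD.  Support intervals come from drop-one LOD re-scans along each
    QTL's chromosome.
    """
    yv, keep = _align_trait(gp, y)
    yk = yv[keep]
    n = len(yk)
    X = gp.dosage[keep]
    yc = yk - yk.mean()
    rss0 = float(yc @ yc)
    trait_name = model.trait

    cols = [gp.column_at(q.chrom, q.pos_cm) for q in model.qtls]
    if len(set(cols)) < len(cols):
        dup = [model.qtls[i] for i in range(len(cols)) if cols.count(cols[i]) > 1]
        raise SeedMqtlError(
            "coincident QTL positions: "
            + ", ".join(f"{q.chrom}@{q.pos_cm}" for q in dup)
        )
    inter = [(a, b) for a, b, _ in model.interactions]
    if not cols:
        return QtlModel(trait=trait_name)

    D = _design_matrix(X, cols, inter)
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise SeedMqtlError(
            "rank-deficient design for QTLs at "
            + ", ".join(f"{q.chrom}@{q.pos_cm}" for q in model.qtls)
        )
    beta, *_ = np.linalg.lstsq(D, yk, rcond=None)
    resid = yk - D @ beta
    rss_full = float(resid @ resid)
    combined_r2 = 100.0 * (1.0 - rss_full / rss0) if rss0 > 0 else 0.0
    full_lod = (n / 2.0) * np.log10(rss0 / max(rss_full, 1e-12))

    grid = gp.grid
    qtls = []
    supports = []
    for k, q in enumerate(model.qtls):
        sub_cols = cols[:k] + cols[k + 1:]
        sub_inter = [
            (a - (a > k), b - (b > k)) for a, b in inter if a != k and b != k
        ]
        rss_red = _model_rss(_design_matrix(X, sub_cols, sub_inter), yk)
        r2_k = 100.0 * (rss_red - rss_full) / rss0 if rss0 > 0 else 0.0
        lod_k = (n / 2.0) * np.log10(max(rss_red, 1e-12) / max(rss_full, 1e-12))
        qtls.append(
            QtlEffect(q.chrom, q.pos_cm, float(beta[1 + k]), float(r2_k), float(lod_k))
        )
        # drop-one profile along this QTL's chromosome for the support interval
        on_chrom = np.flatnonzero(grid["chrom"].to_numpy() == q.chrom)
        prof = np.empty(len(on_chrom))
        for idx, c in enumerate(on_chrom):
            trial = cols[:k] + [int(c)] + cols[k + 1:]
            if len(set(trial)) < len(trial):
                prof[idx] = -np.inf
                continue
            rss_t = _model_rss(_design_matrix(X, trial, inter), yk)
            prof[idx] = (n / 2.0) * np.log10(rss0 / max(rss_t, 1e-12))
        prof[~np.isfinite(prof)] = prof[np.isfinite(prof)].min()
        prof_curve = LodCurve(
            pd.DataFrame(
                {
                    "chrom": q.chrom,
                    "pos_cm": grid["pos_cm"].to_numpy(float)[on_chrom],
                    "lod": prof - prof.min(),
                }
            )
        )
        supports.append(lod_support_interval(prof_curve, gp.gmap, q.chrom, lod_drop))

    interactions = []
    for a, b, _ in model.interactions:
        sub_inter = [(x, z) for x, z in inter if (x, z) != (a, b)]
        rss_red = _model_rss(_design_matrix(X, cols, sub_inter), yk)
        interactions.append(
            (a, b, float((n / 2.0) * np.log10(max(rss_red, 1e-12) / max(rss_full, 1e-12))))
        )

    return QtlModel(
        trait=trait_name,
        qtls=qtls,
        interactions=interactions,
        combined_r2=float(combined_r2),
        lod=float(full_lod),
        support=supports,
    )
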