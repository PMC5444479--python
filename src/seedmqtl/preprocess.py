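"""Intensity normalization and trait preparation for mapping.

Raw relative metabolite intensities carry sample-level nuisance
variation (amount of seed material, internal-standard recovery) and
trait-level instrument drift (detector response differing between
measurement days / extraction batches).  The stages here remove these
in a fixed order:

1. divide by seed weight and internal-standard intensity;
2. per trait, divide by the measurement-day median rescaled to the
   grand median (detector-response correction; per-batch variant by flag);
3. remove outliers outside median +/- 4 SD, once, per trait;
4. Box-Cox power transform, lambda by profile maximum likelihood on the
   grid [-2, 2] in steps of 0.01;
5. drop traits observed in at most the presence-threshold fraction of
   samples (strictly-greater-than survives).

Sample-level corrections run before trait-level statistics so that the
outlier bounds and the transform see comparable values.  Every stage
writes to a NormalizationAudit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import PhenotypeTable, ScanConfig, SeedMqtlError

logger = logging.getLogger("seedmqtl")

LAMBDA_GRID = np.round(np.arange(-2.0, 2.0 + 1e-9, 0.01), 10)


@dataclass
class NormalizationAudit:
    """Per-trait and per-day records of what preprocessing did."""

    outliers_removed: dict[str, int] = field(default_factory=dict)
    lambdas: dict[str, float] = field(default_factory=dict)
    presence_fraction: dict[str, float] = field(default_factory=dict)
    day_factors: dict[tuple[str, str], float] = field(default_factory=dict)
    dropped_traits: list[str] = field(default_factory=list)
    excluded_individuals: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "outliers_removed": self.outliers_removed,
            "lambdas": self.lambdas,
            "presence_fraction": self.presence_fraction,
            "day_factors": {f"{d}/{t}": v for (d, t), v in self.day_factors.items()},
            "dropped_traits": self.dropped_traits,
            "excluded_individuals": self.excluded_individuals,
        }


def normalize_intensities(
    raw: PhenotypeTable,
    audit: NormalizationAudit | None = None,
    group_by: str = "day",
) -> PhenotypeTable:
    """Seed-weight / internal-standard / detector-response normalization.

    value <- raw / seed_weight / IS_intensity, then each trait is divided
    by its measurement-day median rescaled to the trait's grand median.
    Individuals with zero or missing seed weight or internal-standard
    intensity are excluded (logged in the audit).
    """
    if raw.metadata is None:
        raise SeedMqtlError("normalization requires sample metadata")
    audit = audit if audit is not None else NormalizationAudit()
    meta = raw.metadata
    sw = meta["seed_weight"].to_numpy(float)
    is_int = meta["is_intensity"].to_numpy(float)
    bad = ~np.isfinite(sw) | (sw <= 0) | ~np.isfinite(is_int) | (is_int <= 0)
    if bad.any():
        excluded = [str(i) for i in np.asarray(raw.individuals)[bad]]
        logger.warning("excluding %d individuals with invalid seed weight/IS: %s",
                       len(excluded), excluded)
        audit.excluded_individuals.extend(excluded)

    values = raw.values.loc[~bad].div(sw[~bad], axis=0).div(is_int[~bad], axis=0)
    meta = meta.loc[~bad]

    groups = meta[group_by].astype(str)
    grand_median = values.median(axis=0, skipna=True)
    for day, idx in values.groupby(groups).groups.items():
        day_median = values.loc[idx].median(axis=0, skipna=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            factor = day_median / grand_median
        factor = factor.replace([np.inf, -np.inf], np.nan).fillna(1.0)
        factor[factor <= 0] = 1.0
        values.loc[idx] = values.loc[idx].div(factor, axis=1)
        for trait, f in factor.items():
            audit.day_factors[(str(day), str(trait))] = float(f)
    return PhenotypeTable(values, meta.copy())


def remove_outliers(
    values: pd.Series, sd_mult: float = 4.0
) -> tuple[pd.Series, int]:
    """Mask entries outside median +/- sd_mult * SD (applied once).

    SD is the sample standard deviation (n-1 denominator) of the
    non-missing values; a constant vector has SD 0 and is returned
    unchanged.
    """
    obs = values.dropna()
    if len(obs) == 0:
        logger.warning("all-missing trait %r; outlier removal skipped", values.name)
        return values.copy(), 0
    if len(obs) < 3:
        raise SeedMqtlError("need at least 3 non-missing values for outlier removal")
    med = float(obs.median())
    sd = float(obs.std(ddof=1))
    lo, hi = med - sd_mult * sd, med + sd_mult * sd
    mask = (values < lo) | (values > hi)
    out = values.where(~mask)
    return out, int(mask.sum())


def power_transform(values: pd.Series, shift: float = 0.0) -> tuple[pd.Series, float]:
    """One-parameter Box-Cox transform with lambda from a fixed ML grid.

    ``shift`` is added first (documented positive shift for traits with
    non-positive values); remaining non-positive values raise.  lambda
    maximizes the Box-Cox profile log-likelihood over [-2, 2] in 0.01
    steps; lambda = 0 is the log transform.
    """
    x = values + shift
    obs = x.dropna()
    if (obs <= 0).any():
        raise SeedMqtlError(
            f"trait {values.name!r} has non-positive values after shift {shift}"
        )
    arr = obs.to_numpy(float)
    llf = np.array([stats.boxcox_llf(lam, arr) for lam in LAMBDA_GRID])
    lam = float(LAMBDA_GRID[int(np.argmax(llf))])
    transformed = x.copy()
    if lam == 0.0:
        transformed.loc[obs.index] = np.log(arr)
    else:
        transformed.loc[obs.index] = (arr**lam - 1.0) / lam
    return transformed, lam


def presence_filter(
    table: PhenotypeTable, threshold: float = 0.85,
    audit: NormalizationAudit | None = None,
) -> PhenotypeTable:
    """Keep traits observed in strictly more than ``threshold`` of samples."""
    if not 0 < threshold <= 1:
        raise SeedMqtlError("presence threshold must lie in (0, 1]")
    frac = table.values.notna().mean(axis=0)
    keep = frac > threshold if threshold < 1 else frac >= 1.0
    dropped = [str(t) for t in frac.index[~keep]]
    if audit is not None:
        audit.presence_fraction.update({str(t): float(f) for t, f in frac.items()})
        audit.dropped_traits.extend(dropped)
    if dropped:
        logger.info("presence filter dropped %d traits", len(dropped))
    meta = table.metadata.copy() if table.metadata is not None else None
    return PhenotypeTable(table.values.loc[:, keep].copy(), meta)


def preprocess_pipeline(
    raw: PhenotypeTable, cfg: ScanConfig | None = None
) -> tuple[PhenotypeTable, NormalizationAudit]:
    """Full preprocessing chain: normalize, de-outlier, transform, filter."""
    cfg = cfg or ScanConfig()
    audit = NormalizationAudit()
    table = normalize_intensities(raw, audit)
    values = table.values.copy()
    for trait in values.columns:
        cleaned, n_out = remove_outliers(values[trait], cfg.outlier_sd_mult)
        audit.outliers_removed[str(trait)] = n_out
        col = cleaned
        obs = col.dropna()
        shift = 0.0
        if len(obs) and (obs <= 0).any():
            shift = float(-obs.min()) + 1e-6 * max(float(obs.max() - obs.min()), 1.0)
            logger.info("trait %r shifted by %g before power transform", trait, shift)
        transformed, lam = power_transform(col, shift)
        audit.lambdas[str(trait)] = lam
        values[trait] = transformed
    table = PhenotypeTable(values, table.metadata)
    table = presence_filter(table, cfg.presence_threshold, audit)
    return table, audit


def normalize_protein_content(
    concentration: pd.Series,
    buffer_volume_ul: float,
    meta: pd.DataFrame,
    group_by: str = "batch",
) -> pd.Series:
    """Per-seed protein content with batch-median detector correction.

    protein = concentration * buffer volume / seed count, then divided
    by the batch median rescaled to the grand median (same correction
    as the metabolite day/batch step).
    """
    protein = concentration * buffer_volume_ul / meta["seed_count"].astype(float)
    grand = float(protein.median())
    groups = meta[group_by].astype(str)
    for g, idx in protein.groupby(groups).groups.items():
        factor = float(protein.loc[idx].median()) / grand if grand else 1.0
        if factor > 0:
            protein.loc[idx] = protein.loc[idx] / factor
    return protein
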