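"""Weighted genetic risk score construction.

Turns a GWAS weight table and a dosage panel into the per-sample weighted
genetic risk score used as the Mendelian-randomization instrument:

    GRS_i = (sum_j beta_j * g_ij) / (mean_j beta_j)

i.e. the beta-weighted allele-dosage sum divided by the average effect
size, which puts the score back on an "effective allele count" scale.

Upstream filters applied in the canonical order:

1. :func:`filter_genomewide` — keep genome-wide-significant instruments
   (p < 5e-8 by convention);
2. :func:`harmonize_alleles` — align effect alleles to the panel's counted
   allele, flipping dosages (g -> 2-g) on swapped pairs and dropping
   strand-ambiguous (A/T, C/G) SNPs;
3. :func:`ld_prune` — greedy independence pruning at a squared-correlation
   threshold (keep the lowest-p SNP of each correlated clump);
4. :func:`impute_missing` — per-SNP mean imputation of missing dosages.

Every step reports what it dropped/flipped in a :class:`BuildLog`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypePanel",
    "GrsVector",
    "BuildLog",
    "filter_genomewide",
    "ld_prune",
    "impute_missing",
    "harmonize_alleles",
    "compute_grs",
    "build_grs",
    "NoInstrumentsError",
]

GENOME_WIDE_P = 5e-8
LD_R2_THRESHOLD = 0.1

AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


class NoInstrumentsError(ValueError):
    """No SNPs survive a filtering step."""


@dataclass
class GenotypePanel:
    """Samples x SNPs dosage matrix with missingness tracked as NaN."""

    dosages: np.ndarray
    sample_ids: pd.Index
    snp_ids: pd.Index
    eaf: np.ndarray | None = None
    alleles: pd.DataFrame | None = None  # columns: counted_allele, other_allele

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.sample_ids = pd.Index(self.sample_ids, name="sample_id")
        self.snp_ids = pd.Index(self.snp_ids, name="snp_id")
        n, m = self.dosages.shape
        if len(self.sample_ids) != n or len(self.snp_ids) != m:
            raise ValueError("id lengths do not match dosage matrix shape")
        if not self.sample_ids.is_unique or not self.snp_ids.is_unique:
            raise ValueError("sample and SNP ids must be unique")
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > 2)
        if np.any(bad & ~np.isnan(self.dosages)):
            raise ValueError("dosages must lie in [0, 2] (or be missing)")

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosages)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def subset_snps(self, snp_ids) -> "GenotypePanel":
        idx = self.snp_ids.get_indexer(snp_ids)
        if (idx < 0).any():
            missing = [s for s, i in zip(snp_ids, idx) if i < 0]
            raise KeyError(f"SNPs not in panel: {missing}")
        p = GenotypePanel(
            dosages=self.dosages[:, idx],
            sample_ids=self.sample_ids,
            snp_ids=pd.Index(list(snp_ids), name="snp_id"),
            eaf=None if self.eaf is None else self.eaf[idx],
            alleles=None if self.alleles is None else self.alleles.iloc[idx],
        )
        if hasattr(self, "complete"):
            p.complete = self.complete[:, idx]
        return p

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.sample_ids, columns=self.snp_ids)


@dataclass
class BuildLog:
    """Provenance of one GRS build."""

    n_input: int = 0
    n_after_pfilter: int = 0
    flipped: list[str] = field(default_factory=list)
    dropped_ambiguous: list[str] = field(default_factory=list)
    dropped_mismatch: list[str] = field(default_factory=list)
    dropped_absent: list[str] = field(default_factory=list)
    dropped_zero_variance: list[str] = field(default_factory=list)
    pruned_out: list[str] = field(default_factory=list)
    retained: list[str] = field(default_factory=list)
    n_imputed_cells: int = 0

    def to_dict(self):
        return {
            "n_input": self.n_input,
            "n_after_pfilter": self.n_after_pfilter,
            "n_flipped": len(self.flipped),
            "n_dropped_ambiguous": len(self.dropped_ambiguous),
            "n_dropped_mismatch": len(self.dropped_mismatch),
            "n_dropped_absent": len(self.dropped_absent),
            "n_dropped_zero_variance": len(self.dropped_zero_variance),
            "n_pruned_out": len(self.pruned_out),
            "n_retained": len(self.retained),
            "n_imputed_cells": self.n_imputed_cells,
        }


@dataclass
class GrsVector:
    """Per-sample weighted genetic risk score with its provenance."""

    scores: pd.Series
    snp_ids: list[str]
    betas: np.ndarray
    log: BuildLog | None = None

    def __len__(self):
        return len(self.scores)


def _validate_weights(weights: pd.DataFrame):
    required = {"snp_id", "beta", "se", "pvalue"}
    missing = required - set(weights.columns)
    if missing:
        raise ValueError(f"weight table missing columns: {sorted(missing)}")
    if (weights["pvalue"] <= 0).any() or (weights["pvalue"] > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    if (weights["se"] <= 0).any():
        raise ValueError("standard errors must be positive")
    if not np.isfinite(weights["beta"]).all():
        raise ValueError("betas must be finite")


def filter_genomewide(weights: pd.DataFrame, threshold: float = GENOME_WIDE_P):
    """Keep instruments with GWAS p-value strictly below ``threshold``."""
    _validate_weights(weights)
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    kept = weights.loc[weights["pvalue"] < threshold].copy()
    if threshold == 1.0:
        kept = weights.copy()  # p == 1 allowed: identity contract
    if kept.empty:
        raise NoInstrumentsError(
            f"no instruments with p < {threshold:g} (out of {len(weights)})"
        )
    return kept.reset_index(drop=True)


def harmonize_alleles(panel_alleles: pd.DataFrame, weights: pd.DataFrame, log=None):
    """Align weight-file effect alleles with the panel's counted allele.

    ``panel_alleles`` is indexed by snp_id with columns ``counted_allele``
    and ``other_allele``. Returns (aligned weights, flip mask) where
    ``flip`` marks SNPs whose dosages must be replaced by 2-g. Ambiguous
    (A/T, C/G) and unresolvable SNPs are dropped with a logged count.
    """
    if log is None:
        log = BuildLog()
    keep_rows = []
    flip = []
    for _, row in weights.iterrows():
        sid = row["snp_id"]
        ea = str(row["effect_allele"]).upper()
        oa = str(row["other_allele"]).upper()
        if (ea, oa) in AMBIGUOUS_PAIRS:
            log.dropped_ambiguous.append(sid)
            continue
        if sid not in panel_alleles.index:
            log.dropped_absent.append(sid)
            continue
        pa = str(panel_alleles.loc[sid, "counted_allele"]).upper()
        po = str(panel_alleles.loc[sid, "other_allele"]).upper()
        if (ea, oa) == (pa, po):
            keep_rows.append(row)
            flip.append(False)
        elif (ea, oa) == (po, pa):
            keep_rows.append(row)
            flip.append(True)
        else:
            log.dropped_mismatch.append(sid)
    if log.dropped_ambiguous:
        logger.warning("dropped %d strand-ambiguous SNPs", len(log.dropped_ambiguous))
    if log.dropped_mismatch:
        logger.warning("dropped %d allele-mismatched SNPs", len(log.dropped_mismatch))
    log.flipped = [r["snp_id"] for r, f in zip(keep_rows, flip) if f]
    aligned = pd.DataFrame(keep_rows).reset_index(drop=True)
    return aligned, np.asarray(flip, dtype=bool), log


def apply_flips(panel: GenotypePanel, flip_snps) -> GenotypePanel:
    """Replace dosage g by 2-g for the named SNPs (allele flip)."""
    idx = panel.snp_ids.get_indexer(flip_snps)
    if (idx < 0).any():
        raise KeyError("flip list contains SNPs absent from panel")
    dos = panel.dosages.copy()
    dos[:, idx] = 2.0 - dos[:, idx]
    out = GenotypePanel(
        dosages=dos,
        sample_ids=panel.sample_ids,
        snp_ids=panel.snp_ids,
        eaf=None if panel.eaf is None else panel.eaf.copy(),
        alleles=panel.alleles,
    )
    return out


def ld_prune(
    panel: GenotypePanel,
    weights: pd.DataFrame,
    r2_threshold: float = LD_R2_THRESHOLD,
    log=None,
):
    """Greedy LD pruning on sample dosage correlation.

    SNPs are visited in ascending GWAS p-value; a SNP is retained iff its
    squared Pearson correlation with every already-retained SNP is at or
    below ``r2_threshold``. Zero-variance SNPs are excluded with a warning
    (their correlation is undefined). Returns the retained snp_id list.
    """
    if log is None:
        log = BuildLog()
    if not (0.0 <= r2_threshold <= 1.0):
        raise ValueError("r2_threshold must be in [0, 1]")
    w = weights.set_index("snp_id")
    order = w["pvalue"].sort_values(kind="stable").index.tolist()
    idx = panel.snp_ids.get_indexer(order)
    present = [(sid, i) for sid, i in zip(order, idx) if i >= 0]
    absent = [sid for sid, i in zip(order, idx) if i < 0]
    log.dropped_absent.extend(absent)

    # column-standardized dosages with missing cells at the column mean
    # (zero after centring), so correlations use pairwise-complete structure
    retained: list[str] = []
    retained_cols: list[np.ndarray] = []
    n = panel.n_samples
    for sid, i in present:
        col = panel.dosages[:, i]
        col = np.where(np.isnan(col), np.nanmean(col), col)
        sd = col.std()
        if sd == 0.0:
            logger.warning("excluding zero-variance SNP %s from pruning", sid)
            log.dropped_zero_variance.append(sid)
            continue
        z = (col - col.mean()) / sd
        ok = True
        for zr in retained_cols:
            r = float(z @ zr) / n
            if r * r > r2_threshold:
                ok = False
                break
        if ok:
            retained.append(sid)
            retained_cols.append(z)
        else:
            log.pruned_out.append(sid)
    if not retained:
        raise NoInstrumentsError("no SNPs survive LD pruning")
    log.retained = list(retained)
    return retained, log


def impute_missing(panel: GenotypePanel, log=None) -> GenotypePanel:
    """Replace each missing dosage by that SNP's non-missing sample mean."""
    if log is None:
        log = BuildLog()
    dos = panel.dosages
    mask = np.isnan(dos)
    if not mask.any():
        log.n_imputed_cells = 0
        return panel
    n_obs = (~mask).sum(axis=0)
    fully_missing = np.where(n_obs == 0)[0]
    if fully_missing.size:
        names = [panel.snp_ids[j] for j in fully_missing]
        raise ValueError(f"SNP(s) fully missing, cannot mean-impute: {names}")
    col_means = np.nanmean(dos, axis=0)
    filled = np.where(mask, col_means[None, :], dos)
    log.n_imputed_cells = int(mask.sum())
    out = GenotypePanel(
        dosages=filled,
        sample_ids=panel.sample_ids,
        snp_ids=panel.snp_ids,
        eaf=None if panel.eaf is None else panel.eaf.copy(),
        alleles=panel.alleles,
    )
    if hasattr(panel, "complete"):
        out.complete = panel.complete
    return out


def compute_grs(
    panel: GenotypePanel, weights: pd.DataFrame, log=None, abs_denominator=False
) -> GrsVector:
    """Weighted GRS: (sum_j beta_j g_ij) / (mean_j beta_j).

    ``abs_denominator=True`` divides by mean |beta| instead (common practice
    when betas have mixed signs); the signed mean is the default. A signed
    mean of zero makes the score undefined and raises ValueError.
    """
    _validate_weights(weights)
    if weights.empty:
        raise NoInstrumentsError("empty weight table")
    w = weights.set_index("snp_id")
    snps = w.index.tolist()
    sub = panel.subset_snps(snps)
    if np.isnan(sub.dosages).any():
        raise ValueError("panel has missing dosages; impute before computing the GRS")
    betas = w["beta"].to_numpy(dtype=float)
    denom_betas = np.abs(betas) if abs_denominator else betas
    denom = denom_betas.mean()
    if denom == 0.0:
        raise ValueError(
            "mean beta is zero: the weighted-GRS denominator vanishes "
            "(consider abs_denominator=True)"
        )
    raw = sub.dosages @ betas
    scores = pd.Series(raw / denom, index=panel.sample_ids, name="grs")
    return GrsVector(scores=scores, snp_ids=snps, betas=betas, log=log)


def build_grs(
    panel: GenotypePanel,
    weights: pd.DataFrame,
    p_threshold: float = GENOME_WIDE_P,
    r2_threshold: float = LD_R2_THRESHOLD,
    harmonize: bool = False,
    abs_denominator: bool = False,
) -> GrsVector:
    """Full build: p-filter -> (optional allele harmonization) -> drop SNPs
    absent from the panel -> LD prune -> mean-impute -> weighted score."""
    log = BuildLog(n_input=len(weights))
    kept = filter_genomewide(weights, p_threshold)
    log.n_after_pfilter = len(kept)
    if harmonize:
        if panel.alleles is None:
            raise ValueError("panel has no allele metadata; cannot harmonize")
        kept, flip, log = harmonize_alleles(panel.alleles, kept, log)
        if kept.empty:
            raise NoInstrumentsError("no SNPs survive allele harmonization")
        panel = apply_flips(panel, [s for s in log.flipped])
    in_panel = kept["snp_id"].isin(panel.snp_ids)
    log.dropped_absent.extend(kept.loc[~in_panel, "snp_id"].tolist())
    kept = kept.loc[in_panel].reset_index(drop=True)
    if kept.empty:
        raise NoInstrumentsError("none of the filtered SNPs are in the panel")
    retained, log = ld_prune(panel, kept, r2_threshold, log)
    kept = kept.set_index("snp_id").loc[retained].reset_index()
    sub = panel.subset_snps(retained)
    sub = impute_missing(sub, log)
    grs = compute_grs(sub, kept, log, abs_denominator=abs_denominator)
    return grs
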