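"""AP-MS differential-enrichment analysis.

The pipeline mirrors standard label-free quantitative proteomics practice:
a per-group completeness filter (>= 80 % of replicates observed in at least
one group), log transformation with median centering (or a generalized-log
variance-stabilizing option), mixed MAR/MNAR imputation (group-mean for
missing-at-random cells; per-sample down-shifted Gaussian draws, shift
1.8 SD and width 0.3 SD, for missing-not-at-random cells), a two-tailed
Welch's t-test per protein, Benjamini–Hochberg adjustment, and an
enrichment call at log2 fold change >= 2 with adjusted p < 0.05.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig
from .datamodel import QuantMatrix

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    """Per-protein differential-enrichment statistics (test minus control)."""

    accession: str
    log2_fc: float
    t_stat: float
    p: float
    p_adj: float = float("nan")
    enriched: bool = False


def filter_by_completeness(matrix: QuantMatrix, min_frac: float) -> QuantMatrix:
    """Retain proteins observed in >= ``min_frac`` of replicates of any group."""
    if matrix.intensities.empty:
        warnings.warn("completeness filter applied to an empty matrix")
        return matrix.copy_with(matrix.intensities)
    obs = matrix.observed_mask()
    keep = pd.Series(False, index=matrix.intensities.index)
    for g in matrix.group_labels:
        cols = matrix.samples_in(g)
        keep |= obs[cols].mean(axis=1) >= min_frac
    return matrix.copy_with(matrix.intensities.loc[keep])


def normalize(matrix: QuantMatrix, method: str = "log2_median") -> QuantMatrix:
    """Transform raw intensities to a normalized log2 scale.

    ``log2_median`` (default) log2-transforms and subtracts each sample's
    median, removing multiplicative between-sample effects.  ``glog``
    applies a generalized-log transform ``log2((x + sqrt(x^2 + c^2)) / 2)``
    with the per-sample offset ``c`` set to the 5th percentile of that
    sample's observed intensities (a moment-matching surrogate for a full
    variance-stabilizing fit), then median-centers.  An already-log2 matrix
    passes through ``log2_median`` unchanged except for centering.
    """
    vals = matrix.intensities.to_numpy(copy=True)
    if method == "log2_median":
        if matrix.scale == "raw":
            with np.errstate(divide="ignore", invalid="ignore"):
                vals = np.log2(vals)
    elif method == "glog":
        if matrix.scale != "raw":
            raise ValueError("glog expects raw-scale intensities")
        for j in range(vals.shape[1]):
            col = vals[:, j]
            obs = col[np.isfinite(col)]
            c = np.percentile(obs, 5.0) if obs.size else 1.0
            vals[:, j] = np.log2((col + np.sqrt(col ** 2 + c ** 2)) / 2.0)
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    med = np.nanmedian(vals, axis=0)
    vals = vals - med
    out = pd.DataFrame(vals, index=matrix.intensities.index,
                       columns=matrix.intensities.columns)
    return matrix.copy_with(out, scale="log2")


def impute_mixed(matrix: QuantMatrix, downshift: float | None = None,
                 width: float | None = None, seed: int = 0,
                 config: PipelineConfig | None = None) -> QuantMatrix:
    """Impute missing values with the mixed MAR/MNAR strategy.

    A missing cell is MAR if its protein has at least one observed replicate
    in the same group; it is then replaced by the mean of those observed
    replicates.  Otherwise it is MNAR and drawn from
    ``Normal(m_s - downshift * s_s, (width * s_s)^2)`` where ``m_s`` and
    ``s_s`` are the mean and SD of the observed values of that cell's
    sample.  Draws are reproducible for a fixed seed and are consumed in
    protein-major order, so results do not depend on row insertion order.
    """
    cfg = config or PipelineConfig()
    downshift = cfg.imputation_downshift if downshift is None else downshift
    width = cfg.imputation_width if width is None else width
    if matrix.scale != "log2":
        raise ValueError("impute_mixed expects a log2-scale matrix")
    vals = matrix.intensities.to_numpy(copy=True)
    if not np.any(np.isnan(vals)):
        return matrix.copy_with(matrix.intensities)
    n_prot, n_samp = vals.shape
    obs_counts = np.sum(np.isfinite(vals), axis=0)
    if np.any(obs_counts < 2):
        bad = [matrix.samples[j] for j in np.where(obs_counts < 2)[0]]
        raise ValueError(f"samples with < 2 observed values: {bad}")
    m_s = np.nanmean(vals, axis=0)
    s_s = np.nanstd(vals, axis=0, ddof=1)
    group_cols = {g: [matrix.samples.index(s) for s in matrix.samples_in(g)]
                  for g in matrix.group_labels}
    sample_group = [matrix.groups[s] for s in matrix.samples]
    rng = np.random.default_rng(seed)
    for i in range(n_prot):
        row = vals[i]
        if np.all(np.isfinite(row)):
            continue
        group_means = {}
        for g, cols in group_cols.items():
            o = row[cols]
            o = o[np.isfinite(o)]
            group_means[g] = o.mean() if o.size else None
        for j in range(n_samp):
            if np.isfinite(row[j]):
                continue
            gm = group_means[sample_group[j]]
            if gm is not None:                      # MAR: group-mean imputation
                vals[i, j] = gm
            else:                                   # MNAR: down-shifted draw
                vals[i, j] = rng.normal(m_s[j] - downshift * s_s[j],
                                        width * s_s[j])
    out = pd.DataFrame(vals, index=matrix.intensities.index,
                       columns=matrix.intensities.columns)
    return matrix.copy_with(out)


def _welch(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        return float(np.sign(x.mean() - y.mean()) * np.inf), 0.0
    with warnings.catch_warnings():
        # near-identical replicates (e.g. after group-mean imputation) trip
        # scipy's catastrophic-cancellation warning; the guard above already
        # handles the fully degenerate case
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)


def welch_test(matrix: QuantMatrix, group_test: str, group_ctrl: str
               ) -> list[EnrichmentResult]:
    """Per-protein two-tailed Welch's t-test (test group minus control).

    Requires a complete (imputed) matrix and >= 2 samples per group.
    Degenerate proteins with zero variance in both groups and equal means
    yield t = 0, p = 1.
    """
    cols_t = matrix.samples_in(group_test)
    cols_c = matrix.samples_in(group_ctrl)
    if len(cols_t) < 2 or len(cols_c) < 2:
        raise ValueError("both groups need >= 2 samples for Welch's test")
    if matrix.intensities[cols_t + cols_c].isna().any().any():
        raise ValueError("welch_test requires a complete (imputed) matrix")
    xt = matrix.intensities[cols_t].to_numpy()
    xc = matrix.intensities[cols_c].to_numpy()
    results = []
    for i, acc in enumerate(matrix.proteins):
        t, p = _welch(xt[i], xc[i])
        results.append(EnrichmentResult(
            accession=acc, log2_fc=float(xt[i].mean() - xc[i].mean()),
            t_stat=t, p=p))
    return results


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, original order kept."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_enriched(results: list[EnrichmentResult], lfc_min: float = 2.0,
                  alpha: float = 0.05) -> set[str]:
    """Positive-side enrichment call: log2FC >= lfc_min and p_adj < alpha."""
    out = set()
    for r in results:
        r.enriched = bool(r.log2_fc >= lfc_min and r.p_adj < alpha)
        if r.enriched:
            out.add(r.accession)
    return out


def call_depleted(results: list[EnrichmentResult], lfc_min: float = 2.0,
                  alpha: float = 0.05) -> set[str]:
    """Symmetric depletion call: log2FC <= -lfc_min and p_adj < alpha."""
    return {r.accession for r in results
            if r.log2_fc <= -lfc_min and r.p_adj < alpha}


def enrich_pipeline(matrix: QuantMatrix, group_test: str, group_ctrl: str,
                    config: PipelineConfig | None = None, seed: int = 0,
                    normalization: str = "log2_median"
                    ) -> tuple[list[EnrichmentResult], set[str]]:
    """Full AP-MS contrast: filter, normalize, impute, test, adjust, call."""
    cfg = config or PipelineConfig()
    m = filter_by_completeness(matrix, cfg.completeness_min)
    if m.scale == "raw":
        m = normalize(m, normalization)
    m = impute_mixed(m, seed=seed, config=cfg)
    results = welch_test(m, group_test, group_ctrl)
    padj = bh_adjust([r.p for r in results])
    for r, q in zip(results, padj):
        r.p_adj = float(q)
    enriched = call_enriched(results, cfg.lfc_min, cfg.alpha)
    return results, enriched


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "accession": r.accession, "log2_fc": r.log2_fc, "t": r.t_stat,
        "p": r.p, "p_adj": r.p_adj, "enriched": r.enriched,
    } for r in results])
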