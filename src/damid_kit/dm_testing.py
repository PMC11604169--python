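"""Differential methylation testing of GATC regions, Fusion vs Dam-only.

The workflow is the standard count-based differential pipeline adapted to
GATC regions:

1. filter out excessively large regions (>10 kb by default) and low-count
   regions (CPM below a cutoff in too many samples);
2. trimmed-mean-of-M-values (TMM) normalization, which assumes most
   regions are not differentially methylated;
3. a negative-binomial generalized linear model with log link per region,
   with a pooled (common) NB dispersion estimated by maximizing the
   Cox-Reid adjusted profile likelihood, region-wise quasi-dispersions
   from residual deviances, and empirical-Bayes moderation of the
   quasi-dispersions toward their pooled value;
4. a quasi-likelihood F test of the Fusion - Dam contrast, with
   Benjamini-Hochberg FDR across tested regions.

The design always contains the group factor (Dam reference level) and may
include a replicate factor, which absorbs replicate-specific effects such
as the systematic depth and composition differences often seen between
DamID replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .counting import RegionCountMatrix
from .gatc_index import InputError

logger = logging.getLogger(__name__)

DEFAULT_P_THRESHOLD = 0.01
DEFAULT_LFC_THRESHOLD = 1.0

_LN2 = np.log(2.0)


@dataclass
class FilterConfig:
    max_region_width: int = 10_000
    min_cpm: float = 0.5
    min_samples_at_cpm: int | None = None  # None -> size of the smallest group

    def __post_init__(self) -> None:
        if self.max_region_width <= 0:
            raise ValueError("max_region_width must be positive")
        if self.min_cpm < 0:
            raise ValueError("min_cpm must be non-negative")


@dataclass
class DesignSpec:
    """Model design: mandatory group factor, optional replicate factor."""

    replicate_factor: bool = False


@dataclass
class RegionFits:
    """Per-region GLM fits and moderated quasi-dispersions."""

    table: pd.DataFrame = field(repr=False)  # one row per tested region
    common_dispersion: float = np.nan
    prior_df: float = np.nan
    prior_var: float = np.nan
    residual_df: float = np.nan


def filter_regions(
    matrix: RegionCountMatrix, cfg: FilterConfig | None = None
) -> tuple[RegionCountMatrix, pd.DataFrame]:
    """Drop oversized and low-count regions before testing.

    A region is removed when its width strictly exceeds
    ``max_region_width``, or when fewer than ``min_samples_at_cpm``
    samples reach ``min_cpm`` counts per million.  Returns the retained
    matrix and a table of removed region ids with machine-readable
    reasons (``width`` or ``low_count``).
    """
    cfg = cfg or FilterConfig()
    if len(matrix.regions) == 0:
        raise InputError("empty count matrix")

    groups = np.array([s.group for s in matrix.samples])
    min_group = min(int((groups == g).sum()) for g in np.unique(groups))
    min_samples = cfg.min_samples_at_cpm if cfg.min_samples_at_cpm is not None else min_group

    widths = np.array([r.width for r in matrix.regions])
    lib = matrix.counts.sum(axis=0).astype(float)
    lib[lib == 0] = 1.0
    cpm = matrix.counts / lib * 1e6
    n_pass = (cpm >= cfg.min_cpm).sum(axis=1)

    too_wide = widths > cfg.max_region_width
    low = n_pass < min_samples
    keep = ~(too_wide | low)

    reasons = np.where(too_wide, "width", np.where(low, "low_count", ""))
    removed = pd.DataFrame(
        {
            "region_id": [r.region_id for r, k in zip(matrix.regions, keep) if not k],
            "reason": [rs for rs, k in zip(reasons, keep) if not k],
        }
    )
    if not keep.any():
        raise InputError("all regions removed by filtering; nothing to test")

    kept = RegionCountMatrix(
        regions=[r for r, k in zip(matrix.regions, keep) if k],
        samples=matrix.samples,
        counts=matrix.counts[keep],
    )
    return kept, removed


# ---------------------------------------------------------------------------
# TMM normalization


def _tmm_pair(
    obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
    trim_m: float, trim_a: float,
) -> float:
    """Trimmed, precision-weighted mean of M-values of one sample vs the reference."""
    use = (obs > 0) & (ref > 0)
    if not use.any():
        raise InputError("sample shares no nonzero regions with the TMM reference")
    p_obs = obs[use] / n_obs
    p_ref = ref[use] / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # delta-method asymptotic variance of M
    w = (n_obs - obs[use]) / (n_obs * obs[use]) + (n_ref - ref[use]) / (n_ref * ref[use])

    n = m.size
    m_rank = stats.rankdata(m, method="average")
    a_rank = stats.rankdata(a, method="average")
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    keep = (m_rank >= lo_m) & (m_rank <= hi_m) & (a_rank >= lo_a) & (a_rank <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def tmm_factors(
    matrix: RegionCountMatrix | np.ndarray,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> np.ndarray:
    """Per-sample TMM normalization factors, rescaled to geometric mean 1.

    The reference sample is the one whose upper-quartile CPM is closest to
    the mean upper-quartile.  For every other sample the factor is
    2^(precision-weighted mean of M-values) after trimming the most
    extreme ``trim_m`` fraction by M from each tail and ``trim_a`` by A,
    excluding regions with a zero count in either sample.
    """
    counts = matrix.counts if isinstance(matrix, RegionCountMatrix) else np.asarray(matrix)
    counts = counts.astype(float)
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        raise InputError("every sample needs a positive total count for TMM")

    uq = np.array([np.quantile(counts[:, j] / lib[j], 0.75) for j in range(counts.shape[1])])
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))

    factors = np.ones(counts.shape[1])
    for j in range(counts.shape[1]):
        if j == ref_idx:
            continue
        factors[j] = _tmm_pair(
            counts[:, j], counts[:, ref_idx], lib[j], lib[ref_idx], trim_m, trim_a
        )
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


# ---------------------------------------------------------------------------
# NB GLM machinery (vectorized IRLS across regions)

_IRLS_MAX_ITER = 100
_IRLS_TOL = 1e-12
_BETA_CAP = 30.0


def build_design(samples, spec: DesignSpec) -> tuple[np.ndarray, list[str]]:
    """Design matrix (samples x terms): intercept, group, optional replicate dummies.

    Raises on rank deficiency (e.g. replicate fully confounded with group).
    """
    n = len(samples)
    cols = [np.ones(n)]
    names = ["intercept"]
    group = np.array([1.0 if s.group == "Fusion" else 0.0 for s in samples])
    cols.append(group)
    names.append("groupFusion")
    if spec.replicate_factor:
        reps = sorted({s.replicate for s in samples})
        for rep in reps[1:]:
            cols.append(np.array([1.0 if s.replicate == rep else 0.0 for s in samples]))
            names.append(f"replicate{rep}")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise InputError(
            "design matrix is rank deficient (replicate factor confounded with group?)"
        )
    return X, names


def _irls_nb(
    y: np.ndarray, X: np.ndarray, offset: np.ndarray, phi: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fit NB GLMs with log link for all regions at once.

    y: (G, n) counts; X: (n, p); offset: (n,) log effective library sizes.
    Returns (beta (G, p), mu (G, n), deviance (G,), converged (G,) bool).
    """
    G, n = y.shape
    p = X.shape[1]
    # initialize intercept-ish start from adjusted log means
    mean0 = np.maximum(y.mean(axis=1), 1.0 / n)
    beta = np.zeros((G, p))
    beta[:, 0] = np.log(mean0) - offset.mean()
    dev_prev = np.full(G, np.inf)
    converged = np.zeros(G, dtype=bool)
    mu = None
    for _ in range(_IRLS_MAX_ITER):
        eta = beta @ X.T + offset
        mu = np.exp(eta)
        w = mu / (1.0 + phi * mu)  # working weights for NB log link
        z = (eta - offset) + (y - mu) / mu
        # normal equations per region: (X' W X) beta = X' W z
        Xw = X[None, :, :] * w[:, :, None]          # (G, n, p)
        A = np.einsum("gnp,nq->gpq", Xw, X)          # (G, p, p)
        b = np.einsum("gnp,gn->gp", Xw, z)           # (G, p)
        A += 1e-10 * np.eye(p)[None]
        beta_new = np.linalg.solve(A, b[:, :, None])[:, :, 0]
        beta_new = np.clip(beta_new, -_BETA_CAP, _BETA_CAP)
        dev = _nb_deviance(y, np.exp(beta_new @ X.T + offset), phi)
        # enforce monotone deviance by step halving: clipped updates at the
        # parameter box (all-zero groups) would otherwise oscillate
        for _half in range(10):
            worse = dev > dev_prev + 1e-12
            if not worse.any():
                break
            beta_new[worse] = 0.5 * (beta_new[worse] + beta[worse])
            dev_w = _nb_deviance(y[worse], np.exp(beta_new[worse] @ X.T + offset), phi)
            dev = np.where(worse, 0.0, dev)
            dev[worse] = dev_w
        converged = np.abs(dev - dev_prev) < _IRLS_TOL * (np.abs(dev_prev) + 1.0)
        beta = beta_new
        dev_prev = dev
        if converged.all():
            break
    mu = np.exp(beta @ X.T + offset)
    dev = _nb_deviance(y, mu, phi)
    return beta, mu, dev, converged


def _nb_deviance(y: np.ndarray, mu: np.ndarray, phi: float) -> np.ndarray:
    mu = np.maximum(mu, 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(y > 0, y * np.log(np.maximum(y, 1e-300) / mu), 0.0)
    if phi > 0:
        term2 = (y + 1.0 / phi) * np.log((1.0 + phi * y) / (1.0 + phi * mu))
        dev = 2.0 * (term1 - term2)
    else:
        dev = 2.0 * (term1 - (y - mu))
    return dev.sum(axis=1)


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> np.ndarray:
    r = 1.0 / phi
    mu = np.maximum(mu, 1e-12)
    ll = (
        special.gammaln(y + r)
        - special.gammaln(r)
        - special.gammaln(y + 1.0)
        + y * np.log(phi * mu / (1.0 + phi * mu))
        - r * np.log1p(phi * mu)
    )
    return ll.sum(axis=1)


def _cox_reid_adjustment(mu: np.ndarray, X: np.ndarray, phi: float) -> np.ndarray:
    w = mu / (1.0 + phi * mu)
    Xw = X[None, :, :] * w[:, :, None]
    A = np.einsum("gnp,nq->gpq", Xw, X)
    A += 1e-10 * np.eye(X.shape[1])[None]
    sign, logdet = np.linalg.slogdet(A)
    return 0.5 * logdet


def estimate_common_dispersion(
    y: np.ndarray, X: np.ndarray, offset: np.ndarray
) -> float:
    """Common NB dispersion maximizing the pooled Cox-Reid adjusted profile likelihood."""

    def neg_apl(log_phi: float) -> float:
        phi = float(np.exp(log_phi))
        _, mu, _, _ = _irls_nb(y, X, offset, phi)
        apl = _nb_loglik(y, mu, phi) - _cox_reid_adjustment(mu, X, phi)
        return -float(apl.sum())

    res = optimize.minimize_scalar(
        neg_apl, bounds=(np.log(1e-5), np.log(5.0)), method="bounded",
        options={"xatol": 1e-3},
    )
    return float(np.exp(res.x))


def _trigamma_inverse(x: float) -> float:
    # Newton iteration on trigamma(y) = x (limma's approach)
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-8 * y:
            break
    return float(y)


def _squeeze_var(s2: np.ndarray, df: float) -> tuple[np.ndarray, float, float]:
    """Empirical-Bayes moderation of variances toward a pooled prior.

    Moment-matching of log variances against a scaled F distribution
    yields the prior df and prior variance; returns the posterior
    (shrunken) variances, prior df, and prior variance.
    """
    ok = s2 > 0
    z = np.log(np.maximum(s2, 1e-10))
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e[ok].mean()) if ok.any() else 0.0
    n_ok = int(ok.sum())
    if n_ok > 1:
        evar = float(e[ok].var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    else:
        evar = 0.0
    if evar > 0:
        df_prior = 2.0 * _trigamma_inverse(evar)
        s2_prior = float(
            np.exp(emean + special.digamma(df_prior / 2.0) - np.log(df_prior / 2.0))
        )
    else:
        df_prior = np.inf
        s2_prior = float(np.exp(emean))
    if np.isinf(df_prior):
        s2_post = np.full_like(s2, s2_prior)
    else:
        s2_post = (df_prior * s2_prior + df * s2) / (df_prior + df)
    return s2_post, float(df_prior), s2_prior


def fit_ql_nb(
    matrix: RegionCountMatrix,
    factors: np.ndarray | None = None,
    design: DesignSpec | None = None,
) -> RegionFits:
    """Fit the quasi-likelihood NB model and test the Fusion - Dam contrast.

    Offsets are log(library size x TMM factor).  The quasi-likelihood F
    statistic compares the drop in deviance when the group coefficient is
    removed against the region's moderated quasi-dispersion; its null
    distribution is F(1, prior df + residual df).
    """
    design = design or DesignSpec()
    y = matrix.counts.astype(float)
    G, n = y.shape
    lib = y.sum(axis=0)
    if factors is None:
        factors = np.ones(n)
    offset = np.log(lib * np.asarray(factors))

    X, names = build_design(matrix.samples, design)
    p = X.shape[1]
    df_res = n - p
    if df_res < 1:
        raise InputError(f"no residual degrees of freedom (n={n}, p={p})")
    group_col = names.index("groupFusion")
    X_null = np.delete(X, group_col, axis=1)

    # regions where one whole group is zero have an infinite group-coefficient
    # MLE; a small stabilizing prior count keeps the fit finite and makes the
    # result invariant to which group is the baseline
    group_mask = X[:, group_col] > 0
    zero_group = (y[:, group_mask].sum(axis=1) == 0) | (
        y[:, ~group_mask].sum(axis=1) == 0
    )
    y_fit = y.copy()
    y_fit[zero_group] += 0.125

    phi = estimate_common_dispersion(y_fit, X, offset)
    logger.info("common NB dispersion: %.4g", phi)

    beta, mu, dev_full, conv_full = _irls_nb(y_fit, X, offset, phi)
    _, _, dev_null, conv_null = _irls_nb(y_fit, X_null, offset, phi)
    converged = conv_full & conv_null

    s2 = dev_full / df_res
    # stabilized and non-converged deviances stay out of the moderation pool
    pool = converged & ~zero_group
    _, df_prior, s2_prior = _squeeze_var(s2[pool], float(df_res))
    if np.isinf(df_prior):
        s2_post = np.full(G, s2_prior)
    else:
        s2_post = (df_prior * s2_prior + df_res * s2) / (df_prior + df_res)

    df_total = (df_prior + df_res) if np.isfinite(df_prior) else 1e8
    # the deviance drop can be tiny-negative from finite IRLS tolerance
    f_stat = np.maximum(dev_null - dev_full, 0.0) / np.maximum(s2_post, 1e-12)
    p_value = stats.f.sf(f_stat, 1, df_total)
    p_value = np.where(converged, p_value, np.nan)

    logfc = beta[:, group_col] / _LN2
    eff_lib = lib * np.asarray(factors)
    ave_cpm = np.log2(((y + 0.5) / (eff_lib + 1.0) * 1e6).mean(axis=1))

    table = pd.DataFrame(
        {
            "region_id": matrix.region_ids,
            "chrom": [r.chrom for r in matrix.regions],
            "start": [r.start for r in matrix.regions],
            "end": [r.end for r in matrix.regions],
            "width": [r.width for r in matrix.regions],
            "logFC": logfc,
            "aveLogCPM": ave_cpm,
            "stat": f_stat,
            "p_value": p_value,
            "converged": converged,
        }
    )
    if (~converged).any():
        logger.warning("%d region(s) failed to converge; p set to NA", int((~converged).sum()))
    return RegionFits(
        table=table,
        common_dispersion=phi,
        prior_df=df_prior,
        prior_var=s2_prior,
        residual_df=float(df_res),
    )


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values; NaNs are passed through."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.sum() == 0:
        return out
    ps = p[ok]
    m = ps.size
    order = np.argsort(ps, kind="stable")
    ranked = ps[order] * m / (np.arange(m) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(m)
    res[order] = np.minimum(adj, 1.0)
    out[ok] = res
    return out


def test_regions(
    fits: RegionFits,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    removed: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble per-region test results with BH FDR and methylation calls.

    ``meth_status`` is ``Upreg`` when the raw p-value is below
    ``p_threshold`` and logFC is at least ``lfc_threshold``; regions
    removed by filtering are appended as ``Not_included``; everything
    else is ``No``.  Output is ordered by genomic position.
    """
    table = fits.table.copy()
    if len(table) == 0:
        logger.warning("no tested regions")
    table["fdr"] = bh_adjust(table["p_value"].to_numpy())
    sig = (table["p_value"] < p_threshold) & (table["logFC"] >= lfc_threshold)
    table["meth_status"] = np.where(sig.fillna(False), "Upreg", "No")
    table.loc[table["p_value"].isna(), "meth_status"] = "No"

    if removed is not None and len(removed):
        extra = removed.copy()
        parts = extra["region_id"].str.rsplit("-", n=2, expand=True)
        extra["chrom"] = parts[0]
        extra["start"] = parts[1].astype(int)
        extra["end"] = parts[2].astype(int)
        extra["width"] = extra["end"] - extra["start"]
        for col in ["logFC", "aveLogCPM", "stat", "p_value", "fdr"]:
            extra[col] = np.nan
        extra["converged"] = False
        extra["meth_status"] = "Not_included"
        table = pd.concat(
            [table, extra[table.columns.intersection(extra.columns)]], ignore_index=True
        )
    table = table.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    return table
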