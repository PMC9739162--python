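"""Filtering, normalization and moderated-t differential expression.

The expression workflow applied identically to consensus circRNA counts and
gene counts:

1. low-expression filtering on counts per million (CPM);
2. trimmed-mean-of-M-values (TMM) between-sample normalization factors;
3. log2-CPM with a prior count;
4. per-feature ordinary least squares on a case/control design (optionally
   with covariates), with the residual variances shrunk toward a common
   prior estimated across features by empirical Bayes (the moderated
   t-statistic);
5. Benjamini-Hochberg step-up adjustment of the p-values.

A companion routine partitions, per feature, the variance explained by the
sample covariates (RIN, PMI, sex, disease group) as order-averaged
sequential-R^2 fractions, used to decide whether quality covariates enter
the DE design.

The moderation prior follows the classical empirical-Bayes construction:
residual variances s_g^2 with d residual degrees of freedom are modelled as
scaled-inverse-chi-square draws around a prior (d0, s0^2); matching the
first two moments of log s_g^2 through the digamma/trigamma functions gives
closed-form estimating equations, and the posterior variance

    s~_g^2 = (d0 * s0^2 + d * s_g^2) / (d0 + d)

replaces s_g^2 in the t-statistic, which then has d0 + d degrees of
freedom.  d0 = 0 recovers the ordinary t-test; d0 = infinity pools all
features to the common variance s0^2.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "CountMatrix",
    "NormFactors",
    "DEResult",
    "VariancePartition",
    "VariancePartitionResult",
    "cpm",
    "filter_by_expression",
    "auto_min_samples",
    "tmm_factors",
    "log_cpm",
    "moderated_de",
    "bh_adjust",
    "variance_explained",
    "estimate_variance_prior",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class CountMatrix:
    """Features x samples count matrix.

    Counts may be fractional (consensus circRNA counts are caller averages).
    Library sizes are always the column sums.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature IDs")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample IDs")

    @property
    def lib_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_features(self, keep: Sequence[str] | np.ndarray) -> "CountMatrix":
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            pos = {f: i for i, f in enumerate(self.feature_ids)}
            idx = np.array([pos[f] for f in keep], dtype=int)
        return CountMatrix(
            [self.feature_ids[i] for i in idx], list(self.sample_ids), self.counts[idx]
        )

    def subset_samples(self, keep: Sequence[str]) -> "CountMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in keep]
        return CountMatrix(list(self.feature_ids), list(keep), self.counts[:, idx])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.feature_ids, columns=self.sample_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CountMatrix":
        return cls(list(map(str, df.index)), list(map(str, df.columns)), df.to_numpy(float))


@dataclass
class NormFactors:
    """Per-sample TMM normalization factors, geometric mean 1."""

    sample_ids: list[str]
    factors: np.ndarray

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, dtype=float)
        if self.factors.shape != (len(self.sample_ids),):
            raise ValueError("one factor per sample required")
        if np.any(self.factors <= 0):
            raise ValueError("normalization factors must be positive")


@dataclass(frozen=True)
class DEResult:
    """Differential-expression call for one feature (case vs control)."""

    feature_id: str
    log2fc: float
    t_mod: float
    df_total: float
    p: float
    adj_p: float
    mean_log_cpm: float


@dataclass(frozen=True)
class VariancePartition:
    feature_id: str
    fraction_by_covariate: dict[str, float]
    residual: float


@dataclass
class VariancePartitionResult:
    partitions: list[VariancePartition]
    median_fraction: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# CPM / filtering


def _effective_lib_sizes(m: CountMatrix, factors: NormFactors | None) -> np.ndarray:
    lib = m.lib_sizes
    if np.any(lib <= 0):
        bad = [m.sample_ids[i] for i in np.flatnonzero(lib <= 0)]
        raise ValueError(f"zero library size for sample(s) {bad}")
    if factors is None:
        return lib
    if factors.sample_ids != m.sample_ids:
        raise ValueError("normalization factors do not match the matrix samples")
    return lib * factors.factors


def cpm(m: CountMatrix, factors: NormFactors | None = None) -> np.ndarray:
    """Counts per million: count / (lib_size * factor) * 1e6."""
    lib = _effective_lib_sizes(m, factors)
    return m.counts / lib * 1e6


def filter_by_expression(
    m: CountMatrix,
    min_cpm: float = 10.0,
    min_samples: int = 9,
    factors: NormFactors | None = None,
) -> CountMatrix:
    """Keep features with CPM >= ``min_cpm`` in at least ``min_samples`` samples."""
    if min_samples > len(m.sample_ids):
        raise ValueError(
            f"min_samples={min_samples} exceeds the {len(m.sample_ids)} samples present"
        )
    keep = (cpm(m, factors) >= min_cpm).sum(axis=1) >= min_samples
    return m.subset_features(keep)


def auto_min_samples(metadata: pd.DataFrame, fraction: float = 0.7) -> int:
    """``ceil(fraction * size of the smallest tissue dataset)``.

    The smallest per-tissue sample count across the metadata, scaled; an
    alternative to a fixed ``min_samples``.
    """
    sizes = metadata.groupby("tissue").size()
    if sizes.empty:
        raise ValueError("metadata has no tissue column values")
    return math.ceil(fraction * int(sizes.min()))


# ---------------------------------------------------------------------------
# TMM


def _tmm_pair(
    obs: np.ndarray, ref: np.ndarray, lib_obs: float, lib_ref: float,
    trim_m: float, trim_a: float,
) -> float:
    """TMM factor of one column against the reference (log2 scale)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        p_obs = obs / lib_obs
        p_ref = ref / lib_ref
        mask = (obs > 0) & (ref > 0)
        m_vals = np.log2(p_obs[mask] / p_ref[mask])
        a_vals = 0.5 * np.log2(p_obs[mask] * p_ref[mask])
    # asymptotic (delta-method) variance of M, summed over sample and reference
    v = (lib_obs - obs[mask]) / (lib_obs * obs[mask]) + (
        lib_ref - ref[mask]
    ) / (lib_ref * ref[mask])
    finite = np.isfinite(m_vals) & np.isfinite(a_vals)
    m_vals, a_vals, v = m_vals[finite], a_vals[finite], v[finite]
    n = m_vals.size
    if n == 0:
        warnings.warn("no common nonzero features with the reference; factor set to 1")
        return 0.0
    # double trim: drop the extreme trim_m fraction of M on both sides and
    # the extreme trim_a fraction of A on both sides (rank-based)
    lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
    rank_m = stats.rankdata(m_vals)
    rank_a = stats.rankdata(a_vals)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 0.0
    w = 1.0 / v[keep]
    f = float(np.sum(w * m_vals[keep]) / np.sum(w))
    return f if np.isfinite(f) else 0.0


def tmm_factors(
    m: CountMatrix, trim_m: float = 0.3, trim_a: float = 0.05
) -> NormFactors:
    """Trimmed-mean-of-M-values normalization factors.

    The reference sample is the column whose upper-quartile CPM is closest
    to the mean upper-quartile CPM.  For every other sample, log-ratios M
    and average abundances A are computed on features nonzero in both, the
    extremes of M and A are trimmed, and the factor is 2 to the
    precision-weighted mean of the surviving M values.  Factors are rescaled
    to geometric mean exactly 1.
    """
    if len(m.sample_ids) < 2:
        raise ValueError("TMM requires at least two samples")
    lib = m.lib_sizes
    if np.any((m.counts > 0).sum(axis=0) < 1):
        raise ValueError("every sample needs at least one nonzero count")
    q75 = np.percentile(m.counts / lib, 75, axis=0)
    ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    ref = m.counts[:, ref_idx]

    log_f = np.zeros(len(m.sample_ids))
    for j in range(len(m.sample_ids)):
        if j == ref_idx:
            continue
        log_f[j] = _tmm_pair(m.counts[:, j], ref, lib[j], lib[ref_idx], trim_m, trim_a)
    factors = 2.0 ** log_f
    factors /= np.exp(np.mean(np.log(factors)))  # geometric mean 1
    return NormFactors(list(m.sample_ids), factors)


# ---------------------------------------------------------------------------
# log-CPM


def log_cpm(
    m: CountMatrix,
    factors: NormFactors | None = None,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """log2((count + prior) / (effective lib size + 2*prior) * 1e6); finite."""
    if prior_count <= 0:
        raise ValueError("prior_count must be positive")
    lib = _effective_lib_sizes(m, factors)
    vals = np.log2((m.counts + prior_count) / (lib + 2 * prior_count) * 1e6)
    return pd.DataFrame(vals, index=m.feature_ids, columns=m.sample_ids)


# ---------------------------------------------------------------------------
# empirical-Bayes moderated t


def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on a stabilised scale)."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < tol * x:
            break
    return x


def estimate_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Estimate (d0, s0^2) of the scaled-inverse-chi-square variance prior.

    Moment matching on z = log(s^2): under the model, z - digamma(d/2) +
    log(d/2) has mean log(s0^2) + digamma(d0/2) - log(d0/2) and excess
    variance trigamma(d0/2) beyond the known trigamma(d/2).  A non-positive
    excess variance yields d0 = infinity (all features share s0^2).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        return math.inf, float(np.median(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - float(special.digamma(df / 2.0)) + math.log(df / 2.0)
    e_mean = float(e.mean())
    n = e.size
    e_var = float(((e - e_mean) ** 2).sum() / (n - 1)) - float(
        special.polygamma(1, df / 2.0)
    )
    if e_var <= 0:
        # no excess dispersion of log s^2: complete pooling, s0^2 = mean s^2
        return math.inf, float(s2[ok].mean())
    d0 = 2.0 * _trigamma_inverse(e_var)
    s0_sq = math.exp(
        e_mean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0)
    )
    return d0, s0_sq


def _design_matrix(
    groups: Sequence[str], covariates: pd.DataFrame | None
) -> tuple[np.ndarray, np.ndarray]:
    """Intercept + case indicator (+ numeric covariates).  Returns (X, case)."""
    labels = pd.Series(list(groups))
    uniq = sorted(labels.unique())
    if set(uniq) == {"case", "control"}:
        case = (labels == "case").to_numpy(float)
    elif len(uniq) == 2:
        # generic two-level factor: second level (sorted) is the "case"
        case = (labels == uniq[-1]).to_numpy(float)
    else:
        raise ValueError(f"groups must have exactly two levels, got {uniq}")
    for level, lab in (("case", case == 1), ("control", case == 0)):
        if lab.sum() < 2:
            raise ValueError(f"fewer than 2 samples in the {level} group")
    cols = [np.ones(len(labels)), case]
    if covariates is not None:
        for c in covariates.columns:
            col = covariates[c]
            if not pd.api.types.is_numeric_dtype(col):
                col = pd.Categorical(col).codes
            cols.append(np.asarray(col, dtype=float))
    return np.column_stack(cols), case


def moderated_de(
    logcpm: pd.DataFrame,
    groups: Sequence[str],
    covariates: pd.DataFrame | None = None,
    prior_df: float | None = None,
) -> list[DEResult]:
    """Per-feature moderated-t differential expression on log-CPM values.

    ``logcpm`` is features x samples; ``groups`` gives each sample's label
    ("case"/"control").  ``prior_df`` overrides the estimated prior degrees
    of freedom d0 (0 gives the ordinary t-test, ``inf`` fully pools the
    variance); by default d0 is estimated from the data.
    """
    y = logcpm.to_numpy(float)
    n_feat, n_samp = y.shape
    if len(groups) != n_samp:
        raise ValueError("one group label per sample required")
    x, _ = _design_matrix(groups, covariates)
    p_params = x.shape[1]
    d_resid = n_samp - p_params
    if d_resid <= 0:
        raise ValueError("zero residual degrees of freedom")

    xtx_inv = np.linalg.inv(x.T @ x)
    beta = y @ (x @ xtx_inv)  # features x params
    resid = y - beta @ x.T
    rss = (resid**2).sum(axis=1)
    s2 = rss / d_resid
    se_unit = math.sqrt(xtx_inv[1, 1])  # unscaled SE of the case coefficient

    if prior_df is None:
        d0, s0_sq = estimate_variance_prior(s2, d_resid)
    elif prior_df == 0:
        d0, s0_sq = 0.0, 1.0
    elif math.isinf(prior_df):
        d0, s0_sq = math.inf, float(s2.mean())
    else:
        d0 = float(prior_df)
        _, s0_sq = estimate_variance_prior(s2, d_resid)

    # total df capped at the pooled residual df (complete-pooling limit)
    pooled_df = n_feat * d_resid
    if math.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = float(pooled_df)
    else:
        s2_post = (d0 * s0_sq + d_resid * s2) / (d0 + d_resid)
        df_total = float(min(d0 + d_resid, pooled_df))

    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = beta[:, 1] / (se_unit * np.sqrt(s2_post))
    p_vals = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    p_vals = np.clip(np.nan_to_num(p_vals, nan=1.0), 0.0, 1.0)
    adj = bh_adjust(p_vals)
    mean_lcpm = y.mean(axis=1)

    return [
        DEResult(
            feature_id=str(logcpm.index[i]),
            log2fc=float(beta[i, 1]),
            t_mod=float(t_mod[i]),
            df_total=float(df_total),
            p=float(p_vals[i]),
            adj_p=float(adj[i]),
            mean_log_cpm=float(mean_lcpm[i]),
        )
        for i in range(n_feat)
    ]


def bh_adjust(p: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(p) if not isinstance(p, np.ndarray) else p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


# ---------------------------------------------------------------------------
# covariate variance partition


def _encode_covariates(covariates: pd.DataFrame) -> tuple[np.ndarray, list[str], list[str]]:
    """Numeric-encode columns; constant columns are dropped with a warning."""
    cols, names, dropped = [], [], []
    for c in covariates.columns:
        col = covariates[c]
        if not pd.api.types.is_numeric_dtype(col):
            col = pd.Series(pd.Categorical(col).codes, index=col.index)
        arr = np.asarray(col, dtype=float)
        if np.ptp(arr) == 0:
            warnings.warn(f"covariate {c!r} is constant; its fraction is 0")
            dropped.append(c)
        else:
            cols.append(arr)
            names.append(c)
    mat = np.column_stack(cols) if cols else np.empty((len(covariates), 0))
    return mat, names, dropped


def variance_explained(
    logcpm: pd.DataFrame, covariates: pd.DataFrame
) -> VariancePartitionResult:
    """Order-averaged sequential-R^2 variance fractions per covariate.

    For each feature, the fixed-effects model ``expr ~ covariates`` is fitted
    for every covariate subset; each covariate's fraction is its Shapley
    value of R^2 over entry orderings (the LMG decomposition), which removes
    the order dependence of sequential sums of squares.  Fractions plus the
    residual fraction sum to 1 per feature.
    """
    if covariates.isna().any().any():
        raise ValueError("covariate table has missing values")
    y = logcpm.to_numpy(float)
    n_samp = y.shape[1]
    if len(covariates) != n_samp:
        raise ValueError("covariate rows must match logcpm samples")
    mat, names, dropped = _encode_covariates(covariates)
    k = len(names)

    yc = y - y.mean(axis=1, keepdims=True)
    tss = (yc**2).sum(axis=1)
    safe_tss = np.where(tss > 0, tss, 1.0)

    # R^2 for every covariate subset (designs shared across features)
    r2: dict[frozenset[int], np.ndarray] = {frozenset(): np.zeros(y.shape[0])}
    for mask in range(1, 1 << k):
        idx = [i for i in range(k) if mask >> i & 1]
        x = np.column_stack([np.ones(n_samp)] + [mat[:, i] for i in idx])
        q, _ = np.linalg.qr(x)
        resid = yc - (yc @ q) @ q.T
        rss = (resid**2).sum(axis=1)
        r2[frozenset(idx)] = np.where(tss > 0, 1.0 - rss / safe_tss, 0.0)

    # Shapley weights over orderings
    fact = [math.factorial(i) for i in range(k + 1)]
    shapley = np.zeros((y.shape[0], k))
    for i in range(k):
        others = [j for j in range(k) if j != i]
        for mask in range(1 << (k - 1)):
            s = frozenset(others[j] for j in range(k - 1) if mask >> j & 1)
            w = fact[len(s)] * fact[k - len(s) - 1] / fact[k]
            shapley[:, i] += w * (r2[s | {i}] - r2[s])

    full = r2[frozenset(range(k))] if k else np.zeros(y.shape[0])
    partitions = []
    for f in range(y.shape[0]):
        frac = {name: float(shapley[f, i]) for i, name in enumerate(names)}
        frac.update({c: 0.0 for c in dropped})
        partitions.append(
            VariancePartition(
                feature_id=str(logcpm.index[f]),
                fraction_by_covariate=frac,
                residual=float(1.0 - full[f]),
            )
        )
    medians = {
        c: float(np.median([p.fraction_by_covariate[c] for p in partitions]))
        for c in list(names) + dropped
    }
    return VariancePartitionResult(partitions=partitions, median_fraction=medians)
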