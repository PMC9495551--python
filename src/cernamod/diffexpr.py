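"""TMM normalization and stability-selected differential expression.

The between-sample normalization is the trimmed mean of M-values (TMM):
for each library against a reference library (the one whose 0.75 count-rate
quantile is closest to the mean of those quantiles), per-feature log ratios
M = log2((x/N) / (x_ref/N_ref)) are trimmed 30% on each side by M and 5% on
each side by average abundance A, and combined by inverse-asymptotic-variance
weights; the resulting factors are rescaled to geometric mean 1.

Differential expression between matched tumor/normal pairs uses a paired
Wilcoxon signed-rank test on per-pair differences of TMM log-CPM (the
per-feature statistic is pluggable), Benjamini-Hochberg FDR control, and the
joint gate |log2FC| > 1 with FDR < 0.05. For the larger RNA classes the call
set is stability-selected: 50 rounds of subsampling 4/5 of the pairs, keeping
only features significant in every round.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

LOG2FC_THRESHOLD = 1.0
FDR_THRESHOLD = 0.05


def compute_tmm_factors(
    counts: pd.DataFrame,
    trim_m: float = 0.3,
    trim_a: float = 0.05,
    weighted: bool = True,
) -> pd.Series:
    """Per-sample TMM normalization factors (geometric mean 1).

    ``weighted`` applies inverse-asymptotic-variance precision weights to the
    trimmed log-ratios (the standard choice); note the weights depend on
    absolute library depth, so only the unweighted factors are exactly
    invariant to rescaling a single library. Raises ``ValueError`` naming the
    sample if a library is all zero.
    """
    x = counts.to_numpy(dtype=float)
    lib = x.sum(axis=0)
    for j, tot in enumerate(lib):
        if tot <= 0:
            raise ValueError(f"sample {counts.columns[j]!r} has all-zero counts")
    rate_q75 = np.array([np.quantile(x[:, j] / lib[j], 0.75) for j in range(x.shape[1])])
    ref = int(np.argmin(np.abs(rate_q75 - rate_q75.mean())))

    factors = np.ones(x.shape[1])
    for j in range(x.shape[1]):
        factors[j] = _tmm_pair(x[:, j], x[:, ref], lib[j], lib[ref], trim_m, trim_a, weighted)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def _tmm_pair(obs, ref, n_obs, n_ref, trim_m, trim_a, weighted=True) -> float:
    ok = (obs > 0) & (ref > 0)
    if not ok.any():
        return 1.0
    obs, ref = obs[ok], ref[ok]
    log_r = np.log2((obs / n_obs) / (ref / n_ref))
    abs_e = 0.5 * (np.log2(obs / n_obs) + np.log2(ref / n_ref))
    var = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    if np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = scipy.stats.rankdata(log_r)
    rank_a = scipy.stats.rankdata(abs_e)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    if weighted:
        f = np.sum(log_r[keep] / var[keep]) / np.sum(1.0 / var[keep])
    else:
        f = np.mean(log_r[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def normalize_logcpm(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """log2 counts per million on effective library sizes: ``log2(CPM + 0.5)``.

    The half-count pseudocount is applied on the CPM scale (equivalently, the
    count-scale pseudocount is scaled with the effective library size), so
    zero counts stay finite and the normalized values are exactly invariant
    to rescaling any library's counts by a constant.
    """
    if not counts.columns.equals(factors.index):
        raise ValueError("factor index does not match count columns")
    lib = counts.to_numpy(dtype=float).sum(axis=0) * factors.to_numpy(dtype=float)
    cpm = counts.to_numpy(dtype=float) / lib[None, :] * 1.0e6
    return pd.DataFrame(np.log2(cpm + 0.5), index=counts.index, columns=counts.columns)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _pair_arrays(samples: pd.DataFrame):
    """Return (tumor sample ids, normal sample ids) aligned by pair_id."""
    tum = samples[samples["condition"] == "tumor"].set_index("pair_id")["sample_id"]
    nor = samples[samples["condition"] == "normal"].set_index("pair_id")["sample_id"]
    pairs = tum.index.intersection(nor.index)
    if tum.index.duplicated().any() or nor.index.duplicated().any():
        raise ValueError("pair_id must map to exactly one tumor and one normal sample")
    return list(tum.loc[pairs]), list(nor.loc[pairs]), list(pairs)


def wilcoxon_engine(diff: np.ndarray) -> np.ndarray:
    """p-values of the paired Wilcoxon signed-rank test on per-pair differences.

    ``diff`` is features x pairs; rows that are entirely (near) zero get p = 1.
    """
    res = scipy.stats.wilcoxon(
        diff, axis=1, zero_method="zsplit", method="approx", correction=True
    )
    p = np.atleast_1d(np.asarray(res.pvalue, dtype=float))
    p[~np.isfinite(p)] = 1.0
    return p


def test_differential(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    log2fc_threshold: float = LOG2FC_THRESHOLD,
    fdr_threshold: float = FDR_THRESHOLD,
    engine=wilcoxon_engine,
) -> pd.DataFrame:
    """Per-feature paired differential-expression table.

    Returns a DataFrame indexed by feature id with columns ``log2fc``,
    ``pvalue``, ``fdr`` and ``direction`` (``up``/``down``/``none``); the
    direction is assigned only when both |log2FC| and FDR gates pass.
    """
    tum, nor, _ = _pair_arrays(samples)
    if len(tum) < 3:
        raise ValueError(f"need at least 3 tumor/normal pairs, got {len(tum)}")
    factors = compute_tmm_factors(counts)
    logcpm = normalize_logcpm(counts, factors)
    diff = logcpm[tum].to_numpy() - logcpm[nor].to_numpy()
    log2fc = diff.mean(axis=1)
    pvalue = engine(diff)
    fdr = bh_adjust(pvalue)
    sig = (np.abs(log2fc) > log2fc_threshold) & (fdr < fdr_threshold)
    direction = np.where(sig & (log2fc > 0), "up", np.where(sig, "down", "none"))
    return pd.DataFrame(
        {"log2fc": log2fc, "pvalue": pvalue, "fdr": fdr, "direction": direction},
        index=counts.index.rename("feature_id"),
    )


def stability_select(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    rounds: int = 50,
    fraction: float = 0.8,
    seed: int = 0,
    log2fc_threshold: float = LOG2FC_THRESHOLD,
    fdr_threshold: float = FDR_THRESHOLD,
    engine=wilcoxon_engine,
) -> pd.DataFrame:
    """Full-data DE table plus a ``stable`` column from subsampled reruns.

    Each round draws ``ceil(fraction * n_pairs)`` pairs without replacement
    (both members of a pair always travel together), reruns the full test
    including TMM renormalization and the significance gates, and the stable
    set is the intersection of the per-round significant sets. ``rounds=1``
    with ``fraction=1`` reduces to the single-pass test.
    """
    if rounds < 1:
        raise ValueError(f"rounds must be >= 1, got {rounds}")
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    tum, nor, pairs = _pair_arrays(samples)
    n_sub = int(np.ceil(fraction * len(pairs)))
    if n_sub < 3:
        raise ValueError(f"subsample of {n_sub} pairs is too small (need >= 3)")

    table = test_differential(
        counts, samples, log2fc_threshold, fdr_threshold, engine
    )
    stable = table["direction"].to_numpy() != "none"
    children = np.random.SeedSequence(seed).spawn(rounds)
    for child in children:
        if not stable.any():
            break
        rng = np.random.default_rng(child)
        take = rng.choice(len(pairs), size=n_sub, replace=False)
        sub_samples = samples[
            samples["pair_id"].isin([pairs[i] for i in take])
        ].reset_index(drop=True)
        sub = test_differential(
            counts, sub_samples, log2fc_threshold, fdr_threshold, engine
        )
        stable &= sub["direction"].to_numpy() != "none"
    table["stable"] = stable
    return table


def drop_missing_features(
    matrix: pd.DataFrame, max_missing_fraction: float | None = None,
    max_missing: int | None = None,
) -> pd.DataFrame:
    """Drop features with too many missing (NA) entries.

    Mirrors the pipeline's quality-control rule: RNA-seq features with more
    than 1/3 of samples missing, miRNA features with more than 2 samples
    missing. Zeros are observations, not missing values.
    """
    miss = matrix.isna().sum(axis=1)
    keep = np.ones(len(matrix), dtype=bool)
    if max_missing_fraction is not None:
        keep &= (miss <= max_missing_fraction * matrix.shape[1]).to_numpy()
    if max_missing is not None:
        keep &= (miss <= max_missing).to_numpy()
    return matrix.loc[keep]
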