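"""RNA-seq normalization chain feeding the mechanistic model.

Four steps, applied in order to a genes x samples count matrix:

1. TMM (trimmed mean of M-values) between-sample normalization, correcting
   library-composition bias;
2. log2(x + 1) transformation;
3. matrix-wide truncation at the 0.01 / 0.99 empirical quantiles;
4. quantile normalization across samples (every column gets the same
   empirical distribution, the mean of the sorted columns).

A final unit-interval rescale maps the normalized matrix onto [0, 1] as the
propagation model requires.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

SCALES = ("counts", "normalized", "unit")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with a declared scale.

    ``scale`` is one of ``counts`` (non-negative raw counts), ``normalized``
    (arbitrary continuous values) or ``unit`` (values in [0, 1]).
    """

    values: pd.DataFrame  # index = gene ids, columns = sample ids
    scale: str = "normalized"

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        arr = self.values.to_numpy()
        if self.scale == "counts" and (arr < 0).any():
            raise ValueError("count matrix contains negative values")
        if self.scale == "unit" and ((arr < 0) | (arr > 1)).any():
            raise ValueError("unit-scale matrix has values outside [0, 1]")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def with_values(self, arr: np.ndarray, scale: str) -> "ExpressionMatrix":
        return ExpressionMatrix(
            pd.DataFrame(arr, index=self.values.index, columns=self.values.columns),
            scale=scale,
        )


@dataclass
class TMMFactors:
    """Per-sample TMM scaling factors, geometric-mean-normalized to 1."""

    factors: pd.Series  # indexed by sample id
    reference_sample: str

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValueError("TMM factors must be positive")
        log_mean = np.log(self.factors.to_numpy()).mean()
        if abs(log_mean) > 1e-8:
            raise ValueError("TMM factors must have geometric mean 1")


def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> float:
    """log2 TMM factor of one sample against the reference.

    M = log-ratio of depth-normalized abundances, A = average log abundance.
    Genes with zero counts in either sample are excluded, the extreme
    ``trim_m`` fraction of M and ``trim_a`` fraction of A are trimmed from
    each tail, and the surviving M-values are averaged with inverse
    approximate binomial variance weights.
    """
    keep = (obs > 0) & (ref > 0)
    if not keep.any():
        return 0.0
    o, r = obs[keep].astype(float), ref[keep].astype(float)
    p_o, p_r = o / lib_obs, r / lib_ref
    m = np.log2(p_o / p_r)
    a = 0.5 * np.log2(p_o * p_r)
    w = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)
    n = len(m)
    # double trim: keep genes inside both the M-trim and the A-trim windows
    lo_m, hi_m = np.floor(n * trim_m) + 1, n + 1 - (np.floor(n * trim_m) + 1)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n + 1 - (np.floor(n * trim_a) + 1)
    rank_m = rankdata(m, method="average")
    rank_a = rankdata(a, method="average")
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep2.any():
        return 0.0
    return float(np.sum(m[keep2] / w[keep2]) / np.sum(1.0 / w[keep2]))


def tmm_normalize(
    counts: ExpressionMatrix,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> tuple[ExpressionMatrix, TMMFactors]:
    """TMM-normalize a count matrix.

    The reference sample is the one whose upper-quartile (of depth-normalized
    counts) is closest to the mean upper-quartile.  Output values are counts
    per million of the effective library size (library size x factor); the
    returned factors are rescaled to geometric mean 1.
    """
    if counts.scale != "counts":
        raise ValueError("tmm_normalize expects a counts-scale matrix")
    arr = counts.values.to_numpy(dtype=float)
    if arr.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    lib = arr.sum(axis=0)
    if (lib <= 0).any():
        bad = [s for s, tot in zip(counts.sample_ids, lib) if tot <= 0]
        raise ValueError(f"all-zero sample(s): {bad}")
    uq = np.quantile(arr / lib, 0.75, axis=0)
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    log2f = np.array(
        [
            0.0
            if j == ref_idx
            else _tmm_pair_factor(arr[:, j], arr[:, ref_idx], lib[j], lib[ref_idx],
                                  trim_m, trim_a)
            for j in range(arr.shape[1])
        ]
    )
    factors = 2.0 ** log2f
    factors = factors / np.exp(np.mean(np.log(factors)))
    eff_lib = lib * factors
    cpm = arr / eff_lib * 1e6
    return (
        counts.with_values(cpm, scale="normalized"),
        TMMFactors(
            factors=pd.Series(factors, index=counts.sample_ids),
            reference_sample=counts.sample_ids[ref_idx],
        ),
    )


def log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """x -> log2(x + 1); input must be non-negative."""
    arr = m.values.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("log_transform requires non-negative values")
    return m.with_values(np.log2(arr + 1.0), scale="normalized")


def quantile_truncate(
    m: ExpressionMatrix, hi: float = 0.99, lo: float = 0.01
) -> ExpressionMatrix:
    """Clamp to the matrix-wide empirical [lo, hi] quantiles (linear interpolation)."""
    if not (0 <= lo < hi <= 1):
        raise ValueError("need 0 <= lo < hi <= 1")
    arr = m.values.to_numpy(dtype=float)
    q_lo, q_hi = np.quantile(arr, [lo, hi])
    return m.with_values(np.clip(arr, q_lo, q_hi), scale=m.scale)


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force all columns onto the mean-of-sorted-columns distribution.

    Ties within a column receive the mean of the target values they span
    (average-rank convention).
    """
    arr = m.values.to_numpy(dtype=float)
    if arr.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    target = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        ranks = rankdata(arr[:, j], method="average")  # 1-based, .5 on ties
        lo_idx = np.floor(ranks).astype(int) - 1
        hi_idx = np.ceil(ranks).astype(int) - 1
        out[:, j] = 0.5 * (target[lo_idx] + target[hi_idx])
    return m.with_values(out, scale="normalized")


def rescale_unit(m: ExpressionMatrix, per_gene: bool = False) -> ExpressionMatrix:
    """Affinely map the matrix onto [0, 1]: matrix min -> 0, matrix max -> 1.

    With ``per_gene=True`` each gene row is rescaled by its own range
    (constant rows map to 0.5).
    """
    arr = m.values.to_numpy(dtype=float)
    if per_gene:
        lo = arr.min(axis=1, keepdims=True)
        hi = arr.max(axis=1, keepdims=True)
        rng = hi - lo
        flat = rng.ravel() == 0
        rng[flat.reshape(-1, 1)] = 1.0
        out = (arr - lo) / rng
        out[flat, :] = 0.5
    else:
        lo, hi = arr.min(), arr.max()
        if hi == lo:
            raise ValueError("constant matrix: unit rescale undefined")
        out = (arr - lo) / (hi - lo)
    return m.with_values(out, scale="unit")


def normalize_chain(
    counts: ExpressionMatrix, per_gene_rescale: bool = False
) -> tuple[ExpressionMatrix, TMMFactors]:
    """The full chain: TMM -> log2(x+1) -> quantile truncation -> quantile
    normalization -> unit rescale.  Returns the unit matrix and the factors."""
    normalized, factors = tmm_normalize(counts)
    logged = log_transform(normalized)
    truncated = quantile_truncate(logged)
    qn = quantile_normalize(truncated)
    return rescale_unit(qn, per_gene=per_gene_rescale), factors


def read_expression_tsv(path, scale: str = "counts") -> ExpressionMatrix:
    """Read a genes x samples TSV (first column = gene ids, header = samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(df.astype(float), scale=scale)


def write_expression_tsv(m: ExpressionMatrix, path) -> None:
    m.values.to_csv(path, sep="\t")
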