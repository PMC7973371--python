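"""Count filtering, normalization, and per-timepoint differential expression.

The test is a self-contained per-gene negative-binomial Wald test:
library sizes are estimated by median-of-ratios, per-gene dispersions by
method of moments shrunk toward a mean-expression trend, and the Wald
statistic is computed on the log2 fold change of the fitted group means
(disease over control).  Benjamini–Hochberg adjustment is applied per
timepoint over all tested genes, and genes are called induced/repressed
at FDR < α with |log2fc| ≥ lfc_min.

Externally produced differential-expression tables (e.g. from edgeR or
limma) can be supplied to the pipeline instead; everything downstream
consumes only the (gene, log2fc, p, fdr, call) table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

CONDITIONS = ("disease", "control")
CALLS = ("induced", "repressed", "ns")

DEFAULT_ALPHA = 0.01
DEFAULT_LFC_MIN = 1.0


@dataclass
class CountsTable:
    """Integer gene × sample count matrix with sample metadata.

    ``counts`` is a genes × samples DataFrame; ``samples`` is indexed by
    sample id with columns ``condition`` (disease/control),
    ``timepoint`` and ``replicate``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        counts = self.counts
        if counts.index.duplicated().any():
            dupes = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dupes}")
        if counts.columns.duplicated().any():
            raise ValueError("duplicate sample ids in count matrix")
        arr = counts.to_numpy()
        if arr.size and (not np.issubdtype(arr.dtype, np.integer)):
            if not np.allclose(arr, np.round(arr)) or np.isnan(arr).any():
                raise ValueError("counts must be integral")
            self.counts = counts = counts.astype(np.int64)
            arr = counts.to_numpy()
        if arr.size and arr.min() < 0:
            gi, sj = np.unravel_index(arr.argmin(), arr.shape)
            raise ValueError(
                f"negative count at gene {counts.index[gi]!r}, "
                f"sample {counts.columns[sj]!r}"
            )
        missing = [s for s in counts.columns if s not in self.samples.index]
        if missing:
            raise ValueError(f"samples missing from sample sheet: {missing}")
        for col in ("condition", "timepoint", "replicate"):
            if col not in self.samples.columns:
                raise ValueError(f"sample sheet lacks column {col!r}")
        bad = set(self.samples["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown conditions in sample sheet: {sorted(bad)}")
        # canonical axis names so file round-trips compare equal
        self.counts = self.counts.rename_axis(index="gene", columns="sample_id")
        self.samples = self.samples.rename_axis(index="sample_id")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def timepoints(self) -> list:
        return sorted(self.samples["timepoint"].unique())

    def samples_at(self, timepoint, condition: str | None = None) -> list[str]:
        meta = self.samples.loc[list(self.counts.columns)]
        mask = meta["timepoint"] == timepoint
        if condition is not None:
            mask &= meta["condition"] == condition
        return list(meta.index[mask])

    def smallest_group_size(self) -> int:
        meta = self.samples.loc[list(self.counts.columns)]
        sizes = meta.groupby(["condition", "timepoint"], observed=True).size()
        return int(sizes.min())


def filter_low_counts(
    counts: CountsTable,
    min_count: int = 10,
    min_samples: int | None = None,
) -> CountsTable:
    """Drop genes not reaching ``min_count`` raw reads in at least
    ``min_samples`` samples (default: the smallest condition × timepoint
    group size).  The sample set is unchanged; an empty gene set is a
    legal result.
    """
    if min_samples is None:
        min_samples = counts.smallest_group_size()
    if min_samples > counts.counts.shape[1]:
        raise ValueError(
            f"min_samples={min_samples} exceeds the {counts.counts.shape[1]} samples"
        )
    n_ok = (counts.counts >= min_count).sum(axis=1)
    kept = counts.counts.loc[n_ok >= min_samples]
    return CountsTable(kept, counts.samples)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors.

    Genes with a zero count in any sample are excluded from the
    reference geometric mean; if no gene is positive everywhere, the
    factors fall back to total-count ratios.
    """
    arr = counts.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if positive.any():
        log_arr = np.log(arr[positive])
        log_gm = log_arr.mean(axis=1, keepdims=True)
        sf = np.exp(np.median(log_arr - log_gm, axis=0))
    else:
        totals = arr.sum(axis=0)
        mean_total = totals.mean() if totals.mean() > 0 else 1.0
        sf = np.where(totals > 0, totals / mean_total, 1.0)
    return pd.Series(sf, index=counts.columns, name="size_factor")


def adjust_bh(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _moment_dispersion(
    norm: np.ndarray, groups: list[np.ndarray]
) -> np.ndarray:
    """Method-of-moments per-gene dispersion pooled over groups, shrunk
    toward the trend mean of genes at similar expression."""
    num = np.zeros(norm.shape[0])
    den = np.zeros(norm.shape[0])
    for idx in groups:
        sub = norm[:, idx]
        mu = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        w = len(idx) - 1
        num += w * (var - mu)
        den += w * mu**2
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(den > 0, num / den, 0.0)
    raw = np.clip(raw, 0.0, 10.0)
    overall_mu = norm.mean(axis=1)
    # trend: mean raw dispersion within log-mean deciles
    trend = np.full_like(raw, raw.mean() if raw.size else 0.0)
    if raw.size >= 50:
        log_mu = np.log10(overall_mu + 0.5)
        bins = np.quantile(log_mu, np.linspace(0, 1, 11))
        which = np.clip(np.searchsorted(bins, log_mu, side="right") - 1, 0, 9)
        for b in range(10):
            mask = which == b
            if mask.sum() >= 5:
                trend[mask] = raw[mask].mean()
    return np.maximum(0.5 * raw + 0.5 * trend, 1e-8)


def test_differential(
    counts: CountsTable,
    timepoint,
    alpha: float = DEFAULT_ALPHA,
    lfc_min: float = DEFAULT_LFC_MIN,
) -> pd.DataFrame:
    """Disease-vs-control negative-binomial Wald test at one timepoint.

    Returns a table with one row per gene: ``gene``, ``timepoint``,
    ``log2fc`` (disease over control), ``p``, ``fdr`` (BH within the
    timepoint) and ``call`` ∈ {induced, repressed, ns}.
    """
    dis = counts.samples_at(timepoint, "disease")
    con = counts.samples_at(timepoint, "control")
    if len(dis) < 2 or len(con) < 2:
        raise ValueError(
            f"timepoint {timepoint!r} needs ≥2 replicates per condition "
            f"(found {len(dis)} disease, {len(con)} control)"
        )
    sub = counts.counts[dis + con]
    if sub.shape[0] == 0:
        return pd.DataFrame(
            columns=["gene", "timepoint", "log2fc", "p", "fdr", "call"]
        )
    sf = size_factors(sub)
    norm = sub.to_numpy(dtype=float) / sf.to_numpy()
    idx_d = np.arange(len(dis))
    idx_c = np.arange(len(dis), len(dis) + len(con))
    phi = _moment_dispersion(norm, [idx_d, idx_c])

    mu_d = norm[:, idx_d].mean(axis=1)
    mu_c = norm[:, idx_c].mean(axis=1)
    # pseudo-count applied to fitted means only when a group mean is zero
    mu_d_adj = np.where(mu_d == 0, 0.5, mu_d)
    mu_c_adj = np.where(mu_c == 0, 0.5, mu_c)
    log2fc = np.log2(mu_d_adj / mu_c_adj)

    # delta-method variance of log mean of n NB(mu, phi) draws
    var_log = (1.0 / mu_d_adj + phi) / len(dis) + (1.0 / mu_c_adj + phi) / len(con)
    se_log2fc = np.sqrt(var_log) / np.log(2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se_log2fc > 0, log2fc / se_log2fc, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, 0.0, 1.0)
    fdr = adjust_bh(p)
    table = pd.DataFrame(
        {
            "gene": sub.index,
            "timepoint": timepoint,
            "log2fc": log2fc,
            "p": p,
            "fdr": fdr,
        }
    )
    table["call"] = assign_calls(table, alpha=alpha, lfc_min=lfc_min)
    return table.reset_index(drop=True)


def assign_calls(
    table: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    lfc_min: float = DEFAULT_LFC_MIN,
) -> pd.Series:
    """Induced/repressed/ns calls at FDR < alpha and |log2fc| ≥ lfc_min."""
    sig = table["fdr"] < alpha
    call = np.where(
        sig & (table["log2fc"] >= lfc_min),
        "induced",
        np.where(sig & (table["log2fc"] <= -lfc_min), "repressed", "ns"),
    )
    return pd.Series(call, index=table.index, name="call")


def run_differential(
    counts: CountsTable,
    alpha: float = DEFAULT_ALPHA,
    lfc_min: float = DEFAULT_LFC_MIN,
) -> dict:
    """Per-timepoint differential-expression tables for all timepoints."""
    return {
        tp: test_differential(counts, tp, alpha=alpha, lfc_min=lfc_min)
        for tp in counts.timepoints
    }
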