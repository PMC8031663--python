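"""Low-count filtering, normalization and negative-binomial differential
abundance for miRNA count matrices.

The contrast is CAVIN1 vs CONT (positive log2FC = higher in CAVIN1), run
separately within the EV and cell compartments. Normalization combines
DESeq-style median-of-ratios size factors with a remove-unwanted-variation
step: a first-pass test picks the miRNAs least associated with condition as
empirical controls, a factor analysis (SVD) of their centered log counts
yields k unwanted factors, and the fitted unwanted component enters the NB
log-linear model as a known per-observation offset.

This module does not claim numeric equality with DESeq2: there is no
dispersion or LFC shrinkage and no independent filtering. Dispersion is
per-miRNA method-of-moments (optionally pooled), and the Wald statistic is
referred to a t distribution with residual degrees of freedom, which keeps
the test close to nominal level at n = 3 + 3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix

logger = logging.getLogger(__name__)

_DISPERSION_FLOOR = 1e-8


@dataclass
class DiffConfig:
    min_total_count: int = 20
    ruv_k: int = 1
    n_empirical_controls: int | None = None  # None -> 20% of retained miRNAs
    alpha: float = 0.05
    pooled_dispersion: bool = False

    def validate(self, n_samples: int | None = None) -> None:
        if self.min_total_count < 0:
            raise ValueError("min_total_count must be >= 0")
        if self.ruv_k < 0:
            raise ValueError("ruv_k must be >= 0")
        if n_samples is not None and self.ruv_k >= n_samples:
            raise ValueError("ruv_k must be smaller than the number of samples")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


def filter_low_counts(counts: CountMatrix, min_total: int) -> CountMatrix:
    """Retain miRNAs whose total count across ALL samples is >= min_total.

    The boundary is inclusive: a total of exactly ``min_total`` is kept
    (the filter removes "less than min_total"). Order is preserved and the
    operation is idempotent.
    """
    totals = counts.counts.sum(axis=1)
    keep = totals >= min_total
    dropped = int((~keep).sum())
    if dropped:
        logger.info("filter_low_counts: removed %d of %d miRNAs (total < %d)",
                    dropped, len(totals), min_total)
    if not keep.any():
        logger.warning("filter_low_counts: no miRNA passed the filter")
    return CountMatrix(counts.counts.loc[keep].copy(), counts.sample_meta.copy())


def estimate_size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    The reference is the per-miRNA geometric mean over miRNAs with strictly
    positive counts in every sample; each sample's factor is the median of
    its count/reference ratios. When no miRNA is positive in all samples the
    function falls back to total-count scaling (logged).
    """
    mat = counts.counts.to_numpy(float)
    all_pos = (mat > 0).all(axis=1)
    if not all_pos.any():
        logger.warning("estimate_size_factors: no all-positive miRNA; "
                       "falling back to total-count scaling")
        factors = mat.sum(axis=0)
    else:
        logref = np.log(mat[all_pos]).mean(axis=1)
        factors = np.exp(np.median(np.log(mat[all_pos]) - logref[:, None], axis=0))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.counts.columns, name="size_factor")


def _condition_design(meta: pd.DataFrame) -> np.ndarray:
    """Intercept + CAVIN1 indicator (positive coefficient = higher in CAVIN1)."""
    cavin = (meta["condition"] == "CAVIN1").to_numpy(float)
    return np.column_stack([np.ones_like(cavin), cavin])


def _moment_dispersion(y: np.ndarray, mu: np.ndarray) -> float:
    """Method-of-moments NB dispersion with a 0.5 pseudo-count (used only
    here, never in the likelihood) and a floor of 1e-8."""
    y = y + 0.5
    mu = mu + 0.5
    resid = ((y - mu) ** 2 - mu) / mu**2
    df = max(len(y) - 2, 1)
    return float(max(resid.sum() / df, _DISPERSION_FLOOR))


def _fit_one(y: np.ndarray, X: np.ndarray, offset: np.ndarray,
             alpha_disp: float) -> tuple[float, float, float]:
    """NB GLM of one miRNA; returns (log2fc, se_log2, wald_p).

    Wald p refers beta/se to a t distribution with residual df, which is
    closer to nominal than the normal at three replicates per group.
    """
    df_resid = max(len(y) - X.shape[1], 1)
    groups = X[:, 1] > 0.5
    if np.array_equal(np.sort(y[groups]), np.sort(y[~groups])) and np.allclose(
        offset[groups].mean(), offset[~groups].mean()
    ):
        # identical groups: exactly no effect, degenerate Wald handled
        return 0.0, np.nan, 1.0
    model = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=alpha_disp),
                   offset=offset)
    try:
        res = model.fit(maxiter=100, tol=1e-9)
        beta, se = res.params[1], res.bse[1]
    except Exception:  # pragma: no cover - pathological rows
        logger.warning("NB GLM failed; reporting p = 1 for this miRNA")
        return 0.0, np.nan, 1.0
    if not np.isfinite(se) or se == 0:
        return float(beta / np.log(2)), np.nan, 1.0
    p = 2 * stats.t.sf(abs(beta / se), df_resid)
    return float(beta / np.log(2)), float(se / np.log(2)), float(min(p, 1.0))


def nb_differential(
    counts: CountMatrix,
    offsets: pd.DataFrame | None = None,
    config: DiffConfig | None = None,
    *,
    size_factors: pd.Series | None = None,
    contrast: str | None = None,
) -> pd.DataFrame:
    """Per-miRNA NB Wald test of condition (CAVIN1 vs CONT).

    ``counts`` must contain a single compartment (pass
    ``counts.compartment("EV")`` or ``"cell"``). ``offsets`` are additional
    log-scale per-observation offsets (miRNA x sample, e.g. from
    :func:`ruv_normalize`); size factors enter as log offsets too.

    Returns a DataFrame indexed by miRNA id with columns base_mean, log2fc,
    se, wald_p, bh_q and contrast.
    """
    config = config or DiffConfig()
    config.validate()
    comps = set(counts.sample_meta["compartment"])
    if len(comps) != 1:
        raise ValueError("nb_differential expects a single-compartment matrix; "
                         f"got {sorted(comps)}")
    contrast = contrast or comps.pop()
    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    size_factors = size_factors.loc[counts.counts.columns]
    X = _condition_design(counts.sample_meta)

    mat = counts.counts.to_numpy(float)
    keep = mat.sum(axis=1) > 0
    if (~keep).any():
        logger.info("nb_differential: excluding %d all-zero miRNA row(s)",
                    int((~keep).sum()))
    base_offset = np.log(size_factors.to_numpy())
    if offsets is not None:
        off_mat = offsets.loc[counts.counts.index, counts.counts.columns].to_numpy()
    else:
        off_mat = np.zeros_like(mat)

    norm = mat / size_factors.to_numpy()
    base_mean = norm.mean(axis=1)

    # moment dispersion against group-wise fitted means so that real
    # condition effects do not inflate the dispersion estimate
    cavin = X[:, 1] > 0.5
    group_mean = np.empty_like(norm)
    group_mean[:, cavin] = norm[:, cavin].mean(axis=1, keepdims=True)
    group_mean[:, ~cavin] = norm[:, ~cavin].mean(axis=1, keepdims=True)
    mu_hat = group_mean * size_factors.to_numpy() * np.exp(off_mat)
    disp = np.array([
        _moment_dispersion(mat[i], mu_hat[i]) for i in range(mat.shape[0])
    ])
    if config.pooled_dispersion:
        disp[:] = max(float(stats.trim_mean(disp[keep], 0.125)), _DISPERSION_FLOOR)

    rows = []
    for i, mirna in enumerate(counts.counts.index):
        if not keep[i]:
            continue
        l2fc, se, p = _fit_one(mat[i], X, base_offset + off_mat[i], disp[i])
        rows.append((mirna, base_mean[i], l2fc, se, p))
    out = pd.DataFrame(rows, columns=["mirna_id", "base_mean", "log2fc", "se", "wald_p"])
    out = out.set_index("mirna_id")
    out["bh_q"] = multipletests(out["wald_p"], method="fdr_bh")[1] if len(out) else []
    out["contrast"] = contrast
    return out


def select_empirical_controls(
    counts: CountMatrix,
    n_controls: int | None = None,
    *,
    size_factors: pd.Series | None = None,
    config: DiffConfig | None = None,
) -> list[str]:
    """Empirical control miRNAs: run a first-pass test with no RUV factors and
    return the ``n_controls`` miRNAs with the largest p-values (least
    associated with condition). Deterministic. ``n_controls`` defaults to 20%
    of retained miRNAs and is capped at the number available (warned)."""
    first = nb_differential(counts, None, config or DiffConfig(),
                            size_factors=size_factors)
    if n_controls is None:
        n_controls = max(int(round(0.2 * len(first))), 1)
    if n_controls > len(first):
        logger.warning("select_empirical_controls: requested %d controls, "
                       "only %d miRNAs retained", n_controls, len(first))
        n_controls = len(first)
    order = first.reset_index().sort_values(
        ["wald_p", "mirna_id"], ascending=[False, True], kind="mergesort"
    )
    return order["mirna_id"].head(n_controls).tolist()


def ruv_normalize(
    counts: CountMatrix,
    controls: list[str],
    k: int,
    *,
    size_factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Remove-unwanted-variation offsets from empirical controls.

    The centered log normalized counts of the control miRNAs are factor
    analysed by SVD; the top ``k`` left singular directions over samples are
    the unwanted factors W, each miRNA's loadings are fitted by least
    squares, and the returned miRNA x sample offset matrix is the fitted
    unwanted component W @ alpha. k = 0 returns all-zero offsets.
    """
    if k == 0:
        return pd.DataFrame(0.0, index=counts.counts.index,
                            columns=counts.counts.columns)
    if not controls:
        raise ValueError("controls must be non-empty when k > 0")
    n_samples = counts.counts.shape[1]
    if k >= min(len(controls), n_samples):
        raise ValueError(f"ruv_k={k} must be < min(n_controls, n_samples)")
    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    logc = np.log(counts.counts.to_numpy(float) / size_factors.to_numpy() + 1.0)
    ctrl_idx = [counts.counts.index.get_loc(c) for c in controls]
    ctrl = logc[ctrl_idx]
    ctrl_centered = ctrl - ctrl.mean(axis=1, keepdims=True)
    # samples x controls: factors live over samples
    u, s, vt = np.linalg.svd(ctrl_centered.T, full_matrices=False)
    W = u[:, :k] * s[:k]  # n_samples x k
    # deterministic sign: make each factor's largest-|.| entry positive
    for j in range(k):
        lead = np.argmax(np.abs(W[:, j]))
        if W[lead, j] < 0:
            W[:, j] = -W[:, j]
    centered_all = logc - logc.mean(axis=1, keepdims=True)
    alpha, *_ = np.linalg.lstsq(W, centered_all.T, rcond=None)  # k x n_mirna
    fitted = (W @ alpha).T  # n_mirna x n_samples
    return pd.DataFrame(fitted, index=counts.counts.index,
                        columns=counts.counts.columns)


def unwanted_factors(counts: CountMatrix, controls: list[str], k: int,
                     *, size_factors: pd.Series | None = None) -> np.ndarray:
    """The k estimated unwanted factors over samples (n_samples x k); exposed
    for diagnostics and recovery checks."""
    if k <= 0:
        raise ValueError("k must be positive")
    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    logc = np.log(counts.counts.to_numpy(float) / size_factors.to_numpy() + 1.0)
    ctrl_idx = [counts.counts.index.get_loc(c) for c in controls]
    ctrl = logc[ctrl_idx]
    ctrl_centered = ctrl - ctrl.mean(axis=1, keepdims=True)
    u, s, _ = np.linalg.svd(ctrl_centered.T, full_matrices=False)
    W = u[:, :k] * s[:k]
    for j in range(k):
        lead = np.argmax(np.abs(W[:, j]))
        if W[lead, j] < 0:
            W[:, j] = -W[:, j]
    return W
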