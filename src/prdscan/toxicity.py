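"""Per-variant relative toxicity with an explicit error model.

For each replicate selection the enrichment score of a variant is
``ES_x = ln(F_out / F_in)`` and its relative toxicity is ``ES_WT - ES_x``,
so positive values mean slower growth than wild type. The uncertainty
combines the expected Poisson error of the four read counts involved with
an inter-replicate error component ``eps_r`` estimated from well-covered
variants:

    eps_x = sqrt(1/n_in + 1/n_out + 1/n_wt_in + 1/n_wt_out + eps_r**2)

Toxicities and errors are normalized by the replicate-specific number of
cell doublings to growth-rate units per generation. Sparse double mutants
(which drop out of output samples) are re-estimated by a Bayesian
posterior combining a Poisson read-count likelihood with an empirical
prior conditioned on the toxicities of the constituent singles. Replicate
estimates are variance-equalized, merged by error-weighted averaging,
centred on the silent (synonymous) variants and scaled so the STOP-class
means of the two sub-libraries coincide. Variants are finally classified
against wild type by per-variant one-sample t-tests at a
Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .design import LibraryDesign

__all__ = [
    "ReplicateErrorModel",
    "enrichment_score",
    "relative_toxicity",
    "toxicity_error",
    "per_replicate_estimates",
    "normalize_per_generation",
    "estimate_replicate_error",
    "apply_replicate_error",
    "bayesian_double_correction",
    "estimate_toxicity",
    "merge_and_normalize",
    "classify_vs_wt",
]


@dataclass(frozen=True)
class ReplicateErrorModel:
    """Inter-replicate error component (per-generation units).

    ``eps_r`` is the square root of the excess variance of toxicity across
    replicates, beyond the Poisson expectation, among variants whose
    count-based Poisson error approaches zero (the top
    ``1 - count_quantile`` fraction by minimum sample count).
    """

    eps_r: float
    count_threshold: float
    n_variants_used: int

    def __post_init__(self) -> None:
        if self.eps_r < 0:
            raise ValueError("eps_r must be non-negative")


def enrichment_score(f_input, f_output):
    """``ln(F_out / F_in)``; both frequencies must be positive."""
    f_input = np.asarray(f_input, dtype=float)
    f_output = np.asarray(f_output, dtype=float)
    if np.any(f_input <= 0) or np.any(f_output <= 0):
        raise ValueError("frequencies must be positive")
    return np.log(f_output / f_input)


def relative_toxicity(es_variant, es_wt):
    """``ES_WT - ES_x``: positive means more toxic (depleted) than WT."""
    return np.asarray(es_wt, dtype=float) - np.asarray(es_variant, dtype=float)


def toxicity_error(n_in, n_out, n_wt_in, n_wt_out, eps_r: float = 0.0):
    """Poisson + inter-replicate uncertainty of one toxicity estimate.

    The reciprocals are of raw read counts (the squared relative Poisson
    error of each count); ``eps_r`` enters in quadrature. All counts must
    be positive — zero-count variants are routed to the Bayesian path
    (doubles) or dropped (singles) by the caller.
    """
    arrs = [np.asarray(a, dtype=float) for a in (n_in, n_out, n_wt_in, n_wt_out)]
    if any(np.any(a <= 0) for a in arrs):
        raise ValueError("all counts must be positive")
    return np.sqrt(sum(1.0 / a for a in arrs) + float(eps_r) ** 2)


# ---------------------------------------------------------------------------
# Per-replicate estimation


def _output_cols(columns, replicate: int) -> list[str]:
    return [c for c in columns if c.startswith(f"output{replicate}")]


def per_replicate_estimates(
    records: pd.DataFrame, design: LibraryDesign
) -> tuple[pd.DataFrame, dict]:
    """Raw (un-normalized) toxicity and Poisson error per replicate.

    Output cultures of one replicate are pooled before frequencies are
    computed. Variants with zero input or zero output reads in a replicate
    get NaN for that replicate (doubles are later revisited by the
    Bayesian path); drops are tallied in the returned log. The log also
    carries per-replicate sample totals and WT quantities needed by the
    Bayesian likelihood.
    """
    wt_mask = records["is_wt"].to_numpy(dtype=bool)
    if wt_mask.sum() != 1:
        raise ValueError("variant table must contain exactly one WT record")
    wt_idx = int(np.flatnonzero(wt_mask)[0])

    df = records.copy()
    log: dict = {"replicates": {}}
    for r in range(1, design.n_replicates + 1):
        in_col = f"input{r}"
        out_cols = _output_cols(records.columns, r)
        if in_col not in records.columns or not out_cols:
            raise ValueError(f"missing count columns for replicate {r}")
        n_in = records[in_col].to_numpy(dtype=float)
        n_out = records[out_cols].to_numpy(dtype=float).sum(axis=1)
        T_in, T_out = n_in.sum(), n_out.sum()
        n_wt_in, n_wt_out = n_in[wt_idx], n_out[wt_idx]
        if n_wt_in <= 0 or n_wt_out <= 0:
            raise ValueError(f"WT has zero reads in replicate {r}")

        ok = (n_in > 0) & (n_out > 0)
        tox = np.full(len(records), np.nan)
        err = np.full(len(records), np.nan)
        # half-count continuity correction: E[ln(n + 1/2)] tracks ln(lambda)
        # to O(lambda^-2) for Poisson counts, removing the depletion bias
        # that plain ln(n) picks up at low output counts
        with np.errstate(divide="ignore", invalid="ignore"):
            es = np.where(
                ok, np.log(((n_out + 0.5) / T_out) / ((n_in + 0.5) / T_in)), np.nan
            )
        es_wt = float(np.log(((n_wt_out + 0.5) / T_out) / ((n_wt_in + 0.5) / T_in)))
        tox[ok] = relative_toxicity(es[ok], es_wt)
        err[ok] = toxicity_error(n_in[ok], n_out[ok], n_wt_in, n_wt_out)

        df[f"tox_rep{r}"] = tox
        df[f"err_rep{r}"] = err
        df[f"n_in_rep{r}"] = n_in
        df[f"n_out_rep{r}"] = n_out
        log["replicates"][r] = {
            "T_in": float(T_in),
            "T_out": float(T_out),
            "es_wt": es_wt,
            "n_dropped_zero_input": int((n_in <= 0).sum()),
            "n_dropped_zero_output": int(((n_in > 0) & (n_out <= 0)).sum()),
        }
    input_cols = [c for c in records.columns if c.startswith("input")]
    df["mean_input"] = records[input_cols].to_numpy(dtype=float).mean(axis=1)
    return df, log


def normalize_per_generation(
    estimates: pd.DataFrame, doublings_per_replicate
) -> pd.DataFrame:
    """Divide toxicities and errors by replicate-specific cell doublings."""
    doublings = np.asarray(doublings_per_replicate, dtype=float)
    if np.any(doublings <= 0):
        raise ValueError("doublings must be positive")
    df = estimates.copy()
    for r, g in enumerate(doublings, start=1):
        df[f"tox_rep{r}"] = df[f"tox_rep{r}"] / g
        df[f"err_rep{r}"] = df[f"err_rep{r}"] / g
    return df


def _rep_cols(df: pd.DataFrame, prefix: str) -> list[str]:
    cols = [c for c in df.columns if c.startswith(prefix)]
    return sorted(cols, key=lambda c: int(c[len(prefix):]))


def estimate_replicate_error(
    estimates: pd.DataFrame, count_quantile: float = 0.9
) -> ReplicateErrorModel:
    """Estimate ``eps_r`` from the excess inter-replicate variance.

    Uses variants in the top ``1 - count_quantile`` fraction of the
    minimum *input* read count over replicates, where the Poisson error
    approaches zero. Input counts are unaffected by selection, so the
    cut does not condition on the replicate noise being estimated (a
    threshold involving output counts would truncate the noise
    distribution and bias ``eps_r`` downward): ``eps_r**2`` is the
    observed variance
    of toxicity across replicates minus the Poisson-expected variance,
    averaged over the selected variants with inverse-variance weights
    (the sampling variance of an observed variance scales with the
    squared expected variance, so the best-covered variants dominate),
    floored at zero.
    """
    tox = estimates[_rep_cols(estimates, "tox_rep")].to_numpy(dtype=float)
    err = estimates[_rep_cols(estimates, "err_rep")].to_numpy(dtype=float)
    n_in = estimates[_rep_cols(estimates, "n_in_rep")].to_numpy(dtype=float)
    if tox.shape[1] < 2:
        raise ValueError("need at least two replicates")
    min_count = n_in.min(axis=1)
    threshold = float(np.quantile(min_count[min_count > 0], count_quantile))
    # "approaches zero" is an absolute statement: do not let the quantile
    # drag the threshold into the Poisson-dominated count range
    floored = max(threshold, 200.0)
    sel = (min_count >= floored) & np.isfinite(tox).all(axis=1)
    if sel.any():
        threshold = floored
    else:
        sel = (min_count >= threshold) & np.isfinite(tox).all(axis=1)
    if "is_wt" in estimates.columns:
        # WT's toxicity is identically zero by construction: no information
        sel &= ~estimates["is_wt"].to_numpy(dtype=bool)
    if not sel.any():
        raise ValueError(
            "no variants pass the count threshold; lower count_quantile"
        )
    obs_var = tox[sel].var(axis=1, ddof=1)
    exp_var = (err[sel] ** 2).mean(axis=1)
    # inverse-variance weights; Var(obs_var) ~ (exp_var + eps^2)^2, so
    # iterate the weights with the current eps^2 estimate
    eps_sq = 0.0
    for _ in range(10):
        w = 1.0 / (exp_var + eps_sq) ** 2
        new = max(0.0, float(np.sum(w * (obs_var - exp_var)) / w.sum()))
        if abs(new - eps_sq) < 1e-12:
            eps_sq = new
            break
        eps_sq = new
    return ReplicateErrorModel(
        eps_r=float(np.sqrt(eps_sq)),
        count_threshold=threshold,
        n_variants_used=int(sel.sum()),
    )


def apply_replicate_error(
    estimates: pd.DataFrame, model: ReplicateErrorModel
) -> pd.DataFrame:
    """Fold ``eps_r`` into every per-replicate error in quadrature."""
    df = estimates.copy()
    for c in _rep_cols(df, "err_rep"):
        df[c] = np.sqrt(df[c] ** 2 + model.eps_r**2)
    return df


# ---------------------------------------------------------------------------
# Bayesian correction of sparse double mutants


def _merge_rows(tox: np.ndarray, err: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Inverse-variance merge across replicate columns (NaN-aware)."""
    w = np.where(np.isfinite(tox) & np.isfinite(err) & (err > 0), 1.0 / err**2, 0.0)
    wsum = w.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        merged = np.where(wsum > 0, np.nansum(w * np.nan_to_num(tox), axis=1) / wsum,
                          np.nan)
        merged_err = np.where(wsum > 0, np.sqrt(1.0 / wsum), np.nan)
    return merged, merged_err


def bayesian_double_correction(
    estimates: pd.DataFrame,
    design: LibraryDesign,
    rep_log: dict,
    error_model: ReplicateErrorModel,
    *,
    prior_min_input: float = 50.0,
    n_bins: int = 20,
    min_bin_size: int = 5,
    grid_size: int = 241,
) -> pd.DataFrame:
    """Shrink double-mutant estimates toward an empirical conditional prior.

    The prior for a double whose constituent singles have merged
    toxicities ``(t1, t2)`` is a normal distribution fitted to the
    toxicities of well-measured doubles (mean input >= ``prior_min_input``)
    in the same 2D equal-occupancy bin of ``(t1, t2)`` space; bins with
    fewer than ``min_bin_size`` such doubles fall back to an additive
    prior (mean ``t1 + t2``, SD of the additive residuals of all
    well-measured doubles). Per replicate the posterior combines the prior
    with a Poisson likelihood on the variant's output count given its
    input frequency, so doubles with zero output reads receive a finite
    estimate while well-covered doubles are essentially unchanged.
    Posterior mean/SD replace the raw per-replicate toxicity/error;
    corrected rows are flagged ``bayes_corrected``.
    """
    df = estimates.reset_index(drop=True).copy()
    is_double = (
        (df["n_aa_mut"] == 2)
        & ~df["is_stop"].astype(bool)
        & ~df["has_extra_syn"].astype(bool)
    ).to_numpy()
    is_single = (
        (df["n_aa_mut"] == 1)
        & ~df["is_stop"].astype(bool)
        & ~df["has_extra_syn"].astype(bool)
    ).to_numpy()
    df["bayes_corrected"] = False
    if not is_double.any():
        return df

    tox_cols = _rep_cols(df, "tox_rep")
    err_cols = _rep_cols(df, "err_rep")
    merged, _ = _merge_rows(df[tox_cols].to_numpy(float), df[err_cols].to_numpy(float))

    single_tox: dict[tuple, float] = {}
    for i in np.flatnonzero(is_single):
        muts = df.at[i, "mutations"]
        single_tox[muts[0]] = merged[i]
    # constituent single toxicities per double
    dbl_idx = np.flatnonzero(is_double)
    t1 = np.full(len(df), np.nan)
    t2 = np.full(len(df), np.nan)
    for i in dbl_idx:
        m1, m2 = df.at[i, "mutations"]
        t1[i] = single_tox.get(m1, np.nan)
        t2[i] = single_tox.get(m2, np.nan)
    usable = is_double & np.isfinite(t1) & np.isfinite(t2)
    df["t1_single"] = t1
    df["t2_single"] = t2
    df["excluded_missing_single"] = is_double & ~usable

    well = usable & (df["mean_input"].to_numpy(float) >= prior_min_input)
    well &= np.isfinite(merged)
    if well.sum() < 10 * min_bin_size:
        # too few well-measured doubles for binning: purely additive prior
        bins_available = False
    else:
        bins_available = True
    resid = merged[well] - (t1[well] + t2[well])
    add_sd = float(np.std(resid, ddof=1)) if well.sum() >= 3 else 0.2

    prior_mean = t1 + t2
    prior_sd = np.full(len(df), add_sd)
    if bins_available:
        nb = max(2, min(n_bins, int(np.sqrt(well.sum() / min_bin_size))))
        q1 = pd.qcut(t1[well], nb, labels=False, duplicates="drop")
        q2 = pd.qcut(t2[well], nb, labels=False, duplicates="drop")
        edges1 = np.quantile(t1[well], np.linspace(0, 1, nb + 1))
        edges2 = np.quantile(t2[well], np.linspace(0, 1, nb + 1))
        b1 = np.clip(np.searchsorted(edges1[1:-1], t1[usable]), 0, nb - 1)
        b2 = np.clip(np.searchsorted(edges2[1:-1], t2[usable]), 0, nb - 1)
        stat = pd.DataFrame(
            {"b1": np.clip(np.searchsorted(edges1[1:-1], t1[well]), 0, nb - 1),
             "b2": np.clip(np.searchsorted(edges2[1:-1], t2[well]), 0, nb - 1),
             "t": merged[well]}
        ).groupby(["b1", "b2"])["t"].agg(["mean", "std", "count"])
        lookup_mean = {}
        lookup_sd = {}
        for (bi, bj), row in stat.iterrows():
            if row["count"] >= min_bin_size and np.isfinite(row["std"]):
                lookup_mean[(bi, bj)] = row["mean"]
                lookup_sd[(bi, bj)] = max(row["std"], 1e-3)
        for k, i in enumerate(np.flatnonzero(usable)):
            key = (b1[k], b2[k])
            if key in lookup_mean:
                prior_mean[i] = lookup_mean[key]
                prior_sd[i] = lookup_sd[key]

    # posterior per replicate on per-double adaptive grids (the grid must
    # resolve the posterior SD, which varies by orders of magnitude with
    # coverage)
    idx = np.flatnonzero(usable)
    pm = prior_mean[idx]
    ps = prior_sd[idx]
    raw_tox = df.loc[df.index[idx], tox_cols].to_numpy(float)
    raw_err = df.loc[df.index[idx], err_cols].to_numpy(float)
    finite = np.isfinite(raw_tox) & np.isfinite(raw_err)
    raw_lo = np.where(finite, raw_tox - 8 * raw_err, np.inf).min(axis=1)
    raw_hi = np.where(finite, raw_tox + 8 * raw_err, -np.inf).max(axis=1)
    lo = np.minimum(pm - 6 * ps, np.where(np.isfinite(raw_lo), raw_lo, np.inf))
    hi = np.maximum(pm + 6 * ps, np.where(np.isfinite(raw_hi), raw_hi, -np.inf))
    steps = np.linspace(0.0, 1.0, grid_size)
    grid = lo[:, None] + (hi - lo)[:, None] * steps[None, :]

    log_prior = -0.5 * ((grid - pm[:, None]) / ps[:, None]) ** 2 \
        - np.log(ps[:, None])

    for r, col in enumerate(tox_cols, start=1):
        info = rep_log["replicates"][r]
        G = design.generations[r - 1]
        n_in = df[f"n_in_rep{r}"].to_numpy(float)[idx]
        n_out = df[f"n_out_rep{r}"].to_numpy(float)[idx]
        has_input = n_in > 0
        lam0 = info["T_out"] * (n_in / info["T_in"]) * np.exp(info["es_wt"])
        with np.errstate(divide="ignore", invalid="ignore"):
            log_lam = np.log(lam0)[:, None] - grid * G
        loglik = n_out[:, None] * log_lam - np.exp(log_lam)
        logpost = np.where(has_input[:, None], log_prior + loglik, np.nan)

        post_t = np.full(idx.size, np.nan)
        post_e = np.full(idx.size, np.nan)
        ok = has_input
        lp = logpost[ok]
        lp = lp - lp.max(axis=1, keepdims=True)
        w = np.exp(lp)
        w /= w.sum(axis=1, keepdims=True)
        g = grid[ok]
        mean = (w * g).sum(axis=1)
        var = (w * (g - mean[:, None]) ** 2).sum(axis=1)
        post_t[ok] = mean
        post_e[ok] = np.sqrt(var + error_model.eps_r**2)

        df.loc[df.index[idx], f"tox_rep{r}"] = post_t
        df.loc[df.index[idx], f"err_rep{r}"] = post_e
    df.loc[df.index[idx], "bayes_corrected"] = True
    return df


# ---------------------------------------------------------------------------
# Merging, normalization, classification


def _weighted_mean(values: np.ndarray, errors: np.ndarray) -> float:
    ok = np.isfinite(values) & np.isfinite(errors) & (errors > 0)
    if not ok.any():
        raise ValueError("no finite values to average")
    w = 1.0 / errors[ok] ** 2
    return float(np.sum(w * values[ok]) / w.sum())


def estimate_toxicity(
    records: pd.DataFrame,
    design: LibraryDesign,
    *,
    bayesian: bool = True,
    count_quantile: float = 0.9,
    prior_min_input: float = 50.0,
) -> tuple[pd.DataFrame, dict]:
    """Per-replicate, per-generation-normalized estimates for one library.

    Runs the per-replicate estimator, normalizes by cell doublings,
    estimates and applies the inter-replicate error, and (optionally)
    applies the Bayesian double-mutant correction. Returns the estimates
    table plus a log holding the replicate context and the fitted
    :class:`ReplicateErrorModel`.
    """
    est, log = per_replicate_estimates(records, design)
    # raw scale -> per-generation scale (Eq. 1 inverted exactly under
    # exponential competition in natural-log units)
    est = normalize_per_generation(est, design.generations)
    model = estimate_replicate_error(est, count_quantile=count_quantile)
    est = apply_replicate_error(est, model)
    if bayesian:
        est = bayesian_double_correction(
            est, design, log, model, prior_min_input=prior_min_input
        )
    else:
        est["bayes_corrected"] = False
    est["library"] = design.name
    log["error_model"] = model
    return est, log


def merge_and_normalize(
    libraries: list[pd.DataFrame],
) -> pd.DataFrame:
    """Merge replicate estimates and put libraries on one common scale.

    In order: (1) toxicity distributions are normalized between replicate
    selections of each library to equal standard deviations; (2) replicate
    estimates are merged by the error-weighted mean (merged error =
    inverse-variance-weighted SE); (3) each library is centred on the
    error-weighted mean of its silent variants; (4) libraries are scaled
    so the error-weighted means of their single-STOP variants coincide.
    Requires a non-empty silent and (for step 4 with >1 library) STOP
    class per library.
    """
    merged_tables = []
    for df in libraries:
        df = df.copy()
        tox_cols = _rep_cols(df, "tox_rep")
        err_cols = _rep_cols(df, "err_rep")
        if len(tox_cols) < 2:
            raise ValueError("need at least two replicates")
        # (1) equalize replicate SDs
        sds = np.array([np.nanstd(df[c].to_numpy(float)) for c in tox_cols])
        target = sds.mean()
        for c_t, c_e, sd in zip(tox_cols, err_cols, sds):
            scale = target / sd if sd > 0 else 1.0
            df[c_t] = df[c_t] * scale
            df[c_e] = df[c_e] * scale
        # (2) error-weighted merge
        tox, err = _merge_rows(
            df[tox_cols].to_numpy(float), df[err_cols].to_numpy(float)
        )
        df["toxicity"] = tox
        df["sigma"] = err
        # (3) centre on single-codon silent variants (well-covered, so the
        # class mean is free of low-count censoring effects)
        silent = df["is_silent"].to_numpy(bool)
        if "n_codon_mut" in df.columns:
            single_codon = silent & (df["n_codon_mut"].to_numpy() == 1)
            if single_codon.any():
                silent = single_codon
        if not silent.any():
            raise ValueError("empty silent class; cannot centre toxicity scale")
        shift = _weighted_mean(tox[silent], err[silent])
        df["toxicity"] = df["toxicity"] - shift
        for c in tox_cols:
            df[c] = df[c] - shift
        merged_tables.append(df)

    # (4) align STOP-class means across libraries
    if len(merged_tables) > 1:
        stop_means = []
        for df in merged_tables:
            stop = (
                df["is_stop"].to_numpy(bool)
                & (df["n_aa_mut"] == 1).to_numpy()
            )
            if not stop.any():
                raise ValueError("empty STOP class; cannot scale libraries")
            stop_means.append(
                _weighted_mean(
                    df.loc[stop, "toxicity"].to_numpy(float),
                    df.loc[stop, "sigma"].to_numpy(float),
                )
            )
        target = float(np.mean(stop_means))
        for df, m in zip(merged_tables, stop_means):
            scale = target / m if m != 0 else 1.0
            cols = (
                ["toxicity", "sigma"]
                + _rep_cols(df, "tox_rep")
                + _rep_cols(df, "err_rep")
            )
            df[cols] = df[cols] * scale
    return pd.concat(merged_tables, ignore_index=True)


def classify_vs_wt(merged: pd.DataFrame, fdr: float = 0.05) -> pd.Series:
    """Label variants more/less toxic than WT or indistinguishable.

    One-sample two-sided t-test of the per-replicate (normalized, centred)
    toxicities against zero, Benjamini-Hochberg corrected at ``fdr``; the
    sign of the merged toxicity sets the direction. Variants with fewer
    than two finite replicate values are labeled indistinguishable.
    """
    if not 0.0 < fdr < 1.0:
        raise ValueError("fdr must be in (0, 1)")
    tox = merged[_rep_cols(merged, "tox_rep")].to_numpy(float)
    n_ok = np.isfinite(tox).sum(axis=1)
    pvals = np.full(len(merged), np.nan)
    testable = n_ok >= 2
    for i in np.flatnonzero(testable):
        vals = tox[i][np.isfinite(tox[i])]
        if np.allclose(vals, vals[0]):
            pvals[i] = 1.0
        else:
            pvals[i] = stats.ttest_1samp(vals, 0.0).pvalue
    labels = np.full(len(merged), "indistinguishable", dtype=object)
    if testable.any():
        rej, _, _, _ = multipletests(pvals[testable], alpha=fdr, method="fdr_bh")
        sig = np.flatnonzero(testable)[rej]
        direction = merged["toxicity"].to_numpy(float)[sig] > 0
        labels[sig[direction]] = "more_toxic"
        labels[sig[~direction]] = "less_toxic"
    return pd.Series(labels, index=merged.index, name="class_vs_wt")
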