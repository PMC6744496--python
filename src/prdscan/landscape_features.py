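"""Position profiles, hotspot detection and property-based toxicity models.

Three questions about a mutational landscape are answered here:

* *Where do mutations matter?* Per-position aggregates of single-mutant
  toxicity with a loess-smoothed |toxicity| track, and detection of the
  mutant-effect hotspot — the longest contiguous run of positions whose
  smoothed mean |toxicity| exceeds the global mean |toxicity| of all
  single mutants.
* *Which physicochemical changes drive toxicity?* A PCA of an amino-acid
  property matrix (rows = numeric property indices, columns = the 20
  amino acids) yields orthogonal property components; feature values for
  a variant are WT-minus-mutant score differences, summed over the
  constituent singles for doubles.
* *How predictive is a feature?* Ordinary-least-squares models of
  toxicity on a feature, fitted on all variants, inside/outside-hotspot
  subsets, or with a hotspot location variable (0/1/2 mutations inside)
  plus a location-feature interaction.

A small curated matrix of published amino-acid property scales is bundled
so none of this requires external downloads; a full AAindex-style table
can be supplied instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.decomposition import PCA
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "PropertyFeatureSet",
    "PositionProfile",
    "load_property_matrix",
    "build_property_pcs",
    "variant_feature_value",
    "per_position_profile",
    "detect_hotspot",
    "fit_toxicity_model",
    "summarize_residue_scores",
]

_AA20 = list("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class PropertyFeatureSet:
    """PCA of an amino-acid property matrix.

    ``scores`` is a (20 x k) DataFrame of per-amino-acid component scores
    (rows indexed by one-letter code); ``loadings`` the (n_indices x k)
    loadings; ``explained_variance_ratio`` per component. PC1 is oriented
    so hydrophobic residues (Ile/Leu/Val) score positive.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray
    standardized_matrix: pd.DataFrame
    pc1_flipped: bool

    def feature(self, name: str) -> pd.Series:
        """Per-amino-acid values of one component (``"PC1"``) or raw index."""
        if name in self.scores.columns:
            return self.scores[name]
        if name in self.standardized_matrix.index:
            return self.standardized_matrix.loc[name]
        raise KeyError(name)


@dataclass(frozen=True)
class PositionProfile:
    """Per-position single-mutant toxicity aggregates and smoothed track."""

    table: pd.DataFrame  # position, mean_abs, mean, var, n, smoothed_abs
    global_mean_abs: float
    interpolated_positions: tuple[int, ...] = ()


def load_property_matrix(path=None) -> pd.DataFrame:
    """Load a property matrix (rows = indices, columns = 20 AA codes).

    With no path, returns the bundled curated subset of published scales
    (hydrophobicity, charge, volume, secondary-structure propensities...).
    """
    if path is None:
        ref = resources.files("prdscan.data").joinpath("aa_properties.tsv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t", index_col=0)
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
    missing = set(_AA20) - set(df.columns)
    if missing:
        raise ValueError(f"property matrix lacks amino acids {sorted(missing)}")
    return df[_AA20]


def build_property_pcs(index_matrix: pd.DataFrame) -> PropertyFeatureSet:
    """Standardize property indices and extract principal components.

    Indices with any missing value are dropped first; each retained index
    is z-scored across the 20 amino acids; PCA treats amino acids as
    observations. Scores are reconstructable from the standardized matrix
    and loadings.
    """
    mat = index_matrix.dropna(axis=0)
    if len(mat) < 2:
        raise ValueError("need at least two complete property indices")
    X = mat.to_numpy(dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=0, keepdims=True)
    if np.any(sd == 0):
        constant = mat.index[(sd == 0).ravel()].tolist()
        raise ValueError(f"constant property indices: {constant}")
    Z = (X - mu) / sd  # indices x 20
    n_comp = min(Z.shape[0], Z.shape[1] - 1)
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(Z.T)  # 20 x k
    loadings = pca.components_.T  # indices x k

    flipped = False
    hydrophobic = [_AA20.index(a) for a in "ILV"]
    if scores[hydrophobic, 0].mean() < 0:
        scores[:, 0] *= -1
        loadings[:, 0] *= -1
        flipped = True

    names = [f"PC{i + 1}" for i in range(n_comp)]
    return PropertyFeatureSet(
        scores=pd.DataFrame(scores, index=_AA20, columns=names),
        loadings=pd.DataFrame(loadings, index=mat.index, columns=names),
        explained_variance_ratio=pca.explained_variance_ratio_,
        standardized_matrix=pd.DataFrame(Z, index=mat.index, columns=_AA20),
        pc1_flipped=flipped,
    )


def variant_feature_value(mutations, feature: pd.Series, absolute: bool = False):
    """Feature change of a variant: sum over mutations of WT minus mutant score.

    ``mutations`` is a tuple of ``(position, wt_aa, mut_aa)``; the empty
    tuple (synonymous variant) gives 0. With ``absolute=True`` the value
    is ``|sum|`` — used for the change-in-absolute-charge feature. STOP
    mutations are rejected (they are excluded upstream).
    """
    total = 0.0
    for _, wt, mut in mutations:
        if mut == "*" or wt == "*":
            raise ValueError("feature values undefined for STOP variants")
        total += float(feature[wt]) - float(feature[mut])
    return abs(total) if absolute else total


# ---------------------------------------------------------------------------
# Position profiles and hotspot


def per_position_profile(
    singles: pd.DataFrame, *, span: float = 0.3
) -> PositionProfile:
    """Per-position toxicity aggregates with a loess-smoothed |toxicity| track.

    ``singles`` needs columns ``mutations`` (length-1 tuples) and
    ``toxicity``. The loess fit (local polynomial regression, default span
    0.3) runs over all single-mutant |toxicity| values against position;
    positions with no variants are linearly interpolated in the smoothed
    track and reported.
    """
    if len(singles) == 0:
        raise ValueError("no single mutants")
    pos = np.array([m[0][0] for m in singles["mutations"]])
    tox = singles["toxicity"].to_numpy(dtype=float)
    ok = np.isfinite(tox)
    pos, tox = pos[ok], tox[ok]
    abs_tox = np.abs(tox)

    grp = pd.DataFrame({"position": pos, "tox": tox, "abs": abs_tox}).groupby(
        "position"
    )
    table = pd.DataFrame(
        {
            "mean_abs": grp["abs"].mean(),
            "mean": grp["tox"].mean(),
            "var": grp["tox"].var(ddof=1),
            "n": grp["tox"].size(),
        }
    )
    all_positions = np.arange(pos.min(), pos.max() + 1)
    table = table.reindex(all_positions)
    table.index.name = "position"

    smooth_xy = lowess(abs_tox, pos.astype(float), frac=span, return_sorted=True)
    sx, sy = smooth_xy[:, 0], smooth_xy[:, 1]
    smoothed = np.interp(all_positions.astype(float), sx, sy)
    table["smoothed_abs"] = smoothed
    missing = tuple(int(p) for p in all_positions if p not in set(pos.tolist()))
    return PositionProfile(
        table=table.reset_index(),
        global_mean_abs=float(abs_tox.mean()),
        interpolated_positions=missing,
    )


def detect_hotspot(profile: PositionProfile) -> tuple[int, int] | None:
    """Longest run of positions with smoothed mean |toxicity| above the mean.

    The threshold is the global mean |toxicity| over all single mutants.
    Ties in run length are broken by the greater mean smoothed |toxicity|
    within the run; returns ``None`` if no position exceeds the mean.
    Invariant under affine rescaling of toxicities (the threshold scales
    along).
    """
    tab = profile.table
    above = (tab["smoothed_abs"].to_numpy() > profile.global_mean_abs)
    positions = tab["position"].to_numpy()
    best = None  # (length, mean, start, end)
    i = 0
    while i < len(above):
        if above[i]:
            j = i
            while j + 1 < len(above) and above[j + 1]:
                j += 1
            run_mean = float(tab["smoothed_abs"].to_numpy()[i : j + 1].mean())
            cand = (j - i + 1, run_mean, int(positions[i]), int(positions[j]))
            if best is None or cand[:2] > best[:2]:
                best = cand
            i = j + 1
        else:
            i += 1
    if best is None:
        return None
    return best[2], best[3]


# ---------------------------------------------------------------------------
# Regression models


def _location_code(mutations, hotspot: tuple[int, int]) -> int:
    """0: all outside, 1: mixed, 2: all inside the hotspot."""
    lo, hi = hotspot
    inside = sum(1 for p, _, _ in mutations if lo <= p <= hi)
    if inside == 0:
        return 0
    if inside == len(mutations):
        return 2
    return 1


def fit_toxicity_model(
    variants: pd.DataFrame,
    feature_values: np.ndarray,
    mode: str = "all",
    hotspot: tuple[int, int] | None = None,
) -> dict:
    """OLS of variant toxicity on a feature change.

    ``mode``:

    - ``"all"`` — simple regression on all variants;
    - ``"inside"`` / ``"outside"`` — restricted to variants whose
      mutations all fall inside / all outside the hotspot;
    - ``"interaction"`` — all variants, with the hotspot location code
      (0/1/2) and its interaction with the feature as extra terms.

    Returns a dict with ``r_squared``, ``params``, ``n`` and the fitted
    statsmodels results object under ``fit``.
    """
    if mode not in {"all", "inside", "outside", "interaction"}:
        raise ValueError(f"unknown mode {mode!r}")
    y = variants["toxicity"].to_numpy(dtype=float)
    x = np.asarray(feature_values, dtype=float)
    ok = np.isfinite(y) & np.isfinite(x)

    if mode in {"inside", "outside", "interaction"}:
        if hotspot is None:
            raise ValueError(f"mode {mode!r} requires a hotspot interval")
        loc = np.array(
            [_location_code(m, hotspot) for m in variants["mutations"]],
            dtype=float,
        )
    if mode == "inside":
        ok &= loc == 2
    elif mode == "outside":
        ok &= loc == 0

    if ok.sum() < 3:
        raise ValueError("fewer than 3 usable variants in stratum")
    if mode == "interaction":
        X = np.column_stack([x[ok], loc[ok], x[ok] * loc[ok]])
        names = ["feature", "location", "feature:location"]
    else:
        X = x[ok, None]
        names = ["feature"]
    X = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    fit = sm.OLS(y[ok], X).fit()
    params = dict(zip(["const"] + names, fit.params))
    return {
        "mode": mode,
        "r_squared": float(fit.rsquared),
        "params": params,
        "n": int(ok.sum()),
        "fit": fit,
    }


def summarize_residue_scores(track, wt_track=None) -> float:
    """Sum a per-residue score track to one per-sequence score.

    With ``wt_track`` given, returns the WT-minus-variant difference of
    sums (the form used as a regression feature for external per-residue
    predictors). Tracks must have equal lengths.
    """
    track = np.asarray(track, dtype=float)
    if wt_track is None:
        return float(track.sum())
    wt_track = np.asarray(wt_track, dtype=float)
    if wt_track.shape != track.shape:
        raise ValueError("track length mismatch")
    return float(wt_track.sum() - track.sum())
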