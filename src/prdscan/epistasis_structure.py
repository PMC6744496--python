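"""Secondary-structure inference from double-mutant epistasis patterns.

The chain implemented here turns a table of double-mutant toxicities into
per-position secondary-structure propensities:

1. For every double, the expected toxicity given its constituent singles
   is estimated non-parametrically: local 5th/50th/95th percentiles among
   its K nearest neighbours in the 2D single-toxicity space (t1, t2).
2. Doubles below the local 5th or above the local 95th percentile are
   classified as epistatic (negative / positive epistasis for growth
   rate); doubles whose local median sits near the measurement range
   limits are excluded first.
3. Position-pair enrichment of epistatic doubles gives a symmetric
   log-odds matrix E (diagonal imputed as column means).
4. Partial correlations between the interaction profiles (columns of E)
   give the epistasis correlation score matrix C: structurally close
   positions interact similarly with everything else, and partialling
   removes transitive correlations.
5. Two-dimensional periodicity kernels slid along the diagonal of C score
   alpha-helix (period 3.6) and beta-strand (period 2) propensity per
   position; significance comes from propensities of label-permuted
   matrices. A reference-structure contact map (side-chain heavy atoms
   within 4.5 A) scores LARKS-like non-canonical geometry the same way,
   with the randomization restricted to the six-residue window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "EpistasisMatrices",
    "StructurePropensityTrack",
    "ContactMap",
    "expected_double_surface",
    "classify_epistasis",
    "pairwise_enrichment",
    "impute_diagonal",
    "partial_correlation_from_corr",
    "partial_correlation_matrix",
    "helix_kernel",
    "strand_kernel",
    "structure_propensity",
    "randomization_pvalues",
    "pdb_contact_map",
    "larks_propensity",
    "top_contacts",
    "epistasis_pipeline",
]

HELIX_PERIOD = 3.6
STRAND_PERIOD = 2.0


@dataclass(frozen=True)
class EpistasisMatrices:
    """Pairwise enrichment matrix E and correlation score matrix C."""

    positions: tuple[int, ...]
    enrichment: np.ndarray
    correlation: np.ndarray
    pair_counts: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.positions)
        for m in (self.enrichment, self.correlation, self.pair_counts):
            if m.shape != (n, n):
                raise ValueError("matrix dimensions must equal n_positions^2")


@dataclass(frozen=True)
class StructurePropensityTrack:
    """Per-position propensities and empirical p-values for one kernel."""

    positions: tuple[int, ...]
    kernel: str
    propensity: np.ndarray
    pvalue: np.ndarray
    n_randomizations: int
    seed: int


@dataclass(frozen=True)
class ContactMap:
    """Residue-pair contacts of a reference structure (zero-sum normalized)."""

    positions: tuple[int, ...]
    matrix: np.ndarray
    threshold: float
    source: str

    def __post_init__(self) -> None:
        n = len(self.positions)
        if self.matrix.shape != (n, n):
            raise ValueError("contact matrix shape mismatch")


# ---------------------------------------------------------------------------
# Expected-toxicity surface and epistasis classification


def expected_double_surface(
    doubles: pd.DataFrame, *, k_neighbors: int = 1000
) -> pd.DataFrame:
    """Local percentile bounds of double toxicity in single-toxicity space.

    ``doubles`` needs columns ``t1_single``, ``t2_single`` and
    ``toxicity``. For each double, its ``k_neighbors`` nearest neighbours
    (Euclidean in the symmetrized (t1, t2) plane — each double enters with
    both orderings so the surface is symmetric under swapping t1/t2) give
    the local 5th, 50th and 95th percentile of toxicity, returned as
    columns ``p05``, ``p50``, ``p95``.
    """
    need = {"t1_single", "t2_single", "toxicity"}
    if not need <= set(doubles.columns):
        raise ValueError(f"doubles table needs columns {sorted(need)}")
    t1 = doubles["t1_single"].to_numpy(float)
    t2 = doubles["t2_single"].to_numpy(float)
    tox = doubles["toxicity"].to_numpy(float)
    n = len(doubles)
    if k_neighbors > 2 * n:
        raise ValueError(f"k_neighbors={k_neighbors} larger than dataset ({n} doubles)")
    # symmetrize: reference set holds (t1,t2) and (t2,t1) for every double
    ref = np.column_stack([np.r_[t1, t2], np.r_[t2, t1]])
    ref_tox = np.r_[tox, tox]
    nn = NearestNeighbors(n_neighbors=k_neighbors).fit(ref)
    query = np.column_stack([t1, t2])
    out = np.empty((n, 3))
    chunk = 2048
    for s in range(0, n, chunk):
        idx = nn.kneighbors(query[s : s + chunk], return_distance=False)
        vals = ref_tox[idx]
        out[s : s + chunk, 0] = np.percentile(vals, 5, axis=1)
        out[s : s + chunk, 1] = np.percentile(vals, 50, axis=1)
        out[s : s + chunk, 2] = np.percentile(vals, 95, axis=1)
    res = doubles.copy()
    res["p05"], res["p50"], res["p95"] = out[:, 0], out[:, 1], out[:, 2]
    return res


def classify_epistasis(
    surface: pd.DataFrame, *, range_limit_fraction: float = 0.1
) -> pd.Series:
    """Flag doubles as epistatic from their local percentile bounds.

    Doubles whose local median lies within ``range_limit_fraction`` of the
    top or bottom of the observed toxicity range (where the assay
    saturates and power is low) are ``excluded``. Among the rest, toxicity
    below the local 5th percentile is ``negative`` and above the 95th is
    ``positive`` epistasis for growth rate; everything else is ``none``.
    """
    tox = surface["toxicity"].to_numpy(float)
    p05 = surface["p05"].to_numpy(float)
    p50 = surface["p50"].to_numpy(float)
    p95 = surface["p95"].to_numpy(float)
    lo, hi = np.nanmin(tox), np.nanmax(tox)
    span = hi - lo
    excluded = (p50 < lo + range_limit_fraction * span) | (
        p50 > hi - range_limit_fraction * span
    )
    flags = np.full(len(surface), "none", dtype=object)
    flags[tox < p05] = "negative"
    flags[tox > p95] = "positive"
    flags[excluded] = "excluded"
    return pd.Series(flags, index=surface.index, name="epistasis")


# ---------------------------------------------------------------------------
# Enrichment and correlation-score matrices


def pairwise_enrichment(
    doubles: pd.DataFrame, flags: pd.Series, positions=None
) -> tuple[np.ndarray, np.ndarray, tuple[int, ...]]:
    """Log-odds enrichment of epistatic doubles per position pair.

    ``E_ij`` is the Haldane-Anscombe-corrected log odds of a double at
    positions (i, j) being flagged epistatic (positive or negative,
    pooled) versus the odds over all classified doubles. Pairs with no
    classified doubles are NaN (imputed later and logged by the caller).
    Returns ``(E, pair_counts, positions)``.
    """
    keep = flags.isin(["positive", "negative", "none"]).to_numpy()
    sub = doubles.loc[keep]
    hit = flags.loc[keep].isin(["positive", "negative"]).to_numpy()
    p1 = np.array([m[0][0] for m in sub["mutations"]])
    p2 = np.array([m[1][0] for m in sub["mutations"]])
    if positions is None:
        positions = tuple(sorted(set(p1) | set(p2)))
    index = {p: i for i, p in enumerate(positions)}
    n = len(positions)
    a = np.zeros((n, n))
    tot = np.zeros((n, n))
    for x, y, h in zip(p1, p2, hit):
        i, j = index[x], index[y]
        a[i, j] += h
        a[j, i] += h
        tot[i, j] += 1
        tot[j, i] += 1
    A, N = float(hit.sum()), float(hit.size)
    background = np.log((A + 0.5) / (N - A + 0.5))
    with np.errstate(divide="ignore", invalid="ignore"):
        E = np.log((a + 0.5) / (tot - a + 0.5)) - background
    E[tot == 0] = np.nan
    np.fill_diagonal(E, np.nan)
    return E, tot, positions


def impute_diagonal(E: np.ndarray) -> np.ndarray:
    """Impute diagonal entries as column-wise means (excluding the diagonal).

    Off-diagonal NaNs (pairs with no doubles) are first imputed as column
    means as well, then the diagonal is set to the column mean of the
    completed off-diagonal entries. Symmetry is preserved for symmetric
    input.
    """
    E = E.copy()
    n = E.shape[0]
    off = ~np.eye(n, dtype=bool)
    col_mean = np.nanmean(np.where(off, E, np.nan), axis=0)
    # off-diagonal missing pairs: mean of the two column means keeps symmetry
    miss = np.isnan(E) & off
    if miss.any():
        fill = (col_mean[None, :] + col_mean[:, None]) / 2.0
        E[miss] = fill[miss]
        col_mean = np.where(off, E, np.nan)
        col_mean = np.nanmean(col_mean, axis=0)
    np.fill_diagonal(E, col_mean)
    return E


def partial_correlation_from_corr(R: np.ndarray) -> np.ndarray:
    """Exact partial correlations from a (well-conditioned) correlation matrix.

    Precision-matrix scaling: ``C_ij = -P_ij / sqrt(P_ii P_jj)`` with
    ``P = R^-1`` and unit diagonal. For three variables this reduces to
    the textbook formula ``(r_xy - r_xz r_zy) / sqrt((1-r_xz^2)(1-r_zy^2))``.
    """
    R = np.asarray(R, dtype=float)
    if not np.all(np.isfinite(R)):
        raise ValueError("correlation matrix contains non-finite entries")
    P = np.linalg.inv(R)
    d = np.sqrt(np.diag(P))
    C = -P / np.outer(d, d)
    np.fill_diagonal(C, 1.0)
    return np.clip((C + C.T) / 2.0, -1.0, 1.0)


def partial_correlation_matrix(E: np.ndarray, shrinkage="ledoit-wolf") -> np.ndarray:
    """Partial correlations between interaction profiles (columns of E).

    Each pairwise profile correlation is controlled for all remaining
    positions via the precision matrix. Because an n-position enrichment
    matrix gives n profiles of length n, the sample correlation matrix is
    singular by construction and must be regularized before inversion:
    ``shrinkage="ledoit-wolf"`` (default) uses the Ledoit-Wolf shrinkage
    covariance estimator, a float in (0, 1) shrinks the correlation
    matrix linearly toward the identity, and ``None`` inverts the sample
    correlation matrix exactly (only sensible when rows far outnumber
    columns). Entries lie in [-1, 1], unit diagonal, symmetric.
    """
    if not np.all(np.isfinite(E)):
        raise ValueError("enrichment matrix contains non-finite entries")
    if E.shape[0] < 3:
        raise ValueError("need at least 3 positions")
    if shrinkage == "ledoit-wolf":
        from sklearn.covariance import LedoitWolf

        lw = LedoitWolf().fit(np.asarray(E, dtype=float))
        P = lw.precision_
        d = np.sqrt(np.diag(P))
        C = -P / np.outer(d, d)
        np.fill_diagonal(C, 1.0)
        return np.clip((C + C.T) / 2.0, -1.0, 1.0)
    R = np.corrcoef(E, rowvar=False)
    if shrinkage is not None:
        lam = float(shrinkage)
        if not 0.0 < lam < 1.0:
            raise ValueError("shrinkage intensity must be in (0, 1)")
        R = (1.0 - lam) * R + lam * np.eye(R.shape[0])
    return partial_correlation_from_corr(R)


# ---------------------------------------------------------------------------
# Periodicity kernels


def _spacing_autocorrelation(spacings, delta: int) -> int:
    """Coupling partners shared by two positions ``delta`` residues apart.

    For an element whose characteristic coupling spacings are ``spacings``
    (symmetrized to +/- offsets), this counts the offsets at which both
    positions couple to the same third position — the autocorrelation of
    the spacing pattern. It is the similarity signature the element's
    periodicity imprints on a correlation-of-profiles matrix: e.g. the
    helix spacings {3, 4} (period 3.6) make positions 1, 6, 7 and 8 apart
    share partners, the strand spacing {2} (period 2) positions 4 apart.
    """
    S = set(spacings) | {-s for s in spacings}
    return len(S & {s + delta for s in S})


def _periodicity_kernel(spacings, half_window: int, taper_sd: float):
    """Zero-mean matched kernel over a (2w+1)^2 offset window.

    ``K(a, b)`` is the spacing-pattern autocorrelation at offset ``a - b``
    times a Gaussian taper ``w(a) w(b)``, for offsets a != b, centred to
    zero mean so propensities are invariant to adding a constant to the
    correlation matrix.
    """
    offs = np.arange(-half_window, half_window + 1)
    w = np.exp(-0.5 * (offs / taper_sd) ** 2)
    A, B = np.meshgrid(offs, offs, indexing="ij")
    K = np.vectorize(lambda a, b: _spacing_autocorrelation(spacings, a - b))(
        A, B
    ).astype(float)
    K *= np.outer(w, w)
    mask = A != B
    K[~mask] = 0.0
    K[mask] -= K[mask].mean()
    return offs, K, mask


def helix_kernel(half_window: int = 4, taper_sd: float = 10.0):
    """Matched kernel for alpha-helical periodicity (spacings 3 and 4)."""
    return _periodicity_kernel((3, 4), half_window, taper_sd)


def strand_kernel(half_window: int = 4, taper_sd: float = 10.0):
    """Matched kernel for beta-strand periodicity (spacing 2)."""
    return _periodicity_kernel((2,), half_window, taper_sd)


def structure_propensity(
    C: np.ndarray, kernel: str, *, half_window: int = 4, taper_sd: float = 10.0
) -> np.ndarray:
    """Slide a periodicity kernel along the diagonal of C.

    ``propensity(i) = sum_{a != b} K(a, b) * C[i+a, i+b]`` over the offset
    window; positions whose window leaves the matrix are NaN.
    """
    maker = {"helix": helix_kernel, "strand": strand_kernel}
    if kernel not in maker:
        raise ValueError(f"unknown kernel {kernel!r}; use 'helix' or 'strand'")
    offs, K, mask = maker[kernel](half_window, taper_sd)
    n = C.shape[0]
    prop = np.full(n, np.nan)
    w = half_window
    for i in range(w, n - w):
        sub = C[i - w : i + w + 1, i - w : i + w + 1]
        prop[i] = float((K * sub)[mask].sum())
    return prop


def randomization_pvalues(
    C: np.ndarray,
    positions,
    kernels=("helix", "strand"),
    *,
    n_rand: int = 10_000,
    seed: int = 0,
    half_window: int = 4,
    taper_sd: float = 10.0,
) -> dict[str, StructurePropensityTrack]:
    """Empirical p-values from position-label-permuted correlation matrices.

    Rows and columns of C are permuted jointly (preserving symmetry);
    ``p(i) = (1 + #{randomized propensity(i) >= observed(i)}) /
    (n_rand + 1)``, bounded below by ``1/(n_rand + 1)``.
    """
    if n_rand < 100:
        raise ValueError("n_rand must be at least 100")
    rng = np.random.default_rng(seed)
    n = C.shape[0]
    observed = {k: structure_propensity(C, k, half_window=half_window,
                                        taper_sd=taper_sd) for k in kernels}
    exceed = {k: np.zeros(n) for k in kernels}
    for _ in range(n_rand):
        perm = rng.permutation(n)
        Cp = C[np.ix_(perm, perm)]
        for k in kernels:
            rand_prop = structure_propensity(
                Cp, k, half_window=half_window, taper_sd=taper_sd
            )
            with np.errstate(invalid="ignore"):
                exceed[k] += (rand_prop >= observed[k]).astype(float)
    tracks = {}
    for k in kernels:
        p = (1.0 + exceed[k]) / (n_rand + 1.0)
        p[~np.isfinite(observed[k])] = np.nan
        tracks[k] = StructurePropensityTrack(
            positions=tuple(positions),
            kernel=k,
            propensity=observed[k],
            pvalue=p,
            n_randomizations=n_rand,
            seed=seed,
        )
    return tracks


# ---------------------------------------------------------------------------
# Contact maps and LARKS propensity

_BACKBONE = {"N", "CA", "C", "O", "OXT"}


def pdb_contact_map(
    structure_file,
    chain: str,
    residue_range: tuple[int, int],
    threshold: float = 4.5,
) -> ContactMap:
    """Side-chain heavy-atom contact map of a PDB structure.

    Two residues are in contact if the minimal distance between their
    side-chain heavy atoms is at most ``threshold`` Angstrom (glycine
    falls back to its C-alpha). The binary matrix has zero diagonal and is
    normalized to zero sum by subtracting the off-diagonal mean from all
    off-diagonal entries. Missing residues in the range raise an error
    naming them.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("ref", str(structure_file))
    model = next(structure.get_models())
    if chain not in [c.id for c in model]:
        raise ValueError(f"chain {chain!r} not in structure")
    residues = {}
    for res in model[chain]:
        if res.id[0] != " ":
            continue
        residues[res.id[1]] = res
    lo, hi = residue_range
    wanted = list(range(lo, hi + 1))
    missing = [p for p in wanted if p not in residues]
    if missing:
        raise ValueError(f"residues missing from structure: {missing}")

    coords = []
    for p in wanted:
        res = residues[p]
        side = [
            a.coord
            for a in res.get_atoms()
            if a.element != "H" and a.get_name() not in _BACKBONE
        ]
        if not side:  # glycine
            side = [res["CA"].coord]
        coords.append(np.asarray(side))

    n = len(wanted)
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = np.linalg.norm(
                coords[i][:, None, :] - coords[j][None, :, :], axis=-1
            ).min()
            if d <= threshold:
                M[i, j] = M[j, i] = 1.0
    off = ~np.eye(n, dtype=bool)
    M[off] -= M[off].mean()
    return ContactMap(
        positions=tuple(wanted),
        matrix=M,
        threshold=threshold,
        source=str(structure_file),
    )


def larks_propensity(
    C: np.ndarray,
    positions,
    contact_map: ContactMap,
    *,
    n_rand: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Association between epistasis correlations and a reference contact map.

    The correlation-score submatrix over the contact map's residue window
    is standardized (off-diagonal mean 0, unit variance) and multiplied
    elementwise with the zero-sum contact matrix; the association score is
    the sum. Significance by randomization restricted to within-window
    interactions: window labels are permuted ``n_rand`` times. Returns
    ``(score, p_value)``.
    """
    pos_index = {p: i for i, p in enumerate(positions)}
    try:
        idx = [pos_index[p] for p in contact_map.positions]
    except KeyError as exc:
        raise ValueError(f"contact map position {exc} outside coverage") from exc
    sub = C[np.ix_(idx, idx)].copy()
    n = len(idx)
    off = ~np.eye(n, dtype=bool)
    vals = sub[off]
    sd = vals.std()
    if sd == 0:
        raise ValueError("degenerate correlation submatrix")
    sub[off] = (vals - vals.mean()) / sd
    np.fill_diagonal(sub, 0.0)

    def score_of(mat):
        return float((mat * contact_map.matrix)[off].sum())

    observed = score_of(sub)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_rand):
        perm = rng.permutation(n)
        if score_of(sub[np.ix_(perm, perm)]) >= observed:
            exceed += 1
    return observed, (1.0 + exceed) / (n_rand + 1.0)


def top_contacts(
    C: np.ndarray, positions, region: tuple[int, int], k: int = 7
) -> list[tuple[int, int, float]]:
    """The k largest off-diagonal correlation scores within a region.

    Pairs from the upper triangle only (each reported once), ranked by
    score descending with ties broken by smaller first then second
    position. ``k=0`` gives an empty list; if fewer pairs exist than
    ``k``, all are returned.
    """
    lo, hi = region
    idx = [i for i, p in enumerate(positions) if lo <= p <= hi]
    if not idx:
        raise ValueError(f"region {region} outside covered positions")
    pairs = []
    for ii, i in enumerate(idx):
        for j in idx[ii + 1 :]:
            pairs.append((positions[i], positions[j], float(C[i, j])))
    pairs.sort(key=lambda t: (-t[2], t[0], t[1]))
    return pairs[: max(0, k)]


# ---------------------------------------------------------------------------
# Convenience pipeline


def epistasis_pipeline(
    doubles: pd.DataFrame,
    *,
    k_neighbors: int = 1000,
    range_limit_fraction: float = 0.1,
) -> tuple[EpistasisMatrices, pd.Series]:
    """Doubles table -> (matrices, per-double epistasis flags)."""
    surface = expected_double_surface(doubles, k_neighbors=k_neighbors)
    flags = classify_epistasis(surface, range_limit_fraction=range_limit_fraction)
    E, counts, positions = pairwise_enrichment(doubles, flags)
    E = impute_diagonal(E)
    C = partial_correlation_matrix(E)
    return (
        EpistasisMatrices(
            positions=positions, enrichment=E, correlation=C, pair_counts=counts
        ),
        flags,
    )
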