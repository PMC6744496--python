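"""Synthetic doped-library DMS experiments with known ground truth.

This module generates complete, realistic deep-mutational-scanning count
tables for a doped-oligonucleotide library so every downstream stage of
the analysis (aggregation, toxicity estimation, epistasis-based structure
inference) can be validated against a planted truth:

* :func:`simulate_doped_library` draws library molecules with independent
  per-nucleotide doping errors (Binomial(L, rate) mutations per molecule).
* :class:`GroundTruthLandscape` holds a planted toxicity landscape —
  hydrophobicity-driven single-mutant effects with a hotspot amplification
  and a tri-modal effect mixture — plus pairwise epistatic couplings.
* :func:`simulate_selection` grows the library in silico (exponential
  competition, per-generation growth-rate deficit equal to the variant's
  toxicity) and samples sequencing reads Poisson-distributed around the
  expected frequencies for every input/output sample.
* :func:`inject_misreads` corrupts reads with per-base sequencing errors.
* :func:`plant_epistatic_structure` adds periodic couplings (spacing 3-4
  for an alpha-helix, spacing 2 for a beta-strand) for structure-recovery
  experiments.

All randomness flows through one `numpy` generator per operation, seeded
explicitly; the same seed reproduces counts bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import LibraryDesign
from .variant_table import translate_nt, aa_mutations

__all__ = [
    "GroundTruthLandscape",
    "make_landscape",
    "assign_true_toxicity",
    "simulate_doped_library",
    "simulate_selection",
    "inject_misreads",
    "plant_epistatic_structure",
    "simulate_experiment",
    "sample_columns",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# Kyte-Doolittle hydropathy, used by the generative single-mutant model.
_KD = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}
_AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class GroundTruthLandscape:
    """Planted toxicity landscape over one library window.

    Toxicity is the growth-rate deficit per generation in natural-log
    units: a variant with toxicity ``t`` multiplies its frequency by
    ``exp(-t)`` relative to wild type each generation. Wild type has
    toxicity 0 by construction.

    ``single_effects`` maps ``(position, mutant_aa)`` to the effect of
    that substitution; ``couplings`` maps unordered position pairs
    ``(i, j)`` (i < j) to an additive epistatic term applied to doubles
    mutated at both positions. STOP-containing variants get the fixed
    ``stop_toxicity`` regardless of position.
    """

    design: LibraryDesign
    single_effects: Mapping[tuple[int, str], float]
    couplings: Mapping[tuple[int, int], float] = field(default_factory=dict)
    stop_toxicity: float = -0.3
    hotspot: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        pos_ok = self.design.positions
        for (i, j) in self.couplings:
            if i not in pos_ok or j not in pos_ok:
                raise ValueError(f"coupling ({i}, {j}) outside mutated region")
            if i >= j:
                raise ValueError("couplings must be keyed (i, j) with i < j")

    def with_couplings(self, couplings) -> "GroundTruthLandscape":
        return replace(self, couplings=dict(couplings))


def make_landscape(
    design: LibraryDesign,
    seed: int,
    *,
    hotspot: tuple[int, int] | None = (312, 342),
    hotspot_amplification: float = 2.0,
    hydrophobicity_coef: float = 0.03,
    mode_locations: tuple[float, float, float] = (-0.15, 0.0, 0.2),
    mode_weights: tuple[float, float, float] = (0.3, 0.4, 0.3),
    effect_noise_sd: float = 0.05,
    stop_toxicity: float = -0.3,
) -> GroundTruthLandscape:
    """Draw a hydrophobicity-dependent, hotspot-localized toxicity landscape.

    Each substitution effect is ``amp(pos) * (beta * (KD_wt - KD_mut) +
    mode + noise)`` where ``mode`` is drawn from a three-component mixture
    (less-toxic / neutral / more-toxic), producing the tri-modal marginal
    toxicity distribution characteristic of doped PRD libraries, and
    ``amp`` amplifies positions inside the hotspot interval. Mutations
    that increase hydrophobicity (KD_mut > KD_wt) lower toxicity.
    """
    rng = np.random.default_rng(seed)
    if hotspot is not None:
        lo, hi = hotspot
        if lo > hi:
            raise ValueError("hotspot interval reversed")
    effects: dict[tuple[int, str], float] = {}
    for pos in design.positions:
        wt = design.wt_aa(pos)
        amp = 1.0
        if hotspot is not None and hotspot[0] <= pos <= hotspot[1]:
            amp = hotspot_amplification
        for mut in _AA20:
            if mut == wt:
                continue
            mode = rng.choice(mode_locations, p=mode_weights)
            base = (
                hydrophobicity_coef * (_KD[wt] - _KD[mut])
                + mode
                + rng.normal(0.0, effect_noise_sd)
            )
            effects[(pos, mut)] = amp * base
    return GroundTruthLandscape(
        design=design,
        single_effects=effects,
        stop_toxicity=stop_toxicity,
        hotspot=hotspot,
    )


def assign_true_toxicity(
    mutations: Sequence[tuple[int, str]],
    landscape: GroundTruthLandscape,
) -> float:
    """True toxicity of an amino-acid variant given the planted landscape.

    ``mutations`` is a list of ``(position, mutant_aa)`` pairs or
    ``(position, wt_aa, mutant_aa)`` triples; the empty list is wild type
    (toxicity 0). Additive over single effects, plus the planted coupling
    term for mutated position pairs. A premature STOP anywhere returns the
    landscape's fixed STOP-class toxicity.
    """
    mutations = [(m[0], m[-1]) for m in mutations]
    if any(m == "*" for _, m in mutations):
        return landscape.stop_toxicity
    total = 0.0
    positions = []
    for pos, mut in mutations:
        if pos not in landscape.design.positions:
            raise ValueError(f"position {pos} outside mutated region")
        total += landscape.single_effects[(pos, mut)]
        positions.append(pos)
    for a in range(len(positions)):
        for b in range(a + 1, len(positions)):
            i, j = sorted((positions[a], positions[b]))
            total += landscape.couplings.get((i, j), 0.0)
    return total


def plant_epistatic_structure(
    landscape: GroundTruthLandscape,
    element: str,
    positions: tuple[int, int],
    strength: float,
) -> GroundTruthLandscape:
    """Add secondary-structure-like periodic couplings to a landscape.

    ``element`` is ``"helix"`` (couplings at residue spacings 3 and 4, the
    alpha-helical periodicity of 3.6) or ``"strand"`` (spacing 2, the
    alternating side-chain orientation of a beta-strand). Couplings are
    added for every position pair with the element's spacing whose ends
    both lie in the closed interval ``positions``; all other pairs are
    untouched. ``strength=0`` is a no-op.
    """
    spacings = {"helix": (3, 4), "strand": (2,)}
    if element not in spacings:
        raise ValueError(f"unknown element {element!r}; use 'helix' or 'strand'")
    lo, hi = positions
    region = landscape.design.positions
    if lo not in region or hi not in region or lo > hi:
        raise ValueError(f"interval {positions} not inside mutated region")
    new = dict(landscape.couplings)
    if strength != 0.0:
        for i in range(lo, hi + 1):
            for d in spacings[element]:
                j = i + d
                if j <= hi:
                    new[(i, j)] = new.get((i, j), 0.0) + strength
    return landscape.with_couplings(new)


# ---------------------------------------------------------------------------
# Library synthesis


def simulate_doped_library(
    design: LibraryDesign, n_molecules: int, seed: int
) -> pd.DataFrame:
    """Draw a doped library: molecules with independent per-base errors.

    Each of ``n_molecules`` molecules mutates each of the L nucleotide
    positions independently with probability ``design.doping_rate``,
    uniformly among the three alternative bases, so the number of changes
    per molecule is Binomial(L, rate). Returns a DataFrame with columns
    ``nt_seq`` and ``count`` (one row per distinct sequence, counts summing
    to ``n_molecules``).
    """
    if n_molecules <= 0:
        raise ValueError("n_molecules must be positive")
    rng = np.random.default_rng(seed)
    L = design.length_nt
    rate = design.doping_rate
    wt_bytes = np.frombuffer(design.wt_nt_seq.encode(), dtype="S1")
    wt_idx = np.searchsorted(_BASES, wt_bytes)  # A<C<G<T, sorted already

    n_mut = rng.binomial(L, rate, size=n_molecules)
    counts: dict[tuple[tuple[int, int], ...], int] = {}
    n_wt = int((n_mut == 0).sum())
    if n_wt:
        counts[()] = n_wt

    for k in range(1, int(n_mut.max()) + 1):
        m = int((n_mut == k).sum())
        if m == 0:
            continue
        # distinct positions per molecule by vectorized rejection
        pos = rng.integers(0, L, size=(m, k))
        if k > 1:
            while True:
                srt = np.sort(pos, axis=1)
                bad = (np.diff(srt, axis=1) == 0).any(axis=1)
                if not bad.any():
                    pos = srt
                    break
                pos[bad] = rng.integers(0, L, size=(int(bad.sum()), k))
        # new base: offset 1..3 from WT base, mod 4
        off = rng.integers(1, 4, size=(m, k))
        newb = (wt_idx[pos] + off) % 4
        for row_pos, row_b in zip(pos, newb):
            key = tuple(zip(row_pos.tolist(), row_b.tolist()))
            counts[key] = counts.get(key, 0) + 1

    seqs = np.empty(len(counts), dtype=object)
    vals = np.empty(len(counts), dtype=np.int64)
    for idx, (key, c) in enumerate(counts.items()):
        if key:
            arr = wt_bytes.copy()
            for p, b in key:
                arr[p] = _BASES[b]
            seqs[idx] = arr.tobytes().decode()
        else:
            seqs[idx] = design.wt_nt_seq
        vals[idx] = c
    out = pd.DataFrame({"nt_seq": seqs, "count": vals})
    return out.sort_values("count", ascending=False, ignore_index=True)


def sample_columns(design: LibraryDesign) -> list[str]:
    """Sample column names: input{r} then output{r}{a,b,...} per replicate."""
    cols = []
    letters = "abcdefgh"
    for r in range(1, design.n_replicates + 1):
        cols.append(f"input{r}")
    for r in range(1, design.n_replicates + 1):
        for o in range(design.n_output_per_replicate):
            cols.append(f"output{r}{letters[o]}")
    return cols


def true_toxicity_table(
    nt_seqs: Iterable[str], landscape: GroundTruthLandscape
) -> tuple[np.ndarray, np.ndarray]:
    """True toxicity and protein-class index per nucleotide sequence.

    Returns ``(toxicity, aa_class)`` where ``aa_class`` assigns one
    integer per distinct translated amino-acid sequence (so callers can
    apply protein-level effects coherently across synonymous variants).
    """
    design = landscape.design
    wt_aa = design.wt_aa_seq
    cache: dict[str, tuple[int, float]] = {}
    tox = []
    cls = []
    for nt in nt_seqs:
        aa = translate_nt(nt)
        hit = cache.get(aa)
        if hit is None:
            muts = aa_mutations(aa, wt_aa, design.region_start)
            hit = (len(cache), assign_true_toxicity(muts, landscape))
            cache[aa] = hit
        cls.append(hit[0])
        tox.append(hit[1])
    return np.asarray(tox, dtype=float), np.asarray(cls, dtype=np.int64)


def simulate_selection(
    input_counts: pd.DataFrame,
    landscape: GroundTruthLandscape,
    design: LibraryDesign,
    seed: int,
    *,
    depth: float = 5_000_000,
    replicate_noise_sd: float = 0.01,
) -> pd.DataFrame:
    """Grow the library through selection and sequence every sample.

    The library composition ``input_counts`` (columns ``nt_seq``,
    ``count``) defines pre-selection frequencies. Each replicate grows for
    its design-specified number of generations; a variant with toxicity
    ``t`` changes frequency in proportion to ``exp(-(t + eta) * G)`` where
    ``eta ~ N(0, replicate_noise_sd)`` is a per-replicate biological
    noise term drawn once per protein (amino-acid) variant, shared by
    its synonymous codon variants and by the replicate's output
    cultures. Because toxicity is a contrast against wild type, ``eta``
    is expressed directly in that contrast: the WT sequence has
    ``eta = 0`` (a common-mode shift of the reference would be
    unidentifiable from relative frequencies). Read counts for each
    sample
    (one input and ``n_output_per_replicate`` outputs per replicate) are
    independent Poisson draws with mean ``depth`` times the sample's
    expected frequency.

    Returns the count table with one column per sample (see
    :func:`sample_columns`) alongside ``nt_seq``.
    """
    if any(g < 0 for g in design.generations):
        raise ValueError("generations must be non-negative")
    if (input_counts["count"] < 0).any():
        raise ValueError("input counts must be non-negative")
    rng = np.random.default_rng(seed)
    nt = input_counts["nt_seq"].to_numpy()
    f0 = input_counts["count"].to_numpy(dtype=float)
    f0 = f0 / f0.sum()
    tox, aa_class = true_toxicity_table(nt, landscape)
    # biological-noise units mirror the downstream aggregation records:
    # one per amino-acid variant, but silent/WT sequences (which stay at
    # nucleotide resolution) each get their own unit
    wt_class = aa_class[
        np.flatnonzero(nt == design.wt_nt_seq)[0]
    ] if (nt == design.wt_nt_seq).any() else -1
    unit = aa_class.copy()
    next_id = int(aa_class.max()) + 1
    for i in np.flatnonzero(aa_class == wt_class):
        unit[i] = next_id
        next_id += 1
    n_classes = next_id

    out = pd.DataFrame({"nt_seq": nt})
    letters = "abcdefgh"
    for r in range(design.n_replicates):
        out[f"input{r + 1}"] = rng.poisson(depth * f0)
    for r in range(design.n_replicates):
        G = design.generations[r]
        eta_units = rng.normal(0.0, replicate_noise_sd, size=n_classes)
        eta = eta_units[unit]
        eta[nt == design.wt_nt_seq] = 0.0
        w = f0 * np.exp(-(tox + eta) * G)
        w /= w.sum()
        for o in range(design.n_output_per_replicate):
            out[f"output{r + 1}{letters[o]}"] = rng.poisson(depth * w)
    return out


# ---------------------------------------------------------------------------
# Sequencing misreads


def _n_misread_positions(L: int, rate: float, size: int, rng) -> np.ndarray:
    """Sample Binomial(L, rate) conditioned on >= 1 for corrupted reads."""
    kmax = max(4, int(stats.binom.ppf(1 - 1e-12, L, rate)))
    ks = np.arange(1, kmax + 1)
    pmf = stats.binom.pmf(ks, L, rate)
    pmf /= pmf.sum()
    return rng.choice(ks, size=size, p=pmf)


def inject_misreads(
    count_table: pd.DataFrame,
    per_base_misread_rate: float,
    seed: int,
) -> pd.DataFrame:
    """Corrupt sequencing reads with independent per-base call errors.

    Every read in every count column is misread at Binomial(L, rate)
    positions (independently, uniform among the three wrong bases);
    corrupted reads are re-counted under the sequence they appear to be.
    Totals per sample are conserved exactly. ``rate=0`` returns the table
    unchanged (as a copy).
    """
    if not 0.0 <= per_base_misread_rate < 1.0:
        raise ValueError("per_base_misread_rate must be in [0, 1)")
    table = count_table.reset_index(drop=True)
    if per_base_misread_rate == 0.0:
        return table.copy()
    rng = np.random.default_rng(seed)
    nt = table["nt_seq"].to_numpy()
    L = len(nt[0])
    p_corrupt = 1.0 - (1.0 - per_base_misread_rate) ** L
    count_cols = [c for c in table.columns if c != "nt_seq"]

    new_cols = {}
    extra_rows: dict[str, dict[str, int]] = {}
    for col in count_cols:
        counts = table[col].to_numpy(dtype=np.int64).copy()
        k_corrupt = rng.binomial(counts, p_corrupt)
        counts -= k_corrupt
        total_bad = int(k_corrupt.sum())
        if total_bad:
            n_pos = _n_misread_positions(L, per_base_misread_rate, total_bad, rng)
            read_src = np.repeat(np.arange(len(nt)), k_corrupt)
            seq_index = {s: i for i, s in enumerate(nt)}
            cursor = 0
            for src, m in zip(read_src, n_pos):
                arr = bytearray(nt[src], "ascii")
                pos = rng.choice(L, size=int(m), replace=False)
                for p in pos:
                    old = arr[p]
                    choices = [b for b in b"ACGT" if b != old]
                    arr[p] = choices[rng.integers(0, 3)]
                s = arr.decode()
                j = seq_index.get(s)
                if j is not None:
                    counts[j] += 1
                else:
                    extra_rows.setdefault(s, {})[col] = (
                        extra_rows.get(s, {}).get(col, 0) + 1
                    )
                cursor += 1
        new_cols[col] = counts
    out = pd.DataFrame({"nt_seq": nt, **new_cols})
    if extra_rows:
        add = pd.DataFrame(
            [{"nt_seq": s, **cols} for s, cols in extra_rows.items()]
        ).fillna(0)
        for col in count_cols:
            if col not in add.columns:
                add[col] = 0
            add[col] = add[col].astype(np.int64)
        out = pd.concat([out, add[out.columns]], ignore_index=True)
    return out


# ---------------------------------------------------------------------------
# End-to-end convenience


def simulate_experiment(
    design: LibraryDesign,
    landscape: GroundTruthLandscape,
    *,
    n_molecules: int = 200_000,
    depth: float = 5_000_000,
    seed: int = 0,
    misreads: bool = True,
    replicate_noise_sd: float = 0.01,
) -> pd.DataFrame:
    """Full simulated experiment: library -> selection -> (misreads).

    Returns a DiMSum-style nucleotide count table (``nt_seq`` + one column
    per sample). Seeds for the three stages are derived from ``seed`` via
    `numpy`'s SeedSequence spawning, so a single integer reproduces the
    whole experiment.
    """
    child = np.random.SeedSequence(seed).spawn(3)
    lib = simulate_doped_library(
        design, n_molecules, seed=child[0].generate_state(1)[0] % (2**31)
    )
    counts = simulate_selection(
        lib, landscape, design,
        seed=child[1].generate_state(1)[0] % (2**31),
        depth=depth, replicate_noise_sd=replicate_noise_sd,
    )
    if misreads and design.per_base_misread_rate > 0:
        counts = inject_misreads(
            counts, design.per_base_misread_rate,
            seed=child[2].generate_state(1)[0] % (2**31),
        )
    return counts
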