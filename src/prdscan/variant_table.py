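"""Amino-acid-level variant tables: aggregation, filtering, library QC.

Nucleotide-level count tables are translated and aggregated to amino-acid
variants, the study's confidence filters are applied (at most two AA
changes, no synonymous change in other codons, mean input coverage of at
least ten reads), and the small closed-form quantities describing the
doped-library variant space and the impact of sequencing misreads are
computed.

Variant tables are plain :class:`pandas.DataFrame` objects with one row
per amino-acid variant class and the columns

``aa_seq, mutations, n_aa_mut, is_wt, is_silent, is_stop, has_extra_syn``

followed by one integer count column per sequencing sample. ``mutations``
is a tuple of ``(position, wt_aa, mut_aa)`` triples in 1-based
full-protein coordinates. Silent variants (nucleotide changes only) are a
labeled class distinct from the exact-WT sequence; they later centre the
toxicity scale. STOP-containing variants are kept as a class of their own
for cross-library scaling but are excluded from single/double analyses.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .design import LibraryDesign

__all__ = [
    "translate_nt",
    "aa_mutations",
    "translate_and_aggregate",
    "filter_variants",
    "correct_misread_inflow",
    "estimate_misread_probability",
    "count_double_nt_space",
    "misread_double_inflation",
    "write_counts_tsv",
    "read_counts_tsv",
]

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
_CODON2AA = dict(_STANDARD.forward_table)
for stop in _STANDARD.stop_codons:
    _CODON2AA[stop] = "*"


def translate_nt(nt_seq: str) -> str:
    """Translate an in-frame nucleotide sequence (standard code, ``*`` = STOP)."""
    if len(nt_seq) % 3 != 0:
        raise ValueError(f"sequence length {len(nt_seq)} not divisible by 3")
    return "".join(_CODON2AA[nt_seq[i : i + 3]] for i in range(0, len(nt_seq), 3))


def aa_mutations(aa_seq: str, wt_aa_seq: str, region_start: int):
    """List ``(position, wt_aa, mut_aa)`` differences in full-protein coordinates."""
    if len(aa_seq) != len(wt_aa_seq):
        raise ValueError("sequence length mismatch")
    return tuple(
        (region_start + i, w, m)
        for i, (w, m) in enumerate(zip(wt_aa_seq, aa_seq))
        if w != m
    )


def translate_and_aggregate(
    nt_count_table: pd.DataFrame, design: LibraryDesign
) -> pd.DataFrame:
    """Aggregate nucleotide-variant counts to amino-acid variant classes.

    Counts of all nucleotide variants translating to the same amino-acid
    sequence are summed per sample. Because the downstream filters need
    them separated, sequences additionally carrying a synonymous change in
    a codon other than the mutated ones (``has_extra_syn``) are aggregated
    apart from clean variants with the same amino-acid sequence. Purely
    synonymous (silent) variants are kept one record per nucleotide
    sequence — they are distinct library members whose spread later
    centres the toxicity scale. Read totals per sample are conserved
    exactly.
    """
    wt_nt = design.wt_nt_seq
    wt_aa = design.wt_aa_seq
    L = design.length_nt
    count_cols = [c for c in nt_count_table.columns if c != "nt_seq"]

    rows: dict[tuple, np.ndarray] = {}
    meta: dict[tuple, dict] = {}
    counts_matrix = nt_count_table[count_cols].to_numpy(dtype=np.int64)
    for idx, nt in enumerate(nt_count_table["nt_seq"].to_numpy()):
        if len(nt) != L:
            raise ValueError(f"sequence of length {len(nt)}, expected {L}")
        aa = translate_nt(nt)
        is_wt_nt = nt == wt_nt
        muts = aa_mutations(aa, wt_aa, design.region_start)
        n_aa_mut = len(muts)
        n_codon_mut = sum(
            nt[3 * c : 3 * c + 3] != wt_nt[3 * c : 3 * c + 3]
            for c in range(L // 3)
        )
        # synonymous change in a codon that did not change at the AA level
        has_extra_syn = False
        if n_aa_mut > 0 and not is_wt_nt:
            mut_codons = {p - design.region_start for p, _, _ in muts}
            for c in range(L // 3):
                if c in mut_codons:
                    continue
                if nt[3 * c : 3 * c + 3] != wt_nt[3 * c : 3 * c + 3]:
                    has_extra_syn = True
                    break
        is_silent = n_aa_mut == 0 and not is_wt_nt
        # silent variants stay at nucleotide resolution: they provide the
        # distribution that later centres the toxicity scale
        key = (aa, is_wt_nt, is_silent, has_extra_syn, nt if is_silent else None)
        if key in rows:
            rows[key] += counts_matrix[idx]
        else:
            rows[key] = counts_matrix[idx].copy()
            meta[key] = {
                "aa_seq": aa,
                "mutations": muts,
                "n_aa_mut": n_aa_mut,
                "n_codon_mut": n_codon_mut,
                "is_wt": is_wt_nt,
                "is_silent": is_silent,
                "is_stop": "*" in aa,
                "has_extra_syn": has_extra_syn,
            }

    records = []
    for key, counts in rows.items():
        rec = dict(meta[key])
        rec.update(zip(count_cols, counts.tolist()))
        records.append(rec)
    out = pd.DataFrame.from_records(records)
    order = ["aa_seq", "mutations", "n_aa_mut", "n_codon_mut", "is_wt",
             "is_silent", "is_stop", "has_extra_syn"] + count_cols
    return out[order].sort_values(
        ["n_aa_mut", "aa_seq"], ignore_index=True, kind="stable"
    )


def filter_variants(
    records: pd.DataFrame, min_mean_input: float = 10.0
) -> tuple[pd.DataFrame, dict]:
    """Apply the study's confidence filters to an aggregated variant table.

    Retains variants with at most two amino-acid mutations, no synonymous
    change co-occurring in other codons, and a mean input read count of at
    least ``min_mean_input`` (boundary inclusive; the mean is taken over
    all input sample columns). The WT and silent classes are exempt from
    the mutation-count rule but not from the coverage rule. Returns the
    filtered table and a log with per-rule removal counts; the filter is
    idempotent.
    """
    input_cols = [c for c in records.columns if c.startswith("input")]
    if not input_cols:
        raise ValueError("no input count columns found")
    mean_input = records[input_cols].to_numpy(dtype=float).mean(axis=1)

    too_many = (records["n_aa_mut"] > 2).to_numpy()
    extra_syn = records["has_extra_syn"].to_numpy(dtype=bool)
    low_cov = mean_input < float(min_mean_input)
    keep = ~(too_many | extra_syn | low_cov)

    log = {
        "n_input": int(len(records)),
        "removed_gt2_aa_mut": int(too_many.sum()),
        "removed_extra_synonymous": int(extra_syn.sum()),
        "removed_low_input": int(low_cov.sum()),
        "n_retained": int(keep.sum()),
        "min_mean_input": float(min_mean_input),
    }
    return records.loc[keep].reset_index(drop=True), log


def estimate_misread_probability(
    flank_per_base_error: float, region_length: int
) -> float:
    """Per-read probability of at least one misread over the doped region.

    The per-base error rate, measured on the constant flanking sequence,
    times the length of the doped region (the linear small-rate
    approximation used for library QC). Raises if the product reaches 1,
    where the approximation breaks down.
    """
    if not 0.0 <= flank_per_base_error < 1.0:
        raise ValueError("per-base error must be in [0, 1)")
    p = flank_per_base_error * region_length
    if p >= 1.0:
        raise ValueError(
            f"misread probability {p:.3g} >= 1; linear approximation invalid"
        )
    return p


def count_double_nt_space(region_length: int) -> tuple[int, int]:
    """Size of the double-nucleotide variant space of a doped region.

    Returns ``(C(L, 2), C(L, 2) * 9)``: the number of position pairs and,
    with three alternative bases at each of the two positions, the number
    of distinct double-nucleotide variants.
    """
    if region_length < 2:
        raise ValueError("region_length must be >= 2")
    pairs = comb(region_length, 2)
    return pairs, pairs * 9


def misread_double_inflation(
    single_read_total: float, misread_prob: float, n_double_variants: int
) -> float:
    """Expected extra counts per double variant due to misread singles.

    Of the observed single-nucleotide reads, a fraction
    ``misread_prob / (1 - misread_prob)`` are estimated to be misreads; in
    the worst case all of them land uniformly on the possible
    double-nucleotide variants.
    """
    if not 0.0 <= misread_prob < 1.0:
        raise ValueError("misread_prob must be in [0, 1)")
    extra = misread_prob / (1.0 - misread_prob) * single_read_total
    return extra / n_double_variants


def correct_misread_inflow(
    nt_count_table: pd.DataFrame, design: LibraryDesign
) -> pd.DataFrame:
    """Subtract the expected misread inflow from WT into its 1-nt neighbours.

    A read of the (dominant) WT sequence is misread as one *specific*
    single-nucleotide neighbour with probability ``rate / 3`` per base
    call, so every variant one nucleotide away from WT picks up
    ``n_WT * rate / 3`` spurious counts per sample in expectation. This
    removes that expectation (floored at zero). Inflow between mutant
    classes is smaller by the mutant/WT frequency ratio and is left
    uncorrected.
    """
    rate = design.per_base_misread_rate
    df = nt_count_table.reset_index(drop=True).copy()
    if rate == 0.0:
        return df
    wt = design.wt_nt_seq
    nt = df["nt_seq"].to_numpy()
    wt_idx = np.flatnonzero(nt == wt)
    if wt_idx.size == 0:
        return df
    hamming1 = np.array(
        [sum(a != b for a, b in zip(s, wt)) == 1 for s in nt], dtype=bool
    )
    count_cols = [c for c in df.columns if c != "nt_seq"]
    for col in count_cols:
        counts = df[col].to_numpy(dtype=float)
        inflow = counts[wt_idx[0]] * rate / 3.0
        counts[hamming1] = np.maximum(counts[hamming1] - inflow, 0.0)
        df[col] = np.round(counts).astype(np.int64)
    return df


# ---------------------------------------------------------------------------
# DiMSum-style TSV I/O


def write_counts_tsv(table: pd.DataFrame, path, design: LibraryDesign) -> None:
    """Write a nucleotide count table as a DiMSum-style TSV.

    Columns: ``nt_seq, aa_seq, Nham_nt, Nham_aa`` then one column per
    sample.
    """
    wt_nt = design.wt_nt_seq
    wt_aa = design.wt_aa_seq
    out = table.copy()
    aa = [translate_nt(s) for s in out["nt_seq"]]
    out.insert(1, "aa_seq", aa)
    out.insert(2, "Nham_nt",
               [sum(a != b for a, b in zip(s, wt_nt)) for s in out["nt_seq"]])
    out.insert(3, "Nham_aa",
               [sum(a != b for a, b in zip(s, wt_aa)) for s in aa])
    out.to_csv(path, sep="\t", index=False)


def read_counts_tsv(path) -> pd.DataFrame:
    """Read a DiMSum-style TSV back to a nucleotide count table."""
    df = pd.read_csv(path, sep="\t")
    drop = [c for c in ("aa_seq", "Nham_nt", "Nham_aa") if c in df.columns]
    return df.drop(columns=drop)
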