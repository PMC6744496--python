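"""Library designs for doped-oligonucleotide deep mutational scans.

A :class:`LibraryDesign` describes one doped sub-library: the wild-type
nucleotide and amino-acid sequence of the mutagenized window, its
coordinates in full-protein numbering, the per-nucleotide doping rate of
the synthesis, and the replicate/selection structure of the experiment.

The default designs cover the two sub-libraries tiling the prion-like
domain of TDP-43 (amino acids 290-331 and 332-373, 126 nt each, doped at
1.59% per nucleotide, three biological replicates each split into two
output selections grown for 5-6 generations).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "LibraryDesign",
    "TDP43_PRD_290_373",
    "tdp43_library",
    "read_wt_fasta",
    "back_translate",
]

# Human TDP-43 (TARDBP) positions 290-373, the mutagenized prion-like-domain
# window. Anchors: LARKS segment NFGAFS at 312-317, helical segment
# AMMAAAQAAL at 321-330.
TDP43_PRD_290_373 = (
    "GNSRGGGAGLGNNQGSNMGGGMNFGAFSINPAMMAAAQAALQ"  # 290-331
    "SSWGMMGMLASQQNQSGPSGNNQNQGNMQREPNQAFGSGNNS"  # 332-373
)
_PRD_OFFSET = 290

# One codon per amino acid for back-translating a protein window into a
# reference nucleotide sequence (frequent S. cerevisiae codons).
_CODON = {
    "A": "GCT", "R": "AGA", "N": "AAT", "D": "GAT", "C": "TGT",
    "Q": "CAA", "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT",
    "L": "TTG", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCA",
    "S": "TCT", "T": "ACT", "W": "TGG", "Y": "TAT", "V": "GTT",
}

_DNA = set("ACGT")


def back_translate(aa_seq: str) -> str:
    """Back-translate a protein sequence with one fixed codon per residue."""
    try:
        return "".join(_CODON[a] for a in aa_seq)
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"cannot back-translate residue {exc}") from exc


@dataclass(frozen=True)
class LibraryDesign:
    """One doped sub-library and its selection layout.

    Parameters
    ----------
    wt_nt_seq
        Wild-type nucleotide sequence of the doped window (length must be
        three times the protein window).
    region_start, region_end
        1-based first/last amino-acid position of the window in
        full-protein numbering (inclusive).
    doping_rate
        Per-nucleotide probability of an incorrect base during synthesis.
    n_replicates
        Biological replicate selections.
    n_output_per_replicate
        Output cultures sequenced per replicate.
    generations
        Cell doublings during selection, one value per replicate.
    per_base_misread_rate
        Per-base sequencing error probability inside the doped window.
    """

    wt_nt_seq: str
    region_start: int
    region_end: int
    doping_rate: float = 0.0159
    n_replicates: int = 3
    n_output_per_replicate: int = 2
    generations: tuple[float, ...] = (5.0, 5.5, 6.0)
    per_base_misread_rate: float = 1e-4
    name: str = "library"

    def __post_init__(self) -> None:
        if set(self.wt_nt_seq) - _DNA:
            bad = sorted(set(self.wt_nt_seq) - _DNA)
            raise ValueError(f"non-DNA characters in wt_nt_seq: {bad}")
        if len(self.wt_nt_seq) % 3 != 0:
            raise ValueError("wt_nt_seq length must be a multiple of 3")
        if not 0.0 <= self.doping_rate < 1.0:
            raise ValueError("doping_rate must be in [0, 1)")
        if not 0.0 <= self.per_base_misread_rate < 1.0:
            raise ValueError("per_base_misread_rate must be in [0, 1)")
        n_aa = self.region_end - self.region_start + 1
        if len(self.wt_nt_seq) != 3 * n_aa:
            raise ValueError(
                f"window {self.region_start}-{self.region_end} spans {n_aa} "
                f"residues but wt_nt_seq has {len(self.wt_nt_seq)} nt"
            )
        if len(self.generations) != self.n_replicates:
            raise ValueError("need one generations value per replicate")
        if any(g <= 0 for g in self.generations):
            raise ValueError("generations must be positive")

    @property
    def length_nt(self) -> int:
        return len(self.wt_nt_seq)

    @property
    def wt_aa_seq(self) -> str:
        return str(Seq(self.wt_nt_seq).translate())

    @property
    def positions(self) -> range:
        """Full-protein amino-acid positions covered by the window."""
        return range(self.region_start, self.region_end + 1)

    def wt_aa(self, position: int) -> str:
        """Wild-type residue at a full-protein position."""
        if position not in self.positions:
            raise ValueError(
                f"position {position} outside window "
                f"{self.region_start}-{self.region_end}"
            )
        return self.wt_aa_seq[position - self.region_start]

    def with_(self, **kwargs) -> "LibraryDesign":
        """Return a copy with some fields replaced."""
        return replace(self, **kwargs)


def tdp43_library(which: str = "290-331") -> LibraryDesign:
    """Default design for one of the two TDP-43 PRD sub-libraries.

    ``which`` is ``"290-331"`` or ``"332-373"``.
    """
    bounds = {"290-331": (290, 331), "332-373": (332, 373)}
    if which not in bounds:
        raise ValueError(f"unknown sub-library {which!r}; use one of {list(bounds)}")
    start, end = bounds[which]
    aa = TDP43_PRD_290_373[start - _PRD_OFFSET : end - _PRD_OFFSET + 1]
    return LibraryDesign(
        wt_nt_seq=back_translate(aa),
        region_start=start,
        region_end=end,
        name=f"tdp43_{which}",
    )


def read_wt_fasta(path, region_start: int, region_end: int, **kwargs) -> LibraryDesign:
    """Build a design from a FASTA file.

    The record may hold either the nucleotide sequence of the doped window
    or its protein sequence (which is then back-translated).
    """
    record = next(SeqIO.parse(str(path), "fasta"))
    seq = str(record.seq).upper()
    n_aa = region_end - region_start + 1
    if len(seq) == 3 * n_aa and not set(seq) - _DNA:
        nt = seq
    elif len(seq) == n_aa:
        nt = back_translate(seq)
    else:
        raise ValueError(
            f"FASTA record length {len(seq)} matches neither {3 * n_aa} nt "
            f"nor {n_aa} aa for window {region_start}-{region_end}"
        )
    return LibraryDesign(wt_nt_seq=nt, region_start=region_start,
                         region_end=region_end, **kwargs)
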