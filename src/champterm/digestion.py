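"""In-silico protease digestion with missed cleavages.

Three enzymes are modeled:

* LysargiNase — cleaves on the N-terminal side of Lys and Arg, so every
  internal peptide starts with K/R and carries its basic residues at the
  peptide N-terminus (the mirror image of trypsin).
* trypsin — cleaves on the C-terminal side of Lys and Arg.
* V8 protease (Glu-C) — cleaves on the C-terminal side of Asp and Glu.

Cleavage boundaries are between-residue indices: boundary ``i`` sits
between residue ``i`` and residue ``i+1`` (1-based), so valid boundaries
satisfy ``1 <= i < len(sequence)``.  By default proline does not block
cleavage; a configurable flag restores the classical proline exception.

Besides the fully specific digest, a semi-specific "N-terminal free"
expansion is provided: the peptide C-terminus must be enzyme-specific (or
the protein C-terminus) while the N-terminus may fall on any residue.
This is how neo-N-termini — protein starts created by presequence
cleavage, exopeptidase trimming or non-canonical translation initiation —
become visible in a database search.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass

from .proteome_io import ProteinRecord

#: Residues after which the initiator Met is removed by methionine
#: aminopeptidase (small side-chain radius rule).
DEFAULT_IMET_SECOND_RESIDUES = frozenset("ACGPSTV")

DEFAULT_MAX_MISSED = 2
DEFAULT_MIN_LEN = 6
DEFAULT_MAX_LEN = 45

CATEGORIES = ("protein_nt", "protein_ct", "internal", "neo_nt")


@dataclass(frozen=True)
class EnzymeSpec:
    name: str
    residues: frozenset
    side: str  # "n_terminal" or "c_terminal" of the target residue


LYSARGINASE = EnzymeSpec("lysarginase", frozenset("KR"), "n_terminal")
TRYPSIN = EnzymeSpec("trypsin", frozenset("KR"), "c_terminal")
V8 = EnzymeSpec("v8", frozenset("DE"), "c_terminal")

ENZYMES = {e.name: e for e in (LYSARGINASE, TRYPSIN, V8)}


@dataclass
class Peptide:
    """A digest product in 1-based inclusive protein coordinates."""

    accession: str
    start: int
    end: int
    sequence: str
    nt_state: str = "free"
    missed_cleavages: int = 0
    category: str = "internal"

    def __len__(self) -> int:
        return self.end - self.start + 1


def _as_record(protein: ProteinRecord | str) -> ProteinRecord:
    if isinstance(protein, ProteinRecord):
        return protein
    return ProteinRecord(accession="", sequence=protein)


def cleavage_sites(
    sequence: str, enzyme: EnzymeSpec | str, block_proline: bool = False
) -> list[int]:
    """Ordered between-residue cleavage boundaries for an enzyme.

    For an N-terminal-side enzyme the boundary sits before each target
    residue (never at position 0); for a C-terminal-side enzyme it sits
    after each target residue (never past the last residue).
    """
    if isinstance(enzyme, str):
        enzyme = ENZYMES[enzyme]
    n = len(sequence)
    sites = []
    for pos, res in enumerate(sequence, start=1):  # 1-based residue index
        if res not in enzyme.residues:
            continue
        if enzyme.side == "n_terminal":
            if pos == 1:
                continue
            if block_proline and sequence[pos - 2] == "P":
                continue
            sites.append(pos - 1)
        else:
            if pos == n:
                continue
            if block_proline and sequence[pos] == "P":
                continue
            sites.append(pos)
    return sites


def native_starts(
    sequence: str, imet_second_residues: frozenset = DEFAULT_IMET_SECOND_RESIDUES
) -> set:
    """Database-start positions: residue 1 always; residue 2 when the
    initiator Met is removable given the second residue."""
    starts = {1}
    if len(sequence) >= 2 and sequence[0] == "M" and sequence[1] in imet_second_residues:
        starts.add(2)
    return starts


def label_category(
    peptide: Peptide,
    protein: ProteinRecord | str,
    enzyme: EnzymeSpec | str,
    imet_second_residues: frozenset = DEFAULT_IMET_SECOND_RESIDUES,
) -> str:
    """Terminal category of a peptide.

    protein_nt: starts at a native start (residue 1, or residue 2 after
    initiator-Met removal).  protein_ct: ends at the protein C-terminus.
    A start at residue 3 is always a neo-N-terminus (methionine
    aminopeptidase over-cleavage), even if it coincides with an enzyme
    boundary; any other non-native, non-enzyme-specific start is neo_nt,
    and enzyme-specific starts deeper in the protein are internal.
    """
    record = _as_record(protein)
    seq = record.sequence
    if peptide.start in native_starts(seq, imet_second_residues):
        return "protein_nt"
    if peptide.end == len(seq):
        return "protein_ct"
    if peptide.start == 3:
        return "neo_nt"
    sites = set(cleavage_sites(seq, enzyme))
    return "internal" if peptide.start - 1 in sites else "neo_nt"


def _missed_between(sites: list[int], start: int, end: int) -> int:
    """Number of uncut boundaries strictly inside peptide [start, end],
    i.e. boundaries i with start <= i <= end - 1."""
    return bisect_right(sites, end - 1) - bisect_left(sites, start)


def digest(
    protein: ProteinRecord | str,
    enzyme: EnzymeSpec | str,
    max_missed: int = DEFAULT_MAX_MISSED,
    block_proline: bool = False,
    imet_second_residues: frozenset = DEFAULT_IMET_SECOND_RESIDUES,
) -> list[Peptide]:
    """Fully specific digest: every peptide bounded by the protein termini
    or cleavage boundaries, spanning at most ``max_missed`` internal
    boundaries.  The 0-missed peptides tile the protein exactly."""
    record = _as_record(protein)
    seq = record.sequence
    sites = cleavage_sites(seq, enzyme, block_proline)
    edges = [0] + sites + [len(seq)]
    peptides = []
    for a in range(len(edges) - 1):
        for b in range(a + 1, min(a + 2 + max_missed, len(edges))):
            start, end = edges[a] + 1, edges[b]
            pep = Peptide(
                accession=record.accession,
                start=start,
                end=end,
                sequence=seq[start - 1 : end],
                missed_cleavages=b - a - 1,
            )
            pep.category = label_category(pep, record, enzyme, imet_second_residues)
            peptides.append(pep)
    return peptides


def semi_specific_nt_free(
    protein: ProteinRecord | str,
    enzyme: EnzymeSpec | str,
    max_missed: int = DEFAULT_MAX_MISSED,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    block_proline: bool = False,
    imet_second_residues: frozenset = DEFAULT_IMET_SECOND_RESIDUES,
) -> list[Peptide]:
    """Semi-specific "N-terminal free" digest: the C-terminus must be an
    enzyme boundary or the protein C-terminus, the N-terminus may be any
    residue, and lengths are bounded.  The result is a superset of the
    fully specific digest within the same length bounds."""
    if not 1 <= min_len <= max_len:
        raise ValueError("need 1 <= min_len <= max_len")
    record = _as_record(protein)
    seq = record.sequence
    n = len(seq)
    sites = cleavage_sites(seq, enzyme, block_proline)
    ends = sites + [n] if (not sites or sites[-1] != n) else sites
    peptides = []
    for end in ends:
        lo = max(1, end - max_len + 1)
        hi = end - min_len + 1
        for start in range(lo, hi + 1):
            missed = _missed_between(sites, start, end)
            if missed > max_missed:
                continue
            pep = Peptide(
                accession=record.accession,
                start=start,
                end=end,
                sequence=seq[start - 1 : end],
                missed_cleavages=missed,
            )
            pep.category = label_category(pep, record, enzyme, imet_second_residues)
            peptides.append(pep)
    return peptides
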