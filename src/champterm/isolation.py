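"""Charge/orientation retention model and per-method peptide selection.

The three isolation methods share one idea: digest so that non-terminal
peptides carry a retention handle that terminal peptides lack, then keep
the weakly retained material.

* CHAMP-N (LysargiNase digest + SCX at acidic pH).  The peptide charge
  number Z counts the free alpha-amine plus Lys/Arg/His side chains.
  Internal LysargiNase peptides start with K/R, so their two positive
  charges sit adjacent (alpha-amine at position 0, side chain at residue
  1) and are strongly retained.  Selected: Z <= 1, or Z = 2 with the two
  charges at distant positions (e.g. a His deeper in the peptide).
* CHAMP-NC (tryptic digest + SCX).  Selected: Z <= 1, which keeps
  acetylated N-terminal and protein C-terminal peptides; free tryptic
  N-terminal peptides (Z = 2) are lost.
* CHAMP-C (V8 digest + MOLEX on metal oxide).  Non-C-terminal V8 peptides
  end in Asp/Glu and present a dicarboxylate that chelates the metal;
  selected: the C-terminal residue is not D/E.  Protein C-termini ending
  in D/E are an intrinsic blind spot and are flagged as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .digestion import (
    DEFAULT_IMET_SECOND_RESIDUES,
    DEFAULT_MAX_LEN,
    DEFAULT_MIN_LEN,
    ENZYMES,
    Peptide,
    cleavage_sites,
    native_starts,
)
from .proteome_io import ProteinRecord

BASIC_RESIDUES = frozenset("KRH")
ACIDIC_RESIDUES = frozenset("DE")

#: Two charges closer than this many positions count as "in close
#: proximity" (the alpha-amine is position 0, residue side chains are
#: their 1-based peptide positions).
DEFAULT_PROXIMITY_THRESHOLD = 2

METHOD_ENZYMES = {"CHAMP_N": "lysarginase", "CHAMP_NC": "trypsin", "CHAMP_C": "v8"}


@dataclass
class IsolationDecision:
    """Per-peptide verdict of an isolation method."""

    peptide: Peptide
    z: int
    charge_positions: list[int]
    proximal: bool | None
    selected: bool
    reason: str


@dataclass
class CoverageReport:
    """Theoretical per-method terminome coverage over a proteome."""

    method: str
    theoretical_terminal_peptides: int
    detectable_fraction: float
    per_protein: list[dict] = field(default_factory=list)


def charge_z(peptide: Peptide | str, nt_state: str | None = None) -> tuple[int, list[int]]:
    """Charge number at acidic pH and the charge positions.

    Z = (1 for a free alpha-amine) + #Lys + #Arg + #His.  Positions list
    the alpha-amine as 0 and each basic side chain by its 1-based index
    within the peptide.  Acetylation blocks the alpha-amine, so the Z of
    an acetylated peptide is one less than that of its free form.
    """
    if isinstance(peptide, Peptide):
        sequence, state = peptide.sequence, peptide.nt_state
    else:
        sequence, state = peptide, nt_state or "free"
    positions = [0] if state == "free" else []
    positions += [i for i, res in enumerate(sequence, start=1) if res in BASIC_RESIDUES]
    return len(positions), positions


def is_proximal(
    charge_positions: Sequence[int], threshold: int = DEFAULT_PROXIMITY_THRESHOLD
) -> bool:
    """Whether two charges sit in close proximity (|i - j| <= threshold).
    Defined only for exactly two charges."""
    if len(charge_positions) != 2:
        raise ValueError(
            f"is_proximal needs exactly 2 charge positions, got {len(charge_positions)}"
        )
    a, b = charge_positions
    return abs(a - b) <= threshold


def _his_among_side_chains(sequence: str, positions: Sequence[int]) -> bool:
    return any(p > 0 and sequence[p - 1] == "H" for p in positions)


def select_champ_n(
    peptides: Iterable[Peptide],
    proximity_threshold: int = DEFAULT_PROXIMITY_THRESHOLD,
    distant_his_only: bool = False,
) -> list[IsolationDecision]:
    """SCX selection of a LysargiNase digest: keep Z <= 1, and Z = 2 when
    the two charges are distant (optionally only when the extra charge is
    a His side chain).  Z >= 3 is always strongly retained."""
    decisions = []
    for pep in peptides:
        z, positions = charge_z(pep)
        proximal = None
        if z <= 1:
            selected, reason = True, "z_le_1"
        elif z == 2:
            proximal = is_proximal(positions, proximity_threshold)
            ok = not proximal and (
                not distant_his_only or _his_among_side_chains(pep.sequence, positions)
            )
            selected = ok
            reason = "z2_distant" if ok else "z2_proximal"
        else:
            selected, reason = False, "z_ge_3"
        decisions.append(IsolationDecision(pep, z, positions, proximal, selected, reason))
    return decisions


def select_champ_nc(peptides: Iterable[Peptide]) -> list[IsolationDecision]:
    """SCX selection of a tryptic digest: keep Z <= 1 (acetylated
    N-terminal and protein C-terminal peptides); free tryptic N-terminal
    peptides carry Z = 2 and are not isolated."""
    decisions = []
    for pep in peptides:
        z, positions = charge_z(pep)
        selected = z <= 1
        reason = "acetyl_or_ct_plus1" if selected else "z_gt_1"
        decisions.append(IsolationDecision(pep, z, positions, None, selected, reason))
    return decisions


def select_champ_c(peptides: Iterable[Peptide]) -> list[IsolationDecision]:
    """MOLEX selection of a V8 digest: keep peptides whose C-terminal
    residue is not Asp/Glu (a single C-terminal carboxylate retains only
    weakly).  Protein C-terminal peptides ending in D/E are rejected and
    flagged as the method's blind spot.  Selection depends only on the
    C-terminal residue, so missed cleavages do not affect it."""
    decisions = []
    for pep in peptides:
        z, positions = charge_z(pep)
        if pep.sequence[-1] not in ACIDIC_RESIDUES:
            selected, reason = True, "ct_no_acidic_end"
        elif pep.category == "protein_ct":
            selected, reason = False, "blind_spot_acidic_ct"
        else:
            selected, reason = False, "dicarboxylate_chelation"
        decisions.append(IsolationDecision(pep, z, positions, None, selected, reason))
    return decisions


SELECTORS = {
    "CHAMP_N": select_champ_n,
    "CHAMP_NC": select_champ_nc,
    "CHAMP_C": select_champ_c,
}


def select(method: str, peptides: Iterable[Peptide], **kwargs) -> list[IsolationDecision]:
    """Dispatch to the per-method selection rule."""
    return SELECTORS[method](peptides, **kwargs)


def detectable(
    peptide: Peptide | int, min_len: int = DEFAULT_MIN_LEN, max_len: int = DEFAULT_MAX_LEN
) -> bool:
    """Whether a peptide's length falls in the MS-detectable window."""
    n = len(peptide) if isinstance(peptide, Peptide) else peptide
    return min_len <= n <= max_len


def _terminal_peptides_for(
    protein: ProteinRecord,
    enzyme_name: str,
    termini: str,
    imet_second_residues: frozenset,
) -> list[Peptide]:
    """Zero-missed-cleavage terminal peptides of a protein for one enzyme.

    The N-terminal peptide starts at the protein's mature start (residue 2
    when the initiator Met is removed, else residue 1) and runs to the
    first cleavage boundary; its amine state follows the protein's
    Nt-acetylation annotation.  The C-terminal peptide runs from the last
    boundary to the protein end.
    """
    seq = protein.sequence
    n = len(seq)
    sites = cleavage_sites(seq, ENZYMES[enzyme_name])
    peptides = []
    if "N" in termini:
        start = max(native_starts(seq, imet_second_residues))
        end = next((b for b in sites if b >= start), n)
        nt_state = "acetyl" if protein.feature("nt_acetyl") else "free"
        peptides.append(
            Peptide(protein.accession, start, end, seq[start - 1 : end],
                    nt_state=nt_state, category="protein_nt")
        )
    if "C" in termini:
        start = (sites[-1] + 1) if sites else 1
        peptides.append(
            Peptide(protein.accession, start, n, seq[start - 1 :], category="protein_ct")
        )
    return peptides


def theoretical_coverage(
    proteome: Sequence[ProteinRecord],
    method: str,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    proximity_threshold: int = DEFAULT_PROXIMITY_THRESHOLD,
    imet_second_residues: frozenset = DEFAULT_IMET_SECOND_RESIDUES,
) -> CoverageReport:
    """Which protein termini a method could observe, and the fraction of
    terminal peptides with MS-detectable length (the rest are too long or
    too short)."""
    termini = {"CHAMP_N": "N", "CHAMP_NC": "NC", "CHAMP_C": "C"}[method]
    enzyme_name = METHOD_ENZYMES[method]
    kwargs = {"proximity_threshold": proximity_threshold} if method == "CHAMP_N" else {}
    per_protein = []
    n_detectable = 0
    n_total = 0
    for protein in proteome:
        peps = _terminal_peptides_for(protein, enzyme_name, termini, imet_second_residues)
        for pep, dec in zip(peps, SELECTORS[method](peps, **kwargs)):
            ok_len = detectable(pep, min_len, max_len)
            n_total += 1
            n_detectable += ok_len
            per_protein.append(
                {
                    "accession": protein.accession,
                    "terminus": "N" if pep.category == "protein_nt" else "C",
                    "length": len(pep),
                    "selected": dec.selected,
                    "detectable": ok_len,
                    "isolable": dec.selected and ok_len,
                    "reason": dec.reason,
                }
            )
    return CoverageReport(
        method=method,
        theoretical_terminal_peptides=n_total,
        detectable_fraction=(n_detectable / n_total) if n_total else 0.0,
        per_protein=per_protein,
    )
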