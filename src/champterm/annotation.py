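"""Neo-N-terminome annotation.

An identified N-terminal peptide is *native* when it starts at the
database start (residue 1, or residue 2 after initiator-Met removal) and
*neo* otherwise.  Neo-N-termini arise from presequence (signal/transit
peptide) cleavage, exopeptidase trimming, methionine-aminopeptidase
over-cleavage, or non-canonical translation initiation.  This module:

* assigns acetylation classes — Ac-MX (acetylated at a Met), M/Ac-X
  (acetylated at the residue right after a Met, i.e. the Met was
  excised), Other (no Met at or before the acetylated residue);
* matches neo positions to annotated and predicted presequence ends
  (a cleavage at presequence end ``e`` produces a neo start at ``e+1``);
* flags acetylated neo starts whose codon is AUG or a near-cognate
  (one-mismatch) start codon, as alternative translation-initiation
  candidates;
* detects exopeptidase ladders: runs of >= 3 consecutive neo positions
  on one protein, one residue shaved off at a time;
* histograms neo positions (most sit within 50 residues of the native
  N-terminus, with a spike at residue 3).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .digestion import DEFAULT_IMET_SECOND_RESIDUES, native_starts
from .proteome_io import (
    CdsRecord,
    EvidenceEntry,
    NEAR_COGNATE_CODONS,
    PredictedCleavage,
    ProteinRecord,
)

ACETYL_CLASSES = ("Ac_MX", "M_Ac_X", "Other")
MATCH_FLAGS = (
    "uniprot_signal",
    "uniprot_transit",
    "predicted_signal",
    "predicted_transit",
    "near_annotated",
    "unmatched",
)

DEFAULT_RAGGED_WINDOW = 3
DEFAULT_LADDER_MIN_RUN = 3


@dataclass
class NeoNtCall:
    """A distinct identified N-terminal start position on one protein."""

    accession: str
    position: int
    nt_mod: str
    acetyl_class: str = "not_acetylated"
    match_status: set = field(default_factory=set)
    ladder_id: str | None = None

    @property
    def distance_from_native(self) -> int:
        return self.position - 1


@dataclass(frozen=True)
class Ladder:
    """A maximal run of consecutive neo positions on one protein."""

    accession: str
    positions: tuple

    @property
    def length(self) -> int:
        return len(self.positions)


def classify_native_or_neo(
    entry: EvidenceEntry,
    protein: ProteinRecord,
    imet_second_residues: frozenset = DEFAULT_IMET_SECOND_RESIDUES,
) -> str:
    """native if the peptide starts at the database start (allowing
    initiator-Met removal), neo otherwise."""
    return (
        "native"
        if entry.start in native_starts(protein.sequence, imet_second_residues)
        else "neo"
    )


def acetyl_class(position: int, protein: ProteinRecord) -> str:
    """Acetylation class of an Nt-acetylated peptide starting at
    ``position``: Ac_MX if the acetylated residue is Met, M_Ac_X if the
    preceding residue is Met (excised initiator), else Other."""
    seq = protein.sequence
    if seq[position - 1] == "M":
        return "Ac_MX"
    if position >= 2 and seq[position - 2] == "M":
        return "M_Ac_X"
    return "Other"


def second_residue_frequency(
    calls: Iterable[NeoNtCall], proteins: Mapping[str, ProteinRecord]
) -> dict:
    """Amino-acid frequency at the second residue (the one adjacent to the
    initiator Met) of acetylated N-termini, split by whether the iMet is
    present (Ac_MX) or absent (M_Ac_X).  Fractions within each split sum
    to 1."""
    counts = {"imet_present": defaultdict(int), "imet_absent": defaultdict(int)}
    for call in calls:
        seq = proteins[call.accession].sequence
        if call.acetyl_class == "Ac_MX":
            # iMet retained at call.position; the adjacent residue follows it
            if call.position < len(seq):
                counts["imet_present"][seq[call.position]] += 1
        elif call.acetyl_class == "M_Ac_X":
            # iMet excised; the acetylated residue itself was adjacent to it
            counts["imet_absent"][seq[call.position - 1]] += 1
    out = {}
    for split, c in counts.items():
        total = sum(c.values())
        out[split] = {res: c[res] / total for res in sorted(c)} if total else {}
    return out


def match_cleavage(neo_position: int, presequence_end: int) -> bool:
    """A presequence ending at residue ``e`` releases a mature protein
    starting at ``e + 1``; the match is exact."""
    if neo_position < 1 or presequence_end < 1:
        raise ValueError("positions must be >= 1")
    return neo_position == presequence_end + 1


def calls_from_evidence(
    entries: Iterable[EvidenceEntry],
    proteins: Mapping[str, ProteinRecord],
    imet_second_residues: frozenset = DEFAULT_IMET_SECOND_RESIDUES,
    neo_only: bool = True,
) -> list[NeoNtCall]:
    """Pool evidence entries observed in any replicate into distinct
    (accession, position, nt_mod) calls, dropping contaminating internal
    peptides is the caller's concern: every entry is treated as an
    N-terminal start observation.  With ``neo_only`` the native starts are
    excluded."""
    seen = {}
    for e in entries:
        protein = proteins[e.accession]
        if neo_only and classify_native_or_neo(e, protein, imet_second_residues) == "native":
            continue
        key = (e.accession, e.start, e.nt_mod)
        if key in seen:
            continue
        call = NeoNtCall(accession=e.accession, position=e.start, nt_mod=e.nt_mod)
        if e.nt_mod == "acetyl":
            call.acetyl_class = acetyl_class(e.start, protein)
        seen[key] = call
    return list(seen.values())


def annotate_neo(
    calls: Iterable[NeoNtCall],
    proteins: Mapping[str, ProteinRecord],
    predictions: Iterable[PredictedCleavage] = (),
    ragged_window: int = DEFAULT_RAGGED_WINDOW,
    ladder_min_run: int = DEFAULT_LADDER_MIN_RUN,
) -> list[NeoNtCall]:
    """Attach match flags to neo calls.

    Exact matches set uniprot_signal / uniprot_transit (annotated feature
    span ends at position - 1) and predicted_signal / predicted_transit
    (predictor presequence end + 1 equals the position).  A call with no
    exact match that falls within ``ragged_window`` residues of an
    annotated end + 1 is flagged near_annotated for review; calls
    matching nothing are flagged unmatched.  Ladder membership is
    assigned from maximal consecutive runs of neo positions per protein.
    """
    calls = list(calls)
    preds_by_acc = defaultdict(list)
    for p in predictions:
        preds_by_acc[p.accession].append(p)
    for call in calls:
        protein = proteins[call.accession]
        flags = set()
        near = False
        for kind, flag in (("signal_peptide", "uniprot_signal"),
                           ("transit_peptide", "uniprot_transit")):
            feat = protein.feature(kind)
            if feat is None:
                continue
            if match_cleavage(call.position, feat.end):
                flags.add(flag)
            elif abs(call.position - (feat.end + 1)) <= ragged_window:
                near = True
        for pred in preds_by_acc.get(call.accession, ()):
            if match_cleavage(call.position, pred.presequence_end):
                flags.add(
                    "predicted_signal"
                    if pred.predictor == "signal_predictor"
                    else "predicted_transit"
                )
        if not flags:
            flags.add("near_annotated" if near else "unmatched")
        call.match_status = flags

    positions_by_acc = defaultdict(set)
    for call in calls:
        positions_by_acc[call.accession].add(call.position)
    ladder_index = {}
    for acc, positions in positions_by_acc.items():
        for ladder in detect_ladders(sorted(positions), acc, min_run=ladder_min_run):
            lid = f"{acc}:{ladder.positions[0]}-{ladder.positions[-1]}"
            for pos in ladder.positions:
                ladder_index[(acc, pos)] = lid
    for call in calls:
        call.ladder_id = ladder_index.get((call.accession, call.position))
    return calls


def near_cognate_check(
    cds: CdsRecord,
    call: NeoNtCall,
    near_cognate_codons: frozenset = NEAR_COGNATE_CODONS,
) -> str:
    """Start-codon status at the putative initiator Met of an acetylated
    neo call: the call position for Ac_MX, one residue upstream for
    M_Ac_X (the excised Met).  Returns ``canonical_AUG``,
    ``near_cognate:<codon>`` (RNA alphabet) or ``none``."""
    if call.acetyl_class not in ("Ac_MX", "M_Ac_X"):
        raise ValueError("near-cognate check applies to Ac_MX / M_Ac_X calls only")
    pos = call.position if call.acetyl_class == "Ac_MX" else call.position - 1
    codon = cds.codon(pos).upper()
    if codon == "ATG":
        return "canonical_AUG"
    if codon in near_cognate_codons:
        return f"near_cognate:{codon.replace('T', 'U')}"
    return "none"


def detect_ladders(
    positions: Sequence[int],
    accession: str = "",
    min_run: int = DEFAULT_LADDER_MIN_RUN,
) -> list[Ladder]:
    """Maximal runs of consecutive positions (step 1) with run length
    >= ``min_run`` — the signature of one residue shaved off at a time by
    an exopeptidase.  Positions must be sorted and deduplicated."""
    ladders = []
    run: list[int] = []
    for pos in list(positions) + [None]:  # sentinel flushes the last run
        if run and pos is not None and pos == run[-1] + 1:
            run.append(pos)
            continue
        if len(run) >= min_run:
            ladders.append(Ladder(accession=accession, positions=tuple(run)))
        run = [pos] if pos is not None else []
    return ladders


def position_histogram(
    calls: Iterable[NeoNtCall], bin_edges: Sequence[int] | None = None
) -> dict:
    """Histogram of neo start positions.  Reports the per-bin counts, the
    fraction of calls starting before residue 50, and the count at
    residue 3 (the methionine-aminopeptidase over-cleavage hotspot)."""
    positions = np.array([c.position for c in calls], dtype=int)
    if bin_edges is None:
        top = int(positions.max()) + 10 if positions.size else 60
        bin_edges = list(range(0, top + 10, 10))
    counts, edges = np.histogram(positions, bins=bin_edges)
    return {
        "bin_edges": [int(e) for e in edges],
        "counts": [int(c) for c in counts],
        "n_calls": int(positions.size),
        "fraction_below_50": float((positions < 50).mean()) if positions.size else 0.0,
        "count_at_position_3": int((positions == 3).sum()),
    }
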