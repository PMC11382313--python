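"""Shared data model and file input/output.

All coordinates are 1-based inclusive, following UniProt feature notation:
a presequence span "1-24" covers residues 1..24 and the mature protein
starts at residue 25.  Feature and prediction spans may be written either
as a bare integer end ("24") or as a span string with a hyphen or en-dash
("1-24" / "1–24"); both are accepted everywhere.

Tabular inputs (features, predicted presequence ends, identified-peptide
evidence) use simple header-bearing TSV files; FASTA is used for protein
and coding sequences.  Missing intensities are stored as ``None``, never
imputed to zero, so that downstream intensity-weighted statistics are not
distorted.
"""

from __future__ import annotations

import json
import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

FEATURE_KINDS = frozenset({"signal_peptide", "transit_peptide", "imet_removed", "nt_acetyl"})
EVIDENCE_LEVELS = frozenset({"experimental", "predicted", "unknown"})
PREDICTOR_KINDS = frozenset({"signal_predictor", "transit_predictor"})
METHODS = ("CHAMP_N", "CHAMP_NC", "CHAMP_C")
NT_MODS = frozenset({"free", "acetyl"})

#: Single-nucleotide variants of ATG that can serve as translation starts
#: (near-cognate initiation); decoded as Met by the initiator tRNA.
NEAR_COGNATE_CODONS = frozenset(
    {"CTG", "GTG", "TTG", "ATA", "ATC", "ATT", "ACG", "AAG", "AGG"}
)


class ParseError(ValueError):
    """A file could not be parsed into the data model."""


class ValidationError(ValueError):
    """Parsed content violates a data-model invariant."""


# ---------------------------------------------------------------------------
# span parsing
# ---------------------------------------------------------------------------

_SPAN_RE = re.compile(r"^\s*(?:(\d+)\s*[\-–—]\s*)?(\d+)\s*$")


def parse_span(text: str | int) -> tuple[int, int]:
    """Parse a residue span written as ``"start-end"`` (hyphen or en-dash)
    or as a bare end position; a bare integer N means the span 1..N."""
    if isinstance(text, int):
        start, end = 1, text
    else:
        m = _SPAN_RE.match(str(text))
        if m is None:
            raise ParseError(f"cannot parse residue span {text!r}")
        start = int(m.group(1)) if m.group(1) else 1
        end = int(m.group(2))
    if start < 1 or end < start:
        raise ValidationError(f"invalid residue span {text!r}: need 1 <= start <= end")
    return start, end


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Feature:
    """A terminal annotation on a protein (UniProt-style, 1-based inclusive)."""

    kind: str
    start: int
    end: int
    evidence: str = "unknown"

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValidationError(f"unknown feature kind {self.kind!r}")
        if self.evidence not in EVIDENCE_LEVELS:
            raise ValidationError(f"unknown evidence level {self.evidence!r}")
        if not 1 <= self.start <= self.end:
            raise ValidationError(f"feature span {self.start}-{self.end} invalid")
        if self.kind in ("signal_peptide", "transit_peptide") and self.start != 1:
            raise ValidationError(f"{self.kind} must start at residue 1, got {self.start}")


@dataclass
class ProteinRecord:
    """An annotated protein sequence."""

    accession: str
    sequence: str
    gene: str | None = None
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"{self.accession}: empty sequence")
        bad = set(self.sequence) - set(AMINO_ACIDS)
        if bad:
            raise ValidationError(
                f"{self.accession}: non-canonical residues {sorted(bad)}"
            )
        self.validate_features()

    def validate_features(self) -> None:
        n = len(self.sequence)
        for f in self.features:
            if f.end > n:
                raise ValidationError(
                    f"{self.accession}: feature {f.kind} span {f.start}-{f.end} "
                    f"outside sequence of length {n}"
                )
        for kind in ("signal_peptide", "transit_peptide"):
            if sum(1 for f in self.features if f.kind == kind) > 1:
                raise ValidationError(f"{self.accession}: more than one {kind} feature")

    def __len__(self) -> int:
        return len(self.sequence)

    def feature(self, kind: str) -> Feature | None:
        for f in self.features:
            if f.kind == kind:
                return f
        return None

    @property
    def presequence(self) -> Feature | None:
        """The signal or transit peptide feature, if any (mutually exclusive)."""
        return self.feature("signal_peptide") or self.feature("transit_peptide")


@dataclass(frozen=True)
class PredictedCleavage:
    """A predictor-reported presequence end: mature protein starts at
    ``presequence_end + 1``."""

    accession: str
    predictor: str
    presequence_end: int

    def __post_init__(self) -> None:
        if self.predictor not in PREDICTOR_KINDS:
            raise ValidationError(f"unknown predictor {self.predictor!r}")
        if self.presequence_end < 1:
            raise ValidationError(
                f"{self.accession}: presequence_end must be >= 1, "
                f"got {self.presequence_end}"
            )


@dataclass(frozen=True)
class EvidenceEntry:
    """One identified peptide from one replicate of one isolation method."""

    accession: str
    sequence: str
    start: int
    nt_mod: str
    replicate: int
    method: str
    intensity: float | None = None

    def __post_init__(self) -> None:
        if self.nt_mod not in NT_MODS:
            raise ValidationError(f"unknown nt_mod {self.nt_mod!r}")
        if self.method not in METHODS:
            raise ValidationError(f"unknown method {self.method!r}")
        if self.start < 1 or not self.sequence:
            raise ValidationError("evidence entry needs start >= 1 and a sequence")
        if self.intensity is not None and not self.intensity >= 0:
            raise ValidationError(f"negative intensity {self.intensity}")

    @property
    def end(self) -> int:
        return self.start + len(self.sequence) - 1

    def validate_against(self, protein: ProteinRecord) -> None:
        sub = protein.sequence[self.start - 1 : self.end]
        if sub != self.sequence:
            raise ValidationError(
                f"{self.accession}: peptide {self.sequence!r} at {self.start} does "
                f"not match protein subsequence {sub!r}"
            )


@dataclass(frozen=True)
class CdsRecord:
    """Coding sequence for a protein: 3 x (protein length + 1) nt, stop included."""

    accession: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) % 3 != 0:
            raise ValidationError(f"{self.accession}: CDS length not divisible by 3")

    def codon(self, residue_position: int) -> str:
        """Codon for the residue at the given 1-based protein position."""
        i = 3 * (residue_position - 1)
        return self.sequence[i : i + 3]

    def validate_against(self, protein: ProteinRecord, allow_near_cognate_met: bool = True) -> None:
        n = len(protein.sequence)
        if len(self.sequence) != 3 * (n + 1):
            raise ValidationError(
                f"{self.accession}: CDS length {len(self.sequence)} != 3*({n}+1)"
            )
        for pos in range(1, n + 1):
            cod = self.codon(pos)
            aa = str(Seq(cod).translate())
            if aa == protein.sequence[pos - 1]:
                continue
            # a near-cognate start codon is decoded as Met by the initiator tRNA
            if (
                allow_near_cognate_met
                and protein.sequence[pos - 1] == "M"
                and cod in NEAR_COGNATE_CODONS
            ):
                continue
            raise ValidationError(
                f"{self.accession}: codon {cod} at residue {pos} translates to "
                f"{aa}, protein has {protein.sequence[pos - 1]}"
            )


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _read_fasta(path: str | Path) -> list[SeqRecord]:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def read_features(tsv_path: str | Path) -> dict[str, list[Feature]]:
    """Read a feature TSV (columns: accession, kind, start, end[, evidence])
    into a mapping accession -> features."""
    df = pd.read_csv(tsv_path, sep="\t", dtype=str)
    if df.empty:
        return {}
    required = {"accession", "kind", "start", "end"}
    if not required <= set(df.columns):
        raise ParseError(f"{tsv_path}: feature TSV needs columns {sorted(required)}")
    out: dict[str, list[Feature]] = {}
    for row in df.itertuples(index=False):
        ev = getattr(row, "evidence", None)
        if ev is None or (isinstance(ev, float) and math.isnan(ev)):
            ev = "unknown"
        feat = Feature(kind=row.kind, start=int(row.start), end=int(row.end), evidence=ev)
        out.setdefault(row.accession, []).append(feat)
    return out


def read_proteome(
    fasta_path: str | Path, feature_tsv_path: str | Path | None = None
) -> list[ProteinRecord]:
    """Read a proteome FASTA and (optionally) a feature TSV into
    :class:`ProteinRecord` objects, joined by accession.

    The accession is the first whitespace-delimited token of the FASTA
    header.  Feature rows whose accession matches no FASTA entry are
    reported as warnings; feature spans outside the sequence raise
    :class:`ValidationError`.
    """
    features = read_features(feature_tsv_path) if feature_tsv_path else {}
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in _read_fasta(fasta_path):
        accession = rec.id.split("|")[1] if rec.id.count("|") >= 2 else rec.id
        seq = str(rec.seq).upper()
        if not seq or set(seq) - set(AMINO_ACIDS):
            raise ParseError(f"malformed FASTA entry {rec.description!r}")
        gene = None
        m = re.search(r"GN=(\S+)", rec.description)
        if m:
            gene = m.group(1)
        records.append(
            ProteinRecord(
                accession=accession,
                sequence=seq,
                gene=gene,
                features=features.get(accession, []),
            )
        )
        seen.add(accession)
    unmatched = sorted(set(features) - seen)
    if unmatched:
        warnings.warn(
            f"feature rows for {len(unmatched)} accession(s) not in proteome: "
            f"{unmatched[:5]}{'...' if len(unmatched) > 5 else ''}",
            stacklevel=2,
        )
    return records


def read_predictions(tsv_path: str | Path, predictor_kind: str) -> list[PredictedCleavage]:
    """Read predictor output (columns: accession, presequence_end) where the
    end may be a bare integer or a span like "1-29"."""
    df = pd.read_csv(tsv_path, sep="\t", dtype=str)
    if df.empty:
        return []
    if not {"accession", "presequence_end"} <= set(df.columns):
        raise ParseError(f"{tsv_path}: prediction TSV needs accession, presequence_end")
    out = []
    for row in df.itertuples(index=False):
        _, end = parse_span(row.presequence_end)
        out.append(PredictedCleavage(row.accession, predictor_kind, end))
    return out


def read_evidence(
    tsv_path: str | Path, proteome: Sequence[ProteinRecord] | None = None
) -> list[EvidenceEntry]:
    """Read an identified-peptide evidence TSV; when a proteome is given,
    every entry is validated against the protein subsequence."""
    df = pd.read_csv(tsv_path, sep="\t", dtype=str)
    if df.empty:
        return []
    required = {"accession", "sequence", "start", "nt_mod", "replicate", "method"}
    if not required <= set(df.columns):
        raise ParseError(f"{tsv_path}: evidence TSV needs columns {sorted(required)}")
    by_acc = {p.accession: p for p in proteome} if proteome is not None else None
    entries = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        raw = getattr(row, "intensity", None)
        intensity = None
        if raw is not None and str(raw) not in ("", "nan", "None", "NA"):
            intensity = float(raw)
        entry = EvidenceEntry(
            accession=row.accession,
            sequence=row.sequence,
            start=int(row.start),
            nt_mod=row.nt_mod,
            replicate=int(row.replicate),
            method=row.method,
            intensity=intensity,
        )
        if by_acc is not None:
            if entry.accession not in by_acc:
                raise ValidationError(f"{tsv_path} line {i}: unknown accession {entry.accession}")
            try:
                entry.validate_against(by_acc[entry.accession])
            except ValidationError as exc:
                raise ValidationError(f"{tsv_path} line {i}: {exc}") from None
        entries.append(entry)
    return entries


def read_cds(
    fasta_path: str | Path, proteome: Sequence[ProteinRecord] | None = None
) -> list[CdsRecord]:
    by_acc = {p.accession: p for p in proteome} if proteome is not None else None
    out = []
    for rec in _read_fasta(fasta_path):
        cds = CdsRecord(accession=rec.id.split()[0], sequence=str(rec.seq).upper())
        if by_acc is not None and cds.accession in by_acc:
            cds.validate_against(by_acc[cds.accession])
        out.append(cds)
    return out


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_proteome(records: Iterable[ProteinRecord], fasta_path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(p.sequence), id=p.accession,
                  description=f"GN={p.gene}" if p.gene else "")
        for p in records
    ]
    SeqIO.write(seq_records, str(fasta_path), "fasta")


def write_cds(records: Iterable[CdsRecord], fasta_path: str | Path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(c.sequence), id=c.accession, description="") for c in records],
        str(fasta_path),
        "fasta",
    )


def write_features(features: Mapping[str, Sequence[Feature]], tsv_path: str | Path) -> None:
    rows = [
        {"accession": acc, "kind": f.kind, "start": f.start, "end": f.end, "evidence": f.evidence}
        for acc, feats in features.items()
        for f in feats
    ]
    pd.DataFrame(rows, columns=["accession", "kind", "start", "end", "evidence"]).to_csv(
        tsv_path, sep="\t", index=False
    )


def write_predictions(preds: Iterable[PredictedCleavage], tsv_path: str | Path) -> None:
    rows = [
        {"accession": p.accession, "predictor": p.predictor, "presequence_end": p.presequence_end}
        for p in preds
    ]
    pd.DataFrame(rows, columns=["accession", "predictor", "presequence_end"]).to_csv(
        tsv_path, sep="\t", index=False
    )


def write_evidence(entries: Iterable[EvidenceEntry], tsv_path: str | Path) -> None:
    rows = [
        {
            "accession": e.accession,
            "sequence": e.sequence,
            "start": e.start,
            "nt_mod": e.nt_mod,
            "intensity": "" if e.intensity is None else repr(e.intensity),
            "replicate": e.replicate,
            "method": e.method,
        }
        for e in entries
    ]
    pd.DataFrame(
        rows,
        columns=["accession", "sequence", "start", "nt_mod", "intensity", "replicate", "method"],
    ).to_csv(tsv_path, sep="\t", index=False)


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "__dict__"):
        return _jsonable(vars(obj))
    return obj


def write_report(report: Mapping, path: str | Path) -> None:
    """Write an aggregate report as JSON; top-level scalar tables are also
    written as sibling TSV files (``<stem>.<key>.tsv``)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
        fh.write("\n")
    for key, value in report.items():
        if isinstance(value, Mapping) and value and all(
            not isinstance(v, (Mapping, list, tuple, set)) for v in value.values()
        ):
            tsv = path.with_suffix(f".{key}.tsv")
            pd.DataFrame(
                {"key": list(value.keys()), "value": list(value.values())}
            ).to_csv(tsv, sep="\t", index=False)
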