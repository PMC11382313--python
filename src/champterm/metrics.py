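"""Summary statistics for terminal-peptide isolation experiments.

* selectivity — the percentage of total MS signal intensity carried by
  terminal peptides (intensity-weighted, so it is scale-invariant and
  robust to many low-abundance contaminants);
* Z distribution — histogram of peptide charge numbers at acidic pH;
* replicate RSD — per-peptide relative standard deviation of intensity
  across replicates (sample SD / mean, in percent);
* method overlap — three-set partition of the protein accessions whose
  termini each isolation method captured;
* fraction overlap — per-elution-fraction capture and the cumulative
  fraction of all terminal peptides recovered by fractions 1..k.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .isolation import charge_z
from .proteome_io import EvidenceEntry

#: Categories counted as "terminal" per method when computing selectivity.
METHOD_TERMINAL_CATEGORIES = {
    "CHAMP_N": frozenset({"protein_nt", "neo_nt"}),
    "CHAMP_NC": frozenset({"protein_nt", "neo_nt", "protein_ct"}),
    "CHAMP_C": frozenset({"protein_ct"}),
}


@dataclass
class MethodReport:
    """Aggregate per-method summary."""

    method: str
    n_terminal_ids: int
    selectivity_pct: float
    z_histogram: dict
    rsd_distribution: list = field(default_factory=list)
    overlap: dict = field(default_factory=dict)


def selectivity(entries: Sequence[EvidenceEntry], is_terminal: Sequence[bool]) -> float:
    """Terminal-peptide selectivity in percent: 100 x (summed intensity of
    terminal entries) / (summed intensity of all entries).  Entries
    without an intensity are excluded from both sums."""
    if len(entries) != len(is_terminal):
        raise ValueError("entries and is_terminal must be aligned")
    total = 0.0
    terminal = 0.0
    for entry, flag in zip(entries, is_terminal):
        if entry.intensity is None:
            continue
        total += entry.intensity
        if flag:
            terminal += entry.intensity
    if total == 0.0:
        return float("nan")
    return 100.0 * terminal / total


def z_distribution(z_values: Iterable[int]) -> dict:
    """Histogram of charge numbers: Z -> count."""
    return dict(sorted(Counter(int(z) for z in z_values).items()))


def entry_z(entry: EvidenceEntry) -> int:
    z, _ = charge_z(entry.sequence, entry.nt_mod)
    return z


def z_distribution_by(groups: Mapping[object, Iterable[int]]) -> dict:
    """Per-group (e.g. per-elution-fraction) Z histograms."""
    return {key: z_distribution(values) for key, values in groups.items()}


def replicate_rsd(per_peptide: Mapping[object, Sequence[float]]) -> dict:
    """Per-peptide relative standard deviation in percent across replicate
    mean intensities: 100 x sample SD / mean.  Peptides observed in fewer
    than two replicates are excluded."""
    out = {}
    for key, values in per_peptide.items():
        v = np.asarray(list(values), dtype=float)
        if v.size < 2:
            continue
        mean = v.mean()
        out[key] = 100.0 * v.std(ddof=1) / mean if mean > 0 else float("nan")
    return out


def replicate_intensities(entries: Iterable[EvidenceEntry]) -> dict:
    """Per-peptide replicate intensity vectors from an evidence table.
    Within a replicate, intensities of entries sharing (accession, start,
    sequence, nt_mod) are summed."""
    acc: dict = defaultdict(lambda: defaultdict(float))
    for e in entries:
        if e.intensity is None:
            continue
        key = (e.accession, e.start, e.sequence, e.nt_mod)
        acc[key][e.replicate] += e.intensity
    return {key: [by_rep[r] for r in sorted(by_rep)] for key, by_rep in acc.items()}


def method_overlap(sets_by_method: Mapping[str, set]) -> dict:
    """Counts for every region of the set partition across methods, keyed
    by '&'-joined sorted method names; region counts sum to the union."""
    methods = sorted(sets_by_method)
    union = set().union(*sets_by_method.values()) if sets_by_method else set()
    regions: dict = {}
    for item in union:
        members = tuple(m for m in methods if item in sets_by_method[m])
        key = "&".join(members)
        regions[key] = regions.get(key, 0) + 1
    regions["union"] = len(union)
    return regions


def fraction_overlap(fraction_sets: Sequence[set]) -> dict:
    """Per-fraction capture of terminal peptides and the cumulative
    fraction of the union captured by fractions 1..k."""
    union = set().union(*fraction_sets) if fraction_sets else set()
    total = len(union)
    cumulative = []
    seen: set = set()
    for s in fraction_sets:
        seen |= s
        cumulative.append(len(seen) / total if total else 0.0)
    return {
        "per_fraction_counts": [len(s) for s in fraction_sets],
        "cumulative_capture": cumulative,
        "union_count": total,
    }


def build_method_report(
    method: str,
    entries: Sequence[EvidenceEntry],
    categories: Sequence[str],
) -> MethodReport:
    """Assemble the per-method report from an evidence table and the
    per-entry terminal categories."""
    terminal_cats = METHOD_TERMINAL_CATEGORIES[method]
    is_terminal = [c in terminal_cats for c in categories]
    terminal_keys = {
        (e.accession, e.start, e.sequence, e.nt_mod)
        for e, flag in zip(entries, is_terminal)
        if flag
    }
    rsd = replicate_rsd(
        {
            key: vec
            for key, vec in replicate_intensities(entries).items()
            if key in terminal_keys
        }
    )
    return MethodReport(
        method=method,
        n_terminal_ids=len(terminal_keys),
        selectivity_pct=selectivity(entries, is_terminal),
        z_histogram=z_distribution(entry_z(e) for e in entries),
        rsd_distribution=sorted(rsd.values()),
    )
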