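"""Synthetic study generator with exported ground truth.

Generates a proteome with planted terminal biology — signal/transit
presequences (10-50 residues), initiator-Met removal, Nt-acetylation,
neo-N-termini from four mechanisms (presequence cleavage, exopeptidase
ladders, residue-3 over-cleavage by methionine aminopeptidase, and
near-cognate translation starts) — together with back-translated coding
sequences, predictor outputs, and per-method identified-peptide evidence
tables with log-normal intensities and planted internal-peptide
contamination.  Every emitted evidence row is traceable to a ground-truth
record, so each downstream stage of the pipeline can be tested without
external data.

Defaults encode the study conditions: missed-cleavage sampling weights
0.6/0.3/0.1 for 0/1/2 missed sites, triplicate isolation, a 6-45 residue
detectability window, and a 5% internal-intensity contamination share.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .digestion import (
    DEFAULT_IMET_SECOND_RESIDUES,
    DEFAULT_MAX_LEN,
    DEFAULT_MAX_MISSED,
    DEFAULT_MIN_LEN,
    ENZYMES,
    Peptide,
    cleavage_sites,
    digest,
)
from .isolation import METHOD_ENZYMES, SELECTORS, detectable
from .proteome_io import (
    CdsRecord,
    EvidenceEntry,
    Feature,
    METHODS,
    PredictedCleavage,
    ProteinRecord,
)

#: Average human proteome amino-acid frequencies (SwissProt composition).
HUMAN_AA_FREQS = {
    "A": 0.070, "R": 0.056, "N": 0.036, "D": 0.047, "C": 0.023,
    "E": 0.071, "Q": 0.048, "G": 0.066, "H": 0.026, "I": 0.043,
    "L": 0.100, "K": 0.057, "M": 0.021, "F": 0.037, "P": 0.063,
    "S": 0.083, "T": 0.053, "W": 0.012, "Y": 0.027, "V": 0.060,
}

#: Most-used human codon per residue; back-translation is deterministic.
CODON_TABLE = {
    "A": "GCC", "R": "CGG", "N": "AAC", "D": "GAC", "C": "TGC",
    "E": "GAG", "Q": "CAG", "G": "GGC", "H": "CAC", "I": "ATC",
    "L": "CTG", "K": "AAG", "M": "ATG", "F": "TTC", "P": "CCC",
    "S": "AGC", "T": "ACC", "W": "TGG", "Y": "TAC", "V": "GTG",
}
STOP_CODON = "TGA"

MECHANISMS = (
    "presequence_cleavage",
    "exopeptidase_ladder",
    "residue3_overcleavage",
    "near_cognate_start",
)


def default_p_acetyl(second_residue: str) -> float:
    """Probability of Nt-acetylation given the residue adjacent to the
    initiator Met: high for small residues (acetylated after Met
    excision), intermediate for acidic/amide residues (acetylated on the
    retained Met), low otherwise."""
    if second_residue in "ACGSTV":
        return 0.7
    if second_residue in "DENQ":
        return 0.5
    return 0.15


@dataclass
class GeneratorConfig:
    """Study-condition parameters for the synthetic generator."""

    n_proteins: int = 600
    length_range: tuple = (80, 400)
    residue_frequencies: Mapping[str, float] = field(
        default_factory=lambda: dict(HUMAN_AA_FREQS)
    )
    p_signal: float = 0.15
    signal_length_range: tuple = (10, 50)
    p_transit: float = 0.10
    transit_length_range: tuple = (10, 50)
    p_acetyl_by_second_residue: Mapping[str, float] | None = None
    imet_second_residues: frozenset = DEFAULT_IMET_SECOND_RESIDUES
    p_presequence_cleavage: float = 0.9
    p_ladder: float = 0.05
    ladder_run_range: tuple = (3, 7)
    ladder_start_range: tuple = (4, 30)
    p_residue3: float = 0.10
    p_residue3_acetyl: float = 0.17
    p_near_cognate: float = 0.01
    near_cognate_codon: str = "CTG"
    contamination_intensity_share: float = 0.05
    contamination_count_frac: float = 0.15
    log_intensity_mean: float = 14.0
    log_intensity_sigma: float = 1.0
    replicate_cv: float = 0.10
    missed_cleavage_weights: tuple = (0.6, 0.3, 0.1)
    max_missed: int = DEFAULT_MAX_MISSED
    min_len: int = DEFAULT_MIN_LEN
    max_len: int = DEFAULT_MAX_LEN
    n_replicates: int = 3
    predictor_accuracy: float = 0.9
    predictor_max_shift: int = 3
    seed: int = 0

    def p_acetyl(self, second_residue: str) -> float:
        if self.p_acetyl_by_second_residue is not None:
            return self.p_acetyl_by_second_residue.get(second_residue, 0.0)
        return default_p_acetyl(second_residue)


@dataclass
class NeoEvent:
    """A planted neo-N-terminus."""

    accession: str
    position: int
    mechanism: str
    nt_mod: str = "free"
    emitted: set = field(default_factory=set)  # methods that emitted it


@dataclass
class GroundTruth:
    """Everything the generator planted, for parameter-recovery tests."""

    features: dict = field(default_factory=dict)  # accession -> [Feature]
    mechanism: dict = field(default_factory=dict)  # accession -> mechanism or None
    neo_events: list = field(default_factory=list)
    ladders: list = field(default_factory=list)  # (accession, positions tuple)
    near_cognate_positions: dict = field(default_factory=dict)  # accession -> position
    acetyl_class: dict = field(default_factory=dict)  # (accession, position) -> class
    contamination_share: float = 0.0
    entry_labels: dict = field(default_factory=dict)  # method -> {entry key: category}

    def neo_events_for(self, accession: str) -> list:
        return [e for e in self.neo_events if e.accession == accession]


def _entry_key(e: EvidenceEntry) -> tuple:
    return (e.accession, e.start, e.sequence, e.nt_mod)


def generate_proteome(
    config: GeneratorConfig, seed: int | None = None
) -> tuple[list[ProteinRecord], list[CdsRecord], GroundTruth]:
    """Generate the annotated proteome, its coding sequences and the
    ground truth.  Proteins begin with Met; signal and transit peptides
    are mutually exclusive per protein, as are the neo mechanisms."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    residues = sorted(config.residue_frequencies)
    freqs = np.array([config.residue_frequencies[r] for r in residues], dtype=float)
    freqs /= freqs.sum()
    truth = GroundTruth(contamination_share=config.contamination_intensity_share)
    records: list[ProteinRecord] = []
    cds_records: list[CdsRecord] = []

    for i in range(config.n_proteins):
        accession = f"SYN{i:04d}"
        n = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
        body = rng.choice(residues, size=n - 1, p=freqs)
        seq = list("M" + "".join(body))
        features: list[Feature] = []
        mechanism = None
        near_cognate_pos = None

        # one neo mechanism per protein, mutually exclusive
        u = rng.random()
        if u < config.p_signal:
            mechanism = "signal"
        elif u < config.p_signal + config.p_transit:
            mechanism = "transit"
        else:
            v = rng.random()
            if v < config.p_ladder:
                mechanism = "exopeptidase_ladder"
            elif v < config.p_ladder + config.p_residue3:
                mechanism = "residue3_overcleavage"
            elif v < config.p_ladder + config.p_residue3 + config.p_near_cognate:
                mechanism = "near_cognate_start"

        if mechanism in ("signal", "transit"):
            lo, hi = (
                config.signal_length_range
                if mechanism == "signal"
                else config.transit_length_range
            )
            hi = min(hi, n - 30)
            pre_len = int(rng.integers(lo, hi + 1))
            kind = "signal_peptide" if mechanism == "signal" else "transit_peptide"
            evidence = "experimental" if rng.random() < 0.2 else "unknown"
            features.append(Feature(kind, 1, pre_len, evidence))
            if rng.random() < config.p_presequence_cleavage:
                truth.neo_events.append(
                    NeoEvent(accession, pre_len + 1, "presequence_cleavage")
                )
            mechanism = "presequence_cleavage"
        elif mechanism == "exopeptidase_ladder":
            run = int(rng.integers(*config.ladder_run_range, endpoint=True))
            start = int(rng.integers(*config.ladder_start_range, endpoint=True))
            positions = tuple(range(start, start + run))
            truth.ladders.append((accession, positions))
            for pos in positions:
                truth.neo_events.append(NeoEvent(accession, pos, "exopeptidase_ladder"))
        elif mechanism == "residue3_overcleavage":
            acetyl = rng.random() < config.p_residue3_acetyl
            truth.neo_events.append(
                NeoEvent(accession, 3, "residue3_overcleavage",
                         nt_mod="acetyl" if acetyl else "free")
            )
        elif mechanism == "near_cognate_start":
            pos = int(rng.integers(20, min(60, n - 40)))
            seq[pos - 1] = "M"
            near_cognate_pos = pos
            truth.near_cognate_positions[accession] = pos
            truth.neo_events.append(
                NeoEvent(accession, pos, "near_cognate_start", nt_mod="acetyl")
            )
            truth.acetyl_class[(accession, pos)] = "Ac_MX"

        sequence = "".join(seq)
        imet_removed = sequence[1] in config.imet_second_residues
        if imet_removed:
            features.append(Feature("imet_removed", 1, 1))
        mature_start = 2 if imet_removed else 1
        if rng.random() < config.p_acetyl(sequence[1]):
            features.append(Feature("nt_acetyl", mature_start, mature_start))
            truth.acetyl_class[(accession, mature_start)] = (
                "M_Ac_X" if imet_removed else "Ac_MX"
            )
        # classes for planted acetylated neo starts follow the local sequence
        for event in truth.neo_events:
            if event.accession == accession and event.nt_mod == "acetyl":
                key = (accession, event.position)
                if key not in truth.acetyl_class:
                    p = event.position
                    if sequence[p - 1] == "M":
                        truth.acetyl_class[key] = "Ac_MX"
                    elif p >= 2 and sequence[p - 2] == "M":
                        truth.acetyl_class[key] = "M_Ac_X"
                    else:
                        truth.acetyl_class[key] = "Other"

        codons = [CODON_TABLE[aa] for aa in sequence]
        if near_cognate_pos is not None:
            codons[near_cognate_pos - 1] = config.near_cognate_codon
        cds_records.append(CdsRecord(accession, "".join(codons) + STOP_CODON))
        record = ProteinRecord(accession=accession, sequence=sequence, features=features)
        records.append(record)
        truth.features[accession] = list(features)
        truth.mechanism[accession] = mechanism
    return records, cds_records, truth


def generate_predictions(
    records: Sequence[ProteinRecord],
    config: GeneratorConfig,
    seed: int | None = None,
) -> list[PredictedCleavage]:
    """Predictor-style presequence ends: the true end with probability
    ``predictor_accuracy``, otherwise shifted by up to
    ``predictor_max_shift`` residues."""
    rng = np.random.default_rng((config.seed if seed is None else seed) + 1)
    preds = []
    for record in records:
        feat = record.presequence
        if feat is None:
            continue
        predictor = (
            "signal_predictor" if feat.kind == "signal_peptide" else "transit_predictor"
        )
        end = feat.end
        if rng.random() >= config.predictor_accuracy:
            shift = int(rng.integers(1, config.predictor_max_shift + 1))
            end = max(1, end + (shift if rng.random() < 0.5 else -shift))
        preds.append(PredictedCleavage(record.accession, predictor, end))
    return preds


def _nt_peptide(
    record: ProteinRecord, sites: list, missed: int, min_start: int
) -> tuple[Peptide, int] | None:
    """Mature N-terminal peptide spanning ``missed`` cleavage sites."""
    n = len(record.sequence)
    ends = [b for b in sites if b >= min_start] + [n]
    idx = min(missed, len(ends) - 1)
    end = ends[idx]
    nt_state = "acetyl" if record.feature("nt_acetyl") else "free"
    pep = Peptide(
        record.accession, min_start, end, record.sequence[min_start - 1 : end],
        nt_state=nt_state, missed_cleavages=idx, category="protein_nt",
    )
    return pep, idx


def _ct_peptide(record: ProteinRecord, sites: list, missed: int) -> Peptide:
    n = len(record.sequence)
    edges = [0] + list(sites)
    idx = min(missed, len(edges) - 1)
    start = edges[len(edges) - 1 - idx] + 1
    return Peptide(
        record.accession, start, n, record.sequence[start - 1 :],
        missed_cleavages=idx, category="protein_ct",
    )


def _neo_peptide_candidates(
    record: ProteinRecord, sites: list, event: NeoEvent, config: GeneratorConfig
) -> list[Peptide]:
    """Semi-specific peptide variants for a planted neo start, one per
    admissible enzyme-specific C-terminal boundary (in increasing
    missed-cleavage order).  A semi-specific search can identify any of
    them; the simulation emits the first variant that passes selection
    and the detectability window."""
    n = len(record.sequence)
    p = event.position
    out = []
    for end in [b for b in sites if b >= p] + [n]:
        length = end - p + 1
        if length > config.max_len:
            break
        missed = sum(1 for b in sites if p <= b <= end - 1)
        if missed > config.max_missed:
            break
        if length < config.min_len:
            continue
        out.append(
            Peptide(
                record.accession, p, end, record.sequence[p - 1 : end],
                nt_state=event.nt_mod, missed_cleavages=missed, category="neo_nt",
            )
        )
    return out


def simulate_evidence(
    records: Sequence[ProteinRecord],
    truth: GroundTruth,
    method: str,
    config: GeneratorConfig,
    seed: int | None = None,
) -> list[EvidenceEntry]:
    """Simulate one method's identified-peptide evidence table.

    Terminal peptides are digested with the method's enzyme (missed
    cleavages sampled 0.6/0.3/0.1), passed through the isolation rule and
    the detectability window; neo peptides (CHAMP-N's semi-specific
    search) come from the planted neo events.  A contamination sample of
    rejected internal peptides is added and scaled so that its intensity
    share equals ``contamination_intensity_share``.  Replicates share the
    peptide set and jitter intensities only.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(
        (config.seed if seed is None else seed) + 7919 * (METHODS.index(method) + 1)
    )
    enzyme = ENZYMES[METHOD_ENZYMES[method]]
    weights = np.asarray(config.missed_cleavage_weights, dtype=float)
    weights = weights / weights.sum()
    selector = SELECTORS[method]

    candidates: list[Peptide] = []
    internal_pool: list[Peptide] = []
    for record in records:
        sites = cleavage_sites(record.sequence, enzyme)
        missed = int(rng.choice(len(weights), p=weights))
        imet_feat = record.feature("imet_removed")
        min_start = 2 if imet_feat else 1
        if method in ("CHAMP_N", "CHAMP_NC"):
            made = _nt_peptide(record, sites, missed, min_start)
            if made:
                candidates.append(made[0])
        if method in ("CHAMP_NC", "CHAMP_C"):
            candidates.append(_ct_peptide(record, sites, int(rng.choice(len(weights), p=weights))))
        if method == "CHAMP_N":
            for event in truth.neo_events_for(record.accession):
                variants = _neo_peptide_candidates(record, sites, event, config)
                for pep, dec in zip(variants, selector(variants)):
                    if dec.selected and detectable(pep, config.min_len, config.max_len):
                        candidates.append(pep)
                        break
        # internal peptides the method should reject (contamination pool)
        for pep in digest(record, enzyme, max_missed=0):
            if pep.category == "internal" and detectable(pep, config.min_len, config.max_len):
                internal_pool.append(pep)

    emitted: list[Peptide] = []
    for pep, dec in zip(candidates, selector(candidates)):
        if dec.selected and detectable(pep, config.min_len, config.max_len):
            emitted.append(pep)
            if pep.category == "neo_nt":
                for event in truth.neo_events_for(pep.accession):
                    if event.position == pep.start and event.nt_mod == pep.nt_state:
                        event.emitted.add(method)

    share = config.contamination_intensity_share
    contaminants: list[Peptide] = []
    if share > 0 and internal_pool:
        k = max(1, int(round(config.contamination_count_frac * len(emitted))))
        k = min(k, len(internal_pool))
        idx = rng.choice(len(internal_pool), size=k, replace=False)
        contaminants = [internal_pool[int(j)] for j in idx]

    base_term = rng.lognormal(config.log_intensity_mean, config.log_intensity_sigma,
                              size=len(emitted))
    base_cont = rng.lognormal(config.log_intensity_mean, config.log_intensity_sigma,
                              size=len(contaminants))
    if len(contaminants) and share > 0:
        target = share / (1.0 - share) * base_term.sum()
        base_cont *= target / base_cont.sum()

    labels = truth.entry_labels.setdefault(method, {})
    entries: list[EvidenceEntry] = []
    all_peps = list(emitted) + list(contaminants)
    all_base = np.concatenate([base_term, base_cont]) if len(all_peps) else np.array([])
    for pep, base in zip(all_peps, all_base):
        labels[(pep.accession, pep.start, pep.sequence, pep.nt_state)] = pep.category
        for rep in range(1, config.n_replicates + 1):
            jitter = rng.lognormal(0.0, config.replicate_cv)
            entries.append(
                EvidenceEntry(
                    accession=pep.accession,
                    sequence=pep.sequence,
                    start=pep.start,
                    nt_mod=pep.nt_state,
                    replicate=rep,
                    method=method,
                    intensity=float(base * jitter),
                )
            )
    return entries


def labels_for(
    entries: Sequence[EvidenceEntry], method: str, truth: GroundTruth
) -> list[str]:
    """Ground-truth terminal category per evidence entry."""
    labels = truth.entry_labels.get(method, {})
    return [labels[_entry_key(e)] for e in entries]


def simulate_study(
    config: GeneratorConfig | None = None,
    seed: int | None = None,
    methods: Sequence[str] = METHODS,
):
    """One-call convenience: proteome + CDS + predictions + per-method
    evidence + ground truth."""
    config = config or GeneratorConfig()
    records, cds_records, truth = generate_proteome(config, seed)
    predictions = generate_predictions(records, config, seed)
    evidence = {m: simulate_evidence(records, truth, m, config, seed) for m in methods}
    return records, cds_records, predictions, evidence, truth
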