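"""Neo-N-terminus classification, cleavage-site matching, start-codon
checks and ladder detection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import champterm as ct
from champterm.annotation import NeoNtCall


def _entry(accession, protein, start, length=6, nt_mod="free"):
    return ct.EvidenceEntry(
        accession=accession,
        sequence=protein.sequence[start - 1 : start - 1 + length],
        start=start,
        nt_mod=nt_mod,
        replicate=1,
        method="CHAMP_N",
    )


@pytest.fixture
def protein():
    return ct.ProteinRecord(accession="P1", sequence="MASTKLDHRAGEWNCQTV")


def test_classify_native_or_neo(protein):
    assert ct.classify_native_or_neo(_entry("P1", protein, 1), protein) == "native"
    assert ct.classify_native_or_neo(_entry("P1", protein, 2), protein) == "native"  # iMet rule
    assert ct.classify_native_or_neo(_entry("P1", protein, 3), protein) == "neo"


def test_acetyl_classes():
    p = ct.ProteinRecord(accession="X", sequence="MDSTWMSAGE")
    assert ct.acetyl_class(1, p) == "Ac_MX"  # acetylated residue is Met
    assert ct.acetyl_class(6, p) == "Ac_MX"  # internal Met start
    assert ct.acetyl_class(7, p) == "M_Ac_X"  # residue after a Met
    assert ct.acetyl_class(4, p) == "Other"


def test_acetyl_class_partition_is_exhaustive():
    """Every acetylated call lands in exactly one of the three classes."""
    rng = np.random.default_rng(5)
    classes = set()
    for _ in range(100):
        seq = "".join(rng.choice(list(ct.AMINO_ACIDS), size=30))
        pos = int(rng.integers(1, 31))
        classes.add(ct.acetyl_class(pos, ct.ProteinRecord(accession="X", sequence=seq)))
    assert classes <= {"Ac_MX", "M_Ac_X", "Other"}


def test_second_residue_frequency_single_call():
    p = ct.ProteinRecord(accession="X", sequence="MDSTW")
    call = NeoNtCall("X", 1, "acetyl", acetyl_class="Ac_MX")
    freq = ct.second_residue_frequency([call], {"X": p})
    assert freq["imet_present"] == {"D": 1.0}
    assert freq["imet_absent"] == {}


def test_second_residue_frequency_sums_to_one(study):
    calls = []
    for (acc, pos), cls in study["truth"].acetyl_class.items():
        calls.append(NeoNtCall(acc, pos, "acetyl", acetyl_class=cls))
    freq = ct.second_residue_frequency(calls, study["proteins"])
    for split in ("imet_present", "imet_absent"):
        assert sum(freq[split].values()) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# cleavage-site matching
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "neo,end,expected",
    [(30, 29, True), (25, 20, False), (23, 22, True), (17, 16, True), (47, 46, True)],
)
def test_match_cleavage(neo, end, expected):
    assert ct.match_cleavage(neo, end) is expected


def test_match_cleavage_is_exact_for_one_position():
    """Exactly one neo position matches a given presequence end."""
    matches = [p for p in range(1, 100) if ct.match_cleavage(p, 29)]
    assert matches == [30]


def test_match_cleavage_rejects_nonpositive():
    with pytest.raises(ValueError):
        ct.match_cleavage(0, 5)


def _make_annotated(sequence, kind, end):
    return ct.ProteinRecord(
        accession="A1", sequence=sequence, features=[ct.Feature(kind, 1, end)]
    )


def test_annotate_neo_prediction_beats_offset_annotation():
    """Observed neo at 47 with annotation 1-47 but prediction end 46: the
    prediction matches (46+1), the annotation does not (47+1 != 47)."""
    protein = _make_annotated("M" + "A" * 99, "transit_peptide", 47)
    pred = ct.PredictedCleavage("A1", "transit_predictor", 46)
    call = NeoNtCall("A1", 47, "free")
    (annotated,) = ct.annotate_neo([call], {"A1": protein}, [pred])
    assert annotated.match_status == {"predicted_transit"}


def test_annotate_neo_exact_match_suppresses_near_flag():
    """Neo 17 with annotation 1-18 (off by two) and prediction end 16:
    flagged as a predicted match only."""
    protein = _make_annotated("M" + "A" * 59, "signal_peptide", 18)
    pred = ct.PredictedCleavage("A1", "signal_predictor", 16)
    call = NeoNtCall("A1", 17, "free")
    (annotated,) = ct.annotate_neo([call], {"A1": protein}, [pred])
    assert annotated.match_status == {"predicted_signal"}


def test_annotate_neo_near_and_unmatched():
    protein = _make_annotated("M" + "A" * 59, "signal_peptide", 20)
    near = NeoNtCall("A1", 23, "free")  # within 3 of 21, not equal
    far = NeoNtCall("A1", 40, "free")
    annotated = ct.annotate_neo([near, far], {"A1": protein}, [])
    assert annotated[0].match_status == {"near_annotated"}
    assert annotated[1].match_status == {"unmatched"}


def test_annotate_neo_flags_are_monotone_in_predictions():
    """Adding predictions never removes an annotation-based flag."""
    protein = _make_annotated("M" + "A" * 59, "signal_peptide", 20)
    call = NeoNtCall("A1", 21, "free")
    (without,) = ct.annotate_neo([NeoNtCall("A1", 21, "free")], {"A1": protein}, [])
    pred = ct.PredictedCleavage("A1", "signal_predictor", 20)
    (withp,) = ct.annotate_neo([call], {"A1": protein}, [pred])
    assert without.match_status <= withp.match_status


# ---------------------------------------------------------------------------
# near-cognate start codons
# ---------------------------------------------------------------------------


def _cds_for(sequence, override=None):
    from champterm.synthetic import CODON_TABLE, STOP_CODON

    codons = [CODON_TABLE[a] for a in sequence]
    if override:
        pos, codon = override
        codons[pos - 1] = codon
    return ct.CdsRecord("X", "".join(codons) + STOP_CODON)


def test_near_cognate_check_canonical_and_near():
    p = ct.ProteinRecord(accession="X", sequence="MASTWMKAGE")
    cds = _cds_for(p.sequence)
    call = NeoNtCall("X", 6, "acetyl", acetyl_class="Ac_MX")
    assert ct.near_cognate_check(cds, call) == "canonical_AUG"
    cds_ctg = _cds_for(p.sequence, override=(6, "CTG"))
    assert ct.near_cognate_check(cds_ctg, call) == "near_cognate:CUG"


def test_near_cognate_check_m_ac_x_uses_upstream_codon():
    p = ct.ProteinRecord(accession="X", sequence="MASTWMSAGE")
    cds = _cds_for(p.sequence, override=(6, "GTG"))
    call = NeoNtCall("X", 7, "acetyl", acetyl_class="M_Ac_X")
    assert ct.near_cognate_check(cds, call) == "near_cognate:GUG"


def test_near_cognate_check_rejects_non_start_codons():
    p = ct.ProteinRecord(accession="X", sequence="MASTWMKAGE")
    cds = _cds_for(p.sequence, override=(6, "GGG"))
    call = NeoNtCall("X", 6, "acetyl", acetyl_class="Ac_MX")
    assert ct.near_cognate_check(cds, call) == "none"
    with pytest.raises(ValueError):
        ct.near_cognate_check(cds, NeoNtCall("X", 6, "free"))


# ---------------------------------------------------------------------------
# ladders
# ---------------------------------------------------------------------------


def test_detect_ladders_examples():
    assert [l.positions for l in ct.detect_ladders([3, 4, 5, 9])] == [(3, 4, 5)]
    assert ct.detect_ladders([2, 4, 6]) == []
    assert [l.positions for l in ct.detect_ladders([1, 2, 3, 4, 8, 9, 10])] == [
        (1, 2, 3, 4),
        (8, 9, 10),
    ]


@given(st.sets(st.integers(1, 60), max_size=30))
@settings(max_examples=80, deadline=None, derandomize=True)
def test_detect_ladders_matches_bruteforce_runs(positions):
    ordered = sorted(positions)
    expected = []
    run = []
    for p in ordered:
        if run and p == run[-1] + 1:
            run.append(p)
        else:
            if len(run) >= 3:
                expected.append(tuple(run))
            run = [p]
    if len(run) >= 3:
        expected.append(tuple(run))
    assert [l.positions for l in ct.detect_ladders(ordered)] == expected


def test_ladder_min_run_configurable():
    assert [l.positions for l in ct.detect_ladders([5, 6], min_run=2)] == [(5, 6)]


# ---------------------------------------------------------------------------
# position histogram
# ---------------------------------------------------------------------------


def test_position_histogram_fraction_below_50():
    calls = [NeoNtCall("X", p, "free") for p in (3, 3, 60)]
    hist = ct.position_histogram(calls)
    assert hist["fraction_below_50"] == pytest.approx(2 / 3)
    assert hist["count_at_position_3"] == 2


def test_position_histogram_empty():
    hist = ct.position_histogram([])
    assert hist["n_calls"] == 0 and sum(hist["counts"]) == 0
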