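"""Digestion: cleavage boundaries, missed cleavages, semi-specific
expansion and terminal-category labeling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import champterm as ct
from champterm.digestion import ENZYMES

AA = ct.AMINO_ACIDS
sequences = st.text(alphabet=AA, min_size=1, max_size=60)


# ---------------------------------------------------------------------------
# independent brute-force oracle
# ---------------------------------------------------------------------------


def oracle_sites(seq, enzyme_name):
    """Boundary i (1-based, between residues i and i+1) by direct rule."""
    n = len(seq)
    if enzyme_name == "lysarginase":
        return [i for i in range(1, n) if seq[i] in "KR"]
    targets = "KR" if enzyme_name == "trypsin" else "DE"
    return [i for i in range(1, n) if seq[i - 1] in targets]


def oracle_digest(seq, enzyme_name, max_missed):
    """All (start, end, missed) triples by exhaustive substring check."""
    n = len(seq)
    sites = set(oracle_sites(seq, enzyme_name))
    out = set()
    for s in range(1, n + 1):
        for e in range(s, n + 1):
            if (s == 1 or (s - 1) in sites) and (e == n or e in sites):
                m = sum(1 for b in sites if s <= b <= e - 1)
                if m <= max_missed:
                    out.add((s, e, m))
    return out


# ---------------------------------------------------------------------------
# cleavage sites
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "seq,enzyme,expected",
    [
        ("MKRAGDE", "lysarginase", [1, 2]),
        ("MKDAGEQ", "v8", [3, 6]),
        ("MKDAGERQ", "trypsin", [2, 7]),
        ("KASDF", "lysarginase", []),  # K at position 1 gives no boundary
        ("ASDFK", "trypsin", []),  # K at last position gives no boundary
        ("MMMM", "trypsin", []),
    ],
)
def test_cleavage_sites_rules(seq, enzyme, expected):
    assert ct.cleavage_sites(seq, enzyme) == expected


def test_proline_block_is_optional():
    # trypsin classically skips K/R followed by proline
    assert ct.cleavage_sites("AKPA", "trypsin") == [2]
    assert ct.cleavage_sites("AKPA", "trypsin", block_proline=True) == []


# ---------------------------------------------------------------------------
# fully specific digest
# ---------------------------------------------------------------------------


def test_digest_zero_missed_example():
    peps = [p for p in ct.digest("MKRAGDE", "lysarginase", 0)]
    assert [p.sequence for p in peps] == ["M", "K", "RAGDE"]


def test_digest_one_missed_adds_spanning_peptides():
    seqs = {p.sequence for p in ct.digest("MKRAGDE", "lysarginase", 1)}
    assert seqs == {"M", "K", "RAGDE", "MK", "KRAGDE"}


def test_protein_without_sites_is_one_peptide():
    peps = ct.digest("MAGSTW", "lysarginase", 2)
    assert len(peps) == 1 and peps[0].sequence == "MAGSTW"
    assert peps[0].category == "protein_nt"


@pytest.mark.parametrize("enzyme", list(ENZYMES))
@given(seq=sequences, max_missed=st.integers(0, 2))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_digest_matches_bruteforce(seq, enzyme, max_missed):
    got = {(p.start, p.end, p.missed_cleavages) for p in ct.digest(seq, enzyme, max_missed)}
    assert got == oracle_digest(seq, enzyme, max_missed)


@pytest.mark.parametrize("enzyme", list(ENZYMES))
@given(seq=sequences)
@settings(max_examples=60, deadline=None, derandomize=True)
def test_zero_missed_peptides_tile_protein(seq, enzyme):
    peps = sorted(
        (p for p in ct.digest(seq, enzyme, 0)), key=lambda p: p.start
    )
    assert "".join(p.sequence for p in peps) == seq
    pos = 1
    for p in peps:
        assert p.start == pos
        pos = p.end + 1


@given(seq=sequences, max_missed=st.integers(0, 3))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_peptide_count_law(seq, max_missed):
    # with B boundaries there are B + 1 - k peptides at exactly k missed sites
    for enzyme in ENZYMES:
        b = len(ct.cleavage_sites(seq, enzyme))
        expected = sum(max(0, b + 1 - k) for k in range(0, max_missed + 1))
        assert len(ct.digest(seq, enzyme, max_missed)) == expected


def test_boundary_residue_identity():
    rng = np.random.default_rng(0)
    for _ in range(20):
        seq = "".join(rng.choice(list(AA), size=40))
        n = len(seq)
        for p in ct.digest(seq, "lysarginase", 2):
            if p.start != 1:
                assert p.sequence[0] in "KR"
        for p in ct.digest(seq, "trypsin", 2):
            if p.end != n:
                assert p.sequence[-1] in "KR"
        for p in ct.digest(seq, "v8", 2):
            if p.end != n:
                assert p.sequence[-1] in "DE"


def test_digest_agrees_with_pyteomics_on_tryptic_and_v8_products():
    # independent implementation cross-check at zero missed cleavages
    parser = pytest.importorskip("pyteomics.parser")
    seq = "MKAYDDEAGRLLTSHKWQ"
    for enzyme, rule in [("trypsin", r"[KR]"), ("v8", r"[DE]")]:
        ours = {p.sequence for p in ct.digest(seq, enzyme, 0)}
        theirs = set(parser.cleave(seq, rule, missed_cleavages=0))
        assert ours == theirs


# ---------------------------------------------------------------------------
# semi-specific N-terminal-free digest
# ---------------------------------------------------------------------------


def test_semi_specific_includes_free_start_at_specific_end():
    peps = ct.semi_specific_nt_free("MKRAGDE", "lysarginase", 0, 2, 7)
    seqs = {p.sequence for p in peps}
    assert "AGDE" in seqs  # nonspecific start 4, protein C-terminus
    assert "AGD" not in seqs  # end 6 is not a boundary


def test_semi_specific_count_matches_bruteforce():
    seq = "MKRAGDE"
    n = len(seq)
    sites = set(oracle_sites(seq, "lysarginase"))
    expected = set()
    for e in list(sites) + [n]:
        for s in range(1, e + 1):
            m = sum(1 for b in sites if s <= b <= e - 1)
            if 2 <= e - s + 1 <= 7 and m == 0:
                expected.add((s, e))
    got = {(p.start, p.end) for p in ct.semi_specific_nt_free(seq, "lysarginase", 0, 2, 7)}
    assert got == expected


@pytest.mark.parametrize("enzyme", list(ENZYMES))
@given(seq=st.text(alphabet=AA, min_size=6, max_size=40))
@settings(max_examples=40, deadline=None, derandomize=True)
def test_semi_specific_is_superset_of_specific(seq, enzyme):
    semi = {(p.start, p.end) for p in ct.semi_specific_nt_free(seq, enzyme, 2, 1, len(seq))}
    full = {(p.start, p.end) for p in ct.digest(seq, enzyme, 2)}
    assert full <= semi


def test_semi_specific_rejects_bad_length_bounds():
    with pytest.raises(ValueError):
        ct.semi_specific_nt_free("MKRAGDE", "lysarginase", 0, 5, 2)


# ---------------------------------------------------------------------------
# category labeling
# ---------------------------------------------------------------------------


def _pep(protein, start, end):
    return ct.Peptide(protein.accession, start, end, protein.sequence[start - 1 : end])


def test_label_category_imet_removal(tiny_protein):
    # "MASTK...": residue 2 is A (small), so a start at 2 is still native
    assert ct.label_category(_pep(tiny_protein, 2, 5), tiny_protein, "lysarginase") == "protein_nt"


def test_label_category_start3_is_neo(tiny_protein):
    assert ct.label_category(_pep(tiny_protein, 3, 8), tiny_protein, "lysarginase") == "neo_nt"


def test_label_category_protein_ct(tiny_protein):
    n = len(tiny_protein.sequence)
    assert ct.label_category(_pep(tiny_protein, 9, n), tiny_protein, "lysarginase") == "protein_ct"


def test_label_category_specific_vs_nonspecific_start(tiny_protein):
    # "MASTKLDHRAGE": K at 5 -> lysarginase boundary 4; start 5 is specific
    assert ct.label_category(_pep(tiny_protein, 5, 8), tiny_protein, "lysarginase") == "internal"
    assert ct.label_category(_pep(tiny_protein, 6, 8), tiny_protein, "lysarginase") == "neo_nt"


def test_imet_not_removable_start2_is_not_native():
    protein = ct.ProteinRecord(accession="P2", sequence="MWSTKLD")  # W is not small
    assert ct.label_category(_pep(protein, 2, 5), protein, "lysarginase") == "neo_nt"
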