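"""In silico digestion, gel banding and the dRFLP discrimination screen."""

import itertools

import numpy as np
import pytest

import mitomarkers as mm
from mitomarkers.iupac import IUPAC_SETS, reverse_complement
from mitomarkers.restriction import (
    DigestPattern, EnzymeDefinition, GelModel, digest, distinguishable,
    find_sites, render_gel, screen_enzymes, visible_bands,
)

ECORI = EnzymeDefinition("EcoRI", "GAATTC", 1)
HPY = EnzymeDefinition("HpyCH4IV", "ACGT", 1)
TSP = EnzymeDefinition("Tsp45I", "GTSAC", 0)
HINDIII = EnzymeDefinition("HindIII", "AAGCTT", 1)


def expand_site_oracle(seq: str, enzyme: EnzymeDefinition) -> list[int]:
    """Independent oracle: expand the IUPAC site into every concrete word
    and string-search each, on both strands for non-palindromic sites."""
    cuts = set()

    def words(site):
        return ("".join(w) for w in
                itertools.product(*[sorted(IUPAC_SETS[c]) for c in site]))

    for word in words(enzyme.site):
        at = seq.find(word)
        while at != -1:
            cuts.add(at + enzyme.cut_offset)
            at = seq.find(word, at + 1)
    if reverse_complement(enzyme.site) != enzyme.site:
        mirrored = len(enzyme.site) - enzyme.cut_offset
        for word in words(reverse_complement(enzyme.site)):
            at = seq.find(word)
            while at != -1:
                cuts.add(at + mirrored)
                at = seq.find(word, at + 1)
    return sorted(cuts)


def test_enzyme_definition_validation():
    with pytest.raises(ValueError, match="offset"):
        EnzymeDefinition("Bad", "GAATTC", 7)
    with pytest.raises(ValueError, match="non-IUPAC"):
        EnzymeDefinition("Bad", "GAXTTC", 1)
    with pytest.raises(ValueError, match="shorter"):
        EnzymeDefinition("Bad", "GAT", 1)


def test_find_sites_examples():
    assert find_sites("AAAGAATTCAAA", ECORI) == [4]
    assert find_sites("TTTT", ECORI) == []
    assert find_sites("GTGACAAA", TSP) == [0]       # GTSAC matches GTGAC
    assert find_sites("AAACGTAA", HPY) == [3]       # A^CGT


def test_find_sites_matches_expansion_oracle():
    rng = np.random.default_rng(2)
    letters = list("ACGTRYSWKM")
    for _ in range(100):
        seq = "".join(rng.choice(list("ACGT"), 120, p=[0.4, 0.1, 0.1, 0.4]))
        site = "".join(rng.choice(letters, rng.integers(4, 7)))
        enz = EnzymeDefinition("Rnd", site, int(rng.integers(0, len(site) + 1)))
        assert find_sites(seq, enz) == expand_site_oracle(seq, enz)


def test_find_sites_strict_vs_permissive_ambiguous_sequence():
    # consensus W at the A position of ACGT: strict refuses, permissive cuts
    seq = "AAWCGTAA"
    assert find_sites(seq, HPY, ambiguity="strict") == []
    assert find_sites(seq, HPY, ambiguity="permissive") == [3]


def test_digest_fragments_and_conservation():
    pat = digest("AAAGAATTCAAA", [ECORI])
    assert sorted(pat.fragments) == [4, 8]
    assert pat.total_length == 12
    pat = digest("ACGATCGTACTG", [ECORI])
    assert pat.fragments == (12,)                    # no sites


def test_double_digest_is_union_of_cut_sets():
    rng = np.random.default_rng(5)
    for _ in range(50):
        seq = "".join(rng.choice(list("ACGT"), 300))
        cuts_a = set(find_sites(seq, HPY))
        cuts_b = set(find_sites(seq, TSP))
        both = digest(seq, [HPY, TSP])
        bounds = sorted({0, len(seq)} | cuts_a | cuts_b)
        expected = sorted(b - a for a, b in zip(bounds, bounds[1:]) if b > a)
        assert sorted(both.fragments) == expected
        assert both.total_length == len(seq)


def test_digest_reverse_complement_invariance():
    """Exact for non-palindromic sites and symmetric (blunt) cutters;
    asymmetric palindromes shift boundaries by at most the overhang."""
    ecorv = EnzymeDefinition("EcoRV", "GATATC", 3)        # blunt
    bsai = EnzymeDefinition("BsaI", "GGTCTC", 1)          # non-palindromic
    rng = np.random.default_rng(6)
    for enz in (ecorv, bsai):
        for _ in range(30):
            seq = "".join(rng.choice(list("ACGT"), 250))
            a = sorted(digest(seq, [enz]).fragments)
            b = sorted(digest(reverse_complement(seq), [enz]).fragments)
            assert a == b
    overhang = 4                                           # EcoRI G^AATTC
    for _ in range(30):
        seq = "".join(rng.choice(list("ACGT"), 250))
        a = sorted(digest(seq, [ECORI]).fragments)
        b = sorted(digest(reverse_complement(seq), [ECORI]).fragments)
        assert len(a) == len(b)
        assert all(abs(x - y) <= overhang for x, y in zip(a, b))


def test_sequential_digest_matches_joint_digest():
    """Digesting with E then F on the fragments equals the one-pot {E, F}
    digest whenever no F site straddles an E cut."""
    rng = np.random.default_rng(7)
    checked = 0
    for _ in range(200):
        seq = "".join(rng.choice(list("ACGT"), 300))
        cuts_e = find_sites(seq, ECORI)
        straddles = any(c - len(HPY.site) < f < c + len(HPY.site)
                        for f in find_sites(seq, HPY) for c in cuts_e)
        if straddles:
            continue
        checked += 1
        bounds = [0] + cuts_e + [len(seq)]
        sequential = []
        for a, b in zip(bounds, bounds[1:]):
            if b > a:
                sequential.extend(digest(seq[a:b], [HPY]).fragments)
        joint = digest(seq, [ECORI, HPY]).fragments
        assert sorted(sequential) == sorted(joint)
    assert checked >= 150


def test_visible_bands_merge_and_floor():
    gel = GelModel()
    pat = DigestPattern("s", ("E",), (500, 510))
    assert visible_bands(pat, gel) == [505.0]
    assert visible_bands(DigestPattern("s", ("E",), (40,)), gel) == []
    assert visible_bands(DigestPattern("s", ("E",), (100, 400, 1000)), gel) == \
        [100.0, 400.0, 1000.0]


def test_distinguishable_cases():
    gel = GelModel()
    a = DigestPattern("a", ("E",), (200, 800))
    assert not distinguishable(a, a, gel)
    assert distinguishable(DigestPattern("a", ("E",), (1000,)),
                           DigestPattern("b", ("E",), (500, 500)), gel)
    assert not distinguishable(DigestPattern("a", ("E",), (500, 510)),
                               DigestPattern("b", ("E",), (505,)), gel)


def _three_population_fixture():
    """Site X only / site Y only / both sites, on an otherwise site-free
    1000-bp backbone."""
    rng = np.random.default_rng(11)
    backbone = None
    while backbone is None:
        cand = "".join(rng.choice(list("ACGT"), 1000, p=[0.4, 0.1, 0.1, 0.4]))
        if not find_sites(cand, ECORI) and not find_sites(cand, HINDIII):
            backbone = cand
    def with_sites(x, y):
        s = list(backbone)
        if x:
            s[200:206] = list("GAATTC")
        if y:
            s[600:606] = list("AAGCTT")
        return "".join(s)
    seqs = {"pop1": with_sites(True, False),
            "pop2": with_sites(False, True),
            "pop3": with_sites(True, True)}
    # planting the sites must not create the other enzyme's site
    for s in seqs.values():
        assert len(find_sites(s, ECORI)) <= 1 and len(find_sites(s, HINDIII)) <= 1
    return [mm.LabeledSequence(k, k, v) for k, v in seqs.items()]


def test_screen_three_population_fixture_needs_the_pair():
    consensuses = _three_population_fixture()
    entries = screen_enzymes(consensuses, [ECORI, HINDIII], max_set_size=2)
    by_set = {e.enzymes: e for e in entries}
    assert not by_set[("EcoRI",)].full_discrimination
    assert not by_set[("HindIII",)].full_discrimination
    pair = by_set[("EcoRI", "HindIII")]
    assert pair.full_discrimination and pair.score == 3
    # ranking puts the pair first
    assert entries[0].enzymes == ("EcoRI", "HindIII")


def test_screen_identical_consensuses_all_zero():
    seqs = [mm.LabeledSequence(f"p{i}", f"p{i}", "AAAGAATTCAAA" * 20)
            for i in range(3)]
    entries = screen_enzymes(seqs, [ECORI, HINDIII], max_set_size=2)
    assert all(e.score == 0 and not e.full_discrimination for e in entries)
    with pytest.raises(ValueError, match="empty"):
        screen_enzymes(seqs, [], max_set_size=2)


def test_render_gel_monotone_and_reproducible(tmp_path):
    pats = [DigestPattern("lane1", ("E",), (1000,)),
            DigestPattern("lane2", ("E",), (100, 400, 1500)),
            DigestPattern("lane1b", ("E",), (1000,))]
    text = render_gel(pats, GelModel())
    lines = text.splitlines()
    lane_w = len(lines[0]) // 4
    # identical patterns render identically
    def lane(idx):
        return [row[idx * lane_w:(idx + 1) * lane_w] for row in lines[1:]]
    assert lane(1) == lane(3)
    # band rows are monotone in log-length: in lane2, 1500 above 400 above 100
    rows = {}
    for r, row in enumerate(lines[1:]):
        seg = row[2 * lane_w:3 * lane_w]
        if "=" in seg:
            rows[r] = seg
    assert len(rows) == 3
    png = tmp_path / "gel.png"
    render_gel(pats, GelModel(), path=str(png))
    assert png.exists()
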