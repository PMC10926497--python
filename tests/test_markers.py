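"""Tandem-repeat scanning, locus quantification and in silico PCR."""

import numpy as np
import pytest

import mitomarkers as mm
from mitomarkers.iupac import reverse_complement
from mitomarkers.markers import (
    PrimerPair, ScanParams, build_marker_matrix, in_silico_pcr,
    quantify_locus, scan_tandem_repeats, _smallest_period,
)
from mitomarkers.io_formats import LabeledSequence, PopulationSet


def brute_force_pure_runs(seq: str, min_period=2, max_period=50, min_copies=2.0):
    """Independent oracle: every maximal pure (mismatch-free) tandem run,
    found by testing each (start, period) pair and extending greedily."""
    runs = []
    n = len(seq)
    for p in range(min_period, min(max_period, n - 1) + 1):
        i = p
        while i < n:
            if seq[i] != seq[i - p]:
                i += 1
                continue
            j = i
            while j < n and seq[j] == seq[j - p]:
                j += 1
            start, end = i - p, j
            if end - start >= p * min_copies:
                runs.append((start, end, p))
            i = j + 1
    return runs


def test_scanner_matches_brute_force_on_printed_motif_string():
    """On the 75-bp flank+3x21-mer+flank string the oracle's best run is the
    21-periodic array, and the scanner reports exactly it."""
    seq = "TTTT" + mm.TR10_MOTIF * 3 + "AAAA"
    runs = brute_force_pure_runs(seq)
    # oracle: longest-span run, smaller period on ties, after discarding
    # runs that restate a lower-period repeat (homopolymer flanks)
    runs = [r for r in runs
            if _smallest_period(seq[r[0]:r[0] + r[2]]) >= 2
            and _smallest_period(seq[r[0]:r[0] + r[2]]) == r[2]]
    best = sorted(runs, key=lambda r: (-(r[1] - r[0]), r[2]))[0]
    hits = scan_tandem_repeats(seq)
    assert len(hits) == 1
    hit = hits[0]
    assert (hit.start, hit.end, hit.period) == best == (4, 67, 21)
    assert hit.copy_number == 3.0
    assert hit.consensus_motif == mm.TR10_MOTIF
    assert hit.purity == 1.0


def test_scanner_simple_and_empty_cases():
    hits = scan_tandem_repeats("ACGACGACGACG")
    assert [(h.period, h.copy_number, h.consensus_motif, h.purity)
            for h in hits] == [(3, 4.0, "ACG", 1.0)]
    assert scan_tandem_repeats("ACGTTGCA") == []


@pytest.mark.parametrize("seed", range(5))
def test_exact_tandem_recovery_random_motifs(seed):
    """f + motif^k + g yields exactly one hit at the motif's period with
    copy number k.0, for non-periodic motifs and repeat-free flanks."""
    rng = np.random.default_rng(seed)
    for _ in range(20):
        p = int(rng.integers(2, 31))
        motif = "".join(rng.choice(list("ACGT"), p))
        if _smallest_period(motif, 0.2) < len(motif):
            continue
        k = int(rng.integers(2, 7))
        flank_left = "C" if motif[-1] != "C" else "G"
        flank_right = "C" if motif[0] != "C" else "G"
        seq = flank_left * 3 + motif * k + flank_right * 3
        hits = [h for h in scan_tandem_repeats(seq) if h.period == p]
        assert len(hits) == 1
        assert hits[0].copy_number == float(k)
        assert hits[0].consensus_motif == motif


def test_quantify_locus_rotation_and_sum():
    hits = scan_tandem_repeats("CCC" + "ACG" * 5 + "TTT")
    assert quantify_locus(hits, "ACG") == 5.0
    assert quantify_locus(hits, "CGA") == 5.0          # cyclic rotation
    assert quantify_locus(hits, "GGT") == 0.0          # absent
    two = "CC" + "TATGATTGAAGT" * 3 + "CCCC" + "TATGATTGAAGT" * 2 + "CC"
    with pytest.warns(UserWarning, match="2 arrays"):
        assert quantify_locus(scan_tandem_repeats(two), "TATGATTGAAGT") == 5.0


def test_quantify_copy_number_monotonic_in_copies():
    for k in (2, 3, 4, 7):
        seq = "CC" + "TATGATTGAAGT" * k + "CC"
        assert quantify_locus(scan_tandem_repeats(seq), "TATGATTGAAGT") == float(k)


def test_in_silico_pcr_coordinates():
    """Exact forward site at 10, reverse-complement site ending at 150 on a
    200-bp template -> single 140-bp product."""
    rng = np.random.default_rng(0)
    template = list(rng.choice(list("ACGT"), 200, p=[0.4, 0.1, 0.1, 0.4]))
    fwd = "GATTACAGATTA"
    rev_rc = "CCGGTTAACCGG"   # site on template; reverse primer is its RC
    template[10:10 + 12] = list(fwd)
    template[138:150] = list(rev_rc)
    template = "".join(template)
    primers = PrimerPair(fwd, reverse_complement(rev_rc))
    assert in_silico_pcr(template, primers) == [140]
    # no products when primers absent, or in inverted orientation only
    assert in_silico_pcr("A" * 100, primers) == []
    t2 = list(rng.choice(list("ACGT"), 200, p=[0.4, 0.1, 0.1, 0.4]))
    t2[10:22] = list(rev_rc)
    t2[150:162] = list(fwd)
    t2 = "".join(t2)
    assert in_silico_pcr(t2, primers) == []


def test_in_silico_pcr_reverse_complement_invariance():
    rng = np.random.default_rng(3)
    template = list(rng.choice(list("ACGT"), 300, p=[0.4, 0.1, 0.1, 0.4]))
    fwd = "GATTACAGATTA"
    rev_rc = "CCGGTTAACCGG"
    template[40:52] = list(fwd)
    template[200:212] = list(rev_rc)
    template = "".join(template)
    primers = PrimerPair(fwd, reverse_complement(rev_rc))
    assert in_silico_pcr(template, primers) == \
        in_silico_pcr(reverse_complement(template), primers)


def test_marker_matrix_copy_numbers_and_missing_ssr():
    motif = "TATGATTGAAGT"
    pop = PopulationSet([
        LabeledSequence("i1", "A", "CC" + motif * 4 + "CCCC"),
        LabeledSequence("i2", "B", "CC" + motif * 6 + "CCCC"),
    ])
    fwd, rev_rc = "GATTACAGATTA", "CCGGTTAACCGG"
    with_site = PopulationSet([
        LabeledSequence("i1", "A", "CC" + motif * 4 + fwd + "TTTT" + rev_rc),
        LabeledSequence("i2", "B", "CC" + motif * 6 + "CCCC"),
    ])
    table = build_marker_matrix(
        with_site, {"TR2": motif},
        {"ssr": PrimerPair(fwd, reverse_complement(rev_rc))})
    assert table.values["TR2"].tolist() == [4.0, 6.0]
    assert table.values.loc["i1", "ssr"] == 28.0
    assert np.isnan(table.values.loc["i2", "ssr"])
    assert table.groups.tolist() == ["A", "B"]


def test_marker_matrix_equals_truth_at_noise_zero(study0):
    config, pop_set, truth = study0
    from mitomarkers.pipeline import ssr_primer_pairs

    table = build_marker_matrix(
        pop_set, {"TR2": mm.synthetic._TR2_MOTIF, "TR10": mm.TR10_MOTIF},
        ssr_primer_pairs(config))
    for ind in table.samples:
        assert table.values.loc[ind, "TR2"] == truth.copy_numbers[ind]["TR2"]
        assert table.values.loc[ind, "TR10"] == truth.copy_numbers[ind]["TR10"]
        for locus in config.ssr_loci:
            start, end = truth.locus_coords[ind][locus.name]
            assert table.values.loc[ind, locus.name] == 80 + (end - start)
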