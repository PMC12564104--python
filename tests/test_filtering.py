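"""Artifact classification: the four artifact classes and their interplay."""

from __future__ import annotations

import itertools

import pandas as pd
import pytest

from plastedit import calling, filtering
from plastedit.plastome import complement


def pileup_rows(rows):
    return pd.DataFrame(rows, columns=calling.PILEUP_COLUMNS)


def prow(pos, strand, sample="s1", library="total", **counts):
    base = {"nA": 0, "nC": 0, "nG": 0, "nT": 0}
    base.update(counts)
    return [sample, library, pos, strand, base["nA"], base["nC"], base["nG"], base["nT"]]


def call_row(pos, strand, ref, alt, var_reads, depth, sample="s1", library="total"):
    return {
        "sample": sample, "library": library, "pos": pos, "strand": strand,
        "ref": ref, "alt": alt, "var_reads": var_reads, "depth": depth,
        "vaf": var_reads / depth, "multi_allelic": False,
    }


# --- context ----------------------------------------------------------------


def test_add_context_regions_and_coding(mini_features):
    calls = pd.DataFrame(
        [
            call_row(15, "+", "C", "T", 10, 100),   # inside geneP (plus)
            call_row(120, "+", "G", "A", 10, 100),  # antisense to geneM
            call_row(350, "+", "C", "T", 10, 100),  # intergenic
        ]
    )
    out = filtering.add_context(calls, mini_features)
    assert list(out["region"]) == ["CDS", "CDS", "intergenic"]
    assert list(out["coding"]) == [True, False, True]
    assert list(out["substitution"]) == ["C>T", "G>A", "C>T"]


# --- strand reassignment ----------------------------------------------------


def test_reassign_misreported_g_to_a(mini_features):
    # geneM is minus strand; a G>A call on '+' with dominant minus C>T signal
    calls = pd.DataFrame([call_row(156, "+", "G", "A", 40, 100)])
    pileups = pileup_rows(
        [prow(156, "-", nC=50, nT=50), prow(156, "+", nG=60, nA=40)]
    )
    out = filtering.reassign_to_coding_strand(calls, pileups, mini_features)
    r = out.iloc[0]
    assert (r["strand"], r["ref"], r["alt"]) == ("-", "C", "T")
    assert r["vaf"] == 0.5 and r["var_reads"] == 50
    assert r["strand_reassigned"] and r["coding"]


def test_reassign_is_idempotent(mini_features):
    calls = pd.DataFrame([call_row(156, "+", "G", "A", 40, 100)])
    pileups = pileup_rows(
        [prow(156, "-", nC=50, nT=50), prow(156, "+", nG=60, nA=40)]
    )
    once = filtering.reassign_to_coding_strand(calls, pileups, mini_features)
    twice = filtering.reassign_to_coding_strand(once, pileups, mini_features)
    pd.testing.assert_frame_equal(once, twice)


def test_reassign_leaves_coding_and_unsupported_calls(mini_features):
    calls = pd.DataFrame(
        [
            call_row(120, "-", "C", "T", 30, 100),  # already coding on geneM
            call_row(130, "+", "G", "A", 30, 100),  # no complementary signal
        ]
    )
    pileups = pileup_rows(
        [prow(120, "-", nC=70, nT=30), prow(130, "+", nG=70, nA=30), prow(130, "-", nC=100)]
    )
    out = filtering.reassign_to_coding_strand(calls, pileups, mini_features)
    assert not out["strand_reassigned"].any()
    assert list(out.sort_values("pos")["strand"]) == ["-", "+"]


def test_reassign_spares_low_ratio_carryover_shadows(mini_features):
    # shadow at 2% of the coding VAF is carryover, not a misreport
    calls = pd.DataFrame([call_row(156, "+", "G", "A", 1, 100)])
    pileups = pileup_rows(
        [prow(156, "-", nC=50, nT=50), prow(156, "+", nG=99, nA=1)]
    )
    out = filtering.reassign_to_coding_strand(calls, pileups, mini_features)
    assert not out["strand_reassigned"].any()
    assert out.iloc[0]["strand"] == "+"


# --- junction ---------------------------------------------------------------


def test_junction_flags_within_window(mini_features):
    # geneP intron spans 41-60
    calls = pd.DataFrame(
        [
            call_row(38, "+", "C", "T", 10, 100),  # 3 bp from boundary 41
            call_row(90, "+", "C", "T", 10, 100),  # 30 bp away
            call_row(63, "+", "C", "T", 10, 100),  # 3 bp from boundary 60
        ]
    )
    out = filtering.junction_filter(calls, mini_features, window=10)
    assert list(out["flag_junction_artifact"]) == [True, False, True]


def test_junction_no_introns_no_flags(mini_features):
    no_introns = [f for f in mini_features if f.ftype != "intron"]
    calls = pd.DataFrame([call_row(38, "+", "C", "T", 10, 100)])
    out = filtering.junction_filter(calls, no_introns, window=10)
    assert not out["flag_junction_artifact"].any()


# --- rRNA partition & canonical --------------------------------------------


def test_rrna_partition_and_spectrum(mini_features):
    calls = pd.DataFrame(
        [
            call_row(230, "+", "T", "A", 10, 100),  # inside rrnX
            call_row(231, "-", "A", "G", 10, 100),  # inside rrnX
            call_row(15, "+", "C", "T", 10, 100),
            call_row(120, "-", "C", "T", 10, 100),
        ]
    )
    in_rrna, outside, spectrum = filtering.rrna_partition(calls, mini_features)
    assert len(in_rrna) == 2 and len(outside) == 2
    assert spectrum.loc["T>A", "rRNA"] == 1
    assert spectrum.loc["A>G", "rRNA"] == 1
    assert spectrum.loc["C>T", "non_rRNA"] == 2
    assert spectrum["non_rRNA"].sum() == 2  # single type outside rRNA
    assert spectrum.values.sum() == 4


@pytest.mark.parametrize(
    "sub, flagged",
    [("C>T", False), ("T>C", False), ("A>G", True), ("T>G", True), ("G>A", True)],
)
def test_canonical_filter(sub, flagged):
    ref, alt = sub.split(">")
    calls = pd.DataFrame([call_row(15, "+", ref, alt, 10, 100)])
    out = filtering.canonical_filter(calls)
    assert bool(out.loc[0, "flag_noncanonical"]) is flagged


# --- carryover --------------------------------------------------------------


def test_carryover_flags_weak_complementary_shadow(mini_features):
    # coding C>T on geneM at vaf 0.5; '+' shadow G>A at 1/63
    calls = pd.DataFrame(
        [
            call_row(120, "-", "C", "T", 500, 1000),
            call_row(120, "+", "G", "A", 1, 63),
        ]
    )
    pileups = pileup_rows(
        [prow(120, "-", nC=500, nT=500), prow(120, "+", nG=62, nA=1)]
    )
    out = filtering.carryover_detector(calls, pileups, mini_features)
    by_strand = out.set_index("strand")["flag_antisense_carryover"]
    assert bool(by_strand["+"]) and not bool(by_strand["-"])


def test_carryover_ignores_non_complementary_opposite_signal(mini_features):
    # opposite-strand C>T is NOT the reverse complement of coding C>T
    calls = pd.DataFrame([call_row(120, "+", "C", "T", 2, 60)])
    pileups = pileup_rows(
        [prow(120, "-", nC=500, nT=500), prow(120, "+", nC=58, nT=2)]
    )
    out = filtering.carryover_detector(calls, pileups, mini_features)
    assert not out["flag_antisense_carryover"].any()


def test_carryover_respects_ratio_threshold(mini_features):
    calls = pd.DataFrame([call_row(120, "+", "G", "A", 20, 100)])  # 40% of coding
    pileups = pileup_rows(
        [prow(120, "-", nC=500, nT=500), prow(120, "+", nG=80, nA=20)]
    )
    out = filtering.carryover_detector(calls, pileups, mini_features)
    assert not out["flag_antisense_carryover"].any()


# --- strand concordance -----------------------------------------------------


@pytest.mark.parametrize(
    "expected, opposite, flagged",
    [(100, 5, False), (100, 20, True), (100, 0, False)],
)
def test_strand_concordance(mini_features, expected, opposite, flagged):
    calls = pd.DataFrame([call_row(15, "+", "C", "T", expected, 2 * expected)])
    pileups = pileup_rows(
        [
            prow(15, "+", nC=expected, nT=expected),
            prow(15, "-", nG=50, nA=opposite),
        ]
    )
    out = filtering.strand_concordance(calls, pileups)
    d = opposite / (expected + opposite) if expected + opposite else 0.0
    assert out.loc[0, "discordance"] == pytest.approx(d)
    assert bool(out.loc[0, "flag_strand_discordant"]) is flagged


# --- order independence -----------------------------------------------------


def test_flag_filters_commute(mini_features):
    calls = pd.DataFrame(
        [
            call_row(38, "+", "C", "T", 10, 100),
            call_row(230, "+", "T", "A", 10, 100),
            call_row(120, "+", "G", "A", 1, 63),
            call_row(120, "-", "C", "T", 500, 1000),
        ]
    )
    pileups = pileup_rows(
        [
            prow(38, "+", nC=90, nT=10),
            prow(230, "+", nT=90, nA=10),
            prow(120, "+", nG=62, nA=1),
            prow(120, "-", nC=500, nT=500),
        ]
    )
    idx = filtering.PileupIndex(pileups)
    ops = {
        "junction": lambda df: filtering.junction_filter(df, mini_features),
        "rrna": lambda df: df.assign(
            flag_rrna_region=filtering.add_context(df, mini_features)["region"] == "rRNA"
        ),
        "canonical": filtering.canonical_filter,
        "carryover": lambda df: filtering.carryover_detector(df, idx, mini_features),
        "concordance": lambda df: filtering.strand_concordance(df, idx),
    }
    results = []
    for order in itertools.islice(itertools.permutations(ops), 0, 24, 5):
        df = filtering.add_context(calls, mini_features)
        for name in order:
            df = ops[name](df)
        results.append(df[filtering.FLAG_COLUMNS[:-1]].reset_index(drop=True))
    for r in results[1:]:
        pd.testing.assert_frame_equal(results[0], r)


# --- synthetic headline property -------------------------------------------


def test_unflagged_canonical_coding_set_equals_truth_edits(default_run):
    """With every artifact channel on, filtering recovers exactly the edits."""
    _, reference, pileups = default_run
    calls = calling.call_candidates(pileups, reference.genome)
    classified = filtering.classify(calls, pileups, reference.features, reference.genome)
    keep = classified[
        ~classified[
            ["flag_junction_artifact", "flag_rrna_region",
             "flag_noncanonical", "flag_antisense_carryover"]
        ].any(axis=1)
        & classified["coding"]
    ]
    kept_sites = {(int(r.pos), r.strand, r.ref, r.alt) for r in keep.itertuples(index=False)}
    truth = reference.truth[reference.truth.klass == "edit"]
    truth_sites = {(r.pos, r.strand, r.ref, r.alt) for r in truth.itertuples(index=False)}
    assert kept_sites == truth_sites
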