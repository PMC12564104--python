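"""Coordinate harmonization, the site matrix and the high-confidence set."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from plastedit import calling, confidence, filtering
from plastedit.plastome import PlastomeSequence
from plastedit.simulate import SimulationConfig, simulate_dataset

BASE = "ACGT" * 75  # 300 bp


def aligned_trio():
    """A: reference; B: 2 bp insertion after pos 100; C: 10 bp deletion at 151-160."""
    a = BASE
    b = BASE[:100] + "GG" + BASE[100:]
    c = BASE[:150] + BASE[160:]
    aln = {
        "A": a[:100] + "--" + a[100:],
        "B": b,
        "C": a[:100] + "--" + a[100:150] + "-" * 10 + a[160:],
    }
    return {"A": a, "B": b, "C": c}, aln


# --- coordinate maps --------------------------------------------------------


def test_identity_map_for_identical_sequences():
    maps = confidence.build_coordinate_maps({"A": BASE, "B": BASE})
    for pos in (1, 150, 300):
        assert maps["A"].to_column(pos) == pos
        assert maps["B"].to_position(pos) == pos


def test_insertion_shifts_columns():
    seqs, aln = aligned_trio()
    maps = confidence.build_coordinate_maps(aln)
    # B's insertion occupies columns 101-102; A:101 <-> column 103 <-> B:103
    assert maps["A"].to_column(101) == 103
    assert maps["B"].to_column(103) == 103
    assert maps["B"].to_position(103) == 103
    assert maps["A"].to_position(101) is None  # gap column for A
    assert maps["B"].to_position(101) == 101


def test_deletion_unmapped_for_gapped_sample():
    _, aln = aligned_trio()
    maps = confidence.build_coordinate_maps(aln)
    # columns 153-162 are C's deletion gap
    assert maps["C"].to_position(155) is None
    assert maps["A"].to_position(155) == 153


def test_roundtrip_on_all_mapped_positions():
    _, aln = aligned_trio()
    maps = confidence.build_coordinate_maps(aln)
    for m in maps.values():
        for pos in range(1, m.length + 1):
            assert m.to_position(m.to_column(pos)) == pos


def test_genome_mismatch_is_hard_error():
    genomes = {"A": PlastomeSequence(id="A", bases="ACGT")}
    with pytest.raises(ValueError, match="does not match"):
        confidence.build_coordinate_maps({"A": "AC-GA"}, genomes)


def test_unequal_alignment_lengths_rejected():
    with pytest.raises(ValueError, match="unequal"):
        confidence.build_coordinate_maps({"A": "ACGT", "B": "ACGTT"})


# --- site matrix ------------------------------------------------------------

GENOME = PlastomeSequence(id="g", bases="ACGT" * 50)


def _pileup(sample, library, pos, strand, nC, nT):
    return [sample, library, pos, strand, 0, nC, 0, nT]


@pytest.fixture()
def scenario():
    """Two C>T sites across 3 samples x 2 libraries (pos 2 and pos 6).

    Site at pos 2 passes thresholds everywhere; site at pos 6 is detected in
    four experiments, sub-threshold (5%) in one and absent in one.
    """
    rows = []
    for sample in ("S1", "S2", "S3"):
        for library in ("total", "rrna_depleted"):
            rows.append(_pileup(sample, library, 2, "+", 50, 50))
            if (sample, library) == ("S3", "total"):
                rows.append(_pileup(sample, library, 6, "+", 95, 5))
            elif (sample, library) == ("S3", "rrna_depleted"):
                rows.append(_pileup(sample, library, 6, "+", 100, 0))
            else:
                rows.append(_pileup(sample, library, 6, "+", 70, 30))
    pileups = pd.DataFrame(rows, columns=calling.PILEUP_COLUMNS)
    calls = calling.call_candidates(pileups, GENOME)
    classified = filtering.classify(calls, pileups, [], GENOME)
    return classified, pileups


def test_site_matrix_statuses(scenario):
    classified, pileups = scenario
    matrix = confidence.build_site_matrix(classified, pileups)
    assert len(matrix.experiments) == 6
    counts = matrix.status_counts()
    assert counts.loc["2:+:C>T"].tolist() == [6, 0, 0]
    assert counts.loc["6:+:C>T"].tolist() == [4, 1, 1]
    sub = matrix.cells.query("site == '6:+:C>T' and status == 'sub_threshold'")
    assert sub.iloc[0]["efficiency"] == pytest.approx(0.05)


def test_high_confidence_retention_and_corroboration(scenario):
    classified, pileups = scenario
    matrix = confidence.build_site_matrix(classified, pileups)
    hc = confidence.derive_high_confidence(matrix, min_detected=2)
    assert sorted(hc["site"]) == ["2:+:C>T", "6:+:C>T"]


def test_high_confidence_monotone_in_min_detected(scenario):
    classified, pileups = scenario
    matrix = confidence.build_site_matrix(classified, pileups)
    sizes = [
        len(confidence.derive_high_confidence(matrix, k, require_corroboration=False))
        for k in (1, 2, 4, 5, 7)
    ]
    assert sizes == sorted(sizes, reverse=True)
    assert sizes[-1] == 0


def test_two_detections_need_corroboration():
    rows = []
    for i, (sample, library) in enumerate(
        itertools.product(("S1", "S2", "S3"), ("total", "rrna_depleted"))
    ):
        nT = 30 if i < 2 else 0  # detected twice, zero signal elsewhere
        rows.append(_pileup(sample, library, 2, "+", 100 - nT, nT))
    pileups = pd.DataFrame(rows, columns=calling.PILEUP_COLUMNS)
    calls = calling.call_candidates(pileups, GENOME)
    classified = filtering.classify(calls, pileups, [], GENOME)
    matrix = confidence.build_site_matrix(classified, pileups)
    assert len(confidence.derive_high_confidence(matrix, 2, require_corroboration=True)) == 0
    assert len(confidence.derive_high_confidence(matrix, 2, require_corroboration=False)) == 1


def test_coordinate_harmonization_in_matrix():
    # sample B has a 2 bp insertion: the same biological site (a C) sits at
    # B position 104 but at A position 102; alignment reconciles them.
    seqs, aln = aligned_trio()
    genomes = {s: PlastomeSequence(id=s, bases=seq) for s, seq in seqs.items()}
    maps = confidence.build_coordinate_maps(aln, genomes)
    rows = [
        _pileup("A", "total", 102, "+", 50, 50),
        _pileup("B", "total", 104, "+", 40, 60),
    ]
    pileups = pd.DataFrame(rows, columns=calling.PILEUP_COLUMNS)
    calls = pd.concat(
        [
            calling.call_candidates(pileups[pileups["sample"] == s], genomes[s])
            for s in ("A", "B")
        ],
        ignore_index=True,
    )
    classified = filtering.classify(calls, pileups, [], genomes["A"])
    matrix = confidence.build_site_matrix(classified, pileups, maps)
    assert matrix.sites == ["104:+:C>T"]
    assert (matrix.cells["status"] == "detected").all()


# --- intersections ----------------------------------------------------------


def _random_matrix(rng, n_sites=40, n_exp=6):
    experiments = [f"S{i}:total" for i in range(n_exp)]
    cells, meta = [], []
    for s in range(n_sites):
        site = f"{s + 1}:+:C>T"
        detected = rng.random(n_exp) < 0.5
        meta.append(
            {"site": site, "column": s + 1, "strand": "+", "substitution": "C>T",
             "region": "CDS", "gene": "g", "coding": True, "canonical": True}
        )
        for e, d in zip(experiments, detected):
            sample, library = e.split(":")
            cells.append(
                {"site": site, "column": s + 1, "strand": "+", "substitution": "C>T",
                 "sample": sample, "library": library, "experiment": e,
                 "status": "detected" if d else "absent", "efficiency": 0.5 if d else 0.0,
                 "var_reads": 50 if d else 0, "depth": 100, "note": ""}
            )
    return confidence.SiteMatrix(
        cells=pd.DataFrame(cells), meta=pd.DataFrame(meta), experiments=experiments
    )


def test_intersections_match_brute_force_enumeration():
    rng = np.random.default_rng(13)
    matrix = _random_matrix(rng)
    inter, totals = confidence.intersections(matrix)
    det = matrix.detected_sets()
    # brute force over all 63 non-empty experiment subsets
    exps = matrix.experiments
    for r in range(1, len(exps) + 1):
        for subset in itertools.combinations(exps, r):
            expected = sum(1 for v in det.values() if v == frozenset(subset))
            key = ",".join(sorted(subset))
            got = inter.loc[inter["subset"] == key, "count"]
            assert (int(got.iloc[0]) if len(got) else 0) == expected
    assert inter["count"].sum() == sum(1 for v in det.values() if v)
    per_set = dict(zip(totals["experiment"], totals["n_sites"]))
    for e in exps:
        assert per_set[e] == sum(1 for v in det.values() if e in v)


def test_intersections_disjoint_sets_are_singletons():
    experiments = ["S0:total", "S1:total"]
    cells = []
    for i, e in enumerate(experiments):
        sample, library = e.split(":")
        for other in experiments:
            osample, olibrary = other.split(":")
            cells.append(
                {"site": f"{i + 1}:+:C>T", "column": i + 1, "strand": "+",
                 "substitution": "C>T", "sample": osample, "library": olibrary,
                 "experiment": other,
                 "status": "detected" if other == e else "absent",
                 "efficiency": 0.0, "var_reads": 0, "depth": 0, "note": ""}
            )
    meta = pd.DataFrame(
        [{"site": f"{i + 1}:+:C>T", "column": i + 1, "strand": "+",
          "substitution": "C>T", "region": "CDS", "gene": "g", "coding": True,
          "canonical": True} for i in range(2)]
    )
    matrix = confidence.SiteMatrix(pd.DataFrame(cells), meta, experiments)
    inter, _ = confidence.intersections(matrix)
    assert set(inter["degree"]) == {1} and inter["count"].sum() == 2


# --- strategy comparison ----------------------------------------------------


@pytest.fixture(scope="module")
def three_strategy_run():
    config = SimulationConfig(
        seed=21, genome_length=12_000, n_genes=4, n_edit_sites=12,
        coverage={"total": 300.0, "rrna_depleted": 300.0, "mrna": 5.0},
        libraries=("total", "rrna_depleted", "mrna"),
    )
    reference, pileups = simulate_dataset(config)
    calls = calling.call_candidates(pileups, reference.genome)
    classified = filtering.classify(calls, pileups, reference.features, reference.genome)
    matrix = confidence.build_site_matrix(classified, pileups)
    truth = reference.truth[reference.truth.klass == "edit"]
    ref_sites = [f"{r.pos}:{r.strand}:{r.ref}>{r.alt}" for r in truth.itertuples(index=False)]
    return matrix, ref_sites


def test_shallow_mrna_recall_below_total(three_strategy_run):
    matrix, ref_sites = three_strategy_run
    comp = confidence.compare_strategies(matrix, ref_sites).set_index("library")
    assert comp.loc["mrna", "recall_all_replicates"] < comp.loc["total", "recall_all_replicates"]
    assert comp.loc["total", "recall_all_replicates"] == pytest.approx(1.0)


def test_zero_artifact_run_has_zero_artifact_counts(clean_run):
    _, reference, pileups = clean_run
    calls = calling.call_candidates(pileups, reference.genome)
    classified = filtering.classify(calls, pileups, reference.features, reference.genome)
    matrix = confidence.build_site_matrix(classified, pileups)
    comp = confidence.compare_strategies(matrix, matrix.sites)
    assert (comp["rrna_region_sites"] == 0).all()
    assert (comp["noncanonical_sites"] == 0).all()
    assert (comp["noncoding_strand_sites"] == 0).all()
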