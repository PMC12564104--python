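"""Four-class technical artifact filtering for candidate editing sites.

Strand-specific plastid RNA-seq produces four recurrent artifact classes on
top of genuine C→U editing:

1. splice-junction misalignment — spurious mismatches within a few bases of
   exon–intron boundaries;
2. dUTP second-strand carryover — faint opposite-strand signals that are the
   reverse complement of a real coding-strand edit (G→A mirroring C→U);
3. rRNA-modification misincorporation — a diverse multi-type substitution
   spectrum confined to rRNA loci, mostly on the noncoding strand;
4. strand misassignment — a caller reporting a C→U event as G→A on the
   opposite strand when the coding strand carries the dominant signal.

Filters set flags rather than deleting rows: exclusion policy is applied at
the reproducibility/high-confidence stage, keeping every decision auditable.
Every flag is computed from the candidate set, pileups and gene models only,
so the flagging operations commute and are idempotent.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .calling import BASES, COUNT_COLUMNS
from .plastome import GeneFeature, PlastomeSequence, complement, locate

__all__ = [
    "CANONICAL",
    "FLAG_COLUMNS",
    "PileupIndex",
    "add_context",
    "reassign_to_coding_strand",
    "junction_filter",
    "rrna_partition",
    "canonical_filter",
    "carryover_detector",
    "strand_concordance",
    "classify",
    "substitution_types",
    "write_classified",
]

#: substitutions retained as plausible plant-plastid editing chemistry
CANONICAL = frozenset({"C>T", "T>C"})

FLAG_COLUMNS = [
    "flag_junction_artifact",
    "flag_rrna_region",
    "flag_noncanonical",
    "flag_antisense_carryover",
    "flag_strand_discordant",
    "strand_reassigned",
]


def substitution_types() -> list[str]:
    """The 12 directed substitution types in transcript orientation."""
    return [f"{r}>{a}" for r in BASES for a in BASES if r != a]


class PileupIndex:
    """O(1) lookup of per-base counts by (sample, library, pos, strand)."""

    def __init__(self, pileups: pd.DataFrame):
        self._counts: dict[tuple, np.ndarray] = {}
        keys = zip(
            pileups["sample"], pileups["library"], pileups["pos"], pileups["strand"]
        )
        mat = pileups[COUNT_COLUMNS].to_numpy(dtype=np.int64)
        for i, (s, l, p, st) in enumerate(keys):
            self._counts[(s, l, int(p), st)] = mat[i]

    def counts(self, sample: str, library: str, pos: int, strand: str) -> np.ndarray:
        return self._counts.get((sample, library, pos, strand), np.zeros(4, np.int64))

    def base_count(self, sample: str, library: str, pos: int, strand: str, base: str) -> int:
        return int(self.counts(sample, library, pos, strand)[BASES.index(base)])

    def depth(self, sample: str, library: str, pos: int, strand: str) -> int:
        return int(self.counts(sample, library, pos, strand).sum())


def _ensure_context(calls: pd.DataFrame, features: Sequence[GeneFeature]) -> pd.DataFrame:
    if "region" in calls.columns:
        return calls.copy()
    return add_context(calls, features)


def add_context(calls: pd.DataFrame, features: Sequence[GeneFeature]) -> pd.DataFrame:
    """Attach region class, owning gene and coding-strand status to calls.

    Region classification depends on the position only; ``coding`` records
    whether the call's strand matches the owning gene's strand (True for
    positions with no gene model).
    """
    calls = calls.copy()
    cache: dict[int, tuple[str, str | None, str | None]] = {}
    regions, genes, gstrands = [], [], []
    for pos in calls["pos"]:
        pos = int(pos)
        if pos not in cache:
            loc = locate(pos, features)
            cache[pos] = (loc.region, loc.gene, loc.feature.strand if loc.feature else None)
        r, g, gs = cache[pos]
        regions.append(r)
        genes.append(g)
        gstrands.append(gs)
    calls["region"] = regions
    calls["gene"] = genes
    calls["gene_strand"] = gstrands
    calls["coding"] = [
        gs is None or st == gs for st, gs in zip(calls["strand"], gstrands)
    ]
    calls["substitution"] = calls["ref"].str.cat(calls["alt"], sep=">")
    return calls


def reassign_to_coding_strand(
    calls: pd.DataFrame,
    pileups: pd.DataFrame | PileupIndex,
    features: Sequence[GeneFeature],
    carryover_guard_ratio: float = 0.10,
    min_support: int = 3,
) -> pd.DataFrame:
    """Correct G→A calls misassigned to the strand opposite a gene.

    A call reported as G→A antisense to an annotated gene, where the coding
    strand carries the complementary C→T signal at a strictly higher VAF,
    is re-expressed as C→T on the coding strand with its coding-strand
    support, and flagged ``strand_reassigned``. Applying the operation twice
    equals applying it once.

    A misassigned call carries (essentially) the full coding-strand signal
    on the wrong strand, whereas a physical second-strand carryover shadow
    sits far below it; calls whose VAF is at most ``carryover_guard_ratio``
    of the coding-strand VAF are therefore left for the carryover detector
    rather than rewritten.
    """
    calls = _ensure_context(calls, features)
    idx = pileups if isinstance(pileups, PileupIndex) else PileupIndex(pileups)
    if "strand_reassigned" not in calls.columns:
        calls["strand_reassigned"] = False
    for i in calls.index:
        row = calls.loc[i]
        if row["gene_strand"] is None or row["coding"]:
            continue
        if row["substitution"] != "G>A" or row["var_reads"] < min_support:
            # a misassigned call carries real support; sparse antisense
            # reads are error/carryover territory
            continue
        pos, gs = int(row["pos"]), row["gene_strand"]
        coding_counts = idx.counts(row["sample"], row["library"], pos, gs)
        coding_depth = int(coding_counts.sum())
        if coding_depth == 0:
            continue
        alt_reads = int(coding_counts[BASES.index("T")])
        coding_vaf = alt_reads / coding_depth
        if coding_vaf > row["vaf"] > carryover_guard_ratio * coding_vaf:
            calls.loc[i, ["strand", "ref", "alt", "substitution"]] = [gs, "C", "T", "C>T"]
            calls.loc[i, ["var_reads", "depth", "vaf"]] = [alt_reads, coding_depth, coding_vaf]
            calls.loc[i, ["coding", "strand_reassigned"]] = [True, True]
    # a reassigned call may now duplicate a directly-called coding-strand row
    key = ["sample", "library", "pos", "strand", "ref", "alt"]
    calls = (
        calls.sort_values("strand_reassigned")  # keep the original call first
        .groupby(key, as_index=False, sort=False)
        .agg(
            {
                **{c: "first" for c in calls.columns if c not in key + ["strand_reassigned"]},
                "strand_reassigned": "any",
            }
        )
    )
    return calls.sort_values(["sample", "library", "pos", "strand"]).reset_index(drop=True)


def junction_filter(
    calls: pd.DataFrame,
    features: Sequence[GeneFeature],
    window: int = 10,
) -> pd.DataFrame:
    """Flag variants within ``window`` bp of any exon–intron boundary."""
    calls = _ensure_context(calls, features)
    boundaries: list[int] = []
    for f in features:
        if f.ftype != "intron":
            continue
        for s, e in f.exons:
            boundaries.extend((s, e))
    barr = np.array(sorted(boundaries)) if boundaries else np.array([], dtype=int)
    if barr.size:
        pos = calls["pos"].to_numpy(dtype=np.int64)
        j = np.searchsorted(barr, pos)
        dist = np.full(len(pos), np.iinfo(np.int64).max)
        left_ok = j > 0
        dist[left_ok] = np.abs(pos[left_ok] - barr[j[left_ok] - 1])
        right_ok = j < barr.size
        dist[right_ok] = np.minimum(dist[right_ok], np.abs(barr[j[right_ok]] - pos[right_ok]))
        calls["flag_junction_artifact"] = dist <= window
    else:
        calls["flag_junction_artifact"] = False
    return calls


def rrna_partition(
    calls: pd.DataFrame, features: Sequence[GeneFeature]
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Partition calls by rRNA-locus membership and tabulate spectra.

    Returns (rRNA-region calls, non-rRNA calls, spectrum summary). The
    summary counts variants per directed substitution type in each
    partition — the two-way layout contrasting the diverse rRNA spectrum
    with the C→T-dominated pattern elsewhere. Also sets ``flag_rrna_region``.
    """
    calls = _ensure_context(calls, features)
    calls["flag_rrna_region"] = calls["region"] == "rRNA"
    in_rrna = calls[calls["flag_rrna_region"]]
    outside = calls[~calls["flag_rrna_region"]]
    spectrum = pd.DataFrame(
        {
            "rRNA": in_rrna["substitution"].value_counts(),
            "non_rRNA": outside["substitution"].value_counts(),
        }
    ).reindex(substitution_types()).fillna(0).astype(int)
    spectrum.index.name = "substitution"
    return in_rrna, outside, spectrum


def canonical_filter(calls: pd.DataFrame) -> pd.DataFrame:
    """Flag substitutions other than C→T / T→C as noncanonical."""
    calls = calls.copy()
    if "substitution" not in calls.columns:
        calls["substitution"] = calls["ref"].str.cat(calls["alt"], sep=">")
    calls["flag_noncanonical"] = ~calls["substitution"].isin(CANONICAL)
    return calls


def carryover_detector(
    calls: pd.DataFrame,
    pileups: pd.DataFrame | PileupIndex,
    features: Sequence[GeneFeature],
    max_opposite_ratio: float = 0.10,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Flag opposite-strand shadows of coding-strand edits.

    A variant on the strand opposite the local gene is flagged
    ``antisense_carryover`` iff the coding strand carries the
    reverse-complementary substitution at the same position and the
    opposite-strand signal is no stronger than ``max_opposite_ratio`` times
    the coding-strand VAF — the signature of incomplete dUTP second-strand
    degradation. The comparison accepts either the plug-in VAF ratio or,
    because one or two stray reads at shallow opposite-strand depth can
    inflate that ratio far above the true carryover rate, a one-sided
    binomial consistency check: the shadow is also flagged when its read
    count is plausible (tail probability >= ``alpha``) under a carryover
    rate of ``max_opposite_ratio`` x coding VAF. Coding-strand calls are
    never flagged by this rule; outside gene models the higher-VAF strand
    is taken as the source.
    """
    from scipy.stats import binom

    calls = _ensure_context(calls, features)
    idx = pileups if isinstance(pileups, PileupIndex) else PileupIndex(pileups)
    flags = []
    for row in calls.itertuples(index=False):
        source_strand = row.gene_strand
        if source_strand is None:
            source_strand = "-" if row.strand == "+" else "+"
        elif row.strand == source_strand:
            flags.append(False)  # coding-strand calls are candidate sources
            continue
        counts = idx.counts(row.sample, row.library, int(row.pos), source_strand)
        depth = int(counts.sum())
        if depth == 0:
            flags.append(False)
            continue
        source_alt = complement(row.alt)
        source_vaf = counts[BASES.index(source_alt)] / depth
        if source_vaf <= 0:
            flags.append(False)
            continue
        ratio_ok = row.vaf / source_vaf <= max_opposite_ratio
        consistent = (
            binom.sf(row.var_reads - 1, row.depth, max_opposite_ratio * source_vaf)
            >= alpha
        )
        flags.append(bool(ratio_ok or consistent))
    calls["flag_antisense_carryover"] = flags
    return calls


def strand_concordance(
    calls: pd.DataFrame,
    pileups: pd.DataFrame | PileupIndex,
    max_discordance: float = 0.10,
) -> pd.DataFrame:
    """Flag calls whose variant support leaks onto the opposite strand.

    Discordance is opposite-strand variant reads (the complementary base)
    over total variant reads on both strands; values above
    ``max_discordance`` mark the call as needing inspection, not rejection.
    """
    calls = calls.copy()
    idx = pileups if isinstance(pileups, PileupIndex) else PileupIndex(pileups)
    disc, flags = [], []
    for row in calls.itertuples(index=False):
        opp = "-" if row.strand == "+" else "+"
        opp_reads = idx.base_count(
            row.sample, row.library, int(row.pos), opp, complement(row.alt)
        )
        total = row.var_reads + opp_reads
        d = opp_reads / total if total else 0.0
        disc.append(d)
        flags.append(d > max_discordance)
    calls["discordance"] = disc
    calls["flag_strand_discordant"] = flags
    return calls


def classify(
    calls: pd.DataFrame,
    pileups: pd.DataFrame,
    features: Sequence[GeneFeature],
    genome: PlastomeSequence | None = None,
    junction_window: int = 10,
    max_opposite_ratio: float = 0.10,
    max_discordance: float = 0.10,
) -> pd.DataFrame:
    """Run the full artifact classification over candidate calls.

    Strand reassignment (a rewrite) runs first; the four flagging filters
    then commute, so their order is immaterial.
    """
    idx = PileupIndex(pileups)
    out = add_context(calls, features)
    out = reassign_to_coding_strand(
        out, idx, features, carryover_guard_ratio=max_opposite_ratio
    )
    out = junction_filter(out, features, window=junction_window)
    out["flag_rrna_region"] = out["region"] == "rRNA"
    out = canonical_filter(out)
    out = carryover_detector(out, idx, features, max_opposite_ratio=max_opposite_ratio)
    out = strand_concordance(out, idx, max_discordance=max_discordance)
    return out.reset_index(drop=True)


def write_classified(calls: pd.DataFrame, path: str | Path) -> None:
    calls.to_csv(path, sep="\t", index=False, float_format="%.6g")
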