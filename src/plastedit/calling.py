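"""Strand-aware variant calling from strand-specific per-base pileups.

The pileup dialect is a header-bearing TSV with columns
``sample  library  pos  strand  nA  nC  nG  nT`` giving per-base read counts
for one (sample, library, position, strand). Counts are strand-local
(transcript orientation): on a minus-strand row, ``nC`` counts reads whose
base is C when read 5'->3' along the minus strand. Candidate variants are called
per strand under two thresholds: minimum variant-supporting reads (default
3) and minimum variant allele fraction (default 0.10), with the VAF
denominator being the full strand depth at the site. Reference and variant
bases are always expressed in transcript orientation: on the minus strand
the reference is the complement of the plastome-forward base.

A relaxed query (support >= 1 read, any positive VAF) recovers sub-threshold
evidence, which the reproducibility stage uses to distinguish "present but
below threshold" from "absent".
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
import pysam

from .plastome import PlastomeSequence, complement

__all__ = [
    "BASES",
    "LIBRARIES",
    "PILEUP_COLUMNS",
    "StrandPileupRecord",
    "read_pileup",
    "write_pileup",
    "iter_records",
    "call_candidates",
    "relaxed_candidates",
    "pileup_from_alignments",
    "write_calls",
]

BASES = ("A", "C", "G", "T")
LIBRARIES = ("total", "rrna_depleted", "mrna")
PILEUP_COLUMNS = ["sample", "library", "pos", "strand", "nA", "nC", "nG", "nT"]
COUNT_COLUMNS = ["nA", "nC", "nG", "nT"]

CALL_COLUMNS = [
    "sample", "library", "pos", "strand", "ref", "alt",
    "var_reads", "depth", "vaf", "multi_allelic",
]


@dataclass(frozen=True)
class StrandPileupRecord:
    """Per-position, per-strand base counts for one sample x library."""

    sample: str
    library: str
    pos: int
    strand: str
    counts: dict[str, int]

    @property
    def depth(self) -> int:
        return sum(self.counts.values())


def iter_records(pileups: pd.DataFrame) -> Iterator[StrandPileupRecord]:
    for row in pileups.itertuples(index=False):
        yield StrandPileupRecord(
            sample=row.sample,
            library=row.library,
            pos=int(row.pos),
            strand=row.strand,
            counts={b: int(getattr(row, f"n{b}")) for b in BASES},
        )


def _validate(df: pd.DataFrame, origin: str) -> pd.DataFrame:
    missing = [c for c in PILEUP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{origin}: missing pileup columns {missing}")
    df = df[PILEUP_COLUMNS].copy()
    if not df["strand"].isin(["+", "-"]).all():
        bad = sorted(set(df["strand"]) - {"+", "-"})
        raise ValueError(f"{origin}: invalid strand value(s) {bad}")
    counts = df[COUNT_COLUMNS].to_numpy()
    if (counts < 0).any():
        raise ValueError(f"{origin}: negative base counts")
    if (df["pos"] < 1).any():
        raise ValueError(f"{origin}: positions must be 1-based")
    dup = df.duplicated(subset=["sample", "library", "pos", "strand"])
    if dup.any():
        first = df[dup].iloc[0]
        raise ValueError(
            f"{origin}: duplicate pileup row for "
            f"({first['sample']}, {first['library']}, {first['pos']}, {first['strand']})"
        )
    df["depth"] = counts.sum(axis=1)
    return df


def read_pileup(path: str | Path) -> pd.DataFrame:
    """Read and validate a strand-specific pileup TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "library": str, "strand": str})
    return _validate(df, str(path))


def write_pileup(pileups: pd.DataFrame, path: str | Path) -> None:
    pileups[PILEUP_COLUMNS].to_csv(path, sep="\t", index=False)


def _ref_bases(pos: np.ndarray, strand: np.ndarray, genome: PlastomeSequence) -> np.ndarray:
    arr = np.frombuffer(genome.bases.encode(), dtype="S1")
    ref = arr[pos - 1].astype("U1")
    comp = np.array([complement(b) for b in ref])
    return np.where(strand == "+", ref, comp)


def call_candidates(
    pileups: pd.DataFrame,
    genome: PlastomeSequence,
    min_var_reads: int = 3,
    min_vaf: float = 0.10,
) -> pd.DataFrame:
    """Call per-strand candidate variants above support and VAF thresholds.

    For each (sample, library, pos, strand) record the highest-count
    non-reference base is evaluated; a candidate is emitted iff its
    supporting reads >= ``min_var_reads`` and its VAF (variant reads over
    total strand depth) >= ``min_vaf``. Sites where a second non-reference
    base also reaches ``min_var_reads`` are flagged multi-allelic but still
    report only the major alternative.
    """
    if "depth" not in pileups.columns:
        pileups = _validate(pileups, "<memory>")
    if pileups.empty:
        return pd.DataFrame(columns=CALL_COLUMNS)
    pos = pileups["pos"].to_numpy(dtype=np.int64)
    if pos.max() > genome.length:
        raise ValueError("pileup position beyond genome length")
    strand = pileups["strand"].to_numpy(dtype="U1")
    ref = _ref_bases(pos, strand, genome)
    counts = pileups[COUNT_COLUMNS].to_numpy(dtype=np.int64)
    depth = counts.sum(axis=1)

    base_index = {b: i for i, b in enumerate(BASES)}
    ref_idx = np.array([base_index.get(b, -1) for b in ref])
    nonref = counts.copy()
    rows = np.arange(len(nonref))
    valid_ref = ref_idx >= 0  # N reference positions yield no calls
    nonref[rows[valid_ref], ref_idx[valid_ref]] = -1
    alt_idx = nonref.argmax(axis=1)
    var_reads = nonref[rows, alt_idx]
    n_alleles = (nonref >= max(min_var_reads, 1)).sum(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        vaf = np.where(depth > 0, var_reads / np.maximum(depth, 1), 0.0)
    keep = valid_ref & (var_reads >= min_var_reads) & (vaf >= min_vaf) & (var_reads > 0)

    out = pd.DataFrame(
        {
            "sample": pileups["sample"].to_numpy()[keep],
            "library": pileups["library"].to_numpy()[keep],
            "pos": pos[keep],
            "strand": strand[keep],
            "ref": ref[keep],
            "alt": np.array(BASES)[alt_idx[keep]],
            "var_reads": var_reads[keep],
            "depth": depth[keep],
            "vaf": vaf[keep],
            "multi_allelic": (n_alleles[keep] >= 2),
        }
    )
    return out.reset_index(drop=True)


def relaxed_candidates(
    pileups: pd.DataFrame,
    genome: PlastomeSequence,
    positions: Iterable[int] | None = None,
) -> pd.DataFrame:
    """Sub-threshold query: any non-reference signal with >= 1 read.

    Used to report evidence such as a site "present at 9% editing
    frequency" in an experiment where it fails the calling thresholds.
    """
    if positions is not None:
        wanted = set(int(p) for p in positions)
        pileups = pileups[pileups["pos"].isin(wanted)]
    return call_candidates(pileups, genome, min_var_reads=1, min_vaf=0.0)


def write_calls(calls: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in calls.columns]
    calls[cols].to_csv(path, sep="\t", index=False, float_format="%.6g")


def pileup_from_alignments(
    path: str | Path,
    genome: PlastomeSequence,
    sample: str,
    library: str = "total",
    strandedness: str = "RF",
    min_mapq: int = 1,
) -> pd.DataFrame:
    """Build strand-specific pileups from a coordinate-sorted SAM/BAM.

    Transcript strand follows the dUTP (RF) convention: mate 1 maps
    antisense to the transcript, mate 2 sense. Secondary, supplementary,
    duplicate-flagged, QC-fail and sub-MAPQ alignments are skipped, so only
    primary unique alignments contribute. Only aligned matches are counted
    (no indel or clipped bases).
    """
    if strandedness != "RF":
        raise ValueError("only the RF (dUTP) strandedness convention is supported")
    counts: dict[tuple[int, str], np.ndarray] = {}
    base_index = {b: i for i, b in enumerate(BASES)}
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        so = (af.header.to_dict().get("HD") or {}).get("SO")
        if so != "coordinate":
            raise ValueError(f"{path}: alignments must be coordinate-sorted (SO={so})")
        for read in af:
            if (
                read.is_unmapped
                or read.is_secondary
                or read.is_supplementary
                or read.is_duplicate
                or read.is_qcfail
                or read.mapping_quality < min_mapq
                or not read.is_paired
            ):
                continue
            # RF: read1 antisense to transcript
            if read.is_read1:
                strand = "+" if read.is_reverse else "-"
            else:
                strand = "-" if read.is_reverse else "+"
            seq = read.query_sequence
            if seq is None:
                continue
            for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                base = seq[qpos].upper()
                if base not in base_index:
                    continue
                if strand == "-":
                    # pileup counts are strand-local (transcript orientation)
                    base = complement(base)
                key = (rpos + 1, strand)
                if key not in counts:
                    counts[key] = np.zeros(4, dtype=np.int64)
                counts[key][base_index[base]] += 1
    rows = [
        {
            "sample": sample,
            "library": library,
            "pos": pos,
            "strand": strand,
            **{f"n{b}": int(c[i]) for i, b in enumerate(BASES)},
        }
        for (pos, strand), c in sorted(counts.items())
    ]
    df = pd.DataFrame(rows, columns=PILEUP_COLUMNS)
    return _validate(df, str(path)) if not df.empty else df
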