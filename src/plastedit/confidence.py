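"""Cross-sample coordinate harmonization and the high-confidence site set.

Samples are assembled and called against their own plastomes, so positions
are harmonized through a whole-plastome multiple alignment: each sample gets
a bijection between its genome positions and alignment columns (gap columns
are unmapped). Sites are keyed by (alignment column, strand, substitution);
a site x experiment matrix records, per experiment, whether the site was
detected under the calling thresholds, present sub-threshold (any
variant-supporting read), or absent. The high-confidence set retains
canonical, non-rRNA, coding-strand, artifact-unflagged sites reproducibly
detected across experiments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .calling import BASES
from .filtering import CANONICAL, PileupIndex
from .plastome import PlastomeSequence

__all__ = [
    "CoordinateMap",
    "build_coordinate_maps",
    "SiteMatrix",
    "build_site_matrix",
    "derive_high_confidence",
    "intersections",
    "compare_strategies",
]

STATUS = ("detected", "sub_threshold", "absent")


@dataclass(frozen=True)
class CoordinateMap:
    """Bijection between one sample's genome positions and alignment columns."""

    sample: str
    pos_to_col: np.ndarray  # index pos-1 -> 1-based column
    col_to_pos: np.ndarray  # index col-1 -> 1-based position, 0 at gaps

    @classmethod
    def from_aligned(cls, sample: str, aligned: str) -> "CoordinateMap":
        arr = np.frombuffer(aligned.upper().encode(), dtype="S1")
        ungapped = arr != b"-"
        col_to_pos = np.where(ungapped, np.cumsum(ungapped), 0)
        pos_to_col = np.nonzero(ungapped)[0] + 1
        return cls(sample=sample, pos_to_col=pos_to_col, col_to_pos=col_to_pos)

    @property
    def length(self) -> int:
        return len(self.pos_to_col)

    def to_column(self, pos: int) -> int:
        if not 1 <= pos <= self.length:
            raise IndexError(f"position {pos} outside sequence of length {self.length}")
        return int(self.pos_to_col[pos - 1])

    def to_position(self, col: int) -> int | None:
        """Sample position at an alignment column, or None in a gap."""
        if not 1 <= col <= len(self.col_to_pos):
            raise IndexError(f"column {col} outside alignment")
        p = int(self.col_to_pos[col - 1])
        return p if p else None


def build_coordinate_maps(
    alignment: str | Path | Mapping[str, str],
    genomes: Mapping[str, PlastomeSequence] | None = None,
) -> dict[str, CoordinateMap]:
    """Build per-sample coordinate maps from an aligned FASTA (or dict).

    If ``genomes`` is given, each ungapped aligned sequence must equal its
    sample's genome sequence exactly.
    """
    if isinstance(alignment, (str, Path)):
        seqs = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(alignment), "fasta")}
    else:
        seqs = {k: v.upper() for k, v in alignment.items()}
    if not seqs:
        raise ValueError("empty alignment")
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise ValueError("aligned sequences have unequal lengths")
    maps = {}
    for sample, aligned in seqs.items():
        if genomes is not None:
            if sample not in genomes:
                raise ValueError(f"no genome provided for aligned sample {sample!r}")
            if aligned.replace("-", "") != genomes[sample].bases:
                raise ValueError(
                    f"aligned sequence for {sample!r} does not match its genome"
                )
        maps[sample] = CoordinateMap.from_aligned(sample, aligned)
    return maps


def _exp_label(sample: str, library: str) -> str:
    return f"{sample}:{library}"


@dataclass
class SiteMatrix:
    """Site x experiment evidence matrix.

    ``cells`` is long-form: one row per (site, experiment) with status,
    efficiency, variant reads and depth. ``meta`` carries one row per site
    with region/gene context and OR-aggregated artifact flags.
    """

    cells: pd.DataFrame
    meta: pd.DataFrame
    experiments: list[str] = field(default_factory=list)

    @property
    def sites(self) -> list[str]:
        return list(self.meta["site"])

    def detected_sets(self) -> dict[str, frozenset[str]]:
        det = self.cells[self.cells["status"] == "detected"]
        out = {site: frozenset() for site in self.sites}
        for site, grp in det.groupby("site"):
            out[site] = frozenset(grp["experiment"])
        return out

    def status_counts(self) -> pd.DataFrame:
        tab = (
            self.cells.pivot_table(
                index="site", columns="status", values="experiment",
                aggfunc="count", fill_value=0,
            )
            .reindex(columns=list(STATUS), fill_value=0)
        )
        return tab

    def to_wide(self) -> pd.DataFrame:
        wide = self.cells.pivot(index="site", columns="experiment", values="status")
        return self.meta.set_index("site").join(wide)

    def write(self, path: str | Path) -> None:
        self.to_wide().to_csv(path, sep="\t")


def build_site_matrix(
    classified: pd.DataFrame,
    pileups: pd.DataFrame,
    maps: Mapping[str, CoordinateMap] | None = None,
    min_var_reads: int = 3,
    min_vaf: float = 0.10,
) -> SiteMatrix:
    """Assemble the site x experiment matrix from classified calls.

    ``classified`` holds threshold-passing calls from every experiment
    (with context and flags); ``pileups`` supplies sub-threshold evidence
    for experiments where a site was not called. ``maps`` harmonizes
    per-sample coordinates; omit it when all samples share one genome.
    """
    pidx = PileupIndex(pileups)
    experiments = sorted(
        {_exp_label(s, l) for s, l in zip(pileups["sample"], pileups["library"])}
    )

    def site_key(sample: str, pos: int, strand: str, sub: str) -> tuple:
        col = maps[sample].to_column(pos) if maps is not None else pos
        return (col, strand, sub)

    flag_cols = [c for c in classified.columns if c.startswith("flag_")]
    site_meta: dict[tuple, dict] = {}
    site_calls: dict[tuple, dict[str, dict]] = {}
    for row in classified.itertuples(index=False):
        key = site_key(row.sample, int(row.pos), row.strand, f"{row.ref}>{row.alt}")
        exp = _exp_label(row.sample, row.library)
        meta = site_meta.setdefault(
            key,
            {
                "region": row.region,
                "gene": row.gene,
                "coding": bool(row.coding),
                "canonical": f"{row.ref}>{row.alt}" in CANONICAL,
                **{c: False for c in flag_cols},
            },
        )
        for c in flag_cols:
            meta[c] = meta[c] or bool(getattr(row, c))
        detected = row.var_reads >= min_var_reads and row.vaf >= min_vaf
        site_calls.setdefault(key, {})[exp] = {
            "status": "detected" if detected else "sub_threshold",
            "efficiency": float(row.vaf),
            "var_reads": int(row.var_reads),
            "depth": int(row.depth),
            "note": "",
        }

    cells = []
    for key in sorted(site_meta):
        col, strand, sub = key
        site_id = f"{col}:{strand}:{sub}"
        alt = sub.split(">")[1]
        for exp in experiments:
            sample, library = exp.split(":", 1)
            cell = site_calls.get(key, {}).get(exp)
            if cell is None:
                pos = (
                    maps[sample].to_position(col) if maps is not None else col
                )
                if pos is None:
                    cell = {
                        "status": "absent", "efficiency": 0.0,
                        "var_reads": 0, "depth": 0, "note": "no_counterpart",
                    }
                else:
                    counts = pidx.counts(sample, library, pos, strand)
                    depth = int(counts.sum())
                    var = int(counts[BASES.index(alt)])
                    cell = {
                        "status": "sub_threshold" if var > 0 else "absent",
                        "efficiency": var / depth if depth else 0.0,
                        "var_reads": var,
                        "depth": depth,
                        "note": "",
                    }
            cells.append(
                {"site": site_id, "column": col, "strand": strand,
                 "substitution": sub, "sample": sample, "library": library,
                 "experiment": exp, **cell}
            )

    meta_rows = [
        {"site": f"{col}:{strand}:{sub}", "column": col, "strand": strand,
         "substitution": sub, **m}
        for (col, strand, sub), m in sorted(site_meta.items())
    ]
    return SiteMatrix(
        cells=pd.DataFrame(cells),
        meta=pd.DataFrame(meta_rows),
        experiments=experiments,
    )


def derive_high_confidence(
    matrix: SiteMatrix,
    min_detected: int = 2,
    require_corroboration: bool = True,
) -> pd.DataFrame:
    """Select the final high-confidence editing site set.

    Retains sites that are canonical (C→T / T→C in transcript orientation),
    outside rRNA loci, on the coding strand, free of junction and carryover
    flags, and detected in at least ``min_detected`` experiments. With
    ``require_corroboration`` and ``min_detected == 2``, a site detected in
    exactly two experiments must additionally show sub-threshold signal in
    at least one further experiment.
    """
    if matrix.meta.empty:
        return matrix.meta.copy()
    status = matrix.status_counts()
    meta = matrix.meta.set_index("site")
    det = status["detected"].reindex(meta.index, fill_value=0)
    sub = status["sub_threshold"].reindex(meta.index, fill_value=0)
    def _flag(name: str) -> pd.Series:
        if name in meta.columns:
            return meta[name].astype(bool)
        return pd.Series(False, index=meta.index)

    ok = (
        meta["canonical"]
        & meta["coding"]
        & (meta["region"] != "rRNA")
        & ~_flag("flag_junction_artifact")
        & ~_flag("flag_antisense_carryover")
        & (det >= min_detected)
    )
    if require_corroboration and min_detected == 2:
        # a site detected in every experiment has no further experiment
        # left to corroborate it
        ok &= (det > min_detected) | (sub >= 1) | (det >= len(matrix.experiments))
    out = meta[ok].copy()
    out["n_detected"] = det[ok]
    out["n_sub_threshold"] = sub[ok]
    return out.reset_index()


def intersections(matrix: SiteMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exact-subset (UpSet-style) detection counts.

    Returns (intersection counts over exact experiment subsets, per-set
    totals). Sites detected nowhere are not counted in any subset.
    """
    det_sets = matrix.detected_sets()
    subset_counts: dict[frozenset, int] = {}
    for site, exps in det_sets.items():
        if exps:
            subset_counts[exps] = subset_counts.get(exps, 0) + 1
    rows = [
        {"subset": ",".join(sorted(k)), "degree": len(k), "count": v}
        for k, v in subset_counts.items()
    ]
    inter = pd.DataFrame(rows, columns=["subset", "degree", "count"]).sort_values(
        ["degree", "subset"]
    ).reset_index(drop=True)
    totals = [
        {"experiment": e, "n_sites": sum(1 for x in det_sets.values() if e in x)}
        for e in matrix.experiments
    ]
    return inter, pd.DataFrame(totals)


def compare_strategies(
    matrix: SiteMatrix,
    reference_sites: Sequence[str],
) -> pd.DataFrame:
    """Per-library-strategy recall and artifact profile.

    For each library strategy: how many reference sites are detected in all
    of its replicates, how many detected sites fall in rRNA regions or are
    noncanonical, and the coding/noncoding strand tally of detected sites.
    """
    ref = set(reference_sites)
    meta = matrix.meta.set_index("site")
    det = matrix.cells[matrix.cells["status"] == "detected"]
    rows = []
    for library, grp in det.groupby("library"):
        replicates = sorted({e.split(":", 1)[0] for e in matrix.experiments
                             if e.endswith(f":{library}")})
        per_site = grp.groupby("site")["sample"].apply(set)
        all_reps = {s for s, reps in per_site.items() if set(replicates) <= reps}
        detected_any = set(per_site.index)
        rrna_n = int(meta.loc[sorted(detected_any), "region"].eq("rRNA").sum())
        noncanon = int((~meta.loc[sorted(detected_any), "canonical"]).sum())
        coding_n = int(meta.loc[sorted(detected_any), "coding"].sum())
        rows.append(
            {
                "library": library,
                "n_replicates": len(replicates),
                "sites_detected": len(detected_any),
                "ref_sites_all_replicates": len(all_reps & ref),
                "recall_all_replicates": (
                    len(all_reps & ref) / len(ref) if ref else float("nan")
                ),
                "rrna_region_sites": rrna_n,
                "noncanonical_sites": noncanon,
                "coding_strand_sites": coding_n,
                "noncoding_strand_sites": len(detected_any) - coding_n,
            }
        )
    return pd.DataFrame(rows).sort_values("library").reset_index(drop=True)
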