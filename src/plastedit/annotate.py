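"""Codon-level annotation of retained editing sites and summary tables.

Annotates each site with its gene, spliced-CDS position, codon change,
amino-acid change and codon position, and produces the per-gene and
amino-acid distribution summaries (before/after editing) used in reporting.
Efficiency is the fraction of transcript-strand reads carrying the edited
base, reported per experiment; ranges (min~max) are formed only at report
time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .plastome import (
    GeneFeature,
    PlastomeSequence,
    apply_edit,
    codon_context,
    complement,
    locate,
    translate,
)

__all__ = [
    "AnnotatedSite",
    "annotate_sites",
    "sites_from_calls",
    "summarize_genes",
    "summarize_amino_acids",
    "editing_efficiency",
    "annotated_to_frame",
    "write_annotated",
]

_AA3 = {}  # reserved: one-letter codes are used throughout


@dataclass(frozen=True)
class AnnotatedSite:
    """An editing site with genomic, gene and codon context."""

    pos: int
    strand: str
    ref: str
    alt: str
    gene: str  # gene symbol or "intergenic"
    region: str  # CDS / UTR5 / UTR3 / intron / rRNA / tRNA / intergenic
    pos_on_gene: int | None = None
    codon_change: str | None = None
    aa_change: str | None = None
    codon_position: int | None = None
    efficiency: Mapping[str, float] = field(default_factory=dict)
    supporting_reads: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.codon_change is not None:
            before, after = self.codon_change.split(">")
            diff = [i for i in range(3) if before[i] != after[i]]
            if diff != [self.codon_position - 1]:
                raise ValueError(
                    f"codon change {self.codon_change} inconsistent with "
                    f"codon position {self.codon_position}"
                )
            expect = f"{translate(before)}>{translate(after)}"
            if self.aa_change != expect:
                raise ValueError(
                    f"aa change {self.aa_change} does not match translation {expect}"
                )


def editing_efficiency(counts: Mapping[str, int], alt: str) -> float:
    """Edited-read fraction: alt count over total strand depth (0 if empty)."""
    depth = sum(counts.values())
    return counts.get(alt, 0) / depth if depth else 0.0


def sites_from_calls(classified: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-experiment calls into one row per (pos, strand, ref, alt).

    Efficiency and support become per-experiment dicts keyed
    ``sample:library``; flags are OR-ed across experiments.
    """
    rows = []
    flag_cols = [c for c in classified.columns if c.startswith("flag_")]
    for (pos, strand, ref, alt), grp in classified.groupby(
        ["pos", "strand", "ref", "alt"], sort=True
    ):
        eff = {
            f"{r.sample}:{r.library}": float(r.vaf) for r in grp.itertuples(index=False)
        }
        sup = {
            f"{r.sample}:{r.library}": int(r.var_reads)
            for r in grp.itertuples(index=False)
        }
        row = {
            "pos": int(pos),
            "strand": strand,
            "ref": ref,
            "alt": alt,
            "efficiency": eff,
            "supporting_reads": sup,
            "n_experiments": len(grp),
        }
        for c in flag_cols:
            row[c] = bool(grp[c].any())
        rows.append(row)
    return pd.DataFrame(rows)


def annotate_sites(
    sites: pd.DataFrame,
    features: Sequence[GeneFeature],
    genome: PlastomeSequence,
) -> list[AnnotatedSite]:
    """Annotate sites (pos, strand, ref, alt) against the gene models.

    CDS sites receive full codon annotation; other sites get region labels
    only. A site whose transcript-orientation reference base disagrees with
    the genome is a hard error, since it signals a coordinate bug upstream.
    """
    out: list[AnnotatedSite] = []
    for row in sites.itertuples(index=False):
        pos, strand, ref, alt = int(row.pos), row.strand, row.ref, row.alt
        fwd = genome.base(pos)
        coding_base = fwd if strand == "+" else complement(fwd)
        if coding_base != ref:
            raise ValueError(
                f"site {pos}{strand}: reference {ref!r} disagrees with genome "
                f"base {coding_base!r} (transcript orientation)"
            )
        loc = locate(pos, features)
        eff = dict(getattr(row, "efficiency", {}) or {})
        sup = dict(getattr(row, "supporting_reads", {}) or {})
        if loc.region == "CDS" and loc.feature.strand == strand:
            ctx = codon_context(loc.feature, pos, genome)
            edited = apply_edit(ctx.ref_codon, ctx.codon_position, ref, alt)
            out.append(
                AnnotatedSite(
                    pos=pos, strand=strand, ref=ref, alt=alt,
                    gene=ctx.gene, region="CDS",
                    pos_on_gene=ctx.pos_on_gene,
                    codon_change=f"{ctx.ref_codon}>{edited}",
                    aa_change=f"{translate(ctx.ref_codon)}>{translate(edited)}",
                    codon_position=ctx.codon_position,
                    efficiency=eff, supporting_reads=sup,
                )
            )
        else:
            gene = loc.gene if loc.gene else "intergenic"
            region = loc.region if loc.region != "CDS" else "antisense_CDS"
            out.append(
                AnnotatedSite(
                    pos=pos, strand=strand, ref=ref, alt=alt,
                    gene=gene, region=region,
                    efficiency=eff, supporting_reads=sup,
                )
            )
    return out


def summarize_genes(annotated: Sequence[AnnotatedSite]) -> pd.DataFrame:
    """Per-gene counts of CDS editing sites, with a non-CDS note row count.

    Mirrors the gene-level summary tables of plastid editing surveys: only
    coding-sequence sites are counted per gene; other regions are totalled
    in the ``non_CDS`` attribute of the returned frame.
    """
    cds = [a for a in annotated if a.region == "CDS"]
    counts = pd.Series([a.gene for a in cds]).value_counts().sort_index()
    df = counts.rename_axis("gene").reset_index(name="n_sites")
    df.attrs["non_CDS"] = len(annotated) - len(cds)
    return df


def summarize_amino_acids(
    annotated: Sequence[AnnotatedSite],
) -> tuple[pd.Series, pd.Series, pd.Series]:
    """(before, after, codon-position) distributions over CDS sites.

    ``before``/``after`` count sites by the one-letter amino acid encoded
    before and after editing; the third series is the histogram of edited
    codon positions (1-3).
    """
    cds = [a for a in annotated if a.region == "CDS"]
    before = pd.Series([a.aa_change.split(">")[0] for a in cds]).value_counts()
    after = pd.Series([a.aa_change.split(">")[1] for a in cds]).value_counts()
    pos_hist = pd.Series([a.codon_position for a in cds]).value_counts().sort_index()
    before.index.name = after.index.name = "amino_acid"
    pos_hist.index.name = "codon_position"
    return before, after, pos_hist


def annotated_to_frame(annotated: Sequence[AnnotatedSite]) -> pd.DataFrame:
    """Tabular view with min~max efficiency/support ranges per site."""
    rows = []
    for a in annotated:
        effs = list(a.efficiency.values())
        sups = list(a.supporting_reads.values())
        rows.append(
            {
                "gene": a.gene,
                "region": a.region,
                "pos": a.pos,
                "strand": a.strand,
                "substitution": f"{a.ref}>{a.alt}",
                "pos_on_gene": a.pos_on_gene,
                "codon_change": a.codon_change,
                "aa_change": a.aa_change,
                "codon_position": a.codon_position,
                "efficiency": (
                    f"{min(effs):.2g}~{max(effs):.2g}" if effs else ""
                ),
                "supporting_reads": (
                    f"{min(sups)}~{max(sups)}" if sups else ""
                ),
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        for col in ("pos_on_gene", "codon_position"):
            df[col] = df[col].astype("Int64")
    return df


def write_annotated(annotated: Sequence[AnnotatedSite], path: str | Path) -> None:
    annotated_to_frame(annotated).to_csv(path, sep="\t", index=False)
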