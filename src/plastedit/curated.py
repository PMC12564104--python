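"""The curated 38-site plastid editing set and a matching synthetic reference.

The package ships a curated table of 38 high-confidence C→U (and one U→C)
plastid editing sites from *Glycyrrhiza uralensis* leaf tissue: 34 sites in
coding sequences across 18 genes, plus one *ndhA*-intron, one *psbF* 5'-UTR,
one *psbT* 3'-UTR and one intergenic site. Gene-level coordinates (position
on the spliced CDS), codon changes and efficiency/support ranges are as
published; plastome-level coordinates are not part of the table, so
:func:`build_curated_reference` constructs a synthetic plastome and GFF-style
gene models in which every site occupies its published spliced position with
its published reference codon. The synthetic layout (gene order, strands,
intron placement) is arbitrary but deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .plastome import (
    GeneFeature,
    PlastomeSequence,
    complement,
    genomic_position,
    revcomp,
    write_annotation,
    write_genome,
)

__all__ = ["load_curated_sites", "build_curated_reference", "CuratedSite", "CuratedReference"]

_SPACER = 80  # bp between gene segments
_MINUS_GENES = frozenset({"ndhB", "rpoB", "psbT", "ndhD"})  # exercise both strands
_MULTI_EXON = {"ndhA": (540, 300), "rpoB": (900, 150)}  # gene -> (split after spliced pos, intron bp)


def load_curated_sites() -> pd.DataFrame:
    """Load the packaged curated site table (38 rows)."""
    with resources.files("plastedit.data").joinpath("curated_sites.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", na_values=["."])
    return df


@dataclass(frozen=True)
class CuratedSite:
    gene: str
    region: str
    pos: int  # synthetic plastome coordinate, 1-based
    strand: str
    ref: str
    alt: str
    pos_on_gene: int | None
    codon_change: str | None
    aa_change: str | None
    codon_position: int | None
    eff_min: float | None
    eff_max: float | None
    reads_min: int | None
    reads_max: int | None


@dataclass(frozen=True)
class CuratedReference:
    genome: PlastomeSequence
    features: list[GeneFeature]
    sites: list[CuratedSite]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write genome FASTA, annotation GFF3 and the site table."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "curated_genome.fasta",
            "gff": outdir / "curated_genes.gff3",
            "sites": outdir / "curated_sites.tsv",
        }
        write_genome(self.genome, paths["genome"])
        write_annotation(self.features, self.genome, paths["gff"])
        rows = []
        for s in self.sites:
            rows.append(
                {
                    "pos": s.pos,
                    "strand": s.strand,
                    "ref": s.ref,
                    "alt": s.alt,
                    "gene": s.gene,
                    "region": s.region,
                    "eff_min": s.eff_min,
                    "eff_max": s.eff_max,
                    "reads_min": s.reads_min,
                    "reads_max": s.reads_max,
                }
            )
        pd.DataFrame(rows).to_csv(paths["sites"], sep="\t", index=False)
        return paths


def _spliced_cds(gene: str, table: pd.DataFrame) -> str:
    """Build a spliced CDS carrying each curated codon at its printed position."""
    rows = table[(table.gene == gene) & (table.region == "CDS")]
    max_pos = int(rows.pos_on_gene.max())
    n_codons = (max_pos + 2) // 3 + 3  # pad + stop
    codons = ["GCT"] * n_codons
    codons[0] = "ATG"
    codons[-1] = "TAA"
    for _, r in rows.iterrows():
        idx = (int(r.pos_on_gene) - 1) // 3
        codon = r.codon_change.split(">")[0]
        if codons[idx] not in ("GCT", codon) and idx != 0:
            raise AssertionError(f"codon collision in {gene} at index {idx}")
        codons[idx] = codon
        # consistency with the printed codon-position column
        assert codon[(int(r.pos_on_gene) - 1) % 3] == r.ref
    return "".join(codons)


def build_curated_reference() -> CuratedReference:
    """Synthesise a plastome + gene models hosting all 38 curated sites.

    Deterministic: repeated calls return byte-identical sequences.
    """
    table = load_curated_sites()
    rng = np.random.default_rng(20250926)
    bases = np.array(list("ACGT"))

    def fill(n: int) -> str:
        return "".join(rng.choice(bases, size=n))

    cds_genes = list(dict.fromkeys(table[table.region == "CDS"].gene))
    segments: list[str] = [fill(_SPACER)]
    features: list[GeneFeature] = []
    sites: list[CuratedSite] = []
    cursor = _SPACER  # 0-based length so far

    def add_segment(seq: str) -> int:
        """Append a segment, return its 1-based genomic start."""
        nonlocal cursor
        start = cursor + 1
        segments.append(seq)
        cursor += len(seq)
        return start

    gene_layout: dict[str, GeneFeature] = {}
    for gene in cds_genes:
        strand = "-" if gene in _MINUS_GENES else "+"
        spliced = _spliced_cds(gene, table)
        if gene in _MULTI_EXON:
            split, intron_len = _MULTI_EXON[gene]
            intron = fill(intron_len)
            if gene == "ndhA":
                # plant the curated intron site mid-intron (coding-strand C);
                # the offset matches the midpoint used when the site position
                # is recovered from the derived intron feature below
                mid = (intron_len - 1) // 2
                intron = intron[:mid] + "C" + intron[mid + 1 :]
            parts = [spliced[:split], intron, spliced[split:]]
            coding_genomic = "".join(parts)
            # exon intervals within the gene segment, coding orientation
            exon_spans = [(0, split), (split + intron_len, len(coding_genomic))]
        else:
            coding_genomic = spliced
            exon_spans = [(0, len(spliced))]
        genomic = coding_genomic if strand == "+" else revcomp(coding_genomic)
        gstart = add_segment(genomic)
        glen = len(genomic)
        exons = []
        for lo, hi in exon_spans:  # lo/hi are 0-based half-open, coding orientation
            if strand == "+":
                exons.append((gstart + lo, gstart + hi - 1))
            else:
                exons.append((gstart + glen - hi, gstart + glen - lo - 1))
        feat = GeneFeature(gene=gene, ftype="CDS", strand=strand, exons=tuple(sorted(exons)))
        features.append(feat)
        gene_layout[gene] = feat
        if len(exons) > 1:
            ex = sorted(exons)
            introns = tuple((ex[i][1] + 1, ex[i + 1][0] - 1) for i in range(len(ex) - 1))
            intron_feat = GeneFeature(gene=gene, ftype="intron", strand=strand, exons=introns)
            features.append(intron_feat)
            gene_layout[gene + "/intron"] = intron_feat
        add_segment(fill(_SPACER))

    # psbF 5' UTR: 60 bp immediately upstream of the psbF CDS would not be
    # contiguous at this point, so give it its own segment with an explicit
    # UTR5 feature (plus strand, site base C at its centre).
    utr5_seq = fill(60)
    utr5_seq = utr5_seq[:30] + "C" + utr5_seq[31:]
    utr5_start = add_segment(utr5_seq)
    features.append(
        GeneFeature(gene="psbF", ftype="UTR5", strand="+", exons=((utr5_start, utr5_start + 59),))
    )
    utr5_site_pos = utr5_start + 30
    add_segment(fill(_SPACER))

    # psbT: minus-strand CDS (no curated CDS sites) with a 3' UTR downstream
    # in transcript orientation, i.e. genomically before the CDS interval.
    psbt_utr = fill(60)
    psbt_utr = psbt_utr[:30] + "A" + psbt_utr[31:]  # coding-strand T at centre
    psbt_utr_start = add_segment(psbt_utr)
    psbt_spliced = "ATG" + "GCT" * 28 + "TAA"
    psbt_start = add_segment(revcomp(psbt_spliced))
    features.append(
        GeneFeature(
            gene="psbT", ftype="CDS", strand="-",
            exons=((psbt_start, psbt_start + len(psbt_spliced) - 1),),
        )
    )
    features.append(
        GeneFeature(gene="psbT", ftype="UTR3", strand="-", exons=((psbt_utr_start, psbt_utr_start + 59),))
    )
    psbt_site_pos = psbt_utr_start + 30
    add_segment(fill(_SPACER))

    # an rRNA locus so that region classification covers all classes
    rrn_start = add_segment(fill(1500))
    features.append(
        GeneFeature(gene="rrn16", ftype="rRNA", strand="+", exons=((rrn_start, rrn_start + 1499),))
    )

    # intergenic site in a dedicated spacer
    spacer = fill(_SPACER)
    spacer = spacer[:40] + "C" + spacer[41:]
    sp_start = add_segment(spacer)
    intergenic_pos = sp_start + 40
    add_segment(fill(_SPACER))

    genome = PlastomeSequence(id="synthetic_plastome", bases="".join(segments))

    for _, r in table.iterrows():
        if r.region == "CDS":
            feat = gene_layout[r.gene]
            pog = int(r.pos_on_gene)
            pos = genomic_position(feat, pog)
            sites.append(
                CuratedSite(
                    gene=r.gene, region="CDS", pos=pos, strand=feat.strand,
                    ref=r.ref, alt=r.alt, pos_on_gene=pog,
                    codon_change=r.codon_change, aa_change=r.aa_change,
                    codon_position=int(r.codon_position),
                    eff_min=float(r.eff_min), eff_max=float(r.eff_max),
                    reads_min=int(r.reads_min), reads_max=int(r.reads_max),
                )
            )
        else:
            if r.region == "intron":
                feat = gene_layout["ndhA/intron"]
                s, e = feat.exons[0]
                pos, strand = s + (e - s) // 2, "+"
            elif r.region == "UTR5":
                pos, strand = utr5_site_pos, "+"
            elif r.region == "UTR3":
                pos, strand = psbt_site_pos, "-"
            else:
                pos, strand = intergenic_pos, "+"
            sites.append(
                CuratedSite(
                    gene=r.gene, region=r.region, pos=pos, strand=strand,
                    ref=r.ref, alt=r.alt, pos_on_gene=None, codon_change=None,
                    aa_change=None, codon_position=None, eff_min=None,
                    eff_max=None, reads_min=None, reads_max=None,
                )
            )

    # every planted site must expose its reference base on the coding strand
    for s in sites:
        base = genome.base(s.pos)
        coding = base if s.strand == "+" else complement(base)
        assert coding == s.ref, f"{s.gene}:{s.pos} expected {s.ref}, genome has {coding}"

    return CuratedReference(genome=genome, features=features, sites=sites)
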