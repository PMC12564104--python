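"""Plastome sequence and gene-model handling.

Loads a plastid genome (FASTA) and its gene annotation (GFF3), maps genomic
positions to features, and performs codon arithmetic on spliced coding
sequences. All public coordinates are 1-based and inclusive, and positions
within genes ("position on gene") are expressed on the spliced coding-strand
sequence, i.e. the concatenated exons read in translation orientation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "PlastomeSequence",
    "GeneFeature",
    "CodonContext",
    "Located",
    "read_genome",
    "read_annotation",
    "write_genome",
    "write_annotation",
    "locate",
    "spliced_length",
    "spliced_sequence",
    "spliced_position",
    "genomic_position",
    "codon_context",
    "translate",
    "apply_edit",
    "complement",
    "revcomp",
]

_ALPHABET = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: region classes ordered by priority used when a position overlaps
#: several features; protein-coding context wins because codon impact
#: dominates downstream interpretation.
REGION_PRIORITY = ("CDS", "rRNA", "tRNA", "UTR5", "UTR3", "intron")

FEATURE_TYPES = frozenset(REGION_PRIORITY)


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PlastomeSequence:
    """A (linearised) plastid genome sequence."""

    id: str
    bases: str
    circular: bool = False

    def __post_init__(self) -> None:
        bad = set(self.bases) - _ALPHABET
        if bad:
            raise ValueError(
                f"non-nucleotide characters in genome {self.id!r}: {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.bases)

    def base(self, pos: int) -> str:
        """Forward-strand base at a 1-based position."""
        if not 1 <= pos <= self.length:
            raise IndexError(f"position {pos} outside genome of length {self.length}")
        return self.bases[pos - 1]

    def slice(self, start: int, end: int) -> str:
        """Forward-strand sequence of the 1-based inclusive interval."""
        if not (1 <= start <= end <= self.length):
            raise IndexError(f"interval [{start},{end}] outside genome")
        return self.bases[start - 1 : end]


@dataclass(frozen=True)
class GeneFeature:
    """A stranded, possibly multi-exon gene model.

    ``exons`` are 1-based inclusive intervals in plastome-forward
    coordinates, stored sorted ascending regardless of strand.
    ``frame_offset`` shifts the reading frame for CDS features whose first
    stored base is not codon position 1 (phase > 0 in the annotation).
    """

    gene: str
    ftype: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    frame_offset: int = 0
    length_warning: bool = False

    def __post_init__(self) -> None:
        if self.ftype not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {self.ftype!r}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"feature {self.gene} has no exons")
        prev_end = 0
        for start, end in self.exons:
            if start > end:
                raise ValueError(
                    f"feature {self.gene}: interval [{start},{end}] wraps or is "
                    "inverted; origin-wrapping features are not supported"
                )
            if start <= prev_end:
                raise ValueError(f"feature {self.gene}: exons overlap or are unsorted")
            prev_end = end
        if not 0 <= self.frame_offset <= 2:
            raise ValueError("frame_offset must be 0-2")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def contains(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons)

    def spans(self, pos: int) -> bool:
        """True if pos falls in the genomic span (introns included)."""
        return self.start <= pos <= self.end


@dataclass(frozen=True)
class CodonContext:
    """Codon-level context of a position within a spliced CDS."""

    gene: str
    pos_on_gene: int
    codon_index: int
    codon_position: int
    ref_codon: str

    def __post_init__(self) -> None:
        if self.pos_on_gene != 3 * (self.codon_index - 1) + self.codon_position:
            raise ValueError("inconsistent codon arithmetic")


@dataclass(frozen=True)
class Located:
    """Classification of a genomic position against the gene models."""

    region: str  # one of REGION_PRIORITY or "intergenic"
    feature: GeneFeature | None
    overlapping: tuple[GeneFeature, ...] = ()

    @property
    def gene(self) -> str | None:
        return self.feature.gene if self.feature else None


def read_genome(path: str | Path) -> PlastomeSequence:
    """Read the first record of a FASTA file as the plastome.

    The sequence is uppercased and must contain only A/C/G/T/N.
    """
    records = SeqIO.parse(str(path), "fasta")
    first = next(records, None)
    if first is None or len(first.seq) == 0:
        raise ValueError(f"no sequence records in {path}")
    return PlastomeSequence(id=first.id, bases=str(first.seq).upper())


def write_genome(genome: PlastomeSequence, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{genome.id}\n")
        for i in range(0, genome.length, 70):
            fh.write(genome.bases[i : i + 70] + "\n")


_GFF_TYPE_MAP = {
    "CDS": "CDS",
    "rRNA": "rRNA",
    "tRNA": "tRNA",
    "five_prime_UTR": "UTR5",
    "three_prime_UTR": "UTR3",
}


def _parse_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in text.strip().rstrip(";").split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def _gene_symbol(attrs: dict[str, str]) -> str | None:
    # attribute key "gene" or "Name", first present wins
    for key in ("gene", "Name", "ID", "Parent"):
        if key in attrs:
            return attrs[key].split(":")[-1].split(".")[0]
    return None


def read_annotation(
    path: str | Path, genome: PlastomeSequence
) -> list[GeneFeature]:
    """Parse gene models from GFF3.

    CDS lines sharing a gene symbol are merged into a single multi-exon
    feature; introns are derived as the gaps between consecutive CDS exons.
    Explicit five_prime_UTR / three_prime_UTR records become UTR5/UTR3
    features; UTRs are never inferred. A CDS whose spliced length is not a
    multiple of 3 (given its phase) is kept but flagged with a warning.
    """
    grouped: dict[tuple[str, str], dict] = {}
    order: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise ValueError(f"{path}:{lineno}: malformed GFF3 line")
            ftype = _GFF_TYPE_MAP.get(cols[2])
            if ftype is None:
                continue
            start, end = int(cols[3]), int(cols[4])
            if end > genome.length or start < 1:
                raise ValueError(
                    f"{path}:{lineno}: feature [{start},{end}] outside genome "
                    f"of length {genome.length}"
                )
            strand = cols[6]
            if strand not in "+-":
                raise ValueError(f"{path}:{lineno}: feature lacks a strand")
            attrs = _parse_attributes(cols[8])
            gene = _gene_symbol(attrs)
            if gene is None:
                raise ValueError(f"{path}:{lineno}: no gene/Name/ID attribute")
            key = (gene, ftype)
            if key not in grouped:
                grouped[key] = {"strand": strand, "exons": [], "phase": cols[7]}
                order.append(key)
            grouped[key]["exons"].append((start, end))

    features: list[GeneFeature] = []
    for gene, ftype in order:
        entry = grouped[(gene, ftype)]
        exons = tuple(sorted(entry["exons"]))
        frame_offset = int(entry["phase"]) if entry["phase"].isdigit() else 0
        length_warning = False
        if ftype == "CDS":
            total = sum(e - s + 1 for s, e in exons)
            if (total - frame_offset) % 3 != 0:
                warnings.warn(
                    f"CDS of {gene} has spliced length {total} not a multiple "
                    "of 3; keeping with warning flag",
                    stacklevel=2,
                )
                length_warning = True
        features.append(
            GeneFeature(
                gene=gene,
                ftype=ftype,
                strand=entry["strand"],
                exons=exons,
                frame_offset=frame_offset,
                length_warning=length_warning,
            )
        )
        # derive introns from gaps between CDS exons
        if ftype == "CDS" and len(exons) > 1:
            introns = tuple(
                (exons[i][1] + 1, exons[i + 1][0] - 1) for i in range(len(exons) - 1)
            )
            features.append(
                GeneFeature(gene=gene, ftype="intron", strand=entry["strand"], exons=introns)
            )
    return features


def write_annotation(
    features: Iterable[GeneFeature], genome: PlastomeSequence, path: str | Path
) -> None:
    """Write gene models as GFF3 (derived introns are skipped on output)."""
    inverse_type = {"UTR5": "five_prime_UTR", "UTR3": "three_prime_UTR"}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {genome.length}\n")
        for feat in features:
            if feat.ftype == "intron":
                continue
            gtype = inverse_type.get(feat.ftype, feat.ftype)
            for start, end in feat.exons:
                fh.write(
                    f"{genome.id}\tplastedit\t{gtype}\t{start}\t{end}\t.\t"
                    f"{feat.strand}\t{feat.frame_offset if feat.ftype == 'CDS' else '.'}\t"
                    f"ID={feat.gene}_{gtype};gene={feat.gene}\n"
                )


def locate(pos: int, features: Sequence[GeneFeature]) -> Located:
    """Classify a plastome position into exactly one region class.

    Priority when overlapping: CDS > rRNA > tRNA > UTR5 > UTR3 > intron;
    otherwise intergenic.
    """
    hits = tuple(f for f in features if f.contains(pos))
    for region in REGION_PRIORITY:
        for f in hits:
            if f.ftype == region:
                return Located(region=region, feature=f, overlapping=hits)
    return Located(region="intergenic", feature=None, overlapping=hits)


def spliced_length(feature: GeneFeature) -> int:
    return sum(e - s + 1 for s, e in feature.exons)


def spliced_sequence(feature: GeneFeature, genome: PlastomeSequence) -> str:
    """Spliced sequence in coding orientation (5'→3' of the transcript)."""
    forward = "".join(genome.slice(s, e) for s, e in feature.exons)
    return forward if feature.strand == "+" else revcomp(forward)


def spliced_position(feature: GeneFeature, pos: int) -> int:
    """1-based position on the spliced coding-strand sequence.

    For minus-strand genes this counts from the genomic end of the last
    exon, i.e. from the transcript 5' end.
    """
    offset = 0  # 0-based offset in the forward-strand exon concatenation
    for s, e in feature.exons:
        if s <= pos <= e:
            offset += pos - s
            break
        if pos < s:
            raise ValueError(f"position {pos} not in an exon of {feature.gene}")
        offset += e - s + 1
    else:
        raise ValueError(f"position {pos} not in an exon of {feature.gene}")
    if feature.strand == "+":
        return offset + 1
    return spliced_length(feature) - offset


def genomic_position(feature: GeneFeature, pos_on_gene: int) -> int:
    """Inverse of :func:`spliced_position`."""
    total = spliced_length(feature)
    if not 1 <= pos_on_gene <= total:
        raise ValueError(f"pos_on_gene {pos_on_gene} outside spliced length {total}")
    offset = pos_on_gene - 1 if feature.strand == "+" else total - pos_on_gene
    for s, e in feature.exons:
        n = e - s + 1
        if offset < n:
            return s + offset
        offset -= n
    raise AssertionError("unreachable")


def codon_context(
    feature: GeneFeature, pos: int, genome: PlastomeSequence
) -> CodonContext:
    """Codon context of a genomic position inside a CDS feature."""
    if feature.ftype != "CDS":
        raise ValueError(f"{feature.gene}: codon context requires a CDS feature")
    pos_on_gene = spliced_position(feature, pos)
    coding_pos = pos_on_gene - feature.frame_offset
    if coding_pos < 1:
        raise ValueError(
            f"{feature.gene}: position {pos} precedes the reading frame"
        )
    codon_index = (coding_pos - 1) // 3 + 1
    codon_position = (coding_pos - 1) % 3 + 1
    seq = spliced_sequence(feature, genome)
    lo = feature.frame_offset + 3 * (codon_index - 1)
    ref_codon = seq[lo : lo + 3]
    if len(ref_codon) < 3:
        raise ValueError(f"{feature.gene}: truncated terminal codon at {pos}")
    return CodonContext(
        gene=feature.gene,
        pos_on_gene=pos_on_gene,
        codon_index=codon_index,
        codon_position=codon_position,
        ref_codon=ref_codon,
    )


_CODON_TABLE = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TABLE[_stop] = "*"


def translate(codon: str) -> str:
    """Translate one codon with the standard genetic code ('*' for stops).

    The plastid code is identical to the standard table for every codon
    handled here; no start-codon special casing is applied.
    """
    codon = codon.upper()
    if len(codon) != 3 or set(codon) - set("ACGT"):
        raise ValueError(f"invalid or ambiguous codon {codon!r}")
    return _CODON_TABLE[codon]


def apply_edit(codon: str, codon_position: int, ref: str, alt: str) -> str:
    """Apply a single-base substitution at a codon position (1-3)."""
    if not 1 <= codon_position <= 3:
        raise ValueError("codon_position must be 1-3")
    if codon[codon_position - 1] != ref:
        raise ValueError(
            f"reference mismatch: codon {codon} has {codon[codon_position - 1]!r} "
            f"at position {codon_position}, expected {ref!r}"
        )
    out = list(codon)
    out[codon_position - 1] = alt
    return "".join(out)
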