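"""Synthetic plastid RNA-seq data with realistic signal and artifact structure.

Generates a plastome, gene models, a truth set of editing events, and
strand-specific per-base pileups for multiple samples and library
strategies. The generator emulates the structure that strand-specific
(dUTP/RF) plastid RNA-seq exhibits in practice:

* site-specific C→U editing on the coding strand, with per-site efficiency
  ``e`` and edited read counts drawn Binomial(depth, e);
* dUTP second-strand carryover: a fraction ``rho`` of each edited signal
  mirrored on the opposite strand as the complementary substitution
  (G→A opposite C→U), at the low per-read rates seen in real libraries
  (roughly 1/2840 to 1/63 of the coding-strand signal);
* rRNA loci emitting a multi-type substitution spectrum from reverse
  transcriptase misincorporation opposite modified bases, predominantly on
  the noncoding strand;
* splice-junction-proximal mismatch artifacts within a small window of
  intron boundaries;
* uniform per-base sequencing error.

Simulation is pileup-level: the pipeline consumes per-strand counts, so
read-level simulation would add nothing testable. A thin paired-end SAM
emitter is provided separately for exercising the alignment converter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calling import BASES, PILEUP_COLUMNS, write_pileup
from .plastome import (
    GeneFeature,
    PlastomeSequence,
    complement,
    write_annotation,
    write_genome,
)

__all__ = [
    "SimulationConfig",
    "SimulatedReference",
    "simulate_reference",
    "simulate_pileup",
    "simulate_dataset",
    "write_dataset",
    "Fragment",
    "write_fragment_sam",
    "DEFAULT_RRNA_SPECTRUM",
]

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: Default rRNA-region misincorporation spectrum over the 12 directed
#: substitution types (transcript orientation). Modelled on the diverse
#: multi-type pattern real rRNA loci show, where canonical C→T is a small
#: minority (~6%) and T→C / A→G / G→A dominate. Weights are normalised at
#: config validation.
DEFAULT_RRNA_SPECTRUM = {
    "T>C": 0.20, "A>G": 0.17, "G>A": 0.15, "T>A": 0.10, "G>T": 0.08,
    "A>C": 0.07, "C>A": 0.06, "C>T": 0.0625, "T>G": 0.05, "A>T": 0.05,
    "G>C": 0.04, "C>G": 0.03,
}

TRUTH_COLUMNS = ["pos", "strand", "ref", "alt", "rate", "klass"]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic dataset.

    Defaults mirror a three-plant, strand-specific leaf RNA-seq design with
    total-RNA and rRNA-depleted libraries as the primary benchmark pair;
    poly(A) mRNA-seq, when enabled, gets ~1.6% of the total-RNA plastid
    depth, reflecting the poor retention of non-polyadenylated plastid
    transcripts under poly(A) selection.
    """

    seed: int = 0
    genome_length: int = 30_000
    n_genes: int = 8
    samples: tuple[str, ...] = ("HS1", "HS2", "QC1")
    libraries: tuple[str, ...] = ("total", "rrna_depleted")
    coverage: dict = field(
        default_factory=lambda: {"total": 500.0, "rrna_depleted": 500.0, "mrna": 8.0}
    )
    rrna_boost: dict = field(
        default_factory=lambda: {"total": 20.0, "rrna_depleted": 2.0, "mrna": 0.1}
    )
    antisense_fraction: float = 0.10  # opposite-strand depth vs coding depth
    intron_fraction: float = 0.30  # pre-mRNA (intron) depth vs exon depth
    background_fraction: float = 0.02  # intergenic depth vs library mean
    n_edit_sites: int = 40
    efficiency_range: tuple[float, float] = (0.15, 0.95)
    edit_sites: list[tuple[int, str, float, str]] | None = None  # (pos, strand, e, "C>T")
    carryover_rate: float = 1.0 / 100.0
    n_rrna_mod_sites: int = 12
    rrna_mod_rate: float = 0.30
    rrna_mod_spectrum: dict = field(default_factory=lambda: dict(DEFAULT_RRNA_SPECTRUM))
    rrna_noncoding_bias: float = 0.8  # fraction of rRNA artifacts on noncoding strand
    junction_window: int = 6
    junction_rate: float = 0.15
    base_error: float = 1e-3

    def __post_init__(self) -> None:
        for name in ("carryover_rate", "base_error", "antisense_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        lo, hi = self.efficiency_range
        if not 0.0 <= lo <= hi <= 1.0:
            raise ValueError("efficiency_range must lie in [0,1]")
        total = sum(self.rrna_mod_spectrum.values())
        if total <= 0:
            raise ValueError("rRNA spectrum weights must be positive")
        self.rrna_mod_spectrum = {k: v / total for k, v in self.rrna_mod_spectrum.items()}
        if self.edit_sites is not None:
            positions = [p for p, *_ in self.edit_sites]
            if len(set(positions)) != len(positions):
                raise ValueError("edit site positions must be distinct")

    def to_yaml(self, path: str | Path) -> None:
        data = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        for key in ("samples", "libraries", "efficiency_range"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        if data.get("edit_sites"):
            data["edit_sites"] = [tuple(x) for x in data["edit_sites"]]
        return cls(**data)


@dataclass(frozen=True)
class SimulatedReference:
    genome: PlastomeSequence
    features: list[GeneFeature]
    truth: pd.DataFrame  # pos, strand, ref, alt, rate, klass


def _coding_base(genome: PlastomeSequence, pos: int, strand: str) -> str:
    base = genome.base(pos)
    return base if strand == "+" else complement(base)


def simulate_reference(config: SimulationConfig) -> SimulatedReference:
    """Build genome, gene models and the truth event set.

    Deterministic for a fixed seed. Gene placement is sequential with
    random spacing; the layout always includes at least one multi-exon CDS
    and one rRNA locus, with genes on both strands.
    """
    if config.genome_length < 10 * config.n_genes * 300:
        raise ValueError(
            f"genome_length {config.genome_length} too small for "
            f"{config.n_genes} genes (need >= {10 * config.n_genes * 300})"
        )
    rng = np.random.default_rng([config.seed, 0])
    bases_arr = np.array(list("ACGT"))
    genome_bases = "".join(rng.choice(bases_arr, size=config.genome_length))
    genome = PlastomeSequence(id=f"sim_plastome_seed{config.seed}", bases=genome_bases)

    features: list[GeneFeature] = []
    cursor = 1 + int(rng.integers(100, 300))
    for i in range(config.n_genes):
        strand = "+" if i % 2 == 0 else "-"
        if i == 0:
            # multi-exon CDS: 600 + 450 bp exons around a 200 bp intron
            e1 = (cursor, cursor + 599)
            intron = (cursor + 600, cursor + 799)
            e2 = (cursor + 800, cursor + 1249)
            features.append(
                GeneFeature(gene="simA", ftype="CDS", strand=strand, exons=(e1, e2))
            )
            features.append(
                GeneFeature(gene="simA", ftype="intron", strand=strand, exons=(intron,))
            )
            cursor = e2[1] + 1
        elif i == 1:
            features.append(
                GeneFeature(
                    gene="rrn16", ftype="rRNA", strand=strand,
                    exons=((cursor, cursor + 1499),),
                )
            )
            cursor += 1500
        else:
            length = int(rng.choice([900, 1200, 1500]))
            features.append(
                GeneFeature(
                    gene=f"sim{chr(ord('A') + i)}", ftype="CDS", strand=strand,
                    exons=((cursor, cursor + length - 1),),
                )
            )
            cursor += length
        cursor += int(rng.integers(150, 400))
        if cursor >= config.genome_length - 2000:
            raise ValueError("infeasible gene placement: genome too short")

    truth_rows: list[dict] = []

    # --- editing sites -----------------------------------------------------
    if config.edit_sites is not None:
        for pos, strand, eff, sub in config.edit_sites:
            ref, alt = sub.split(">")
            if _coding_base(genome, pos, strand) != ref:
                raise ValueError(
                    f"edit site {pos}{strand} requires coding-strand base {ref}, "
                    f"genome has {_coding_base(genome, pos, strand)}"
                )
            truth_rows.append(
                dict(pos=pos, strand=strand, ref=ref, alt=alt, rate=eff, klass="edit")
            )
    else:
        # keep edits clear of splice boundaries: a planted edit inside the
        # junction window would be operationally indistinguishable from a
        # junction artifact, and truth classes must stay mutually exclusive
        exclusion = 2 * config.junction_window
        boundaries = [
            b
            for f in features
            if f.ftype == "intron"
            for s, e in f.exons
            for b in (s, e)
        ]
        cds_feats = [f for f in features if f.ftype == "CDS"]
        candidates: list[tuple[int, str]] = []
        for f in cds_feats:
            for s, e in f.exons:
                for pos in range(s, e + 1):
                    if _coding_base(genome, pos, f.strand) != "C":
                        continue
                    if any(abs(pos - b) <= exclusion for b in boundaries):
                        continue
                    candidates.append((pos, f.strand))
        if len(candidates) < config.n_edit_sites:
            raise ValueError("not enough coding-strand C positions for edit sites")
        picks = rng.choice(len(candidates), size=config.n_edit_sites, replace=False)
        lo, hi = config.efficiency_range
        for k in sorted(picks):
            pos, strand = candidates[k]
            eff = float(rng.uniform(lo, hi))
            truth_rows.append(
                dict(pos=pos, strand=strand, ref="C", alt="T", rate=eff, klass="edit")
            )

    # --- second-strand carryover shadows -----------------------------------
    if config.carryover_rate > 0:
        for row in list(truth_rows):
            if row["klass"] != "edit":
                continue
            opp = "-" if row["strand"] == "+" else "+"
            truth_rows.append(
                dict(
                    pos=row["pos"], strand=opp,
                    ref=complement(row["ref"]), alt=complement(row["alt"]),
                    rate=config.carryover_rate * row["rate"], klass="carryover",
                )
            )

    # --- rRNA misincorporation sites ---------------------------------------
    rrna_feats = [f for f in features if f.ftype == "rRNA"]
    if config.n_rrna_mod_sites > 0 and rrna_feats:
        rrna = rrna_feats[0]
        types = list(config.rrna_mod_spectrum)
        weights = np.array([config.rrna_mod_spectrum[t] for t in types])
        used = {(r["pos"], r["strand"]) for r in truth_rows}
        placed = 0
        attempts = 0
        while placed < config.n_rrna_mod_sites:
            attempts += 1
            if attempts > 200 * config.n_rrna_mod_sites:
                raise ValueError("infeasible rRNA artifact placement")
            sub = types[int(rng.choice(len(types), p=weights))]
            ref, alt = sub.split(">")
            strand = (
                ("-" if rrna.strand == "+" else "+")
                if rng.random() < config.rrna_noncoding_bias
                else rrna.strand
            )
            pos = int(rng.integers(rrna.start, rrna.end + 1))
            if (pos, strand) in used or _coding_base(genome, pos, strand) != ref:
                continue
            used.add((pos, strand))
            truth_rows.append(
                dict(pos=pos, strand=strand, ref=ref, alt=alt,
                     rate=config.rrna_mod_rate, klass="rrna_artifact")
            )
            placed += 1

    # --- splice-junction-proximal artifacts --------------------------------
    if config.junction_rate > 0 and config.junction_window > 0:
        used = {(r["pos"], r["strand"]) for r in truth_rows}
        for f in features:
            if f.ftype != "intron":
                continue
            for s, e in f.exons:
                for boundary, direction in ((s, -1), (e, +1)):
                    for _ in range(50):
                        offset = int(rng.integers(1, config.junction_window + 1))
                        pos = boundary + direction * offset  # exon side
                        ref = _coding_base(genome, pos, f.strand)
                        if (pos, f.strand) in used or ref == "N":
                            continue
                        alt = str(rng.choice([b for b in BASES if b != ref]))
                        used.add((pos, f.strand))
                        truth_rows.append(
                            dict(pos=pos, strand=f.strand, ref=ref, alt=alt,
                                 rate=config.junction_rate, klass="junction_artifact")
                        )
                        break

    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return SimulatedReference(genome=genome, features=features, truth=truth)


def _depth_means(
    config: SimulationConfig, reference: SimulatedReference, library: str
) -> np.ndarray:
    """Mean depth per (strand, position); strand 0 is '+', 1 is '-'."""
    G = reference.genome.length
    cov = config.coverage[library]
    means = np.full((2, G), config.background_fraction * cov)
    boost = config.rrna_boost.get(library, 1.0)
    for f in reference.features:
        level = cov
        if f.ftype == "rRNA":
            level = cov * boost
        elif f.ftype == "intron":
            level = cov * config.intron_fraction
        coding_row = 0 if f.strand == "+" else 1
        for s, e in f.exons:
            sl = slice(s - 1, e)
            means[coding_row, sl] = np.maximum(means[coding_row, sl], level)
            means[1 - coding_row, sl] = np.maximum(
                means[1 - coding_row, sl], config.antisense_fraction * level
            )
    return means


def simulate_pileup(
    config: SimulationConfig, reference: SimulatedReference
) -> pd.DataFrame:
    """Draw strand-specific pileups for every sample x library.

    Depth is Poisson around the strategy mean; sequencing errors are spread
    uniformly over the three alternative bases; each truth event converts
    Binomial(ref reads, rate) reads at its position/strand to its
    alternative base.
    """
    G = reference.genome.length
    genome_idx = np.frombuffer(reference.genome.bases.encode(), dtype="S1")
    ref_plus = np.searchsorted(np.array([b"A", b"C", b"G", b"T"]), genome_idx)
    # complement index: A<->T (0<->3), C<->G (1<->2)
    ref_minus = 3 - ref_plus

    frames = []
    for si, sample in enumerate(config.samples):
        for li, library in enumerate(config.libraries):
            rng = np.random.default_rng([config.seed, 1, si, li])
            means = _depth_means(config, reference, library)
            counts = np.zeros((2, G, 4), dtype=np.int64)
            for row, ref_idx in ((0, ref_plus), (1, ref_minus)):
                depth = rng.poisson(means[row])
                n_err = (
                    rng.binomial(depth, config.base_error)
                    if config.base_error > 0
                    else np.zeros(G, dtype=np.int64)
                )
                err_split = rng.multinomial(n_err, [1 / 3] * 3)
                counts[row, np.arange(G), ref_idx] = depth - n_err
                for j in range(3):
                    alt_idx = np.where(j < ref_idx, j, j + 1)
                    counts[row, np.arange(G), alt_idx] += err_split[:, j]

            for t in reference.truth.itertuples(index=False):
                row = 0 if t.strand == "+" else 1
                i = t.pos - 1
                r_idx, a_idx = _BASE_INDEX[t.ref], _BASE_INDEX[t.alt]
                n_ref = counts[row, i, r_idx]
                k = rng.binomial(n_ref, t.rate)
                counts[row, i, r_idx] -= k
                counts[row, i, a_idx] += k

            for row, strand in ((0, "+"), (1, "-")):
                depth_arr = counts[row].sum(axis=1)
                keep = depth_arr > 0
                pos = np.nonzero(keep)[0] + 1
                frames.append(
                    pd.DataFrame(
                        {
                            "sample": sample,
                            "library": library,
                            "pos": pos,
                            "strand": strand,
                            "nA": counts[row, keep, 0],
                            "nC": counts[row, keep, 1],
                            "nG": counts[row, keep, 2],
                            "nT": counts[row, keep, 3],
                        }
                    )
                )
    out = pd.concat(frames, ignore_index=True)
    out["depth"] = out[["nA", "nC", "nG", "nT"]].sum(axis=1)
    return out


def simulate_dataset(config: SimulationConfig) -> tuple[SimulatedReference, pd.DataFrame]:
    reference = simulate_reference(config)
    pileups = simulate_pileup(config, reference)
    return reference, pileups


def write_dataset(
    config: SimulationConfig,
    reference: SimulatedReference,
    pileups: pd.DataFrame,
    outdir: str | Path,
) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fasta",
        "gff": outdir / "genes.gff3",
        "truth": outdir / "truth.tsv",
        "pileup": outdir / "pileups.tsv",
        "config": outdir / "config.yaml",
    }
    write_genome(reference.genome, paths["genome"])
    write_annotation(reference.features, reference.genome, paths["gff"])
    reference.truth.to_csv(paths["truth"], sep="\t", index=False)
    write_pileup(pileups, paths["pileup"])
    config.to_yaml(paths["config"])
    return paths


# --- minimal paired-end SAM emitter (for converter testing only) -----------


@dataclass(frozen=True)
class Fragment:
    """A sequenced cDNA fragment for the SAM emitter.

    ``strand`` is the transcript strand; under the RF (dUTP) convention
    mate 1 is written antisense to it. ``subs`` maps 1-based genomic
    positions to substituted bases (forward genome orientation).
    """

    name: str
    start: int  # 1-based leftmost genomic position
    length: int
    strand: str = "+"
    read_len: int = 50
    subs: dict = field(default_factory=dict)
    duplicate: bool = False
    secondary: bool = False
    mapq: int = 60


def write_fragment_sam(
    genome: PlastomeSequence, fragments: list[Fragment], path: str | Path
) -> None:
    """Write coordinate-sorted proper pairs covering the given fragments."""
    lines = []
    for frag in fragments:
        left = frag.start
        right = frag.start + frag.length - frag.read_len
        if right < left:
            raise ValueError("fragment shorter than read length")

        def seq_at(start: int) -> str:
            s = list(genome.slice(start, start + frag.read_len - 1))
            for p, b in frag.subs.items():
                if start <= p < start + frag.read_len:
                    s[p - start] = b
            return "".join(s)

        # transcript '+': left mate is sense (read2), right mate antisense (read1)
        if frag.strand == "+":
            mates = [(left, 2, False, right), (right, 1, True, left)]
        else:
            mates = [(left, 1, False, right), (right, 2, True, left)]
        for pos, readno, is_rev, mate_pos in mates:
            flag = 0x1 | 0x2
            flag |= 0x40 if readno == 1 else 0x80
            flag |= 0x10 if is_rev else 0x20
            if frag.duplicate:
                flag |= 0x400
            if frag.secondary:
                flag |= 0x100
            tlen = frag.length if pos == left else -frag.length
            lines.append(
                (
                    pos,
                    f"{frag.name}\t{flag}\t{genome.id}\t{pos}\t{frag.mapq}\t"
                    f"{frag.read_len}M\t=\t{mate_pos}\t{tlen}\t{seq_at(pos)}\t"
                    f"{'I' * frag.read_len}",
                )
            )
    lines.sort(key=lambda x: x[0])
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        fh.write(f"@SQ\tSN:{genome.id}\tLN:{genome.length}\n")
        for _, line in lines:
            fh.write(line + "\n")
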