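"""Readers and writers for the standard formats the nick-analysis pipeline touches.

All internal coordinates are 0-based half-open. GFF3 is read and written in
its native 1-based inclusive convention; BED output is 0-based half-open.
Strand-specific depth tables are TSV with a 0-based ``pos`` column.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq

# IUPAC nucleotide codes accepted in genome sequences (U is folded to T on read).
VALID_NUC = set("ACGTUNRYSWKMBDHV")


@dataclass(frozen=True)
class Genome:
    """A named nucleotide sequence with its base composition.

    ``base_freqs`` holds A/C/G/T fractions computed over unambiguous bases
    only (N and other ambiguity codes are excluded from the denominator),
    which is what the motif chance-expectation model needs.
    """

    id: str
    seq: str
    length: int = field(init=False)
    base_freqs: dict = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "length", len(self.seq))
        if self.length == 0:
            raise ValueError(f"genome {self.id!r}: empty sequence")
        counts = {b: self.seq.count(b) for b in "ACGT"}
        total = sum(counts.values())
        freqs = {b: (counts[b] / total if total else 0.0) for b in "ACGT"}
        object.__setattr__(self, "base_freqs", freqs)

    @property
    def gc(self) -> float:
        return self.base_freqs["G"] + self.base_freqs["C"]

    def reverse_complement(self) -> "Genome":
        return Genome(id=self.id, seq=str(Seq(self.seq).reverse_complement()))


@dataclass(frozen=True)
class CDSFeature:
    """One CDS interval, 0-based half-open on the forward genome sequence."""

    start: int
    end: int
    strand: str
    product: str = ""
    id: str = ""

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"CDS {self.id!r}: bad interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"CDS {self.id!r}: unknown strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AnnotatedGenome:
    genome: Genome
    cds: list  # list[CDSFeature], sorted by start

    def __post_init__(self):
        self.cds = sorted(self.cds, key=lambda c: (c.start, c.end))
        for c in self.cds:
            if c.end > self.genome.length:
                raise ValueError(
                    f"CDS {c.id!r} [{c.start}, {c.end}) exceeds genome "
                    f"length {self.genome.length}"
                )


@dataclass
class StrandCoverage:
    """Per-base read depth on each strand of one genome, for one sample."""

    genome_id: str
    depth_fwd: np.ndarray
    depth_rev: np.ndarray
    sample_label: str = "native"

    def __post_init__(self):
        self.depth_fwd = np.asarray(self.depth_fwd, dtype=np.int64)
        self.depth_rev = np.asarray(self.depth_rev, dtype=np.int64)
        if self.depth_fwd.shape != self.depth_rev.shape:
            raise ValueError("strand depth arrays differ in length")
        if (self.depth_fwd < 0).any() or (self.depth_rev < 0).any():
            raise ValueError("negative depth")

    def depth(self, strand: str) -> np.ndarray:
        return self.depth_fwd if strand == "+" else self.depth_rev


def read_fasta(path) -> list:
    """Read a (multi-)FASTA into :class:`Genome` records.

    Sequences are uppercased and U is mapped to T. Characters outside the
    IUPAC nucleotide alphabet raise, naming the offending record.
    """
    genomes = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        bad = set(seq) - VALID_NUC
        if bad:
            raise ValueError(
                f"record {rec.id!r}: illegal sequence characters {sorted(bad)}"
            )
        genomes.append(Genome(id=rec.id, seq=seq))
    if not genomes:
        raise ValueError(f"no records in {path}")
    return genomes


def write_fasta(genomes: Iterable[Genome], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.id}\n")
            for i in range(0, g.length, width):
                fh.write(g.seq[i : i + width] + "\n")


def read_protein_fasta(path) -> list:
    """Read a protein FASTA as ``[(id, sequence), ...]`` (validated later)."""
    records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"no records in {path}")
    return records


def read_gff_cds(path, genome: Genome) -> AnnotatedGenome:
    """Read CDS features for ``genome`` from a GFF3 file.

    GFF3 1-based inclusive coordinates are converted to internal 0-based
    half-open; features are returned sorted by start. Features on other
    seqids are ignored.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    feats = []
    for f in db.features_of_type("CDS"):
        if f.seqid != genome.id:
            continue
        if f.strand not in "+-":
            raise ValueError(f"CDS {f.id!r}: unknown strand {f.strand!r}")
        start, end = f.start - 1, f.end  # GFF 1-based inclusive -> 0-based half-open
        product = f.attributes.get("product", [""])[0]
        fid = f.attributes.get("ID", [f.id or ""])[0]
        feats.append(CDSFeature(start=start, end=end, strand=f.strand, product=product, id=fid))
    return AnnotatedGenome(genome=genome, cds=feats)


def write_gff_cds(annotated: AnnotatedGenome, path) -> None:
    """Write CDS features as GFF3 (1-based inclusive)."""
    g = annotated.genome
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {g.id} 1 {g.length}\n")
        for c in annotated.cds:
            attrs = f"ID={c.id}"
            if c.product:
                attrs += f";product={c.product}"
            fh.write(
                f"{g.id}\tphagenick\tCDS\t{c.start + 1}\t{c.end}\t.\t{c.strand}\t0\t{attrs}\n"
            )


def load_strand_coverage(source, genome: Genome, sample_label: str = "native",
                         min_mapq: int = 0) -> StrandCoverage:
    """Per-base per-strand depth from SAM/BAM alignments or a depth TSV.

    From alignments, a read contributes +1 to every reference base it spans,
    on the strand given by its orientation flag; secondary and supplementary
    alignments are excluded. Mapping quality 0 is kept by default (small,
    non-repetitive phage genomes).
    """
    source = str(source)
    if source.endswith((".sam", ".bam", ".cram")):
        return _coverage_from_alignments(source, genome, sample_label, min_mapq)
    return _coverage_from_tsv(source, genome, sample_label)


def _coverage_from_alignments(path, genome, sample_label, min_mapq):
    L = genome.length
    fwd = np.zeros(L + 1, dtype=np.int64)
    rev = np.zeros(L + 1, dtype=np.int64)
    with pysam.AlignmentFile(path, check_sq=False) as af:
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.mapping_quality < min_mapq:
                continue
            if read.reference_name != genome.id:
                raise ValueError(
                    f"alignment reference {read.reference_name!r} does not match "
                    f"genome {genome.id!r}"
                )
            s, e = read.reference_start, read.reference_end
            arr = rev if read.is_reverse else fwd
            arr[s] += 1
            arr[e] -= 1
    return StrandCoverage(
        genome_id=genome.id,
        depth_fwd=np.cumsum(fwd[:-1]),
        depth_rev=np.cumsum(rev[:-1]),
        sample_label=sample_label,
    )


def _coverage_from_tsv(path, genome, sample_label):
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"pos", "depth_fwd", "depth_rev"}
    if not required.issubset(df.columns):
        raise ValueError(f"depth TSV {path} must have columns {sorted(required)}")
    if len(df) != genome.length:
        raise ValueError(
            f"depth TSV has {len(df)} rows but genome {genome.id!r} is "
            f"{genome.length} bp"
        )
    df = df.sort_values("pos")
    return StrandCoverage(
        genome_id=genome.id,
        depth_fwd=df["depth_fwd"].to_numpy(),
        depth_rev=df["depth_rev"].to_numpy(),
        sample_label=sample_label,
    )


def write_depth_tsv(cov: StrandCoverage, path) -> None:
    df = pd.DataFrame({
        "pos": np.arange(len(cov.depth_fwd)),
        "depth_fwd": cov.depth_fwd,
        "depth_rev": cov.depth_rev,
    })
    df.to_csv(path, sep="\t", index=False)


def write_nick_bed(calls: Sequence, path) -> None:
    """Write nick calls as BED6 (0-based half-open).

    Strand column is the depleted (nicked) strand; the score column is "1"
    for motif-associated calls and "." otherwise.
    """
    with open(path, "w") as fh:
        fh.write("# BED6 nick calls: chrom start end name score(motif-associated) strand\n")
        for call in calls:
            iv = call.interval
            score = "1" if call.motif_associated else "."
            fh.write(f"{iv.genome_id}\t{iv.start}\t{iv.end}\t.\t{score}\t{iv.strand}\n")
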