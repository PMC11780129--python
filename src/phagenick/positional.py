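"""terL-based genome reorientation and motif positional statistics.

To compare motif placement across a diverse phage collection, every genome
is rotated (and reverse-complemented when needed) so that the conserved
large-terminase (terL) gene starts at coordinate 0 on the plus strand.
Motif positions are then expressed relative to genome length, and relative
to the coding sequence they fall in (0 = start codon, 1 = end, measured in
the CDS's own 5'->3' direction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .motif import MotifHit
from .sequence_io import AnnotatedGenome, CDSFeature, Genome


@dataclass
class ReorientedGenome:
    """An annotated genome after the terL-start transform.

    ``flipped`` records a reverse-complement applied before rotating by
    ``offset`` bp. Rotation treats coordinates as circular for bookkeeping
    even though the physical genome is linear (the terL start generally is
    not the physical end of the molecule).
    """

    annotated: AnnotatedGenome
    offset: int
    flipped: bool
    source_length: int

    def map_position(self, pos: int) -> int:
        """Map a forward-strand base coordinate from the source genome into
        the reoriented genome."""
        L = self.source_length
        if self.flipped:
            pos = L - 1 - pos
        return (pos - self.offset) % L

    def map_hit(self, hit: MotifHit) -> MotifHit:
        """Map a motif hit through the transform (hits spanning the new
        origin cannot be represented and raise)."""
        L = self.source_length
        k = hit.k
        if self.flipped:
            start = L - hit.end
            strand = "-" if hit.strand == "+" else "+"
        else:
            start, strand = hit.start, hit.strand
        start = (start - self.offset) % L
        if start + k > L:
            raise ValueError("hit spans the rotated origin")
        return MotifHit(hit.genome_id, start, strand, hit.matched)


def reorient_to_terl(annotated: AnnotatedGenome,
                     terl_label: str = "terminase large subunit") -> ReorientedGenome:
    """Transform a genome so its unique terL CDS starts at 0 on strand +.

    Exactly one CDS whose product contains ``terl_label``
    (case-insensitively) must exist. CDS that would span the new origin
    after rotation cannot satisfy the linear-interval invariant and are
    dropped with a warning (they do not occur on annotations whose terL
    boundary is intergenic on the rotated side).
    """
    matches = [c for c in annotated.cds if terl_label.lower() in c.product.lower()]
    if len(matches) != 1:
        raise ValueError(
            f"need exactly one CDS labelled {terl_label!r}, found {len(matches)}: "
            f"{[c.id for c in matches]}"
        )
    terl = matches[0]
    g = annotated.genome
    L = g.length
    flipped = terl.strand == "-"
    if flipped:
        genome = g.reverse_complement()
        cds = [
            CDSFeature(start=L - c.end, end=L - c.start,
                       strand="-" if c.strand == "+" else "+",
                       product=c.product, id=c.id)
            for c in annotated.cds
        ]
        terl_start = L - terl.end
    else:
        genome = g
        cds = list(annotated.cds)
        terl_start = terl.start

    offset = terl_start
    seq = genome.seq[offset:] + genome.seq[:offset]
    new_cds = []
    for c in cds:
        start = (c.start - offset) % L
        end = start + c.length
        if end > L:
            warnings.warn(
                f"CDS {c.id!r} spans the rotated origin and is dropped", stacklevel=2
            )
            continue
        new_cds.append(CDSFeature(start=start, end=end, strand=c.strand,
                                  product=c.product, id=c.id))
    return ReorientedGenome(
        annotated=AnnotatedGenome(genome=Genome(id=g.id, seq=seq), cds=new_cds),
        offset=offset, flipped=flipped, source_length=L,
    )


def relative_genome_positions(hits: Sequence[MotifHit], genome_length: int) -> list:
    """Hit midpoint / genome length for each hit, in [0, 1)."""
    out = []
    for h in hits:
        if h.end > genome_length:
            raise ValueError(f"hit at {h.start} exceeds genome length {genome_length}")
        out.append((h.start + h.k / 2) / genome_length)
    return out


@dataclass(frozen=True)
class MotifPositionRecord:
    hit: MotifHit
    rel_genome: float
    cds_id: Optional[str] = None
    rel_cds: Optional[float] = None
    cds_strand_relation: str = "outside"  # coding-strand | template-strand | outside


def cds_relative_position(hit: MotifHit, annotated: AnnotatedGenome,
                          overlap_mode: str = "any") -> MotifPositionRecord:
    """Place one motif hit relative to the CDS it occurs in.

    ``overlap_mode="any"`` counts a hit as inside a CDS when any base
    overlaps (matching the usual "at least partly within" phrasing);
    ``"midpoint"`` requires the central base to fall inside. The assigned
    CDS is the one overlapping the most hit bases (ties: smaller start).
    ``rel_cds`` is the central base's offset from the start codon divided by
    CDS length, measured 5'->3' on the CDS strand, clamped to [0, 1].
    """
    if overlap_mode not in ("any", "midpoint"):
        raise ValueError(f"unknown overlap mode {overlap_mode!r}")
    mid = hit.midpoint
    best, best_ov = None, 0
    for c in annotated.cds:
        if overlap_mode == "midpoint":
            ov = 1 if c.start <= mid < c.end else 0
        else:
            ov = min(hit.end, c.end) - max(hit.start, c.start)
        if ov > best_ov:
            best, best_ov = c, ov
    rel_genome = (hit.start + hit.k / 2) / annotated.genome.length
    if best is None:
        return MotifPositionRecord(hit=hit, rel_genome=rel_genome)
    if best.strand == "+":
        rel = (mid - best.start) / best.length
    else:
        rel = (best.end - 1 - mid) / best.length
    rel = min(max(rel, 0.0), 1.0)
    relation = "coding-strand" if hit.strand == best.strand else "template-strand"
    return MotifPositionRecord(hit=hit, rel_genome=rel_genome, cds_id=best.id,
                               rel_cds=rel, cds_strand_relation=relation)


def coding_density(annotated: AnnotatedGenome) -> float:
    """Fraction of genome bases covered by at least one CDS (interval union)."""
    covered, cur_start, cur_end = 0, None, None
    for c in annotated.cds:
        if cur_end is None or c.start > cur_end:
            if cur_end is not None:
                covered += cur_end - cur_start
            cur_start, cur_end = c.start, c.end
        else:
            cur_end = max(cur_end, c.end)
    if cur_end is not None:
        covered += cur_end - cur_start
    return covered / annotated.genome.length
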