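"""Ground-truth simulators for every input the nick pipeline consumes.

Three generators, all deterministic for a fixed seed:

* :func:`make_genome` — a phage-sized genome with degenerate-motif
  occurrences planted on one strand, each carrying a nick.
* :func:`simulate_reads` — long reads whose molecules terminate at nick
  positions on the nicked strand (native sample) or never (amplified WGA
  control), emitted as exact-coordinate SAM alignments.
* :func:`make_family` — a multi-genome family with a motif-enriched clade
  and a motif-poor outgroup, orthologous proteomes at controlled identity,
  and CDS annotations whose first gene is the large terminase subunit;
  genome orientation and start are scrambled so the terL reorientation step
  has real work to do.

Default parameters mirror the focal nicked phage: a 45,228 bp genome at
52.5% GC with 13 minus-strand WACTRTGAC nicks sequenced to ~50x per strand,
an annotation at 89% coding density, and an outgroup whose motif counts are
Poisson with mean 0.7 (the chance expectation for a 45 kbp genome).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pysam

from .motif import IUPACMotif, expand_motif, _revcomp
from . import motif as _motif_mod
from .sequence_io import (AnnotatedGenome, CDSFeature, Genome, write_fasta,
                          write_gff_cds)
from .wgrr import ProteinSet

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of the simulated two-clade phage family."""

    n_in_clade: int = 10
    n_outgroup: int = 10
    proteins_per_genome: int = 12
    protein_length: int = 120
    within_identity: float = 0.9
    between_identity: float = 0.2
    clade_motif_range: Tuple[int, int] = (8, 12)
    outgroup_motif_lambda: float = 0.7
    genome_length: int = 20000
    # clade motifs are planted in the back part of the terL-oriented genome
    motif_position_range: Tuple[float, float] = (0.52, 0.95)


@dataclass(frozen=True)
class SimulationSpec:
    """Conditions of the single-genome nick simulation."""

    seed: int = 0
    genome_length: int = 45228
    gc: float = 0.525
    n_nicks: int = 13
    motif: IUPACMotif = field(default_factory=lambda: IUPACMotif("WACTRTGAC"))
    nick_strand: str = "-"
    mean_depth: float = 50.0        # per-strand coverage
    read_length_mean: float = 4000.0
    read_length_sd: float = 2000.0
    min_read_length: int = 200
    nick_end_loss: int = 25         # bp lost from each cut molecule end
    readthrough_prob: float = 0.0   # chance a molecule survives a nick intact
    substitution_rate: float = 0.0  # optional uniform read error rate
    coding_density_target: float = 0.89
    min_motif_spacing: int = 500
    end_margin: int = 500
    family: Optional[FamilySpec] = None

    def __post_init__(self):
        for name in ("gc", "coding_density_target"):
            if not (0 < getattr(self, name) < 1):
                raise ValueError(f"{name} must be in (0, 1)")
        if self.nick_strand not in "+-":
            raise ValueError("nick_strand must be + or -")


@dataclass
class GroundTruth:
    """Planted truth; everything the pipeline is later asked to recover."""

    motif_positions: list = field(default_factory=list)   # (start, strand, variant)
    nick_positions: list = field(default_factory=list)    # bp, inside planted motifs
    background_positions: list = field(default_factory=list)  # unplanted scan hits
    clade_assignment: dict = field(default_factory=dict)  # genome_id -> clade
    orthology: dict = field(default_factory=dict)         # protein_id -> ancestral index
    family_motifs: dict = field(default_factory=dict)     # genome_id -> [(start, strand, variant)]
    orientations: dict = field(default_factory=dict)      # genome_id -> {offset, flipped}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


def _random_bases(rng, n: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=n, p=probs)


def _plant_sites(rng, n: int, lo: int, hi: int, spacing: int) -> np.ndarray:
    """n jittered, roughly evenly spaced positions in [lo, hi] at least
    ``spacing`` apart."""
    if n == 0:
        return np.array([], dtype=int)
    if n == 1:
        return np.array([int(rng.integers(lo, hi + 1))])
    gap = (hi - lo) / (n - 1)
    if gap < spacing:
        raise ValueError(
            f"cannot place {n} sites {spacing} bp apart in {hi - lo} bp"
        )
    jitter = (gap - spacing) / 2
    slots = lo + gap * np.arange(n)
    pos = np.round(slots + rng.uniform(-jitter, jitter, size=n)).astype(int)
    # clipping the boundary slots back into range cannot violate the spacing
    # floor: neighbours stay >= (gap + spacing)/2 - jitter >= spacing apart
    return np.clip(pos, lo, hi)


def make_genome(spec: SimulationSpec, rng: Optional[np.random.Generator] = None):
    """Random genome at the requested GC with motif occurrences planted on
    ``nick_strand``, each carrying one nick at the motif's central base.

    Returns ``(Genome, GroundTruth)``; accidental background occurrences
    arising from the random sequence are found by scanning and recorded in
    the truth as well.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    L, k = spec.genome_length, spec.motif.k
    seq = _random_bases(rng, L, spec.gc)
    variants = expand_motif(spec.motif)
    starts = _plant_sites(rng, spec.n_nicks, spec.end_margin,
                          L - spec.end_margin - k, spec.min_motif_spacing)
    truth = GroundTruth()
    for s in np.sort(starts):
        variant = variants[rng.integers(len(variants))]
        planted = variant if spec.nick_strand == "+" else _revcomp(variant)
        seq[s : s + k] = np.frombuffer(planted.encode(), dtype="S1")
        truth.motif_positions.append((int(s), spec.nick_strand, variant))
        truth.nick_positions.append(int(s) + k // 2)
    genome = Genome(id=f"sim_{spec.seed}", seq=seq.tobytes().decode())
    planted_keys = {(s, st) for s, st, _ in truth.motif_positions}
    for h in _motif_mod.scan_genome(genome, spec.motif):
        if (h.start, h.strand) not in planted_keys:
            truth.background_positions.append((h.start, h.strand, h.matched))
    return genome, truth


@dataclass(frozen=True)
class SimRead:
    start: int
    end: int
    strand: str

    @property
    def length(self) -> int:
        return self.end - self.start


def _draw_length(rng, spec: SimulationSpec, L: int) -> int:
    while True:
        ln = int(round(rng.normal(spec.read_length_mean, spec.read_length_sd)))
        if ln >= spec.min_read_length:
            return min(ln, L)


def _fragments(read: SimRead, nicks: np.ndarray, loss: int, min_len: int,
               rng, readthrough: float) -> List[SimRead]:
    cuts = [int(p) for p in nicks[(nicks > read.start) & (nicks < read.end)]
            if not (readthrough and rng.random() < readthrough)]
    if not cuts:
        return [read]
    bounds = [read.start] + cuts + [read.end]
    out = []
    for i in range(len(bounds) - 1):
        a, b = bounds[i], bounds[i + 1]
        if i > 0:
            a += loss
        if i < len(bounds) - 2:
            b -= loss
        if b - a >= min_len:
            out.append(SimRead(a, b, read.strand))
    return out


def simulate_reads(genome: Genome, truth: GroundTruth, spec: SimulationSpec,
                   rng: Optional[np.random.Generator] = None):
    """Native and WGA control read sets as ``(native, control)`` SimRead lists.

    Reads are exact genome substrings with truncated-normal lengths, strand
    assigned uniformly, drawn per strand until each strand reaches
    ``mean_depth`` x genome-length emitted bases. Native molecules on the
    nicked strand are cut at every nick they span, losing ``nick_end_loss``
    terminal bases at each cut end (sub-minimum fragments are dropped), so
    native coverage on that strand falls to near zero at each nick while the
    control is unaffected.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    L = genome.length
    nicks = np.asarray(sorted(truth.nick_positions), dtype=int)
    native, control = [], []
    for sample, reads in (("native", native), ("wga", control)):
        for strand in "+-":
            target = spec.mean_depth * L
            total = 0
            while total < target:
                ln = _draw_length(rng, spec, L)
                # molecules may abut the physical termini: sample the
                # interval before clipping so end coverage stays flat
                raw = int(rng.integers(-(ln - spec.min_read_length),
                                       L - spec.min_read_length + 1))
                start, end = max(0, raw), min(L, raw + ln)
                if end - start < spec.min_read_length:
                    continue
                read = SimRead(start, end, strand)
                if sample == "native" and strand == spec.nick_strand and nicks.size:
                    frags = _fragments(read, nicks, spec.nick_end_loss,
                                       spec.min_read_length, rng,
                                       spec.readthrough_prob)
                else:
                    frags = [read]
                for f in frags:
                    reads.append(f)
                    total += f.length
    native.sort(key=lambda r: (r.start, r.end, r.strand))
    control.sort(key=lambda r: (r.start, r.end, r.strand))
    return native, control


def reads_to_coverage(reads: List[SimRead], length: int):
    """Per-strand depth arrays ``(fwd, rev)`` by direct accumulation."""
    fwd = np.zeros(length + 1, dtype=np.int64)
    rev = np.zeros(length + 1, dtype=np.int64)
    for r in reads:
        arr = fwd if r.strand == "+" else rev
        arr[r.start] += 1
        arr[r.end] -= 1
    return np.cumsum(fwd[:-1]), np.cumsum(rev[:-1])


def reads_to_sam(reads: List[SimRead], genome: Genome, path,
                 spec: Optional[SimulationSpec] = None,
                 rng: Optional[np.random.Generator] = None) -> None:
    """Write simulated reads as coordinate-sorted SAM with exact full-match
    alignments; optional uniform substitution noise in the SEQ field only."""
    sub_rate = spec.substitution_rate if spec else 0.0
    if sub_rate and rng is None:
        rng = np.random.default_rng(0)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": genome.id, "LN": genome.length}],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i, r in enumerate(reads):
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"read{i:06d}"
            seq = genome.seq[r.start:r.end]
            if sub_rate:
                arr = np.frombuffer(seq.encode(), dtype="S1").copy()
                flip = np.flatnonzero(rng.random(len(arr)) < sub_rate)
                for pos in flip:
                    arr[pos] = rng.choice(np.frombuffer(b"ACGT", dtype="S1"))
                seq = arr.tobytes().decode()
            a.query_sequence = seq
            a.flag = 0 if r.strand == "+" else 16
            a.reference_id = 0
            a.reference_start = r.start
            a.mapping_quality = 60
            a.cigarstring = f"{r.length}M"
            out.write(a)


def plant_annotation(genome: Genome, coding_density_target: float,
                     rng: np.random.Generator,
                     terl_index: int = 0) -> AnnotatedGenome:
    """Non-overlapping CDS annotation hitting a target coding density.

    Gene lengths ~N(900, 150) bp (floored at 300) and exponential
    intergenic gaps are rescaled so the interval union covers
    ``coding_density_target`` of the genome to within rounding. Gene number
    ``terl_index`` is labelled "terminase large subunit"; strands alternate
    in runs, as phage genomes do.
    """
    L, d = genome.length, coding_density_target
    n_genes = max(2, int(round(L * d / 900)))
    genes = np.clip(rng.normal(900, 150, n_genes), 300, None)
    gaps = rng.exponential(900 * (1 - d) / d, n_genes)
    genes *= d * L / genes.sum()
    gaps *= (1 - d) * L / gaps.sum()
    cds, cur, strand = [], 0.0, "+"
    for i in range(n_genes):
        cur += gaps[i]
        start = int(round(cur))
        cur += genes[i]
        end = min(int(round(cur)), L)
        if end - start < 3:
            continue
        if rng.random() < 0.3:  # strand switches come in runs
            strand = "-" if strand == "+" else "+"
        product = ("terminase large subunit" if i == terl_index
                   else "hypothetical protein")
        cds.append(CDSFeature(start=start, end=end, strand=strand,
                              product=product, id=f"{genome.id}_cds_{i:04d}"))
    return AnnotatedGenome(genome=genome, cds=cds)


# ---------------------------------------------------------------------------
# family simulation


def _mutate_protein(rng, seq: str, keep_prob: float) -> str:
    arr = list(seq)
    for i in range(len(arr)):
        if rng.random() >= keep_prob:
            choices = AA20.replace(arr[i], "")
            arr[i] = choices[rng.integers(len(choices))]
    return "".join(arr)


@dataclass
class FamilyBundle:
    genomes: Dict[str, Genome]
    annotations: Dict[str, AnnotatedGenome]
    proteomes: Dict[str, ProteinSet]
    truth: GroundTruth


def _flip_coords(L: int, start: int, k: int, strand: str):
    return L - start - k, ("-" if strand == "+" else "+")


def make_family(spec: SimulationSpec) -> FamilyBundle:
    """Two-clade phage family with orthologous proteomes and planted motifs.

    Clade genomes get Uniform(clade_motif_range) same-strand motif
    occurrences concentrated in the back part of the terL-oriented genome;
    outgroup genomes get Poisson(outgroup_motif_lambda) occurrences on
    random strands anywhere. Proteomes descend from a shared ancestral set
    by i.i.d. substitution calibrated so within-clade pairwise identity is
    ~``within_identity`` and between-clade ~``between_identity``. Each
    emitted genome is randomly reverse-complemented and rotated (recorded in
    the truth) so the terL reorientation step is exercised.
    """
    fspec = spec.family or FamilySpec()
    rng = np.random.default_rng(spec.seed)
    k = spec.motif.k
    variants = expand_motif(spec.motif)
    L = fspec.genome_length
    plen, nprot = fspec.protein_length, fspec.proteins_per_genome
    cds_len, gap = 3 * plen, 60
    coding_end = nprot * (cds_len + gap)
    if coding_end + 1000 >= L:
        raise ValueError("genome_length too small for the requested proteome")

    root = ["".join(AA20[i] for i in rng.integers(20, size=plen))
            for _ in range(nprot)]
    clade_anc = {
        1: root,
        2: [_mutate_protein(rng, p, fspec.between_identity) for p in root],
    }
    keep = float(np.sqrt(fspec.within_identity))

    truth = GroundTruth()
    genomes, annotations, proteomes = {}, {}, {}
    names = [(f"clade{i:02d}", 1) for i in range(fspec.n_in_clade)] + \
            [(f"out{i:02d}", 2) for i in range(fspec.n_outgroup)]
    for gid, clade in names:
        truth.clade_assignment[gid] = clade
        # proteome
        prots = []
        for j, anc in enumerate(clade_anc[clade]):
            pid = f"{gid}_p{j:02d}"
            prots.append((pid, _mutate_protein(rng, anc, keep)))
            truth.orthology[pid] = j
        proteomes[gid] = ProteinSet(genome_id=gid, proteins=prots)
        # terL-oriented genome: CDS block at the front, motifs at the back
        seq = _random_bases(rng, L, 0.5)
        if clade == 1:
            m = int(rng.integers(fspec.clade_motif_range[0],
                                 fspec.clade_motif_range[1] + 1))
            lo = int(fspec.motif_position_range[0] * L)
            hi = int(fspec.motif_position_range[1] * L) - k
            starts = _plant_sites(rng, m, lo, hi, 300)
            strands = ["-"] * m
        else:
            m = int(rng.poisson(fspec.outgroup_motif_lambda))
            starts = _plant_sites(rng, m, 500, L - 500 - k, 300) if m else []
            strands = ["+-"[rng.integers(2)] for _ in range(m)]
        motifs = []
        for s, st in zip(np.sort(starts) if len(starts) else [], strands):
            v = variants[rng.integers(len(variants))]
            planted = v if st == "+" else _revcomp(v)
            seq[int(s) : int(s) + k] = np.frombuffer(planted.encode(), dtype="S1")
            motifs.append((int(s), st, v))
        cds = []
        for j in range(nprot):
            start = j * (cds_len + gap)
            product = "terminase large subunit" if j == 0 else "hypothetical protein"
            cds.append(CDSFeature(start=start, end=start + cds_len, strand="+",
                                  product=product, id=f"{gid}_p{j:02d}"))
        # scramble orientation: optional flip, then rotate at an intergenic point
        flipped = bool(rng.random() < 0.5)
        seq_str = seq.tobytes().decode()
        if flipped:
            seq_str = _revcomp(seq_str)
            cds = [CDSFeature(start=L - c.end, end=L - c.start,
                              strand="-" if c.strand == "+" else "+",
                              product=c.product, id=c.id) for c in cds]
            motifs = [(_flip_coords(L, s, k, st)[0],
                       _flip_coords(L, s, k, st)[1], v) for s, st, v in motifs]
        offset = int(rng.integers(coding_end + 200, L - 200)) if not flipped \
            else int(rng.integers(200, L - coding_end - 200))
        seq_str = seq_str[offset:] + seq_str[:offset]

        def _rot(pos, span):
            p = (pos - offset) % L
            return p if p + span <= L else None

        new_cds = []
        for c in cds:
            p = _rot(c.start, c.length)
            assert p is not None, "rotation point fell inside a CDS"
            new_cds.append(CDSFeature(start=p, end=p + c.length, strand=c.strand,
                                      product=c.product, id=c.id))
        new_motifs = []
        for s, st, v in motifs:
            p = _rot(s, k)
            if p is None:  # motif split by the rotation point (rare)
                continue
            new_motifs.append((p, st, v))
        genome = Genome(id=gid, seq=seq_str)
        genomes[gid] = genome
        annotations[gid] = AnnotatedGenome(genome=genome, cds=new_cds)
        truth.family_motifs[gid] = sorted(new_motifs)
        truth.orientations[gid] = {"offset": offset, "flipped": flipped}
    return FamilyBundle(genomes=genomes, annotations=annotations,
                        proteomes=proteomes, truth=truth)


# ---------------------------------------------------------------------------
# bundle writers (the ``simulate`` CLI surface)


def write_nicked_bundle(spec: SimulationSpec, outdir) -> dict:
    """Write genome.fa, annotation.gff3, native.sam, wga.sam and truth.json
    for one simulated nicked genome; returns the file paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    genome, truth = make_genome(spec, rng)
    annotated = plant_annotation(genome, spec.coding_density_target, rng)
    native, control = simulate_reads(genome, truth, spec, rng)
    paths = {
        "genome": outdir / "genome.fa",
        "annotation": outdir / "annotation.gff3",
        "native": outdir / "native.sam",
        "control": outdir / "wga.sam",
        "truth": outdir / "truth.json",
    }
    write_fasta([genome], paths["genome"])
    write_gff_cds(annotated, paths["annotation"])
    reads_to_sam(native, genome, paths["native"], spec, rng)
    reads_to_sam(control, genome, paths["control"], spec, rng)
    truth.to_json(paths["truth"])
    return {k: str(v) for k, v in paths.items()}


def write_family_bundle(spec: SimulationSpec, outdir) -> dict:
    """Write per-genome FASTA/GFF3/protein FASTA plus truth.json for the
    simulated family; returns {genome_id: {fna, gff, faa}} plus 'truth'."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = make_family(spec)
    paths = {}
    for gid, genome in bundle.genomes.items():
        fna = outdir / f"{gid}.fna"
        gff = outdir / f"{gid}.gff3"
        faa = outdir / f"{gid}.faa"
        write_fasta([genome], fna)
        write_gff_cds(bundle.annotations[gid], gff)
        with open(faa, "w") as fh:
            for pid, seq in bundle.proteomes[gid].proteins:
                fh.write(f">{pid}\n{seq}\n")
        paths[gid] = {"fna": str(fna), "gff": str(gff), "faa": str(faa)}
    truth_path = outdir / "truth.json"
    bundle.truth.to_json(truth_path)
    paths["truth"] = str(truth_path)
    return paths
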