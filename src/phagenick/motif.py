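"""IUPAC degenerate motifs: expansion, strand-aware genome scanning, strand
counting statistics, the analytic chance-expectation model, and a
deterministic consensus-motif finder for aligned site windows.

The motif of interest in the nicked-phage analysis is WACTRTGAC
(W = A/T, R = A/G), a 9-mer matching four concrete sequences. All scanning
is done on the linear sequence (no origin wraparound); overlapping
occurrences are counted separately; ambiguous genome bases (N etc.) never
match.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .sequence_io import Genome

IUPAC_BASES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

# complement of each IUPAC code (W and S are self-complementary)
IUPAC_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

_BASE_TO_IUPAC = {frozenset(v): k for k, v in IUPAC_BASES.items()}

_COMPL_TABLE = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMPL_TABLE)[::-1]


@dataclass(frozen=True)
class IUPACMotif:
    """A degenerate nucleotide pattern such as ``WACTRTGAC``."""

    pattern: str

    def __post_init__(self):
        for i, c in enumerate(self.pattern):
            if c not in IUPAC_BASES:
                raise ValueError(f"invalid IUPAC code {c!r} at position {i}")
        if not self.pattern:
            raise ValueError("empty motif pattern")

    @property
    def k(self) -> int:
        return len(self.pattern)

    @property
    def n_concrete(self) -> int:
        n = 1
        for c in self.pattern:
            n *= len(IUPAC_BASES[c])
        return n

    def matches(self, kmer: str) -> bool:
        return len(kmer) == self.k and all(
            b in IUPAC_BASES[c] for b, c in zip(kmer, self.pattern)
        )


@dataclass(frozen=True)
class MotifHit:
    """One concrete occurrence of a motif on a genome.

    ``start`` is the 0-based position of the hit's leftmost base on the
    forward sequence; ``matched`` is the concrete k-mer as read 5'->3' on the
    hit strand (so for a minus-strand hit it is the reverse complement of
    the forward-sequence substring).
    """

    genome_id: str
    start: int
    strand: str
    matched: str

    @property
    def k(self) -> int:
        return len(self.matched)

    @property
    def end(self) -> int:
        return self.start + self.k

    @property
    def midpoint(self) -> int:
        """Central base of the hit (integer genome coordinate)."""
        return self.start + self.k // 2


@dataclass(frozen=True)
class MotifStrandStats:
    genome_id: str
    n_fwd: int
    n_rev: int
    expected_per_strand: float
    length: int = 0
    gc: float = float("nan")

    @property
    def net(self) -> int:
        """Absolute net strand difference (assembly orientation is arbitrary)."""
        return abs(self.n_fwd - self.n_rev)


def expand_motif(motif: IUPACMotif) -> list:
    """All concrete k-mers matched by the motif, lexicographically sorted."""
    choices = [sorted(IUPAC_BASES[c]) for c in motif.pattern]
    return ["".join(p) for p in itertools.product(*choices)]


def reverse_complement_motif(motif: IUPACMotif) -> IUPACMotif:
    """IUPAC-aware reverse complement; an involution preserving degeneracy."""
    return IUPACMotif("".join(IUPAC_COMPLEMENT[c] for c in reversed(motif.pattern)))


def _motif_regex(motif: IUPACMotif) -> re.Pattern:
    # lookahead so overlapping occurrences are all reported
    body = "".join(
        c if len(IUPAC_BASES[c]) == 1 else "[" + IUPAC_BASES[c] + "]"
        for c in motif.pattern
    )
    return re.compile(f"(?=({body}))")


def scan_genome(genome: Genome, motif: IUPACMotif) -> list:
    """All occurrences of ``motif`` on both strands of the linear sequence.

    Hits are ordered by start coordinate, with + before - at equal starts.
    """
    if genome.length < motif.k:
        return []
    hits = []
    for m in _motif_regex(motif).finditer(genome.seq):
        hits.append(MotifHit(genome.id, m.start(), "+", m.group(1)))
    rc = reverse_complement_motif(motif)
    for m in _motif_regex(rc).finditer(genome.seq):
        hits.append(MotifHit(genome.id, m.start(), "-", _revcomp(m.group(1))))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def expected_count(motif: IUPACMotif, length: int, base_freqs="uniform",
                   count_full_length: bool = False,
                   both_strands: bool = False) -> float:
    """Expected chance occurrences of the motif under an i.i.d. base model.

    Per-strand expectation ``E = W * prod_i sum_{b in code_i} p(b)`` where
    ``W = length - k + 1`` sliding windows (or ``length`` with
    ``count_full_length=True``; the two differ negligibly on genome-scale
    inputs). ``base_freqs`` is either the string ``"uniform"`` or an
    A/C/G/T fraction map summing to 1. ``both_strands=True`` doubles E.
    """
    if length < motif.k:
        raise ValueError(f"length {length} shorter than motif ({motif.k})")
    if base_freqs == "uniform":
        p = {b: 0.25 for b in "ACGT"}
    else:
        p = dict(base_freqs)
        total = sum(p.get(b, 0.0) for b in "ACGT")
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"base frequencies sum to {total}, not 1")
    windows = length if count_full_length else length - motif.k + 1
    per_window = 1.0
    for c in motif.pattern:
        per_window *= sum(p[b] for b in IUPAC_BASES[c])
    e = windows * per_window
    return 2.0 * e if both_strands else e


def strand_stats(hits: Sequence[MotifHit], genome: Genome,
                 motif: IUPACMotif) -> MotifStrandStats:
    """Per-strand counts, absolute net difference, and the genome's own
    composition-based chance expectation."""
    for h in hits:
        if h.genome_id != genome.id:
            raise ValueError(f"hit on {h.genome_id!r} passed with genome {genome.id!r}")
    n_fwd = sum(1 for h in hits if h.strand == "+")
    n_rev = sum(1 for h in hits if h.strand == "-")
    exp = expected_count(motif, genome.length, genome.base_freqs)
    return MotifStrandStats(
        genome_id=genome.id, n_fwd=n_fwd, n_rev=n_rev,
        expected_per_strand=exp, length=genome.length, gc=genome.gc,
    )


@dataclass(frozen=True)
class ConsensusResult:
    """Outcome of consensus search; ``motif`` is None when no consensus
    satisfying the degeneracy constraint exists (distinct from an error)."""

    motif: Optional[IUPACMotif]
    offsets: tuple = ()

    @property
    def found(self) -> bool:
        return self.motif is not None


def consensus_from_sites(genome: Genome, sites: Sequence[int], flank: int,
                         k_min: int = 6, k_max: int = 12,
                         max_degenerate_bases: int = 2,
                         max_degenerate_cols: int = 3) -> ConsensusResult:
    """Deterministic shared-motif finder over windows around candidate sites.

    Extracts ``[site - flank, site + flank)`` windows from the forward
    strand and, for k from ``k_max`` down to ``k_min``, anchors on each
    k-mer of the first window, aligns every other window to the anchor by
    its minimum-Hamming-distance k-mer (leftmost on ties), and merges the
    aligned columns into IUPAC codes. The longest pattern in which every
    column has at most ``max_degenerate_bases`` alternative bases is
    returned; candidates of equal length are ranked by fewer degenerate
    columns, then lexicographically. At most ``max_degenerate_cols`` columns
    may be degenerate at all, which keeps two arbitrary windows from merging
    into a vacuous all-ambiguous pattern. Plays the role of a
    motif-discovery tool on nick-site windows.
    """
    if len(sites) < 2:
        raise ValueError("need at least 2 sites")
    if flank < k_max:
        raise ValueError("flank must be >= k_max")
    windows = []
    for s in sites:
        lo, hi = s - flank, s + flank
        if lo < 0 or hi > genome.length:
            raise ValueError(f"window around site {s} exceeds genome bounds")
        windows.append(genome.seq[lo:hi])

    def clean_kmers(w, k):
        return [(off, w[off : off + k]) for off in range(len(w) - k + 1)
                if not set(w[off : off + k]) - set("ACGT")]

    for k in range(k_max, k_min - 1, -1):
        best = None  # (n_degenerate, pattern, offsets)
        window_kmers = [clean_kmers(w, k) for w in windows]
        if any(not wk for wk in window_kmers):
            continue
        for a0, anchor in window_kmers[0]:
            # initial alignment: per window the min-Hamming k-mer vs anchor
            picks = [(a0, anchor)]
            for wk in window_kmers[1:]:
                picks.append(min(
                    wk, key=lambda item: (sum(x != y for x, y in
                                              zip(item[1], anchor)), item[0])))
            # refine against the column profile: chance ties with random
            # k-mers lose to the consistent planted set
            for _ in range(2):
                counts = [dict() for _ in range(k)]
                for _, kmer in picks:
                    for col, b in zip(counts, kmer):
                        col[b] = col.get(b, 0) + 1
                new = []
                for wk in window_kmers:
                    new.append(max(
                        wk, key=lambda item: (sum(counts[i].get(b, 0)
                                                  for i, b in enumerate(item[1])),
                                              -item[0])))
                if new == picks:
                    break
                picks = new
            columns = [set() for _ in range(k)]
            for _, kmer in picks:
                for col, b in zip(columns, kmer):
                    col.add(b)
            if any(len(col) > max_degenerate_bases for col in columns):
                continue
            n_deg = sum(1 for col in columns if len(col) > 1)
            if n_deg > max_degenerate_cols:
                continue
            pattern = "".join(_BASE_TO_IUPAC[frozenset(col)] for col in columns)
            cand = (n_deg, pattern, tuple(off for off, _ in picks))
            if best is None or (cand[0], cand[1]) < (best[0], best[1]):
                best = cand
        if best is not None:
            return ConsensusResult(motif=IUPACMotif(best[1]), offsets=best[2])
    return ConsensusResult(motif=None)
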