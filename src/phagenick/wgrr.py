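"""Weighted gene repertoire relatedness (wGRR) between genomes.

wGRR(A, B) = sum over bidirectional best hits (BBH) of protein identity,
divided by the size of the smaller proteome. It is 1 when every protein has
an identical counterpart in the other genome and 0 when no proteins are
similar, which makes it a convenient intergenomic distance (1 - wGRR) for
clustering a phage collection and asking whether a motif-rich clade stands
out from its relatives.

Pairwise protein comparison is global alignment with BLOSUM62 and affine
gaps (open 11, extend 1); identity is identical aligned pairs over
alignment columns, gap columns included (a ``shorter``-sequence denominator
is available as an option since the convention differs between wGRR
implementations in the literature).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import squareform

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY") | {"X"}

_aligner = None


def _get_aligner() -> Align.PairwiseAligner:
    global _aligner
    if _aligner is None:
        a = Align.PairwiseAligner()
        a.mode = "global"
        a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        a.open_gap_score = -11.0
        a.extend_gap_score = -1.0
        _aligner = a
    return _aligner


@dataclass
class ProteinSet:
    """The proteome of one genome: ``[(protein_id, aa_sequence), ...]``."""

    genome_id: str
    proteins: List[Tuple[str, str]]

    def __post_init__(self):
        if not self.proteins:
            raise ValueError(f"empty protein set for {self.genome_id!r}")
        for pid, seq in self.proteins:
            bad = set(seq) - AA_ALPHABET
            if bad:
                raise ValueError(f"protein {pid!r}: non-amino-acid characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.proteins)


@dataclass
class BBHMap:
    """Bidirectional best hits between two proteomes, with identities."""

    pairs: List[Tuple[str, str, float]]


@dataclass
class WGRRMatrix:
    genome_ids: List[str]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        n = len(self.genome_ids)
        if v.shape != (n, n):
            raise ValueError("matrix shape does not match genome_ids")
        if not np.allclose(v, v.T):
            raise ValueError("wGRR matrix must be symmetric")
        if (v < -1e-9).any() or (v > 1 + 1e-9).any():
            raise ValueError("wGRR values must lie in [0, 1]")
        self.values = np.clip(v, 0.0, 1.0)
        np.fill_diagonal(self.values, 1.0)


def pairwise_identity(a: str, b: str, denominator: str = "columns"):
    """Global-alignment score and identity fraction for two protein sequences.

    ``denominator="columns"`` divides identical pairs by all alignment
    columns (gaps included); ``"shorter"`` divides by the shorter sequence
    length. Returns ``(score, identity)``.
    """
    for seq in (a, b):
        bad = set(seq) - AA_ALPHABET
        if bad:
            raise ValueError(f"non-amino-acid characters {sorted(bad)}")
        if not seq:
            raise ValueError("empty protein sequence")
    aln = _get_aligner().align(a, b)[0]
    c = aln.counts()
    columns = c.identities + c.mismatches + c.gaps
    if denominator == "columns":
        ident = c.identities / columns
    elif denominator == "shorter":
        ident = c.identities / min(len(a), len(b))
    else:
        raise ValueError(f"unknown identity denominator {denominator!r}")
    return float(aln.score), float(ident)


def _alignment_stats(a: str, b: str):
    """(score, identities, aligned_columns_with_both_residues, total_columns)."""
    aln = _get_aligner().align(a, b)[0]
    c = aln.counts()
    return float(aln.score), c.identities, c.identities + c.mismatches, \
        c.identities + c.mismatches + c.gaps


def best_bidirectional_hits(A: ProteinSet, B: ProteinSet,
                            min_identity: float = 0.35,
                            min_coverage: float = 0.5,
                            identity_denominator: str = "columns") -> BBHMap:
    """Mutual best-scoring protein pairs passing identity and coverage floors.

    Coverage is aligned (residue-vs-residue) span over the shorter sequence.
    Best partners are by alignment score, ties to the lower partner index.
    """
    nA, nB = len(A), len(B)
    score = np.full((nA, nB), -np.inf)
    ident = np.zeros((nA, nB))
    cover = np.zeros((nA, nB))
    for i, (_, sa) in enumerate(A.proteins):
        for j, (_, sb) in enumerate(B.proteins):
            s, n_id, n_aligned, n_cols = _alignment_stats(sa, sb)
            score[i, j] = s
            denom = n_cols if identity_denominator == "columns" else min(len(sa), len(sb))
            ident[i, j] = n_id / denom
            cover[i, j] = n_aligned / min(len(sa), len(sb))
    best_for_a = score.argmax(axis=1)  # argmax takes the first (lowest) index on ties
    best_for_b = score.argmax(axis=0)
    pairs = []
    for i, j in enumerate(best_for_a):
        if best_for_b[j] == i and ident[i, j] >= min_identity and cover[i, j] >= min_coverage:
            pairs.append((A.proteins[i][0], B.proteins[j][0], float(ident[i, j])))
    return BBHMap(pairs=pairs)


def wgrr(A: ProteinSet, B: ProteinSet, **bbh_kwargs) -> float:
    """wGRR = sum of BBH identities / min(|A|, |B|); 1 for identical
    repertoires, 0 when nothing matches."""
    if A.genome_id == B.genome_id and A.proteins == B.proteins:
        return 1.0
    bbh = best_bidirectional_hits(A, B, **bbh_kwargs)
    return sum(p[2] for p in bbh.pairs) / min(len(A), len(B))


def wgrr_matrix(protein_sets: Sequence[ProteinSet], **bbh_kwargs) -> WGRRMatrix:
    """All-vs-all wGRR over a genome collection (O(n^2) pairwise DPs)."""
    n = len(protein_sets)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = wgrr(protein_sets[i], protein_sets[j], **bbh_kwargs)
    return WGRRMatrix(genome_ids=[p.genome_id for p in protein_sets], values=values)


def cluster_genomes(matrix: WGRRMatrix, cut: float, method: str = "average"):
    """Flat clusters from average-linkage hierarchical clustering on 1 - wGRR.

    Clusters are cut at distance ``1 - cut`` (i.e. genomes with wGRR above
    ``cut`` tend to co-cluster). Returns ``(assignment, leaf_order)`` where
    ``assignment`` maps genome_id -> cluster label (labels numbered by first
    member appearance) and ``leaf_order`` is the dendrogram leaf sequence
    for heatmap export.
    """
    ids = matrix.genome_ids
    if len(ids) < 2:
        return {i: 1 for i in ids}, list(ids)
    dist = 1.0 - matrix.values
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    Z = linkage(squareform(dist, checks=False), method=method)
    raw = fcluster(Z, t=1.0 - cut, criterion="distance")
    relabel, assignment = {}, {}
    for gid, lab in zip(ids, raw):
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
        assignment[gid] = relabel[lab]
    leaf_order = [ids[i] for i in leaves_list(Z)]
    return assignment, leaf_order


def cluster_motif_summary(assignment: Dict[str, int], stats_by_genome: Dict,
                          focal_genome_id: str) -> dict:
    """Mean net motif-strand difference inside vs outside the focal cluster.

    ``stats_by_genome`` maps genome_id to MotifStrandStats (or anything with
    a ``net`` attribute). The outside mean is ``None`` (not applicable) when
    the focal cluster contains every genome.
    """
    if focal_genome_id not in assignment:
        raise ValueError(f"focal genome {focal_genome_id!r} not in cluster assignment")
    missing = [g for g in assignment if g not in stats_by_genome]
    if missing:
        raise ValueError(f"missing motif stats for {missing}")
    focal_cluster = assignment[focal_genome_id]
    inside = [stats_by_genome[g].net for g, c in assignment.items() if c == focal_cluster]
    outside = [stats_by_genome[g].net for g, c in assignment.items() if c != focal_cluster]
    return {
        "focal_genome": focal_genome_id,
        "focal_cluster": focal_cluster,
        "n_inside": len(inside),
        "n_outside": len(outside),
        "mean_net_inside": float(np.mean(inside)),
        "mean_net_outside": float(np.mean(outside)) if outside else None,
    }
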