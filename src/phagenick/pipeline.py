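"""End-to-end orchestration: nick analysis on one genome, and family-level
motif-conservation surveys, with reproducible tabular report bundles.

Every output table starts with ``#``-prefixed header lines recording the
package version and all resolved parameters, and contains nothing
non-deterministic, so a rerun on identical inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import shutil
import warnings
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .motif import IUPACMotif, scan_genome, strand_stats
from .nickcall import DropParams, associate_motif_hits, detect_drops, nick_report
from .positional import cds_relative_position, coding_density, reorient_to_terl
from .sequence_io import (Genome, StrandCoverage, load_strand_coverage,
                          read_fasta, read_gff_cds, read_protein_fasta,
                          write_depth_tsv, write_nick_bed)
from .wgrr import (ProteinSet, WGRRMatrix, cluster_genomes,
                   cluster_motif_summary, wgrr_matrix)


class PipelineError(RuntimeError):
    pass


def _header(params: dict) -> str:
    lines = [f"# phagenick {__version__}"]
    for key in sorted(params):
        lines.append(f"# {key} = {params[key]}")
    return "\n".join(lines) + "\n"


def _write_table(df: pd.DataFrame, path: Path, params: dict) -> None:
    with open(path, "w") as fh:
        fh.write(_header(params))
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def _prepare_outdir(outdir, force: bool) -> Path:
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()):
        if not force:
            raise PipelineError(
                f"output directory {outdir} is not empty (use force to overwrite)"
            )
    outdir.mkdir(parents=True, exist_ok=True)
    return outdir


def rolling_depth(cov: StrandCoverage, window: int = 1000) -> pd.DataFrame:
    """Centered rolling-average depth per strand, for depth-profile plots."""
    df = pd.DataFrame({
        "pos": np.arange(len(cov.depth_fwd)),
        "depth_fwd": cov.depth_fwd,
        "depth_rev": cov.depth_rev,
    })
    for col in ("depth_fwd", "depth_rev"):
        df[col + "_rolling"] = (
            df[col].rolling(window, center=True, min_periods=1).mean().round(3)
        )
    return df


def run_nick_analysis(genome_fa, native, control, outdir, *,
                      pattern: str = "WACTRTGAC",
                      gff: Optional[str] = None,
                      params: DropParams = DropParams(),
                      association_window: float = 50,
                      rolling_window: int = 1000,
                      min_mapq: int = 0,
                      force: bool = False) -> dict:
    """Nick calling + motif association on one genome; writes a report
    bundle (BED, TSVs, JSON summary) and returns the summary dict."""
    outdir = _prepare_outdir(outdir, force)
    meta = {
        "genome_fa": genome_fa, "native": native, "control": control,
        "pattern": pattern, "association_window": association_window,
        "rolling_window": rolling_window, "min_mapq": min_mapq,
        **{f"drop_{k}": v for k, v in asdict(params).items()},
    }
    written = []
    try:
        genomes = read_fasta(genome_fa)
        if len(genomes) != 1:
            raise PipelineError(f"expected one genome in {genome_fa}, got {len(genomes)}")
        genome = genomes[0]
        for path in (native, control):
            if not Path(path).exists():
                raise PipelineError(f"input file missing: {path}")
        native_cov = load_strand_coverage(native, genome, "native", min_mapq)
        control_cov = load_strand_coverage(control, genome, "wga", min_mapq)

        motif = IUPACMotif(pattern)
        hits = scan_genome(genome, motif)
        stats = strand_stats(hits, genome, motif)
        intervals = detect_drops(native_cov, control_cov, params)
        calls = associate_motif_hits(intervals, hits, window=association_window)
        summary = nick_report(calls, stats)
        summary["genome_length"] = genome.length
        summary["gc"] = round(genome.gc, 4)

        bed = outdir / "nicks.bed"
        write_nick_bed(calls, bed)
        written.append(bed)

        stats_df = pd.DataFrame([{
            "genome_id": stats.genome_id, "n_fwd": stats.n_fwd,
            "n_rev": stats.n_rev, "net": stats.net,
            "expected_per_strand": stats.expected_per_strand,
            "length": stats.length, "gc": stats.gc,
        }])
        _write_table(stats_df, outdir / "motif_stats.tsv", meta)
        written.append(outdir / "motif_stats.tsv")

        for label, cov in (("native", native_cov), ("wga", control_cov)):
            p = outdir / f"depth_{label}.tsv"
            write_depth_tsv(cov, p)
            written.append(p)
            p = outdir / f"depth_{label}_rolling.tsv"
            _write_table(rolling_depth(cov, rolling_window), p, meta)
            written.append(p)

        if gff:
            annotated = read_gff_cds(gff, genome)
            records = [cds_relative_position(h, annotated) for h in hits]
            pos_df = pd.DataFrame([{
                "genome_id": genome.id, "start": r.hit.start,
                "strand": r.hit.strand, "matched": r.hit.matched,
                "rel_genome": round(r.rel_genome, 6),
                "cds_id": r.cds_id or "",
                "rel_cds": "" if r.rel_cds is None else round(r.rel_cds, 6),
                "cds_strand_relation": r.cds_strand_relation,
            } for r in records])
            _write_table(pos_df, outdir / "positional.tsv", meta)
            written.append(outdir / "positional.tsv")
            summary["coding_density"] = round(coding_density(annotated), 4)

        summary_path = outdir / "summary.json"
        with open(summary_path, "w") as fh:
            json.dump({"parameters": meta, "summary": summary}, fh, indent=1,
                      sort_keys=True)
        written.append(summary_path)
        with open(outdir / "summary.txt", "w") as fh:
            fh.write(_header(meta))
            for key in sorted(summary):
                fh.write(f"{key}\t{summary[key]}\n")
        return summary
    except Exception as exc:
        for p in written:
            Path(p).unlink(missing_ok=True)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"nickcall: {exc}") from exc


def _collect_family_inputs(genome_dir) -> list:
    """Genome ids from <id>.fna / <id>.gff3 / <id>.faa triples in a directory."""
    genome_dir = Path(genome_dir)
    ids = sorted(p.stem for p in genome_dir.glob("*.fna"))
    if not ids:
        raise PipelineError(f"no *.fna genomes in {genome_dir}")
    return ids


def run_family_survey(genome_dir, outdir, *,
                      pattern: str = "WACTRTGAC",
                      cut: float = 0.5,
                      focal: Optional[str] = None,
                      terl_label: str = "terminase large subunit",
                      force: bool = False) -> dict:
    """wGRR clustering + per-genome motif stats + terL-oriented positional
    records over a directory of <id>.fna/<id>.gff3/<id>.faa files.

    Genomes lacking annotation or a unique terL are excluded from the
    positional table with a warning, never an error.
    """
    outdir = _prepare_outdir(outdir, force)
    genome_dir = Path(genome_dir)
    meta = {"genome_dir": str(genome_dir), "pattern": pattern, "cut": cut,
            "focal": focal, "terl_label": terl_label}
    ids = _collect_family_inputs(genome_dir)
    motif = IUPACMotif(pattern)

    genomes, proteomes, stats_by_genome, hits_by_genome = {}, {}, {}, {}
    for gid in ids:
        genome = read_fasta(genome_dir / f"{gid}.fna")[0]
        genomes[gid] = genome
        hits = scan_genome(genome, motif)
        hits_by_genome[gid] = hits
        stats_by_genome[gid] = strand_stats(hits, genome, motif)
        faa = genome_dir / f"{gid}.faa"
        if faa.exists():
            proteomes[gid] = ProteinSet(genome_id=gid,
                                        proteins=read_protein_fasta(faa))

    stats_df = pd.DataFrame([{
        "genome_id": s.genome_id, "n_fwd": s.n_fwd, "n_rev": s.n_rev,
        "net": s.net, "expected_per_strand": s.expected_per_strand,
        "length": s.length, "gc": s.gc,
    } for s in stats_by_genome.values()])
    _write_table(stats_df, outdir / "motif_stats.tsv", meta)

    summary = {"n_genomes": len(ids)}
    if len(proteomes) >= 2:
        matrix = wgrr_matrix([proteomes[g] for g in ids if g in proteomes])
        assignment, leaf_order = cluster_genomes(matrix, cut=cut)
        long = pd.DataFrame([
            {"genome_a": a, "genome_b": b,
             "wgrr": matrix.values[i, j]}
            for i, a in enumerate(matrix.genome_ids)
            for j, b in enumerate(matrix.genome_ids) if i < j
        ])
        _write_table(long, outdir / "wgrr_pairs.tsv", meta)
        wide = pd.DataFrame(matrix.values, index=matrix.genome_ids,
                            columns=matrix.genome_ids).loc[leaf_order, leaf_order]
        with open(outdir / "wgrr_matrix.tsv", "w") as fh:
            fh.write(_header(meta))
            wide.to_csv(fh, sep="\t", float_format="%.6g")
        _write_table(
            pd.DataFrame({"genome_id": list(assignment),
                          "cluster": [assignment[g] for g in assignment]}),
            outdir / "clusters.tsv", meta)
        summary["clusters"] = assignment
        summary["leaf_order"] = leaf_order
        focal_id = focal or matrix.genome_ids[0]
        summary["cluster_motif_summary"] = cluster_motif_summary(
            assignment, stats_by_genome, focal_id)
    elif len(proteomes) == 1:
        only = next(iter(proteomes))
        summary["clusters"] = {only: 1}
        with open(outdir / "wgrr_matrix.tsv", "w") as fh:
            fh.write(_header(meta))
            fh.write(f"\t{only}\n{only}\t1\n")

    pos_rows = []
    for gid in ids:
        gff = genome_dir / f"{gid}.gff3"
        if not gff.exists():
            warnings.warn(f"{gid}: no annotation, skipped in positional output")
            continue
        annotated = read_gff_cds(gff, genomes[gid])
        try:
            reo = reorient_to_terl(annotated, terl_label)
        except ValueError as exc:
            warnings.warn(f"{gid}: {exc}; skipped in positional output")
            continue
        hits = scan_genome(reo.annotated.genome, motif)
        for h in hits:
            r = cds_relative_position(h, reo.annotated)
            pos_rows.append({
                "genome_id": gid, "start": h.start, "strand": h.strand,
                "matched": h.matched, "rel_genome": round(r.rel_genome, 6),
                "cds_id": r.cds_id or "",
                "rel_cds": "" if r.rel_cds is None else round(r.rel_cds, 6),
                "cds_strand_relation": r.cds_strand_relation,
            })
    pos_df = pd.DataFrame(pos_rows, columns=[
        "genome_id", "start", "strand", "matched", "rel_genome", "cds_id",
        "rel_cds", "cds_strand_relation"])
    _write_table(pos_df, outdir / "positional.tsv", meta)
    summary["n_positional_records"] = len(pos_rows)

    with open(outdir / "summary.json", "w") as fh:
        json.dump({"parameters": meta, "summary": summary}, fh, indent=1,
                  sort_keys=True)
    return summary


def checksum_tree(outdir) -> dict:
    """sha256 of every regular file in a report bundle (reproducibility aid)."""
    out = {}
    for p in sorted(Path(outdir).rglob("*")):
        if p.is_file():
            out[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    return out
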