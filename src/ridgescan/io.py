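"""Readers and writers for the external formats.

Annotation comes in as GFF3 (gene/mRNA/exon features, parsed with gffutils)
or as a tab-separated dialect with columns::

    gene_id  chrom  start  end  strand  gc_fraction  [exons]

where ``exons`` optionally encodes transcript structure as
``s1-e1,s2-e2;s1-e1,...`` (transcripts separated by ``;``, exons by ``,``,
1-based inclusive).  Chromosome lengths may be declared in comment lines
``##chrom-length <name> <bp>``; otherwise the maximal gene end per
chromosome is used.

Expression matrices are TSV with a ``gene_id`` column and one column per
tissue; negative-control intensities are a single-column TSV.  Regions are
exported as BED6 (0-based half-open) with a companion TSV carrying member
gene lists.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .model import (
    Annotation,
    ExpressionMatrix,
    GeneModel,
    PipelineConfig,
    RegionCall,
)

logger = logging.getLogger("ridgescan")

_FLOAT_FMT = "%.12g"  # 12 significant digits: lossless enough to round-trip


# ---------------------------------------------------------------------------
# annotation

def _parse_exons_field(field: str) -> tuple[tuple[tuple[int, int], ...], ...]:
    transcripts = []
    for tpart in field.split(";"):
        tpart = tpart.strip()
        if not tpart:
            continue
        exons = []
        for epart in tpart.split(","):
            s, e = epart.split("-")
            exons.append((int(s), int(e)))
        transcripts.append(tuple(exons))
    return tuple(transcripts)


def _format_exons_field(transcripts) -> str:
    return ";".join(
        ",".join(f"{s}-{e}" for s, e in t) for t in transcripts
    )


def read_annotation(path, format: str | None = None) -> Annotation:
    """Read a gene annotation from GFF3 or the TSV dialect.

    Records with ``end < start`` are rejected with a logged warning;
    duplicate gene ids are a hard error.
    """
    path = Path(path)
    if format is None:
        format = "gff3" if path.suffix.lower() in (".gff", ".gff3") else "tsv"
    if format == "gff3":
        return _read_annotation_gff3(path)
    if format == "tsv":
        return _read_annotation_tsv(path)
    raise ValueError(f"unknown annotation format {format!r}")


def _read_annotation_tsv(path: Path) -> Annotation:
    chrom_lengths: dict[str, int] = {}
    genes: list[GeneModel] = []
    with open(path) as fh:
        header: list[str] | None = None
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##chrom-length"):
                _, name, length = line.split()
                chrom_lengths[name] = int(length)
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None and fields[0] == "gene_id":
                header = fields
                continue
            rec = dict(zip(header or
                           ["gene_id", "chrom", "start", "end", "strand",
                            "gc_fraction", "exons"], fields))
            start, end = int(rec["start"]), int(rec["end"])
            if end < start:
                logger.warning(
                    "rejecting %s: end %d < start %d", rec["gene_id"], end, start
                )
                continue
            gc = rec.get("gc_fraction")
            transcripts = _parse_exons_field(rec.get("exons", "") or "")
            genes.append(
                GeneModel(
                    gene_id=rec["gene_id"],
                    chrom=rec["chrom"],
                    start=start,
                    end=end,
                    strand=rec.get("strand", "."),
                    transcripts=transcripts,
                    gc_fraction=float(gc) if gc not in (None, "", "NA") else None,
                )
            )
    return Annotation.from_genes(genes, chrom_lengths or None)


def _read_annotation_gff3(path: Path) -> Annotation:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="error",
    )
    chrom_lengths: dict[str, int] = {}
    for d in db.directives:
        # ##sequence-region <seqid> <start> <end>
        parts = d.split()
        if parts and parts[0] == "sequence-region" and len(parts) == 4:
            chrom_lengths[parts[1]] = int(parts[3])
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        if gene.end < gene.start:
            logger.warning("rejecting %s: end < start", gene.id)
            continue
        transcripts = []
        for t in db.children(gene, featuretype=("mRNA", "transcript"), order_by="start"):
            exons = tuple(
                sorted((e.start, e.end) for e in db.children(t, featuretype="exon"))
            )
            if exons:
                transcripts.append(exons)
        gc = gene.attributes.get("gc_fraction", [None])[0]
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                start=gene.start,
                end=gene.end,
                strand=gene.strand or ".",
                transcripts=tuple(transcripts),
                gc_fraction=float(gc) if gc is not None else None,
            )
        )
    return Annotation.from_genes(genes, chrom_lengths or None)


def write_annotation_tsv(annotation: Annotation, path) -> None:
    with open(path, "w") as fh:
        for chrom, length in sorted(annotation.index.chrom_lengths.items()):
            fh.write(f"##chrom-length {chrom} {length}\n")
        fh.write("gene_id\tchrom\tstart\tend\tstrand\tgc_fraction\texons\n")
        for chrom in annotation.index.chromosomes:
            for gid in annotation.index.order[chrom]:
                g = annotation.genes[gid]
                gc = "" if g.gc_fraction is None else _FLOAT_FMT % g.gc_fraction
                fh.write(
                    f"{g.gene_id}\t{g.chrom}\t{g.start}\t{g.end}\t{g.strand}"
                    f"\t{gc}\t{_format_exons_field(g.transcripts)}\n"
                )


# ---------------------------------------------------------------------------
# expression

def read_expression(
    path,
    annotation: Annotation | None = None,
    controls_path=None,
) -> ExpressionMatrix:
    """Read a gene x tissue expression TSV.

    Duplicate gene rows are averaged per gene (multiple probes per gene on
    the array).  Genes absent from ``annotation`` are retained but flagged
    in ``unmapped_genes``.  Non-numeric cells are a hard error naming the
    offending row and column.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if df.columns[0] != "gene_id":
        df = df.rename(columns={df.columns[0]: "gene_id"})
    tissues = [c for c in df.columns if c != "gene_id"]
    if not tissues:
        raise ValueError(f"{path}: no tissue columns")
    body = pd.DataFrame(index=df.index)
    for col in tissues:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} "
                f"at row {row + 2}, column {col!r}"
            )
        if converted.isna().any():
            row = int(np.flatnonzero(converted.isna())[0])
            raise ValueError(f"{path}: missing value at row {row + 2}, column {col!r}")
        body[col] = converted
    body.index = pd.Index(df["gene_id"], name="gene_id")
    if not body.index.is_unique:
        body = body.groupby(level=0, sort=False).mean()
    controls = None
    if controls_path is not None:
        controls = read_controls(controls_path)
    unmapped = None
    if annotation is not None:
        unmapped = set(body.index) - set(annotation.genes)
        if unmapped:
            logger.warning("%d expression genes not in annotation", len(unmapped))
    return ExpressionMatrix(body, negative_controls=controls, unmapped_genes=unmapped)


def read_controls(path) -> np.ndarray:
    """Read negative-control log intensities (single-column TSV, optional
    header line ``intensity``)."""
    vals = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if i == 0 and line.lower() in ("intensity", "value", "control"):
                continue
            vals.append(float(line))
    return np.asarray(vals, dtype=float)


def write_expression(expr: ExpressionMatrix, path, controls_path=None) -> None:
    out = expr.values.copy()
    out.insert(0, "gene_id", out.index)
    out.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    if controls_path is not None and len(expr.negative_controls):
        with open(controls_path, "w") as fh:
            fh.write("intensity\n")
            for v in expr.negative_controls:
                fh.write((_FLOAT_FMT % v) + "\n")


# ---------------------------------------------------------------------------
# regions

def write_regions_bed(regions: Sequence[RegionCall], path, track: bool = True) -> None:
    """Write BED6: chrom, start-1, end, RIDGE_n/ANTIRIDGE_n, score =
    n_gene_positions, strand '.'; sorted by (chrom, start)."""
    counters: dict[str, int] = {}
    lines = []
    for r in sorted(regions, key=lambda r: (r.chrom, r.start, r.end)):
        counters[r.kind] = counters.get(r.kind, 0) + 1
        name = f"{r.kind}_{counters[r.kind]}"
        lines.append(
            f"{r.chrom}\t{r.start - 1}\t{r.end}\t{name}\t{r.n_gene_positions}\t.\n"
        )
    with open(path, "w") as fh:
        if track:
            fh.write('track name=ridgescan description="RIDGE/anti-RIDGE calls"\n')
        fh.writelines(lines)


def read_regions_bed(path) -> list[RegionCall]:
    regions = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            chrom, start, end, name, score = line.split("\t")[:5]
            kind = name.rsplit("_", 1)[0]
            regions.append(
                RegionCall(
                    chrom=chrom,
                    start=int(start) + 1,
                    end=int(end),
                    kind=kind,
                    n_gene_positions=int(score),
                )
            )
    return regions


def write_regions_tsv(regions: Sequence[RegionCall], path) -> None:
    """Companion table with member gene lists (comma-separated)."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tkind\tn_gene_positions\tmember_genes\n")
        for r in sorted(regions, key=lambda r: (r.chrom, r.start, r.end)):
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.kind}\t{r.n_gene_positions}"
                f"\t{','.join(r.member_genes)}\n"
            )


def read_regions_tsv(path) -> list[RegionCall]:
    regions = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            chrom, start, end, kind, npos, members = line.rstrip("\n").split("\t")
            regions.append(
                RegionCall(
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    kind=kind,
                    n_gene_positions=int(npos),
                    member_genes=tuple(m for m in members.split(",") if m),
                )
            )
    return regions


# ---------------------------------------------------------------------------
# config / reports

def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(data)


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")
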