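"""Readers and writers for every external format the pipeline touches.

Conventions
-----------
* BED is 0-based half-open and is taken verbatim.
* GTF/GFF is 1-based inclusive and converted to the internal 0-based
  convention on read (``start - 1``), and back on write.
* Network edge lists are tab-separated ``tf<TAB>target`` with a header row.
* SIF rows are ``tf<TAB>regulates<TAB>target``.
* STRING-style scored edge tables are tab-separated with a header naming at
  least two protein columns plus one or more score columns; scores on the
  0-1000 integer scale are rescaled to 0-1 on read.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Optional, Sequence

import networkx as nx
import pandas as pd

from .errors import ConfigurationError, ParseError
from .model import (
    ExpressionMatrix,
    Gene,
    GenomicInterval,
    InteractionNetwork,
    Peak,
    RegulatoryNetwork,
)

_BED_SKIP = ("#", "track", "browser")

NETWORK_FORMATS = ("tsv", "sif", "graphml")


def _data_lines(path):
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if any(line.startswith(p) for p in _BED_SKIP):
                continue
            yield lineno, line


def parse_peaks(
    path,
    tf_id: Optional[str] = None,
    name_column: Optional[int] = None,
) -> list[Peak]:
    """Read a BED-dialect peak file into :class:`Peak` records.

    The TF identity comes either from ``tf_id`` (one-TF-per-file layout) or
    from the 0-based column index ``name_column`` (TF named per row).
    Coordinates are used verbatim: BED is already 0-based half-open.
    """
    if tf_id is None and name_column is None:
        raise ConfigurationError(
            "no TF identifier: pass tf_id (one TF per file) or name_column"
        )
    peaks: list[Peak] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"expected >= 3 tab-separated columns, got {len(fields)}",
                             path, lineno)
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError:
            raise ParseError(f"non-integer coordinates {fields[1]!r}, {fields[2]!r}",
                             path, lineno) from None
        if end <= start or start < 0:
            raise ParseError(f"invalid interval [{start}, {end})", path, lineno)
        if name_column is not None:
            if name_column >= len(fields):
                raise ParseError(f"name column {name_column} out of range", path, lineno)
            tf = fields[name_column]
        else:
            tf = tf_id
        if not tf:
            raise ParseError("empty TF identifier", path, lineno)
        score = None
        if len(fields) >= 5 and fields[4] not in (".", ""):
            try:
                score = float(fields[4])
            except ValueError:
                score = None
        peaks.append(Peak(GenomicInterval(chrom, start, end), tf, score))
    return peaks


_GTF_GENE_ID = re.compile(r'gene_id\s+"([^"]+)"')
_GFF3_ID = re.compile(r"(?:^|;)\s*(?:ID|gene_id)=([^;]+)")


def parse_annotation(path, feature: str = "gene") -> list[Gene]:
    """Read gene records from a GTF/GFF file into :class:`Gene` objects.

    Only rows whose feature column equals ``feature`` are used, one TSS per
    gene record.  The TSS is the strand-aware 5' end after conversion to
    0-based coordinates: ``start - 1`` on the + strand, ``end - 1`` on -.
    ``is_tf`` is left False; callers flag TFs from a separate list.
    """
    genes: list[Gene] = []
    seen: set[str] = set()
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 8:
            raise ParseError(f"expected >= 8 GTF/GFF columns, got {len(fields)}",
                             path, lineno)
        if fields[2] != feature:
            continue
        chrom, start_s, end_s, strand = fields[0], fields[3], fields[4], fields[6]
        try:
            start1, end1 = int(start_s), int(end_s)
        except ValueError:
            raise ParseError(f"non-integer coordinates {start_s!r}, {end_s!r}",
                             path, lineno) from None
        if strand not in ("+", "-"):
            raise ParseError(f"missing or invalid strand {strand!r}", path, lineno)
        attrs = fields[8] if len(fields) > 8 else ""
        m = _GTF_GENE_ID.search(attrs) or _GFF3_ID.search(attrs)
        if not m:
            raise ParseError("no gene identifier in attributes", path, lineno)
        gene_id = m.group(1).strip()
        if gene_id in seen:
            raise ParseError(f"duplicate gene id {gene_id!r}", path, lineno)
        seen.add(gene_id)
        tss = start1 - 1 if strand == "+" else end1 - 1
        genes.append(Gene(gene_id, chrom, strand, tss))
    return genes


def mark_tfs(genes: Sequence[Gene], tf_ids: Iterable[str]) -> list[Gene]:
    """Return a copy of ``genes`` with ``is_tf`` set for ids in ``tf_ids``."""
    tfs = set(tf_ids)
    return [
        Gene(g.gene_id, g.chrom, g.strand, g.tss, is_tf=g.gene_id in tfs)
        for g in genes
    ]


def read_tf_list(path) -> list[str]:
    """Plain text, one gene id per line; blank lines and # comments skipped."""
    out = []
    for _, line in _data_lines(path):
        out.append(line.strip())
    return out


def parse_expression(path, sep: Optional[str] = None) -> ExpressionMatrix:
    """Read a delimited genes x samples count matrix.

    First column holds gene ids, header row holds sample ids.  The delimiter
    is sniffed unless given.
    """
    import csv

    try:
        df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c",
                         index_col=0)
    except (pd.errors.EmptyDataError, csv.Error):
        raise ParseError("empty or undelimited expression file", path) from None
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ParseError("expression file has no data section", path)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"duplicate gene id {dup!r}", path)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~df.isna()
    if bad.any().any() or df.isna().any().any():
        mask = bad | df.isna()
        gene = mask.any(axis=1).idxmax()
        sample = mask.loc[gene].idxmax()
        raise ParseError(
            f"non-numeric or missing value at gene {gene!r}, sample {sample!r}", path
        )
    if (numeric.to_numpy() < 0).any():
        mask = numeric < 0
        gene = mask.any(axis=1).idxmax()
        sample = mask.loc[gene].idxmax()
        raise ParseError(f"negative value at gene {gene!r}, sample {sample!r}", path)
    return ExpressionMatrix(numeric)


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.data.to_csv(path, sep="\t")


def write_peaks_bed(peaks: Iterable[Peak], path) -> None:
    """Write peaks as BED (chrom, start, end, name, score); verbatim coordinates."""
    with open(path, "w", encoding="utf-8") as fh:
        for p in sorted(peaks, key=lambda p: (p.interval.chrom, p.interval.start,
                                              p.interval.end, p.tf_id)):
            score = "." if p.score is None else f"{p.score:g}"
            fh.write(f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}"
                     f"\t{p.tf_id}\t{score}\n")


def write_annotation_gtf(genes: Iterable[Gene], path, gene_length: int = 1000) -> None:
    """Write gene records as GTF (1-based inclusive), one row per gene.

    The gene body extends ``gene_length`` nt downstream of the TSS on the
    gene's strand; only the strand-aware 5' end matters downstream, so the
    body length is nominal.  Inverse of :func:`parse_annotation`:
    parse(write(genes)) reproduces chrom/strand/TSS exactly.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.tss, g.gene_id)):
            if g.strand == "+":
                start1 = g.tss + 1
                end1 = g.tss + gene_length
            else:
                end1 = g.tss + 1
                start1 = max(1, g.tss + 2 - gene_length)
            fh.write(
                f"{g.chrom}\tgrnprune\tgene\t{start1}\t{end1}\t.\t{g.strand}\t.\t"
                f'gene_id "{g.gene_id}";\n'
            )


# ---------------------------------------------------------------------------
# regulatory network writers / readers


def _sorted_edges(net: RegulatoryNetwork):
    return sorted(net.edges)


def write_network(net: RegulatoryNetwork, path, format: str = "tsv") -> None:
    """Write a regulatory network as edge-list TSV, SIF, or GraphML.

    Writers emit edges in sorted order so identical networks produce
    byte-identical files.
    """
    path = Path(path)
    if format == "tsv":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("tf\ttarget\n")
            for tf, tgt in _sorted_edges(net):
                fh.write(f"{tf}\t{tgt}\n")
    elif format == "sif":
        with open(path, "w", encoding="utf-8") as fh:
            for tf, tgt in _sorted_edges(net):
                fh.write(f"{tf}\tregulates\t{tgt}\n")
    elif format == "graphml":
        g = nx.DiGraph()
        g.add_edges_from(_sorted_edges(net))
        nx.write_graphml(g, path, encoding="utf-8")
    else:
        raise ConfigurationError(
            f"unknown network format {format!r}; choose from {NETWORK_FORMATS}"
        )


def read_network(path, format: Optional[str] = None, label: str = "") -> RegulatoryNetwork:
    """Read a network written by :func:`write_network` (format from extension
    when not given)."""
    path = Path(path)
    if format is None:
        ext = path.suffix.lstrip(".").lower()
        format = {"tsv": "tsv", "txt": "tsv", "sif": "sif", "graphml": "graphml"}.get(ext)
        if format is None:
            raise ConfigurationError(f"cannot infer network format from {path.name!r}")
    if format == "tsv":
        edges = []
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()
            if header.strip() and header.split("\t")[0].strip() != "tf":
                raise ParseError("expected header starting with 'tf'", path, 1)
            for lineno, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 2:
                    raise ParseError("expected two tab-separated columns", path, lineno)
                edges.append((parts[0], parts[1]))
        return RegulatoryNetwork(edges, label=label or path.stem)
    if format == "sif":
        edges = []
        for lineno, line in _data_lines(path):
            parts = line.split("\t")
            if len(parts) != 3:
                raise ParseError("expected 'tf<TAB>relation<TAB>target'", path, lineno)
            edges.append((parts[0], parts[2]))
        return RegulatoryNetwork(edges, label=label or path.stem)
    if format == "graphml":
        g = nx.read_graphml(path)
        return RegulatoryNetwork(g.edges(), label=label or path.stem)
    raise ConfigurationError(
        f"unknown network format {format!r}; choose from {NETWORK_FORMATS}"
    )


# ---------------------------------------------------------------------------
# interaction networks


def read_interaction_network(path, source_label: str = "") -> InteractionNetwork:
    """Two-column (or more; extras ignored) TSV of undirected TF-TF edges.

    A header row is detected by non-identical first line reappearing as data;
    for simplicity any first line whose columns are 'protein1/protein2',
    'tf1/tf2', 'node1/node2' or 'a/b' (case-insensitive) is treated as header.
    """
    header_words = {"protein1", "protein2", "tf1", "tf2", "node1", "node2", "source",
                    "target", "a", "b"}
    edges = []
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) < 2:
            raise ParseError("expected >= 2 tab-separated columns", path, lineno)
        if lineno == 1 and {parts[0].lower(), parts[1].lower()} <= header_words:
            continue
        if parts[0] == parts[1]:
            continue  # self-interactions carry no pair information
        edges.append((parts[0], parts[1]))
    return InteractionNetwork(edges, source_label=source_label or Path(path).stem)


def write_interaction_network(net: InteractionNetwork, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("protein1\tprotein2\n")
        for a, b in sorted(net.edges):
            fh.write(f"{a}\t{b}\n")


def read_scored_edges(path) -> pd.DataFrame:
    """Read a STRING-style scored edge table.

    Returns a DataFrame whose first two columns are the protein pair and the
    remaining columns numeric scores rescaled to [0, 1] (columns with values
    above 1 are assumed to be on the 0-1000 STRING scale).
    """
    sep = None
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    sep = "\t" if "\t" in first else r"\s+"
    df = pd.read_csv(path, sep=sep, engine="python")
    if df.shape[1] < 3:
        raise ParseError("expected two protein columns plus >= 1 score column", path)
    pair_cols = list(df.columns[:2])
    for col in df.columns[2:]:
        df[col] = pd.to_numeric(df[col], errors="raise")
        if df[col].max() > 1.0:
            df[col] = df[col] / 1000.0
    df = df.rename(columns={pair_cols[0]: "protein1", pair_cols[1]: "protein2"})
    return df
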