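"""Readers and writers for the standard formats the pipeline touches.

GTF is 1-based inclusive on disk and converted to 0-based half-open
internally.  All writes go through a temp-file-plus-rename so partial runs
never leave corrupt outputs.
"""

from __future__ import annotations

import json
import os
import tempfile
from contextlib import contextmanager
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import AnnotationSet, GeneAnnotation
from .diffexp import DEProfile, ExpressionMatrix
from .networks import TypedNetwork

import networkx as nx


class FormatError(ValueError):
    pass


@contextmanager
def atomic_write(path: str | Path, mode: str = "w"):
    """Write to a temp file in the target directory, then rename into place."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, mode) as fh:
            yield fh
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# ---------------------------------------------------------------------------
# GTF

def _parse_attributes(attr_field: str, lineno: int) -> Dict[str, str]:
    out: Dict[str, str] = {}
    for chunk in attr_field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " not in chunk:
            raise FormatError(f"GTF line {lineno}: malformed attribute {chunk!r}")
        key, value = chunk.split(" ", 1)
        out[key] = value.strip().strip('"')
    return out


def read_gtf(path: str | Path) -> AnnotationSet:
    """Parse gene models from GTF (1-based inclusive -> 0-based half-open).

    Exon features are grouped under their ``gene_id``; ``gene_biotype`` is
    required on every record.  Errors report the offending line number.
    """
    genes: Dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"GTF line {lineno}: expected 9 fields, got {len(fields)}")
            chrom, _, feature, start, end, _, strand, _, attrs = fields
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise FormatError(f"GTF line {lineno}: non-integer coordinates") from None
            attr = _parse_attributes(attrs, lineno)
            if "gene_id" not in attr:
                raise FormatError(f"GTF line {lineno}: missing gene_id")
            if "gene_biotype" not in attr:
                raise FormatError(f"GTF line {lineno}: missing gene_biotype")
            gid = attr["gene_id"]
            rec = genes.setdefault(
                gid,
                {
                    "chrom": chrom,
                    "strand": strand,
                    "biotype": attr["gene_biotype"],
                    "span": None,
                    "exons": [],
                },
            )
            interval = (start_i - 1, end_i)  # to 0-based half-open
            if feature == "gene":
                rec["span"] = interval
            elif feature == "exon":
                rec["exons"].append(interval)
    ann = AnnotationSet()
    for gid, rec in genes.items():
        exons = sorted(rec["exons"])
        if not exons:
            raise FormatError(f"gene {gid!r}: no exon records")
        span = rec["span"] or (exons[0][0], exons[-1][1])
        ann.add(
            GeneAnnotation(
                gid, rec["chrom"], rec["strand"], span[0], span[1],
                tuple(exons), rec["biotype"],
            )
        )
    return ann


def write_gtf(annotation: AnnotationSet, path: str | Path, source: str = "ceranet") -> None:
    """Write gene and exon records, converting back to 1-based inclusive."""
    with atomic_write(path) as fh:
        for gene in annotation:
            attrs = f'gene_id "{gene.gene_id}"; gene_biotype "{gene.biotype}";'
            fh.write(
                "\t".join(
                    [
                        gene.chrom, source, "gene", str(gene.start + 1),
                        str(gene.end), ".", gene.strand, ".", attrs,
                    ]
                )
                + "\n"
            )
            for s, e in gene.exons:
                fh.write(
                    "\t".join(
                        [gene.chrom, source, "exon", str(s + 1), str(e),
                         ".", gene.strand, ".", attrs]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# counts

def read_counts(path: str | Path, biotype: Mapping[str, str] | None = None) -> ExpressionMatrix:
    """Read a counts TSV (feature_id column + one column per sample).

    A ``biotype`` column in the file takes priority; otherwise a mapping
    must be supplied.  Duplicate feature ids are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    df = df.set_index(df.columns[0])
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()[:5]
        raise FormatError(f"duplicate feature ids in {path}: {dups}")
    if "biotype" in df.columns:
        bt = df.pop("biotype")
    elif biotype is not None:
        bt = pd.Series({f: biotype[f] for f in df.index}, name="biotype")
    else:
        raise FormatError(f"{path}: no biotype column and no biotype mapping given")
    return ExpressionMatrix(counts=df.astype(int), biotype=bt)


def write_counts(matrix: ExpressionMatrix, path: str | Path) -> None:
    out = matrix.counts.copy()
    out.insert(0, "biotype", matrix.biotype)
    out.index.name = "feature_id"
    with atomic_write(path) as fh:
        out.to_csv(fh, sep="\t")


def write_de_profile(profile: DEProfile, path: str | Path) -> None:
    table = profile.table.copy()
    table.index.name = "feature_id"
    with atomic_write(path) as fh:
        table.to_csv(fh, sep="\t")


def read_de_profile(path: str | Path, contrast: Tuple[str, str] = ("?", "?")) -> DEProfile:
    table = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    return DEProfile(contrast=contrast, table=table)


# ---------------------------------------------------------------------------
# PPI edge lists

def read_ppi(path: str | Path) -> List[Tuple[str, str]]:
    """Read an undirected edge list from two-column TSV or SIF ("A pp B")."""
    edges: List[Tuple[str, str]] = []
    seen = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) == 3 and fields[1] == "pp":
                a, b = fields[0], fields[2]
            elif len(fields) == 2:
                a, b = fields
            else:
                raise FormatError(f"{path} line {lineno}: expected 2 columns or SIF 'A pp B'")
            if a == b:
                raise FormatError(f"{path} line {lineno}: self-loop {a!r}")
            key = tuple(sorted((a, b)))
            if key in seen:
                continue
            seen.add(key)
            edges.append((a, b))
    return edges


def write_ppi(edges: Iterable[Tuple[str, str]], path: str | Path, fmt: str = "tsv") -> None:
    with atomic_write(path) as fh:
        for a, b in edges:
            if fmt == "sif":
                fh.write(f"{a}\tpp\t{b}\n")
            else:
                fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> Dict[str, str]:
    """FASTA -> {id: sequence}; ids tokenized at the first whitespace."""
    out: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        out[rec.id] = str(rec.seq)
    return out


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    """Write sequences wrapped at 60 columns."""
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    with atomic_write(path) as fh:
        SeqIO.write(records, fh, "fasta")


# ---------------------------------------------------------------------------
# GMT

def read_gmt(path: str | Path) -> Tuple[Dict[str, List[str]], Dict[str, str]]:
    """GMT -> (term -> member genes, term -> description)."""
    sets: Dict[str, List[str]] = {}
    descs: Dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path} line {lineno}: GMT needs term, description, >=1 gene")
            term, desc, *genes = fields
            if term in sets:
                raise FormatError(f"{path} line {lineno}: duplicate term {term!r}")
            sets[term] = genes
            descs[term] = desc
    return sets, descs


def write_gmt(gene_sets: Mapping[str, Sequence[str]], path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with atomic_write(path) as fh:
        for term in gene_sets:
            desc = descriptions.get(term, term)
            fh.write("\t".join([term, desc, *gene_sets[term]]) + "\n")


# ---------------------------------------------------------------------------
# networks

def write_network(net: TypedNetwork, path: str | Path, fmt: str = "graphml") -> None:
    """Export a typed network as GraphML or SIF (edge type as relation)."""
    path = Path(path)
    if fmt == "graphml":
        # write to temp then rename; networkx wants a path or handle
        with atomic_write(path, mode="wb") as fh:
            nx.write_graphml(net.graph, fh)
    elif fmt == "sif":
        with atomic_write(path) as fh:
            for a, b, t in sorted(net.graph.edges(data="type")):
                fh.write(f"{a}\t{t}\t{b}\n")
            for node in sorted(nx.isolates(net.graph)):
                fh.write(f"{node}\n")
    else:
        raise FormatError(f"unknown network format {fmt!r}")


def read_network_sif(path: str | Path, node_types: Mapping[str, str] | None = None) -> TypedNetwork:
    """Read a SIF file written by :func:`write_network` back into a network."""
    net = TypedNetwork()
    node_types = node_types or {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                net.add_node(fields[0], node_types.get(fields[0], "protein"))
            elif len(fields) == 3:
                a, t, b = fields
                net.add_node(a, node_types.get(a, "protein"))
                net.add_node(b, node_types.get(b, "protein"))
                net.add_edge(a, b, "ppi" if t == "pp" else t)
            else:
                raise FormatError(f"{path} line {lineno}: malformed SIF record")
    return net


def read_network_graphml(path: str | Path) -> TypedNetwork:
    g = nx.read_graphml(str(path))
    net = TypedNetwork()
    for node, data in g.nodes(data=True):
        net.add_node(str(node), data.get("type", "protein"))
    for a, b, data in g.edges(data=True):
        net.add_edge(str(a), str(b), data.get("type", "ppi"))
    return net


# ---------------------------------------------------------------------------
# JSON report / ground truth

def write_json(obj, path: str | Path) -> None:
    with atomic_write(path) as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
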