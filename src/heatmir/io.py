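"""Readers and writers for every external artifact the pipeline touches.

All tabular formats are tab-delimited text with a header row; sequences are
FASTA (T and U both accepted on input, unified to the RNA alphabet
internally, written back with U); networks go out as GraphML or SIF with
deterministic node/edge ordering.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import networkx as nx
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from heatmir.containers import DIRECTIONS, ExpressionMatrix
from heatmir.errors import FormatError, MetadataError

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGUN")
LOCUS_RE = re.compile(r"LOC_Os\d{2}g\d{5}")


# ---------------------------------------------------------------------------
# expression matrices and sample sheets
# ---------------------------------------------------------------------------

def read_sample_sheet(path) -> pd.DataFrame:
    """Read a sample sheet (columns sample_id, timepoint, replicate).

    Timepoint order is taken from order of first appearance in the file.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "timepoint": str})
    required = {"sample_id", "timepoint", "replicate"}
    if not required.issubset(df.columns):
        raise FormatError(f"sample sheet must have columns {sorted(required)}")
    if df["sample_id"].duplicated().any():
        raise FormatError("duplicate sample_id in sample sheet")
    if df.duplicated(["timepoint", "replicate"]).any():
        raise FormatError("duplicate (timepoint, replicate) pair in sample sheet")
    if (df["replicate"].astype(int) < 1).any():
        raise FormatError("replicate indices must be positive")
    df = df.set_index("sample_id")
    df["replicate"] = df["replicate"].astype(int)
    df["timepoint"] = pd.Categorical(
        df["timepoint"],
        categories=list(dict.fromkeys(df["timepoint"])),
        ordered=True,
    )
    return df


def read_expression_matrix(path, sample_sheet, flag_path=None) -> ExpressionMatrix:
    """Read a probes x samples log2-intensity TSV (+ optional flag TSV).

    First column holds probe ids, header row holds sample ids; the flag file,
    if given, has the identical layout with cells in {P, A, M}.
    """
    samples = (
        sample_sheet
        if isinstance(sample_sheet, pd.DataFrame)
        else read_sample_sheet(sample_sheet)
    )
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    if values.index.duplicated().any():
        dup = values.index[values.index.duplicated()][0]
        raise FormatError(f"duplicate probe id {dup!r} in {path}")
    missing = [s for s in values.columns if s not in samples.index]
    if missing:
        raise MetadataError(f"samples {missing} in {path} missing from sample sheet")
    flags = None
    if flag_path is not None:
        flags = pd.read_csv(flag_path, sep="\t", index_col=0, dtype=str)
        flags.index = flags.index.astype(str)
        if flags.shape != values.shape or list(flags.index) != list(values.index) \
                or list(flags.columns) != list(values.columns):
            raise FormatError(
                f"flag file {flag_path} layout does not match matrix {path}"
            )
    return ExpressionMatrix(values=values, samples=samples, flags=flags)


def write_expression_matrix(m: ExpressionMatrix, path, flag_path=None,
                            sample_sheet_path=None) -> None:
    m.values.to_csv(path, sep="\t", index_label="probe_id", float_format="%.6g")
    if flag_path is not None:
        if m.flags is None:
            raise FormatError("matrix has no flags to write")
        m.flags.to_csv(flag_path, sep="\t", index_label="probe_id")
    if sample_sheet_path is not None:
        sheet = m.samples.loc[list(m.values.columns)].reset_index()
        sheet.columns = ["sample_id", "timepoint", "replicate"]
        sheet.to_csv(sample_sheet_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Read FASTA into {id: sequence}, unified to uppercase RNA (T -> U)."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seq = str(rec.seq).upper().replace("T", "U")
        if not seq:
            raise FormatError(f"empty record {rec.id!r} in {path}")
        bad = set(seq) - RNA_ALPHABET
        if bad:
            raise FormatError(
                f"illegal character(s) {sorted(bad)} in record {rec.id!r}"
            )
        seqs[rec.id] = seq
    return seqs


def write_fasta(seqs: dict[str, str], path) -> None:
    """Write sequences as FASTA in the RNA alphabet (U, not T)."""
    records = [
        SeqRecord(Seq(seq.upper().replace("T", "U")), id=name, description="")
        for name, seq in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# PPI edges
# ---------------------------------------------------------------------------

def read_ppi_edges(path, score_scale: str = "unit") -> pd.DataFrame:
    """Read a 3-column PPI table and normalize scores to [0, 1].

    ``score_scale`` declares the input scale: ``unit`` for scores already in
    [0, 1], ``thousand`` for STRING-style integer scores in [0, 1000].
    Self-edges are dropped with a warning; duplicate undirected edges are
    collapsed keeping the maximum score (conservative toward inclusion at a
    fixed cutoff).  Endpoints are stored sorted so each undirected edge has
    one canonical row.
    """
    if score_scale not in ("unit", "thousand"):
        raise FormatError(f"unknown score_scale {score_scale!r}")
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    if df.shape[1] != 3:
        raise FormatError(f"PPI table must have 3 columns, got {df.shape[1]}")
    df.columns = ["protein_a", "protein_b", "combined_score"]
    score = df["combined_score"].astype(float)
    hi = 1.0 if score_scale == "unit" else 1000.0
    if ((score < 0) | (score > hi)).any():
        bad = score[(score < 0) | (score > hi)].iloc[0]
        raise FormatError(f"score {bad} outside declared range [0, {hi}]")
    df["combined_score"] = score / hi
    self_edges = df["protein_a"] == df["protein_b"]
    if self_edges.any():
        logger.warning("dropping %d self-edge(s) from %s", self_edges.sum(), path)
        df = df[~self_edges]
    pairs = [tuple(sorted(p)) for p in zip(df["protein_a"], df["protein_b"])]
    df = pd.DataFrame(
        {
            "protein_a": [p[0] for p in pairs],
            "protein_b": [p[1] for p in pairs],
            "combined_score": df["combined_score"].to_numpy(),
        }
    )
    df = (
        df.groupby(["protein_a", "protein_b"], as_index=False)["combined_score"]
        .max()
        .sort_values(["protein_a", "protein_b"])
        .reset_index(drop=True)
    )
    return df


# ---------------------------------------------------------------------------
# curated-table fixtures
# ---------------------------------------------------------------------------

def read_family_target_table(path) -> pd.DataFrame:
    """Read the curated family->gene direction table.

    Columns: family, family_direction, gene_id, gene_direction, with
    directions in {up, down, up_down} and gene ids in rice
    LOC_OsNNgNNNNN form.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["family", "family_direction", "gene_id", "gene_direction"]
    if list(df.columns) != required:
        raise FormatError(f"family-target table must have columns {required}")
    for col in ("family_direction", "gene_direction"):
        bad = set(df[col]) - set(DIRECTIONS)
        if bad:
            raise FormatError(f"unknown direction token {sorted(bad)[0]!r} in {col}")
    bad_loci = [g for g in df["gene_id"] if not LOCUS_RE.fullmatch(g)]
    if bad_loci:
        raise FormatError(f"malformed locus id {bad_loci[0]!r}")
    return df


def read_ogro_table(path) -> pd.DataFrame:
    """Read a characterized-gene record table (OGRO-style export)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = [
        "locus_id", "gene_symbol", "character_major", "character_minor",
        "isolation", "objective", "reference_doi",
    ]
    if list(df.columns) != required:
        raise FormatError(f"characterized-gene table must have columns {required}")
    bad = [g for g in df["locus_id"] if not LOCUS_RE.fullmatch(g)]
    if bad:
        raise FormatError(f"malformed locus id {bad[0]!r}")
    return df


def read_goslim_table(path) -> pd.DataFrame:
    """Read a GO-Slim annotation table (gene_id, aspect in {BP,CC,MF}, term)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != ["gene_id", "aspect", "term"]:
        raise FormatError("GO-Slim table must have columns gene_id, aspect, term")
    bad = set(df["aspect"]) - {"BP", "CC", "MF"}
    if bad:
        raise FormatError(f"unknown GO aspect {sorted(bad)[0]!r}")
    return df


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

def _sorted_copy(graph: nx.Graph) -> nx.Graph:
    """Rebuild a graph with nodes and edges inserted in sorted order."""
    g = nx.Graph()
    for node in sorted(graph.nodes):
        g.add_node(node, **dict(sorted(graph.nodes[node].items())))
    for u, v in sorted(tuple(sorted(e)) for e in graph.edges):
        g.add_edge(u, v, **dict(sorted(graph.edges[u, v].items())))
    return g


def write_network(graph: nx.Graph, path, format: str = "graphml") -> None:
    """Write a regulatory network as graphml, sif, or an edge-list tsv.

    GraphML is lossless for node/edge attributes; SIF encodes the edge
    ``kind`` as the relation token.  Output is deterministic: nodes and
    edges are emitted sorted by id.
    """
    g = _sorted_copy(graph)
    if format == "graphml":
        nx.write_graphml(g, str(path), named_key_ids=True)
    elif format == "sif":
        with open(path, "w") as fh:
            for u, v, data in g.edges(data=True):
                fh.write(f"{u}\t{data.get('kind', 'edge')}\t{v}\n")
            for node in g.nodes:
                if g.degree(node) == 0:
                    fh.write(f"{node}\n")
    elif format == "tsv":
        with open(path, "w") as fh:
            fh.write("source\ttarget\tkind\tscore\n")
            for u, v, data in g.edges(data=True):
                score = data.get("score", "")
                fh.write(f"{u}\t{v}\t{data.get('kind', '')}\t{score}\n")
    else:
        raise FormatError(f"unsupported network format {format!r}")


def read_network(path) -> nx.Graph:
    """Read a GraphML network back (round trip partner of write_network)."""
    return nx.read_graphml(str(path))
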