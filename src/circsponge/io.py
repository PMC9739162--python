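"""Readers and writers for the pipeline's external formats.

Tabular files are tab-delimited with a header row, UTF-8; an empty string is
the only missing-value marker ('.' is rejected to avoid silent BED-style
placeholders).  FASTA goes through Biopython; sequences are stored
internally in the RNA alphabet (upper case, T -> U) because seed matching
is defined on RNA.

Two circRNA caller-output dialects are supported:

* ``ciri2_like``            - 1-based inclusive coordinates, with a
                              ``chr:start|end`` ID column;
* ``circexplorer2_like``    - BED-derived 0-based half-open coordinates.

Both are converted on read to the canonical 1-based inclusive
:class:`~circsponge.junction.BackspliceJunction`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .enrichment import GeneSet
from .junction import BackspliceJunction, CircRecord
from .sponge import SpongeNetwork, TargetRecord

__all__ = [
    "CallerDialect",
    "CIRI2_LIKE",
    "CIRCEXPLORER2_LIKE",
    "read_caller_table",
    "write_caller_table",
    "read_fasta",
    "write_fasta",
    "read_gmt",
    "write_gmt",
    "read_counts",
    "write_counts",
    "read_metadata",
    "write_metadata",
    "read_targets",
    "write_targets",
    "write_network",
    "read_tsv",
]


@dataclass(frozen=True)
class CallerDialect:
    name: str
    coordinate_convention: str

    def __post_init__(self) -> None:
        allowed = {
            "ciri2_like": "one_based_inclusive",
            "circexplorer2_like": "zero_based_half_open",
        }
        if allowed.get(self.name) != self.coordinate_convention:
            raise ValueError(
                f"dialect {self.name!r} requires convention "
                f"{allowed.get(self.name)!r}, got {self.coordinate_convention!r}"
            )


CIRI2_LIKE = CallerDialect("ciri2_like", "one_based_inclusive")
CIRCEXPLORER2_LIKE = CallerDialect("circexplorer2_like", "zero_based_half_open")

_DIALECT_COLUMNS = {
    "ciri2_like": ["circRNA_ID", "chrom", "start", "end", "junction_reads", "strand"],
    "circexplorer2_like": ["chrom", "start", "end", "name", "junction_reads", "strand"],
}


class ParseError(ValueError):
    """A malformed row or file, with location information."""


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    """Tab-delimited table; empty string is NA; '.' cells are rejected."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, **kwargs)
    if (df == ".").any().any():
        raise ParseError(f"{path}: '.' is not a valid NA marker (use empty string)")
    return df.replace("", pd.NA)


def read_caller_table(
    path: str | Path, dialect: CallerDialect, caller: str | None = None
) -> list[CircRecord]:
    """Parse one caller-output table into canonical circRNA records.

    Both dialects may carry an optional ``sample_id`` column; without it a
    single sample named after the file stem is assumed.  The caller label
    defaults to "A" for ciri2_like and "B" for circexplorer2_like.
    """
    path = Path(path)
    df = read_tsv(path)
    required = _DIALECT_COLUMNS[dialect.name]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing} for dialect {dialect.name}")
    if caller is None:
        caller = "A" if dialect.name == "ciri2_like" else "B"

    records: list[CircRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        try:
            start = int(getattr(row, "start"))
            end = int(getattr(row, "end"))
            reads = float(getattr(row, "junction_reads"))
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: non-numeric coordinates/reads at line {i}") from exc
        strand = getattr(row, "strand") or "."
        try:
            if dialect.coordinate_convention == "zero_based_half_open":
                junction = BackspliceJunction.from_zero_based(
                    str(getattr(row, "chrom")), start, end, strand
                )
            else:
                junction = BackspliceJunction(str(getattr(row, "chrom")), start, end, strand)
                declared = getattr(row, "circRNA_ID")
                if declared and junction.circ_id != declared:
                    raise ValueError(
                        f"ID {declared!r} disagrees with coordinates {junction.circ_id!r}"
                    )
        except ValueError as exc:
            raise ParseError(f"{path}: line {i}: {exc}") from exc
        sample = getattr(row, "sample_id", None) if "sample_id" in df.columns else None
        records.append(
            CircRecord(
                junction=junction,
                sample_id=str(sample) if sample is not None else path.stem,
                junction_reads=reads,
                caller=caller,
            )
        )
    return records


def write_caller_table(
    records: Iterable[CircRecord], path: str | Path, dialect: CallerDialect
) -> None:
    rows = []
    for rec in records:
        j = rec.junction
        if dialect.name == "ciri2_like":
            rows.append(
                {
                    "circRNA_ID": j.circ_id,
                    "chrom": j.chrom,
                    "start": j.start,
                    "end": j.end,
                    "junction_reads": rec.junction_reads,
                    "strand": j.strand,
                    "sample_id": rec.sample_id,
                }
            )
        else:
            chrom, s0, e0 = j.to_zero_based()
            rows.append(
                {
                    "chrom": chrom,
                    "start": s0,
                    "end": e0,
                    "name": j.circ_id,
                    "junction_reads": rec.junction_reads,
                    "strand": j.strand,
                    "sample_id": rec.sample_id,
                }
            )
    cols = _DIALECT_COLUMNS[dialect.name] + ["sample_id"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA -> ordered {id: RNA sequence} (upper case, T->U); IDs unique."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ParseError(f"{path}: duplicate FASTA ID {rec.id!r}")
        seq = str(rec.seq).upper().replace("T", "U")
        if not seq:
            raise ParseError(f"{path}: empty sequence for {rec.id!r}")
        seqs[rec.id] = seq
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GMT


def read_gmt(path: str | Path) -> list[GeneSet]:
    """GMT: term, description, then >= 1 gene per line; genes de-duplicated."""
    out: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: fewer than 3 tab-separated fields")
            term, name, *genes = fields
            out.append(GeneSet(term_id=term, name=name, genes=frozenset(g for g in genes if g)))
    return out


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in sets:
            fh.write("\t".join([gs.term_id, gs.name, *sorted(gs.genes)]) + "\n")


# ---------------------------------------------------------------------------
# count matrices / metadata / targets


def read_counts(path: str | Path):
    from .diffexp import CountMatrix

    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ParseError(f"{path}: missing values in count matrix")
    return CountMatrix.from_dataframe(df)


def write_counts(matrix, path: str | Path) -> None:
    df = matrix.to_dataframe()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t")


METADATA_COLUMNS = ["sample", "tissue", "condition", "RIN", "PMI", "sex"]


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = read_tsv(path)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: metadata missing column(s) {missing}")
    df["RIN"] = df["RIN"].astype(float)
    df["PMI"] = df["PMI"].astype(float)
    bad = set(df["condition"].dropna()) - {"ALS", "control"}
    if bad:
        raise ParseError(f"{path}: unknown condition label(s) {sorted(bad)}")
    return df


def write_metadata(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_targets(path: str | Path) -> list[TargetRecord]:
    df = read_tsv(path)
    required = ["mirna_id", "gene_id", "context_score"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: target table missing column(s) {missing}")
    return [
        TargetRecord(str(r.mirna_id), str(r.gene_id), float(r.context_score))
        for r in df.itertuples(index=False)
    ]


def write_targets(records: Iterable[TargetRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"mirna_id": r.mirna_id, "gene_id": r.gene_id, "context_score": r.context_score}
            for r in records
        ],
        columns=["mirna_id", "gene_id", "context_score"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# network export


def write_network(net: SpongeNetwork, path: str | Path, format: str = "edge_list") -> None:
    """Write the sponge network.

    ``edge_list`` writes two TSVs: ``<path>`` with columns source_id,
    source_class, target_id, target_class, tissue_of_origin, and a node
    table ``<path stem>.nodes.tsv`` with the log2 size attribute.
    ``graphml_like_xml`` writes GraphML.
    """
    net.validate()
    g = net.graph
    path = Path(path)
    if format == "graphml_like_xml":
        import networkx as nx

        nx.write_graphml(g, str(path))
        return
    if format != "edge_list":
        raise ValueError(f"unknown network format {format!r}")
    edges = pd.DataFrame(
        [
            {
                "source_id": u,
                "source_class": g.nodes[u]["node_class"],
                "target_id": v,
                "target_class": g.nodes[v]["node_class"],
                "tissue_of_origin": d.get("tissue_of_origin", ""),
            }
            for u, v, d in g.edges(data=True)
        ],
        columns=["source_id", "source_class", "target_id", "target_class", "tissue_of_origin"],
    )
    edges.to_csv(path, sep="\t", index=False)
    if path.name.endswith(".edges.tsv"):
        nodes_path = path.with_name(path.name[: -len(".edges.tsv")] + ".nodes.tsv")
    else:
        nodes_path = path.with_suffix(".nodes.tsv")
    nodes = pd.DataFrame(
        [
            {
                "node_id": n,
                "node_class": d["node_class"],
                "tissue_of_origin": d.get("tissue_of_origin", ""),
                "degree": d.get("degree", 0),
                "log2_size": d.get("log2_size", 0.0),
            }
            for n, d in g.nodes(data=True)
        ],
        columns=["node_id", "node_class", "tissue_of_origin", "degree", "log2_size"],
    )
    nodes.to_csv(nodes_path, sep="\t", index=False)
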