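"""miRNA seed-site scanning on circRNA sequences and sponge-network assembly.

A miRNA represses targets through Watson-Crick pairing of its seed region
(nucleotides 2-7 from the 5' end) with a complementary site on the target.
Canonical site classes, from weakest to strongest:

* 6mer     - the target hexamer is the reverse complement of the seed;
* 7mer-A1  - 6mer plus an adenine on the target immediately 3' of the
             hexamer (opposite miRNA position 1);
* 7mer-m8  - 6mer plus pairing of miRNA nucleotide 8 immediately 5' of the
             hexamer;
* 8mer     - both the m8 pair and the A1 adenine.

Because a circRNA is covalently closed, a site may straddle the back-spliced
junction; scanning therefore wraps around the sequence end and flags such
sites.  Each seed-hexamer match yields exactly one site of its best class.

The downstream steps mirror a sponge (competing endogenous RNA) analysis:
miRNAs are kept if they hit enough differentially expressed circRNAs,
ranked by their site burden on upregulated circRNAs, intersected with
upregulated DE genes through a miRNA-target table, and assembled into a
tripartite circRNA-miRNA-mRNA graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .diffexp import DEResult

__all__ = [
    "MiRNA",
    "SeedSite",
    "SiteCountTable",
    "TargetRecord",
    "SpongeNetwork",
    "revcomp_rna",
    "scan_sites",
    "site_count_table",
    "select_mirnas",
    "integrate_targets",
    "build_network",
]

_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")
_RNA_ALPHABET = frozenset("ACGU")

SITE_TYPES = ("6mer", "7mer-A1", "7mer-m8", "8mer")

# span length of each site class, counted from the reported start
_SITE_SPAN = {"6mer": 6, "7mer-A1": 7, "7mer-m8": 7, "8mer": 8}


def revcomp_rna(seq: str) -> str:
    """Reverse complement of an RNA string."""
    return seq.translate(_RNA_COMPLEMENT)[::-1]


def _check_rna(seq: str, what: str) -> None:
    bad = set(seq) - _RNA_ALPHABET
    if bad:
        raise ValueError(f"{what} contains non-RNA characters {sorted(bad)}")


@dataclass(frozen=True)
class MiRNA:
    """A mature miRNA sequence, 5'->3', RNA alphabet."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 7:
            raise ValueError(f"miRNA {self.id}: sequence shorter than 7 nt")
        _check_rna(self.sequence, f"miRNA {self.id}")

    @property
    def seed6(self) -> str:
        """Seed region: nucleotides 2-7."""
        return self.sequence[1:7]

    @property
    def nt8(self) -> str | None:
        """Nucleotide 8, or None for a 7-nt miRNA."""
        return self.sequence[7] if len(self.sequence) >= 8 else None


@dataclass(frozen=True)
class SeedSite:
    """One predicted binding site on a circRNA.

    ``start`` is 1-based on the circular sequence and points at the first
    nucleotide of the full site span (the m8-pairing position for
    8mer/7mer-m8 sites, the seed hexamer otherwise).
    """

    circ_id: str
    mirna_id: str
    start: int
    site_type: str
    wraps_junction: bool


@dataclass
class SiteCountTable:
    """circRNA x miRNA site counts (NaN = sequence unavailable)."""

    table: pd.DataFrame
    mean_sites_per_circ: float
    sites: list[SeedSite] = field(default_factory=list)


@dataclass(frozen=True)
class TargetRecord:
    """One miRNA-mRNA target pair with a context-style score (more negative
    = stronger predicted repression)."""

    mirna_id: str
    gene_id: str
    context_score: float


def _classify(hexamer_found: bool, m8_match: bool, a1_match: bool) -> str | None:
    if not hexamer_found:
        return None
    if m8_match and a1_match:
        return "8mer"
    if m8_match:
        return "7mer-m8"
    if a1_match:
        return "7mer-A1"
    return "6mer"


def scan_sites(
    circ_seq: str, mirna: MiRNA, circ_id: str = "", circular: bool = True
) -> list[SeedSite]:
    """Find all seed-complementary sites of ``mirna`` on ``circ_seq``.

    The target is scanned 5'->3' for the reverse complement of the seed
    hexamer; each match is promoted to 7mer/8mer by the m8 pair (target
    base immediately 5' of the hexamer complementary to miRNA nt 8) and/or
    the A1 adenine (target base immediately 3' of the hexamer).  With
    ``circular=True`` matches may wrap across the sequence end
    (back-spliced junction) and carry ``wraps_junction=True``.
    """
    seq = circ_seq.upper().replace("T", "U")
    _check_rna(seq, "circRNA sequence")
    length = len(seq)
    if length < 6:
        raise ValueError("circRNA sequence shorter than 6 nt")
    hexamer = revcomp_rna(mirna.seed6)
    m8_target = revcomp_rna(mirna.nt8) if mirna.nt8 is not None else None

    doubled = seq + seq if circular else seq
    sites: list[SeedSite] = []
    last_start = length - 1 if circular else length - 6
    # locate seed-hexamer occurrences with C-speed substring search
    starts: list[int] = []
    c = doubled.find(hexamer)
    while c != -1 and c <= last_start:
        starts.append(c)
        c = doubled.find(hexamer, c + 1)
    for c in starts:
        if circular:
            m8 = m8_target is not None and seq[(c - 1) % length] == m8_target
            a1 = doubled[c + 6] == "A"
        else:
            m8 = m8_target is not None and c >= 1 and seq[c - 1] == m8_target
            a1 = c + 6 < length and seq[c + 6] == "A"
        site_type = _classify(True, m8, a1)
        assert site_type is not None
        span = _SITE_SPAN[site_type]
        start0 = (c - 1) % length if site_type in ("8mer", "7mer-m8") else c
        if circular:
            wraps = start0 + span > length
        else:
            wraps = False
        sites.append(
            SeedSite(
                circ_id=circ_id,
                mirna_id=mirna.id,
                start=start0 + 1,
                site_type=site_type,
                wraps_junction=wraps,
            )
        )
    sites.sort(key=lambda s: (s.start, s.site_type))
    return sites


def site_count_table(
    circ_seqs: Mapping[str, str],
    mirna_panel: Sequence[MiRNA],
    circ_ids: Sequence[str] | None = None,
    circular: bool = True,
    site_classes: Sequence[str] = SITE_TYPES,
) -> SiteCountTable:
    """Count binding sites for every (circRNA, miRNA) pair.

    ``circ_ids`` restricts/orders the rows (e.g. the DE circRNAs); IDs
    without a sequence get NaN rows, are excluded from the per-circRNA mean
    and trigger a warning.  ``site_classes`` restricts which site types are
    counted (all four canonical classes by default).
    """
    if circ_ids is None:
        circ_ids = list(circ_seqs)
    bad_classes = set(site_classes) - set(SITE_TYPES)
    if bad_classes:
        raise ValueError(f"unknown site classes {sorted(bad_classes)}")
    mirna_ids = [m.id for m in mirna_panel]
    table = pd.DataFrame(
        np.zeros((len(circ_ids), len(mirna_ids))), index=list(circ_ids), columns=mirna_ids
    )
    all_sites: list[SeedSite] = []
    missing = [c for c in circ_ids if c not in circ_seqs]
    if missing:
        warnings.warn(f"no sequence for {len(missing)} circRNA(s); cells set to NaN")
        table.loc[missing, :] = np.nan
    for circ in circ_ids:
        if circ in missing:
            continue
        for mirna in mirna_panel:
            found = [
                s
                for s in scan_sites(circ_seqs[circ], mirna, circ_id=circ, circular=circular)
                if s.site_type in site_classes
            ]
            table.loc[circ, mirna.id] = len(found)
            all_sites.extend(found)
    with_seq = table.dropna()
    mean_sites = float(with_seq.sum(axis=1).mean()) if len(with_seq) else float("nan")
    return SiteCountTable(table=table, mean_sites_per_circ=mean_sites, sites=all_sites)


def _as_tissue_map(obj, default_tissue: str = "all") -> dict:
    return dict(obj) if isinstance(obj, Mapping) else {default_tissue: obj}


def select_mirnas(
    tables: SiteCountTable | Mapping[str, SiteCountTable],
    de_circ_up: Iterable[str] | Mapping[str, Iterable[str]],
    min_circ: int = 10,
    top_k: int = 12,
) -> pd.DataFrame:
    """Two-stage miRNA selection.

    Stage 1 keeps miRNAs with a nonzero site count in at least ``min_circ``
    distinct DE circRNAs in some tissue (rows of that tissue's table).
    Stage 2 ranks the kept miRNAs by total site count over upregulated DE
    circRNAs pooled across tissues, descending, ties broken lexicographically
    by miRNA ID, and returns the top ``top_k`` as a DataFrame (rank order)
    with per-tissue qualifying circRNA counts and the up-circRNA site total.
    """
    tabs = _as_tissue_map(tables)
    if not tabs or all(t.table.empty for t in tabs.values()):
        raise ValueError("empty site-count table")
    up = _as_tissue_map(de_circ_up)
    up_all: set[str] = set()
    for ids in up.values():
        up_all |= set(ids)

    mirna_ids = sorted({m for t in tabs.values() for m in t.table.columns})
    qual = pd.DataFrame(0, index=mirna_ids, columns=list(tabs))
    up_total = pd.Series(0.0, index=mirna_ids)
    for tissue, sct in tabs.items():
        tbl = sct.table
        qual.loc[tbl.columns, tissue] = (tbl > 0).sum(axis=0).astype(int)
        rows = [c for c in tbl.index if c in up_all]
        if rows:
            up_total.loc[tbl.columns] += tbl.loc[rows].fillna(0).sum(axis=0)

    kept = qual.index[(qual >= min_circ).any(axis=1)].tolist()
    kept.sort(key=lambda m: (-up_total[m], m))
    if len(kept) < top_k:
        warnings.warn(
            f"only {len(kept)} miRNA(s) pass the >= {min_circ} DE-circRNA filter "
            f"(top_k={top_k} requested)"
        )
    chosen = kept[:top_k]
    out = pd.DataFrame(
        {
            "mirna_id": chosen,
            "up_circ_site_total": [float(up_total[m]) for m in chosen],
        }
    )
    for tissue in tabs:
        out[f"n_de_circ_{tissue}"] = [int(qual.loc[m, tissue]) for m in chosen]
    out.index = range(1, len(chosen) + 1)
    out.index.name = "rank"
    return out


def integrate_targets(
    selected: Iterable[str],
    targets: Iterable[TargetRecord],
    de_genes: Sequence[DEResult],
    alpha: float = 0.05,
    max_context_score: float | None = None,
) -> pd.DataFrame:
    """Intersect selected-miRNA targets with upregulated DE genes.

    A gene is "affected" if it is targeted by at least one selected miRNA
    and is significantly upregulated (adj_p < alpha, log2fc > 0).  Returns
    one row per affected gene with the targeting miRNAs, sorted by gene ID.
    ``max_context_score`` optionally drops weaker target pairs (scores above
    the threshold; more negative = stronger).
    """
    selected = set(selected)
    target_list = list(targets)
    if not target_list:
        warnings.warn("empty target table; no affected genes")
    by_gene: dict[str, set[str]] = {}
    for rec in target_list:
        if rec.mirna_id not in selected:
            continue
        if max_context_score is not None and rec.context_score > max_context_score:
            continue
        by_gene.setdefault(rec.gene_id, set()).add(rec.mirna_id)

    rows = []
    for res in de_genes:
        if res.feature_id in by_gene and res.adj_p < alpha and res.log2fc > 0:
            rows.append(
                {
                    "gene_id": res.feature_id,
                    "mirnas": ",".join(sorted(by_gene[res.feature_id])),
                    "log2fc": res.log2fc,
                    "adj_p": res.adj_p,
                }
            )
    out = pd.DataFrame(rows, columns=["gene_id", "mirnas", "log2fc", "adj_p"])
    # a gene significant in several tissues is reported once (smallest adj_p)
    out = out.sort_values(["gene_id", "adj_p"]).drop_duplicates("gene_id")
    return out.reset_index(drop=True)


@dataclass
class SpongeNetwork:
    """Tripartite circRNA -> miRNA -> mRNA graph.

    Wraps a :class:`networkx.DiGraph`; nodes carry ``node_class``
    ("circRNA"/"miRNA"/"mRNA"), ``tissue_of_origin`` (circRNA nodes),
    ``degree`` and ``log2_size`` = log2(degree); edges carry
    ``mirna_color_key`` (the miRNA on the edge) and ``tissue_of_origin``.
    """

    graph: nx.DiGraph

    def nodes_by_class(self, node_class: str) -> list[str]:
        return [
            n for n, d in self.graph.nodes(data=True) if d["node_class"] == node_class
        ]

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def validate(self) -> None:
        for u, v in self.graph.edges:
            cu = self.graph.nodes[u]["node_class"]
            cv = self.graph.nodes[v]["node_class"]
            if (cu, cv) not in (("circRNA", "miRNA"), ("miRNA", "mRNA")):
                raise ValueError(f"illegal edge {u}({cu}) -> {v}({cv})")


def build_network(
    de_circ_up_by_tissue: Mapping[str, Iterable[str]],
    selected_mirnas: Iterable[str],
    site_tables: SiteCountTable | Mapping[str, SiteCountTable],
    affected_genes: pd.DataFrame,
    targets: Iterable[TargetRecord],
) -> SpongeNetwork:
    """Assemble the tripartite sponge network.

    circRNA->miRNA edges exist where a selected miRNA has a positive site
    count on an upregulated DE circRNA; miRNA->mRNA edges where a selected
    miRNA targets an affected gene.  Node sizes are log2 of the degree
    (total number of interactions).
    """
    selected = sorted(set(selected_mirnas))
    tabs = _as_tissue_map(site_tables)
    g = nx.DiGraph()
    for m in selected:
        g.add_node(m, node_class="miRNA")

    for tissue, circ_ids in de_circ_up_by_tissue.items():
        sct = tabs.get(tissue) or next(iter(tabs.values()))
        tbl = sct.table
        for circ in circ_ids:
            if circ not in tbl.index:
                continue
            for m in selected:
                if m in tbl.columns and tbl.loc[circ, m] > 0:
                    g.add_node(circ, node_class="circRNA", tissue_of_origin=tissue)
                    g.add_edge(circ, m, mirna_color_key=m, tissue_of_origin=tissue)

    affected = set(affected_genes["gene_id"]) if len(affected_genes) else set()
    for rec in targets:
        if rec.mirna_id in selected and rec.gene_id in affected:
            g.add_node(rec.gene_id, node_class="mRNA")
            g.add_edge(rec.mirna_id, rec.gene_id, mirna_color_key=rec.mirna_id,
                       tissue_of_origin="")

    # drop selected miRNAs that ended up with no interactions at all
    isolated = [n for n in g.nodes if g.degree(n) == 0]
    g.remove_nodes_from(isolated)

    for n in g.nodes:
        deg = g.degree(n)
        g.nodes[n]["degree"] = deg
        g.nodes[n]["log2_size"] = float(np.log2(deg)) if deg >= 1 else 0.0
        g.nodes[n].setdefault("tissue_of_origin", "")
    net = SpongeNetwork(graph=g)
    net.validate()
    return net
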