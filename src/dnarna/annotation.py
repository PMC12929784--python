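"""Gene-set over-representation and transcription-factor annotation of
significant DNA-RNA gene pairs, and the weighted association network.

Over-representation uses the one-sided hypergeometric upper tail: with a
background universe of N genes of which K belong to a set, and a query of n
genes, the p-value is P(X >= overlap) for X ~ Hypergeom(N, K, n).  BH
correction runs across all size-filtered sets.  Unless overridden, the
universe is the union of members of the filtered collection.

TF annotation joins significant (dna_gene, rna_gene) pairs against a
directed regulator->target edge list (TRRUST-v2-style TSV): a pair is
annotated when the DNA-altered gene is the transcription factor and the
expression-altered gene is one of its targets — direction matters.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import networkx as nx
from scipy import stats

from .io_model import normalize_gene_symbol
from .pairwise_screen import GenePairResult, bh_adjust

logger = logging.getLogger(__name__)

EDGE_MODES = frozenset({"activation", "repression", "unknown"})


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str]


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    set_size: int
    overlap: int
    overlap_genes: frozenset[str]
    p_value: float
    adjusted_p: float


@dataclass(frozen=True)
class RegulatoryEdge:
    tf: str
    target: str
    mode: str = "unknown"


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read a GMT gene-set collection: name <tab> description <tab> members."""
    sets: list[GeneSet] = []
    seen = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path} line {lineno}: GMT lines need >=3 tab-separated "
                    f"fields (name, description, members), got {len(fields)}"
                )
            name = fields[0].strip()
            if name in seen:
                raise ValueError(f"{path} line {lineno}: duplicate set name {name!r}")
            seen.add(name)
            members = frozenset(
                normalize_gene_symbol(g) for g in fields[2:] if g.strip()
            )
            sets.append(GeneSet(name=name, members=members))
    if not sets:
        logger.warning("%s: empty GMT collection", path)
    return sets


def filter_gene_sets(
    collection: Iterable[GeneSet],
    min_size: int = 10,
    max_size_exclusive: int = 250,
) -> list[GeneSet]:
    """Keep sets with min_size <= |members| < max_size_exclusive."""
    return [
        s for s in collection if min_size <= len(s.members) < max_size_exclusive
    ]


def enrich_overrepresentation(
    query: Iterable[str],
    collection: Sequence[GeneSet],
    universe: Optional[Iterable[str]] = None,
    min_overlap: int = 10,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of ``query`` in each gene set.

    Query genes outside the universe are dropped with a warning, and each
    set is intersected with the universe.  BH runs across *all* sets in the
    collection; only sets with overlap >= ``min_overlap`` and adjusted
    p < ``alpha`` are reported, sorted ascending by adjusted p.
    """
    if universe is None:
        uni: set[str] = set()
        for s in collection:
            uni |= s.members
    else:
        uni = set(universe)
    if not uni:
        raise ValueError("enrichment universe is empty")
    query_all = set(query)
    if not query_all:
        raise ValueError("enrichment query is empty")
    q = query_all & uni
    if len(q) < len(query_all):
        logger.warning(
            "%d of %d query genes are outside the universe and were dropped",
            len(query_all) - len(q),
            len(query_all),
        )
    if not q:
        raise ValueError("no query genes remain inside the universe")

    big_n, small_n = len(uni), len(q)
    rows = []
    p_values = []
    for s in collection:
        members = s.members & uni
        overlap_genes = frozenset(q & members)
        k, overlap = len(members), len(overlap_genes)
        # P(X >= overlap), X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(overlap - 1, big_n, k, small_n))
        rows.append((s.name, k, overlap, overlap_genes, min(1.0, p)))
        p_values.append(min(1.0, p))
    adjusted = bh_adjust(p_values)
    results = [
        EnrichmentResult(
            set_name=name,
            set_size=k,
            overlap=overlap,
            overlap_genes=genes,
            p_value=p,
            adjusted_p=float(adj),
        )
        for (name, k, overlap, genes, p), adj in zip(rows, adjusted)
    ]
    reported = [
        r for r in results if r.overlap >= min_overlap and r.adjusted_p < alpha
    ]
    reported.sort(key=lambda r: (r.adjusted_p, r.p_value, r.set_name))
    return reported


def build_query_from_pairs(pairs: Iterable[GenePairResult]) -> set[str]:
    """Union of DNA and RNA genes over significant pairs."""
    out: set[str] = set()
    for p in pairs:
        out.add(p.dna_gene)
        out.add(p.rna_gene)
    return out


def read_trrust(path: str | Path) -> list[RegulatoryEdge]:
    """Read a TRRUST-v2-dialect TSV: tf, target, mode, references; no header."""
    edges = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(
                    f"{path} line {lineno}: need at least tf and target columns"
                )
            mode = fields[2].strip().lower() if len(fields) > 2 else "unknown"
            if mode not in EDGE_MODES:
                mode = "unknown"
            edges.append(
                RegulatoryEdge(
                    tf=normalize_gene_symbol(fields[0]),
                    target=normalize_gene_symbol(fields[1]),
                    mode=mode,
                )
            )
    return edges


def annotate_tf_target_pairs(
    pairs: Sequence[GenePairResult], edges: Sequence[RegulatoryEdge]
) -> dict[tuple[str, str], str]:
    """Pairs whose DNA gene is a TF with the RNA gene among its targets.

    Returns {(dna_gene, rna_gene): regulation mode}.  The match is directed:
    dna_gene must be the regulator.
    """
    edge_map = {(e.tf, e.target): e.mode for e in edges}
    out = {}
    for p in pairs:
        mode = edge_map.get((p.dna_gene, p.rna_gene))
        if mode is not None:
            out[(p.dna_gene, p.rna_gene)] = mode
    return out


def build_association_network(
    pairs: Sequence[GenePairResult],
    tf_annotation: Optional[dict[tuple[str, str], str]] = None,
) -> tuple[nx.MultiDiGraph, nx.MultiDiGraph]:
    """Directed weighted networks of significant pairs.

    DNA-altered genes are edge sources and expression-altered genes are edge
    targets; edge weight is -log10(adjusted p).  An adjusted p that
    underflows to 0 is replaced by the smallest positive float, keeping
    weights finite (the substitution is logged).  Returns
    (TF-target subnetwork, remainder); their edge sets partition the input.
    """
    tf_annotation = tf_annotation or {}
    tf_net = nx.MultiDiGraph()
    other_net = nx.MultiDiGraph()
    for p in pairs:
        q = p.adjusted_p
        if q <= 0.0:
            q = math.ulp(0.0)
            logger.warning(
                "adjusted p underflow for (%s, %s); clamped to %g before log",
                p.dna_gene,
                p.rna_gene,
                q,
            )
        weight = -math.log10(q)
        key = (p.dna_gene, p.rna_gene)
        is_tf = key in tf_annotation
        net = tf_net if is_tf else other_net
        for gene, role in ((p.dna_gene, "dna_source"), (p.rna_gene, "rna_target")):
            if gene in net.nodes and net.nodes[gene]["role"] != role:
                net.nodes[gene]["role"] = "both"
            elif gene not in net.nodes:
                net.add_node(gene, role=role)
        net.add_edge(
            p.dna_gene,
            p.rna_gene,
            weight=weight,
            tf_target_flag=is_tf,
            mode=tf_annotation.get(key),
        )
    return tf_net, other_net


def write_enrichment(results: Sequence[EnrichmentResult], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("set_name\tset_size\toverlap\toverlap_genes\tp_value\tadjusted_p\n")
        for r in results:
            fh.write(
                f"{r.set_name}\t{r.set_size}\t{r.overlap}\t"
                f"{','.join(sorted(r.overlap_genes))}\t{r.p_value!r}\t"
                f"{r.adjusted_p!r}\n"
            )


def write_dot(tf_net: nx.MultiDiGraph, other_net: nx.MultiDiGraph, path) -> None:
    """Minimal Graphviz DOT export of both subnetworks (TF edges solid,
    others dashed; penwidth proportional to -log10 adjusted p)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("digraph associations {\n")
        for net, style in ((tf_net, "solid"), (other_net, "dashed")):
            for u, v, data in sorted(net.edges(data=True)):
                fh.write(
                    f'  "{u}" -> "{v}" [style={style}, '
                    f'penwidth={max(0.5, min(8.0, data["weight"])):.2f}];\n'
                )
        fh.write("}\n")


def write_network_edges(
    tf_net: nx.MultiDiGraph, other_net: nx.MultiDiGraph, path
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("source\ttarget\tweight\ttf_target_flag\n")
        for net, flag in ((tf_net, "true"), (other_net, "false")):
            for u, v, data in sorted(net.edges(data=True)):
                fh.write(f"{u}\t{v}\t{data['weight']!r}\t{flag}\n")
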