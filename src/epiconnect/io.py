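"""File formats: proteinGroups-style TSV, design TSV, GMT, chaperome lists,
intensity/DC/result tables, SIF + GraphML network export, PPI edge lists.

Every writer has a matching reader and round-trips losslessly on the
package's own synthetic fixtures. All tabular outputs are sorted on their
primary key so files are byte-stable across platforms.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import pandas as pd

from .igesa import ConnectivityMap, EnrichmentResult, results_to_frame
from .matrix import InputError, IntensityMatrix, SampleDesign
from .ppi import PPIReference

log = logging.getLogger(__name__)

LFQ_PREFIX = "LFQ intensity "
CONTAMINANT_PREFIXES = ("CON__", "REV__")


class FormatError(ValueError):
    """File does not follow the expected dialect."""


# ---------------------------------------------------------------------------
# proteinGroups dialect (MaxQuant-style): 0 = missing
# ---------------------------------------------------------------------------

def read_protein_groups(path) -> tuple[IntensityMatrix, list[str]]:
    """Read a proteinGroups-style TSV into a raw intensity matrix.

    The first semicolon-separated entry of the protein-ID column becomes the
    canonical ID (the full list is preserved in the ``all_ids`` attribute of
    the returned values frame); 0 and empty cells become missing;
    contaminant/decoy rows (``CON__``/``REV__`` prefixes) are dropped and
    counted in the returned warnings.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    id_col = None
    for candidate in ("Protein IDs", "Majority protein IDs", "protein_id"):
        if candidate in df.columns:
            id_col = candidate
            break
    if id_col is None:
        id_col = df.columns[0]
    lfq_cols = [c for c in df.columns if c.startswith(LFQ_PREFIX)]
    if not lfq_cols:
        raise FormatError(f"no '{LFQ_PREFIX}<sample>' columns in {path}")

    warnings: list[str] = []
    all_ids = df[id_col].fillna("")
    contaminant = all_ids.str.startswith(CONTAMINANT_PREFIXES)
    n_dropped = int(contaminant.sum())
    if n_dropped:
        warnings.append(f"dropped {n_dropped} contaminant/decoy rows")
        df = df[~contaminant]
        all_ids = all_ids[~contaminant]

    canonical = all_ids.str.split(";").str[0].str.strip()
    if canonical.duplicated().any():
        n_dup = int(canonical.duplicated().sum())
        warnings.append(f"suffix-deduplicated {n_dup} duplicate canonical IDs")
        counts: dict[str, int] = {}
        deduped = []
        for cid in canonical:
            if cid in counts:
                counts[cid] += 1
                deduped.append(f"{cid}.{counts[cid]}")
            else:
                counts[cid] = 0
                deduped.append(cid)
        canonical = pd.Series(deduped, index=canonical.index)

    values = df[lfq_cols].apply(pd.to_numeric, errors="coerce")
    values = values.mask(values == 0)  # MaxQuant convention: 0 = missing
    values.columns = [c[len(LFQ_PREFIX):] for c in lfq_cols]
    values.index = pd.Index(canonical, name="protein_id")
    values.attrs["all_ids"] = dict(zip(canonical, all_ids))
    for w in warnings:
        log.warning("%s: %s", path, w)
    return IntensityMatrix(values, scale="raw"), warnings


def write_protein_groups(m: IntensityMatrix, path) -> None:
    """Write a raw matrix in the proteinGroups dialect (missing written as 0)."""
    df = m.values.fillna(0.0).copy()
    df.columns = [f"{LFQ_PREFIX}{c}" for c in df.columns]
    df.insert(0, "Protein IDs", m.values.index)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# plain intensity TSV (processed dialect): empty = missing
# ---------------------------------------------------------------------------

def write_intensity_tsv(m: IntensityMatrix, path) -> None:
    out = m.values.copy()
    out.index.name = f"protein_id#scale={m.scale}"
    out.to_csv(path, sep="\t")


def read_intensity_tsv(path) -> IntensityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    scale = "raw"
    if df.index.name and "#scale=" in str(df.index.name):
        name, _, scale = str(df.index.name).partition("#scale=")
        df.index.name = name
    return IntensityMatrix(df, scale=scale)


# ---------------------------------------------------------------------------
# design TSV
# ---------------------------------------------------------------------------

def write_design(design: SampleDesign, path) -> None:
    design.table.rename_axis("sample").to_csv(path, sep="\t")


def read_design(path) -> SampleDesign:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={"condition": str})
    return SampleDesign(df)


# ---------------------------------------------------------------------------
# GMT and two-column annotation dialects
# ---------------------------------------------------------------------------

def write_gmt(terms: dict[str, tuple[str, frozenset[str]]], path) -> None:
    """GMT dialect: term_id TAB description TAB member1 TAB member2 ..."""
    with open(path, "w") as fh:
        for term_id in sorted(terms):
            desc, members = terms[term_id]
            fh.write("\t".join([term_id, desc, *sorted(members)]) + "\n")


def read_gmt(path) -> tuple[dict[str, set[str]], dict[str, str]]:
    term_sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has < 3 fields")
            term_id, desc, *members = parts
            term_sets[term_id] = {m for m in members if m}
            descriptions[term_id] = desc or term_id
    return term_sets, descriptions


def read_annotation_pairs(path) -> tuple[dict[str, set[str]], dict[str, str]]:
    """Two-column (protein, term) TSV; descriptions default to the term ID."""
    term_sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"bad two-column annotation line: {line!r}")
            protein, term = parts[0].strip(), parts[1].strip()
            term_sets.setdefault(term, set()).add(protein)
    return term_sets, {t: t for t in term_sets}


def read_chaperome_list(path) -> set[str]:
    """One identifier per line; blank lines and '#' comments ignored."""
    out = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line)
    if not out:
        raise InputError(f"chaperome list {path} is empty")
    return out


def write_chaperome_list(members, path) -> None:
    with open(path, "w") as fh:
        for m in sorted(members):
            fh.write(m + "\n")


# ---------------------------------------------------------------------------
# DC table
# ---------------------------------------------------------------------------

def write_dc_table(table: pd.DataFrame, path) -> None:
    table.sort_index().to_csv(path, sep="\t")


def read_dc_table(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", index_col=0, dtype={"direction": str}
    )
    df["is_dc"] = df["is_dc"].astype(bool)
    return df


# ---------------------------------------------------------------------------
# PPI reference
# ---------------------------------------------------------------------------

def write_ppi_reference(ref: PPIReference, edges_path, report_path=None) -> None:
    rows = [
        {
            "protein_a": a,
            "protein_b": b,
            "sources": ",".join(sorted(ref.provenance.get((a, b), ()))),
        }
        for a, b in sorted(ref.interactions)
    ]
    pd.DataFrame(rows, columns=["protein_a", "protein_b", "sources"]).to_csv(
        edges_path, sep="\t", index=False
    )
    if report_path is not None:
        report = pd.DataFrame(
            sorted(ref.filter_report.items()), columns=["rule", "n_removed"]
        )
        report.to_csv(report_path, sep="\t", index=False)


def read_ppi_reference(edges_path) -> PPIReference:
    from collections import Counter

    df = pd.read_csv(edges_path, sep="\t", dtype=str)
    interactions = set()
    provenance = {}
    for _, row in df.iterrows():
        pair = (row["protein_a"], row["protein_b"])
        interactions.add(pair)
        sources = row.get("sources")
        provenance[pair] = frozenset(
            s for s in str(sources).split(",") if s and s != "nan"
        )
    return PPIReference(
        interactions=interactions, provenance=provenance, filter_report=Counter()
    )


# ---------------------------------------------------------------------------
# network export: SIF + GraphML + attribute TSVs
# ---------------------------------------------------------------------------

NODE_ATTRS = ("neg_log10_p", "fold_change", "grey")


def export_network(net: nx.Graph, prefix) -> dict[str, Path]:
    """Write SIF, GraphML and node/edge attribute TSVs under ``prefix``.

    The SIF uses the ``pp`` relation; degree-0 nodes appear only in the
    node-attribute TSV (the SIF line format has no isolated-node syntax).
    GraphML embeds the node attributes typed, so re-reading reconstructs an
    identical network.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "sif": Path(str(prefix) + ".sif"),
        "graphml": Path(str(prefix) + ".graphml"),
        "nodes": Path(str(prefix) + ".nodes.tsv"),
        "edges": Path(str(prefix) + ".edges.tsv"),
    }
    edges = sorted((a, b) if a <= b else (b, a) for a, b in net.edges())
    with open(paths["sif"], "w") as fh:
        for a, b in edges:
            fh.write(f"{a}\tpp\t{b}\n")
    node_rows = []
    for n in sorted(net.nodes()):
        d = net.nodes[n]
        node_rows.append(
            {
                "node": n,
                "neg_log10_p": float(d.get("neg_log10_p", 0.0)),
                "fold_change": float(d.get("fold_change", 1.0)),
                "grey": bool(d.get("grey", True)),
            }
        )
    pd.DataFrame(node_rows, columns=["node", *NODE_ATTRS]).to_csv(
        paths["nodes"], sep="\t", index=False
    )
    pd.DataFrame(edges, columns=["protein_a", "protein_b"]).to_csv(
        paths["edges"], sep="\t", index=False
    )
    nx.write_graphml(net, paths["graphml"], named_key_ids=True)
    return paths


def read_network_graphml(path) -> nx.Graph:
    g = nx.read_graphml(path)
    out = nx.Graph()
    for n, d in g.nodes(data=True):
        out.add_node(
            n,
            neg_log10_p=float(d.get("neg_log10_p", 0.0)),
            fold_change=float(d.get("fold_change", 1.0)),
            grey=bool(d.get("grey", True)),
        )
    out.add_edges_from(g.edges())
    return out


# ---------------------------------------------------------------------------
# iGESA results and connectivity maps
# ---------------------------------------------------------------------------

def write_results_tsv(results: list[EnrichmentResult], path) -> None:
    results_to_frame(results).to_csv(path, sep="\t", index=False)


def read_results_tsv(path) -> list[EnrichmentResult]:
    df = pd.read_csv(path, sep="\t", dtype={"Direction": str, "geneID": str})
    out = []
    for _, row in df.iterrows():
        k, n = (int(x) for x in str(row["GeneRatio"]).split("/"))
        K, N = (int(x) for x in str(row["BgRatio"]).split("/"))
        genes = tuple(str(row["geneID"]).split(";")) if pd.notna(row["geneID"]) else ()
        out.append(
            EnrichmentResult(
                chaperome_id=str(row["Chaperome_ID"]),
                direction=str(row["Direction"]),
                term_id=str(row["term_id"]),
                description=str(row["Description"]),
                k=k,
                n=n,
                K=K,
                N=N,
                p_value=float(row["pvalue"]),
                p_adjust=float(row["p.adjust"]),
                q_value=float(row["qvalue"]),
                gene_ids=genes,
            )
        )
    return out


def export_connectivity_map(
    cmap: ConnectivityMap, prefix, condition: str = ""
) -> dict[str, Path]:
    """Bipartite SIF (Chaperome_ID -- Description) + edge-attribute TSV.

    The edge attributes carry the enrichment statistics plus the condition
    label (the attribute external viewers colour edges by).
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "sif": Path(str(prefix) + ".sif"),
        "edges": Path(str(prefix) + ".edges.tsv"),
    }
    items = sorted(cmap.links.items())
    with open(paths["sif"], "w") as fh:
        for _key, r in items:
            fh.write(f"{r.chaperome_id}\tlink\t{r.description}\n")
    rows = [
        {
            "Chaperome_ID": r.chaperome_id,
            "Description": r.description,
            "Direction": key[2],
            "term_id": r.term_id,
            "pvalue": r.p_value,
            "GeneRatio": r.gene_ratio,
            "BgRatio": r.bg_ratio,
            "qvalue": r.q_value,
            "p.adjust": r.p_adjust,
            "condition": condition,
        }
        for key, r in items
    ]
    pd.DataFrame(
        rows,
        columns=[
            "Chaperome_ID",
            "Description",
            "Direction",
            "term_id",
            "pvalue",
            "GeneRatio",
            "BgRatio",
            "qvalue",
            "p.adjust",
            "condition",
        ],
    ).to_csv(paths["edges"], sep="\t", index=False)
    return paths


def export_heatmap_matrix(
    m: IntensityMatrix, proteins: list[str], path
) -> None:
    """Export the processed-intensity submatrix external heatmap tools plot."""
    present = [p for p in proteins if p in m.values.index]
    m.values.loc[present].to_csv(path, sep="\t")
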