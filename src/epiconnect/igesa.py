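"""iGESA — interactome gene-set enrichment analysis.

For each chaperome (hub) member detected in the experiment, the method

  (i)   extracts the member's direct interactors from the PPI reference,
  (ii)  keeps only differentially connected (DC) interactors
        (DC.p <= dc_alpha),
  (iii) stratifies the remaining interactors by the sign of their fold
        change ("direction" + or -),
  (iv)  tests each direction's interactor set for term over-representation
        with a one-sided Fisher's exact test against an annotation table,
        adjusting p within the (member, direction) stratum by
        Benjamini-Hochberg, and
  (v)   links each enriched term to the member and direction.

Links surviving an adjusted-p cutoff (default 0.001) form the functional
connectivity map; the map's cardinality is the "functional connections"
count, and set algebra between two maps yields the connections shared by /
unique to each cellular state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .matrix import ConfigError, InputError
from .ppi import PPIReference

log = logging.getLogger(__name__)

__all__ = [
    "AnnotationTable",
    "EnrichmentResult",
    "ConnectivityMap",
    "fisher_enrichment",
    "bh_adjust",
    "storey_q",
    "run_igesa",
    "build_connectivity_map",
    "compare_maps",
    "results_to_frame",
]


@dataclass
class AnnotationTable:
    """Flat term -> member-set annotations over a protein universe."""

    terms: dict[str, tuple[str, frozenset[str]]]  # term_id -> (description, members)
    universe: frozenset[str]

    def __post_init__(self) -> None:
        if not self.universe:
            raise InputError("annotation universe is empty")
        for term_id, (desc, members) in self.terms.items():
            if not desc:
                raise InputError(f"term {term_id!r} has an empty description")
            extra = members - self.universe
            if extra:
                raise InputError(
                    f"term {term_id!r} has members outside the universe "
                    f"(e.g. {sorted(extra)[:3]})"
                )

    @classmethod
    def from_sets(
        cls,
        term_sets: dict[str, set[str]],
        descriptions: dict[str, str] | None = None,
        universe: set[str] | None = None,
    ) -> "AnnotationTable":
        if universe is None:
            universe = set().union(*term_sets.values()) if term_sets else set()
        descriptions = descriptions or {}
        terms = {
            t: (descriptions.get(t, t), frozenset(m) & frozenset(universe))
            for t, m in term_sets.items()
        }
        return cls(terms=terms, universe=frozenset(universe))

    def restrict(self, universe: set[str]) -> "AnnotationTable":
        """Restrict the table to ``universe`` (e.g. the detected proteins)."""
        new_universe = frozenset(self.universe) & frozenset(universe)
        if not new_universe:
            raise InputError("restriction leaves an empty universe")
        terms = {
            t: (d, m & new_universe)
            for t, (d, m) in self.terms.items()
            if m & new_universe
        }
        return AnnotationTable(terms=terms, universe=new_universe)


@dataclass(frozen=True)
class EnrichmentResult:
    """One Fisher over-representation test of a query against a term."""

    chaperome_id: str
    direction: str  # "+" or "-"; "." for a bare (member-free) enrichment
    term_id: str
    description: str
    k: int  # |query & term|
    n: int  # |query|
    K: int  # |term| within the universe
    N: int  # |universe|
    p_value: float
    p_adjust: float = float("nan")
    q_value: float = float("nan")
    gene_ids: tuple[str, ...] = ()

    @property
    def gene_ratio(self) -> str:
        return f"{self.k}/{self.n}"

    @property
    def bg_ratio(self) -> str:
        return f"{self.K}/{self.N}"

    @property
    def link_key(self) -> tuple[str, str, str]:
        return (self.chaperome_id, self.term_id, self.direction)


def fisher_enrichment(
    query: set[str],
    ann: AnnotationTable,
    chaperome_id: str = ".",
    direction: str = ".",
) -> list[EnrichmentResult]:
    """One-sided (over-representation) Fisher's exact test per term.

    The p-value is the hypergeometric upper tail P(X >= k) for drawing n
    query proteins from a universe of N containing K term members. Query
    proteins outside the universe are dropped with a warning; terms with
    zero overlap are omitted. p values are unadjusted here.
    """
    if not ann.universe:
        raise InputError("empty annotation universe")
    stray = query - ann.universe
    if stray:
        log.warning(
            "%d query proteins outside the annotation universe dropped", len(stray)
        )
        query = query & ann.universe
    if not query:
        return []
    N = len(ann.universe)
    n = len(query)
    results: list[EnrichmentResult] = []
    for term_id in sorted(ann.terms):
        desc, members = ann.terms[term_id]
        overlap = query & members
        k = len(overlap)
        if k == 0:
            continue
        K = len(members)
        p = float(sps.hypergeom.sf(k - 1, N, K, n))
        results.append(
            EnrichmentResult(
                chaperome_id=chaperome_id,
                direction=direction,
                term_id=term_id,
                description=desc,
                k=k,
                n=n,
                K=K,
                N=N,
                p_value=min(p, 1.0),
                gene_ids=tuple(sorted(overlap)),
            )
        )
    return results


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def storey_q(p_values, lam: float = 0.5) -> np.ndarray:
    """Storey q-values with a single-lambda pi0 estimate (optional mode)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    pi0 = min(1.0, float(np.mean(p > lam)) / (1.0 - lam)) if p.size else 1.0
    pi0 = max(pi0, 1.0 / p.size)
    return np.minimum(pi0 * bh_adjust(p), 1.0)


def _adjust_stratum(rows: list[EnrichmentResult], use_storey: bool) -> list[EnrichmentResult]:
    if not rows:
        return rows
    p = [r.p_value for r in rows]
    adj = bh_adjust(p)
    q = storey_q(p) if use_storey else adj
    return [
        EnrichmentResult(
            chaperome_id=r.chaperome_id,
            direction=r.direction,
            term_id=r.term_id,
            description=r.description,
            k=r.k,
            n=r.n,
            K=r.K,
            N=r.N,
            p_value=r.p_value,
            p_adjust=float(a),
            q_value=float(qq),
            gene_ids=r.gene_ids,
        )
        for r, a, qq in zip(rows, adj, q)
    ]


def run_igesa(
    dc: pd.DataFrame,
    ppi: PPIReference,
    ann: AnnotationTable,
    chaperome: set[str],
    dc_alpha: float = 0.1,
    min_stratum: int = 3,
    background: str = "detected",
    global_adjust: bool = False,
    use_storey: bool = False,
    report: dict | None = None,
) -> list[EnrichmentResult]:
    """Run the full iGESA loop over every chaperome member.

    Parameters
    ----------
    dc
        DC table (from :func:`epiconnect.dc.dc_table`) over the detected
        proteins.
    background
        "detected" restricts the enrichment universe to detected proteins
        present in the annotation (the default, appropriate for AP-MS
        experiments); "annotation" uses the whole annotation universe.
    min_stratum
        Minimum number of DC interactors a (member, direction) stratum
        needs to be tested; smaller strata are skipped and counted.
    global_adjust
        Adjust p across all strata jointly instead of within each
        (member, direction) stratum.
    report
        Optional dict populated with bookkeeping counts (members without
        neighbours, skipped small strata, universe size).
    """
    if not chaperome:
        raise InputError("chaperome member set is empty")
    if not (0 < dc_alpha <= 1):
        raise ConfigError(f"dc_alpha must be in (0, 1], got {dc_alpha}")
    if background not in ("detected", "annotation"):
        raise ConfigError(f"unknown background mode {background!r}")

    detected = set(dc.index)
    overlap = detected & set(ann.universe)
    if detected and len(overlap) < 0.5 * len(detected):
        raise InputError(
            f"only {len(overlap)}/{len(detected)} detected proteins found in "
            "the annotation universe; likely an identifier-namespace mix-up"
        )
    if background == "detected":
        universe_ann = ann.restrict(overlap)
    else:
        universe_ann = ann

    dc_ok = dc["p_value"] <= dc_alpha
    plus = set(dc.index[dc_ok & (dc["direction"] == "+")])
    minus = set(dc.index[dc_ok & (dc["direction"] == "-")])

    adj = ppi.neighbor_index()
    results: list[EnrichmentResult] = []
    n_no_neighbors = 0
    n_small = 0
    for member in sorted(chaperome):
        neighbors = adj.get(member, set()) & detected
        if not neighbors:
            n_no_neighbors += 1
            continue
        for direction, dc_set in (("+", plus), ("-", minus)):
            query = neighbors & dc_set & universe_ann.universe
            if not query:
                continue
            if len(query) < min_stratum:
                n_small += 1
                continue
            rows = fisher_enrichment(
                query, universe_ann, chaperome_id=member, direction=direction
            )
            if not global_adjust:
                rows = _adjust_stratum(rows, use_storey)
            results.extend(rows)
    if global_adjust:
        results = _adjust_stratum(results, use_storey)
    if report is not None:
        report.update(
            {
                "members_without_neighbors": n_no_neighbors,
                "strata_below_min_size": n_small,
                "universe_size": len(universe_ann.universe),
                "n_results": len(results),
            }
        )
    if n_no_neighbors:
        log.info("%d chaperome members had no detected PPI neighbours", n_no_neighbors)
    return results


@dataclass
class ConnectivityMap:
    """Significant (member, term, direction) links at an adjusted-p cutoff."""

    links: dict[tuple[str, str, str], EnrichmentResult] = field(default_factory=dict)
    adj_p_max: float = 0.001
    collapse_direction: bool = False

    @property
    def n_connections(self) -> int:
        return len(self.links)

    @property
    def link_keys(self) -> set[tuple[str, str, str]]:
        return set(self.links)


def build_connectivity_map(
    results: list[EnrichmentResult],
    adj_p_max: float = 0.001,
    collapse_direction: bool = False,
) -> ConnectivityMap:
    """Keep links with p_adjust <= adj_p_max (inclusive).

    The uniqueness key is (member, term, direction) by default; with
    ``collapse_direction=True`` the direction is dropped from the key and
    the smallest-p result is kept per (member, term).
    """
    if not (0 < adj_p_max <= 1):
        raise ConfigError(f"adj_p_max must be in (0, 1], got {adj_p_max}")
    links: dict[tuple[str, str, str], EnrichmentResult] = {}
    for r in sorted(results, key=lambda r: (r.chaperome_id, r.term_id, r.direction)):
        if np.isnan(r.p_adjust) or r.p_adjust > adj_p_max:
            continue
        key = (
            (r.chaperome_id, r.term_id, ".")
            if collapse_direction
            else r.link_key
        )
        if key not in links or r.p_adjust < links[key].p_adjust:
            links[key] = r
    return ConnectivityMap(
        links=links, adj_p_max=adj_p_max, collapse_direction=collapse_direction
    )


def compare_maps(a: ConnectivityMap, b: ConnectivityMap):
    """Links shared by and unique to each of two connectivity maps."""
    if a.collapse_direction != b.collapse_direction:
        raise ConfigError("maps were built under different uniqueness keys")
    ka, kb = a.link_keys, b.link_keys
    return {"shared": ka & kb, "only_a": ka - kb, "only_b": kb - ka}


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Deterministically ordered result table in the export column layout."""
    rows = [
        {
            "Chaperome_ID": r.chaperome_id,
            "Direction": r.direction,
            "term_id": r.term_id,
            "Description": r.description,
            "GeneRatio": r.gene_ratio,
            "BgRatio": r.bg_ratio,
            "pvalue": r.p_value,
            "p.adjust": r.p_adjust,
            "qvalue": r.q_value,
            "geneID": ";".join(r.gene_ids),
            "Count": r.k,
        }
        for r in sorted(results, key=lambda r: (r.chaperome_id, r.direction, r.term_id))
    ]
    columns = [
        "Chaperome_ID",
        "Direction",
        "term_id",
        "Description",
        "GeneRatio",
        "BgRatio",
        "pvalue",
        "p.adjust",
        "qvalue",
        "geneID",
        "Count",
    ]
    return pd.DataFrame(rows, columns=columns)
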