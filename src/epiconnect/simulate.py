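"""Synthetic epichaperomics study generator with known planted truth.

Emulates the data shapes of an epichaperome AP-MS study so every pipeline
stage is testable without external downloads:

* replicate LFQ intensity matrices with a multiplicative condition effect on
  a planted protein subset, log10-normal base abundances, multiplicative
  replicate noise, and a missingness mixture of intensity-dependent (MNAR,
  logistic in log10 intensity) and completely-random (MCAR) dropout;
* an undirected PPI "database" written in both the BioGrid-tab and PSI-MITAB
  2.5 dialects, where chaperome members are high-degree hubs, and a
  configurable fraction of records carry filterable annotations (genetic /
  MI:0208 / the excluded experimental systems) or non-human taxon IDs;
* a flat term-annotation table with enrichment planted among the
  differential interactors of designated chaperome members.

Everything is driven by one integer seed; fixed seed means bit-identical
outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .igesa import AnnotationTable
from .matrix import ConfigError, IntensityMatrix, SampleDesign

log = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "PPISimResult",
    "simulate_intensities",
    "simulate_ppi_sources",
    "simulate_annotations",
    "simulate_study",
]

_CONDITION_LABELS = "ABCDEFGH"


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic study.

    Intensity model: per protein a base log10 abundance ~
    Normal(base_log10_mean, base_log10_sd); planted differential proteins
    carry a multiplicative fold (effect_fold or its reciprocal) in condition
    B; replicate noise is mean-one log-normal with coefficient of variation
    cv_replicate. Dropout probability is
    ``mcar_rate + (1 - mcar_rate) * logistic(-mnar_strength * (x - c))``
    in log10 intensity x with centre c (``mnar_center``, defaulting to
     1.5 SD below the base mean); ``mnar_strength = 0`` disables the MNAR
    component entirely.
    """

    n_proteins: int = 2000
    n_conditions: int = 2
    n_replicates: int = 6
    frac_differential: float = 0.1
    effect_fold: float = 2.0
    frac_effect_up: float = 0.5
    base_log10_mean: float = 7.0
    base_log10_sd: float = 0.8
    cv_replicate: float = 0.1
    mnar_strength: float = 3.0
    mnar_center: float | None = None
    mcar_rate: float = 0.02
    n_chaperome: int = 20
    n_terms: int = 200
    term_size_range: tuple[int, int] = (10, 100)
    planted_links: tuple[tuple[int, int, str], ...] | None = None
    enrichment_fraction: float = 0.8
    min_planted_dc_interactors: int = 8
    hub_degree: int = 100
    background_edges_per_protein: float = 2.0
    filterable_fraction: float = 0.1
    foreign_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            ("n_proteins", self.n_proteins >= 2),
            ("n_conditions", 2 <= self.n_conditions <= len(_CONDITION_LABELS)),
            ("n_replicates", self.n_replicates >= 2),
            ("frac_differential", 0.0 <= self.frac_differential <= 1.0),
            ("effect_fold", self.effect_fold > 0),
            ("frac_effect_up", 0.0 <= self.frac_effect_up <= 1.0),
            ("cv_replicate", self.cv_replicate >= 0),
            ("mnar_strength", self.mnar_strength >= 0),
            ("mcar_rate", 0.0 <= self.mcar_rate <= 1.0),
            ("n_chaperome", 1 <= self.n_chaperome <= self.n_proteins),
            ("n_terms", self.n_terms >= 1),
            (
                "term_size_range",
                2 <= self.term_size_range[0] <= self.term_size_range[1],
            ),
            ("enrichment_fraction", 0.0 <= self.enrichment_fraction <= 1.0),
            ("min_planted_dc_interactors", self.min_planted_dc_interactors >= 1),
            ("hub_degree", 1 <= self.hub_degree < self.n_proteins),
            ("background_edges_per_protein", self.background_edges_per_protein >= 0),
            ("filterable_fraction", 0.0 <= self.filterable_fraction < 1.0),
            ("foreign_fraction", 0.0 <= self.foreign_fraction < 1.0),
            ("seed", 0 <= int(self.seed) < 2**31),
        ]
        for name, ok in checks:
            if not ok:
                raise ConfigError(f"invalid configuration value for {name!r}")
        if self.term_size_range[1] > self.n_proteins:
            raise ConfigError(
                "invalid configuration value for 'term_size_range': "
                "maximum term size exceeds the protein universe"
            )
        if self.planted_links is not None:
            for member_i, term_i, direction in self.planted_links:
                if not (0 <= member_i < self.n_chaperome):
                    raise ConfigError(
                        "invalid configuration value for 'planted_links': "
                        f"member index {member_i} out of range"
                    )
                if not (0 <= term_i < self.n_terms):
                    raise ConfigError(
                        "invalid configuration value for 'planted_links': "
                        f"term index {term_i} out of range"
                    )
                if direction not in ("+", "-"):
                    raise ConfigError(
                        "invalid configuration value for 'planted_links': "
                        f"direction must be '+' or '-', got {direction!r}"
                    )

    def null(self) -> "SimConfig":
        """A matched null configuration: no effects, no planted links."""
        return replace(self, frac_differential=0.0, planted_links=())

    @property
    def protein_ids(self) -> list[str]:
        width = len(str(self.n_proteins))
        return [f"P{i + 1:0{width}d}" for i in range(self.n_proteins)]

    @property
    def term_ids(self) -> list[str]:
        width = len(str(self.n_terms))
        return [f"T{i + 1:0{width}d}" for i in range(self.n_terms)]

    @property
    def conditions(self) -> list[str]:
        return list(_CONDITION_LABELS[: self.n_conditions])

    def resolved_planted_links(self) -> list[tuple[str, str, str]]:
        """Planted links as (member_id, term_id, direction) triples.

        ``planted_links=None`` plants one link per chaperome member on the
        first terms, alternating direction.
        """
        proteins = self.protein_ids
        terms = self.term_ids
        members = proteins[: self.n_chaperome]
        if self.planted_links is None:
            n = min(self.n_chaperome, self.n_terms)
            return [
                (members[i], terms[i], "+" if i % 2 == 0 else "-") for i in range(n)
            ]
        return [
            (members[mi], terms[ti], d) for mi, ti, d in self.planted_links
        ]


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated study."""

    differential: dict[str, float]  # protein -> true linear fold (cond B / A)
    members: list[str]
    planted_links: list[tuple[str, str, str]]
    missing_mask: pd.DataFrame = field(repr=False)
    design: SampleDesign = field(repr=False)

    @property
    def differential_proteins(self) -> set[str]:
        return set(self.differential)

    def differential_with_direction(self, direction: str) -> set[str]:
        if direction == "+":
            return {p for p, f in self.differential.items() if f > 1}
        if direction == "-":
            return {p for p, f in self.differential.items() if f < 1}
        raise ValueError(f"direction must be '+' or '-', got {direction!r}")


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([stream, int(config.seed)])


def simulate_intensities(config: SimConfig) -> tuple[IntensityMatrix, SyntheticTruth]:
    """Generate a raw LFQ matrix and its ground truth.

    The matrix has n_proteins rows and n_conditions * n_replicates columns;
    the condition effect applies to condition B (vs the baseline A); missing
    cells are NaN in the matrix and recorded in the truth's missing mask.
    """
    rng = _rng(config, 0)
    proteins = config.protein_ids
    members = proteins[: config.n_chaperome]
    conditions = config.conditions
    samples = [
        (f"{c}_{r + 1}", c, r + 1)
        for c in conditions
        for r in range(config.n_replicates)
    ]
    design = SampleDesign.from_records(samples)

    n_diff = int(round(config.frac_differential * config.n_proteins))
    pool = np.array([p for p in proteins if p not in set(members)])
    n_diff = min(n_diff, len(pool))
    chosen = rng.choice(pool, size=n_diff, replace=False) if n_diff else np.array([])
    n_up = int(round(config.frac_effect_up * n_diff))
    folds = {}
    for i, p in enumerate(sorted(chosen)):
        folds[p] = config.effect_fold if i < n_up else 1.0 / config.effect_fold

    base = rng.normal(config.base_log10_mean, config.base_log10_sd, config.n_proteins)
    fold_vec = np.array([folds.get(p, 1.0) for p in proteins])
    cols = {}
    sigma = np.sqrt(np.log1p(config.cv_replicate**2))
    for sample_id, cond, _ in samples:
        x = np.power(10.0, base)
        if cond == "B":
            x = x * fold_vec
        if sigma > 0:
            noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=len(x))
        else:
            noise = 1.0
        cols[sample_id] = x * noise
    values = pd.DataFrame(cols, index=pd.Index(proteins, name="protein_id"))

    log10_vals = np.log10(values.to_numpy())
    center = (
        config.mnar_center
        if config.mnar_center is not None
        else config.base_log10_mean - 1.5 * config.base_log10_sd
    )
    if config.mnar_strength > 0:
        p_mnar = 1.0 / (1.0 + np.exp(config.mnar_strength * (log10_vals - center)))
    else:
        p_mnar = np.zeros_like(log10_vals)
    p_drop = config.mcar_rate + (1.0 - config.mcar_rate) * p_mnar
    mask = rng.random(size=log10_vals.shape) < p_drop
    values = values.mask(mask)
    missing_mask = pd.DataFrame(mask, index=values.index, columns=values.columns)

    truth = SyntheticTruth(
        differential=folds,
        members=members,
        planted_links=config.resolved_planted_links(),
        missing_mask=missing_mask,
        design=design,
    )
    return IntensityMatrix(values, scale="raw"), truth


@dataclass
class PPISimResult:
    """Generator bookkeeping for a pair of simulated PPI source files."""

    true_edges: set[tuple[str, str]]
    n_records_total: int
    n_physical_records: int
    n_filterable_records: int
    n_foreign_records: int
    n_duplicate_records: int  # physical records present in both files
    # planted (member, term, direction) -> the differential partners wired
    # for it; partners are kept disjoint across members where the pool
    # allows, so planted enrichment stays specific to its member
    planted_partners: dict[tuple[str, str, str], tuple[str, ...]] = field(
        default_factory=dict
    )


def _canonical(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


_BIOGRID_HEADER = (
    "Official Symbol Interactor A\tOfficial Symbol Interactor B\t"
    "Experimental System\tExperimental System Type\t"
    "Organism Interactor A\tOrganism Interactor B\n"
)

_FILTERABLE_BIOGRID = [
    ("Synthetic Lethality", "genetic"),
    ("Synthetic Rescue", "genetic"),
    ("Synthetic Growth Defect", "genetic"),
    ("Genetic interference", "genetic"),
    ("Co-localization", "physical"),
    ("Dosage Rescue", "genetic"),
]


def _biogrid_row(a: str, b: str, system: str, stype: str, taxa: str, taxb: str) -> str:
    return f"{a}\t{b}\t{system}\t{stype}\t{taxa}\t{taxb}\n"


def _mitab_row(
    a: str,
    b: str,
    mi_type: str = "psi-mi:MI:0915(physical association)",
    taxa: str = "taxid:9606(human)",
    taxb: str = "taxid:9606(human)",
) -> str:
    cols = [
        f"uniprotkb:{a}",
        f"uniprotkb:{b}",
        "-",
        "-",
        f"uniprotkb:{a}(gene name)",
        f"uniprotkb:{b}(gene name)",
        "psi-mi:MI:0004(affinity chromatography technology)",
        "-",
        "pubmed:000000",
        taxa,
        taxb,
        mi_type,
        "psi-mi:MI:0469(IntAct)",
        "-",
        "-",
    ]
    return "\t".join(cols) + "\n"


def simulate_ppi_sources(
    config: SimConfig,
    universe: set[str] | list[str],
    biogrid_path,
    mitab_path,
    truth: SyntheticTruth | None = None,
) -> PPISimResult:
    """Write a BioGrid-tab and a PSI-MITAB 2.5 file over the universe.

    The physical human-human subset of the written records equals the
    returned true edge set. Chaperome members are high-degree hubs (each is
    wired to ``hub_degree`` partners), and when a truth is supplied each
    planted link's member additionally gets
    ``min_planted_dc_interactors`` partners that are differential with the
    planted direction, so planted local interactomes are guaranteed
    testable. ``filterable_fraction`` / ``foreign_fraction`` of all records
    carry filterable annotations or non-human taxon IDs.
    """
    universe = sorted(universe)
    if len(universe) < 2:
        raise ConfigError("invalid configuration value: universe smaller than 2")
    rng = _rng(config, 1)
    uni_arr = np.array(universe)
    members = truth.members if truth is not None else universe[: config.n_chaperome]
    members = [m for m in members if m in set(universe)]

    edges: set[tuple[str, str]] = set()
    for member in members:
        partners = rng.choice(uni_arr, size=min(config.hub_degree, len(universe) - 1) + 1, replace=False)
        partners = [p for p in partners if p != member][: config.hub_degree]
        for p in partners:
            edges.add(_canonical(member, p))
    planted_partners: dict[tuple[str, str, str], tuple[str, ...]] = {}
    if truth is not None:
        used_by_direction: dict[str, set[str]] = {"+": set(), "-": set()}
        for member, term, direction in truth.planted_links:
            full_pool = sorted(
                truth.differential_with_direction(direction) & set(universe)
            )
            pool = [p for p in full_pool if p not in used_by_direction[direction]]
            if not pool:
                pool = full_pool  # small pools: allow sharing rather than fail
            if not pool:
                continue
            k = min(config.min_planted_dc_interactors, len(pool))
            chosen = [
                p
                for p in rng.choice(np.array(pool), size=k, replace=False)
                if p != member
            ]
            used_by_direction[direction].update(chosen)
            for p in chosen:
                edges.add(_canonical(member, p))
            planted_partners[(member, term, direction)] = tuple(sorted(chosen))
    n_background = int(round(config.background_edges_per_protein * len(universe)))
    if n_background:
        ia = rng.integers(0, len(universe), size=2 * n_background)
        ib = rng.integers(0, len(universe), size=2 * n_background)
        added = 0
        for x, y in zip(ia, ib):
            if added >= n_background:
                break
            if x == y:
                continue
            edges.add(_canonical(universe[x], universe[y]))
            added += 1

    true_edges = set(edges)
    edge_list = sorted(true_edges)

    # physical records: each true edge appears in one or both source files
    dest = rng.random(len(edge_list))
    biogrid_rows: list[str] = []
    mitab_rows: list[str] = []
    n_duplicates = 0
    for (a, b), u in zip(edge_list, dest):
        if u < 0.45:
            biogrid_rows.append(
                _biogrid_row(a, b, "Affinity Capture-MS", "physical", "9606", "9606")
            )
        elif u < 0.90:
            mitab_rows.append(_mitab_row(a, b))
        else:
            biogrid_rows.append(
                _biogrid_row(a, b, "Affinity Capture-MS", "physical", "9606", "9606")
            )
            mitab_rows.append(_mitab_row(a, b))
            n_duplicates += 1
    n_physical = len(edge_list) + n_duplicates

    # decoy records: filterable annotations and non-human pairs
    def _random_pair() -> tuple[str, str]:
        while True:
            x, y = rng.integers(0, len(universe), size=2)
            if x != y:
                return universe[x], universe[y]

    f, g = config.filterable_fraction, config.foreign_fraction
    decoy_share = f + g
    n_decoys_total = (
        int(round(decoy_share * n_physical / (1.0 - decoy_share)))
        if decoy_share > 0
        else 0
    )
    n_filterable = int(round(n_decoys_total * (f / decoy_share))) if decoy_share else 0
    n_foreign = n_decoys_total - n_filterable
    for i in range(n_filterable):
        a, b = _random_pair()
        if rng.random() < 0.5:
            system, stype = _FILTERABLE_BIOGRID[
                int(rng.integers(0, len(_FILTERABLE_BIOGRID)))
            ]
            if system == "Dosage Rescue":
                system = "Synthetic Lethality"  # keep to the excluded set
            biogrid_rows.append(_biogrid_row(a, b, system, stype, "9606", "9606"))
        else:
            mitab_rows.append(
                _mitab_row(a, b, mi_type="psi-mi:MI:0208(genetic interaction)")
            )
    for i in range(n_foreign):
        a, b = _random_pair()
        if rng.random() < 0.5:
            biogrid_rows.append(
                _biogrid_row(a, b, "Affinity Capture-MS", "physical", "9606", "10090")
            )
        else:
            mitab_rows.append(_mitab_row(a, b, taxb="taxid:10090(mouse)"))

    with open(biogrid_path, "w") as fh:
        fh.write(_BIOGRID_HEADER)
        fh.writelines(biogrid_rows)
    with open(mitab_path, "w") as fh:
        fh.writelines(mitab_rows)

    return PPISimResult(
        true_edges=true_edges,
        n_records_total=n_physical + n_filterable + n_foreign,
        n_physical_records=n_physical,
        n_filterable_records=n_filterable,
        n_foreign_records=n_foreign,
        n_duplicate_records=n_duplicates,
        planted_partners=planted_partners,
    )


def simulate_annotations(
    config: SimConfig,
    truth: SyntheticTruth,
    true_edges: set[tuple[str, str]],
    planted_partners: dict[tuple[str, str, str], tuple[str, ...]] | None = None,
) -> AnnotationTable:
    """Generate term annotations with planted local-interactome enrichment.

    For each planted (member, term, direction) link, a fraction
    ``enrichment_fraction`` of the term is drawn from the member's
    differential interactors of that direction (capped by their number);
    the remainder, and all non-planted terms, are uniform draws from the
    protein universe. When ``planted_partners`` (the generator's wiring
    bookkeeping) is supplied, the enriched portion is drawn from the
    member-exclusive wired partners, which keeps planted enrichment
    specific to its member even when the direction-stratified differential
    pool is small.
    """
    rng = _rng(config, 2)
    universe = config.protein_ids
    uni_arr = np.array(universe)
    lo, hi = config.term_size_range
    if hi > len(universe):
        raise ConfigError(
            "invalid configuration value for 'term_size_range': infeasible "
            "for the protein universe"
        )

    adj: dict[str, set[str]] = {}
    for a, b in true_edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)

    planted_by_term: dict[str, tuple[str, str]] = {
        term: (member, direction) for member, term, direction in truth.planted_links
    }
    for member, term, direction in truth.planted_links:
        pool = adj.get(member, set()) & truth.differential_with_direction(direction)
        if not pool:
            raise ConfigError(
                f"planted link ({member}, {term}, {direction}) is not "
                "realizable: the member has no differential interactors of "
                "that direction"
            )

    term_sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    for term in config.term_ids:
        size = int(rng.integers(lo, hi + 1))
        members_of_term: set[str] = set()
        if term in planted_by_term:
            member, direction = planted_by_term[term]
            key = (member, term, direction)
            if planted_partners and key in planted_partners:
                pool = sorted(planted_partners[key])
            else:
                pool = sorted(
                    adj.get(member, set())
                    & truth.differential_with_direction(direction)
                )
            n_enriched = min(int(round(config.enrichment_fraction * size)), len(pool))
            members_of_term.update(
                rng.choice(np.array(pool), size=n_enriched, replace=False)
            )
        while len(members_of_term) < size:
            need = size - len(members_of_term)
            members_of_term.update(rng.choice(uni_arr, size=need, replace=False))
        descriptions[term] = f"synthetic process {term}"
        term_sets[term] = members_of_term

    return AnnotationTable.from_sets(
        term_sets, descriptions=descriptions, universe=set(universe)
    )


def simulate_study(config: SimConfig, out_dir) -> dict:
    """Generate and write a complete synthetic study to ``out_dir``.

    Files written: proteinGroups-style intensity TSV, design TSV,
    BioGrid-tab + PSI-MITAB PPI sources, GMT annotations, chaperome member
    list, and a truth TSV (planted folds and links) for test harnesses.
    Returns a dict with the file paths and the in-memory objects.
    """
    from pathlib import Path

    from . import io

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    matrix, truth = simulate_intensities(config)
    paths = {
        "intensities": out_dir / "proteinGroups.tsv",
        "design": out_dir / "design.tsv",
        "biogrid": out_dir / "biogrid.tsv",
        "mitab": out_dir / "intact.mitab.tsv",
        "annotations": out_dir / "annotations.gmt",
        "chaperome": out_dir / "chaperome.txt",
        "truth": out_dir / "truth.tsv",
    }
    io.write_protein_groups(matrix, paths["intensities"])
    io.write_design(truth.design, paths["design"])
    ppi_sim = simulate_ppi_sources(
        config, set(matrix.protein_ids), paths["biogrid"], paths["mitab"], truth=truth
    )
    annotations = simulate_annotations(
        config, truth, ppi_sim.true_edges, planted_partners=ppi_sim.planted_partners
    )
    io.write_gmt(annotations.terms, paths["annotations"])
    io.write_chaperome_list(truth.members, paths["chaperome"])

    with open(paths["truth"], "w") as fh:
        fh.write("record\tfield_1\tfield_2\tfield_3\n")
        for p in sorted(truth.differential):
            fh.write(f"differential\t{p}\t{truth.differential[p]!r}\t\n")
        for member, term, direction in truth.planted_links:
            fh.write(f"planted_link\t{member}\t{term}\t{direction}\n")

    return {
        "paths": {k: str(v) for k, v in paths.items()},
        "matrix": matrix,
        "truth": truth,
        "ppi_sim": ppi_sim,
        "annotations": annotations,
    }
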