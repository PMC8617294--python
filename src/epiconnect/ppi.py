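"""PPI reference assembly: parse BioGrid-tab and PSI-MITAB 2.5 sources,
apply quality filters, and merge into one deduplicated undirected
human-human interaction set.

Quality filters remove interactions that are not physical human-human PPIs:
records annotated as genetic (experimental system type "genetic", or
psi-mi code MI:0208), records from co-localization / genetic interference /
synthetic rescue / synthetic growth defect / synthetic lethality
experiments, cross-species or non-human pairs, and (by default) self-pairs.
Records whose annotations are unknown are retained: only positively
matching annotations are removed.
"""

from __future__ import annotations

import csv
import logging
import re
from collections import Counter
from dataclasses import dataclass, field

log = logging.getLogger(__name__)

HUMAN_TAXID = "9606"
GENETIC_MI_CODE = "MI:0208"

# experimental systems removed by the reference filter, normalized by
# lower-casing and stripping spaces/hyphens/underscores (covers both the
# -ise and -ize spellings of co-localization)
EXCLUDED_SYSTEMS = frozenset(
    {
        "colocalization",
        "colocalisation",
        "geneticinterference",
        "syntheticrescue",
        "syntheticgrowthdefect",
        "syntheticlethality",
    }
)

BIOGRID_COLUMNS = [
    "Official Symbol Interactor A",
    "Official Symbol Interactor B",
    "Experimental System",
    "Experimental System Type",
    "Organism Interactor A",
    "Organism Interactor B",
]

_MI_RE = re.compile(r"MI:\d{4}")


class FormatError(ValueError):
    """Source file does not follow the declared dialect."""


def _norm_label(text: str | None) -> str:
    if text is None:
        return ""
    return re.sub(r"[\s\-_]+", "", text.strip().lower())


@dataclass(frozen=True)
class Interaction:
    """One source record: an unordered protein pair with its annotations."""

    protein_a: str
    protein_b: str
    source: str  # "biogrid" | "intact"
    interaction_type: str | None = None  # PSI-MI code, e.g. "MI:0208"
    experimental_system: str | None = None  # e.g. "Two-hybrid"
    system_type: str | None = None  # e.g. "physical" / "genetic"
    taxid_a: str | None = None
    taxid_b: str | None = None

    @property
    def pair(self) -> tuple[str, str]:
        return (self.protein_a, self.protein_b)


def make_interaction(a: str, b: str, source: str, **kw) -> Interaction:
    """Create an Interaction with the pair stored in lexicographic order.

    Taxid annotations follow their protein when the pair is swapped.
    """
    a, b = a.strip(), b.strip()
    if not a or not b:
        raise ValueError("empty interactor identifier")
    if a > b:
        a, b = b, a
        ta, tb = kw.get("taxid_a"), kw.get("taxid_b")
        kw["taxid_a"], kw["taxid_b"] = tb, ta
    return Interaction(protein_a=a, protein_b=b, source=source, **kw)


@dataclass
class PPIReference:
    """Deduplicated, filtered, undirected human PPI set."""

    interactions: set[tuple[str, str]]
    provenance: dict[tuple[str, str], frozenset[str]] = field(default_factory=dict)
    filter_report: Counter = field(default_factory=Counter)

    def __len__(self) -> int:
        return len(self.interactions)

    def neighbors(self, protein: str) -> set[str]:
        out: set[str] = set()
        for a, b in self.interactions:
            if a == protein:
                out.add(b)
            elif b == protein:
                out.add(a)
        return out

    def neighbor_index(self) -> dict[str, set[str]]:
        """Adjacency map; build once when many lookups are needed."""
        adj: dict[str, set[str]] = {}
        for a, b in self.interactions:
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
        return adj


def parse_biogrid_tab(path) -> list[Interaction]:
    """Parse a BioGrid tab-dialect TSV (header row, official symbols).

    Malformed rows (too few fields, empty symbols) are skipped and counted
    in a warning; a missing mandatory column is a format error.
    """
    interactions: list[Interaction] = []
    n_skipped = 0
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            log.warning("empty BioGrid file: %s", path)
            return []
        missing = [c for c in BIOGRID_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise FormatError(f"BioGrid file lacks mandatory column(s): {missing}")
        for row in reader:
            try:
                if any(row.get(c) is None for c in BIOGRID_COLUMNS):
                    raise ValueError("truncated row")
                a = (row["Official Symbol Interactor A"] or "").strip()
                b = (row["Official Symbol Interactor B"] or "").strip()
                if not a or not b:
                    raise ValueError("empty symbol")
                interactions.append(
                    make_interaction(
                        a,
                        b,
                        source="biogrid",
                        experimental_system=(row["Experimental System"] or "").strip()
                        or None,
                        system_type=(row["Experimental System Type"] or "").strip()
                        or None,
                        taxid_a=(row["Organism Interactor A"] or "").strip() or None,
                        taxid_b=(row["Organism Interactor B"] or "").strip() or None,
                    )
                )
            except (ValueError, KeyError, TypeError):
                n_skipped += 1
    if n_skipped:
        log.warning("skipped %d malformed BioGrid rows in %s", n_skipped, path)
    if not interactions:
        log.warning("no interactions parsed from %s", path)
    return interactions


def _mitab_field(text: str) -> str | None:
    text = text.strip()
    return None if (not text or text == "-") else text


def _mitab_symbol(alias_field: str | None, id_field: str | None) -> str | None:
    """Gene symbol from a MITAB alias field, e.g. ``uniprotkb:TP53(gene name)``.

    Falls back to the primary-ID field (text after the first colon) when no
    alias is present.
    """
    for candidate in (alias_field, id_field):
        if candidate is None:
            continue
        first = candidate.split("|")[0]
        body = first.split(":", 1)[1] if ":" in first else first
        body = body.split("(", 1)[0].strip()
        if body:
            return body
    return None


def _mitab_accession(id_field: str | None) -> str | None:
    if id_field is None:
        return None
    first = id_field.split("|")[0]
    body = first.split(":", 1)[1] if ":" in first else first
    body = body.split("(", 1)[0].strip()
    return body or None


def _mitab_taxid(field_text: str | None) -> str | None:
    if field_text is None:
        return None
    m = re.search(r"taxid:(-?\d+)", field_text)
    return m.group(1) if m else None


def _mitab_mi_code(field_text: str | None) -> str | None:
    if field_text is None:
        return None
    m = _MI_RE.search(field_text)
    return m.group(0) if m else None


def parse_psimitab(path, id_key: str = "symbol") -> list[Interaction]:
    """Parse a PSI-MITAB 2.5 TSV (no header, ``-`` = missing, 15 columns).

    Columns used: 1/2 unique IDs, 5/6 aliases, 10/11 taxids, 12 interaction
    type. ``id_key`` selects the identifier space: "symbol" takes the gene
    symbol from the alias column (falling back to the primary accession),
    "accession" takes the primary ID directly.
    """
    if id_key not in ("symbol", "accession"):
        raise ValueError(f"id_key must be 'symbol' or 'accession', got {id_key!r}")
    interactions: list[Interaction] = []
    n_skipped = 0
    with open(path, newline="") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                n_skipped += 1
                continue
            id_a, id_b = _mitab_field(cols[0]), _mitab_field(cols[1])
            alias_a, alias_b = _mitab_field(cols[4]), _mitab_field(cols[5])
            if id_key == "symbol":
                a = _mitab_symbol(alias_a, id_a)
                b = _mitab_symbol(alias_b, id_b)
            else:
                a = _mitab_accession(id_a)
                b = _mitab_accession(id_b)
            if not a or not b:
                n_skipped += 1
                continue
            interactions.append(
                make_interaction(
                    a,
                    b,
                    source="intact",
                    interaction_type=_mitab_mi_code(_mitab_field(cols[11])),
                    taxid_a=_mitab_taxid(_mitab_field(cols[9])),
                    taxid_b=_mitab_taxid(_mitab_field(cols[10])),
                )
            )
    if n_skipped:
        log.warning("skipped %d malformed MITAB rows in %s", n_skipped, path)
    if not interactions:
        log.warning("no interactions parsed from %s", path)
    return interactions


def classify_interaction(
    rec: Interaction, keep_self: bool = False
) -> str | None:
    """Return the removal rule a record positively matches, or None to keep.

    Rules, in order: "genetic" (MI:0208 or a type/system labelled genetic),
    one of the five excluded experimental systems, non-human pair, self-pair.
    """
    if rec.interaction_type == GENETIC_MI_CODE:
        return "genetic"
    if _norm_label(rec.system_type) == "genetic":
        return "genetic"
    if _norm_label(rec.experimental_system) == "genetic":
        return "genetic"
    sys_norm = _norm_label(rec.experimental_system)
    if sys_norm in EXCLUDED_SYSTEMS:
        return sys_norm
    for tax in (rec.taxid_a, rec.taxid_b):
        if tax is not None and tax != HUMAN_TAXID:
            return "non_human"
    if not keep_self and rec.protein_a == rec.protein_b:
        return "self_pair"
    return None


def build_reference(
    *sources: list[Interaction],
    keep_self: bool = False,
    mapping: dict[str, str] | None = None,
) -> PPIReference:
    """Filter and merge parsed interaction lists into one reference set.

    Parameters
    ----------
    sources
        One or more lists of parsed Interactions (any order; the result is
        order-invariant).
    keep_self
        Retain self-pairs instead of dropping them.
    mapping
        Optional identifier mapping (e.g. accession -> gene symbol) applied
        before filtering; identifiers absent from the mapping pass through.

    The ``filter_report`` counts removed records per rule plus
    ``duplicate`` for records collapsing onto an already-retained pair, so
    retained pairs + sum(filter_report) equals the parsed record count.
    """
    report: Counter = Counter()
    pairs: dict[tuple[str, str], set[str]] = {}
    for records in sources:
        for rec in records:
            if mapping:
                a = mapping.get(rec.protein_a, rec.protein_a)
                b = mapping.get(rec.protein_b, rec.protein_b)
                if (a, b) != (rec.protein_a, rec.protein_b):
                    rec = make_interaction(
                        a,
                        b,
                        rec.source,
                        interaction_type=rec.interaction_type,
                        experimental_system=rec.experimental_system,
                        system_type=rec.system_type,
                        taxid_a=rec.taxid_a,
                        taxid_b=rec.taxid_b,
                    )
            rule = classify_interaction(rec, keep_self=keep_self)
            if rule is not None:
                report[rule] += 1
                continue
            if rec.pair in pairs:
                report["duplicate"] += 1
                pairs[rec.pair].add(rec.source)
            else:
                pairs[rec.pair] = {rec.source}
    if not pairs:
        log.warning("PPI reference is empty after filtering")
    return PPIReference(
        interactions=set(pairs),
        provenance={p: frozenset(s) for p, s in pairs.items()},
        filter_report=report,
    )
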