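"""End-to-end orchestration: preprocess -> DC -> PPI reference -> networks
-> iGESA -> connectivity maps, with all artifacts written to an output
directory plus a machine-readable run manifest.

The manifest records package and dependency versions, the seed, thresholds
and SHA-256 digests of every input, so a run is fully determined by its
manifest: replaying one reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__, io
from .dc import dc_table
from .igesa import (
    build_connectivity_map,
    compare_maps,
    run_igesa,
)
from .matrix import ConfigError, InputError
from .network import build_network, diff_networks
from .ppi import build_reference, parse_biogrid_tab, parse_psimitab
from .preprocess import preprocess

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything one analysis run needs, serializable to/from YAML."""

    intensities: str
    design: str
    biogrid: str | None = None
    mitab: str | None = None
    annotations: str = ""
    chaperome: str = ""
    out_dir: str = "results"
    comparisons: list[tuple[str, str]] = field(default_factory=lambda: [("A", "B")])
    dc_alpha: float = 0.1
    adj_p_max: float = 0.001
    welch: bool = False
    background: str = "detected"
    collapse_direction: bool = False
    use_storey: bool = False
    keep_self: bool = False
    min_stratum: int = 3
    remap_imputed: bool = False
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not (0 < self.dc_alpha <= 1):
            raise ConfigError(f"dc_alpha must be in (0, 1], got {self.dc_alpha}")
        if not (0 < self.adj_p_max <= 1):
            raise ConfigError(f"adj_p_max must be in (0, 1], got {self.adj_p_max}")
        self.comparisons = [tuple(c) for c in self.comparisons]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class RunResult:
    """In-memory bundle of one pipeline run."""

    dc_tables: dict
    networks: dict
    network_diffs: dict
    igesa_results: dict
    maps: dict
    map_comparison: dict | None
    manifest: dict


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> RunResult:
    """Execute the full analysis described by ``config``.

    For each configured condition pair (a, b): preprocess the intensity
    matrix, compute the DC table for b vs a, build DC-annotated state
    networks over each condition's detected proteins and their diff, run
    iGESA, and threshold the results into a connectivity map. When two
    comparisons are configured, the two maps are compared link-by-link.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    raw, _warnings = io.read_protein_groups(config.intensities)
    design = io.read_design(config.design)
    design.check_matches(raw)

    processed = preprocess(raw, design, remap_imputed=config.remap_imputed)
    io.write_intensity_tsv(processed, out_dir / "intensities.log10.tsv")

    sources = []
    if config.biogrid:
        sources.append(parse_biogrid_tab(config.biogrid))
    if config.mitab:
        sources.append(parse_psimitab(config.mitab))
    if not sources:
        raise InputError("no PPI source files configured")
    reference = build_reference(*sources, keep_self=config.keep_self)
    io.write_ppi_reference(
        reference, out_dir / "ppi_reference.tsv", out_dir / "ppi_filter_report.tsv"
    )

    term_sets, descriptions = (
        io.read_gmt(config.annotations)
        if _looks_like_gmt(config.annotations)
        else io.read_annotation_pairs(config.annotations)
    )
    from .igesa import AnnotationTable

    annotations = AnnotationTable.from_sets(term_sets, descriptions)
    chaperome = io.read_chaperome_list(config.chaperome)

    detected_by_condition = {
        cond: set(raw.values.index[raw.values[cols].notna().any(axis=1)])
        for cond, cols in design.groups().items()
    }

    dc_tables, networks, network_diffs, igesa_results, maps = {}, {}, {}, {}, {}
    for cond_a, cond_b in config.comparisons:
        tag = f"{cond_b}_vs_{cond_a}"
        dc = dc_table(
            processed,
            design,
            cond_a,
            cond_b,
            dc_alpha=config.dc_alpha,
            welch=config.welch,
        )
        dc_tables[tag] = dc
        io.write_dc_table(dc, out_dir / f"dc.{tag}.tsv")

        for cond in (cond_a, cond_b):
            if cond in networks:
                continue
            net = build_network(
                detected_by_condition[cond], reference, dc, dc_alpha=config.dc_alpha
            )
            networks[cond] = net
            io.export_network(net, out_dir / f"network.{cond}")
        diff = diff_networks(networks[cond_a], networks[cond_b])
        network_diffs[tag] = diff
        with open(out_dir / f"network_diff.{tag}.json", "w") as fh:
            json.dump(diff.summary(), fh, indent=2, sort_keys=True)

        report: dict = {}
        results = run_igesa(
            dc,
            reference,
            annotations,
            chaperome,
            dc_alpha=config.dc_alpha,
            min_stratum=config.min_stratum,
            background=config.background,
            use_storey=config.use_storey,
            report=report,
        )
        igesa_results[tag] = results
        io.write_results_tsv(results, out_dir / f"igesa.{tag}.tsv")
        cmap = build_connectivity_map(
            results,
            adj_p_max=config.adj_p_max,
            collapse_direction=config.collapse_direction,
        )
        maps[tag] = cmap
        io.export_connectivity_map(cmap, out_dir / f"map.{tag}", condition=tag)

    map_comparison = None
    if len(config.comparisons) == 2:
        tags = [f"{b}_vs_{a}" for a, b in config.comparisons]
        cmp = compare_maps(maps[tags[0]], maps[tags[1]])
        map_comparison = {
            "shared": sorted(cmp["shared"]),
            "only_a": sorted(cmp["only_a"]),
            "only_b": sorted(cmp["only_b"]),
            "n_shared": len(cmp["shared"]),
            "n_only_a": len(cmp["only_a"]),
            "n_only_b": len(cmp["only_b"]),
        }
        with open(out_dir / "map_comparison.json", "w") as fh:
            json.dump(map_comparison, fh, indent=2, sort_keys=True)

    inputs = {
        "intensities": config.intensities,
        "design": config.design,
        "biogrid": config.biogrid,
        "mitab": config.mitab,
        "annotations": config.annotations,
        "chaperome": config.chaperome,
    }
    manifest = {
        "epiconnect_version": __version__,
        "seed": config.seed,
        "dc_alpha": config.dc_alpha,
        "adj_p_max": config.adj_p_max,
        "comparisons": [list(c) for c in config.comparisons],
        "flags": {
            "welch": config.welch,
            "background": config.background,
            "collapse_direction": config.collapse_direction,
            "use_storey": config.use_storey,
            "keep_self": config.keep_self,
            "remap_imputed": config.remap_imputed,
            "min_stratum": config.min_stratum,
        },
        "input_digests": {
            k: _sha256(v) for k, v in inputs.items() if v
        },
        "n_connections": {tag: maps[tag].n_connections for tag in maps},
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return RunResult(
        dc_tables=dc_tables,
        networks=networks,
        network_diffs=network_diffs,
        igesa_results=igesa_results,
        maps=maps,
        map_comparison=map_comparison,
        manifest=manifest,
    )


def _looks_like_gmt(path) -> bool:
    """GMT lines have >= 3 fields; two-column pair files have exactly 2."""
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return len(line.rstrip("\n").split("\t")) >= 3
    return True
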