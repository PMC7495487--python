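"""End-to-end orchestration: fixture simulation, staged runs, run reports.

`simulate_fixtures` writes a complete, internally consistent set of input
files (compound table, per-source target lists, expression study, STRING
edge list, tissue atlas, organ panel, GMT term map, compound-target map)
with a ground-truth manifest, all derived from one seed. `run` executes
the analysis stages in order on such inputs and emits every artifact plus
a machine-readable JSON report whose counts are recomputable from the
artifacts on disk. Reports carry no timestamp, so a fixed seed and fixed
inputs reproduce the report byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as npio
from .compound_screen import adme_filter
from .diffexpr import batch_adjust, de_test, volcano_filter
from .enrichment import TermMap, ora, select_top
from .network_assembly import build_hct, build_tp, export
from .organ_localization import build_target_organ_network, default_organ_panel
from .ppi_topology import (
    centralities,
    drop_isolated,
    induced_subgraph,
    load_edges,
    screen_core,
    screen_thresholds,
)
from .synthetic_data import (
    gen_compound_table,
    gen_expression,
    gen_ppi,
    gen_target_universe,
    gen_tissue_matrix,
)
from .target_assembly import TargetSet, intersect, union_dedup, venn_counts

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "simulate_fixtures", "run"]

HERB_NAME = "herb"


@dataclass
class PipelineConfig:
    """Input paths and parameters for a full pipeline run.

    Any optional stage input left as ``None`` skips that stage; a stage
    whose required upstream output is unavailable is a configuration
    error raised before any stage executes.
    """

    compounds: Path | None = None
    whitelist: Path | None = None
    fishing: list[Path] = field(default_factory=list)
    disease: list[Path] = field(default_factory=list)
    expression_matrix: Path | None = None
    sample_sheet: Path | None = None
    edges: Path | None = None
    tissue_matrix: Path | None = None
    tissue_missing: Path | None = None
    panel: Path | None = None
    gmt: Path | None = None
    compound_targets: Path | None = None
    alias: Path | None = None
    herb_name: str = HERB_NAME
    ob_min: float = 30.0
    dl_min: float = 0.18
    p_max: float = 0.05
    lfc_min: float = 1.0
    score_min: int = 400
    fdr_max: float = 0.05
    top_k: int = 20
    seed: int = 0

    @classmethod
    def from_ini(cls, path: str | Path) -> "PipelineConfig":
        """Parse a flat key=value / INI config (section headers optional)."""
        import configparser

        text = Path(path).read_text()
        parser = configparser.ConfigParser()
        if not text.lstrip().startswith("["):
            text = "[netpharm]\n" + text
        parser.read_string(text)
        merged: dict[str, str] = {}
        for section in parser.sections():
            merged.update(parser[section])
        base = Path(path).parent
        cfg = cls()

        def as_path(v: str) -> Path:
            p = Path(v)
            return p if p.is_absolute() else base / p

        for key, value in merged.items():
            if key in ("fishing", "disease"):
                setattr(cfg, key, [as_path(v) for v in value.split(",") if v.strip()])
            elif key in ("ob_min", "dl_min", "p_max", "lfc_min", "fdr_max"):
                setattr(cfg, key, float(value))
            elif key in ("score_min", "top_k", "seed"):
                setattr(cfg, key, int(value))
            elif key == "herb_name":
                cfg.herb_name = value
            elif hasattr(cfg, key):
                setattr(cfg, key, as_path(value))
            else:
                raise ValueError(f"unknown config key {key!r}")
        return cfg


def simulate_fixtures(out_dir: str | Path, seed: int) -> dict:
    """Write a complete synthetic input set and its ground-truth manifest.

    The defaults mirror the study conditions the pipeline was designed
    around: 29 compounds of which 9 pass the ADME screen and 1 is a
    whitelist rescue; 933 drug targets and 913 disease targets sharing
    exactly 184 symbols; an 800-gene two-batch expression study with 50
    planted DE genes at log2 fold change 2; a preferential-attachment PPI
    graph over the composite targets with a 40-node planted hub module
    and two unconnected targets; a 20-tissue atlas with 170 targets
    planted into the 17-organ immune panel and two atlas gaps; a 200-term
    GMT with one term planted around the hub module; and a
    compound-target map sized to give the Herb-Component-Target network
    192 nodes and 748 edges.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(99,)))

    # --- compounds -------------------------------------------------------
    compounds = gen_compound_table(29, 9, 1, seed)
    npio.write_compound_table(compounds, out_dir / "compounds.tsv")
    whitelist = sorted(compounds.loc[compounds["whitelisted"], "name"])
    npio.write_target_list(whitelist, out_dir / "whitelist.txt")

    # --- target universes ------------------------------------------------
    drug, disease = gen_target_universe(2000, 933, 913, 184, seed)
    composite = sorted(drug & disease)
    fishing_files = []
    drug_sorted = sorted(drug)
    n_src = 5
    assignments = rng.integers(0, n_src, size=len(drug_sorted))
    extra = rng.random(size=(len(drug_sorted), n_src)) < 0.15
    for s in range(n_src):
        members = [
            g
            for i, g in enumerate(drug_sorted)
            if assignments[i] == s or extra[i, s]
        ]
        path = out_dir / f"fishing_src{s + 1}.tsv"
        npio.write_target_list(members, path)
        fishing_files.append(path)

    # planted DE genes live inside the disease set so database lists plus
    # DEGs reunite to exactly the planted disease set
    disease_sorted = sorted(disease)
    expr_genes = [
        disease_sorted[i]
        for i in sorted(rng.choice(len(disease_sorted), size=800, replace=False))
    ]
    study, de_genes = gen_expression(
        800, 20, 20, 50, 2.0, 0.5, 1.0, 2, seed, genes=expr_genes
    )
    npio.write_expression_study(
        study, out_dir / "expression.tsv", out_dir / "samples.tsv"
    )
    disease_files = []
    db_assign = rng.integers(0, 3, size=len(disease_sorted))
    db_extra = rng.random(size=(len(disease_sorted), 3)) < 0.2
    for s in range(3):
        members = [
            g
            for i, g in enumerate(disease_sorted)
            if db_assign[i] == s or db_extra[i, s]
        ]
        path = out_dir / f"disease_db{s + 1}.tsv"
        npio.write_target_list(members, path)
        disease_files.append(path)

    # --- PPI graph over the composite targets ----------------------------
    # two targets stay unconnected: the edge list never mentions them
    connected = composite[:-2]
    graph, hubs = gen_ppi(
        len(connected), "preferential", 2, 40, 0.8, seed, nodes=connected
    )
    edges = [
        (u, v, int(rng.integers(400, 1001))) for u, v in sorted(map(sorted, graph.edges()))
    ]
    npio.write_string_edges(edges, out_dir / "string_edges.tsv")

    # --- tissue atlas ----------------------------------------------------
    panel = default_organ_panel()
    extra_tissues = ["whole blood", "kidney", "pancreas"]
    tissues = panel + extra_tissues
    missing_genes = composite[-2:]  # atlas gaps; also the unconnected pair
    locatable = [g for g in composite if g not in missing_genes]
    planted: dict[str, str] = {}
    for i, g in enumerate(locatable):
        if i < 170:
            planted[g] = panel[int(rng.integers(len(panel)))]
        else:
            planted[g] = extra_tissues[int(rng.integers(len(extra_tissues)))]
    expr_atlas = gen_tissue_matrix(
        composite,
        len(tissues),
        planted,
        fold=10.0,
        seed=seed,
        missing_fraction=len(missing_genes) / len(composite),
        tissue_names=tissues,
    )
    # the generator picks gaps among unplanted genes; by construction the
    # only unplanted genes are the intended pair
    assert expr_atlas.missing == set(missing_genes)
    npio.write_tissue_matrix(
        expr_atlas, out_dir / "tissue_matrix.tsv", out_dir / "tissue_missing.txt"
    )
    npio.write_panel(panel, out_dir / "panel.txt")

    # --- term map planted around the hub module --------------------------
    universe = [f"G{i:06d}" for i in range(1, 2001)]
    planted_members = set(
        np.array(sorted(hubs))[rng.choice(len(hubs), size=25, replace=False)]
    )
    non_hub_pool = sorted(set(universe) - set(hubs))
    planted_members |= set(
        np.array(non_hub_pool)[rng.choice(len(non_hub_pool), size=5, replace=False)]
    )
    terms = {"TERM0001": ("planted hub pathway", frozenset(planted_members))}
    uni_arr = np.array(universe)
    for i in range(2, 201):
        size = int(rng.integers(10, 41))
        members = frozenset(uni_arr[rng.choice(len(uni_arr), size=size, replace=False)])
        terms[f"TERM{i:04d}"] = (f"random term {i}", members)
    term_map = TermMap(terms=terms, universe=frozenset(universe))
    term_map.to_gmt(out_dir / "terms.gmt")

    # --- compound-target map sized for a 192-node / 748-edge HCT ---------
    retained_names = sorted(
        compounds.loc[compounds["passes_adme"] | compounds["whitelisted"], "name"]
    )
    hct_targets = composite[:181]
    links: set[tuple[str, str]] = set()
    for i, t in enumerate(hct_targets):
        links.add((retained_names[i % len(retained_names)], t))
    all_pairs = [
        (c, t) for c in retained_names for t in hct_targets if (c, t) not in links
    ]
    order = rng.permutation(len(all_pairs))
    for idx in order:
        if len(links) >= 738:
            break
        links.add(all_pairs[idx])
    mapping: dict[str, list[str]] = {c: [] for c in retained_names}
    for c, t in sorted(links):
        mapping[c].append(t)
    npio.write_compound_target_map(mapping, out_dir / "compound_targets.tsv")

    manifest = {
        "seed": int(seed),
        "compounds": {"n_total": 29, "n_pass": 9, "n_whitelist_rescue": 1},
        "targets": {
            "n_drug": len(drug),
            "n_disease": len(disease),
            "n_composite": len(composite),
        },
        "expression": {"n_genes": 800, "n_de": len(de_genes), "de_genes": de_genes},
        "ppi": {
            "n_connected": len(connected),
            "n_edges": len(edges),
            "hubs": sorted(hubs),
            "unconnected": missing_genes,
        },
        "tissue": {
            "n_panel_planted": 170,
            "missing": sorted(missing_genes),
            "planted": planted,
        },
        "terms": {"planted_term": "TERM0001", "n_terms": 200},
        "hct": {"n_compounds": len(retained_names), "n_targets": 181, "n_links": 738},
    }
    with open(out_dir / "ground_truth.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _check_inputs(cfg: PipelineConfig) -> None:
    """Raise before any stage runs if a referenced input is unreadable."""
    paths: list[tuple[str, Path]] = []
    for name in (
        "compounds",
        "whitelist",
        "expression_matrix",
        "sample_sheet",
        "edges",
        "tissue_matrix",
        "panel",
        "gmt",
        "compound_targets",
        "alias",
    ):
        p = getattr(cfg, name)
        if p is not None:
            paths.append((name, Path(p)))
    paths.extend(("fishing", Path(p)) for p in cfg.fishing)
    paths.extend(("disease", Path(p)) for p in cfg.disease)
    missing = [f"{name}: {p}" for name, p in paths if not p.exists()]
    if missing:
        raise FileNotFoundError("missing pipeline inputs: " + "; ".join(missing))
    if not cfg.fishing:
        raise ValueError("at least one fishing-source target list is required")
    if not cfg.disease and cfg.expression_matrix is None:
        raise ValueError("need disease target lists and/or an expression study")
    if cfg.edges is None:
        raise ValueError("a STRING-dialect edge list is required")


def run(cfg: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the pipeline stages in order; return the run report dict.

    Stage order: compound screen -> target assembly (DEGs merged into the
    disease set) -> PPI topology and core screen -> organ localization ->
    enrichment -> display networks. Artifacts and ``report.json`` are
    written under ``out_dir``.
    """
    _check_inputs(cfg)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "tool": "netpharm",
        "version": __version__,
        "seed": int(cfg.seed),
        "config": {
            k: (str(v) if isinstance(v, Path) else [str(x) for x in v] if isinstance(v, list) else v)
            for k, v in vars(cfg).items()
        },
        "warnings": [],
        "stages": {},
    }
    alias = npio.read_alias_map(cfg.alias) if cfg.alias else None

    # --- stage: compound screen -----------------------------------------
    retained_names: list[str] = []
    if cfg.compounds is not None:
        table = npio.read_compound_table(cfg.compounds)
        whitelist = npio.read_target_list(cfg.whitelist) if cfg.whitelist else []
        retained, audit = adme_filter(
            table, ob_min=cfg.ob_min, dl_min=cfg.dl_min, whitelist=whitelist
        )
        npio.write_compound_table(retained, out_dir / "compounds_retained.tsv")
        with open(out_dir / "compound_audit.json", "w") as fh:
            json.dump(audit, fh, indent=2)
        retained_names = [str(n) for n in retained["name"]]
        report["stages"]["compound_screen"] = {
            "n_input": int(len(table)),
            "n_retained": int(len(retained)),
            "n_whitelist_rescued": sum(1 for a in audit if a["reason"] == "whitelist"),
        }

    # --- stage: differential expression ---------------------------------
    deg_set: TargetSet | None = None
    if cfg.expression_matrix is not None and cfg.sample_sheet is not None:
        study = npio.read_expression_study(cfg.expression_matrix, cfg.sample_sheet)
        adjusted = batch_adjust(study)
        de = de_test(adjusted)
        de.to_csv(out_dir / "de_table.tsv", sep="\t", float_format="%.6g")
        deg_set = volcano_filter(de, p_max=cfg.p_max, lfc_min=cfg.lfc_min)
        npio.write_target_list(deg_set.symbols, out_dir / "deg_list.tsv")
        report["stages"]["diffexpr"] = {
            "n_genes_tested": int(len(de)),
            "n_deg": len(deg_set),
            "n_batches": int(study.batches.nunique()),
        }

    # --- stage: target assembly -----------------------------------------
    drug_set = union_dedup(
        [(Path(p).stem, npio.read_target_list(p)) for p in cfg.fishing],
        alias_map=alias,
        label="drug-targets",
    )
    disease_lists = [(Path(p).stem, npio.read_target_list(p)) for p in cfg.disease]
    if deg_set is not None:
        disease_lists.append(("GEO-DE", sorted(deg_set.symbols)))
    disease_set = union_dedup(disease_lists, alias_map=alias, label="disease-targets")
    composite = intersect(drug_set, disease_set, label="composite")
    venn = venn_counts(drug_set, disease_set)
    npio.write_target_set(drug_set, out_dir / "drug_targets.tsv")
    npio.write_target_set(disease_set, out_dir / "disease_targets.tsv")
    npio.write_target_set(composite, out_dir / "composite_targets.tsv")
    report["stages"]["target_assembly"] = {
        "n_drug": len(drug_set),
        "n_disease": len(disease_set),
        "n_composite": len(composite),
        "venn": {"drug_only": venn[0], "disease_only": venn[1], "shared": venn[2]},
    }

    # --- stage: PPI topology and core screen ----------------------------
    graph, warnings = load_edges(cfg.edges, restrict_to=composite, score_min=cfg.score_min)
    report["warnings"].extend(warnings)
    graph, removed = drop_isolated(graph)
    if graph.number_of_nodes() == 0:
        raise ValueError("PPI graph is empty after restriction and cleanup")
    cent = centralities(graph)
    thresholds = screen_thresholds(cent)
    core = screen_core(cent, thresholds)
    cent_out = cent.copy()
    cent_out["is_core"] = [v in core.symbols for v in cent_out.index]
    cent_out.to_csv(out_dir / "centralities.tsv", sep="\t", float_format="%.6g")
    core_graph = induced_subgraph(graph, core.symbols)
    npio.write_target_set(core, out_dir / "core_targets.tsv")
    report["stages"]["ppi_topology"] = {
        "n_nodes": int(graph.number_of_nodes()),
        "n_edges": int(graph.number_of_edges()),
        "n_unconnected_removed": len(removed),
        "thresholds": {
            "dc_min": thresholds.dc_min,
            "bc_min": thresholds.bc_min,
            "cc_min": thresholds.cc_min,
        },
        "n_core": len(core),
        "core_subgraph_edges": int(core_graph.number_of_edges()),
    }

    # --- stage: organ localization --------------------------------------
    to_graph = None
    if cfg.tissue_matrix is not None:
        atlas = npio.read_tissue_matrix(cfg.tissue_matrix, cfg.tissue_missing)
        panel = npio.read_panel(cfg.panel) if cfg.panel else None
        to_graph, organ_counts, audit = build_target_organ_network(
            atlas, composite, panel
        )
        export(to_graph, out_dir / "network_target_organ")
        pd.DataFrame(
            sorted(organ_counts.items()), columns=["organ", "n_targets"]
        ).to_csv(out_dir / "organ_counts.tsv", sep="\t", index=False)
        report["stages"]["organ_localization"] = {
            "n_nodes": int(to_graph.number_of_nodes()),
            "n_edges": int(to_graph.number_of_edges()),
            "n_organs": len(organ_counts),
            "n_targets_localized": sum(
                1 for n, d in to_graph.nodes(data=True) if d["role"] == "target"
            ),
            "n_missing_from_atlas": sum(
                1 for a in audit if a["status"] == "missing-from-atlas"
            ),
        }

    # --- stage: enrichment ----------------------------------------------
    top = None
    if cfg.gmt is not None:
        term_map = TermMap.from_gmt(cfg.gmt)
        table = ora(core, term_map)
        table.to_csv(out_dir / "enrichment.tsv", sep="\t", index=False, float_format="%.6g")
        top = select_top(table, fdr_max=cfg.fdr_max, top_k=cfg.top_k)
        bubble = top.copy()
        if len(bubble):
            bubble["gene_ratio"] = bubble["k"] / bubble["n"]
            bubble = bubble[["term_id", "name", "gene_ratio", "p_adj", "k"]]
        bubble.to_csv(out_dir / "enrichment_top.tsv", sep="\t", index=False, float_format="%.6g")
        report["stages"]["enrichment"] = {
            "n_terms_tested": int(len(table)),
            "n_significant": int((table["p_adj"] < cfg.fdr_max).sum()) if len(table) else 0,
            "n_top": int(len(top)),
        }

    # --- stage: display networks ----------------------------------------
    networks: dict[str, dict] = {}
    if cfg.compound_targets is not None and retained_names:
        c2t = npio.read_compound_target_map(cfg.compound_targets)
        c2t = {
            c: sorted(set(ts) & composite.symbols)
            for c, ts in c2t.items()
            if c in set(retained_names)
        }
        hct = build_hct(cfg.herb_name, retained_names, c2t)
        export(hct, out_dir / "network_hct")
        networks["hct"] = {
            "n_nodes": int(hct.number_of_nodes()),
            "n_edges": int(hct.number_of_edges()),
        }
    if to_graph is not None:
        networks["target_organ"] = {
            "n_nodes": int(to_graph.number_of_nodes()),
            "n_edges": int(to_graph.number_of_edges()),
        }
    if top is not None and len(top):
        tp = build_tp(core.symbols, top)
        export(tp, out_dir / "network_tp")
        networks["target_pathway"] = {
            "n_nodes": int(tp.number_of_nodes()),
            "n_edges": int(tp.number_of_edges()),
        }
    if networks:
        report["stages"]["network_assembly"] = networks

    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def config_for_fixture_dir(fixture_dir: str | Path, seed: int = 0) -> PipelineConfig:
    """PipelineConfig wired to the file layout `simulate_fixtures` writes."""
    d = Path(fixture_dir)
    return PipelineConfig(
        compounds=d / "compounds.tsv",
        whitelist=d / "whitelist.txt",
        fishing=sorted(d.glob("fishing_src*.tsv")),
        disease=sorted(d.glob("disease_db*.tsv")),
        expression_matrix=d / "expression.tsv",
        sample_sheet=d / "samples.tsv",
        edges=d / "string_edges.tsv",
        tissue_matrix=d / "tissue_matrix.tsv",
        tissue_missing=d / "tissue_missing.txt",
        panel=d / "panel.txt",
        gmt=d / "terms.gmt",
        compound_targets=d / "compound_targets.tsv",
        seed=seed,
    )
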