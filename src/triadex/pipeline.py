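"""End-to-end orchestration: DE → classification → summaries → enrichment.

``run_pipeline`` takes a run configuration pointing at a counts matrix,
sample sheet and optional phenotype/annotation tables, analyses every
requested triad at every time point, and writes deterministic TSV
outputs plus a manifest JSON (seed, thresholds, input checksums).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Union

import pandas as pd
import yaml

from . import __version__, de, enrich, heterosis, io, patterns

log = logging.getLogger("triadex")
PathLike = Union[str, Path]


@dataclasses.dataclass
class RunConfig:
    counts: str
    design: str
    out_dir: str
    phenotypes: Optional[str] = None
    annotation: Optional[str] = None
    triads: Optional[List[str]] = None          # hybrid genotype labels
    time_points: Optional[List[str]] = None
    alpha: float = 0.05
    lfc_threshold: float = 1.0
    min_term: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.alpha <= 0 or self.lfc_threshold <= 0:
            raise ValueError("thresholds must be positive")
        for attr in ("counts", "design"):
            p = getattr(self, attr)
            if not Path(p).exists():
                raise FileNotFoundError(f"{attr} file not found: {p}")
        for attr in ("phenotypes", "annotation"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{attr} file not found: {p}")

    @classmethod
    def from_yaml(cls, path: PathLike) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def triad_roles(design: pd.DataFrame, hybrid_genotype: str) -> Dict[str, str]:
    """Resolve (female_parent, male_parent, hybrid) genotypes for a triad.

    With a single triad in the sheet the parents are unambiguous; with
    several, a ``triad_id`` column ties parents to their hybrid.
    """
    if "triad_id" in design.columns:
        tid = design.loc[design["genotype"] == hybrid_genotype, "triad_id"]
        if tid.empty:
            raise ValueError(f"hybrid genotype {hybrid_genotype!r} not in design")
        sub = design[design["triad_id"] == tid.iloc[0]]
    else:
        sub = design
    roles: Dict[str, str] = {}
    for role in ("female_parent", "male_parent"):
        genos = sub.loc[sub["role"] == role, "genotype"].unique()
        if len(genos) != 1:
            raise ValueError(
                f"triad of {hybrid_genotype!r} needs exactly one {role}, "
                f"found {list(genos)}"
            )
        roles[role] = genos[0]
    roles["hybrid"] = hybrid_genotype
    return roles


def triad_calls(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    roles: Mapping[str, str],
    time_point: Optional[str],
    alpha: float = 0.05,
    tau: float = 1.0,
    tau_relation: float = 0.0,
    size_factors: Optional[pd.Series] = None,
) -> tuple:
    """Run the three pairwise comparisons of a triad.

    Two call sets are derived from the same DE tables.  ``call_FM`` /
    ``call_HF`` / ``call_HM`` are *relation* calls for inheritance-mode
    classification: significance (adjusted p < ``alpha``) plus direction,
    with fold-change threshold ``tau_relation`` (default 0 — an additive
    hybrid sits at most half the parental contrast away from either
    parent, so applying the DEG fold-change filter to the hybrid-parent
    relations would structurally forbid the additive classes).
    ``deg_FM`` / ``deg_HF`` / ``deg_HM`` are DEG calls at the reporting
    threshold ``tau`` and define the DEG universe and Venn counts.

    Returns (calls DataFrame, dict of the three full DE tables keyed
    "F vs M", "F vs H", "M vs H").
    """
    f, m, h = roles["female_parent"], roles["male_parent"], roles["hybrid"]
    tables = {
        "F vs M": de.de_comparison(counts, design, f, m, alpha, tau, time_point,
                                   size_factors=size_factors),
        "F vs H": de.de_comparison(counts, design, f, h, alpha, tau, time_point,
                                   size_factors=size_factors),
        "M vs H": de.de_comparison(counts, design, m, h, alpha, tau, time_point,
                                   size_factors=size_factors),
    }
    calls = pd.DataFrame(
        {
            "call_FM": de.call_degs(tables["F vs M"], alpha, tau_relation),
            "call_HF": de.call_degs(tables["F vs H"], alpha, tau_relation),
            "call_HM": de.call_degs(tables["M vs H"], alpha, tau_relation),
            "deg_FM": tables["F vs M"]["call"],
            "deg_HF": tables["F vs H"]["call"],
            "deg_HM": tables["M vs H"]["call"],
        }
    )
    return calls, tables


def deg_universe(calls: pd.DataFrame) -> pd.Index:
    """Genes that are DEGs in at least one of the three comparisons."""
    mask = (
        (calls["deg_FM"] != "ns")
        | (calls["deg_HF"] != "ns")
        | (calls["deg_HM"] != "ns")
    )
    return calls.index[mask]


def _sha256(path: PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Dict[str, object]:
    """Execute the full triad analysis and write all result tables.

    Per triad and time point: three DE tables with calls, the pattern
    assignment with class/category counts, and Venn counts of the two
    hybrid-parent DEG sets; once per run: the heterosis table (if
    phenotypes given) and an enrichment table of the up-overdominant
    gene set (if an annotation map is given).  A manifest JSON records
    versions, seed, thresholds and input checksums.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    def stage(name: str):
        log.info("[%s] %.1fs", name, time.time() - t0)

    counts = io.read_counts(config.counts)
    design = io.read_sample_sheet(config.design)
    stage("load")

    hybrids = config.triads or sorted(
        design.loc[design["role"] == "hybrid", "genotype"].unique()
    )
    tps = config.time_points or sorted(design["time_point"].unique())

    size_factors = de.estimate_size_factors(counts)
    results: Dict[str, object] = {"size_factors": size_factors}
    category_counts: Dict[str, pd.Series] = {}
    try:
        for hybrid in hybrids:
            roles = triad_roles(design, hybrid)
            for tp in tps:
                key = f"{hybrid}_{tp}"
                calls, tables = triad_calls(
                    counts, design, roles, tp,
                    alpha=config.alpha, tau=config.lfc_threshold,
                    size_factors=size_factors,
                )
                for name, table in tables.items():
                    fname = f"de_{key}_{name.replace(' ', '_')}.tsv"
                    io.write_de_table(table, out_dir / fname)
                assignment = patterns.classify_triad(
                    calls, universe=deg_universe(calls)
                )
                class_counts, cat_counts = patterns.summarize_patterns(assignment)
                io.write_de_table(assignment, out_dir / f"patterns_{key}.tsv")
                summary = pd.DataFrame(
                    {
                        "label": list(class_counts.index) + list(cat_counts.index),
                        "kind": ["class"] * len(class_counts)
                        + ["category"] * len(cat_counts),
                        "count": list(class_counts) + list(cat_counts),
                    }
                )
                io.write_table(summary, out_dir / f"pattern_summary_{key}.tsv")

                deg_hf = set(calls.index[calls["deg_HF"] != "ns"])
                deg_hm = set(calls.index[calls["deg_HM"] != "ns"])
                venn = patterns.intersect_deg_sets(
                    {"F_vs_H": deg_hf, "M_vs_H": deg_hm}
                )
                venn_df = pd.DataFrame(
                    sorted(venn.items()), columns=["region", "count"]
                )
                io.write_table(venn_df, out_dir / f"venn_{key}.tsv")

                results[f"calls_{key}"] = calls
                results[f"patterns_{key}"] = assignment
                results[f"category_counts_{key}"] = cat_counts
                results[f"venn_{key}"] = venn
                category_counts[key] = cat_counts
                stage(f"triad {key}")

        if config.phenotypes:
            pheno = io.read_phenotypes(config.phenotypes)
            het_parts = []
            for hybrid in hybrids:
                roles = triad_roles(design, hybrid)
                het = heterosis.compute_heterosis(pheno, roles)
                het.insert(0, "triad", hybrid)
                het_parts.append(het)
            het_all = pd.concat(het_parts, ignore_index=True)
            io.write_table(het_all, out_dir / "heterosis.tsv")
            results["heterosis"] = het_all
            stage("heterosis")

        if config.annotation:
            path = config.annotation
            anno = (
                io.read_gmt(path, min_term=config.min_term)
                if str(path).endswith(".gmt")
                else io.read_annotation_tsv(path)
            )
            background = list(counts.index)
            for key, assignment in list(results.items()):
                if not key.startswith("patterns_"):
                    continue
                tag = key.removeprefix("patterns_")
                od_up = list(
                    assignment.index[assignment["category"] == "up-overdominant"]
                )
                if not od_up:
                    continue
                table = enrich.hypergeom_enrich(
                    od_up, background, anno,
                    alpha=config.alpha, min_term=config.min_term,
                )
                io.write_table(table, out_dir / f"enrich_od_up_{tag}.tsv")
                results[f"enrich_{tag}"] = table
            stage("enrichment")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc

    manifest = {
        "triadex_version": __version__,
        "python": sys.version.split()[0],
        "seed": config.seed,
        "alpha": config.alpha,
        "lfc_threshold": config.lfc_threshold,
        "inputs": {
            name: _sha256(p)
            for name, p in (
                ("counts", config.counts),
                ("design", config.design),
                ("phenotypes", config.phenotypes),
                ("annotation", config.annotation),
            )
            if p
        },
        "triads": list(hybrids),
        "time_points": list(tps),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    results["manifest"] = manifest
    return results
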