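"""End-to-end orchestration: counts -> FPKM -> DE -> clusters -> groups ->
intersex patterns (-> phenotype statistics), with a JSON manifest.

The pipeline is deterministic: re-running with unchanged config and inputs
reproduces byte-identical tabular outputs (the manifest carries no
timestamps).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .clusters import CLUSTERS, Thresholds, build_all_clusters, cluster_comparisons
from .de import compare_groups
from .groups import intersect_groups, write_group
from .io import (
    check_samples_match,
    read_counts,
    read_de_table,
    read_gene_lengths,
    read_sample_sheet,
    write_de_table,
    write_fpkm,
    write_membership,
)
from .patterns import COMPARISON_ORDER, classify_genes, comparison_groups, PATTERNS
from .phenotype import g_test, pearson_chi2, read_records
from .quantify import compute_fpkm
from .records import intersex_by_pupa_table

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    counts: str
    samples: str
    out_dir: str
    lengths: str | None = None
    de_dir: str | None = None  # precomputed DE tables, <comparison_id>.tsv
    phenotypes: str | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    combine_rule: str = "any"
    #: (sex, tissue) settings for the six-group analyses
    analyses: list[tuple[str, str]] = field(
        default_factory=lambda: [("female", "reproductive"), ("male", "reproductive")]
    )
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path, overrides: dict[str, str] | None = None
                  ) -> "PipelineConfig":
        """Parse a flat ``key = value`` config file, then apply overrides."""
        kv: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"config line without '=': {line!r}")
            k, v = line.split("=", 1)
            kv[k.strip()] = v.strip()
        kv.update(overrides or {})
        thresholds = Thresholds(
            fpkm_low=float(kv.pop("fpkm_low", 1.0)),
            lfc=float(kv.pop("lfc", 2.0)),
            fdr=float(kv.pop("fdr", 0.05)),
        )
        analyses = [
            tuple(a.split(":"))
            for a in kv.pop("analyses", "female:reproductive,male:reproductive").split(",")
        ]
        return cls(
            counts=kv.pop("counts"),
            samples=kv.pop("samples"),
            out_dir=kv.pop("out_dir"),
            lengths=kv.pop("lengths", None),
            de_dir=kv.pop("de_dir", None),
            phenotypes=kv.pop("phenotypes", None),
            thresholds=thresholds,
            combine_rule=kv.pop("combine_rule", "any"),
            seed=int(kv.pop("seed", 0)),
            analyses=analyses,  # type: ignore[arg-type]
        )


def _comparison_plan(cfg: PipelineConfig) -> dict[str, tuple[str, str]]:
    """All (comparison_id -> (group_A, group_B)) pairs the run needs."""
    plan: dict[str, tuple[str, str]] = {}
    for cluster in CLUSTERS:
        for comp_id, ga, gb in cluster_comparisons(cluster):
            plan[comp_id] = (ga, gb)
    for sex, tissue in cfg.analyses:
        for comp_id, pair in comparison_groups(tissue, sex).items():
            plan[f"{tissue}:{sex}:{comp_id}"] = pair
    return plan


def _safe_name(comparison_id: str) -> str:
    return comparison_id.replace(":", "-")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written to out_dir)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "intersexpr",
        "version": __version__,
        "config": {
            "counts": cfg.counts, "samples": cfg.samples, "lengths": cfg.lengths,
            "de_dir": cfg.de_dir, "phenotypes": cfg.phenotypes,
            "thresholds": {
                "fpkm_low": cfg.thresholds.fpkm_low,
                "lfc": cfg.thresholds.lfc,
                "fdr": cfg.thresholds.fdr,
            },
            "combine_rule": cfg.combine_rule,
            "analyses": [list(a) for a in cfg.analyses],
            "seed": cfg.seed,
        },
        "outputs": {},
    }

    def stage(name):
        log.info("stage %s", name)
        t0 = time.monotonic()

        class _Ctx:
            def __enter__(self):
                return self

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise PipelineError(name, exc) from exc
                log.info("stage %s done in %.1fs", name, time.monotonic() - t0)
                return False

        return _Ctx()

    with stage("load"):
        counts = read_counts(cfg.counts)
        design = read_sample_sheet(cfg.samples)
        check_samples_match(counts, design)
        lengths = (
            read_gene_lengths(cfg.lengths)
            if cfg.lengths
            else pd.Series(1000.0, index=counts.gene_ids)
        )

    with stage("quantify"):
        fpkm = compute_fpkm(counts, lengths)
        write_fpkm(fpkm, out / "fpkm.tsv")
        manifest["outputs"]["fpkm"] = "fpkm.tsv"

    plan = _comparison_plan(cfg)
    de_tables: dict[str, pd.DataFrame] = {}
    with stage("differential_expression"):
        de_out = out / "de"
        de_out.mkdir(exist_ok=True)
        for comp_id, (ga, gb) in plan.items():
            if cfg.de_dir:
                src = Path(cfg.de_dir) / f"{_safe_name(comp_id)}.tsv"
                if not src.exists():
                    raise FileNotFoundError(f"precomputed DE table missing: {src}")
                de = read_de_table(src)
            else:
                de = compare_groups(
                    counts, design, ga, gb, lengths=lengths, comparison_id=comp_id
                )
            de_tables[comp_id] = de
            write_de_table(de, de_out / f"{_safe_name(comp_id)}.tsv")
        manifest["outputs"]["de_tables"] = sorted(
            f"de/{_safe_name(c)}.tsv" for c in plan
        )

    with stage("clusters"):
        membership = build_all_clusters(
            de_tables, thresholds=cfg.thresholds, rule=cfg.combine_rule
        )
        write_membership(membership, out / "membership.tsv")
        manifest["outputs"]["membership"] = "membership.tsv"

    with stage("groups_and_patterns"):
        summaries: dict[str, dict] = {}
        for sex, tissue in cfg.analyses:
            groups = intersect_groups(membership, sex, tissue)
            comp_set = {
                base: de_tables[f"{tissue}:{sex}:{base}"] for base in COMPARISON_ORDER
            }
            for kind, grp in groups.items():
                tag = f"{sex}_{tissue}_{kind}"
                write_group(grp, out / f"group_{tag}.tsv")
                table = classify_genes(comp_set, grp.members, cfg.thresholds)
                table.to_csv(out / f"patterns_{tag}.tsv", sep="\t")
                summaries[tag] = {
                    "n_members": len(grp),
                    "n_classified": int(len(table)),
                    "counts": {
                        p: int((table["pattern"] == p).sum()) for p in PATTERNS
                    },
                }
        with open(out / "pattern_summary.json", "w") as fh:
            json.dump(summaries, fh, indent=2, sort_keys=True)
        manifest["outputs"]["pattern_summary"] = "pattern_summary.json"
        manifest["pattern_summary"] = summaries

    if cfg.phenotypes:
        with stage("phenotype"):
            recs = read_records(cfg.phenotypes)
            table = intersex_by_pupa_table(recs)
            x2, df, p_x2 = pearson_chi2(table)
            g, _, p_g = g_test(table)
            res = pd.DataFrame(
                [
                    ("intersex_by_pupa", "pearson_chi2", x2, df, p_x2),
                    ("intersex_by_pupa", "g_test", g, df, p_g),
                ],
                columns=["table", "test", "statistic", "df", "pvalue"],
            )
            res.to_csv(out / "phenotype_tests.tsv", sep="\t", index=False)
            manifest["outputs"]["phenotype_tests"] = "phenotype_tests.tsv"

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
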