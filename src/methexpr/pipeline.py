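"""End-to-end orchestration of the four analysis protocols.

Given a dataset directory in the standard formats (as written by
:func:`methexpr.simulate.write_dataset`, or assembled from real inputs),
``run_all`` executes, in dependency order:

1. low-coverage filtering and the normalized-entropy screens,
2. expression centering, median-based down-calls and the per-bin /
   per-region correlation analysis,
3. decision-tree induction with cross-validation per called subtype,
4. TFBS-methylation-blocking inference,

writing one result file per stage plus a run manifest (resolved
parameters, seed, input checksums and per-stage record counts).  Outputs
carry no timestamps, so identical configs produce byte-identical runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from . import correlation as corr
from . import diffexp, entropy, io as mio, tfbs, tree as treemod
from .core import REGION_ORDER, SUBTYPES, UsageError
from .profiles import RAW_COUNT, BinnedMethylation, combine_cell_lines, filter_low_coverage
from .regions import build_region_catalog
from .tfbs import PROMOTER_BINS


class PipelineError(RuntimeError):
    """A stage failure, naming the stage and the offending input."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


_DEFAULTS: dict[str, object] = {
    "min_reads": 3,
    "entropy_threshold_methylation": 0.2,
    "entropy_threshold_expression": 0.5,
    "entropy_pseudo": 1e-6,
    "log_ratio_criterion": 1.5,
    "tree_max_depth": 3,
    "cv_folds": 10,
    "bin_alpha": 0.005,
    "tf_expression_alpha": 0.05,
    "min_support_rate": 50.0,
    "target_fp_rate": 1e-4,
    "seed": 0,
}

_RANGES = {
    "min_reads": (0, 1_000_000),
    "entropy_threshold_methylation": (0.0, 1.0),
    "entropy_threshold_expression": (0.0, 1.0),
    "entropy_pseudo": (0.0, 1.0),
    "log_ratio_criterion": (0.0, 100.0),
    "tree_max_depth": (1, 50),
    "cv_folds": (2, 1000),
    "bin_alpha": (0.0, 1.0),
    "tf_expression_alpha": (0.0, 1.0),
    "min_support_rate": (0.0, 100.0),
    "target_fp_rate": (0.0, 0.5),
}


@dataclass
class RunConfig:
    """Resolved configuration of a pipeline run."""

    data_dir: str
    out_dir: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        merged = dict(_DEFAULTS)
        merged.update(self.params)
        self.params = merged


def validate_config(raw: Mapping[str, object]) -> RunConfig:
    """Normalize a flat config mapping; all problems reported at once."""
    errors: list[str] = []
    known = {"data_dir", "out_dir"} | set(_DEFAULTS)
    for key in raw:
        if key not in known:
            errors.append(f"unknown config key {key!r}")
    for key in ("data_dir", "out_dir"):
        if key not in raw:
            errors.append(f"missing required key {key!r}")
    params = {}
    for key, value in raw.items():
        if key in ("data_dir", "out_dir"):
            continue
        if key in _RANGES:
            lo, hi = _RANGES[key]
            try:
                v = float(value)  # type: ignore[arg-type]
            except (TypeError, ValueError):
                errors.append(f"{key}: not a number ({value!r})")
                continue
            strict_lo = key in (
                "entropy_threshold_methylation",
                "entropy_threshold_expression",
                "bin_alpha",
                "tf_expression_alpha",
                "target_fp_rate",
                "log_ratio_criterion",
            )
            if (v <= lo if strict_lo else v < lo) or v > hi:
                errors.append(f"{key}: {value!r} outside ({lo}, {hi}]")
                continue
            params[key] = int(v) if key in ("min_reads", "tree_max_depth", "cv_folds", "seed") else v
        else:
            params[key] = value
    if errors:
        raise UsageError("; ".join(errors))
    return RunConfig(str(raw["data_dir"]), str(raw["out_dir"]), params)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: RunConfig) -> Path:
    """Execute the four protocols; returns the output directory."""
    data = Path(config.data_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    p = config.params
    manifest: dict = {
        "version": __version__,
        "params": p,
        "inputs": {},
        "counts": {},
    }

    # ------------------------------------------------------------------ load
    stage = "data_io"
    try:
        subtypes = mio.read_subtype_table(data / "subtypes.tsv")
        genes = mio.read_gene_models(data / "genes.bed")
        cgis = mio.read_intervals_bed(data / "cgis.bed")
        expression = mio.read_expression_matrix(data / "expression.tsv")
        cols = [
            mio.read_bin_counts(data / "bins" / f"{cl}.tsv")
            for cl in subtypes.cell_lines
        ]
        binned = combine_cell_lines(cols, normalization=RAW_COUNT)
        pwms = mio.read_pwms(data / "pwms.transfac")
        promoter_seqs = {
            cl: mio.read_fasta(data / "promoters" / f"{cl}.fa")
            for cl in subtypes.cell_lines
        }
        tf_gene_map = {}
        for line in (data / "tf_gene_map.tsv").read_text().splitlines()[1:]:
            mid, gid = line.split("\t")
            tf_gene_map[mid] = gid
        for rel in sorted(
            str(f.relative_to(data)) for f in data.rglob("*") if f.is_file()
        ):
            manifest["inputs"][rel] = _sha256(data / rel)
    except FileNotFoundError as exc:
        raise PipelineError(stage, f"missing input: {exc.filename}") from exc
    except (OSError, ValueError) as exc:
        raise PipelineError(stage, str(exc)) from exc

    catalog = build_region_catalog(genes, cgis)
    subtypes.require_all_subtypes()

    # ------------------------------------------------------- protocol 1
    stage = "entropy_screen"
    try:
        filtered = filter_low_coverage(binned, min_reads=int(p["min_reads"]))
        manifest["counts"]["genes_after_coverage_filter"] = len(filtered.gene_ids)
        meth_units = filtered.gene_totals()
        meth_screen = entropy.entropy_screen(
            meth_units, subtypes, p["entropy_threshold_methylation"], p["entropy_pseudo"]
        )
        expr_units = entropy.expression_units(expression)
        expr_screen = entropy.entropy_screen(
            expr_units, subtypes, p["entropy_threshold_expression"], p["entropy_pseudo"]
        )
        both = sorted(
            entropy.intersect_screens(
                entropy.flagged_units(meth_screen), entropy.flagged_units(expr_screen)
            )
        )
        meth_screen.to_csv(out / "entropy_methylation.tsv", sep="\t", index=False)
        expr_screen.to_csv(out / "entropy_expression.tsv", sep="\t", index=False)
        (out / "entropy_common_genes.txt").write_text("".join(g + "\n" for g in both))
        manifest["counts"]["differentially_methylated"] = int(
            meth_screen["flagged"].sum()
        )
        manifest["counts"]["differentially_expressed"] = int(
            expr_screen["flagged"].sum()
        )
        manifest["counts"]["common_to_both_screens"] = len(both)
    except ValueError as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ------------------------------------------------------- protocol 2
    stage = "expression_screen"
    try:
        medians = diffexp.subtype_medians(expression, subtypes)
        calls = diffexp.call_differential(
            medians, criterion=p["log_ratio_criterion"], direction="down"
        )
        calls.to_csv(out / "down_calls.tsv", sep="\t", index=False)
        manifest["counts"]["downregulated_calls"] = {
            st: int((calls["subtype"] == st).sum()) for st in SUBTYPES
        }
    except ValueError as exc:
        raise PipelineError(stage, str(exc)) from exc

    stage = "correlation"
    try:
        profiles_by_subtype: dict[str, list] = {}
        for st in SUBTYPES:
            st_genes = [
                g
                for g in diffexp.calls_for_subtype(calls, st)["gene_id"]
                if g in binned.gene_ids and g in set(expression.genes)
            ]
            st_genes = corr.exclude_unmethylated(binned, st_genes, list(PROMOTER_BINS))
            profiles = [
                corr.correlate_gene(g, binned, expression, axis="bins", bins=list(PROMOTER_BINS))
                for g in st_genes
            ]
            profiles_by_subtype[st] = profiles
            if profiles:
                corr.heatmap_matrix(profiles).to_csv(
                    out / f"promoter_correlation_{st}.tsv", sep="\t"
                )
            region_profiles = [
                corr.correlate_gene(
                    g, binned, expression, axis="regions",
                    catalog=catalog, regions=list(REGION_ORDER),
                )
                for g in st_genes
            ]
            if region_profiles:
                corr.heatmap_matrix(region_profiles, proximal_first=False).to_csv(
                    out / f"region_correlation_{st}.tsv", sep="\t"
                )
        if len(profiles_by_subtype.get("Lu", [])) >= 2 and len(
            profiles_by_subtype.get("BaB", [])
        ) >= 2:
            comparison = corr.compare_profiles(
                profiles_by_subtype["Lu"], profiles_by_subtype["BaB"]
            )
            comparison.to_csv(out / "correlation_comparison_Lu_vs_BaB.tsv", sep="\t", index=False)
        manifest["counts"]["correlated_genes"] = {
            st: len(profs) for st, profs in profiles_by_subtype.items()
        }
    except ValueError as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ------------------------------------------------------- protocol 3
    stage = "tree_learner"
    try:
        cv_rows = []
        for st in SUBTYPES:
            st_calls = diffexp.calls_for_subtype(calls, st)
            if len(st_calls) < 2:
                continue
            instances = treemod.build_instances(st_calls, binned, catalog, subtypes)
            if len(instances) < int(p["cv_folds"]):
                continue
            tree = treemod.induce_tree(
                instances, max_depth=int(p["tree_max_depth"]), seed=int(p["seed"])
            )
            (out / f"tree_{st}.txt").write_text(treemod.render_tree(tree))
            (out / f"tree_{st}.json").write_text(treemod.tree_to_json(tree) + "\n")
            acc, folds = treemod.cross_validate(
                instances,
                max_depth=int(p["tree_max_depth"]),
                k=int(p["cv_folds"]),
                seed=int(p["seed"]),
            )
            cv_rows.append((st, len(instances), acc, *folds))
        if cv_rows:
            width = max(len(r) for r in cv_rows) - 3
            cols = ["subtype", "n_instances", "cv_accuracy"] + [
                f"fold_{i + 1}" for i in range(width)
            ]
            pd.DataFrame(cv_rows, columns=cols[: max(len(r) for r in cv_rows)]).to_csv(
                out / "tree_cv.tsv", sep="\t", index=False
            )
    except ValueError as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ------------------------------------------------------- protocol 4
    stage = "tfbs_blocking"
    try:
        candidates = tfbs.find_blocked_tfs(
            binned,
            calls,
            subtypes,
            promoter_seqs,
            pwms,
            expression,
            tf_gene_map,
            alpha_bin=p["bin_alpha"],
            alpha_tf=p["tf_expression_alpha"],
            min_support=p["min_support_rate"],
            target_fp_rate=p["target_fp_rate"],
            seed=int(p["seed"]),
        )
        candidates.to_csv(out / "tfbs_candidates.tsv", sep="\t", index=False)
        manifest["counts"]["tfbs_candidates"] = len(candidates)
    except ValueError as exc:
        raise PipelineError(stage, str(exc)) from exc

    with (out / "run_manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
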