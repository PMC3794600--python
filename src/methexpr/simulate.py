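"""Synthetic MBDCap-seq-like datasets with planted, subtype-structured
effects.

The generator emulates the statistical structure the analysis protocols
assume: a 30-cell-line panel split 13 Lu / 7 BaA / 10 BaB, per-gene bin
grids of negative-binomial read counts with subtype-specific
hypermethylation planted in a chosen promoter region, log-scale expression
with a planted inverse dependence on the planted region's methylation, and
per-cell-line promoter sequences carrying TF motifs under hypermethylated
bins.  Every planted effect is recorded in a :class:`GroundTruth` so
downstream protocols can be scored for recovery.

All genes sit on one toy chromosome with non-overlapping TSS +/- 10 kb
windows; everything is reproducible from the config seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as mio
from .core import (
    BIN_INDICES,
    BIN_SIZE,
    ExpressionMatrix,
    GeneModel,
    PROMOTER_LENGTH,
    PWM,
    PWMSet,
    SubtypeTable,
    SUBTYPES,
    UsageError,
)
from .profiles import BinnedMethylation, RAW_COUNT, combine_cell_lines, region_level
from .regions import RegionCatalog, build_region_catalog
from .tree import HIGH, LOW, TreeInstance

GENE_SPACING = 24_000
FIRST_TSS = 12_000


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the generator; defaults are the study conditions.

    ``methylation_effect`` multiplies the negative-binomial mean of planted
    (gene, subtype, region) bins; ``coupling_strength`` (<= 0) is the slope
    of planted expression on the standardized planted-region methylation;
    ``noise_sd`` is the Gaussian expression noise (log2 units).
    """

    n_genes: int = 60
    subtype_sizes: tuple[int, int, int] = (13, 7, 10)
    baseline_mean: float = 2.0  # NB mean reads per 100 bp bin
    baseline_dispersion: float = 0.3  # var = mu + disp * mu^2
    methylation_effect: float = 8.0
    coupling_strength: float = -1.0
    noise_sd: float = 0.2
    planted_fraction: float = 0.1
    planted_region: str = "TSS1-1000"
    planted_subtypes: tuple[str, ...] = ("Lu", "BaA", "BaB")
    motif_ids: tuple[str, ...] = ("MSIM001",)
    motif_width: int = 8
    expression_baseline: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.subtype_sizes) <= 0:
            raise UsageError("subtype_sizes must sum to a positive cell-line count")
        if not 0 < self.planted_fraction < 1:
            raise UsageError("planted_fraction must be in (0, 1)")
        if self.methylation_effect <= 1:
            raise UsageError("methylation_effect must exceed 1 for hypermethylation")
        if self.coupling_strength > 0:
            raise UsageError("coupling_strength must be <= 0 (inhibitory)")
        for st in self.planted_subtypes:
            if st not in SUBTYPES:
                raise UsageError(f"unknown planted subtype {st!r}")


@dataclass(frozen=True)
class GroundTruth:
    """Planted effects, keyed the way the protocols report them."""

    planted_dm_genes: Mapping[str, tuple[str, ...]]  # subtype -> genes
    planted_down_genes: Mapping[str, tuple[str, ...]]
    planted_region: Mapping[str, str]  # gene -> region name
    planted_tf_pairs: tuple[tuple[str, str, int], ...]  # (gene, matrix id, bin)

    def all_planted(self) -> set[str]:
        return {g for gs in self.planted_dm_genes.values() for g in gs}

    def to_dict(self) -> dict:
        return {
            "planted_dm_genes": {k: list(v) for k, v in self.planted_dm_genes.items()},
            "planted_down_genes": {
                k: list(v) for k, v in self.planted_down_genes.items()
            },
            "planted_region": dict(self.planted_region),
            "planted_tf_pairs": [list(t) for t in self.planted_tf_pairs],
        }


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    subtypes: SubtypeTable
    genes: list[GeneModel]
    cgis: list[tuple[str, int, int]]
    catalog: RegionCatalog
    binned: BinnedMethylation
    expression: ExpressionMatrix
    promoter_reference: dict[str, str]  # gene -> 2 kb promoter (transcription 5'->3')
    promoter_seqs: dict[str, dict[str, str]]  # cell line -> gene -> sequence
    pwms: PWMSet
    tf_gene_map: dict[str, str]
    truth: GroundTruth


def _panel(sizes: tuple[int, int, int]) -> SubtypeTable:
    if tuple(sizes) == (13, 7, 10):
        return mio.load_cell_line_panel()
    entries = []
    for st, n, prefix in zip(SUBTYPES, sizes, ("LU", "BA", "BB")):
        entries.extend((f"{prefix}{i + 1:02d}", st) for i in range(n))
    return SubtypeTable(tuple(entries))


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = mu + dispersion * mu^2 (Poisson at 0)."""
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def _make_pwm(rng: np.random.Generator, matrix_id: str, width: int) -> PWM:
    consensus = rng.integers(0, 4, size=width)
    probs = []
    for b in consensus:
        row = np.full(4, 0.02)
        row[b] = 0.94
        probs.append(tuple(row))
    return PWM(matrix_id, tuple(probs))


def simulate_dataset(config: SimulationConfig = SimulationConfig()) -> SyntheticDataset:
    """Generate a complete synthetic dataset with recorded ground truth."""
    rng = np.random.default_rng(config.seed)
    subtypes = _panel(config.subtype_sizes)
    cell_lines = list(subtypes.cell_lines)
    n_lines = len(cell_lines)
    n_genes = config.n_genes

    # gene models on one toy chromosome, all forward strand
    genes: list[GeneModel] = []
    cgis: list[tuple[str, int, int]] = []
    for i in range(n_genes):
        tss = FIRST_TSS + i * GENE_SPACING
        gid = f"G{i + 1:04d}"
        exons = ((tss, tss + 200), (tss + 800, tss + 1000), (tss + 1600, tss + 1800))
        genes.append(GeneModel(gid, "chrS", "+", exons))
        cgis.append(("chrS", tss - 300, tss + 250))
    catalog = build_region_catalog(genes, cgis)

    # planted assignment
    n_planted = max(1, round(config.planted_fraction * n_genes))
    planted_subtype: dict[str, str] = {}
    for k in range(n_planted):
        planted_subtype[genes[k].gene_id] = config.planted_subtypes[
            k % len(config.planted_subtypes)
        ]

    # planted promoter bins of the planted region
    n_bins = len(BIN_INDICES)
    bin_arr = np.array(BIN_INDICES)
    region_bins: dict[str, np.ndarray] = {}
    for g in genes:
        gr = catalog[g.gene_id]
        ivs = gr.regions[config.planted_region]
        bounds = gr.bin_bounds()
        w = np.zeros(n_bins)
        for s, e in ivs:
            ov = np.minimum(bounds[:, 1], e) - np.maximum(bounds[:, 0], s)
            w += np.clip(ov, 0, None)
        region_bins[g.gene_id] = bin_arr[w > 0]

    # bin counts
    masks = {st: subtypes.mask(cell_lines, st) for st in SUBTYPES}
    mu = np.full((n_genes, n_bins, n_lines), config.baseline_mean)
    for gi, g in enumerate(genes):
        st = planted_subtype.get(g.gene_id)
        if st is None:
            continue
        sel = np.isin(bin_arr, region_bins[g.gene_id])
        mu[gi][np.ix_(sel, masks[st])] *= config.methylation_effect
    draws = _nb_draw(rng, mu.reshape(-1, n_lines), config.baseline_dispersion)
    index = pd.MultiIndex.from_product(
        [[g.gene_id for g in genes], list(BIN_INDICES)], names=["gene", "bin"]
    )
    binned = BinnedMethylation(
        pd.DataFrame(draws.astype(float), index=index, columns=cell_lines),
        normalization=RAW_COUNT,
    )

    # expression coupled to planted-region methylation
    lvl = region_level(binned, catalog, config.planted_region)
    baseline = config.expression_baseline + rng.normal(0, 1, size=n_genes)
    expr = np.zeros((n_genes, n_lines))
    for gi, g in enumerate(genes):
        noise = rng.normal(0, config.noise_sd, size=n_lines)
        if g.gene_id in planted_subtype and config.coupling_strength != 0:
            m = lvl.loc[g.gene_id].to_numpy(dtype=float)
            sd = m.std()
            z = (m - m.mean()) / sd if sd > 0 else np.zeros(n_lines)
            expr[gi] = baseline[gi] + config.coupling_strength * z + noise
        else:
            expr[gi] = baseline[gi] + noise

    # PWMs, TF expression rows and planted motifs
    pwms = PWMSet(
        tuple(
            _make_pwm(rng, mid, config.motif_width) for mid in config.motif_ids
        )
    )
    tf_gene_map = {mid: f"TF_{mid}" for mid in config.motif_ids}
    tf_expr = np.zeros((len(pwms), n_lines))
    for ti in range(len(pwms)):
        tf_expr[ti] = config.expression_baseline + rng.normal(
            0, config.noise_sd, size=n_lines
        )
    expr_df = pd.DataFrame(
        np.vstack([expr, tf_expr]),
        index=[g.gene_id for g in genes] + [tf_gene_map[m] for m in config.motif_ids],
        columns=cell_lines,
    )
    expression = ExpressionMatrix(expr_df, centered=False)

    # promoter sequences (transcription orientation, 2 kb upstream of TSS)
    promoter_reference = {
        g.gene_id: _random_seq(rng, PROMOTER_LENGTH) for g in genes
    }
    planted_pairs: list[tuple[str, str, int]] = []
    planted_genes = [g for g in genes if g.gene_id in planted_subtype]
    for mi, mid in enumerate(config.motif_ids):
        if mi >= len(planted_genes):
            break
        gid = planted_genes[mi].gene_id
        # a promoter bin inside the planted region (TSS-proximal end)
        target_bin = int(region_bins[gid][region_bins[gid] < 0].max())
        offset_in_prom = PROMOTER_LENGTH + 100 * target_bin + 30
        word = pwms[mid].consensus
        ref = promoter_reference[gid]
        promoter_reference[gid] = (
            ref[:offset_in_prom] + word + ref[offset_in_prom + len(word):]
        )
        planted_pairs.append((gid, mid, target_bin))

    promoter_seqs = {
        cl: dict(promoter_reference) for cl in cell_lines
    }  # motifs are genomic: present in every line

    truth = GroundTruth(
        planted_dm_genes={
            st: tuple(g for g, s in planted_subtype.items() if s == st)
            for st in SUBTYPES
        },
        planted_down_genes={
            st: tuple(
                g for g, s in planted_subtype.items() if s == st
            ) if config.coupling_strength != 0 else ()
            for st in SUBTYPES
        },
        planted_region={g: config.planted_region for g in planted_subtype},
        planted_tf_pairs=tuple(planted_pairs),
    )
    return SyntheticDataset(
        config,
        subtypes,
        genes,
        cgis,
        catalog,
        binned,
        expression,
        promoter_reference,
        promoter_seqs,
        pwms,
        tf_gene_map,
        truth,
    )


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> dict:
    """Serialize a dataset in the pipeline's input formats; returns the
    manifest (also written as ``manifest.json``)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, object] = {"files": {}, "config": dataclasses.asdict(dataset.config)}
    files: dict[str, str] = manifest["files"]  # type: ignore[assignment]

    mio.write_subtype_table(dataset.subtypes, out / "subtypes.tsv")
    files["subtypes.tsv"] = "subtype table"
    mio.write_gene_models_bed12(dataset.genes, out / "genes.bed")
    files["genes.bed"] = "gene models (BED12)"
    mio.write_intervals_bed(dataset.cgis, out / "cgis.bed")
    files["cgis.bed"] = "CpG islands (BED3)"
    mio.write_expression_matrix(dataset.expression, out / "expression.tsv")
    files["expression.tsv"] = "expression matrix"

    bins_dir = out / "bins"
    bins_dir.mkdir(exist_ok=True)
    for cl in dataset.binned.cell_lines:
        mio.write_bin_counts(dataset.binned.data[[cl]], bins_dir / f"{cl}.tsv")
        files[f"bins/{cl}.tsv"] = "bin counts"

    prom_dir = out / "promoters"
    prom_dir.mkdir(exist_ok=True)
    mio.write_fasta(dataset.promoter_reference, prom_dir / "reference.fa")
    files["promoters/reference.fa"] = "reference promoter sequences"
    for cl, per_gene in dataset.promoter_seqs.items():
        mio.write_fasta(per_gene, prom_dir / f"{cl}.fa")
        files[f"promoters/{cl}.fa"] = "cell-line promoter sequences"

    mio.write_pwms(dataset.pwms, out / "pwms.transfac")
    files["pwms.transfac"] = "position weight matrices (TRANSFAC)"
    with (out / "tf_gene_map.tsv").open("w") as fh:
        fh.write("matrix_id\tgene_id\n")
        for mid, gid in sorted(dataset.tf_gene_map.items()):
            fh.write(f"{mid}\t{gid}\n")
    files["tf_gene_map.tsv"] = "PWM -> TF gene mapping"

    with (out / "ground_truth.json").open("w") as fh:
        json.dump(dataset.truth.to_dict(), fh, indent=2, sort_keys=True)
    files["ground_truth.json"] = "planted effects"

    with (out / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def load_dataset(out_dir: str | Path) -> SyntheticDataset:
    """Read a written dataset back through the standard readers."""
    out = Path(out_dir)
    config = SimulationConfig(
        **{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in json.loads((out / "manifest.json").read_text())["config"].items()
        }
    )
    subtypes = mio.read_subtype_table(out / "subtypes.tsv")
    genes = mio.read_gene_models(out / "genes.bed")
    cgis = mio.read_intervals_bed(out / "cgis.bed")
    catalog = build_region_catalog(genes, cgis)
    expression = mio.read_expression_matrix(out / "expression.tsv")
    cols = [
        mio.read_bin_counts(out / "bins" / f"{cl}.tsv") for cl in subtypes.cell_lines
    ]
    binned = combine_cell_lines(cols, normalization=RAW_COUNT)
    promoter_reference = mio.read_fasta(out / "promoters" / "reference.fa")
    promoter_seqs = {
        cl: mio.read_fasta(out / "promoters" / f"{cl}.fa")
        for cl in subtypes.cell_lines
    }
    pwms = mio.read_pwms(out / "pwms.transfac")
    tf_gene_map = {}
    for line in (out / "tf_gene_map.tsv").read_text().splitlines()[1:]:
        mid, gid = line.split("\t")
        tf_gene_map[mid] = gid
    td = json.loads((out / "ground_truth.json").read_text())
    truth = GroundTruth(
        {k: tuple(v) for k, v in td["planted_dm_genes"].items()},
        {k: tuple(v) for k, v in td["planted_down_genes"].items()},
        dict(td["planted_region"]),
        tuple((g, m, int(b)) for g, m, b in td["planted_tf_pairs"]),
    )
    return SyntheticDataset(
        config,
        subtypes,
        genes,
        cgis,
        catalog,
        binned,
        expression,
        promoter_reference,
        promoter_seqs,
        pwms,
        tf_gene_map,
        truth,
    )


# ---------------------------------------------------------------------------
# planted decision-tree scenarios

def simulate_tree_instances(
    n_genes: int = 20,
    rule: str = "conjunctive",
    seed: int = 0,
    label_noise: float = 0.0,
    subtype_sizes: tuple[int, int, int] = (13, 7, 10),
    attributes: Sequence[str] = ("TSS1-1000", "TSS1001-2000", "CGI", "CGIShore", "Exon1"),
) -> list[TreeInstance]:
    """Instance sets with a planted class rule for exercising the tree.

    ``rule``:
      * ``"single"``       low iff CGI attribute > 0.5
      * ``"conjunctive"``  low iff TSS1001-2000 > 0 and Exon1 > 0
      * ``"null"``         labels follow the subtype layout, attributes
                           are independent noise
    """
    if rule not in ("single", "conjunctive", "null"):
        raise UsageError(f"unknown rule {rule!r}")
    rng = np.random.default_rng(seed)
    panel = _panel(subtype_sizes)
    instances: list[TreeInstance] = []
    for gi in range(n_genes):
        gid = f"G{gi + 1:04d}"
        for cl in panel.cell_lines:
            attrs = {a: float(rng.normal()) for a in attributes}
            if rule == "single":
                label = LOW if attrs["CGI"] > 0.5 else HIGH
            elif rule == "conjunctive":
                label = LOW if attrs["TSS1001-2000"] > 0 and attrs["Exon1"] > 0 else HIGH
            else:
                label = LOW if panel.subtype_of(cl) == "Lu" else HIGH
            if label_noise > 0 and rng.random() < label_noise:
                label = HIGH if label == LOW else LOW
            instances.append(TreeInstance(gid, cl, attrs, label))
    return instances
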