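"""Synthetic fixtures: screens with planted dependencies and matching
genotype, interaction, drug and gene-index tables.

The generator encodes the statistical structure the dependency test
assumes: for each gene target, scores are i.i.d. noise around zero, and a
planted dependency shifts the altered group's scores downward (negative =
more sensitive) by a fixed effect size.  Defaults mirror the benchmark
conditions used throughout the test-suite: panels of 30 cell lines with 10
altered / 20 wild-type, 100 targets, standard-normal noise (sd 1) and a
planted mean shift of -2.  Background noise is Gaussian by default; a
heavy-tailed alternative (Student t with 3 df) exercises the rank test's
distributional robustness.  Everything is deterministic given (parameters,
seed).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .depstats import PANCAN
from .genotype import (
    CopyNumberRecord,
    DriverGeneSpec,
    MIN_ALTERED_DEFAULT,
    MutationRecord,
)
from .screen_io import CellLineName, ScreenMatrix, TargetLabel, split_full_name

__all__ = [
    "PlantedDependency",
    "PlantedTruth",
    "make_truth",
    "generate_screen",
    "generate_genotype",
    "generate_annotation_fixtures",
    "write_demo_workspace",
    "DEFAULT_TISSUES",
    "N_ALTERED_DEFAULT",
    "N_WILDTYPE_DEFAULT",
    "N_TARGETS_DEFAULT",
    "EFFECT_SIZE_DEFAULT",
    "NOISE_SD_DEFAULT",
]

DEFAULT_TISSUES = ("BREAST", "LUNG", "OVARY")
N_ALTERED_DEFAULT = 10
N_WILDTYPE_DEFAULT = 20
N_TARGETS_DEFAULT = 100
EFFECT_SIZE_DEFAULT = -2.0
NOISE_SD_DEFAULT = 1.0


@dataclass(frozen=True)
class PlantedDependency:
    """One true driver->target sensitivity association to embed in a screen."""

    driver: DriverGeneSpec
    target: TargetLabel
    effect_size: float  # mean shift added to altered lines; <= 0
    context: str = PANCAN

    def __post_init__(self) -> None:
        if self.effect_size > 0:
            raise ValueError(
                "effect_size must be <= 0 (negative scores = more sensitive)"
            )


@dataclass
class PlantedTruth:
    """Ground truth for a synthetic screen: who is altered, what is planted."""

    cell_lines: list[str]  # full NAME_TISSUE strings
    drivers: list[DriverGeneSpec]
    assignments: np.ndarray  # bool (n_cell_lines, n_drivers)
    planted: list[PlantedDependency] = field(default_factory=list)
    noise_sd: float = NOISE_SD_DEFAULT
    noise: str = "normal"  # "normal" or "t3"
    seed: int = 0

    def __post_init__(self) -> None:
        self.assignments = np.asarray(self.assignments, dtype=bool)
        if self.assignments.shape != (len(self.cell_lines), len(self.drivers)):
            raise ValueError("assignments shape must be (n_cell_lines, n_drivers)")
        driver_set = set(self.drivers)
        for p in self.planted:
            if p.driver not in driver_set:
                raise ValueError(f"planted driver {p.driver.symbol} not in drivers")

    def altered_count(self, driver: DriverGeneSpec) -> int:
        return int(self.assignments[:, self.drivers.index(driver)].sum())

    def altered_lines(self, driver: DriverGeneSpec) -> list[str]:
        j = self.drivers.index(driver)
        return [cl for i, cl in enumerate(self.cell_lines) if self.assignments[i, j]]


def _default_drivers() -> list[DriverGeneSpec]:
    return [DriverGeneSpec(TargetLabel("DRV1", 9001), "tumor_suppressor", "both")]


def make_truth(
    n_cell_lines: int = N_ALTERED_DEFAULT + N_WILDTYPE_DEFAULT,
    drivers: list[DriverGeneSpec] | None = None,
    n_altered: int = N_ALTERED_DEFAULT,
    planted: list[PlantedDependency] | None = None,
    noise_sd: float = NOISE_SD_DEFAULT,
    noise: str = "normal",
    seed: int = 0,
    tissues: tuple[str, ...] = DEFAULT_TISSUES,
) -> PlantedTruth:
    """Construct a ground truth with random altered-line assignments.

    Cell lines are named ``CL001_<TISSUE>`` ... with tissues assigned
    round-robin.  Each driver is independently altered in exactly
    *n_altered* lines chosen uniformly at random (reproducibly from
    *seed*).
    """
    if drivers is None:
        drivers = _default_drivers()
    if n_altered > n_cell_lines:
        raise ValueError("n_altered cannot exceed n_cell_lines")
    rng = np.random.default_rng(seed)
    cell_lines = [
        f"CL{i + 1:03d}_{tissues[i % len(tissues)]}" for i in range(n_cell_lines)
    ]
    assignments = np.zeros((n_cell_lines, len(drivers)), dtype=bool)
    for j in range(len(drivers)):
        idx = rng.choice(n_cell_lines, size=n_altered, replace=False)
        assignments[idx, j] = True
    return PlantedTruth(
        cell_lines, list(drivers), assignments, list(planted or []),
        noise_sd, noise, seed,
    )


def generate_screen(
    truth: PlantedTruth,
    n_targets: int = N_TARGETS_DEFAULT,
    dataset_id: str = "SYNTH",
    seed: int | None = None,
    min_altered: int = MIN_ALTERED_DEFAULT,
) -> ScreenMatrix:
    """Draw a screen matrix with the truth's dependencies planted.

    Background scores are i.i.d. noise (standard normal scaled by
    ``truth.noise_sd``, or t(3) when ``truth.noise == "t3"``); each planted
    (driver, target) pair adds its effect size to the scores of altered
    lines (restricted to the planted context's tissue when not
    pan-cancer).  Planted targets occupy the first columns, followed by
    background targets ``BG0001_910001`` ...  Raises if a planted driver is
    altered in fewer than *min_altered* lines.
    """
    if seed is None:
        seed = truth.seed
    for p in truth.planted:
        if truth.altered_count(p.driver) < min_altered:
            raise ValueError(
                f"planted driver {p.driver.symbol} altered in "
                f"{truth.altered_count(p.driver)} lines; need >= {min_altered}"
            )

    planted_targets: list[TargetLabel] = []
    for p in truth.planted:
        if p.target not in planted_targets:
            planted_targets.append(p.target)
    if len(planted_targets) > n_targets:
        raise ValueError("n_targets smaller than the number of planted targets")
    targets = list(planted_targets)
    j = 0
    while len(targets) < n_targets:
        j += 1
        targets.append(TargetLabel(f"BG{j:04d}", 910000 + j))

    n = len(truth.cell_lines)
    rng = np.random.default_rng(seed)
    if truth.noise == "t3":
        scores = rng.standard_t(3, size=(n, n_targets)) * truth.noise_sd
    elif truth.noise == "normal":
        scores = rng.standard_normal((n, n_targets)) * truth.noise_sd
    else:
        raise ValueError(f"unknown noise model {truth.noise!r}")

    col_of = {t.key: k for k, t in enumerate(targets)}
    for p in truth.planted:
        k = col_of[p.target.key]
        dj = truth.drivers.index(p.driver)
        for i, cl in enumerate(truth.cell_lines):
            if not truth.assignments[i, dj]:
                continue
            if p.context != PANCAN and split_full_name(cl).tissue != p.context:
                continue
            scores[i, k] += p.effect_size

    cell_lines = [split_full_name(cl) for cl in truth.cell_lines]
    return ScreenMatrix(cell_lines, targets, scores, dataset_id)


# decoy genotype records straddle each rule boundary without qualifying:
# recurrence 2 (< 3), min_cn 7 (< 8), min_cn 1 (> 0)
_DECOY_RECURRENCE = 2
_DECOY_AMP_CN = 7
_DECOY_DEL_CN = 1


def generate_genotype(
    truth: PlantedTruth,
    seed: int | None = None,
    qualifying_recurrence: int = 5,
    amplified_cn: int = 9,
) -> tuple[list[MutationRecord], list[CopyNumberRecord]]:
    """Emit mutation and copy-number tables that invert to the truth.

    For each altered (cell line, driver) the records satisfy the driver's
    alteration rule (amplification for ``amplification_only``, a recurrent
    missense for ``mutation_only``, a random choice of branch for mode
    ``both``).  Unaltered lines receive decoy records that fail each rule
    at its boundary, so threshold regressions flip calls and are caught by
    the round-trip test.
    """
    if seed is None:
        seed = truth.seed
    rng = np.random.default_rng(seed + 1)
    mutations: list[MutationRecord] = []
    cnvs: list[CopyNumberRecord] = []

    for j, d in enumerate(truth.drivers):
        sym, ent = d.gene.symbol, d.gene.entrez_id
        for i, cl in enumerate(truth.cell_lines):
            if truth.assignments[i, j]:
                if d.alteration_mode == "amplification_only":
                    branch = "amp"
                elif d.alteration_mode == "mutation_only":
                    branch = "mut"
                elif d.gene_class == "oncogene":
                    branch = "amp" if rng.random() < 0.5 else "mut"
                else:
                    branch = "del" if rng.random() < 0.5 else "trunc"
                if branch == "amp":
                    cnvs.append(
                        CopyNumberRecord(cl, sym, ent, amplified_cn, amplified_cn + 3)
                    )
                elif branch == "mut":
                    mutations.append(
                        MutationRecord(cl, sym, ent, "missense", qualifying_recurrence)
                    )
                elif branch == "del":
                    cnvs.append(CopyNumberRecord(cl, sym, ent, 0, 2))
                else:  # truncating mutation, unconditionally functional in TS
                    mutations.append(MutationRecord(cl, sym, ent, "nonsense", 0))
            else:
                # one decoy per unaltered line, cycling the rule boundaries
                kind = i % 3
                if kind == 0:
                    mutations.append(
                        MutationRecord(cl, sym, ent, "missense", _DECOY_RECURRENCE)
                    )
                elif kind == 1 and d.gene_class == "oncogene":
                    cnvs.append(CopyNumberRecord(cl, sym, ent, _DECOY_AMP_CN, 20))
                elif kind == 1:
                    cnvs.append(CopyNumberRecord(cl, sym, ent, _DECOY_DEL_CN, 2))
                elif d.gene_class == "oncogene":
                    # truncating events are not functional calls in oncogenes
                    mutations.append(MutationRecord(cl, sym, ent, "nonsense", 0))
                else:
                    cnvs.append(CopyNumberRecord(cl, sym, ent, 2, 2))
    return mutations, cnvs


def generate_annotation_fixtures(
    genes: list[TargetLabel], seed: int = 0
) -> tuple[str, str, str]:
    """Build interaction, drug-gene and gene-index file contents.

    The interaction edges straddle every tier boundary (scores 0.35, 0.45,
    0.75, 0.95 over consecutive gene pairs); the drug table covers kept and
    excluded categories/sources; the gene index includes a synthetic
    synonym alias (``<SYMBOL>ALIAS``) for the first gene so synonym
    resolution is exercised.
    """
    if not genes:
        raise ValueError("gene list must be non-empty")
    boundary_scores = (0.35, 0.45, 0.75, 0.95)
    ilines = ["id1\tid2\tcombined_score"]
    for k in range(len(genes) - 1):
        score = boundary_scores[k % len(boundary_scores)]
        ilines.append(f"{genes[k].symbol}\t{genes[k + 1].symbol}\t{score}")
    interactions = "\n".join(ilines) + "\n"

    first = genes[0].symbol
    dlines = [
        "gene\tdrug\tinteraction_category\tsource",
        f"{first}\tinhibinol\tinhibitor\tTALC",
        f"{first}\texcludinib\tinhibitor\tMyCancerGenome",
        f"{first}\ttrialomab\tinhibitor\tMyCancerGenomeClinicalTrial",
        f"{first}\tagonexol\tagonist\tTALC",
    ]
    if len(genes) > 1:
        dlines.append(f"{genes[1].symbol}\tsecondib\tinhibitor\tTTD")
    drugs = "\n".join(dlines) + "\n"

    glines = ["symbol\tentrez\tensembl_gene\tensembl_protein\tsynonyms"]
    for k, g in enumerate(genes):
        syn = f"{g.symbol}ALIAS" if k == 0 else ""
        glines.append(
            f"{g.symbol}\t{g.entrez_id}\tENSG{g.entrez_id:011d}"
            f"\tENSP{g.entrez_id:011d}\t{syn}"
        )
    gene_index = "\n".join(glines) + "\n"
    return interactions, drugs, gene_index


def write_demo_workspace(
    outdir: str | Path,
    seed: int = 0,
    n_cell_lines: int = N_ALTERED_DEFAULT + N_WILDTYPE_DEFAULT,
    n_targets: int = 20,
    n_datasets: int = 2,
) -> Path:
    """Write a complete, ready-to-scan demo workspace.

    Produces *n_datasets* screens sharing one planted driver->target
    dependency (so the Multiple Hit flag is exercised), the matching
    genotype tables, driver config, annotation fixtures and a flat
    key-value run config.  Returns the config path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    driver = DriverGeneSpec(TargetLabel("DRV1", 9001), "tumor_suppressor", "both")
    target = TargetLabel("TGT1", 9101)
    # keep roughly a third of the panel altered when it is smaller than the
    # default benchmark size
    n_altered = min(N_ALTERED_DEFAULT, max(MIN_ALTERED_DEFAULT, n_cell_lines // 3))
    truth = make_truth(
        n_cell_lines=n_cell_lines,
        drivers=[driver],
        n_altered=n_altered,
        planted=[PlantedDependency(driver, target, EFFECT_SIZE_DEFAULT)],
        seed=seed,
    )

    from . import screen_io

    screen_paths = []
    for d in range(n_datasets):
        screen = generate_screen(
            truth, n_targets=n_targets, dataset_id=f"DS{d + 1}", seed=seed * 1000 + d
        )
        path = outdir / f"screen_DS{d + 1}.txt"
        with open(path, "w") as fh:
            screen_io.write_screen(screen, fh)
        screen_paths.append(path)

    mutations, cnvs = generate_genotype(truth)
    with open(outdir / "mutations.tsv", "w") as fh:
        fh.write("cell_line\tgene_symbol\tentrez_id\teffect\tsite_recurrence\n")
        for m in mutations:
            fh.write(
                f"{m.cell_line}\t{m.gene_symbol}\t{m.entrez_id}\t{m.effect}"
                f"\t{m.site_recurrence}\n"
            )
    with open(outdir / "copy_number.tsv", "w") as fh:
        fh.write("cell_line\tgene_symbol\tentrez_id\tmin_cn\tmax_cn\n")
        for c in cnvs:
            fh.write(
                f"{c.cell_line}\t{c.gene_symbol}\t{c.entrez_id}\t{c.min_cn}\t{c.max_cn}\n"
            )
    with open(outdir / "drivers.tsv", "w") as fh:
        fh.write("gene_symbol\tentrez_id\tgene_class\talteration_mode\n")
        for d in truth.drivers:
            fh.write(
                f"{d.gene.symbol}\t{d.gene.entrez_id}\t{d.gene_class}"
                f"\t{d.alteration_mode}\n"
            )

    genes = [d.gene for d in truth.drivers] + [target]
    interactions, drugs, gene_index = generate_annotation_fixtures(genes, seed)
    (outdir / "interactions.tsv").write_text(interactions)
    (outdir / "drug_gene.tsv").write_text(drugs)
    (outdir / "gene_index.tsv").write_text(gene_index)

    config = "\n".join(
        [
            "# demo run configuration",
            "screens: " + ",".join(str(p.name) for p in screen_paths),
            "mutations: mutations.tsv",
            "copy_number: copy_number.tsv",
            "drivers: drivers.tsv",
            "interactions: interactions.tsv",
            "drug_gene: drug_gene.tsv",
            "gene_index: gene_index.tsv",
            "output_dir: results",
            "p_max: 0.05",
            "cles_min: 0.65",
            "amp_threshold: 8",
            "recurrence_threshold: 3",
            "min_altered: 3",
            "min_wildtype: 3",
            "min_cell_lines: 10",
            "normalize: none",
            "contexts: all",
            f"seed: {seed}",
            "",
        ]
    )
    config_path = outdir / "config.yaml"
    config_path.write_text(config)
    return config_path
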