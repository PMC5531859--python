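"""Driver/target dependency testing: one-sided Mann-Whitney U and CLES.

For every driver gene, target gene and context (pan-cancer or a single
tissue), cell lines carrying a likely functional alteration in the driver
are compared with wild-type lines on the target's sensitivity scores.  The
alternative hypothesis is that the altered group is *more sensitive*, i.e.
stochastically smaller under the negative-is-sensitive score convention.

Two quantities summarize each comparison:

* the one-sided Mann-Whitney p-value, computed exactly (enumeration of the
  tie-free null distribution) for small samples and by the tie- and
  continuity-corrected normal approximation otherwise;
* the common-language effect size (CLES), the probability that a random
  altered line is more sensitive than a random wild-type line — identical
  to the area under the ROC curve, with tied pairs counted one half.

Retained dependencies satisfy p < 0.05 and CLES >= 0.65 (nominal
significance with a moderate effect size); no multiple-testing correction
is applied by default, though Benjamini-Hochberg q-values are available
as an opt-in annotation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Literal, Sequence

import numpy as np
from scipy import stats

from .genotype import (
    AlterationMatrix,
    DriverGeneSpec,
    MIN_ALTERED_DEFAULT,
    select_testable_drivers,
)
from .screen_io import ScreenMatrix, TargetLabel, tissue_of

__all__ = [
    "DependencyRecord",
    "cles",
    "mann_whitney_one_sided",
    "delta_median",
    "scan",
    "filter_cgds",
    "resolve_multiscore",
    "adjust_pvalues",
    "write_results_table",
    "boxplot_table",
    "P_MAX_DEFAULT",
    "CLES_MIN_DEFAULT",
    "PANCAN",
]

logger = logging.getLogger(__name__)

P_MAX_DEFAULT = 0.05
CLES_MIN_DEFAULT = 0.65
MIN_WILDTYPE_DEFAULT = 3
#: sample-size bound below which the exact tie-free null distribution is used
EXACT_MAX_N = 30
PANCAN = "PANCAN"


@dataclass(frozen=True)
class DependencyRecord:
    """One driver x target x context test result, plus annotation flags."""

    driver: DriverGeneSpec
    target: TargetLabel
    dataset_id: str
    context: str  # PANCAN or a tissue token
    n_altered: int
    n_wildtype: int
    U: float  # altered-beats-wildtype pair count, ties weighted 1/2
    p_one_sided: float
    cles: float
    delta_median: float
    multiple_hit: bool = False
    string_tier: Literal["none", "medium", "high", "highest"] = "none"
    inhibitors: tuple[str, ...] = ()
    q_value: float | None = None

    def __post_init__(self) -> None:
        if self.n_altered < 1 or self.n_wildtype < 1:
            raise ValueError("both groups must be non-empty")
        if not 0 <= self.U <= self.n_altered * self.n_wildtype:
            raise ValueError("U outside [0, n1*n2]")
        if not 0 < self.p_one_sided <= 1:
            raise ValueError("p must be in (0, 1]")

    @property
    def pair_key(self) -> tuple[int, int]:
        """(driver entrez, target entrez) — the cross-dataset match key."""
        return (self.driver.entrez_id, self.target.entrez_id)


def _as_arrays(altered: Sequence[float], wildtype: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(altered, dtype=float)
    w = np.asarray(wildtype, dtype=float)
    if a.size == 0 or w.size == 0:
        raise ValueError("both groups must be non-empty")
    if not (np.isfinite(a).all() and np.isfinite(w).all()):
        raise ValueError("scores must be finite")
    return a, w


def _u_statistic(a: np.ndarray, w: np.ndarray) -> float:
    """Number of (altered, wildtype) pairs with altered < wildtype, ties 1/2.

    Computed from midranks so that it is exact for tied data and O(n log n).
    """
    n1, n2 = a.size, w.size
    ranks = stats.rankdata(np.concatenate([a, w]))
    r1 = ranks[:n1].sum()
    u_greater = r1 - n1 * (n1 + 1) / 2.0  # pairs with altered > wildtype (+ ties/2)
    return n1 * n2 - u_greater


def cles(altered: Sequence[float], wildtype: Sequence[float]) -> float:
    """Common-language effect size: P(altered line more sensitive than wild-type).

    "More sensitive" means a strictly lower score; tied pairs count 1/2.
    Equals U/(n1*n2) and the AUROC of the scores as a classifier of group.
    """
    a, w = _as_arrays(altered, wildtype)
    return _u_statistic(a, w) / (a.size * w.size)


def mann_whitney_one_sided(
    altered: Sequence[float], wildtype: Sequence[float]
) -> tuple[float, float]:
    """One-sided Mann-Whitney U test that the altered group is more sensitive.

    Returns ``(U, p)`` where U counts altered-beats-wildtype pairs (ties
    weighted 1/2) and p is the one-sided tail probability that the altered
    group is stochastically smaller.  The exact null distribution is used
    when the data are tie-free and n1 + n2 <= 30; otherwise the normal
    approximation with tie correction and continuity correction.  If every
    value in both groups is identical the test is degenerate: p = 1 with a
    warning.
    """
    a, w = _as_arrays(altered, wildtype)
    u = _u_statistic(a, w)

    pooled = np.concatenate([a, w])
    if np.all(pooled == pooled[0]):
        warnings.warn(
            "degenerate comparison: all scores identical across both groups",
            RuntimeWarning,
            stacklevel=2,
        )
        return u, 1.0

    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and a.size + w.size <= EXACT_MAX_N:
        method = "exact"
    else:
        method = "asymptotic"
    # alternative="less": the altered distribution is stochastically smaller
    res = stats.mannwhitneyu(
        a, w, alternative="less", method=method, use_continuity=True
    )
    logger.debug(
        "mann-whitney n=(%d,%d) method=%s U=%g p=%g", a.size, w.size, method, u, res.pvalue
    )
    return u, float(res.pvalue)


def delta_median(altered: Sequence[float], wildtype: Sequence[float]) -> float:
    """median(altered) - median(wildtype); negative = altered more sensitive."""
    a, w = _as_arrays(altered, wildtype)
    return float(np.median(a) - np.median(w))


def scan(
    screen: ScreenMatrix,
    alterations: AlterationMatrix,
    contexts: Sequence[str] | None = None,
    min_altered: int = MIN_ALTERED_DEFAULT,
    min_wildtype: int = MIN_WILDTYPE_DEFAULT,
    exclude_nonfunctional: bool = False,
) -> list[DependencyRecord]:
    """Test every (context, driver, target) combination in a screen.

    Parameters
    ----------
    contexts:
        Contexts to scan; ``None`` means pan-cancer plus every tissue
        present in the screen.
    min_altered, min_wildtype:
        Minimum group sizes; smaller splits are skipped silently.
    exclude_nonfunctional:
        If true, wild-type groups drop cell lines that carry a
        non-qualifying mutation in the driver (rather than pooling them
        with the unaltered lines).

    Output order is deterministic: (context, driver entrez, target entrez,
    suffix), with PANCAN first followed by tissues alphabetically.
    """
    alt_rows = {cl: i for i, cl in enumerate(alterations.cell_lines)}
    shared = [cl for cl in screen.cell_line_names if cl in alt_rows]
    if not shared:
        raise ValueError(
            "screen and alteration matrix share no cell lines; "
            "check name harmonization"
        )

    if contexts is None:
        tissues = sorted({tissue_of(cl) for cl in shared})
        contexts = [PANCAN] + tissues
    else:
        ordered = sorted(set(contexts) - {PANCAN})
        contexts = ([PANCAN] if PANCAN in contexts else []) + ordered

    records: list[DependencyRecord] = []
    screen_rows = {cl: i for i, cl in enumerate(screen.cell_line_names)}

    for context in contexts:
        if context == PANCAN:
            ctx_lines = shared
        else:
            ctx_lines = [cl for cl in shared if tissue_of(cl) == context]
        if not ctx_lines:
            continue
        drivers = select_testable_drivers(alterations, set(ctx_lines), min_altered)
        for driver in sorted(drivers, key=lambda d: d.entrez_id):
            j = alterations.drivers.index(driver)
            altered_lines, wildtype_lines = [], []
            for cl in ctx_lines:
                i = alt_rows[cl]
                if alterations.calls[i, j]:
                    altered_lines.append(cl)
                elif exclude_nonfunctional and alterations.mutated_any[i, j]:
                    continue
                else:
                    wildtype_lines.append(cl)
            for t_idx, target in sorted(
                enumerate(screen.targets),
                key=lambda it: (it[1].entrez_id, it[1].suffix or ""),
            ):
                col = screen.scores[:, t_idx]
                a = [col[screen_rows[cl]] for cl in altered_lines]
                w = [col[screen_rows[cl]] for cl in wildtype_lines]
                a = [v for v in a if not np.isnan(v)]
                w = [v for v in w if not np.isnan(v)]
                if len(a) < min_altered or len(w) < min_wildtype:
                    continue
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    u, p = mann_whitney_one_sided(a, w)
                records.append(
                    DependencyRecord(
                        driver=driver,
                        target=target,
                        dataset_id=screen.dataset_id,
                        context=context,
                        n_altered=len(a),
                        n_wildtype=len(w),
                        U=u,
                        p_one_sided=p,
                        cles=u / (len(a) * len(w)),
                        delta_median=delta_median(a, w),
                    )
                )
    return records


def filter_cgds(
    records: Iterable[DependencyRecord],
    p_max: float = P_MAX_DEFAULT,
    cles_min: float = CLES_MIN_DEFAULT,
) -> list[DependencyRecord]:
    """Keep records with p < p_max (strict) and CLES >= cles_min; order kept."""
    return [r for r in records if r.p_one_sided < p_max and r.cles >= cles_min]


def resolve_multiscore(records: Iterable[DependencyRecord]) -> list[DependencyRecord]:
    """Collapse multiple score variants (ATARiS-style suffixes) per gene.

    Within each (driver, target entrez, context, dataset) group, keep only
    the record with the lowest p-value; ties broken by higher CLES, then by
    lexicographically smallest suffix.  Runs before filtering so each gene
    is represented by its best-supported score variant.
    """
    best: dict[tuple, DependencyRecord] = {}
    order: list[tuple] = []
    for r in records:
        key = (r.driver.entrez_id, r.target.entrez_id, r.context, r.dataset_id)
        prev = best.get(key)
        if prev is None:
            best[key] = r
            order.append(key)
            continue
        cand = min(
            (prev, r),
            key=lambda x: (x.p_one_sided, -x.cles, x.target.suffix or ""),
        )
        best[key] = cand
    return [best[k] for k in order]


def adjust_pvalues(
    records: Sequence[DependencyRecord],
    method: Literal["none", "benjamini_hochberg"] = "none",
) -> list[DependencyRecord]:
    """Optionally attach BH q-values per (dataset, context) family.

    Original p-values are never modified; ``method="none"`` returns the
    records unchanged.
    """
    if method == "none":
        return list(records)
    if method != "benjamini_hochberg":
        raise ValueError(f"unknown adjustment method {method!r}")
    from statsmodels.stats.multitest import multipletests

    out = list(records)
    families: dict[tuple[str, str], list[int]] = {}
    for idx, r in enumerate(out):
        families.setdefault((r.dataset_id, r.context), []).append(idx)
    for idxs in families.values():
        pvals = [out[i].p_one_sided for i in idxs]
        _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
        for i, q in zip(idxs, qvals):
            out[i] = replace(out[i], q_value=float(q))
    return out


RESULT_COLUMNS = [
    "dataset",
    "context",
    "driver_symbol",
    "driver_entrez",
    "target_symbol",
    "target_entrez",
    "suffix",
    "n_altered",
    "n_wildtype",
    "U",
    "p",
    "cles",
    "delta_median",
    "multiple_hit",
    "string_tier",
    "inhibitors",
]


def write_results_table(records: Iterable[DependencyRecord], stream: IO[str]) -> None:
    """Write retained CGDs as a tab-delimited results table."""
    stream.write("\t".join(RESULT_COLUMNS) + "\n")
    for r in records:
        row = [
            r.dataset_id,
            r.context,
            r.driver.symbol,
            str(r.driver.entrez_id),
            r.target.symbol,
            str(r.target.entrez_id),
            r.target.suffix or "",
            str(r.n_altered),
            str(r.n_wildtype),
            f"{r.U:g}",
            f"{r.p_one_sided:.6g}",
            f"{r.cles:.4f}",
            f"{r.delta_median:.6g}",
            "yes" if r.multiple_hit else "no",
            r.string_tier,
            ";".join(r.inhibitors),
        ]
        stream.write("\t".join(row) + "\n")


def boxplot_table(
    record: DependencyRecord,
    screen: ScreenMatrix,
    alterations: AlterationMatrix,
) -> list[tuple[str, str, str, float]]:
    """Per-CGD boxplot data: (cell_line, tissue, group, score) rows.

    Mirrors the downloadable per-plot CSV: every context cell line with a
    score for the record's target, labelled altered or wildtype.
    """
    j = alterations.drivers.index(record.driver)
    t_idx = next(
        i for i, t in enumerate(screen.targets) if t.key == record.target.key
    )
    alt_rows = {cl: i for i, cl in enumerate(alterations.cell_lines)}
    rows = []
    for i, cl in enumerate(screen.cell_line_names):
        if cl not in alt_rows:
            continue
        tissue = tissue_of(cl)
        if record.context != PANCAN and tissue != record.context:
            continue
        score = screen.scores[i, t_idx]
        if np.isnan(score):
            continue
        group = "altered" if alterations.calls[alt_rows[cl], j] else "wildtype"
        rows.append((cl, tissue, group, float(score)))
    return rows
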