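"""Call likely-functional driver-gene alterations from mutation and copy-number data.

Alteration rules
----------------
Oncogenes: recurrent missense or in-frame indel mutations are considered
likely functional, where recurrence means at least 3 prior mutations of the
site in COSMIC; amplification means the entire coding sequence has 8 or
more copies (so the *minimum* gene-level copy number over the CDS must
reach the threshold).

Tumor suppressors: all nonsense, frameshift and splice-site mutations are
likely functional, as are recurrent missense/in-frame indels; deletion
means any part of the coding sequence has copy number 0 (minimum CN == 0).

Most drivers combine both evidence sources (mode ``both``).  A few
oncogenes use a single source: ERBB2, MYC and MYCN count only
amplifications (``amplification_only``); KRAS, BRAF, NRAS and HRAS count
only recurrent mutations/indels (``mutation_only``).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Literal, Sequence

import numpy as np

from .screen_io import ScreenFormatError, TargetLabel, parse_target_label

__all__ = [
    "GeneClass",
    "AlterationMode",
    "MutationEffect",
    "DriverGeneSpec",
    "MutationRecord",
    "CopyNumberRecord",
    "AlterationMatrix",
    "classify_mutation",
    "call_amplification",
    "call_deletion",
    "build_alteration_matrix",
    "select_testable_drivers",
    "default_drivers",
    "read_driver_config",
    "read_mutation_table",
    "read_copy_number_table",
]

logger = logging.getLogger(__name__)

GeneClass = Literal["oncogene", "tumor_suppressor"]
AlterationMode = Literal["both", "amplification_only", "mutation_only"]

MUTATION_EFFECTS = frozenset(
    {"missense", "inframe_indel", "nonsense", "frameshift", "splice_site", "other"}
)
#: effect classes that require COSMIC site recurrence to count as functional
RECURRENT_EFFECTS = frozenset({"missense", "inframe_indel"})
#: effect classes unconditionally functional in tumor suppressors
TRUNCATING_EFFECTS = frozenset({"nonsense", "frameshift", "splice_site"})

MutationEffect = Literal[
    "missense", "inframe_indel", "nonsense", "frameshift", "splice_site", "other"
]

AMP_THRESHOLD_DEFAULT = 8
RECURRENCE_THRESHOLD_DEFAULT = 3
MIN_ALTERED_DEFAULT = 3


@dataclass(frozen=True)
class DriverGeneSpec:
    """A driver gene plus the rules governing its alteration calls."""

    gene: TargetLabel
    gene_class: GeneClass
    alteration_mode: AlterationMode = "both"

    def __post_init__(self) -> None:
        if self.gene_class not in ("oncogene", "tumor_suppressor"):
            raise ValueError(f"unknown gene class {self.gene_class!r}")
        if self.alteration_mode not in ("both", "amplification_only", "mutation_only"):
            raise ValueError(f"unknown alteration mode {self.alteration_mode!r}")
        if self.gene_class == "tumor_suppressor" and self.alteration_mode != "both":
            raise ValueError(
                f"{self.gene.symbol}: tumor suppressors always use mode 'both', "
                f"not {self.alteration_mode!r}"
            )

    @property
    def symbol(self) -> str:
        return self.gene.symbol

    @property
    def entrez_id(self) -> int:
        return self.gene.entrez_id


@dataclass(frozen=True)
class MutationRecord:
    cell_line: str  # full NAME_TISSUE
    gene_symbol: str
    entrez_id: int
    effect: MutationEffect
    site_recurrence: int  # prior COSMIC mutations at this site

    def __post_init__(self) -> None:
        if self.effect not in MUTATION_EFFECTS:
            raise ValueError(f"unknown mutation effect class {self.effect!r}")
        if self.site_recurrence < 0:
            raise ValueError("site_recurrence must be >= 0")


@dataclass(frozen=True)
class CopyNumberRecord:
    cell_line: str
    gene_symbol: str
    entrez_id: int
    min_cn: int  # minimum copy number over the coding sequence
    max_cn: int

    def __post_init__(self) -> None:
        if not 0 <= self.min_cn <= self.max_cn:
            raise ValueError(
                f"{self.gene_symbol}/{self.cell_line}: require 0 <= min_cn <= max_cn, "
                f"got ({self.min_cn}, {self.max_cn})"
            )


def classify_mutation(
    record: MutationRecord,
    gene_class: GeneClass,
    recurrence_threshold: int = RECURRENCE_THRESHOLD_DEFAULT,
) -> bool:
    """Is this mutation a likely functional alteration for *gene_class*?

    Oncogene: recurrent missense / in-frame indel only.  Tumor suppressor:
    any nonsense, frameshift or splice-site mutation (no recurrence
    requirement), plus recurrent missense / in-frame indel.
    """
    if record.effect not in MUTATION_EFFECTS:
        raise ValueError(f"unknown mutation effect class {record.effect!r}")
    recurrent = (
        record.effect in RECURRENT_EFFECTS
        and record.site_recurrence >= recurrence_threshold
    )
    if gene_class == "oncogene":
        return recurrent
    if gene_class == "tumor_suppressor":
        return record.effect in TRUNCATING_EFFECTS or recurrent
    raise ValueError(f"unknown gene class {gene_class!r}")


def call_amplification(
    record: CopyNumberRecord, amp_threshold: int = AMP_THRESHOLD_DEFAULT
) -> bool:
    """Amplified iff the entire coding sequence has >= *amp_threshold* copies."""
    return record.min_cn >= amp_threshold


def call_deletion(record: CopyNumberRecord) -> bool:
    """Deleted iff any part of the coding sequence has copy number 0."""
    return record.min_cn == 0


@dataclass
class AlterationMatrix:
    """Boolean cell-line x driver matrix of likely functional alterations.

    ``provenance[i][j]`` records which rule branch(es) fired for a true
    call: a subset of {"mutation", "amplification", "deletion"}, non-empty
    exactly where ``calls`` is true.
    """

    cell_lines: list[str]  # full NAME_TISSUE strings
    drivers: list[DriverGeneSpec]
    calls: np.ndarray  # bool (n_cell_lines, n_drivers)
    provenance: list[list[frozenset[str]]]
    #: any mutation record observed, functional or not; lets callers exclude
    #: lines carrying non-qualifying alterations from the wild-type group
    mutated_any: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=bool)
        if self.mutated_any is None:
            self.mutated_any = np.zeros_like(self.calls)
        else:
            self.mutated_any = np.asarray(self.mutated_any, dtype=bool)
        if self.calls.shape != (len(self.cell_lines), len(self.drivers)):
            raise ValueError("calls shape does not match cell lines x drivers")
        for i in range(len(self.cell_lines)):
            for j in range(len(self.drivers)):
                if bool(self.calls[i, j]) != bool(self.provenance[i][j]):
                    raise ValueError(
                        "provenance must be non-empty exactly where calls is true"
                    )

    def altered_lines(self, driver: DriverGeneSpec) -> list[str]:
        j = self.drivers.index(driver)
        return [cl for i, cl in enumerate(self.cell_lines) if self.calls[i, j]]

    def column(self, driver: DriverGeneSpec) -> np.ndarray:
        return self.calls[:, self.drivers.index(driver)]


def build_alteration_matrix(
    mutations: Iterable[MutationRecord],
    cnv: Iterable[CopyNumberRecord],
    drivers: Sequence[DriverGeneSpec],
    cell_lines: Sequence[str],
    amp_threshold: int = AMP_THRESHOLD_DEFAULT,
    recurrence_threshold: int = RECURRENCE_THRESHOLD_DEFAULT,
) -> AlterationMatrix:
    """Combine mutation and copy-number evidence into per-driver calls.

    Records referring to cell lines or genes outside the declared universe
    are dropped with a logged warning (genotype files are typically
    supersets of the screened panel).
    """
    entrez_to_col = {d.entrez_id: j for j, d in enumerate(drivers)}
    if len(entrez_to_col) != len(drivers):
        raise ValueError("duplicate driver entrez_id in driver list")
    line_to_row = {cl: i for i, cl in enumerate(cell_lines)}

    n, m = len(cell_lines), len(drivers)
    calls = np.zeros((n, m), dtype=bool)
    mutated_any = np.zeros((n, m), dtype=bool)
    prov: list[list[set[str]]] = [[set() for _ in range(m)] for _ in range(n)]

    n_dropped = 0
    for rec in mutations:
        i = line_to_row.get(rec.cell_line)
        j = entrez_to_col.get(rec.entrez_id)
        if i is None or j is None:
            n_dropped += 1
            continue
        d = drivers[j]
        mutated_any[i, j] = True
        if d.alteration_mode == "amplification_only":
            continue  # mutations never count for these oncogenes
        if classify_mutation(rec, d.gene_class, recurrence_threshold):
            prov[i][j].add("mutation")

    for rec in cnv:
        i = line_to_row.get(rec.cell_line)
        j = entrez_to_col.get(rec.entrez_id)
        if i is None or j is None:
            n_dropped += 1
            continue
        d = drivers[j]
        if d.alteration_mode == "mutation_only":
            continue
        if d.gene_class == "oncogene":
            if call_amplification(rec, amp_threshold):
                prov[i][j].add("amplification")
        else:  # tumor suppressors use deletion, never amplification
            if call_deletion(rec):
                prov[i][j].add("deletion")

    if n_dropped:
        logger.warning(
            "dropped %d genotype records outside the declared cell-line/driver universe",
            n_dropped,
        )

    for i in range(n):
        for j in range(m):
            calls[i, j] = bool(prov[i][j])
    frozen = [[frozenset(p) for p in row] for row in prov]
    return AlterationMatrix(list(cell_lines), list(drivers), calls, frozen, mutated_any)


def select_testable_drivers(
    alterations: AlterationMatrix,
    screen_cell_lines: set[str] | Sequence[str],
    min_altered: int = MIN_ALTERED_DEFAULT,
) -> list[DriverGeneSpec]:
    """Drivers altered in at least *min_altered* of the screened cell lines."""
    screened = set(screen_cell_lines)
    out = []
    for j, d in enumerate(alterations.drivers):
        n_alt = sum(
            1
            for i, cl in enumerate(alterations.cell_lines)
            if cl in screened and alterations.calls[i, j]
        )
        if n_alt >= min_altered:
            out.append(d)
    return out


# -- driver configuration -------------------------------------------------

#: the explicitly single-source oncogenes; every other driver comes from a
#: user configuration file with mode "both"
_DEFAULT_DRIVER_ROWS = [
    ("ERBB2", 2064, "oncogene", "amplification_only"),
    ("MYC", 4609, "oncogene", "amplification_only"),
    ("MYCN", 4613, "oncogene", "amplification_only"),
    ("KRAS", 3845, "oncogene", "mutation_only"),
    ("BRAF", 673, "oncogene", "mutation_only"),
    ("NRAS", 4893, "oncogene", "mutation_only"),
    ("HRAS", 3265, "oncogene", "mutation_only"),
]


def default_drivers() -> list[DriverGeneSpec]:
    """The built-in single-evidence-source driver specs."""
    return [
        DriverGeneSpec(TargetLabel(sym, ent), cls, mode)
        for sym, ent, cls, mode in _DEFAULT_DRIVER_ROWS
    ]


def read_driver_config(stream: IO[str] | str) -> list[DriverGeneSpec]:
    """Read a tab-delimited driver config.

    Columns: gene_symbol, entrez_id, gene_class, alteration_mode.  A header
    row is detected and skipped.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    out: list[DriverGeneSpec] = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if lineno == 1 and parts[0].lower() in ("gene_symbol", "symbol", "gene"):
            continue
        if len(parts) != 4:
            raise ScreenFormatError(
                f"driver config line {lineno}: expected 4 fields, got {len(parts)}"
            )
        sym, ent, cls, mode = (p.strip() for p in parts)
        out.append(DriverGeneSpec(TargetLabel(sym, int(ent)), cls, mode))
    return out


def read_mutation_table(stream: IO[str] | str) -> list[MutationRecord]:
    """Read a tab-delimited mutation table.

    Columns: cell_line, gene_symbol, entrez_id, effect, site_recurrence.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    out: list[MutationRecord] = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if lineno == 1 and parts[0].lower() == "cell_line":
            continue
        if len(parts) != 5:
            raise ScreenFormatError(
                f"mutation table line {lineno}: expected 5 fields, got {len(parts)}"
            )
        out.append(
            MutationRecord(parts[0], parts[1], int(parts[2]), parts[3], int(parts[4]))
        )
    return out


def read_copy_number_table(stream: IO[str] | str) -> list[CopyNumberRecord]:
    """Read a tab-delimited gene-level copy-number table.

    Columns: cell_line, gene_symbol, entrez_id, min_cn, max_cn.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    out: list[CopyNumberRecord] = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if lineno == 1 and parts[0].lower() == "cell_line":
            continue
        if len(parts) != 5:
            raise ScreenFormatError(
                f"copy-number table line {lineno}: expected 5 fields, got {len(parts)}"
            )
        out.append(
            CopyNumberRecord(parts[0], parts[1], int(parts[2]), int(parts[3]), int(parts[4]))
        )
    return out
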