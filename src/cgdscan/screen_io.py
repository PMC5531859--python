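"""Read, validate, normalize and write loss-of-function screen matrices.

A screen is a cell-line x gene-target matrix of quantitative sensitivity
scores (more negative = greater inhibition of growth).  The on-disk dialect
is a UTF-8 tab-delimited table: row 1 is a header whose first field is
``cell_line`` (or empty) followed by target labels of the form
``SYMBOL_ENTREZID`` or ``SYMBOL_ENTREZID_SUFFIX``; each subsequent row is a
cell-line name followed by scores.  Cell-line names follow the CCLE
convention ``NAME_TISSUE`` where NAME contains only digits and uppercase
letters and TISSUE is an uppercase token that may itself contain
underscores (e.g. ``HAEMATOPOIETIC_AND_LYMPHOID_TISSUE``).
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Literal, Mapping, Sequence

import numpy as np

__all__ = [
    "TargetLabel",
    "CellLineName",
    "ScreenMatrix",
    "ValidationReport",
    "ValidationIssue",
    "ScreenFormatError",
    "parse_target_label",
    "parse_screen",
    "harmonize_cell_line_name",
    "tissue_of",
    "validate_screen",
    "zscore_normalize",
    "write_screen",
    "read_rename_map",
]

#: strings accepted as a missing score on read; written back as empty cells
MISSING_TOKENS = frozenset({"", "NA", "NaN", "nan"})

_NAME_RE = re.compile(r"^[0-9A-Z]+$")
_TISSUE_RE = re.compile(r"^[0-9A-Z_]+$")


class ScreenFormatError(ValueError):
    """Raised for malformed screen files or invalid screen values."""


@dataclass(frozen=True, order=True)
class TargetLabel:
    """A gene reagent column label: symbol, Entrez ID and optional suffix.

    The suffix distinguishes multiple score variants for one gene, e.g.
    distinct ATARiS solutions published as ``KRAS_3846_1``, ``KRAS_3846_2``.
    """

    symbol: str
    entrez_id: int
    suffix: str | None = None

    def __post_init__(self) -> None:
        if not self.symbol:
            raise ScreenFormatError("target symbol must be non-empty")
        if self.entrez_id <= 0:
            raise ScreenFormatError(
                f"entrez_id must be a positive integer, got {self.entrez_id}"
            )
        if self.suffix is not None and not self.suffix:
            raise ScreenFormatError("suffix must be absent or non-empty")

    @property
    def label(self) -> str:
        """The header form, ``SYMBOL_ENTREZ`` or ``SYMBOL_ENTREZ_SUFFIX``."""
        base = f"{self.symbol}_{self.entrez_id}"
        return base if self.suffix is None else f"{base}_{self.suffix}"

    @property
    def key(self) -> tuple[int, str]:
        """Uniqueness key within a screen: (entrez_id, suffix-or-empty)."""
        return (self.entrez_id, self.suffix or "")

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def parse_target_label(text: str) -> TargetLabel:
    """Parse a header label into a :class:`TargetLabel`.

    The grammar is ``SYMBOL_ENTREZ[_SUFFIX]``.  When the label has three or
    more underscore-separated segments, the final segment is treated as a
    suffix only if the second-to-last segment parses as an Entrez ID;
    otherwise parsing fails rather than guessing.
    """
    parts = text.strip().split("_")
    if len(parts) < 2:
        raise ScreenFormatError(
            f"target label {text!r} lacks an _ENTREZID segment"
        )
    if len(parts) >= 3 and parts[-2].isdigit():
        return TargetLabel("_".join(parts[:-2]), int(parts[-2]), parts[-1])
    if parts[-1].isdigit():
        return TargetLabel("_".join(parts[:-1]), int(parts[-1]), None)
    raise ScreenFormatError(
        f"target label {text!r} lacks a numeric Entrez ID segment"
    )


@dataclass(frozen=True, order=True)
class CellLineName:
    """A harmonized CCLE-style cell-line name, ``NAME_TISSUE``."""

    name: str
    tissue: str

    def __post_init__(self) -> None:
        if not _NAME_RE.match(self.name):
            raise ScreenFormatError(
                f"cell-line name {self.name!r} must contain only digits "
                "and uppercase letters"
            )
        if not self.tissue or not _TISSUE_RE.match(self.tissue):
            raise ScreenFormatError(
                f"tissue token {self.tissue!r} must be non-empty uppercase"
            )

    @property
    def full(self) -> str:
        return f"{self.name}_{self.tissue}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.full


_PUNCT_RE = re.compile(r"[^0-9A-Za-z]")


def harmonize_cell_line_name(raw: str, tissue: str) -> CellLineName:
    """Convert a raw cell-line name to the CCLE convention.

    Punctuation and whitespace are stripped from *raw* and letters
    uppercased (``MDA-MB-231`` -> ``MDAMB231``); *tissue* is uppercased.
    Idempotent: harmonizing an already-conforming name is a no-op.
    """
    if not raw:
        raise ScreenFormatError("cell-line name must be non-empty")
    if not tissue:
        raise ScreenFormatError("tissue must be non-empty")
    name = _PUNCT_RE.sub("", raw).upper()
    if not name:
        raise ScreenFormatError(
            f"cell-line name {raw!r} is empty after punctuation removal"
        )
    return CellLineName(name, tissue.strip().upper())


def tissue_of(full_name: str) -> str:
    """Return the tissue token of a full cell-line name.

    Splits on the FIRST underscore: the name part never contains
    underscores, while tissues may (``KMH2_HAEMATOPOIETIC_AND_LYMPHOID_TISSUE``
    -> ``HAEMATOPOIETIC_AND_LYMPHOID_TISSUE``).
    """
    if "_" not in full_name:
        raise ScreenFormatError(
            f"cell-line name {full_name!r} has no _TISSUE part"
        )
    return full_name.split("_", 1)[1]


def split_full_name(full_name: str) -> CellLineName:
    """Parse and harmonize a full ``NAME_TISSUE`` string."""
    if "_" not in full_name:
        raise ScreenFormatError(
            f"cell-line name {full_name!r} has no _TISSUE part"
        )
    name, tissue = full_name.split("_", 1)
    return harmonize_cell_line_name(name, tissue)


@dataclass
class ScreenMatrix:
    """A cell-line x target sensitivity matrix for one dataset.

    ``scores`` is a float array with rows in ``cell_lines`` order and
    columns in ``targets`` order; missing entries are NaN.
    """

    cell_lines: list[CellLineName]
    targets: list[TargetLabel]
    scores: np.ndarray
    dataset_id: str

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.cell_lines), len(self.targets)):
            raise ScreenFormatError(
                f"score matrix shape {self.scores.shape} does not match "
                f"{len(self.cell_lines)} cell lines x {len(self.targets)} targets"
            )
        fulls = [c.full for c in self.cell_lines]
        if len(set(fulls)) != len(fulls):
            dup = _first_duplicate(fulls)
            raise ScreenFormatError(f"duplicate cell line {dup!r}")
        keys = [t.key for t in self.targets]
        if len(set(keys)) != len(keys):
            dup = _first_duplicate(keys)
            raise ScreenFormatError(
                f"duplicate target (entrez={dup[0]}, suffix={dup[1] or None})"
            )
        if np.isinf(self.scores).any():
            raise ScreenFormatError("scores must be finite or missing (NaN)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.scores.shape

    @property
    def cell_line_names(self) -> list[str]:
        return [c.full for c in self.cell_lines]

    @property
    def tissues(self) -> list[str]:
        """Distinct tissue tokens, in first-appearance order."""
        seen: dict[str, None] = {}
        for c in self.cell_lines:
            seen.setdefault(c.tissue, None)
        return list(seen)

    def row(self, full_name: str) -> np.ndarray:
        return self.scores[self.cell_line_names.index(full_name)]

    def to_frame(self):
        """View as a pandas DataFrame (cell lines x target labels)."""
        import pandas as pd

        return pd.DataFrame(
            self.scores,
            index=self.cell_line_names,
            columns=[t.label for t in self.targets],
        )


def _first_duplicate(items: Iterable) -> object:
    seen: set = set()
    for it in items:
        if it in seen:
            return it
        seen.add(it)
    raise AssertionError("no duplicate present")


@dataclass(frozen=True)
class ValidationIssue:
    severity: Literal["error", "warning"]
    code: str
    message: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not any(i.severity == "error" for i in self.issues)

    def add(self, severity: Literal["error", "warning"], code: str, message: str) -> None:
        self.issues.append(ValidationIssue(severity, code, message))

    def __str__(self) -> str:
        lines = [f"ok: {self.ok}"]
        lines += [f"{i.severity.upper()} [{i.code}] {i.message}" for i in self.issues]
        return "\n".join(lines)


def read_rename_map(stream: IO[str] | str) -> dict[str, str]:
    """Read a two-column (raw_name, harmonized_full_name) alias table.

    Used to apply manual cell-line renames (e.g. ``H1299_LUNG`` ->
    ``NCIH1299_LUNG``) and to map COSMIC numeric IDs to CCLE-style names
    before harmonization.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    out: dict[str, str] = {}
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ScreenFormatError(
                f"rename map line {lineno}: expected 2 tab-separated fields"
            )
        out[parts[0]] = parts[1]
    return out


def parse_screen(
    stream: IO[str] | str,
    dataset_id: str,
    rename_map: Mapping[str, str] | None = None,
) -> ScreenMatrix:
    """Parse a tab-delimited screen file into a :class:`ScreenMatrix`.

    Parameters
    ----------
    stream:
        Open text stream or the file content itself.
    dataset_id:
        Name for the screen, stored on the matrix and in result records.
    rename_map:
        Optional raw-name -> full-name aliases applied to the first column
        before harmonization.

    Blank cells (and the tokens ``NA``/``NaN``) become missing values.
    Duplicate cell lines or (entrez, suffix) target pairs, non-numeric
    score cells and unparseable header labels raise
    :class:`ScreenFormatError` with the offending location.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    lines = stream.read().splitlines()
    if not lines:
        raise ScreenFormatError("empty screen file")
    header = lines[0].split("\t")
    targets: list[TargetLabel] = []
    for col, cell in enumerate(header[1:], start=2):
        try:
            targets.append(parse_target_label(cell))
        except ScreenFormatError as exc:
            raise ScreenFormatError(f"header column {col}: {exc}") from None

    cell_lines: list[CellLineName] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        raw_name = fields[0].strip()
        if rename_map and raw_name in rename_map:
            raw_name = rename_map[raw_name]
        cl = split_full_name(raw_name)
        if len(fields) - 1 != len(targets):
            raise ScreenFormatError(
                f"line {lineno} ({cl.full}): expected {len(targets)} scores, "
                f"found {len(fields) - 1}"
            )
        row: list[float] = []
        for col, cell in enumerate(fields[1:], start=2):
            cell = cell.strip()
            if cell in MISSING_TOKENS:
                row.append(np.nan)
                continue
            try:
                row.append(float(cell))
            except ValueError:
                raise ScreenFormatError(
                    f"non-numeric score {cell!r} at line {lineno}, column {col}"
                ) from None
        cell_lines.append(cl)
        rows.append(row)

    scores = (
        np.array(rows, dtype=float)
        if rows
        else np.empty((0, len(targets)), dtype=float)
    )
    return ScreenMatrix(cell_lines, targets, scores, dataset_id)


def _format_score(value: float) -> str:
    """Shortest decimal text that round-trips through float()."""
    if np.isnan(value):
        return ""
    if value == int(value) and abs(value) < 1e16:
        return str(int(value))
    return repr(float(value))


def write_screen(screen: ScreenMatrix, stream: IO[str]) -> None:
    """Write a screen in the tab-delimited dialect accepted by parse_screen.

    ``parse_screen(write_screen(x))`` reproduces *x* exactly: scores are
    written with round-trip-exact decimal text and missing values as empty
    cells.
    """
    stream.write("cell_line")
    for t in screen.targets:
        stream.write("\t" + t.label)
    stream.write("\n")
    for i, cl in enumerate(screen.cell_lines):
        stream.write(cl.full)
        for v in screen.scores[i]:
            stream.write("\t" + _format_score(v))
        stream.write("\n")


def validate_screen(screen: ScreenMatrix, min_cell_lines: int = 10) -> ValidationReport:
    """Check a parsed screen against the submission requirements.

    A panel smaller than *min_cell_lines* (default 10, the minimum panel
    size for inclusion) is an error.  All-missing and constant target
    columns produce warnings, as they can never yield a dependency.
    """
    report = ValidationReport()
    n = len(screen.cell_lines)
    if n < min_cell_lines:
        report.add(
            "error",
            "panel_too_small",
            f"screen has {n} cell lines; a minimum of {min_cell_lines} is required",
        )
    for j, t in enumerate(screen.targets):
        col = screen.scores[:, j]
        present = col[~np.isnan(col)]
        if present.size == 0:
            report.add("warning", "all_missing_column", f"target {t.label} has no scores")
        elif present.size > 1 and np.all(present == present[0]):
            report.add(
                "warning",
                "constant_column",
                f"target {t.label} has constant score {present[0]:g}",
            )
    return report


def zscore_normalize(
    screen: ScreenMatrix,
    axis: Literal["per_cell_line", "per_target"] = "per_cell_line",
) -> ScreenMatrix:
    """Standardize scores to mean 0, sample SD 1 along the chosen axis.

    ``per_cell_line`` standardizes each row (each cell line's score vector),
    making scores comparable between cell lines — the treatment applied to
    zGARP scores; ``per_target`` standardizes each column.  The sample
    standard deviation uses the n-1 denominator.  Missing entries are
    preserved.  A vector with fewer than two non-missing values or zero
    variance raises, naming the offending cell line or target.
    """
    if axis not in ("per_cell_line", "per_target"):
        raise ValueError(f"unknown axis {axis!r}")
    scores = screen.scores.copy()
    np_axis = 1 if axis == "per_cell_line" else 0
    labels = (
        screen.cell_line_names
        if axis == "per_cell_line"
        else [t.label for t in screen.targets]
    )
    n_ok = np.sum(~np.isnan(scores), axis=np_axis)
    with np.errstate(invalid="ignore"):
        sd = np.nanstd(scores, axis=np_axis, ddof=1)
    for i, label in enumerate(labels):
        if n_ok[i] < 2:
            raise ScreenFormatError(
                f"cannot z-normalize {label}: fewer than 2 scores present"
            )
        if sd[i] == 0:
            raise ScreenFormatError(f"cannot z-normalize {label}: zero variance")
    mean = np.nanmean(scores, axis=np_axis)
    if np_axis == 1:
        scores = (scores - mean[:, None]) / sd[:, None]
    else:
        scores = (scores - mean[None, :]) / sd[None, :]
    return ScreenMatrix(
        list(screen.cell_lines), list(screen.targets), scores, screen.dataset_id
    )
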