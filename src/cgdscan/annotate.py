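"""Annotate retained dependencies with functional-interaction, inhibitor
and cross-dataset evidence, plus gene-identifier resolution.

Functional interactions come from a STRING-style edge list of combined
confidence scores.  Only medium-confidence or better edges (score > 0.4)
are stored, tiered medium / high / highest at the conventional 0.4 / 0.7 /
0.9 cut-offs (configurable).  Drug-gene relationships come from a
DGIdb-style table; only "inhibitor" interactions are kept and two
mutation-targeted sources (MyCancerGenome and MyCancerGenomeClinicalTrial)
are excluded, since the interest is drugs that inhibit a gene product
rather than drugs indicated by a gene's mutation.  A dependency observed
(retained after filtering) in two or more independent datasets is flagged
as a Multiple Hit.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Literal, Mapping, Sequence

from .depstats import DependencyRecord
from .screen_io import ScreenFormatError

__all__ = [
    "InteractionSet",
    "InhibitorMap",
    "GeneIndex",
    "GeneEntry",
    "AmbiguousGeneError",
    "load_interactions",
    "annotate_string",
    "load_inhibitors",
    "annotate_inhibitors",
    "flag_multiple_hits",
    "resolve_gene",
    "export_network",
    "EXCLUDED_DRUG_SOURCES",
    "STRING_SCORE_MIN",
]

logger = logging.getLogger(__name__)

STRING_SCORE_MIN = 0.4
HIGH_CUT_DEFAULT = 0.7
HIGHEST_CUT_DEFAULT = 0.9
EXCLUDED_DRUG_SOURCES = frozenset({"MyCancerGenome", "MyCancerGenomeClinicalTrial"})

Tier = Literal["medium", "high", "highest"]


@dataclass
class InteractionSet:
    """Symmetric gene-gene functional interactions with confidence tiers.

    Edges are keyed on frozenset pairs of canonical identifiers (gene
    symbols after optional protein->gene mapping).  Every stored edge has
    combined score > 0.4; tiers partition (0.4, 1] with no gaps:
    medium (0.4, high_cut], high (high_cut, highest_cut],
    highest (highest_cut, 1].
    """

    scores: dict[frozenset[str], float] = field(default_factory=dict)
    high_cut: float = HIGH_CUT_DEFAULT
    highest_cut: float = HIGHEST_CUT_DEFAULT

    def tier_of_score(self, score: float) -> Tier:
        if score > self.highest_cut:
            return "highest"
        if score > self.high_cut:
            return "high"
        return "medium"

    def add(self, a: str, b: str, score: float) -> None:
        if a == b:
            return  # self-edges carry no annotation value
        if score <= STRING_SCORE_MIN:
            return
        key = frozenset((a, b))
        # keep the best score if the file lists both directions
        if score > self.scores.get(key, 0.0):
            self.scores[key] = score

    def lookup(self, a: str, b: str) -> tuple[float, Tier] | None:
        """Symmetric edge lookup; None when absent (including a == b)."""
        if a == b:
            return None
        score = self.scores.get(frozenset((a, b)))
        if score is None:
            return None
        return score, self.tier_of_score(score)

    def __len__(self) -> int:
        return len(self.scores)


def load_interactions(
    stream: IO[str] | str,
    score_scale: Literal["auto", "unit", "milli"] = "auto",
    protein_to_gene: Mapping[str, str] | None = None,
    high_cut: float = HIGH_CUT_DEFAULT,
    highest_cut: float = HIGHEST_CUT_DEFAULT,
) -> InteractionSet:
    """Load a STRING-like edge list (id1, id2, combined_score).

    The distributed STRING files use integer milli-scores 0-999; unit-scale
    fixtures use floats in [0, 1].  With ``score_scale="auto"`` the milli
    convention is detected when any score exceeds 1.  Declaring ``milli``
    for a file whose scores never exceed 1 is an error (the scale would be
    ambiguous).  Identifiers are passed through *protein_to_gene* when
    given, so STRING protein IDs can be mapped onto gene symbols.  Edges
    with unit score <= 0.4 and self-edges are discarded.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    rows: list[tuple[str, str, float]] = []
    for lineno, line in enumerate(stream, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if lineno == 1 and parts and parts[-1].lower() in ("combined_score", "score"):
            continue
        if len(parts) != 3:
            raise ScreenFormatError(
                f"interaction file line {lineno}: expected 3 fields, got {len(parts)}"
            )
        try:
            score = float(parts[2])
        except ValueError:
            raise ScreenFormatError(
                f"interaction file line {lineno}: non-numeric score {parts[2]!r}"
            ) from None
        rows.append((parts[0], parts[1], score))

    max_score = max((s for _, _, s in rows), default=0.0)
    if score_scale == "auto":
        scale = "milli" if max_score > 1 else "unit"
    else:
        scale = score_scale
    if scale == "milli" and max_score <= 1 and rows:
        raise ScreenFormatError(
            "score scale declared milli but no score exceeds 1; scale is ambiguous"
        )

    iset = InteractionSet(high_cut=high_cut, highest_cut=highest_cut)
    for a, b, score in rows:
        if scale == "milli":
            score /= 1000.0
        if protein_to_gene is not None:
            a = protein_to_gene.get(a, a)
            b = protein_to_gene.get(b, b)
        iset.add(a, b, score)
    return iset


def annotate_string(
    records: Iterable[DependencyRecord],
    interactions: InteractionSet,
    gene_index: "GeneIndex | None" = None,
) -> list[DependencyRecord]:
    """Set each record's string_tier from the driver-target edge, if any.

    Identifiers are the gene symbols; when a *gene_index* is supplied,
    symbols are first canonicalized through it so synonym spellings in the
    edge list still match.  Records are otherwise unchanged.
    """

    def canon(symbol: str) -> str:
        if gene_index is None:
            return symbol
        entry = gene_index.get(symbol)
        if entry is None:
            logger.warning("gene %s not resolvable in the gene index", symbol)
            return symbol
        return entry.symbol

    out = []
    for r in records:
        hit = interactions.lookup(canon(r.driver.symbol), canon(r.target.symbol))
        tier = hit[1] if hit is not None else "none"
        out.append(replace(r, string_tier=tier))
    return out


@dataclass
class InhibitorMap:
    """Per-gene inhibitor lists: gene symbol -> [(drug, source), ...]."""

    by_gene: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    def drugs_for(self, gene: str) -> tuple[str, ...]:
        return tuple(drug for drug, _ in self.by_gene.get(gene, []))

    def __len__(self) -> int:
        return sum(len(v) for v in self.by_gene.values())


def load_inhibitors(
    stream: IO[str] | str,
    excluded_sources: frozenset[str] | set[str] = EXCLUDED_DRUG_SOURCES,
) -> InhibitorMap:
    """Load a DGIdb-style drug-gene table (gene, drug, category, source).

    Keeps rows whose interaction category is ``inhibitor`` and whose source
    is not excluded; drugs are de-duplicated per gene case-insensitively
    (first spelling wins).
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    imap = InhibitorMap()
    seen: set[tuple[str, str]] = set()
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if lineno == 1 and parts[0].lower() in ("gene", "gene_symbol"):
            continue
        if len(parts) != 4:
            raise ScreenFormatError(
                f"drug-gene file line {lineno}: expected 4 fields, got {len(parts)}"
            )
        gene, drug, category, source = (p.strip() for p in parts)
        if category.lower() != "inhibitor":
            continue
        if source in excluded_sources:
            continue
        key = (gene, drug.lower())
        if key in seen:
            continue
        seen.add(key)
        imap.by_gene.setdefault(gene, []).append((drug, source))
    return imap


def annotate_inhibitors(
    records: Iterable[DependencyRecord], inhibitors: InhibitorMap
) -> list[DependencyRecord]:
    """Attach the available inhibitors of each record's target gene."""
    return [
        replace(r, inhibitors=inhibitors.drugs_for(r.target.symbol)) for r in records
    ]


def flag_multiple_hits(
    record_sets: Sequence[Sequence[DependencyRecord]],
) -> list[DependencyRecord]:
    """Merge per-dataset retained records, flagging cross-dataset pairs.

    A record is a Multiple Hit when its (driver entrez, target entrez) pair
    is retained in at least two distinct datasets, matching in any context
    and ignoring score-variant suffixes.  The flag is symmetric: every
    occurrence of such a pair is flagged.
    """
    dataset_ids = [
        {r.dataset_id for r in rs} for rs in record_sets
    ]
    flat_ids: list[str] = []
    for ids in dataset_ids:
        flat_ids.extend(ids)
    if len(flat_ids) != len(set(flat_ids)):
        raise ValueError("duplicate dataset_id across record sets")

    pair_datasets: dict[tuple[int, int], set[str]] = {}
    for rs in record_sets:
        for r in rs:
            pair_datasets.setdefault(r.pair_key, set()).add(r.dataset_id)

    merged: list[DependencyRecord] = []
    for rs in record_sets:
        for r in rs:
            merged.append(
                replace(r, multiple_hit=len(pair_datasets[r.pair_key]) >= 2)
            )
    return merged


@dataclass(frozen=True)
class GeneEntry:
    symbol: str
    entrez_id: int
    ensembl_gene: str = ""
    ensembl_protein: str = ""
    synonyms: frozenset[str] = frozenset()


class AmbiguousGeneError(LookupError):
    """A query symbol matches two or more distinct genes via synonyms."""

    def __init__(self, query: str, candidates: Sequence[str]):
        self.candidates = sorted(candidates)
        super().__init__(
            f"{query!r} is a synonym of multiple genes: {', '.join(self.candidates)}"
        )


class GeneIndex:
    """Multi-identifier gene lookup with case-insensitive synonym search.

    Primary symbols win over synonyms: a query that is both someone's
    primary symbol and another gene's synonym resolves to the primary.
    """

    def __init__(self, entries: Iterable[GeneEntry] = ()):
        self.entries: list[GeneEntry] = []
        self._by_symbol: dict[str, GeneEntry] = {}
        self._by_synonym: dict[str, list[GeneEntry]] = {}
        self._by_entrez: dict[int, GeneEntry] = {}
        for e in entries:
            self.add(e)

    def add(self, entry: GeneEntry) -> None:
        if entry.entrez_id in self._by_entrez:
            raise ValueError(f"duplicate entrez_id {entry.entrez_id}")
        self.entries.append(entry)
        self._by_entrez[entry.entrez_id] = entry
        self._by_symbol[entry.symbol.upper()] = entry
        for syn in entry.synonyms:
            self._by_synonym.setdefault(syn.upper(), []).append(entry)

    def get(self, query: str) -> GeneEntry | None:
        """Resolve a symbol or synonym; None if unknown.

        Raises :class:`AmbiguousGeneError` when the query matches several
        genes via synonyms and none as a primary symbol.
        """
        q = query.strip().upper()
        hit = self._by_symbol.get(q)
        if hit is not None:
            return hit
        candidates = self._by_synonym.get(q, [])
        if len(candidates) > 1:
            raise AmbiguousGeneError(query, [c.symbol for c in candidates])
        return candidates[0] if candidates else None

    def by_entrez(self, entrez_id: int) -> GeneEntry | None:
        return self._by_entrez.get(entrez_id)

    @classmethod
    def from_table(cls, stream: IO[str] | str) -> "GeneIndex":
        """Read a tab-delimited gene index.

        Columns: symbol, entrez, ensembl_gene, ensembl_protein,
        pipe-separated synonyms (HGNC-extract compatible).
        """
        if isinstance(stream, str):
            stream = io.StringIO(stream)
        idx = cls()
        for lineno, line in enumerate(stream, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0].lower() == "symbol":
                continue
            if len(parts) != 5:
                raise ScreenFormatError(
                    f"gene index line {lineno}: expected 5 fields, got {len(parts)}"
                )
            syns = frozenset(s for s in parts[4].split("|") if s)
            idx.add(
                GeneEntry(parts[0], int(parts[1]), parts[2], parts[3], syns)
            )
        return idx


def resolve_gene(query: str, index: GeneIndex) -> GeneEntry | None:
    """Case-insensitive gene lookup, primary symbols before synonyms."""
    return index.get(query)


def export_network(
    records: Sequence[DependencyRecord],
    interactions: InteractionSet,
    stream: IO[str],
) -> None:
    """Write one driver's dependency network as a static edge-list file.

    Nodes are the driver plus its retained targets; edges are the induced
    interactions among targets together with any driver-target edges.  The
    output has a node section and an edge section, both tab-delimited.
    """
    drivers = {r.driver for r in records}
    if len(drivers) > 1:
        raise ValueError("export_network expects records for a single driver")
    stream.write("#nodes\tsymbol\trole\n")
    targets: list[str] = []
    if drivers:
        (driver,) = drivers
        stream.write(f"node\t{driver.symbol}\tdriver\n")
        seen: set[str] = set()
        for r in records:
            if r.target.symbol not in seen:
                seen.add(r.target.symbol)
                targets.append(r.target.symbol)
        for t in targets:
            stream.write(f"node\t{t}\ttarget\n")
    stream.write("#edges\tsymbol_a\tsymbol_b\tscore\ttier\n")
    if drivers:
        nodes = [driver.symbol] + targets
        for i, a in enumerate(nodes):
            for b in nodes[i + 1 :]:
                hit = interactions.lookup(a, b)
                if hit is not None:
                    stream.write(f"edge\t{a}\t{b}\t{hit[0]:g}\t{hit[1]}\n")
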