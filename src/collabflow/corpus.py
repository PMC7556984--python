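"""Bibliographic corpus data model and I/O.

A corpus is a keyed collection of paper records, each carrying a
publication year, a deduplicated set of institutional affiliations, author
ids, referenced paper ids, and normalized topic tags.  This is the shape
of data exported from large bibliographic databases after affiliation
resolution; everything downstream (network projection, indices) consumes
these records only.

On-disk formats:

* corpus — JSON Lines, one object per paper with keys ``id``, ``year``,
  ``institutions``, ``authors``, ``references``, ``tags``;
* sector map — CSV with header ``institution,sector`` where sector is one
  of ``industrial``, ``academic``, ``unknown``;
* tag query — plain-text alias list, one alias per line, ``#`` comments.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from .errors import IntegrityError, ParseError, SchemaError, UnknownPaperError

logger = logging.getLogger(__name__)

#: Default calendar-year validity window for paper records.
DEFAULT_YEAR_WINDOW: tuple[int, int] = (1900, 2100)

#: Recognized sector labels for institutions.
SECTOR_LABELS = frozenset({"industrial", "academic", "unknown"})

_REQUIRED_KEYS = ("id", "year", "institutions", "authors", "references", "tags")


def normalize_tag(tag: str) -> str:
    """Normalize a topic tag: lowercase, trim, collapse internal whitespace.

    Matching of tags against query aliases is exact string equality on
    this normalized form; there is no substring matching.
    """
    return " ".join(tag.split()).lower()


@dataclass(frozen=True)
class PaperRecord:
    """One publication.

    ``institutions``, ``authors``, ``references`` and ``tags`` have set
    semantics: duplicates in the input are silently collapsed.  Tags are
    stored normalized (see :func:`normalize_tag`).  A paper may not
    reference itself.
    """

    paper_id: str
    year: int
    institutions: frozenset[str] = frozenset()
    authors: frozenset[str] = frozenset()
    references: frozenset[str] = frozenset()
    tags: frozenset[str] = frozenset()

    def __post_init__(self):
        if not self.paper_id:
            raise SchemaError("paper_id must be a non-empty string")
        object.__setattr__(self, "institutions", frozenset(self.institutions))
        object.__setattr__(self, "authors", frozenset(self.authors))
        object.__setattr__(self, "references", frozenset(self.references))
        object.__setattr__(
            self, "tags", frozenset(normalize_tag(t) for t in self.tags)
        )
        if self.paper_id in self.references:
            raise IntegrityError(
                f"paper {self.paper_id!r} references itself"
            )


class Corpus:
    """Keyed collection of :class:`PaperRecord` with dangling-reference
    bookkeeping.

    ``dangling_refs`` is the set of referenced paper ids that are not
    themselves keys of the corpus; these contribute nothing to citation
    pairs but are tracked so incomplete extractions are visible.
    Records with an empty institution set are retained (they contribute
    no network edges) and counted in :attr:`n_without_institutions`.
    """

    def __init__(
        self,
        records: Iterable[PaperRecord],
        year_window: tuple[int, int] = DEFAULT_YEAR_WINDOW,
    ):
        self.year_window = year_window
        papers: dict[str, PaperRecord] = {}
        lo, hi = year_window
        for rec in records:
            if rec.paper_id in papers:
                raise IntegrityError(f"duplicate paper id {rec.paper_id!r}")
            if not (lo <= rec.year <= hi):
                raise SchemaError(
                    f"paper {rec.paper_id!r}: year {rec.year} outside "
                    f"validity window [{lo}, {hi}]"
                )
            papers[rec.paper_id] = rec
        self._papers = papers
        all_refs: set[str] = set()
        for rec in papers.values():
            all_refs.update(rec.references)
        self.dangling_refs: frozenset[str] = frozenset(all_refs - papers.keys())
        self.n_without_institutions = sum(
            1 for rec in papers.values() if not rec.institutions
        )
        if self.n_without_institutions:
            logger.info(
                "corpus contains %d record(s) without institutional "
                "affiliations; they contribute no network edges",
                self.n_without_institutions,
            )

    @property
    def papers(self) -> Mapping[str, PaperRecord]:
        return self._papers

    def __len__(self) -> int:
        return len(self._papers)

    def __iter__(self) -> Iterator[PaperRecord]:
        return iter(self._papers.values())

    def __contains__(self, paper_id: str) -> bool:
        return paper_id in self._papers

    def __getitem__(self, paper_id: str) -> PaperRecord:
        try:
            return self._papers[paper_id]
        except KeyError:
            raise UnknownPaperError(paper_id) from None

    def __eq__(self, other) -> bool:
        if not isinstance(other, Corpus):
            return NotImplemented
        return self._papers == other._papers

    def ids(self) -> set[str]:
        return set(self._papers)


@dataclass(frozen=True)
class SectorMap:
    """Institution → sector lookup.

    Lookups of unmapped institutions return ``"unknown"`` rather than
    raising; affiliation data is never complete.
    """

    sector: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        bad = {v for v in self.sector.values()} - SECTOR_LABELS
        if bad:
            raise SchemaError(f"unrecognized sector label(s): {sorted(bad)}")

    def __getitem__(self, institution: str) -> str:
        return self.sector.get(institution, "unknown")

    def is_industrial(self, institution: str) -> bool:
        return self[institution] == "industrial"

    def industrial(self) -> frozenset[str]:
        """The set of corporate institutions."""
        return frozenset(
            i for i, s in self.sector.items() if s == "industrial"
        )


@dataclass(frozen=True)
class TagQuery:
    """A focal topic and its aliases, e.g. a gene symbol plus the synonym
    list curated from a gene database.  All aliases are stored normalized;
    the canonical name is itself an alias."""

    canonical_name: str
    aliases: frozenset[str]

    def __post_init__(self):
        object.__setattr__(
            self, "canonical_name", normalize_tag(self.canonical_name)
        )
        aliases = frozenset(normalize_tag(a) for a in self.aliases) | {
            self.canonical_name
        }
        if not aliases or aliases == {""}:
            raise SchemaError("empty tag query")
        object.__setattr__(self, "aliases", aliases - {""})


@dataclass(frozen=True)
class CitationPairs:
    """Directed citation events ``(citing_id, cited_id)`` collected for a
    core paper set.

    ``core_internal`` retains the pairs whose *both* endpoints lie in the
    core set (citations among the tagged papers themselves).  Because the
    field never states whether "additional relevant citations" counts
    events or citing papers, both counts are exposed.
    """

    pairs: frozenset[tuple[str, str]]
    core_internal: frozenset[tuple[str, str]]

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair) -> bool:
        return pair in self.pairs

    @property
    def n_events(self) -> int:
        """Number of (citing, cited) citation events."""
        return len(self.pairs)

    @property
    def n_citing_papers(self) -> int:
        """Number of distinct citing papers."""
        return len({citing for citing, _ in self.pairs})

    def citing_ids(self) -> set[str]:
        return {citing for citing, _ in self.pairs}


# ---------------------------------------------------------------------------
# I/O


def read_corpus(
    path: str | Path,
    year_window: tuple[int, int] = DEFAULT_YEAR_WINDOW,
) -> Corpus:
    """Read a JSON-Lines corpus file.

    One object per line with keys ``id``, ``year``, ``institutions``,
    ``authors``, ``references``, ``tags``.  Blank lines are ignored.
    Duplicate entries within a record's arrays are silently deduplicated;
    duplicate paper ids across records raise :class:`IntegrityError`.
    """
    records = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ParseError(lineno, f"invalid JSON ({exc.msg})") from exc
            if not isinstance(obj, dict):
                raise ParseError(lineno, "record is not a JSON object")
            missing = [k for k in _REQUIRED_KEYS if k not in obj]
            if missing:
                raise SchemaError(
                    f"line {lineno}: missing required field(s) {missing}"
                )
            if not isinstance(obj["year"], int) or isinstance(obj["year"], bool):
                raise SchemaError(f"line {lineno}: year must be an integer")
            records.append(
                PaperRecord(
                    paper_id=str(obj["id"]),
                    year=obj["year"],
                    institutions=frozenset(map(str, obj["institutions"])),
                    authors=frozenset(map(str, obj["authors"])),
                    references=frozenset(map(str, obj["references"])),
                    tags=frozenset(map(str, obj["tags"])),
                )
            )
    return Corpus(records, year_window=year_window)


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus as JSON Lines, sorted by paper id with sorted array
    fields, so identical corpora serialize byte-identically."""
    with open(path, "w", encoding="utf-8") as fh:
        for pid in sorted(corpus.papers):
            rec = corpus[pid]
            fh.write(
                json.dumps(
                    {
                        "id": rec.paper_id,
                        "year": rec.year,
                        "institutions": sorted(rec.institutions),
                        "authors": sorted(rec.authors),
                        "references": sorted(rec.references),
                        "tags": sorted(rec.tags),
                    },
                    sort_keys=True,
                )
                + "\n"
            )


def load_sector_map(path: str | Path) -> SectorMap:
    """Load an institution → sector CSV (header ``institution,sector``).

    Unrecognized labels raise :class:`SchemaError`; the same institution
    listed twice with conflicting labels raises :class:`IntegrityError`.
    """
    mapping: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [
            f.strip() for f in reader.fieldnames[:2]
        ] != ["institution", "sector"]:
            raise SchemaError(
                "sector map must have CSV header 'institution,sector'"
            )
        for row in reader:
            inst = (row["institution"] or "").strip()
            label = (row["sector"] or "").strip().lower()
            if not inst:
                continue
            if label not in SECTOR_LABELS:
                raise SchemaError(
                    f"unknown sector label {label!r} for {inst!r} "
                    f"(expected one of {sorted(SECTOR_LABELS)})"
                )
            if inst in mapping and mapping[inst] != label:
                raise IntegrityError(
                    f"institution {inst!r} mapped to both "
                    f"{mapping[inst]!r} and {label!r}"
                )
            mapping[inst] = label
    return SectorMap(mapping)


def write_sector_map(sectors: SectorMap, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["institution", "sector"])
        for inst in sorted(sectors.sector):
            writer.writerow([inst, sectors.sector[inst]])


def read_tag_query(path: str | Path) -> TagQuery:
    """Read a plain-text alias list: one alias per line, ``#`` starts a
    comment.  The first alias is taken as the canonical name."""
    aliases: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            text = line.split("#", 1)[0].strip()
            if text:
                aliases.append(text)
    if not aliases:
        raise SchemaError("empty tag query")
    return TagQuery(canonical_name=aliases[0], aliases=frozenset(aliases))


# ---------------------------------------------------------------------------
# Selection


def select_tagged(corpus: Corpus, query: TagQuery) -> set[str]:
    """Ids of papers whose tag set intersects the query's aliases.

    Matching is exact equality on normalized tags.  An empty result is
    valid (the topic simply does not occur in the corpus).
    """
    return {
        rec.paper_id for rec in corpus if rec.tags & query.aliases
    }


def collect_citations(corpus: Corpus, core_ids: set[str]) -> CitationPairs:
    """Every citation event ``(citing, cited)`` with the cited paper in
    ``core_ids`` and the citing paper anywhere in the corpus.

    Reference lists have set semantics, so a citing paper contributes at
    most one event per cited paper.  Pairs with both endpoints in the
    core are included and additionally retrievable via
    :attr:`CitationPairs.core_internal`.
    """
    unknown = core_ids - corpus.ids()
    if unknown:
        raise UnknownPaperError(
            f"core ids absent from corpus: {sorted(unknown)[:5]}"
        )
    pairs = set()
    internal = set()
    for rec in corpus:
        for cited in rec.references & core_ids:
            pairs.add((rec.paper_id, cited))
            if rec.paper_id in core_ids:
                internal.add((rec.paper_id, cited))
    return CitationPairs(frozenset(pairs), frozenset(internal))
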