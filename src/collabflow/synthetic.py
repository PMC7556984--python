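"""Synthetic bibliographic corpora with the statistical structure the
network analysis assumes.

Real institution-level publication data is heavily skewed: a small
number of institutions carry most of the collaboration weight, papers
span several institutions, and citations accrue preferentially to
already-cited work.  The generator reproduces those features from a
handful of interpretable knobs so every pipeline stage can be exercised,
at any scale, without any external download:

* institutional activity follows a Zipf-like law with exponent
  ``institution_activity_exponent`` (0 = uniform participation; larger
  values concentrate activity in a few institutions);
* references are drawn from strictly earlier papers with probability
  proportional to ``(1 + in-citations) ** citation_attachment_exponent``
  (0 = uniform over earlier papers; larger values yield rich-get-richer
  citation counts);
* each institution is labeled industrial independently with probability
  ``industrial_share``;
* a focal topic tag is planted on a configurable fraction of papers.

The generator makes no claim of fitting any real bibliographic database;
its contract is qualitative: planted concentration and industrial-share
parameters are recoverable from the built networks, monotonically.

A hand-sized three-paper fixture (:func:`fig1_corpus`) encodes the
canonical worked example: paper I (institutions a, b) cites papers II
(c, d, e) and III (c, d), giving collaboration weight 2 on {c, d} and
flow weights 2 from c/d to a/b and 1 from e to a/b.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .corpus import Corpus, PaperRecord, SectorMap
from .errors import SchemaError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IntSpec:
    """Bounded integer distribution on [lo, hi] with probability
    ∝ (k − lo + 1)^(−skew); skew 0 is uniform, larger skew favors the
    low end (most papers have few institutions, a tail has many)."""

    lo: int
    hi: int
    skew: float = 0.0

    def __post_init__(self):
        if self.lo < 0 or self.hi < self.lo:
            raise SchemaError(f"invalid integer range [{self.lo}, {self.hi}]")
        if self.skew < 0:
            raise SchemaError("skew must be non-negative")

    def pmf(self) -> np.ndarray:
        ranks = np.arange(1, self.hi - self.lo + 2, dtype=float)
        weights = ranks ** (-self.skew)
        return weights / weights.sum()

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        values = np.arange(self.lo, self.hi + 1)
        return rng.choice(values, size=size, p=self.pmf())


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic corpus generator.

    Defaults describe a mid-sized single-topic literature: a few hundred
    institutions with Zipf-concentrated activity (exponent 1.0), papers
    spanning 1–5 institutions, reference lists of up to 15 earlier
    papers with linear preferential attachment, one fifth of
    institutions corporate, and the focal tag on roughly a third of the
    papers.
    """

    n_institutions: int = 200
    industrial_share: float = 0.2
    n_papers: int = 1000
    year_range: tuple[int, int] = (2000, 2017)
    institutions_per_paper: IntSpec = IntSpec(1, 5, 1.0)
    authors_per_paper: IntSpec = IntSpec(1, 8, 0.5)
    institution_activity_exponent: float = 1.0
    citation_attachment_exponent: float = 1.0
    refs_per_paper: IntSpec = IntSpec(0, 15, 0.5)
    tag_fraction: float = 0.35
    focal_tag: str = "focal topic"
    author_pool: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.n_institutions < 1 or self.n_papers < 1:
            raise SchemaError("n_institutions and n_papers must be positive")
        for name in ("industrial_share", "tag_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SchemaError(f"{name} must lie in [0, 1]")
        for name in (
            "institution_activity_exponent",
            "citation_attachment_exponent",
        ):
            if getattr(self, name) < 0:
                raise SchemaError(f"{name} must be non-negative")
        y0, y1 = self.year_range
        if y0 > y1:
            raise SchemaError("year_range start must not exceed end")
        if self.author_pool < 1:
            raise SchemaError("author_pool must be positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "GeneratorConfig":
        """Read a flat ``key = value`` config file (``#`` comments).

        Triplet keys (``institutions_per_paper`` etc.) take
        ``lo,hi,skew``; ``year_range`` takes ``start,end``.
        """
        cfg = cls()
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                text = line.split("#", 1)[0].strip()
                if not text:
                    continue
                if "=" not in text:
                    raise SchemaError(
                        f"line {lineno}: expected 'key = value', got {text!r}"
                    )
                key, _, value = (s.strip() for s in text.partition("="))
                cfg = cfg.with_override(key, value)
        return cfg

    def with_override(self, key: str, value: str) -> "GeneratorConfig":
        """Apply one textual ``key=value`` override (the CLI hook)."""
        if key in ("n_institutions", "n_papers", "seed", "author_pool"):
            return replace(self, **{key: int(value)})
        if key in (
            "industrial_share",
            "tag_fraction",
            "institution_activity_exponent",
            "citation_attachment_exponent",
        ):
            return replace(self, **{key: float(value)})
        if key == "focal_tag":
            return replace(self, focal_tag=value)
        if key == "year_range":
            y0, y1 = (int(v) for v in value.split(","))
            return replace(self, year_range=(y0, y1))
        if key in (
            "institutions_per_paper",
            "authors_per_paper",
            "refs_per_paper",
        ):
            parts = value.split(",")
            lo, hi = int(parts[0]), int(parts[1])
            skew = float(parts[2]) if len(parts) > 2 else 0.0
            return replace(self, **{key: IntSpec(lo, hi, skew)})
        raise SchemaError(f"unknown generator config key {key!r}")


# ---------------------------------------------------------------------------
# The worked-example fixture


def fig1_corpus() -> Corpus:
    """The canonical three-paper toy corpus.

    Paper II (2003, institutions c, d, e) and paper III (2004,
    institutions c, d) carry the focal tag; paper I (2005, institutions
    a, b) cites both.  Author ids are distinct per institution and per
    paper, so author- and institution-level self-citation checks are
    exercised independently.
    """
    return Corpus(
        [
            PaperRecord(
                paper_id="II",
                year=2003,
                institutions=frozenset({"c", "d", "e"}),
                authors=frozenset({"c_auth1", "d_auth1", "e_auth1"}),
                references=frozenset(),
                tags=frozenset({"pcsk9", "narc-1"}),
            ),
            PaperRecord(
                paper_id="III",
                year=2004,
                institutions=frozenset({"c", "d"}),
                authors=frozenset({"c_auth2", "d_auth2"}),
                references=frozenset(),
                tags=frozenset({"pcsk9"}),
            ),
            PaperRecord(
                paper_id="I",
                year=2005,
                institutions=frozenset({"a", "b"}),
                authors=frozenset({"a_auth1", "b_auth1"}),
                references=frozenset({"II", "III"}),
                tags=frozenset(),
            ),
        ]
    )


# ---------------------------------------------------------------------------
# Random corpora


def sample_references(
    rng: np.random.Generator,
    citation_counts: np.ndarray,
    k: int,
    exponent: float,
) -> np.ndarray:
    """Draw ``k`` distinct reference targets from candidates with
    probability ∝ (1 + citations)^exponent.

    Uses the Gumbel-top-k trick: adding i.i.d. Gumbel noise to the log
    attachment weights and taking the k largest keys samples without
    replacement from the normalized weights.  With exponent 0 this is
    exactly uniform sampling.
    """
    m = len(citation_counts)
    if k >= m:
        return np.arange(m)
    keys = exponent * np.log1p(citation_counts) + rng.gumbel(size=m)
    return np.argpartition(keys, m - k)[m - k:]


def generate_corpus(cfg: GeneratorConfig) -> Corpus:
    """Generate a reproducible synthetic corpus.

    Years are uniform over ``year_range`` (records emitted in year
    order); institutions are drawn per paper, without replacement, from
    the Zipf-like activity law; authors are nested within the paper's
    institutions; references target strictly earlier papers under
    preferential attachment.  Infeasible reference requests (no earlier
    paper exists yet) are truncated and logged, never raised.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_papers
    y0, y1 = cfg.year_range

    width = max(4, len(str(n)))
    paper_ids = [f"p{k:0{width}d}" for k in range(n)]
    inst_ids = np.array(
        [f"inst{k:04d}" for k in range(cfg.n_institutions)], dtype=object
    )

    years = np.sort(rng.integers(y0, y1 + 1, size=n))

    activity = np.arange(1, cfg.n_institutions + 1, dtype=float) ** (
        -cfg.institution_activity_exponent
    )
    activity /= activity.sum()

    n_inst_draw = cfg.institutions_per_paper.sample(rng, n)
    n_auth_draw = cfg.authors_per_paper.sample(rng, n)
    n_refs_draw = cfg.refs_per_paper.sample(rng, n)
    tagged = rng.random(n) < cfg.tag_fraction

    # First index of each paper's own year in the year-sorted order:
    # everything before it was published strictly earlier.
    first_same_year = np.searchsorted(years, years, side="left")

    citation_counts = np.zeros(n)
    truncated = 0
    records = []
    for p in range(n):
        k_inst = min(int(n_inst_draw[p]), cfg.n_institutions)
        insts = (
            rng.choice(cfg.n_institutions, size=k_inst, replace=False, p=activity)
            if k_inst
            else np.empty(0, dtype=int)
        )
        inst_names = [str(inst_ids[i]) for i in insts]

        authors = set()
        if inst_names:
            hosts = rng.integers(len(inst_names), size=int(n_auth_draw[p]))
            members = rng.integers(cfg.author_pool, size=int(n_auth_draw[p]))
            authors = {
                f"{inst_names[h]}:a{m:03d}" for h, m in zip(hosts, members)
            }

        # Only strictly earlier YEARS are citable, keeping the annual
        # citation series causally ordered.
        m = int(first_same_year[p])
        want = int(n_refs_draw[p])
        if want > m:
            truncated += 1
        k_refs = min(want, m)
        refs: frozenset[str] = frozenset()
        if k_refs:
            chosen = sample_references(
                rng,
                citation_counts[:m],
                k_refs,
                cfg.citation_attachment_exponent,
            )
            citation_counts[chosen] += 1
            refs = frozenset(paper_ids[int(c)] for c in chosen)

        records.append(
            PaperRecord(
                paper_id=paper_ids[p],
                year=int(years[p]),
                institutions=frozenset(inst_names),
                authors=frozenset(authors),
                references=refs,
                tags=frozenset({cfg.focal_tag}) if tagged[p] else frozenset(),
            )
        )
    if truncated:
        logger.info(
            "truncated reference lists for %d paper(s) with no earlier "
            "papers available",
            truncated,
        )
    return Corpus(records)


def generate_sector_map(cfg: GeneratorConfig) -> SectorMap:
    """Sector labels for the generator's institutions: industrial with
    probability ``industrial_share``, academic otherwise.

    Drawn from a substream independent of the corpus draws, so the map
    depends only on ``seed``, ``n_institutions`` and
    ``industrial_share`` — the corpus itself is identical across
    industrial-share settings at a fixed seed.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    industrial = rng.random(cfg.n_institutions) < cfg.industrial_share
    return SectorMap(
        {
            f"inst{k:04d}": ("industrial" if industrial[k] else "academic")
            for k in range(cfg.n_institutions)
        }
    )
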