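"""Taxonomic incongruence screening of BLAST best hits.

A plant (self-clade) query whose best protein hit is fungal, animal, or
protist is *incongruent* and must be explained as contamination, horizontal
gene transfer, or genuine orthology.  The first, alignment-level part of that
decision is made here from percent identity and query coverage of the best
hit:

* best hit inside the self clade -> ``self`` (no incongruence);
* identity at or above ~98% -> ``evident_contamination`` (an essentially
  identical foreign sequence cannot be an old transfer or an ortholog);
* identity *and* coverage both above 90% -> ``likely_contamination``;
* anything weaker -> ``candidate_foreign``, to be resolved by tree placement.

The module also implements the neighborhood screen: given accessions that
follow a sequential numbering scheme, take a window of +/-w accessions around
each flagged hit and tally what their best hits are — the quick test for
whether an assembly carries contamination beyond the sequences that triggered
the search.
"""

from __future__ import annotations

import csv
import enum
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "DEFAULT_BLAST_COLUMNS",
    "BlastRow",
    "Category",
    "TaxonomyMap",
    "Thresholds",
    "HitClassification",
    "QueryScreen",
    "ScreenReport",
    "Tallies",
    "BlastFormatError",
    "parse_blast_tab",
    "best_hit_per_query",
    "classify_best_hit",
    "window_neighbors",
    "screen_queries",
    "tally_report",
]

DEFAULT_BLAST_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()

_OPTIONAL_COLUMNS = {"qcovs", "ssciname"}


class BlastFormatError(ValueError):
    pass


@dataclass
class BlastRow:
    """One tabular (outfmt-6 style) alignment row."""

    qseqid: str
    sseqid: str
    pident: float
    length: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    qcov: float | None = None
    subject_species: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.pident <= 100:
            raise ValueError(f"pident out of range: {self.pident}")
        if self.evalue < 0:
            raise ValueError(f"negative evalue: {self.evalue}")
        if self.qstart > self.qend:
            raise ValueError(f"qstart > qend for {self.qseqid}")


class Category(str, enum.Enum):
    self_clade = "self_clade"
    fungi = "fungi"
    oomycota = "oomycota"
    animal = "animal"
    protist = "protist"
    other = "other"


@dataclass
class TaxonomyMap:
    """Species -> taxonomic group -> screening category.

    Species lookups are case-insensitive; unmapped species fall into
    ``other`` (a warning, not an error — real best-hit tables contain
    species the map does not know).
    """

    species_to_group: dict[str, str]
    group_to_category: dict[str, Category]
    self_clade_name: str = "Streptophyta"

    def __post_init__(self) -> None:
        self.species_to_group = {
            k.strip().lower(): v for k, v in self.species_to_group.items()
        }
        self.group_to_category = {
            k: Category(v) for k, v in self.group_to_category.items()
        }

    def group_for(self, species: str | None) -> str | None:
        if species is None:
            return None
        return self.species_to_group.get(species.strip().lower())

    def category_for(self, species: str | None) -> Category:
        group = self.group_for(species)
        if group is None:
            return Category.other
        return self.group_to_category.get(group, Category.other)

    @classmethod
    def from_tsv(cls, path: str | Path, self_clade_name: str = "Streptophyta") -> "TaxonomyMap":
        """Read a species<TAB>group<TAB>category table."""
        s2g: dict[str, str] = {}
        g2c: dict[str, Category] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 3:
                    raise BlastFormatError(f"{path}: expected 3 columns, got {len(parts)}")
                species, group, cat = parts
                s2g[species] = group
                g2c[group] = Category(cat)
        return cls(s2g, g2c, self_clade_name)


@dataclass(frozen=True)
class Thresholds:
    """Identity/coverage thresholds (percent).

    ``evident_identity``: identity at which contamination is evident on its
    own.  ``dual_rule``: identity *and* coverage must strictly exceed this for
    ``likely_contamination`` (and for dual-rule tallies).  ``strong_dual``:
    the stricter dual bound reported alongside.
    """

    evident_identity: float = 98.0
    dual_rule: float = 90.0
    strong_dual: float = 97.0

    def __post_init__(self) -> None:
        if not 0 < self.dual_rule <= self.strong_dual <= self.evident_identity <= 100:
            raise ValueError(
                "require 0 < dual_rule <= strong_dual <= evident_identity <= 100"
            )


class HitClassification(str, enum.Enum):
    self = "self"
    evident_contamination = "evident_contamination"
    likely_contamination = "likely_contamination"
    candidate_foreign = "candidate_foreign"
    no_hit = "no_hit"


def parse_blast_tab(
    path: str | Path, dialect: list[str] | None = None
) -> list[BlastRow]:
    """Parse BLAST tabular output.

    ``dialect`` is the ordered column list; default is the standard 12-column
    outfmt-6 layout.  ``qcovs`` and ``ssciname`` may be appended and populate
    ``qcov`` / ``subject_species``.
    """
    cols = list(dialect) if dialect else list(DEFAULT_BLAST_COLUMNS)
    unknown = set(cols) - set(DEFAULT_BLAST_COLUMNS) - _OPTIONAL_COLUMNS
    if unknown:
        raise ValueError(f"unknown blast columns: {sorted(unknown)}")
    rows: list[BlastRow] = []
    with open(path) as fh:
        for lineno, parts in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not parts or (len(parts) == 1 and not parts[0].strip()):
                continue
            if parts[0].startswith("#"):
                continue
            if len(parts) != len(cols):
                raise BlastFormatError(
                    f"{path}:{lineno}: expected {len(cols)} columns, got {len(parts)}"
                )
            d = dict(zip(cols, parts))
            try:
                rows.append(
                    BlastRow(
                        qseqid=d["qseqid"],
                        sseqid=d["sseqid"],
                        pident=float(d["pident"]),
                        length=int(d["length"]),
                        mismatch=int(d["mismatch"]),
                        gapopen=int(d["gapopen"]),
                        qstart=int(d["qstart"]),
                        qend=int(d["qend"]),
                        sstart=int(d["sstart"]),
                        send=int(d["send"]),
                        evalue=float(d["evalue"]),
                        bitscore=float(d["bitscore"]),
                        qcov=float(d["qcovs"]) if "qcovs" in d else None,
                        subject_species=d.get("ssciname"),
                    )
                )
            except ValueError as exc:
                raise BlastFormatError(f"{path}:{lineno}: {exc}") from exc
    return rows


def best_hit_per_query(rows: list[BlastRow]) -> dict[str, BlastRow]:
    """Single winning row per query.

    Maximal bitscore; ties broken by larger pident, then lexicographically
    smallest sseqid.
    """
    best: dict[str, BlastRow] = {}
    for row in rows:
        cur = best.get(row.qseqid)
        if cur is None:
            best[row.qseqid] = row
            continue
        if (row.bitscore, row.pident, _neg_str(row.sseqid)) > (
            cur.bitscore,
            cur.pident,
            _neg_str(cur.sseqid),
        ):
            best[row.qseqid] = row
    return best


class _neg_str(str):
    """Reverses string comparison so 'smallest sseqid' wins a max()-style tie."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def resolve_qcov(row: BlastRow, qlen: dict[str, int] | None = None) -> float:
    """Query coverage percent; computed from qlen when absent in the table."""
    if row.qcov is not None:
        return row.qcov
    if qlen and row.qseqid in qlen:
        return 100.0 * (row.qend - row.qstart + 1) / qlen[row.qseqid]
    raise ValueError(
        f"query {row.qseqid!r}: no qcovs column and no query length available"
    )


def classify_best_hit(
    best: BlastRow | None,
    tax: TaxonomyMap,
    th: Thresholds = Thresholds(),
    qlen: dict[str, int] | None = None,
) -> HitClassification:
    """Contamination-status call for one query's best hit.

    Self-clade hits are ``self``; otherwise identity >= ``evident_identity``
    is ``evident_contamination``; otherwise identity and coverage both
    strictly above ``dual_rule`` is ``likely_contamination``; anything else
    is ``candidate_foreign`` (to be adjudicated phylogenetically).
    """
    if best is None:
        return HitClassification.no_hit
    if tax.category_for(best.subject_species) is Category.self_clade:
        return HitClassification.self
    if best.pident >= th.evident_identity:
        return HitClassification.evident_contamination
    qcov = resolve_qcov(best, qlen)
    if best.pident > th.dual_rule and qcov > th.dual_rule:
        return HitClassification.likely_contamination
    return HitClassification.candidate_foreign


_ACC_RE = re.compile(r"^(.*?)(\d+)$")


def window_neighbors(
    accessions: list[str], flagged: list[str], w: int = 5
) -> list[str]:
    """Accessions within +/-``w`` of each flagged id, in the numeric scheme.

    All accessions must share one prefix and zero-padding width.  Neighbors
    outside the known accession set are dropped; the union over flagged ids
    is returned ascending, deduplicated, and includes the flagged ids.
    """
    parsed: dict[str, tuple[str, int, int]] = {}
    for acc in accessions:
        m = _ACC_RE.match(acc)
        if not m:
            raise ValueError(f"accession {acc!r} has no numeric suffix")
        parsed[acc] = (m.group(1), int(m.group(2)), len(m.group(2)))
    prefixes = {p for p, _, _ in parsed.values()}
    widths = {wd for _, _, wd in parsed.values()}
    if len(prefixes) > 1 or len(widths) > 1:
        raise ValueError(
            f"mixed accession schemes: prefixes={sorted(prefixes)} widths={sorted(widths)}"
        )
    by_number = {n: acc for acc, (_, n, _) in parsed.items()}
    out: set[int] = set()
    for f in flagged:
        if f not in parsed:
            m = _ACC_RE.match(f)
            if not m or m.group(1) not in prefixes or len(m.group(2)) not in widths:
                raise ValueError(f"flagged id {f!r} does not match the accession scheme")
            n = int(m.group(2))
        else:
            n = parsed[f][1]
        for k in range(n - w, n + w + 1):
            if k in by_number:
                out.add(k)
    return [by_number[n] for n in sorted(out)]


@dataclass
class QueryScreen:
    qseqid: str
    best: BlastRow | None
    group: str | None
    category: Category | None
    classification: HitClassification
    qcov: float | None = None


@dataclass
class ScreenReport:
    records: list[QueryScreen] = field(default_factory=list)

    def with_hits(self) -> list[QueryScreen]:
        return [r for r in self.records if r.best is not None]


def screen_queries(
    best_hits: dict[str, BlastRow],
    tax: TaxonomyMap,
    th: Thresholds = Thresholds(),
    qlen: dict[str, int] | None = None,
    all_queries: list[str] | None = None,
) -> ScreenReport:
    """Classify every query's best hit; hitless queries are kept as ``no_hit``."""
    queries = list(all_queries) if all_queries is not None else sorted(best_hits)
    records = []
    for q in queries:
        best = best_hits.get(q)
        if best is None:
            records.append(QueryScreen(q, None, None, None, HitClassification.no_hit))
            continue
        records.append(
            QueryScreen(
                qseqid=q,
                best=best,
                group=tax.group_for(best.subject_species),
                category=tax.category_for(best.subject_species),
                classification=classify_best_hit(best, tax, th, qlen),
                qcov=resolve_qcov(best, qlen),
            )
        )
    return ScreenReport(records)


@dataclass
class Tallies:
    """Category and dual-rule counts over the queries that had hits."""

    n_queries: int
    n_with_hits: int
    by_category: dict[Category, int]
    dual_count: int
    dual_by_category: dict[Category, int]
    strong_dual_count: int
    dual_by_species: dict[str, int]

    @property
    def collapsed(self) -> dict[str, int]:
        """Self / fungi / oomycota / other summary (animal+protist fold into other)."""
        out = {"self": 0, "fungi": 0, "oomycota": 0, "other": 0}
        for cat, n in self.by_category.items():
            if cat is Category.self_clade:
                out["self"] += n
            elif cat is Category.fungi:
                out["fungi"] += n
            elif cat is Category.oomycota:
                out["oomycota"] += n
            else:
                out["other"] += n
        return out


def tally_report(report: ScreenReport, th: Thresholds = Thresholds()) -> Tallies:
    """Table-style tallies: best hits per category, dual-rule counts.

    The dual-rule set is the non-self queries whose best hit has identity and
    coverage both strictly above ``th.dual_rule``; ``strong_dual_count`` uses
    ``th.strong_dual`` the same way.  Hitless queries are excluded from every
    denominator.
    """
    by_cat: Counter = Counter()
    dual_by_cat: Counter = Counter()
    dual_by_species: Counter = Counter()
    dual = strong = 0
    withhits = report.with_hits()
    for rec in withhits:
        by_cat[rec.category] += 1
        if rec.category is Category.self_clade:
            continue
        assert rec.best is not None
        qcov = rec.qcov if rec.qcov is not None else rec.best.qcov
        if qcov is None:
            continue
        if rec.best.pident > th.dual_rule and qcov > th.dual_rule:
            dual += 1
            dual_by_cat[rec.category] += 1
            if rec.best.subject_species:
                dual_by_species[rec.best.subject_species] += 1
        if rec.best.pident > th.strong_dual and qcov > th.strong_dual:
            strong += 1
    return Tallies(
        n_queries=len(report.records),
        n_with_hits=len(withhits),
        by_category=dict(by_cat),
        dual_count=dual,
        dual_by_category=dict(dual_by_cat),
        strong_dual_count=strong,
        dual_by_species=dict(dual_by_species),
    )
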