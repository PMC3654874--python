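"""Local knowledge store of genomic regions and region groups.

The store standardizes three concepts commonly used when collapsing
variants by biological feature:

* a *position* — a single 1-based genomic coordinate (supplied at query
  time, e.g. a variant locus);
* a *region* — a labelled segment ``[start, stop]`` such as a gene, exon
  or conserved element;
* a *group* — a named collection of regions, e.g. a pathway over genes.

Everything lives in a single SQLite file (or an in-memory database with
the identical contract), so no server or network connection is needed.
Coordinates are stored 1-based and inclusive on both ends; BED input
(0-based, half-open) is converted on load.  Strand is ignored: bin
construction is purely positional.
"""

from __future__ import annotations

import logging
import sqlite3
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

REGION_TYPES = ("gene", "exon", "intron", "regulatory", "ECR", "other")

SCHEMA_VERSION = "1"

_SCHEMA = """
CREATE TABLE IF NOT EXISTS meta (key TEXT PRIMARY KEY, value TEXT);
CREATE TABLE IF NOT EXISTS region (
    region_id INTEGER PRIMARY KEY,
    label TEXT NOT NULL,
    chromosome TEXT NOT NULL,
    start INTEGER NOT NULL,
    stop INTEGER NOT NULL,
    region_type TEXT NOT NULL,
    source TEXT NOT NULL,
    UNIQUE (source, label, region_type)
);
CREATE INDEX IF NOT EXISTS region_pos ON region (chromosome, start, stop);
CREATE TABLE IF NOT EXISTS grp (
    group_id INTEGER PRIMARY KEY,
    label TEXT NOT NULL,
    source TEXT NOT NULL,
    UNIQUE (source, label)
);
CREATE TABLE IF NOT EXISTS grp_member (
    group_id INTEGER NOT NULL REFERENCES grp (group_id) ON DELETE CASCADE,
    region_id INTEGER NOT NULL REFERENCES region (region_id),
    PRIMARY KEY (group_id, region_id)
);
"""


class KnowledgeError(Exception):
    """Raised for malformed knowledge input or missing records."""


@dataclass(frozen=True)
class Region:
    region_id: int
    label: str
    chromosome: str
    start: int
    stop: int
    region_type: str
    source: str = "user"


@dataclass(frozen=True)
class Group:
    group_id: int
    label: str
    source: str
    members: frozenset  # of region_id


@dataclass(frozen=True)
class RejectedRow:
    line_number: int
    reason: str
    text: str


class KnowledgeBase:
    """SQLite-backed store of regions and groups.

    Use :meth:`create` to build a new single-file store, :meth:`open` to
    attach to an existing one, or :meth:`in_memory` for a throwaway store
    with the same contract.
    """

    def __init__(self, conn: sqlite3.Connection):
        self._conn = conn
        self._conn.execute("PRAGMA foreign_keys = ON")

    # -- construction ------------------------------------------------------

    @classmethod
    def create(cls, path, genome_build: str = "unspecified",
               overwrite: bool = False) -> "KnowledgeBase":
        path = Path(path)
        if path.exists():
            if not overwrite:
                raise KnowledgeError(
                    f"knowledge store {path} already exists (pass overwrite/--force)")
            path.unlink()
        conn = sqlite3.connect(path)
        kb = cls(conn)
        kb._init_schema(genome_build)
        return kb

    @classmethod
    def open(cls, path) -> "KnowledgeBase":
        path = Path(path)
        if not path.exists():
            raise KnowledgeError(f"knowledge store {path} does not exist")
        return cls(sqlite3.connect(path))

    @classmethod
    def in_memory(cls, genome_build: str = "unspecified") -> "KnowledgeBase":
        kb = cls(sqlite3.connect(":memory:"))
        kb._init_schema(genome_build)
        return kb

    def _init_schema(self, genome_build: str) -> None:
        with self._conn:
            self._conn.executescript(_SCHEMA)
            self._conn.execute(
                "INSERT OR REPLACE INTO meta VALUES ('schema_version', ?)",
                (SCHEMA_VERSION,))
            self._conn.execute(
                "INSERT OR REPLACE INTO meta VALUES ('genome_build', ?)",
                (genome_build,))

    def close(self) -> None:
        self._conn.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()

    # -- metadata ----------------------------------------------------------

    @property
    def genome_build(self) -> str:
        row = self._conn.execute(
            "SELECT value FROM meta WHERE key = 'genome_build'").fetchone()
        return row[0] if row else "unspecified"

    @property
    def sources(self) -> list:
        rows = self._conn.execute(
            "SELECT DISTINCT source FROM region "
            "UNION SELECT DISTINCT source FROM grp").fetchall()
        return sorted(r[0] for r in rows)

    # -- loading -----------------------------------------------------------

    def load_regions(self, path, region_type: str | None = "gene",
                     dialect: str = "tsv1", source: str = "user") -> int:
        """Load a region table; returns the number of regions newly stored.

        ``dialect`` selects the coordinate convention explicitly (never
        sniffed): ``"tsv1"`` is 1-based inclusive columns
        ``chrom  start  stop  label  [type]``; ``"bed"`` is standard
        0-based half-open BED with the name in column 4.

        ``region_type`` stamps every row; pass ``None`` with the tsv1
        dialect to take the per-row type column instead.  Malformed rows
        and rows with start > stop are rejected and reported (see
        :meth:`last_rejected_rows`); the remaining rows still load.
        Duplicate (source, label, type, coordinates) rows collapse to one
        record; a conflicting reuse of (source, label, type) with
        different coordinates is rejected.
        """
        if dialect not in ("tsv1", "bed"):
            raise KnowledgeError(f"unknown region dialect {dialect!r}")
        if region_type is not None and region_type not in REGION_TYPES:
            raise KnowledgeError(f"unknown region type {region_type!r}")
        rejected: list[RejectedRow] = []
        added = 0
        with self._conn:
            for lineno, line in enumerate(Path(path).open(), start=1):
                line = line.rstrip("\n")
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                try:
                    rec = self._parse_region_row(line, dialect, region_type)
                except KnowledgeError as exc:
                    rejected.append(RejectedRow(lineno, str(exc), line))
                    continue
                chrom, start, stop, label, rtype = rec
                existing = self._conn.execute(
                    "SELECT chromosome, start, stop FROM region "
                    "WHERE source=? AND label=? AND region_type=?",
                    (source, label, rtype)).fetchone()
                if existing is not None:
                    if tuple(existing) != (chrom, start, stop):
                        rejected.append(RejectedRow(
                            lineno,
                            f"label {label!r} ({rtype}) already stored with "
                            f"different coordinates", line))
                    continue  # identical duplicate: idempotent
                self._conn.execute(
                    "INSERT INTO region (label, chromosome, start, stop, "
                    "region_type, source) VALUES (?,?,?,?,?,?)",
                    (label, chrom, start, stop, rtype, source))
                added += 1
        self._last_rejected = rejected
        for row in rejected:
            logger.warning("rejected region row %d: %s", row.line_number, row.reason)
        return added

    @staticmethod
    def _parse_region_row(line: str, dialect: str,
                          region_type: str | None) -> tuple:
        fields = line.split("\t")
        if len(fields) < (4 if dialect == "tsv1" else 4):
            raise KnowledgeError(f"expected >=4 tab-separated columns, got {len(fields)}")
        chrom = fields[0].strip()
        if not chrom:
            raise KnowledgeError("empty chromosome")
        try:
            start, stop = int(fields[1]), int(fields[2])
        except ValueError:
            raise KnowledgeError(f"unparseable coordinates {fields[1]!r}/{fields[2]!r}")
        if dialect == "bed":
            start += 1  # 0-based half-open -> 1-based inclusive
        label = fields[3].strip()
        if not label:
            raise KnowledgeError("empty label")
        if region_type is None:
            if dialect == "bed" or len(fields) < 5:
                raise KnowledgeError("no region type given and none in row")
            rtype = fields[4].strip()
        else:
            rtype = region_type
        if rtype not in REGION_TYPES:
            raise KnowledgeError(f"unknown region type {rtype!r}")
        if start < 1:
            raise KnowledgeError(f"start {start} < 1")
        if start > stop:
            raise KnowledgeError(f"start {start} > stop {stop}")
        return chrom, start, stop, label, rtype

    def last_rejected_rows(self) -> Sequence[RejectedRow]:
        return tuple(getattr(self, "_last_rejected", ()))

    def load_groups(self, path, source: str = "user") -> int:
        """Load a GMT gene-set file; returns the number of groups stored.

        Each line is ``group<TAB>description<TAB>member...``.  Member
        labels resolve against stored *gene* regions; unresolvable labels
        are logged and skipped, and a group with no resolvable member is
        not stored.  Re-loading a group label from the same source
        replaces the previous definition (with a warning).
        """
        added = 0
        any_line = False
        with self._conn:
            for lineno, line in enumerate(Path(path).open(), start=1):
                line = line.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                any_line = True
                fields = line.split("\t")
                if len(fields) < 3:
                    logger.warning(
                        "group line %d: expected >=3 columns, skipped", lineno)
                    continue
                label = fields[0].strip()
                member_labels = [f.strip() for f in fields[2:] if f.strip()]
                member_ids = []
                for ml in member_labels:
                    row = self._conn.execute(
                        "SELECT region_id FROM region WHERE label=? AND "
                        "region_type='gene'", (ml,)).fetchone()
                    if row is None:
                        logger.warning(
                            "group %s line %d: member %r does not resolve "
                            "to a gene region, skipped", label, lineno, ml)
                    else:
                        member_ids.append(row[0])
                if not member_ids:
                    logger.warning(
                        "group %s line %d: no members resolved, group not "
                        "stored", label, lineno)
                    continue
                old = self._conn.execute(
                    "SELECT group_id FROM grp WHERE source=? AND label=?",
                    (source, label)).fetchone()
                if old is not None:
                    logger.warning(
                        "group %s from source %s replaced", label, source)
                    self._conn.execute(
                        "DELETE FROM grp WHERE group_id=?", (old[0],))
                cur = self._conn.execute(
                    "INSERT INTO grp (label, source) VALUES (?,?)",
                    (label, source))
                gid = cur.lastrowid
                self._conn.executemany(
                    "INSERT OR IGNORE INTO grp_member VALUES (?,?)",
                    [(gid, rid) for rid in member_ids])
                added += 1
        if not any_line:
            logger.warning("group file %s is empty; zero groups loaded", path)
        return added

    # -- queries -----------------------------------------------------------

    def regions_containing(self, chromosome: str, position: int,
                           region_type: str | None = None) -> list:
        """All regions whose inclusive span [start, stop] contains *position*."""
        sql = ("SELECT region_id, label, chromosome, start, stop, region_type, "
               "source FROM region WHERE chromosome=? AND start<=? AND stop>=?")
        args: list = [chromosome, position, position]
        if region_type is not None:
            sql += " AND region_type=?"
            args.append(region_type)
        sql += " ORDER BY start, stop, label"
        return [Region(*row) for row in self._conn.execute(sql, args)]

    def regions_overlapping(self, chromosome: str, start: int, stop: int,
                            region_type: str | None = None) -> list:
        sql = ("SELECT region_id, label, chromosome, start, stop, region_type, "
               "source FROM region WHERE chromosome=? AND start<=? AND stop>=?")
        args: list = [chromosome, stop, start]
        if region_type is not None:
            sql += " AND region_type=?"
            args.append(region_type)
        sql += " ORDER BY start, stop, label"
        return [Region(*row) for row in self._conn.execute(sql, args)]

    def groups_of(self, region_id: int) -> list:
        """All groups whose member set contains *region_id*."""
        if self._conn.execute("SELECT 1 FROM region WHERE region_id=?",
                              (region_id,)).fetchone() is None:
            raise KnowledgeError(f"unknown region_id {region_id}")
        gids = [r[0] for r in self._conn.execute(
            "SELECT group_id FROM grp_member WHERE region_id=? ORDER BY group_id",
            (region_id,))]
        return [self._group(gid) for gid in gids]

    def _group(self, group_id: int) -> Group:
        row = self._conn.execute(
            "SELECT group_id, label, source FROM grp WHERE group_id=?",
            (group_id,)).fetchone()
        if row is None:
            raise KnowledgeError(f"unknown group_id {group_id}")
        members = frozenset(r[0] for r in self._conn.execute(
            "SELECT region_id FROM grp_member WHERE group_id=?", (group_id,)))
        return Group(row[0], row[1], row[2], members)

    def region(self, region_id: int) -> Region:
        row = self._conn.execute(
            "SELECT region_id, label, chromosome, start, stop, region_type, "
            "source FROM region WHERE region_id=?", (region_id,)).fetchone()
        if row is None:
            raise KnowledgeError(f"unknown region_id {region_id}")
        return Region(*row)

    def region_by_label(self, label: str,
                        region_type: str = "gene") -> Region:
        row = self._conn.execute(
            "SELECT region_id, label, chromosome, start, stop, region_type, "
            "source FROM region WHERE label=? AND region_type=?",
            (label, region_type)).fetchone()
        if row is None:
            raise KnowledgeError(f"no {region_type} region labelled {label!r}")
        return Region(*row)

    def regions(self, region_type: str | None = None) -> list:
        sql = ("SELECT region_id, label, chromosome, start, stop, region_type, "
               "source FROM region")
        args: tuple = ()
        if region_type is not None:
            sql += " WHERE region_type=?"
            args = (region_type,)
        sql += " ORDER BY chromosome, start, stop, label"
        return [Region(*row) for row in self._conn.execute(sql, args)]

    def groups(self) -> list:
        gids = [r[0] for r in self._conn.execute(
            "SELECT group_id FROM grp ORDER BY group_id")]
        return [self._group(gid) for gid in gids]

    def n_regions(self, region_type: str | None = None) -> int:
        return len(self.regions(region_type))

    def n_groups(self) -> int:
        row = self._conn.execute("SELECT COUNT(*) FROM grp").fetchone()
        return row[0]

    # -- direct insertion (used by fixture generators) ---------------------

    def add_region(self, label: str, chromosome: str, start: int, stop: int,
                   region_type: str = "gene", source: str = "user") -> Region:
        if start > stop:
            raise KnowledgeError(f"start {start} > stop {stop}")
        if region_type not in REGION_TYPES:
            raise KnowledgeError(f"unknown region type {region_type!r}")
        with self._conn:
            cur = self._conn.execute(
                "INSERT INTO region (label, chromosome, start, stop, "
                "region_type, source) VALUES (?,?,?,?,?,?)",
                (label, chromosome, start, stop, region_type, source))
        return self.region(cur.lastrowid)

    def add_group(self, label: str, member_region_ids: Iterable[int],
                  source: str = "user") -> Group:
        members = list(member_region_ids)
        if not members:
            raise KnowledgeError("a group needs at least one member")
        for rid in members:
            self.region(rid)  # raises on dangling member
        with self._conn:
            cur = self._conn.execute(
                "INSERT INTO grp (label, source) VALUES (?,?)", (label, source))
            gid = cur.lastrowid
            self._conn.executemany(
                "INSERT OR IGNORE INTO grp_member VALUES (?,?)",
                [(gid, rid) for rid in members])
        return self._group(gid)
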