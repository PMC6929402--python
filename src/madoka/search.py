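"""One-against-all and all-against-all structural-neighbor search.

Phase 1 (SSE-string LCS filter) runs on every database entry; phase 2 (the
residue-level alignment) only on entries whose LCS length clears the
threshold.  Each pair is an independent pure task, so parallel execution
(joblib) is bit-identical to a serial run regardless of worker count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from joblib import Parallel, delayed

from .accurate_align import DEFAULT_GAP_PENALTY, PART_GROUPS, align_pair
from .lcs_filter import DEFAULT_FILTER_FACTOR, lcs_length, passes_filter
from .sse_assign import SSEString, assign_sse_from_ca
from .structure_io import Chain, list_chains, read_pdb_chain

logger = logging.getLogger(__name__)

__all__ = [
    "SearchHit",
    "SearchParams",
    "DatabaseEntry",
    "load_database",
    "search_one_vs_all",
    "all_vs_all",
    "format_report",
    "write_report",
    "read_report",
]

# below this many pairs the parallel machinery is bypassed entirely
PARALLEL_THRESHOLD = 8


@dataclass(frozen=True)
class SearchHit:
    """Result for one database entry; phase-2 fields are None for entries
    removed by the phase-1 filter."""

    db_id: str
    lcs_length: int
    passed_filter: bool
    tm: float | None = None
    rmsd: float | None = None
    n_ali: int | None = None

    @property
    def sort_key(self) -> tuple[float, str]:
        return (-(self.tm if self.tm is not None else -1.0), self.db_id)


@dataclass(frozen=True)
class SearchParams:
    """Tunables of the two-phase search, defaulting to the published
    settings: filter factor 0.7, gap penalty 3e-6, part groups 1/2/3/5/8."""

    filter_factor: float = DEFAULT_FILTER_FACTOR
    gap_penalty: float = DEFAULT_GAP_PENALTY
    parts: tuple[int, ...] = PART_GROUPS
    workers: int = 1
    skip_filter: bool = False   # Phase 2 on every entry (benchmark mode)
    phase2: bool = True         # False: filter only, no residue alignment

    def __post_init__(self) -> None:
        if self.workers < 1:
            raise ValueError("workers must be >= 1")


@dataclass(frozen=True)
class DatabaseEntry:
    db_id: str
    chain: Chain
    sse: SSEString


def load_database(
    directory: str | Path,
    *,
    sse_cache: str | Path | None = None,
    pattern: str = "*.pdb",
) -> list[DatabaseEntry]:
    """Load every chain of every PDB file in a directory.

    ``sse_cache`` is an optional sidecar TSV (``file<TAB>chain<TAB>SSE``)
    of precomputed 4-state strings; entries missing from it fall back to
    the Cα-geometric assigner.  Unreadable files are logged and skipped.
    """
    directory = Path(directory)
    cache: dict[tuple[str, str], str] = {}
    if sse_cache is not None and Path(sse_cache).exists():
        for line in Path(sse_cache).read_text().splitlines():
            if not line.strip():
                continue
            fname, ch, sse = line.split("\t")
            cache[(fname, ch)] = sse
    entries: list[DatabaseEntry] = []
    for path in sorted(directory.glob(pattern)):
        try:
            for chain_id in list_chains(path):
                chain = read_pdb_chain(path, chain_id)
                cached = cache.get((path.name, chain_id))
                sse = (
                    SSEString(cached)
                    if cached is not None and len(cached) == len(chain)
                    else assign_sse_from_ca(chain)
                )
                entries.append(
                    DatabaseEntry(db_id=f"{path.stem}_{chain_id}", chain=chain, sse=sse)
                )
        except Exception as exc:  # noqa: BLE001 - skip bad entries, keep searching
            logger.warning("skipping %s: %s", path, exc)
    return entries


def _score_entry(
    query_chain: Chain,
    query_sse: SSEString,
    entry: DatabaseEntry,
    params: SearchParams,
) -> SearchHit:
    L = lcs_length(query_sse, entry.sse)
    passed = params.skip_filter or passes_filter(
        L, len(query_sse), len(entry.sse), params.filter_factor
    )
    if not passed or not params.phase2:
        return SearchHit(db_id=entry.db_id, lcs_length=L, passed_filter=passed)
    aln = align_pair(query_chain, entry.chain, params.gap_penalty, parts=params.parts)
    return SearchHit(
        db_id=entry.db_id,
        lcs_length=L,
        passed_filter=True,
        tm=aln.tm,
        rmsd=aln.rmsd,
        n_ali=aln.n_ali,
    )


def _run_tasks(tasks: list, workers: int) -> list:
    if workers > 1 and len(tasks) > PARALLEL_THRESHOLD:
        return Parallel(n_jobs=workers)(tasks)
    return [t[0](*t[1], **t[2]) for t in tasks]


def search_one_vs_all(
    query_chain: Chain,
    query_sse: SSEString,
    db: Sequence[DatabaseEntry],
    params: SearchParams = SearchParams(),
) -> list[SearchHit]:
    """Two-phase search of one query against a database.

    Results are sorted by TM-score descending, then db_id ascending;
    entries that fail the filter sort after all aligned entries.  The
    output is identical for any worker count.
    """
    if not db:
        raise ValueError("empty database")
    tasks = [
        delayed(_score_entry)(query_chain, query_sse, entry, params) for entry in db
    ]
    hits = _run_tasks(tasks, params.workers)
    return sorted(hits, key=lambda h: h.sort_key)


@dataclass(frozen=True)
class AllVsAllResult:
    """Pairwise table plus summary means over phase-2-completed pairs."""

    pairs: tuple[tuple[str, str, SearchHit], ...]
    n_pairs: int
    n_passed: int
    mean_tm: float | None
    mean_rmsd: float | None


def all_vs_all(
    db: Sequence[DatabaseEntry], params: SearchParams = SearchParams()
) -> AllVsAllResult:
    """Evaluate every unordered pair of database entries once: n(n-1)/2
    pairs in total."""
    if len(db) < 2:
        raise ValueError("all-vs-all needs at least 2 entries")
    index_pairs = [
        (i, j) for i in range(len(db)) for j in range(i + 1, len(db))
    ]
    tasks = [
        delayed(_score_entry)(db[i].chain, db[i].sse, db[j], params)
        for i, j in index_pairs
    ]
    hits = _run_tasks(tasks, params.workers)
    rows = tuple(
        (db[i].db_id, db[j].db_id, hit) for (i, j), hit in zip(index_pairs, hits)
    )
    done = [h for _, _, h in rows if h.tm is not None]
    return AllVsAllResult(
        pairs=rows,
        n_pairs=len(rows),
        n_passed=sum(1 for _, _, h in rows if h.passed_filter),
        mean_tm=(sum(h.tm for h in done) / len(done)) if done else None,
        mean_rmsd=(sum(h.rmsd for h in done) / len(done)) if done else None,
    )


_HEADER = ["rank", "db_id", "tm", "rmsd", "n_ali", "lcs_length", "passed_filter"]


def _fmt(x: float | int | None, floatfmt: str = "{:.3f}") -> str:
    if x is None:
        return ""
    if isinstance(x, float):
        return floatfmt.format(x)
    return str(x)


def format_report(hits: Iterable[SearchHit]) -> str:
    """Ranked TSV report text (floats at 3 decimals, empty cells for
    entries without phase-2 results)."""
    lines = ["\t".join(_HEADER)]
    for rank, h in enumerate(hits, start=1):
        lines.append(
            "\t".join(
                [
                    str(rank),
                    h.db_id,
                    _fmt(h.tm),
                    _fmt(h.rmsd),
                    _fmt(h.n_ali),
                    str(h.lcs_length),
                    "true" if h.passed_filter else "false",
                ]
            )
        )
    return "\n".join(lines) + "\n"


def write_report(hits: Iterable[SearchHit], path: str | Path) -> None:
    """Write the ranked TSV report of :func:`format_report` to a file."""
    Path(path).write_text(format_report(hits))


def read_report(path: str | Path) -> list[SearchHit]:
    """Parse a report written by :func:`write_report` (round-trip helper)."""
    lines = Path(path).read_text().splitlines()
    hits = []
    for line in lines[1:]:
        rank, db_id, tm, rm, n_ali, lcs, passed = line.split("\t")
        hits.append(
            SearchHit(
                db_id=db_id,
                lcs_length=int(lcs),
                passed_filter=passed == "true",
                tm=float(tm) if tm else None,
                rmsd=float(rm) if rm else None,
                n_ali=int(n_ali) if n_ali else None,
            )
        )
    return hits
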