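"""Multi-source drug-gene interaction matching.

Four sources (DGIdb, CIViC, OncoKB public tier, ChEMBL) are queried
through adapter contracts. The shipped adapters answer from local
tab-separated snapshots loaded once into memory, so no per-patient network
calls occur; live-HTTP adapters implement the same contract. Results are
deduplicated by normalized (drug, gene) pair, raw evidence labels are
harmonized into the four-tier system with the strongest (numerically
smallest) tier retained, and every multi-tier pair is logged as a conflict
for audit.
"""

from __future__ import annotations

import logging
import threading
import time
from collections import OrderedDict
from concurrent.futures import ThreadPoolExecutor
from pathlib import Path
from typing import Callable, Iterable, Optional, Protocol

import pandas as pd
from pydantic import BaseModel, Field

from . import config

logger = logging.getLogger(__name__)

__all__ = [
    "DrugGeneInteraction",
    "ConflictRecord",
    "SourceAdapter",
    "SnapshotAdapter",
    "TtlCache",
    "load_snapshot",
    "query_sources",
    "deduplicate_and_harmonize",
    "normalize_drug_name",
]

SOURCES = ("DGIdb", "CIViC", "OncoKB", "ChEMBL")


class DrugGeneInteraction(BaseModel):
    drug_name: str
    gene_symbol: str
    source: str
    raw_level: str
    harmonized_tier: int = Field(ge=1, le=4)
    mechanism: str = ""


class ConflictRecord(BaseModel):
    drug_name: str
    gene_symbol: str
    competing: list[tuple[str, str, int]]  # (source, raw_level, tier)
    resolved_tier: int


class SourceAdapter(Protocol):
    """Adapter contract: a named source answering per-gene queries."""

    name: str

    def query(self, gene: str) -> list[DrugGeneInteraction]: ...


def normalize_drug_name(name: str, synonyms: Optional[dict[str, str]] = None) -> str:
    """Case-fold + trim + optional brand/generic synonym table."""
    key = name.strip().casefold()
    if synonyms:
        key = synonyms.get(key, key)
    return key


def harmonize_level(source: str, raw_level: str) -> int:
    """Map a source's raw evidence label to the four-tier system.

    Unmapped labels default to Tier 3 (uncurated interaction) with a
    warning, so harmonization is total.
    """
    table = config.SOURCE_LEVEL_TIER_MAP.get(source, {})
    if raw_level in table:
        return table[raw_level]
    logger.warning("unmapped %s evidence label %r -> Tier %d",
                   source, raw_level, config.UNCURATED_INTERACTION_TIER)
    return config.UNCURATED_INTERACTION_TIER


class TtlCache:
    """Thread-safe TTL cache: one-hour expiry, 2000-entry cap,
    least-recently-written eviction. All mutations are lock-protected."""

    def __init__(
        self,
        ttl: float = config.CACHE_TTL_SECONDS,
        max_entries: int = config.CACHE_MAX_ENTRIES,
        clock: Callable[[], float] = time.monotonic,
    ) -> None:
        self.ttl = ttl
        self.max_entries = max_entries
        self._clock = clock
        self._lock = threading.Lock()
        self._data: OrderedDict[tuple, tuple[float, object]] = OrderedDict()

    def get(self, key: tuple):
        with self._lock:
            entry = self._data.get(key)
            if entry is None:
                return None
            written, value = entry
            if self._clock() - written > self.ttl:
                del self._data[key]
                return None
            return value

    def put(self, key: tuple, value) -> None:
        with self._lock:
            self._data[key] = (self._clock(), value)
            self._data.move_to_end(key)
            while len(self._data) > self.max_entries:
                self._data.popitem(last=False)

    def __len__(self) -> int:
        return len(self._data)


class SnapshotAdapter:
    """In-memory adapter over a tab-separated source snapshot.

    Schema: drug_name, gene_symbol, raw_level, mechanism (header required).
    Loading validates that every raw_level in the snapshot is mappable
    (harmonization totality is checked at load, not query time).
    """

    def __init__(self, name: str, table: pd.DataFrame) -> None:
        self.name = name
        self._by_gene: dict[str, list[DrugGeneInteraction]] = {}
        for row in table.itertuples(index=False):
            rec = DrugGeneInteraction(
                drug_name=row.drug_name,
                gene_symbol=row.gene_symbol,
                source=name,
                raw_level=str(row.raw_level),
                harmonized_tier=harmonize_level(name, str(row.raw_level)),
                mechanism=getattr(row, "mechanism", "") or "",
            )
            self._by_gene.setdefault(rec.gene_symbol, []).append(rec)

    def query(self, gene: str) -> list[DrugGeneInteraction]:
        return list(self._by_gene.get(gene, []))


def load_snapshot(source: str, path: str | Path) -> SnapshotAdapter:
    """Build an adapter from a snapshot file; configuration errors surface
    here, not at query time."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{source} snapshot missing: {path}")
    try:
        table = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    except Exception as exc:
        raise ValueError(f"{source} snapshot unreadable: {exc}") from exc
    required = {"drug_name", "gene_symbol", "raw_level"}
    if not required <= set(table.columns):
        raise ValueError(f"{source} snapshot missing columns {required - set(table.columns)}")
    return SnapshotAdapter(source, table)


def query_sources(
    genes: list[str],
    adapters: Iterable[SourceAdapter],
    concurrency_limit: int = config.CONCURRENCY_LIMIT,
    cache: Optional[TtlCache] = None,
) -> list[DrugGeneInteraction]:
    """Union of adapter results over all genes, queried concurrently with a
    semaphore holding at most ``concurrency_limit`` requests in flight.

    Results are cached per (source, gene) with TTL/capacity per config and
    are independent of completion order (stable sort on (source, gene,
    drug) at the end). An adapter failure empties that (source, gene) cell
    and is logged, never fatal.
    """
    adapters = list(adapters)
    if not adapters:
        raise ValueError("at least one adapter must be registered")
    semaphore = threading.Semaphore(concurrency_limit)
    results: list[DrugGeneInteraction] = []
    lock = threading.Lock()

    def one(adapter: SourceAdapter, gene: str) -> None:
        key = (adapter.name, gene)
        if cache is not None:
            hit = cache.get(key)
            if hit is not None:
                with lock:
                    results.extend(hit)
                return
        with semaphore:
            try:
                rows = adapter.query(gene)
            except Exception as exc:
                logger.warning("%s query for %s failed: %s", adapter.name, gene, exc)
                rows = []
        if cache is not None:
            cache.put(key, rows)
        with lock:
            results.extend(rows)

    with ThreadPoolExecutor(max_workers=max(1, concurrency_limit)) as pool:
        futures = [pool.submit(one, a, g) for g in genes for a in adapters]
        for f in futures:
            f.result()
    results.sort(key=lambda r: (r.source, r.gene_symbol, r.drug_name, r.raw_level))
    return results


def deduplicate_and_harmonize(
    raw: list[DrugGeneInteraction],
    synonyms: Optional[dict[str, str]] = None,
) -> tuple[list[DrugGeneInteraction], list[ConflictRecord]]:
    """Collapse to one record per (drug, gene) pair keeping the strongest
    tier; every multi-tier pair yields one ConflictRecord.

    Permutation-invariant: grouping keys and tie-breaks are value-based.
    """
    groups: dict[tuple[str, str], list[DrugGeneInteraction]] = {}
    for rec in raw:
        key = (normalize_drug_name(rec.drug_name, synonyms), rec.gene_symbol)
        groups.setdefault(key, []).append(rec)

    deduped: list[DrugGeneInteraction] = []
    conflicts: list[ConflictRecord] = []
    for (drug, gene) in sorted(groups):
        members = sorted(groups[(drug, gene)],
                         key=lambda r: (r.harmonized_tier, r.source, r.raw_level))
        best = members[0]
        deduped.append(best.model_copy(update={"drug_name": drug}))
        tiers = {m.harmonized_tier for m in members}
        if len(tiers) > 1:
            conflict = ConflictRecord(
                drug_name=drug,
                gene_symbol=gene,
                competing=[(m.source, m.raw_level, m.harmonized_tier) for m in members],
                resolved_tier=best.harmonized_tier,
            )
            conflicts.append(conflict)
            logger.info("tier conflict %s/%s resolved to Tier %d from %s",
                        drug, gene, conflict.resolved_tier, conflict.competing)
    return deduped, conflicts
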