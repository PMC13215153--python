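"""Citation-grounded literature evidence retrieval.

Abstracts (keyed by PMID) are chunked into 512-token windows, embedded
through a pluggable embedder contract, and retrieved by cosine similarity
(top 5 above 0.65, threshold applied before truncation). Any synthesized
claim citing a PMID outside the retrieval set is flagged unsupported and
excluded — retained evidence is always traceable to indexed literature.

"Token" is relative to the configured embedder's tokenizer. The bundled
deterministic embedder tokenizes on whitespace and maps each document to a
hashed bag-of-words vector, so the whole retrieval path runs offline and
bit-reproducibly; a sentence-transformer-class backend implements the same
two-method contract.
"""

from __future__ import annotations

import hashlib
import logging
from typing import Iterable, Optional, Protocol

import numpy as np
from pydantic import BaseModel, Field

from . import config

logger = logging.getLogger(__name__)

__all__ = [
    "DocumentChunk",
    "EvidenceClaim",
    "Embedder",
    "HashedBagOfWordsEmbedder",
    "VectorIndex",
    "chunk_corpus",
    "retrieve",
    "ground_citations",
    "read_corpus_tsv",
    "read_corpus_xml",
]


class DocumentChunk(BaseModel):
    pmid: str
    chunk_index: int = Field(ge=0)
    text: str
    token_count: int = Field(ge=1, le=config.CHUNK_WINDOW_TOKENS)
    embedding: Optional[list[float]] = None


class EvidenceClaim(BaseModel):
    statement: str
    cited_pmids: list[str] = Field(default_factory=list)
    supported: bool = False
    exclusion_reason: Optional[str] = None


class Embedder(Protocol):
    """Embedder contract: tokenize + embed, shared by the bundled test
    embedder and real sentence-embedding backends."""

    def tokenize(self, text: str) -> list[str]: ...

    def embed(self, text: str) -> np.ndarray: ...


class HashedBagOfWordsEmbedder:
    """Deterministic hashed bag-of-words embedder (no model download).

    Each whitespace token hashes to a (dimension, sign) pair; the document
    vector is the signed token-count histogram, L2-normalized.
    """

    def __init__(self, dim: int = config.EMBEDDING_DIM) -> None:
        self.dim = dim

    def tokenize(self, text: str) -> list[str]:
        return text.split()

    def embed(self, text: str) -> np.ndarray:
        vec = np.zeros(self.dim)
        for token in self.tokenize(text):
            h = int(hashlib.sha256(token.casefold().encode()).hexdigest()[:12], 16)
            vec[h % self.dim] += 1.0 if (h >> 13) % 2 == 0 else -1.0
        norm = np.linalg.norm(vec)
        return vec / norm if norm > 0 else vec


def chunk_corpus(
    corpus: dict[str, str],
    embedder: Embedder,
    window: int = config.CHUNK_WINDOW_TOKENS,
    overlap: int = config.CHUNK_OVERLAP_TOKENS,
) -> list[DocumentChunk]:
    """Split each abstract into consecutive windows of at most ``window``
    tokens (lossless: concatenating a document's chunks minus any overlap
    reproduces its token stream). Empty abstracts yield no chunks."""
    if overlap >= window:
        raise ValueError("overlap must be smaller than the window")
    chunks: list[DocumentChunk] = []
    for pmid in sorted(corpus):
        tokens = embedder.tokenize(corpus[pmid])
        if not tokens:
            logger.warning("empty abstract for PMID %s: skipped", pmid)
            continue
        step = window - overlap
        for i, start in enumerate(range(0, len(tokens), step)):
            piece = tokens[start:start + window]
            if not piece:
                break
            text = " ".join(piece)
            chunks.append(DocumentChunk(
                pmid=pmid, chunk_index=i, text=text, token_count=len(piece),
                embedding=embedder.embed(text).tolist(),
            ))
    return chunks


class VectorIndex:
    """Brute-force cosine index over embedded chunks (numpy matmul)."""

    def __init__(self, chunks: list[DocumentChunk]) -> None:
        self.chunks = list(chunks)
        if self.chunks:
            self._matrix = np.array([c.embedding for c in self.chunks])
        else:
            self._matrix = np.zeros((0, 1))

    def similarities(self, query_vec: np.ndarray) -> np.ndarray:
        if not self.chunks:
            return np.zeros(0)
        qn = np.linalg.norm(query_vec)
        q = query_vec / qn if qn > 0 else query_vec
        rows = self._matrix
        norms = np.linalg.norm(rows, axis=1)
        norms[norms == 0] = 1.0
        return (rows / norms[:, None]) @ q


def retrieve(
    query: str,
    index: VectorIndex,
    embedder: Embedder,
    k: int = config.RETRIEVE_TOP_K,
    threshold: float = config.RETRIEVE_COSINE_THRESHOLD,
) -> list[DocumentChunk]:
    """Top ``min(k, #above-threshold)`` chunks by descending cosine; ties
    broken by (pmid, chunk_index). Threshold filters before truncation."""
    sims = index.similarities(embedder.embed(query))
    eligible = [
        (float(s), c) for s, c in zip(sims, index.chunks) if s >= threshold
    ]
    eligible.sort(key=lambda sc: (-sc[0], sc[1].pmid, sc[1].chunk_index))
    return [c for _, c in eligible[:k]]


def ground_citations(
    claims: Iterable[EvidenceClaim],
    retrieval_set: set[str],
) -> tuple[list[EvidenceClaim], list[EvidenceClaim]]:
    """Split claims into (retained, excluded).

    A claim is supported iff it cites at least one PMID and every cited
    PMID is in the retrieval set; anything else is excluded with a reason.
    """
    retained: list[EvidenceClaim] = []
    excluded: list[EvidenceClaim] = []
    for claim in claims:
        if not claim.cited_pmids:
            excluded.append(claim.model_copy(update={
                "supported": False, "exclusion_reason": "no PMID cited",
            }))
            continue
        missing = [p for p in claim.cited_pmids if p not in retrieval_set]
        if missing:
            excluded.append(claim.model_copy(update={
                "supported": False,
                "exclusion_reason": f"cited PMIDs absent from retrieval set: {missing}",
            }))
        else:
            retained.append(claim.model_copy(update={"supported": True}))
    return retained, excluded


# --- corpus readers --------------------------------------------------------

def read_corpus_tsv(path) -> dict[str, str]:
    """Plain (pmid, title, abstract) tab-separated corpus; title and
    abstract are concatenated into the indexed text."""
    corpus: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["pmid", "title", "abstract"]:
            raise ValueError("corpus TSV must have pmid/title/abstract columns")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                corpus[parts[0]] = f"{parts[1]} {parts[2]}".strip()
    return corpus


def read_corpus_xml(path) -> dict[str, str]:
    """PubMed-style XML reader (PubmedArticle/MedlineCitation layout)."""
    from lxml import etree

    corpus: dict[str, str] = {}
    tree = etree.parse(str(path))
    for article in tree.iter("PubmedArticle"):
        pmid = article.findtext(".//MedlineCitation/PMID")
        title = article.findtext(".//ArticleTitle") or ""
        abstract = " ".join(
            (el.text or "") for el in article.iter("AbstractText")
        )
        if pmid:
            corpus[pmid] = f"{title} {abstract}".strip()
    return corpus


def keyword_prefilter(
    corpus: dict[str, str],
    keywords: Iterable[str] = ("sarcoma", "neoantigen", "radioligand"),
) -> dict[str, str]:
    """Topic prefilter used when ingesting larger corpora."""
    kws = [k.casefold() for k in keywords]
    return {
        pmid: text for pmid, text in corpus.items()
        if any(k in text.casefold() for k in kws)
    }
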