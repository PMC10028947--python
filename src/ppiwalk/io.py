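"""Parsing, filtering and caching of PPI edge lists and expression tables.

Supported dialects:

* StringDB ``protein.links`` — whitespace-delimited with a header containing
  ``protein1 protein2 combined_score``; identifiers may carry a numeric
  species prefix (``9606.ENSP...``) which is stripped on ingest.
* BioGRID tab-delimited — header row with ``Official Symbol Interactor A``
  and ``Official Symbol Interactor B`` columns.
* Expression TSV — ``identifier<TAB>value``, optional header auto-detected
  by a non-numeric second field.

The local cache is a gzipped three-column TSV (``node_a  node_b
confidence``): portable, inspectable and diff-able, unlike a language-native
binary serialization.
"""

from __future__ import annotations

import gzip
import io as _stdlib_io
import logging
import math
import urllib.request
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .graph import CONFIDENCE, NODE_WEIGHT, build_graph

logger = logging.getLogger(__name__)

__all__ = [
    "PpiFormatError",
    "PpiSource",
    "parse_stringdb_links",
    "parse_biogrid",
    "load_ppi",
    "load_expression",
    "write_cache",
    "read_cache",
    "write_edgelist_tsv",
    "read_edgelist_tsv",
    "read_graph_file",
    "write_graphml",
    "write_node_scores_tsv",
]

BIOGRID_COL_A = "Official Symbol Interactor A"
BIOGRID_COL_B = "Official Symbol Interactor B"

STRINGDB_URL = (
    "https://stringdb-downloads.org/download/protein.links.v12.0/"
    "{species}.protein.links.v12.0.txt.gz"
)


class PpiFormatError(ValueError):
    """Raised when an input file does not match the expected dialect."""


@dataclass
class PpiSource:
    """Where and how to obtain a PPI network.

    ``min_confidence`` is on the StringDB combined_score scale (0–1000) and
    is only meaningful for the stringdb repository; 400 is the conventional
    medium-confidence cutoff.
    """

    repository: str = "stringdb"
    species_code: str = "9606"
    min_confidence: int = 400
    cache_path: Path | None = None

    def __post_init__(self) -> None:
        if self.repository not in ("stringdb", "biogrid"):
            raise ValueError(f"unknown repository {self.repository!r}")
        if not 0 <= self.min_confidence <= 1000:
            raise ValueError("min_confidence must be in [0, 1000]")
        if self.cache_path is not None:
            self.cache_path = Path(self.cache_path)

    def cache_file(self) -> Path | None:
        if self.cache_path is None:
            return None
        name = f"{self.repository}_{self.species_code}_{self.min_confidence}.tsv.gz"
        return self.cache_path / name


def _strip_species_prefix(identifier: str) -> str:
    head, dot, tail = identifier.partition(".")
    if dot and head.isdigit() and tail:
        return tail
    return identifier


def parse_stringdb_links(lines: Iterable[str], source: PpiSource | None = None) -> nx.Graph:
    """Parse a StringDB protein.links stream into a graph.

    Keeps edges with ``combined_score >= source.min_confidence``; species
    prefixes are stripped from identifiers; duplicate/symmetric rows are
    collapsed keeping the maximum score.
    """
    if source is None:
        source = PpiSource()
    it = iter(lines)
    try:
        header = next(it).split()
    except StopIteration:
        raise PpiFormatError("empty StringDB input: no header line") from None
    required = ("protein1", "protein2", "combined_score")
    for col in required:
        if col not in header:
            raise PpiFormatError(f"StringDB input is missing required column {col!r}")
    i1, i2, isc = (header.index(c) for c in required)
    total = 0
    records = []
    for lineno, line in enumerate(it, start=2):
        fields = line.split()
        if not fields:
            continue
        total += 1
        try:
            score = float(fields[isc])
        except (IndexError, ValueError):
            raise PpiFormatError(
                f"line {lineno}: cannot read combined_score from {line!r}"
            ) from None
        if score < source.min_confidence:
            continue
        records.append(
            (
                _strip_species_prefix(fields[i1]),
                _strip_species_prefix(fields[i2]),
                score,
            )
        )
    if not records:
        raise PpiFormatError(
            f"no edge met combined_score >= {source.min_confidence} "
            f"({total} input rows)"
        )
    return build_graph(records)


def parse_biogrid(lines: Iterable[str]) -> nx.Graph:
    """Parse a BioGRID tab-delimited stream into a symbol–symbol graph."""
    it = iter(lines)
    try:
        header = next(it).rstrip("\n").split("\t")
    except StopIteration:
        raise PpiFormatError("empty BioGRID input: no header line") from None
    for col in (BIOGRID_COL_A, BIOGRID_COL_B):
        if col not in header:
            raise PpiFormatError(f"BioGRID input is missing required column {col!r}")
    ia, ib = header.index(BIOGRID_COL_A), header.index(BIOGRID_COL_B)
    records = []
    for line in it:
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        try:
            records.append((fields[ia], fields[ib]))
        except IndexError:
            raise PpiFormatError(f"BioGRID row with too few columns: {line!r}") from None
    if not records:
        raise PpiFormatError("BioGRID input has a header but no interaction rows")
    return build_graph(records)


# -- cache / serialization ---------------------------------------------------


def _edge_rows(g: nx.Graph):
    for u, v, data in sorted(g.edges(data=True)):
        a, b = (u, v) if u <= v else (v, u)
        conf = data.get(CONFIDENCE)
        yield a, b, ("" if conf is None else format(conf, "g"))


def write_cache(g: nx.Graph, path: Path) -> None:
    """Serialize a graph as a gzipped edge-list TSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with gzip.open(path, "wt") as fh:
        fh.write("node_a\tnode_b\tconfidence\n")
        for a, b, conf in _edge_rows(g):
            fh.write(f"{a}\t{b}\t{conf}\n")


def read_cache(path: Path) -> nx.Graph:
    """Load a graph cached by :func:`write_cache`; fail loud on corruption."""
    path = Path(path)
    try:
        with gzip.open(path, "rt") as fh:
            return read_edgelist_tsv(fh)
    except (OSError, EOFError, PpiFormatError, ValueError) as exc:
        raise PpiFormatError(f"corrupt or unreadable cache file {path}: {exc}") from exc


def write_edgelist_tsv(g: nx.Graph, path_or_stream) -> None:
    """Plain (uncompressed) edge-list TSV: node_a, node_b, confidence."""
    if hasattr(path_or_stream, "write"):
        fh = path_or_stream
        fh.write("node_a\tnode_b\tconfidence\n")
        for a, b, conf in _edge_rows(g):
            fh.write(f"{a}\t{b}\t{conf}\n")
    else:
        with open(path_or_stream, "w") as fh:
            write_edgelist_tsv(g, fh)


def read_edgelist_tsv(lines: Iterable[str]) -> nx.Graph:
    it = iter(lines)
    try:
        header = next(it).rstrip("\n").split("\t")
    except StopIteration:
        raise PpiFormatError("empty edge list") from None
    if header[:2] != ["node_a", "node_b"]:
        raise PpiFormatError("edge list must start with header 'node_a\\tnode_b'")
    records = []
    for line in it:
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise PpiFormatError(f"edge row with fewer than two columns: {line!r}")
        conf = None
        if len(fields) > 2 and fields[2] != "":
            conf = float(fields[2])
        records.append((fields[0], fields[1], conf) if conf is not None else fields[:2])
    return build_graph(records)


def write_graphml(g: nx.Graph, path: Path) -> None:
    nx.write_graphml(g, path)


def write_node_scores_tsv(scores: pd.Series, path_or_stream, value_name: str = "score") -> None:
    """Two-column TSV serialization for any per-node score vector."""
    df = scores.rename(value_name).rename_axis("node").reset_index()
    df = df.sort_values("node")
    df.to_csv(path_or_stream, sep="\t", index=False)


# -- remote loading ----------------------------------------------------------


def _default_fetch(source: PpiSource) -> Iterable[str]:
    """Download the repository file and return its decoded text lines."""
    if source.repository == "stringdb":
        url = STRINGDB_URL.format(species=source.species_code)
    else:
        raise ValueError(
            "automated BioGRID download is not configured; pass a local file "
            "to parse_biogrid or supply a fetcher"
        )
    logger.info("fetching %s", url)
    with urllib.request.urlopen(url) as resp:  # pragma: no cover - network
        raw = resp.read()
    if url.endswith(".gz"):
        raw = gzip.decompress(raw)
    return _stdlib_io.StringIO(raw.decode()).readlines()


def load_ppi(
    source: PpiSource,
    fetcher: Callable[[PpiSource], Iterable[str]] | None = None,
) -> nx.Graph:
    """Return the requested PPI graph, from cache when available.

    A cache hit performs no fetch. On a miss, the repository stream is
    obtained via ``fetcher`` (defaults to HTTP download), parsed, and — when
    ``cache_path`` is set — persisted for future calls.
    """
    cache = source.cache_file()
    if cache is not None and cache.exists():
        logger.info("loading cached PPI from %s", cache)
        return read_cache(cache)
    if fetcher is None:
        fetcher = _default_fetch
    try:
        lines = fetcher(source)
    except OSError as exc:
        raise OSError(
            f"could not fetch {source.repository} and no cache exists"
            f"{'' if cache is None else f' at {cache}'}; "
            "supply a local file via parse_stringdb_links/parse_biogrid"
        ) from exc
    if source.repository == "stringdb":
        g = parse_stringdb_links(lines, source)
    else:
        g = parse_biogrid(lines)
    if cache is not None:
        write_cache(g, cache)
        logger.info("cached PPI at %s", cache)
    return g


# -- expression --------------------------------------------------------------


def load_expression(lines: Iterable[str], log2_transform: bool = True) -> pd.Series:
    """Read a two-column (identifier, value) table into a named Series.

    With ``log2_transform`` the values become ``log2(E + 1)``: the
    pseudocount keeps zero counts finite on the log scale. Non-positive
    post-transform values are retained but reported via a warning, since the
    network-potential score must drop them downstream.
    """
    ids: list[str] = []
    vals: list[float] = []
    for lineno, line in enumerate(iter(lines), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) == 1:
            fields = line.split()
        if len(fields) < 2:
            raise PpiFormatError(f"line {lineno}: expected two columns, got {line!r}")
        try:
            val = float(fields[1])
        except ValueError:
            if lineno == 1:
                continue  # header row
            raise PpiFormatError(
                f"line {lineno}: non-numeric value field {fields[1]!r}"
            ) from None
        ids.append(fields[0])
        vals.append(val)
    if not ids:
        raise PpiFormatError("expression input contains no (identifier, value) rows")
    dupes = pd.Index(ids).duplicated()
    if dupes.any():
        offenders = sorted({i for i, d in zip(ids, dupes) if d})
        raise PpiFormatError(f"duplicate identifiers in expression input: {offenders}")
    values = pd.Series(vals, index=pd.Index(ids, name="node"), dtype=float, name="value")
    if not np.isfinite(values).all():
        raise PpiFormatError("expression values must be finite")
    if log2_transform:
        if (values <= -1).any():
            raise PpiFormatError("cannot log2-transform values <= -1")
        values = np.log2(values + 1.0)
    n_bad = int((values <= 0).sum())
    if n_bad:
        warnings.warn(
            f"{n_bad} expression value(s) are non-positive; network potential "
            "will drop these nodes",
            stacklevel=2,
        )
    return values


def read_graph_file(path: Path, min_confidence: int = 0, species_code: str = "9606") -> nx.Graph:
    """Read a graph from a local file, sniffing the dialect from the header.

    Recognizes StringDB protein.links, BioGRID tab-delimited, the package's
    own edge-list TSV, and the gzipped cache format.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        lines = fh.readlines()
    if not lines:
        raise PpiFormatError(f"{path} is empty")
    header = lines[0]
    if "protein1" in header.split():
        src = PpiSource(min_confidence=min_confidence, species_code=species_code)
        return parse_stringdb_links(lines, src)
    if BIOGRID_COL_A in header:
        return parse_biogrid(lines)
    if header.startswith("node_a"):
        return read_edgelist_tsv(lines)
    raise PpiFormatError(f"{path}: unrecognized graph file header {header!r}")
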