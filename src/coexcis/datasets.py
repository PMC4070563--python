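"""Domain types and file I/O for ternary expression data, promoters and networks.

The expression encoding is ternary: for every (gene, condition) cell the value
is +1 if the gene was called up-regulated under that condition, -1 if
down-regulated, and 0 otherwise.  A condition is whatever granularity the
differential-expression calls were made at (one microarray contrast, one
treatment, ...); the reader accepts any granularity and records it in
``condition_ids``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import networkx as nx
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

TERNARY_VALUES = (-1, 0, 1)
_PROMOTER_ALPHABET = set("ACGTN")
_ELEMENT_ALPHABET = set("ACGT")


@dataclass
class TernaryExpressionMatrix:
    """Genes x conditions matrix with values in {-1, 0, +1}.

    Parameters
    ----------
    gene_ids : ordered unique gene identifiers (rows).
    condition_ids : ordered unique condition labels (columns).
    values : integer array of shape (n_genes, n_conditions), cells in {-1,0,1}.
    """

    gene_ids: list[str]
    condition_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.condition_ids = [str(c) for c in self.condition_ids]
        self.values = np.asarray(self.values, dtype=np.int8)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene IDs")
        if len(set(self.condition_ids)) != len(self.condition_ids):
            raise ValueError("duplicate condition IDs")
        if len(self.condition_ids) < 2:
            raise ValueError("at least 2 conditions are required")
        if self.values.shape != (len(self.gene_ids), len(self.condition_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.condition_ids)} conditions"
            )
        if not np.isin(self.values, TERNARY_VALUES).all():
            bad = np.unique(self.values[~np.isin(self.values, TERNARY_VALUES)])
            raise ValueError(f"non-ternary values present: {bad.tolist()}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_conditions(self) -> int:
        return len(self.condition_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.condition_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TernaryExpressionMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TernaryExpressionMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.condition_ids == other.condition_ids
            and np.array_equal(self.values, other.values)
        )


@dataclass
class PromoterSet:
    """Mapping of gene ID to upstream promoter sequence (A/C/G/T/N).

    Sequences are stored uppercase.  ``total_length`` is the summed sequence
    length, the search-space term of alignment statistics.  ``metadata`` holds
    optional provenance such as planted-motif positions from a generator.
    """

    records: dict[str, str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, str] = {}
        for gene_id, seq in self.records.items():
            s = str(seq).upper()
            bad = set(s) - _PROMOTER_ALPHABET
            if bad:
                raise ValueError(
                    f"record {gene_id!r} contains non-ACGTN characters: {sorted(bad)}"
                )
            if gene_id in clean:
                raise ValueError(f"duplicate gene ID {gene_id!r}")
            clean[str(gene_id)] = s
        self.records = clean

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.records.values())

    @property
    def gene_ids(self) -> list[str]:
        return list(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, gene_id: str) -> str:
        return self.records[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.records

    def subset(self, gene_ids: Iterable[str]) -> "PromoterSet":
        ids = list(gene_ids)
        missing = [g for g in ids if g not in self.records]
        if missing:
            raise KeyError(f"gene IDs absent from promoter set: {missing[:5]}")
        return PromoterSet({g: self.records[g] for g in ids})


@dataclass
class KnownElementList:
    """Experimentally known cis-regulatory elements (plain ACGT strings)."""

    elements: list[str]

    def __post_init__(self) -> None:
        clean = []
        for e in self.elements:
            s = str(e).upper()
            if len(s) < 4:
                raise ValueError(f"element {s!r} shorter than 4 nt")
            bad = set(s) - _ELEMENT_ALPHABET
            if bad:
                raise ValueError(f"element {s!r} has non-ACGT characters: {sorted(bad)}")
            clean.append(s)
        self.elements = clean

    def __len__(self) -> int:
        return len(self.elements)

    def __iter__(self):
        return iter(self.elements)


# ---------------------------------------------------------------------------
# ternary encoding


def encode_updown(
    calls: Mapping[str, tuple[Iterable[str], Iterable[str]]],
) -> TernaryExpressionMatrix:
    """Encode per-condition up/down gene lists as a ternary matrix.

    ``calls`` maps condition label -> (up gene list, down gene list).  The gene
    universe is the union of all genes ever listed; a gene not listed under a
    condition is 0 there.  A gene listed both up and down under the same
    condition is a hard error.  Duplicates within one list count once.
    """
    if not calls:
        raise ValueError("no conditions")
    conditions = list(calls)
    per_cond: dict[str, tuple[set, set]] = {}
    universe: set[str] = set()
    for cond, (up, down) in calls.items():
        up_l, down_l = [str(g) for g in up], [str(g) for g in down]
        up_s, down_s = set(up_l), set(down_l)
        if len(up_s) < len(up_l) or len(down_s) < len(down_l):
            logger.warning("condition %s: duplicate gene IDs within a list ignored", cond)
        both = up_s & down_s
        if both:
            raise ValueError(
                f"gene {sorted(both)[0]!r} listed both up and down in condition {cond!r}"
            )
        per_cond[cond] = (up_s, down_s)
        universe |= up_s | down_s
    genes = sorted(universe)
    idx = {g: i for i, g in enumerate(genes)}
    values = np.zeros((len(genes), len(conditions)), dtype=np.int8)
    for j, cond in enumerate(conditions):
        up_s, down_s = per_cond[cond]
        for g in up_s:
            values[idx[g], j] = 1
        for g in down_s:
            values[idx[g], j] = -1
    return TernaryExpressionMatrix(genes, conditions, values)


def read_updown_tables(paths: Sequence[str | Path]) -> TernaryExpressionMatrix:
    """Read per-condition two-column TSV files (gene_id, direction in {up,down}).

    One file per condition; the condition label is the file stem.
    """
    paths = [Path(p) for p in paths]
    if not paths:
        raise ValueError("no conditions")
    calls: dict[str, tuple[list[str], list[str]]] = {}
    for path in paths:
        up: list[str] = []
        down: list[str] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields")
                gene, direction = parts[0].strip(), parts[1].strip().lower()
                if direction == "up":
                    up.append(gene)
                elif direction == "down":
                    down.append(gene)
                else:
                    raise ValueError(
                        f"{path}:{lineno}: direction must be 'up' or 'down', got {direction!r}"
                    )
        calls[path.stem] = (up, down)
    return encode_updown(calls)


def write_updown_tables(m: TernaryExpressionMatrix, out_dir: str | Path) -> list[Path]:
    """Write one two-column TSV per condition; inverse of :func:`read_updown_tables`."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for j, cond in enumerate(m.condition_ids):
        path = out_dir / f"{cond}.tsv"
        col = m.values[:, j]
        with open(path, "w") as fh:
            for i in np.flatnonzero(col == 1):
                fh.write(f"{m.gene_ids[i]}\tup\n")
            for i in np.flatnonzero(col == -1):
                fh.write(f"{m.gene_ids[i]}\tdown\n")
        written.append(path)
    return written


# ---------------------------------------------------------------------------
# promoters and element lists


def read_fasta_promoters(path: str | Path) -> PromoterSet:
    """Read promoter sequences from FASTA; IDs from the first header token."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate gene ID {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq)
    return PromoterSet(records)


def write_fasta_promoters(promoters: PromoterSet, path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(seq), id=gene_id, description="")
        for gene_id, seq in promoters.records.items()
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_known_elements(path: str | Path) -> KnownElementList:
    """Read a plain-text element list, one ACGT string per line."""
    elements = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                elements.append(line)
    if not elements:
        raise ValueError("element list is empty")
    return KnownElementList(elements)


# ---------------------------------------------------------------------------
# network round-trip

_NODES_HEADER = "#nodes"
_EDGES_HEADER = "#edges"


def new_network(
    nodes: Iterable[str], edges: Iterable[tuple] = ()
) -> nx.Graph:
    """Build a simple undirected co-expression graph (no self-loops)."""
    g = nx.Graph()
    g.add_nodes_from(str(n) for n in nodes)
    for e in edges:
        u, v = str(e[0]), str(e[1])
        if u == v:
            raise ValueError(f"self-loop on node {u!r}")
        if not g.has_node(u) or not g.has_node(v):
            raise ValueError(f"edge endpoint not in node set: ({u}, {v})")
        if len(e) > 2:
            g.add_edge(u, v, weight=float(e[2]))
        else:
            g.add_edge(u, v)
    return g


def write_network(net: nx.Graph, path: str | Path) -> None:
    """Write a graph as a node manifest plus tab-separated edge list.

    The manifest section keeps isolated nodes alive across a round-trip.
    """
    with open(path, "w") as fh:
        fh.write(_NODES_HEADER + "\n")
        for n in sorted(net.nodes):
            fh.write(f"{n}\n")
        fh.write(_EDGES_HEADER + "\n")
        for u, v, data in sorted(net.edges(data=True)):
            if "weight" in data:
                fh.write(f"{u}\t{v}\t{data['weight']:.10g}\n")
            else:
                fh.write(f"{u}\t{v}\n")


def read_network(path: str | Path) -> nx.Graph:
    g = nx.Graph()
    section = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line == _NODES_HEADER:
                section = "nodes"
                continue
            if line == _EDGES_HEADER:
                section = "edges"
                continue
            if section == "nodes":
                if "\t" in line:
                    raise ValueError(f"{path}:{lineno}: malformed node line")
                g.add_node(line)
            elif section == "edges":
                parts = line.split("\t")
                if len(parts) not in (2, 3):
                    raise ValueError(f"{path}:{lineno}: malformed edge line")
                u, v = parts[0], parts[1]
                if u == v or not g.has_node(u) or not g.has_node(v):
                    raise ValueError(f"{path}:{lineno}: invalid edge ({u}, {v})")
                if len(parts) == 3:
                    try:
                        w = float(parts[2])
                    except ValueError as exc:
                        raise ValueError(f"{path}:{lineno}: bad weight {parts[2]!r}") from exc
                    g.add_edge(u, v, weight=w)
                else:
                    g.add_edge(u, v)
            else:
                raise ValueError(f"{path}:{lineno}: content before section header")
    if section is None:
        raise ValueError(f"{path}: no section headers found")
    return g


def write_modules(modules: Sequence[Iterable[str]], path: str | Path) -> None:
    """Write a module TSV (module_id TAB gene_id)."""
    with open(path, "w") as fh:
        for i, mod in enumerate(modules, 1):
            for gene in sorted(mod):
                fh.write(f"M{i}\t{gene}\n")
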