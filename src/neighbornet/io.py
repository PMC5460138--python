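"""Readers and writers for every external file format the pipeline touches.

All formats are plain text, UTF-8, tab-separated with a header line unless
noted (gene lists are one identifier per line; GAF is the standard
tab-separated association format with ``!`` comment lines).

The pipeline is identifier-namespace agnostic: any consistent non-empty
string works as a protein/gene ID. A two-column mapping table reader is
provided for translating between namespaces; unmapped IDs are dropped with
a logged count and one-to-many mappings are expanded.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import networkx as nx
import pandas as pd

from .errors import ConfigError, DataError, ParseError

logger = logging.getLogger(__name__)

ACTIVITY_TYPES = ("IC50", "Ki", "Kd")

BIOACTIVITY_COLUMNS = [
    "compound_id",
    "target_id",
    "activity_type",
    "value_nM",
    "max_phase",
    "indication_class",
]


class Interactome:
    """An unweighted protein interaction network with optional edge directions.

    The topology lives in an undirected simple :class:`networkx.Graph`
    (self-loops removed on ingestion, duplicate edges collapsed, each edge
    stored once under a canonical endpoint ordering). Direction annotations
    — present for signalling resources, absent for plain PPI data — are kept
    separately as a set of ordered ``(source, target)`` pairs; they are
    consulted only where direction matters (influencer detection), never for
    topology metrics.
    """

    def __init__(self, resource_name: str = "interactome"):
        self.resource_name = resource_name
        self.graph = nx.Graph()
        self.directed_edges: set[tuple[str, str]] = set()
        self.n_self_loops_dropped = 0
        self.n_duplicates_collapsed = 0

    # -- construction -------------------------------------------------
    def add_node(self, node: str) -> None:
        if not node:
            raise DataError("empty node identifier")
        self.graph.add_node(node)

    def add_edge(self, u: str, v: str, directed: bool = False) -> None:
        """Add an interaction; a directed edge points ``u -> v``.

        Self-loops are dropped (with a count); re-adding an existing edge
        unions the direction flags.
        """
        if not u or not v:
            raise DataError(f"empty node identifier in edge ({u!r}, {v!r})")
        if u == v:
            self.graph.add_node(u)  # the protein stays; the loop goes
            self.n_self_loops_dropped += 1
            return
        if self.graph.has_edge(u, v):
            self.n_duplicates_collapsed += 1
        self.graph.add_edge(u, v)
        if directed:
            self.directed_edges.add((u, v))

    # -- queries ------------------------------------------------------
    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def edges(self) -> Iterator[tuple[str, str, bool]]:
        """Yield ``(u, v, has_direction)`` with canonical ``u <= v`` ordering."""
        for a, b in self.graph.edges:
            u, v = (a, b) if a <= b else (b, a)
            yield u, v, (u, v) in self.directed_edges or (v, u) in self.directed_edges

    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def neighbors(self, node: str) -> set[str]:
        return set(self.graph.neighbors(node))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Interactome):
            return NotImplemented
        return (
            set(self.graph.nodes) == set(other.graph.nodes)
            and set(map(frozenset, self.graph.edges)) == set(map(frozenset, other.graph.edges))
            and self.directed_edges == other.directed_edges
        )


@dataclass
class ExpressionProfile:
    """Gene-level expression values split into a normal and a cancer group.

    ``values`` is a genes x samples table on the (log) intensity scale; the
    two sample lists partition its columns. One row per gene is guaranteed
    by the reader (highest-mean row kept for duplicated gene IDs).
    """

    values: pd.DataFrame
    normal_samples: list[str]
    cancer_samples: list[str]

    def __post_init__(self) -> None:
        overlap = set(self.normal_samples) & set(self.cancer_samples)
        if overlap:
            raise ConfigError(f"samples in both groups: {sorted(overlap)}")
        if not self.normal_samples or not self.cancer_samples:
            raise DataError("both sample groups must be non-empty")
        missing = (set(self.normal_samples) | set(self.cancer_samples)) - set(self.values.columns)
        if missing:
            raise DataError(f"sample columns not in matrix: {sorted(missing)}")
        if not self.values.index.is_unique:
            raise DataError("duplicate gene IDs in expression profile")

    @property
    def genes(self) -> set[str]:
        return set(self.values.index)

    def state_means(self) -> pd.DataFrame:
        """Per-gene arithmetic mean per state; columns ``normal``/``cancer``."""
        return pd.DataFrame(
            {
                "normal": self.values[self.normal_samples].mean(axis=1),
                "cancer": self.values[self.cancer_samples].mean(axis=1),
            }
        )

    def state_medians(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "normal": self.values[self.normal_samples].median(axis=1),
                "cancer": self.values[self.cancer_samples].median(axis=1),
            }
        )


@dataclass
class BioactivityTable:
    """Compound-target bioactivity records (a ChEMBL-extract work-alike).

    Columns: compound_id, target_id, activity_type, value_nM (> 0),
    max_phase (0-4), indication_class (optional free-text label).
    """

    records: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=BIOACTIVITY_COLUMNS))

    def __post_init__(self) -> None:
        df = self.records
        for col in BIOACTIVITY_COLUMNS[:5]:
            if col not in df.columns:
                raise DataError(f"bioactivity table missing column {col!r}")
        if "indication_class" not in df.columns:
            df = df.assign(indication_class="")
        df = df.copy()
        df["indication_class"] = df["indication_class"].fillna("").astype(str)
        df["value_nM"] = pd.to_numeric(df["value_nM"], errors="raise")
        df["max_phase"] = pd.to_numeric(df["max_phase"], errors="raise").astype(int)
        if len(df) and (df["value_nM"] <= 0).any():
            bad = df.index[df["value_nM"] <= 0][0]
            raise DataError(f"non-positive value_nM in bioactivity record {bad}")
        if len(df) and (~df["max_phase"].between(0, 4)).any():
            bad = df.index[~df["max_phase"].between(0, 4)][0]
            raise DataError(f"max_phase outside 0-4 in bioactivity record {bad}")
        unknown = set(df["activity_type"]) - set(ACTIVITY_TYPES)
        if unknown:
            logger.warning("bioactivity table has unknown activity types %s; "
                           "records will be skipped by the potency filter", sorted(unknown))
        self.records = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# edge lists
# ---------------------------------------------------------------------------

def read_edge_list(
    path: str | Path,
    resource_name: str = "interactome",
    directed_values: Iterable[str] = ("directed", "true", "1"),
    header: bool = True,
) -> Interactome:
    """Read a TSV edge list into an :class:`Interactome`.

    Expected columns: source, target, optional direction flag. A third-column
    value in ``directed_values`` (case-insensitive) marks the edge as
    directed source -> target; anything else (or a missing column) means
    undirected. Duplicate edges collapse with a union of direction flags;
    self-loops are dropped and counted.
    """
    path = Path(path)
    directed_values = {v.lower() for v in directed_values}
    net = Interactome(resource_name)
    with path.open(encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if header and lineno == 1:
                continue
            if len(row) < 2 or not row[0].strip() or not row[1].strip():
                raise ParseError(f"{path}:{lineno}: malformed edge row {row!r}")
            u, v = row[0].strip(), row[1].strip()
            flag = row[2].strip().lower() if len(row) > 2 else ""
            net.add_edge(u, v, directed=flag in directed_values)
    if net.n_edges() == 0 and net.n_nodes() == 0:
        raise DataError(f"{path}: empty interactome")
    if net.n_self_loops_dropped:
        logger.info("%s: dropped %d self-loop(s)", path, net.n_self_loops_dropped)
    return net


def write_edge_list(net: Interactome, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("source\ttarget\tdirection\n")
        for u, v, _ in sorted(net.edges()):
            if (u, v) in net.directed_edges:
                fh.write(f"{u}\t{v}\tdirected\n")
            elif (v, u) in net.directed_edges:
                fh.write(f"{v}\t{u}\tdirected\n")
            else:
                fh.write(f"{u}\t{v}\tundirected\n")


def read_sif(
    path: str | Path,
    resource_name: str = "interactome",
    directed_types: Iterable[str] = (),
) -> Interactome:
    """Read a SIF file (``source<TAB>interaction-type<TAB>target...``).

    Edges are undirected unless their interaction type is listed in
    ``directed_types``.
    """
    path = Path(path)
    directed_types = set(directed_types)
    net = Interactome(resource_name)
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: malformed SIF row {line!r}")
            source, itype, *targets = parts
            for target in targets:
                net.add_edge(source, target, directed=itype in directed_types)
    if net.n_edges() == 0 and net.n_nodes() == 0:
        raise DataError(f"{path}: empty interactome")
    return net


# ---------------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------------

def read_expression_matrix(
    path: str | Path,
    normal_group: list[str],
    cancer_group: list[str],
) -> ExpressionProfile:
    """Read a gene x sample TSV (first column gene ID, header row of samples).

    When several rows share a gene ID, the row with the highest mean across
    all listed samples is kept (mirrors picking the strongest probe set of a
    gene on an array). Missing or non-numeric cells are a parse error.
    """
    path = Path(path)
    if set(normal_group) & set(cancer_group):
        raise ConfigError("a sample cannot be in both the normal and cancer group")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    wanted = list(normal_group) + list(cancer_group)
    missing = set(wanted) - set(raw.columns)
    if missing:
        raise DataError(f"{path}: sample columns not found: {sorted(missing)}")
    raw = raw[wanted]
    values = pd.DataFrame(index=raw.index, columns=wanted, dtype=float)
    for col in wanted:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.index[converted.isna()]
        if len(bad):
            raise ParseError(
                f"{path}: non-numeric or missing cell at gene {bad[0]!r}, sample {col!r}"
            )
        values[col] = converted
    if values.index.has_duplicates:
        means = values.mean(axis=1)
        order = means.groupby(level=0).transform("max") == means
        # keep the first of equal-mean duplicates
        values = values[order]
        values = values[~values.index.duplicated(keep="first")]
        logger.info("%s: collapsed duplicate gene rows, kept highest-mean row", path)
    return ExpressionProfile(values, list(normal_group), list(cancer_group))


def write_expression_matrix(profile: ExpressionProfile, path: str | Path) -> None:
    path = Path(path)
    profile.values.to_csv(path, sep="\t", index_label="gene", float_format="%.6g")


# ---------------------------------------------------------------------------
# gene lists and identifier mapping
# ---------------------------------------------------------------------------

def read_gene_list(path: str | Path) -> set[str]:
    """One identifier per line; blank lines and ``#`` comments skipped."""
    path = Path(path)
    out: set[str] = set()
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            token = line.strip()
            if token and not token.startswith("#"):
                out.add(token)
    return out


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(genes)), encoding="utf-8")


def read_id_mapping(path: str | Path) -> dict[str, set[str]]:
    """Two-column TSV (from-ID, to-ID); one-to-many rows accumulate."""
    path = Path(path)
    mapping: dict[str, set[str]] = {}
    with path.open(encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or not row[0].strip():
                continue
            if len(row) < 2 or not row[1].strip():
                raise ParseError(f"{path}:{lineno}: malformed mapping row {row!r}")
            mapping.setdefault(row[0].strip(), set()).add(row[1].strip())
    return mapping


def map_identifiers(net: Interactome, mapping: Mapping[str, set[str]]) -> Interactome:
    """Translate node IDs through a one-to-many mapping.

    Nodes with several target accessions are expanded (all kept); nodes
    without any mapping are discarded with a logged count, together with
    their edges.
    """
    out = Interactome(net.resource_name)
    unmapped = [n for n in net.graph.nodes if n not in mapping]
    if unmapped:
        logger.info("%s: dropped %d unmapped node(s)", net.resource_name, len(unmapped))
    for u, v, _ in net.edges():
        for mu in mapping.get(u, ()):  # empty -> edge dropped
            for mv in mapping.get(v, ()):
                directed = (u, v) in net.directed_edges
                reverse = (v, u) in net.directed_edges
                out.add_edge(mu, mv, directed=directed)
                if reverse:
                    out.add_edge(mv, mu, directed=True)
    for n in net.graph.nodes:
        for mn in mapping.get(n, ()):
            out.add_node(mn)
    return out


# ---------------------------------------------------------------------------
# GO annotations (GAF 2.x)
# ---------------------------------------------------------------------------

def read_gaf(path: str | Path, aspect: str = "P") -> dict[str, set[str]]:
    """Read a GAF 2.x association file; keep only the requested aspect.

    Returns protein -> set of GO term IDs. Only biological-process rows
    (aspect ``P``) are kept by default; molecular-function (``F``) and
    cellular-component (``C``) rows are discarded. Column 2 is the object
    ID, column 5 the GO ID, column 9 the aspect (1-based GAF columns).
    """
    path = Path(path)
    annotations: dict[str, set[str]] = {}
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("!") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                raise ParseError(f"{path}:{lineno}: GAF row has {len(cols)} columns (< 9)")
            if cols[8] != aspect:
                continue
            protein, term = cols[1], cols[4]
            if not protein or not term.startswith("GO:"):
                raise ParseError(f"{path}:{lineno}: bad GAF identifiers {cols[1]!r}/{cols[4]!r}")
            annotations.setdefault(protein, set()).add(term)
    return annotations


def write_gaf(annotations: Mapping[str, Iterable[str]], path: str | Path,
              aspect: str = "P") -> None:
    """Write a minimal syntactically valid GAF 2.2 file."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("!gaf-version: 2.2\n")
        for protein in sorted(annotations):
            for term in sorted(annotations[protein]):
                cols = [
                    "SYNTH", protein, protein, "involved_in", term, "SYNTH:0000000",
                    "IEA", "", aspect, "", "", "protein", "taxon:9606",
                    "20150602", "SYNTH", "", "",
                ]
                fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# bioactivity table
# ---------------------------------------------------------------------------

def read_bioactivity(path: str | Path) -> BioactivityTable:
    """Read a TSV bioactivity table; duplicate rows are dropped."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"compound_id": str, "target_id": str})
    df = df.drop_duplicates()
    try:
        return BioactivityTable(df)
    except (ValueError, TypeError) as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_bioactivity(table: BioactivityTable, path: str | Path) -> None:
    path = Path(path)
    table.records.to_csv(path, sep="\t", index=False, float_format="%.6g")
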