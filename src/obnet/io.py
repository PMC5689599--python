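"""Readers and writers for the plain-text formats the package consumes.

All gene symbols are upper-cased at ingest: trait catalogues, interaction
databases and gene-set collections mix symbol casing freely, and silent
case mismatches are the classic way to lose half of a gene set on the way
into a network analysis.

Formats
-------
* edge list — TSV with columns ``gene1, gene2[, confidence]``, header
  optional (STRING-style exports fit directly);
* gene sets — GMT (``set_id TAB description TAB gene1 TAB gene2 ...``);
* trait-gene map — two-column TSV ``trait_id TAB gene``;
* gold trait list — one trait id per line;
* expression — TSV genes x samples plus a two-column sample/condition file;
* module assignment — two-column TSV ``gene TAB module_label``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

# A GeneNetwork is a networkx.Graph whose nodes are upper-case gene symbols
# and whose edges optionally carry a "confidence" attribute.
GeneNetwork = nx.Graph

_HEADER_TOKENS = {
    "gene1", "gene2", "protein1", "protein2", "node1", "node2",
    "source", "target", "combined_score", "confidence", "score",
}


@dataclass
class GeneSetCollection:
    """A named collection of gene sets (GO BP / KEGG style).

    ``entries`` maps a set id to a frozen set of upper-case gene symbols;
    ``descriptions`` keeps the GMT description column as metadata.
    """

    entries: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    source_tag: str = ""

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries.items())


@dataclass
class TraitGeneMap:
    """Map from trait id to its associated gene set."""

    traits: dict[str, frozenset[str]]

    def __len__(self) -> int:
        return len(self.traits)

    def __getitem__(self, trait_id: str) -> frozenset[str]:
        return self.traits[trait_id]

    def __contains__(self, trait_id: str) -> bool:
        return trait_id in self.traits


def _looks_like_header(cells: list[str]) -> bool:
    return any(c.strip().lower() in _HEADER_TOKENS for c in cells)


def read_edge_list(
    path: str | Path,
    min_confidence: float = 0.0,
    delimiter: str = "\t",
    id_map: dict[str, str] | None = None,
) -> GeneNetwork:
    """Read an undirected interaction network from a (STRING-style) edge list.

    Rows with a third numeric column are kept only when that confidence is
    ``>= min_confidence`` (inclusive, matching the "confidence 400" naming of
    STRING cut-offs); rows without a confidence column always pass.
    Self-loops are dropped and duplicate / reversed pairs collapsed, both with
    a logged count.

    Parameters
    ----------
    id_map
        Optional protein-id -> gene-symbol mapping (e.g. for
        ``9606.ENSP...`` STRING identifiers). Rows whose endpoints are not
        both mappable are dropped with a logged count.
    """
    path = Path(path)
    net: GeneNetwork = nx.Graph()
    if id_map is not None:
        id_map = {k.strip().upper(): v.strip().upper() for k, v in id_map.items()}
    n_self, n_unmapped = 0, 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            cells = line.split(delimiter)
            if lineno == 1 and _looks_like_header(cells):
                continue
            if len(cells) < 2:
                raise ValueError(f"{path}:{lineno}: expected >=2 columns, got {len(cells)}")
            a, b = cells[0].strip().upper(), cells[1].strip().upper()
            if not a or not b:
                raise ValueError(f"{path}:{lineno}: blank gene symbol")
            conf = None
            if len(cells) >= 3 and cells[2].strip():
                try:
                    conf = float(cells[2])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: non-numeric confidence {cells[2]!r}") from exc
            if id_map is not None:
                if a not in id_map or b not in id_map:
                    n_unmapped += 1
                    continue
                a, b = id_map[a], id_map[b]
            if a == b:
                n_self += 1
                continue
            if conf is not None and conf < min_confidence:
                continue
            if conf is None:
                net.add_edge(a, b)
            else:
                # keep the max confidence over duplicate rows
                prev = net.edges[a, b]["confidence"] if net.has_edge(a, b) else -1.0
                net.add_edge(a, b, confidence=max(conf, prev))
    if n_self:
        logger.info("read_edge_list: dropped %d self-loop row(s)", n_self)
    if n_unmapped:
        logger.info("read_edge_list: dropped %d unmappable row(s)", n_unmapped)
    if net.number_of_edges() == 0:
        raise ValueError(f"{path}: no edges remain after filtering (min_confidence={min_confidence})")
    return net


def write_edge_list(net: GeneNetwork, path: str | Path, delimiter: str = "\t") -> None:
    """Write a network as a canonical (sorted unordered pairs) edge list."""
    path = Path(path)
    has_conf = any("confidence" in d for _, _, d in net.edges(data=True))
    with path.open("w") as fh:
        header = ["gene1", "gene2"] + (["confidence"] if has_conf else [])
        fh.write(delimiter.join(header) + "\n")
        for a, b in sorted(tuple(sorted(e)) for e in net.edges()):
            row = [a, b]
            if has_conf:
                row.append(format(net.edges[a, b].get("confidence", 0.0), "g"))
            fh.write(delimiter.join(row) + "\n")


def read_gmt(path: str | Path, source_tag: str = "") -> GeneSetCollection:
    """Read a GMT gene-set file (id, description, then one gene per field)."""
    path = Path(path)
    entries: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            cells = line.split("\t")
            if len(cells) < 3:
                raise ValueError(f"{path}:{lineno}: GMT row needs id, description and >=1 gene")
            set_id, desc = cells[0].strip(), cells[1].strip()
            genes = frozenset(g.strip().upper() for g in cells[2:] if g.strip())
            if not genes:
                raise ValueError(f"{path}:{lineno}: gene set {set_id!r} is empty")
            if set_id in entries:
                raise ValueError(f"{path}:{lineno}: duplicate set id {set_id!r}")
            entries[set_id] = genes
            descriptions[set_id] = desc
    return GeneSetCollection(entries=entries, descriptions=descriptions, source_tag=source_tag)


def write_gmt(sets: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for set_id, genes in sets.entries.items():
            desc = sets.descriptions.get(set_id, "")
            fh.write("\t".join([set_id, desc] + sorted(genes)) + "\n")


def read_trait_table(path: str | Path) -> TraitGeneMap:
    """Read a two-column ``trait_id TAB gene`` table into a TraitGeneMap.

    Rows with a blank gene symbol are skipped with a logged warning;
    duplicate (trait, gene) rows collapse by set semantics.
    """
    path = Path(path)
    traits: dict[str, set[str]] = {}
    n_blank = 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            cells = line.split("\t")
            if lineno == 1 and cells[0].strip().lower() in {"trait", "trait_id", "disease", "disease_id"}:
                continue
            if len(cells) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            trait, gene = cells[0].strip(), cells[1].strip().upper()
            if not gene:
                n_blank += 1
                logger.warning("read_trait_table: %s:%d blank gene symbol, row skipped", path, lineno)
                continue
            traits.setdefault(trait, set()).add(gene)
    return TraitGeneMap(traits={t: frozenset(g) for t, g in traits.items()})


def write_trait_table(tm: TraitGeneMap, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("trait_id\tgene\n")
        for trait in sorted(tm.traits):
            for gene in sorted(tm.traits[trait]):
                fh.write(f"{trait}\t{gene}\n")


def read_gold_list(path: str | Path) -> frozenset[str]:
    """Read a gold trait list, one trait id per line."""
    with Path(path).open() as fh:
        return frozenset(line.strip() for line in fh if line.strip())


def write_gold_list(ids, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for t in sorted(ids):
            fh.write(t + "\n")


def read_expression(values_path: str | Path, condition_path: str | Path):
    """Read a genes x samples expression TSV and its sample/condition file.

    Returns an :class:`obnet.validation.ExpressionMatrix`.
    """
    from .validation import ExpressionMatrix

    values = pd.read_csv(values_path, sep="\t", index_col=0)
    values.index = values.index.astype(str).str.upper()
    cond = pd.read_csv(condition_path, sep="\t", index_col=0).iloc[:, 0]
    cond.index = cond.index.astype(str)
    missing = [s for s in values.columns if s not in cond.index]
    if missing:
        raise ValueError(f"samples without condition label: {missing[:5]}")
    return ExpressionMatrix(values=values, condition=cond.loc[values.columns])


def read_module_assignment(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a two-column ``gene TAB module_label`` assignment table."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "label"], dtype=str)
    if df["gene"].iloc[0].strip().lower() == "gene":
        df = df.iloc[1:]
    out: dict[str, set[str]] = {}
    for gene, label in zip(df["gene"], df["label"]):
        out.setdefault(label.strip(), set()).add(gene.strip().upper())
    return {k: frozenset(v) for k, v in out.items()}
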