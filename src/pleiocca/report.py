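"""Thresholds, gene-set algebra, gene classification, and graph summaries.

The triangulation step of a pleiotropy analysis is set arithmetic: genes
significant in the summary-statistics CCA are intersected with externally
produced validation sets (gene-based tests, TWAS hits, predicted drug
targets) and classified against literature-curated known-gene lists.  A
small rule grammar ("CCA & (VEGAS_HF | VEGAS_CKD)") expresses which
combination counts as validated.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import pandas as pd

from .errors import DomainError, FormatError

__all__ = [
    "GeneSet",
    "GeneClassification",
    "bonferroni_threshold",
    "read_gene_list",
    "read_edge_list",
    "intersect_gene_sets",
    "select_genes",
    "classify_genes",
    "graph_summary",
]


@dataclass(frozen=True)
class GeneSet:
    """A labelled set of gene symbols (upper-cased, whitespace-trimmed)."""

    label: str
    genes: frozenset

    @classmethod
    def from_iterable(cls, label: str, genes) -> "GeneSet":
        return cls(label=label, genes=frozenset(str(g).strip().upper() for g in genes))

    def __contains__(self, gene: str) -> bool:
        return str(gene).strip().upper() in self.genes

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class GeneClassification:
    """A gene's literature status with respect to the two diseases."""

    gene: str
    status: str  # confirmed | potential | novel
    evidence_1: bool
    evidence_2: bool


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance threshold ``alpha / m`` for m tests."""
    if not (0 < alpha < 1):
        raise DomainError("alpha must lie in (0, 1)")
    if m < 1:
        raise DomainError("number of tests must be >= 1")
    return alpha / m


def format_threshold(value: float) -> str:
    """Human-readable threshold at 3 significant figures (e.g. 6.54e-07)."""
    return f"{value:.2e}"


def read_gene_list(path, label: str) -> GeneSet:
    """One gene symbol per line; ``#`` comments and blank lines ignored."""
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                genes.append(line)
    return GeneSet.from_iterable(label, genes)


def read_edge_list(path) -> list[tuple[str, str]]:
    """Tab-separated two-column undirected edge list."""
    edges = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}: expected 2 tab-separated fields")
            edges.append((parts[0].strip(), parts[1].strip()))
    return edges


def intersect_gene_sets(sets: list[GeneSet]) -> tuple[pd.DataFrame, dict]:
    """Membership table and Venn-region counts for >= 2 gene sets.

    Returns a per-gene boolean membership frame (one column per set label)
    and a dict mapping each non-empty label combination (as a sorted tuple)
    to the count of genes belonging to exactly those sets.
    """
    if len(sets) < 2:
        raise DomainError("need at least two gene sets")
    labels = [s.label for s in sets]
    if len(set(labels)) != len(labels):
        raise DomainError("gene-set labels must be unique")
    universe = sorted(set().union(*(s.genes for s in sets)))
    table = pd.DataFrame(
        {s.label: [g in s.genes for g in universe] for s in sets}, index=universe
    )
    table.index.name = "GENE"
    regions = {}
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            inside = table[list(combo)].all(axis=1)
            outside = ~table[[l for l in labels if l not in combo]].any(axis=1) \
                if len(combo) < len(labels) else pd.Series(True, index=table.index)
            regions[tuple(sorted(combo))] = int((inside & outside).sum())
    return table, regions


class _RuleParser:
    """Tiny recursive-descent parser for set rules: ``A & (B | C)``.

    ``|`` binds loosest, ``&`` tighter; parentheses group; names are set
    labels (letters, digits, ``_``, ``-``).
    """

    def __init__(self, text: str, sets: dict):
        self.tokens = self._lex(text)
        self.pos = 0
        self.sets = sets

    @staticmethod
    def _lex(text: str):
        tokens, i = [], 0
        while i < len(text):
            c = text[i]
            if c.isspace():
                i += 1
            elif c in "&|()":
                tokens.append(c)
                i += 1
            else:
                j = i
                while j < len(text) and (text[j].isalnum() or text[j] in "_-"):
                    j += 1
                if j == i:
                    raise FormatError(f"bad character {c!r} in rule")
                tokens.append(text[i:j])
                i = j
        return tokens

    def _peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def _eat(self, tok=None):
        cur = self._peek()
        if cur is None or (tok is not None and cur != tok):
            raise FormatError(f"rule syntax error near token {cur!r}")
        self.pos += 1
        return cur

    def parse(self) -> frozenset:
        out = self._or()
        if self._peek() is not None:
            raise FormatError(f"unexpected trailing token {self._peek()!r}")
        return out

    def _or(self):
        left = self._and()
        while self._peek() == "|":
            self._eat("|")
            left = left | self._and()
        return left

    def _and(self):
        left = self._atom()
        while self._peek() == "&":
            self._eat("&")
            left = left & self._atom()
        return left

    def _atom(self):
        tok = self._eat()
        if tok == "(":
            inner = self._or()
            self._eat(")")
            return inner
        if tok in "&|)":
            raise FormatError(f"rule syntax error near token {tok!r}")
        if tok not in self.sets:
            raise FormatError(f"unknown set label {tok!r} in rule")
        return self.sets[tok].genes


def select_genes(sets: list[GeneSet], rule: str) -> GeneSet:
    """Evaluate a set rule like ``"CCA & (VEGAS | TWAS)"`` over labelled sets."""
    by_label = {s.label: s for s in sets}
    selected = _RuleParser(rule, by_label).parse()
    return GeneSet(label=rule, genes=frozenset(selected))


def classify_genes(
    selected: GeneSet,
    known_1: GeneSet,
    known_2: GeneSet,
    pvalues: dict | None = None,
) -> pd.DataFrame:
    """Classify each selected gene against two known-disease-gene lists.

    confirmed: present in both known lists; potential: in exactly one;
    novel: in neither.  Sorted by the supplied p-values when given (then
    alphabetically), else alphabetically.
    """
    rows = []
    for gene in sorted(selected.genes):
        e1, e2 = gene in known_1, gene in known_2
        status = "confirmed" if (e1 and e2) else ("potential" if (e1 or e2) else "novel")
        rows.append(
            {
                "GENE": gene,
                "STATUS": status,
                f"KNOWN_{known_1.label}": e1,
                f"KNOWN_{known_2.label}": e2,
            }
        )
    out = pd.DataFrame(rows)
    if pvalues and len(out):
        out["PVAL"] = [pvalues.get(g, float("nan")) for g in out["GENE"]]
        out = out.sort_values(["PVAL", "GENE"], na_position="last").reset_index(drop=True)
    return out


@dataclass(frozen=True)
class GraphSummary:
    n_nodes: int
    n_edges: int
    mean_degree: float

    @property
    def mean_degree_display(self) -> float:
        """Mean degree rounded to 2 decimals for human-readable output."""
        return round(self.mean_degree, 2)


def graph_summary(edges) -> GraphSummary:
    """Node count, edge count and average degree of an undirected graph.

    Duplicate edges (either orientation) are collapsed; self-loops are
    rejected.  Average degree is 2E/N.
    """
    g = nx.Graph()
    for u, v in edges:
        if u == v:
            raise DomainError(f"self-loop on node {u!r} rejected")
        g.add_edge(u, v)
    n, e = g.number_of_nodes(), g.number_of_edges()
    if n == 0:
        raise DomainError("empty edge list")
    return GraphSummary(n_nodes=n, n_edges=e, mean_degree=2.0 * e / n)
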