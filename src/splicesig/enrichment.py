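"""Gene-set enrichment by Fisher's exact test and proteomics set logic.

Enrichment of a query gene list against GMT gene-set collections is tested
one-sided (over-representation) on the 2x2 table
[[overlap, query - overlap], [set - overlap, rest of universe]] with BH
adjustment across sets; gene symbols are case-normalized. Term hierarchies
are not modelled — each supplied set is tested flat.

The proteomics operations mirror a three-experiment pull-down design: an
anchor list (tight binders) filtered for common contaminants (keratins,
ribosomal proteins) and intersected with the union of support lists yields
high-confidence interactors; category fractions report how many of those
fall in a functional category.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .usage import ConfigurationError

__all__ = [
    "GeneSet",
    "ProteinListSet",
    "read_gmt",
    "write_gmt",
    "fisher_enrich",
    "high_confidence_interactors",
    "category_fraction",
    "DEFAULT_CONTAMINANT_PATTERNS",
]

DEFAULT_CONTAMINANT_PATTERNS = (r"^KRT", r"^RPL", r"^RPS")


def _norm(symbols: Iterable[str]) -> set[str]:
    return {s.strip().upper() for s in symbols if s and s.strip()}


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(_norm(self.members)))
        if not self.members:
            raise ValueError(f"gene set {self.set_id!r} has no members")


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read a GMT file: set_id <tab> description <tab> member..."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3 or not fields[0]:
                continue
            sets.append(GeneSet(fields[0], fields[1], frozenset(fields[2:])))
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.set_id, s.description, *sorted(s.members)]) + "\n")


def fisher_enrich(
    query: Iterable[str],
    sets: Sequence[GeneSet],
    universe: Iterable[str],
    alpha: float = 0.05,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Fisher-exact enrichment of ``query`` against each gene set.

    Query members outside the universe are dropped with a warning; set
    members are likewise restricted to the universe. ``fold_enrichment`` is
    (overlap/query) / (set/universe). Returns a DataFrame indexed by set_id
    with BH-adjusted p-values.
    """
    uni = _norm(universe)
    q = _norm(query)
    if not uni:
        raise ConfigurationError("empty universe")
    if not q:
        raise ConfigurationError("empty query")
    dropped = q - uni
    if dropped:
        warnings.warn(f"{len(dropped)} query genes outside the universe dropped")
        q = q & uni
        if not q:
            raise ConfigurationError("no query genes left inside the universe")
    N, nq = len(uni), len(q)
    rows = []
    for s in sets:
        members = s.members & uni
        k = len(q & members)
        ns = len(members)
        table = [[k, nq - k], [ns - k, N - nq - ns + k]]
        odds, p = stats.fisher_exact(table, alternative=alternative)
        fold = (k / nq) / (ns / N) if ns else 0.0
        rows.append((s.set_id, nq, ns, k, N, odds, fold, p))
    df = pd.DataFrame(
        rows,
        columns=[
            "set_id",
            "n_query",
            "n_set",
            "n_overlap",
            "n_universe",
            "odds_ratio",
            "fold_enrichment",
            "p_value",
        ],
    ).set_index("set_id")
    df["p_adjust"] = multipletests(df["p_value"], method="fdr_bh")[1] if len(df) else []
    df["significant"] = df["p_adjust"] <= alpha
    return df


@dataclass
class ProteinListSet:
    """Labelled protein-identifier lists with shared contaminant-exclusion rules."""

    lists: dict[str, set[str]]
    contaminant_patterns: tuple[str, ...] = DEFAULT_CONTAMINANT_PATTERNS
    _regex: re.Pattern = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.lists = {label: _norm(ids) for label, ids in self.lists.items()}
        self._regex = re.compile("|".join(self.contaminant_patterns)) if self.contaminant_patterns else None

    @classmethod
    def from_files(
        cls,
        paths: Mapping[str, str | Path],
        contaminant_patterns: tuple[str, ...] = DEFAULT_CONTAMINANT_PATTERNS,
    ) -> "ProteinListSet":
        lists = {}
        for label, path in paths.items():
            with open(path) as fh:
                lists[label] = {line.strip() for line in fh if line.strip()}
        return cls(lists, contaminant_patterns)

    def is_contaminant(self, identifier: str) -> bool:
        return bool(self._regex and self._regex.match(identifier.upper()))

    def without_contaminants(self, label: str) -> set[str]:
        if label not in self.lists:
            raise ConfigurationError(f"unknown protein list label {label!r}")
        return {p for p in self.lists[label] if not self.is_contaminant(p)}


def high_confidence_interactors(
    lists: ProteinListSet,
    anchor_label: str,
    support_labels: Sequence[str],
) -> set[str]:
    """(anchor minus contaminants) intersected with the union of support lists.

    Mirrors the three-experiment design: proteins from the tight-binding
    anchor experiment, cleaned of keratin/ribosomal contaminants, that were
    also observed in at least one supporting experiment.
    """
    anchor = lists.without_contaminants(anchor_label)
    support: set[str] = set()
    for label in support_labels:
        if label not in lists.lists:
            raise ConfigurationError(f"unknown protein list label {label!r}")
        support |= lists.lists[label]
    return anchor & support


def category_fraction(
    proteins: Iterable[str], category_set: GeneSet
) -> tuple[int, int, float]:
    """|proteins in category| / |proteins|; empty input reported as (0, 0, 0.0)."""
    prot = _norm(proteins)
    if not prot:
        return (0, 0, 0.0)
    k = len(prot & category_set.members)
    return (k, len(prot), k / len(prot))
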