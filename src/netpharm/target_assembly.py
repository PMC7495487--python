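"""Canonicalization and set algebra for gene-symbol target lists.

Target lists arrive from heterogeneous sources — compound-target "fishing"
services, disease databases, differential-expression output — with
inconsistent casing, stray whitespace, and occasional alternative symbols.
This module normalizes every list to canonical uppercase gene symbols,
merges lists with per-source provenance, and intersects the drug-target
set with the disease-target set to obtain the composite targets that seed
all downstream network analysis.

Matching is case-insensitive and exact (after an optional user-supplied
alias lookup); no fuzzy matching is attempted — a silent wrong merge is
worse than a miss, and misses remain visible in the provenance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

__all__ = [
    "TargetSet",
    "canonicalize",
    "union_dedup",
    "intersect",
    "venn_counts",
]


@dataclass
class TargetSet:
    """A deduplicated set of canonical gene symbols with provenance.

    Parameters
    ----------
    label:
        Human-readable name of the set (e.g. ``"drug-targets"``).
    symbols:
        Canonical (trimmed, uppercase) gene symbols.
    provenance:
        Maps each symbol to the set of source tags that contributed it.
        Every symbol carries at least one tag.
    """

    label: str
    symbols: set[str] = field(default_factory=set)
    provenance: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.symbols = set(self.symbols)
        for s in self.symbols:
            if not s or s != s.strip() or s != s.upper():
                raise ValueError(f"non-canonical symbol in TargetSet: {s!r}")
            self.provenance.setdefault(s, {self.label})
        # provenance may not reference symbols outside the set
        extra = set(self.provenance) - self.symbols
        if extra:
            raise ValueError(f"provenance for unknown symbols: {sorted(extra)}")

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.symbols

    def __iter__(self):
        return iter(sorted(self.symbols))


def canonicalize(raw: str, alias_map: Mapping[str, str] | None = None) -> str | None:
    """Normalize one raw identifier to a canonical gene symbol.

    The identifier is trimmed, passed through the optional alias map
    (exact-match lookup on the trimmed string), and uppercased. Empty or
    whitespace-only input is rejected with a warning and ``None`` is
    returned so callers can drop it.
    """
    s = str(raw).strip()
    if not s:
        logger.warning("empty identifier rejected during canonicalization")
        return None
    if alias_map is not None:
        s = alias_map.get(s, s)
    return s.upper()


def union_dedup(
    lists: Iterable[tuple[str, Iterable[str]]],
    alias_map: Mapping[str, str] | None = None,
    label: str = "union",
) -> TargetSet:
    """Merge labelled symbol lists into one deduplicated TargetSet.

    Each input is a ``(source_label, symbols)`` pair. Symbols are
    canonicalized; a symbol contributed by several sources keeps the union
    of their labels as provenance.
    """
    symbols: set[str] = set()
    prov: dict[str, set[str]] = {}
    n_lists = 0
    for source, raw_symbols in lists:
        n_lists += 1
        for raw in raw_symbols:
            sym = canonicalize(raw, alias_map)
            if sym is None:
                continue
            symbols.add(sym)
            prov.setdefault(sym, set()).add(source)
    if n_lists == 0:
        logger.warning("union_dedup called with no input lists; empty set returned")
    return TargetSet(label=label, symbols=symbols, provenance=prov)


def intersect(a: TargetSet, b: TargetSet, label: str | None = None) -> TargetSet:
    """Intersect two target sets, merging provenance from both sides."""
    common = a.symbols & b.symbols
    prov = {
        s: set(a.provenance.get(s, set())) | set(b.provenance.get(s, set()))
        for s in common
    }
    return TargetSet(
        label=label if label is not None else f"{a.label}&{b.label}",
        symbols=common,
        provenance=prov,
    )


def venn_counts(a: TargetSet, b: TargetSet) -> tuple[int, int, int]:
    """Return ``(|a only|, |b only|, |a ∩ b|)``; the three sum to |a ∪ b|."""
    both = len(a.symbols & b.symbols)
    return (len(a.symbols) - both, len(b.symbols) - both, both)
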