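"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as directly as possible from the definitions —
explicit double loops, exhaustive enumeration — and deliberately shares no
code with the package internals it checks.
"""

from __future__ import annotations

import math
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple


def go_score_oracle(
    terms: Iterable[str],
    class_term_counts: Mapping[str, Mapping[str, int]],
    proteome_term_counts: Mapping[str, int],
) -> Dict[str, float]:
    """Double-loop mean of n_ct / n_t over usable terms, per class."""
    usable = sorted(t for t in set(terms) if proteome_term_counts.get(t, 0) >= 1)
    out = {}
    for cls, counts in class_term_counts.items():
        total = 0.0
        for t in usable:
            total += counts.get(t, 0) / proteome_term_counts[t]
        out[cls] = total / len(usable)
    return out


def npi_oracle(
    protein: str,
    edges: Sequence[Tuple[str, str]],
    localisations: Mapping[str, Sequence[str]],
    label_distance: Mapping[str, float],
    excluded: Set[str] = frozenset(),
):
    """Enumerate partners and regions straight from the definitions."""
    partners = set()
    for a, b in edges:
        if a == b:
            continue
        if a == protein:
            partners.add(b)
        if b == protein:
            partners.add(a)
    partners -= set(excluded)
    np_values = []
    for p in sorted(partners):
        regions = list(localisations.get(p, ()))
        if not regions:
            continue
        np_values.append(sum(label_distance[r] for r in regions) / len(regions))
    if not np_values:
        return None
    return sum(np_values) / len(np_values)


def product_score_oracle(
    priors: Sequence[float],
    tables: Mapping[str, Sequence[Sequence[float]]],
    bins: Mapping[str, int | None],
) -> List[float]:
    """Plain-float prior x product of table entries, skipping missing."""
    scores = list(priors)
    for ch, b in bins.items():
        if b is None:
            continue
        row = tables[ch][b]
        scores = [s * row[i] for i, s in enumerate(scores)]
    return scores


def one_vs_rest_metrics(confusion: Sequence[Sequence[int]]):
    """Per-class sensitivity/PPV from explicit TP/FP/FN tallies."""
    k = len(confusion)
    total = sum(sum(row) for row in confusion)
    sens, ppv = [], []
    for c in range(k):
        tp = confusion[c][c]
        fn = sum(confusion[c][j] for j in range(k) if j != c)
        fp = sum(confusion[i][c] for i in range(k) if i != c)
        sens.append(tp / (tp + fn) if tp + fn else math.nan)
        ppv.append(tp / (tp + fp) if tp + fp else math.nan)
    accuracy = sum(confusion[c][c] for c in range(k)) / total
    return sens, ppv, accuracy


def closure_oracle(edges: Sequence[Tuple[str, str]], term: str) -> Set[str]:
    """All nodes with a child->parent path into ``term``, by exhaustive
    path search."""
    nodes = {term}
    for a, b in edges:
        nodes.add(a)
        nodes.add(b)

    def reaches(u: str, target: str, seen: Set[str]) -> bool:
        if u == target:
            return True
        for a, b in edges:
            if a == u and b not in seen and reaches(b, target, seen | {b}):
                return True
        return False

    return {u for u in nodes if reaches(u, term, {u})}


def enumerate_global_alignments(a: str, b: str):
    """Yield (score, identical_columns, total_columns) for every global
    alignment under match 1 / mismatch 0 / linear gap -1 scoring."""
    standard = set("ACDEFGHIKLMNPQRSTVWY")

    def rec(i: int, j: int):
        if i == len(a) and j == len(b):
            yield (0.0, 0, 0)
            return
        if i < len(a) and j < len(b):
            ident = int(a[i] == b[j] and a[i] in standard)
            sc = 1.0 if ident else 0.0
            for s, d, c in rec(i + 1, j + 1):
                yield (s + sc, d + ident, c + 1)
        if i < len(a):
            for s, d, c in rec(i + 1, j):
                yield (s - 1.0, d, c + 1)
        if j < len(b):
            for s, d, c in rec(i, j + 1):
                yield (s - 1.0, d, c + 1)

    yield from rec(0, 0)


def optimal_alignment_identities(a: str, b: str) -> Set[float]:
    """Identity fractions of every optimal-score global alignment."""
    alignments = list(enumerate_global_alignments(a, b))
    best = max(s for s, _, _ in alignments)
    return {d / c for s, d, c in alignments if s == best}
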