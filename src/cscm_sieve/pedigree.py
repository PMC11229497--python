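"""Pedigree analysis: ancestor closures, inbreeding loops, Wright's F and
carrier tracing toward a putative founder.

Wright's inbreeding coefficient is computed by explicit path counting
(feasible at the pedigree sizes of a case series):

    F_X = sum over common ancestors A of X's parents, over pairs of
          ancestor-disjoint paths (sire -> A, dam -> A),
          (1/2)^(n1 + n2 + 1) * (1 + F_A)

with F_A computed recursively and memoized.  The tabular
additive-relationship method is provided as an independent cross-check
(:func:`additive_relationship`).  Unknown parents are treated as unique,
non-inbred founders.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

GENOTYPE_LABELS = ("hom_alt", "het", "hom_ref", "unknown")


@dataclass
class Pedigree:
    """A sire/dam DAG with optional per-animal genotype labels."""

    parents: dict[str, tuple[str | None, str | None]]
    sex: dict[str, str] = field(default_factory=dict)
    genotype_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for animal, (sire, dam) in self.parents.items():
            for p in (sire, dam):
                if p is not None and p not in self.parents:
                    # implicit founder: register with unknown parents
                    self.parents[p] = (None, None)
        for label in self.genotype_labels.values():
            if label not in GENOTYPE_LABELS:
                raise ValueError(f"bad genotype label {label!r}")
        self._assert_acyclic()

    def _assert_acyclic(self) -> None:
        state: dict[str, int] = {}

        def visit(node: str) -> None:
            state[node] = 1
            for p in self.parents[node]:
                if p is None:
                    continue
                s = state.get(p)
                if s == 1:
                    raise ValueError(f"pedigree cycle through {p!r}")
                if s is None:
                    visit(p)
            state[node] = 2

        for animal in list(self.parents):
            if animal not in state:
                visit(animal)

    @property
    def animals(self) -> list[str]:
        return list(self.parents)

    def founders(self) -> set[str]:
        return {a for a, (s, d) in self.parents.items() if s is None and d is None}

    def topological_order(self) -> list[str]:
        """Ancestors-first ordering (parents before offspring)."""
        order: list[str] = []
        seen: set[str] = set()

        def visit(node: str) -> None:
            if node in seen:
                return
            seen.add(node)
            for p in self.parents[node]:
                if p is not None:
                    visit(p)
            order.append(node)

        for animal in self.parents:
            visit(animal)
        return order

    @classmethod
    def from_ped(cls, df: pd.DataFrame) -> "Pedigree":
        parents = {}
        sex = {}
        labels = {}
        for row in df.itertuples(index=False):
            sire = None if pd.isna(row.sire) else row.sire
            dam = None if pd.isna(row.dam) else row.dam
            parents[row.id] = (sire, dam)
            sex[row.id] = str(row.sex)
            label = getattr(row, "genotype_label", None)
            if label is not None and not pd.isna(label) and label != "unknown":
                labels[row.id] = label
        return cls(parents, sex, labels)


def ancestors(ped: Pedigree, animal: str, max_gen: int | None = None) -> dict[str, int]:
    """Ancestor closure of one animal: {ancestor id: minimum generation distance}.

    Breadth-first over sire/dam links up to ``max_gen`` (None = unlimited);
    an ancestor reachable by several paths appears once at its minimum
    distance.  The animal itself is not included.
    """
    if animal not in ped.parents:
        raise KeyError(f"unknown animal {animal!r}")
    out: dict[str, int] = {}
    frontier = [animal]
    gen = 0
    while frontier and (max_gen is None or gen < max_gen):
        gen += 1
        nxt = []
        for node in frontier:
            for p in ped.parents[node]:
                if p is not None and p not in out:
                    out[p] = gen
                    nxt.append(p)
        frontier = nxt
    return out


def common_ancestors(
    ped: Pedigree, sire: str, dam: str, max_gen: int | None = None
) -> set[str]:
    """Ancestors shared by two animals (each animal counts as its own ancestor
    at distance 0, so a parent-offspring mating reports the parent).

    A non-empty result for the two parents of an animal flags an inbreeding
    loop for their offspring.
    """
    a = set(ancestors(ped, sire, max_gen)) | {sire}
    b = set(ancestors(ped, dam, max_gen)) | {dam}
    return a & b


def _paths_up(ped: Pedigree, start: str, target: str) -> list[tuple[str, ...]]:
    """All simple parent-link paths from ``start`` up to ``target``,
    as node tuples excluding the endpoints' duplicates (start...target)."""
    out: list[tuple[str, ...]] = []

    def walk(node: str, path: tuple[str, ...]) -> None:
        if node == target:
            out.append(path + (node,))
            return
        for p in ped.parents[node]:
            if p is not None:
                walk(p, path + (node,))

    walk(start, ())
    return out


def wright_inbreeding(ped: Pedigree, animal: str) -> float:
    """Wright's inbreeding coefficient by path counting (see module docstring)."""
    if animal not in ped.parents:
        raise KeyError(f"unknown animal {animal!r}")
    memo: dict[str, float] = {}

    def f(x: str) -> float:
        if x in memo:
            return memo[x]
        memo[x] = 0.0  # guards against revisits; pedigree already checked acyclic
        sire, dam = ped.parents[x]
        if sire is None or dam is None:
            return 0.0
        commons = common_ancestors(ped, sire, dam)
        total = 0.0
        for a in sorted(commons):
            for p1, p2 in product(_paths_up(ped, sire, a), _paths_up(ped, dam, a)):
                # ancestor-disjoint: the two paths may share only A itself
                if set(p1) & set(p2) != {a}:
                    continue
                n1, n2 = len(p1) - 1, len(p2) - 1
                total += 0.5 ** (n1 + n2 + 1) * (1.0 + f(a))
        memo[x] = total
        return total

    return f(animal)


def additive_relationship(ped: Pedigree) -> tuple[pd.DataFrame, dict[str, float]]:
    """Tabular (recursive) additive-relationship matrix A and inbreeding F.

    a_ii = 1 + 0.5 * a(sire_i, dam_i); a_ij = 0.5 * (a(sire_i, j) + a(dam_i, j))
    filling ancestors-first.  Returns (A as DataFrame, {animal: F}).
    Kept as the independent oracle for :func:`wright_inbreeding`.
    """
    order = ped.topological_order()
    idx = {a: i for i, a in enumerate(order)}
    n = len(order)
    A = np.zeros((n, n))
    for i, animal in enumerate(order):
        sire, dam = ped.parents[animal]
        si = idx[sire] if sire is not None else None
        di = idx[dam] if dam is not None else None
        for j in range(i):
            contrib = 0.0
            if si is not None:
                contrib += A[si, j]
            if di is not None:
                contrib += A[di, j]
            A[i, j] = A[j, i] = 0.5 * contrib
        A[i, i] = 1.0 + (0.5 * A[si, di] if si is not None and di is not None else 0.0)
    F = {a: A[idx[a], idx[a]] - 1.0 for a in order}
    return pd.DataFrame(A, index=order, columns=order), F


@dataclass(frozen=True)
class CarrierTrace:
    """Result of tracing labeled carriers to candidate founder animals."""

    candidate_founders: tuple[str, ...]
    carrier_paths: dict[str, dict[str, tuple[tuple[str, ...], ...]]]
    inconsistent_carriers: tuple[str, ...]


def trace_carriers(ped: Pedigree, max_gen: int | None = None) -> CarrierTrace:
    """Trace the labeled carriers (het / hom_alt) to minimal common ancestors.

    Candidate founders are ancestors reachable from every carrier (a carrier
    counts as its own ancestor, covering the single-carrier case), minimised
    by dropping any candidate that is an ancestor of another candidate (the
    most recent plausible founders are kept).  A carrier is flagged
    genotype-inconsistent when, for every candidate founder, each of its
    descent paths passes through an animal labeled hom_ref.
    """
    carriers = [a for a, g in ped.genotype_labels.items() if g in ("het", "hom_alt")]
    if not carriers:
        raise ValueError("no animals labeled het or hom_alt")
    closures = {c: set(ancestors(ped, c, max_gen)) | {c} for c in carriers}
    common = set.intersection(*closures.values())
    # keep minimal (most recent) candidates
    minimal = {
        a for a in common if not any(b != a and a in ancestors(ped, b) for b in common)
    }
    paths: dict[str, dict[str, tuple[tuple[str, ...], ...]]] = {}
    inconsistent = []
    for c in carriers:
        paths[c] = {a: tuple(_paths_up(ped, c, a)) for a in sorted(minimal)}
        if minimal:
            blocked = all(
                all(
                    any(ped.genotype_labels.get(n) == "hom_ref" for n in p[1:-1])
                    for p in paths[c][a]
                )
                for a in paths[c]
                if paths[c][a]
            ) and any(paths[c][a] for a in paths[c])
            if blocked and c not in minimal:
                inconsistent.append(c)
    return CarrierTrace(tuple(sorted(minimal)), paths, tuple(inconsistent))
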