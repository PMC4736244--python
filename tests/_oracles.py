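"""Independent brute-force oracles for the similarity and closure math.

Everything here is deliberately naive (DFS, triple loops over term
pairs) and shares no code with the package implementation: these are the
reference answers the optimized paths are checked against.
"""

from __future__ import annotations

import math
import random

from phenoprior import Disease, DiseaseCatalog, OntologyDAG, Term


# ---------------------------------------------------------------------------
# naive closures by depth-first search over the raw parent map

def dfs_ancestors(parents: dict[str, set[str]], t: str) -> set[str]:
    out = set()

    def walk(x):
        if x in out:
            return
        out.add(x)
        for p in parents[x]:
            walk(p)

    walk(t)
    return out


def dfs_descendants(parents: dict[str, set[str]], t: str) -> set[str]:
    return {x for x in parents if t in dfs_ancestors(parents, x)}


def closure(parents: dict[str, set[str]], terms) -> set[str]:
    out = set()
    for t in terms:
        out |= dfs_ancestors(parents, t)
    return out


# ---------------------------------------------------------------------------
# naive metrics

def naive_ic(parents: dict[str, set[str]], diseases: dict[str, set[str]]) -> dict[str, float]:
    """ic(t) = -log(fraction of diseases with a term at or below t)."""
    n = sum(1 for ts in diseases.values() if ts)
    ic = {}
    for t in parents:
        count = sum(
            1 for ts in diseases.values()
            if any(t in dfs_ancestors(parents, s) for s in ts)
        )
        if count:
            ic[t] = -math.log(count / n) + 0.0
    return ic


def naive_resnik(parents, ic: dict[str, float], q: set[str], d: set[str]) -> float:
    qk = [t for t in q if t in ic]
    dk = [t for t in d if t in ic]
    if not qk or not dk:
        return 0.0

    def mica(a, b):
        common = dfs_ancestors(parents, a) & dfs_ancestors(parents, b)
        return max((ic.get(x, 0.0) for x in common), default=0.0)

    half_d = sum(max(mica(t1, t2) for t2 in qk) for t1 in dk) / len(dk)
    half_q = sum(max(mica(t1, t2) for t2 in dk) for t1 in qk) / len(qk)
    return 0.5 * half_d + 0.5 * half_q


def naive_ato(parents, q: set[str], d: set[str]) -> int:
    return len(closure(parents, q) & closure(parents, d))


def naive_weighted_ato(parents, q, d, weights: dict[str, float]) -> float:
    shared = closure(parents, q) & closure(parents, d)
    return sum(weights[t] for t in shared if t in weights)


def naive_tpc(parents: dict[str, set[str]], root: str) -> dict[str, float]:
    children: dict[str, set[str]] = {t: set() for t in parents}
    for t, ps in parents.items():
        for p in ps:
            children[p].add(t)

    memo: dict[str, float] = {}

    def tpc(t: str) -> float:
        if t == root:
            return 1.0
        if t not in memo:
            memo[t] = math.prod(tpc(p) / len(children[p]) for p in parents[t])
        return memo[t]

    return {t: tpc(t) for t in parents}


# ---------------------------------------------------------------------------
# random small fixtures, independent of the package generator

def random_parent_map(rng: random.Random, n_terms: int) -> dict[str, set[str]]:
    """Random rooted DAG: term i attaches to 1-2 earlier terms."""
    ids = [f"R{i:03d}" for i in range(n_terms)]
    parents: dict[str, set[str]] = {ids[0]: set()}
    for i in range(1, n_terms):
        k = min(i, rng.choice([1, 1, 2]))
        parents[ids[i]] = set(rng.sample(ids[:i], k))
    return parents


def random_fixture(seed: int, max_terms: int = 30, max_diseases: int = 10):
    """(parent map, disease term sets, query) for oracle comparisons."""
    rng = random.Random(seed)
    n_terms = rng.randint(6, max_terms)
    parents = random_parent_map(rng, n_terms)
    ids = sorted(parents)
    n_dis = rng.randint(2, max_diseases)
    diseases = {
        f"OD{j}": set(rng.sample(ids[1:], rng.randint(1, min(4, n_terms - 1))))
        for j in range(n_dis)
    }
    query = set(rng.sample(ids[1:], rng.randint(1, 4)))
    return parents, diseases, query


def build_package_objects(parents, diseases) -> tuple[OntologyDAG, DiseaseCatalog]:
    dag = OntologyDAG({t: Term(t, t, set(ps)) for t, ps in parents.items()})
    catalog = DiseaseCatalog()
    for did, ts in sorted(diseases.items()):
        for t in sorted(ts):
            catalog.add_annotation(did, did, t)
    return dag, catalog
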