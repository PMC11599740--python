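"""Independent brute-force oracles used to cross-check the implementation.

These deliberately use different machinery from the library: CTL semantics
via explicit reachability/cycle search instead of fixpoint labeling, and
betweenness via explicit enumeration of every shortest path instead of
Brandes' accumulation.
"""

from __future__ import annotations

from collections import deque
from typing import Dict, Iterable, List, Sequence, Set, Tuple

from qualdyn.ctl import (
    And,
    Atom,
    BoolConst,
    CtlFormula,
    Implies,
    Not,
    Or,
    Temporal,
    Until,
)

Node = object


def _reachable(succ: Dict[Node, List[Node]], start: Node) -> Set[Node]:
    seen = {start}
    queue = deque([start])
    while queue:
        u = queue.popleft()
        for v in succ[u]:
            if v not in seen:
                seen.add(v)
                queue.append(v)
    return seen


def ctl_sat_bruteforce(
    nodes: Sequence[Node],
    succ: Dict[Node, List[Node]],
    labels: Dict[Node, Dict[str, int]],
    formula: CtlFormula,
) -> Set[Node]:
    """Satisfaction set by explicit path reasoning on a totalized relation.

    ``succ`` must already be total (deadlocks carry a self-loop).  EG is
    decided by searching for a reachable cycle inside the subgraph of
    satisfying states; EF and EU by breadth-first reachability.
    """
    node_set = set(nodes)

    def sat(f: CtlFormula) -> Set[Node]:
        if isinstance(f, BoolConst):
            return set(node_set) if f.value else set()
        if isinstance(f, Atom):
            return {n for n in node_set if labels[n].get(f.entity) == f.level}
        if isinstance(f, Not):
            return node_set - sat(f.operand)
        if isinstance(f, And):
            return sat(f.left) & sat(f.right)
        if isinstance(f, Or):
            return sat(f.left) | sat(f.right)
        if isinstance(f, Implies):
            return (node_set - sat(f.left)) | sat(f.right)
        if isinstance(f, Temporal):
            if f.op == "EX":
                phi = sat(f.operand)
                return {n for n in node_set if any(v in phi for v in succ[n])}
            if f.op == "AX":
                phi = sat(f.operand)
                return {n for n in node_set if all(v in phi for v in succ[n])}
            if f.op == "EF":
                phi = sat(f.operand)
                return {n for n in node_set if _reachable(succ, n) & phi}
            if f.op == "AG":
                phi = sat(f.operand)
                return {n for n in node_set if _reachable(succ, n) <= phi}
            if f.op == "EG":
                phi = sat(f.operand)
                # restrict to phi; n satisfies iff it can reach a cycle
                # (incl. self-loop) lying wholly inside phi
                sub = {u: [v for v in succ[u] if v in phi] for u in phi}
                on_cycle = {
                    u
                    for u in phi
                    if any(u in _reachable(sub, v) for v in sub[u])
                }
                return {
                    n
                    for n in phi
                    if _reachable(sub, n) & on_cycle or n in on_cycle
                }
            if f.op == "AF":
                return node_set - sat(Temporal("EG", Not(f.operand)))
        if isinstance(f, Until):
            p, q = sat(f.left), sat(f.right)
            if f.quantifier == "E":
                out = set()
                for n in node_set:
                    sub = {u: [v for v in succ[u] if v in p | q] for u in p | q}
                    if n in q:
                        out.add(n)
                    elif n in p:
                        sub_reach = _reachable(sub, n)
                        if sub_reach & q:
                            out.add(n)
                return out
            # A[p U q] = ¬( E[¬q U ¬p∧¬q] ∨ EG ¬q )
            e_side = sat(Until("E", Not(f.right), And(Not(f.left), Not(f.right))))
            eg_side = sat(Temporal("EG", Not(f.right)))
            return node_set - (e_side | eg_side)
        raise TypeError(type(f))

    return sat(formula)


def betweenness_bruteforce(
    nodes: Sequence[Node], edges: Iterable[Tuple[Node, Node]]
) -> Dict[Node, float]:
    """Directed unnormalized betweenness by enumerating all shortest paths."""
    succ: Dict[Node, List[Node]] = {n: [] for n in nodes}
    for a, b in edges:
        succ[a].append(b)
    bc = {n: 0.0 for n in nodes}
    for s in nodes:
        # BFS distances from s
        dist = {s: 0}
        queue = deque([s])
        while queue:
            u = queue.popleft()
            for v in succ[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    queue.append(v)
        for t in nodes:
            if t == s or t not in dist or dist[t] == 0:
                continue
            # enumerate every shortest s->t path explicitly
            paths: List[List[Node]] = []
            stack = [[s]]
            while stack:
                path = stack.pop()
                u = path[-1]
                if u == t:
                    paths.append(path)
                    continue
                for v in succ[u]:
                    if v in dist and dist[v] == len(path) and dist[v] <= dist[t]:
                        stack.append(path + [v])
            if not paths:
                continue
            for path in paths:
                for mid in path[1:-1]:
                    bc[mid] += 1.0 / len(paths)
    return bc


def random_ctl_formula(rng, entities: Sequence[str], max_level: int, depth: int):
    """A random CTL formula of bounded depth over the given atoms."""
    if depth == 0 or rng.random() < 0.25:
        r = rng.random()
        if r < 0.1:
            return BoolConst(rng.random() < 0.5)
        return Atom(rng.choice(list(entities)), rng.randint(0, max_level))
    choice = rng.randint(0, 6)
    if choice == 0:
        return Not(random_ctl_formula(rng, entities, max_level, depth - 1))
    if choice == 1:
        return And(
            random_ctl_formula(rng, entities, max_level, depth - 1),
            random_ctl_formula(rng, entities, max_level, depth - 1),
        )
    if choice == 2:
        return Or(
            random_ctl_formula(rng, entities, max_level, depth - 1),
            random_ctl_formula(rng, entities, max_level, depth - 1),
        )
    if choice == 3:
        return Implies(
            random_ctl_formula(rng, entities, max_level, depth - 1),
            random_ctl_formula(rng, entities, max_level, depth - 1),
        )
    if choice == 4:
        op = rng.choice(["EX", "EF", "EG", "AX", "AF", "AG"])
        return Temporal(op, random_ctl_formula(rng, entities, max_level, depth - 1))
    return Until(
        rng.choice(["E", "A"]),
        random_ctl_formula(rng, entities, max_level, depth - 1),
        random_ctl_formula(rng, entities, max_level, depth - 1),
    )
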