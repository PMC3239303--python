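"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by exhaustive enumeration or a naive
fixpoint re-scan, sharing as little code as possible with the package
implementation it checks.
"""

from __future__ import annotations

import itertools

from regevents.semantics import (
    Call,
    EntityRef,
    Literal,
    SemanticStructure,
    Var,
    canonical,
)


# --------------------------------------------------------------------------
# Ontology: reflexive-transitive closure by boolean-matrix expansion.

def subsumption_closure(concepts, edges):
    """{(child, ancestor)} pairs, reflexive and transitive, from is-a pairs."""
    pairs = {(c, c) for c in concepts} | set(edges)
    while True:
        extra = {(a, c) for (a, b1) in pairs for (b2, c) in pairs if b1 == b2} - pairs
        if not extra:
            return pairs
        pairs |= extra


# --------------------------------------------------------------------------
# Trees: reachability over the child relation.

def reachable_descendants(children, node):
    out = set()
    frontier = [node]
    while frontier:
        for child in children.get(frontier.pop(), ()):
            if child not in out:
                out.add(child)
                frontier.append(child)
    return out


# --------------------------------------------------------------------------
# Dictionary NER: recursive leftmost-longest reference.

def leftmost_longest_spans(forms, surfaces):
    """Greedy leftmost-longest tiling computed recursively; surfaces is a
    set of token tuples."""
    widths = sorted({len(s) for s in surfaces}, reverse=True)

    def rec(i):
        if i >= len(forms):
            return []
        for width in widths:
            if i + width <= len(forms) and tuple(forms[i : i + width]) in surfaces:
                return [(i + 1, i + 1 + width)] + rec(i + width)
        return rec(i + 1)

    return rec(0)


def all_tilings(forms, surfaces):
    """Every set of non-overlapping dictionary spans (token-index pairs)."""
    n = len(forms)
    spans = [
        (i + 1, i + w + 1)
        for i in range(n)
        for w in range(1, n - i + 1)
        if tuple(forms[i : i + w]) in surfaces
    ]
    tilings = []
    for r in range(len(spans) + 1):
        for combo in itertools.combinations(spans, r):
            if all(a2 <= b1 or b2 <= a1 for (a1, a2), (b1, b2) in itertools.combinations(combo, 2)):
                tilings.append(frozenset(combo))
    return tilings


# --------------------------------------------------------------------------
# Loose matching: exhaustive assignment enumeration on small trees.

def _tree_path(graph, ancestor, node):
    """Token indices from *ancestor* (exclusive) to *node* (inclusive),
    recomputed by walking head links."""
    path, current = [], node
    while current != ancestor:
        path.append(current)
        head = graph.token(current).head
        if head == 0:
            return None
        current = head
    return list(reversed(path))


def _ok_path(graph, anchor, node, config):
    path = _tree_path(graph, anchor, node)
    if path is None:
        return False
    for mid in path[:-1]:
        lemma = graph.token(mid).lemma.lower()
        if lemma in config.boundary_lemmas or lemma in config.exception_lemmas:
            return False
        for other in graph.tokens.values():
            if other.head == mid and other.lemma.lower() in config.boundary_lemmas:
                return False
    return True


def _ok_role(graph, anchor, node, role, config):
    path = _tree_path(graph, anchor, node)
    return path is not None and any(
        config.satisfies_role(role, graph.token(n).role) for n in path
    )


def _item_list(item, parent_id=None, out=None):
    """Flatten a pattern's dependent items to (id, item, parent_id)."""
    if out is None:
        out = []
    for child in item.children:
        cid = len(out)
        out.append((cid, child, parent_id))
        _item_list(child, cid, out)
    return out


def _sem_ok(value, concept, ont):
    if concept is None:
        return True
    if isinstance(value, SemanticStructure):
        return ont.is_subconcept(value.concept, concept)
    if isinstance(value, EntityRef):
        return any(ont.is_subconcept(label, concept) for label in value.labels)
    return False


def enumerate_matches(pattern, node, graph, semantics_index, ont, config):
    """All condition-1..3-valid full assignments, by brute force over the
    cartesian product of (node, semantics) choices per item, followed by
    the same distinct-entities deduplication rule the implementation
    documents (prefer minimal depth, then leftmost)."""
    head = pattern.syntax
    tok = graph.token(node)
    if tok.lemma.lower() != head.lexeme.lower() or tok.pos != head.pos:
        return []
    items = _item_list(head)
    if not items:
        return [({}, ())]

    per_item_choices = []
    all_nodes = sorted(graph.tokens)
    for _, item, _ in items:
        choices = []
        for cand in all_nodes:
            if cand == node:
                continue
            if item.var is not None:
                for k, sem in enumerate(semantics_index.get(cand, [])):
                    if _sem_ok(sem, item.var.concept, ont):
                        choices.append((cand, k, sem))
            elif item.lexeme is not None:
                t = graph.token(cand)
                if t.lemma.lower() == item.lexeme.lower() and t.pos == item.pos:
                    choices.append((cand, 0, None))
            else:
                choices.append((cand, 0, None))
        per_item_choices.append(choices)

    anchors = {None: node}
    valid = []
    for combo in itertools.product(*per_item_choices):
        nodes = {iid: combo[iid][0] for iid, _, _ in items}
        ok = True
        for iid, item, parent in items:
            anchor = node if parent is None else nodes[parent]
            cand = nodes[iid]
            if _tree_path(graph, anchor, cand) is None:  # must be a strict descendant
                ok = False
                break
            if not _ok_path(graph, anchor, cand, config):
                ok = False
                break
            if item.role and not _ok_role(graph, anchor, cand, item.role, config):
                ok = False
                break
        if not ok:
            continue
        # condition 2: nodes of non-ancestor item pairs are non-dominating
        ancestors_of = {}
        for iid, _, parent in items:
            chain = set()
            p = parent
            while p is not None:
                chain.add(p)
                p = next(pp for (i2, _, pp) in items if i2 == p)
            ancestors_of[iid] = chain
        for (i1, _, _), (i2, _, _) in itertools.combinations(items, 2):
            if i1 in ancestors_of[i2] or i2 in ancestors_of[i1]:
                continue
            n1, n2 = nodes[i1], nodes[i2]
            if n1 == n2 or _tree_path(graph, n1, n2) is not None or _tree_path(graph, n2, n1) is not None:
                ok = False
                break
        if not ok:
            continue
        valid.append(combo)

    # replicate the preference order: per item, (depth, position, sem index)
    def depth(n):
        d, cur = 0, n
        while graph.token(cur).head != 0:
            d += 1
            cur = graph.token(cur).head
        return d

    valid.sort(key=lambda combo: tuple((depth(c[0]), c[0], c[1]) for c in combo))
    results, seen = [], set()
    for combo in valid:
        binding = {
            item.var.name: (combo[iid][0], combo[iid][2])
            for iid, item, _ in items
            if item.var is not None
        }
        signature = []
        for name in sorted(binding):
            _, value = binding[name]
            ids = frozenset(r.grounding_id for r in _iter_refs(value))
            signature.append((name, ids if ids else canonical(value)))
        signature = tuple(signature)
        if signature in seen:
            continue
        seen.add(signature)
        results.append((binding, tuple(combo[iid][0] for iid, _, _ in items)))
    return results


def _iter_refs(value):
    if isinstance(value, EntityRef):
        yield value
    elif isinstance(value, SemanticStructure):
        for sub in value.slots.values():
            yield from _iter_refs(sub)


# --------------------------------------------------------------------------
# Strict (direct-child, exact-role) pattern matching.

def strict_matches(pattern, node, graph, semantics_index, ont, config):
    """Matches where every dependent item binds a *direct child* of its
    head item's node; a subset of loose matching by construction of the
    loose conditions.  Returns canonical instantiated structures."""
    head = pattern.syntax
    tok = graph.token(node)
    if tok.lemma.lower() != head.lexeme.lower() or tok.pos != head.pos:
        return set()
    children = [t.index for t in graph.tokens.values() if t.head == node]

    def item_options(item, kids):
        options = []
        for cand in kids:
            t = graph.token(cand)
            if item.role and not config.satisfies_role(item.role, t.role):
                continue
            if item.lexeme is not None and not (
                t.lemma.lower() == item.lexeme.lower() and t.pos == item.pos
            ):
                continue
            if item.children:
                sub_kids = [x.index for x in graph.tokens.values() if x.head == cand]
                for sub in assignments(item.children, sub_kids):
                    options.append((cand, None, sub))
            elif item.var is not None:
                for sem in semantics_index.get(cand, []):
                    if _sem_ok(sem, item.var.concept, ont):
                        options.append((cand, sem, []))
            else:
                options.append((cand, None, []))
        return options

    def assignments(items, kids):
        if not items:
            return [[]]
        out = []
        first, rest = items[0], items[1:]
        for cand, sem, sub in item_options(first, kids):
            for tail in assignments(rest, [k for k in kids if k != cand]):
                out.append([(first, cand, sem)] + sub + tail)
        return out

    structures = set()
    for assignment in assignments(head.children, children):
        binding = {
            item.var.name: sem for item, _, sem in assignment if item.var is not None
        }
        structures.add(canonical(_instantiate(pattern.semantics, binding)))
    return structures


def _instantiate(sem, binding):
    slots = {}
    for prop, value in sem.slots.items():
        if isinstance(value, Var):
            slots[prop] = binding[value.name]
        elif isinstance(value, SemanticStructure):
            slots[prop] = _instantiate(value, binding)
        else:
            slots[prop] = value
    return SemanticStructure(sem.concept, slots)


# --------------------------------------------------------------------------
# Naive inference closure: re-scan every rule x event-tuple each pass.

def _naive_match_value(cval, value, binding, isa):
    if isinstance(cval, Var):
        if cval.concept is not None:
            if isinstance(value, SemanticStructure):
                if (value.concept, cval.concept) not in isa:
                    return None
            elif isinstance(value, EntityRef):
                if not any((label, cval.concept) in isa for label in value.labels):
                    return None
            else:
                return None
        if cval.name in binding:
            return binding if canonical(binding[cval.name]) == canonical(value) else None
        new = dict(binding)
        new[cval.name] = value
        return new
    if isinstance(cval, Literal):
        return binding if isinstance(value, Literal) and value.value == cval.value else None
    if isinstance(cval, SemanticStructure):
        if not isinstance(value, SemanticStructure) or (value.concept, cval.concept) not in isa:
            return None
        return _naive_match_slots(cval, value, binding, isa)
    return None


def _naive_match_slots(cond, struct, binding, isa):
    for prop, cval in cond.slots.items():
        value = struct.slots.get(prop)
        if value is None:
            if prop == "hasPolarity" and isinstance(cval, Var):
                value = Literal("positive")
            else:
                return None
        binding = _naive_match_value(cval, value, binding, isa)
        if binding is None:
            return None
    return binding


def _naive_resolve(value, binding):
    if isinstance(value, Var):
        return binding[value.name]
    if isinstance(value, Call):
        args = [
            _naive_resolve(a, binding).value for a in value.args
        ]
        if "unknown" in args:
            return Literal("unknown")
        return Literal("positive" if args[0] == args[1] else "negative")
    if isinstance(value, SemanticStructure):
        return SemanticStructure(value.concept, {p: _naive_resolve(v, binding) for p, v in value.slots.items()})
    return value


def naive_closure(structs, rules, ont):
    """Canonical forms of the closure of ground structures under rules,
    computed by a naive full re-scan each pass; subsumption comes from the
    matrix-expansion oracle."""
    isa = subsumption_closure(ont.concepts, {(c, p) for c, ps in ont.isa_edges.items() for p in ps})
    pool = {canonical(s): s for s in structs}
    while True:
        added = False
        for rule in rules:
            for combo in itertools.product(list(pool.values()), repeat=len(rule.conditions)):
                binding = {}
                ok = True
                for cond, struct in zip(rule.conditions, combo):
                    if (struct.concept, cond.concept) not in isa:
                        ok = False
                        break
                    binding = _naive_match_slots(cond, struct, binding, isa)
                    if binding is None:
                        ok = False
                        break
                if not ok:
                    continue
                slots = dict(combo[0].slots)
                for prop, cval in rule.conclusion.slots.items():
                    slots[prop] = _naive_resolve(cval, binding)
                conclusion = SemanticStructure(rule.conclusion.concept, slots)
                key = canonical(conclusion)
                if key not in pool:
                    pool[key] = conclusion
                    added = True
        if not added:
            return set(pool)
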