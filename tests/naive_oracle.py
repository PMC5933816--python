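"""Independent brute-force oracles used by the tests.

Deliberately written against the raw data model (plain loops, own
subsumption lookup) so they share no code with the package's evaluation
or induction paths.
"""

import math


def naive_subsumes(parent_map, query, hit_sub):
    return query == hit_sub or parent_map.get(hit_sub) == query


def naive_evaluate(hits, test, parent_map):
    """Double-loop evaluation of one relational test on a list of hits."""
    v = test.variant
    if v == "OCCURS":
        for h in hits:
            if naive_subsumes(parent_map, test.domain, h.subject_id):
                if h.evalue <= test.evalue_max:
                    return True
        return False
    if v == "OCCURS_LEN":
        for h in hits:
            if not naive_subsumes(parent_map, test.domain, h.subject_id):
                continue
            if h.evalue > test.evalue_max:
                continue
            length = h.end - h.start
            if test.length_dir == "min":
                if length >= test.length_limit:
                    return True
            else:
                if length <= test.length_limit:
                    return True
        return False
    if v == "BEFORE":
        for h1 in hits:
            if not naive_subsumes(parent_map, test.domain, h1.subject_id):
                continue
            if h1.evalue > test.evalue_max:
                continue
            for h2 in hits:
                if not naive_subsumes(parent_map, test.domain2, h2.subject_id):
                    continue
                if h2.evalue > test.evalue_max:
                    continue
                if h1.start < h2.start:
                    return True
        return False
    if v == "COUNT":
        n = 0
        for h in hits:
            if naive_subsumes(parent_map, test.domain, h.subject_id):
                n += 1
        return n > test.count_threshold
    raise AssertionError(v)


def naive_entropy(n_pos, n):
    if n == 0 or n_pos == 0 or n_pos == n:
        return 0.0
    p = n_pos / n
    return -(p * math.log2(p) + (1 - p) * math.log2(1 - p))


def naive_gain(examples, test, parent_map):
    """Information gain of one test over (hits, label) examples."""
    n = len(examples)
    n_pos = sum(1 for _h, y in examples if y)
    yes = [(h, y) for h, y in examples if naive_evaluate(h, test, parent_map)]
    no = [(h, y) for h, y in examples if not naive_evaluate(h, test, parent_map)]
    yes_pos = sum(1 for _h, y in yes if y)
    no_pos = sum(1 for _h, y in no if y)
    return naive_entropy(n_pos, n) - (
        len(yes) / n * naive_entropy(yes_pos, len(yes))
        + len(no) / n * naive_entropy(no_pos, len(no))
    )


def naive_best_split(examples, tests, parent_map, min_leaf):
    """Exhaustive gain-optimal valid test; ties broken by enumeration order."""
    best = None
    for i, test in enumerate(tests):
        n_yes = sum(1 for h, _y in examples if naive_evaluate(h, test, parent_map))
        n_no = len(examples) - n_yes
        if n_yes < min_leaf or n_no < min_leaf:
            continue
        gain = naive_gain(examples, test, parent_map)
        if gain <= 1e-12:
            continue
        if best is None or gain > best[1] + 1e-12:
            best = (i, gain)
    return best
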