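"""Brute-force reference evaluator for the query patterns.

Deliberately independent of the package internals: traversal is a naive
recursive reachability over a plain parent map (no networkx, no shared
code), statuses are recomputed per call, and every pattern is a nested
loop. Used to cross-check the query engine on random cohorts.
"""

from __future__ import annotations

import math
from fractions import Fraction


def parent_map(ontology):
    return {tid: set(t.parent_ids) for tid, t in ontology.terms.items()}


def reach_ancestors(parents, term):
    """All strict ancestors by exhaustive path following."""
    out = set()
    stack = [term]
    while stack:
        for p in parents[stack.pop()]:
            if p not in out:
                out.add(p)
                stack.append(p)
    return out


def is_or_descendant(parents, general, specific):
    return general == specific or general in reach_ancestors(parents, specific)


def naive_status(parents, patient, term, hierarchy=True, closed_world=False):
    for a in patient.assertions:
        if a.polarity == "present":
            if a.term_id == term:
                return "present"
            if hierarchy and a.term_id in parents and term in reach_ancestors(parents, a.term_id):
                return "present"
    for a in patient.assertions:
        if a.polarity == "absent" and a.term_id == term:
            return "absent"
    return "absent" if closed_world else "unknown"


def naive_variants_with_trait(parents, cohort, term, polarity,
                              hierarchy=True, closed_world=False):
    out = set()
    for p in cohort.patients:
        if naive_status(parents, p, term, hierarchy, closed_world) == polarity:
            for v in p.variants:
                out.add(v.variant_id)
    return out


def naive_variants_with_all_traits(parents, cohort, terms):
    out = set()
    for p in cohort.patients:
        if all(naive_status(parents, p, t) == "present" for t in terms):
            for v in p.variants:
                out.add(v.variant_id)
    return out


def naive_partition(parents, cohort, term, closed_world=False):
    carried, present, absent = set(), set(), set()
    for p in cohort.patients:
        vids = {v.variant_id for v in p.variants}
        carried |= vids
        st = naive_status(parents, p, term, True, closed_world)
        if st == "present":
            present |= vids
        elif st == "absent":
            absent |= vids
    return {
        "always": present - absent,
        "never": absent - present,
        "mixed": present & absent,
        "do-not-know": carried - present - absent,
    }


def naive_traits_for_variant(parents, cohort, variant, scope):
    out = set()
    for p in cohort.patients:
        if not any(v.variant_id == variant for v in p.variants):
            continue
        for a in p.assertions:
            if a.polarity == "present" and a.term_id in parents:
                if is_or_descendant(parents, scope, a.term_id):
                    out.add(a.term_id)
    return out


def naive_trait_frequency(parents, cohort, variant, term):
    carriers = [p for p in cohort.patients
                if any(v.variant_id == variant for v in p.variants)]
    if not carriers:
        return None
    hits = sum(1 for p in carriers if naive_status(parents, p, term) == "present")
    return math.floor(100 * hits / len(carriers)), hits, len(carriers)


def naive_cohort_frequency(parents, cohort, term, polarity):
    if not cohort.patients:
        return None
    hits = sum(1 for p in cohort.patients
               if naive_status(parents, p, term) == polarity)
    return math.floor(100 * hits / len(cohort.patients))


def half_up(mean_fraction, digits=1):
    """Round an exact rational half-up (ties away from zero) at 0.1."""
    scale = 10 ** digits
    scaled = abs(mean_fraction) * scale
    rounded = math.floor(scaled + Fraction(1, 2))
    sign = -1 if mean_fraction < 0 else 1
    return sign * rounded / scale


def naive_mean_attribute(parents, cohort, attribute, filters):
    values = []
    for p in cohort.patients:
        if attribute not in p.attributes:
            continue
        ok = True
        for f in filters:
            if f[0] == "term":
                ok = ok and naive_status(parents, p, f[1]) == f[2]
            else:
                ok = ok and any(v.variant_id == f[1] for v in p.variants)
        if ok:
            values.append(Fraction(str(p.attributes[attribute])))
    if not values:
        return None
    return half_up(sum(values) / len(values))


def naive_mean_interval(parents, cohort, start, end, filters):
    diffs = []
    for p in cohort.patients:
        if start not in p.attributes or end not in p.attributes:
            continue
        ok = True
        for f in filters:
            if f[0] == "term":
                ok = ok and naive_status(parents, p, f[1]) == f[2]
            else:
                ok = ok and any(v.variant_id == f[1] for v in p.variants)
        if ok:
            diffs.append(Fraction(str(p.attributes[end]))
                         - Fraction(str(p.attributes[start])))
    if not diffs:
        return None
    return half_up(sum(diffs) / len(diffs))
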