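"""Independent brute-force oracles used by the test-suite.

Everything here works in exact rational arithmetic (``fractions.Fraction``)
and enumerates pedigrees and gamete transmissions directly, without using
any IBD shortcut from the package under test.
"""

from fractions import Fraction
from itertools import combinations_with_replacement


def hw_genotypes(freqs):
    """All unordered genotypes with Hardy–Weinberg probabilities."""
    alleles = sorted(freqs)
    out = []
    for a, b in combinations_with_replacement(alleles, 2):
        p = freqs[a] * freqs[b]
        out.append(((a, b), p if a == b else 2 * p))
    return out


def gametes(genotype):
    a, b = genotype
    if a == b:
        return [(a, Fraction(1))]
    return [(a, Fraction(1, 2)), (b, Fraction(1, 2))]


def _norm(a, b):
    return (a, b) if a <= b else (b, a)


def dyad_joint_probability(relationship, g1, g2, freqs):
    """P(observing unordered genotypes g1, g2) for a dyad of the given
    relationship, by full enumeration of parental genotypes and gamete
    transmissions (exact rational arithmetic)."""
    g1, g2 = _norm(*g1), _norm(*g2)
    genos = hw_genotypes(freqs)
    total = Fraction(0)
    if relationship == "UR":
        p1 = dict(genos).get(g1, Fraction(0))
        p2 = dict(genos).get(g2, Fraction(0))
        return p1 * p2
    if relationship == "PO":
        # parent with genotype gp mates a random individual; child receives
        # one gamete from each.  Observed pair = (parent, child).
        for gp, wp in genos:
            for gm, wm in genos:
                for a, wa in gametes(gp):
                    for b, wb in gametes(gm):
                        if _norm(a, b) == g2 and gp == g1:
                            total += wp * wm * wa * wb
        return total
    if relationship == "FS":
        for gm, wm in genos:
            for gf, wf in genos:
                w_parents = wm * wf
                for a1, wa1 in gametes(gm):
                    for b1, wb1 in gametes(gf):
                        if _norm(a1, b1) != g1:
                            continue
                        for a2, wa2 in gametes(gm):
                            for b2, wb2 in gametes(gf):
                                if _norm(a2, b2) == g2:
                                    total += w_parents * wa1 * wb1 * wa2 * wb2
        return total
    if relationship == "HS":
        # shared mother, two independent fathers
        for gm, wm in genos:
            for gf1, wf1 in genos:
                for gf2, wf2 in genos:
                    w = wm * wf1 * wf2
                    for a1, wa1 in gametes(gm):
                        for b1, wb1 in gametes(gf1):
                            if _norm(a1, b1) != g1:
                                continue
                            for a2, wa2 in gametes(gm):
                                for b2, wb2 in gametes(gf2):
                                    if _norm(a2, b2) == g2:
                                        total += w * wa1 * wb1 * wa2 * wb2
        return total
    raise ValueError(relationship)


def transitive_closure_components(nodes, edges):
    """Connected components by brute-force transitive closure."""
    comp = {n: {n} for n in nodes}
    changed = True
    while changed:
        changed = False
        for a, b in edges:
            merged = comp[a] | comp[b]
            if merged != comp[a] or merged != comp[b]:
                for n in merged:
                    comp[n] = merged
                changed = True
    seen = []
    for n in nodes:
        if comp[n] not in seen:
            seen.append(comp[n])
    return seen
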