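"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive results the slow, obvious way: substring-by-
substring constraint checks, full double loops over primer pairs, and
exhaustive enumeration of gamete combinations.
"""

from itertools import product as iproduct

from knockkit import thermo

COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def revcomp(seq):
    return "".join(COMP[b] for b in reversed(seq.upper()))


def naive_self_complementarity(seq):
    """O(L^2) antidiagonal scan of two antiparallel copies of seq."""
    n = len(seq)
    best = 0
    for d in range(2 * n - 1):
        s = 0
        for i in range(max(0, d - n + 1), min(n, d + 1)):
            if COMP[seq[i]] == seq[d - i]:
                s += 1
        best = max(best, s)
    return best


def candidate_passes(sub, orientation, c):
    """Hard-constraint check for one substring, via the scalar thermo API."""
    if not all(b in "ACGT" for b in sub):
        return None
    if not c.gc_min - 1e-12 <= thermo.gc_content(sub) <= c.gc_max + 1e-12:
        return None
    core = sub if orientation == "forward" else revcomp(sub)
    tm = thermo.melting_temperature(core, c.thermo)
    if not c.tm_min <= tm <= c.tm_max:
        return None
    if thermo.gc_clamp_run(core) > c.gc_clamp_max_run:
        return None
    if naive_self_complementarity(core) > c.self_comp_max:
        return None
    return tm


def naive_enumerate(window, orientation, c):
    """All (offset, length, tm, penalty) passing the hard constraints."""
    out = []
    for length in range(c.primer_len_min, c.primer_len_max + 1):
        for i in range(len(window) - length + 1):
            tm = candidate_passes(window[i : i + length], orientation, c)
            if tm is None:
                continue
            penalty = c.w_tm * abs(tm - c.tm_opt) + c.w_len * abs(
                length - c.primer_len_opt
            )
            out.append((i, length, tm, penalty))
    return out


def brute_force_pick(window, c):
    """Globally optimal pair by full enumeration with the documented tie-break:
    minimise (penalty sum, -product, fwd start, fwd len, rev start, rev len)."""
    fwds = naive_enumerate(window, "forward", c)
    revs = naive_enumerate(window, "reverse", c)
    best_key, best = None, None
    for fi, flen, _, fpen in fwds:
        for ri, rlen, _, rpen in revs:
            rend = ri + rlen
            prod = rend - fi
            if not c.product_min <= prod <= c.product_max:
                continue
            if ri < fi + flen:
                continue
            key = (fpen + rpen, -prod, fi, flen, ri, rlen)
            if best_key is None or key < best_key:
                best_key, best = key, (fi, flen, ri, rlen)
    return best, best_key


def gamete_genotype_frequency(loci):
    """P(desired multi-locus progeny genotype) by enumerating every way the
    haploid progeny can inherit one parental allele per unlinked locus."""
    n = len(loci)
    hits = 0
    total = 0
    for picks in iproduct((0, 1), repeat=n):
        total += 1
        ok = True
        for locus, pick in zip(loci, picks):
            allele = locus.parent_a if pick == 0 else locus.parent_b
            if allele != locus.desired:
                ok = False
                break
        if ok:
            hits += 1
    return hits / total if total else 1.0


def min_progeny_by_scan(p, confidence, n_max=10_000):
    for n in range(1, n_max + 1):
        if 1.0 - (1.0 - p) ** n >= confidence:
            return n
    raise AssertionError("scan exhausted")
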