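"""Independent brute-force oracle for elementary flux modes.

Enumerates support-minimal, sign-feasible kernel vectors of the (reversible-
split) stoichiometric matrix by subset enumeration with exact sympy
nullspaces — no code shared with the package's tableau implementation.
"""

from fractions import Fraction
from itertools import combinations
from math import gcd

import sympy


def _scale_integer(vals):
    lcm = 1
    for v in vals:
        lcm = lcm * v.denominator // gcd(lcm, v.denominator)
    ints = [int(v * lcm) for v in vals]
    g = 0
    for v in ints:
        g = gcd(g, abs(v))
    return [v // (g or 1) for v in ints]


def brute_force_efms(matrix):
    """All EFMs of a StoichiometricMatrix as a set of canonical
    frozenset((column id, integer flux)) items."""
    cols = []
    col_map = []
    for cid in matrix.col_ids:
        col = [sympy.Rational(v) for v in matrix.column(cid)]
        cols.append(col)
        col_map.append((cid, 1))
        if matrix.reversible[cid]:
            cols.append([-v for v in col])
            col_map.append((cid, -1))
    n, m = len(cols), len(matrix.met_ids)
    found_supports = []
    modes = set()
    for size in range(1, n + 1):
        for subset in combinations(range(n), size):
            sset = set(subset)
            if any(fs <= sset for fs in found_supports):
                continue
            # sign feasibility: every metabolite row must admit cancellation
            ok = True
            for i in range(m):
                vals = [cols[j][i] for j in subset]
                if any(v > 0 for v in vals) != any(v < 0 for v in vals):
                    ok = False
                    break
            if not ok:
                continue
            sub = sympy.Matrix([[cols[j][i] for j in subset] for i in range(m)])
            null = sub.nullspace()
            if len(null) != 1:
                continue
            vec = list(null[0])
            if all(v < 0 for v in vec):
                vec = [-v for v in vec]
            if not all(v > 0 for v in vec):
                continue
            found_supports.append(sset)
            # map back to signed original columns
            flux = {}
            used = {}
            for j, v in zip(subset, vec):
                cid, sign = col_map[j]
                flux[cid] = flux.get(cid, sympy.Rational(0)) + sign * v
                used.setdefault(cid, set()).add(sign)
            if any(len(s) == 2 for s in used.values()):
                continue  # futile two-cycle of one split column
            flux = {c: v for c, v in flux.items() if v}
            order = sorted(flux)
            ref = matrix.sink_col if flux.get(matrix.sink_col) else order[0]
            if flux[ref] < 0:
                if all(matrix.reversible[c] for c in flux):
                    flux = {c: -v for c, v in flux.items()}
                else:
                    continue
            items = sorted(flux.items())
            ints = _scale_integer(
                [Fraction(int(v.p), int(v.q)) for _, v in items])
            modes.add(frozenset((c, i) for (c, _), i in zip(items, ints)))
    return modes
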