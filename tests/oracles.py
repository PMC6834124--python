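"""Independent reference implementations used only by the test suite.

These re-derive expected values by brute force or naive counting, sharing no
code with the package's computational paths: structure enumeration is a plain
recursion, loop scoring re-reads the parameter JSON, CpG statistics use
regex/str counting, and triplex registers are scored one base at a time.
"""

from __future__ import annotations

import json
import math
import re
from pathlib import Path

PAIRABLE = {"AU", "UA", "GC", "CG", "GU", "UG"}
WEAK = {"AU", "UA", "GU", "UG"}

_PARAMS = json.loads(
    (Path(__file__).resolve().parents[1] / "src/mirfunc/data/nn_energies.json").read_text()
)
_COEFF = 1.75 * 0.0019872 * 310.15


def enumerate_structures(seq: str, min_loop: int = 3):
    """Every nested structure (as a frozenset of pairs) by plain recursion
    on the leftmost position: unpaired, or paired with each legal partner."""

    def gen(i, j):
        if i > j:
            yield frozenset()
            return
        yield from gen(i + 1, j)
        for k in range(i + min_loop + 1, j + 1):
            if seq[i] + seq[k] in PAIRABLE:
                for inside in gen(i + 1, k - 1):
                    for outside in gen(k + 1, j):
                        yield inside | outside | {(i, k)}

    return gen(0, len(seq) - 1)


def _loop_table(name: str, n: int) -> float:
    table = {int(k): v for k, v in _PARAMS[name].items()}
    m = max(table)
    return table[n] if n <= m else table[m] + _COEFF * math.log(n / m)


def loop_score(seq: str, pairs) -> float:
    """Score a pair set by explicit loop decomposition (reference scorer)."""
    pairs = sorted(pairs)
    pairset = set(pairs)
    ml = _PARAMS["multiloop"]
    term_au = _PARAMS["terminal_au"]

    def bp(p):
        return seq[p[0]] + seq[p[1]]

    def au(p):
        return term_au if bp(p) in WEAK else 0.0

    def enclosed(p):
        i, j = p
        out, k = [], i + 1
        while k < j:
            hit = next((q for q in pairs if q[0] == k), None)
            if hit and hit[1] < j:
                out.append(hit)
                k = hit[1] + 1
            else:
                k += 1
        return out

    top, k, n = [], 0, len(seq)
    while k < n:
        hit = next((q for q in pairs if q[0] == k), None)
        if hit:
            top.append(hit)
            k = hit[1] + 1
        else:
            k += 1

    e = sum(au(p) for p in top)
    for p in pairset:
        i, j = p
        kids = enclosed(p)
        if not kids:
            e += _loop_table("hairpin", j - i - 1) + au(p)
        elif len(kids) == 1:
            (a, b), = kids
            if (a, b) == (i + 1, j - 1):
                e += _PARAMS["stack"][f"{bp(p)}/{bp((a, b))}"]
            else:
                s1, s2 = a - i - 1, j - b - 1
                name = "bulge" if min(s1, s2) == 0 else "internal"
                e += _loop_table(name, s1 + s2) + au(p) + au((a, b))
        else:
            unpaired = (j - i - 1) - sum(b - a + 1 for a, b in kids)
            e += (
                ml["a"] + ml["b"] * (len(kids) + 1) + ml["c"] * unpaired
                + au(p) + sum(au(q) for q in kids)
            )
    return e


def brute_force_mfe(seq: str) -> float:
    """Minimum loop_score over all structures, capped at 0 (empty fold)."""
    return min(min(loop_score(seq, s) for s in enumerate_structures(seq)), 0.0)


# --- CpG reference -----------------------------------------------------------


def naive_cpg_stats(window: str) -> tuple[float, float]:
    """(gc_percent, obs_exp) by regex/str counting."""
    n = len(window)
    n_c, n_g = window.count("C"), window.count("G")
    n_cpg = len(re.findall("(?=CG)", window))
    gc = 100.0 * (n_c + n_g) / n
    obs_exp = n_cpg * n / (n_c * n_g) if n_c and n_g else 0.0
    return gc, obs_exp


# --- triplex reference -------------------------------------------------------

PAR = {("U", "A"), ("C", "G"), ("G", "G"), ("A", "A")}
ANTI = {("A", "A"), ("U", "A"), ("G", "G")}
DNA_COMP = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}


def naive_register_score(
    third: str, duplex: str, start: int, orientation: str, strand: str,
    wc=8.0, wn=-8.0, ec=-8.0, en=4.0,
) -> tuple[float, float]:
    """(score, energy) of one register, one triplet at a time."""
    L = len(third)
    code = PAR if orientation == "direct" else ANTI
    score = energy = 0.0
    for k in range(L):
        if strand == "given":
            pb = duplex[start + k]
            tb = third[k] if orientation == "direct" else third[L - 1 - k]
        else:
            pb = DNA_COMP[duplex[start + k]]
            tb = third[L - 1 - k] if orientation == "direct" else third[k]
        if (tb, pb) in code:
            score += wc
            energy += ec
        else:
            score += wn
            energy += en
    return score, energy


def naive_scan(third: str, duplex: str, score_thr: float, energy_thr: float):
    """All qualifying (start, orientation, strand, score, energy), sorted."""
    L = len(third)
    out = []
    for s in range(len(duplex) - L + 1):
        if "N" in duplex[s : s + L]:
            continue
        for orientation in ("direct", "indirect"):
            for strand in ("given", "complement"):
                sc, en = naive_register_score(third, duplex, s, orientation, strand)
                if sc > score_thr and en < energy_thr:
                    out.append((s, orientation, strand, sc, en))
    return sorted(out)
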