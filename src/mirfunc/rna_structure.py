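"""Minimum-free-energy secondary-structure prediction for short RNAs.

Implements a Zuker-style dynamic program over a nearest-neighbor loop model
(stacks, hairpins, bulges, internal loops, affine multiloops, terminal AU/GU
penalties) with suboptimal enumeration of every pseudoknot-free structure
within an energy window of the MFE, and a dot-plot pair-frequency matrix over
the retained structures.

The model is additive over loops. The energy of a structure is the sum, over
every loop closed by a base pair, of that loop's term; the empty structure has
energy 0, so the MFE is never positive. A terminal penalty applies once per
non-GC pair side that is not continued by a direct stack. Suboptimal folds are
enumerated with an energy-bounded backtrack over an unambiguous decomposition
(each structure is produced exactly once), which is complete within the window.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .sequence_io import RnaSequence

PAIRABLE = frozenset({"AU", "UA", "GC", "CG", "GU", "UG"})
_WEAK_PAIRS = frozenset({"AU", "UA", "GU", "UG"})

# 1.75 * RT at 310.15 K, the Jacobson-Stockmayer coefficient for long loops
_LOOP_EXTRAPOLATION = 1.75 * 0.0019872 * 310.15

_INF = math.inf


@dataclass(frozen=True)
class EnergyModel:
    """Nearest-neighbor loop-energy tables (kcal/mol at 37 C).

    ``stack`` maps (outer pair, inner pair) strings such as ("GC", "CG");
    loop tables map unpaired-base counts to initiation energies and are
    log-extrapolated beyond their tabulated range. ``multiloop_*`` are the
    affine multiloop offset / per-branch / per-unpaired-base terms.
    """

    stack: dict
    hairpin: dict
    bulge: dict
    internal: dict
    multiloop_a: float
    multiloop_b: float
    multiloop_c: float
    terminal_au: float
    min_loop: int = 3
    temperature_C: int = 37
    version: str = "1.0"

    @classmethod
    def default(cls) -> "EnergyModel":
        """Load the versioned parameter file shipped with the package."""
        with resources.files("mirfunc").joinpath("data/nn_energies.json").open() as fh:
            raw = json.load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "EnergyModel":
        stack = {tuple(k.split("/")): float(v) for k, v in raw["stack"].items()}
        return cls(
            stack=stack,
            hairpin={int(k): float(v) for k, v in raw["hairpin"].items()},
            bulge={int(k): float(v) for k, v in raw["bulge"].items()},
            internal={int(k): float(v) for k, v in raw["internal"].items()},
            multiloop_a=float(raw["multiloop"]["a"]),
            multiloop_b=float(raw["multiloop"]["b"]),
            multiloop_c=float(raw["multiloop"]["c"]),
            terminal_au=float(raw["terminal_au"]),
            min_loop=int(raw.get("min_loop", 3)),
            temperature_C=int(raw.get("temperature_C", 37)),
            version=str(raw.get("version", "unversioned")),
        )

    def _loop(self, table: dict, n: int) -> float:
        m = max(table)
        if n <= m:
            return table[n]
        return table[m] + _LOOP_EXTRAPOLATION * math.log(n / m)

    def hairpin_energy(self, n: int) -> float:
        if n < self.min_loop:
            return _INF
        return self._loop(self.hairpin, n)

    def bulge_energy(self, n: int) -> float:
        return self._loop(self.bulge, n)

    def internal_energy(self, n: int) -> float:
        return self._loop(self.internal, n)

    def au_penalty(self, pair: str) -> float:
        return self.terminal_au if pair in _WEAK_PAIRS else 0.0


@dataclass(frozen=True)
class SecondaryStructure:
    """A pseudoknot-free secondary structure with its free energy."""

    pairs: frozenset
    dot_bracket: str
    energy: float

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for i, j in self.pairs:
            if not i < j:
                raise ValueError(f"pair ({i},{j}) must satisfy i < j")
            if i in seen or j in seen:
                raise ValueError("an index participates in more than one pair")
            seen.update((i, j))


@dataclass(frozen=True)
class FoldResult:
    """Optimal and suboptimal folds of one sequence.

    ``structures`` is sorted by energy ascending (ties by dot-bracket);
    ``pair_matrix`` is the boolean union of pairs over retained structures.
    """

    sequence: RnaSequence
    structures: tuple
    energy_window: float
    pair_matrix: np.ndarray

    @property
    def structure_count(self) -> int:
        return len(self.structures)

    @property
    def mfe(self) -> float:
        return self.structures[0].energy


def pairs_to_dot_bracket(pairs: Iterable, n: int) -> str:
    out = ["."] * n
    for i, j in pairs:
        out[i] = "("
        out[j] = ")"
    return "".join(out)


def dot_bracket_to_pairs(db: str) -> frozenset:
    stack: list[int] = []
    pairs = set()
    for i, ch in enumerate(db):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            pairs.add((stack.pop(), i))
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return frozenset(pairs)


def structure_energy(seq: str, pairs: Iterable, model: EnergyModel) -> float:
    """Score an arbitrary nested pair set under the loop model.

    This is the defining scorer for the model: the DP below computes the
    minimum of this function over all legal structures.
    """
    plist = sorted(pairs)
    pairset = set(map(tuple, plist))
    bp = {p: seq[p[0]] + seq[p[1]] for p in pairset}
    # immediate children of each pair, and the external (top-level) branches
    children: dict = {p: [] for p in pairset}
    external: list[tuple[int, int]] = []
    stack: list[tuple[int, int]] = []
    for p in plist:
        while stack and not (stack[-1][0] < p[0] and p[1] < stack[-1][1]):
            stack.pop()
        if stack:
            children[stack[-1]].append(p)
        else:
            external.append(p)
        stack.append(p)
    e = sum(model.au_penalty(bp[p]) for p in external)
    for p, cs in children.items():
        i, j = p
        if not cs:
            e += model.hairpin_energy(j - i - 1) + model.au_penalty(bp[p])
        elif len(cs) == 1:
            k, l = cs[0]
            if (k, l) == (i + 1, j - 1):
                e += model.stack[(bp[p], bp[(k, l)])]
            else:
                size1, size2 = k - i - 1, j - l - 1
                table = model.bulge_energy if min(size1, size2) == 0 else model.internal_energy
                e += table(size1 + size2) + model.au_penalty(bp[p]) + model.au_penalty(bp[cs[0]])
        else:
            unpaired = (j - i - 1) - sum(l - k + 1 for k, l in cs)
            e += (
                model.multiloop_a
                + model.multiloop_b * (len(cs) + 1)
                + model.multiloop_c * unpaired
                + model.au_penalty(bp[p])
                + sum(model.au_penalty(bp[c]) for c in cs)
            )
    return e


class _Folder:
    """Zuker DP matrices plus bounded suboptimal backtrack for one sequence.

    Matrices: C[i][j] = MFE given (i,j) paired; M[i][j] = MFE of a multiloop
    interior segment with >= 1 branch (per-branch b and terminal penalties and
    per-unpaired c included); F[i] = MFE of the suffix [i, n) in the external
    loop. The decomposition used for both fill and backtrack is unambiguous,
    so the backtrack visits each structure exactly once.
    """

    def __init__(self, seq: str, model: EnergyModel):
        self.seq = seq
        self.model = model
        self.n = len(seq)
        self._fill()

    def _pair(self, i: int, j: int) -> str | None:
        p = self.seq[i] + self.seq[j]
        if p in PAIRABLE and j - i - 1 >= self.model.min_loop:
            return p
        return None

    def _fill(self) -> None:
        n, m = self.n, self.model
        C = [[_INF] * n for _ in range(n)]
        M = [[_INF] * n for _ in range(n)]
        au = [[0.0] * n for _ in range(n)]
        pairable = [[False] * n for _ in range(n)]
        for i in range(n):
            for j in range(i + 1, n):
                p = self._pair(i, j)
                if p is not None:
                    pairable[i][j] = True
                    au[i][j] = m.au_penalty(p)
        # C and M filled together by increasing span: each cell reads only
        # strictly shorter intervals of either matrix.
        for span in range(n):
            for i in range(n - span):
                j = i + span
                # C: (i, j) paired
                if pairable[i][j]:
                    best = m.hairpin_energy(j - i - 1) + au[i][j]
                    if pairable[i + 1][j - 1]:
                        s = m.stack[(self.seq[i] + self.seq[j], self.seq[i + 1] + self.seq[j - 1])] + C[i + 1][j - 1]
                        if s < best:
                            best = s
                    for k in range(i + 1, j):
                        for l in range(j - 1, k, -1):
                            if (k, l) == (i + 1, j - 1) or not pairable[k][l]:
                                continue
                            size1, size2 = k - i - 1, j - l - 1
                            pen = (
                                m.bulge_energy(size1 + size2)
                                if min(size1, size2) == 0
                                else m.internal_energy(size1 + size2)
                            )
                            s = pen + au[i][j] + au[k][l] + C[k][l]
                            if s < best:
                                best = s
                    # multiloop closure: first branch (h,k), >=1 further branch
                    for h in range(i + 1, j - 1):
                        for k in range(h + 1, j - 1):
                            if pairable[h][k] and M[k + 1][j - 1] < _INF:
                                s = (
                                    m.multiloop_a
                                    + 2 * m.multiloop_b
                                    + au[i][j]
                                    + m.multiloop_c * (h - i - 1)
                                    + C[h][k]
                                    + au[h][k]
                                    + M[k + 1][j - 1]
                                )
                                if s < best:
                                    best = s
                    C[i][j] = best
                # M: multiloop interior with >= 1 branch on [i, j]
                best = _INF
                if i < j and M[i + 1][j] < _INF:
                    best = m.multiloop_c + M[i + 1][j]
                for k in range(i + 1, j + 1):
                    if pairable[i][k] and C[i][k] < _INF:
                        base = C[i][k] + m.multiloop_b + au[i][k]
                        tail = m.multiloop_c * (j - k)
                        if base + tail < best:
                            best = base + tail
                        if k < j and M[k + 1][j] < _INF and base + M[k + 1][j] < best:
                            best = base + M[k + 1][j]
                M[i][j] = best
        F = [0.0] * (n + 1)
        for i in range(n - 1, -1, -1):
            best = F[i + 1]
            for k in range(i + 1, n):
                if pairable[i][k] and C[i][k] < _INF:
                    s = C[i][k] + au[i][k] + F[k + 1]
                    if s < best:
                        best = s
            F[i] = best
        self.C, self.M, self.F, self.au, self.pairable = C, M, F, au, pairable

    @property
    def mfe(self) -> float:
        return self.F[0] if self.n else 0.0

    def _bound(self, label: str, i: int, j: int) -> float:
        if label == "F":
            return self.F[i]
        if label == "C":
            return self.C[i][j]
        return self.M[i][j]

    def enumerate(self, threshold: float) -> list[tuple[frozenset, float]]:
        """All structures with energy <= threshold, each exactly once."""
        m, n = self.model, self.n
        eps = 1e-9
        out: list[tuple[frozenset, float]] = []
        # state: (tasks tuple, pairs tuple, accumulated energy)
        init = ((("F", 0, n - 1),), (), 0.0) if n else ((), (), 0.0)
        stack = [init]
        while stack:
            tasks, pairs, acc = stack.pop()
            if not tasks:
                out.append((frozenset(pairs), acc))
                continue
            (label, i, j), rest = tasks[0], tasks[1:]
            rest_bound = acc + sum(self._bound(*t) for t in rest)

            def push(new_tasks, new_pairs, delta):
                tot = rest_bound + delta + sum(self._bound(*t) for t in new_tasks)
                if tot <= threshold + eps:
                    stack.append((tuple(new_tasks) + rest, new_pairs, acc + delta))

            if label == "F":
                if i > j:
                    push((), pairs, 0.0)
                    continue
                push((("F", i + 1, j),) if i + 1 <= j else (), pairs, 0.0)
                for k in range(i + 1, j + 1):
                    if self.pairable[i][k]:
                        nt = [("C", i, k)]
                        if k + 1 <= j:
                            nt.append(("F", k + 1, j))
                        push(nt, pairs, self.au[i][k])
            elif label == "C":
                np_ = pairs + ((i, j),)
                push((), np_, m.hairpin_energy(j - i - 1) + self.au[i][j])
                if self.pairable[i + 1][j - 1]:
                    push(
                        (("C", i + 1, j - 1),),
                        np_,
                        m.stack[(self.seq[i] + self.seq[j], self.seq[i + 1] + self.seq[j - 1])],
                    )
                for k in range(i + 1, j):
                    for l in range(j - 1, k, -1):
                        if (k, l) == (i + 1, j - 1) or not self.pairable[k][l]:
                            continue
                        size1, size2 = k - i - 1, j - l - 1
                        pen = (
                            m.bulge_energy(size1 + size2)
                            if min(size1, size2) == 0
                            else m.internal_energy(size1 + size2)
                        )
                        push((("C", k, l),), np_, pen + self.au[i][j] + self.au[k][l])
                for h in range(i + 1, j - 1):
                    for k in range(h + 1, j - 1):
                        if self.pairable[h][k]:
                            push(
                                (("C", h, k), ("M", k + 1, j - 1)),
                                np_,
                                m.multiloop_a
                                + 2 * m.multiloop_b
                                + self.au[i][j]
                                + m.multiloop_c * (h - i - 1)
                                + self.au[h][k],
                            )
            else:  # M
                if i < j:
                    push((("M", i + 1, j),), pairs, m.multiloop_c)
                for k in range(i + 1, j + 1):
                    if self.pairable[i][k]:
                        delta = m.multiloop_b + self.au[i][k]
                        push((("C", i, k),), pairs, delta + m.multiloop_c * (j - k))
                        if k < j:
                            push((("C", i, k), ("M", k + 1, j)), pairs, delta)
        return out


def default_energy_window(mfe: float) -> float:
    """Suboptimal enumeration window: 5% of |MFE| with a 1.0 kcal/mol floor."""
    return max(1.0, 0.05 * abs(mfe))


def fold_mfe(seq: RnaSequence, model: EnergyModel | None = None) -> SecondaryStructure:
    """Minimum-free-energy pseudoknot-free structure of a short RNA.

    The empty structure (energy 0) is always legal, so the returned energy is
    never positive. Co-optimal ties are broken lexicographically by
    dot-bracket.
    """
    model = model or EnergyModel.default()
    folder = _Folder(seq.seq, model)
    structs = folder.enumerate(folder.mfe)
    best = min(
        structs,
        key=lambda s: (s[1], pairs_to_dot_bracket(s[0], seq.length)),
    )
    return SecondaryStructure(
        pairs=best[0],
        dot_bracket=pairs_to_dot_bracket(best[0], seq.length),
        energy=best[1],
    )


def fold_suboptimal(
    seq: RnaSequence,
    model: EnergyModel | None = None,
    energy_window: float | None = None,
) -> FoldResult:
    """All structures within ``energy_window`` of the MFE, sorted ascending.

    With ``energy_window=None`` the window defaults to 5% of |MFE| with a
    floor of 1.0 kcal/mol. ``energy_window=0`` returns exactly the co-optimal
    MFE structures.
    """
    model = model or EnergyModel.default()
    folder = _Folder(seq.seq, model)
    mfe = folder.mfe
    if energy_window is None:
        energy_window = default_energy_window(mfe)
    if energy_window < 0:
        raise ValueError("energy_window must be >= 0")
    raw = folder.enumerate(mfe + energy_window)
    structs = sorted(
        (
            SecondaryStructure(
                pairs=p, dot_bracket=pairs_to_dot_bracket(p, seq.length), energy=e
            )
            for p, e in raw
        ),
        key=lambda s: (s.energy, s.dot_bracket),
    )
    matrix = np.zeros((seq.length, seq.length), dtype=bool)
    for s in structs:
        for i, j in s.pairs:
            matrix[i, j] = matrix[j, i] = True
    return FoldResult(
        sequence=seq,
        structures=tuple(structs),
        energy_window=energy_window,
        pair_matrix=matrix,
    )


def dot_plot(fold: FoldResult, path: str | Path | None = None) -> np.ndarray:
    """Pair-frequency matrix over retained structures; optionally render it.

    M[i, j] counts the retained structures containing pair (i, j); the matrix
    is returned symmetric. If ``path`` is given, a dot plot in the style of the
    classic energy dot plot (superposition of all retained foldings) is
    written to that image file.
    """
    n = fold.sequence.length
    matrix = np.zeros((n, n), dtype=int)
    for s in fold.structures:
        for i, j in s.pairs:
            matrix[i, j] += 1
            matrix[j, i] += 1
    if path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4, 4))
        ii, jj = np.nonzero(np.triu(matrix))
        ax.scatter(jj, ii, s=30 * matrix[ii, jj] / max(1, matrix.max()), c="black")
        ax.set_xlim(-0.5, n - 0.5)
        ax.set_ylim(n - 0.5, -0.5)
        ax.set_xlabel("3' position")
        ax.set_ylabel("5' position")
        ax.set_title(f"{fold.sequence.id}: {fold.structure_count} structure(s)")
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return matrix


def stability_rank(folds: Sequence[FoldResult]) -> list[str]:
    """Sequence ids ordered most stable first (lowest MFE; ties by id)."""
    if not folds:
        raise ValueError("at least one fold required")
    return [f.sequence.id for f in sorted(folds, key=lambda f: (f.mfe, f.sequence.id))]


def write_fold_table(folds: Sequence[FoldResult], path: str | Path) -> None:
    """TSV report: one row per sequence with window, energies and count."""
    with open(path, "w") as fh:
        fh.write("id\tlength\tenergy_window\tenergies\tstructure_count\n")
        for f in folds:
            energies = ",".join(f"{s.energy:.2f}" for s in f.structures)
            fh.write(
                f"{f.sequence.id}\t{f.sequence.length}\t{f.energy_window:.2f}\t"
                f"{energies}\t{f.structure_count}\n"
            )


def write_dot_bracket(folds: Sequence[FoldResult], path: str | Path) -> None:
    """Vienna-style text: header, sequence, then one structure per line."""
    with open(path, "w") as fh:
        for f in folds:
            fh.write(f">{f.sequence.id}\n{f.sequence.seq}\n")
            for s in f.structures:
                fh.write(f"{s.dot_bracket} ({s.energy:.2f})\n")
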