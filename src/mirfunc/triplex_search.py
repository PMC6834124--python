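"""Triplex-forming site search between a microRNA third strand and duplex DNA.

An intermolecular triple helix forms when a single-stranded oligonucleotide
(here a 20-22 nt microRNA) binds the major groove of duplex DNA along a
purine-rich strand. Canonical base triplets (third-strand base . purine :
pyrimidine) differ by orientation of the third strand relative to the purine
strand:

* parallel ("direct", Hoogsteen): U.A:T, C.G:C, G.G:C, A.A:T
* antiparallel ("indirect", reverse Hoogsteen): A.A:T, U.A:T, G.G:C

The scan slides every ungapped, full-length register of the third strand along
the promoter, testing both the given strand and its complement as the
purine-carrying strand, in both orientations. Per register, the hit score is
the sum of triplet weights and the hit energy the sum of triplet energies;
registers are retained only when score > score_threshold AND
energy < energy_threshold (both strict). Defaults (+8/-8 weight, -8/+4 energy
per canonical/non-canonical triplet) make a perfect 22-mer register score 176
with energy -176, so the published retention thresholds (score > 140,
energy < -140) admit registers with at most two non-canonical triplets.

Hits are graded against a null distribution of best-register scores from
dinucleotide-preserving shuffles of the third strand: grade 5 at or above the
99th percentile, then 4/3/2 at the 95th/90th/75th, else 1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .sequence_io import DnaSequence, RnaSequence

PARALLEL_CANONICAL = frozenset({("U", "A"), ("C", "G"), ("G", "G"), ("A", "A")})
ANTIPARALLEL_CANONICAL = frozenset({("A", "A"), ("U", "A"), ("G", "G")})

DEFAULT_SCORE_THRESHOLD = 140.0
DEFAULT_ENERGY_THRESHOLD = -140.0

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_GRADE_CUTPOINTS = ((0.99, 5), (0.95, 4), (0.90, 3), (0.75, 2))


@dataclass(frozen=True)
class TripletCode:
    """Triplet alphabet and scoring for one third-strand orientation.

    ``canonical`` holds (third-strand base, duplex purine base) pairs; any
    other combination is non-canonical. Weights and energies are per triplet;
    canonical triplets score positively with favorable (negative) energy.
    """

    orientation: Literal["parallel", "antiparallel"]
    canonical: frozenset
    weight_canonical: float = 8.0
    weight_noncanonical: float = -8.0
    energy_canonical: float = -8.0
    energy_noncanonical: float = 4.0

    def is_canonical(self, third_base: str, purine_base: str) -> bool:
        return (third_base, purine_base) in self.canonical

    def weight(self, third_base: str, purine_base: str) -> float:
        return (
            self.weight_canonical
            if self.is_canonical(third_base, purine_base)
            else self.weight_noncanonical
        )

    def energy(self, third_base: str, purine_base: str) -> float:
        return (
            self.energy_canonical
            if self.is_canonical(third_base, purine_base)
            else self.energy_noncanonical
        )


def default_codes() -> tuple[TripletCode, TripletCode]:
    """The (parallel, antiparallel) codes with default scoring tables."""
    return (
        TripletCode(orientation="parallel", canonical=PARALLEL_CANONICAL),
        TripletCode(orientation="antiparallel", canonical=ANTIPARALLEL_CANONICAL),
    )


@dataclass(frozen=True)
class TriplexHit:
    """One retained ungapped microRNA-duplex register.

    Coordinates are 0-based half-open on the given (promoter) strand;
    ``orientation`` is "direct" (parallel / Hoogsteen) or "indirect"
    (antiparallel / reverse Hoogsteen); ``purine_strand`` says which duplex
    strand carried the purine tract. ``grade`` is None until graded.
    """

    mirna_id: str
    gene_id: str
    orientation: Literal["direct", "indirect"]
    target_start: int
    target_end: int
    purine_strand: Literal["given", "complement"]
    hit_score: float
    hit_energy: float
    grade: int | None = None


@dataclass(frozen=True)
class TriplexSummary:
    """Signed per-(microRNA, gene) hit-count matrix (direct, indirect)."""

    matrix: dict

    def cell_text(self, mirna_id: str, gene_id: str) -> str:
        n_direct, n_indirect = self.matrix.get((mirna_id, gene_id), (0, 0))
        if n_direct == 0 and n_indirect == 0:
            return "0"
        parts = []
        if n_indirect:
            parts.append(f"-{n_indirect}")
        if n_direct:
            parts.append(f"+{n_direct}")
        return "/".join(parts)


def _registers(
    third: str, duplex: str, codes: tuple[TripletCode, TripletCode]
):
    """Yield (orientation, strand, score array, energy array, valid mask).

    Element s of each array describes the register occupying duplex positions
    [s, s + L) on the given strand. Registers covering an N are invalid.
    """
    L, n = len(third), len(duplex)
    if L > n:
        raise ValueError(f"third strand ({L} nt) longer than duplex ({n} bp)")
    par, anti = codes
    comp = duplex.translate(_COMPLEMENT)
    n_reg = n - L + 1
    # register s covers given-strand positions [s, s+L); any N invalidates it
    is_n = np.frombuffer(duplex.encode(), dtype=np.uint8) == ord("N")
    cn = np.concatenate(([0], np.cumsum(is_n)))
    valid = (cn[L : n + 1] - cn[0 : n - L + 1]) == 0

    def rows(code: TripletCode, third_bases: Sequence[str], strand_seq: str):
        w = np.empty((L, n))
        e = np.empty((L, n))
        sarr = np.frombuffer(strand_seq.encode(), dtype=np.uint8)
        for k, tb in enumerate(third_bases):
            canon = np.zeros(n, dtype=bool)
            for _, pb in [t for t in code.canonical if t[0] == tb]:
                canon |= sarr == ord(pb)
            w[k] = np.where(canon, code.weight_canonical, code.weight_noncanonical)
            e[k] = np.where(canon, code.energy_canonical, code.energy_noncanonical)
        return w, e

    def register_sums(rowvals: np.ndarray) -> np.ndarray:
        tot = np.zeros(n_reg)
        for k in range(L):
            tot += rowvals[k, k : k + n_reg]
        return tot

    # combo -> per-k third-strand base aligned at given-strand offset s + k
    combos = [
        ("direct", "given", par, list(third), duplex),
        ("indirect", "given", anti, list(third[::-1]), duplex),
        ("direct", "complement", par, list(third[::-1]), comp),
        ("indirect", "complement", anti, list(third), comp),
    ]
    for orientation, strand, code, bases, strand_seq in combos:
        w, e = rows(code, bases, strand_seq)
        yield orientation, strand, register_sums(w), register_sums(e), valid


def find_triplex_sites(
    third: RnaSequence,
    duplex: DnaSequence,
    codes: tuple[TripletCode, TripletCode] | None = None,
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
    energy_threshold: float = DEFAULT_ENERGY_THRESHOLD,
) -> list[TriplexHit]:
    """Scan every ungapped register, both orientations, both duplex strands.

    Returns hits passing both thresholds strictly, sorted by hit score
    descending (ties by start, orientation, strand).
    """
    codes = codes or default_codes()
    L = third.length
    hits: list[TriplexHit] = []
    for orientation, strand, scores, energies, valid in _registers(
        third.seq, duplex.seq, codes
    ):
        keep = valid & (scores > score_threshold) & (energies < energy_threshold)
        for s in np.nonzero(keep)[0]:
            hits.append(
                TriplexHit(
                    mirna_id=third.id,
                    gene_id=duplex.id,
                    orientation=orientation,
                    target_start=int(s),
                    target_end=int(s) + L,
                    purine_strand=strand,
                    hit_score=float(scores[s]),
                    hit_energy=float(energies[s]),
                )
            )
    hits.sort(
        key=lambda h: (-h.hit_score, h.target_start, h.orientation, h.purine_strand)
    )
    return hits


def best_register_score(
    third_seq: str,
    duplex: DnaSequence,
    codes: tuple[TripletCode, TripletCode] | None = None,
) -> float:
    """Maximum register score over all orientations/strands (no thresholds)."""
    codes = codes or default_codes()
    best = -np.inf
    for _, _, scores, _, valid in _registers(third_seq, duplex.seq, codes):
        if valid.any():
            best = max(best, float(scores[valid].max()))
    return best


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Dinucleotide-preserving shuffle (Altschul-Erikson Eulerian walk)."""
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    first, last = seq[0], seq[-1]
    vertices = [v for v in edges if v != last]
    for _ in range(1000):
        # pick a random terminal edge per vertex; must form a tree into `last`
        terminal = {v: edges[v][rng.integers(len(edges[v]))] for v in vertices}
        ok = True
        for v in vertices:
            seen = {v}
            cur = v
            while cur != last:
                cur = terminal.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - virtually impossible for valid inputs
        raise RuntimeError("dinucleotide shuffle failed to find an Eulerian order")
    order: dict[str, list[str]] = {}
    for v, outs in edges.items():
        rest = list(outs)
        if v in terminal:
            rest.remove(terminal[v])
        perm = [rest[i] for i in rng.permutation(len(rest))] if rest else []
        order[v] = perm + ([terminal[v]] if v in terminal else [])
    out = [first]
    cur = first
    while order.get(cur):
        cur = order[cur].pop(0)
        out.append(cur)
    return "".join(out)


def background_scores(
    third: RnaSequence,
    duplex: DnaSequence,
    codes: tuple[TripletCode, TripletCode] | None = None,
    n: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Null sample: best-register scores of n dinucleotide-shuffled strands."""
    if n < 1:
        raise ValueError("background sample size must be >= 1")
    rng = np.random.default_rng(seed)
    return np.array(
        [
            best_register_score(dinucleotide_shuffle(third.seq, rng), duplex, codes)
            for _ in range(n)
        ]
    )


def score_percentile(background: np.ndarray, score: float) -> float:
    """Empirical percentile: fraction of background scores <= score."""
    background = np.asarray(background)
    if background.size == 0:
        raise ValueError("empty background sample")
    return float(np.count_nonzero(background <= score) / background.size)


def grade_hits(hits: Sequence[TriplexHit], background: np.ndarray) -> list[TriplexHit]:
    """Assign percentile grades 1-5 against a null score sample.

    Grade 5 requires the hit score to reach the 99th percentile of the
    background (fraction-at-or-below convention), grade 4 the 95th, 3 the
    90th, 2 the 75th; everything below is grade 1.
    """
    graded = []
    for h in hits:
        pct = score_percentile(background, h.hit_score)
        grade = 1
        for cut, g in _GRADE_CUTPOINTS:
            if pct >= cut:
                grade = g
                break
        graded.append(replace(h, grade=grade))
    return graded


def summarize_matrix(
    hits: Sequence[TriplexHit], mirnas: Sequence[str], genes: Sequence[str]
) -> TriplexSummary:
    """Dense (microRNA x gene) matrix of direct/indirect hit counts."""
    matrix = {(m, g): (0, 0) for m in mirnas for g in genes}
    for h in hits:
        key = (h.mirna_id, h.gene_id)
        nd, ni = matrix.get(key, (0, 0))
        if h.orientation == "direct":
            nd += 1
        else:
            ni += 1
        matrix[key] = (nd, ni)
    return TriplexSummary(matrix=matrix)


def write_hit_table(hits: Sequence[TriplexHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "mirna_id\tgene_id\torientation\ttarget_start\ttarget_end\t"
            "purine_strand\thit_score\thit_energy\tgrade\n"
        )
        for h in hits:
            grade = "" if h.grade is None else str(h.grade)
            fh.write(
                f"{h.mirna_id}\t{h.gene_id}\t{h.orientation}\t{h.target_start}\t"
                f"{h.target_end}\t{h.purine_strand}\t{h.hit_score:.1f}\t"
                f"{h.hit_energy:.1f}\t{grade}\n"
            )


def write_hit_bed(hits: Sequence[TriplexHit], path: str | Path) -> None:
    """BED6 of hit intervals: name = microRNA, score = hit score, strand by
    orientation (+ direct, - indirect)."""
    with open(path, "w") as fh:
        for h in hits:
            strand = "+" if h.orientation == "direct" else "-"
            fh.write(
                f"{h.gene_id}\t{h.target_start}\t{h.target_end}\t{h.mirna_id}\t"
                f"{h.hit_score:.0f}\t{strand}\n"
            )


def write_summary_table(
    summary: TriplexSummary,
    mirnas: Sequence[str],
    genes: Sequence[str],
    path: str | Path,
) -> None:
    """TSV matrix in the signed notation: +n direct, -n indirect, 0 no hit."""
    with open(path, "w") as fh:
        fh.write("mirna\t" + "\t".join(genes) + "\n")
        for m in mirnas:
            cells = [summary.cell_text(m, g) for g in genes]
            fh.write(m + "\t" + "\t".join(cells) + "\n")
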