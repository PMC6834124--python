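"""Seeded synthetic fixtures that plant the features each analysis stage must
recover: hairpin-forming microRNAs, promoters with CpG islands of controlled
GC% and Obs/Exp, promoters carrying polypurine triplex target tracts for a
given third strand, and somatic-event / interaction tables.

Every generator is a pure function of (seed, params) and returns the planted
truth alongside the artifact, so recovery can be scored without re-deriving
it. The generators' guarantees (e.g. no spurious triplex register anywhere in
a background) are enforced by construction, with explicit repair passes where
random background could otherwise produce near-misses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .sequence_io import DnaSequence, RnaSequence, write_fasta
from .triplex_search import ANTIPARALLEL_CANONICAL, PARALLEL_CANONICAL

TARGET_GENES = ("APC", "GNAS", "EGFR", "TCF7L2", "KRAS", "IGF1R", "CASP8")

_RNA_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}
# third-strand base -> duplex purine base completing an all-canonical triplet
_PARALLEL_PARTNER = {"U": "A", "A": "A", "C": "G", "G": "G"}
_ANTIPARALLEL_PARTNER = {"A": "A", "U": "A", "G": "G"}
_DNA_COMP = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}


@dataclass(frozen=True)
class FixtureSpec:
    """A reproducible fixture request: (seed, kind, params) -> artifact + truth."""

    seed: int
    kind: Literal[
        "hairpin_rna", "cpg_promoter", "triplex_promoter", "event_table", "edge_list"
    ]
    params: dict = field(default_factory=dict)


def make_fixture(spec: FixtureSpec):
    """Dispatch a FixtureSpec to its generator."""
    fn = {
        "hairpin_rna": make_hairpin_rna,
        "cpg_promoter": make_cpg_promoter,
        "triplex_promoter": make_triplex_promoter,
        "event_table": make_event_table,
        "edge_list": make_edge_list,
    }[spec.kind]
    return fn(seed=spec.seed, **spec.params)


# ---------------------------------------------------------------------------
# hairpin RNAs


def make_hairpin_rna(
    stem_len: int,
    loop_len: int = 4,
    total_len: int = 22,
    seed: int = 0,
    rna_id: str = "hairpin",
    c_free: bool = False,
) -> tuple[RnaSequence, dict]:
    """A short RNA with a planted stem around an A/U loop.

    Layout: [flank][stem 5'][loop][stem 3' = reverse partner][flank]. By
    default the stem is drawn from {G, C} so the planted helix dominates the
    folding landscape; flanks are A/U-biased random so they rarely compete.
    With ``c_free=True`` the whole sequence avoids C (stems use A-U and
    wobble G-U pairs), which keeps the RNA able to act as a reverse-Hoogsteen
    third strand. Truth lists the planted pair coordinates. ``stem_len=0``
    yields an unstructured random sequence with empty truth.
    """
    if loop_len < 3:
        raise ValueError("loop_len must be >= 3 (minimum hairpin loop)")
    if 2 * stem_len + (loop_len if stem_len else 0) > total_len:
        raise ValueError("stem and loop do not fit in total_len")
    rng = np.random.default_rng(seed)

    def flank(k: int) -> str:
        if c_free:
            return "".join(rng.choice(list("AUG"), size=k, p=[0.45, 0.45, 0.1]))
        return "".join(rng.choice(list("AUCG"), size=k, p=[0.4, 0.4, 0.1, 0.1]))

    if stem_len == 0:
        return RnaSequence(id=rna_id, seq=flank(total_len)), {"pairs": []}
    core = 2 * stem_len + loop_len
    left = int(rng.integers(0, total_len - core + 1))
    if c_free:
        stem5 = "".join(rng.choice(list("AG"), size=stem_len, p=[0.6, 0.4]))
        stem3 = "U" * stem_len  # A-U and G-U pairs, read 3' side
    else:
        stem5 = "".join(rng.choice(list("GC"), size=stem_len))
        stem3 = "".join(_RNA_COMP[b] for b in reversed(stem5))
    loop = "".join(rng.choice(list("AU"), size=loop_len))
    seq = flank(left) + stem5 + loop + stem3 + flank(total_len - core - left)
    pairs = [
        [left + i, left + 2 * stem_len + loop_len - 1 - i] for i in range(stem_len)
    ]
    return RnaSequence(id=rna_id, seq=seq), {"pairs": pairs}


# ---------------------------------------------------------------------------
# CpG-island promoters


def _markov_background(
    n: int, gc: float, obs_exp: float, rng: np.random.Generator, prev: str = ""
) -> str:
    """CpG-depleted background: i.i.d. base composition at the requested GC
    fraction except that the C->G transition is damped by ``obs_exp``."""
    bases = "ACGT"
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    p_after_c = p.copy()
    p_after_c[2] *= obs_exp
    p_after_c /= p_after_c.sum()
    out = []
    for _ in range(n):
        probs = p_after_c if prev == "C" else p
        prev = bases[rng.choice(4, p=probs)]
        out.append(prev)
    return "".join(out)


def _island_block(
    n: int, gc: float, obs_exp: float, rng: np.random.Generator
) -> tuple[str, int]:
    """A CpG-rich block hitting the requested GC fraction and Obs/Exp.

    Built from shuffled tokens ("CG" dimers, single C/G/A/T) with a
    calibration loop that retunes the number of planted dimers against the
    dimers arising by chance at token boundaries, until the realized Obs/Exp
    is within 5% of the request.
    """
    n_c = n_g = int(round(n * gc / 2))
    want_cpg = int(round(obs_exp * n_c * n_g / n))
    d = want_cpg
    best = None
    for _ in range(60):
        d = max(0, min(d, min(n_c, n_g)))
        tokens = (
            ["CG"] * d
            + ["C"] * (n_c - d)
            + ["G"] * (n_g - d)
        )
        n_at = n - n_c - n_g
        tokens += ["A"] * (n_at // 2) + ["T"] * (n_at - n_at // 2)
        perm = rng.permutation(len(tokens))
        seq = "".join(tokens[i] for i in perm)
        realized = seq.count("CG")
        if best is None or abs(realized - want_cpg) < abs(best[1] - want_cpg):
            best = (seq, realized)
        if abs(realized - want_cpg) <= max(1, round(0.03 * want_cpg)):
            return seq, realized
        d -= realized - want_cpg
    return best  # closest attempt


def make_cpg_promoter(
    length: int = 600,
    island_start: int = 150,
    island_len: int = 300,
    island_gc: float = 65.0,
    island_obs_exp_target: float = 0.9,
    background_gc: float = 35.0,
    background_obs_exp: float = 0.3,
    seed: int = 0,
    gene_id: str = "promoter",
) -> tuple[DnaSequence, dict]:
    """A promoter with one planted CpG island on a CpG-depleted background.

    The island block is sampled to hit the requested GC% and Obs/Exp within
    about 5%; the background uses a first-order chain with suppressed C->G
    transitions (an i.i.d. background would itself have Obs/Exp near 1 and
    defeat the planting). Truth records the island span and realized stats.
    """
    if island_len < 200:
        raise ValueError("island_len must be >= 200 (island definition)")
    if not (0 <= island_start and island_start + island_len <= length):
        raise ValueError("island must lie within the promoter")
    rng = np.random.default_rng(seed)
    left = _markov_background(island_start, background_gc / 100, background_obs_exp, rng)
    island, realized_cpg = _island_block(
        island_len, island_gc / 100, island_obs_exp_target, rng
    )
    right = _markov_background(
        length - island_start - island_len,
        background_gc / 100,
        background_obs_exp,
        rng,
        prev=island[-1],
    )
    seq = left + island + right
    n_c, n_g = island.count("C"), island.count("G")
    truth = {
        "island_start": island_start,
        "island_end": island_start + island_len,
        "realized_gc": 100.0 * (n_c + n_g) / island_len,
        "realized_obs_exp": realized_cpg * island_len / (n_c * n_g),
    }
    return DnaSequence(id=gene_id, seq=seq), truth


# ---------------------------------------------------------------------------
# triplex-target promoters


def _canonical_count(
    third: str, duplex: str, start: int, orientation: str, strand: str
) -> int:
    """Canonical triplets in one register (independent of the scan module's
    vectorized path; used for the generator's specificity guarantee)."""
    L = len(third)
    cnt = 0
    for k in range(L):
        if strand == "given":
            pb = duplex[start + k]
            tb = third[k] if orientation == "direct" else third[L - 1 - k]
            code = PARALLEL_CANONICAL if orientation == "direct" else ANTIPARALLEL_CANONICAL
        else:
            pb = _DNA_COMP[duplex[start + k]]
            tb = third[L - 1 - k] if orientation == "direct" else third[k]
            code = PARALLEL_CANONICAL if orientation == "direct" else ANTIPARALLEL_CANONICAL
        if (tb, pb) in code:
            cnt += 1
    return cnt


def planted_tract(third: RnaSequence, orientation: str) -> str:
    """Given-strand purine tract forming an all-canonical register.

    Raises if the third strand cannot form the orientation (antiparallel
    triplets exist only for A, U and G third-strand bases).
    """
    t = third.seq
    if orientation == "direct":
        return "".join(_PARALLEL_PARTNER[b] for b in t)
    missing = sorted({b for b in t if b not in _ANTIPARALLEL_PARTNER})
    if missing:
        raise ValueError(
            f"third strand contains {missing}: no canonical reverse-Hoogsteen "
            "triplet exists for C"
        )
    return "".join(_ANTIPARALLEL_PARTNER[b] for b in reversed(t))


def make_triplex_promoter(
    third: RnaSequence,
    sites: Sequence[tuple[int, str]],
    length: int = 600,
    seed: int = 0,
    gene_id: str = "promoter",
    protected_blocks: Sequence[tuple[int, str]] = (),
) -> tuple[DnaSequence, dict]:
    """A promoter with perfect triplex target tracts planted for ``third``.

    ``sites`` is a list of (start, orientation) with orientation "direct" or
    "indirect"; tracts must not overlap. The background is pyrimidine-biased
    and then repaired so that no non-planted register on either strand, in
    either orientation, reaches L-2 canonical triplets (i.e. nothing else can
    pass the retention thresholds). If a planted tract itself induces a
    passing register in another (orientation, strand) combination that cannot
    be broken without touching a planted tract, the third strand is
    orientation-ambiguous and an error is raised.

    ``protected_blocks`` optionally places fixed content (e.g. a planted CpG
    island) at given positions; such positions are never mutated by the
    repair pass, and an unbreakable near-register inside them is an error.
    """
    L = third.length
    spans = []
    for pos, orientation in sites:
        if orientation not in ("direct", "indirect"):
            raise ValueError(f"orientation must be direct/indirect, got {orientation!r}")
        if not (0 <= pos and pos + L <= length):
            raise ValueError(f"site at {pos} does not fit")
        spans.append((pos, pos + L))
    spans.sort()
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 < e1:
            raise ValueError("planted sites overlap")
    rng = np.random.default_rng(seed)
    # GC-poor, pyrimidine-biased background: stays clear of both the CpG
    # island criteria (GC << 50%) and purine-tract false positives
    seq = list(
        "".join(rng.choice(list("ACGT"), size=length, p=[0.1, 0.25, 0.05, 0.6]))
    )
    for pos, block in protected_blocks:
        if not (0 <= pos and pos + len(block) <= length):
            raise ValueError("protected block does not fit")
        seq[pos : pos + len(block)] = block
    for pos, orientation in sites:
        seq[pos : pos + L] = planted_tract(third, orientation)
    planted = {
        (pos, orientation, "given") for pos, orientation in sites
    }
    in_planted = [False] * length
    for s, e in spans:
        for i in range(s, e):
            in_planted[i] = True
    for pos, block in protected_blocks:
        for i in range(pos, pos + len(block)):
            in_planted[i] = True

    # specificity repair: break every non-planted near-canonical register
    for _ in range(200):
        dirty = False
        for start in range(length - L + 1):
            for orientation in ("direct", "indirect"):
                for strand in ("given", "complement"):
                    if (start, orientation, strand) in planted:
                        continue
                    if (
                        _canonical_count("".join(third.seq), "".join(seq), start, orientation, strand)
                        < L - 2
                    ):
                        continue
                    free = [
                        i for i in range(start, start + L) if not in_planted[i]
                    ]
                    if not free:
                        raise ValueError(
                            f"{third.id}: orientation-ambiguous third strand -- a "
                            "planted tract matches another orientation/strand"
                        )
                    # set 3 free positions to bases breaking canonicity in
                    # every code (pyrimidines are never canonical purines)
                    for i in rng.permutation(free)[:3]:
                        seq[i] = "T" if seq[i] != "T" else "C"
                    dirty = True
        if not dirty:
            break
    else:  # pragma: no cover
        raise RuntimeError("triplex background repair did not converge")
    truth = {
        "sites": [
            {"start": pos, "end": pos + L, "orientation": orientation}
            for pos, orientation in sites
        ]
    }
    return DnaSequence(id=gene_id, seq="".join(seq)), truth


# ---------------------------------------------------------------------------
# event tables and edge lists


def make_event_table(
    path: str | Path | None = None, seed: int = 0, n_filler: int = 6
) -> tuple["object", dict]:
    """Somatic-event TSV emulating a stage/temporal-order database export.

    Encodes the colorectal-cancer facts the analysis expects to surface (APC
    early-stage; GNAS metastatic; KRAS early/late/drug-resistance; the
    APC -> TP53 -> TCF7L2 and CASP8 -> KRAS -> PIK3CA temporal chains; EGFR
    drug-induced/drug-resistance) plus seeded random filler genes that never
    collide with the seven target genes.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = [
        ("APC", "early", "LOH", "TP53"),
        ("APC", "early", "mutation", ""),
        ("APC", "early", "methylation", ""),
        ("APC", "early", "alteration", ""),
        ("APC", "early", "CNV-loss", ""),
        ("TP53", "early", "mutation", "TCF7L2"),
        ("TCF7L2", "late", "mutation", ""),
        ("GNAS", "metastatic", "mutation", ""),
        ("KRAS", "early", "mutation", "PIK3CA"),
        ("KRAS", "late", "mutation", ""),
        ("KRAS", "drug-resistance", "mutation", ""),
        ("CASP8", "early", "mutation", "KRAS"),
        ("PIK3CA", "late", "mutation", ""),
        ("EGFR", "drug-induced", "mutation", ""),
        ("EGFR", "drug-resistance", "mutation", ""),
        ("IGF1R", "", "mutation", ""),
    ]
    stages = sorted({"early", "late", "relapse", "metastatic"})
    variants = sorted({"mutation", "methylation", "CNV-gain"})
    for i in range(n_filler):
        gene = f"FILLER{i + 1}"
        rows.append(
            (
                gene,
                stages[rng.integers(len(stages))],
                variants[rng.integers(len(variants))],
                "",
            )
        )
    df = pd.DataFrame(rows, columns=["gene", "stage", "variant_type", "antecedent_of"])
    truth = {
        "stage_of": {"APC": ["early"], "GNAS": ["metastatic"],
                     "KRAS": ["early", "late", "drug-resistance"]},
        "paths": [["APC", "TP53", "TCF7L2"], ["CASP8", "KRAS", "PIK3CA"]],
    }
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df, truth


def make_edge_list(
    path: str | Path | None = None, seed: int = 0
) -> tuple["object", dict]:
    """Interaction edge list covering all six kinds with fixed weights.

    Kind weights follow the renormalized composition used throughout the
    package's worked examples: genetic 4383, shared-domain 2628, physical
    1423, co-expression 1014, pathway 389, predicted 163 (per mille of total
    weight x 100).
    """
    import pandas as pd

    kind_weights = {
        "genetic": 4383.0,
        "shared-domain": 2628.0,
        "physical": 1423.0,
        "co-expression": 1014.0,
        "pathway": 389.0,
        "predicted": 163.0,
    }
    # split each kind's weight over a couple of named edges
    rows = [
        ("KCTD1", "APC", "genetic", 2383.0),
        ("ADCY6", "GNAS", "genetic", 2000.0),
        ("APC", "TCF7L2", "shared-domain", 1628.0),
        ("EGFR", "IGF1R", "shared-domain", 1000.0),
        ("KRAS", "EGFR", "physical", 1423.0),
        ("APC", "CASP8", "co-expression", 514.0),
        ("BCL2", "MAPK1", "co-expression", 500.0),
        ("KRAS", "CASP8", "pathway", 389.0),
        ("IGF1R", "GNAS", "predicted", 163.0),
    ]
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "kind", "weight"])
    total = sum(kind_weights.values())
    truth = {
        "composition": {k: 100.0 * w / total for k, w in kind_weights.items()}
    }
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df, truth


# ---------------------------------------------------------------------------
# the demo bundle

# mir-1 and mir-5 host reverse-Hoogsteen plantings, so they are C-free
# (antiparallel triplets exist only for A, U and G third-strand bases);
# their A-U/G-U stems give shallow landscapes with several near-optimal
# folds, while mir-3's G-C stem folds into a single dominant hairpin.
_DEMO_MIRNAS: dict[str, dict] = {
    "mir-1": {"stem_len": 5, "loop_len": 4, "total_len": 22, "seed_off": 14, "c_free": True},
    "mir-2": {"stem_len": 3, "loop_len": 4, "total_len": 22, "seed_off": 11},
    "mir-3": {"stem_len": 6, "loop_len": 4, "total_len": 22, "seed_off": 11},
    "mir-4": {"stem_len": 3, "loop_len": 4, "total_len": 20, "seed_off": 15},
    "mir-5": {"stem_len": 4, "loop_len": 4, "total_len": 22, "seed_off": 19, "c_free": True},
}


def make_demo_bundle(outdir: str | Path, seed: int = 17) -> dict:
    """Write the paper-shaped demo dataset: five hairpin microRNAs, seven
    600-bp promoters with planted CpG islands, triplex target tracts for a
    subset of (microRNA, gene) pairs, a somatic-event table and an
    interaction edge list, plus a JSON truth sidecar. Returns the manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rnas = []
    truth: dict = {"mirnas": {}, "promoters": {}, "triplex_sites": {}}
    for name, p in _DEMO_MIRNAS.items():
        rna, t = make_hairpin_rna(
            stem_len=p["stem_len"],
            loop_len=p["loop_len"],
            total_len=p["total_len"],
            seed=seed + p["seed_off"],
            rna_id=name,
            c_free=p.get("c_free", False),
        )
        rnas.append(rna)
        truth["mirnas"][name] = {"length": rna.length, **t}
    write_fasta(rnas, outdir / "mirnas.fasta")
    rna_by_id = {r.id: r for r in rnas}

    island_params = {
        "APC": (52.0, 0.65), "KRAS": (70.0, 1.0), "TCF7L2": (60.0, 0.8),
        "EGFR": (56.5, 0.75), "IGF1R": (66.0, 1.1), "CASP8": (68.0, 0.7),
        "GNAS": (68.0, 0.7),
    }
    # sparse (microRNA, gene) plantings shaping the triplex summary matrix
    plantings = {
        "KRAS": ("mir-1", [(380, "indirect"), (450, "indirect")]),
        "TCF7L2": ("mir-5", [(400, "indirect"), (520, "indirect")]),
        "APC": ("mir-5", [(450, "indirect")]),
        "EGFR": ("mir-1", [(390, "indirect"), (470, "direct")]),
        "CASP8": ("mir-5", [(430, "direct")]),
    }
    promoters = []
    for k, gene in enumerate(TARGET_GENES):
        gc, oe = island_params[gene]
        prom, t = make_cpg_promoter(
            length=600,
            island_start=60,
            island_len=260,
            island_gc=gc,
            island_obs_exp_target=oe,
            background_gc=36.0,
            seed=seed + 100 + k,
            gene_id=gene,
        )
        if gene in plantings:
            mirna_id, sites = plantings[gene]
            third = rna_by_id[mirna_id]
            # rebuild around the island block so the specificity repair sees
            # the final composite sequence
            island_block = prom.seq[60:320]
            prom, tt = make_triplex_promoter(
                third,
                sites,
                length=600,
                seed=seed + 200 + k,
                gene_id=gene,
                protected_blocks=[(60, island_block)],
            )
            truth["triplex_sites"][gene] = {"mirna": mirna_id, **tt}
        promoters.append(prom)
        truth["promoters"][gene] = t
    write_fasta(promoters, outdir / "promoters.fasta")

    # guard: no microRNA may reach a near-canonical register anywhere except
    # its own planted tracts (cross-reactive demo seeds are rejected)
    expected = {
        (t["mirna"], gene, s["start"], s["orientation"], "given")
        for gene, t in truth["triplex_sites"].items()
        for s in t["sites"]
    }
    for rna in rnas:
        L = rna.length
        for prom in promoters:
            for start in range(prom.length - L + 1):
                for orientation in ("direct", "indirect"):
                    for strand in ("given", "complement"):
                        if (
                            _canonical_count(rna.seq, prom.seq, start, orientation, strand)
                            >= L - 2
                            and (rna.id, prom.id, start, orientation, strand)
                            not in expected
                        ):
                            raise ValueError(
                                f"demo seed {seed}: spurious near-canonical register "
                                f"({rna.id} x {prom.id} at {start})"
                            )

    _, event_truth = make_event_table(outdir / "events.tsv", seed=seed)
    _, edge_truth = make_edge_list(outdir / "interactions.tsv", seed=seed)
    truth["events"] = event_truth
    truth["interactions"] = edge_truth
    manifest = {
        "seed": seed,
        "mirna_fasta": str(outdir / "mirnas.fasta"),
        "promoter_fasta": str(outdir / "promoters.fasta"),
        "event_table": str(outdir / "events.tsv"),
        "edge_list": str(outdir / "interactions.tsv"),
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return manifest
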