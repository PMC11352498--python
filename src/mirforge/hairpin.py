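"""Candidate-hairpin folding, structure decomposition and criteria filtering.

Novel-miRNA candidates are genomic loci whose 120-nt flanking window folds
into a single stem-loop.  Folding uses an energy-weighted Nussinov dynamic
program: the returned structure minimises the sum of per-pair energies
(G:C -3.0, A:U -2.0, G:U -1.0 kcal/mol) over all pseudoknot-free structures
with a minimum hairpin-loop of 3 nt.  This pseudo-energy is monotone with
thermodynamic stability but carries no stacking or dangle terms; Vienna
RNAfold output can be dropped in through
:func:`mirforge.formats_io.read_vienna_fold` and is scored by the same
criteria, including the -15 kcal/mol stability cutoff.

A folded candidate is accepted as a plausible pre-miRNA only when eleven
structural criteria all hold (bounds inclusive):

1.  largest bulge in the stem               <= 12 nt
2.  base pairs in the stem                  >= 16
3.  free energy                             <= -15 kcal/mol
4.  hairpin length (stems + terminal loop)  >= 50 nt
5.  terminal loop length                    <= 200 nt
6.  largest bulge touching the mature span  <= 4 nt
7.  largest mature-bulge asymmetry          <= 2 nt
8.  asymmetric bulges in the mature span    <= 2
9.  unpaired bases in the mature span       <= 4
10. base pairs in the mature span           >= 12
11. percent of mature bases in the stem     >= 80

"Bias" in criteria 7-8 is read as bulge asymmetry: the unpaired-base count
contributed by the 5' arm minus that of the 3' arm; the verdict records this
interpretation explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np

from .formats_io import revcomp, to_dna

__all__ = [
    "PAIR_ENERGIES",
    "MIN_LOOP",
    "HairpinStructure",
    "Decomposition",
    "Bulge",
    "StructuralFeatures",
    "CriteriaConfig",
    "CriterionResult",
    "CriteriaVerdict",
    "fold",
    "decompose",
    "extract_features",
    "apply_criteria",
    "evaluate_candidate",
    "extract_flank",
]

# per-pair pseudo-energies, kcal/mol (DNA alphabet internally: U==T)
PAIR_ENERGIES: dict[frozenset, float] = {
    frozenset("GC"): -3.0,
    frozenset("AT"): -2.0,
    frozenset("GT"): -1.0,
}
MIN_LOOP = 3  # minimum unpaired bases inside any hairpin loop

_BASES = "ACGT"
_INF = np.inf


def pair_energy(a: str, b: str) -> float:
    """Energy of pairing bases a/b; +inf when they cannot pair."""
    return PAIR_ENERGIES.get(frozenset((a, b)) if a != b else frozenset(a), _INF)


def _pairing_from_dotbracket(db: str) -> dict[int, int]:
    stack: list[int] = []
    pairing: dict[int, int] = {}
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            pairing[i] = j
            pairing[j] = i
        elif c != ".":
            raise ValueError(f"invalid dot-bracket character {c!r} at position {i}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return pairing


@dataclass(frozen=True)
class HairpinStructure:
    """One candidate secondary structure: sequence, pairing and energy.

    Sequence is held in the DNA alphabet (T for U) like the rest of the
    package; ``free_energy`` is in kcal/mol (non-positive for any structure
    with at least one pair).
    """

    sequence: str
    dot_bracket: str
    free_energy: float
    pairing: Mapping[int, int] = field(default=None)  # type: ignore[assignment]
    id: str | None = None

    def __post_init__(self) -> None:
        if len(self.dot_bracket) != len(self.sequence):
            raise ValueError(
                f"dot-bracket length {len(self.dot_bracket)} != sequence length {len(self.sequence)}"
            )
        if self.pairing is None:
            object.__setattr__(self, "pairing", _pairing_from_dotbracket(self.dot_bracket))
        for i, j in self.pairing.items():
            if self.pairing.get(j) != i:
                raise ValueError(f"pairing map not symmetric at {i}<->{j}")

    @classmethod
    def from_dotbracket(
        cls, sequence: str, dot_bracket: str, free_energy: float, id: str | None = None
    ) -> "HairpinStructure":
        return cls(to_dna(sequence), dot_bracket, free_energy, None, id)

    @property
    def n_pairs(self) -> int:
        return len(self.pairing) // 2

    def pairs(self) -> list[tuple[int, int]]:
        """Base pairs (i, j), i < j, sorted by i."""
        return sorted((i, j) for i, j in self.pairing.items() if i < j)


# ---------------------------------------------------------------------------
# Folding
# ---------------------------------------------------------------------------

def fold(sequence: str) -> HairpinStructure:
    """Minimum-pseudo-energy nested structure of ``sequence``.

    Dynamic program over intervals; ties in the traceback are broken by
    pairing the left end with the smallest admissible partner, so the result
    is deterministic.  Raises ValueError for length < 10 or characters
    outside ACGU/ACGT.
    """
    seq = to_dna(sequence)
    n = len(seq)
    if n < 10:
        raise ValueError(f"sequence too short to fold ({n} < 10 nt)")
    if any(c not in _BASES for c in seq):
        bad = sorted({c for c in seq if c not in _BASES})
        raise ValueError(f"non-ACGU characters in sequence: {bad}")

    codes = np.frombuffer(seq.encode(), dtype=np.uint8)
    lut = np.full(256, -1, dtype=np.int8)
    for k, b in enumerate(_BASES):
        lut[ord(b)] = k
    ci = lut[codes].astype(np.intp)
    emat = np.full((4, 4), _INF)
    for pair, e in PAIR_ENERGIES.items():
        a, b = tuple(pair) if len(pair) == 2 else (next(iter(pair)),) * 2
        ia, ib = _BASES.index(a), _BASES.index(b)
        emat[ia, ib] = emat[ib, ia] = e
    pe = emat[np.ix_(ci, ci)]  # n x n pair-energy table

    # E[i, j]: best energy of subsequence i..j inclusive; 0 when i > j.
    E = np.zeros((n + 1, n))
    for span in range(MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = E[i + 1, j]
            # pair i with k in [i+MIN_LOOP+1 .. j]
            vals = pe[i, i + MIN_LOOP + 1 : j + 1] \
                + E[i + 1, i + MIN_LOOP : j] \
                + E[i + MIN_LOOP + 2 : j + 2, j]
            vb = vals.min()
            if vb < best:
                best = vb
            E[i, j] = best

    # traceback (pairing preferred on ties, smallest partner first)
    pairing: dict[int, int] = {}
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= MIN_LOOP:
            continue
        vals = pe[i, i + MIN_LOOP + 1 : j + 1] \
            + E[i + 1, i + MIN_LOOP : j] \
            + E[i + MIN_LOOP + 2 : j + 2, j]
        target = E[i, j]
        hit = np.flatnonzero(vals == target)
        if hit.size:
            k = i + MIN_LOOP + 1 + int(hit[0])
            pairing[i] = k
            pairing[k] = i
            stack.append((i + 1, k - 1))
            stack.append((k + 1, j))
        else:
            stack.append((i + 1, j))

    db = ["."] * n
    for i, j in pairing.items():
        if i < j:
            db[i] = "("
            db[j] = ")"
    energy = float(E[0, n - 1]) if pairing else 0.0
    return HairpinStructure(seq, "".join(db), energy, pairing)


# ---------------------------------------------------------------------------
# Decomposition: stem / terminal loop / bulges
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Bulge:
    """Unpaired run(s) between two consecutive stem pairs.

    ``nt5``/``nt3`` count unpaired bases on the 5' and 3' arm respectively;
    ``positions`` holds every unpaired index the bulge owns.
    """

    nt5: int
    nt3: int
    positions: tuple[int, ...]

    @property
    def size(self) -> int:
        return self.nt5 + self.nt3

    @property
    def asymmetry(self) -> int:
        return abs(self.nt5 - self.nt3)


@dataclass(frozen=True)
class Decomposition:
    is_hairpin: bool
    reason: str | None = None
    pairs: tuple[tuple[int, int], ...] = ()
    loop_positions: tuple[int, ...] = ()
    bulges: tuple[Bulge, ...] = ()
    external_positions: tuple[int, ...] = ()

    @property
    def stem_positions(self) -> frozenset:
        return frozenset(p for ij in self.pairs for p in ij)

    @property
    def loop_length(self) -> int:
        return len(self.loop_positions)

    @property
    def hairpin_length(self) -> int:
        """Outermost-pair span: both stems plus terminal loop, bulges included."""
        if not self.pairs:
            return 0
        (i0, j0) = self.pairs[0]
        return j0 - i0 + 1


def decompose(structure: HairpinStructure) -> Decomposition:
    """Split a structure into stem pairs, terminal loop and bulges.

    Only single stem-loops are accepted: the pairs must form one nested
    chain.  Two terminal loops (a multiloop) or zero pairs yield a
    not-a-hairpin verdict rather than an exception, so criteria evaluation
    can record the reason.
    """
    pairs = structure.pairs()
    if not pairs:
        return Decomposition(False, "no base pairs")
    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
        if not (i1 < i2 and j2 < j1):
            return Decomposition(False, "more than one terminal loop")

    n = len(structure.sequence)
    im, jm = pairs[-1]
    loop = tuple(range(im + 1, jm))
    bulges: list[Bulge] = []
    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
        g5 = tuple(range(i1 + 1, i2))
        g3 = tuple(range(j2 + 1, j1))
        if g5 or g3:
            bulges.append(Bulge(len(g5), len(g3), g5 + g3))
    i0, j0 = pairs[0]
    external = tuple(range(0, i0)) + tuple(range(j0 + 1, n))
    return Decomposition(True, None, tuple(pairs), loop, tuple(bulges), external)


# ---------------------------------------------------------------------------
# Features and criteria
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StructuralFeatures:
    max_stem_bulge_nt: int
    stem_base_pairs: int
    free_energy: float
    hairpin_length: int
    loop_length: int
    max_mature_bulge_nt: int
    max_mature_bulge_bias: int
    mature_biased_bulges: int
    mature_errors: int
    mature_base_pairs: int
    mature_in_stem_pct: float


def extract_features(
    structure: HairpinStructure, mature: tuple[int, int]
) -> StructuralFeatures:
    """Compute the eleven structural features for one mature placement.

    ``mature`` is 0-based half-open on the folded sequence.  Raises
    ValueError when the interval is out of bounds or the structure is not a
    single hairpin (use :func:`evaluate_candidate` for a verdict instead).
    """
    s, e = mature
    if not (0 <= s < e <= len(structure.sequence)):
        raise ValueError(f"mature interval {mature} out of bounds for length {len(structure.sequence)}")
    dec = decompose(structure)
    if not dec.is_hairpin:
        raise ValueError(f"not a single hairpin: {dec.reason}")
    mature_set = set(range(s, e))
    stem = dec.stem_positions
    mature_bulges = [b for b in dec.bulges if mature_set.intersection(b.positions)]
    mature_paired = len(mature_set & stem)
    return StructuralFeatures(
        max_stem_bulge_nt=max((b.size for b in dec.bulges), default=0),
        stem_base_pairs=len(dec.pairs),
        free_energy=structure.free_energy,
        hairpin_length=dec.hairpin_length,
        loop_length=dec.loop_length,
        max_mature_bulge_nt=max((b.size for b in mature_bulges), default=0),
        max_mature_bulge_bias=max((b.asymmetry for b in mature_bulges), default=0),
        mature_biased_bulges=sum(1 for b in mature_bulges if b.asymmetry > 0),
        mature_errors=len(mature_set) - mature_paired,
        mature_base_pairs=mature_paired,
        mature_in_stem_pct=100.0 * mature_paired / len(mature_set),
    )


@dataclass(frozen=True)
class CriteriaConfig:
    """Inclusive thresholds for the eleven-criterion filter."""

    max_stem_bulge_nt: float = 12
    min_stem_base_pairs: float = 16
    max_free_energy: float = -15.0
    min_hairpin_length: float = 50
    max_loop_length: float = 200
    max_mature_bulge_nt: float = 4
    max_mature_bulge_bias: float = 2
    max_mature_biased_bulges: float = 2
    max_mature_errors: float = 4
    min_mature_base_pairs: float = 12
    min_mature_in_stem_pct: float = 80.0


# (feature name, config name, comparison) in criterion order
_CRITERIA: tuple[tuple[str, str, str], ...] = (
    ("max_stem_bulge_nt", "max_stem_bulge_nt", "le"),
    ("stem_base_pairs", "min_stem_base_pairs", "ge"),
    ("free_energy", "max_free_energy", "le"),
    ("hairpin_length", "min_hairpin_length", "ge"),
    ("loop_length", "max_loop_length", "le"),
    ("max_mature_bulge_nt", "max_mature_bulge_nt", "le"),
    ("max_mature_bulge_bias", "max_mature_bulge_bias", "le"),
    ("mature_biased_bulges", "max_mature_biased_bulges", "le"),
    ("mature_errors", "max_mature_errors", "le"),
    ("mature_base_pairs", "min_mature_base_pairs", "ge"),
    ("mature_in_stem_pct", "min_mature_in_stem_pct", "ge"),
)


@dataclass(frozen=True)
class CriterionResult:
    name: str
    value: float
    threshold: float
    comparison: str  # "le" | "ge"
    passed: bool


@dataclass(frozen=True)
class CriteriaVerdict:
    passed: bool
    results: tuple[CriterionResult, ...]
    reason: str | None = None  # set when the candidate was not a hairpin
    bias_interpretation: str = "bulge asymmetry (5'-arm nt minus 3'-arm nt)"

    def failed_names(self) -> list[str]:
        return [r.name for r in self.results if not r.passed]

    def to_dict(self) -> dict:
        return {
            "passed": self.passed,
            "reason": self.reason,
            "bias_interpretation": self.bias_interpretation,
            "criteria": [asdict(r) for r in self.results],
        }


def apply_criteria(
    features: StructuralFeatures, config: CriteriaConfig | None = None
) -> CriteriaVerdict:
    """Evaluate all eleven criteria; overall pass iff every one passes."""
    config = config or CriteriaConfig()
    results = []
    for feat_name, cfg_name, cmp_ in _CRITERIA:
        value = getattr(features, feat_name)
        threshold = getattr(config, cfg_name)
        ok = value <= threshold if cmp_ == "le" else value >= threshold
        results.append(CriterionResult(feat_name, float(value), float(threshold), cmp_, bool(ok)))
    return CriteriaVerdict(all(r.passed for r in results), tuple(results))


def evaluate_candidate(
    structure: HairpinStructure,
    mature: tuple[int, int],
    config: CriteriaConfig | None = None,
) -> CriteriaVerdict:
    """Criteria verdict for one candidate, tolerant of non-hairpin folds."""
    dec = decompose(structure)
    if not dec.is_hairpin:
        return CriteriaVerdict(False, (), reason=dec.reason)
    return apply_criteria(extract_features(structure, mature), config)


# ---------------------------------------------------------------------------
# Stem-loop extraction from a multi-branch fold
# ---------------------------------------------------------------------------

def extract_stemloop(
    structure: HairpinStructure,
    interval: tuple[int, int],
    max_extension_gap: int = 12,
) -> tuple[HairpinStructure, int] | None:
    """Isolate the stem-loop containing ``interval`` from a larger fold.

    A folded 120-nt-flank window usually carries side helices besides the
    candidate hairpin; criteria apply to the stem-loop the mature sequence
    lives in.  Every maximal helix chain (terminal loop walked outward until
    a multibranch junction, the exterior loop, or an internal loop larger
    than ``max_extension_gap`` nt) is a candidate; the one pairing the most
    interval positions wins, with ties to the longer then leftmost chain.
    Pairs outside the chosen chain are discarded (positions become unpaired)
    and the pseudo-energy is recomputed over the kept pairs.  Returns
    (sub-structure, offset on the input) or None for a pairless fold.
    """
    s, e = interval
    pairs = structure.pairs()
    if not pairs:
        return None
    # nesting tree: parent = closest enclosing pair
    parent: dict[tuple[int, int], tuple[int, int] | None] = {}
    children: dict[tuple[int, int] | None, list[tuple[int, int]]] = {None: []}
    stack: list[tuple[int, int]] = []
    for p in pairs:
        while stack and not (stack[-1][0] < p[0] and p[1] < stack[-1][1]):
            stack.pop()
        par = stack[-1] if stack else None
        parent[p] = par
        children.setdefault(par, []).append(p)
        children.setdefault(p, [])
        stack.append(p)

    def chain_from(leaf: tuple[int, int]) -> list[tuple[int, int]]:
        chain = [leaf]
        cur = leaf
        while True:
            par = parent[cur]
            if par is None or len(children[par]) != 1:
                break
            gap = (cur[0] - par[0] - 1) + (par[1] - cur[1] - 1)
            if gap > max_extension_gap:
                break
            chain.append(par)
            cur = par
        return chain  # innermost first

    best: tuple[tuple[int, int, int], list[tuple[int, int]]] | None = None
    for leaf in (p for p in pairs if not children[p]):
        chain = chain_from(leaf)
        paired_in_interval = sum(
            1 for p in chain for x in p if s <= x < e
        )
        key = (paired_in_interval, len(chain), -chain[-1][0])
        if best is None or key > best[0]:
            best = (key, chain)
    chain = best[1]
    top = chain[-1]

    lo = min(top[0], s)
    hi = max(top[1], e - 1)
    keep = set(chain)
    sub_seq = structure.sequence[lo : hi + 1]
    db = ["."] * len(sub_seq)
    energy = 0.0
    for i, j in keep:
        db[i - lo] = "("
        db[j - lo] = ")"
        energy += pair_energy(structure.sequence[i], structure.sequence[j])
    return HairpinStructure(sub_seq, "".join(db), energy), lo


def evaluate_window(
    structure: HairpinStructure,
    mature: tuple[int, int],
    config: CriteriaConfig | None = None,
) -> CriteriaVerdict:
    """Criteria verdict for a mature interval inside a folded flank window.

    Extracts the mature-containing stem-loop first, then applies the
    criteria to it; the candidate fails outright when the mature sits in a
    completely unpaired region.
    """
    sub = extract_stemloop(structure, mature)
    if sub is None:
        return CriteriaVerdict(False, (), reason="mature region is unpaired")
    substructure, lo = sub
    return evaluate_candidate(substructure, (mature[0] - lo, mature[1] - lo), config)


# ---------------------------------------------------------------------------
# Flank extraction
# ---------------------------------------------------------------------------

def extract_flank(
    scaffold: str,
    start: int,
    end: int,
    strand: str = "+",
    flank: int = 120,
) -> tuple[str, int, int]:
    """Window of ``flank`` nt either side of a genomic hit, clipped at the
    scaffold ends; minus-strand hits are reverse-complemented.

    ``start``/``end`` are 0-based half-open on the plus strand.  Returns
    (window sequence, mature start, mature end) with the mature interval in
    window coordinates (on the reported strand).
    """
    if not (0 <= start < end <= len(scaffold)):
        raise ValueError(f"hit {start}-{end} out of bounds for scaffold length {len(scaffold)}")
    ws = max(0, start - flank)
    we = min(len(scaffold), end + flank)
    window = scaffold[ws:we]
    if strand == "+":
        return window, start - ws, end - ws
    if strand == "-":
        return revcomp(window), we - end, we - start
    raise ValueError(f"strand must be '+' or '-', got {strand!r}")
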