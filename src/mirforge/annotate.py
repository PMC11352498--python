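"""Known/novel miRNA classification and the isomiR naming grammar.

Each retained tag is assigned to exactly one category by first-match
precedence:

1. ``known_species``  — tag sits on an annotated mature arm of a
   same-species precursor (end shifts within the allowed variation, at most
   one internal mismatch);
2. ``novel_arm``      — tag maps to the arm opposite the annotated mature of
   a same-species precursor (a previously unannotated 5p/3p product);
3. ``known_xeno``     — tag matches a mature arm of another species'
   precursor whose hairpin also occurs in the study genome;
4. ``candidate_pc``   — tag matches the genome and its 120-nt flanking
   window folds into a hairpin passing all eleven structural criteria;
5. ``unannotated``    — everything else.

Names follow the community grammar: the mature name (``zma-miR395a-3p``)
with ``_L{+-}n`` / ``_R{+-}n`` suffixes for 5'/3' end shifts (positive =
extended outward relative to the annotated mature, negative = trimmed),
``-p5``/``-p3`` appended to the precursor name for opposite-arm products,
and ``PC-<arm>-<serial>_<count>`` for genome-derived candidates.  Distinct
tags that would collide on a name (e.g. a sequencing-error variant of the
canonical tag) receive a ``_v2``, ``_v3`` ... suffix so names stay unique
within a run; ``parse_mirna_name`` inverts all of these forms exactly.

"BLAST" steps of the reference workflow are realised as exact/one-mismatch
ungapped search (pigeonhole-seeded, then verified), which at tag lengths of
at most 25 nt has equivalent sensitivity without an external aligner.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .formats_io import MatureCoordinateSidecar, SequenceRecord, revcomp, to_dna
from .hairpin import CriteriaConfig, evaluate_window, extract_flank, fold
from .preprocess import RETAINED, UniqueTag

__all__ = [
    "PrecursorRecord",
    "TagAlignment",
    "MiRNAAnnotation",
    "GenomeIndex",
    "align_tag_to_precursor",
    "classify_tag",
    "classify_tags",
    "name_mirna",
    "parse_mirna_name",
    "mature_name_from_precursor",
    "annotation_count_matrix",
    "KNOWN_SPECIES",
    "NOVEL_ARM",
    "KNOWN_XENO",
    "CANDIDATE_PC",
    "UNANNOTATED",
]

KNOWN_SPECIES = "known_species"
NOVEL_ARM = "novel_arm"
KNOWN_XENO = "known_xeno"
CANDIDATE_PC = "candidate_pc"
UNANNOTATED = "unannotated"

ANNOTATED_MATURE = "annotated_mature"
OPPOSITE_ARM = "opposite_arm"
ELSEWHERE = "elsewhere"


@dataclass(frozen=True)
class PrecursorRecord:
    """A pre-miRNA hairpin with its annotated mature-arm interval(s)."""

    id: str
    species: str
    sequence: str
    mature_arms: tuple[MatureCoordinateSidecar, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", to_dna(self.sequence))
        arms = set()
        for c in self.mature_arms:
            if c.end > len(self.sequence):
                raise ValueError(f"{self.id}: mature interval {c} beyond precursor end")
            if c.arm in arms:
                raise ValueError(f"{self.id}: duplicate {c.arm} interval")
            arms.add(c.arm)

    def mature_sequence(self, arm: str) -> str:
        for c in self.mature_arms:
            if c.arm == arm:
                s, e = c.slice0
                return self.sequence[s:e]
        raise KeyError(f"{self.id}: no annotated {arm} arm")


@dataclass(frozen=True)
class TagAlignment:
    """Ungapped placement of a tag on a precursor.

    ``shift5``/``shift3`` are the signed outward extensions of the tag
    relative to the nearest annotated mature interval: positive means the
    tag extends beyond the mature end, negative that it is trimmed.
    """

    tag_sequence: str
    precursor_id: str
    start: int  # 0-based offset on the precursor
    internal_mismatches: int
    shift5: int
    shift3: int
    arm_hit: str  # annotated_mature | opposite_arm | elsewhere
    arm: str  # 5p | 3p


@dataclass(frozen=True)
class MiRNAAnnotation:
    tag_sequence: str
    category: str
    name: str
    source: str  # precursor id or "scaffold:start-end(strand)"
    arm: str | None = None
    alignment: TagAlignment | None = None
    secondary_sources: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def _tag_arm(start: int, length: int, precursor_len: int) -> str:
    midpoint = start + length / 2
    return "5p" if midpoint < precursor_len / 2 else "3p"


def _score_placement(
    tag: str, precursor: PrecursorRecord, start: int, max_end_variation: int
) -> TagAlignment | None:
    """Exact evaluation of one ungapped placement (the defining rule for a
    valid hit; the seeded search only proposes candidates for this check).

    Mismatches inside the outer ``max_end_variation`` bases at each end are
    treated as end variation, not internal mismatches.
    """
    seq = precursor.sequence
    L = len(tag)
    window = seq[start : start + L]
    if len(window) < L:
        return None
    internal = sum(
        1
        for idx in range(max_end_variation, L - max_end_variation)
        if tag[idx] != window[idx]
    )
    end = start + L
    best: tuple | None = None
    for c in precursor.mature_arms:
        ms, me = c.slice0
        shift5 = ms - start
        shift3 = end - me
        dist = abs(shift5) + abs(shift3)
        if best is None or dist < best[0]:
            best = (dist, shift5, shift3, c.arm)
    if best is None:
        return TagAlignment(tag, precursor.id, start, internal, 0, 0, ELSEWHERE,
                            _tag_arm(start, L, len(seq)))
    _, shift5, shift3, near_arm = best
    arm = _tag_arm(start, L, len(seq))
    if abs(shift5) <= max_end_variation and abs(shift3) <= max_end_variation:
        hit = ANNOTATED_MATURE
        arm = near_arm
    elif arm not in {c.arm for c in precursor.mature_arms}:
        hit = OPPOSITE_ARM
        shift5 = shift3 = 0
    else:
        hit = ELSEWHERE
        shift5 = shift3 = 0
    return TagAlignment(tag, precursor.id, start, internal, shift5, shift3, hit, arm)


def align_tag_to_precursor(
    tag: str | UniqueTag,
    precursor: PrecursorRecord,
    max_internal_mismatch: int = 1,
    max_end_variation: int = 3,
) -> list[TagAlignment]:
    """All ungapped placements of a tag on a precursor with at most
    ``max_internal_mismatch`` internal mismatches, ordered by start then
    mismatch count."""
    seq = tag.sequence if isinstance(tag, UniqueTag) else to_dna(tag)
    hits = []
    for start in range(0, len(precursor.sequence) - len(seq) + 1):
        aln = _score_placement(seq, precursor, start, max_end_variation)
        if aln is not None and aln.internal_mismatches <= max_internal_mismatch:
            hits.append(aln)
    hits.sort(key=lambda a: (a.start, a.internal_mismatches))
    return hits


class _SeededText:
    """Pigeonhole-seeded substring search over concatenated sequences."""

    def __init__(self, records: Sequence[tuple[str, str]]):
        # records: (name, sequence); '#' separators prevent cross-boundary hits
        parts, offsets = [], []
        pos = 0
        for name, seq in records:
            parts.append(seq)
            offsets.append((pos, pos + len(seq), name))
            pos += len(seq) + 1
        self.text = "#".join(parts)
        self.offsets = offsets

    def _locate(self, pos: int) -> tuple[str, int] | None:
        for s, e, name in self.offsets:
            if s <= pos < e:
                return name, pos - s
        return None

    def find_all(self, pattern: str) -> list[tuple[str, int]]:
        # ACGT-only patterns cannot span the '#' separators, so any hit lies
        # wholly inside one record
        out = []
        p = self.text.find(pattern)
        while p >= 0:
            loc = self._locate(p)
            if loc is not None:
                out.append(loc)
            p = self.text.find(pattern, p + 1)
        return out


def _candidate_starts_precursors(
    tag: str, text: _SeededText, max_end_variation: int
) -> dict[str, set[int]]:
    """Candidate (precursor, start) placements via central-region seeds.

    Any valid placement has <= 1 mismatch in the central region (outside the
    end-variation zones), so one of its two central halves matches exactly.
    """
    L = len(tag)
    mev = min(max_end_variation, (L - 2) // 2)
    central = tag[mev : L - mev]
    h = len(central) // 2
    seeds = [(tag[mev : mev + h], mev), (tag[mev + h : L - mev], mev + h)]
    starts: dict[str, set[int]] = {}
    for seed, off in seeds:
        if not seed:
            continue
        for name, pos in text.find_all(seed):
            start = pos - off
            if start >= 0:
                starts.setdefault(name, set()).add(start)
    return starts


# ---------------------------------------------------------------------------
# Genome search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeHit:
    scaffold: str
    start: int  # 0-based, plus-strand coordinates
    end: int
    strand: str
    mismatches: int


class GenomeIndex:
    """Exact/one-mismatch ungapped search over genome scaffolds."""

    def __init__(self, scaffolds: Mapping[str, str] | Iterable[SequenceRecord]):
        if isinstance(scaffolds, Mapping):
            self.scaffolds = {k: to_dna(v) for k, v in scaffolds.items()}
        else:
            self.scaffolds = {r.id: to_dna(r.sequence) for r in scaffolds}

    def _find_candidates(self, seq: str, pattern: str, offset: int) -> set[int]:
        out = set()
        p = seq.find(pattern)
        while p >= 0:
            if p - offset >= 0:
                out.add(p - offset)
            p = seq.find(pattern, p + 1)
        return out

    def search(self, tag: str, max_mismatch: int = 1) -> list[GenomeHit]:
        tag = to_dna(tag)
        L = len(tag)
        h = L // 2
        hits = []
        for name, seq in self.scaffolds.items():
            for strand in "+-":
                query = tag if strand == "+" else revcomp(tag)
                starts = self._find_candidates(seq, query[:h], 0)
                starts |= self._find_candidates(seq, query[h:], h)
                for s in sorted(starts):
                    window = seq[s : s + L]
                    if len(window) < L:
                        continue
                    mm = sum(a != b for a, b in zip(query, window))
                    if mm <= max_mismatch:
                        hits.append(GenomeHit(name, s, s + L, strand, mm))
        hits.sort(key=lambda x: (x.mismatches, x.scaffold, x.start, x.strand))
        return hits

    def contains(self, sequence: str) -> bool:
        sequence = to_dna(sequence)
        rc = revcomp(sequence)
        return any(sequence in s or rc in s for s in self.scaffolds.values())


# ---------------------------------------------------------------------------
# Naming grammar
# ---------------------------------------------------------------------------

_PC_RE = re.compile(r"^PC-(5p|3p)-(\d+)_(\d+)(?:_v(\d+))?$")
_SHIFT_RE = re.compile(r"^(?P<base>.+?)(?:_L(?P<left>[+-]\d+))?(?:_R(?P<right>[+-]\d+))?(?:_v(?P<variant>\d+))?$")


def mature_name_from_precursor(precursor_id: str, arm: str) -> str:
    """miRBase-style mature name: zma-MIR395a + 5p -> zma-miR395a-5p."""
    base = precursor_id.replace("MIR", "miR", 1) if "MIR" in precursor_id else precursor_id
    return f"{base}-{arm}"


def name_mirna(
    base: str,
    shift5: int = 0,
    shift3: int = 0,
    variant: int = 0,
) -> str:
    """Assemble a name from its base and signed end shifts.

    ``_L{+-}n`` encodes the 5' (left) end shift, ``_R{+-}n`` the 3' (right)
    end shift; positive = extended outward, negative = trimmed.  ``variant``
    >= 2 appends the collision-breaking ``_v`` suffix.
    """
    name = base
    if shift5:
        name += f"_L{shift5:+d}"
    if shift3:
        name += f"_R{shift3:+d}"
    if variant >= 2:
        name += f"_v{variant}"
    return name


def parse_mirna_name(name: str) -> dict:
    """Invert :func:`name_mirna` (and the PC candidate form).

    Returns {"kind": "pc", arm, serial, count, variant} or
    {"kind": "mirna", base, left, right, variant}.  Raises ValueError on a
    malformed suffix (including explicit zero shifts, which are never
    emitted).
    """
    m = _PC_RE.match(name)
    if m:
        return {
            "kind": "pc",
            "arm": m.group(1),
            "serial": int(m.group(2)),
            "count": int(m.group(3)),
            "variant": int(m.group(4)) if m.group(4) else 1,
        }
    m = _SHIFT_RE.match(name)
    if not m or not m.group("base"):
        raise ValueError(f"malformed miRNA name {name!r}")
    left = int(m.group("left")) if m.group("left") else 0
    right = int(m.group("right")) if m.group("right") else 0
    if (m.group("left") and left == 0) or (m.group("right") and right == 0):
        raise ValueError(f"zero end-shift suffix in {name!r}")
    base = m.group("base")
    if "_L" in base or re.search(r"_R[+-]", base):
        raise ValueError(f"malformed shift suffix in {name!r}")
    return {
        "kind": "mirna",
        "base": base,
        "left": left,
        "right": right,
        "variant": int(m.group("variant")) if m.group("variant") else 1,
    }


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

class _NameRegistry:
    def __init__(self) -> None:
        self._used: dict[str, int] = {}

    def claim(self, name: str) -> str:
        k = self._used.get(name, 0) + 1
        self._used[name] = k
        if k == 1:
            return name
        return f"{name}_v{k}"


def _best_alignment(alignments: list[TagAlignment], arm_hit: str) -> TagAlignment | None:
    pool = [a for a in alignments if a.arm_hit == arm_hit]
    if not pool:
        return None
    return min(
        pool,
        key=lambda a: (
            a.internal_mismatches,
            abs(a.shift5) + abs(a.shift3),
            a.precursor_id,
            a.start,
        ),
    )


@dataclass
class _Classifier:
    """Shared indexes for classifying many tags; see :func:`classify_tags`."""

    species_precursors: dict[str, PrecursorRecord]
    xeno_precursors: dict[str, PrecursorRecord]
    genome: GenomeIndex | None
    max_internal_mismatch: int = 1
    max_end_variation: int = 3
    criteria: CriteriaConfig | None = None
    flank: int = 120
    genome_max_mismatch: int = 1

    def __post_init__(self) -> None:
        self._sp_text = _SeededText(
            [(p.id, p.sequence) for p in self.species_precursors.values()]
        )
        self._xe_text = _SeededText(
            [(p.id, p.sequence) for p in self.xeno_precursors.values()]
        )
        self._xeno_in_genome = {
            pid: (self.genome.contains(p.sequence) if self.genome else False)
            for pid, p in self.xeno_precursors.items()
        }
        self._fold_cache: dict[str, object] = {}
        self._pc_serial = 0

    def _alignments(
        self, tag: str, precursors: dict[str, PrecursorRecord], text: _SeededText
    ) -> list[TagAlignment]:
        out = []
        for pid, starts in _candidate_starts_precursors(
            tag, text, self.max_end_variation
        ).items():
            prec = precursors[pid]
            for start in sorted(starts):
                aln = _score_placement(tag, prec, start, self.max_end_variation)
                if aln is not None and aln.internal_mismatches <= self.max_internal_mismatch:
                    out.append(aln)
        return out

    def _fold_window(self, window: str):
        structure = self._fold_cache.get(window)
        if structure is None:
            structure = self._fold_cache[window] = fold(window)
        return structure

    def classify(self, tag: UniqueTag, registry: _NameRegistry) -> MiRNAAnnotation:
        seq = tag.sequence
        sp = self._alignments(seq, self.species_precursors, self._sp_text)

        best = _best_alignment(sp, ANNOTATED_MATURE)
        if best is not None:
            base = mature_name_from_precursor(best.precursor_id, best.arm)
            name = registry.claim(name_mirna(base, best.shift5, best.shift3))
            secondary = tuple(
                a.precursor_id for a in sp
                if a.arm_hit == ANNOTATED_MATURE and a is not best
            )
            return MiRNAAnnotation(seq, KNOWN_SPECIES, name, best.precursor_id,
                                   best.arm, best, secondary)

        best = _best_alignment(sp, OPPOSITE_ARM)
        if best is not None:
            suffix = "p5" if best.arm == "5p" else "p3"
            name = registry.claim(f"{best.precursor_id}-{suffix}")
            return MiRNAAnnotation(seq, NOVEL_ARM, name, best.precursor_id,
                                   best.arm, best)

        xe = [
            a
            for a in self._alignments(seq, self.xeno_precursors, self._xe_text)
            if a.arm_hit == ANNOTATED_MATURE and self._xeno_in_genome[a.precursor_id]
        ]
        best = _best_alignment(xe, ANNOTATED_MATURE)
        if best is not None:
            base = mature_name_from_precursor(best.precursor_id, best.arm)
            name = registry.claim(name_mirna(base, best.shift5, best.shift3))
            return MiRNAAnnotation(seq, KNOWN_XENO, name, best.precursor_id,
                                   best.arm, best)

        if self.genome is not None:
            for hit in self.genome.search(seq, self.genome_max_mismatch):
                scaffold = self.genome.scaffolds[hit.scaffold]
                window, m0, m1 = extract_flank(
                    scaffold, hit.start, hit.end, hit.strand, self.flank
                )
                verdict = evaluate_window(
                    self._fold_window(window), (m0, m1), self.criteria
                )
                if not verdict.passed:
                    continue
                from .hairpin import extract_stemloop

                substructure, lo = extract_stemloop(self._fold_window(window), (m0, m1))
                im, jm = substructure.pairs()[-1]
                arm = "5p" if (m0 - lo + m1 - lo) / 2 <= (im + jm) / 2 else "3p"
                self._pc_serial += 1
                name = registry.claim(f"PC-{arm}-{self._pc_serial}_{tag.total}")
                source = f"{hit.scaffold}:{hit.start + 1}-{hit.end}({hit.strand})"
                return MiRNAAnnotation(seq, CANDIDATE_PC, name, source, arm)

        return MiRNAAnnotation(seq, UNANNOTATED, registry.claim(f"tag-{seq}"), "", None)


def classify_tag(
    tag: UniqueTag | str,
    species_precursors: Sequence[PrecursorRecord],
    xeno_precursors: Sequence[PrecursorRecord] = (),
    genome: GenomeIndex | Mapping[str, str] | None = None,
    **kwargs,
) -> MiRNAAnnotation:
    """Classify a single tag (convenience wrapper over :func:`classify_tags`)."""
    if isinstance(tag, str):
        tag = UniqueTag(to_dna(tag), {"sample": 1})
    return classify_tags([tag], species_precursors, xeno_precursors, genome, **kwargs)[0]


def classify_tags(
    tags: Sequence[UniqueTag],
    species_precursors: Sequence[PrecursorRecord],
    xeno_precursors: Sequence[PrecursorRecord] = (),
    genome: GenomeIndex | Mapping[str, str] | None = None,
    max_internal_mismatch: int = 1,
    max_end_variation: int = 3,
    criteria: CriteriaConfig | None = None,
    flank: int = 120,
) -> list[MiRNAAnnotation]:
    """Annotate every retained tag with exactly one category and name.

    Tags are processed by descending total count (ties by sequence) so the
    most abundant variant claims the bare name; the returned list is in the
    same order as the input.  Results are independent of precursor input
    order: candidate hits are re-scored and ties broken by precursor id.
    """
    if genome is not None and not isinstance(genome, GenomeIndex):
        genome = GenomeIndex(genome)
    clf = _Classifier(
        {p.id: p for p in sorted(species_precursors, key=lambda p: p.id)},
        {p.id: p for p in sorted(xeno_precursors, key=lambda p: p.id)},
        genome,
        max_internal_mismatch,
        max_end_variation,
        criteria,
        flank,
    )
    registry = _NameRegistry()
    retained = [t for t in tags if t.disposition == RETAINED]
    order = sorted(range(len(retained)), key=lambda i: (-retained[i].total, retained[i].sequence))
    results: dict[int, MiRNAAnnotation] = {}
    for i in order:
        results[i] = clf.classify(retained[i], registry)
    annotations = [results[i] for i in range(len(retained))]
    assert len(annotations) == len(retained), "annotation must partition retained tags"
    return annotations


def annotation_count_matrix(
    annotations: Sequence[MiRNAAnnotation],
    tags: Sequence[UniqueTag],
    samples: Sequence[str] | None = None,
    collapse_variants: bool = True,
    include_categories: tuple[str, ...] = (KNOWN_SPECIES, NOVEL_ARM, KNOWN_XENO, CANDIDATE_PC),
) -> pd.DataFrame:
    """Per-miRNA raw count matrix (rows = annotation names, cols = samples).

    With ``collapse_variants`` the ``_v`` collision suffixes are stripped so
    sequencing-error copies of a tag pool with their canonical entry.
    """
    by_seq = {t.sequence: t for t in tags}
    if samples is None:
        seen: list[str] = []
        for t in tags:
            for s in t.counts:
                if s not in seen:
                    seen.append(s)
        samples = sorted(seen)
    rows: dict[str, dict[str, int]] = {}
    for ann in annotations:
        if ann.category not in include_categories:
            continue
        name = ann.name
        if collapse_variants:
            name = re.sub(r"_v\d+$", "", name)
        tag = by_seq[ann.tag_sequence]
        row = rows.setdefault(name, {s: 0 for s in samples})
        for s, c in tag.counts.items():
            row[s] = row.get(s, 0) + c
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(samples)).fillna(0).astype(int)
    return df.sort_index()
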