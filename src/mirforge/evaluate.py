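"""Scoring pipeline output against a simulation's truth manifest.

Used by the test-suite and the reproduction script to turn a simulated run
into summary metrics: classification accuracy per entity, recall of
known-mature reads, and differential-expression recall/direction accuracy
on the spiked miRNAs.
"""

from __future__ import annotations

import re
from typing import Iterable, Mapping, Sequence

from .annotate import CANDIDATE_PC, KNOWN_SPECIES, KNOWN_XENO, NOVEL_ARM, MiRNAAnnotation
from .diffexpr import DEResult

__all__ = [
    "EXPECTED_CATEGORY",
    "annotation_by_sequence",
    "classification_accuracy",
    "known_mature_recall",
    "entity_row_names",
    "de_recall",
]

EXPECTED_CATEGORY = {
    "known": KNOWN_SPECIES,
    "star": NOVEL_ARM,
    "xeno": KNOWN_XENO,
    "novel": CANDIDATE_PC,
}


def _strip_variant(name: str) -> str:
    return re.sub(r"_v\d+$", "", name)


def annotation_by_sequence(
    annotations: Iterable[MiRNAAnnotation],
) -> dict[str, MiRNAAnnotation]:
    return {a.tag_sequence: a for a in annotations}


def classification_accuracy(
    manifest: Mapping, annotations: Iterable[MiRNAAnnotation]
) -> tuple[float, list[dict]]:
    """Fraction of simulated entities whose canonical mature tag was
    classified into the expected category (entities whose tag never survived
    to annotation count as misses)."""
    by_seq = annotation_by_sequence(annotations)
    details = []
    hits = 0
    entities = manifest["entities"]
    for e in entities:
        ann = by_seq.get(e["mature"])
        expected = EXPECTED_CATEGORY[e["kind"]]
        got = ann.category if ann is not None else "absent"
        ok = got == expected
        hits += ok
        details.append({"name": e["name"], "expected": expected, "got": got, "ok": ok})
    return hits / len(entities), details


def known_mature_recall(
    manifest: Mapping, annotations: Iterable[MiRNAAnnotation]
) -> float:
    """Recall of error-free reads from annotated mature arms.

    Every canonical or end-shifted variant of a known mature that appears
    among the annotated tags must be classified known_species; variants that
    were never sequenced are skipped.
    """
    by_seq = annotation_by_sequence(annotations)
    total = correct = 0
    for e in manifest["entities"]:
        if e["kind"] != "known":
            continue
        for seq in set(e["variants"].values()):
            ann = by_seq.get(seq)
            if ann is None:
                continue  # variant never sequenced in this run
            total += 1
            correct += ann.category == KNOWN_SPECIES
    return correct / total if total else 0.0


def entity_row_names(
    manifest: Mapping, annotations: Iterable[MiRNAAnnotation]
) -> dict[str, str]:
    """Map each simulated entity name to its canonical count-matrix row.

    Known/star/xeno entities carry their expected annotation name directly;
    novel loci are resolved through the annotation of their mature tag
    (their PC- serial is assigned at run time)."""
    by_seq = annotation_by_sequence(annotations)
    out = {}
    for e in manifest["entities"]:
        ann = by_seq.get(e["mature"])
        if ann is not None:
            out[e["name"]] = _strip_variant(ann.name)
    return out


def de_recall(
    manifest: Mapping,
    de_results: Sequence[DEResult],
    row_names: Mapping[str, str],
    contrast: str,
    kinds: tuple[str, ...] = ("known", "xeno", "novel"),
) -> dict:
    """Recall and direction accuracy for truth-DE entities in one contrast.

    Returns {"n_true", "called", "recall", "direction_accuracy"}; entities
    whose canonical row is missing from the results count as misses.
    """
    by_name = {r.mirna: r for r in de_results if r.contrast == contrast}
    n_true = called = correct_dir = 0
    for e in manifest["entities"]:
        if e["kind"] not in kinds:
            continue
        truth = e["contrasts"].get(contrast)
        if truth is None or not truth["de"]:
            continue
        n_true += 1
        row = row_names.get(e["name"])
        r = by_name.get(row) if row else None
        if r is not None and r.significant:
            called += 1
            correct_dir += r.direction == truth["direction"]
    return {
        "n_true": n_true,
        "called": called,
        "recall": called / n_true if n_true else float("nan"),
        "direction_accuracy": correct_dir / called if called else float("nan"),
    }
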