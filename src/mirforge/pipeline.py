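"""End-to-end orchestration: simulate -> preprocess -> annotate -> fold ->
differential expression (-> qPCR), with a machine-readable run report.

The report carries per-stage totals (read dispositions, annotation category
counts, DE up/down totals per contrast at both significance thresholds), the
package version, a config hash and the seed; identical config + seed gives
an identical report.  Conservation is asserted at every stage boundary.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .annotate import (
    CANDIDATE_PC, KNOWN_SPECIES, KNOWN_XENO, NOVEL_ARM, UNANNOTATED,
    GenomeIndex, PrecursorRecord, annotation_count_matrix, classify_tags,
)
from .diffexpr import CountMatrix, call_de, de_table, ddct, pearson_matrix
from .formats_io import (
    FormatError, read_fasta, read_mature_coords, write_count_matrix, write_gff3,
)
from .preprocess import RETAINED, PreprocessConfig, preprocess_samples
from .synthetic_data import SimulationConfig, simulate_library

__all__ = ["PipelineConfig", "StageError", "run_pipeline"]

DEFAULT_CONTRASTS = (("NaCl", "H2O"), ("Na2CO3", "H2O"), ("Na2CO3", "NaCl"))


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """One reproducible run.  Either ``simulate`` is set (inputs generated
    under ``out_dir/sim``) or explicit input paths are given."""

    out_dir: str | Path = "run"
    simulate: SimulationConfig | None = None
    fastq: Mapping[str, str | Path] | None = None
    sample_groups: Mapping[str, str] | None = None
    precursor_fasta: str | Path | None = None
    mature_coords: str | Path | None = None
    xeno_fasta: str | Path | None = None
    xeno_coords: str | Path | None = None
    genome_fasta: str | Path | None = None
    contaminants: Mapping[str, str | Path] | None = None
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    contrasts: Sequence[tuple[str, str]] = DEFAULT_CONTRASTS
    p_threshold: float = 0.05
    fc_threshold: float = 2.0
    ct_table: str | Path | None = None
    ct_reference: str = "U6"
    ct_calibrator: str = "H2O"


def _load_precursors(fasta, coords_path, species_default: str) -> list[PrecursorRecord]:
    coords = read_mature_coords(coords_path) if coords_path else []
    by_prec: dict[str, list] = {}
    for c in coords:
        by_prec.setdefault(c.precursor_id, []).append(c)
    out = []
    for rec in read_fasta(fasta):
        species = rec.id.split("-")[0] if "-" in rec.id else species_default
        out.append(
            PrecursorRecord(rec.id, species, rec.sequence, tuple(by_prec.get(rec.id, ())))
        )
    return out


def _config_hash(config: PipelineConfig) -> str:
    def default(o):
        if isinstance(o, Path):
            return str(o)
        if hasattr(o, "__dict__"):
            return o.__dict__
        return str(o)

    d = asdict(config)
    d.pop("out_dir", None)  # where outputs land does not define the run
    blob = json.dumps(d, sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, log=None) -> dict:
    """Execute all stages in order and return the run report (also written
    to ``out_dir/report.json``).  A failure aborts with a stage-named error;
    missing inputs are rejected before any stage runs."""
    log = log or (lambda msg: print(msg, file=sys.stderr))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    # --- validate / simulate -------------------------------------------------
    if config.simulate is not None:
        log("stage simulate: generating synthetic study")
        sim = simulate_library(config.simulate, out_dir / "sim")
        fastq = sim.fastq
        sample_groups = sim.sample_groups
        precursors = sim.precursors
        xeno = sim.xeno_precursors
        genome = GenomeIndex(sim.genome)
        pp_config = PreprocessConfig(
            adapter=config.simulate.adapter,
            contaminant_sets={k: v for k, v in sim.contaminants.items()},
        )
        seed = config.simulate.seed
    else:
        for name in ("fastq", "sample_groups", "precursor_fasta", "mature_coords"):
            if getattr(config, name) is None:
                raise StageError("config", f"{name} is required without --simulate")
        paths = list(config.fastq.values()) + [config.precursor_fasta, config.mature_coords]
        for p in (config.xeno_fasta, config.genome_fasta, *(config.contaminants or {}).values()):
            if p is not None:
                paths.append(p)
        missing = [str(p) for p in paths if not Path(p).exists()]
        if missing:
            raise StageError("config", f"missing input file(s): {missing}")
        fastq = dict(config.fastq)
        sample_groups = dict(config.sample_groups)
        precursors = _load_precursors(config.precursor_fasta, config.mature_coords, "zma")
        xeno = (
            _load_precursors(config.xeno_fasta, config.xeno_coords, "xeno")
            if config.xeno_fasta
            else []
        )
        genome = (
            GenomeIndex(read_fasta(config.genome_fasta)) if config.genome_fasta else None
        )
        pp_config = config.preprocess
        if config.contaminants:
            pp_config = PreprocessConfig(
                adapter=pp_config.adapter,
                min_len=pp_config.min_len,
                max_len=pp_config.max_len,
                max_adapter_mismatch=pp_config.max_adapter_mismatch,
                min_overlap=pp_config.min_overlap,
                low_complexity_threshold=pp_config.low_complexity_threshold,
                di_repeat_threshold=pp_config.di_repeat_threshold,
                contaminant_sets=dict(config.contaminants),
            )
        seed = None

    # --- preprocess -----------------------------------------------------------
    log(f"stage preprocess: {len(fastq)} libraries")
    try:
        tags, ledger = preprocess_samples(fastq, pp_config)
    except FormatError as exc:
        raise StageError("preprocess", str(exc)) from exc
    (out_dir / "ledger.json").write_text(json.dumps(ledger, indent=1, sort_keys=True))
    retained = [t for t in tags if t.disposition == RETAINED]
    log(f"stage preprocess: {len(tags)} unique tags, {len(retained)} retained "
        f"({time.time() - t0:.1f}s)")

    # --- annotate -------------------------------------------------------------
    annotations = classify_tags(retained, precursors, xeno, genome)
    category_counts: dict[str, int] = {}
    for a in annotations:
        category_counts[a.category] = category_counts.get(a.category, 0) + 1
    if sum(category_counts.values()) != len(retained):
        raise StageError("annotate", "annotation does not partition retained tags")
    counts = annotation_count_matrix(annotations, retained, samples=sorted(fastq))
    write_count_matrix(counts, out_dir / "counts.tsv")
    _write_annotation_gff3(annotations, out_dir / "annotations.gff3")
    log(f"stage annotate: categories {category_counts} ({time.time() - t0:.1f}s)")

    # --- differential expression ---------------------------------------------
    matrix = CountMatrix(counts, sample_groups)
    norm = matrix.cpm()
    write_count_matrix(norm.round(6), out_dir / "counts_cpm.tsv")
    pearson = pearson_matrix(norm)
    pearson.to_csv(out_dir / "sample_correlation.tsv", sep="\t", float_format="%.6f")
    de_summary = {}
    all_de = []
    for treat, control in config.contrasts:
        if treat not in set(sample_groups.values()) or control not in set(sample_groups.values()):
            raise StageError("de", f"unknown group in contrast {treat} vs {control}")
        results = call_de(matrix, (treat, control), config.p_threshold, config.fc_threshold)
        all_de.append(de_table(results))
        name = f"{treat} vs {control}"
        de_summary[name] = {
            "tested": len(results),
            "significant": sum(r.significant for r in results),
            "up": sum(r.significant and r.direction == "up" for r in results),
            "down": sum(r.significant and r.direction == "down" for r in results),
            "significant_01": sum(r.significant_01 for r in results),
            "up_01": sum(r.significant_01 and r.direction == "up" for r in results),
            "down_01": sum(r.significant_01 and r.direction == "down" for r in results),
        }
    pd.concat(all_de, ignore_index=True).to_csv(out_dir / "de.tsv", sep="\t", index=False)
    log(f"stage de: {de_summary} ({time.time() - t0:.1f}s)")

    # --- qPCR (optional) ------------------------------------------------------
    qpcr = None
    if config.ct_table is not None:
        ct = pd.read_csv(config.ct_table, sep="\t")
        folds = ddct(ct, config.ct_reference, config.ct_calibrator)
        folds.to_csv(out_dir / "qpcr_folds.tsv", sep="\t", float_format="%.6f")
        qpcr = {"targets": folds.shape[0], "groups": list(folds.columns)}

    report = {
        "version": __version__,
        "seed": seed,
        "config_hash": _config_hash(config),
        "samples": {s: sample_groups[s] for s in sorted(fastq)},
        "preprocess": ledger,
        "annotation_categories": category_counts,
        "n_mirnas": int(counts.shape[0]),
        "de": de_summary,
        "qpcr": qpcr,
    }
    (out_dir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report


def _write_annotation_gff3(annotations, path) -> None:
    rows = []
    for a in annotations:
        if a.category == UNANNOTATED:
            continue
        if a.category == CANDIDATE_PC:
            # source like "scaffold_1:2001-2021(+)"
            loc, strand = a.source[:-3], a.source[-2]
            seqid, span = loc.split(":")
            start, end = (int(x) for x in span.split("-"))
        elif a.alignment is not None:
            seqid = a.source
            start = a.alignment.start + 1
            end = a.alignment.start + len(a.tag_sequence)
            strand = "+"
        else:
            continue
        rows.append(
            {
                "seqid": seqid,
                "type": "miRNA",
                "start": start,
                "end": end,
                "strand": strand,
                "attributes": {"ID": a.name, "category": a.category},
            }
        )
    write_gff3(rows, path)
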