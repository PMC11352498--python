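"""Seed-reproducible synthetic small-RNA study with ground truth.

Emulates the design of a three-condition (H2O, NaCl, Na2CO3), three-replicate
plant small-RNA-seq experiment at desk scale: a random genome with implanted
stem-loop loci, a species precursor set with annotated mature arms, a foreign
("xeno") precursor set whose hairpins also occur in the genome, contaminant
references (rRNA/tRNA), and one FASTQ per library.  Reads are mature
sequences with configurable 5'/3' end-shift variants, substitution errors,
an appended 3' adapter and random padding to the read length; a truth
manifest records every entity's expected abundance and differential-
expression status, and every read id encodes its origin.

Abundances are lognormal around condition means (the replicate CV is the
tunable noise knob, transparent by construction); no attempt is made to
model ligation/GC bias or quality-score error profiles.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .formats_io import (
    MatureCoordinateSidecar,
    SequenceRecord,
    revcomp,
    write_fasta,
    write_mature_coords,
)
from .annotate import PrecursorRecord, mature_name_from_precursor
from .hairpin import PAIR_ENERGIES, HairpinStructure, pair_energy

__all__ = [
    "SimulationConfig",
    "SimulationOutput",
    "make_precursor",
    "simulate_library",
    "simulate_count_matrix",
    "build_hairpin",
    "criterion_fixture",
    "baseline_fixture",
    "CRITERION_NAMES",
]

_BASES = "ACGT"
CONDITIONS = ("H2O", "NaCl", "Na2CO3")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Study-design parameters for one synthetic experiment.

    Defaults describe the reference desk-scale study: 12 known precursors,
    6 novel genomic loci, 2 xeno miRNAs, 20 true-DE miRNAs at fold 4 (ten
    responding to NaCl, ten to Na2CO3), 200k reads per library, 0.1% per-base
    substitution error, 20% contaminant reads, replicate CV 10%, and an
    80/5/5/5/5 canonical/L+1/L-1/R+1/R-1 end-shift mix.
    """

    seed: int = 1
    n_known_precursors: int = 12
    n_novel_loci: int = 6
    n_xeno: int = 2
    n_de_per_condition: Mapping[str, int] = field(
        default_factory=lambda: {"NaCl": 10, "Na2CO3": 10}
    )
    de_fold: float = 4.0
    de_frac_up: Mapping[str, float] = field(
        default_factory=lambda: {"NaCl": 0.5, "Na2CO3": 0.5}
    )
    reads_per_library: int = 200_000
    read_length: int = 50
    error_rate: float = 0.001
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    end_shift_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "canonical": 0.8, "L+1": 0.05, "L-1": 0.05, "R+1": 0.05, "R-1": 0.05,
        }
    )
    contaminant_fraction: float = 0.2
    replicate_cv: float = 0.1
    star_fraction: float = 0.05
    mature_len_range: tuple[int, int] = (20, 22)
    loop_len: int = 8
    pad_len: int = 4
    n_scaffolds: int = 3
    scaffold_len: int = 20_000
    replicates: int = 3
    conditions: tuple[str, ...] = CONDITIONS

    def __post_init__(self) -> None:
        for frac in (self.contaminant_fraction, self.star_fraction, self.error_rate):
            if not 0 <= frac <= 1:
                raise ValueError(f"fraction {frac} outside [0, 1]")
        if self.de_fold <= 0:
            raise ValueError("de_fold must be positive")
        if self.reads_per_library <= 0:
            raise ValueError("reads_per_library must be positive")
        if abs(sum(self.end_shift_probs.values()) - 1.0) > 1e-9:
            raise ValueError("end_shift_probs must sum to 1")
        n_entities = self.n_known_precursors + self.n_novel_loci + self.n_xeno
        if sum(self.n_de_per_condition.values()) > n_entities:
            raise ValueError(
                f"{sum(self.n_de_per_condition.values())} DE miRNAs requested "
                f"but only {n_entities} miRNA entities are simulated"
            )
        unknown = set(self.n_de_per_condition) - set(self.conditions)
        if unknown:
            raise ValueError(f"DE conditions not in design: {sorted(unknown)}")


# ---------------------------------------------------------------------------
# Direct hairpin construction (sequence + structure, no folding involved)
# ---------------------------------------------------------------------------

def build_hairpin(
    n_stem_pairs: int,
    loop_len: int,
    bulges: Sequence[tuple[int, int, int]] = (),
    energy: float | None = None,
) -> tuple[HairpinStructure, list[int], list[int]]:
    """Construct a stem-loop with prescribed geometry, outside-in.

    ``bulges`` lists (pair_index, nt5, nt3): before stem pair ``pair_index``
    (0 = outermost), insert ``nt5`` unpaired bases on the 5' arm and ``nt3``
    on the 3' arm.  Paired bases are G:C (-3 kcal/mol each); fillers are A.
    ``energy`` overrides the pair-sum pseudo-energy when given.

    Returns (structure, pos5, pos3) where pos5[i]/pos3[i] are the sequence
    positions of stem pair i's 5'/3' bases, for placing mature intervals.
    """
    bulge_at = {i: (n5, n3) for i, n5, n3 in bulges}
    left: list[str] = []
    right: list[str] = []
    ldb: list[str] = []
    rdb: list[str] = []
    pos5_rel: list[int] = []
    pos3_rel: list[int] = []
    for i in range(n_stem_pairs):
        if i in bulge_at:
            n5, n3 = bulge_at[i]
            left.extend("A" * n5)
            ldb.extend("." * n5)
            right.extend("A" * n3)
            rdb.extend("." * n3)
        pos5_rel.append(len(left))
        left.append("G")
        ldb.append("(")
        pos3_rel.append(len(right))
        right.append("C")
        rdb.append(")")
    loop = "A" * loop_len
    seq = "".join(left) + loop + "".join(reversed(right))
    db = "".join(ldb) + "." * loop_len + "".join(reversed(rdb))
    n = len(seq)
    pos5 = pos5_rel
    pos3 = [n - 1 - p for p in pos3_rel]
    if energy is None:
        energy = -3.0 * n_stem_pairs
    return HairpinStructure(seq, db, float(energy)), pos5, pos3


CRITERION_NAMES = (
    "max_stem_bulge_nt",
    "stem_base_pairs",
    "free_energy",
    "hairpin_length",
    "loop_length",
    "max_mature_bulge_nt",
    "max_mature_bulge_bias",
    "mature_biased_bulges",
    "mature_errors",
    "mature_base_pairs",
    "mature_in_stem_pct",
)


def baseline_fixture() -> tuple[HairpinStructure, tuple[int, int]]:
    """A comfortable all-pass hairpin: 30-bp stem, 8-nt loop, 21-nt mature
    wholly paired on the 5' arm."""
    structure, pos5, _ = build_hairpin(30, 8)
    return structure, (pos5[4], pos5[24] + 1)


def criterion_fixture(criterion: int) -> tuple[HairpinStructure, tuple[int, int]]:
    """A constructed hairpin violating exactly one criterion (1-based index
    into :data:`CRITERION_NAMES`); every other criterion passes at default
    thresholds."""
    if criterion == 1:  # 13-nt stem bulge outside the mature span
        s, pos5, _ = build_hairpin(30, 8, bulges=[(27, 13, 0)])
        return s, (pos5[4], pos5[24] + 1)
    if criterion == 2:  # 15 stem pairs; symmetric bulges keep length >= 50
        s, pos5, pos3 = build_hairpin(15, 3, bulges=[(3, 6, 6), (6, 6, 6)])
        return s, (pos5[6], pos3[6] + 1)  # spans the loop: 18 of 21 paired
    if criterion == 3:  # structurally sound but weak pseudo-energy
        s, pos5, _ = build_hairpin(30, 8, energy=-14.9)
        return s, (pos5[4], pos5[24] + 1)
    if criterion == 4:  # 21 + 7 + 21 = 49 < 50
        s, pos5, _ = build_hairpin(21, 7)
        return s, (pos5[0], pos5[20] + 1)
    if criterion == 5:  # 201-nt terminal loop
        s, pos5, _ = build_hairpin(30, 201)
        return s, (pos5[4], pos5[24] + 1)
    if criterion == 6:  # 5-nt near-symmetric bulge inside the mature span
        s, pos5, _ = build_hairpin(30, 8, bulges=[(14, 3, 2)])
        return s, (pos5[4], pos5[24] + 1)
    if criterion == 7:  # 3-nt fully asymmetric mature bulge
        s, pos5, _ = build_hairpin(30, 8, bulges=[(14, 3, 0)])
        return s, (pos5[4], pos5[24] + 1)
    if criterion == 8:  # three 1-nt asymmetric bulges in the mature span
        s, pos5, _ = build_hairpin(30, 8, bulges=[(10, 1, 0), (14, 1, 0), (18, 1, 0)])
        return s, (pos5[4], pos5[24] + 1)
    if criterion == 9:  # 25-nt mature with 5 bases in the terminal loop
        s, pos5, _ = build_hairpin(30, 8)
        return s, (pos5[10], pos5[29] + 1 + 5)
    if criterion == 10:  # 13-nt mature with only 11 paired bases
        s, pos5, _ = build_hairpin(30, 8)
        return s, (pos5[19], pos5[29] + 1 + 2)
    if criterion == 11:  # 15 of 19 mature bases paired: 78.9% < 80%
        s, pos5, _ = build_hairpin(30, 8)
        return s, (pos5[15], pos5[29] + 1 + 4)
    raise ValueError(f"criterion must be 1..11, got {criterion}")


# ---------------------------------------------------------------------------
# Precursor construction
# ---------------------------------------------------------------------------

def _random_mature(rng: np.random.Generator, length: int, loop_side: str) -> str:
    """Random mature sequence whose loop-adjacent base is G/C so the A-only
    terminal loop cannot trade pairs with the stem."""
    seq = [_BASES[i] for i in rng.integers(0, 4, size=length)]
    anchor = 0 if loop_side == "first" else length - 1
    if seq[anchor] not in "GC":
        seq[anchor] = "G" if rng.integers(0, 2) else "C"
    return "".join(seq)


def make_precursor(
    mature: str,
    loop_len: int = 8,
    stem_mismatches: int = 0,
    bulge: tuple[int, int] | None = None,
    seed: int = 0,
    arm: str = "5p",
    pad_len: int = 4,
    id: str = "syn-MIR001",
    species: str = "syn",
) -> PrecursorRecord:
    """Build a precursor as mature + loop + reverse complement (plus pads).

    The loop is non-pairing (all A) and the arms fully complementary, so with
    zero defects and a short loop the default fold recovers the intended stem
    and passes all eleven criteria.  ``stem_mismatches`` substitutes bases on
    the non-mature arm; ``bulge`` = (offset, n) inserts ``n`` unpaired bases
    into the non-mature arm ``offset`` pairs from the loop.
    """
    rng = np.random.default_rng(seed)
    mature = mature.upper().replace("U", "T")
    star = list(revcomp(mature))
    if stem_mismatches:
        positions = rng.choice(len(star), size=min(stem_mismatches, len(star)), replace=False)
        for p in positions:
            partner = mature[len(mature) - 1 - p]
            choices = [b for b in _BASES if pair_energy(b, partner) == float("inf")]
            star[p] = choices[rng.integers(0, len(choices))]
    star_s = "".join(star)
    if bulge is not None:
        offset, n = bulge
        insert = "".join(_BASES[i] for i in rng.integers(0, 4, size=n))
        star_s = star_s[:offset] + insert + star_s[offset:]
    loop = "A" * loop_len
    pad5 = "".join(_BASES[i] for i in rng.integers(0, 4, size=pad_len))
    pad3 = "".join(_BASES[i] for i in rng.integers(0, 4, size=pad_len))
    if arm == "5p":
        core = mature + loop + star_s
        m_start = pad_len
    elif arm == "3p":
        core = star_s + loop + mature
        m_start = pad_len + len(star_s) + loop_len
    else:
        raise ValueError(f"arm must be 5p or 3p, got {arm!r}")
    seq = pad5 + core + pad3
    coord = MatureCoordinateSidecar(id, arm, m_start + 1, m_start + len(mature))
    return PrecursorRecord(id, species, seq, (coord,))


# ---------------------------------------------------------------------------
# The full study simulation
# ---------------------------------------------------------------------------

@dataclass
class _Entity:
    """One mature-miRNA-producing unit with its truth bookkeeping."""

    name: str  # expected annotation name (novel loci: canonical unknown -> locus tag)
    kind: str  # known | star | xeno | novel
    mature: str
    source: str  # precursor id or "scaffold:start(strand)"
    base_weight: float
    multipliers: dict  # condition -> expected fold vs H2O
    # sequence context for end-shift variants: (context, start, end)
    context: str = ""
    c_start: int = 0
    c_end: int = 0
    variants: dict = field(default_factory=dict)  # shift label -> insert seq


@dataclass
class SimulationOutput:
    out_dir: Path
    fastq: dict  # sample -> path
    genome_fasta: Path
    precursor_fasta: Path
    mature_coords: Path
    xeno_fasta: Path
    xeno_coords: Path
    contaminants: dict  # family -> path
    manifest_path: Path
    manifest: dict
    precursors: list
    xeno_precursors: list
    genome: dict
    sample_groups: dict  # sample -> condition


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def _lognormal_around(rng: np.random.Generator, mean: float, cv: float) -> float:
    if mean <= 0:
        return 0.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return mean * rng.lognormal(-0.5 * sigma * sigma, sigma)


def _shift_window(label: str, start: int, end: int) -> tuple[int, int]:
    if label == "canonical":
        return start, end
    kind, delta = label[0], int(label[1:])
    if kind == "L":
        return start - delta, end
    return start, end + delta


def simulate_library(
    config: SimulationConfig | None = None, out_dir: str | Path = "simdir"
) -> SimulationOutput:
    """Generate the complete synthetic study under ``out_dir``.

    Writes the genome, precursor/xeno FASTA + mature-coordinate sidecars,
    contaminant FASTA, one FASTQ per (condition, replicate), and truth.json.
    Byte-identical for identical (config, seed).
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    out_dir = Path(out_dir)
    (out_dir / "reads").mkdir(parents=True, exist_ok=True)

    # -- genome scaffolds ---------------------------------------------------
    genome = {
        f"scaffold_{i + 1}": _random_seq(rng, config.scaffold_len)
        for i in range(config.n_scaffolds)
    }

    # -- known species precursors ------------------------------------------
    lo, hi = config.mature_len_range
    precursors: list[PrecursorRecord] = []
    entities: list[_Entity] = []
    for i in range(config.n_known_precursors):
        arm = "5p" if i % 2 == 0 else "3p"
        mlen = int(rng.integers(lo, hi + 1))
        mature = _random_mature(rng, mlen, "last" if arm == "5p" else "first")
        pid = f"zma-MIR{i + 1:03d}"
        prec = make_precursor(
            mature, config.loop_len, seed=int(rng.integers(0, 2**31)),
            arm=arm, pad_len=config.pad_len, id=pid, species="zma",
        )
        precursors.append(prec)
        coord = prec.mature_arms[0]
        s0, e0 = coord.slice0
        entities.append(_Entity(
            name=mature_name_from_precursor(pid, arm), kind="known",
            mature=mature, source=pid, base_weight=0.0, multipliers={},
            context=prec.sequence, c_start=s0, c_end=e0,
        ))
        # the opposite-arm (star) product at a fixed fraction of the mature
        L = len(prec.sequence)
        star_arm = "3p" if arm == "5p" else "5p"
        ss, se = L - e0, L - s0
        entities.append(_Entity(
            name=f"{pid}-p{star_arm[0]}",  # e.g. zma-MIR001-p3
            kind="star", mature=prec.sequence[ss:se], source=pid,
            base_weight=0.0, multipliers={},
            context=prec.sequence, c_start=ss, c_end=se,
        ))

    # -- xeno precursors (implanted into the genome) ------------------------
    xeno_precursors: list[PrecursorRecord] = []
    implants: list[tuple[str, str]] = []  # (sequence, tag) to place in genome
    for i in range(config.n_xeno):
        arm = "5p" if i % 2 == 0 else "3p"
        mlen = int(rng.integers(lo, hi + 1))
        mature = _random_mature(rng, mlen, "last" if arm == "5p" else "first")
        pid = f"osa-MIR9{i + 1:02d}"
        prec = make_precursor(
            mature, config.loop_len, seed=int(rng.integers(0, 2**31)),
            arm=arm, pad_len=config.pad_len, id=pid, species="osa",
        )
        xeno_precursors.append(prec)
        implants.append((prec.sequence, f"xeno:{pid}"))
        coord = prec.mature_arms[0]
        s0, e0 = coord.slice0
        entities.append(_Entity(
            name=mature_name_from_precursor(pid, arm), kind="xeno",
            mature=mature, source=pid, base_weight=0.0, multipliers={},
            context=prec.sequence, c_start=s0, c_end=e0,
        ))

    # -- novel loci (hairpins only present in the genome) --------------------
    # stem extensions beyond the mature give the hairpin margin over the
    # 50-nt length criterion even when the window fold nibbles an outer pair
    novel_cores: list[tuple[str, str, int]] = []  # (core seq, mature, mature offset)
    ext_len = 8
    for i in range(config.n_novel_loci):
        mlen = int(rng.integers(lo, hi + 1))
        mature = _random_mature(rng, mlen, "last")
        ext = _random_seq(rng, ext_len)
        core = ext + mature + "A" * config.loop_len + revcomp(ext + mature)
        novel_cores.append((core, mature, ext_len))
        implants.append((core, f"novel:{i + 1}"))

    # implant sequences at well-separated genome positions (one per slot)
    implant_info: dict[str, tuple[str, int, str]] = {}
    n_impl = len(implants)
    scaffold_names = sorted(genome)
    slot = 0
    for seq_to_place, tag in implants:
        scf = scaffold_names[slot % len(scaffold_names)]
        offset = 2000 + (slot // len(scaffold_names)) * 3000
        strand = "-" if tag.startswith("novel:") and slot % 5 == 3 else "+"
        placed = seq_to_place if strand == "+" else revcomp(seq_to_place)
        g = genome[scf]
        genome[scf] = g[:offset] + placed + g[offset + len(placed):]
        implant_info[tag] = (scf, offset, strand)
        slot += 1

    for i, (core, mature, m_off) in enumerate(novel_cores):
        tag = f"novel:{i + 1}"
        scf, offset, strand = implant_info[tag]
        if strand == "+":
            context = genome[scf]
            c_start = offset + m_off  # mature sits on the 5' arm of the core
        else:
            # reads come off the minus strand; in minus-strand coordinates
            # the implanted segment starts at len(g) - (offset + len(core))
            context = revcomp(genome[scf])
            c_start = len(genome[scf]) - (offset + len(core)) + m_off
        entities.append(_Entity(
            name=tag, kind="novel", mature=mature,
            source=f"{scf}:{offset + 1}({strand})",
            base_weight=0.0, multipliers={},
            context=context, c_start=c_start, c_end=c_start + len(mature),
        ))

    # -- abundance weights and DE assignment --------------------------------
    primary = [e for e in entities if e.kind != "star"]
    weights = rng.lognormal(0.0, 1.0, size=len(primary))
    weights /= weights.sum()
    for e, w in zip(primary, weights):
        e.base_weight = float(w)
        e.multipliers = {c: 1.0 for c in config.conditions}
    pool = list(range(len(primary)))
    rng.shuffle(pool)
    cursor = 0
    for cond in sorted(config.n_de_per_condition):
        n_de = config.n_de_per_condition[cond]
        frac_up = config.de_frac_up.get(cond, 0.5)
        chosen = pool[cursor : cursor + n_de]
        cursor += n_de
        # assign directions greedily down the abundance ranking so the
        # expected library mass stays balanced between conditions —
        # otherwise CPM normalisation compresses the spiked folds
        ranked = sorted(chosen, key=lambda idx: -primary[idx].base_weight)
        n_up = round(frac_up * n_de)
        n_down = n_de - n_up
        f = config.de_fold
        drift = 0.0  # running expected change in library mass
        for idx in ranked:
            w = primary[idx].base_weight
            d_up = w * (f - 1.0)
            d_down = w * (1.0 / f - 1.0)
            if n_up and (not n_down or abs(drift + d_up) <= abs(drift + d_down)):
                up, n_up = True, n_up - 1
                drift += d_up
            else:
                up, n_down = False, n_down - 1
                drift += d_down
            primary[idx].multipliers[cond] = f if up else 1.0 / f
    by_source = {e.source: e for e in primary}
    for e in entities:
        if e.kind == "star":
            parent = by_source[e.source]
            e.base_weight = parent.base_weight * config.star_fraction
            e.multipliers = dict(parent.multipliers)
    total_w = sum(e.base_weight for e in entities)
    mirna_depth = config.reads_per_library * (1.0 - config.contaminant_fraction)

    # -- contaminant references ---------------------------------------------
    contaminant_refs = {
        "rRNA": [("rRNA_1", _random_seq(rng, 800)), ("rRNA_2", _random_seq(rng, 600))],
        "tRNA": [("tRNA_1", _random_seq(rng, 150)), ("tRNA_2", _random_seq(rng, 150))],
    }
    cont_split = {"rRNA": 0.6, "tRNA": 0.4}

    # -- per-library read generation ----------------------------------------
    shift_labels = sorted(config.end_shift_probs)
    shift_p = np.array([config.end_shift_probs[s] for s in shift_labels])
    for e in entities:
        for label in shift_labels:
            s, t = _shift_window(label, e.c_start, e.c_end)
            if s < 0 or t > len(e.context):
                s, t = e.c_start, e.c_end  # clipped at the context edge
            e.variants[label] = e.context[s:t]
    samples: dict[str, Path] = {}
    sample_groups: dict[str, str] = {}
    realized: dict[str, dict[str, int]] = {e.name: {} for e in entities}
    adapter = config.adapter

    def _emit_read(fh, rid: str, insert: str, pad_tail: str) -> None:
        read = (insert + adapter + pad_tail)[: config.read_length]
        fh.write(f"@{rid}\n{read}\n+\n{'I' * len(read)}\n")

    for cond in config.conditions:
        for rep in range(1, config.replicates + 1):
            sample = f"{cond}_{rep}"
            path = out_dir / "reads" / f"{sample}.fastq"
            samples[sample] = path
            sample_groups[sample] = cond
            serial = 0
            with open(path, "w") as fh:
                for e in entities:
                    mean = mirna_depth * (e.base_weight / total_w) * e.multipliers.get(cond, 1.0)
                    count = int(round(_lognormal_around(rng, mean, config.replicate_cv)))
                    realized[e.name][sample] = count
                    if count == 0:
                        continue
                    var_counts = rng.multinomial(count, shift_p)
                    for label, c in zip(shift_labels, var_counts):
                        if c == 0:
                            continue
                        insert = e.variants[label]
                        pad_tail = _random_seq(rng, config.read_length)
                        p_any = 1.0 - (1.0 - config.error_rate) ** len(insert)
                        k_err = rng.binomial(c, p_any) if config.error_rate > 0 else 0
                        for _ in range(c - k_err):
                            serial += 1
                            _emit_read(fh, f"{sample}:{serial}|src={e.name}|shift={label}|err=0", insert, pad_tail)
                        for _ in range(k_err):
                            serial += 1
                            pos = int(rng.integers(0, len(insert)))
                            alt = _BASES[(_BASES.index(insert[pos]) + int(rng.integers(1, 4))) % 4]
                            mutated = insert[:pos] + alt + insert[pos + 1:]
                            _emit_read(fh, f"{sample}:{serial}|src={e.name}|shift={label}|err=1", mutated, pad_tail)
                n_cont = config.reads_per_library - int(round(mirna_depth))
                fam_counts = rng.multinomial(n_cont, [cont_split["rRNA"], cont_split["tRNA"]])
                for fam, n_fam in zip(("rRNA", "tRNA"), fam_counts):
                    refs = contaminant_refs[fam]
                    for _ in range(n_fam):
                        serial += 1
                        ref_name, ref_seq = refs[int(rng.integers(0, len(refs)))]
                        ln = int(rng.integers(18, 26))
                        start = int(rng.integers(0, len(ref_seq) - ln + 1))
                        insert = ref_seq[start : start + ln]
                        pad_tail = _random_seq(rng, config.read_length)
                        _emit_read(fh, f"{sample}:{serial}|src=contaminant:{ref_name}|shift=NA|err=0", insert, pad_tail)

    # -- reference files -----------------------------------------------------
    genome_fa = out_dir / "genome.fa"
    write_fasta([SequenceRecord(k, v) for k, v in sorted(genome.items())], genome_fa)
    prec_fa = out_dir / "precursors.fa"
    write_fasta([SequenceRecord(p.id, p.sequence) for p in precursors], prec_fa, alphabet="rna")
    coords_tsv = out_dir / "mature_coords.tsv"
    write_mature_coords([c for p in precursors for c in p.mature_arms], coords_tsv)
    xeno_fa = out_dir / "xeno.fa"
    write_fasta([SequenceRecord(p.id, p.sequence) for p in xeno_precursors], xeno_fa, alphabet="rna")
    xeno_tsv = out_dir / "xeno_coords.tsv"
    write_mature_coords([c for p in xeno_precursors for c in p.mature_arms], xeno_tsv)
    contaminant_paths = {}
    for fam, refs in contaminant_refs.items():
        p = out_dir / f"contaminants_{fam}.fa"
        write_fasta([SequenceRecord(n, s) for n, s in refs], p)
        contaminant_paths[fam] = p

    # -- truth manifest -------------------------------------------------------
    def _truth_contrasts(e: _Entity) -> dict:
        out = {}
        for treat, control in (("NaCl", "H2O"), ("Na2CO3", "H2O"), ("Na2CO3", "NaCl")):
            f = e.multipliers.get(treat, 1.0) / e.multipliers.get(control, 1.0)
            out[f"{treat} vs {control}"] = {
                "fold": f,
                "de": bool(abs(math.log2(f)) >= 1e-9),
                "direction": "up" if f > 1 else ("down" if f < 1 else "none"),
            }
        return out

    manifest = {
        "schema_version": 1,
        "config": {k: (dict(v) if isinstance(v, Mapping) else list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "read_id_format": "sample:serial|src=<entity or contaminant:ref>|shift=<label>|err=<0/1>",
        "entities": [
            {
                "name": e.name,
                "kind": e.kind,
                "mature": e.mature,
                "variants": dict(e.variants),
                "source": e.source,
                "expected_share": e.base_weight / total_w,
                "expected_mean_counts": {
                    c: mirna_depth * (e.base_weight / total_w) * e.multipliers.get(c, 1.0)
                    for c in config.conditions
                },
                "realized_counts": realized[e.name],
                "contrasts": _truth_contrasts(e),
            }
            for e in entities
        ],
        "implants": {tag: {"scaffold": scf, "offset0": off, "strand": strand}
                     for tag, (scf, off, strand) in implant_info.items()},
    }
    manifest_path = out_dir / "truth.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))

    return SimulationOutput(
        out_dir=out_dir,
        fastq=samples,
        genome_fasta=genome_fa,
        precursor_fasta=prec_fa,
        mature_coords=coords_tsv,
        xeno_fasta=xeno_fa,
        xeno_coords=xeno_tsv,
        contaminants=contaminant_paths,
        manifest_path=manifest_path,
        manifest=manifest,
        precursors=precursors,
        xeno_precursors=xeno_precursors,
        genome=genome,
        sample_groups=sample_groups,
    )


# ---------------------------------------------------------------------------
# Count-matrix simulation for DE calibration
# ---------------------------------------------------------------------------

def simulate_count_matrix(
    n_mirnas: int = 2000,
    n_per_group: int = 3,
    groups: tuple[str, str] = ("NaCl", "H2O"),
    n_spiked: int = 0,
    fold: float = 1.0,
    cv: float = 0.1,
    mean_range: tuple[float, float] = (50.0, 5000.0),
    frac_up: float = 0.5,
    seed: int = 0,
):
    """Count matrix with optional spiked fold changes, for DE calibration.

    The first ``n_spiked`` miRNAs change by ``fold`` in the treatment group
    (``groups[0]``), a ``frac_up`` share of them upward.  Returns
    (CountMatrix, truth dict name -> "up"/"down").
    """
    from .diffexpr import CountMatrix
    import pandas as pd

    rng = np.random.default_rng(seed)
    base = np.exp(rng.uniform(np.log(mean_range[0]), np.log(mean_range[1]), size=n_mirnas))
    names = [f"mir-{i + 1:04d}" for i in range(n_mirnas)]
    truth: dict[str, str] = {}
    mult = {g: np.ones(n_mirnas) for g in groups}
    n_up = round(frac_up * n_spiked)
    for i in range(n_spiked):
        up = i < n_up
        mult[groups[0]][i] = fold if up else 1.0 / fold
        truth[names[i]] = "up" if up else "down"
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    cols = {}
    group_of = {}
    for g in groups:
        for r in range(1, n_per_group + 1):
            sample = f"{g}_{r}"
            mean = base * mult[g]
            noise = rng.lognormal(-0.5 * sigma * sigma, sigma, size=n_mirnas)
            cols[sample] = np.round(mean * noise).astype(int)
            group_of[sample] = g
    counts = pd.DataFrame(cols, index=names)
    return CountMatrix(counts, group_of), truth
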