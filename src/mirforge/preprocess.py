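"""Raw-read cleanup: adapter trimming, quality-independent filters, and
collapsing into unique 18-25 nt tags with per-sample counts.

Every raw read ends up in exactly one disposition bucket (retained,
adapter_fail, length_fail, low_complexity, contaminant:<family>, repeat), and
the per-sample ledger is checked for conservation on every run: the counts
across buckets always sum to the raw read count.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .formats_io import SequenceRecord, read_fasta, read_fastq, revcomp

__all__ = [
    "PreprocessConfig",
    "UniqueTag",
    "ConservationError",
    "trim_adapter",
    "filter_low_complexity",
    "filter_contaminants",
    "collapse_reads",
    "preprocess_samples",
    "CONTAMINANT_PRECEDENCE",
]

# fixed precedence when a tag matches several contaminant families
CONTAMINANT_PRECEDENCE = ("rRNA", "tRNA", "snRNA", "snoRNA", "repeat")

RETAINED = "retained"
ADAPTER_FAIL = "adapter_fail"
LENGTH_FAIL = "length_fail"
LOW_COMPLEXITY = "low_complexity"


class ConservationError(RuntimeError):
    """Raised when the disposition ledger fails to account for every read."""


@dataclass(frozen=True)
class PreprocessConfig:
    """Filter parameters for read cleanup.

    ``adapter`` is the 3' ligation adapter searched as a 3'-anchored
    substring (mismatches allowed, no indels); ``min_overlap`` guards the
    prefix match at the read end against spurious 1-2 nt "hits".
    """

    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    min_len: int = 18
    max_len: int = 25
    max_adapter_mismatch: int = 1
    min_overlap: int = 3
    low_complexity_threshold: float = 0.8
    di_repeat_threshold: float = 0.9
    contaminant_sets: Mapping[str, str | Path] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.adapter:
            raise ValueError("adapter must be non-empty")
        if self.min_len > self.max_len:
            raise ValueError("min_len > max_len")
        for frac in (self.low_complexity_threshold, self.di_repeat_threshold):
            if not 0 < frac <= 1:
                raise ValueError(f"threshold {frac} outside (0, 1]")
        unknown = set(self.contaminant_sets) - set(CONTAMINANT_PRECEDENCE)
        if unknown:
            raise ValueError(f"unknown contaminant families: {sorted(unknown)}")


@dataclass
class UniqueTag:
    """A collapsed distinct read sequence with per-sample raw counts."""

    sequence: str
    counts: dict[str, int]
    disposition: str = RETAINED

    @property
    def total(self) -> int:
        return sum(self.counts.values())


# ---------------------------------------------------------------------------
# Adapter trimming
# ---------------------------------------------------------------------------

def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def trim_adapter(read: str | SequenceRecord, config: PreprocessConfig) -> str:
    """Insert sequence before the leftmost adapter match; '' for a dimer.

    The adapter may match in full anywhere, or as a prefix (>= min_overlap
    nt) running off the 3' end of the read.  Up to ``max_adapter_mismatch``
    mismatches are tolerated, but never as many as the matched length.  A
    read with no adapter hit is returned unchanged (already-clean input is
    a no-op), so this is a total function.
    """
    seq = read.sequence if isinstance(read, SequenceRecord) else read
    adapter = config.adapter
    n, m = len(seq), len(adapter)

    first_exact = seq.find(adapter)
    limit = first_exact if first_exact >= 0 else max(0, n - config.min_overlap + 1)
    if config.max_adapter_mismatch > 0:
        for p in range(0, limit):
            matched = min(m, n - p)
            if matched < config.min_overlap and matched < m:
                break
            allowed = min(config.max_adapter_mismatch, matched - 1)
            if _hamming(seq[p : p + matched], adapter[:matched]) <= allowed:
                return seq[:p]
    if first_exact >= 0:
        return seq[:first_exact]
    # mismatch-free prefix match at the end was covered above when
    # max_adapter_mismatch > 0; handle the exact-only configuration here
    if config.max_adapter_mismatch == 0:
        for p in range(max(0, n - m + 1), n - config.min_overlap + 1):
            if seq[p:] == adapter[: n - p]:
                return seq[:p]
    return seq


# ---------------------------------------------------------------------------
# Low complexity
# ---------------------------------------------------------------------------

_DIMERS = [a + b for a in "ACGT" for b in "ACGT"]


def filter_low_complexity(
    sequence: str,
    mono_threshold: float = 0.8,
    di_threshold: float = 0.9,
) -> bool:
    """True when the sequence should be kept.

    Dropped when the most frequent single base exceeds ``mono_threshold`` of
    the length, or some mono/di-nucleotide repeat pattern covers at least
    ``di_threshold`` of it (both phases of all 16 dimers are scanned).
    """
    n = len(sequence)
    if n == 0:
        return False
    counts = Counter(sequence)
    if max(counts.values()) / n > mono_threshold:
        return False
    for d in _DIMERS:
        for phase in (0, 1):
            cover = sum(1 for i, c in enumerate(sequence) if c == d[(i + phase) % 2])
            if cover / n >= di_threshold:
                return False
    return True


# ---------------------------------------------------------------------------
# Contaminants
# ---------------------------------------------------------------------------

class ContaminantIndex:
    """Concatenated contaminant references per family for substring tests.

    Structural RNA families (rRNA/tRNA/snRNA/snoRNA) are matched sense-only;
    repeats on either strand.  A '#' separator prevents matches spanning two
    reference sequences.
    """

    def __init__(self, families: Mapping[str, Iterable[str]]):
        self._text: dict[str, str] = {}
        for family, seqs in families.items():
            if family not in CONTAMINANT_PRECEDENCE:
                raise ValueError(f"unknown contaminant family {family!r}")
            self._text[family] = "#" + "#".join(seqs) + "#" if seqs else ""

    @classmethod
    def from_fasta(cls, paths: Mapping[str, str | Path]) -> "ContaminantIndex":
        return cls(
            {fam: [r.sequence for r in read_fasta(p)] for fam, p in paths.items()}
        )

    def classify(self, tag: str) -> str | None:
        """First matching family in precedence order, or None."""
        for family in CONTAMINANT_PRECEDENCE:
            text = self._text.get(family, "")
            if not text:
                continue
            if tag in text:
                return family
            if family == "repeat" and revcomp(tag) in text:
                return family
        return None


def filter_contaminants(tag: str, index: ContaminantIndex) -> str | None:
    """Family label ('repeat' included) for a contaminating tag, else None."""
    return index.classify(tag)


# ---------------------------------------------------------------------------
# Collapsing and the full per-sample pipeline
# ---------------------------------------------------------------------------

def _disposition(
    insert: str, config: PreprocessConfig, index: ContaminantIndex | None
) -> str:
    if not insert:
        return ADAPTER_FAIL
    if not (config.min_len <= len(insert) <= config.max_len):
        return LENGTH_FAIL
    if not filter_low_complexity(
        insert, config.low_complexity_threshold, config.di_repeat_threshold
    ):
        return LOW_COMPLEXITY
    if index is not None:
        family = index.classify(insert)
        if family == "repeat":
            return "repeat"
        if family is not None:
            return f"contaminant:{family}"
    return RETAINED


def collapse_reads(
    inserts_per_sample: Mapping[str, Sequence[str]],
    config: PreprocessConfig | None = None,
    index: ContaminantIndex | None = None,
) -> tuple[list[UniqueTag], dict[str, dict[str, int]]]:
    """Collapse trimmed inserts into unique tags plus a disposition ledger.

    Tags are sorted lexicographically, so the output is independent of read
    order.  Adapter dimers (empty inserts) appear only in the ledger.
    """
    config = config or PreprocessConfig()
    per_seq: dict[str, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    ledger: dict[str, dict[str, int]] = {}
    for sample, inserts in inserts_per_sample.items():
        counts = ledger.setdefault(sample, defaultdict(int))
        counts["raw_reads"] += len(inserts)
        for ins in inserts:
            if ins:
                per_seq[ins][sample] += 1
            else:
                counts[ADAPTER_FAIL] += 1

    tags: list[UniqueTag] = []
    disp_cache: dict[str, str] = {}
    for seq in sorted(per_seq):
        disp = disp_cache.get(seq)
        if disp is None:
            disp = disp_cache[seq] = _disposition(seq, config, index)
        tag = UniqueTag(seq, dict(per_seq[seq]), disp)
        tags.append(tag)
        for sample, c in tag.counts.items():
            ledger[sample][disp] += c

    ledger = {s: dict(c) for s, c in ledger.items()}
    _check_conservation(ledger)
    return tags, ledger


def _check_conservation(ledger: Mapping[str, Mapping[str, int]]) -> None:
    for sample, counts in ledger.items():
        total = sum(
            v for k, v in counts.items() if k not in ("raw_reads", "valid_reads")
        )
        if total != counts.get("raw_reads", 0):
            raise ConservationError(
                f"sample {sample}: dispositions sum to {total}, "
                f"raw reads {counts.get('raw_reads', 0)}"
            )


def preprocess_samples(
    fastq_paths: Mapping[str, str | Path],
    config: PreprocessConfig | None = None,
) -> tuple[list[UniqueTag], dict[str, dict[str, int]]]:
    """Run the full cleanup on one FASTQ per sample.

    Returns (unique tags sorted lexicographically, per-sample ledger).  The
    ledger's ``valid_reads`` entry — the retained-tag read total — is the
    'valid data' figure a sequencing report would quote.
    """
    config = config or PreprocessConfig()
    index = (
        ContaminantIndex.from_fasta(config.contaminant_sets)
        if config.contaminant_sets
        else None
    )
    inserts = {
        sample: [trim_adapter(rec.sequence, config) for rec in read_fastq(path)]
        for sample, path in fastq_paths.items()
    }
    tags, ledger = collapse_reads(inserts, config, index)
    for counts in ledger.values():
        counts["valid_reads"] = counts.get(RETAINED, 0)
    return tags, ledger
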