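"""Normalization, ANOVA differential expression, set logic, clustering and
2^-ddCt qPCR quantification.

Counts are scaled to counts-per-million (CPM) over retained miRNAs, log2(x+1)
transformed for testing, and compared with a one-way fixed-effects ANOVA
F-test (for two groups this is exactly the pooled-variance t-test, F = t^2).
A miRNA is called differentially expressed in a contrast "treatment vs
control" when the raw ANOVA p-value is at or below the significance
threshold AND the fold change — (mean treatment CPM + 1)/(mean control CPM
+ 1) — is at least the fold gate in either direction.  Calls are gated on
raw p-values at both 0.05 and 0.01; Benjamini-Hochberg q-values are reported
alongside but do not gate the calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "CountMatrix",
    "DEResult",
    "normalize",
    "anova_p",
    "call_de",
    "venn_partition",
    "concordance_classes",
    "pearson_matrix",
    "cluster_de",
    "ddct",
]

GROUPS = ("H2O", "NaCl", "Na2CO3")


@dataclass
class CountMatrix:
    """Raw counts (miRNA x sample) plus a sample -> group map."""

    counts: pd.DataFrame
    groups: Mapping[str, str]

    def __post_init__(self) -> None:
        missing = [s for s in self.counts.columns if s not in self.groups]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")

    def samples_in(self, group: str) -> list[str]:
        cols = [s for s in self.counts.columns if self.groups[s] == group]
        if not cols:
            raise ValueError(f"no samples in group {group!r}")
        return cols

    def cpm(self) -> pd.DataFrame:
        return normalize(self.counts)


def normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million: each sample column scaled to a 1e6 total."""
    totals = matrix.sum(axis=0)
    zero = totals[totals == 0].index.tolist()
    if zero:
        raise ValueError(f"all-zero sample column(s): {zero}")
    return matrix * (1e6 / totals)


def anova_p(
    values: np.ndarray | Sequence[Sequence[float]] | pd.DataFrame,
    labels: Sequence[str],
    transform: bool = False,
) -> np.ndarray | float:
    """One-way fixed-effects ANOVA p-value(s), vectorised over rows.

    ``values`` is (n_features, n_samples) or a single 1-D sample vector;
    ``labels`` assigns each column to a group.  ``transform`` applies
    log2(x+1) first.  Rows with zero total variance return p = 1 by
    convention; every group must have >= 2 replicates.
    """
    arr = np.asarray(values, dtype=float)
    single = arr.ndim == 1
    if single:
        arr = arr[None, :]
    if arr.shape[1] != len(labels):
        raise ValueError("labels length must match number of columns")
    labels = np.asarray(labels)
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    for g in uniq:
        if (labels == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 replicates")
    if transform:
        arr = np.log2(arr + 1.0)

    N = arr.shape[1]
    k = len(uniq)
    grand = arr.mean(axis=1, keepdims=True)
    sst = ((arr - grand) ** 2).sum(axis=1)
    ssb = np.zeros(arr.shape[0])
    for g in uniq:
        cols = labels == g
        n_g = cols.sum()
        ssb += n_g * (arr[:, cols].mean(axis=1) - grand[:, 0]) ** 2
    ssw = sst - ssb
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / (k - 1)) / (ssw / (N - k))
    p = stats.f.sf(f, k - 1, N - k)
    p = np.where(ssw <= 1e-300, np.where(ssb <= 1e-300, 1.0, 0.0), p)
    p = np.where(sst <= 1e-300, 1.0, p)  # total variance zero -> p = 1
    return float(p[0]) if single else p


@dataclass(frozen=True)
class DEResult:
    mirna: str
    contrast: str
    group_means: dict  # group -> mean CPM
    log2_fc: float
    p_value: float
    q_value: float
    direction: str  # "up" | "down"
    significant: bool  # p <= p_threshold and |fold| >= fc_threshold
    significant_01: bool  # same gate at p <= 0.01


def call_de(
    matrix: CountMatrix,
    contrast: tuple[str, str] | Sequence[str],
    p_threshold: float = 0.05,
    fc_threshold: float = 2.0,
    transform: bool = True,
) -> list[DEResult]:
    """Differential-expression calls for one contrast.

    ``contrast`` is (treatment, control) for a pairwise test, or a list of
    >= 3 group names for a single across-groups ANOVA (fold change and
    direction are then taken from the first-vs-last pair).
    """
    names = list(contrast)
    if len(names) < 2:
        raise ValueError("contrast needs at least two groups")
    treat, control = names[0], names[-1]
    cpm = matrix.cpm()
    cols: list[str] = []
    labels: list[str] = []
    for g in names:
        for s in matrix.samples_in(g):
            cols.append(s)
            labels.append(g)
    sub = cpm[cols]
    p = anova_p(sub.values, labels, transform=transform)
    q = stats.false_discovery_control(p, method="bh")
    means = {g: cpm[matrix.samples_in(g)].mean(axis=1) for g in names}
    fold = (means[treat] + 1.0) / (means[control] + 1.0)
    log2_fc = np.log2(fold)
    contrast_name = f"{treat} vs {control}" if len(names) == 2 else " vs ".join(names)
    results = []
    for i, mirna in enumerate(cpm.index):
        fc_mag = max(fold.iloc[i], 1.0 / fold.iloc[i])
        gate = fc_mag >= fc_threshold
        results.append(
            DEResult(
                mirna=mirna,
                contrast=contrast_name,
                group_means={g: float(means[g].iloc[i]) for g in names},
                log2_fc=float(log2_fc.iloc[i]),
                p_value=float(p[i]),
                q_value=float(q[i]),
                direction="up" if log2_fc.iloc[i] >= 0 else "down",
                significant=bool(p[i] <= p_threshold and gate),
                significant_01=bool(p[i] <= 0.01 and gate),
            )
        )
    return results


def de_table(results: Iterable[DEResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {
            "miRNA": r.mirna,
            "contrast": r.contrast,
            "log2_fc": r.log2_fc,
            "p_value": r.p_value,
            "q_value": r.q_value,
            "direction": r.direction,
            "significant": r.significant,
            "significant_01": r.significant_01,
        }
        for g, m in r.group_means.items():
            row[f"mean_{g}"] = m
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Set logic over contrasts
# ---------------------------------------------------------------------------

def venn_partition(
    set_a: set, set_b: set, set_c: set, labels: tuple[str, str, str] = ("A", "B", "C")
) -> dict[str, set]:
    """Disjoint 7-region partition of three DE sets; regions cover the union."""
    a, b, c = set(set_a), set(set_b), set(set_c)
    la, lb, lc = labels
    return {
        f"{la} only": a - b - c,
        f"{lb} only": b - a - c,
        f"{lc} only": c - a - b,
        f"{la}&{lb} only": (a & b) - c,
        f"{la}&{lc} only": (a & c) - b,
        f"{lb}&{lc} only": (b & c) - a,
        f"{la}&{lb}&{lc}": a & b & c,
    }


def concordance_classes(
    directions_a: Mapping[str, str], directions_b: Mapping[str, str]
) -> dict[str, set]:
    """Partition miRNAs DE in both contrasts by direction agreement."""
    shared = set(directions_a) & set(directions_b)
    return {
        "consistent_up": {m for m in shared if directions_a[m] == directions_b[m] == "up"},
        "consistent_down": {m for m in shared if directions_a[m] == directions_b[m] == "down"},
        "a_up_b_down": {m for m in shared if directions_a[m] == "up" and directions_b[m] == "down"},
        "a_down_b_up": {m for m in shared if directions_a[m] == "down" and directions_b[m] == "up"},
    }


# ---------------------------------------------------------------------------
# Correlation and clustering
# ---------------------------------------------------------------------------

def pearson_matrix(normalized: pd.DataFrame) -> pd.DataFrame:
    """Sample-by-sample Pearson correlation of a normalized matrix."""
    r = np.corrcoef(normalized.values, rowvar=False)
    return pd.DataFrame(r, index=normalized.columns, columns=normalized.columns)


def cluster_de(
    matrix: pd.DataFrame,
) -> dict:
    """Average-linkage hierarchical clustering of DE miRNAs.

    Rows are z-scored log2(x+1) expression; the distance is 1 - Pearson
    correlation.  Input rows are sorted by name first so the leaf order is
    deterministic under input permutation.  Returns linkages plus row/column
    leaf orders (names).
    """
    m = matrix.sort_index().loc[:, sorted(matrix.columns)]
    logm = np.log2(m.values.astype(float) + 1.0)
    z = logm - logm.mean(axis=1, keepdims=True)
    sd = z.std(axis=1)
    sd[sd == 0] = 1.0
    z = z / sd[:, None]

    def _linkage(data: np.ndarray) -> np.ndarray:
        if data.shape[0] < 2:
            return np.empty((0, 4))
        r = np.corrcoef(data)
        d = np.clip(1.0 - r, 0.0, 2.0)
        np.fill_diagonal(d, 0.0)
        return hierarchy.linkage(squareform(d, checks=False), method="average")

    row_link = _linkage(z)
    col_link = _linkage(z.T)
    row_order = (
        [m.index[i] for i in hierarchy.leaves_list(row_link)]
        if len(row_link)
        else list(m.index)
    )
    col_order = (
        [m.columns[i] for i in hierarchy.leaves_list(col_link)]
        if len(col_link)
        else list(m.columns)
    )
    return {
        "row_linkage": row_link,
        "col_linkage": col_link,
        "row_order": row_order,
        "col_order": col_order,
    }


# ---------------------------------------------------------------------------
# qPCR: 2^-ddCt
# ---------------------------------------------------------------------------

def ddct(
    ct_table: pd.DataFrame,
    reference: str = "U6",
    calibrator: str = "H2O",
) -> pd.DataFrame:
    """Relative expression by the 2^-ddCt method.

    ``ct_table`` columns: sample, group, target, ct.  Per sample,
    dCt = Ct(target) - Ct(reference); per target and group,
    ddCt = mean dCt(group) - mean dCt(calibrator); fold = 2^-ddCt, so the
    calibrator group's fold is 1 by construction.
    """
    required = {"sample", "group", "target", "ct"}
    if not required.issubset(ct_table.columns):
        raise ValueError(f"ct table needs columns {sorted(required)}")
    if (ct_table["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    ref = ct_table[ct_table["target"] == reference].set_index("sample")["ct"]
    samples = ct_table["sample"].unique()
    missing = [s for s in samples if s not in ref.index]
    if missing:
        raise ValueError(f"missing {reference} Ct for sample(s): {missing}")
    targets = ct_table[ct_table["target"] != reference].copy()
    targets["dct"] = targets["ct"].values - ref.loc[targets["sample"]].values
    mean_dct = targets.groupby(["target", "group"])["dct"].mean().unstack()
    if calibrator not in mean_dct.columns:
        raise ValueError(f"calibrator group {calibrator!r} absent from ct table")
    ddct_mat = mean_dct.sub(mean_dct[calibrator], axis=0)
    fold = np.power(2.0, -ddct_mat)
    fold.columns.name = "group"
    return fold
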