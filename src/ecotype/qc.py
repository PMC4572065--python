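"""Marker-validation cascade for array genotypes.

Validation mirrors the standard post-clustering workflow for a custom
Infinium-style assay: cluster-quality metrics (R mean, cluster
separation), per-marker missingness, Mendelian trio heritability errors
in a bi-parental mapping family, minor allele frequency, and an exact
heterozygote-excess test combined across accessions.  Each stage removes
markers and the counts telescope, so the surviving panel is reproducible
from the report alone.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DegenerateDataError, FormatError
from .hwe import MonomorphicMarkerError, fisher_combine, het_excess_probability
from .matrix import GenotypeMatrix

__all__ = [
    "TrioSet",
    "QcThresholds",
    "QcStage",
    "QcReport",
    "apply_cluster_qc",
    "missingness_filter",
    "minor_allele_frequency",
    "count_trio_errors",
    "trio_error_filter",
    "het_excess_filter",
    "replicate_concordance",
    "call_rate",
    "run_qc",
]


@dataclass(frozen=True)
class TrioSet:
    """A parent-parent-offspring family used for heritability checks."""

    parent1_id: str
    parent2_id: str
    offspring_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.parent1_id == self.parent2_id:
            raise ConfigError("trio parents must be distinct samples")


@dataclass
class QcThresholds:
    """All cascade thresholds; defaults follow the validated-assay protocol."""

    fail_rmean: float = 0.2
    fail_separation: float = 0.3
    review_separation_hi: float = 0.45
    max_missing: float = 0.10  # markers removed when strictly above
    max_trio_errors: int = 4  # removed when strictly above
    min_maf: float = 0.05  # removed when strictly below
    het_excess_p: float = 0.5  # removed when combined P strictly below
    het_combine: str = "fisher"  # or "min"
    drop_review: bool = False  # review markers are listed, kept by default


# -- cluster QC --------------------------------------------------------

_RMEAN_COLS = ("r_mean_aa", "r_mean_ab", "r_mean_bb")


def apply_cluster_qc(
    stats: pd.DataFrame,
    fail_rmean: float = 0.2,
    fail_sep: float = 0.3,
    review_sep_hi: float = 0.45,
    marker_ids: Sequence[str] | None = None,
) -> pd.Series:
    """Label markers pass/review/fail from clustering metrics.

    Fail when any occupied cluster's R mean is below ``fail_rmean`` or the
    cluster separation is below ``fail_sep``; review when separation lies
    in [``fail_sep``, ``review_sep_hi``).  Unoccupied clusters carry NaN R
    means and are ignored.  Markers without stats are labelled
    ``unscored`` rather than silently passed.
    """
    for col in ("marker_id", "separation"):
        if col not in stats.columns:
            raise FormatError(f"cluster-stats table lacks column {col!r}")
    stats = stats.set_index("marker_id")
    rmeans = stats[[c for c in _RMEAN_COLS if c in stats.columns]]
    low_r = (rmeans < fail_rmean).any(axis=1)
    occupied = rmeans.notna().any(axis=1)
    if not occupied.all():
        raise FormatError(
            f"markers with no occupied cluster: {list(stats.index[~occupied][:5])}"
        )
    sep = stats["separation"]
    label = pd.Series("pass", index=stats.index, dtype=object)
    label[(sep >= fail_sep) & (sep < review_sep_hi)] = "review"
    label[low_r | (sep < fail_sep)] = "fail"
    if marker_ids is not None:
        label = label.reindex(marker_ids, fill_value="unscored")
    label.index.name = "marker_id"
    return label


# -- missingness / MAF -------------------------------------------------

def missingness_filter(
    matrix: GenotypeMatrix, max_missing: float = 0.10
) -> tuple[list[str], list[str]]:
    """(kept, removed) marker lists; removed when NC fraction > max_missing."""
    frac = matrix.missing_fraction()
    removed = frac.index[frac > max_missing]
    kept = frac.index.difference(removed, sort=False)
    return list(kept), list(removed)


def minor_allele_frequency(
    matrix: GenotypeMatrix, marker: str | None = None
) -> "pd.Series | float":
    """MAF per marker (or for one marker) over non-missing calls.

    AA contributes two A alleles, AB one of each; NC calls are excluded
    from the denominator.  All-missing markers are undefined.
    """
    codes = matrix.codes()
    present = codes >= 0
    n_called = present.sum(axis=0)
    a_count = np.where(present, codes, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_a = np.where(n_called > 0, a_count / (2.0 * n_called), np.nan)
    maf = pd.Series(np.minimum(p_a, 1.0 - p_a), index=matrix.marker_ids)
    if marker is not None:
        value = maf.loc[marker]
        if np.isnan(value):
            raise DegenerateDataError(f"MAF undefined for all-missing {marker!r}")
        return float(value)
    return maf


# -- Mendelian trio errors ---------------------------------------------

def _allowed_table() -> np.ndarray:
    """allowed[p1, p2, child] over dosage codes 0/1/2 (B count mirrored)."""
    allowed = np.zeros((3, 3, 3), dtype=bool)
    for p1 in range(3):
        for p2 in range(3):
            g1 = {0: (0,), 1: (0, 1), 2: (1,)}[p1]
            g2 = {0: (0,), 1: (0, 1), 2: (1,)}[p2]
            for a in g1:
                for b in g2:
                    allowed[p1, p2, a + b] = True
    return allowed


_ALLOWED = _allowed_table()


def count_trio_errors(
    matrix: GenotypeMatrix,
    trios: Sequence[TrioSet],
    marker: str | None = None,
) -> "pd.Series | int":
    """Per-marker count of offspring calls impossible under Mendelian rules.

    Parent-offspring triplets containing any NC call are skipped, not
    counted as errors.
    """
    for trio in trios:
        ids = (trio.parent1_id, trio.parent2_id) + tuple(trio.offspring_ids)
        unknown = [s for s in ids if s not in matrix.sample_ids]
        if unknown:
            raise ConfigError(f"unknown sample ids in trio definition: {unknown[:5]}")
    codes = pd.DataFrame(
        matrix.codes(), index=matrix.sample_ids, columns=matrix.marker_ids
    )
    errors = np.zeros(matrix.n_markers, dtype=np.int64)
    for trio in trios:
        p1 = codes.loc[trio.parent1_id].to_numpy()
        p2 = codes.loc[trio.parent2_id].to_numpy()
        kids = codes.loc[list(trio.offspring_ids)].to_numpy()
        parents_ok = (p1 >= 0) & (p2 >= 0)
        child_ok = kids >= 0
        ok = parents_ok[None, :] & child_ok
        bad = ~_ALLOWED[
            np.clip(p1, 0, 2)[None, :].repeat(kids.shape[0], axis=0),
            np.clip(p2, 0, 2)[None, :].repeat(kids.shape[0], axis=0),
            np.clip(kids, 0, 2),
        ]
        errors += (bad & ok).sum(axis=0)
    out = pd.Series(errors, index=matrix.marker_ids)
    if marker is not None:
        return int(out.loc[marker])
    return out


def trio_error_filter(
    matrix: GenotypeMatrix,
    trios: Sequence[TrioSet],
    max_errors: int = 4,
) -> tuple[list[str], list[str]]:
    """(kept, removed): markers removed when errors strictly exceed max."""
    errors = count_trio_errors(matrix, trios)
    removed = errors.index[errors > max_errors]
    kept = errors.index.difference(removed, sort=False)
    return list(kept), list(removed)


# -- heterozygote excess ------------------------------------------------

def het_excess_filter(
    matrix: GenotypeMatrix,
    p_threshold: float = 0.5,
    combine: str = "fisher",
) -> tuple[list[str], list[str], pd.Series]:
    """(kept, removed, combined P) from per-accession exact excess tests.

    The exact one-sided excess P is computed per accession (monomorphic
    accessions are skipped) and combined across accessions by Fisher's
    method (or the per-accession minimum with ``combine="min"``).  A
    marker is removed when the combined P is strictly below the
    threshold; markers with no defined test anywhere are kept.
    """
    if combine not in ("fisher", "min"):
        raise ConfigError(f"unknown combination rule {combine!r}")
    codes = matrix.codes()
    acc = matrix.accessions.to_numpy()
    combined = pd.Series(np.nan, index=matrix.marker_ids)
    groups: dict = {}
    for i, a in enumerate(acc):
        groups.setdefault(a, []).append(i)
    # per-accession genotype counts per marker
    per_acc_counts = []
    for idx in groups.values():
        sub = codes[idx]
        n_aa = (sub == 2).sum(axis=0)
        n_ab = (sub == 1).sum(axis=0)
        n_bb = (sub == 0).sum(axis=0)
        per_acc_counts.append((n_aa, n_ab, n_bb))
    cache: dict[tuple[int, int, int], float | None] = {}
    for j, m in enumerate(matrix.marker_ids):
        pvals = []
        for n_aa, n_ab, n_bb in per_acc_counts:
            key = (int(n_aa[j]), int(n_ab[j]), int(n_bb[j]))
            if key not in cache:
                try:
                    cache[key] = het_excess_probability(*key)
                except MonomorphicMarkerError:
                    cache[key] = None
            if cache[key] is not None:
                pvals.append(cache[key])
        if pvals:
            combined.loc[m] = (
                fisher_combine(pvals) if combine == "fisher" else min(pvals)
            )
    removed = combined.index[combined < p_threshold]
    kept = combined.index.difference(removed, sort=False)
    return list(kept), list(removed), combined


# -- replicates / call rates -------------------------------------------

def replicate_concordance(
    matrix: GenotypeMatrix,
    pairs: Sequence[tuple[str, str]],
) -> tuple[float, pd.Series]:
    """(overall, per-pair) fraction of agreeing calls where both are non-NC."""
    per_pair = {}
    agree_total = 0
    compared_total = 0
    for s1, s2 in pairs:
        for s in (s1, s2):
            if s not in matrix.sample_ids:
                raise ConfigError(f"unknown replicate sample {s!r}")
        c1 = matrix.calls.loc[s1].to_numpy()
        c2 = matrix.calls.loc[s2].to_numpy()
        both = (c1 != "NC") & (c2 != "NC")
        n = int(both.sum())
        agree = int(((c1 == c2) & both).sum())
        per_pair[(s1, s2)] = agree / n if n else np.nan
        agree_total += agree
        compared_total += n
    if compared_total == 0:
        raise DegenerateDataError("no comparable non-missing call pairs")
    return agree_total / compared_total, pd.Series(per_pair)


def call_rate(matrix: GenotypeMatrix, group_by: str = "accession") -> pd.Series:
    """Per-group fraction of non-missing calls."""
    present = pd.DataFrame(
        matrix.calls.to_numpy() != "NC",
        index=matrix.sample_ids,
        columns=matrix.marker_ids,
    )
    if group_by == "accession":
        grouped = present.groupby(matrix.accessions)
        return grouped.mean().mean(axis=1)
    if group_by == "sample":
        return present.mean(axis=1)
    raise ConfigError(f"unknown grouping {group_by!r}")


# -- the cascade --------------------------------------------------------

@dataclass
class QcStage:
    name: str
    n_input: int
    removed: list[str]

    @property
    def n_removed(self) -> int:
        return len(self.removed)

    @property
    def n_surviving(self) -> int:
        return self.n_input - self.n_removed


@dataclass
class QcReport:
    """Ordered record of the validation cascade."""

    stages: list[QcStage]
    survivors: list[str]
    review_markers: list[str] = field(default_factory=list)
    call_rates: dict = field(default_factory=dict)
    replicate_concordance: float | None = None
    het_excess_p: dict = field(default_factory=dict)

    @property
    def n_input(self) -> int:
        return self.stages[0].n_input if self.stages else 0

    def counts(self) -> list[tuple[str, int]]:
        """Telescoping (stage name, surviving count) sequence."""
        return [(s.name, s.n_surviving) for s in self.stages]

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "stages": [
                {
                    "name": s.name,
                    "n_input": s.n_input,
                    "n_removed": s.n_removed,
                    "removed": list(s.removed),
                }
                for s in self.stages
            ],
            "survivors": list(self.survivors),
            "review_markers": list(self.review_markers),
            "call_rates": {str(k): v for k, v in self.call_rates.items()},
            "replicate_concordance": self.replicate_concordance,
        }


def run_qc(
    matrix: GenotypeMatrix,
    cluster_stats: pd.DataFrame | None = None,
    trios: Sequence[TrioSet] | None = None,
    trio_matrix: GenotypeMatrix | None = None,
    replicate_pairs: Sequence[tuple[str, str]] | None = None,
    thresholds: QcThresholds | None = None,
) -> tuple[GenotypeMatrix, QcReport]:
    """Run the full validation cascade and return (filtered matrix, report).

    Stage order: cluster QC, missingness, trio heritability errors (on the
    mapping-family matrix when given), minor allele frequency,
    heterozygote excess.  A marker failing several criteria is attributed
    to the first stage that removes it.
    """
    cfg = thresholds or QcThresholds()
    current = list(matrix.marker_ids)
    stages: list[QcStage] = []
    review: list[str] = []

    if cluster_stats is not None:
        labels = apply_cluster_qc(
            cluster_stats,
            cfg.fail_rmean,
            cfg.fail_separation,
            cfg.review_separation_hi,
            marker_ids=current,
        )
        review = [m for m in current if labels.get(m) == "review"]
        drop_labels = {"fail"} | ({"review"} if cfg.drop_review else set())
        removed = [m for m in current if labels.get(m) in drop_labels]
        stages.append(QcStage("cluster_qc", len(current), removed))
        current = [m for m in current if m not in set(removed)]

    sub = matrix.subset_markers(current)
    kept, removed = missingness_filter(sub, cfg.max_missing)
    stages.append(QcStage("missingness", len(current), removed))
    current = kept

    if trios:
        target = trio_matrix if trio_matrix is not None else matrix
        trio_sub = target.subset_markers(
            [m for m in current if m in target.marker_ids]
        )
        kept_t, removed_t = trio_error_filter(trio_sub, trios, cfg.max_trio_errors)
        stages.append(QcStage("trio_errors", len(current), removed_t))
        current = [m for m in current if m not in set(removed_t)]

    sub = matrix.subset_markers(current)
    maf = minor_allele_frequency(sub)
    removed = list(maf.index[maf < cfg.min_maf])
    stages.append(QcStage("maf", len(current), removed))
    current = [m for m in current if m not in set(removed)]

    sub = matrix.subset_markers(current)
    kept, removed, het_p = het_excess_filter(sub, cfg.het_excess_p, cfg.het_combine)
    stages.append(QcStage("het_excess", len(current), removed))
    current = kept

    filtered = matrix.subset_markers(current)
    report = QcReport(
        stages=stages,
        survivors=current,
        review_markers=review,
        call_rates=call_rate(filtered).to_dict() if current else {},
        het_excess_p=het_p.dropna().to_dict(),
    )
    if replicate_pairs:
        overall, _ = replicate_concordance(filtered, replicate_pairs)
        report.replicate_concordance = overall
    return filtered, report
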