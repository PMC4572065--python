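"""Distance-based hierarchical analysis of molecular variance (AMOVA).

Genotypes encoded as per-individual allele-frequency vectors (AA=1, AB=0.5,
BB/missing=0 for the A column and vice versa for B) are decomposed into
variance among regions (AR), among accessions within regions (AP) and
within accessions (WP) from pairwise squared Euclidean distances, following
the standard nested AMOVA sums-of-squares identities:

    SS_total        = (1/N) sum_{i<j} d2_ij
    SS_within(G)    = sum_g (1/n_g) sum_{i<j in g} d2_ij
    SS_AR           = SS_total - SS_withinRegions
    SS_AP           = SS_withinRegions - SS_WP

Variance components use the unbalanced-design coefficients

    n1 = (N - sum_r (sum_{p in r} n_p^2)/N_r) / (P - R)
    n2 = (sum_r (sum_{p in r} n_p^2)/N_r - sum_p n_p^2 / N) / (R - 1)
    n3 = (N - sum_r N_r^2 / N) / (R - 1)

    WP = MS_WP;  AP = (MS_AP - WP)/n1;  AR = (MS_AR - WP - n2*AP)/n3

and the fixation indices are Phi_RT = AR/TOT, Phi_PR = AP/(AP+WP),
Phi_PT = (AP+AR)/TOT with negative components truncated at zero.
Significance comes from label permutations: individuals among accessions
(Phi_PT), individuals among accessions within their region (Phi_PR), and
whole accessions among regions (Phi_RT).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DegenerateDataError

__all__ = [
    "AmovaResult",
    "squared_distance_matrix",
    "amova_nested",
    "phi_from_components",
    "permutation_test",
    "pairwise_region_amova",
]

_EPS = 1e-12


@dataclass
class AmovaResult:
    """Nested AMOVA table: df/SS/MS per stratum, components, Phi, P values."""

    df: dict[str, int]
    ss: dict[str, float]
    ms: dict[str, float]
    components: dict[str, float]  # raw (possibly negative) estimates
    percentages: dict[str, float]  # from components truncated at 0
    phi: dict[str, float]
    p_values: dict[str, float] = field(default_factory=dict)
    coefficients: dict[str, float] = field(default_factory=dict)
    n_permutations: int = 0
    seed: int | None = None
    degenerate: bool = False

    def to_frame(self) -> pd.DataFrame:
        """Render the classic AMOVA table (Source, df, SS, MS, Est. var., %)."""
        rows = []
        names = {
            "AR": "Between regions",
            "AP": "Between accessions",
            "WP": "Between individuals",
        }
        for key in ("AR", "AP", "WP"):
            if key not in self.df:
                continue
            rows.append(
                {
                    "Source": names[key],
                    "df": self.df[key],
                    "SS": self.ss[key],
                    "MS": self.ms[key],
                    "Est. var.": self.components[key],
                    "%": self.percentages[key],
                }
            )
        rows.append(
            {
                "Source": "Total",
                "df": self.df["total"],
                "SS": self.ss["total"],
                "MS": np.nan,
                "Est. var.": sum(max(v, 0.0) for v in self.components.values()),
                "%": 100.0,
            }
        )
        return pd.DataFrame(rows)


def squared_distance_matrix(encoded: "pd.DataFrame | np.ndarray") -> np.ndarray:
    """Pairwise squared Euclidean distances between encoded individuals.

    Under the (1, 0)/(0, 1) allele coding an AA vs BB difference at one
    marker contributes (1-0)^2 + (0-1)^2 = 2.
    """
    x = np.asarray(encoded, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least two individuals")
    sq = np.einsum("ij,ij->i", x, x)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (x @ x.T)
    np.fill_diagonal(d2, 0.0)
    return np.maximum(d2, 0.0)


def _group_indices(labels: np.ndarray) -> dict:
    idx: dict = {}
    for i, lab in enumerate(labels):
        idx.setdefault(lab, []).append(i)
    return {k: np.asarray(v) for k, v in idx.items()}


def _ss_within(d2: np.ndarray, labels: np.ndarray) -> float:
    """sum_g (1/n_g) sum_{i<j in g} d2_ij."""
    total = 0.0
    for idx in _group_indices(labels).values():
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            total += sub.sum() / (2.0 * len(idx))
    return total


def phi_from_components(
    ar: float, ap: float, wp: float
) -> tuple[float, float, float]:
    """(Phi_RT, Phi_PR, Phi_PT) from variance components.

    Negative components are truncated at zero first.  All-zero components
    are degenerate; zeros are returned.
    """
    ar, ap, wp = (max(v, 0.0) for v in (ar, ap, wp))
    tot = ar + ap + wp
    if tot <= _EPS:
        return 0.0, 0.0, 0.0
    phi_rt = ar / tot
    phi_pr = ap / (ap + wp) if (ap + wp) > _EPS else 0.0
    phi_pt = (ap + ar) / tot
    return phi_rt, phi_pr, phi_pt


def _component_estimates(
    d2: np.ndarray,
    acc: np.ndarray,
    reg: np.ndarray | None,
) -> tuple[dict, dict, dict, dict]:
    """Return (df, ss, ms, components) for the nested (or 2-level) design."""
    n = len(acc)
    acc_groups = _group_indices(acc)
    p = len(acc_groups)
    ss_tot = d2.sum() / (2.0 * n)
    ss_wp = _ss_within(d2, acc)
    sizes = {k: len(v) for k, v in acc_groups.items()}

    if reg is None:
        df = {"AP": p - 1, "WP": n - p, "total": n - 1}
        if p < 2:
            raise ConfigError("need at least two accessions")
        ss_ap = ss_tot - ss_wp
        ms = {
            "AP": ss_ap / df["AP"],
            "WP": ss_wp / df["WP"] if df["WP"] > 0 else 0.0,
        }
        n0 = (n - sum(s * s for s in sizes.values()) / n) / (p - 1)
        wp = ms["WP"]
        ap = (ms["AP"] - wp) / n0
        return (
            df,
            {"AP": ss_ap, "WP": ss_wp, "total": ss_tot},
            ms,
            {"AP": ap, "WP": wp},
            {"n0": n0},
        )

    # nested: regions / accessions / individuals
    acc_region: dict = {}
    for a, r in zip(acc, reg):
        if a in acc_region and acc_region[a] != r:
            raise ConfigError(f"accession {a!r} assigned to more than one region")
        acc_region[a] = r
    regions = sorted(set(acc_region.values()), key=str)
    r_count = len(regions)
    if r_count < 2:
        raise ConfigError("nested analysis needs at least two regions")
    if p - r_count < 1:
        raise ConfigError("nested analysis needs more accessions than regions")

    ss_wr = _ss_within(d2, reg)
    ss_ar = ss_tot - ss_wr
    ss_ap = ss_wr - ss_wp
    df = {"AR": r_count - 1, "AP": p - r_count, "WP": n - p, "total": n - 1}
    ms = {k: (ss / df[k] if df[k] > 0 else 0.0)
          for k, ss in (("AR", ss_ar), ("AP", ss_ap), ("WP", ss_wp))}

    reg_sizes = {r: 0 for r in regions}
    reg_sq_acc = {r: 0.0 for r in regions}
    for a, s in sizes.items():
        r = acc_region[a]
        reg_sizes[r] += s
        reg_sq_acc[r] += s * s
    sum_sq_over_reg = sum(reg_sq_acc[r] / reg_sizes[r] for r in regions)
    sum_sq_acc = sum(s * s for s in sizes.values())
    sum_sq_reg = sum(v * v for v in reg_sizes.values())
    n1 = (n - sum_sq_over_reg) / (p - r_count)
    n2 = (sum_sq_over_reg - sum_sq_acc / n) / (r_count - 1)
    n3 = (n - sum_sq_reg / n) / (r_count - 1)

    wp = ms["WP"]
    ap = (ms["AP"] - wp) / n1
    ar = (ms["AR"] - wp - n2 * ap) / n3
    return (
        df,
        {"AR": ss_ar, "AP": ss_ap, "WP": ss_wp, "total": ss_tot},
        ms,
        {"AR": ar, "AP": ap, "WP": wp},
        {"n1": n1, "n2": n2, "n3": n3},
    )


def _percentages(components: dict) -> dict:
    trunc = {k: max(v, 0.0) for k, v in components.items()}
    tot = sum(trunc.values())
    if tot <= _EPS:
        return {k: 0.0 for k in components}
    return {k: 100.0 * v / tot for k, v in trunc.items()}


def amova_nested(
    encoded: "pd.DataFrame | np.ndarray",
    accession_labels: Sequence,
    region_labels: Sequence | None = None,
    *,
    n_permutations: int = 0,
    seed: int | None = None,
    strict: bool = False,
) -> AmovaResult:
    """Hierarchical AMOVA on encoded genotypes.

    With ``region_labels`` a three-stratum decomposition (AR/AP/WP) is
    returned; without, a two-level one (AP/WP, Phi_PT = AP/(AP+WP)).
    ``strict=True`` raises on negative variance components instead of
    truncating them for percentages and Phi.
    """
    x = np.asarray(encoded, dtype=float)
    acc = np.asarray(list(accession_labels))
    if len(acc) != x.shape[0]:
        raise ConfigError("accession labels do not match matrix rows")
    reg = None
    if region_labels is not None:
        reg = np.asarray(list(region_labels))
        if len(reg) != x.shape[0]:
            raise ConfigError("region labels do not match matrix rows")

    d2 = squared_distance_matrix(x)
    df, ss, ms, comp, coef = _component_estimates(d2, acc, reg)

    if strict and any(v < -_EPS for v in comp.values()):
        raise DegenerateDataError(f"negative variance component: {comp}")

    degenerate = ss["total"] <= _EPS
    if reg is not None:
        phi_rt, phi_pr, phi_pt = phi_from_components(
            comp["AR"], comp["AP"], comp["WP"]
        )
        phi = {"Phi_RT": phi_rt, "Phi_PR": phi_pr, "Phi_PT": phi_pt}
    else:
        _, _, phi_pt = phi_from_components(0.0, comp["AP"], comp["WP"])
        phi = {"Phi_PT": phi_pt}

    result = AmovaResult(
        df=df,
        ss=ss,
        ms=ms,
        components=comp,
        percentages=_percentages(comp),
        phi=phi,
        coefficients=coef,
        degenerate=degenerate,
        seed=seed,
        n_permutations=n_permutations,
    )
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        for stat in phi:
            result.p_values[stat] = permutation_test(
                x,
                acc,
                region_labels=reg,
                statistic=stat,
                n_perm=n_permutations,
                seed=int(rng.integers(2**31 - 1)),
                _d2=d2,
            )
    return result


def _phi_statistic(
    d2: np.ndarray,
    acc: np.ndarray,
    reg: np.ndarray | None,
    statistic: str,
    raw: bool = False,
) -> float:
    """Phi for one stratum; ``raw=True`` skips the negative-component
    truncation so the permutation null stays continuous (truncation
    would pile ties at zero and bias permutation P upward)."""
    _, _, _, comp, _ = _component_estimates(d2, acc, reg)
    if statistic != "Phi_PT" and reg is None:
        raise ConfigError(f"{statistic} requires region labels")
    ar = comp.get("AR", 0.0)
    ap, wp = comp["AP"], comp["WP"]
    if raw:
        tot = ar + ap + wp
        if statistic == "Phi_RT":
            return ar / tot if abs(tot) > _EPS else 0.0
        if statistic == "Phi_PR":
            return ap / (ap + wp) if abs(ap + wp) > _EPS else 0.0
        return (ar + ap) / tot if abs(tot) > _EPS else 0.0
    phi_rt, phi_pr, phi_pt = phi_from_components(ar, ap, wp)
    return {"Phi_RT": phi_rt, "Phi_PR": phi_pr, "Phi_PT": phi_pt}[statistic]


def permutation_test(
    encoded: "pd.DataFrame | np.ndarray",
    accession_labels: Sequence,
    region_labels: Sequence | None = None,
    *,
    statistic: str = "Phi_PT",
    n_perm: int = 999,
    seed: int | None = None,
    _d2: np.ndarray | None = None,
) -> float:
    """Permutation P value for one Phi statistic.

    P = (#{permuted >= observed} + 1) / (n_perm + 1); the smallest
    attainable value with 999 permutations is 0.001.
    """
    if n_perm < 1:
        raise ConfigError("n_perm must be >= 1")
    acc = np.asarray(list(accession_labels))
    reg = np.asarray(list(region_labels)) if region_labels is not None else None
    if statistic not in ("Phi_PT", "Phi_PR", "Phi_RT"):
        raise ConfigError(f"unknown statistic {statistic!r}")
    if statistic in ("Phi_PR", "Phi_RT") and reg is None:
        raise ConfigError(f"{statistic} requires region labels")

    d2 = _d2 if _d2 is not None else squared_distance_matrix(encoded)
    observed = _phi_statistic(d2, acc, reg, statistic, raw=True)
    rng = np.random.default_rng(seed)
    hits = 0
    n = len(acc)

    if statistic == "Phi_RT":
        # permute whole accessions among regions
        acc_ids = sorted(set(acc), key=str)
        acc_region = {a: r for a, r in zip(acc, reg)}
        region_of = np.array([acc_region[a] for a in acc_ids], dtype=object)
        for _ in range(n_perm):
            shuffled = region_of[rng.permutation(len(acc_ids))]
            lookup = dict(zip(acc_ids, shuffled))
            perm_reg = np.array([lookup[a] for a in acc], dtype=object)
            if _phi_statistic(d2, acc, perm_reg, statistic, raw=True) >= observed - _EPS:
                hits += 1
    elif statistic == "Phi_PR":
        # permute individuals among accessions within their region
        reg_groups = _group_indices(reg)
        for _ in range(n_perm):
            perm_acc = acc.copy()
            for idx in reg_groups.values():
                perm_acc[idx] = acc[idx][rng.permutation(len(idx))]
            if _phi_statistic(d2, perm_acc, reg, statistic, raw=True) >= observed - _EPS:
                hits += 1
    else:
        # Phi_PT: permute individuals among accessions (regions follow
        # the accession assignment)
        acc_region = dict(zip(acc, reg)) if reg is not None else None
        for _ in range(n_perm):
            order = rng.permutation(n)
            perm_acc = acc[order]
            perm_reg = (
                np.array([acc_region[a] for a in perm_acc], dtype=object)
                if acc_region is not None
                else None
            )
            if _phi_statistic(d2, perm_acc, perm_reg, statistic, raw=True) >= observed - _EPS:
                hits += 1
    return (hits + 1) / (n_perm + 1)


def pairwise_region_amova(
    encoded: "pd.DataFrame | np.ndarray",
    region_labels: Sequence,
    pair: tuple,
    *,
    n_permutations: int = 0,
    seed: int | None = None,
) -> AmovaResult:
    """Two-level AMOVA between one pair of regions, each treated as a single
    population (1 df between)."""
    x = np.asarray(encoded, dtype=float)
    reg = np.asarray(list(region_labels))
    a, b = pair
    for name in (a, b):
        if name not in reg:
            raise ConfigError(f"unknown region {name!r}")
    mask = (reg == a) | (reg == b)
    return amova_nested(
        x[mask],
        reg[mask],
        None,
        n_permutations=n_permutations,
        seed=seed,
    )
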