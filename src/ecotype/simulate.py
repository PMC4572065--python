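"""Synthetic-data generators with known ground truth.

Every downstream stage of the package (probe design, marker QC, PCA,
AMOVA) can be exercised on data generated here, with the generator
logging exactly what each stage should find.

The genotype generator uses a two-level Balding-Nichols hierarchy:
region allele frequencies are Beta-distributed around an ancestral
frequency p0 and accession frequencies Beta-distributed around their
region's, with genotypes drawn Binomial(2, p) under Hardy-Weinberg.
The differentiation parameters ``f_rt`` and ``f_pr`` are specified on
the *realized Phi scale* (the value a distance AMOVA of the generated
genotypes is expected to return) and converted internally to Beta
concentration parameters; see docs/methods.md for the algebra.  A
configurable fraction of markers carries a longitudinal or latitudinal
cline added on the logit scale.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .matrix import GenotypeMatrix, from_codes
from .probes import VARIANT_COLUMNS
from .qc import TrioSet

__all__ = [
    "SimulationParams",
    "SimulationTruth",
    "phi_to_beta_f",
    "gen_hierarchical_genotypes",
    "gen_mapping_family",
    "gen_variant_report",
    "gen_cluster_stats",
    "gen_validation_fixture",
    "VariantReport",
]

_REGION_NAMES = ("East", "North", "South", "West")


def phi_to_beta_f(phi: float) -> float:
    """Beta-hierarchy F giving realized two-level Phi equal to ``phi``.

    Individual-level distance AMOVA of Hardy-Weinberg genotypes places
    the binomial within-individual variance p(1-p)/2 in the within
    stratum, so a Beta parameter F yields Phi = 2F/(1+F); inverting
    gives F = phi/(2-phi).
    """
    if not 0.0 <= phi < 1.0:
        raise ConfigError(f"differentiation must be in [0, 1), got {phi}")
    return phi / (2.0 - phi)


def _nested_beta_f(phi_rt: float, phi_pr: float) -> tuple[float, float]:
    """(F_rt, F_pr) Beta parameters for target (Phi_RT, Phi_PR)."""
    f_pr = phi_to_beta_f(phi_pr)
    if not 0.0 <= phi_rt < 1.0:
        raise ConfigError(f"differentiation must be in [0, 1), got {phi_rt}")
    c = (1.0 + f_pr) / 2.0
    f_rt = phi_rt * c / (1.0 - phi_rt * (1.0 - c))
    return f_rt, f_pr


@dataclass
class SimulationParams:
    """Design of a hierarchical ecotype-collection simulation.

    Defaults emulate a European ecotype survey: 90 accessions in four
    regions (12/45/16/17), eight individuals each except one accession
    of four (716 individuals), ~2185 biallelic markers, accession-level
    differentiation around 0.25-0.30 with a modest geographic cline and
    about 1% missing calls.
    """

    n_regions: int = 4
    accessions_per_region: tuple[int, ...] = (12, 45, 16, 17)
    individuals_per_accession: int = 8
    deviating_sizes: dict[int, int] = field(default_factory=lambda: {73: 4})
    n_markers: int = 2185
    # targets on the realized-Phi scale for the *non-clinal* part of the
    # hierarchy; the geographic cline (regions occupy distinct areas)
    # contributes the rest of the regional differentiation
    f_rt: float = 0.02
    f_pr: float = 0.20
    cline_fraction: float = 0.4
    cline_strength: float = 0.9  # logit slope per standardized coordinate
    # share of clinal markers on the longitudinal axis; >0.5 makes the
    # East-West cline dominant so PC1 aligns with longitude and PC2 with
    # latitude instead of rotating arbitrarily in the cline plane
    cline_lon_fraction: float = 0.65
    missing_rate: float = 0.01
    seed: int = 0
    lon_bounds: tuple[float, float] = (-10.0, 42.0)
    lat_bounds: tuple[float, float] = (36.0, 62.0)
    p0_bounds: tuple[float, float] = (0.1, 0.9)

    def __post_init__(self) -> None:
        if isinstance(self.accessions_per_region, int):
            self.accessions_per_region = tuple(
                [self.accessions_per_region] * self.n_regions
            )
        if len(self.accessions_per_region) != self.n_regions:
            raise ConfigError("accessions_per_region must match n_regions")
        if self.n_markers < 1:
            raise ConfigError("n_markers must be >= 1")
        for name in ("f_rt", "f_pr"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ConfigError(f"{name} must be in [0, 1), got {v}")
        if not 0.0 <= self.cline_fraction <= 1.0:
            raise ConfigError("cline_fraction must be in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError("missing_rate must be in [0, 1)")
        n_acc = sum(self.accessions_per_region)
        for idx in self.deviating_sizes:
            if not 0 <= idx < n_acc:
                raise ConfigError(f"deviating accession index {idx} out of range")

    @property
    def n_accessions(self) -> int:
        return sum(self.accessions_per_region)

    def accession_sizes(self) -> list[int]:
        sizes = [self.individuals_per_accession] * self.n_accessions
        for idx, n in self.deviating_sizes.items():
            sizes[idx] = n
        return sizes

    @property
    def n_individuals(self) -> int:
        return sum(self.accession_sizes())


@dataclass
class SimulationTruth:
    """Ground truth logged by a generator run."""

    p0: np.ndarray | None = None
    accession_frequencies: pd.DataFrame | None = None
    clinal_axis: pd.Series | None = None  # marker -> "longitude"/"latitude"/None
    injected_errors: list[dict] = field(default_factory=list)
    expected_survivors: list[str] | None = None
    removal_reasons: dict | None = None
    cluster_labels: pd.Series | None = None
    expected_counts: dict | None = None


def _region_boxes(
    region_names: list[str],
    lon_bounds: tuple[float, float],
    lat_bounds: tuple[float, float],
) -> dict[str, tuple[tuple[float, float], tuple[float, float]]]:
    """Per-region coordinate sub-boxes within the overall bounds.

    The four named regions get overlapping quadrant-like areas (West,
    South, East, North); any other region count gets longitude bands.
    """
    x0, x1 = lon_bounds
    y0, y1 = lat_bounds
    lx, ly = x1 - x0, y1 - y0
    if set(region_names) == set(_REGION_NAMES):
        return {
            "West": ((x0, x0 + 0.40 * lx), (y0, y0 + 0.60 * ly)),
            "South": ((x0 + 0.35 * lx, x0 + 0.80 * lx), (y0, y0 + 0.42 * ly)),
            "East": ((x0 + 0.60 * lx, x1), (y0 + 0.15 * ly, y0 + 0.77 * ly)),
            "North": ((x0 + 0.05 * lx, x0 + 0.60 * lx), (y0 + 0.55 * ly, y1)),
        }
    n = len(region_names)
    return {
        r: ((x0 + i * lx / n, x0 + (i + 1) * lx / n), (y0, y1))
        for i, r in enumerate(region_names)
    }


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1.0 - p))


def _beta_around(
    rng: np.random.Generator, mean: np.ndarray, f: float
) -> np.ndarray:
    """Beta draw with mean ``mean`` and Balding-Nichols parameter ``f``."""
    if f == 0.0:
        return mean.copy()
    m = np.clip(mean, 1e-6, 1.0 - 1e-6)
    scale = (1.0 - f) / f
    return rng.beta(m * scale, (1.0 - m) * scale)


def gen_hierarchical_genotypes(
    params: SimulationParams,
    coordinates: pd.DataFrame | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame, SimulationTruth]:
    """Simulate a hierarchically structured ecotype genotype matrix.

    Returns (genotype matrix, accession table, truth).  The accession
    table mirrors a collection-passport schema: ID, Accession, Country,
    Longitude, Latitude, Altitude, Region.  ``coordinates`` may supply
    Longitude/Latitude per accession; otherwise they are drawn uniformly
    within the configured bounds.
    """
    rng = np.random.default_rng(params.seed)
    n_acc = params.n_accessions
    n_mark = params.n_markers
    sizes = params.accession_sizes()

    region_names = (
        list(_REGION_NAMES)
        if params.n_regions == 4
        else [f"R{i + 1}" for i in range(params.n_regions)]
    )
    acc_ids = [f"P{i + 1:03d}" for i in range(n_acc)]
    acc_region: list[str] = []
    for r, count in zip(region_names, params.accessions_per_region):
        acc_region.extend([r] * count)

    if coordinates is not None:
        lon = coordinates["Longitude"].reindex(acc_ids).to_numpy(dtype=float)
        lat = coordinates["Latitude"].reindex(acc_ids).to_numpy(dtype=float)
        if np.isnan(lon).any() or np.isnan(lat).any():
            raise ConfigError("supplied coordinates missing for some accessions")
    else:
        # regions are geographic areas: each accession's coordinates are
        # uniform within its region's sub-box of the overall bounds, so
        # region-level differentiation correlates with geography as it
        # does in a real regional survey
        boxes = _region_boxes(
            region_names, params.lon_bounds, params.lat_bounds
        )
        lon = np.empty(n_acc)
        lat = np.empty(n_acc)
        for i, r in enumerate(acc_region):
            (x0, x1), (y0, y1) = boxes[r]
            lon[i] = rng.uniform(x0, x1)
            lat[i] = rng.uniform(y0, y1)
        lon = np.round(lon, 2)
        lat = np.round(lat, 2)
    altitude = np.round(rng.uniform(0, 2000, size=n_acc), 0)

    info = pd.DataFrame(
        {
            "ID": acc_ids,
            "Accession": [f"Ba{10000 + i}" for i in range(n_acc)],
            "Country": ["synthetic"] * n_acc,
            "Longitude": lon,
            "Latitude": lat,
            "Altitude": altitude,
            "Region": acc_region,
        }
    ).set_index("ID")

    # -- allele-frequency hierarchy ------------------------------------
    f_rt_beta, f_pr_beta = _nested_beta_f(params.f_rt, params.f_pr)
    p0 = rng.uniform(*params.p0_bounds, size=n_mark)
    region_freq = np.vstack(
        [_beta_around(rng, p0, f_rt_beta) for _ in region_names]
    )
    region_index = {r: i for i, r in enumerate(region_names)}
    acc_freq = np.vstack(
        [
            _beta_around(rng, region_freq[region_index[r]], f_pr_beta)
            for r in acc_region
        ]
    )

    # -- geographic cline ----------------------------------------------
    n_clinal = int(round(params.cline_fraction * n_mark))
    clinal_axis = pd.Series([None] * n_mark, index=[f"M{j + 1:05d}" for j in range(n_mark)], dtype=object)
    if n_clinal > 0 and params.cline_strength != 0.0:
        clinal = rng.choice(n_mark, size=n_clinal, replace=False)
        axis_is_lon = rng.random(n_clinal) < params.cline_lon_fraction
        z_lon = (lon - lon.mean()) / (lon.std() or 1.0)
        z_lat = (lat - lat.mean()) / (lat.std() or 1.0)
        logit_f = _logit(np.clip(acc_freq, 1e-6, 1 - 1e-6))
        for j, use_lon in zip(clinal, axis_is_lon):
            z = z_lon if use_lon else z_lat
            logit_f[:, j] = logit_f[:, j] + params.cline_strength * z
            clinal_axis.iloc[j] = "longitude" if use_lon else "latitude"
        acc_freq = np.where(
            np.isin(np.arange(n_mark), clinal)[None, :],
            _logistic(logit_f),
            acc_freq,
        )

    # -- genotypes ------------------------------------------------------
    marker_ids = list(clinal_axis.index)
    sample_ids: list[str] = []
    sample_acc: list[str] = []
    blocks = []
    for i, (acc, n_i) in enumerate(zip(acc_ids, sizes)):
        blocks.append(rng.binomial(2, acc_freq[i], size=(n_i, n_mark)))
        sample_ids.extend(f"{acc}_{k + 1}" for k in range(n_i))
        sample_acc.extend([acc] * n_i)
    codes = np.vstack(blocks).astype(np.int8)
    if params.missing_rate > 0:
        codes[rng.random(codes.shape) < params.missing_rate] = -1

    matrix = from_codes(codes, sample_ids, marker_ids, sample_acc)
    truth = SimulationTruth(
        p0=p0,
        accession_frequencies=pd.DataFrame(
            acc_freq, index=acc_ids, columns=marker_ids
        ),
        clinal_axis=clinal_axis,
    )
    return matrix, info, truth


# -- bi-parental mapping family -----------------------------------------

_GAMETES = {0: (0,), 1: (0, 1), 2: (1,)}


def _mendelian_children(p1: int, p2: int) -> set[int]:
    return {a + b for a in _GAMETES[p1] for b in _GAMETES[p2]}


def gen_mapping_family(
    parent_maf_spec: tuple[float, float] = (0.2, 0.5),
    n_progeny: int = 193,
    error_rate: float = 0.0,
    n_markers: int = 500,
    seed: int | None = None,
) -> tuple[GenotypeMatrix, list[TrioSet], SimulationTruth]:
    """Two parents and their progeny under Mendelian transmission.

    Each progeny call draws one allele from each parent; with
    probability ``error_rate`` the call is replaced by a uniformly
    chosen different call, and the injection is logged together with
    whether it is Mendelian-detectable given the parents.
    """
    if n_progeny < 1:
        raise ConfigError("n_progeny must be >= 1")
    if not 0.0 <= error_rate < 1.0:
        raise ConfigError("error_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    p = rng.uniform(*parent_maf_spec, size=n_markers)
    parent1 = rng.binomial(2, p)
    parent2 = rng.binomial(2, p)
    a1 = rng.random((n_progeny, n_markers)) < parent1 / 2.0
    a2 = rng.random((n_progeny, n_markers)) < parent2 / 2.0
    kids = (a1.astype(np.int8) + a2.astype(np.int8))

    marker_ids = [f"M{j + 1:05d}" for j in range(n_markers)]
    kid_ids = [f"F1_{k + 1:03d}" for k in range(n_progeny)]
    injected: list[dict] = []
    if error_rate > 0:
        mask = rng.random(kids.shape) < error_rate
        shifts = rng.integers(1, 3, size=kids.shape)
        for i, j in np.argwhere(mask):
            old = int(kids[i, j])
            new = (old + int(shifts[i, j])) % 3
            kids[i, j] = new
            detectable = new not in _mendelian_children(
                int(parent1[j]), int(parent2[j])
            )
            injected.append(
                {
                    "sample": kid_ids[i],
                    "marker": marker_ids[j],
                    "old": old,
                    "new": new,
                    "detectable": detectable,
                }
            )

    codes = np.vstack([parent1[None, :], parent2[None, :], kids]).astype(np.int8)
    sample_ids = ["P1", "P2"] + kid_ids
    matrix = from_codes(
        codes, sample_ids, marker_ids, ["MAP"] * len(sample_ids)
    )
    trios = [TrioSet("P1", "P2", tuple(kid_ids))]
    return matrix, trios, SimulationTruth(injected_errors=injected)


# -- variant-report fixture ---------------------------------------------

_SOURCES = (
    "forage_variety",
    "substitution_line",
    "late_heading_line",
    "amenity_variety",
    "wild_ecotype",
)
_BLACKLIST_DESCRIPTIONS = (
    "putative chloroplast envelope protein",
    "mitochondrial carrier protein",
    "retrotransposon gag-pol polyprotein",
)
_CLEAN_DESCRIPTIONS = (
    "histidine-containing phosphotransfer protein",
    "formate-tetrahydrofolate ligase-like",
    "predicted protein",
    "66 kDa stress protein-like",
)


@dataclass
class VariantReport:
    """A generated probe-design fixture plus its filter-by-filter truth."""

    contigs: dict[str, str]
    variants: pd.DataFrame
    blast: pd.DataFrame
    scores: dict[str, float]
    truth: SimulationTruth


def gen_variant_report(
    n_contigs: int = 60,
    contig_length_spec: tuple[int, int] = (120, 1500),
    snp_density: float = 0.004,
    coverage_spec: tuple[int, int] = (20, 200),
    quality_spec: tuple[int, int] = (10, 45),
    blacklist_fraction: float = 0.1,
    frameshift_fraction: float = 0.1,
    seed: int | None = None,
) -> VariantReport:
    """Generate contigs, a variant report and BLAST annotations with
    planted violations of every probe-design filter.

    Truth is built during generation by straightforward per-SNP checks in
    cascade order (thresholds, shared polymorphism, annotation, spacing,
    flanks, designability), independent of the vectorized filters.
    """
    for frac in (blacklist_fraction, frameshift_fraction):
        if not 0.0 <= frac <= 1.0:
            raise ConfigError("fractions must be in [0, 1]")
    if snp_density < 0:
        raise ConfigError("snp_density must be >= 0")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))

    contigs: dict[str, str] = {}
    rows: list[dict] = []
    blast_rows: list[dict] = []
    bad_contigs: dict[str, str] = {}
    snp_meta: list[dict] = []

    for c in range(n_contigs):
        cid = f"Contig{c + 1}"
        length = int(rng.integers(contig_length_spec[0], contig_length_spec[1] + 1))
        seq = "".join(rng.choice(bases, size=length))
        contigs[cid] = seq

        u = rng.random()
        if u < frameshift_fraction:
            bad_contigs[cid] = "frameshift"
            subject = f"sp|FS{c:04d}"
            for hsp in range(2):
                blast_rows.append(
                    _blast_row(cid, subject, rng, _CLEAN_DESCRIPTIONS[c % 4])
                )
        elif u < frameshift_fraction + blacklist_fraction:
            bad_contigs[cid] = "blacklist"
            blast_rows.append(
                _blast_row(
                    cid,
                    f"sp|BL{c:04d}",
                    rng,
                    _BLACKLIST_DESCRIPTIONS[c % len(_BLACKLIST_DESCRIPTIONS)],
                )
            )
        elif rng.random() < 0.8:  # some contigs stay unannotated
            blast_rows.append(
                _blast_row(cid, f"sp|OK{c:04d}", rng, _CLEAN_DESCRIPTIONS[c % 4])
            )

        n_snps = rng.poisson(snp_density * length)
        n_snps = min(n_snps, length)
        if n_snps == 0:
            continue
        positions = np.sort(rng.choice(length, size=n_snps, replace=False)) + 1
        for pos in positions:
            ref = seq[pos - 1]
            var = str(rng.choice([b for b in "ACGT" if b != ref]))
            k_sources = int(rng.choice([1, 2, 3, 4], p=[0.3, 0.4, 0.2, 0.1]))
            sources = list(rng.choice(_SOURCES, size=k_sources, replace=False))
            obs_pass = []
            for s in sources:
                cov = int(rng.integers(*coverage_spec))
                sq = int(rng.integers(*quality_spec))
                nq = int(rng.integers(*quality_spec))
                vf = float(np.round(rng.uniform(10, 50), 1))
                nonspec = bool(rng.random() < 0.05)
                rows.append(
                    {
                        "contig_id": cid,
                        "position": int(pos),
                        "ref_allele": ref,
                        "var_allele": var,
                        "coverage": cov,
                        "variant_frequency": vf,
                        "snp_quality": sq,
                        "neighbourhood_quality": nq,
                        "source_genotype": s,
                        "nonspecific_flag": nonspec,
                    }
                )
                obs_pass.append(
                    cov >= 50 and sq >= 30 and nq >= 20 and vf >= 25 and not nonspec
                )
            snp_meta.append(
                {
                    "contig": cid,
                    "position": int(pos),
                    "length": length,
                    "n_passing_sources": sum(obs_pass),
                }
            )

    variants = pd.DataFrame(rows, columns=list(VARIANT_COLUMNS))
    blast = pd.DataFrame(
        blast_rows,
        columns=[
            "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
            "qstart", "qend", "sstart", "send", "evalue", "bitscore",
            "description",
        ],
    )

    # -- truth, cascade order, simple loops -----------------------------
    reasons: dict[str, str] = {}
    stage2 = []
    for m in snp_meta:
        name = f"{m['contig']}_{m['position']}"
        if m["n_passing_sources"] == 0:
            reasons[name] = "variant_thresholds"
        elif m["n_passing_sources"] < 2:
            reasons[name] = "shared_polymorphism"
        elif m["contig"] in bad_contigs:
            reasons[name] = "annotation"
        else:
            stage2.append(m)
    by_contig: dict[str, list[dict]] = {}
    for m in stage2:
        by_contig.setdefault(m["contig"], []).append(m)
    stage3 = []
    for cid, group in by_contig.items():
        for m in group:
            close = any(
                other is not m and abs(other["position"] - m["position"]) < 50
                for other in group
            )
            if close:
                reasons[f"{cid}_{m['position']}"] = "spacing"
            else:
                stage3.append(m)
    survivors: list[str] = []
    scores: dict[str, float] = {}
    for m in stage3:
        name = f"{m['contig']}_{m['position']}"
        left = m["position"] - 1
        right = m["length"] - m["position"]
        if left < 50 or right < 50:
            reasons[name] = "flanking"
            continue
        score = float(np.round(rng.uniform(0.3, 1.0), 3))
        scores[name] = score
        if score < 0.6:
            reasons[name] = "designability"
        else:
            survivors.append(name)

    truth = SimulationTruth(
        expected_survivors=sorted(survivors),
        removal_reasons=reasons,
    )
    return VariantReport(contigs, variants, blast, scores, truth)


def _blast_row(
    cid: str, subject: str, rng: np.random.Generator, description: str
) -> dict:
    start = int(rng.integers(1, 50))
    return {
        "qseqid": cid,
        "sseqid": subject,
        "pident": float(np.round(rng.uniform(60, 100), 1)),
        "length": int(rng.integers(50, 300)),
        "mismatch": int(rng.integers(0, 20)),
        "gapopen": int(rng.integers(0, 3)),
        "qstart": start,
        "qend": start + int(rng.integers(50, 200)),
        "sstart": 1,
        "send": int(rng.integers(50, 200)),
        "evalue": 10.0 ** -float(rng.integers(5, 50)),
        "bitscore": float(np.round(rng.uniform(50, 400), 1)),
        "description": description,
    }


# -- cluster-statistics fixture -----------------------------------------

def gen_cluster_stats(
    marker_ids: Sequence[str],
    fail_fractions: Mapping[str, float] | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Cluster metrics (R means, separation) with known pass/review/fail.

    ``fail_fractions`` maps ``rmean``, ``separation`` and ``review`` to
    the fraction of markers planted in each category; the rest pass.
    """
    frac = {"rmean": 0.0, "separation": 0.0, "review": 0.0}
    frac.update(fail_fractions or {})
    if sum(frac.values()) > 1.0 + 1e-9:
        raise ConfigError("fail fractions must sum to <= 1")
    rng = np.random.default_rng(seed)
    n = len(marker_ids)
    n_rmean = int(round(frac["rmean"] * n))
    n_sep = int(round(frac["separation"] * n))
    n_review = int(round(frac["review"] * n))
    order = rng.permutation(n)
    cat = np.array(["pass"] * n, dtype=object)
    cat[order[:n_rmean]] = "fail_rmean"
    cat[order[n_rmean : n_rmean + n_sep]] = "fail_separation"
    cat[order[n_rmean + n_sep : n_rmean + n_sep + n_review]] = "review"

    rows = []
    labels = []
    for m, c in zip(marker_ids, cat):
        rmeans = rng.uniform(0.5, 1.5, size=3)
        sep = float(np.round(rng.uniform(0.46, 0.95), 3))
        if c == "fail_rmean":
            rmeans[rng.integers(0, 3)] = rng.uniform(0.02, 0.19)
            label = "fail"
        elif c == "fail_separation":
            sep = float(np.round(rng.uniform(0.02, 0.29), 3))
            label = "fail"
        elif c == "review":
            sep = float(np.round(rng.uniform(0.30, 0.449), 3))
            label = "review"
        else:
            label = "pass"
        rows.append(
            {
                "marker_id": m,
                "r_mean_aa": float(np.round(rmeans[0], 3)),
                "r_mean_ab": float(np.round(rmeans[1], 3)),
                "r_mean_bb": float(np.round(rmeans[2], 3)),
                "separation": sep,
            }
        )
        labels.append(label)
    stats = pd.DataFrame(rows)
    truth = SimulationTruth(
        cluster_labels=pd.Series(labels, index=list(marker_ids))
    )
    return stats, truth


# -- validation-cascade fixture -----------------------------------------

def gen_validation_fixture(
    n_markers: int = 2501,
    n_trio_fail: int = 43,
    n_maf_fail: int = 239,
    n_het_fail: int = 34,
    n_accessions: int = 90,
    individuals_per_accession: int = 8,
    n_progeny: int = 193,
    seed: int | None = None,
) -> tuple[GenotypeMatrix, GenotypeMatrix, list[TrioSet], SimulationTruth]:
    """Ecotype + mapping-family matrices with exact planted QC failures.

    Plants exactly ``n_trio_fail`` markers with five Mendelian errors,
    ``n_maf_fail`` with a global minor allele frequency below 5% and
    ``n_het_fail`` with extreme heterozygote excess in every accession;
    the remaining markers pass every stage.  Returns the matrices, the
    trio definition and the expected telescoping counts.
    """
    if n_trio_fail + n_maf_fail + n_het_fail > n_markers:
        raise ConfigError("planted failures exceed marker count")
    rng = np.random.default_rng(seed)
    marker_ids = [f"M{j + 1:05d}" for j in range(n_markers)]
    order = rng.permutation(n_markers)
    trio_fail = set(order[:n_trio_fail])
    maf_fail = set(order[n_trio_fail : n_trio_fail + n_maf_fail])
    het_fail = set(
        order[n_trio_fail + n_maf_fail : n_trio_fail + n_maf_fail + n_het_fail]
    )

    acc_ids = [f"P{i + 1:03d}" for i in range(n_accessions)]
    n_ind = n_accessions * individuals_per_accession
    codes = np.empty((n_ind, n_markers), dtype=np.int8)
    # per-accession clean pattern: 3 AA, 2 AB, 3 BB => het deficit, MAF 0.5
    clean_block = np.resize(
        np.array([2, 2, 2, 1, 1, 0, 0, 0], dtype=np.int8),
        individuals_per_accession,
    )
    clean = np.tile(clean_block[:, None], (n_accessions, 1))
    for j in range(n_markers):
        if j in het_fail:
            codes[:, j] = 1  # every individual heterozygous
        elif j in maf_fail:
            codes[:, j] = 2  # monomorphic AA ...
            codes[0, j] = 1  # ... except a single heterozygote
        else:
            codes[:, j] = clean[:, 0]

    sample_ids = [
        f"{acc}_{k + 1}"
        for acc in acc_ids
        for k in range(individuals_per_accession)
    ]
    sample_acc = [
        acc for acc in acc_ids for _ in range(individuals_per_accession)
    ]
    matrix = from_codes(codes, sample_ids, marker_ids, sample_acc)

    # mapping family: AB x AB everywhere (never an error) except planted
    # trio-fail markers: AA x AA parents with five BB progeny
    fam_codes = np.ones((2 + n_progeny, n_markers), dtype=np.int8)
    for j in trio_fail:
        fam_codes[:, j] = 2
        fam_codes[2 : 2 + 5, j] = 0
    kid_ids = [f"F1_{k + 1:03d}" for k in range(n_progeny)]
    fam_ids = ["P1", "P2"] + kid_ids
    family = from_codes(fam_codes, fam_ids, marker_ids, ["MAP"] * len(fam_ids))
    trios = [TrioSet("P1", "P2", tuple(kid_ids))]

    truth = SimulationTruth(
        expected_counts={
            "input": n_markers,
            "after_trio": n_markers - n_trio_fail,
            "after_maf": n_markers - n_trio_fail - n_maf_fail,
            "after_het": n_markers - n_trio_fail - n_maf_fail - n_het_fail,
        }
    )
    return matrix, family, trios, truth
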