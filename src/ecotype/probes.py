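"""Transcriptome-variant to array-probe filter cascade.

Reduces an in-silico SNP report (one row per putative SNP per sequenced
source genotype) to a panel of designable fixed-array probe candidates:

1. per-observation thresholds: read coverage, SNP quality, neighbourhood
   quality, minor-variant frequency, non-specific-mapping exclusion;
2. shared polymorphism: the same (contig, position, allele pair) must be
   observed in at least two source genotypes;
3. contig annotation: frameshift evidence (multiple HSPs to the same
   protein subject) and an organellar/repeat keyword blacklist;
4. SNP spacing: both members of any pair closer than 50 bp are dropped;
5. flanking sequence: 50 bp minimum (60 preferred) each side, rendered
   as ``LEFT[A/B]RIGHT``;
6. designability: externally supplied probe-design scores, keep >= 0.6.

All numeric thresholds are inclusive on the passing side.  Coordinates
are 1-based; marker names follow ``<contig>_<position>``.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataIntegrityError, FormatError

__all__ = [
    "VARIANT_COLUMNS",
    "DEFAULT_BLACKLIST",
    "ProbeCandidate",
    "CascadeReport",
    "filter_variant_calls",
    "shared_polymorphism_filter",
    "annotation_filter",
    "spacing_filter",
    "build_probe_candidates",
    "designability_filter",
    "design_panel",
    "render_probe_sequence",
    "parse_probe_sequence",
]

VARIANT_COLUMNS = (
    "contig_id",
    "position",
    "ref_allele",
    "var_allele",
    "coverage",
    "variant_frequency",
    "snp_quality",
    "neighbourhood_quality",
    "source_genotype",
    "nonspecific_flag",
)

DEFAULT_BLACKLIST = (
    "chloroplast",
    "mitochondri",
    "plastid",
    "retrotransposon",
    "transposon",
    "gag-pol",
    "reverse transcriptase",
    "polyprotein",
)


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{what} lacks required column(s): {missing}")


@dataclass
class CascadeReport:
    """Input count and per-stage removals of the probe-design cascade."""

    n_input: int
    stages: list[tuple[str, int, int]] = field(default_factory=list)
    # (stage name, n removed, n remaining)

    def add(self, name: str, removed: int, remaining: int) -> None:
        self.stages.append((name, removed, remaining))

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "stages": [
                {"name": n, "n_removed": r, "n_remaining": s}
                for n, r, s in self.stages
            ],
        }


# -- stage 1: per-observation thresholds --------------------------------

_VARIANT_FILTER_ORDER = (
    ("coverage", lambda df, cfg: df["coverage"] >= cfg["min_coverage"]),
    ("snp_quality", lambda df, cfg: df["snp_quality"] >= cfg["min_snp_quality"]),
    (
        "neighbourhood_quality",
        lambda df, cfg: df["neighbourhood_quality"]
        >= cfg["min_neighbourhood_quality"],
    ),
    (
        "variant_frequency",
        lambda df, cfg: df["variant_frequency"] >= cfg["min_variant_freq"],
    ),
    ("nonspecific", lambda df, cfg: ~df["nonspecific_flag"].astype(bool)),
)


def filter_variant_calls(
    variants: pd.DataFrame,
    min_coverage: float = 50,
    min_snp_quality: float = 30,
    min_neighbourhood_quality: float = 20,
    min_variant_freq: float = 25,
    drop_nonspecific: bool = True,
) -> tuple[pd.DataFrame, pd.Series, dict[str, int]]:
    """Apply per-observation thresholds (inclusive on the passing side).

    Returns (survivors, removal reason per dropped row, per-filter counts).
    The reason is the first failing filter in the documented order.
    """
    _require_columns(variants, VARIANT_COLUMNS, "variant table")
    cfg = {
        "min_coverage": min_coverage,
        "min_snp_quality": min_snp_quality,
        "min_neighbourhood_quality": min_neighbourhood_quality,
        "min_variant_freq": min_variant_freq,
    }
    reason = pd.Series(pd.NA, index=variants.index, dtype=object)
    for name, rule in _VARIANT_FILTER_ORDER:
        if name == "nonspecific" and not drop_nonspecific:
            continue
        failing = ~rule(variants, cfg) & reason.isna()
        reason[failing] = name
    counts = reason.value_counts().to_dict()
    survivors = variants[reason.isna()].copy()
    return survivors, reason.dropna(), {k: int(v) for k, v in counts.items()}


# -- stage 2: shared polymorphism ---------------------------------------

def _allele_key(row_ref: str, row_var: str) -> tuple[str, str]:
    return tuple(sorted((row_ref.upper(), row_var.upper())))


def shared_polymorphism_filter(
    variants: pd.DataFrame, min_sources: int = 2
) -> pd.DataFrame:
    """Collapse observations to unique SNPs seen in >= min_sources genotypes.

    SNPs are keyed on (contig, position, sorted allele pair); survivors
    carry the union of source genotypes in a ``sources`` column.
    """
    _require_columns(
        variants,
        ("contig_id", "position", "ref_allele", "var_allele", "source_genotype"),
        "variant table",
    )
    if len(variants) == 0:
        return pd.DataFrame(
            columns=["contig_id", "position", "ref_allele", "var_allele", "sources"]
        )
    keyed = variants.copy()
    keyed["_alleles"] = [
        _allele_key(r, v)
        for r, v in zip(keyed["ref_allele"], keyed["var_allele"])
    ]
    grouped = keyed.groupby(["contig_id", "position", "_alleles"], sort=False)
    records = []
    for (contig, pos, alleles), grp in grouped:
        sources = frozenset(grp["source_genotype"])
        if len(sources) >= min_sources:
            first = grp.iloc[0]
            records.append(
                {
                    "contig_id": contig,
                    "position": int(pos),
                    "ref_allele": alleles[0],
                    "var_allele": alleles[1],
                    "sources": sorted(sources),
                }
            )
    return pd.DataFrame(
        records,
        columns=["contig_id", "position", "ref_allele", "var_allele", "sources"],
    )


# -- stage 3: contig annotation -----------------------------------------

def annotation_filter(
    blast: pd.DataFrame,
    contig_ids: Sequence[str],
    blacklist_keywords: Sequence[str] = DEFAULT_BLACKLIST,
) -> tuple[set, dict]:
    """Allowed contig set plus removal reasons from BLAST annotations.

    A contig is removed when any protein subject occurs in more than one
    HSP for that contig (frameshift evidence) or any hit description
    matches a case-insensitive blacklist keyword.  Contigs with no
    annotation at all are retained: absence of evidence is not evidence.
    """
    _require_columns(blast, ("qseqid", "sseqid", "description"), "BLAST table")
    removal: dict = {}
    hsp_counts = blast.groupby(["qseqid", "sseqid"]).size()
    for (contig, _subject), n in hsp_counts.items():
        if n > 1 and contig not in removal:
            removal[contig] = "frameshift"
    pattern = "|".join(re.escape(k) for k in blacklist_keywords)
    desc = blast["description"].fillna("").str.contains(
        pattern, case=False, regex=True
    )
    for contig in blast.loc[desc, "qseqid"]:
        removal.setdefault(contig, "blacklist")
    allowed = {c for c in contig_ids if c not in removal}
    return allowed, {c: r for c, r in removal.items() if c in set(contig_ids)}


# -- stage 4: spacing ---------------------------------------------------

def spacing_filter(variants: pd.DataFrame, min_gap: int = 50) -> pd.DataFrame:
    """Drop BOTH members of any same-contig pair closer than ``min_gap`` bp.

    The inequality is strict: positions exactly ``min_gap`` apart survive.
    """
    _require_columns(variants, ("contig_id", "position"), "variant table")
    keep_mask = pd.Series(True, index=variants.index)
    for _contig, grp in variants.groupby("contig_id", sort=False):
        pos = grp["position"].to_numpy()
        order = np.argsort(pos, kind="stable")
        sorted_pos = pos[order]
        close_next = np.diff(sorted_pos) < min_gap
        bad_sorted = np.zeros(len(pos), dtype=bool)
        bad_sorted[:-1] |= close_next
        bad_sorted[1:] |= close_next
        bad = np.zeros(len(pos), dtype=bool)
        bad[order] = bad_sorted
        keep_mask.loc[grp.index[bad]] = False
    return variants[keep_mask].copy()


# -- stage 5: flanking sequence -----------------------------------------

@dataclass
class ProbeCandidate:
    """A marker with flanks and alphabetically ordered [A/B] annotation."""

    marker_name: str
    contig_id: str
    position: int  # 1-based
    left_flank: str
    right_flank: str
    alleles: tuple[str, str]
    designability: float | None = None
    status: str = "survived"
    reason: str | None = None

    @property
    def probe_sequence(self) -> str:
        return render_probe_sequence(self.left_flank, self.alleles, self.right_flank)


def render_probe_sequence(
    left: str, alleles: tuple[str, str], right: str
) -> str:
    return f"{left}[{alleles[0]}/{alleles[1]}]{right}"


_PROBE_RE = re.compile(r"^([ACGTN]*)\[([ACGT])/([ACGT])\]([ACGTN]*)$")


def parse_probe_sequence(text: str) -> tuple[str, tuple[str, str], str]:
    """Inverse of :func:`render_probe_sequence`."""
    m = _PROBE_RE.match(text)
    if not m:
        raise FormatError(f"not a valid probe sequence: {text!r}")
    return m.group(1), (m.group(2), m.group(3)), m.group(4)


def build_probe_candidates(
    contigs: Mapping[str, str],
    variants: pd.DataFrame,
    min_flank: int = 50,
    preferred_flank: int = 60,
) -> tuple[list[ProbeCandidate], list[ProbeCandidate]]:
    """Extract flanks around each surviving SNP; reject short-flanked ones.

    Each side takes min(preferred_flank, available bases); a candidate is
    rejected when either side falls below ``min_flank``.  The contig base
    at the SNP position must match one of the two alleles.
    """
    _require_columns(
        variants, ("contig_id", "position", "ref_allele", "var_allele"), "variants"
    )
    kept: list[ProbeCandidate] = []
    rejected: list[ProbeCandidate] = []
    for row in variants.itertuples(index=False):
        contig_id = row.contig_id
        pos = int(row.position)
        seq = contigs.get(contig_id)
        if seq is None:
            raise DataIntegrityError(f"contig {contig_id!r} missing from FASTA")
        seq = str(seq).upper()
        if not (1 <= pos <= len(seq)):
            raise DataIntegrityError(
                f"{contig_id}_{pos}: position outside contig ({len(seq)} bp)"
            )
        alleles = tuple(sorted((row.ref_allele.upper(), row.var_allele.upper())))
        if seq[pos - 1] not in alleles:
            raise DataIntegrityError(
                f"{contig_id}_{pos}: contig base {seq[pos - 1]!r} "
                f"matches neither allele {alleles}"
            )
        left_avail = pos - 1
        right_avail = len(seq) - pos
        left_len = min(preferred_flank, left_avail)
        right_len = min(preferred_flank, right_avail)
        cand = ProbeCandidate(
            marker_name=f"{contig_id}_{pos}",
            contig_id=contig_id,
            position=pos,
            left_flank=seq[pos - 1 - left_len : pos - 1],
            right_flank=seq[pos : pos + right_len],
            alleles=alleles,
        )
        if left_avail < min_flank or right_avail < min_flank:
            cand.status = "removed"
            cand.reason = "flank"
            rejected.append(cand)
        else:
            kept.append(cand)
    return kept, rejected


# -- stage 6: designability ---------------------------------------------

def designability_filter(
    candidates: Sequence[ProbeCandidate],
    scores: Mapping[str, float],
    min_score: float = 0.6,
) -> tuple[list[ProbeCandidate], list[ProbeCandidate]]:
    """Keep candidates with designability score >= min_score (inclusive)."""
    missing = [c.marker_name for c in candidates if c.marker_name not in scores]
    if missing:
        raise ConfigError(f"markers without designability score: {missing[:10]}")
    kept, removed = [], []
    for cand in candidates:
        cand.designability = float(scores[cand.marker_name])
        if cand.designability >= min_score:
            kept.append(cand)
        else:
            cand.status = "removed"
            cand.reason = "designability"
            removed.append(cand)
    return kept, removed


# -- orchestration ------------------------------------------------------

@dataclass
class ProbeDesignConfig:
    min_coverage: float = 50
    min_snp_quality: float = 30
    min_neighbourhood_quality: float = 20
    min_variant_freq: float = 25
    drop_nonspecific: bool = True
    min_sources: int = 2
    blacklist_keywords: tuple[str, ...] = DEFAULT_BLACKLIST
    min_gap: int = 50
    min_flank: int = 50
    preferred_flank: int = 60
    min_designability: float = 0.6


def design_panel(
    variants: pd.DataFrame,
    contigs: Mapping[str, str],
    blast: pd.DataFrame,
    scores: Mapping[str, float] | None = None,
    config: ProbeDesignConfig | None = None,
) -> tuple[list[ProbeCandidate], CascadeReport]:
    """Full cascade: thresholds, shared polymorphism, annotation, spacing,
    flanks, designability.  ``scores`` may be omitted to skip the final
    stage (e.g. when design scores are not yet available)."""
    cfg = config or ProbeDesignConfig()
    report = CascadeReport(n_input=len(variants))

    surviving, _, _ = filter_variant_calls(
        variants,
        cfg.min_coverage,
        cfg.min_snp_quality,
        cfg.min_neighbourhood_quality,
        cfg.min_variant_freq,
        cfg.drop_nonspecific,
    )
    report.add("variant_thresholds", len(variants) - len(surviving), len(surviving))

    unique_snps = shared_polymorphism_filter(surviving, cfg.min_sources)
    report.add(
        "shared_polymorphism",
        len(surviving) - len(unique_snps),
        len(unique_snps),
    )

    allowed, _reasons = annotation_filter(
        blast, list(dict.fromkeys(unique_snps["contig_id"])), cfg.blacklist_keywords
    )
    annotated = unique_snps[unique_snps["contig_id"].isin(allowed)]
    report.add("annotation", len(unique_snps) - len(annotated), len(annotated))

    spaced = spacing_filter(annotated, cfg.min_gap)
    report.add("spacing", len(annotated) - len(spaced), len(spaced))

    candidates, flank_rejected = build_probe_candidates(
        contigs, spaced, cfg.min_flank, cfg.preferred_flank
    )
    report.add("flanking", len(flank_rejected), len(candidates))

    if scores is not None:
        candidates, removed = designability_filter(
            candidates, scores, cfg.min_designability
        )
        report.add("designability", len(removed), len(candidates))

    return candidates, report


def panel_manifest(candidates: Sequence[ProbeCandidate]) -> pd.DataFrame:
    """Probe manifest table (Locus_Name, Target_Sequence, Designability...)."""
    return pd.DataFrame(
        [
            {
                "Locus_Name": c.marker_name,
                "Target_Sequence": c.probe_sequence,
                "Designability": c.designability,
                "Status": c.status,
                "Reason": c.reason,
            }
            for c in candidates
        ]
    )
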