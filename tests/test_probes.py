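"""Variant-to-probe filter cascade tests."""
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecotype.errors import ConfigError, DataIntegrityError, FormatError
from ecotype.probes import (
    ProbeDesignConfig,
    annotation_filter,
    build_probe_candidates,
    design_panel,
    designability_filter,
    filter_variant_calls,
    parse_probe_sequence,
    render_probe_sequence,
    shared_polymorphism_filter,
    spacing_filter,
)
from ecotype.simulate import gen_variant_report


def _variant(contig="Contig1", pos=100, ref="A", var="G", cov=60, vf=30.0,
             sq=35, nq=25, source="g1", nonspec=False):
    return {
        "contig_id": contig, "position": pos, "ref_allele": ref,
        "var_allele": var, "coverage": cov, "variant_frequency": vf,
        "snp_quality": sq, "neighbourhood_quality": nq,
        "source_genotype": source, "nonspecific_flag": nonspec,
    }


def test_variant_thresholds_inclusive_boundaries():
    """49x coverage fails with reason 'coverage'; the exact thresholds
    (50/30/20/25%) all pass."""
    df = pd.DataFrame([
        _variant(pos=100, cov=49),
        _variant(pos=200, cov=50, sq=30, nq=20, vf=25.0),
        _variant(pos=300, sq=29),
        _variant(pos=400, nq=19),
        _variant(pos=500, vf=24.9),
        _variant(pos=600, nonspec=True),
    ])
    survivors, reasons, counts = filter_variant_calls(df)
    assert survivors["position"].tolist() == [200]
    assert reasons.tolist() == [
        "coverage", "snp_quality", "neighbourhood_quality",
        "variant_frequency", "nonspecific",
    ]
    assert counts == {k: 1 for k in counts}


def test_variant_table_missing_column_named():
    with pytest.raises(FormatError, match="coverage"):
        filter_variant_calls(pd.DataFrame([{"contig_id": "c", "position": 1}]))


def test_shared_polymorphism_source_counting():
    df = pd.DataFrame([
        _variant(pos=100, source="g1"),
        _variant(pos=200, source="g1"),
        _variant(pos=200, source="g2"),
        _variant(pos=300, source="g1", ref="A", var="G"),
        _variant(pos=300, source="g2", ref="G", var="A"),  # same pair, swapped
    ])
    out = shared_polymorphism_filter(df)
    assert out["position"].tolist() == [200, 300]
    assert out.loc[out["position"] == 200, "sources"].iloc[0] == ["g1", "g2"]


def test_shared_polymorphism_matches_dictionary_oracle(rng):
    """Brute-force dictionary counting over a random 200-observation
    fixture gives the same survivor key set."""
    rows = [
        _variant(
            contig=f"Contig{rng.integers(1, 6)}",
            pos=int(rng.integers(1, 40)) * 10,
            source=f"g{rng.integers(1, 6)}",
        )
        for _ in range(200)
    ]
    df = pd.DataFrame(rows)
    out = shared_polymorphism_filter(df)
    counter: dict = {}
    for r in rows:
        key = (r["contig_id"], r["position"])
        counter.setdefault(key, set()).add(r["source_genotype"])
    oracle = {k for k, v in counter.items() if len(v) >= 2}
    got = set(zip(out["contig_id"], out["position"]))
    assert got == oracle


def test_annotation_filter_frameshift_and_blacklist():
    blast = pd.DataFrame([
        {"qseqid": "c1", "sseqid": "sp1", "description": "kinase"},
        {"qseqid": "c1", "sseqid": "sp1", "description": "kinase"},
        {"qseqid": "c2", "sseqid": "sp2",
         "description": "putative chloroplast protein"},
        {"qseqid": "c3", "sseqid": "sp3", "description": "Polyprotein X"},
        {"qseqid": "c4", "sseqid": "sp4", "description": "laccase"},
    ])
    allowed, reasons = annotation_filter(blast, ["c1", "c2", "c3", "c4", "c5"])
    assert allowed == {"c4", "c5"}  # unannotated c5 is retained
    assert reasons == {"c1": "frameshift", "c2": "blacklist", "c3": "blacklist"}


def test_spacing_removes_both_members_of_close_pairs():
    """{100, 130, 300}: the 30 bp pair removes both, leaving {300};
    {100, 150} survive (distance exactly 50 is not 'within 50 bp')."""
    df = pd.DataFrame([
        _variant(pos=100), _variant(pos=130), _variant(pos=300),
        _variant(contig="Contig2", pos=100), _variant(contig="Contig2", pos=150),
        _variant(contig="Contig3", pos=77),
    ])
    out = spacing_filter(df)
    got = set(zip(out["contig_id"], out["position"]))
    assert got == {("Contig1", 300), ("Contig2", 100), ("Contig2", 150),
                   ("Contig3", 77)}


@settings(max_examples=60, deadline=None)
@given(
    st.lists(st.integers(min_value=1, max_value=600), min_size=0, max_size=25)
)
def test_spacing_filter_equals_pairwise_oracle(positions):
    """The vectorized spacing filter equals the O(n^2) pairwise oracle."""
    positions = list(dict.fromkeys(positions))
    df = pd.DataFrame([_variant(pos=p) for p in positions])
    if len(df) == 0:
        df = pd.DataFrame(columns=["contig_id", "position"])
    out = spacing_filter(df, min_gap=50)
    surviving = set(out["position"]) if len(out) else set()
    oracle = {
        p for p in positions
        if all(q == p or abs(q - p) >= 50 for q in positions)
    }
    assert surviving == oracle


def test_flank_extraction_coordinates(rng):
    """SNP at position 30 of a 120 bp contig is rejected (left flank 29);
    at 61 of 200 both flanks are 60; at 55 of 120 flanks are (54, 60)."""
    bases = np.array(list("ACGT"))
    seqs = {
        "Contig1": "".join(rng.choice(bases, 120)),
        "Contig2": "".join(rng.choice(bases, 200)),
    }

    def at(contig, pos):
        ref = seqs[contig][pos - 1]
        var = "A" if ref != "A" else "G"
        return _variant(contig=contig, pos=pos, ref=ref, var=var)

    df = pd.DataFrame([at("Contig1", 30), at("Contig2", 61),
                       at("Contig1", 55)])
    kept, rejected = build_probe_candidates(seqs, df)
    names = {c.marker_name: c for c in kept}
    assert [c.marker_name for c in rejected] == ["Contig1_30"]
    c61 = names["Contig2_61"]
    assert (len(c61.left_flank), len(c61.right_flank)) == (60, 60)
    c55 = names["Contig1_55"]
    assert (len(c55.left_flank), len(c55.right_flank)) == (54, 60)
    # string-slicing oracle: flanks are literal substrings around the SNP
    assert seqs["Contig1"][:54] == c55.left_flank
    assert seqs["Contig1"][55:115] == c55.right_flank


def test_flank_allele_contig_mismatch_raises():
    seqs = {"Contig1": "A" * 200}
    df = pd.DataFrame([_variant(pos=100, ref="C", var="G")])
    with pytest.raises(DataIntegrityError, match="Contig1_100"):
        build_probe_candidates(seqs, df)


def test_probe_text_round_trip(rng):
    bases = np.array(list("ACGT"))
    left = "".join(rng.choice(bases, 57))
    right = "".join(rng.choice(bases, 60))
    text = render_probe_sequence(left, ("C", "T"), right)
    l2, alleles, r2 = parse_probe_sequence(text)
    assert (l2, alleles, r2) == (left, ("C", "T"), right)


def test_designability_inclusive_at_threshold():
    seqs = {"Contig1": "ACGT" * 50}
    df = pd.DataFrame([
        _variant(pos=100, ref=seqs["Contig1"][99], var="T"
                 if seqs["Contig1"][99] != "T" else "A"),
        _variant(pos=140, ref=seqs["Contig1"][139], var="T"
                 if seqs["Contig1"][139] != "T" else "A"),
    ])
    cands, _ = build_probe_candidates(seqs, df)
    kept, removed = designability_filter(
        cands, {"Contig1_100": 0.6, "Contig1_140": 0.59}
    )
    assert [c.marker_name for c in kept] == ["Contig1_100"]
    assert [c.marker_name for c in removed] == ["Contig1_140"]
    with pytest.raises(ConfigError):
        designability_filter(cands, {"Contig1_100": 0.8})


@pytest.mark.parametrize("seed", [1, 7, 42])
def test_design_panel_round_trips_generator_truth(seed):
    """The full cascade on a generated variant report returns exactly the
    generator's expected survivor set, and the per-stage removals for the
    SNP-level stages match the truth's removal reasons."""
    rep = gen_variant_report(seed=seed)
    panel, cascade = design_panel(rep.variants, rep.contigs, rep.blast,
                                  rep.scores)
    assert sorted(c.marker_name for c in panel) == rep.truth.expected_survivors
    by_reason: dict = {}
    for reason in rep.truth.removal_reasons.values():
        by_reason[reason] = by_reason.get(reason, 0) + 1
    stage_removed = {name: n for name, n, _ in cascade.stages}
    for stage in ("annotation", "spacing", "flanking", "designability"):
        assert stage_removed.get(stage, 0) == by_reason.get(stage, 0)


def test_empty_variant_table_gives_empty_panel():
    rep = gen_variant_report(snp_density=0.0, seed=1)
    assert len(rep.variants) == 0
    panel, cascade = design_panel(rep.variants, rep.contigs, rep.blast, {})
    assert panel == []
    assert cascade.n_input == 0
    assert all(removed == 0 for _, removed, _ in cascade.stages)


def test_threshold_tightening_is_monotone():
    """Tightening any threshold never enlarges the survivor set."""
    rep = gen_variant_report(seed=3)
    base_panel, _ = design_panel(rep.variants, rep.contigs, rep.blast,
                                 rep.scores)
    base = {c.marker_name for c in base_panel}
    for override in (
        {"min_coverage": 80}, {"min_snp_quality": 38},
        {"min_variant_freq": 35}, {"min_gap": 120},
        {"min_designability": 0.8}, {"min_flank": 58},
    ):
        cfg = ProbeDesignConfig(**override)
        panel, _ = design_panel(rep.variants, rep.contigs, rep.blast,
                                rep.scores, cfg)
        assert {c.marker_name for c in panel} <= base


def test_multiply_failing_markers_absent_under_any_stage_order():
    """A SNP violating two or more criteria stays removed however the
    cascade stages are ordered (checked over all 4! orders of the
    SNP-level stages on a small crafted fixture)."""
    seqs = {"ContigA": "ACGT" * 60, "ContigB": "ACGT" * 60}

    def ref(c, p):
        return seqs[c][p - 1]

    rows = []
    # good SNP: two sources, well spaced, central, high score
    for s in ("g1", "g2"):
        rows.append(_variant("ContigA", 120, ref("ContigA", 120), "T"
                             if ref("ContigA", 120) != "T" else "A", source=s))
    # doubly bad: close pair AND low designability
    for p in (100, 130):
        for s in ("g1", "g2"):
            rows.append(_variant("ContigB", p, ref("ContigB", p), "T"
                                 if ref("ContigB", p) != "T" else "A",
                                 source=s))
    df = pd.DataFrame(rows)
    scores = {"ContigA_120": 0.9, "ContigB_100": 0.3, "ContigB_130": 0.9}
    blast = pd.DataFrame(
        [{"qseqid": "ContigA", "sseqid": "x", "description": "kinase"}]
    )

    def run_order(order):
        current, _, _ = filter_variant_calls(df)
        current = shared_polymorphism_filter(current)
        for stage in order:
            if stage == "annotation":
                allowed, _ = annotation_filter(
                    blast, list(dict.fromkeys(current["contig_id"]))
                )
                current = current[current["contig_id"].isin(allowed)]
            elif stage == "spacing":
                current = spacing_filter(current)
            elif stage == "flanking":
                cands, _ = build_probe_candidates(seqs, current)
                keep = {(c.contig_id, c.position) for c in cands}
                current = current[
                    [tuple(t) in keep
                     for t in zip(current["contig_id"], current["position"])]
                ]
            elif stage == "designability":
                names = [f"{c}_{p}" for c, p
                         in zip(current["contig_id"], current["position"])]
                ok = [scores.get(n, 0.0) >= 0.6 for n in names]
                current = current[ok]
        return {f"{c}_{p}" for c, p
                in zip(current["contig_id"], current["position"])}

    for order in itertools.permutations(
        ("annotation", "spacing", "flanking", "designability")
    ):
        result = run_order(order)
        assert "ContigB_100" not in result  # fails spacing AND designability
        assert "ContigA_120" in result
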