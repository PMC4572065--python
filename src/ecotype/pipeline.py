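"""End-to-end orchestration: simulate -> design -> qc -> diversity -> amova.

Each stage reads either the configured input paths or the previous
stage's in-memory outputs, writes its artifacts under the output
directory, and contributes counts to a manifest sufficient to re-run the
analysis bit-identically (all randomness flows from the single seed).
"""
from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import amova as amova_mod
from . import diversity as div
from . import io as eio
from . import probes, qc, simulate
from .config import RunConfig, validate_config
from .errors import ConfigError
from .matrix import GenotypeMatrix

logger = logging.getLogger("ecotype")

#: distinct exit codes per failing stage
STAGE_EXIT_CODES = {
    "config": 2,
    "simulate": 10,
    "design": 11,
    "qc": 12,
    "diversity": 13,
    "amova": 14,
}


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.exit_code = STAGE_EXIT_CODES.get(stage, 1)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run the selected stages; return the artifact manifest."""
    violations = validate_config(config)
    if violations:
        raise StageFailure(
            "config", ConfigError("; ".join(str(v) for v in violations))
        )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    manifest: dict = {"seed": config.seed, "stages": {}, "files": {}}

    matrix = info = None
    variants = contigs = blast = scores = None

    def record(path: Path) -> None:
        manifest["files"][str(path.relative_to(out))] = _sha256(path)

    if "simulate" in config.stages:
        try:
            params = simulate.SimulationParams(
                seed=int(rng.integers(2**31 - 1)), **config.simulation
            )
            matrix, info, truth = simulate.gen_hierarchical_genotypes(params)
            matrix.to_tsv(out / "genotypes.tsv")
            eio.write_accession_table(info, out / "accessions.csv")
            eio.write_json(
                {
                    "p0": truth.p0,
                    "clinal_axis": {
                        k: v for k, v in truth.clinal_axis.items() if v
                    },
                },
                out / "truth.json",
            )
            report = simulate.gen_variant_report(
                seed=int(rng.integers(2**31 - 1))
            )
            variants, contigs, blast, scores = (
                report.variants, report.contigs, report.blast, report.scores,
            )
            eio.write_contigs(contigs, out / "contigs.fasta")
            eio.write_variant_table(variants, out / "variants.tsv")
            blast.to_csv(out / "blast.tsv", sep="\t", index=False)
            for name in ("genotypes.tsv", "accessions.csv", "truth.json",
                         "contigs.fasta", "variants.tsv", "blast.tsv"):
                record(out / name)
            manifest["stages"]["simulate"] = {
                "n_samples": matrix.n_samples,
                "n_markers": matrix.n_markers,
                "n_variant_rows": len(variants),
            }
        except StageFailure:
            raise
        except Exception as exc:  # noqa: BLE001 - named-stage abort
            raise StageFailure("simulate", exc) from exc

    if "design" in config.stages:
        try:
            if variants is None:
                variants = eio.read_variant_table(config.variants)
                contigs = eio.read_contigs(config.contigs)
                blast = eio.read_blast_table(config.blast)
            panel, cascade = probes.design_panel(
                variants, contigs, blast, scores, config.probe
            )
            probes.panel_manifest(panel).to_csv(
                out / "probe_manifest.csv", index=False
            )
            eio.write_json(cascade.to_dict(), out / "design_cascade.json")
            record(out / "probe_manifest.csv")
            record(out / "design_cascade.json")
            manifest["stages"]["design"] = cascade.to_dict()
        except Exception as exc:
            raise StageFailure("design", exc) from exc

    if "qc" in config.stages:
        try:
            if matrix is None:
                matrix = GenotypeMatrix.from_tsv(config.genotypes)
            cluster_stats = (
                pd.read_csv(config.cluster_stats, sep="\t")
                if config.cluster_stats
                else None
            )
            matrix, report = qc.run_qc(
                matrix, cluster_stats=cluster_stats, thresholds=config.qc
            )
            matrix.to_tsv(out / "genotypes_filtered.tsv")
            eio.write_json(report.to_dict(), out / "qc_report.json")
            record(out / "genotypes_filtered.tsv")
            record(out / "qc_report.json")
            manifest["stages"]["qc"] = {
                "counts": report.counts(), "n_survivors": len(report.survivors)
            }
        except Exception as exc:
            raise StageFailure("qc", exc) from exc

    if "diversity" in config.stages or "amova" in config.stages:
        if matrix is None:
            matrix = GenotypeMatrix.from_tsv(config.genotypes)
        if info is None:
            info = eio.read_accession_table(config.accessions)
        encoded = div.encode_genotypes(matrix)

    if "diversity" in config.stages:
        try:
            freqs = div.accession_allele_frequencies(encoded, matrix.accessions)
            freqs.to_csv(out / "allele_frequencies.csv")
            result = div.pca(freqs, n_components=config.n_components)
            result.scores.to_csv(out / "pca_scores.csv")
            result.loadings.to_csv(out / "pca_loadings.csv")
            correlations = {}
            for comp, coord in ((1, "longitude"), (2, "latitude"),
                                (2, "altitude")):
                try:
                    c = div.correlate_pc_with_geography(result, info, comp, coord)
                    correlations[f"PC{comp}_{coord}"] = {
                        "r": c.r, "r_squared": c.r_squared,
                        "p_value": c.p_value, "n": c.n,
                    }
                except Exception as exc:  # degenerate coordinate: report, go on
                    correlations[f"PC{comp}_{coord}"] = {"error": str(exc)}
            eio.write_json(correlations, out / "geo_correlations.json")
            div.top_loading_markers(result, 1, min(config.top_k, matrix.n_markers)).to_csv(
                out / "top_loadings_pc1.csv"
            )
            for name in ("allele_frequencies.csv", "pca_scores.csv",
                         "pca_loadings.csv", "geo_correlations.json",
                         "top_loadings_pc1.csv"):
                record(out / name)
            manifest["stages"]["diversity"] = {
                "explained_variance_ratio":
                    result.explained_variance_ratio[:5].tolist(),
                "correlations": correlations,
            }
        except Exception as exc:
            raise StageFailure("diversity", exc) from exc

    if "amova" in config.stages:
        try:
            regions = info["Region"].reindex(matrix.accessions).to_numpy()
            result = amova_mod.amova_nested(
                encoded.to_numpy(),
                matrix.accessions.to_numpy(),
                regions,
                n_permutations=config.n_permutations,
                seed=int(rng.integers(2**31 - 1)),
            )
            result.to_frame().to_csv(out / "amova_table.csv", index=False)
            eio.write_json(
                {"phi": result.phi, "p_values": result.p_values,
                 "n_permutations": result.n_permutations},
                out / "amova_phi.json",
            )
            record(out / "amova_table.csv")
            record(out / "amova_phi.json")
            manifest["stages"]["amova"] = {
                "phi": result.phi, "p_values": result.p_values
            }
        except Exception as exc:
            raise StageFailure("amova", exc) from exc

    eio.write_json(manifest, out / "manifest.json")
    return manifest
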