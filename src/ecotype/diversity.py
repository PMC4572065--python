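"""Allele-frequency encoding, PCA and genetic-geographic correlation.

Array calls are converted to allele-specific presence values: for the A
allele of each marker AA individuals are coded 1, AB 0.5 and BB or missing
0, and vice versa for the B allele (missing data are therefore 0 for both
columns and are not imputed).  Accession allele frequencies are the means
of these values over all individuals of the accession.  A principal
component analysis of the accession x (2 x markers) frequency matrix then
summarises population structure, and Pearson correlation of component
scores with collection-site longitude, latitude or altitude quantifies
isolation by distance.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DegenerateDataError, FormatError
from .matrix import GenotypeMatrix

__all__ = [
    "encode_genotypes",
    "accession_allele_frequencies",
    "pca",
    "PcaResult",
    "CorrelationResult",
    "correlate_pc_with_geography",
    "top_loading_markers",
]

_A_VALUE = np.array([0.0, 0.5, 1.0, 0.0])  # index = dosage code 0,1,2; 3 = NC


def encode_genotypes(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Samples x (2 x markers) allele-presence values in {0, 0.5, 1}.

    Columns are interleaved ``<marker>_A``, ``<marker>_B``; for any
    non-missing call the two values sum to 1, for NC both are 0.
    """
    codes = matrix.codes().astype(np.int64)
    idx = np.where(codes < 0, 3, codes)
    a_vals = _A_VALUE[idx]
    b_vals = np.where(codes < 0, 0.0, 1.0 - a_vals)
    out = np.empty((matrix.n_samples, 2 * matrix.n_markers))
    out[:, 0::2] = a_vals
    out[:, 1::2] = b_vals
    cols: list[str] = []
    for m in matrix.marker_ids:
        cols.extend((f"{m}_A", f"{m}_B"))
    return pd.DataFrame(out, index=matrix.sample_ids, columns=cols)


def accession_allele_frequencies(
    encoded: pd.DataFrame,
    accessions: pd.Series,
    *,
    corrected: bool = False,
) -> pd.DataFrame:
    """Accessions x (2 x markers) relative allele frequencies.

    Default denominator is the number of individuals in the accession,
    missing calls included, so freqA + freqB < 1 where data are missing.
    ``corrected=True`` divides by the non-missing count instead.
    """
    acc = accessions.reindex(encoded.index)
    if acc.isna().any():
        raise ConfigError("every sample needs an accession assignment")
    if not len(encoded):
        raise ConfigError("empty encoded matrix")
    sums = encoded.groupby(acc, sort=True).sum()
    counts = encoded.groupby(acc, sort=True).size()
    if not corrected:
        return sums.div(counts, axis=0)
    # non-missing individuals per (accession, marker): A + B columns sum to 1
    a = encoded.to_numpy()[:, 0::2]
    b = encoded.to_numpy()[:, 1::2]
    present = pd.DataFrame(
        (a + b) > 0, index=encoded.index, columns=encoded.columns[0::2]
    )
    n_present = present.groupby(acc, sort=True).sum().to_numpy()
    denom = np.repeat(n_present, 2, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(denom > 0, sums.to_numpy() / denom, 0.0)
    return pd.DataFrame(vals, index=sums.index, columns=sums.columns)


@dataclass
class PcaResult:
    """Principal components of the frequency matrix (centered, unscaled)."""

    scores: pd.DataFrame  # accessions x components, columns PC1..PCk
    loadings: pd.DataFrame  # frequency columns x components
    explained_variance_ratio: np.ndarray
    mean_: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def pca(freqs: pd.DataFrame, n_components: int | None = None) -> PcaResult:
    """PCA of the accession frequency matrix via SVD of the centered data.

    Columns are centered but not variance-scaled.  The sign of each
    component is fixed so that its largest-|loading| entry is positive,
    making results deterministic.
    """
    if freqs.shape[0] < 2:
        raise ConfigError("PCA needs at least two accessions")
    x = freqs.to_numpy(dtype=float)
    mean = x.mean(axis=0)
    xc = x - mean
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    rank = min(xc.shape[0] - 1, xc.shape[1])
    if n_components is None:
        n_components = rank
    n_components = min(n_components, rank)
    u, s, vt = u[:, :n_components], s[:n_components], vt[:n_components]
    # deterministic sign: largest-|loading| entry positive per component
    for k in range(n_components):
        j = int(np.argmax(np.abs(vt[k])))
        if vt[k, j] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0
    scores = u * s
    total_var = (xc**2).sum()
    explained = (s**2) / total_var if total_var > 0 else np.zeros(n_components)
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=freqs.index, columns=comp_names),
        loadings=pd.DataFrame(vt.T, index=freqs.columns, columns=comp_names),
        explained_variance_ratio=explained,
        mean_=mean,
    )


@dataclass
class CorrelationResult:
    r: float
    r_squared: float
    p_value: float
    n: int


def correlate_pc_with_geography(
    pca_result: PcaResult,
    accession_info: pd.DataFrame,
    component: int = 1,
    coordinate: str = "longitude",
) -> CorrelationResult:
    """Pearson correlation of a PC score with a geographic coordinate.

    ``accession_info`` must be indexed by accession id with columns
    ``Longitude``, ``Latitude`` and optionally ``Altitude``; rows with a
    missing coordinate are dropped pairwise.  P is two-sided from
    t = r sqrt((n-2)/(1-r^2)).
    """
    colmap = {"longitude": "Longitude", "latitude": "Latitude",
              "altitude": "Altitude"}
    if coordinate not in colmap:
        raise ConfigError(f"unknown coordinate {coordinate!r}")
    name = f"PC{component}"
    if name not in pca_result.scores.columns:
        raise ConfigError(f"component {name} not available")
    col = colmap[coordinate]
    if col not in accession_info.columns:
        raise FormatError(f"accession table lacks column {col!r}")
    coords = pd.to_numeric(
        accession_info[col].reindex(pca_result.scores.index), errors="coerce"
    )
    mask = coords.notna()
    if mask.sum() < 3:
        raise DegenerateDataError("need at least 3 accessions with coordinates")
    x = pca_result.scores.loc[mask, name].to_numpy()
    y = coords[mask].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateDataError("zero variance in scores or coordinates")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    return CorrelationResult(
        r=r, r_squared=r * r, p_value=float(res.pvalue), n=int(mask.sum())
    )


def top_loading_markers(
    pca_result: PcaResult,
    component: int = 1,
    k: int = 50,
    annotations: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Top-k markers ranked by absolute loading on one component.

    The A/B twin columns of each marker collapse to a single entry
    carrying the larger |loading|; ties break on marker name.  An optional
    annotation table (indexed by marker) is joined onto the result.
    """
    name = f"PC{component}"
    if name not in pca_result.loadings.columns:
        raise ConfigError(f"component {name} not available")
    load = pca_result.loadings[name]
    base = load.index.str.replace(r"_(A|B)$", "", regex=True)
    df = pd.DataFrame({"marker": base, "loading": load.to_numpy()})
    df["abs_loading"] = df["loading"].abs()
    best = (
        df.sort_values(["abs_loading", "marker"], ascending=[False, True])
        .drop_duplicates("marker", keep="first")
    )
    if k > best.shape[0]:
        raise ConfigError("k exceeds number of markers")
    out = (
        best.sort_values(["abs_loading", "marker"], ascending=[False, True])
        .head(k)
        .set_index("marker")[["loading", "abs_loading"]]
    )
    if annotations is not None:
        out = out.join(annotations, how="left")
    return out
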