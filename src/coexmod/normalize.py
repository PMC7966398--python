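"""TMM normalization and conversion to the correlation scale.

TMM (trimmed mean of M-values) estimates a relative scaling factor per
sample from precision-weighted, doubly trimmed log2 expression ratios
against a reference sample, then rescales factors to geometric mean 1.
The defaults follow the method's canonical parameterization: 30% trim on
M-values, 5% trim on A-values, inverse approximate-binomial-variance
weights, and reference selection by the sample whose 75th-percentile
library-scaled proportion is closest to the across-sample mean.

Correlations downstream run by default on log2(CPM + 1) where CPM uses
TMM-adjusted library sizes; raw (unlogged) CPM is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from coexmod.errors import ConfigurationError, DataError
from coexmod.simulate import TissueMatrix


@dataclass(frozen=True)
class TmmParams:
    trim_m: float = 0.30       # fraction trimmed from each tail of M-values
    trim_a: float = 0.05       # fraction trimmed from each tail of A-values
    reference_rule: str = "auto"   # "auto" (75th-percentile rule) or "fixed"
    fixed_reference: str | None = None

    def validate(self) -> None:
        if not 0.0 <= self.trim_m < 0.5:
            raise ConfigurationError("trim_m must lie in [0, 0.5)")
        if not 0.0 <= self.trim_a < 0.5:
            raise ConfigurationError("trim_a must lie in [0, 0.5)")
        if self.reference_rule not in ("auto", "fixed"):
            raise ConfigurationError("reference_rule must be 'auto' or 'fixed'")
        if self.reference_rule == "fixed" and self.fixed_reference is None:
            raise ConfigurationError("fixed_reference required when reference_rule='fixed'")


@dataclass
class NormalizedMatrix:
    """Expression values on the correlation scale plus the TMM factors used."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray            # genes x samples, finite reals
    factors: np.ndarray           # per-sample positive reals, geometric mean 1
    tissue_name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.factors = np.asarray(self.factors, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise DataError("normalized values must all be finite")
        if np.any(self.factors <= 0):
            raise DataError("TMM factors must be positive")
        if abs(np.exp(np.mean(np.log(self.factors))) - 1.0) > 1e-9:
            raise DataError("TMM factors must have geometric mean 1")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_vector(self, gene_id: str) -> np.ndarray:
        try:
            i = self.gene_ids.index(gene_id)
        except ValueError:
            raise DataError(f"gene {gene_id!r} not present") from None
        return self.values[i]


def _pair_factor(
    obs: np.ndarray, ref: np.ndarray, lib_obs: float, lib_ref: float,
    params: TmmParams, sample_id: str,
) -> float:
    """TMM factor of one sample against the reference sample."""
    mask = (obs > 0) & (ref > 0)
    if not np.any(mask):
        raise DataError(
            f"sample {sample_id!r} shares no co-expressed genes with the reference"
        )
    o, r = obs[mask].astype(float), ref[mask].astype(float)
    po, pr = o / lib_obs, r / lib_ref
    log_r = np.log2(po / pr)                       # M
    abs_e = (np.log2(po) + np.log2(pr)) / 2.0      # A
    # approximate binomial variance of M (delta method)
    v = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)

    if np.max(np.abs(log_r)) < 1e-6:
        return 1.0

    n = log_r.size
    lo_m = int(np.floor(n * params.trim_m)) + 1
    hi_m = n + 1 - lo_m
    lo_a = int(np.floor(n * params.trim_a)) + 1
    hi_a = n + 1 - lo_a
    rank_m = rankdata(log_r)
    rank_a = rankdata(abs_e)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not np.any(keep):
        return 1.0
    f = np.sum(log_r[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def _pick_reference(counts: np.ndarray, lib: np.ndarray) -> int:
    """Sample whose 75th-percentile proportion is closest to the mean."""
    f75 = np.array([
        np.quantile(counts[:, j], 0.75) / lib[j] for j in range(counts.shape[1])
    ])
    return int(np.argmin(np.abs(f75 - f75.mean())))


def tmm_factors(counts: TissueMatrix, params: TmmParams | None = None) -> np.ndarray:
    """Per-sample TMM scaling factors, rescaled to geometric mean 1.

    All-zero gene rows are tolerated (they drop out of every pairwise
    comparison); a sample with no gene co-expressed with the reference is
    an error naming the sample.
    """
    params = params or TmmParams()
    params.validate()
    X = np.asarray(counts.counts, dtype=float)
    if X.shape[1] < 2:
        raise DataError("TMM needs at least 2 samples")
    lib = X.sum(axis=0)
    if np.any(lib == 0):
        j = int(np.where(lib == 0)[0][0])
        raise DataError(f"sample {counts.sample_ids[j]!r} has zero library size")

    if params.reference_rule == "auto":
        ref_j = _pick_reference(X, lib)
    else:
        if params.fixed_reference not in counts.sample_ids:
            raise ConfigurationError(
                f"fixed_reference {params.fixed_reference!r} not among samples"
            )
        ref_j = counts.sample_ids.index(params.fixed_reference)

    factors = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        if j == ref_j:
            factors[j] = 1.0
        else:
            factors[j] = _pair_factor(
                X[:, j], X[:, ref_j], lib[j], lib[ref_j], params,
                counts.sample_ids[j],
            )
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def to_log_cpm(counts: TissueMatrix, factors: np.ndarray) -> NormalizedMatrix:
    """log2(counts-per-million + 1) on TMM-adjusted library sizes.

    value(g, s) = log2( count(g,s) / (library_size(s) * factor(s)) * 1e6 + 1 ).
    """
    factors = np.asarray(factors, dtype=float)
    X = np.asarray(counts.counts, dtype=float)
    if factors.shape != (X.shape[1],):
        raise DataError("factors length must equal the number of samples")
    if np.any(factors <= 0):
        raise DataError("factors must be positive")
    lib = X.sum(axis=0)
    if np.any(lib == 0):
        j = int(np.where(lib == 0)[0][0])
        raise DataError(f"sample {counts.sample_ids[j]!r} has zero library size")
    values = np.log2(X / (lib * factors)[None, :] * 1e6 + 1.0)
    return NormalizedMatrix(
        gene_ids=list(counts.gene_ids),
        sample_ids=list(counts.sample_ids),
        values=values,
        factors=factors,
        tissue_name=counts.tissue_name,
    )


def to_cpm(counts: TissueMatrix, factors: np.ndarray) -> NormalizedMatrix:
    """Unlogged counts-per-million on TMM-adjusted library sizes."""
    factors = np.asarray(factors, dtype=float)
    X = np.asarray(counts.counts, dtype=float)
    if factors.shape != (X.shape[1],):
        raise DataError("factors length must equal the number of samples")
    if np.any(factors <= 0):
        raise DataError("factors must be positive")
    lib = X.sum(axis=0)
    if np.any(lib == 0):
        j = int(np.where(lib == 0)[0][0])
        raise DataError(f"sample {counts.sample_ids[j]!r} has zero library size")
    values = X / (lib * factors)[None, :] * 1e6
    return NormalizedMatrix(
        gene_ids=list(counts.gene_ids),
        sample_ids=list(counts.sample_ids),
        values=values,
        factors=factors,
        tissue_name=counts.tissue_name,
    )


def normalize_tissue(
    counts: TissueMatrix, params: TmmParams | None = None, scale: str = "log_cpm"
) -> NormalizedMatrix:
    """TMM factors followed by conversion to the requested scale."""
    factors = tmm_factors(counts, params)
    if scale == "log_cpm":
        return to_log_cpm(counts, factors)
    if scale == "cpm":
        return to_cpm(counts, factors)
    raise ConfigurationError(f"unknown correlation scale {scale!r}")


def read_gct(path: str | Path, tissue_name: str | None = None) -> TissueMatrix:
    """Read a GCT 1.2 matrix (``#1.2`` header + dimensions line)."""
    path = Path(path)
    with path.open() as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise DataError(f"not a GCT 1.2 file (header {version!r})")
        dims = fh.readline().split()
        if len(dims) < 2:
            raise DataError("malformed GCT dimensions line")
        n_genes, n_samples = int(dims[0]), int(dims[1])
        df = pd.read_csv(fh, sep="\t", index_col=0)
    sample_cols = [c for c in df.columns if c.lower() != "description"]
    if df.shape[0] != n_genes or len(sample_cols) != n_samples:
        raise DataError(
            f"GCT dimensions ({n_genes}, {n_samples}) do not match table "
            f"({df.shape[0]}, {len(sample_cols)})"
        )
    return TissueMatrix(
        tissue_name=tissue_name if tissue_name is not None else path.stem,
        gene_ids=[str(g) for g in df.index],
        sample_ids=[str(c) for c in sample_cols],
        counts=df[sample_cols].to_numpy(),
    )
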