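"""Seed-versus-all correlation sweeps and the cross-tissue R_sum ranking.

Within each tissue the seed transcript is correlated (Pearson) against
every transcript; per-gene coefficients are then summed across tissues
into R_sum, which is bounded by the tissue count T and equals T exactly
for the seed itself. Genes are ranked by descending R_sum and the top-k
extreme is the seed's co-expression module. Individual pairs of interest
are confirmed with Spearman's rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from coexmod.errors import ConfigurationError, DataError
from coexmod.normalize import NormalizedMatrix


@dataclass
class CorrelationProfile:
    """Per-tissue Pearson correlation of every gene against the seed.

    ``r`` is indexed by gene id; zero-variance genes carry NaN (undefined).
    """

    tissue_name: str
    seed_gene_id: str
    r: pd.Series
    n_samples: int


@dataclass
class RsumRanking:
    seed_gene_id: str
    tissues_used: list[str]
    rsum: pd.Series               # gene id -> summed correlation
    rank: pd.Series               # gene id -> 1-based rank, 1 = highest rsum
    per_tissue: list[CorrelationProfile]
    n_dropped_genes: int = 0      # genes outside the cross-tissue intersection

    @property
    def n_genes(self) -> int:
        return int(self.rsum.size)

    def to_tsv(self, path) -> None:
        """gene_id, rsum, rank, then one r column per tissue."""
        df = pd.DataFrame({"rsum": self.rsum, "rank": self.rank})
        for prof in self.per_tissue:
            df[f"r_{prof.tissue_name}"] = prof.r.reindex(df.index)
        df.index.name = "gene_id"
        df.sort_values("rank").to_csv(path, sep="\t")


@dataclass
class CoexpressionModule:
    """The top-k genes of a descending R_sum ranking."""

    seed_gene_id: str
    k: int
    member_gene_ids: list[str]    # in rank order
    include_seed: bool

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in set(self.member_gene_ids)

    def to_json_dict(self) -> dict:
        return {
            "seed_gene_id": self.seed_gene_id,
            "k": self.k,
            "include_seed": self.include_seed,
            "member_gene_ids": list(self.member_gene_ids),
        }


@dataclass
class SpearmanResult:
    gene_a: str
    gene_b: str
    tissue_name: str
    rho: float
    p_value: float
    n: int
    undefined: bool = False       # zero rank variance in either gene


def pearson_profile(norm: NormalizedMatrix, seed: str) -> CorrelationProfile:
    """Pearson correlation of the seed against all genes in one tissue.

    Vectorized over genes; zero-variance genes are flagged undefined (NaN)
    and the seed's own entry is exactly 1.
    """
    if norm.n_samples < 3:
        raise DataError("Pearson profile needs at least 3 samples")
    if seed not in norm.gene_ids:
        raise DataError(f"seed gene {seed!r} not present in {norm.tissue_name!r}")
    X = norm.values
    s = norm.gene_vector(seed)
    s_c = s - s.mean()
    s_norm = np.sqrt(np.sum(s_c**2))
    if s_norm == 0:
        raise DataError(
            f"seed gene {seed!r} has zero variance in tissue {norm.tissue_name!r}"
        )
    X_c = X - X.mean(axis=1, keepdims=True)
    g_norm = np.sqrt(np.sum(X_c**2, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (X_c @ s_c) / (g_norm * s_norm)
    r[g_norm == 0] = np.nan
    r = np.clip(r, -1.0, 1.0)
    series = pd.Series(r, index=pd.Index(norm.gene_ids, name="gene_id"))
    series[seed] = 1.0
    return CorrelationProfile(
        tissue_name=norm.tissue_name,
        seed_gene_id=seed,
        r=series,
        n_samples=norm.n_samples,
    )


def rsum_ranking(
    profiles: list[CorrelationProfile], policy: str = "zero"
) -> RsumRanking:
    """Sum per-tissue correlations and rank genes by descending R_sum.

    Gene universe is the intersection across profiles (order of the first
    profile); the number of dropped genes is recorded. Undefined (NaN)
    correlations contribute 0 under the default ``zero`` policy; the
    ``drop-gene`` policy removes genes undefined in any tissue. Ties are
    broken by lexicographic gene id so ranks are reproducible.
    """
    if not profiles:
        raise DataError("rsum_ranking needs at least one correlation profile")
    seeds = {p.seed_gene_id for p in profiles}
    if len(seeds) != 1:
        raise DataError(f"profiles disagree on the seed gene: {sorted(seeds)}")
    seed = profiles[0].seed_gene_id
    if policy not in ("zero", "drop-gene"):
        raise ConfigurationError(f"unknown undefined-handling policy {policy!r}")

    common = set(profiles[0].r.index)
    for p in profiles[1:]:
        common &= set(p.r.index)
    universe = [g for g in profiles[0].r.index if g in common]
    n_dropped = len(set().union(*(set(p.r.index) for p in profiles))) - len(universe)
    if seed not in common:
        raise DataError(f"seed gene {seed!r} absent from the common gene universe")

    table = pd.DataFrame({p.tissue_name: p.r.reindex(universe) for p in profiles})
    if policy == "drop-gene":
        defined = table.notna().all(axis=1)
        defined[seed] = True
        table = table[defined]
        universe = list(table.index)
    rsum = table.fillna(0.0).sum(axis=1)

    order = sorted(universe, key=lambda g: (-rsum[g], g))
    rank = pd.Series(np.arange(1, len(order) + 1), index=order).reindex(universe)
    return RsumRanking(
        seed_gene_id=seed,
        tissues_used=[p.tissue_name for p in profiles],
        rsum=rsum,
        rank=rank.astype(int),
        per_tissue=list(profiles),
        n_dropped_genes=int(n_dropped),
    )


def extract_extreme(
    ranking: RsumRanking, k: int, include_seed: bool = False
) -> CoexpressionModule:
    """The k top-ranked genes; the seed itself is excluded by default."""
    n = ranking.n_genes
    if not 1 <= k <= n:
        raise ConfigurationError(f"k={k} out of range 1..{n}")
    ordered = list(ranking.rank.sort_values().index)
    if not include_seed:
        ordered = [g for g in ordered if g != ranking.seed_gene_id]
        if k > len(ordered):
            raise ConfigurationError(f"k={k} exceeds the {len(ordered)} non-seed genes")
    return CoexpressionModule(
        seed_gene_id=ranking.seed_gene_id,
        k=k,
        member_gene_ids=ordered[:k],
        include_seed=include_seed,
    )


def spearman_confirm(
    norm: NormalizedMatrix, gene_a: str, gene_b: str
) -> SpearmanResult:
    """Spearman rank correlation of one gene pair in one tissue.

    rho is Pearson on mid-ranks (average ranks for ties); the two-sided
    p-value uses the t approximation with n-2 degrees of freedom. Zero
    rank variance yields an explicitly flagged undefined result.
    """
    if norm.n_samples < 4:
        raise DataError("Spearman confirmation needs at least 4 samples")
    a = norm.gene_vector(gene_a)
    b = norm.gene_vector(gene_b)
    if np.all(a == a[0]) or np.all(b == b[0]):
        return SpearmanResult(gene_a, gene_b, norm.tissue_name,
                              rho=float("nan"), p_value=float("nan"),
                              n=norm.n_samples, undefined=True)
    res = stats.spearmanr(a, b)
    return SpearmanResult(
        gene_a=gene_a, gene_b=gene_b, tissue_name=norm.tissue_name,
        rho=float(res.statistic), p_value=float(res.pvalue),
        n=norm.n_samples, undefined=bool(np.isnan(res.statistic)),
    )


def correlation_count(n_genes: int, n_tissues: int) -> int:
    """Number of seed-versus-transcript correlations the sweep performs."""
    if n_genes <= 0 or n_tissues <= 0:
        raise ConfigurationError("n_genes and n_tissues must be positive")
    return n_genes * n_tissues
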