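"""Probability statistics on co-expression modules.

Two questions arise once a top-k module has been extracted from a universe
of N transcripts: (1) how likely is it that m given marker genes all land
in the module by chance, and (2) is a gene set over-represented in the
module. Co-occurrence is computed under two standard null models —
independent placement, (k/N)^m, and sampling without replacement,
prod_i (k-i)/(N-i) — and the enrichment question uses the upper-tail
hypergeometric probability. Binomial coefficients are evaluated in log
space so transcriptome-scale N is safe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import hypergeom

from coexmod.errors import ConfigurationError
from coexmod.coexpression import CoexpressionModule


@dataclass(frozen=True)
class CooccurrenceQuery:
    """N transcripts, a top-k module, m markers, and the null model."""

    universe_size: int
    module_size: int
    n_markers: int
    model: str = "independent"     # or "without_replacement"

    def validate(self) -> None:
        if not 0 <= self.n_markers <= self.module_size <= self.universe_size:
            raise ConfigurationError(
                "invariant 0 <= n_markers <= module_size <= universe_size violated: "
                f"m={self.n_markers}, k={self.module_size}, N={self.universe_size}"
            )
        if self.model not in ("independent", "without_replacement"):
            raise ConfigurationError(f"unknown co-occurrence model {self.model!r}")


def cooccurrence_probability(q: CooccurrenceQuery) -> float:
    """Chance probability that all m markers fall inside the top-k module."""
    q.validate()
    N, k, m = q.universe_size, q.module_size, q.n_markers
    if m == 0:
        return 1.0
    if q.model == "independent":
        return math.exp(m * (math.log(k) - math.log(N)))
    # without replacement: falling factorials in log space
    log_p = (math.lgamma(k + 1) - math.lgamma(k - m + 1)
             - math.lgamma(N + 1) + math.lgamma(N - m + 1))
    return math.exp(log_p)


def cooccurrence_report(universe_size: int, module_size: int, n_markers: int) -> dict:
    """Both null-model probabilities for the same (N, k, m) query."""
    out = {"universe_size": universe_size, "module_size": module_size,
           "n_markers": n_markers}
    for model in ("independent", "without_replacement"):
        q = CooccurrenceQuery(universe_size, module_size, n_markers, model)
        out[f"p_{model}"] = cooccurrence_probability(q)
    return out


def hypergeometric_enrichment(
    module: CoexpressionModule | set, gene_set: set, universe: set
) -> float:
    """Upper-tail hypergeometric p-value of the module/gene-set overlap.

    P(X >= observed overlap) when |module| genes are drawn from the
    universe without replacement and |gene_set| of the universe are marked.
    """
    if not universe:
        raise ConfigurationError("universe must be non-empty")
    members = set(module.member_gene_ids) if isinstance(module, CoexpressionModule) else set(module)
    gene_set = set(gene_set)
    universe = set(universe)
    if not gene_set <= universe:
        raise ConfigurationError("gene_set must be a subset of the universe")
    if not members <= universe:
        raise ConfigurationError("module members must be a subset of the universe")
    overlap = len(members & gene_set)
    # sf(x) = P(X > x), so sf(overlap - 1) = P(X >= overlap)
    return float(hypergeom.sf(overlap - 1, len(universe), len(gene_set), len(members)))
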