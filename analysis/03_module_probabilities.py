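#!/usr/bin/env python
"""Chance co-occurrence and enrichment statistics for the module.

Computes, at the transcriptome scale the cross-tissue sweep operates on
(56,202 transcripts, top-600 extreme), the probability that 2 or 3 given
marker genes all land in the extreme by chance under both null models,
and the hypergeometric enrichment of the planted module in the extracted
extreme from 02_rank_coexpression.py.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from coexmod import cooccurrence_report, hypergeometric_enrichment
from coexmod.coexpression import CoexpressionModule
from coexmod.simulate import SyntheticTruth


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--coex", type=Path, default=Path("results/coexpression"))
    ap.add_argument("--out", type=Path, default=Path("results/module_stats"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    out = {"cooccurrence": []}
    for m in (2, 3):
        rep = cooccurrence_report(56_202, 600, m)
        out["cooccurrence"].append(rep)
        print(f"P(all {m} markers in top-600 of 56,202 by chance): "
              f"independent {rep['p_independent']:.3e}, "
              f"without replacement {rep['p_without_replacement']:.3e}")

    module_spec = json.loads((args.coex / "module.json").read_text())
    truth = SyntheticTruth.from_json(args.data / "truth.json")
    ranking = pd.read_csv(args.coex / "ranking.tsv", sep="\t", index_col=0)
    universe = set(ranking.index)
    module = CoexpressionModule(
        module_spec["seed_gene_id"], module_spec["k"],
        module_spec["member_gene_ids"], module_spec["include_seed"],
    )
    planted = (truth.module_gene_ids - {truth.seed_gene_id}) & universe
    p = hypergeometric_enrichment(module, planted, universe)
    out["planted_module_enrichment_p"] = p
    print(f"hypergeometric enrichment of the planted module in the "
          f"top-{module.k} extreme: p = {p:.3e}")

    (args.out / "module_stats.json").write_text(json.dumps(out, indent=2))


if __name__ == "__main__":
    main()
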