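"""End-to-end orchestration: simulate/load -> normalize -> rank -> extract
-> score -> scan, with a machine-readable run report.

Tissues with fewer donors than ``min_donors`` are excluded with a logged
warning (mirroring the >= 90-donor inclusion rule of the cross-tissue
sweep); a missing seed gene is fatal. All randomness flows through the
single ``rng_seed``, so a run is byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from coexmod.errors import ConfigurationError, DataError
from coexmod.simulate import SimulationConfig, TissueMatrix, simulate_collection
from coexmod.normalize import TmmParams, normalize_tissue, read_gct
from coexmod.coexpression import (
    pearson_profile,
    rsum_ranking,
    extract_extreme,
    correlation_count,
)
from coexmod.module_stats import cooccurrence_report, hypergeometric_enrichment
from coexmod.carg import scan_fasta, write_bed

logger = logging.getLogger("coexmod")


@dataclass
class RunConfig:
    mode: str = "simulate"                    # "simulate" or "files"
    sim: SimulationConfig | None = None       # simulate mode
    count_files: list[str] = field(default_factory=list)  # files mode
    seed_gene_id: str | None = None
    min_donors: int = 90
    k: int | None = None          # None -> ~1% of the universe
    correlation_scale: str = "log_cpm"
    undefined_policy: str = "zero"
    tmm: TmmParams = field(default_factory=TmmParams)
    marker_gene_ids: list[str] = field(default_factory=list)
    promoter_fasta: str | None = None
    out_dir: str = "results/run"
    rng_seed: int = 0

    def validate(self) -> None:
        if self.mode not in ("simulate", "files"):
            raise ConfigurationError(f"mode must be 'simulate' or 'files', got {self.mode!r}")
        if self.mode == "files" and not self.count_files:
            raise ConfigurationError("files mode requires count_files")
        if self.mode == "simulate" and self.count_files:
            raise ConfigurationError("exactly one input mode may be active")
        if self.k is not None and self.k < 1:
            raise ConfigurationError("k must be >= 1")
        if self.min_donors < 2:
            raise ConfigurationError("min_donors must be >= 2")
        self.tmm.validate()

    _KNOWN_KEYS = (
        "mode", "sim", "count_files", "seed_gene_id", "min_donors", "k",
        "correlation_scale", "undefined_policy", "tmm", "marker_gene_ids",
        "promoter_fasta", "out_dir", "rng_seed",
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        """One flat YAML document; unknown keys are errors (fail-fast)."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError("config file must be a mapping")
        unknown = set(raw) - set(cls._KNOWN_KEYS)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "sim" in raw and raw["sim"] is not None:
            raw["sim"] = SimulationConfig(**raw["sim"])
        if "tmm" in raw and raw["tmm"] is not None:
            raw["tmm"] = TmmParams(**raw["tmm"])
        return cls(**raw)


def _load_tissues(config: RunConfig):
    if config.mode == "simulate":
        sim = config.sim or SimulationConfig(rng_seed=config.rng_seed)
        if sim.rng_seed != config.rng_seed:
            sim = dataclasses.replace(sim, rng_seed=config.rng_seed)
        matrices, truth = simulate_collection(sim)
        return matrices, truth
    matrices = []
    for f in config.count_files:
        path = Path(f)
        if path.suffix == ".gct":
            matrices.append(read_gct(path))
        else:
            matrices.append(TissueMatrix.from_tsv(path))
    return matrices, None


def run(config: RunConfig) -> dict:
    """Execute the full pipeline and return the run report (also written
    as report.json in the output directory)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run_inner(config, out)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run_inner(config: RunConfig, out: Path) -> dict:
    matrices, truth = _load_tissues(config)
    seed = config.seed_gene_id
    if seed is None:
        if truth is not None:
            seed = truth.seed_gene_id
        else:
            raise ConfigurationError("seed_gene_id is required in files mode")

    used, excluded = [], []
    for tm in matrices:
        if tm.n_samples >= config.min_donors:
            used.append(tm)
        else:
            excluded.append(tm)
            logger.warning(
                "excluding tissue %s: %d donors < min_donors=%d",
                tm.tissue_name, tm.n_samples, config.min_donors,
            )
    if not used:
        raise DataError("no tissue passes the min_donors filter")

    profiles = []
    for tm in used:
        if seed not in tm.gene_ids:
            raise DataError(f"seed gene {seed!r} missing from tissue {tm.tissue_name!r}")
        norm = normalize_tissue(tm, config.tmm, scale=config.correlation_scale)
        profiles.append(pearson_profile(norm, seed))
        logger.info("correlated %s (%d samples)", tm.tissue_name, tm.n_samples)

    ranking = rsum_ranking(profiles, policy=config.undefined_policy)
    n_universe = ranking.n_genes
    k = config.k if config.k is not None else max(1, round(0.01 * n_universe))
    module = extract_extreme(ranking, k=k, include_seed=False)

    ranking.to_tsv(out / "ranking.tsv")
    (out / "module.txt").write_text("\n".join(module.member_gene_ids) + "\n")
    (out / "module.json").write_text(json.dumps(module.to_json_dict(), indent=2))

    stats: dict = {"cooccurrence": None, "enrichment": None}
    markers = [g for g in config.marker_gene_ids if g != seed]
    if markers:
        stats["cooccurrence"] = cooccurrence_report(n_universe, k, len(markers))
        universe = set(ranking.rsum.index)
        present = set(markers) & universe
        stats["enrichment"] = {
            "gene_set_size": len(present),
            "overlap": len(present & set(module.member_gene_ids)),
            "p_value": hypergeometric_enrichment(module, present, universe),
        }
    elif truth is not None:
        planted = set(truth.module_gene_ids) - {seed}
        universe = set(ranking.rsum.index)
        stats["enrichment"] = {
            "gene_set_size": len(planted),
            "overlap": len(planted & set(module.member_gene_ids)),
            "p_value": hypergeometric_enrichment(module, planted & universe, universe),
        }
    (out / "stats.json").write_text(json.dumps(stats, indent=2, sort_keys=True))

    carg_bed = None
    if config.promoter_fasta is not None:
        hits = scan_fasta(config.promoter_fasta)
        carg_bed = str(out / "carg_hits.bed")
        write_bed(hits, carg_bed)
        logger.info("CArG scan: %d hits", len(hits))

    report = {
        "seed_gene_id": seed,
        "tissues_used": [
            {"tissue": tm.tissue_name, "donors": tm.n_samples} for tm in used
        ],
        "tissues_excluded": [
            {"tissue": tm.tissue_name, "donors": tm.n_samples} for tm in excluded
        ],
        "universe_size": n_universe,
        "n_dropped_genes": ranking.n_dropped_genes,
        "correlation_count": correlation_count(n_universe, len(used)),
        "seed_rsum": float(ranking.rsum[seed]),
        "k": k,
        "top_k": module.member_gene_ids,
        "outputs": {
            "ranking": str(out / "ranking.tsv"),
            "module_list": str(out / "module.txt"),
            "module_json": str(out / "module.json"),
            "stats": str(out / "stats.json"),
            "carg_bed": carg_bed,
        },
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
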