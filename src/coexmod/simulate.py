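"""Synthetic multi-tissue count data with a planted co-expression module.

The generator emulates the data regime of a GTEx-style multi-tissue
RNA-Seq panel: ~20 tissues, >=90 donors per tissue, a shared transcript
universe, negative-binomial counts with sample-specific sequencing depth.
A latent per-sample regulator activity drives a planted module of genes
(including the seed) in a configurable fraction of tissues, so the
downstream R_sum ranking has a known ground truth to recover.

Counts follow a gamma-Poisson (negative binomial) model on a log-linear
mean: log mu_gj = base_g + beta_g * z_j, scaled by a log-normal per-sample
depth factor. Only the correlation structure the analysis consumes is
matched, not GTEx marginal distributions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from coexmod.errors import ConfigurationError

# Fixed stream offsets: stream 0 draws universe-level quantities (baselines,
# module membership), stream (1, t) draws tissue t. Adding tissues therefore
# never perturbs earlier tissues.
_UNIVERSE_STREAM = 0
_TISSUE_STREAM = 1
_PROMOTER_STREAM = 2


def _gene_ids(n_genes: int) -> list[str]:
    width = max(5, len(str(n_genes - 1)))
    return [f"G{i:0{width}d}" for i in range(n_genes)]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the planted-module multi-tissue simulation.

    effect_size is the loading of module genes on the shared latent
    regulator (per-sample standard-normal activity); 0 removes all planted
    co-variation. active_tissue_fraction controls in how many tissues the
    module is switched on — the remainder emulate tissues (e.g. brain)
    where the seed's co-expression is weak.
    """

    n_tissues: int = 20
    n_samples_per_tissue: int = 100
    n_genes: int = 5000
    module_size: int = 50
    seed_gene_id: str | None = None  # default: first gene of the universe
    effect_size: float = 1.0
    active_tissue_fraction: float = 0.9
    nb_dispersion: float = 0.1
    library_size_sigma: float = 0.3
    rng_seed: int = 0

    def resolved_seed_gene(self) -> str:
        if self.seed_gene_id is not None:
            return self.seed_gene_id
        return _gene_ids(self.n_genes)[0]

    def validate(self) -> None:
        if self.n_tissues < 1:
            raise ConfigurationError("n_tissues must be >= 1")
        if self.n_samples_per_tissue < 2:
            raise ConfigurationError("n_samples_per_tissue must be >= 2")
        if self.n_genes < 2:
            raise ConfigurationError("n_genes must be >= 2")
        if not 0 < self.module_size < self.n_genes:
            raise ConfigurationError("module_size must satisfy 0 < module_size < n_genes")
        if self.effect_size < 0:
            raise ConfigurationError("effect_size must be non-negative")
        if not 0.0 <= self.active_tissue_fraction <= 1.0:
            raise ConfigurationError("active_tissue_fraction must lie in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be positive")
        if self.library_size_sigma < 0:
            raise ConfigurationError("library_size_sigma must be non-negative")
        if self.seed_gene_id is not None and self.seed_gene_id not in _gene_ids(self.n_genes):
            raise ConfigurationError(
                f"seed_gene_id {self.seed_gene_id!r} is not in the simulated gene universe"
            )


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth: module members and per-tissue effect sizes."""

    module_gene_ids: frozenset[str]
    per_tissue_effect: dict[str, float]
    seed_gene_id: str
    rng_seed: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "module_gene_ids": sorted(self.module_gene_ids),
            "per_tissue_effect": self.per_tissue_effect,
            "seed_gene_id": self.seed_gene_id,
            "rng_seed": self.rng_seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            module_gene_ids=frozenset(payload["module_gene_ids"]),
            per_tissue_effect=dict(payload["per_tissue_effect"]),
            seed_gene_id=payload["seed_gene_id"],
            rng_seed=int(payload["rng_seed"]),
        )


@dataclass
class TissueMatrix:
    """One tissue's genes x samples count table."""

    tissue_name: str
    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # non-negative integers, shape (genes, samples)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ConfigurationError(f"duplicate gene_ids in tissue {self.tissue_name}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ConfigurationError(f"duplicate sample_ids in tissue {self.tissue_name}")
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ConfigurationError(
                f"counts shape {self.counts.shape} does not match "
                f"({len(self.gene_ids)}, {len(self.sample_ids)})"
            )
        if np.any(self.counts < 0):
            raise ConfigurationError("counts must be non-negative")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_tsv(self, path: str | Path) -> None:
        """Write rows=genes, first column gene_id, header=sample ids."""
        df = pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, tissue_name: str | None = None) -> "TissueMatrix":
        path = Path(path)
        df = pd.read_csv(path, sep="\t", index_col=0)
        stem = path.stem
        if stem.endswith(".counts"):
            stem = stem[: -len(".counts")]
        return cls(
            tissue_name=tissue_name if tissue_name is not None else stem,
            gene_ids=[str(g) for g in df.index],
            sample_ids=[str(s) for s in df.columns],
            counts=df.to_numpy(),
        )


def simulate_collection(
    config: SimulationConfig,
) -> tuple[list[TissueMatrix], SyntheticTruth]:
    """Simulate one count matrix per tissue plus the planted truth.

    Fully reproducible from ``config.rng_seed``; each tissue uses its own
    RNG stream so the collection is stable under adding tissues.
    """
    config.validate()
    gene_ids = _gene_ids(config.n_genes)
    seed_gene = config.resolved_seed_gene()
    seed_idx = gene_ids.index(seed_gene)

    uni_rng = np.random.default_rng([config.rng_seed, _UNIVERSE_STREAM])
    # Baseline log-means (natural log) shared across tissues so the gene
    # universe is comparable between tissues, as in a real multi-tissue panel.
    base = uni_rng.normal(loc=np.log(50.0), scale=1.5, size=config.n_genes)

    other = [i for i in range(config.n_genes) if i != seed_idx]
    picked = uni_rng.choice(other, size=config.module_size - 1, replace=False)
    module_idx = np.sort(np.concatenate([[seed_idx], picked]))
    module_ids = frozenset(gene_ids[i] for i in module_idx)

    n_active = int(round(config.active_tissue_fraction * config.n_tissues))
    tissue_names = [f"tissue_{t:02d}" for t in range(config.n_tissues)]
    per_tissue_effect = {
        name: (config.effect_size if t < n_active else 0.0)
        for t, name in enumerate(tissue_names)
    }

    beta = np.zeros(config.n_genes)
    beta[module_idx] = 1.0  # scaled per tissue below

    matrices: list[TissueMatrix] = []
    for t, name in enumerate(tissue_names):
        rng = np.random.default_rng([config.rng_seed, _TISSUE_STREAM, t])
        z = rng.normal(size=config.n_samples_per_tissue)
        if config.library_size_sigma > 0:
            depth = rng.lognormal(mean=0.0, sigma=config.library_size_sigma,
                                  size=config.n_samples_per_tissue)
        else:
            depth = np.ones(config.n_samples_per_tissue)
        eff = per_tissue_effect[name]
        log_mu = base[:, None] + eff * beta[:, None] * z[None, :]
        mu = np.exp(log_mu) * depth[None, :]
        shape = 1.0 / config.nb_dispersion
        lam = rng.gamma(shape=shape, scale=mu / shape)
        counts = rng.poisson(lam)
        sample_ids = [f"{name}_s{j:03d}" for j in range(config.n_samples_per_tissue)]
        matrices.append(
            TissueMatrix(tissue_name=name, gene_ids=list(gene_ids),
                         sample_ids=sample_ids, counts=counts)
        )

    truth = SyntheticTruth(
        module_gene_ids=module_ids,
        per_tissue_effect=per_tissue_effect,
        seed_gene_id=seed_gene,
        rng_seed=config.rng_seed,
    )
    return matrices, truth


def write_collection(
    matrices: list[TissueMatrix], truth: SyntheticTruth, out_dir: str | Path
) -> list[Path]:
    """Write one TSV per tissue plus a truth JSON; returns the TSV paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for tm in matrices:
        p = out_dir / f"{tm.tissue_name}.counts.tsv"
        tm.to_tsv(p)
        paths.append(p)
    truth.to_json(out_dir / "truth.json")
    return paths


def simulate_promoters(
    n_seq: int,
    length: int,
    planted: list[tuple[int, int]],
    rng_seed: int,
    alphabet: str = "ACGT",
) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Random promoter sequences with CArG boxes written at given offsets.

    Background is iid uniform over ``alphabet`` (restrict the alphabet to
    build e.g. a C-free background in which no CArG can occur by chance).
    Each planted entry (seq_index, offset) writes a 10-mer drawn from the
    CC(A/T)6GG consensus family at that 0-based offset. Returns Biopython
    records and a truth table with columns seq_index, seq_id, offset, motif.
    """
    if n_seq < 0 or length < 0:
        raise ConfigurationError("n_seq and length must be non-negative")
    rng = np.random.default_rng([rng_seed, _PROMOTER_STREAM])
    letters = np.array(list(alphabet))
    seqs = [rng.choice(letters, size=length) for _ in range(n_seq)]

    rows = []
    for seq_index, offset in planted:
        if not 0 <= seq_index < n_seq:
            raise ConfigurationError(f"planted seq_index {seq_index} out of range")
        if offset < 0 or offset + 10 > length:
            raise ConfigurationError(
                f"planted offset {offset} out of range for length {length}"
            )
        core = rng.choice(np.array(["A", "T"]), size=6)
        motif = "CC" + "".join(core) + "GG"
        seqs[seq_index][offset : offset + 10] = list(motif)
        rows.append({"seq_index": seq_index, "seq_id": f"promoter_{seq_index}",
                     "offset": offset, "motif": motif})

    records = [
        SeqRecord(Seq("".join(s)), id=f"promoter_{i}", description="")
        for i, s in enumerate(seqs)
    ]
    truth = pd.DataFrame(rows, columns=["seq_index", "seq_id", "offset", "motif"])
    return records, truth


def write_promoters(records: list[SeqRecord], path: str | Path) -> None:
    SeqIO.write(records, str(path), "fasta")
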