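"""Synthetic microarray-like data with planted ground truth.

Emulates the regime of small tumour cohorts profiled on large cDNA arrays:
a handful of samples per class, thousands of mostly uninformative genes, a
small planted set of class-discriminative genes whose means shift with
disease stage, and equicorrelated gene blocks standing in for co-regulated
transcripts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data import ExpressionMatrix, LabelVector, write_expression, write_labels

__all__ = ["SimulationConfig", "SimulatedDataset", "simulate", "write_dataset"]

#: Baseline log-intensity around which genes fluctuate; arbitrary but keeps
#: simulated values on a microarray-like scale.
BASELINE_MEAN = 7.0
BASELINE_SD = 1.0


@dataclass
class SimulationConfig:
    """Parameters of the planted-signal generator.

    effect is the class-mean separation between adjacent classes in units of
    the within-class standard deviation (noise_sd); block_rho is the
    equicorrelation within consecutive blocks of block_size genes.
    """

    p: int = 9600
    classes: tuple[str, ...] = ("OVT", "OVC_I", "OVC_III")
    n_per_class: int = 5
    n_informative: int = 20
    effect: float = 3.0
    block_size: int = 10
    block_rho: float = 0.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.p:
            raise ValueError(f"n_informative={self.n_informative} exceeds p={self.p}")
        if not (0.0 <= self.block_rho < 1.0):
            raise ValueError("block_rho must be in [0, 1)")
        if self.effect < 0:
            raise ValueError("effect must be >= 0")
        if self.block_size < 1 or self.n_per_class < 1 or self.p < 1:
            raise ValueError("p, n_per_class and block_size must be positive")
        if len(self.classes) < 2:
            raise ValueError("at least two classes required")


@dataclass
class SimulatedDataset:
    matrix: ExpressionMatrix
    labels: LabelVector
    truth: list[str] = field(default_factory=list)


def _informative_positions(cfg: SimulationConfig) -> np.ndarray:
    """Spread planted genes over distinct correlation blocks when possible.

    Placing two planted genes in the same equicorrelated block would make
    them partially redundant and weaken the planted signal; one per block
    (first gene of every k-th block) keeps the ground truth unambiguous.
    """
    n_blocks = (cfg.p + cfg.block_size - 1) // cfg.block_size
    if cfg.n_informative <= n_blocks:
        blocks = np.linspace(0, n_blocks - 1, cfg.n_informative).astype(int)
        return blocks * cfg.block_size
    return np.arange(cfg.n_informative)


def simulate(cfg: SimulationConfig) -> SimulatedDataset:
    """Draw one dataset: genes x samples matrix, labels and planted truth.

    Informative genes get class-specific means evenly spaced by
    effect * noise_sd along class_order (a stage-progression-like monotone
    signal); all other genes share one mean across classes.  Within-class
    noise is Gaussian with an equicorrelated block structure: for genes in
    the same block of block_size, cor = block_rho.
    """
    rng = np.random.default_rng(cfg.seed)
    C = len(cfg.classes)
    n = C * cfg.n_per_class
    width = len(str(cfg.p - 1))
    gene_ids = [f"g{i:0{width}d}" for i in range(cfg.p)]
    sample_ids = [
        f"{cls}_{j + 1}" for cls in cfg.classes for j in range(cfg.n_per_class)
    ]
    labels = [cls for cls in cfg.classes for _ in range(cfg.n_per_class)]
    class_code = np.repeat(np.arange(C), cfg.n_per_class)

    baseline = rng.normal(BASELINE_MEAN, BASELINE_SD, size=cfg.p)

    # Equicorrelated noise per block: x = sqrt(rho)*shared + sqrt(1-rho)*own.
    eps = rng.standard_normal((cfg.p, n))
    if cfg.block_rho > 0:
        n_blocks = (cfg.p + cfg.block_size - 1) // cfg.block_size
        shared = rng.standard_normal((n_blocks, n))
        block_of = np.arange(cfg.p) // cfg.block_size
        eps = np.sqrt(cfg.block_rho) * shared[block_of] + np.sqrt(1 - cfg.block_rho) * eps

    values = baseline[:, None] + cfg.noise_sd * eps

    info_pos = _informative_positions(cfg)
    # Centered, evenly spaced class means: adjacent classes differ by
    # effect * noise_sd, monotone along class_order.
    offsets = (class_code - (C - 1) / 2.0) * cfg.effect * cfg.noise_sd
    values[info_pos] += offsets[None, :]

    matrix = ExpressionMatrix(gene_ids, sample_ids, values)
    lv = LabelVector(sample_ids, labels, list(cfg.classes))
    truth = [gene_ids[i] for i in info_pos]
    return SimulatedDataset(matrix=matrix, labels=lv, truth=truth)


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write expression.tsv, labels.tsv and truth.txt beside each other."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "labels": outdir / "labels.tsv",
        "truth": outdir / "truth.txt",
    }
    write_expression(ds.matrix, paths["expression"])
    write_labels(ds.labels, paths["labels"])
    paths["truth"].write_text("\n".join(ds.truth) + ("\n" if ds.truth else ""))
    return paths
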