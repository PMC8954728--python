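"""Seeded synthetic drug-target datasets with a known, learnable signal.

The generator emulates the structural summaries of the public kinase
benchmarks — random SMILES-alphabet strings with mean length 64 and random
amino-acid strings with mean length 728, an interaction matrix of
configurable density — while the affinity is constructed, by design, in
exactly the feature space the signature-image encoder produces:

    y(d, t) = a * g(d) + b * h(t) + c * g(d) * h(t) + noise,

where g(d) = <u, f_mol(d)> and h(t) = <v, f_prot(t)> are projections of the
normalized k-mer profiles onto latent weight vectors u, v (standardized
across the sampled entities), and the combined signal is rescaled to a
pKd-like scale (center 7, unit standard deviation) before Gaussian noise is
added.  The ground truth (u, v, a, b, c, per-entity projections, realized
noise level) is returned so recovery tests can verify the pipeline
end-to-end.  This is a test harness, not a biological simulator.

Everything is a pure function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dataset_io import (
    AFFINITY_FILE,
    LIGANDS_FILE,
    PROTEINS_FILE,
    TEST_FOLD_FILE,
    TRAIN_FOLDS_FILE,
    ExperimentPlan,
    InteractionTable,
)
from .encoder import (
    MOLECULE_SPACE,
    PROTEIN_SPACE,
    KmerSpace,
    count_kmers,
    normalize,
    tokenize,
)

import json


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic dataset.

    ``noise_sd`` is the noise standard deviation as a fraction of the signal
    standard deviation (the signal itself has unit SD on the affinity
    scale).  Length distributions are lognormal, clipped to the stated
    ranges; the defaults match the benchmark summaries (molecule mean 64,
    range 20-590; protein mean 728, range 215-4128).
    """

    n_drugs: int = 200
    n_targets: int = 50
    density: float = 0.2
    mol_len_mean: float = 64.0
    mol_len_range: tuple[int, int] = (20, 590)
    prot_len_mean: float = 728.0
    prot_len_range: tuple[int, int] = (215, 4128)
    len_shape: float = 0.4  # lognormal sigma of both length distributions
    a: float = 1.0
    b: float = 1.0
    c: float = 0.5
    noise_sd: float = 0.2
    affinity_center: float = 7.0
    affinity_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.density <= 1.0:
            raise ValueError("density must be in (0, 1]")
        if min(self.n_drugs, self.n_targets) < 1:
            raise ValueError("need at least one drug and one target")
        for rng_, mean, space in (
            (self.mol_len_range, self.mol_len_mean, MOLECULE_SPACE),
            (self.prot_len_range, self.prot_len_mean, PROTEIN_SPACE),
        ):
            if rng_[0] < space.k:
                raise ValueError(f"minimum length {rng_[0]} is shorter than k={space.k}")
            if not rng_[0] <= mean <= rng_[1]:
                raise ValueError("mean length must lie inside the range")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class GroundTruth:
    """The generating parameters, returned for recovery tests."""

    u: np.ndarray  # latent weights in the molecule k-mer space
    v: np.ndarray  # latent weights in the protein k-mer space
    a: float
    b: float
    c: float
    g: np.ndarray  # standardized per-drug projections <u, f_mol>
    h: np.ndarray  # standardized per-target projections <v, f_prot>
    noise_sd_abs: float  # realized noise SD on the affinity scale
    signal: np.ndarray  # noise-free affinity of every sampled interaction


def _sample_lengths(
    n: int, mean: float, bounds: tuple[int, int], sigma: float, rng: np.random.Generator
) -> np.ndarray:
    mu = np.log(mean) - sigma**2 / 2.0
    lengths = np.round(np.exp(rng.normal(mu, sigma, size=n))).astype(np.int64)
    return np.clip(lengths, bounds[0], bounds[1])


def _sample_records(
    n: int, lengths: np.ndarray, space: KmerSpace, prefix: str, rng: np.random.Generator
):
    symbols = np.array(space.alphabet.symbols)
    records = []
    for i in range(n):
        raw = "".join(symbols[rng.integers(0, space.n, size=lengths[i])])
        records.append(tokenize(raw, space.alphabet, identifier=f"{prefix}{i:04d}"))
    return records


def _profiles(records, space: KmerSpace) -> np.ndarray:
    out = np.empty((len(records), space.nk), dtype=np.float64)
    for i, rec in enumerate(records):
        out[i] = normalize(count_kmers(rec, space))
    return out


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise ValueError("degenerate projections: zero variance")
    return (x - x.mean()) / sd


def generate(spec: SyntheticSpec) -> tuple[InteractionTable, GroundTruth]:
    """Draw one dataset; bit-identical for a given spec (incl. its seed)."""
    rng = np.random.default_rng(spec.seed)
    mol_len = _sample_lengths(
        spec.n_drugs, spec.mol_len_mean, spec.mol_len_range, spec.len_shape, rng
    )
    prot_len = _sample_lengths(
        spec.n_targets, spec.prot_len_mean, spec.prot_len_range, spec.len_shape, rng
    )
    drugs = _sample_records(spec.n_drugs, mol_len, MOLECULE_SPACE, "D", rng)
    targets = _sample_records(spec.n_targets, prot_len, PROTEIN_SPACE, "T", rng)

    u = rng.standard_normal(MOLECULE_SPACE.nk)
    v = rng.standard_normal(PROTEIN_SPACE.nk)
    g = _standardize(_profiles(drugs, MOLECULE_SPACE) @ u)
    h = _standardize(_profiles(targets, PROTEIN_SPACE) @ v)

    n_cells = spec.n_drugs * spec.n_targets
    n_obs = max(1, int(round(spec.density * n_cells)))
    chosen = np.sort(rng.choice(n_cells, size=n_obs, replace=False))
    rows, cols = np.divmod(chosen, spec.n_targets)

    raw = spec.a * g[rows] + spec.b * h[cols] + spec.c * g[rows] * h[cols]
    raw_sd = raw.std()
    if raw_sd == 0:
        raise ValueError("degenerate affinity signal: zero variance")
    signal = spec.affinity_center + spec.affinity_scale * (raw - raw.mean()) / raw_sd
    noise_sd_abs = spec.noise_sd * spec.affinity_scale
    y = signal + rng.normal(0.0, noise_sd_abs, size=n_obs) if spec.noise_sd > 0 else signal.copy()

    affinity = np.full((spec.n_drugs, spec.n_targets), np.nan)
    affinity[rows, cols] = y
    table = InteractionTable(drugs=drugs, targets=targets, affinity=affinity, kind="synthetic")
    truth = GroundTruth(
        u=u, v=v, a=spec.a, b=spec.b, c=spec.c, g=g, h=h,
        noise_sd_abs=noise_sd_abs, signal=signal,
    )
    return table, truth


def write_fixture(
    table: InteractionTable, directory: str | Path, plan: ExperimentPlan | None = None
) -> Path:
    """Write *table* (and optionally a fold plan) in the benchmark layout
    consumed by :func:`kmersig.dataset_io.load_benchmark`; round-trips
    exactly."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ligands = {rec.identifier: rec.raw for rec in table.drugs}
    proteins = {rec.identifier: rec.raw for rec in table.targets}
    (directory / LIGANDS_FILE).write_text(json.dumps(ligands, indent=0))
    (directory / PROTEINS_FILE).write_text(json.dumps(proteins, indent=0))
    np.savetxt(directory / AFFINITY_FILE, table.affinity, fmt="%.17g")
    if plan is not None:
        (directory / TRAIN_FOLDS_FILE).parent.mkdir(exist_ok=True)
        (directory / TRAIN_FOLDS_FILE).write_text(
            json.dumps([p.tolist() for p in plan.parts[:-1]])
        )
        (directory / TEST_FOLD_FILE).write_text(json.dumps(plan.parts[-1].tolist()))
    return directory
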