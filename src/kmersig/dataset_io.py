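"""Benchmark reading and the cross-validation experiment plan.

The reader consumes the public layout of the kinase-affinity benchmarks
(Davis, KIBA) used throughout the affinity-regression literature:

- ``ligands_can.txt``   JSON object mapping drug id -> SMILES
- ``proteins.txt``      JSON object mapping target id -> amino-acid sequence
- ``Y.txt``             whitespace-delimited drugs x targets affinity matrix,
                        ``nan`` marking missing cells (KIBA is sparse)
- ``folds/train_fold_setting1.txt``  JSON: five lists of interaction indices
- ``folds/test_fold_setting1.txt``   JSON: one list of interaction indices

Interaction index i refers to the i-th non-missing cell of the affinity
matrix in row-major order, matching the published fold files.  Davis raw Kd
values (nM) are transformed to pKd on load; KIBA scores pass through.

The experiment plan is a six-way partition of the interactions: five
cross-validation folds plus one held-out test part.  Within each fold, four
parts train and the fifth validates.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .alphabets import MOLECULE_ALPHABET, PROTEIN_ALPHABET
from .encoder import Policy, SequenceRecord, tokenize
from .metrics import DatasetKind, pkd_transform

logger = logging.getLogger(__name__)

LIGANDS_FILE = "ligands_can.txt"
PROTEINS_FILE = "proteins.txt"
AFFINITY_FILE = "Y.txt"
TRAIN_FOLDS_FILE = "folds/train_fold_setting1.txt"
TEST_FOLD_FILE = "folds/test_fold_setting1.txt"


@dataclass
class InteractionTable:
    """Drugs, targets and their (possibly sparse) affinity matrix."""

    drugs: list[SequenceRecord]
    targets: list[SequenceRecord]
    affinity: np.ndarray  # (n_drugs, n_targets) float64, NaN = missing
    kind: DatasetKind

    def __post_init__(self) -> None:
        if self.affinity.shape != (len(self.drugs), len(self.targets)):
            raise ValueError(
                f"affinity matrix shape {self.affinity.shape} does not match "
                f"{len(self.drugs)} drugs x {len(self.targets)} targets"
            )

    @property
    def n_interactions(self) -> int:
        return int(np.isfinite(self.affinity).sum())

    def interaction_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Row/column indices of non-missing cells, row-major order."""
        return np.where(np.isfinite(self.affinity))

    def interaction_values(self) -> np.ndarray:
        rows, cols = self.interaction_indices()
        return self.affinity[rows, cols]


@dataclass(frozen=True)
class ExperimentPlan:
    """Six-way interaction partition: parts[0..4] are CV folds, parts[5] is
    the held-out test set."""

    parts: tuple[np.ndarray, ...]

    N_PARTS = 6

    def __post_init__(self) -> None:
        if len(self.parts) != self.N_PARTS:
            raise ValueError(f"need exactly {self.N_PARTS} parts, got {len(self.parts)}")
        allidx = np.concatenate(self.parts)
        if len(np.unique(allidx)) != allidx.size:
            raise ValueError("parts overlap: an interaction appears more than once")

    @property
    def n_folds(self) -> int:
        return self.N_PARTS - 1

    @property
    def n_interactions(self) -> int:
        return sum(p.size for p in self.parts)

    def train_indices(self, fold: int) -> np.ndarray:
        """The four CV parts other than *fold*, concatenated."""
        self._check_fold(fold)
        return np.concatenate([p for i, p in enumerate(self.parts[:-1]) if i != fold])

    def validation_indices(self, fold: int) -> np.ndarray:
        self._check_fold(fold)
        return self.parts[fold]

    def test_indices(self) -> np.ndarray:
        return self.parts[-1]

    def _check_fold(self, fold: int) -> None:
        if not 0 <= fold < self.n_folds:
            raise ValueError(f"fold must be in [0, {self.n_folds}), got {fold}")

    def assert_exhaustive(self, n_interactions: int) -> None:
        """Check the parts cover exactly [0, n_interactions)."""
        allidx = np.sort(np.concatenate(self.parts))
        if not np.array_equal(allidx, np.arange(n_interactions)):
            raise ValueError("plan does not partition the interaction set")


def _tokenize_map(
    mapping: dict[str, str], alphabet, policy: Policy, label: str
) -> list[SequenceRecord]:
    records = []
    total_dropped = 0
    for ident, raw in mapping.items():
        rec = tokenize(raw, alphabet, policy=policy, identifier=ident)
        total_dropped += rec.dropped_count
        records.append(rec)
    if total_dropped:
        logger.info(
            "%s: dropped %d out-of-alphabet characters across %d sequences",
            label, total_dropped, len(records),
        )
    return records


def load_benchmark(path: str | Path, kind: DatasetKind, policy: Policy = "drop") -> InteractionTable:
    """Read a benchmark directory into an :class:`InteractionTable`.

    Davis affinities (raw Kd in nM) are converted to pKd; KIBA and synthetic
    affinities are taken as printed.  Sequences are tokenized under *policy*
    and the number of dropped characters is logged.
    """
    path = Path(path)
    for fname in (LIGANDS_FILE, PROTEINS_FILE, AFFINITY_FILE):
        if not (path / fname).is_file():
            raise FileNotFoundError(f"benchmark file missing: {path / fname}")
    ligands = json.loads((path / LIGANDS_FILE).read_text())
    proteins = json.loads((path / PROTEINS_FILE).read_text())
    affinity = np.loadtxt(path / AFFINITY_FILE, dtype=np.float64, ndmin=2)
    if affinity.shape != (len(ligands), len(proteins)):
        raise ValueError(
            f"{path / AFFINITY_FILE}: shape {affinity.shape} does not match "
            f"{len(ligands)} ligands x {len(proteins)} proteins"
        )
    if kind == "davis":
        finite = np.isfinite(affinity)
        transformed = np.full_like(affinity, np.nan)
        transformed[finite] = pkd_transform(affinity[finite])
        affinity = transformed
    drugs = _tokenize_map(ligands, MOLECULE_ALPHABET, policy, "ligands")
    targets = _tokenize_map(proteins, PROTEIN_ALPHABET, policy, "proteins")
    return InteractionTable(drugs=drugs, targets=targets, affinity=affinity, kind=kind)


def load_fold_files(path: str | Path) -> tuple[list[np.ndarray], np.ndarray]:
    """Read the published fold-index files (five CV folds + test)."""
    path = Path(path)
    for fname in (TRAIN_FOLDS_FILE, TEST_FOLD_FILE):
        if not (path / fname).is_file():
            raise FileNotFoundError(f"fold file missing: {path / fname}")
    cv = json.loads((path / TRAIN_FOLDS_FILE).read_text())
    test = json.loads((path / TEST_FOLD_FILE).read_text())
    if len(cv) != 5:
        raise ValueError(f"{path / TRAIN_FOLDS_FILE}: expected 5 folds, got {len(cv)}")
    return [np.asarray(f, dtype=np.int64) for f in cv], np.asarray(test, dtype=np.int64)


def make_plan(
    table: InteractionTable,
    fold_indices: tuple[list[np.ndarray], np.ndarray] | None = None,
    seed: int | None = None,
) -> ExperimentPlan:
    """Build the six-way plan, either from published fold indices (used
    verbatim) or as a seeded uniform random partition into six near-equal
    parts."""
    n = table.n_interactions
    if fold_indices is not None:
        cv, test = fold_indices
        plan = ExperimentPlan(parts=tuple([*(np.asarray(f, dtype=np.int64) for f in cv), np.asarray(test, dtype=np.int64)]))
    else:
        if seed is None:
            raise ValueError("either fold_indices or a seed is required")
        order = np.random.default_rng(seed).permutation(n)
        plan = ExperimentPlan(parts=tuple(np.sort(p) for p in np.array_split(order, ExperimentPlan.N_PARTS)))
    plan.assert_exhaustive(n)
    return plan
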