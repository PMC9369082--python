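"""Benchmark loading and synthetic drug-target affinity data.

Two sources of (drug, protein, affinity) triples are supported:

* the Davis / KiBA kinase benchmarks in the DeepDTA directory layout
  (JSON maps of ligand id -> SMILES and protein id -> sequence, an affinity
  matrix with NaN for unmeasured cells, and fold-index files), and
* a seeded synthetic generator that plants a drug x protein interaction
  signal in the sequences themselves, so that training and evaluation are
  fully testable offline.

The synthetic generator gives every drug and protein a latent binary motif
membership vector and splices the member motifs (short in-vocabulary
substrings) into otherwise random sequences.  The affinity of a pair is
``effect_size * <drug motifs, protein motifs>`` plus Gaussian noise,
affinely mapped into the target affinity range (Davis-like 5.0-10.8 by
default), so the signal is recoverable only by combining both sequences.
Motifs carry geometrically decaying weights (folded into the latent
membership vectors), so different motif combinations yield distinct
affinities rather than collapsing onto a few tied levels that would bound
the achievable concordance from above.
"""

from __future__ import annotations

import json
import logging
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .encoding import encode_protein, encode_smiles

logger = logging.getLogger(__name__)

__all__ = [
    "AffinityRecord",
    "DatasetSplit",
    "SyntheticSpec",
    "SyntheticDataset",
    "load_deepdta_dataset",
    "generate_synthetic",
    "generate_synthetic_full",
    "make_split",
    "records_to_dataframe",
    "records_to_csv",
    "records_from_csv",
]

AffinityScale = Literal["pKd", "kiba_score", "synthetic"]

_SOFT_BOUNDS = {"pKd": (5.0, 10.8), "kiba_score": (0.0, 17.2)}


@dataclass(frozen=True)
class AffinityRecord:
    """One measured or simulated drug-protein binding affinity."""

    drug_id: str
    smiles: str
    protein_id: str
    sequence: str
    affinity: float
    scale: AffinityScale

    def __post_init__(self) -> None:
        if not np.isfinite(self.affinity):
            raise ValueError("affinity must be finite")
        bounds = _SOFT_BOUNDS.get(self.scale)
        if bounds and not bounds[0] - 1.0 <= self.affinity <= bounds[1] + 1.0:
            logger.warning(
                "affinity %.3f for (%s, %s) outside the usual %s range %s",
                self.affinity, self.drug_id, self.protein_id, self.scale, bounds,
            )


@dataclass(frozen=True)
class DatasetSplit:
    """Disjoint train/validation/test index lists over a record list."""

    train: tuple[int, ...]
    validation: tuple[int, ...]
    test: tuple[int, ...]
    fold_id: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        parts = [set(self.train), set(self.validation), set(self.test)]
        total = sum(len(p) for p in parts)
        if len(set().union(*parts)) != total:
            raise ValueError("split partitions overlap")


# ---------------------------------------------------------------------------
# DeepDTA-layout benchmark loader


def _read_affinity_matrix(path: Path) -> np.ndarray:
    """Read the Y matrix: binary pickle, JSON, or whitespace text with nan."""
    raw = path.read_bytes()
    try:
        return np.asarray(pickle.loads(raw), dtype=np.float64)
    except Exception:
        pass
    text = raw.decode("utf-8", errors="strict")
    try:
        return np.asarray(json.loads(text), dtype=np.float64)
    except Exception:
        pass
    rows = [
        [float(tok) for tok in line.replace(",", " ").split()]
        for line in text.splitlines()
        if line.strip()
    ]
    return np.asarray(rows, dtype=np.float64)


def _read_json_map(path: Path) -> dict[str, str]:
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(
            f"malformed JSON in {path}: line {exc.lineno} column {exc.colno}"
        ) from exc
    if not isinstance(data, dict):
        raise ValueError(f"{path} must contain a JSON object")
    return data


def load_deepdta_dataset(
    directory: str | Path, dataset_name: Literal["davis", "kiba"]
) -> tuple[list[AffinityRecord], dict]:
    """Load a benchmark directory into records plus fold definitions.

    Expects ``ligands_can.txt`` (JSON id -> SMILES), ``proteins.txt``
    (JSON id -> sequence), ``Y`` (affinity matrix, drugs x proteins; pickle,
    JSON or plain text) and, optionally, ``folds/train_fold_setting1.txt``
    and ``folds/test_fold_setting1.txt`` (JSON index lists into the
    row-major enumeration of non-missing cells).

    Davis affinities stored as raw nanomolar Kd (detected when any value
    exceeds 100) are converted to pKd = -log10(Kd / 1e9); KiBA scores pass
    through unchanged.  NaN cells are dropped with a logged count.
    """
    directory = Path(directory)
    if dataset_name not in ("davis", "kiba"):
        raise ValueError(f"unknown dataset {dataset_name!r}")
    expected = ["ligands_can.txt", "proteins.txt", "Y"]
    missing = [n for n in expected if not (directory / n).exists()]
    if missing:
        raise FileNotFoundError(
            f"{directory} is missing expected files: {', '.join(missing)}"
        )
    ligands = _read_json_map(directory / "ligands_can.txt")
    proteins = _read_json_map(directory / "proteins.txt")
    y = _read_affinity_matrix(directory / "Y")
    if y.shape != (len(ligands), len(proteins)):
        raise ValueError(
            f"affinity matrix shape {y.shape} does not match "
            f"{len(ligands)} ligands x {len(proteins)} proteins"
        )

    scale: AffinityScale = "pKd" if dataset_name == "davis" else "kiba_score"
    finite = y[np.isfinite(y)]
    if dataset_name == "davis" and finite.size and finite.max() > 100:
        logger.info("Davis matrix looks raw-nanomolar; applying pKd transform")
        y = -np.log10(y / 1e9)

    drug_ids = list(ligands)
    protein_ids = list(proteins)
    records: list[AffinityRecord] = []
    n_missing = 0
    for i, did in enumerate(drug_ids):  # row-major over non-missing cells
        for j, pid in enumerate(protein_ids):
            if not np.isfinite(y[i, j]):
                n_missing += 1
                continue
            records.append(
                AffinityRecord(
                    drug_id=did,
                    smiles=ligands[did],
                    protein_id=pid,
                    sequence=proteins[pid],
                    affinity=float(y[i, j]),
                    scale=scale,
                )
            )
    logger.info(
        "%s: %d proteins, %d compounds, %d interactions (%d missing cells)",
        dataset_name, len(protein_ids), len(drug_ids), len(records), n_missing,
    )

    folds: dict = {}
    fold_dir = directory / "folds"
    train_path = fold_dir / "train_fold_setting1.txt"
    test_path = fold_dir / "test_fold_setting1.txt"
    if train_path.exists():
        folds["train_folds"] = json.loads(train_path.read_text())
    if test_path.exists():
        folds["test_fold"] = json.loads(test_path.read_text())
    return records, folds


# ---------------------------------------------------------------------------
# synthetic generator


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-signal synthetic benchmark.

    Defaults emulate a compact Davis-like screen: every drug is paired with
    every protein, affinities live on the 5.0-10.8 pKd-like scale, and a
    moderate interaction signal (effect_size 2.0 per shared motif) is
    overlaid with measurement noise of 0.2 affinity units.
    """

    n_drugs: int = 50
    n_proteins: int = 30
    drug_len_range: tuple[int, int] = (24, 64)
    protein_len_range: tuple[int, int] = (80, 200)
    n_motifs: int = 6
    effect_size: float = 2.0
    noise_sd: float = 0.2
    affinity_range: tuple[float, float] = (5.0, 10.8)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_drugs", "n_proteins", "n_motifs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.affinity_range[0] >= self.affinity_range[1]:
            raise ValueError("affinity_range must be increasing")
        for lo, hi in (self.drug_len_range, self.protein_len_range):
            if not 1 <= lo <= hi:
                raise ValueError("length ranges must satisfy 1 <= lo <= hi")


# alphabets kept strictly inside the packaged vocabularies
_DRUG_BACKGROUND = "CCCCNNOOcccnos=()123"
_DRUG_MOTIF_ALPHABET = "CNOSPcnos"
_PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_DRUG_MOTIF_LEN = 5
_PROTEIN_MOTIF_LEN = 6
_MOTIF_WEIGHT_DECAY = 0.8  # weight of motif i is 0.8**i


@dataclass(frozen=True)
class SyntheticDataset:
    """Synthetic records together with the latent structure that made them."""

    spec: SyntheticSpec
    records: tuple[AffinityRecord, ...]
    drug_motifs: tuple[str, ...]
    protein_motifs: tuple[str, ...]
    drug_memberships: np.ndarray  # (n_drugs, n_motifs), weighted latent vectors
    protein_memberships: np.ndarray  # (n_proteins, n_motifs)
    noiseless_affinity: np.ndarray = field(repr=False)  # (n_drugs, n_proteins)

    def analytic_prediction(self, drug_index: int, protein_index: int) -> float:
        """Noise-free affinity implied by the latent memberships."""
        return float(self.noiseless_affinity[drug_index, protein_index])


def _splice(background: str, motifs: list[str], rng: np.random.Generator) -> str:
    """Interleave motifs between background chunks, keeping each intact."""
    if not motifs:
        return background
    order = rng.permutation(len(motifs))
    cuts = np.sort(rng.integers(0, len(background) + 1, size=len(motifs)))
    pieces = []
    prev = 0
    for cut, m in zip(cuts, order):
        pieces.append(background[prev:cut])
        pieces.append(motifs[int(m)])
        prev = cut
    pieces.append(background[prev:])
    return "".join(pieces)


def _random_string(alphabet: str, length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def generate_synthetic_full(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate the full synthetic dataset including its latent structure."""
    rng = np.random.default_rng(spec.seed)
    drug_motifs = [
        _random_string(_DRUG_MOTIF_ALPHABET, _DRUG_MOTIF_LEN, rng)
        for _ in range(spec.n_motifs)
    ]
    protein_motifs = [
        _random_string(_PROTEIN_ALPHABET, _PROTEIN_MOTIF_LEN, rng)
        for _ in range(spec.n_motifs)
    ]
    d_present = rng.integers(0, 2, size=(spec.n_drugs, spec.n_motifs))
    p_present = rng.integers(0, 2, size=(spec.n_proteins, spec.n_motifs))
    # distinct per-motif weights, split evenly between the two latent vectors
    weights = _MOTIF_WEIGHT_DECAY ** np.arange(spec.n_motifs)
    d_mem = d_present * np.sqrt(weights)
    p_mem = p_present * np.sqrt(weights)

    drugs: list[str] = []
    for d in range(spec.n_drugs):
        target_len = int(rng.integers(*spec.drug_len_range, endpoint=True))
        members = [m for j, m in enumerate(drug_motifs) if d_present[d, j]]
        bg_len = max(1, target_len - sum(len(m) for m in members))
        drugs.append(_splice(_random_string(_DRUG_BACKGROUND, bg_len, rng),
                             members, rng))
    prots: list[str] = []
    for p in range(spec.n_proteins):
        target_len = int(rng.integers(*spec.protein_len_range, endpoint=True))
        members = [m for j, m in enumerate(protein_motifs) if p_present[p, j]]
        bg_len = max(1, target_len - sum(len(m) for m in members))
        prots.append(_splice(_random_string(_PROTEIN_ALPHABET, bg_len, rng),
                             members, rng))

    # affinity = effect_size * <u_d, v_p> + noise, affinely mapped into the
    # target range (the map rescales signal and noise together); the rare
    # noise excursions beyond the range are clipped back onto its ends
    lo, hi = spec.affinity_range
    signal = spec.effect_size * (d_mem @ p_mem.T)  # (n_drugs, n_proteins)
    max_signal = spec.effect_size * float(weights.sum())
    scale = (hi - lo) / max_signal
    noiseless = lo + scale * signal
    noise = rng.normal(0.0, spec.noise_sd, size=signal.shape)
    affinities = np.clip(noiseless + scale * noise, lo, hi)

    records = []
    for d in range(spec.n_drugs):
        for p in range(spec.n_proteins):
            records.append(
                AffinityRecord(
                    drug_id=f"D{d:04d}",
                    smiles=drugs[d],
                    protein_id=f"P{p:04d}",
                    sequence=prots[p],
                    affinity=float(affinities[d, p]),
                    scale="synthetic",
                )
            )
    return SyntheticDataset(
        spec=spec,
        records=tuple(records),
        drug_motifs=tuple(drug_motifs),
        protein_motifs=tuple(protein_motifs),
        drug_memberships=d_mem,
        protein_memberships=p_mem,
        noiseless_affinity=noiseless,
    )


def generate_synthetic(spec: SyntheticSpec) -> list[AffinityRecord]:
    """Generate synthetic affinity records (latent structure discarded)."""
    return list(generate_synthetic_full(spec).records)


# ---------------------------------------------------------------------------
# splitting


def make_split(
    records: Sequence[AffinityRecord],
    scheme: Literal["random_pairs", "provided_folds"] = "random_pairs",
    seed: int = 0,
    fractions: tuple[float, float, float] = (0.7, 0.1, 0.2),
    folds: dict | None = None,
    fold_id: int = 0,
) -> DatasetSplit:
    """Partition record indices into train/validation/test.

    ``random_pairs`` shuffles interaction pairs with the seed and cuts at
    the given fractions.  ``provided_folds`` reproduces DeepDTA fold files:
    the ``fold_id``-th train fold becomes validation, the remaining train
    folds become train, and the held-out test fold is the test set.
    """
    n = len(records)
    if scheme == "random_pairs":
        if abs(sum(fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        order = np.random.default_rng(seed).permutation(n)
        n_train = int(round(fractions[0] * n))
        n_val = int(round(fractions[1] * n))
        return DatasetSplit(
            train=tuple(int(i) for i in order[:n_train]),
            validation=tuple(int(i) for i in order[n_train : n_train + n_val]),
            test=tuple(int(i) for i in order[n_train + n_val :]),
            fold_id=fold_id,
            seed=seed,
        )
    if scheme == "provided_folds":
        if not folds or "train_folds" not in folds or "test_fold" not in folds:
            raise ValueError("provided_folds requires train_folds and test_fold")
        train_folds = folds["train_folds"]
        if not 0 <= fold_id < len(train_folds):
            raise ValueError(f"fold_id {fold_id} out of range")
        validation = [int(i) for i in train_folds[fold_id]]
        train = [
            int(i)
            for k, f in enumerate(train_folds)
            if k != fold_id
            for i in f
        ]
        return DatasetSplit(
            train=tuple(train),
            validation=tuple(validation),
            test=tuple(int(i) for i in folds["test_fold"]),
            fold_id=fold_id,
            seed=seed,
        )
    raise ValueError(f"unknown split scheme {scheme!r}")


# ---------------------------------------------------------------------------
# tabular round-trips


def records_to_dataframe(records: Sequence[AffinityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "drug_id": [r.drug_id for r in records],
            "smiles": [r.smiles for r in records],
            "protein_id": [r.protein_id for r in records],
            "protein_sequence": [r.sequence for r in records],
            "affinity": [r.affinity for r in records],
        }
    )


def records_to_csv(records: Sequence[AffinityRecord], path: str | Path) -> None:
    records_to_dataframe(records).to_csv(path, index=False)


def records_from_csv(
    path: str | Path, scale: AffinityScale = "synthetic"
) -> list[AffinityRecord]:
    df = pd.read_csv(path)
    return [
        AffinityRecord(
            drug_id=str(r.drug_id),
            smiles=r.smiles,
            protein_id=str(r.protein_id),
            sequence=r.protein_sequence,
            affinity=float(r.affinity),
            scale=scale,
        )
        for r in df.itertuples()
    ]


def encode_records(
    records: Sequence[AffinityRecord],
    drug_max_len: int,
    protein_max_len: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Encode records into token matrices and an affinity vector."""
    drugs = np.stack(
        [encode_smiles(r.smiles, max_len=drug_max_len).tokens for r in records]
    )
    prots = np.stack(
        [encode_protein(r.sequence, max_len=protein_max_len).tokens for r in records]
    )
    y = np.array([r.affinity for r in records], dtype=np.float64)
    return drugs, prots, y
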