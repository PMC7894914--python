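"""Risk labels and per-zone stratified cross-validation.

The 12 ACGIH lifting zones collapse to three relative risk levels (a
simplification of the Los Alamos National Laboratory recommendations):

    low    : zones 4, 5
    medium : zones 6, 7, 8, 9
    high   : zones 1, 2, 3, 10, 11, 12

Cross-validation is the "modified" scheme used for all headline numbers:
four independent stratified subsamples where *every zone individually*
contributes 75% of its trials to training and 25% to testing, so no zone
can ever be absent from either side of a fold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RISK_NAMES",
    "N_CLASSES",
    "ZONE_TO_RISK",
    "zone_to_risk",
    "risk_name",
    "one_hot",
    "FoldSplit",
    "make_folds",
    "make_subject_folds",
]

RISK_NAMES = ("low", "medium", "high")
N_CLASSES = 3

ZONE_TO_RISK = {
    4: 0, 5: 0,
    6: 1, 7: 1, 8: 1, 9: 1,
    1: 2, 2: 2, 3: 2, 10: 2, 11: 2, 12: 2,
}


def zone_to_risk(zone: int) -> int:
    """Map an ACGIH zone (1-12) to a risk class index (0=low, 1=medium, 2=high)."""
    zone = int(zone)
    if zone not in ZONE_TO_RISK:
        raise ValueError(f"zone must be in 1..12, got {zone}")
    return ZONE_TO_RISK[zone]


def risk_name(level: int) -> str:
    return RISK_NAMES[level]


def one_hot(labels, n_classes: int = N_CLASSES) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if labels.min() < 0 or labels.max() >= n_classes:
        raise ValueError("label outside class range")
    out = np.zeros((labels.size, n_classes), dtype=np.float32)
    out[np.arange(labels.size), labels] = 1.0
    return out


@dataclass(frozen=True)
class FoldSplit:
    fold_id: int
    train_indices: np.ndarray
    test_indices: np.ndarray
    seed: int

    def __post_init__(self):
        train = set(self.train_indices.tolist())
        test = set(self.test_indices.tolist())
        if train & test:
            raise ValueError("train and test indices overlap")


def _per_zone_test_counts(zone_counts: dict[int, int], test_fraction: float) -> dict[int, int]:
    """Per-zone test-set sizes: floor quotas plus largest-remainder top-up so
    the global test fraction is hit exactly when possible."""
    total = sum(zone_counts.values())
    target = int(round(test_fraction * total))
    quotas = {z: test_fraction * n for z, n in zone_counts.items()}
    counts = {z: int(np.floor(q)) for z, q in quotas.items()}
    short = target - sum(counts.values())
    remainders = sorted(
        zone_counts, key=lambda z: (quotas[z] - counts[z], -z), reverse=True
    )
    for z in remainders[: max(0, short)]:
        counts[z] += 1
    for z, n in zone_counts.items():
        if counts[z] < 1 and n >= 2:
            counts[z] = 1  # every zone must appear in test
        if counts[z] >= n:
            counts[z] = n - 1  # ... and in train
    return counts


def make_folds(zones, n_folds: int = 4, test_fraction: float = 0.25, seed: int = 0):
    """Build per-zone stratified Monte-Carlo CV folds.

    Parameters
    ----------
    zones
        Sequence of ACGIH zone labels, one per trial; fold indices refer to
        positions in this sequence.
    n_folds, test_fraction
        Number of independent train/test subsamples and the test share of
        every zone (default four folds of 75%/25%).

    Each fold samples, within every zone, the zone's test quota without
    replacement; the folds are independent draws, not a disjoint partition.
    Deterministic given ``seed``.
    """
    zones = np.asarray([int(z) for z in zones])
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    zone_values = sorted(set(zones.tolist()))
    zone_indices = {z: np.flatnonzero(zones == z) for z in zone_values}
    missing = [z for z in range(1, 13) if z not in zone_indices]
    if missing:
        raise ValueError(f"zones with no trials: {missing}")
    thin = [z for z, idx in zone_indices.items() if idx.size < 2]
    if thin:
        raise ValueError(f"zones need at least 2 trials each, too few in: {thin}")
    counts = _per_zone_test_counts({z: idx.size for z, idx in zone_indices.items()}, test_fraction)
    rng = np.random.default_rng(seed)
    folds = []
    for fold_id in range(n_folds):
        test = []
        for z in zone_values:
            idx = zone_indices[z]
            test.append(rng.choice(idx, size=counts[z], replace=False))
        test = np.sort(np.concatenate(test))
        mask = np.ones(zones.size, dtype=bool)
        mask[test] = False
        folds.append(
            FoldSplit(
                fold_id=fold_id,
                train_indices=np.flatnonzero(mask),
                test_indices=test,
                seed=seed,
            )
        )
    return folds


def make_subject_folds(subjects, n_folds: int = 4, test_fraction: float = 0.25, seed: int = 0):
    """Subject-wise alternative to :func:`make_folds` (not the default).

    Each fold holds out ``round(test_fraction * n_subjects)`` (at least one)
    whole subjects: all of a subject's trials land on the same side, the
    stricter generalisation test.  With a full factorial design every zone
    still appears on both sides; no per-zone guarantee is made otherwise.
    """
    subjects = np.asarray([str(s) for s in subjects])
    unique = np.unique(subjects)
    if unique.size < 2:
        raise ValueError("subject-wise folds need at least 2 subjects")
    n_test = min(max(1, int(round(test_fraction * unique.size))), unique.size - 1)
    rng = np.random.default_rng(seed)
    folds = []
    for fold_id in range(n_folds):
        held_out = rng.choice(unique, size=n_test, replace=False)
        mask = np.isin(subjects, held_out)
        folds.append(
            FoldSplit(
                fold_id=fold_id,
                train_indices=np.flatnonzero(~mask),
                test_indices=np.flatnonzero(mask),
                seed=seed,
            )
        )
    return folds
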