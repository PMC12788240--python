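"""Mixed supervision data partitioning.

Training folds mix the full synthetic cohort with 80% of the real subjects;
test folds contain held-out real subjects only, so reported performance
reflects generalization to new real-world writers rather than memorization
of simulator artifacts.  Across the K folds every real subject appears in a
test partition exactly once.
"""

from __future__ import annotations

from typing import List, Sequence, Tuple

import numpy as np
from sklearn.model_selection import StratifiedKFold


def mixed_supervision_split(
    real: Sequence,
    synthetic: Sequence,
    fold: int,
    n_folds: int = 5,
    seed: int = 0,
    real_train_frac: float = None,
) -> Tuple[list, list]:
    """Return (train, test) for one fold of the mixed supervision protocol.

    ``real`` and ``synthetic`` are sequences of objects carrying
    ``subject_id`` and ``label`` attributes (recordings or feature tensors).
    Real subjects are partitioned by a stratified K-fold over unique subject
    ids (stratification key: class label), so splits are subject-disjoint
    and class-balanced.  Train = all synthetic + the real training subjects;
    test = the held-out real subjects only.

    ``real_train_frac`` is implied by ``n_folds`` (1 - 1/K); passing an
    inconsistent value raises.
    """
    if not 0 <= fold < n_folds:
        raise ValueError(f"fold must lie in [0, {n_folds})")
    if real_train_frac is not None and abs(real_train_frac - (1 - 1 / n_folds)) > 1e-9:
        raise ValueError(
            f"real_train_frac={real_train_frac} inconsistent with {n_folds}-fold protocol"
        )
    subjects: List[str] = []
    labels: List[str] = []
    seen = {}
    for item in real:
        if item.subject_id not in seen:
            seen[item.subject_id] = item.label
            subjects.append(item.subject_id)
            labels.append(item.label)
        elif seen[item.subject_id] != item.label:
            raise ValueError(f"subject {item.subject_id} carries conflicting labels")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    splits = list(skf.split(np.zeros(len(subjects)), labels))
    train_idx, test_idx = splits[fold]
    train_subjects = {subjects[i] for i in train_idx}
    test_subjects = {subjects[i] for i in test_idx}
    if train_subjects & test_subjects:  # structurally impossible; guard anyway
        raise RuntimeError("subject appears in both train and test partitions")
    train = list(synthetic) + [r for r in real if r.subject_id in train_subjects]
    test = [r for r in real if r.subject_id in test_subjects]
    return train, test
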