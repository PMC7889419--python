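"""Shared fixtures: synthetic cohorts and the trained-model runs that the
learning and permutation tests evaluate.  The heavy fixtures are
session-scoped so the cohort is rendered and the network trained once."""

from __future__ import annotations

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

import scindex
from scindex.evaluation import make_subject_folds
from scindex.spectrogram import patches_to_arrays


def cohort_patch_arrays(params):
    """Generate a cohort and run it through preprocessing + STFT."""
    xs, ys, subjects = [], [], []
    for rec in scindex.generate_cohort(params):
        patches = scindex.make_patches(scindex.preprocess_recording(rec))
        x, y, s, _, _ = patches_to_arrays(patches)
        xs.append(x)
        ys.append(y)
        subjects.append(s)
    return np.concatenate(xs), np.concatenate(ys), np.concatenate(subjects)


def subsample_per_recording(y, subjects, per_rec, rng):
    """Pick ``per_rec`` patch indices from every (subject, label) recording."""
    keep = []
    for s in sorted(set(subjects.tolist())):
        for lab in (0, 1):
            idx = np.nonzero((subjects == s) & (y == lab))[0]
            if idx.size:
                keep.append(rng.choice(idx, size=min(per_rec, idx.size), replace=False))
    return np.concatenate(keep)


@pytest.fixture(scope="session")
def separable_cohort():
    """40-subject cohort with the default pain signature, as patch arrays."""
    params = scindex.SynthCohortParams(n_subjects=40, seed=11)
    x, y, subjects = cohort_patch_arrays(params)
    return {"params": params, "x": x, "y": y, "subjects": subjects}


@pytest.fixture(scope="session")
def learning_runs(separable_cohort):
    """Five seeded train/evaluate runs on the separable cohort.

    Each run uses its own subject-disjoint split (fold 0 of a seeded
    5-fold partition: 26 train / 6 validation / 8 test subjects) and a
    short training schedule; AUCs are computed per role and the test
    scores of the first run are kept for the permutation null.
    """
    x, y, subjects = (separable_cohort[k] for k in ("x", "y", "subjects"))
    runs = []
    for seed in range(5):
        fold = make_subject_folds(subjects, k=5, val_fraction=0.2, seed=seed)[0]
        rng = np.random.default_rng(1000 + seed)
        masks = {
            "train": np.isin(subjects, fold.train_subjects),
            "val": np.isin(subjects, fold.validation_subjects),
            "test": np.isin(subjects, fold.test_subjects),
        }
        sel = {}
        for role, per_rec in (("train", 6), ("val", 10), ("test", 10)):
            idx = np.nonzero(masks[role])[0]
            sub = subsample_per_recording(y[idx], subjects[idx], per_rec, rng)
            sel[role] = idx[sub]
        model = scindex.SpectrogramCNN(
            x[sel["train"]], y[sel["train"]],
            subject_ids=subjects[sel["train"]])
        res = model.fit(
            scindex.TrainConfig(max_epochs=6, early_stop_patience=3, seed=seed),
            validation=(x[sel["val"]], y[sel["val"]], subjects[sel["val"]]))
        aucs = {role: roc_auc_score(y[sel[role]], res.pain_index(x[sel[role]]))
                for role in sel}
        run = {"seed": seed, "auc": aucs,
               "history": res.history, "best_epoch": res.best_epoch}
        if seed == 0:
            run["test_scores"] = res.pain_index(x[sel["test"]])
            run["test_labels"] = y[sel["test"]]
            run["results"] = res
        runs.append(run)
    return runs


@pytest.fixture(scope="session")
def null_cohort_auc():
    """Held-out patch-level AUC after training on a null cohort (pain
    parameters identical to no-pain): there is no signal to learn."""
    params = scindex.SynthCohortParams(n_subjects=60, seed=21).null_cohort()
    x, y, subjects = cohort_patch_arrays(params)
    uniq = sorted(set(subjects.tolist()))
    rng = np.random.default_rng(0)
    order = rng.permutation(uniq)
    train_ids, val_ids, test_ids = order[:8], order[8:10], order[10:]
    sel = {}
    for role, ids, per_rec in (("train", train_ids, 6), ("val", val_ids, 8),
                               ("test", test_ids, 6)):
        idx = np.nonzero(np.isin(subjects, ids))[0]
        sub = subsample_per_recording(y[idx], subjects[idx], per_rec, rng)
        sel[role] = idx[sub]
    model = scindex.SpectrogramCNN(x[sel["train"]], y[sel["train"]],
                                   subject_ids=subjects[sel["train"]])
    res = model.fit(scindex.TrainConfig(max_epochs=2, seed=0),
                    validation=(x[sel["val"]], y[sel["val"]], subjects[sel["val"]]))
    return float(roc_auc_score(y[sel["test"]], res.pain_index(x[sel["test"]])))


@pytest.fixture(scope="session")
def tiny_trained():
    """A quickly trained scorer on random patches, for interface tests
    (determinism, persistence, scoring) that do not need a learned signal."""
    rng = np.random.default_rng(0)
    x = rng.random((48, 124, 124), dtype=np.float32)
    y = np.tile([0, 1], 24)
    x[y == 1, 10:30, :] += 0.4  # make the classes learnable
    model = scindex.SpectrogramCNN(x, y)
    return model.fit(scindex.TrainConfig(max_epochs=1, seed=1))
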