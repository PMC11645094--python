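"""Shared fixtures: a scaled-down study cohort and trained fold models.

Training uses a reduced budget (40 epochs, batch 16, learning rate 1e-3,
up to 3 KL-gated restarts) so the whole suite stays within CPU-minutes;
heavier session fixtures are shared across the tests that need them.
"""

import warnings

import numpy as np
import pandas as pd
import pytest

from fatlat import aae
from fatlat import preprocess as pp
from fatlat import synthio as sio

#: reduced training budget used throughout the suite
SCALED = dict(batch_size=16, lr=1e-3, max_epochs=40, n_restarts=3)


@pytest.fixture(autouse=True)
def quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture(scope="session")
def study_cohort():
    """In-memory synthetic cohort: 10 Group-A and 4 Group-B subjects."""
    cfg = sio.GeneratorConfig(n_group_a=10, n_group_b=4, sets_range=(6, 10),
                              seed=202)
    manifest, reps = sio.generate_cohort(cfg)
    return sio.InMemoryCohort(manifest, reps)


def _preprocessed(cohort, db):
    ds = pp.assemble_dataset(cohort, db)
    X, y = pp.dataset_arrays(ds)
    pid = np.array([d.participant_id for d in ds])
    return ds, X, y, pid


@pytest.fixture(scope="session")
def db4_model(study_cohort):
    """Res-SSAAE trained on synthetic DB4 with 8 train / 2 val subjects."""
    group_a = sorted(p.id for p in study_cohort.manifest.participants
                     if p.group == "A")
    _, X, y, pid = _preprocessed(study_cohort, "DB4")
    tr, va = group_a[:8], group_a[8:]
    trm, vam = np.isin(pid, tr), np.isin(pid, va)
    stats = pp.compute_standardization(X[trm], [t for _, t in pp.db_channels("DB4")])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = aae.AdversarialAutoencoder(random_state=40, **SCALED)
        model.fit(stats.transform(X[trm]), y[trm],
                  X_val=stats.transform(X[vam]), y_val=y[vam])
    return {"model": model, "stats": stats,
            "X_val": stats.transform(X[vam]), "y_val": y[vam]}


@pytest.fixture(scope="session")
def db3_bundles(study_cohort):
    """Two user-independent DB3 folds: trained, fine-tuned on Group B.

    Returns per-fold (model, stats) plus pre/post fine-tune validation
    accuracies, and an ``encode_group_b`` helper producing a tidy latents
    table for any Group-B-only cohort.
    """
    participants = study_cohort.manifest.participants
    group_a = sorted(p.id for p in participants if p.group == "A")
    group_b = sorted(p.id for p in participants if p.group == "B")
    _, X, y, pid = _preprocessed(study_cohort, "DB3")
    types = [t for _, t in pp.db_channels("DB3")]
    folds = [(group_a[:5], group_a[5:]), (group_a[5:], group_a[:5])]
    bundles, pre_accs, post_accs = [], [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k, (tr, va) in enumerate(folds):
            trm, vam, bm = (np.isin(pid, s) for s in (tr, va, group_b))
            stats = pp.compute_standardization(X[trm], types)
            model = aae.AdversarialAutoencoder(random_state=1000 + k, **SCALED)
            model.fit(stats.transform(X[trm]), y[trm],
                      X_val=stats.transform(X[vam]), y_val=y[vam])
            pre_accs.append(model.score(stats.transform(X[vam]), y[vam]))
            model.fine_tune(stats.transform(X[bm]), y[bm], epochs=10)
            post_accs.append(model.score(stats.transform(X[vam]), y[vam]))
            bundles.append((model, stats))

    def encode_group_b(manifest, reps):
        cohort = sio.InMemoryCohort(manifest, reps)
        ds = pp.assemble_dataset(cohort, "DB3")
        Xb, yb = pp.dataset_arrays(ds)
        frames = []
        for k, (model, stats) in enumerate(bundles):
            z = model.transform(stats.transform(Xb), yb)
            frames.append(pd.DataFrame({
                "participant": [d.participant_id for d in ds],
                "exercise": [d.exercise for d in ds],
                "set": [d.set_index for d in ds],
                "rep": [d.rep_index for d in ds],
                "z1": z[:, 0], "z2": z[:, 1], "fold": k, "variant": "res"}))
        return pd.concat(frames, ignore_index=True)

    return {"bundles": bundles, "pre_ft_accuracy": pre_accs,
            "post_ft_accuracy": post_accs, "encode_group_b": encode_group_b}
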