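"""Shared fixtures: the desk-scale fixture profile and trained models.

Training runs are expensive, so everything downstream of them (classifier
checks, saliency statistics, acceptance tests) shares session-scoped
fixtures built from one fixed protocol: 32 x 32 x 16 grid, feature size 8
with 4 downsamples, 4 masking blocks of edge 8, pretraining 20 epochs on 8
phantoms, fine-tuning 30 epochs at cosine lr 3e-3 -> 1e-9 on 40 subjects
per class.
"""

from __future__ import annotations

import numpy as np
import pytest

from neuromae import classifier as clf
from neuromae import masking as mk
from neuromae import phantom
from neuromae import recon_model as rm
from neuromae import saliency_stats as ss
from neuromae._seeds import derive_seed

GRID = (32, 32, 16)


@pytest.fixture(scope="session")
def encoder_cfg() -> rm.EncoderConfig:
    return rm.EncoderConfig(feature_size=8, input_grid=GRID, n_downsamples=4, seed=0)


@pytest.fixture(scope="session")
def mask_scheme() -> mk.MaskScheme:
    return mk.MaskScheme(n_blocks=4, block_edge=8, fill_value=0.0, seed=1)


@pytest.fixture(scope="session")
def finetune_cfg() -> clf.FinetuneConfig:
    return clf.FinetuneConfig(lr_init=3e-3, lr_floor=1e-9, epochs=30, batch_size=8, seed=0)


@pytest.fixture(scope="session")
def occlusion_params() -> ss.OcclusionParams:
    return ss.OcclusionParams(patch_edge=8, stride=4, fill_value=0.0)


@pytest.fixture(scope="session")
def pretrain_corpus():
    """Eight noise-free phantoms: the tiny self-supervised corpus."""
    vols = []
    for i in range(8):
        tmap = phantom.generate_tissue_map(GRID, derive_seed(0, 7000 + i))
        vols.append(phantom.render_contrasts(tmap, 0.0, 0.0, derive_seed(i, 2)))
    return vols


@pytest.fixture(scope="session")
def pretrain_result(encoder_cfg, mask_scheme, pretrain_corpus, tmp_path_factory):
    model = rm.build_autoencoder(encoder_cfg)
    cfg = rm.PretrainConfig(
        learning_rate=1e-3, epochs=20, eval_interval=5, batch_size=4, seed=0,
        held_out_test_size=2, mask_scheme=mask_scheme,
    )
    out = tmp_path_factory.mktemp("pretrain")
    return rm.train_pretrain(model, pretrain_corpus, cfg, out_dir=out)


@pytest.fixture(scope="session")
def high_cohort() -> phantom.PhantomCohort:
    return phantom.generate_cohort(
        phantom.CohortSpec(n_per_class=40, effect_size=1.0, master_seed=0))


@pytest.fixture(scope="session")
def null_cohort() -> phantom.PhantomCohort:
    return phantom.generate_cohort(
        phantom.CohortSpec(n_per_class=40, effect_size=0.0, master_seed=0))


def _finetune(cohort, encoder_cfg, finetune_cfg, checkpoint):
    model = clf.build_classifier(encoder_cfg, hidden_width=128,
                                 pretrained_checkpoint=checkpoint)
    splits = {n: cohort.split(n) for n in ("train", "val", "test")}
    result = clf.train_finetune(model, splits, finetune_cfg)
    preds = clf.predict(result.model, splits["test"])
    return result, preds


@pytest.fixture(scope="session")
def clf_high(high_cohort, encoder_cfg, finetune_cfg, pretrain_result):
    return _finetune(high_cohort, encoder_cfg, finetune_cfg,
                     pretrain_result.checkpoint_path)


@pytest.fixture(scope="session")
def clf_null(null_cohort, encoder_cfg, finetune_cfg, pretrain_result):
    return _finetune(null_cohort, encoder_cfg, finetune_cfg,
                     pretrain_result.checkpoint_path)


@pytest.fixture(scope="session")
def saliency_positive(clf_high, occlusion_params):
    """Smoothed occlusion maps of correctly classified high-effect subjects.

    A fresh evaluation cohort (15/class) stands in for the independent test
    set; returns (maps_by_class, lesion_union).
    """
    result, _ = clf_high
    cohort = phantom.generate_cohort(
        phantom.CohortSpec(n_per_class=15, effect_size=1.0, master_seed=1))
    preds = clf.predict(result.model, cohort.subjects)
    correct = (preds["predicted_label"] == preds["true_label"]).to_numpy()
    maps = {"A": [], "B": []}
    lesion_union = np.zeros(GRID, dtype=bool)
    for ok, subj in zip(correct, cohort.subjects):
        if not ok:
            continue
        m = ss.occlusion_map(result.model, subj.volume, subj.class_label,
                             occlusion_params)
        maps[subj.class_label].append(ss.smooth_map(m, 4.0))
        lesion_union |= subj.lesion_mask
    return maps, lesion_union


@pytest.fixture(scope="session")
def null_map_pool(clf_null, occlusion_params):
    """Occlusion maps of a pool of 80 effect-free subjects (40 per arbitrary class).

    Every map is computed against the same fixed target class: with two
    classes the P(A) and P(B) occlusion deltas are exact negatives, so maps
    taken w.r.t. each subject's own (arbitrary) label would differ between
    the groups by sign alone.  With a fixed target the maps are iid and any
    subset forms an exchangeable two-group sample.
    """
    result, _ = clf_null
    cohort = phantom.generate_cohort(
        phantom.CohortSpec(n_per_class=40, effect_size=0.0, master_seed=2))
    maps = {"A": [], "B": []}
    for subj in cohort.subjects:
        m = ss.occlusion_map(result.model, subj.volume, "A", occlusion_params)
        maps[subj.class_label].append(ss.smooth_map(m, 4.0))
    return maps
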