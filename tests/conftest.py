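import numpy as np
import pytest

from sparsect.metrics import evaluate
from sparsect.networks import build_3lssnet, build_resunet
from sparsect.phantoms import PhantomSpec, generate_dataset
from sparsect.projector import make_geometry
from sparsect.training import (DESK_IMAGE_SIZE, build_pairs,
                               desk_train_config, train)


def make_disk(size: int, radius: float, supersample: int = 4) -> np.ndarray:
    """Area-weighted rasterization of a centred disk."""
    n = size * supersample
    yy, xx = np.mgrid[0:n, 0:n]
    c = (n - 1) / 2.0
    d = ((xx - c) ** 2 + (yy - c) ** 2 <= (radius * supersample) ** 2)
    d = d.astype(float)
    if supersample == 1:
        return d
    return d.reshape(size, supersample, size, supersample).mean(axis=(1, 3))


@pytest.fixture(scope="session")
def disk128():
    return make_disk(128, 40.0)


@pytest.fixture(scope="session")
def desk_study():
    """The desk-scale training study shared by the training-efficacy and
    OOD acceptance checks: one network per architecture and geometry
    preset (the study protocol), trained with the desk recipe (15 epochs,
    batch 8, fixed seeds) on 100 pairs per preset — 200 pairs per
    architecture across the two protocol-specific trainings — at the
    package's desk image size, and evaluated against FBP per preset."""
    size = DESK_IMAGE_SIZE
    tmpl = PhantomSpec(family="chest-like", size=size)
    gts_train = generate_dataset(100, tmpl, seed=7, split="train")
    gts_test = generate_dataset(12, tmpl, seed=7, split="test")

    models = {}
    histories = {}
    test_sets = {}
    reports = {}
    for tag in ("full-range", "half-range"):
        geom = make_geometry(tag, size)
        train_set = build_pairs(gts_train, geom, 1e-2, seed=11)
        test_sets[tag] = build_pairs(gts_test, geom, 1e-2, seed=13,
                                     split="test")
        reports[tag] = {"FBP": evaluate(None, test_sets[tag])}
        for name, spec in [("3l-ssnet", build_3lssnet()),
                           ("resunet", build_resunet(c0=16))]:
            cfg = desk_train_config(name, seed=1)
            net, hist = train(spec, train_set, cfg)
            models[name, tag] = net
            histories[name, tag] = hist
            reports[tag][name] = evaluate(net, test_sets[tag], method=name)
    return {"size": size, "models": models, "histories": histories,
            "test_sets": test_sets, "reports": reports,
            "train_noise": 1e-2}
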