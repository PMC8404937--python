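"""Out-of-domain robustness protocol.

Two stress scenarios probe a trained post-processing network on inputs
whose statistics differ from the training distribution:

* ``unseen-noise`` — same phantom family, measurement noise raised above
  the training level (2e-2 vs the 1e-2 training default);
* ``unseen-image`` — training noise level, but the noise-free flat-sharp
  phantom family (flat regions with small sharp objects) replacing the
  textured chest-like family.

Every OOD report carries the paired in-domain evaluation computed under
identical conditions, so the robustness gap is a logged quantity rather
than an assumption about which network degrades more.
"""

from __future__ import annotations

from dataclasses import dataclass

from .fbp import FilterSpec
from .metrics import MetricsReport, evaluate
from .networks import Network
from .phantoms import PhantomSpec, generate_dataset
from .projector import make_geometry
from .training import build_pairs

__all__ = ["OODScenario", "run_ood", "TRAIN_NOISE_LEVEL", "OOD_NOISE_LEVEL"]

TRAIN_NOISE_LEVEL = 1e-2
OOD_NOISE_LEVEL = 2e-2


@dataclass(frozen=True)
class OODScenario:
    """kind: "unseen-noise" (in-domain family, raised noise) or
    "unseen-image" (flat-sharp family, training noise)."""
    kind: str
    geometry_tag: str = "full-range"
    noise_level: float = OOD_NOISE_LEVEL     # unseen-noise only
    family: str = "flat-sharp"               # unseen-image only

    def __post_init__(self):
        if self.kind not in ("unseen-noise", "unseen-image"):
            raise ValueError(f"unknown OOD scenario kind {self.kind!r}")


def run_ood(model: Network, scenario: OODScenario, *, image_size: int,
            n_images: int = 16, seed: int = 0,
            in_domain_family: str = "chest-like",
            train_noise: float = TRAIN_NOISE_LEVEL,
            filt: FilterSpec = FilterSpec()) -> dict:
    """Evaluate a trained model under an OOD scenario and its paired
    in-domain baseline.

    Returns {"in_domain": MetricsReport, "ood": MetricsReport,
    "delta": mean metric differences (ood - in_domain)}.  Raises if the
    model has not been trained.
    """
    if not getattr(model, "trained", False):
        raise ValueError("run_ood requires a trained network")
    geom = make_geometry(scenario.geometry_tag, image_size)

    base_spec = PhantomSpec(family=in_domain_family, size=image_size)
    gts_id = generate_dataset(n_images, base_spec, seed=seed, split="test")
    pairs_id = build_pairs(gts_id, geom, train_noise, filt,
                           seed=seed + 1, split="test")

    if scenario.kind == "unseen-noise":
        gts_ood = gts_id
        pairs_ood = build_pairs(gts_ood, geom, scenario.noise_level, filt,
                                seed=seed + 1, split="test")
    else:
        ood_spec = PhantomSpec(family=scenario.family, size=image_size,
                               texture_sigma=0.0)
        gts_ood = generate_dataset(n_images, ood_spec, seed=seed,
                                   split="test")
        pairs_ood = build_pairs(gts_ood, geom, train_noise, filt,
                                seed=seed + 1, split="test")

    rep_id = evaluate(model, pairs_id)
    rep_ood = evaluate(model, pairs_ood)
    fbp_id = evaluate(None, pairs_id)
    fbp_ood = evaluate(None, pairs_ood)
    delta = {k: rep_ood.means[k] - rep_id.means[k] for k in rep_id.means}
    return {"in_domain": rep_id, "ood": rep_ood,
            "in_domain_fbp": fbp_id, "ood_fbp": fbp_ood,
            "delta": delta, "scenario": scenario}
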