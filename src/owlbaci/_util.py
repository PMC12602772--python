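"""Small shared numerics: link functions and seed plumbing."""

from __future__ import annotations

import numpy as np
from numpy.random import Generator, SeedSequence, default_rng
from scipy.special import expit, logit  # noqa: F401  (re-exported)

__all__ = ["expit", "logit", "stage_seed", "rng_for", "split_rngs"]


def stage_seed(master: int, stage: str) -> int:
    """Derive a stable per-stage integer seed (< 2**31) from a master seed.

    The stage name is folded into the entropy so that changing one stage's
    label (or adding a stage) never perturbs another stage's stream.
    """
    entropy = [int(master)] + [ord(c) for c in stage]
    return int(SeedSequence(entropy).generate_state(1, dtype=np.uint32)[0] >> 1)


def rng_for(master: int, stage: str) -> Generator:
    return default_rng(stage_seed(master, stage))


def split_rngs(seed: int, n: int) -> list[Generator]:
    """n independent generators spawned from one seed (chain streams)."""
    return [default_rng(s) for s in SeedSequence(int(seed)).spawn(n)]
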