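"""Shared fixtures: small trained networks reused across test modules.

Training runs once per session on seeded synthetic corpora at reduced
network size (shorter history, 64 hidden units) so the suite stays within a
single-CPU budget while exercising the full training path.
"""

import numpy as np
import pytest

from mirrorgame.follow_net import FollowNetConfig, make_windows, train_follow
from mirrorgame.synthetic import SynthesisConfig, generate_dyad_corpus

RATE = 90.0

#: Reduced-size follow-net used throughout the suite.
TOY_FOLLOW_CONFIG = FollowNetConfig(
    history=40, stride=4, hidden=64, dense_widths=(64,), epochs=15
)


@pytest.fixture(scope="session")
def toy_follow():
    """Follow-net trained on a lag-0, zero-noise corpus (identity coupling),
    plus a held-out trial from a different seed."""
    corpus = generate_dyad_corpus(
        SynthesisConfig(seed=11, rate=RATE, lag=0, follower_noise=0.0),
        2,
        ("lead", "follow"),
        duration=30.0,
    )
    model, losses = train_follow(corpus, TOY_FOLLOW_CONFIG, seed=5)
    held = generate_dyad_corpus(
        SynthesisConfig(seed=99, rate=RATE, lag=0, follower_noise=0.0),
        1,
        ("lead",),
        duration=10.0,
    )[0]
    return {
        "model": model,
        "losses": losses,
        "config": TOY_FOLLOW_CONFIG,
        "corpus": corpus,
        "held": held,
    }


@pytest.fixture(scope="session")
def lag20_follow():
    """Follow-net trained on a 20-frame-lag, zero-noise corpus, with a fresh
    long leader for rollout checks."""
    corpus = generate_dyad_corpus(
        SynthesisConfig(seed=21, rate=RATE, lag=20, follower_noise=0.0),
        2,
        ("lead", "follow"),
        duration=30.0,
    )
    model, losses = train_follow(corpus, TOY_FOLLOW_CONFIG, seed=6)
    fresh_leader = generate_dyad_corpus(
        SynthesisConfig(seed=77, rate=RATE, lag=20, follower_noise=0.0),
        1,
        ("lead",),
        duration=60.0,
    )[0].leader
    return {
        "model": model,
        "losses": losses,
        "config": TOY_FOLLOW_CONFIG,
        "corpus": corpus,
        "leader": fresh_leader,
    }
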