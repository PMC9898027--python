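"""Shared fixtures.

The trained ranking model is expensive (minutes), so one session-scoped
study feeds every test that needs real CIF scores. Unit tests that only
need *a* calibrated scorer use the cheap intensity stub instead.
"""

from __future__ import annotations

import numpy as np
import pytest

from reticulin_cif import pipeline as pl
from reticulin_cif.ranker import RankingModel


class _IntensityScorer:
    """Stub backbone: score = mean darkness of the tile (no learning)."""

    input_size = 32
    channels = ()
    in_channels = 2

    def score(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 2:
            x = x[None]
        # channel 1 of preprocessed tiles is the dark-pixel fraction
        if x.ndim == 4:
            return x[..., -1].mean(axis=(1, 2))
        return -x.mean(axis=(1, 2))


@pytest.fixture()
def intensity_model() -> RankingModel:
    """Calibrated stand-in model whose score is mean tile darkness."""
    return RankingModel(
        scorer=_IntensityScorer(), input_size=32, norm_low=-0.5, norm_high=0.0
    )


@pytest.fixture(scope="session")
def demo_study() -> dict:
    """The scaled-down ranking study: trained + calibrated model and metrics."""
    return pl.train_demo_ranker(seed=20260101)


@pytest.fixture(scope="session")
def demo_model(demo_study):
    return demo_study["model"]
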