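"""Classical-test records: social recognition, odor discrimination,
dark-light box."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import SimConfig

SRT_ENCOUNTERS = ("Hab", "E1", "E2", "E3", "E4", "Enew")


def simulate_srt(
    config: SimConfig, genotype: str, animals, rng: np.random.Generator
) -> pd.DataFrame:
    """Interaction durations (s) per encounter of the recognition task."""
    params = config.genotype_params[genotype]
    rows = []
    for animal in animals:
        sociability = float(np.exp(rng.normal(0.0, 0.15)))
        durations = {
            enc: float(
                np.round(
                    max(0.5, rng.normal(params.srt_mean_s[enc] * sociability,
                                        params.srt_mean_s[enc] * 0.15)),
                    1,
                )
            )
            for enc in SRT_ENCOUNTERS
        }
        rows.append({"animal": animal, **durations})
    return pd.DataFrame(rows).set_index("animal")


def simulate_odor(
    config: SimConfig, genotype: str, animals, rng: np.random.Generator
) -> pd.DataFrame:
    """Exploration time (s) of social (spoiled) vs fresh bedding."""
    rows = []
    for animal in animals:
        rows.append(
            {
                "animal": animal,
                "time_spoiled_s": float(np.round(max(0.5, rng.normal(40.0, 10.0)), 1)),
                "time_fresh_s": float(np.round(max(0.5, rng.normal(25.0, 8.0)), 1)),
            }
        )
    return pd.DataFrame(rows).set_index("animal")


def simulate_dlbox(
    config: SimConfig, genotype: str, animals, rng: np.random.Generator
) -> pd.DataFrame:
    """Dark-light box visit summaries over the 10-min session."""
    rows = []
    for animal in animals:
        dark_time = float(np.clip(rng.normal(350.0, 80.0), 0.0, 600.0))
        first_visit = float(np.clip(rng.normal(60.0, 25.0), 0.0, dark_time if dark_time > 0 else 0.0))
        rows.append(
            {
                "animal": animal,
                "first_dark_visit_s": np.round(first_visit, 1),
                "n_risk_assessments": int(rng.poisson(8.0)),
                "dark_time_s": np.round(dark_time, 1),
            }
        )
    return pd.DataFrame(rows).set_index("animal")
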