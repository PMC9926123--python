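"""Configuration of the synthetic colony generator.

The generator emulates the study design it stands in for: cohorts of six
same-genotype rats housed four days in the instrumented burrow cage
(RFID dwell streams, scan-sampled ethogram events, pre/post body weight
and fecal corticosterone), plus the operant and classical test records
of the same animals.  Genotype presets encode the direction and size of
the effects: large (Cohen's d around 2) on the home-cage and physiology
variables, null on the cognitive task variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from ..grid import ZoneGrid, default_vbs_grid

DM_CLASSES = ("GDM", "INT", "PDM")
FLEX_CLASSES = ("flexible", "undecided", "inflexible")

DDT_DELAYS_S = (0.0, 10.0, 20.0, 30.0, 40.0)
PDT_PROBABILITIES = (0.66, 0.33, 0.20, 0.14, 0.09)


@dataclass(frozen=True)
class GenotypeParams:
    """Per-genotype generating parameters.

    Rates are events per animal per scored 4-h phase; dwell and zone
    weights drive the 1-Hz Markov walk over the detector grid; mixtures
    and steepness parameters drive the operant records.
    """

    name: str
    # dyadic/solitary ethogram event rates (events / animal / 4-h phase)
    event_rates: dict = field(default_factory=dict)
    #: relative initiator propensity of the group's despot (animal 0)
    #: for aggressive and sexual interactions
    despot_weight: float = 6.0
    # movement: zone preference by label and mean dwell per detector visit
    zone_label_weights: dict = field(default_factory=dict)
    mean_dwell_s: float = 40.0
    light_phase_dwell_factor: float = 2.5
    light_phase_event_factor: float = 0.5
    # physiology
    weight_before_g: tuple = (300.0, 15.0)
    weight_change_g: tuple = (-5.0, 3.0)     # after - before; negative = loss
    cort_before_ugg: tuple = (2.0, 0.4)
    cort_multiplier: tuple = (1.1, 0.25)
    # operant decision making
    dm_mixture: tuple = (0.74, 0.09, 0.17)   # GDM / INT / PDM proportions
    dm_asymptote: dict = field(
        default_factory=lambda: {"GDM": 0.92, "INT": 0.50, "PDM": 0.10}
    )
    reward_latency_s: dict = field(
        default_factory=lambda: {"GDM": 1.6, "INT": 1.3, "PDM": 1.0}
    )
    flex_mixture: tuple = (0.40, 0.20, 0.40)  # flexible/undecided/inflexible
    #: hyperbolic delay steepness; 0.2 /s puts the large-vs-small
    #: indifference point (5/(1+kD) = 1) at a 20-s delay
    ddt_k_per_s: float = 0.2
    pdt_h_per_odds: float = 1.0               # hyperbolic odds steepness
    choice_temperature: float = 0.8
    # classical tests
    srt_mean_s: dict = field(
        default_factory=lambda: {
            "Hab": 25.0, "E1": 60.0, "E2": 45.0, "E3": 30.0,
            "E4": 35.0, "Enew": 55.0,
        }
    )

    def __post_init__(self):
        if any(r < 0 for r in self.event_rates.values()):
            raise ValueError("event rates must be non-negative")
        for mix, names in ((self.dm_mixture, "dm_mixture"),
                           (self.flex_mixture, "flex_mixture")):
            if abs(sum(mix) - 1.0) > 1e-9 or any(p < 0 for p in mix):
                raise ValueError(f"{names} must be non-negative and sum to 1")
        if self.mean_dwell_s <= 0 or self.choice_temperature <= 0:
            raise ValueError("dwell time and choice temperature must be positive")
        if self.ddt_k_per_s < 0 or self.pdt_h_per_odds < 0:
            raise ValueError("discounting steepness must be non-negative")


#: home-cage behavior rates of the control genotype
_WT_RATES = {
    "huddling": 12.0, "sniffing": 8.0, "allogrooming": 1.0, "attending": 1.5,
    "general_aggression": 2.0, "struggling_at_feeder": 2.5,
    "sexual": 0.3, "defensive": 1.5,
    "eating": 6.0, "drinking": 2.0, "grooming": 5.0,
}

#: serotonin-depleted genotype: more aggression/sexual/defensive/sniffing,
#: less huddling, feeding and self-care
_KO_RATES = {
    "huddling": 6.0, "sniffing": 12.0, "allogrooming": 0.7, "attending": 1.5,
    "general_aggression": 6.0, "struggling_at_feeder": 1.0,
    "sexual": 4.0, "defensive": 5.0,
    "eating": 3.0, "drinking": 1.2, "grooming": 2.5,
}

_WT_ZONE_WEIGHTS = {
    "open_area": 1.2, "feeder": 3.0, "water": 2.0, "tunnel": 1.0, "burrow": 1.0,
}
_KO_ZONE_WEIGHTS = {
    "open_area": 0.5, "feeder": 0.4, "water": 0.4, "tunnel": 3.0, "burrow": 4.0,
}


def wildtype_params() -> GenotypeParams:
    return GenotypeParams(
        name="wildtype",
        event_rates=dict(_WT_RATES),
        zone_label_weights=dict(_WT_ZONE_WEIGHTS),
        mean_dwell_s=40.0,
        weight_change_g=(-5.0, 3.0),
        cort_multiplier=(1.1, 0.25),
        dm_mixture=(0.74, 0.09, 0.17),
    )


def knockout_params() -> GenotypeParams:
    return GenotypeParams(
        name="knockout",
        event_rates=dict(_KO_RATES),
        zone_label_weights=dict(_KO_ZONE_WEIGHTS),
        mean_dwell_s=20.0,                 # hyperactive
        despot_weight=3.0,                 # less stable hierarchy
        weight_change_g=(-25.0, 5.0),      # pronounced weight loss
        cort_multiplier=(3.0, 0.6),        # corticosterone surge
        dm_mixture=(0.73, 0.10, 0.17),     # cognition unaffected
    )


@dataclass(frozen=True)
class SimConfig:
    """Study layout and per-genotype generating parameters."""

    n_groups_per_genotype: dict = field(
        default_factory=lambda: {"wildtype": 8, "knockout": 5}
    )
    group_size: int = 6
    n_days: int = 4
    grid: ZoneGrid = field(default_factory=default_vbs_grid)
    genotype_params: dict = field(
        default_factory=lambda: {
            "wildtype": wildtype_params(),
            "knockout": knockout_params(),
        }
    )
    phase_seconds: int = 12 * 3600
    seed: int = 0

    def __post_init__(self):
        if self.group_size < 2:
            raise ValueError("group_size must be >= 2")
        for geno in self.n_groups_per_genotype:
            if geno not in self.genotype_params:
                raise ValueError(f"no parameters for genotype {geno!r}")


def null_config(seed: int = 0, n_groups: int | dict = 4) -> SimConfig:
    """A no-signal study: both genotype labels share the control parameters.

    Used to check that the discrimination stage reports chance accuracy
    when nothing distinguishes the genotypes.  The default is a balanced
    cohort (equal groups per label).
    """
    if isinstance(n_groups, int):
        n_groups = {"wildtype": n_groups, "knockout": n_groups}
    wt = wildtype_params()
    return SimConfig(
        n_groups_per_genotype=dict(n_groups),
        genotype_params={
            "wildtype": wt,
            "knockout": replace(wt, name="knockout"),
        },
        seed=seed,
    )


def config_from_yaml(path) -> SimConfig:
    """Load a SimConfig from a YAML file of keyword overrides."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    genos = {}
    for name, overrides in raw.pop("genotype_params", {}).items():
        base = wildtype_params() if name == "wildtype" else knockout_params()
        genos[name] = replace(base, name=name, **overrides)
    kwargs = dict(raw)
    if genos:
        kwargs["genotype_params"] = genos
    return SimConfig(**kwargs)
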