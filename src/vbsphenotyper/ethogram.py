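"""Ethogram of scored home-cage behaviors.

Every scored behavior belongs to exactly one of five categories
(affiliative, aggressive, sexual, defensive, maintenance) and to exactly
one *grouped* label used for counting and network construction: the three
sniffing variants collapse to ``sniffing``, every aggressive behavior
except struggling at the feeder collapses to ``general_aggression``, and
mounting + embracing collapse to ``sexual``.

Affiliative, aggressive and sexual behaviors are dyadic (a receiver is
required); defensive and maintenance behaviors are scored on the focal
animal alone (a receiver may still be recorded for defensive behaviors,
e.g. who the animal fled from).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Behavior:
    name: str
    category: str
    grouped_category: str


#: name -> (category, grouped label)
_ETHOGRAM = {
    # affiliative
    "allogrooming": ("affiliative", "allogrooming"),
    "attending": ("affiliative", "attending"),
    "huddle": ("affiliative", "huddling"),
    "sniffing_anogenital": ("affiliative", "sniffing"),
    "sniffing_nose": ("affiliative", "sniffing"),
    "sniffing_body": ("affiliative", "sniffing"),
    # aggressive
    "struggling_at_feeder": ("aggressive", "struggling_at_feeder"),
    "aggressive_grooming": ("aggressive", "general_aggression"),
    "attack": ("aggressive", "general_aggression"),
    "following": ("aggressive", "general_aggression"),
    "fight": ("aggressive", "general_aggression"),
    "mutual_upright_posture": ("aggressive", "general_aggression"),
    "pinning": ("aggressive", "general_aggression"),
    "struggle_in_tunnels": ("aggressive", "general_aggression"),
    # sexual
    "mounting": ("sexual", "sexual"),
    "embracing": ("sexual", "sexual"),
    # defensive (solitary: scored on the focal animal)
    "flight": ("defensive", "defensive"),
    "freezing": ("defensive", "defensive"),
    "lateral_defense": ("defensive", "defensive"),
    "supine_posture": ("defensive", "defensive"),
    "upright_defense": ("defensive", "defensive"),
    # maintenance (solitary)
    "drinking": ("maintenance", "drinking"),
    "eating": ("maintenance", "eating"),
    "grooming": ("maintenance", "grooming"),
}

ETHOGRAM = {
    name: Behavior(name, cat, grp) for name, (cat, grp) in _ETHOGRAM.items()
}

CATEGORIES = ("affiliative", "aggressive", "sexual", "defensive", "maintenance")

#: categories whose events are directed dyads (receiver required)
DYADIC_CATEGORIES = frozenset({"affiliative", "aggressive", "sexual"})

GROUPED_CATEGORIES = tuple(
    dict.fromkeys(b.grouped_category for b in ETHOGRAM.values())
)


def behavior(name: str) -> Behavior:
    """Look up a behavior by name; raise for labels not in the ethogram."""
    try:
        return ETHOGRAM[name]
    except KeyError:
        raise KeyError(f"unknown behavior label: {name!r}") from None


def category_of(name: str) -> str:
    return behavior(name).category


def grouped_label_of(name: str) -> str:
    return behavior(name).grouped_category


def is_dyadic(name: str) -> bool:
    return behavior(name).category in DYADIC_CATEGORIES
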