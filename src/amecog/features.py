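"""Linguistic feature schemes for the 8 consonant-vowel syllables.

Two three-way gold-standard groupings of the consonants /b d g p t k sh s/:
by place of articulation (where the vocal tract constricts) and by manner
(voiced plosive / voiceless plosive / fricative), the acoustic scheme.
"""

from __future__ import annotations

from .errors import ParameterError
from .stats import Partition

#: Default CV syllable inventory.
TOKENS = ("ba", "da", "ga", "pa", "ta", "ka", "sha", "sa")

PLACE_GROUPS = {
    "labial": frozenset({"b", "p"}),
    "alveolar": frozenset({"d", "t", "s", "sh"}),
    "velar": frozenset({"g", "k"}),
}

MANNER_GROUPS = {
    "voiced_plosive": frozenset({"b", "d", "g"}),
    "voiceless_plosive": frozenset({"p", "t", "k"}),
    "fricative": frozenset({"s", "sh"}),
}

SCHEMES = {"place": PLACE_GROUPS, "manner": MANNER_GROUPS}


def consonant(token: str) -> str:
    """Consonant of a CV token (strips the trailing vowel)."""
    if len(token) < 2 or not token.endswith("a"):
        raise ParameterError(f"not a CV token: {token!r}")
    return token[:-1]


def token_group(token: str, scheme: str) -> str:
    """Feature group of a token's consonant under 'place' or 'manner'."""
    if scheme not in SCHEMES:
        raise ParameterError(f"unknown scheme {scheme!r}")
    c = consonant(token)
    for name, members in SCHEMES[scheme].items():
        if c in members:
            return name
    raise ParameterError(f"consonant {c!r} not covered by scheme {scheme!r}")


def scheme_partition(tokens, scheme: str) -> Partition:
    """Partition of ``tokens`` by their feature group under ``scheme``."""
    return Partition(tuple(tokens), tuple(token_group(t, scheme) for t in tokens))
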