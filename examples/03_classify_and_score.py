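"""Classify species presence patterns into communities and scores.

The classifier is a priority cascade over the five scored taxa; every one
of the 32 presence patterns lands in exactly one of seven communities
with an ordinal score 0 (bare rock) to 6 (mixed perennial Sargassum and
U. pinnatifida bed). Scores >= 3 count as rich vegetation.
"""

from boulderreef import (
    COMMUNITY_DISPLAY,
    SpeciesPresence,
    classify_vegetation,
    richness_dichotomy,
)

examples = [
    ("everything present", SpeciesPresence(True, True, True, True, True)),
    ("U. pinnatifida only", SpeciesPresence(True, False, False, False, False)),
    ("S. horneri + C. sinuosa", SpeciesPresence(False, False, True, True, False)),
    ("C. sinuosa only", SpeciesPresence(False, False, False, True, False)),
    ("nothing", SpeciesPresence(False, False, False, False, False)),
]
for label, presence in examples:
    community, score = classify_vegetation(presence)
    print(f"{label:25s} -> score {score}  {COMMUNITY_DISPLAY[community]:40s} "
          f"({richness_dichotomy(score)})")
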