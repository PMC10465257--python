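"""Published per-rater annotated-area counts from the clinical OCT grading
study this package models (10 B-scans, 5 clinicians, up to 2 rounds).

The source images are not publicly deposited, so these counts are the one
piece of the clinical study that can be checked exactly: the per-rater,
per-round numbers of annotated fluid areas must sum to the study's stated
grand total of annotated areas.
"""

from __future__ import annotations

__all__ = [
    "ANNOTATED_AREAS_ROUND1",
    "ANNOTATED_AREAS_ROUND2",
    "TOTAL_ANNOTATED_AREAS",
    "annotated_area_total",
]

# number of annotated fluid areas per clinician, round 1 (all 5 clinicians)
ANNOTATED_AREAS_ROUND1: dict[str, int] = {
    "Ex1": 411,
    "Ex2": 285,
    "Jr1": 219,
    "Jr2": 254,
    "Jr3": 307,
}

# round 2 (the 4 clinicians who annotated twice)
ANNOTATED_AREAS_ROUND2: dict[str, int] = {
    "Ex2": 285,
    "Jr1": 191,
    "Jr2": 111,
    "Jr3": 336,
}

# grand total of annotated areas stated for the whole study
TOTAL_ANNOTATED_AREAS: int = 2399


def annotated_area_total() -> int:
    """Sum of all published per-rater, per-round annotated-area counts."""
    return sum(ANNOTATED_AREAS_ROUND1.values()) + sum(
        ANNOTATED_AREAS_ROUND2.values()
    )
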