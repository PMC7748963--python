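"""Scoring of the momentary self-report instrument and the BIS-11 baseline.

The hourly ecological momentary assessment (EMA) has six items rated 0-6,
three of them negatively worded; the trait baseline is the sum of the six
Barratt Impulsiveness Scale (BIS-11) items loading on the second-order
self-control factor (higher sum = lower trait inhibitory control).
"""

from __future__ import annotations

from typing import Sequence

# Item order of the six momentary items; polarity True = positively worded.
EMA_ITEMS: tuple[tuple[str, bool], ...] = (
    ("force myself to stay focused", False),
    ("full of willpower", True),
    ("trouble pulling myself together", False),
    ("could resist any temptation", True),
    ("trouble paying attention", False),
    ("no trouble doing disagreeable things", True),
)

EMA_POLARITY: tuple[bool, ...] = tuple(p for _, p in EMA_ITEMS)

# Default BIS-11 second-order self-control items (1-based questionnaire
# numbering); configurable because published factor solutions vary.
BIS_SELF_CONTROL_ITEMS: tuple[int, ...] = (1, 7, 8, 12, 13, 14)


def aggregate_ema(
    scores: Sequence[int], polarity: Sequence[bool] = EMA_POLARITY
) -> int:
    """Aggregate the six momentary items into a 0-36 score.

    Negatively worded items are inverted (x -> 6 - x) before summing, so a
    higher aggregate always means higher self-reported inhibitory control.
    """
    if len(scores) != len(polarity):
        raise ValueError(f"expected {len(polarity)} item scores, got {len(scores)}")
    for s in scores:
        if not 0 <= s <= 6:
            raise ValueError(f"item score {s} outside 0-6")
    return sum(s if pos else 6 - s for s, pos in zip(scores, polarity))


def bis_self_control(
    item_scores: Sequence[int],
    items: Sequence[int] = BIS_SELF_CONTROL_ITEMS,
) -> int:
    """Sum the self-control subset of a 30-item BIS-11 response (range 6-24).

    ``item_scores`` holds all 30 items in questionnaire order (scores 1-4);
    ``items`` are 1-based indices of the subset.  No reverse scoring is
    applied inside the subset.
    """
    if len(item_scores) != 30:
        raise ValueError("BIS-11 has 30 items")
    if len(set(items)) != 6:
        raise ValueError("the self-control factor has exactly 6 distinct items")
    for s in item_scores:
        if not 1 <= s <= 4:
            raise ValueError(f"item score {s} outside 1-4")
    return sum(item_scores[i - 1] for i in items)
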