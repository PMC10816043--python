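"""k-of-7 damaging consensus over categorical pathogenicity predictors.

A variant is called *damaging* when at least ``k`` (default 3) of seven
voting units label it as not neutral to the encoded protein.  The voters are
SIFT, LRT, MutationTaster, PolyPhen-2, MutationAssessor, FATHMM and one
merged meta-predictor voter.  PolyPhen-2 HumDiv and HumVar feed a single
voter (damaging if either label is damaging), as do MetaSVM and MetaLR.
A voter with no label abstains, and abstentions count against the threshold:
the denominator stays at seven, so absence of evidence is not evidence of
damage.

Tool label vocabularies and their damaging/neutral binarisation live in a
packaged table (``data/predictor_vocab.tsv``); dialects (e.g. single-letter
codes) can be added there without a code change.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import TYPE_CHECKING, Mapping

if TYPE_CHECKING:  # pragma: no cover - import cycle guard, typing only
    from .variants import AnnotationRecord

#: The seven voting units, in canonical order.
VOTERS = (
    "SIFT",
    "LRT",
    "MutationTaster",
    "PolyPhen2",
    "MutationAssessor",
    "FATHMM",
    "Meta",
)

#: Annotation-table tool columns and the voter each one feeds.
TOOL_TO_VOTER = {
    "SIFT": "SIFT",
    "LRT": "LRT",
    "MutationTaster": "MutationTaster",
    "Polyphen2_HumDiv": "PolyPhen2",
    "Polyphen2_HumVar": "PolyPhen2",
    "MutationAssessor": "MutationAssessor",
    "FATHMM": "FATHMM",
    "MetaSVM": "Meta",
    "MetaLR": "Meta",
}

TOOL_COLUMNS = tuple(TOOL_TO_VOTER)

DAMAGING = "damaging"
NEUTRAL = "neutral"
ABSTAIN = "abstain"


class LabelError(ValueError):
    """A predictor label outside the tool's vocabulary."""


@lru_cache(maxsize=1)
def _vocabulary() -> dict[tuple[str, str], str]:
    vocab_path = resources.files("modscreen").joinpath("data", "predictor_vocab.tsv")
    table: dict[tuple[str, str], str] = {}
    with vocab_path.open() as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            table[(row["tool"], row["label"])] = row["vote"]
    return table


def binarize(tool: str, label: str) -> str:
    """Map one tool's categorical label to a ``damaging``/``neutral`` vote.

    Raises :class:`LabelError` naming the tool and label when either is
    outside the packaged vocabulary.
    """
    if tool not in TOOL_TO_VOTER:
        raise LabelError(f"unknown tool {tool!r}; accepted: {list(TOOL_COLUMNS)}")
    vote = _vocabulary().get((tool, label))
    if vote is None:
        known = sorted(l for (t, l) in _vocabulary() if t == tool)
        raise LabelError(f"{tool}: unknown label {label!r}; vocabulary: {known}")
    return vote


@dataclass(frozen=True)
class ConsensusVerdict:
    """The damaging-consensus outcome for one variant."""

    is_damaging: bool
    n_damaging_votes: int
    contributing_voters: tuple[str, ...]


def votes_from_labels(predictor_labels: Mapping[str, str]) -> dict[str, str]:
    """Collapse per-tool labels into one vote per voting unit.

    A merged voter (PolyPhen-2, Meta) votes damaging if any of its tools
    does; it abstains only when none of its tools made a call.
    """
    votes = {v: ABSTAIN for v in VOTERS}
    for tool, label in predictor_labels.items():
        voter = TOOL_TO_VOTER.get(tool)
        if voter is None:
            raise LabelError(f"unknown tool {tool!r}; accepted: {list(TOOL_COLUMNS)}")
        vote = binarize(tool, label)
        if vote == DAMAGING:
            votes[voter] = DAMAGING
        elif votes[voter] == ABSTAIN:
            votes[voter] = NEUTRAL
    return votes


def verdict_from_votes(votes: Mapping[str, str], k: int = 3) -> ConsensusVerdict:
    """Apply the at-least-``k``-voters rule to a per-voter vote map."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    unknown = set(votes) - set(VOTERS)
    if unknown:
        raise LabelError(f"unknown voters {sorted(unknown)}; accepted: {list(VOTERS)}")
    contributing = tuple(v for v in VOTERS if votes.get(v) == DAMAGING)
    n = len(contributing)
    return ConsensusVerdict(
        is_damaging=n >= k, n_damaging_votes=n, contributing_voters=contributing
    )


def consensus(annotation: "AnnotationRecord", k: int = 3) -> ConsensusVerdict:
    """Damaging consensus for one annotated variant at threshold ``k``."""
    return verdict_from_votes(votes_from_labels(annotation.predictor_labels), k=k)
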