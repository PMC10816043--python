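"""Case/control segregation filtering of variants.

A variant segregates with the phenotype for one positive subgroup when its
zygosity pattern satisfies either of two clauses against the shared negative
controls:

* **presence rule** — the alternate allele is carried (het or hom-alt) by
  every symptom-positive member and absent (hom-ref) from every control;
* **zygosity rule** — every positive member is homozygous for the alternate
  allele while every control is heterozygous.

Both clauses quantify over *all* relevant samples, so by default a missing
genotype in any of them fails the variant for that subgroup (the
``ignore_negatives`` policy instead drops missing controls, provided at
least one control call remains).  Under either rule no positive can share a
zygosity state with any negative; this global exclusion is asserted as a
post-condition.

A surviving variant must additionally be damaging by the k-of-7 predictor
consensus (:mod:`modscreen.consensus`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .cohort import AnalysisDesign, Subgroup
from .consensus import ConsensusVerdict, consensus
from .variants import (
    AnnotationRecord,
    GenotypeMatrix,
    JoinedVariant,
    VariantKey,
    genomic_order,
    join_variants,
)

PRESENCE_RULE = "presence_rule"
ZYGOSITY_RULE = "zygosity_rule"
NO_RULE = "none"

_CARRIER = {"het", "hom_alt"}

MISSING_POLICIES = ("strict", "ignore_negatives")


@dataclass(frozen=True)
class SegregationResult:
    """Outcome of the segregation + consensus filter for one variant/subgroup."""

    key: VariantKey
    subgroup_id: str
    passed: bool
    rule: str
    positive_calls: tuple[str, ...]
    negative_calls: tuple[str, ...]
    verdict: ConsensusVerdict | None = None
    annotation: AnnotationRecord | None = None


def segregates(
    calls_pos: Sequence[str],
    calls_neg: Sequence[str],
    *,
    missing_policy: str = "strict",
) -> tuple[bool, str]:
    """Evaluate the two segregation clauses for one variant.

    ``calls_pos`` / ``calls_neg`` are zygosity states of the subgroup members
    and of the negative controls.  Returns ``(passed, rule)`` with ``rule``
    in ``{presence_rule, zygosity_rule, none}``.
    """
    if not calls_pos or not calls_neg:
        raise ValueError("both groups must be non-empty")
    if missing_policy not in MISSING_POLICIES:
        raise ValueError(f"missing_policy must be one of {MISSING_POLICIES}")

    neg = list(calls_neg)
    if missing_policy == "ignore_negatives":
        neg = [c for c in neg if c != "missing"]
        if not neg:
            return False, NO_RULE
    if "missing" in calls_pos or "missing" in neg:
        return False, NO_RULE

    if all(c in _CARRIER for c in calls_pos) and all(c == "hom_ref" for c in neg):
        rule = PRESENCE_RULE
    elif all(c == "hom_alt" for c in calls_pos) and all(c == "het" for c in neg):
        rule = ZYGOSITY_RULE
    else:
        return False, NO_RULE

    # Global exclusion: a passing variant never shares a zygosity state
    # between the two arms.  True by construction under both rules.
    assert not (set(calls_pos) & set(neg)), "zygosity state shared across arms"
    return True, rule


def evaluate_subgroup(
    gm: GenotypeMatrix,
    annotations: Sequence[AnnotationRecord],
    design: AnalysisDesign,
    subgroup: Subgroup,
    *,
    k: int = 3,
    missing_policy: str = "strict",
    joined: Sequence[JoinedVariant] | None = None,
) -> list[SegregationResult]:
    """Segregation + consensus outcome for every annotated variant.

    Returns one :class:`SegregationResult` per joined variant, in genomic
    order; ``passed`` reflects segregation only, ``verdict`` the consensus.
    """
    for pid in (*subgroup.member_ids, *design.negative_ids):
        gm.sample_column(pid)  # raises naming the sample if absent
    if joined is None:
        joined = join_variants(gm, annotations)

    results: list[SegregationResult] = []
    for jv in joined:
        pos_calls = tuple(gm.states(jv.index, subgroup.member_ids))
        neg_calls = tuple(gm.states(jv.index, design.negative_ids))
        passed, rule = segregates(pos_calls, neg_calls, missing_policy=missing_policy)
        results.append(
            SegregationResult(
                key=jv.key,
                subgroup_id=subgroup.subgroup_id,
                passed=passed,
                rule=rule,
                positive_calls=pos_calls,
                negative_calls=neg_calls,
                verdict=consensus(jv.annotation, k=k),
                annotation=jv.annotation,
            )
        )
    results.sort(key=lambda r: genomic_order(r.key))
    return results


def filter_subgroup(
    gm: GenotypeMatrix,
    annotations: Sequence[AnnotationRecord],
    design: AnalysisDesign,
    subgroup: Subgroup,
    *,
    k: int = 3,
    missing_policy: str = "strict",
    joined: Sequence[JoinedVariant] | None = None,
) -> list[SegregationResult]:
    """Variants that both segregate for this subgroup and are damaging.

    Output is sorted by chromosome and position.
    """
    results = evaluate_subgroup(
        gm, annotations, design, subgroup, k=k,
        missing_policy=missing_policy, joined=joined,
    )
    return [r for r in results if r.passed and r.verdict and r.verdict.is_damaging]


def genes_per_subgroup(results: Sequence[SegregationResult]) -> list[str]:
    """Unique gene symbols of surviving variants, in first-occurrence order."""
    genes: dict[str, None] = {}
    for r in results:
        if r.annotation is not None:
            genes.setdefault(r.annotation.gene_symbol, None)
    return list(genes)
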