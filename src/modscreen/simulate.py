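"""Synthetic cohorts with planted modifier variants.

The generator emulates the statistical structure the screening analysis
assumes: a small cohort of families plus unrelated patients, bi-allelic
background variants drawn under Hardy–Weinberg equilibrium at configurable
minor-allele frequencies (family members receive Mendelian transmissions
from two simulated founders), planted modifier variants whose genotype
patterns deterministically satisfy a chosen segregation rule in chosen
positive subgroups, per-tool predictor labels with configurable spurious
damaging-call noise, and a GMT collection containing one planted set of all
modifier genes among decoy sets.

Two cohort layouts mirror the study's two analyses:

* ``adrenal`` — four positive subgroups (one member of family 1, all of
  family 2, two unrelated singletons) against four shared controls
  (one member of family 1 and three unrelated patients);
* ``pituitary`` — three positive subgroups (two members of family 1, two
  unrelated singletons) against three shared controls.

Defaults follow the worked synthetic condition used throughout the test
suite: two families of sizes (3, 2), five unrelated patients, 200 background
variants with MAF uniform in (0.01, 0.5), predictor-label noise 0.02 per
voter, and one planted presence-rule variant supported by 4 damaging votes
at population frequency 0.3691 (modelled on the common TLR10 missense
modifier).  Every run emits a truth table making each pipeline stage
testable, and identical seed + config yields byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .cohort import AnalysisDesign, Patient, build_design
from .variants import (
    HET,
    HOM_ALT,
    HOM_REF,
    AnnotationRecord,
    GenotypeMatrix,
    VariantKey,
    write_annotations,
    write_genotypes,
)

_VOTER_COLUMNS = {
    "SIFT": ("SIFT", "damaging", "tolerated"),
    "LRT": ("LRT", "deleterious", "neutral"),
    "MutationTaster": ("MutationTaster", "disease_causing", "polymorphism"),
    "PolyPhen2": ("Polyphen2_HumDiv", "probably_damaging", "benign"),
    "MutationAssessor": ("MutationAssessor", "medium", "low"),
    "FATHMM": ("FATHMM", "damaging", "tolerated"),
    "Meta": ("MetaSVM", "damaging", "tolerated"),
}
_VOTER_ORDER = tuple(_VOTER_COLUMNS)

PRESENCE_RULE = "presence_rule"
ZYGOSITY_RULE = "zygosity_rule"


class SimulationError(ValueError):
    """A configuration demanding an impossible or inconsistent cohort."""


@dataclass(frozen=True)
class PlantedVariant:
    """A modifier variant planted to segregate in chosen positive subgroups."""

    gene_symbol: str
    target_subgroups: tuple[str, ...]
    rule: str = PRESENCE_RULE
    n_damaging_votes: int = 4
    maf: float = 0.3691


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one synthetic cohort (defaults = study conditions)."""

    seed: int = 1
    family_sizes: tuple[int, ...] = (3, 2)
    n_unrelated: int = 5
    n_background_variants: int = 200
    background_maf_range: tuple[float, float] = (0.01, 0.5)
    planted: tuple[PlantedVariant, ...] = ()
    predictor_noise: float = 0.02
    n_gene_sets: int = 10
    planted_set_size: int = 18
    design_style: str = "adrenal"  # adrenal | pituitary
    phenotype: str = "adrenocortical"
    consensus_k: int = 3

    def __post_init__(self) -> None:
        lo, hi = self.background_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise SimulationError(f"background_maf_range {self.background_maf_range} "
                                  "must lie within (0, 0.5]")
        if not (0.0 <= self.predictor_noise <= 1.0):
            raise SimulationError("predictor_noise must be a probability")
        if sum(self.family_sizes) + self.n_unrelated < 1:
            raise SimulationError("cohort must contain at least one sample")
        if self.design_style not in ("adrenal", "pituitary"):
            raise SimulationError(f"unknown design_style {self.design_style!r}")


@dataclass(frozen=True)
class PlantedTruth:
    key: VariantKey
    gene_symbol: str
    rule: str
    target_subgroups: tuple[str, ...]


@dataclass(frozen=True)
class TruthTable:
    """The simulator's record of what each pipeline stage must recover."""

    planted: tuple[PlantedTruth, ...]
    expected_genes: dict[str, tuple[str, ...]]  # subgroup -> surviving genes
    expected_shared: tuple[str, ...]

    def to_json(self) -> str:
        doc = {
            "planted": [
                {
                    "chrom": p.key.chrom, "pos": p.key.pos,
                    "ref": p.key.ref, "alt": p.key.alt,
                    "gene": p.gene_symbol, "rule": p.rule,
                    "target_subgroups": list(p.target_subgroups),
                }
                for p in self.planted
            ],
            "expected_genes": {sg: list(g) for sg, g in self.expected_genes.items()},
            "expected_shared": list(self.expected_shared),
        }
        return json.dumps(doc, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthTable":
        doc = json.loads(text)
        return cls(
            planted=tuple(
                PlantedTruth(
                    key=VariantKey(d["chrom"], d["pos"], d["ref"], d["alt"]),
                    gene_symbol=d["gene"], rule=d["rule"],
                    target_subgroups=tuple(d["target_subgroups"]),
                )
                for d in doc["planted"]
            ),
            expected_genes={sg: tuple(g) for sg, g in doc["expected_genes"].items()},
            expected_shared=tuple(doc["expected_shared"]),
        )


@dataclass
class SimulatedCohort:
    """Paths and in-memory artefacts of one simulated cohort."""

    outdir: Path
    vcf_path: Path
    annotations_path: Path
    cohort_path: Path
    gmt_path: Path
    truth_path: Path
    run_config_path: Path
    truth: TruthTable
    design_blocks: list[dict]
    genotypes: GenotypeMatrix
    annotations: list[AnnotationRecord]
    #: alt-allele counts of the two founders per family, per variant:
    #: shape (n_variants, n_families, 2)
    founder_alt_counts: np.ndarray
    family_members: dict[str, list[str]]


# ---------------------------------------------------------------------------
# cohort layout

def _sample_ids(config: SimulationConfig) -> tuple[dict[str, list[str]], list[str]]:
    families = {
        f"F{i + 1}": [f"F{i + 1}_{j + 1}" for j in range(size)]
        for i, size in enumerate(config.family_sizes)
    }
    unrelated = [f"U{i + 1}" for i in range(config.n_unrelated)]
    return families, unrelated


def _design_block(config: SimulationConfig,
                  families: Mapping[str, list[str]],
                  unrelated: list[str]) -> dict:
    """Positive subgroups and controls for the chosen layout."""
    if config.design_style == "adrenal":
        if len(families) < 2 or len(families["F1"]) < 2 or len(unrelated) < 4:
            raise SimulationError(
                "adrenal layout needs 2 families (first of size >= 2) and "
                ">= 4 unrelated samples"
            )
        positives = [[families["F1"][0]], list(families["F2"]),
                     [unrelated[0]], [unrelated[1]]]
        negatives = [families["F1"][1]] + unrelated[2:]
    else:  # pituitary
        if len(families["F1"]) < 3 or len(unrelated) < 4:
            raise SimulationError(
                "pituitary layout needs a first family of size >= 3 and "
                ">= 4 unrelated samples"
            )
        positives = [families["F1"][:2], [unrelated[0]], [unrelated[1]]]
        negatives = [families["F1"][2], unrelated[2], unrelated[3]]
    return {
        "name": config.phenotype,
        "phenotype": config.phenotype,
        "positive_subgroups": positives,
        "negatives": negatives,
    }


def _write_cohort_table(path: Path, config: SimulationConfig,
                        families: Mapping[str, list[str]], unrelated: list[str],
                        block: dict) -> None:
    positive_ids = {pid for grp in block["positive_subgroups"] for pid in grp}
    negative_ids = set(block["negatives"])
    rows = []
    idx = 0
    for fi, (fam, members) in enumerate(families.items()):
        for pid in members:
            rows.append((pid, fam, fi, idx))
            idx += 1
    for pid in unrelated:
        rows.append((pid, "-", -1, idx))
        idx += 1
    with open(path, "w") as fh:
        fh.write("patient_id\tfamily_id\tmen1_variant\tage\tsex\t"
                 f"{config.phenotype}\n")
        for pid, fam, fi, i in rows:
            status = ("yes" if pid in positive_ids
                      else "no" if pid in negative_ids else "n/d")
            # one positive is deliberately under 40: the control age rule
            # must not exclude young cases
            age = 33 if (config.design_style == "adrenal" and fam == "F2"
                         and pid.endswith("_2")) else 45 + 2 * i
            sex = "F" if i % 2 == 0 else "M"
            hgvs = f"c.{100 + 10 * fi}A>G" if fi >= 0 else f"c.{200 + i}A>G"
            fh.write(f"{pid}\t{fam}\t{hgvs}\t{age}\t{sex}\t{status}\n")


# ---------------------------------------------------------------------------
# genotypes

def _hwe_genotype(rng: np.random.Generator, maf: float) -> int:
    return int(rng.binomial(2, maf))


def _child_alt_count(rng: np.random.Generator, f1: int, f2: int) -> int:
    return int(rng.random() < f1 / 2) + int(rng.random() < f2 / 2)


_CODE_FROM_COUNT = {0: HOM_REF, 1: HET, 2: HOM_ALT}


def _required_states(planted: PlantedVariant, block: dict,
                     subgroup_ids: Sequence[str]) -> dict[str, int]:
    """Deterministic genotype codes every sample must take for one planted variant."""
    unknown = set(planted.target_subgroups) - set(subgroup_ids)
    if unknown:
        raise SimulationError(
            f"planted {planted.gene_symbol}: unknown target subgroups {sorted(unknown)}"
        )
    if planted.rule not in (PRESENCE_RULE, ZYGOSITY_RULE):
        raise SimulationError(f"planted {planted.gene_symbol}: unknown rule {planted.rule!r}")
    if not (0 <= planted.n_damaging_votes <= 7):
        raise SimulationError(f"planted {planted.gene_symbol}: votes must be 0..7")
    if not planted.target_subgroups:
        raise SimulationError(f"planted {planted.gene_symbol}: no target subgroups")

    required: dict[str, int] = {}

    def require(pid: str, code: int) -> None:
        if required.get(pid, code) != code:
            raise SimulationError(
                f"planted {planted.gene_symbol}: sample {pid} required to be "
                f"both {required[pid]} and {code} — impossible genotype pattern"
            )
        required[pid] = code

    neg_code = HOM_REF if planted.rule == PRESENCE_RULE else HET
    for pid in block["negatives"]:
        require(pid, neg_code)
    for sg_id, members in zip(subgroup_ids, block["positive_subgroups"]):
        if sg_id in planted.target_subgroups:
            code = HET if planted.rule == PRESENCE_RULE else HOM_ALT
            for pid in members:
                require(pid, code)
        else:
            # must not segregate here: absent from non-target positives
            for pid in members:
                require(pid, HOM_REF)
    return required


# ---------------------------------------------------------------------------
# main entry point

def simulate(config: SimulationConfig, outdir: str | Path) -> SimulatedCohort:
    """Generate a full synthetic cohort under ``outdir``.

    Writes ``genotypes.vcf``, ``annotations.tsv``, ``cohort.tsv``,
    ``gene_sets.gmt``, ``truth.json`` and a ready-to-run pipeline config
    ``run_config.yaml``.  Identical seed + config produces byte-identical
    files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    families, unrelated = _sample_ids(config)
    block = _design_block(config, families, unrelated)
    subgroup_ids = [
        _subgroup_label(grp, families) for grp in block["positive_subgroups"]
    ]

    samples = [pid for members in families.values() for pid in members] + unrelated
    family_of = {pid: fam for fam, members in families.items() for pid in members}
    fam_names = list(families)

    n_bg = config.n_background_variants
    n_total = n_bg + len(config.planted)
    codes = np.zeros((n_total, len(samples)), dtype=np.int8)
    founder_counts = np.zeros((n_total, len(fam_names), 2), dtype=np.int8)
    keys: list[VariantKey] = []
    mafs: list[float] = []

    lo, hi = config.background_maf_range
    bases = ("A", "C", "G", "T")
    for i in range(n_bg):
        maf = float(rng.uniform(lo, hi))
        mafs.append(maf)
        ref, alt = bases[i % 4], bases[(i + 1) % 4]
        keys.append(VariantKey("1", 1000 * (i + 1), ref, alt))
        for fi, fam in enumerate(fam_names):
            f1, f2 = _hwe_genotype(rng, maf), _hwe_genotype(rng, maf)
            founder_counts[i, fi] = (f1, f2)
            for pid in families[fam]:
                codes[i, samples.index(pid)] = _CODE_FROM_COUNT[
                    _child_alt_count(rng, f1, f2)
                ]
        for pid in unrelated:
            codes[i, samples.index(pid)] = _CODE_FROM_COUNT[_hwe_genotype(rng, maf)]

    planted_truths: list[PlantedTruth] = []
    for j, pv in enumerate(config.planted):
        i = n_bg + j
        required = _required_states(pv, block, subgroup_ids)
        mafs.append(pv.maf)
        key = VariantKey("1", 1000 * (i + 1), "A", "G")
        keys.append(key)
        # founders het/het: every required child genotype stays Mendelian-possible
        founder_counts[i, :, :] = 1
        for pid in samples:
            codes[i, samples.index(pid)] = required.get(pid, HOM_REF)
        planted_truths.append(
            PlantedTruth(key=key, gene_symbol=pv.gene_symbol, rule=pv.rule,
                         target_subgroups=tuple(pv.target_subgroups))
        )

    gm = GenotypeMatrix(variants=keys, samples=samples, codes=codes)

    # --- annotations -------------------------------------------------------
    annotations: list[AnnotationRecord] = []
    for i in range(n_bg):
        labels: dict[str, str] = {}
        for voter in _VOTER_ORDER:
            col, dmg, neu = _VOTER_COLUMNS[voter]
            labels[col] = dmg if rng.random() < config.predictor_noise else neu
        annotations.append(
            AnnotationRecord(key=keys[i], gene_symbol=f"BG{i + 1:04d}",
                             predictor_labels=labels, maf=round(mafs[i], 4))
        )
    for j, pv in enumerate(config.planted):
        i = n_bg + j
        chosen = set(rng.choice(len(_VOTER_ORDER), size=pv.n_damaging_votes,
                                replace=False).tolist())
        labels = {}
        for vi, voter in enumerate(_VOTER_ORDER):
            col, dmg, neu = _VOTER_COLUMNS[voter]
            labels[col] = dmg if vi in chosen else neu
        annotations.append(
            AnnotationRecord(key=keys[i], gene_symbol=pv.gene_symbol,
                             rsid=f"rs9{i:06d}", predictor_labels=labels,
                             maf=pv.maf)
        )

    # --- truth table -------------------------------------------------------
    expected_genes: dict[str, tuple[str, ...]] = {}
    for sg in subgroup_ids:
        genes = [
            pv.gene_symbol for pv in config.planted
            if sg in pv.target_subgroups and pv.n_damaging_votes >= config.consensus_k
        ]
        expected_genes[sg] = tuple(dict.fromkeys(genes))
    shared = [
        pv.gene_symbol for pv in config.planted
        if set(subgroup_ids) <= set(pv.target_subgroups)
        and pv.n_damaging_votes >= config.consensus_k
    ]
    truth = TruthTable(
        planted=tuple(planted_truths),
        expected_genes=expected_genes,
        expected_shared=tuple(dict.fromkeys(shared)),
    )

    # --- gene sets ---------------------------------------------------------
    bg_genes = [f"BG{i + 1:04d}" for i in range(n_bg)]
    planted_genes = list(dict.fromkeys(pv.gene_symbol for pv in config.planted))
    gmt_lines = []
    if planted_genes:
        n_fill = max(config.planted_set_size - len(planted_genes), 0)
        fill = (list(rng.choice(bg_genes, size=min(n_fill, len(bg_genes)),
                                replace=False)) if n_fill and bg_genes else [])
        gmt_lines.append(("SET_PLANTED", "planted modifier set",
                          planted_genes + fill))
    for s in range(config.n_gene_sets):
        size = min(config.planted_set_size, len(bg_genes))
        members = list(rng.choice(bg_genes, size=size, replace=False)) if size else []
        if members:
            gmt_lines.append((f"SET{s + 1:03d}", f"decoy set {s + 1}", members))

    # --- write everything --------------------------------------------------
    vcf_path = outdir / "genotypes.vcf"
    ann_path = outdir / "annotations.tsv"
    cohort_path = outdir / "cohort.tsv"
    gmt_path = outdir / "gene_sets.gmt"
    truth_path = outdir / "truth.json"
    run_config_path = outdir / "run_config.yaml"

    write_genotypes(gm, vcf_path)
    write_annotations(annotations, ann_path)
    _write_cohort_table(cohort_path, config, families, unrelated, block)
    with open(gmt_path, "w") as fh:
        for set_id, name, members in gmt_lines:
            fh.write("\t".join([set_id, name, *members]) + "\n")
    truth_path.write_text(truth.to_json() + "\n")

    run_config = {
        "inputs": {
            "vcf": vcf_path.name,
            "annotations": ann_path.name,
            "cohort": cohort_path.name,
            "gene_sets": [gmt_path.name],
        },
        "analyses": [block],
        "parameters": {
            "k": config.consensus_k,
            "alpha": 0.05,
            "missing_policy": "strict",
            "universe": "observed",
        },
    }
    with open(run_config_path, "w") as fh:
        yaml.safe_dump(run_config, fh, sort_keys=True)

    return SimulatedCohort(
        outdir=outdir, vcf_path=vcf_path, annotations_path=ann_path,
        cohort_path=cohort_path, gmt_path=gmt_path, truth_path=truth_path,
        run_config_path=run_config_path, truth=truth, design_blocks=[block],
        genotypes=gm, annotations=annotations,
        founder_alt_counts=founder_counts, family_members=dict(families),
    )


def _subgroup_label(members: Sequence[str], families: Mapping[str, list[str]]) -> str:
    for fam, ids in families.items():
        if members[0] in ids:
            return fam
    return members[0]


# ---------------------------------------------------------------------------
# preset conditions

def adrenal_style_config(seed: int = 1, **overrides) -> SimulationConfig:
    """Four positive subgroups with one modifier planted in all of them."""
    planted = (PlantedVariant(gene_symbol="TLR10",
                              target_subgroups=("F1", "F2", "U1", "U2")),)
    return SimulationConfig(seed=seed, design_style="adrenal",
                            phenotype="adrenocortical", planted=planted,
                            **overrides)


def pituitary_style_config(seed: int = 1, **overrides) -> SimulationConfig:
    """Three positive subgroups with no modifier shared by all of them."""
    planted = (
        PlantedVariant(gene_symbol="NGF", target_subgroups=("F1", "U1")),
        PlantedVariant(gene_symbol="RELN", target_subgroups=("U2",)),
    )
    return SimulationConfig(seed=seed, design_style="pituitary",
                            phenotype="pituitary", planted=planted,
                            **overrides)


# ---------------------------------------------------------------------------
# recovery metrics

def _set_metrics(truth: set[str], observed: set[str]) -> tuple[float, float]:
    if not truth and not observed:
        return 1.0, 1.0
    tp = len(truth & observed)
    precision = tp / len(observed) if observed else 1.0
    recall = tp / len(truth) if truth else 1.0
    return precision, recall


def recovery_metrics(
    truth: TruthTable, observed: Mapping[str, Sequence[str]]
) -> dict:
    """Set precision/recall of observed gene lists against the truth table.

    ``observed`` maps subgroup id to its recovered gene list; the shared
    signature is the intersection of the observed lists.  Empty truth with
    empty observation counts as precision = recall = 1.
    """
    out: dict = {"per_subgroup": {}}
    observed_sets = {}
    for sg, expected in truth.expected_genes.items():
        obs = {g.upper() for g in observed.get(sg, ())}
        observed_sets[sg] = obs
        p, r = _set_metrics({g.upper() for g in expected}, obs)
        out["per_subgroup"][sg] = {"precision": p, "recall": r}
    shared_obs = (set.intersection(*observed_sets.values())
                  if observed_sets else set())
    p, r = _set_metrics({g.upper() for g in truth.expected_shared}, shared_obs)
    out["shared"] = {"precision": p, "recall": r}
    return out
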