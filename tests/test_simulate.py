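"""Synthetic-cohort generator: determinism, Mendelian and Hardy–Weinberg
structure, planted-variant guarantees, and recovery metrics."""

import hashlib
from math import comb
from pathlib import Path

import numpy as np
import pytest

from modscreen import (
    PlantedVariant,
    SimulationConfig,
    SimulationError,
    TruthTable,
    adrenal_style_config,
    build_design,
    filter_subgroup,
    genes_per_subgroup,
    load_cohort_table,
    recovery_metrics,
    segregates,
    simulate,
)
from modscreen.variants import CODE_TO_STATE

NOISE = 0.02


def _file_hashes(outdir: Path) -> dict:
    return {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(Path(outdir).iterdir())
    }


def _design_for(sim):
    cohort = load_cohort_table(sim.cohort_path)
    block = sim.design_blocks[0]
    return build_design(cohort, block["phenotype"], block["positive_subgroups"],
                        block["negatives"])


class TestDeterminism:
    def test_same_seed_gives_byte_identical_files(self, tmp_path):
        config = adrenal_style_config(seed=5, n_background_variants=40)
        a = simulate(config, tmp_path / "a")
        b = simulate(config, tmp_path / "b")
        assert _file_hashes(a.outdir) == _file_hashes(b.outdir)

    def test_different_seed_gives_different_genotypes(self, tmp_path):
        a = simulate(adrenal_style_config(seed=5, n_background_variants=40),
                     tmp_path / "a")
        b = simulate(adrenal_style_config(seed=6, n_background_variants=40),
                     tmp_path / "b")
        assert (a.genotypes.codes != b.genotypes.codes).any()


class TestPopulationStructure:
    def test_mendelian_consistency(self, adrenal_sim):
        """No family member carries a genotype impossible under its founders."""
        gm = adrenal_sim.genotypes
        possible_from = {0: {0}, 1: {0, 1}, 2: {1}}
        fam_names = list(adrenal_sim.family_members)
        for i in range(gm.n_variants):
            for fi, fam in enumerate(fam_names):
                f1, f2 = adrenal_sim.founder_alt_counts[i, fi]
                allowed = {
                    a + b
                    for a in possible_from[int(f1)]
                    for b in possible_from[int(f2)]
                }
                for pid in adrenal_sim.family_members[fam]:
                    state = gm.states(i, [pid])[0]
                    count = {"hom_ref": 0, "het": 1, "hom_alt": 2}[state]
                    assert count in allowed, (i, pid, (f1, f2), state)

    def test_unrelated_allele_frequencies_track_nominal_maf(self, adrenal_sim):
        """Observed alt frequency within 3 SE of nominal for almost all variants."""
        gm = adrenal_sim.genotypes
        unrelated = [s for s in gm.samples if s.startswith("U")]
        cols = [gm.samples.index(s) for s in unrelated]
        n_alleles = 2 * len(unrelated)
        outside = 0
        n_bg = gm.n_variants - len(adrenal_sim.truth.planted)
        anns = {a.key: a for a in adrenal_sim.annotations}
        for i in range(n_bg):
            maf = anns[gm.variants[i]].maf
            counts = gm.codes[i, cols]
            observed = counts.sum() / n_alleles
            se = np.sqrt(maf * (1 - maf) / n_alleles)
            if abs(observed - maf) > 3 * se:
                outside += 1
        assert outside / n_bg <= 0.02

    def test_planted_variants_pass_their_rule_by_construction(self, adrenal_sim):
        design = _design_for(adrenal_sim)
        gm = adrenal_sim.genotypes
        index = {k: i for i, k in enumerate(gm.variants)}
        for planted in adrenal_sim.truth.planted:
            i = index[planted.key]
            neg = gm.states(i, design.negative_ids)
            for sg in design.positive_subgroups:
                pos = gm.states(i, sg.member_ids)
                passed, rule = segregates(pos, neg)
                if sg.subgroup_id in planted.target_subgroups:
                    assert passed and rule == planted.rule
                else:
                    assert not passed


class TestPlantingLogic:
    def test_no_planting_no_noise_gives_empty_gene_lists(self, tmp_path):
        config = SimulationConfig(seed=3, n_background_variants=60,
                                  predictor_noise=0.0, planted=())
        sim = simulate(config, tmp_path / "sim")
        design = _design_for(sim)
        for sg in design.positive_subgroups:
            res = filter_subgroup(sim.genotypes, sim.annotations, design, sg)
            assert genes_per_subgroup(res) == []

    def test_planted_below_consensus_threshold_never_survives(self, tmp_path):
        planted = (PlantedVariant(gene_symbol="WEAK",
                                  target_subgroups=("F1", "F2", "U1", "U2"),
                                  n_damaging_votes=2),)
        config = SimulationConfig(seed=3, n_background_variants=60,
                                  predictor_noise=0.0, planted=planted)
        sim = simulate(config, tmp_path / "sim")
        assert sim.truth.expected_shared == ()
        design = _design_for(sim)
        for sg in design.positive_subgroups:
            res = filter_subgroup(sim.genotypes, sim.annotations, design, sg, k=3)
            assert "WEAK" not in genes_per_subgroup(res)

    def test_unknown_target_subgroup_rejected(self, tmp_path):
        planted = (PlantedVariant(gene_symbol="G", target_subgroups=("NOPE",)),)
        config = SimulationConfig(seed=1, planted=planted)
        with pytest.raises(SimulationError, match="NOPE"):
            simulate(config, tmp_path / "sim")

    def test_invalid_maf_range_rejected(self):
        with pytest.raises(SimulationError):
            SimulationConfig(background_maf_range=(0.0, 0.6))

    def test_truth_table_round_trips_through_json(self, adrenal_sim):
        text = adrenal_sim.truth_path.read_text()
        assert TruthTable.from_json(text) == adrenal_sim.truth


class TestRecoveryMetrics:
    def test_perfect_recovery(self):
        truth = TruthTable(planted=(), expected_genes={"s1": ("A",)},
                           expected_shared=("A",))
        m = recovery_metrics(truth, {"s1": ["A"]})
        assert m["per_subgroup"]["s1"] == {"precision": 1.0, "recall": 1.0}
        assert m["shared"] == {"precision": 1.0, "recall": 1.0}

    def test_one_spurious_survivor(self):
        truth = TruthTable(planted=(), expected_genes={"s1": ("A",)},
                           expected_shared=())
        m = recovery_metrics(truth, {"s1": ["A", "BG0001"]})
        assert m["per_subgroup"]["s1"] == {"precision": 0.5, "recall": 1.0}

    def test_empty_truth_and_empty_observation(self):
        truth = TruthTable(planted=(), expected_genes={"s1": ()},
                           expected_shared=())
        m = recovery_metrics(truth, {"s1": []})
        assert m["per_subgroup"]["s1"] == {"precision": 1.0, "recall": 1.0}


# ---------------------------------------------------------------------------
# replicate study with a closed-form false-survivor oracle


def _binom_tail_ge(n, k, p):
    return sum(comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(k, n + 1))


def _hwe(maf):
    return {0: (1 - maf) ** 2, 1: 2 * maf * (1 - maf), 2: maf**2}


def _child_dist(f1, f2):
    pa = {0: 0.0, 1: 0.5, 2: 1.0}
    dist = {0: 0.0, 1: 0.0, 2: 0.0}
    for a in (0, 1):
        for b in (0, 1):
            prob = (pa[f1] if a else 1 - pa[f1]) * (pa[f2] if b else 1 - pa[f2])
            dist[a + b] += prob
    return dist


def _family_pattern_prob(maf, member_required):
    """P(every sibling's genotype lies in its required set), founders HWE."""
    hwe = _hwe(maf)
    total = 0.0
    for f1, p1 in hwe.items():
        for f2, p2 in hwe.items():
            dist = _child_dist(f1, f2)
            prob = p1 * p2
            for required in member_required:
                prob *= sum(dist[c] for c in required)
            total += prob
    return total


def _false_survival_prob(maf, subgroup_members, negatives, family_of, noise):
    """P(a HWE background variant segregates for this subgroup AND wins >= 3 votes)."""
    p_votes = _binom_tail_ge(7, 3, noise)
    p_pattern = 0.0
    for required_pos, required_neg in (
        ({1, 2}, {0}),  # presence rule
        ({2}, {1}),     # zygosity rule
    ):
        requirements = [(pid, required_pos) for pid in subgroup_members]
        requirements += [(pid, required_neg) for pid in negatives]
        by_family: dict = {}
        p = 1.0
        for pid, req in requirements:
            fam = family_of.get(pid)
            if fam is None:
                p *= sum(_hwe(maf)[c] for c in req)
            else:
                by_family.setdefault(fam, []).append(req)
        for reqs in by_family.values():
            p *= _family_pattern_prob(maf, reqs)
        p_pattern += p
    return p_pattern * p_votes


@pytest.mark.parametrize("n_replicates", [50])
def test_replicate_recovery_study(tmp_path, n_replicates):
    """Across replicates the planted modifier is always recovered, and the
    number of spurious background survivors is consistent with the
    closed-form HWE x voting expectation."""
    total_false = 0
    expected_false = 0.0
    recalls = []
    for rep in range(n_replicates):
        config = adrenal_style_config(seed=1000 + rep,
                                      n_background_variants=200,
                                      predictor_noise=NOISE)
        sim = simulate(config, tmp_path / f"rep{rep}")
        design = _design_for(sim)
        family_of = {pid: fam for fam, ids in sim.family_members.items()
                     for pid in ids}
        anns = {a.key: a for a in sim.annotations}
        planted_keys = {p.key for p in sim.truth.planted}
        observed = {}
        for sg in design.positive_subgroups:
            res = filter_subgroup(sim.genotypes, sim.annotations, design, sg)
            observed[sg.subgroup_id] = genes_per_subgroup(res)
            total_false += sum(1 for r in res if r.key not in planted_keys)
            for key in (k for k in anns if k not in planted_keys):
                expected_false += _false_survival_prob(
                    anns[key].maf, sg.member_ids, design.negative_ids,
                    family_of, NOISE,
                )
        metrics = recovery_metrics(sim.truth, observed)
        recalls.append(metrics["shared"]["recall"])
        recalls.extend(m["recall"] for m in metrics["per_subgroup"].values())
    assert recalls == [1.0] * len(recalls)
    # Poisson-style bound around the closed-form expectation
    assert total_false <= expected_false + 4 * np.sqrt(expected_false) + 3
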