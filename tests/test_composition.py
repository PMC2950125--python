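"""Tests for per-branch composition, enrichment, and strata association."""

import numpy as np
import pandas as pd
import pytest

from chromage import (
    GenomePartition,
    SimulationConfig,
    bias_by_age,
    bias_contingency,
    branch_proportions,
    enrichment_heatmap,
    simulate_genome,
    stage_presence_table,
    strata_age_association,
)
from chromage.dating import AgeAssignment
from chromage.expression import PresenceCall, SexBiasCall
from chromage.simulate import strata_bed_frame
from chromage.composition import assign_strata, read_strata_bed


def partition_for(classes: dict[str, str], **kwargs) -> GenomePartition:
    return GenomePartition(chromosome_class=classes, **kwargs)


class TestBranchProportions:
    def test_all_autosomal_gives_zero_share(self, ladder):
        assignments = [AgeAssignment(f"g{i}", i % 3) for i in range(30)]
        partition = partition_for({a.gene_id: "autosome" for a in assignments})
        frame = branch_proportions(assignments, partition, ladder)
        populated = frame.loc[frame.n_gained > 0]
        assert (populated.x_share == 0).all()

    def test_empty_branch_is_undefined_not_zero(self, ladder):
        assignments = [AgeAssignment("g0", 5)]
        partition = partition_for({"g0": "X"})
        frame = branch_proportions(assignments, partition, ladder)
        assert frame.loc[5, "x_share"] == 1.0
        assert np.isnan(frame.loc[4, "x_share"])

    def test_counts_sum_to_branch_gains(self, ladder, rng):
        assignments = [
            AgeAssignment(f"g{i}", int(rng.integers(0, ladder.n_branches)))
            for i in range(200)
        ]
        partition = partition_for(
            {a.gene_id: ("X" if rng.random() < 0.1 else "autosome")
             for a in assignments}
        )
        frame = branch_proportions(assignments, partition, ladder)
        n_auto = frame.n_gained - frame.n_x
        assert ((frame.n_x + n_auto) == frame.n_gained).all()
        assert frame.n_gained.sum() == 200

    def test_missing_partition_entry_is_error(self, ladder):
        with pytest.raises(KeyError):
            branch_proportions(
                [AgeAssignment("gX", 2)], partition_for({"other": "X"}), ladder
            )

    def test_two_peak_curve_recovered(self, ladder):
        # study conditions: baseline 3% X share, peaks 8-14%
        config = SimulationConfig(seed=3)
        genome = simulate_genome(config)
        assignments = [
            AgeAssignment(r.gene_id, r.branch) for r in genome.truth.itertuples()
        ]
        frame = branch_proportions(assignments, genome.partition, ladder)
        peaks = frame.loc[[5, 12], "x_share"]
        baseline = frame.loc[[0, 1, 2, 3, 4], "x_share"]
        assert (peaks > 0.08).all()
        assert (baseline < 0.04).all()


class TestBiasByAge:
    @staticmethod
    def setup_calls(ladder, rng, n=300, x_frac=0.3):
        assignments = [
            AgeAssignment(f"g{i}", int(rng.integers(0, ladder.n_branches)))
            for i in range(n)
        ]
        partition = partition_for(
            {a.gene_id: ("X" if rng.random() < x_frac else "autosome")
             for a in assignments}
        )
        return assignments, partition

    def test_underpowered_branch_omitted(self, ladder):
        # 4 assayed X genes on a branch is below the 5-gene floor
        assignments = [AgeAssignment(f"g{i}", 3) for i in range(4)]
        assignments += [AgeAssignment(f"a{i}", 3) for i in range(6)]
        partition = partition_for(
            {f"g{i}": "X" for i in range(4)} | {f"a{i}": "autosome" for i in range(6)}
        )
        calls = [
            SexBiasCall(g, "male") for g in partition.chromosome_class
        ]
        points, _ = bias_by_age(calls, assignments, partition, ladder)
        assert set(points.chromosome_class) == {"autosome"}

    def test_all_unbiased_flat_zero(self, ladder, rng):
        assignments, partition = self.setup_calls(ladder, rng)
        calls = [SexBiasCall(g, "unbiased") for g in partition.chromosome_class]
        points, regressions = bias_by_age(calls, assignments, partition, ladder)
        assert (points.male_proportion == 0).all()
        assert regressions.slope.abs().max() == pytest.approx(0.0, abs=1e-12)

    def test_not_assayed_excluded(self, ladder, rng):
        assignments, partition = self.setup_calls(ladder, rng)
        calls = [SexBiasCall(g, "not_assayed") for g in partition.chromosome_class]
        points, _ = bias_by_age(calls, assignments, partition, ladder)
        assert points.empty

    def test_decay_planted_slopes(self, ladder):
        # male-bias decays with age on the X, flat on autosomes: the X
        # regression slope on (negative) age must be positive, autosome ~ 0
        config = SimulationConfig(seed=9)
        genome = simulate_genome(config)
        assignments = [
            AgeAssignment(r.gene_id, r.branch) for r in genome.truth.itertuples()
        ]
        calls = [
            SexBiasCall(r.gene_id, r.bias if r.bias != "none" else "unbiased")
            for r in genome.truth.itertuples()
        ]
        points, regressions = bias_by_age(calls, assignments, genome.partition, ladder)
        slopes = dict(zip(regressions.chromosome_class, regressions.slope))
        assert slopes["X"] > 0
        assert abs(slopes["autosome"]) < slopes["X"] / 5


class TestBiasContingency:
    @pytest.mark.parametrize(
        "x_counts, a_counts, expected_p",
        [
            ((28, 35, 27), (187, 137, 409), 2e-6),
            ((27, 26, 13), (263, 127, 216), 0.001),
        ],
    )
    def test_branch5_tables(self, x_counts, a_counts, expected_p):
        calls, classes = [], {}
        labels = ("male", "female", "unbiased")
        for chrom_class, counts in (("X", x_counts), ("autosome", a_counts)):
            for label, n in zip(labels, counts):
                for i in range(n):
                    g = f"{chrom_class}_{label}_{i}"
                    classes[g] = chrom_class
                    calls.append(SexBiasCall(g, label))
        table, result = bias_contingency(classes, partition_for(classes), calls)
        assert table.counts.tolist() == [list(x_counts), list(a_counts)]
        assert result.p_value == pytest.approx(expected_p, rel=0.5)

    def test_proportional_rows_p_one(self):
        calls, classes = [], {}
        for chrom_class, mult in (("X", 1), ("autosome", 4)):
            for label, n in (("male", 5), ("female", 10), ("unbiased", 15)):
                for i in range(n * mult):
                    g = f"{chrom_class}_{label}_{i}"
                    classes[g] = chrom_class
                    calls.append(SexBiasCall(g, label))
        _, result = bias_contingency(classes, partition_for(classes), calls)
        assert result.p_value == pytest.approx(1.0)
        assert result.statistic == pytest.approx(0.0, abs=1e-9)

    def test_empty_after_exclusion_is_error(self):
        calls = [SexBiasCall("g0", "not_assayed")]
        with pytest.raises(ValueError):
            bias_contingency(["g0"], partition_for({"g0": "X"}), calls)


class TestStagePresence:
    def test_worked_proportion_69_percent(self):
        calls = {"stage": (
            [PresenceCall(f"x{i}", "stage", "present") for i in range(319)]
            + [PresenceCall(f"x{i+319}", "stage", "absent") for i in range(141)]
            + [PresenceCall(f"x{i+460}", "stage", "ambiguous") for i in range(29)]
            + [PresenceCall(f"a{i}", "stage", "present") for i in range(60)]
            + [PresenceCall(f"a{i+60}", "stage", "absent") for i in range(40)]
        )}
        young = {f"x{i}": False for i in range(489)} | {f"a{i}": False for i in range(100)}
        classes = {f"x{i}": "X" for i in range(489)} | {
            f"a{i}": "autosome" for i in range(100)
        }
        frame = stage_presence_table(calls, young, partition_for(classes))
        row = frame.loc[(frame.age_class == "old") & (frame.stage == "stage")].iloc[0]
        assert row.X_present == 319 and row.X_absent == 141
        assert round(100 * row.X_proportion) == 69

    def test_all_ambiguous_flagged_undefined(self):
        calls = {"s": [PresenceCall(f"g{i}", "s", "ambiguous") for i in range(10)]}
        young = {f"g{i}": True for i in range(10)}
        classes = {f"g{i}": "X" for i in range(10)}
        frame = stage_presence_table(calls, young, partition_for(classes))
        row = frame.loc[(frame.age_class == "young")].iloc[0]
        assert row.undefined
        assert np.isnan(row.p_value)


class TestEnrichmentHeatmap:
    @staticmethod
    def presence_set(n_x_present, n_x_absent, n_a_present, n_a_absent, tissue="t"):
        calls, classes, assignments = [], {}, []
        i = 0
        for chrom_class, state, n in (
            ("X", "present", n_x_present), ("X", "absent", n_x_absent),
            ("autosome", "present", n_a_present), ("autosome", "absent", n_a_absent),
        ):
            for _ in range(n):
                g = f"g{i}"
                i += 1
                classes[g] = chrom_class
                calls.append(PresenceCall(g, tissue, state))
                assignments.append(AgeAssignment(g, 0))
        return {tissue: calls}, partition_for(classes), assignments

    def test_score_is_signed_log10_p(self, toy_ladder):
        calls, partition, assignments = self.presence_set(30, 0, 50, 50)
        scores, _ = enrichment_heatmap(calls, assignments, partition, toy_ladder)
        from chromage.stats import ContingencyTable, fisher_exact

        p = fisher_exact(
            ContingencyTable(np.array([[30, 0], [50, 50]])), "two"
        ).p_value
        assert scores.loc[0, "t"] == pytest.approx(-np.log10(p))
        assert scores.loc[0, "t"] > 0  # X overrepresented

    def test_autosome_enrichment_is_negative(self, toy_ladder):
        calls, partition, assignments = self.presence_set(5, 45, 45, 5)
        scores, _ = enrichment_heatmap(calls, assignments, partition, toy_ladder)
        assert scores.loc[0, "t"] < 0

    def test_extreme_p_clamped_to_eight(self, toy_ladder):
        # a p ~ 1e-22 excess is reset to the symmetric bound of 8
        calls, partition, assignments = self.presence_set(0, 200, 200, 0)
        scores, _ = enrichment_heatmap(calls, assignments, partition, toy_ladder)
        assert scores.loc[0, "t"] == -8.0

    def test_sign_flips_with_partition_swap(self, toy_ladder):
        calls, partition, assignments = self.presence_set(40, 10, 25, 25)
        swapped = GenomePartition(
            chromosome_class={
                g: ("autosome" if c == "X" else "X")
                for g, c in partition.chromosome_class.items()
            }
        )
        s1, _ = enrichment_heatmap(calls, assignments, partition, toy_ladder)
        s2, _ = enrichment_heatmap(calls, assignments, swapped, toy_ladder)
        assert s1.loc[0, "t"] == pytest.approx(-s2.loc[0, "t"])

    def test_tissue_clustering_groups_similar_columns(self, toy_ladder):
        base, partition, assignments = self.presence_set(40, 10, 25, 25, tissue="a")
        twin, _, _ = self.presence_set(40, 10, 25, 25, tissue="b")
        opposite, _, _ = self.presence_set(5, 45, 45, 5, tissue="c")
        calls = {**base, **twin, **opposite}
        _, order = enrichment_heatmap(calls, assignments, partition, toy_ladder)
        assert abs(order.index("a") - order.index("b")) == 1


class TestStrataAssociation:
    def test_perfect_segregation_minimal_p(self):
        classes = {f"y{i}": "X" for i in range(10)} | {f"o{i}": "X" for i in range(10)}
        stratum = {f"y{i}": "4" for i in range(10)} | {f"o{i}": "1" for i in range(10)}
        partition = GenomePartition(chromosome_class=classes, stratum=stratum)
        assignments = [AgeAssignment(f"y{i}", 9) for i in range(10)] + [
            AgeAssignment(f"o{i}", 2) for i in range(10)
        ]
        young = {g: g.startswith("y") for g in classes}
        table, result = strata_age_association(assignments, partition, young)
        # minimal attainable p for these margins: 1 / C(20, 10)
        from math import comb

        assert result.p_value == pytest.approx(1 / comb(20, 10))

    def test_par_and_undefined_excluded(self):
        classes = {f"g{i}": "X" for i in range(6)}
        stratum = {"g0": "1", "g1": "4", "g2": "PAR1", "g3": "undefined",
                   "g4": "2", "g5": "5"}
        partition = GenomePartition(chromosome_class=classes, stratum=stratum)
        assignments = [AgeAssignment(f"g{i}", 9 if i % 2 else 2) for i in range(6)]
        young = {f"g{i}": bool(i % 2) for i in range(6)}
        table, _ = strata_age_association(assignments, partition, young)
        assert table.counts.sum() == 4  # PAR1 and undefined dropped

    def test_null_placement_p_uniform(self, rng):
        # independent stratum/age placement: p approximately U(0,1)
        p_values = []
        for _ in range(200):
            n = 40
            classes = {f"g{i}": "X" for i in range(n)}
            stratum = {
                f"g{i}": rng.choice(["1", "2", "3", "4", "5"]) for i in range(n)
            }
            partition = GenomePartition(chromosome_class=classes, stratum=stratum)
            assignments = [
                AgeAssignment(f"g{i}", int(rng.integers(0, 13))) for i in range(n)
            ]
            young = {f"g{i}": bool(rng.random() < 0.5) for i in range(n)}
            try:
                _, result = strata_age_association(assignments, partition, young)
            except ValueError:
                continue
            p_values.append(result.p_value)
        # exact one-sided p under the null is stochastically >= uniform
        assert np.mean(np.asarray(p_values) < 0.05) < 0.12
        assert np.median(p_values) > 0.3

    def test_single_informative_gene_is_uninformative(self):
        # one gene leaves a zero margin: the exact test carries no signal
        classes = {"g0": "X"}
        partition = GenomePartition(chromosome_class=classes, stratum={"g0": "1"})
        _, result = strata_age_association(
            [AgeAssignment("g0", 9)], partition, {"g0": True}
        )
        assert result.p_value == 1.0

    def test_no_informative_strata_is_error(self):
        classes = {"g0": "X"}
        partition = GenomePartition(chromosome_class=classes, stratum={"g0": "PAR1"})
        with pytest.raises(ValueError):
            strata_age_association([AgeAssignment("g0", 9)], partition, {"g0": True})


def test_strata_bed_round_trip(tmp_path):
    frame = strata_bed_frame()
    path = tmp_path / "strata.bed"
    frame.to_csv(path, sep="\t", header=False, index=False)
    regions = read_strata_bed(path)
    assert regions[0][3] == "PAR1"
    classes = {"gx": "X", "ga": "autosome"}
    partition = GenomePartition(
        chromosome_class=classes, position={"gx": 30_000_000, "ga": 5}
    )
    annotated = assign_strata(partition, regions)
    assert annotated.stratum["gx"] == "3"
    assert "ga" not in annotated.stratum
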